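import dataclasses

import numpy as np
import pytest

from altcomp.network import ConfigurationError
from altcomp.scenarios import (ScenarioConfig, human_regulation_assay,
                               normalize_hemolysis, run_fluid_phase_assay,
                               run_hemolytic_assay, run_knockout_grid,
                               standard_rabbit_assay)


@pytest.fixture(scope="module")
def knockout_results():
    """Single and pairwise knockout lysis on the standard human assay."""
    base = human_regulation_assay()
    out = {}
    for kos in [(), ("DAF",), ("CD59",), ("FH_surface",), ("FI",),
                ("FH_total",), ("P",), ("CR1",), ("Vn",), ("Cn",),
                ("CD59", "DAF"), ("FH_surface", "DAF")]:
        cfg = dataclasses.replace(base, knockouts=frozenset(kos))
        out[frozenset(kos)] = run_hemolytic_assay(cfg)
    return out


class TestFluidPhaseAssay:
    def test_pure_c3_decays_only_by_hydrolysis(self):
        cfg = ScenarioConfig(readout_time=3600.0,
                             only_species={"C3": 5e-6})
        frame, traj = run_fluid_phase_assay(cfg, n_times=10)
        c3 = traj.conc("C3")
        k = -np.log(c3[-1] / c3[0]) / 3600.0
        # without FB/FD the only loss channel is spontaneous hydrolysis
        assert k == pytest.approx(6.0e-7, rel=1e-3)
        assert traj.final("C3a") == 0.0

    def test_whole_serum_c3a_rises_to_plateau(self):
        cfg = ScenarioConfig(readout_time=7200.0, serum_fraction=1.0)
        frame, traj = run_fluid_phase_assay(cfg, n_times=30)
        c3a = traj.conc("C3a")
        assert c3a[-1] > 0
        assert np.all(np.diff(c3a) >= -1e-18)  # monotone accumulation
        # decelerating: production slows as the pool is consumed/regulated
        assert (c3a[10] - c3a[0]) > (c3a[-1] - c3a[-11])

    def test_all_zero_inputs_stay_zero(self):
        cfg = ScenarioConfig(readout_time=600.0, only_species={})
        frame, traj = run_fluid_phase_assay(cfg, n_times=5)
        assert np.allclose(traj.states, 0.0, atol=1e-18)

    def test_cells_rejected(self):
        cfg = standard_rabbit_assay()
        with pytest.raises(ConfigurationError):
            run_fluid_phase_assay(cfg)


class TestHemolyticAssay:
    def test_rabbit_cells_lyse_nearly_completely(self):
        assert run_hemolytic_assay(standard_rabbit_assay()) > 90.0

    def test_zero_serum_no_lysis(self):
        cfg = dataclasses.replace(standard_rabbit_assay(), serum_fraction=0.0)
        assert run_hemolytic_assay(cfg) == 0.0

    def test_lysis_monotone_in_serum_fraction(self):
        vals = [run_hemolytic_assay(standard_rabbit_assay(serum_fraction=f))
                for f in (0.02, 0.06, 0.2)]
        assert vals[0] < vals[1] < vals[2]

    def test_lysis_monotone_in_readout_time(self):
        vals = [run_hemolytic_assay(
            standard_rabbit_assay(serum_fraction=0.05, readout_s=t))
            for t in (600.0, 1800.0, 3600.0)]
        assert vals[0] < vals[1] < vals[2]

    def test_healthy_human_cells_protected(self, knockout_results):
        assert knockout_results[frozenset()] < 1.0

    def test_daf_knockout_alone_harmless(self, knockout_results):
        assert knockout_results[frozenset({"DAF"})] < 1.0

    def test_properdin_required_for_hemolysis(self, knockout_results):
        assert knockout_results[frozenset({"P"})] < 1.0


class TestKnockoutSeverity:
    def test_severity_ordering(self, knockout_results):
        """Regulator-suppression severity follows the established ranking:
        total FH loss >= FI > CD59+DAF > CD59 > FH-surface > DAF ~ 0."""
        r = knockout_results
        v = lambda *k: r[frozenset(k)]
        assert v("FH_total") >= v("FI") - 0.25
        assert v("FI") > v("CD59", "DAF")
        assert v("CD59", "DAF") > v("CD59")
        assert v("CD59") > v("FH_surface")
        assert v("FH_surface") > v("DAF")
        assert v("DAF") < 1.0

    def test_fi_knockout_near_complete_lysis(self, knockout_results):
        assert knockout_results[frozenset({"FI"})] > 90.0

    def test_weak_regulators_negligible(self, knockout_results):
        for reg in ("CR1", "Vn", "Cn"):
            assert knockout_results[frozenset({reg})] < 2.0

    def test_combined_daf_exceeds_singles(self, knockout_results):
        r = knockout_results
        assert (r[frozenset({"FH_surface", "DAF"})]
                >= r[frozenset({"FH_surface"})])


class TestKnockoutGrid:
    def test_grid_symmetric_with_single_diagonal(self, knockout_results):
        regs = ["DAF", "CD59"]
        grid = run_knockout_grid(human_regulation_assay(), regs)
        assert np.allclose(grid.values, grid.values.T)
        assert grid.loc["CD59", "CD59"] == pytest.approx(
            knockout_results[frozenset({"CD59"})], rel=1e-6)
        assert grid.loc["CD59", "DAF"] == pytest.approx(
            knockout_results[frozenset({"CD59", "DAF"})], rel=1e-6)

    def test_unknown_regulator_rejected(self):
        with pytest.raises(ConfigurationError):
            run_knockout_grid(human_regulation_assay(), ["FX"])


class TestTreatment:
    def test_doubling_doses_lowers_free_c5_everywhere(self):
        """Comparative short-horizon treatment runs: doubling every dose
        keeps free C5 at or below the single-dose level at all times."""
        from altcomp.pharmacology import Regimen
        from altcomp.scenarios import ScenarioConfig, run_treatment

        reg = Regimen.clinical_default(2.0)
        base = ScenarioConfig(context="in_vivo", cell_type="pnh3", regimen=reg)
        double = ScenarioConfig(context="in_vivo", cell_type="pnh3",
                                regimen=reg.scaled(2.0))
        f1, _ = run_treatment(base, months=2.0, n_times=30)
        f2, _ = run_treatment(double, months=2.0, n_times=30)
        assert np.all(f2.free_C5_molar.values
                      <= f1.free_C5_molar.values + 1e-12)

    def test_empty_regimen_rejected(self):
        from altcomp.scenarios import ScenarioConfig, run_treatment
        cfg = ScenarioConfig(context="in_vivo", cell_type="pnh3")
        with pytest.raises(ConfigurationError):
            run_treatment(cfg)


class TestNormalization:
    def test_modes(self):
        assert normalize_hemolysis(40.0, 80.0, "NHS_control") == pytest.approx(50.0)
        assert normalize_hemolysis(40.0, None, "water") == 40.0
        with pytest.raises(ConfigurationError):
            normalize_hemolysis(40.0, 0.0, "NHS_control")
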