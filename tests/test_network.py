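import numpy as np
import pytest

from altcomp.catalog import build_full_network, default_parameters, parameter_table
from altcomp.engine import SolverOptions, simulate
from altcomp.network import (ConfigurationError, MissingParameterError,
                             ParameterEntry, ParameterSet, Phase, Tag,
                             configure_surface, stoichiometry_matrix,
                             subset_fluid_phase)

from conftest import brute_force_rhs, random_mass_action_network


class TestStructure:
    def test_reaction_partition(self, full_network):
        counts = full_network.tag_counts()
        assert full_network.n_reactions == 226
        ap = counts["ap_fluid"] + counts["ap_surface"]
        turnover = (counts["cell_turnover"] + counts["synthesis"]
                    + counts["elimination"])
        assert ap == 111
        assert turnover == 112
        assert counts["drug"] == 3
        assert counts["ap_fluid"] == 36

    def test_parameter_partition(self, params):
        cats = {c: len(params.names(c)) for c in
                ("kinetic", "turnover", "drug", "other")}
        assert len(params) == 121
        assert cats == {"kinetic": 70, "turnover": 39, "drug": 2, "other": 10}

    def test_published_refit_values_are_exact(self, params):
        # the eight re-estimated constants load bit-exact from the catalog
        expected = {
            "kp_C3b_surface": 2.16e9,
            "kp_CD59C5b9": 6.03e11,
            "kp_C3bP": 1.24e8,
            "kp_C3bBbDAF": 2.53e10,
            "Km_C3_C3H2OBb": 4.19e-6,
            "km_C3bBbDAF_decay": 2.28e-3,
            "kp_C5bC6": 7.74e4,
            "kp_C3bBb...": None,
        }
        expected.pop("kp_C3bBb...")
        for name, value in expected.items():
            entry = params.entry(name)
            assert entry.value == value
            assert entry.provenance == "Table1_final"
        assert params.entry("kp_C3bB").value == 2.23e5

    def test_missing_parameter_is_named(self, full_network):
        entries = [e for e in full_network.params if e.name != "kp_C3bB"]
        broken = ParameterSet(entries)
        with pytest.raises(MissingParameterError, match="kp_C3bB"):
            build_full_network(broken)

    def test_duplicate_parameter_rejected(self):
        e = ParameterEntry("k", 1.0, "s^-1", "kinetic", "derived")
        with pytest.raises(Exception, match="duplicate"):
            ParameterSet([e, e])

    def test_invivo_context_rescaling(self, params):
        vivo = params.with_context("in_vivo")
        assert vivo.value("kp_C3_H2O") == params.value("kp_C3_H2O") * 1e-2
        assert vivo.value("kp_C3b_surface") == params.value("kp_C3b_surface") * 1e-5
        assert vivo.value("kp_C3bB") == params.value("kp_C3bB")

    def test_parameter_table_shape(self):
        tbl = parameter_table()
        assert len(tbl) == 121
        assert set(tbl.columns) >= {"name", "value", "units", "context",
                                    "category", "provenance"}


class TestFluidSubset:
    def test_subset_counts_and_idempotence(self, full_network):
        fluid = subset_fluid_phase(full_network)
        assert fluid.n_reactions == 36
        assert all(r.tag == Tag.AP_FLUID for r in fluid.reactions)
        again = subset_fluid_phase(fluid)
        assert again.n_reactions == fluid.n_reactions
        assert [s.id for s in again.species] == [s.id for s in fluid.species]

    def test_no_surface_species_reachable(self, full_network):
        fluid = subset_fluid_phase(full_network)
        assert all(s.phase != Phase.SURFACE for s in fluid.species)

    def test_c3_moiety_conservation_under_simulation(self, full_network):
        """Closed fluid system with FH and FI absent conserves the total
        C3-derived core count to 1e-6 relative."""
        fluid = subset_fluid_phase(full_network)
        y0 = fluid.initial_state(serum_fraction=0.5,
                                 overrides={"FH": 0.0, "FI": 0.0})
        w = np.array([s.c3_moiety for s in fluid.species], dtype=float)
        total0 = w @ y0
        traj = simulate(fluid, y0, np.linspace(0, 1800.0, 7), SolverOptions())
        totals = w @ traj.states
        assert np.max(np.abs(totals - total0)) / total0 < 1e-6

    def test_c3_moiety_weights_annihilate_fluid_stoichiometry(self, full_network):
        # structural form of the same invariant: weighted row sums vanish
        fluid = subset_fluid_phase(full_network)
        S = stoichiometry_matrix(fluid)
        w = np.array([s.c3_moiety for s in fluid.species], dtype=float)
        assert np.all(w @ S == 0)


class TestConfigureSurface:
    def test_rabbit_lacks_regulators(self, full_network):
        rab = configure_surface(full_network, "rabbit", 1e11)
        for sid in ("CR1", "DAF", "CD59"):
            assert rab.species_def(sid).initial_concentration == 0.0
        assert rab.params.value("kp_C3bH_surf") == 0.0
        assert rab.species_def("E").initial_concentration == pytest.approx(
            1e11 / 6.02214076e23)

    def test_pnh2_regulators_at_ten_percent(self, full_network):
        human = configure_surface(full_network, "human", 2e11)
        pnh2 = configure_surface(full_network, "pnh2", 2e11)
        for sid in ("DAF", "CD59"):
            assert pnh2.species_def(sid).initial_concentration == pytest.approx(
                0.1 * human.species_def(sid).initial_concentration)
            assert pnh2.params.value(f"s_{sid}") == pytest.approx(
                0.1 * human.params.value(f"s_{sid}"))

    def test_configuration_is_absolute_not_incremental(self, full_network):
        direct = configure_surface(full_network, "rabbit", 1e11)
        via_human = configure_surface(
            configure_surface(full_network, "human", 5e11), "rabbit", 1e11)
        for sid in ("CR1", "DAF", "CD59", "E"):
            assert (via_human.species_def(sid).initial_concentration
                    == direct.species_def(sid).initial_concentration)
        assert via_human.params.value("kp_C3bH_surf") == 0.0

    def test_unknown_cell_type(self, full_network):
        with pytest.raises(ConfigurationError):
            configure_surface(full_network, "sheep")


class TestStoichiometryMatrix:
    def test_toy_column(self, rng):
        net = random_mass_action_network(rng, n_species=3, n_reactions=1)
        S = stoichiometry_matrix(net)
        assert S.shape == (3, 1)

    def test_full_network_shape(self, full_network):
        S = stoichiometry_matrix(full_network)
        assert S.shape == (full_network.n_species, 226)

    def test_matrix_times_rates_matches_brute_force(self, rng):
        from altcomp.engine import CompiledNetwork
        for _ in range(20):
            net = random_mass_action_network(rng)
            cn = CompiledNetwork(net)
            y = rng.uniform(0.0, 2.0, net.n_species)
            assert np.allclose(cn.rhs(0.0, y), brute_force_rhs(net, y),
                               rtol=1e-12, atol=1e-14)

    def test_serum_scaling_of_initial_state(self, full_network):
        y_half = full_network.initial_state(serum_fraction=0.5)
        y_full = full_network.initial_state(serum_fraction=1.0)
        for s in full_network.species:
            i = full_network.species_index(s.id)
            if s.serum_scaled:
                assert y_half[i] == pytest.approx(0.5 * y_full[i])
            else:
                assert y_half[i] == y_full[i]
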