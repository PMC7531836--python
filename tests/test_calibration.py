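import numpy as np
import pytest

from altcomp.calibration import (CalibrationError, CalibrationProblem, Dataset,
                                 coordinate_descent, iteration_log_frame,
                                 local_sensitivity, ssr, ssr_sum)


def _quadratic_problem(start=(1.0, 1.0), targets=(3.0, 5.0)):
    ds = Dataset(y=np.asarray(targets, dtype=float),
                 model=lambda p: np.array([p["a"], p["b"]]), name="toy")
    return CalibrationProblem([ds], {"a": start[0], "b": start[1]})


class TestObjective:
    def test_ssr_values(self):
        ds = Dataset(y=np.array([1.0, 2.0]), model=lambda p: np.array([2.0, 2.0]))
        assert ssr(ds, {}) == pytest.approx(0.5)   # ((1-2)^2 + 0)/2
        perfect = Dataset(y=np.array([1.0]), model=lambda p: np.array([1.0]))
        assert ssr(perfect, {}) == 0.0

    def test_point_duplication_invariance(self):
        """Normalization by n makes the per-study score independent of
        duplicating every observation."""
        ds1 = Dataset(y=np.array([1.0, 3.0]), model=lambda p: np.array([2.0, 2.0]))
        ds2 = Dataset(y=np.array([1.0, 3.0, 1.0, 3.0]),
                      model=lambda p: np.array([2.0, 2.0, 2.0, 2.0]))
        assert ssr(ds1, {}) == pytest.approx(ssr(ds2, {}))

    def test_ssr_sum_additivity(self):
        ds = Dataset(y=np.array([1.0, 2.0]), model=lambda p: np.array([2.0, 2.0]))
        single = CalibrationProblem([ds], {"a": 1.0})
        double = CalibrationProblem([ds, ds], {"a": 1.0})
        assert ssr_sum(single, {}) == pytest.approx(ssr(ds, {}))
        assert ssr_sum(double, {}) == pytest.approx(2 * ssr(ds, {}))

    def test_empty_dataset_rejected(self):
        with pytest.raises(CalibrationError):
            Dataset(y=np.array([]), model=lambda p: np.array([]))
        with pytest.raises(CalibrationError):
            CalibrationProblem([], {"a": 1.0})


class TestCoordinateDescent:
    def test_separable_quadratic_recovered(self):
        prob = _quadratic_problem()
        fitted = coordinate_descent(prob)
        # TolX 0.01 on the log10 coordinate bounds precision at ~2.3%
        assert fitted["a"] == pytest.approx(3.0, rel=0.025)
        assert fitted["b"] == pytest.approx(5.0, rel=0.025)
        # single-best-update: one parameter changes per logged iteration
        log = iteration_log_frame(prob)
        assert len(log) >= 3

    def test_objective_non_increasing(self):
        prob = _quadratic_problem(start=(0.1, 90.0))
        coordinate_descent(prob)
        objectives = [row[2] for row in prob.log]
        assert all(b <= a + 1e-12 for a, b in zip(objectives, objectives[1:]))

    def test_start_at_optimum_terminates_without_update(self):
        prob = _quadratic_problem(start=(3.0, 5.0))
        fitted = coordinate_descent(prob)
        updates = [row for row in prob.log if row[1] is not None]
        assert fitted == {"a": 3.0, "b": 5.0}
        assert len(updates) == 0

    def test_gamma_recovery_from_synthetic_lysis_data(self):
        """The optimizer recovers the Hill steepness from a seeded noisy
        lysis curve within 5%."""
        from altcomp.fixtures import FixtureSpec, generate
        from altcomp.hemolysis import HemolysisModel, percent_hemolysis

        df = generate(FixtureSpec(kind="hill_curve", noise_pct=2.0, n=20,
                                  seed=7))
        mac = df["mac_per_cell"].values

        def model(p):
            return percent_hemolysis(mac, HemolysisModel(gamma=p["gamma"],
                                                         mac50=p["mac50"]))

        prob = CalibrationProblem(
            [Dataset(y=df["percent_hemolysis"].values, model=model)],
            {"gamma": 1.0, "mac50": 0.5})
        fitted = coordinate_descent(prob)
        assert fitted["gamma"] == pytest.approx(1.60, rel=0.05)
        assert fitted["mac50"] == pytest.approx(1.15, rel=0.05)


class TestLocalSensitivity:
    def test_quadratic_plus_ten_percent(self):
        table = local_sensitivity(lambda p: p["x"] ** 2, {"x": 1.0},
                                  deltas=(0.10,))
        up = table[(table.direction == "up")].iloc[0]
        assert up.relative_change == pytest.approx(0.21, rel=1e-9)

    def test_inactive_parameter_zero_change(self):
        table = local_sensitivity(lambda p: p["x"] ** 2,
                                  {"x": 1.0, "unused": 5.0}, deltas=(0.2,))
        unused = table[table.parameter == "unused"]
        assert np.allclose(unused.relative_change, 0.0)

    def test_rabbit_assay_most_sensitive_inputs(self):
        """Pathway activation in the rabbit assay is dominated by the
        upstream amplification inputs (C3, FH, FD), while late terminal
        components (C8, vitronectin) are comparatively insensitive."""
        import dataclasses

        from altcomp.hemolysis import macs_per_cell
        from altcomp.scenarios import run_hemolytic_assay, standard_rabbit_assay

        base_cfg = standard_rabbit_assay(serum_fraction=0.05)
        from altcomp.catalog import build_full_network
        levels = {s.id: s.initial_concentration
                  for s in build_full_network().species}
        names = ["C3", "FB", "FD", "FH", "C6", "C8", "Vn"]

        def target(p):
            cfg = dataclasses.replace(
                base_cfg,
                initial_overrides={k: v * base_cfg.serum_fraction
                                   for k, v in p.items()})
            _, traj = run_hemolytic_assay(cfg, return_trajectory=True)
            return macs_per_cell(traj.final("MAC"), cfg.cell_concentration)

        table = local_sensitivity(target, {n: levels[n] for n in names},
                                  deltas=(0.2,))
        strength = table.groupby("parameter").relative_change.apply(
            lambda s: s.abs().max())
        upstream = min(strength[n] for n in ("C3", "FD", "FH"))
        terminal = max(strength[n] for n in ("C8", "Vn"))
        assert upstream > terminal
        # the amplification substrate is the single most sensitive input
        assert strength.idxmax() == "C3"
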