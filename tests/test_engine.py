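import numpy as np
import pytest

from altcomp.engine import (CompiledNetwork, SolverOptions, Trajectory, rhs,
                            simulate, simulate_with_doses, steady_state)
from altcomp.network import (ParameterEntry, ParameterSet, Phase, RateLaw,
                             RateLawKind, Reaction, ReactionNetwork,
                             SpeciesDef, Tag)

from conftest import brute_force_rhs, random_mass_action_network


def _toy(entries, species, reactions):
    return ReactionNetwork(
        [SpeciesDef(id=s, phase=Phase.FLUID, initial_concentration=c)
         for s, c in species],
        reactions, ParameterSet([ParameterEntry(n, v, "a.u.", "kinetic",
                                                "derived")
                                 for n, v in entries]))


def _r(rid, tag, reac, prod, kind, params, enzyme=None):
    return Reaction(id=rid, tag=tag, reactants=reac, products=prod,
                    rate_law=RateLaw(kind, params), enzyme=enzyme)


class TestRhs:
    def test_reversible_pair_detailed_balance(self):
        net = _toy([("kf", 2.0), ("kr", 2.0)], [("A", 1.0), ("B", 1.0)],
                   [_r(1, Tag.AP_FLUID, (("A", 1),), (("B", 1),),
                       RateLawKind.MASS_ACTION_1, {"k": "kf"}),
                    _r(2, Tag.AP_FLUID, (("B", 1),), (("A", 1),),
                       RateLawKind.MASS_ACTION_1, {"k": "kr"})])
        dy = rhs(net, np.array([1.0, 1.0]))
        assert np.allclose(dy, 0.0)

    def test_michaelis_menten_saturation(self):
        net = _toy([("kcat", 3.0), ("Km", 1e-6)],
                   [("S", 1.0), ("E", 0.5), ("P", 0.0)],
                   [_r(1, Tag.AP_FLUID, (("S", 1),), (("P", 1),),
                       RateLawKind.MICHAELIS_MENTEN,
                       {"kcat": "kcat", "Km": "Km"}, enzyme="E")])
        dy = rhs(net, np.array([1.0, 0.5, 0.0]))
        assert dy[2] == pytest.approx(3.0 * 0.5, rel=1e-5)  # S >> Km

    def test_matches_brute_force_on_many_random_networks(self, rng):
        """rhs equals an independent per-reaction accumulation oracle on
        over a hundred random small mass-action networks."""
        for _ in range(120):
            net = random_mass_action_network(
                rng, n_species=int(rng.integers(3, 7)),
                n_reactions=int(rng.integers(2, 10)))
            y = rng.uniform(0.0, 3.0, net.n_species)
            assert np.allclose(rhs(net, y), brute_force_rhs(net, y),
                               rtol=1e-12, atol=1e-14)

    def test_state_length_check(self, full_network):
        with pytest.raises(ValueError):
            rhs(full_network, np.zeros(3))


class TestSimulate:
    def test_synthesis_elimination_closed_form(self):
        s, k = 2.0e-9, 1e-3
        net = _toy([("s", s), ("k", k)], [("X", 0.0)],
                   [_r(114, Tag.SYNTHESIS, (), (("X", 1),),
                       RateLawKind.ZERO_ORDER_SYNTHESIS, {"k": "s"}),
                    _r(130, Tag.ELIMINATION, (("X", 1),), (),
                       RateLawKind.MASS_ACTION_1, {"k": "k"})])
        t = np.linspace(0, 5000.0, 11)
        traj = simulate(net, np.array([0.0]), t)
        expected = s / k * (1.0 - np.exp(-k * t))
        assert np.allclose(traj.conc("X"), expected, rtol=1e-6, atol=1e-15)

    def test_binding_equilibrium_matches_quadratic_root(self):
        """A+B<->AB equilibrates to the closed-form root of the binding
        quadratic."""
        kon, koff = 1e6, 1e-3
        a0, b0 = 2e-6, 1e-6
        net = _toy([("kon", kon), ("koff", koff)],
                   [("A", a0), ("B", b0), ("AB", 0.0)],
                   [_r(1, Tag.AP_FLUID, (("A", 1), ("B", 1)), (("AB", 1),),
                       RateLawKind.MASS_ACTION_2, {"k": "kon"}),
                    _r(2, Tag.AP_FLUID, (("AB", 1),), (("A", 1), ("B", 1)),
                       RateLawKind.MASS_ACTION_1, {"k": "koff"})])
        traj = simulate(net, np.array([a0, b0, 0.0]),
                        np.linspace(0, 5e5, 5))
        kd = koff / kon
        s = a0 + b0 + kd
        ab_eq = (s - np.sqrt(s * s - 4 * a0 * b0)) / 2
        assert traj.final("AB") == pytest.approx(ab_eq, rel=1e-6)

    def test_tolerance_halving_convergence(self, full_network):
        from altcomp.network import subset_fluid_phase
        fluid = subset_fluid_phase(full_network)
        y0 = fluid.initial_state(serum_fraction=0.25)
        t = np.linspace(0, 1800, 4)
        a = simulate(fluid, y0, t, SolverOptions()).final_state()
        b = simulate(fluid, y0, t, SolverOptions(rtol=5e-9, atol=5e-17)
                     ).final_state()
        scale = np.maximum(np.abs(a), 1e-18)
        assert np.max(np.abs(a - b) / scale) < 1e-3

    def test_non_negativity(self, full_network):
        from altcomp.network import subset_fluid_phase
        fluid = subset_fluid_phase(full_network)
        opts = SolverOptions()
        traj = simulate(fluid, fluid.initial_state(serum_fraction=1.0),
                        np.linspace(0, 3600, 13), opts)
        assert traj.states.min() >= -opts.atol

    def test_times_strictly_increasing_enforced(self):
        with pytest.raises(ValueError):
            Trajectory(times=np.array([0.0, 0.0]), states=np.zeros((1, 2)),
                       species_ids=["X"])


class TestDosing:
    def test_bolus_increments_exact(self):
        kel = 1e-6
        net = _toy([("kel", kel)], [("D", 0.0)],
                   [_r(130, Tag.ELIMINATION, (("D", 1),), (),
                       RateLawKind.MASS_ACTION_1, {"k": "kel"})])
        t = np.linspace(0, 10.0, 3)
        traj = simulate_with_doses(net, np.array([0.0]), t,
                                   [(0.0, "D", 1.5e-6)])
        assert traj.conc("D")[-1] == pytest.approx(1.5e-6, rel=1e-4)
        assert traj.events == [(0.0, "D", 1.5e-6)]

    def test_multi_dose_superposition(self):
        """Drug-only decay with repeated boluses matches the analytic
        superposition of exponentials."""
        from altcomp.constants import SECONDS_PER_DAY
        kel = np.log(2) / (14.3 * SECONDS_PER_DAY)
        net = _toy([("kel", kel)], [("D", 0.0)],
                   [_r(130, Tag.ELIMINATION, (("D", 1),), (),
                       RateLawKind.MASS_ACTION_1, {"k": "kel"})])
        doses = [(i * 14.0 * SECONDS_PER_DAY, "D", 1e-6) for i in range(4)]
        t_end = 70.0 * SECONDS_PER_DAY
        t = np.linspace(0, t_end, 15)
        traj = simulate_with_doses(net, np.array([0.0]), t, doses)
        expect = sum(1e-6 * np.exp(-kel * (t_end - td))
                     for td, _, _ in doses if td <= t_end)
        assert traj.final("D") == pytest.approx(expect, rel=1e-6)


class TestSteadyState:
    def test_turnover_only_equals_ratio(self):
        s, k = 3.3e-12, 2e-6
        net = _toy([("s", s), ("k", k)], [("X", 0.0)],
                   [_r(114, Tag.SYNTHESIS, (), (("X", 1),),
                       RateLawKind.ZERO_ORDER_SYNTHESIS, {"k": "s"}),
                    _r(130, Tag.ELIMINATION, (("X", 1),), (),
                       RateLawKind.MASS_ACTION_1, {"k": "k"})])
        y = steady_state(net, horizon_s=5e7)
        assert y[0] == pytest.approx(s / k, rel=1e-6)

    def test_closed_system_rejected(self, rng):
        net = random_mass_action_network(rng)
        from altcomp.engine import SteadyStateError
        with pytest.raises(SteadyStateError):
            steady_state(net)

    def test_healthy_invivo_levels_within_20pct(self):
        """The healthy open system holds the homeostatic plasma levels of
        the major pathway proteins, and the cell count stays 5e6/uL."""
        from altcomp.scenarios import healthy_steady_state
        net, y = healthy_steady_state()
        for sid in ("C3", "FB", "FH", "FI", "C5", "C6", "C7", "C8", "C9"):
            target = net.species_def(sid).invivo_concentration
            assert y[net.species_index(sid)] == pytest.approx(target, rel=0.2)
        cells_ul = y[net.species_index("E")] * 6.02214076e23 / 1e6
        assert cells_ul == pytest.approx(5e6, rel=0.05)
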