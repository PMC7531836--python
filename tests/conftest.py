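import numpy as np
import pytest

from altcomp.catalog import build_full_network, default_parameters


@pytest.fixture(scope="session")
def full_network():
    return build_full_network()


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_mass_action_network(rng, n_species=5, n_reactions=8):
    """Small random mass-action network for oracle tests."""
    from altcomp.network import (ParameterEntry, ParameterSet, Phase, RateLaw,
                                 RateLawKind, Reaction, ReactionNetwork,
                                 SpeciesDef, Tag)

    species = [SpeciesDef(id=f"X{i}", phase=Phase.FLUID,
                          initial_concentration=float(rng.uniform(0.1, 2.0)))
               for i in range(n_species)]
    entries, reactions = [], []
    for j in range(n_reactions):
        order = int(rng.integers(1, 3))
        picks = rng.choice(n_species, size=order, replace=False)
        prods = rng.choice(n_species, size=int(rng.integers(1, 3)), replace=False)
        k = float(rng.uniform(0.01, 2.0))
        entries.append(ParameterEntry(f"k{j}", k, "a.u.", "kinetic", "derived"))
        kind = (RateLawKind.MASS_ACTION_1 if order == 1
                else RateLawKind.MASS_ACTION_2)
        reactions.append(Reaction(
            id=j + 1, tag=Tag.AP_FLUID,
            reactants=tuple((f"X{i}", 1) for i in picks),
            products=tuple((f"X{i}", 1) for i in prods),
            rate_law=RateLaw(kind, {"k": f"k{j}"})))
    return ReactionNetwork(species, reactions, ParameterSet(entries))


def brute_force_rhs(net, state):
    """Independent per-reaction accumulation oracle for mass-action nets."""
    dy = np.zeros(net.n_species)
    for r in net.reactions:
        rate = net.params.value(r.rate_law.params["k"]) * r.rate_scale
        for sid, nu in r.reactants:
            rate *= max(state[net.species_index(sid)], 0.0) ** nu
        for sid in r.modifiers:
            rate *= max(state[net.species_index(sid)], 0.0)
        for sid, nu in r.reactants:
            dy[net.species_index(sid)] -= nu * rate
        for sid, nu in r.products:
            dy[net.species_index(sid)] += nu * rate
    return dy
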