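"""Declarative reaction-network representation of the alternative complement pathway.

The full model is a fixed catalog of 226 reactions over 97 molecular species:
the fluid-phase cascade (reactions 1-36), the surface cascade on erythrocytes
(37-111), erythrocyte turnover (112-113), synthesis of plasma and membrane
proteins (114-129), first-order degradation/conversion of every protein and
complex (130-223) and eculizumab binding and clearance (224-226).

Species are tracked as molar concentrations in the suspension or plasma
volume, including membrane-bound complexes; per-cell pore counts are derived
downstream (see :mod:`altcomp.hemolysis`).  Reaction identifiers are canonical
catalog numbers; subsetting always selects by tag, never by position.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Sequence

import numpy as np


class Phase(str, Enum):
    FLUID = "fluid"
    SURFACE = "surface"
    CELL = "cell"
    DRUG = "drug"


class Tag(str, Enum):
    """Reaction tag; consistent with the canonical id ranges."""

    AP_FLUID = "ap_fluid"          # 1-36
    AP_SURFACE = "ap_surface"      # 37-111
    CELL_TURNOVER = "cell_turnover"  # 112-113
    SYNTHESIS = "synthesis"        # 114-129
    ELIMINATION = "elimination"    # 130-223
    DRUG = "drug"                  # 224-226


TAG_ID_RANGES = {
    Tag.AP_FLUID: (1, 36),
    Tag.AP_SURFACE: (37, 111),
    Tag.CELL_TURNOVER: (112, 113),
    Tag.SYNTHESIS: (114, 129),
    Tag.ELIMINATION: (130, 223),
    Tag.DRUG: (224, 226),
}


class RateLawKind(str, Enum):
    MASS_ACTION_1 = "mass_action_order1"
    MASS_ACTION_2 = "mass_action_order2"
    MICHAELIS_MENTEN = "michaelis_menten"
    ZERO_ORDER_SYNTHESIS = "zero_order_synthesis"
    # kon/koff pair carried by a single reversible reaction (drug binding)
    REVERSIBLE_MASS_ACTION = "reversible_mass_action"
    # k_el,S = k_s + k_H(state): state-dependent loss of cells and
    # surface-bound species due to hemolysis (in vivo only)
    SURFACE_ELIMINATION = "surface_elimination"


class NetworkError(ValueError):
    """Structural problem in a network definition."""


class MissingParameterError(KeyError):
    """A rate law references a parameter absent from the parameter set."""


class ConfigurationError(ValueError):
    """Invalid scenario/cell-type configuration."""


@dataclass(frozen=True)
class SpeciesDef:
    """One molecular species.

    ``initial_concentration`` is the in-vitro concentration in 100% serum
    (molar); ``invivo_concentration`` the homeostatic plasma level used as the
    in-vivo initial condition and synthesis target.  ``serum_scaled`` species
    scale with serum dilution; ``surface_bound`` species are lost together
    with their host cell.  ``c3_moiety`` counts C3-derived cores for
    conservation checks.
    """

    id: str
    phase: Phase
    initial_concentration: float = 0.0
    invivo_concentration: float = 0.0
    molecular_weight: float | None = None  # kDa
    serum_scaled: bool = False
    surface_bound: bool = False
    c3_moiety: int = 0

    def __post_init__(self):
        if self.initial_concentration < 0 or self.invivo_concentration < 0:
            raise NetworkError(f"negative concentration for species {self.id!r}")
        if self.surface_bound and self.phase not in (Phase.SURFACE, Phase.CELL):
            raise NetworkError(f"surface_bound species {self.id!r} must be surface phase")


@dataclass(frozen=True)
class RateLaw:
    """A rate law referencing named parameters of the catalog.

    ``params`` maps a role (``k``, ``kcat``, ``Km``, ``kon``, ``koff``,
    ``ks``) to a parameter name resolved against the :class:`ParameterSet`.
    """

    kind: RateLawKind
    params: Mapping[str, str]

    def required_roles(self) -> tuple[str, ...]:
        return {
            RateLawKind.MASS_ACTION_1: ("k",),
            RateLawKind.MASS_ACTION_2: ("k",),
            RateLawKind.MICHAELIS_MENTEN: ("kcat", "Km"),
            RateLawKind.ZERO_ORDER_SYNTHESIS: ("k",),
            RateLawKind.REVERSIBLE_MASS_ACTION: ("kon", "KD"),
            RateLawKind.SURFACE_ELIMINATION: ("ks",),
        }[self.kind]


@dataclass(frozen=True)
class Reaction:
    id: int
    tag: Tag
    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate_law: RateLaw
    enzyme: str | None = None
    # species that enter the rate expression but are not consumed
    # (unsaturable surface: the cell acts as a second-order partner)
    modifiers: tuple[str, ...] = ()
    # structural multiplier on the rate constant (e.g. membrane sites per
    # cell when the modifier is the cell concentration)
    rate_scale: float = 1.0
    note: str = ""

    def __post_init__(self):
        lo, hi = TAG_ID_RANGES[self.tag]
        if not lo <= self.id <= hi:
            raise NetworkError(f"reaction {self.id} inconsistent with tag {self.tag}")
        if self.rate_law.kind == RateLawKind.MICHAELIS_MENTEN and self.enzyme is None:
            raise NetworkError(f"reaction {self.id}: Michaelis-Menten requires an enzyme")
        order = len(self.reactants) + len(self.modifiers)
        if self.rate_law.kind == RateLawKind.MASS_ACTION_1 and order != 1:
            raise NetworkError(f"reaction {self.id}: first-order law with {order} reactants")
        if self.rate_law.kind == RateLawKind.MASS_ACTION_2 and order != 2:
            raise NetworkError(f"reaction {self.id}: second-order law with {order} reactants")


@dataclass(frozen=True)
class ParameterEntry:
    name: str
    value: float
    units: str
    category: str      # kinetic | turnover | drug | other
    provenance: str    # Table1_final | literature_baseline | derived
    note: str = ""

    def __post_init__(self):
        if self.value < 0:
            raise NetworkError(f"negative parameter {self.name}")


# the two constants rescaled between the in-vitro and in-vivo context
INVIVO_RESCALED = {
    "kp_C3_H2O": 1e-2,        # tick-over, reduced 10^2-fold in vivo
    "kp_C3b_surface": 1e-5,   # nascent C3b attachment, reduced 10^5-fold
}


class ParameterSet:
    """Named constants with units, category tags and provenance notes.

    ``context`` is ``in_vitro`` or ``in_vivo``; switching context rescales
    the tick-over and surface-attachment constants by the fixed factors the
    in-vivo parameterization prescribes.
    """

    def __init__(self, entries: Sequence[ParameterEntry], context: str = "in_vitro"):
        if context not in ("in_vitro", "in_vivo"):
            raise ConfigurationError(f"unknown context {context!r}")
        self._entries: dict[str, ParameterEntry] = {}
        for e in entries:
            if e.name in self._entries:
                raise NetworkError(f"duplicate parameter {e.name}")
            self._entries[e.name] = e
        self.context = context

    def __contains__(self, name: str) -> bool:
        return name in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.values())

    def entry(self, name: str) -> ParameterEntry:
        try:
            return self._entries[name]
        except KeyError:
            raise MissingParameterError(f"parameter {name!r} not in catalog") from None

    def base_value(self, name: str) -> float:
        return self.entry(name).value

    def value(self, name: str) -> float:
        """Context-resolved value (in-vivo rescaling applied)."""
        v = self.entry(name).value
        if self.context == "in_vivo" and name in INVIVO_RESCALED:
            v *= INVIVO_RESCALED[name]
        return v

    def with_context(self, context: str) -> "ParameterSet":
        return ParameterSet(list(self._entries.values()), context=context)

    def with_values(self, overrides: Mapping[str, float]) -> "ParameterSet":
        entries = []
        for e in self._entries.values():
            if e.name in overrides:
                e = replace(e, value=float(overrides[e.name]), provenance="derived")
            entries.append(e)
        unknown = set(overrides) - set(self._entries)
        if unknown:
            raise MissingParameterError(f"unknown parameters {sorted(unknown)}")
        return ParameterSet(entries, context=self.context)

    def names(self, category: str | None = None) -> list[str]:
        return [e.name for e in self._entries.values()
                if category is None or e.category == category]


@dataclass
class ReactionNetwork:
    species: list[SpeciesDef]
    reactions: list[Reaction]
    params: ParameterSet
    volume: float = 1.0  # L; concentrations are per-liter so volume only
    #      matters for dose bookkeeping

    def __post_init__(self):
        self._index = {s.id: i for i, s in enumerate(self.species)}
        if len(self._index) != len(self.species):
            raise NetworkError("duplicate species ids")
        ids = [r.id for r in self.reactions]
        if len(set(ids)) != len(ids):
            raise NetworkError("duplicate reaction ids")

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def species_index(self, sid: str) -> int:
        try:
            return self._index[sid]
        except KeyError:
            raise NetworkError(f"unknown species {sid!r}") from None

    def species_def(self, sid: str) -> SpeciesDef:
        return self.species[self.species_index(sid)]

    def has_species(self, sid: str) -> bool:
        return sid in self._index

    def reactions_by_tag(self, tag: Tag) -> list[Reaction]:
        return [r for r in self.reactions if r.tag == tag]

    def tag_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.reactions:
            out[r.tag.value] = out.get(r.tag.value, 0) + 1
        return out

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Check structural invariants; raise on violation."""
        for r in self.reactions:
            for sid, _ in (*r.reactants, *r.products):
                self.species_index(sid)
            for sid in r.modifiers:
                self.species_index(sid)
            if r.enzyme is not None:
                self.species_index(r.enzyme)
            for role in r.rate_law.required_roles():
                pname = r.rate_law.params.get(role)
                if pname is None:
                    raise NetworkError(f"reaction {r.id}: rate law missing role {role!r}")
                self.params.entry(pname)  # raises MissingParameterError
        # every surface species must take part in at least one surface reaction
        touched: set[str] = set()
        for r in self.reactions_by_tag(Tag.AP_SURFACE):
            touched.update(sid for sid, _ in (*r.reactants, *r.products))
            touched.update(r.modifiers)
            if r.enzyme:
                touched.add(r.enzyme)
        for s in self.species:
            if s.phase == Phase.SURFACE and s.id not in touched:
                raise NetworkError(f"surface species {s.id!r} unused in surface reactions")

    # ------------------------------------------------------------------
    def initial_state(self, context: str = "in_vitro", serum_fraction: float = 1.0,
                      overrides: Mapping[str, float] | None = None) -> np.ndarray:
        """Initial concentration vector.

        In vitro, serum-scaled species start at ``serum_fraction`` times their
        100%-serum level; in vivo every species starts at its homeostatic
        plasma level.
        """
        if not 0.0 <= serum_fraction <= 1.0:
            raise ConfigurationError("serum_fraction must lie in [0, 1]")
        y0 = np.zeros(self.n_species)
        for i, s in enumerate(self.species):
            if context == "in_vivo":
                y0[i] = s.invivo_concentration
            else:
                y0[i] = s.initial_concentration * (serum_fraction if s.serum_scaled else 1.0)
        if overrides:
            for sid, v in overrides.items():
                y0[self.species_index(sid)] = v
        return y0


# ----------------------------------------------------------------------
# Operations

def stoichiometry_matrix(net: ReactionNetwork) -> np.ndarray:
    """Integer matrix (n_species x n_reactions); column j is the net
    stoichiometric change of reaction j.  Modifiers do not appear."""
    S = np.zeros((net.n_species, net.n_reactions), dtype=np.int64)
    for j, r in enumerate(net.reactions):
        for sid, nu in r.reactants:
            S[net.species_index(sid), j] -= nu
        for sid, nu in r.products:
            S[net.species_index(sid), j] += nu
    return S


def subset_fluid_phase(net: ReactionNetwork) -> ReactionNetwork:
    """Closed fluid-phase submodel: only reactions tagged ``ap_fluid`` are
    kept (surface, turnover, synthesis, elimination and drug reactions are
    all removed, matching the in-vitro fluid assay where the sample is a
    closed system).  Species reachable only through removed reactions are
    dropped."""
    reactions = net.reactions_by_tag(Tag.AP_FLUID)
    keep: set[str] = set()
    for r in reactions:
        keep.update(sid for sid, _ in (*r.reactants, *r.products))
        keep.update(r.modifiers)
        if r.enzyme:
            keep.add(r.enzyme)
    species = [s for s in net.species if s.id in keep]
    return ReactionNetwork(species, reactions, net.params, net.volume)


#: per-cell copy numbers of membrane regulators on healthy human erythrocytes
HUMAN_REGULATOR_COPIES = {"CR1": 700.0, "DAF": 3000.0, "CD59": 25000.0}


def configure_surface(net: ReactionNetwork, cell_type: str,
                      cell_concentration: float | None = None) -> ReactionNetwork:
    """Return a network configured for a given erythrocyte type.

    Configuration is absolute, not incremental: species levels and the FH
    surface-attachment constant are set from the cell type regardless of any
    previous configuration.

    * ``rabbit`` - no CR1/DAF/CD59 and no FH surface binding
      (kp_C3bH_surf = 0): the foreign surface is unprotected.
    * ``human`` - regulators at healthy copy numbers.
    * ``pnh2``  - DAF and CD59 at 10% of healthy levels (subtotal
      GPI-anchor deficiency).
    * ``pnh3``  - DAF and CD59 entirely absent.

    ``cell_concentration`` (cells L^-1) sets the in-vitro cell level and the
    membrane-regulator pools via per-cell copy numbers; if omitted the
    current species table levels are kept and only scaled/zeroed.
    """
    from .constants import AVOGADRO

    factors = {
        "rabbit": {"CR1": 0.0, "DAF": 0.0, "CD59": 0.0},
        "human": {"CR1": 1.0, "DAF": 1.0, "CD59": 1.0},
        "pnh2": {"CR1": 1.0, "DAF": 0.1, "CD59": 0.1},
        "pnh3": {"CR1": 1.0, "DAF": 0.0, "CD59": 0.0},
    }
    if cell_type not in factors:
        raise ConfigurationError(f"unknown cell type {cell_type!r}")
    fac = factors[cell_type]

    species = []
    for s in net.species:
        if s.id == "E" and cell_concentration is not None:
            s = replace(s, initial_concentration=cell_concentration / AVOGADRO)
        elif s.id in fac:
            if cell_concentration is not None:
                invitro = (HUMAN_REGULATOR_COPIES[s.id] * cell_concentration
                           / AVOGADRO) * fac[s.id]
            else:
                invitro = _healthy_invitro_level(net, s.id) * fac[s.id]
            # in vivo the regulator pool follows its (possibly reduced)
            # synthesis; the initial level scales the same way
            s = replace(s, initial_concentration=invitro,
                        invivo_concentration=_healthy_invivo_level(net, s.id) * fac[s.id])
        species.append(s)

    overrides: dict[str, float] = {
        "kp_C3bH_surf": 0.0 if cell_type == "rabbit"
        else _healthy_base(net, "kp_C3bH_surf"),
    }
    # membrane-regulator synthesis (in vivo) follows the deficiency
    for reg, sname in (("DAF", "s_DAF"), ("CD59", "s_CD59"), ("CR1", "s_CR1")):
        if sname in net.params:
            overrides[sname] = _healthy_base(net, sname) * fac[reg]

    params = net.params.with_values(overrides)
    out = ReactionNetwork(species, net.reactions, params, net.volume)
    out._cell_type = cell_type  # type: ignore[attr-defined]
    return out


def _healthy_base(net: ReactionNetwork, pname: str) -> float:
    """Healthy-reference value of a parameter, independent of previous
    configuration (kept on the catalog entry's note or recomputed)."""
    from . import catalog
    return catalog.healthy_parameter_value(pname)


def _healthy_invitro_level(net: ReactionNetwork, sid: str) -> float:
    from . import catalog
    return catalog.healthy_species_levels()[sid][0]


def _healthy_invivo_level(net: ReactionNetwork, sid: str) -> float:
    from . import catalog
    return catalog.healthy_species_levels()[sid][1]
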