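"""Eculizumab pharmacology: C5 target engagement and one-compartment PK.

The antibody binds C5 reversibly (KD 120 pM, assumed on-rate 20 nM^-1
day^-1); drug-bound C5 is functionally inert and takes part in no convertase
reaction.  Systemic kinetics are linear with a 14.3-day elimination
half-life and a 6.5 L volume of distribution; intravenous infusions are
treated as instantaneous boluses.  The default clinical regimen is 600 mg
weekly for 4 weeks, then 900 mg every 2 weeks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .constants import SECONDS_PER_DAY


class DosingError(ValueError):
    pass


@dataclass(frozen=True)
class DrugParams:
    KD: float = 120e-12             # M
    kon: float = 20e9               # M^-1 day^-1 (20 nM^-1 day^-1)
    half_life_days: float = 14.3
    MW: float = 148.0               # kDa
    Vd: float = 6.5                 # L

    def __post_init__(self):
        if min(self.KD, self.kon, self.half_life_days, self.MW, self.Vd) <= 0:
            raise DosingError("all drug parameters must be positive")

    @property
    def koff(self) -> float:
        """day^-1"""
        return self.KD * self.kon

    @property
    def kel(self) -> float:
        """day^-1"""
        return math.log(2.0) / self.half_life_days


@dataclass(frozen=True)
class Regimen:
    """Dose schedule: (time days, dose mg, route) triples."""

    doses: tuple[tuple[float, float, str], ...] = ()

    def __post_init__(self):
        times = [t for t, _, _ in self.doses]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise DosingError("dose times must be non-decreasing")
        if any(d <= 0 for _, d, _ in self.doses):
            raise DosingError("doses must be positive")

    @classmethod
    def clinical_default(cls, months: float = 36.0) -> "Regimen":
        """600 mg weekly x 4, then 900 mg every 2 weeks."""
        doses = [(7.0 * w, 600.0, "iv") for w in range(4)]
        t = 28.0
        end = months * 30.4375
        while t <= end:
            doses.append((t, 900.0, "iv"))
            t += 14.0
        return cls(tuple(doses))

    def scaled(self, factor: float) -> "Regimen":
        return Regimen(tuple((t, d * factor, r) for t, d, r in self.doses))


def dose_to_concentration(dose_mg: float, p: DrugParams = DrugParams()) -> float:
    """Molar plasma increment of one intravenous bolus."""
    if dose_mg <= 0:
        raise DosingError("dose must be positive")
    grams = dose_mg * 1e-3
    mol = grams / (p.MW * 1e3)
    return mol / p.Vd


def pk_elimination(p: DrugParams = DrugParams()) -> float:
    """First-order elimination rate constant, day^-1."""
    return p.kel


def binding_parameter_overrides(p: DrugParams) -> dict[str, float]:
    """Catalog overrides (SI units) realizing the drug parameters."""
    return {
        "kon_ecu": p.kon / SECONDS_PER_DAY,
        "KD_ecu": p.KD,
        "kel_ecu": p.kel / SECONDS_PER_DAY,
    }


def binding_reactions(net):
    """The drug-tagged reactions of a network (reversible binding + PK)."""
    from .network import Tag

    return net.reactions_by_tag(Tag.DRUG)


def equilibrium_bound_fraction(free_drug_molar: float,
                               p: DrugParams = DrugParams()) -> float:
    """Fraction of C5 drug-bound at a given free-drug level (isotherm)."""
    return free_drug_molar / (free_drug_molar + p.KD)


def superposition_concentration(t_days: float, regimen: Regimen,
                                p: DrugParams = DrugParams()) -> float:
    """Closed-form drug-only concentration by bolus superposition (M)."""
    c = 0.0
    for t_d, dose, _ in regimen.doses:
        if t_d <= t_days:
            c += dose_to_concentration(dose, p) * math.exp(-p.kel * (t_days - t_d))
    return c
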