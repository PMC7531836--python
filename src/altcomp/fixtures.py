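"""Seeded synthetic datasets for offline testing of every fitting stage.

The generators emulate the structure of the digitized literature datasets
the model was estimated against: Hill-type lysis curves, assay time
courses, inhibitor dose-response curves and paired hemoglobin/LDH patient
values.  Noise is additive Gaussian expressed as a percentage of the full
scale, clipped to the valid range; a seed fixes the output exactly.

A packaged synthetic stand-in for the digitized lysis-versus-pore-density
curve ships as ``data/mac_lysis_curve_synthetic.csv``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .biomarkers import BiomarkerParams, ldh
from .hemolysis import HemolysisModel, percent_hemolysis

KINDS = ("hill_curve", "hemolysis_timecourse", "dose_response",
         "marker_timecourse", "ldh_hb_pairs")


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class FixtureSpec:
    kind: str
    truth: dict = field(default_factory=dict)
    noise_pct: float = 0.0      # Gaussian sigma as % of full scale
    n: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise FixtureError(f"unknown fixture kind {self.kind!r}")
        if self.noise_pct < 0:
            raise FixtureError("noise must be non-negative")
        if self.n < 2:
            raise FixtureError("need at least 2 points")


def generate(spec: FixtureSpec) -> pd.DataFrame:
    """Deterministic synthetic dataset for ``spec``."""
    rng = np.random.default_rng(spec.seed)
    t = dict(spec.truth)
    if spec.kind == "hill_curve":
        model = HemolysisModel(gamma=t.get("gamma", 1.60),
                               mac50=t.get("mac50", 1.15),
                               tau=t.get("tau", 1.0))
        mac = np.geomspace(t.get("mac_min", 0.05), t.get("mac_max", 30.0),
                           spec.n)
        h = percent_hemolysis(mac, model)
        h = _noise(h, spec.noise_pct, rng, 100.0, lo=0.0, hi=100.0)
        return pd.DataFrame({"mac_per_cell": mac, "percent_hemolysis": h})

    if spec.kind == "hemolysis_timecourse":
        hmax = t.get("hmax", 100.0)
        rate = t.get("rate", 1.0 / 600.0)       # s^-1
        lag = t.get("lag", 120.0)               # s
        times = np.linspace(0.0, t.get("t_end", 1800.0), spec.n)
        h = hmax * np.clip(1.0 - np.exp(-rate * np.maximum(times - lag, 0.0)),
                           0.0, 1.0)
        h = _noise(h, spec.noise_pct, rng, 100.0, lo=0.0, hi=100.0)
        return pd.DataFrame({"time_s": times, "percent_hemolysis": h})

    if spec.kind == "dose_response":
        ic50 = t.get("ic50", 3e-7)
        hill = t.get("hill", 1.0)
        top = t.get("top", 100.0)
        conc = np.geomspace(t.get("c_min", 1e-9), t.get("c_max", 1e-5), spec.n)
        y = top / (1.0 + (conc / ic50) ** hill)
        y = _noise(y, spec.noise_pct, rng, top, lo=0.0, hi=top)
        return pd.DataFrame({"concentration_molar": conc, "response_pct": y})

    if spec.kind == "marker_timecourse":
        c0 = t.get("c0", 1e-6)
        rate = t.get("rate", 1e-4)
        times = np.linspace(0.0, t.get("t_end", 3600.0), spec.n)
        y = c0 * (1.0 - np.exp(-rate * times))
        y = _noise(y, spec.noise_pct, rng, c0, lo=0.0)
        return pd.DataFrame({"time_s": times, "concentration_molar": y})

    # ldh_hb_pairs
    p = BiomarkerParams(LDHmax=t.get("LDHmax", 1495.0),
                        HLDH50=t.get("HLDH50", 7.94),
                        LDH0=t.get("LDH0", 296.0))
    hb = np.linspace(t.get("hb_min", 2.0), t.get("hb_max", 15.0), spec.n)
    y = ldh(hb, p)
    y = _noise(y, spec.noise_pct, rng, p.LDHmax, lo=0.0)
    return pd.DataFrame({"hemoglobin_g_dl": hb, "ldh_u_l": y})


def _noise(y: np.ndarray, pct: float, rng, full_scale: float,
           lo: float | None = None, hi: float | None = None) -> np.ndarray:
    if pct == 0:
        return y
    out = y + rng.normal(0.0, pct / 100.0 * full_scale, size=y.shape)
    return np.clip(out, lo, hi)


def packaged_lysis_curve() -> pd.DataFrame:
    """The packaged synthetic lysis-versus-MAC-density curve.

    A synthetic stand-in (gamma 1.60, MAC50 1.15, mild noise) for the
    digitized experimental dose-response of complement-mediated lysis of
    antibody-sensitized erythrocytes; see the file header for provenance.
    """
    ref = resources.files("altcomp.data").joinpath("mac_lysis_curve_synthetic.csv")
    with ref.open() as fh:
        return pd.read_csv(fh, comment="#")
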