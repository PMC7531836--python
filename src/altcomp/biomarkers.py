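"""Hematological biomarkers derived from the circulating erythrocyte count.

Hematocrit is cell count times mean corpuscular volume; hemoglobin is cell
count times per-cell hemoglobin mass; LDH follows a decreasing sigmoid of
hemoglobin fitted to paired patient measurements (intravascular lysis
releases LDH, so low hemoglobin maps to high LDH).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import AVOGADRO


class BiomarkerError(ValueError):
    pass


@dataclass(frozen=True)
class BiomarkerParams:
    Ve: float = 90.0          # mean corpuscular volume, fL
    Nhe: float = 270e6        # hemoglobin molecules per erythrocyte
    MWh: float = 64.5         # hemoglobin molecular weight, kDa
    LDHmax: float = 1495.0    # U L^-1
    HLDH50: float = 7.94      # g dL^-1
    LDH0: float = 296.0       # U L^-1

    def __post_init__(self):
        if min(self.Ve, self.Nhe, self.MWh, self.LDHmax, self.HLDH50,
               self.LDH0) <= 0:
            raise BiomarkerError("all biomarker parameters must be positive")


def hematocrit(cell_conc_per_ul: float, p: BiomarkerParams = BiomarkerParams()) -> float:
    """Hematocrit (%) from erythrocyte count (cells uL^-1)."""
    if cell_conc_per_ul < 0:
        raise BiomarkerError("cell concentration must be non-negative")
    # cells/uL * fL/cell: fL per uL is a volume fraction of 1e-9
    return cell_conc_per_ul * p.Ve * 1e-9 * 100.0


def hemoglobin(cell_conc_per_ul: float, p: BiomarkerParams = BiomarkerParams()) -> float:
    """Hemoglobin concentration (g dL^-1) from erythrocyte count."""
    if cell_conc_per_ul < 0:
        raise BiomarkerError("cell concentration must be non-negative")
    cells_per_l = cell_conc_per_ul * 1e6
    grams_per_l = cells_per_l * p.Nhe * (p.MWh * 1e3) / AVOGADRO
    return grams_per_l / 10.0  # g/L -> g/dL


def mean_corpuscular_hemoglobin(p: BiomarkerParams = BiomarkerParams()) -> float:
    """Hemoglobin mass per cell in picograms."""
    return p.Nhe * (p.MWh * 1e3) / AVOGADRO * 1e12


def ldh(hb_g_dl, p: BiomarkerParams = BiomarkerParams()):
    """Serum LDH (U L^-1) as a decreasing sigmoid of hemoglobin (g dL^-1)."""
    hb = np.asarray(hb_g_dl, dtype=float)
    if np.any(hb < 0):
        raise BiomarkerError("hemoglobin must be non-negative")
    out = p.LDHmax / (1.0 + np.exp(hb - p.HLDH50)) + p.LDH0
    return float(out) if out.ndim == 0 else out


def panel(cell_conc_per_ul: float, p: BiomarkerParams = BiomarkerParams()) -> dict:
    """Full biomarker panel from a cell count."""
    hb = hemoglobin(cell_conc_per_ul, p)
    return {
        "cells_per_ul": cell_conc_per_ul,
        "hemoglobin_g_dl": hb,
        "hematocrit_pct": hematocrit(cell_conc_per_ul, p),
        "ldh_u_l": ldh(hb, p),
    }


def fit_ldh_curve(pairs) -> tuple[float, float, float]:
    """Least-squares (LDHmax, HLDH50, LDH0) from (hemoglobin, LDH) pairs."""
    from scipy.optimize import least_squares

    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 4:
        raise BiomarkerError("need at least 4 (hb, ldh) points")
    hb, y = arr[:, 0], arr[:, 1]
    if np.ptp(y) < 1e-9 or np.ptp(hb) < 1e-9:
        raise BiomarkerError("non-identifiable flat data")

    def resid(x):
        lmax, h50, l0 = x
        return lmax / (1.0 + np.exp(hb - h50)) + l0 - y

    x0 = (max(np.ptp(y), 1.0), float(np.median(hb)), float(np.min(y)))
    fit = least_squares(resid, x0)
    if not fit.success:
        raise BiomarkerError(f"LDH curve fit failed: {fit.message}")
    lmax, h50, l0 = (float(v) for v in fit.x)
    if lmax <= 0 or h50 <= 0:
        raise BiomarkerError("non-physical LDH fit")
    return lmax, h50, l0
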