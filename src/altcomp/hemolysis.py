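"""MAC-mediated cell lysis and the elimination kinetics of lysing cells.

The percent hemolysis follows a Hill function of the number of membrane
attack complexes per cell,

    H = 100 / (1 + (MAC50 / MAC)^gamma),

with gamma = 1.60 and MAC50 = 1.15 pores/cell fitted to complement-lysis
dose-response data.  Only complete pores (18 C9 molecules) count.  In vivo
the hemolytic elimination rate k_H = -ln(1 - H/100)/tau adds to the
physiological erythrocyte turnover k_s = ln2/60 d^-1; surface-bound proteins
are removed at the same rate as their host cell.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .constants import AVOGADRO, ERYTHROCYTE_HALF_LIFE_DAYS


class HemolysisError(ValueError):
    pass


@dataclass(frozen=True)
class HemolysisModel:
    gamma: float = 1.60     # Hill coefficient
    mac50: float = 1.15     # MAC per cell at 50% lysis
    tau: float = 0.3        # scaling time constant of the lysis rate, days

    def __post_init__(self):
        if self.gamma <= 0 or self.mac50 <= 0 or self.tau <= 0:
            raise HemolysisError("gamma, mac50 and tau must be positive")


@dataclass(frozen=True)
class TurnoverParams:
    """Physiological erythrocyte turnover."""

    ks: float = math.log(2.0) / ERYTHROCYTE_HALF_LIFE_DAYS  # day^-1
    healthy_cells_per_liter: float = 5.0e12

    @property
    def production(self) -> float:
        """Cell production rate (cells L^-1 day^-1) balancing turnover."""
        return self.ks * self.healthy_cells_per_liter


def macs_per_cell(mac_conc: float, cell_conc: float) -> float:
    """Pores per cell from a molar MAC concentration and cells L^-1."""
    if cell_conc <= 0:
        raise HemolysisError("cell concentration must be positive")
    return mac_conc * AVOGADRO / cell_conc


def percent_hemolysis(mac, model: HemolysisModel = HemolysisModel()):
    """Percent of cells lysed at a given MAC density per cell (Hill)."""
    mac = np.asarray(mac, dtype=float)
    if np.any(mac < 0):
        raise HemolysisError("MAC density must be non-negative")
    with np.errstate(divide="ignore", over="ignore"):
        out = 100.0 / (1.0 + (model.mac50 / mac) ** model.gamma)
    out = np.where(mac == 0, 0.0, out)
    return float(out) if out.ndim == 0 else out


def hemolysis_rate(h_percent: float, tau: float,
                   max_rate: float | None = None) -> float:
    """Hemolytic elimination rate k_H (day^-1) from percent hemolysis."""
    if tau <= 0:
        raise HemolysisError("tau must be positive")
    if h_percent < 0:
        raise HemolysisError("H must be non-negative")
    if max_rate is None:
        max_rate = -math.log(1e-6) / tau
    if h_percent >= 100.0:
        warnings.warn("H >= 100%: hemolytic rate capped at configured maximum",
                      RuntimeWarning, stacklevel=2)
        return max_rate
    return min(-math.log1p(-h_percent / 100.0) / tau, max_rate)


def fit_hill(curve, p0: tuple[float, float] = (1.5, 1.0)) -> HemolysisModel:
    """Least-squares fit of (MAC/cell, percent lysis) pairs.

    ``curve`` is a sequence of pairs or a two-column array.  Fitting is done
    on log-parameters to keep gamma and MAC50 positive.
    """
    from scipy.optimize import least_squares

    arr = np.asarray(curve, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise HemolysisError("need at least 3 (mac, percent) points")
    mac, h = arr[:, 0], arr[:, 1]
    if np.all(h <= 0) or np.all(h >= 100):
        raise HemolysisError("degenerate curve: no transition to fit")

    def resid(logp):
        g, m50 = np.exp(logp)
        pred = percent_hemolysis(mac, HemolysisModel(g, m50))
        return pred - h

    fit = least_squares(resid, np.log(p0), method="lm")
    if not fit.success:
        raise HemolysisError(f"Hill fit failed: {fit.message}")
    g, m50 = np.exp(fit.x)
    return HemolysisModel(gamma=float(g), mac50=float(m50))
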