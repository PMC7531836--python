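"""Objective function, iterative one-parameter-at-a-time optimizer and
local sensitivity scans.

The objective is the sum over datasets of the per-dataset sum of squared
residuals normalized by its number of points (equal weighting among
studies).  The optimizer mirrors the published estimation procedure: at
each iteration every free parameter is minimized alone by a bounded scalar
search spanning +/-7 decades around its current value (on a log10 scale);
only the single best-improving update is applied; iteration stops when the
objective improves by less than 1%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar


class CalibrationError(RuntimeError):
    pass


@dataclass
class Dataset:
    """Observations paired with a model mapping.

    ``model`` maps a parameter dict to predictions aligned with ``y``.
    """

    y: np.ndarray
    model: Callable[[Mapping[str, float]], np.ndarray]
    name: str = ""

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        if self.y.size == 0:
            raise CalibrationError(f"dataset {self.name!r} is empty")


@dataclass
class CalibrationProblem:
    datasets: Sequence[Dataset]
    free_parameters: Mapping[str, float]      # name -> starting value
    bounds_decades: float = 7.0               # +/- decades around the start
    log: list = field(default_factory=list)   # (iteration, name, objective)

    def __post_init__(self):
        if not self.datasets:
            raise CalibrationError("no datasets")
        if not self.free_parameters:
            raise CalibrationError("no free parameters")
        for v in self.free_parameters.values():
            if v <= 0:
                raise CalibrationError("free parameters must start positive "
                                       "(searched on a log scale)")


def ssr(dataset: Dataset, params: Mapping[str, float]) -> float:
    """Sum of squared residuals divided by the number of points."""
    m = np.asarray(dataset.model(params), dtype=float)
    if m.shape != dataset.y.shape:
        raise CalibrationError(
            f"model returned shape {m.shape}, expected {dataset.y.shape}")
    return float(np.sum((dataset.y - m) ** 2) / dataset.y.size)


def ssr_sum(problem: CalibrationProblem, params: Mapping[str, float]) -> float:
    """Objective: sum of per-dataset normalized SSR values."""
    return float(sum(ssr(d, params) for d in problem.datasets))


def coordinate_descent(problem: CalibrationProblem, tolx: float = 0.01,
                       tolfun: float = 0.5, max_iterations: int = 50,
                       rel_improvement: float = 0.01) -> dict[str, float]:
    """Iterative single-best-update parameter estimation.

    Each iteration fits every free parameter individually by bounded scalar
    minimization on log10 scale within +/-``bounds_decades`` of its
    starting value; the single parameter giving the lowest objective is
    updated.  ``tolx`` is the absolute tolerance on the log10 coordinate
    and ``tolfun`` a floor below which objective differences are treated as
    converged.  Stops when the relative improvement falls below 1%.

    Returns the fitted parameter dict; ``problem.log`` records
    (iteration, updated name, objective) rows.
    """
    current = dict(problem.free_parameters)
    start_logs = {k: np.log10(v) for k, v in current.items()}
    obj = ssr_sum(problem, current)
    problem.log.append((0, None, obj))
    for it in range(1, max_iterations + 1):
        best: tuple[float, str, float] | None = None
        failures = 0
        for name in current:
            lo = start_logs[name] - problem.bounds_decades
            hi = start_logs[name] + problem.bounds_decades

            def f1d(logv, _name=name):
                trial = dict(current)
                trial[_name] = 10.0 ** logv
                try:
                    return ssr_sum(problem, trial)
                except Exception:
                    return np.inf

            try:
                res = minimize_scalar(f1d, bounds=(lo, hi), method="bounded",
                                      options={"xatol": tolx})
            except Exception:
                failures += 1
                continue
            if not np.isfinite(res.fun):
                failures += 1
                continue
            if best is None or res.fun < best[0]:
                best = (float(res.fun), name, 10.0 ** float(res.x))
        if best is None or failures == len(current):
            raise CalibrationError("all scalar searches failed")
        new_obj, name, value = best
        improvement = obj - new_obj
        if improvement > 0:
            current[name] = value
            obj = new_obj
            problem.log.append((it, name, obj))
        # stop once the improvement falls below 1% of the objective (with a
        # small absolute floor so that near-zero objectives terminate)
        if improvement <= max(rel_improvement * abs(obj), 1e-12):
            break
    return current


def iteration_log_frame(problem: CalibrationProblem):
    """Iteration log as a DataFrame (iteration, parameter, objective)."""
    import pandas as pd

    return pd.DataFrame(problem.log, columns=["iteration", "parameter",
                                              "objective"])


def local_sensitivity(target: Callable[[Mapping[str, float]], float],
                      baseline: Mapping[str, float],
                      deltas: Sequence[float] = (0.01, 0.05, 0.10, 0.20),
                      two_sided: bool = True):
    """One-at-a-time local sensitivity of a scalar target.

    Perturbs each baseline parameter by +/-1, 5, 10 and 20% and reports the
    relative change of the target.  Returns a tidy DataFrame
    (parameter, delta, direction, target, relative_change).
    """
    import pandas as pd

    base_val = float(target(baseline))
    rows = []
    directions = (+1, -1) if two_sided else (+1,)
    for name, v in baseline.items():
        for d in deltas:
            for sign in directions:
                trial = dict(baseline)
                trial[name] = v * (1.0 + sign * d)
                t = float(target(trial))
                rel = (t - base_val) / base_val if base_val != 0 else np.nan
                rows.append({"parameter": name, "delta": d,
                             "direction": "up" if sign > 0 else "down",
                             "target": t, "relative_change": rel})
    out = pd.DataFrame(rows)
    out.attrs["baseline_target"] = base_val
    return out
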