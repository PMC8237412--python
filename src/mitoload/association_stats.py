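"""Correlation between breed age and deleterious fraction.

The headline result of the pipeline is the (negative) correlation between
breed age and the deleterious fraction delta across breeds, assessed on
log10-transformed axes with Pearson's r (p from the t statistic with n-2
degrees of freedom) and cross-checked with Spearman's rank correlation.
Breeds are not phylogenetically independent; this is reported as-is, not
modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ComputationError, InputError

_METHODS = ("pearson", "spearman")
_TRANSFORMS = ("log10", "none")


@dataclass(frozen=True)
class CorrelationResult:
    method: str
    r: float
    p_value: float
    n: int
    transform: str
    slope: float
    intercept: float
    n_dropped: int = 0  # non-positive pairs excluded by the log transform


def pearson_p(r: float, n: int) -> float:
    """Two-sided p for a Pearson r at sample size n, from the t statistic

        t = r * sqrt((n-2) / (1-r^2)),  df = n-2.
    """
    if not -1.0 <= r <= 1.0:
        raise InputError(f"correlation coefficient out of range: {r}")
    if n < 3:
        raise InputError("p-value needs n >= 3")
    if abs(r) == 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return 2.0 * float(stats.t.sf(abs(t), n - 2))


def correlate(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "pearson",
    transform: str = "log10",
) -> CorrelationResult:
    """Correlate two breed-level variables, optionally on log10 axes.

    With ``transform="log10"`` pairs where either value is non-positive are
    dropped and counted (the transform forces it). The least-squares line is
    fitted on the transformed scale regardless of method. Zero variance in
    either variable, or fewer than 3 usable pairs, raises.
    """
    if method not in _METHODS:
        raise InputError(f"unknown method {method!r}; choose from {_METHODS}")
    if transform not in _TRANSFORMS:
        raise InputError(f"unknown transform {transform!r}; choose from {_TRANSFORMS}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be 1-D of equal length")
    n_dropped = 0
    if transform == "log10":
        keep = (x > 0) & (y > 0)
        n_dropped = int((~keep).sum())
        x, y = np.log10(x[keep]), np.log10(y[keep])
    n = x.size
    if n < 3:
        raise InputError(f"need >= 3 usable pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ComputationError("zero variance in x or y; correlation undefined")
    if method == "pearson":
        r = float(np.corrcoef(x, y)[0, 1])
    else:
        r = float(np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1])
    slope, intercept = np.polyfit(x, y, 1)
    return CorrelationResult(
        method=method, r=r, p_value=pearson_p(r, n), n=n,
        transform=transform, slope=float(slope), intercept=float(intercept),
        n_dropped=n_dropped,
    )


def fold_range(values: Sequence[float]) -> float:
    """max/min of positive values — the spread of omega_P across breeds."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InputError("fold range needs at least 2 values")
    if (v <= 0).any():
        raise InputError("fold range requires all values > 0")
    return float(v.max() / v.min())


def correlation_summary(
    ages: Sequence[float], deltas: Sequence[float]
) -> pd.DataFrame:
    """All four method x transform correlations of age vs delta, tidy."""
    rows = []
    for transform in _TRANSFORMS:
        for method in _METHODS:
            res = correlate(ages, deltas, method=method, transform=transform)
            rows.append(
                {
                    "method": res.method, "transform": res.transform,
                    "r": res.r, "p_value": res.p_value, "n": res.n,
                    "slope": res.slope, "intercept": res.intercept,
                    "n_dropped": res.n_dropped,
                }
            )
    return pd.DataFrame(rows)


def scatter_table(
    breeds: Sequence[str], ages: Sequence[float], deltas: Sequence[float]
) -> pd.DataFrame:
    """Per-breed plot-ready table with log10 columns (NaN where non-positive)."""
    ages = np.asarray(ages, dtype=float)
    deltas = np.asarray(deltas, dtype=float)

    def _safe_log10(v: np.ndarray) -> np.ndarray:
        out = np.full(v.shape, np.nan)
        mask = v > 0
        out[mask] = np.log10(v[mask])
        return out

    log_age = _safe_log10(ages)
    log_delta = _safe_log10(deltas)
    return pd.DataFrame(
        {
            "breed": list(breeds), "age_years": ages, "delta": deltas,
            "log10_age": log_age, "log10_delta": log_delta,
        }
    )
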