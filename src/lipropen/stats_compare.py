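"""Pearson comparison of residue-level vectors with jackknife errors.

Propensity vectors (20 amino acid values, possibly with undefined entries)
are compared with each other and with experimental lipophilicity scales
using Pearson's correlation over the common defined types.  The standard
error is the leave-one-type-out jackknife

    sigma^2 = (N + 1) / N * sum_i (C_(-i) - <C>)^2

with N the number of common types; this (N+1)/N prefactor is the published
convention for these tables and is the default here, while the
conventional (N-1)/N jackknife is available via ``factor='conventional'``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CorrelationResult",
    "pearson",
    "jackknife_se",
    "correlate",
    "correlation_with_exclusions",
    "correlation_matrix",
]

MIN_POINTS = 3


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    jackknife_se: float
    n_points: int
    excluded_types: tuple[str, ...] = ()

    def __str__(self) -> str:
        return f"{self.r:.2f} ({self.jackknife_se:.2f})"


def _common(x: Mapping[str, float], y: Mapping[str, float]) -> list[str]:
    keys = [
        k
        for k in x
        if k in y
        and x[k] is not None
        and y[k] is not None
        and not (math.isnan(x[k]) or math.isnan(y[k]))
    ]
    return keys


def _pearson_arrays(xv: np.ndarray, yv: np.ndarray) -> float:
    if len(xv) < MIN_POINTS:
        raise ValueError(f"need at least {MIN_POINTS} common defined values")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(np.corrcoef(xv, yv)[0, 1])


def pearson(x: Mapping[str, float], y: Mapping[str, float]) -> float:
    """Pearson's r over the intersection of defined (non-NaN) types."""
    keys = _common(x, y)
    xv = np.asarray([x[k] for k in keys], dtype=float)
    yv = np.asarray([y[k] for k in keys], dtype=float)
    return _pearson_arrays(xv, yv)


def jackknife_se(
    x: Mapping[str, float],
    y: Mapping[str, float],
    factor: str = "as-printed",
) -> float:
    """Leave-one-type-out jackknife standard error of Pearson's r.

    ``factor='as-printed'`` uses the (N+1)/N prefactor; ``'conventional'``
    uses the textbook (N-1)/N.  Replicates whose leave-one-out subset is
    degenerate (zero variance) are skipped and N reduced accordingly.
    """
    keys = _common(x, y)
    if len(keys) < MIN_POINTS + 1:
        raise ValueError("need at least 4 common values for the jackknife")
    xv = np.asarray([x[k] for k in keys], dtype=float)
    yv = np.asarray([y[k] for k in keys], dtype=float)
    reps = []
    for i in range(len(keys)):
        sel = np.arange(len(keys)) != i
        try:
            reps.append(_pearson_arrays(xv[sel], yv[sel]))
        except ValueError:
            continue
    n = len(reps)
    if n < MIN_POINTS:
        raise ValueError("too many degenerate jackknife replicates")
    reps = np.asarray(reps)
    pref = (n + 1) / n if factor == "as-printed" else (n - 1) / n
    return float(np.sqrt(pref * np.sum((reps - reps.mean()) ** 2)))


def correlate(
    x: Mapping[str, float],
    y: Mapping[str, float],
    factor: str = "as-printed",
) -> CorrelationResult:
    keys = _common(x, y)
    return CorrelationResult(
        pearson(x, y), jackknife_se(x, y, factor), len(keys)
    )


def correlation_with_exclusions(
    x: Mapping[str, float],
    y: Mapping[str, float],
    excluded: Iterable[str],
    factor: str = "as-printed",
) -> CorrelationResult:
    """Correlation after removing named outlier types from both vectors."""
    excluded = tuple(excluded)
    xr = {k: v for k, v in x.items() if k not in excluded}
    yr = {k: v for k, v in y.items() if k not in excluded}
    keys = _common(xr, yr)
    return CorrelationResult(
        pearson(xr, yr), jackknife_se(xr, yr, factor), len(keys), excluded
    )


def correlation_matrix(
    vectors: Mapping[str, Mapping[str, float]],
    factor: str = "as-printed",
) -> pd.DataFrame:
    """Symmetric matrix of "r (se)" strings over a set of labelled vectors
    (propensity columns and lipophilicity scales alike)."""
    labels = list(vectors)
    out = pd.DataFrame("", index=labels, columns=labels)
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if j < i:
                out.loc[a, b] = out.loc[b, a]
            elif i == j:
                out.loc[a, b] = "1.00 (0.00)"
            else:
                out.loc[a, b] = str(correlate(vectors[a], vectors[b], factor))
    out.attrs["jackknife_factor"] = factor
    return out
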