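"""Scale conversions and the two per-protein normalization schemes.

Two normalizations are provided, both operating protein-wise on log2(RFU):

* **iterative scaling** — z-score standardization with outlier handling:
  standardize, flag values more than ``sd_bound`` (default 4) standard
  deviations from the mean, exclude them, re-standardize, repeat until no new
  outliers, then impute flagged values to exactly ±``sd_bound`` in units of
  the final (outlier-excluded) distribution.
* **robust scaling** — (x − median) / IQR, which preserves extreme values.

Both rely on the shared 1.5·IQR outlier machinery: lower = Q1 − m·(Q3 − Q1),
upper = Q3 + m·(Q3 − Q1), with quartiles computed by linear interpolation
between order statistics (configurable, since the thresholds depend on the
quartile convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ProteomicMatrix, Scale

__all__ = [
    "OutlierBounds",
    "IterativeScaleParams",
    "iqr_bounds",
    "log2_transform",
    "zscore_per_protein",
    "iterative_scale",
    "robust_scale",
    "iterative_reference_moments",
]

ZERO_VARIANCE = "zero_variance"
ALL_OUTLIERS = "all_values_flagged"


@dataclass(frozen=True)
class OutlierBounds:
    """Quartile-based outlier thresholds: lower = q1 − m·IQR, upper = q3 + m·IQR."""

    q1: float
    q3: float
    lower: float
    upper: float
    multiplier: float = 1.5

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    def outside(self, values) -> np.ndarray:
        """Boolean mask of values strictly beyond either threshold."""
        v = np.asarray(values, dtype=float)
        return (v < self.lower) | (v > self.upper)


@dataclass(frozen=True)
class IterativeScaleParams:
    """Knobs of iterative scaling: the |z| exclusion bound (default 4 standard
    deviations) and an iteration cap that guarantees termination."""

    sd_bound: float = 4.0
    max_iterations: int = 50
    ddof: int = 1

    def __post_init__(self) -> None:
        if self.sd_bound <= 0:
            raise ValueError("sd_bound must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be a positive integer")


def iqr_bounds(values, multiplier: float = 1.5, method: str = "linear") -> OutlierBounds:
    """Outlier thresholds from the first/third quartiles of ``values``.

    Requires at least 4 finite values so that the quartiles describe an
    actual distribution. ``method`` is the quantile interpolation convention
    (passed to :func:`numpy.percentile`).
    """
    arr = np.asarray(values, dtype=float).ravel()
    arr = arr[np.isfinite(arr)]
    if arr.size < 4:
        raise ValueError(f"iqr_bounds requires ≥4 finite values, got {arr.size}")
    if multiplier < 0:
        raise ValueError("multiplier must be non-negative")
    q1, q3 = np.percentile(arr, [25.0, 75.0], method=method)
    iqr = q3 - q1
    return OutlierBounds(q1=float(q1), q3=float(q3),
                         lower=float(q1 - multiplier * iqr),
                         upper=float(q3 + multiplier * iqr),
                         multiplier=float(multiplier))


def log2_transform(m: ProteomicMatrix) -> ProteomicMatrix:
    """Elementwise log2 of a raw-RFU matrix. RFUs are positive by
    construction, so no pseudocount is applied; a non-positive value is an
    upstream data error and raises (enforced by the matrix invariant)."""
    if m.scale is not Scale.RAW_RFU:
        raise ValueError("log2_transform expects a raw-RFU matrix")
    return m.with_values(np.log2(m.values), scale=Scale.LOG2)


def _column_moments(x: np.ndarray, include: np.ndarray, ddof: int):
    """Mean/sd per column over the included entries only."""
    n = include.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(include, x, 0.0).sum(axis=0)
        mean = s / n
        ss = np.where(include, (x - mean) ** 2, 0.0).sum(axis=0)
        denom = n - ddof
        sd = np.sqrt(np.where(denom > 0, ss / np.maximum(denom, 1), np.nan))
    return mean, sd, n


def zscore_per_protein(m: ProteomicMatrix, ddof: int = 1) -> ProteomicMatrix:
    """Standardize each protein column to mean 0, sd 1 (sample sd by default).

    Zero-variance proteins are set to 0 and flagged ``zero_variance`` rather
    than erroring: assay panels routinely contain saturated or dead analytes
    and the pipeline must proceed.
    """
    if m.scale is not Scale.LOG2:
        raise ValueError("zscore_per_protein expects a log2 matrix")
    if m.n_samples < 2:
        raise ValueError("zscore_per_protein requires ≥2 samples")
    x = m.values.to_numpy(dtype=float)
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=ddof)
    degenerate = (sd == 0) | ~np.isfinite(sd)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mean) / sd
    z[:, degenerate] = 0.0
    flags = {m.protein_ids[j]: ZERO_VARIANCE for j in np.flatnonzero(degenerate)}
    out = pd.DataFrame(z, index=m.values.index, columns=m.values.columns)
    return m.with_values(out, extra_flags=flags)


def _iterative_moments(x: np.ndarray, params: IterativeScaleParams):
    """Run the exclusion loop of iterative scaling on a (samples × proteins)
    array. Returns (mean, sd, outlier_mask, degenerate_mask) where mean/sd
    describe the final outlier-excluded ("modified") distribution per column.

    The excluded set grows monotonically, so the loop terminates in at most
    n_samples iterations; ``max_iterations`` is a hard cap on top of that.
    """
    x = np.asarray(x, dtype=float)
    include = np.ones_like(x, dtype=bool)
    degenerate = np.zeros(x.shape[1], dtype=bool)
    mean = np.zeros(x.shape[1])
    sd = np.ones(x.shape[1])
    for _ in range(params.max_iterations):
        mean, sd, n = _column_moments(x, include, params.ddof)
        bad = (n <= params.ddof + 1) | (sd == 0) | ~np.isfinite(sd)
        newly_degenerate = bad & ~degenerate
        if newly_degenerate.any():
            degenerate |= newly_degenerate
            include[:, newly_degenerate] = False
            sd = np.where(degenerate, 1.0, sd)
            mean = np.where(degenerate, 0.0, mean)
        with np.errstate(invalid="ignore"):
            z = (x - mean) / sd
        new_outliers = include & (np.abs(z) > params.sd_bound)
        new_outliers[:, degenerate] = False
        if not new_outliers.any():
            break
        include &= ~new_outliers
    outliers = ~include
    outliers[:, degenerate] = False
    mean = np.where(degenerate, np.nan, mean)
    sd = np.where(degenerate, np.nan, sd)
    return mean, sd, outliers, degenerate


def iterative_scale(m: ProteomicMatrix,
                    params: IterativeScaleParams | None = None) -> ProteomicMatrix:
    """Iterative scaling: per-protein z-scores of the outlier-excluded
    distribution, with outliers imputed to exactly ±``sd_bound``.

    When no value exceeds the bound this is identical to
    :func:`zscore_per_protein`. Pathological columns where every value ends up
    excluded (or the variance collapses) are returned as zeros and flagged.
    """
    params = params or IterativeScaleParams()
    if m.scale is not Scale.LOG2:
        raise ValueError("iterative_scale expects a log2 matrix")
    if m.n_samples < 3:
        raise ValueError("iterative_scale requires ≥3 samples")
    x = m.values.to_numpy(dtype=float)
    mean, sd, outliers, degenerate = _iterative_moments(x, params)
    with np.errstate(invalid="ignore"):
        z = (x - mean) / sd
    # impute: above the final mean → +sd_bound, below → −sd_bound
    z = np.where(outliers, np.sign(x - mean) * params.sd_bound, z)
    z[:, degenerate] = 0.0
    flags = {}
    for j in np.flatnonzero(degenerate):
        flags[m.protein_ids[j]] = ALL_OUTLIERS
    out = pd.DataFrame(z, index=m.values.index, columns=m.values.columns)
    return m.with_values(out, extra_flags=flags)


def iterative_reference_moments(reference: ProteomicMatrix,
                                params: IterativeScaleParams | None = None):
    """Fit iterative-scaling parameters (final mean/sd per protein) on a
    reference matrix, for standardizing other samples against it.

    Returns (mean, sd, degenerate) as pandas Series indexed by protein.
    """
    params = params or IterativeScaleParams()
    if reference.scale is not Scale.LOG2:
        raise ValueError("iterative_reference_moments expects a log2 matrix")
    x = reference.values.to_numpy(dtype=float)
    mean, sd, _, degenerate = _iterative_moments(x, params)
    idx = reference.values.columns
    return (pd.Series(mean, index=idx), pd.Series(sd, index=idx),
            pd.Series(degenerate, index=idx))


def robust_scale(m: ProteomicMatrix, method: str = "linear") -> ProteomicMatrix:
    """Robust scaling: (x − median) / IQR per protein; extreme values are
    preserved rather than imputed. Zero-IQR proteins are zeroed and flagged."""
    if m.scale is not Scale.LOG2:
        raise ValueError("robust_scale expects a log2 matrix")
    if m.n_samples < 4:
        raise ValueError("robust_scale requires ≥4 samples")
    x = m.values.to_numpy(dtype=float)
    med = np.percentile(x, 50.0, axis=0, method=method)
    q1, q3 = np.percentile(x, [25.0, 75.0], axis=0, method=method)
    iqr = q3 - q1
    degenerate = iqr == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (x - med) / iqr
    out[:, degenerate] = 0.0
    flags = {m.protein_ids[j]: ZERO_VARIANCE for j in np.flatnonzero(degenerate)}
    df = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return m.with_values(df, extra_flags=flags)
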