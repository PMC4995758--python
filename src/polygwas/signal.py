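"""Allele-signal transformation: quantile normalization, theta/s, filters.

The continuous genotype value of a bi-allelic probe is the log2 contrast of
its two allele signals, ``theta = log2(B) - log2(A)``, with signal strength
``s = (log2(A) + log2(B)) / 2``.  Probes whose theta range across samples is
below 2 do not segregate and are removed before association; the retained
theta rows are mean-centered to serve as regression covariates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "quantile_normalize",
    "compute_theta_s",
    "compute_theta_multiallelic",
    "filter_by_theta_range",
    "mean_center",
]


def quantile_normalize(intensities: pd.DataFrame) -> pd.DataFrame:
    """Force every sample column onto the mean order-statistic distribution.

    After normalization each column holds the identical multiset of values
    (the across-sample mean of the k-th smallest values), assigned by the
    column's own ranks; ties receive the average of the values their tied
    ranks would get.  A single-column matrix is returned unchanged.
    """
    if intensities.shape[1] <= 1:
        return intensities.copy()
    x = intensities.to_numpy(dtype=np.float64)
    if np.isnan(x).any():
        raise ValueError("quantile normalization requires complete columns")
    order = np.argsort(x, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(x, order, axis=0)
    mean_quantiles = sorted_vals.mean(axis=1)

    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        # average ranks over ties -> average of the tied mean quantiles
        _, inv, counts = np.unique(col, return_inverse=True, return_counts=True)
        # per-rank assignment, then group-average duplicates
        assigned = np.empty_like(col)
        assigned[order[:, j]] = mean_quantiles
        sums = np.bincount(inv, weights=assigned)
        assigned = sums[inv] / counts[inv]
        out[:, j] = assigned
    return pd.DataFrame(out, index=intensities.index, columns=intensities.columns)


def compute_theta_s(
    a: pd.DataFrame, b: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Elementwise ``theta = log2(B) - log2(A)`` and ``s = (log2 A + log2 B)/2``.

    Missing entries propagate as missing; non-positive observed signals are
    an error (log domain) reported with probe and sample.
    """
    if a.shape != b.shape or not a.index.equals(b.index) or not a.columns.equals(b.columns):
        raise ValueError("A and B matrices must share probes and samples")
    av = a.to_numpy(dtype=np.float64)
    bv = b.to_numpy(dtype=np.float64)
    for name, v in (("A", av), ("B", bv)):
        bad = (v <= 0) & ~np.isnan(v)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-positive {name} signal at probe {a.index[i]!r}, "
                f"sample {a.columns[j]!r}"
            )
    la, lb = np.log2(av), np.log2(bv)
    theta = pd.DataFrame(lb - la, index=a.index, columns=a.columns)
    s = pd.DataFrame((la + lb) / 2.0, index=a.index, columns=a.columns)
    return theta, s


def compute_theta_multiallelic(counts, i: int) -> float:
    """Multi-allelic extension: ``theta_i = log2(G_i) - sum_{j!=i} log2(G_j)``.

    ``counts`` are the four allele read counts / signals ``G_1..G_4``; ``i``
    is the 1-based target allele.  With only two alleles present and the sum
    restricted to them this reduces to the bi-allelic log-ratio.  Note the
    value scales with total depth through the summed log terms; this is the
    transformation as defined, not corrected for depth.
    """
    g = np.asarray(counts, dtype=float)
    if g.ndim != 1 or len(g) != 4:
        raise ValueError("expected exactly four allele counts")
    if not 1 <= i <= 4:
        raise ValueError("target allele index must be 1..4")
    if (g <= 0).any():
        raise ValueError("zero or negative allele count: log undefined")
    lg = np.log2(g)
    return float(lg[i - 1] - (lg.sum() - lg[i - 1]))


def filter_by_theta_range(
    theta: pd.DataFrame, min_range: float = 2.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop probes whose observed theta range is below ``min_range``.

    Returns the retained matrix and a report with every probe's range and
    retention flag.  Ranges use the probe's non-missing samples.
    """
    x = theta.to_numpy(dtype=np.float64)
    if x.shape[1] < 1:
        raise ValueError("need at least one sample")
    rng_ = np.nanmax(x, axis=1) - np.nanmin(x, axis=1)
    retained = rng_ >= min_range
    report = pd.DataFrame(
        {"theta_range": rng_, "retained": retained}, index=theta.index
    )
    return theta.loc[retained], report


def mean_center(theta: pd.DataFrame) -> pd.DataFrame:
    """Subtract each probe's mean over non-missing samples (idempotent)."""
    x = theta.to_numpy(dtype=np.float64)
    with np.errstate(invalid="ignore"):
        centered = x - np.nanmean(x, axis=1, keepdims=True)
    return pd.DataFrame(centered, index=theta.index, columns=theta.columns)
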