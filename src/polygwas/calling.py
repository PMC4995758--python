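"""Naive genotype-class caller and continuous-vs-class comparison.

The caller assigns each sample the dosage whose theta cluster center is
nearest, the assumption being ``ploidy + 1`` classes spread over a fixed
theta span (clusters near -2, 0, +2 in a diploid, and proportionally closer
together at higher ploidy).  Two center modes are provided: a global fixed
grid equally spaced on [-2, 2], and an adaptive per-probe grid equally
spaced over the probe's central 95% theta span (clamped to [-2, 2]), which
is the fairer comparator when cluster positions drift.  Every sample is
assigned a class — there is no outlier category — deliberately mirroring
the behavior of the callers this comparator stands in for.

The comparison runs the same linear scan on continuous genotypes and on
class-derived covariates (the difference between first- and second-allele
counts, an affine function of dosage) and tabulates per-probe agreement of
the significance calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CallResult", "call_nearest_cluster", "compare_associations"]


@dataclass
class CallResult:
    """Nearest-center dosage calls and derived association covariates."""

    dosage: pd.DataFrame  # probes x samples, integer calls in [0, ploidy]
    covariate: pd.DataFrame  # (ploidy - dosage) - dosage, per probe/sample
    confidence: pd.DataFrame  # |theta - nearest center|
    ploidy: int


def _default_centers(ploidy: int, span: tuple[float, float] = (-2.0, 2.0)) -> np.ndarray:
    return np.linspace(span[0], span[1], ploidy + 1)


def call_nearest_cluster(
    theta: pd.DataFrame,
    ploidy: int = 6,
    centers: np.ndarray | None = None,
    mode: str = "fixed",
) -> CallResult:
    """Assign every sample the dosage of its nearest theta cluster center.

    ``mode="fixed"`` uses one center grid for all probes (``centers`` or the
    default equally spaced grid on [-2, 2]); ``mode="adaptive"`` spaces the
    grid over each probe's central 95% theta span, clamped to [-2, 2].
    Ties between two centers go to the lower dosage.
    """
    x = theta.to_numpy(dtype=np.float64)
    n_probes, n_samples = x.shape
    if mode not in ("fixed", "adaptive"):
        raise ValueError("mode must be 'fixed' or 'adaptive'")
    if centers is not None:
        centers = np.asarray(centers, dtype=float)
        if len(centers) != ploidy + 1:
            raise ValueError("need ploidy + 1 centers")
        if not np.all(np.diff(centers) > 0):
            raise ValueError("centers must be strictly increasing")
        grid = np.broadcast_to(centers, (n_probes, ploidy + 1))
    elif mode == "fixed":
        grid = np.broadcast_to(_default_centers(ploidy), (n_probes, ploidy + 1))
    else:
        lo = np.clip(np.nanquantile(x, 0.025, axis=1), -2.0, 2.0)
        hi = np.clip(np.nanquantile(x, 0.975, axis=1), -2.0, 2.0)
        degenerate = hi - lo < 1e-9
        lo = np.where(degenerate, -2.0, lo)
        hi = np.where(degenerate, 2.0, hi)
        grid = lo[:, None] + (hi - lo)[:, None] * np.linspace(0, 1, ploidy + 1)

    # distance to each center; argmin returns the first (lower-dosage) tie.
    # chunked over probes to keep the (probes, samples, classes) cube small
    calls = np.empty((n_probes, n_samples), dtype=np.int64)
    conf = np.empty((n_probes, n_samples))
    step = max(1, 4_000_000 // max(n_samples * (ploidy + 1), 1))
    for start in range(0, n_probes, step):
        stop = min(start + step, n_probes)
        dist = np.abs(x[start:stop, :, None] - grid[start:stop, None, :])
        calls[start:stop] = np.argmin(dist, axis=2)
        conf[start:stop] = np.min(dist, axis=2)
    calls = np.where(np.isnan(x), -1, calls)

    dosage = pd.DataFrame(calls.astype(np.int16), index=theta.index,
                          columns=theta.columns)
    cov = (ploidy - dosage) - dosage
    cov = cov.where(dosage >= 0)
    confidence = pd.DataFrame(conf, index=theta.index, columns=theta.columns)
    return CallResult(dosage=dosage, covariate=cov.astype(float),
                      confidence=confidence, ploidy=ploidy)


def compare_associations(
    continuous: pd.DataFrame, classed: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Pair two linear-scan results probe by probe.

    Both inputs are scan tables (as produced by
    :func:`polygwas.linear.genome_scan_lr`) over the same probes and the
    same response.  Returns a per-probe table of paired p/q values with an
    agreement label (``both`` / ``continuous_only`` / ``class_only`` /
    ``neither``) and the summary counts.
    """
    if not continuous.index.equals(classed.index):
        diff = continuous.index.symmetric_difference(classed.index)
        raise ValueError(
            f"probe sets differ between the two scans ({len(diff)} probes, "
            f"e.g. {diff[:5].tolist()})"
        )
    cont_sig = continuous["significant"].to_numpy(dtype=bool)
    class_sig = classed["significant"].to_numpy(dtype=bool)
    label = np.select(
        [cont_sig & class_sig, cont_sig & ~class_sig, ~cont_sig & class_sig],
        ["both", "continuous_only", "class_only"],
        default="neither",
    )
    table = pd.DataFrame(
        {
            "p_continuous": continuous["p"],
            "q_continuous": continuous["q"],
            "p_class": classed["p"],
            "q_class": classed["q"],
            "agreement": label,
        },
        index=continuous.index,
    )
    counts = table["agreement"].value_counts().reindex(
        ["both", "continuous_only", "class_only", "neither"], fill_value=0
    )
    return table, counts
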