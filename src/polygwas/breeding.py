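"""REML mixed model for repeated measurements and deregressed breeding values.

The phenotype model is a random-intercept mixed model

    y = alpha + block + plate + g + e,     g ~ N(0, s2_g),  e ~ N(0, s2_e),

fitted by restricted maximum likelihood.  The restricted log-likelihood is
profiled down to the single variance ratio gamma = s2_g / s2_e, which is
optimized by bounded scalar search on the log scale; all matrix quantities
reduce to per-sample group sums, so a fit costs O(records) per likelihood
evaluation.  BLUPs of g and their prediction error variances (PEV) come
from the mixed-model equations at the REML estimates.

Deregression divides each EBV by its reliability r2 = 1 - PEV / s2_g,
undoing BLUP shrinkage so the deregressed values are suitable responses for
genome-wide association.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = ["MixedModelFit", "BreedingValueSet", "fit_mixed_model", "deregress"]


@dataclass(frozen=True)
class MixedModelFit:
    """REML fit of the random-intercept model."""

    sigma2_g: float
    sigma2_e: float
    fixed_effects: pd.Series  # intercept + reference-coded block/plate effects
    ebv: pd.Series  # BLUP of g per sample
    pev: pd.Series  # prediction error variance per sample
    n_records: int
    log_reml: float

    @property
    def heritability(self) -> float:
        """Intra-class correlation s2_g / (s2_g + s2_e) at the record level."""
        tot = self.sigma2_g + self.sigma2_e
        return self.sigma2_g / tot if tot > 0 else 0.0


@dataclass(frozen=True)
class BreedingValueSet:
    """Per-sample EBV, PEV, reliability and deregressed EBV."""

    table: pd.DataFrame  # columns: ebv, pev, r2, debv

    @property
    def debv(self) -> pd.Series:
        return self.table["debv"]


def _design(records: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list, list]:
    """Fixed-effect design (reference coding) and sample index per record."""
    for col in ("sample_id", "value"):
        if col not in records.columns:
            raise ValueError(f"records need a {col!r} column")
    n = len(records)
    parts = [np.ones((n, 1))]
    names = ["intercept"]
    for factor in ("block", "plate"):
        if factor in records.columns:
            levels = pd.unique(records[factor])
            if len(levels) > 1:
                d = pd.get_dummies(
                    pd.Categorical(records[factor], categories=levels),
                    drop_first=True, dtype=float,
                )
                parts.append(d.to_numpy())
                names.extend(f"{factor}[{lv}]" for lv in levels[1:])
    x = np.hstack(parts)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError(
            "fixed-effect design is rank deficient (confounded block/plate levels)"
        )
    samples = pd.unique(records["sample_id"])
    sidx = pd.Categorical(records["sample_id"], categories=samples).codes
    return x, np.asarray(sidx), list(samples), names


def _profile_reml(log_gamma, y, x, sidx, q):
    """-2 restricted log-likelihood (up to a constant) profiled over s2_e."""
    gamma = np.exp(log_gamma)
    n, p = x.shape
    counts = np.bincount(sidx, minlength=q).astype(float)
    d = gamma / (1.0 + gamma * counts)  # W^{-1} = I - Z diag(d) Z'

    zty = np.bincount(sidx, weights=y, minlength=q)
    ztx = np.vstack([np.bincount(sidx, weights=x[:, j], minlength=q)
                     for j in range(p)]).T  # (q, p)

    xtwx = x.T @ x - ztx.T @ (d[:, None] * ztx)
    xtwy = x.T @ y - ztx.T @ (d * zty)
    ytwy = y @ y - zty @ (d * zty)

    beta = np.linalg.solve(xtwx, xtwy)
    rss = ytwy - beta @ xtwy
    rss = max(rss, 1e-300)
    sigma2_e = rss / (n - p)
    logdet_w = np.sum(np.log1p(gamma * counts))
    sign, logdet_xtwx = np.linalg.slogdet(xtwx)
    if sign <= 0:
        return np.inf, None
    neg2 = (n - p) * np.log(sigma2_e) + logdet_w + logdet_xtwx
    return neg2, (beta, sigma2_e, gamma)


def fit_mixed_model(records: pd.DataFrame, max_log_gamma: float = 25.0) -> MixedModelFit:
    """Fit the random-intercept mixed model by REML.

    ``records`` is long format with columns ``sample_id``, ``value`` and
    optional ``block`` / ``plate`` factors.  Variance components are
    constrained non-negative; a boundary solution s2_g = 0 is returned when
    the between-sample variance vanishes.
    """
    x, sidx, samples, names = _design(records)
    y = records["value"].to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite phenotype values")
    n, p = x.shape
    q = len(samples)
    if q < 2:
        raise ValueError("need at least two samples")
    if n - p < 1:
        raise ValueError("not enough records for the fixed-effect design")

    obj = lambda lg: _profile_reml(lg, y, x, sidx, q)[0]
    res = minimize_scalar(
        obj, bounds=(-max_log_gamma, max_log_gamma), method="bounded",
        options={"xatol": 1e-12, "maxiter": 500},
    )
    if not np.isfinite(res.fun):
        raise RuntimeError(f"REML optimization failed: {res}")
    # compare against the s2_g -> 0 boundary
    boundary = _profile_reml(-max_log_gamma, y, x, sidx, q)[0]
    log_gamma = -max_log_gamma if boundary < res.fun else res.x
    neg2, (beta, sigma2_e, gamma) = _profile_reml(log_gamma, y, x, sidx, q)
    if log_gamma <= -max_log_gamma + 1e-9:
        gamma = 0.0
    sigma2_g = gamma * sigma2_e

    # BLUP at the REML estimates; PEV with fixed effects taken as known:
    # PEV_i = Var(g_i - ebv_i) = s2_g / (1 + gamma * n_i), which lies in
    # (0, s2_g), vanishes as the residual noise does, and satisfies
    # Var(ebv_i) = s2_g - PEV_i (the reliability * s2_g identity behind
    # using EBV variances as the PEV measure)
    counts = np.bincount(sidx, minlength=q).astype(float)
    resid = y - x @ beta
    ztr = np.bincount(sidx, weights=resid, minlength=q)
    if gamma > 0:
        ebv = gamma * ztr / (1.0 + gamma * counts)
        pev = sigma2_g / (1.0 + gamma * counts)
    else:
        ebv = np.zeros(q)
        pev = np.zeros(q)

    return MixedModelFit(
        sigma2_g=float(sigma2_g),
        sigma2_e=float(sigma2_e),
        fixed_effects=pd.Series(beta, index=names),
        ebv=pd.Series(ebv, index=samples, name="ebv"),
        pev=pd.Series(pev, index=samples, name="pev"),
        n_records=n,
        log_reml=float(-0.5 * neg2),
    )


def deregress(fit: MixedModelFit) -> BreedingValueSet:
    """Deregress EBVs: ``debv_i = ebv_i / r2_i`` with ``r2_i = 1 - PEV_i/s2_g``.

    Requires s2_g > 0 and PEV_i < s2_g for every sample; otherwise the
    reliability is non-positive and deregression is undefined.
    """
    if fit.sigma2_g <= 0:
        raise ValueError("deregression requires positive additive genetic variance")
    r2 = 1.0 - fit.pev / fit.sigma2_g
    if (r2 <= 0).any():
        bad = r2.index[r2 <= 0][:5].tolist()
        raise ValueError(
            f"PEV >= sigma2_g for sample(s) {bad}: reliability <= 0, "
            "deregression undefined"
        )
    table = pd.DataFrame(
        {"ebv": fit.ebv, "pev": fit.pev, "r2": r2, "debv": fit.ebv / r2}
    )
    table.index.name = "sample_id"
    return BreedingValueSet(table)
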