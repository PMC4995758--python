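"""Per-probe linear regression scan with Storey q-values.

Each probe is tested with the simple regression ``Y_i = alpha + beta x_i +
eps_i`` of the (deregressed) breeding values on the mean-centered continuous
genotype.  The whole scan is vectorized through masked cross-products, so
probes with missing samples are handled pairwise-complete without a Python
loop.  Multiple testing is controlled by transforming p-values to q-values
(Storey's pi0-adaptive step-up procedure); probes with q <= 0.01 are flagged
significant, and the F >= 4 prefilter feeding the PLS engine is provided
here as well.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "genome_scan_lr",
    "compute_qvalues",
    "estimate_pi0",
    "prefilter_by_f",
]

_VAR_EPS = 1e-12


def genome_scan_lr(
    x: pd.DataFrame,
    y: pd.Series,
    q_threshold: float = 0.01,
) -> pd.DataFrame:
    """OLS scan of ``y`` on each probe row of ``x``.

    Parameters
    ----------
    x : probes x samples matrix of (centered) continuous genotypes; may
        contain missing values, which are dropped per probe.
    y : response indexed by sample (DEBVs or simulated phenotypes).

    Returns
    -------
    DataFrame indexed by probe with columns ``beta``, ``se``, ``t``, ``F``,
    ``p``, ``r2``, ``n``, ``degenerate``, ``q``, ``significant``.  Probes
    with (near-)zero genotype variance are reported with ``p = 1`` and
    ``degenerate = True`` and are excluded from the q-value computation.
    """
    common = x.columns.intersection(y.index)
    if len(common) != x.shape[1] or len(common) != len(y):
        raise ValueError("sample mismatch between genotype matrix and response")
    xv = x.loc[:, common].to_numpy(dtype=np.float64)
    yv = y.loc[common].to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(yv)):
        raise ValueError("non-finite response values")

    mask = np.isfinite(xv)
    xz = np.where(mask, xv, 0.0)
    n = mask.sum(axis=1).astype(np.float64)
    if (n < 3).any():
        raise ValueError("every probe needs at least 3 complete (x, y) pairs")

    sx = xz.sum(axis=1)
    sy = mask @ yv
    sxx = (xz * xz).sum(axis=1)
    sxy = xz @ yv
    syy = mask @ (yv * yv)

    ssx = sxx - sx * sx / n
    ssy = syy - sy * sy / n
    sxy_c = sxy - sx * sy / n

    degenerate = ssx <= _VAR_EPS * np.maximum(sxx, 1.0)
    ssx_safe = np.where(degenerate, 1.0, ssx)
    beta = sxy_c / ssx_safe
    rss = np.maximum(ssy - beta * sxy_c, 0.0)
    df = n - 2
    sigma2 = rss / df
    se = np.sqrt(sigma2 / ssx_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
        r2 = np.where(ssy > 0, 1.0 - rss / ssy, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    beta = np.where(degenerate, 0.0, beta)
    se = np.where(degenerate, np.nan, se)
    t = np.where(degenerate, 0.0, t)
    r2 = np.where(degenerate, 0.0, r2)
    p = np.where(degenerate, 1.0, p)

    result = pd.DataFrame(
        {
            "beta": beta,
            "se": se,
            "t": t,
            "F": t * t,
            "p": np.clip(p, 0.0, 1.0),
            "r2": np.clip(r2, 0.0, 1.0),
            "n": n.astype(int),
            "degenerate": degenerate,
        },
        index=x.index,
    )
    q = np.full(len(result), np.nan)
    tested = ~degenerate
    if tested.any():
        q[tested] = compute_qvalues(result.loc[tested, "p"].to_numpy())[0]
    result["q"] = q
    result["significant"] = tested & (result["q"] <= q_threshold)
    return result


def estimate_pi0(p: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Storey's smoother estimate of the null proportion pi0.

    ``pi0(lambda) = #{p > lambda} / (m (1 - lambda))`` is computed on a
    lambda grid (default 0.05..0.90 step 0.05), a cubic polynomial is fit to
    the spectrum and extrapolated to lambda -> 1, and the result is clamped
    to (0, 1].  With fewer than 100 p-values the estimate is unstable and
    pi0 = 1 (the Benjamini-Hochberg limit) is returned.
    """
    p = np.asarray(p, dtype=float)
    m = len(p)
    if m < 100:
        return 1.0
    if lambdas is None:
        lambdas = np.arange(0.05, 0.9001, 0.05)
    pi0_lambda = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    coefs = np.polyfit(lambdas, pi0_lambda, deg=3)
    pi0 = float(np.polyval(coefs, 1.0))
    return float(min(max(pi0, 1.0 / m), 1.0))


def compute_qvalues(
    p: np.ndarray, pi0: float | None = None
) -> tuple[np.ndarray, float]:
    """q-values: ``q_(i) = pi0 * min_{j >= i} m p_(j) / j`` in p order.

    Returns the q-values (aligned with the input order) and the pi0 used.
    With ``pi0`` forced to 1 this is exactly Benjamini-Hochberg.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p)
    if not 0 < pi0 <= 1:
        raise ValueError("pi0 must be in (0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(pi0 * q_sorted, 1.0)
    return q, float(pi0)


def prefilter_by_f(result: pd.DataFrame, f_min: float = 4.0) -> pd.Index:
    """Probes whose scan F-statistic is at least ``f_min``, in input order."""
    if "F" not in result.columns:
        raise ValueError("scan result lacks an F column")
    keep = result["F"].to_numpy() >= f_min
    return result.index[keep]
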