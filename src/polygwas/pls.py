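"""Partial least squares association on the F-prefiltered probe subset.

The protocol follows the three-step design used for multivariate
association: (1) a seeded 80/20 calibration/test split, (2) latent-variable
(LV) selection on the calibration set by 10-fold cross-validation repeated
20 times over 1-10 LVs, choosing the count with the lowest mean RMSE, and
(3) a final fit at the chosen LV count with per-probe variable importance
(VIM) scores; probes with VIM >= 2 form the significant set.

The PLS core is the orthogonal-scores (NIPALS) algorithm for a univariate
response as implemented in scikit-learn; per-component regression
coefficient increments and explained-variance weights are recovered from
the fitted weights/loadings so importance scores and incremental
cross-validation predictions need only one fit per fold.

VIM is the explained-variance-weighted sum of absolute per-component
regression-coefficient increments, rescaled so its mean square over probes
is 1 (the same calibration as VIP, whose formula is available via
``score="vip"``); on that scale the conventional threshold of 2 marks
probes four times as important as the average.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import RepeatedKFold

__all__ = [
    "PLSConfig",
    "PLSModel",
    "PLSResult",
    "rmse",
    "fit_pls",
    "select_lv_by_cv",
    "compute_vim",
    "run_plsr_association",
]


@dataclass(frozen=True)
class PLSConfig:
    """Cross-validation protocol for PLS association."""

    calibration_fraction: float = 0.8
    folds: int = 10
    repeats: int = 20
    lv_grid: tuple[int, ...] = tuple(range(1, 11))
    vim_threshold: float = 2.0
    scale: bool = True
    score: str = "vim"  # "vim" (weighted |coefficient| sums) or "vip"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.calibration_fraction < 1.0:
            raise ValueError("calibration_fraction must be in (0, 1)")
        if self.score not in ("vim", "vip"):
            raise ValueError("score must be 'vim' or 'vip'")
        if min(self.lv_grid) < 1:
            raise ValueError("LV grid entries must be >= 1")


@dataclass
class PLSModel:
    """Fitted univariate-response PLS model with per-component detail."""

    estimator: PLSRegression = field(repr=False)
    n_lv: int
    probe_ids: pd.Index
    coef_increments: np.ndarray = field(repr=False)  # (p, H) standardized space
    variance_weights: np.ndarray  # fraction of y variance per component
    x_mean: np.ndarray = field(repr=False)
    x_std: np.ndarray = field(repr=False)
    y_mean: float

    def predict(self, x: pd.DataFrame, n_lv: int | None = None) -> np.ndarray:
        """Predict the response, optionally truncated to fewer components."""
        h = self.n_lv if n_lv is None else n_lv
        if not 1 <= h <= self.n_lv:
            raise ValueError("n_lv out of fitted range")
        xs = (x.loc[self.probe_ids].to_numpy(dtype=float).T - self.x_mean) / self.x_std
        beta = self.coef_increments[:, :h].sum(axis=1)
        return self.y_mean + xs @ beta

    def coefficients(self, n_lv: int | None = None) -> np.ndarray:
        """Regression coefficients on the original (unstandardized) X scale."""
        h = self.n_lv if n_lv is None else n_lv
        return self.coef_increments[:, :h].sum(axis=1) / self.x_std


@dataclass
class PLSResult:
    """Outcome of the three-step PLS association."""

    chosen_lv: int
    cv_table: pd.DataFrame  # n_lv, mean_rmse, sd_rmse
    vim: pd.Series
    significant: pd.Index
    test_rmse: float
    model: PLSModel = field(repr=False)
    calibration_samples: list = field(repr=False, default_factory=list)
    test_samples: list = field(repr=False, default_factory=list)


def rmse(observed, predicted) -> float:
    """Root mean squared error ``sqrt(mean((obs - pred)^2))``."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted lengths differ")
    if obs.size == 0:
        raise ValueError("need at least one value")
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def fit_pls(x: pd.DataFrame, y: pd.Series, n_lv: int, scale: bool = True) -> PLSModel:
    """Fit orthogonal-scores PLS of ``y`` on the probes-x-samples matrix.

    ``n_lv`` sequential components are extracted, each maximizing the
    covariance between an X-score and the (deflated) response.  Raises when
    ``n_lv`` exceeds what the data can support.
    """
    common = x.columns.intersection(y.index)
    if len(common) != x.shape[1] or len(common) != len(y):
        raise ValueError("sample mismatch between genotype matrix and response")
    xv = x.loc[:, common].to_numpy(dtype=float).T  # samples x probes
    yv = y.loc[common].to_numpy(dtype=float)
    n, p = xv.shape
    max_lv = min(n - 1, p)
    if not 1 <= n_lv <= max_lv:
        raise ValueError(f"n_lv must be in [1, {max_lv}] for this matrix")
    if n_lv > np.linalg.matrix_rank(xv - xv.mean(axis=0)):
        raise ValueError("n_lv exceeds the rank of the centered genotype matrix")

    est = PLSRegression(n_components=n_lv, scale=scale)
    est.fit(xv, yv)

    # per-component coefficient increments in standardized-X space:
    # B^(h) = R[:, :h] @ q[:h] with R the x rotations, q the y loadings
    rot = est.x_rotations_  # (p, H)
    q = est.y_loadings_.ravel()  # (H,)
    incr = rot * q[None, :]

    # fraction of response variance captured by each (orthogonal) score
    t = est.x_scores_  # (n, H)
    y_c = yv - yv.mean()
    ss_tot = float(y_c @ y_c)
    tt = (t * t).sum(axis=0)
    ty = t.T @ y_c
    with np.errstate(invalid="ignore", divide="ignore"):
        ss_h = np.where(tt > 0, ty * ty / tt, 0.0)
    weights = ss_h / ss_tot if ss_tot > 0 else np.zeros_like(ss_h)

    # map increments from scaled-y space back to the raw response scale
    y_std = float(np.atleast_1d(est._y_std)[0])
    return PLSModel(
        estimator=est,
        n_lv=n_lv,
        probe_ids=x.index,
        coef_increments=incr * y_std,
        variance_weights=weights,
        x_mean=np.asarray(est._x_mean, dtype=float),
        x_std=np.asarray(est._x_std, dtype=float),
        y_mean=float(yv.mean()),
    )


def select_lv_by_cv(
    x: pd.DataFrame, y: pd.Series, config: PLSConfig | None = None
) -> tuple[int, pd.DataFrame]:
    """Repeated k-fold CV over the LV grid; lowest mean RMSE wins.

    Returns the chosen component count (ties broken toward fewer
    components) and the CV table of per-LV mean and sd of the fold RMSEs.
    """
    config = config or PLSConfig()
    common = x.columns.intersection(y.index)
    samples = np.asarray(common)
    n = len(samples)
    if config.folds > n or n - n // config.folds < 2:
        raise ValueError("cross-validation folds would leave < 2 training samples")
    max_lv = max(config.lv_grid)
    rkf = RepeatedKFold(
        n_splits=config.folds, n_repeats=config.repeats, random_state=config.seed
    )
    grid = sorted(config.lv_grid)
    errs: dict[int, list[float]] = {h: [] for h in grid}
    for train_idx, test_idx in rkf.split(samples):
        tr, te = samples[train_idx], samples[test_idx]
        cap = min(max_lv, len(tr) - 1, x.shape[0])
        model = fit_pls(x.loc[:, tr], y.loc[tr], cap, scale=config.scale)
        for h in grid:
            pred = model.predict(x.loc[:, te], n_lv=min(h, cap))
            errs[h].append(rmse(y.loc[te].to_numpy(), pred))
    table = pd.DataFrame(
        {
            "n_lv": grid,
            "mean_rmse": [float(np.mean(errs[h])) for h in grid],
            "sd_rmse": [float(np.std(errs[h], ddof=1)) for h in grid],
        }
    )
    chosen = int(table.loc[table["mean_rmse"].idxmin(), "n_lv"])
    return chosen, table


def compute_vim(model: PLSModel, score: str = "vim") -> pd.Series:
    """Variable importance per probe.

    ``score="vim"``: weighted sum over components of the absolute
    standardized-coefficient increment, with weights the fraction of
    response variance each component explains, rescaled so the mean square
    over probes is 1.  ``score="vip"``: the classical variable importance
    in projection, ``sqrt(p * sum_h w_h (w_jh/||w_h||)^2 / sum_h w_h)``.
    """
    w = model.variance_weights[: model.n_lv]
    if score == "vim":
        raw = np.abs(model.coef_increments[:, : model.n_lv]) @ w
        p = len(raw)
        denom = np.sqrt(np.mean(raw**2))
        scores = raw / denom if denom > 0 else raw
    elif score == "vip":
        wmat = model.estimator.x_weights_[:, : model.n_lv]
        wnorm = wmat / np.linalg.norm(wmat, axis=0, keepdims=True)
        p = wmat.shape[0]
        denom = w.sum()
        scores = (
            np.sqrt(p * (wnorm**2) @ w / denom) if denom > 0 else np.zeros(p)
        )
    else:
        raise ValueError("score must be 'vim' or 'vip'")
    return pd.Series(scores, index=model.probe_ids, name=score)


def run_plsr_association(
    x: pd.DataFrame, y: pd.Series, config: PLSConfig | None = None
) -> PLSResult:
    """Three-step PLS association on a prefiltered genotype matrix.

    Splits samples 80/20 (seeded shuffle), selects the LV count by repeated
    CV on the calibration set, refits at that count, scores probes and
    flags those at or above the VIM threshold, and reports the held-out
    test-set RMSE.
    """
    config = config or PLSConfig()
    if x.shape[0] == 0:
        raise ValueError("empty probe subset: prefilter removed everything")
    common = x.columns.intersection(y.index)
    samples = np.asarray(common)
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(len(samples))
    n_cal = int(round(config.calibration_fraction * len(samples)))
    cal = samples[perm[:n_cal]]
    test = samples[perm[n_cal:]]

    chosen, table = select_lv_by_cv(x.loc[:, cal], y.loc[cal], config)
    model = fit_pls(x.loc[:, cal], y.loc[cal], chosen, scale=config.scale)
    vim = compute_vim(model, config.score)
    significant = vim.index[vim.to_numpy() >= config.vim_threshold]
    test_rmse = (
        rmse(y.loc[test].to_numpy(), model.predict(x.loc[:, test]))
        if len(test) > 0
        else float("nan")
    )
    return PLSResult(
        chosen_lv=chosen,
        cv_table=table,
        vim=vim,
        significant=significant,
        test_rmse=test_rmse,
        model=model,
        calibration_samples=list(cal),
        test_samples=list(test),
    )
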