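"""Metabolome- and genome-based phenotype prediction.

Kernel BLUP: line similarity is summarized by K = WW'/p, where W is the
column-centered, column-scaled (sample SD, n-1) line x feature matrix and p
the number of features. Phenotypes follow

    y = 1*mu + g_K + e,         g_K ~ N(0, K sigma2_K), e ~ N(0, I sigma2_e)

or the two-kernel extension y = 1*mu + g_K1 + g_K2 + e. Variance components
are estimated by REML (bounded at zero, profiled over the residual variance);
held-out lines are predicted as mu + Cov(g*, y) V^-1 (y - mu), where the
cross-covariance row comes from the held-out line's scaled features.

All cross-validation is leave-one-out, and strictly fold-internal: feature
centering/scaling, any enrichment selection, and variance-component
estimation see training lines only. Accuracy is the Pearson correlation
between observed and predicted phenotypes.

The combined MWAS-BLUP model re-runs a single-metabolite linear regression
screen inside every fold and builds the kernel from metabolites with
P < x, for x in {0.5, 0.4, 0.3, 0.2, 0.1, 0.05} by default.

With a fixed variance ratio, kernel BLUP on K = WW'/p is algebraically
identical to ridge regression on W with penalty p * sigma2_e / sigma2_K —
used as an independent cross-check in the test suite.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import enet_path
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

DEFAULT_ENRICHMENT_THRESHOLDS = (0.5, 0.4, 0.3, 0.2, 0.1, 0.05)


@dataclass
class KernelMatrix:
    matrix: np.ndarray
    tag: str
    p: int

    def __post_init__(self) -> None:
        K = self.matrix
        if not np.allclose(K, K.T, atol=1e-8):
            raise ValueError("kernel must be symmetric")
        w = np.linalg.eigvalsh(K)
        if w.min() < -1e-8 * max(np.trace(K) / K.shape[0], 1.0):
            raise ValueError("kernel is not positive semidefinite")


def _center_scale(X: np.ndarray, means=None, sds=None):
    """Column-center and scale to unit sample SD (n-1); constant columns dropped."""
    if means is None:
        means = X.mean(axis=0)
        sds = X.std(axis=0, ddof=1)
    keep = sds > 0
    W = (X[:, keep] - means[keep]) / sds[keep]
    return W, means, sds, keep


def build_kernel(features: pd.DataFrame | np.ndarray, tag: str = "features") -> KernelMatrix:
    """K = WW'/p from column-centered, unit-SD-scaled features.

    Constant columns carry no line information and are dropped with a warning
    (p adjusted accordingly).
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("features must be a 2-D matrix with >= 1 column")
    if X.shape[0] < 3:
        raise ValueError("need >= 3 lines to build a kernel")
    W, _, sds, keep = _center_scale(X)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("build_kernel(%s): dropped %d constant columns", tag, n_dropped)
    p = int(keep.sum())
    if p == 0:
        raise ValueError("all feature columns are constant")
    return KernelMatrix(W @ W.T / p, tag, p)


# ---------------------------------------------------------------------------
# REML for y = 1 mu + sum_k g_k + e with Cov(g_k) = sigma2_k K_k
# ---------------------------------------------------------------------------


def _neg2_reml(gammas: np.ndarray, y: np.ndarray, Ks: list[np.ndarray]) -> float:
    n = len(y)
    V0 = np.eye(n)
    for g, K in zip(gammas, Ks):
        V0 = V0 + g * K
    try:
        c = np.linalg.cholesky(V0)
    except np.linalg.LinAlgError:
        return np.inf
    logdet = 2.0 * np.log(np.diag(c)).sum()
    ones = np.ones(n)
    sol = np.linalg.solve(V0, np.column_stack([y, ones]))
    xtvx = float(ones @ sol[:, 1])
    mu = float(ones @ sol[:, 0]) / xtvx
    ypy = float(y @ sol[:, 0]) - xtvx * mu**2
    df = n - 1
    s2e = max(ypy / df, 1e-12)
    return df * math.log(2 * math.pi) + df * math.log(s2e) + logdet + math.log(xtvx) + df


def fit_blup(y: np.ndarray, kernels: list[KernelMatrix]) -> dict:
    """REML fit of the one- or two-kernel BLUP model.

    Returns mu, per-kernel variances, residual variance, the inverse-V
    rotated residual (for prediction), fitted random effects, and the
    restricted log-likelihood.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    Ks = [k.matrix for k in kernels]
    if any(K.shape != (n, n) for K in Ks):
        raise ValueError("kernels not conformable with y")
    if np.std(y) == 0:
        return {
            "mu": float(y[0]) if n else 0.0,
            "sigma2_k": [0.0] * len(Ks),
            "sigma2_e": 0.0,
            "alpha": np.zeros(n),
            "g_hat": [np.zeros(n) for _ in Ks],
            "converged": True,
        }

    if len(Ks) == 1:
        # profile the single variance ratio on the eigenbasis of K: every
        # likelihood evaluation is then O(n)
        lam, U = np.linalg.eigh(Ks[0])
        lam = np.clip(lam, 0.0, None)
        yr = U.T @ y
        onesr = U.T @ np.ones(n)
        df = n - 1

        def obj1(g):
            d = 1.0 + float(g[0]) * lam
            sol_y = yr / d
            sol_1 = onesr / d
            xtvx = float(onesr @ sol_1)
            if xtvx <= 0:
                return np.inf
            mu = float(onesr @ sol_y) / xtvx
            ypy = float(yr @ sol_y) - xtvx * mu**2
            s2e = max(ypy / df, 1e-12)
            return df * math.log(2 * math.pi) + df * math.log(s2e) + np.log(d).sum() + math.log(xtvx) + df

        obj = obj1
    else:
        def obj(g):
            return _neg2_reml(np.asarray(g), y, Ks)

    bounds = [(0.0, 1e8)] * len(Ks)
    x0 = np.ones(len(Ks))
    res = optimize.minimize(obj, x0, method="L-BFGS-B", bounds=bounds)
    res2 = optimize.minimize(
        obj, res.x, method="Nelder-Mead", bounds=bounds,
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
    )
    best = res2 if res2.fun <= res.fun else res
    g = np.clip(best.x, 0.0, None)

    V0 = np.eye(n)
    for gk, K in zip(g, Ks):
        V0 = V0 + gk * K
    ones = np.ones(n)
    sol = np.linalg.solve(V0, np.column_stack([y, ones]))
    xtvx = float(ones @ sol[:, 1])
    mu = float(ones @ sol[:, 0]) / xtvx
    df = n - 1
    s2e = max((float(y @ sol[:, 0]) - xtvx * mu**2) / df, 0.0)
    sigma2_k = [float(gk * s2e) for gk in g]
    # alpha = V^-1 (y - 1 mu); V = s2e * V0
    resid = y - mu
    alpha = np.linalg.solve(V0, resid) / s2e if s2e > 0 else np.zeros(n)
    g_hat = [s2k * K @ alpha for s2k, K in zip(sigma2_k, Ks)]
    return {
        "mu": mu,
        "sigma2_k": sigma2_k,
        "sigma2_e": float(s2e),
        "alpha": alpha,
        "g_hat": g_hat,
        "neg2ll": float(best.fun),
        "converged": bool(np.isfinite(best.fun)),
    }


class KernelBLUP(BaseEstimator, RegressorMixin):
    """Sklearn-style kernel BLUP regressor over inbred lines.

    Parameters
    ----------
    feature_blocks : None for a single kernel built from all columns, or a
        list of column-index arrays, one kernel per block (two blocks give the
        two-kernel model).
    tag : provenance label carried on the kernels.

    Centering/scaling is estimated in ``fit`` (training lines only), so the
    estimator is leakage-safe inside cross-validation by construction.
    """

    def __init__(self, feature_blocks=None, tag: str = "features"):
        self.feature_blocks = feature_blocks
        self.tag = tag

    def _blocks(self, X: np.ndarray):
        if self.feature_blocks is None:
            return [np.arange(X.shape[1])]
        return [np.asarray(b) for b in self.feature_blocks]

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != len(y):
            raise ValueError("X and y have different numbers of lines")
        self._scalers = []
        self._Ws = []
        kernels = []
        for bi, block in enumerate(self._blocks(X)):
            W, means, sds, keep = _center_scale(X[:, block])
            if keep.sum() == 0:
                raise ValueError("feature block is entirely constant")
            self._scalers.append((block, means, sds, keep))
            self._Ws.append(W)
            kernels.append(KernelMatrix(W @ W.T / int(keep.sum()), f"{self.tag}[{bi}]", int(keep.sum())))
        self.kernels_ = kernels
        fit = fit_blup(y, kernels)
        self.mu_ = fit["mu"]
        self.intercept_ = fit["mu"]
        self.sigma2_k_ = fit["sigma2_k"]
        self.sigma2_e_ = fit["sigma2_e"]
        self.alpha_ = fit["alpha"]
        self.g_hat_ = fit["g_hat"]
        self.converged_ = fit["converged"]
        # zero kernel variance everywhere: the fitted predictor is a constant
        self.is_degenerate_ = all(s == 0.0 for s in self.sigma2_k_)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "mu_")
        X = np.asarray(X, dtype=float)
        pred = np.full(X.shape[0], self.mu_)
        for (block, means, sds, keep), W_tr, s2k in zip(self._scalers, self._Ws, self.sigma2_k_):
            if s2k == 0:
                continue
            w_new = (X[:, block][:, keep] - means[keep]) / sds[keep]
            k_star = w_new @ W_tr.T / W_tr.shape[1]
            pred = pred + s2k * k_star @ self.alpha_
        return pred


@dataclass
class CVResult:
    """Leave-one-out predictions and their accuracy for one model."""

    predictions: pd.DataFrame  # line, observed, predicted
    accuracy: float
    model: str
    degenerate: bool = False  # constant predictions: accuracy reported as 0


def accuracy(predicted, observed) -> tuple[float, bool]:
    """Pearson correlation of predicted and observed; (0, True) if either is
    constant."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if len(predicted) != len(observed):
        raise ValueError("length mismatch")
    if len(predicted) < 3:
        raise ValueError("need >= 3 pairs")
    if np.std(predicted) == 0 or np.std(observed) == 0:
        return 0.0, True
    r, _ = stats.pearsonr(predicted, observed)
    return float(r), False


def _loo_indices(n: int):
    for i in range(n):
        train = np.r_[0:i, i + 1 : n]
        yield train, i


def loocv_estimator(estimator, X: pd.DataFrame, y: pd.Series, model: str) -> CVResult:
    """Leave-one-out CV of any sklearn-style regressor over lines.

    Accuracy is computed on predictions with each fold's fitted intercept
    aligned to the common mean of the fold intercepts. Each fold's training
    mean is (S - y_i)/(n - 1), exactly anti-correlated with the held-out
    value, so with weak or absent signal raw leave-one-out predictions are
    biased toward accuracy -1; aligning the intercepts correlates the fitted
    line effects with the observations instead. A model with zero predictive
    variance in every fold yields constant aligned predictions and is
    reported as accuracy 0 with the degenerate flag.
    """
    Xv = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float)
    lines = list(X.index) if hasattr(X, "index") else list(range(len(yv)))
    preds = np.empty(len(yv))
    intercepts = np.zeros(len(yv))
    from sklearn.base import clone

    for train, test in _loo_indices(len(yv)):
        assert test not in train, "held-out line leaked into training"
        est = clone(estimator)
        est.fit(Xv[train], yv[train])
        preds[test] = est.predict(Xv[test][None, :])[0]
        intercepts[test] = getattr(est, "intercept_", 0.0)
    aligned = preds - intercepts + intercepts.mean()
    table = pd.DataFrame({"line": lines, "observed": yv, "predicted": preds,
                          "predicted_aligned": aligned})
    if np.std(aligned) < 1e-12:
        return CVResult(table, 0.0, model, degenerate=True)
    acc, flat = accuracy(aligned, yv)
    return CVResult(table, acc, model, degenerate=flat)


def loocv_blup(y: pd.Series, features: pd.DataFrame, feature_blocks=None, tag="features") -> CVResult:
    """Leave-one-out kernel BLUP; variance components re-estimated per fold."""
    aligned = features.loc[y.index]
    est = KernelBLUP(feature_blocks=feature_blocks, tag=tag)
    return loocv_estimator(est, aligned, y, model=f"blup[{tag}]")


def _marginal_regression_p(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided P of the slope in y ~ x_j, for every column j (vectorized)."""
    n = len(y)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = math.sqrt(float(yc @ yc))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = Xc.T @ yc / (sx * sy)
        r = np.clip(np.nan_to_num(r, nan=0.0), -1.0, 1.0)
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    return 2.0 * stats.t.sf(np.abs(t), n - 2)


class MWASEnrichedBLUP(BaseEstimator, RegressorMixin):
    """Kernel BLUP on the metabolites passing a fold-internal MWAS screen.

    In ``fit``, each feature is regressed on the phenotype (training lines
    only) and features with P < ``threshold`` build the kernel. If none pass,
    the model degenerates to the training mean (logged).
    """

    def __init__(self, threshold: float = 0.05):
        self.threshold = threshold

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        p = _marginal_regression_p(X, y)
        self.selected_ = np.where(p < self.threshold)[0]
        if len(self.selected_) == 0:
            logger.info("enrichment at P<%g selected no features; using training mean", self.threshold)
            self._fallback_mean = float(y.mean())
            self._inner = None
            self.is_degenerate_ = True
            self.intercept_ = self._fallback_mean
        else:
            self._fallback_mean = None
            self._inner = KernelBLUP(tag=f"enriched<{self.threshold}").fit(X[:, self.selected_], y)
            self.is_degenerate_ = self._inner.is_degenerate_
            self.intercept_ = self._inner.intercept_
        return self

    def predict(self, X):
        check_is_fitted(self, "selected_")
        X = np.asarray(X, dtype=float)
        if self._inner is None:
            return np.full(X.shape[0], self._fallback_mean)
        return self._inner.predict(X[:, self.selected_])


def mwas_enriched_loocv(
    y: pd.Series,
    metabolite_line_means: pd.DataFrame,
    thresholds=DEFAULT_ENRICHMENT_THRESHOLDS,
) -> dict[float, CVResult]:
    """Combined MWAS-BLUP leave-one-out CV, one result per threshold."""
    aligned = metabolite_line_means.loc[y.index]
    out = {}
    for x in thresholds:
        est = MWASEnrichedBLUP(threshold=x)
        out[x] = loocv_estimator(est, aligned, y, model=f"mwas-blup[P<{x}]")
    return out


def _lambda_grid(X: np.ndarray, y: np.ndarray, l1_ratio: float, n_lambdas: int, decades: float):
    Xs, *_ = _center_scale(X)
    yc = y - y.mean()
    lmax = np.abs(Xs.T @ yc).max() / (len(y) * max(l1_ratio, 1e-3))
    return np.logspace(math.log10(lmax), math.log10(lmax) - decades, n_lambdas)


def elastic_net_loocv(
    y: pd.Series,
    features: pd.DataFrame,
    alpha_grid=tuple(np.round(np.arange(0.05, 1.0001, 0.05), 2)),
    lambda_grid=None,
    n_lambdas: int = 50,
    decades: float = 4.0,
) -> tuple[CVResult, float, float, pd.DataFrame]:
    """Elastic-net LOOCV over an (alpha, lambda) grid; best point reported.

    alpha is the lasso/ridge mixing weight (1 = lasso), lambda the penalty
    strength. Features are re-standardized inside every fold. The returned
    grid point is the one with the highest LOOCV accuracy (non-nested
    selection); the full accuracy grid is also returned.
    """
    X = features.loc[y.index].to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)
    n = len(yv)
    lines = list(y.index)
    results = []
    best = None
    for a in alpha_grid:
        lambdas = np.asarray(lambda_grid if lambda_grid is not None
                             else _lambda_grid(X, yv, a, n_lambdas, decades), dtype=float)
        lambdas = np.sort(lambdas)[::-1]
        preds = np.zeros((len(lambdas), n))
        fold_means = np.zeros(n)
        for train, test in _loo_indices(n):
            Xt = X[train]
            means = Xt.mean(axis=0)
            sds = Xt.std(axis=0, ddof=1)
            sds[sds == 0] = 1.0
            Xs = (Xt - means) / sds
            yt = yv[train]
            ybar = yt.mean()
            fold_means[test] = ybar
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                lam_ret, coefs, _ = enet_path(Xs, yt - ybar, l1_ratio=a, alphas=lambdas)
            order = np.argsort(-lam_ret)  # align returned path with the decreasing grid
            xtest = (X[test] - means) / sds
            preds[:, test] = (xtest @ coefs)[order] + ybar
        for li, lam in enumerate(lambdas):
            # fold intercepts aligned for scoring (see loocv_estimator)
            aligned = preds[li] - fold_means + fold_means.mean()
            if np.std(aligned) < 1e-12:
                acc, flat = 0.0, True
            else:
                acc, flat = accuracy(aligned, yv)
            results.append({"alpha": a, "lambda": lam, "accuracy": 0.0 if flat else acc,
                            "degenerate": flat})
            if best is None or results[-1]["accuracy"] > best[0]:
                best = (results[-1]["accuracy"], a, lam, preds[li].copy(), flat)
    grid = pd.DataFrame(results)
    acc, a_best, lam_best, pred_best, flat = best
    cv = CVResult(
        pd.DataFrame({"line": lines, "observed": yv, "predicted": pred_best}),
        acc, model=f"enet[alpha={a_best},lambda={lam_best:.4g}]", degenerate=flat,
    )
    return cv, a_best, lam_best, grid
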