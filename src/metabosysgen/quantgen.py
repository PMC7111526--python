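"""Per-metabolite variance components and broad-sense heritability.

The full model for replicate-level abundance is

    Y = mu + L + S + LxS + e

with line (L) and line-by-sex (LxS) random, sex (S) fixed. The per-sex reduced
model is Y = mu + L + e. Components are estimated by REML with variances
bounded at zero; for balanced data the estimates coincide with the classical
expected-mean-squares (method-of-moments) ANOVA estimators whenever those are
all positive, which is used as an internal cross-check and exposed as
``method="anova"``.

Broad-sense heritability is H2 = (s2_L + s2_LxS) / (s2_L + s2_LxS + s2_e):
the total genetic variance over the total phenotypic variance, with sex (a
fixed effect) excluded from both.

Random-term P-values come from restricted likelihood-ratio tests against the
model without the term, referred to the boundary mixture 0.5*chi2_0 +
0.5*chi2_1; the fixed sex effect is tested by a Wald F with the balanced-ANOVA
denominator degrees of freedom. EMS F-tests are the ``method="anova"``
alternative.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("line", "sex", "replicate", "metabolite", "abundance")
_VAR_FLOOR = 1e-12


class ModelError(ValueError):
    """Raised when the data cannot support the requested model."""


@dataclass
class VarianceComponents:
    """REML (or EMS) variance components for one analyte."""

    analyte: str
    scope: str  # "full", "F" or "M"
    sigma2_L: float
    sigma2_LxS: float
    sigma2_e: float
    p_L: float
    p_S: float
    p_LxS: float
    H2: float
    method: str = "reml"
    converged: bool = True

    def __post_init__(self) -> None:
        for v in (self.sigma2_L, self.sigma2_LxS, self.sigma2_e):
            if v < -1e-9:
                raise ModelError(f"negative variance component: {v}")


def validate_replicate_table(tbl: pd.DataFrame) -> pd.DataFrame:
    """Check the tidy replicate table contract; returns the table unchanged."""
    missing = [c for c in REQUIRED_COLUMNS if c not in tbl.columns]
    if missing:
        raise ModelError(f"replicate table missing columns: {missing}")
    dup = tbl.duplicated(subset=["line", "sex", "replicate", "metabolite"])
    if dup.any():
        raise ModelError("duplicate (line, sex, replicate, metabolite) rows")
    if tbl["line"].nunique() < 2:
        raise ModelError("need at least 2 lines")
    return tbl


# ---------------------------------------------------------------------------
# REML for random-intercept models grouped by line (blocks are independent
# across lines, so the restricted likelihood factorizes into per-line blocks).
# ---------------------------------------------------------------------------


def _block_solve(data: dict, g_line: float, g_lxs: float):
    """Accumulate logdet(V0), X'V0^-1 X, X'V0^-1 y, y'V0^-1 y over line blocks.

    Uses a batched path when every line has the same block shape (the
    balanced case); falls back to a per-block loop otherwise.
    """
    if data.get("stacked") is not None:
        Y, Xb, J, S = data["stacked"]  # (L,m), (L,m,p), (m,m), (L,m,m)
        L, m, p = Xb.shape
        B = np.eye(m)[None, :, :] + g_line * J[None, :, :] + g_lxs * S
        try:
            c = np.linalg.cholesky(B)
        except np.linalg.LinAlgError:
            return None
        logdet = float(2.0 * np.log(np.diagonal(c, axis1=1, axis2=2)).sum())
        rhs = np.concatenate([Y[:, :, None], Xb], axis=2)
        sol = np.linalg.solve(B, rhs)
        ytvy = float(np.einsum("lm,lm->", Y, sol[:, :, 0]))
        xtvy = np.einsum("lmp,lm->p", Xb, sol[:, :, 0])
        xtvx = np.einsum("lmp,lmq->pq", Xb, sol[:, :, 1:])
        return logdet, xtvx, xtvy, ytvy
    p = data["p"]
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    ytvy = 0.0
    logdet = 0.0
    for y_l, X_l, J, Ssame in data["blocks"]:
        m = len(y_l)
        B = np.eye(m) + g_line * J + g_lxs * Ssame
        try:
            c = np.linalg.cholesky(B)
        except np.linalg.LinAlgError:
            return None
        logdet += 2.0 * np.log(np.diag(c)).sum()
        sol = np.linalg.solve(B, np.column_stack([y_l, X_l]))
        ytvy += float(y_l @ sol[:, 0])
        xtvy += X_l.T @ sol[:, 0]
        xtvx += X_l.T @ sol[:, 1:]
    return logdet, xtvx, xtvy, ytvy


def _neg2_restricted_ll(gammas: np.ndarray, data: dict) -> float:
    """-2 * restricted log-likelihood, profiled over sigma2_e.

    gammas = (g_line, g_lxs) are variance ratios sigma2 / sigma2_e; either may
    be structurally absent (data["use_lxs"] False).
    """
    g_line = float(gammas[0])
    g_lxs = float(gammas[1]) if data["use_lxs"] else 0.0
    n, p = data["n"], data["p"]
    acc = _block_solve(data, g_line, g_lxs)
    if acc is None:
        return np.inf
    logdet, xtvx, xtvy, ytvy = acc
    sign, ld_x = np.linalg.slogdet(xtvx)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(xtvx, xtvy)
    ypy = ytvy - float(xtvy @ beta)
    df = n - p
    s2e = max(ypy / df, _VAR_FLOOR)
    return df * math.log(2.0 * math.pi) + df * math.log(s2e) + logdet + ld_x + df


def _make_blocks(y: np.ndarray, X: np.ndarray, line: np.ndarray, sex: np.ndarray) -> dict:
    blocks = []
    for l in np.unique(line):
        idx = np.where(line == l)[0]
        s = sex[idx]
        same = (s[:, None] == s[None, :]).astype(float)
        blocks.append((y[idx], X[idx], np.ones((len(idx), len(idx))), same))
    data = {"blocks": blocks, "n": len(y), "p": X.shape[1], "use_lxs": True, "stacked": None}
    sizes = {len(b[0]) for b in blocks}
    if len(sizes) == 1:
        data["stacked"] = (
            np.stack([b[0] for b in blocks]),
            np.stack([b[1] for b in blocks]),
            blocks[0][2],
            np.stack([b[3] for b in blocks]),
        )
    return data


def _fit_reml(data: dict, free: tuple[bool, bool], start: tuple[float, float]) -> dict:
    """Maximize the restricted likelihood over the free variance ratios."""

    free_idx = [i for i, f in enumerate(free) if f]

    def obj(theta: np.ndarray) -> float:
        g = np.zeros(2)
        g[free_idx] = theta
        return _neg2_restricted_ll(g, data)

    converged = True
    if free_idx:
        x0 = np.asarray([start[i] for i in free_idx], dtype=float)
        x0 = np.clip(x0, 0.0, 1e6)
        bounds = [(0.0, 1e8)] * len(free_idx)
        res = optimize.minimize(obj, x0, method="L-BFGS-B", bounds=bounds)
        res2 = optimize.minimize(
            obj,
            res.x,
            method="Nelder-Mead",
            bounds=bounds,
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
        )
        best = res2 if res2.fun <= res.fun else res
        converged = bool(best.fun < np.inf)
        g = np.zeros(2)
        g[free_idx] = best.x
    else:
        g = np.zeros(2)

    # recover components at the optimum
    n, p = data["n"], data["p"]
    _logdet, xtvx, xtvy, ytvy = _block_solve(
        data, float(g[0]), float(g[1]) if data["use_lxs"] else 0.0
    )
    beta = np.linalg.solve(xtvx, xtvy)
    s2e = max((ytvy - float(xtvy @ beta)) / (n - p), 0.0)
    return {
        "gamma": g,
        "sigma2_e": s2e,
        "sigma2_L": g[0] * s2e,
        "sigma2_LxS": g[1] * s2e,
        "beta": beta,
        "beta_cov": s2e * np.linalg.inv(xtvx),
        "neg2ll": _neg2_restricted_ll(g, data),
        "converged": converged,
    }


def _lrt_boundary_p(neg2_full: float, neg2_reduced: float) -> float:
    """P-value for dropping one variance, 0.5*chi2_0 + 0.5*chi2_1 mixture."""
    stat = max(neg2_reduced - neg2_full, 0.0)
    return float(0.5 * stats.chi2.sf(stat, df=1)) if stat > 0 else 1.0


def _ems_start(y: np.ndarray, line: np.ndarray, sex: np.ndarray | None) -> tuple[float, float]:
    """Crude EMS-style starting ratios for the optimizer."""
    df = pd.DataFrame({"y": y, "line": line})
    v_between = df.groupby("line")["y"].mean().var()
    v_within = df.groupby("line")["y"].var().mean()
    if not np.isfinite(v_within) or v_within <= 0:
        v_within = max(np.var(y), _VAR_FLOOR)
    g = max((v_between - v_within / max(np.bincount(pd.factorize(line)[0]).mean(), 1)) / v_within, 0.0)
    return (g, g * 0.5)


def fit_full_model(tbl: pd.DataFrame, analyte: str, method: str = "reml") -> VarianceComponents:
    """Fit Y = mu + L + S + LxS + e for one analyte over both sexes."""
    sub = tbl[tbl["metabolite"] == analyte].dropna(subset=["abundance"])
    if sub.empty:
        raise ModelError(f"no data for analyte {analyte!r}")
    if sub["line"].nunique() < 2:
        raise ModelError("full model needs >= 2 lines")
    if sub["sex"].nunique() < 2:
        raise ModelError("full model needs both sexes")

    y = sub["abundance"].to_numpy(dtype=float)
    line = sub["line"].to_numpy()
    sexm = (sub["sex"].to_numpy() == "M").astype(float)
    n_lines = sub["line"].nunique()

    if np.var(y) < _VAR_FLOOR:
        return VarianceComponents(analyte, "full", 0.0, 0.0, 0.0, 1.0, 1.0, 1.0, 0.0, method)

    if method == "anova":
        return _fit_full_anova(sub, analyte)

    X = np.column_stack([np.ones_like(y), sexm])
    data = _make_blocks(y, X, line, sexm)
    start = _ems_start(y, line, sexm)
    full = _fit_reml(data, free=(True, True), start=start)
    no_line = _fit_reml(data, free=(False, True), start=start)
    no_lxs = _fit_reml(data, free=(True, False), start=start)
    p_L = _lrt_boundary_p(full["neg2ll"], no_line["neg2ll"])
    p_LxS = _lrt_boundary_p(full["neg2ll"], no_lxs["neg2ll"])
    # Wald F for fixed sex; denominator df from the balanced interaction stratum
    se = math.sqrt(max(full["beta_cov"][1, 1], _VAR_FLOOR))
    f_stat = (full["beta"][1] / se) ** 2
    df2 = max(n_lines - 1, 1)
    p_S = float(stats.f.sf(f_stat, 1, df2))
    h2 = heritability(full["sigma2_L"], full["sigma2_LxS"], full["sigma2_e"])
    return VarianceComponents(
        analyte,
        "full",
        full["sigma2_L"],
        full["sigma2_LxS"],
        full["sigma2_e"],
        p_L,
        p_S,
        p_LxS,
        h2,
        method="reml",
        converged=full["converged"],
    )


def _balanced_cells(sub: pd.DataFrame) -> tuple[np.ndarray, int, int, int]:
    counts = sub.groupby(["line", "sex"], observed=True)["abundance"].count()
    r = counts.iloc[0]
    if counts.nunique() != 1:
        raise ModelError("ANOVA (EMS) method requires balanced data; use method='reml'")
    L = sub["line"].nunique()
    S = sub["sex"].nunique()
    return counts.to_numpy(), L, S, int(r)


def _fit_full_anova(sub: pd.DataFrame, analyte: str) -> VarianceComponents:
    """Balanced two-way mixed ANOVA with EMS estimators and F-tests."""
    _, L, S, r = _balanced_cells(sub)
    y = sub["abundance"]
    grand = y.mean()
    m_l = sub.groupby("line")["abundance"].mean()
    m_s = sub.groupby("sex")["abundance"].mean()
    m_ls = sub.groupby(["line", "sex"])["abundance"].mean()
    ss_l = S * r * ((m_l - grand) ** 2).sum()
    ss_s = L * r * ((m_s - grand) ** 2).sum()
    fit_cell = sub.set_index(["line", "sex"]).join(m_ls.rename("cell"))
    ss_e = ((fit_cell["abundance"] - fit_cell["cell"]) ** 2).sum()
    ss_ls = (
        r * ((m_ls - m_l.reindex(m_ls.index.get_level_values(0)).to_numpy()
              - m_s.reindex(m_ls.index.get_level_values(1)).to_numpy() + grand) ** 2).sum()
    )
    df_l, df_s, df_ls, df_e = L - 1, S - 1, (L - 1) * (S - 1), L * S * (r - 1)
    ms_l, ms_s, ms_ls = ss_l / df_l, ss_s / df_s, ss_ls / df_ls
    ms_e = ss_e / df_e if df_e > 0 else 0.0
    s2e = ms_e
    s2lxs = max((ms_ls - ms_e) / r, 0.0)
    s2l = max((ms_l - ms_ls) / (S * r), 0.0)
    p_l = float(stats.f.sf(ms_l / ms_ls, df_l, df_ls)) if ms_ls > 0 else 0.0
    p_s = float(stats.f.sf(ms_s / ms_ls, df_s, df_ls)) if ms_ls > 0 else 0.0
    p_lxs = float(stats.f.sf(ms_ls / ms_e, df_ls, df_e)) if ms_e > 0 and df_e > 0 else 0.0
    return VarianceComponents(
        analyte, "full", s2l, s2lxs, s2e, p_l, p_s, p_lxs,
        heritability(s2l, s2lxs, s2e), method="anova",
    )


def fit_reduced_model(tbl: pd.DataFrame, analyte: str, sex: str, method: str = "reml") -> VarianceComponents:
    """Fit the per-sex reduced model Y = mu + L + e."""
    sub = tbl[(tbl["metabolite"] == analyte) & (tbl["sex"] == sex)].dropna(subset=["abundance"])
    if sub["line"].nunique() < 2:
        raise ModelError(f"reduced model needs >= 2 lines for sex {sex!r}")
    y = sub["abundance"].to_numpy(dtype=float)
    line = sub["line"].to_numpy()
    if np.var(y) < _VAR_FLOOR:
        return VarianceComponents(analyte, sex, 0.0, 0.0, 0.0, 1.0, np.nan, np.nan, 0.0, method)

    if method == "anova":
        counts = sub.groupby("line")["abundance"].count()
        if counts.nunique() != 1:
            raise ModelError("ANOVA (EMS) method requires balanced data; use method='reml'")
        L, r = len(counts), int(counts.iloc[0])
        grand = y.mean()
        m_l = sub.groupby("line")["abundance"].mean()
        ss_l = r * ((m_l - grand) ** 2).sum()
        ss_e = ((sub.set_index("line")["abundance"] - m_l.reindex(sub["line"]).to_numpy()) ** 2).sum()
        df_l, df_e = L - 1, L * (r - 1)
        ms_l = ss_l / df_l
        ms_e = ss_e / df_e if df_e > 0 else 0.0
        s2l = max((ms_l - ms_e) / r, 0.0)
        p_l = float(stats.f.sf(ms_l / ms_e, df_l, df_e)) if ms_e > 0 else 0.0
        return VarianceComponents(
            analyte, sex, s2l, 0.0, ms_e, p_l, np.nan, np.nan,
            heritability(s2l, 0.0, ms_e), method="anova",
        )

    X = np.ones((len(y), 1))
    sex_code = np.zeros(len(y))
    data = _make_blocks(y, X, line, sex_code)
    data["use_lxs"] = False
    start = _ems_start(y, line, None)
    fit = _fit_reml(data, free=(True, False), start=start)
    null = _fit_reml(data, free=(False, False), start=start)
    p_L = _lrt_boundary_p(fit["neg2ll"], null["neg2ll"])
    return VarianceComponents(
        analyte, sex, fit["sigma2_L"], 0.0, fit["sigma2_e"], p_L, np.nan, np.nan,
        heritability(fit["sigma2_L"], 0.0, fit["sigma2_e"]),
        method="reml", converged=fit["converged"],
    )


def heritability(sigma2_L: float, sigma2_LxS: float = 0.0, sigma2_e: float = 0.0) -> float:
    """Broad-sense heritability (s2_L + s2_LxS) / (s2_L + s2_LxS + s2_e).

    Defined as 0 when the total variance is 0. Accepts a VarianceComponents
    via ``heritability(vc.sigma2_L, vc.sigma2_LxS, vc.sigma2_e)``.
    """
    for v in (sigma2_L, sigma2_LxS, sigma2_e):
        if v < 0:
            raise ModelError(f"negative variance: {v}")
    total = sigma2_L + sigma2_LxS + sigma2_e
    if total == 0:
        return 0.0
    h2 = (sigma2_L + sigma2_LxS) / total
    return float(min(max(h2, 0.0), 1.0))


def bh_adjust(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and FDR flags.

    Returns (qvalues, flags) aligned with the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("P-values must be in [0, 1]")
    flags, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, flags


def line_means(tbl: pd.DataFrame, sex: str) -> pd.DataFrame:
    """Line x analyte matrix of replicate means for one sex.

    Missing replicates are skipped; a (line, analyte) cell is missing only if
    all its replicates are missing.
    """
    sub = tbl[tbl["sex"] == sex]
    lm = sub.pivot_table(index="line", columns="metabolite", values="abundance", aggfunc="mean")
    n_missing = int(lm.isna().sum().sum())
    if n_missing:
        logger.warning("line_means: %d (line, analyte) cells entirely missing", n_missing)
    return lm


def variance_component_table(
    tbl: pd.DataFrame, scope: str = "full", method: str = "reml", fdr: float = 0.05
) -> pd.DataFrame:
    """Variance components for every analyte, with BH q-values on the line term.

    scope: "full" (both sexes, full model) or "F"/"M" (reduced model).
    """
    validate_replicate_table(tbl)
    analytes = sorted(tbl["metabolite"].unique())
    records = []
    for a in analytes:
        vc = (
            fit_full_model(tbl, a, method=method)
            if scope == "full"
            else fit_reduced_model(tbl, a, scope, method=method)
        )
        records.append(vc)
    out = pd.DataFrame(
        {
            "analyte": [v.analyte for v in records],
            "scope": scope,
            "sigma2_L": [v.sigma2_L for v in records],
            "sigma2_LxS": [v.sigma2_LxS for v in records],
            "sigma2_e": [v.sigma2_e for v in records],
            "p_L": [v.p_L for v in records],
            "p_S": [v.p_S for v in records],
            "p_LxS": [v.p_LxS for v in records],
            "H2": [v.H2 for v in records],
            "converged": [v.converged for v in records],
        }
    )
    q, flags = bh_adjust(out["p_L"].to_numpy(), alpha=fdr)
    out["q_L"] = q
    out["variable"] = flags
    return out
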