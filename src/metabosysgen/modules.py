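"""Correlation modules of the genetically variable metabolome, and module PCs.

Metabolites are clustered on the absolute correlation of their line means:
|r| is passed through a sigmoid transform w = s(|r|) chosen over a fixed
(steepness, threshold) grid, and the weighted modularity of the resulting
graph is maximized by recursive spectral bipartition with Kernighan-Lin
refinement. The transform that yields the highest-modularity partition wins.
The sigmoid is shifted so that |r| = 0 maps to weight 0 exactly: uncorrelated
analytes are disconnected and an identity correlation matrix yields the
all-singleton partition.

Each module is summarized by principal components of the standardized line
means; PCs explaining more than 4% of the module's variance are retained, and
further PCs are added in decreasing order until the retained set cumulatively
explains more than 90%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin

logger = logging.getLogger(__name__)

DEFAULT_S_GRID = (5.0, 10.0, 20.0, 30.0)
DEFAULT_T_GRID = (0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8)
_EIG_TOL = 1e-10


def metabolite_correlations(line_means: pd.DataFrame, method: str = "pearson") -> pd.DataFrame:
    """Analyte x analyte correlation of line means, pairwise-complete.

    Constant analytes get correlation 0 with everything (logged), 1 with
    themselves.
    """
    if line_means.shape[0] < 3:
        raise ValueError("need >= 3 lines to correlate analytes")
    corr = line_means.corr(method=method, min_periods=3)
    const = line_means.std(ddof=1) == 0
    if const.any():
        logger.warning("constant analytes, correlations set to 0: %s", list(const[const].index))
    corr = corr.fillna(0.0)
    np.fill_diagonal(corr.values, 1.0)
    return corr


@dataclass
class ModulePartition:
    """Metabolite -> module assignment, ordered by within-module mean |r|."""

    assignment: pd.Series  # analyte -> module id (0-based, in final order)
    mean_abs_corr: pd.Series  # module id -> mean |r| over distinct pairs (0 for singletons)
    modularity: float
    transform: tuple[float, float]  # (steepness, threshold) of the winning sigmoid

    @property
    def n_modules(self) -> int:
        return int(self.assignment.max()) + 1 if len(self.assignment) else 0

    def members(self, module: int) -> list:
        return list(self.assignment.index[self.assignment == module])


def _sigmoid_weights(abs_r: np.ndarray, s: float, t: float) -> np.ndarray:
    """Shifted sigmoid of |r|: 0 at |r| = 0, increasing, < 1."""
    w = 1.0 / (1.0 + np.exp(-s * (abs_r - t))) - 1.0 / (1.0 + np.exp(s * t))
    w = np.clip(w, 0.0, None)
    np.fill_diagonal(w, 0.0)
    return w


def _modularity(W: np.ndarray, labels: np.ndarray) -> float:
    two_m = W.sum()
    if two_m <= 0:
        return 0.0
    k = W.sum(axis=1)
    q = 0.0
    for c in np.unique(labels):
        idx = labels == c
        q += W[np.ix_(idx, idx)].sum() / two_m - (k[idx].sum() / two_m) ** 2
    return float(q)


def _leading_eig(B: np.ndarray) -> tuple[float, np.ndarray]:
    vals, vecs = np.linalg.eigh(B)
    v = vecs[:, -1]
    j = int(np.argmax(np.abs(v)))
    if v[j] < 0:
        v = -v
    return float(vals[-1]), v


def _kl_refine(Bg: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Kernighan-Lin style single-vertex moves maximizing s'Bs; deterministic."""
    n = len(s)
    best_s = s.copy()
    best_val = float(s @ Bg @ s)
    improved = True
    while improved:
        improved = False
        s_work = best_s.copy()
        moved = np.zeros(n, dtype=bool)
        trace = []
        val = best_val
        for _ in range(n):
            # gain of flipping vertex i: delta = -4 s_i (Bg s)_i + 4 Bg_ii
            bs = Bg @ s_work
            gains = -4.0 * s_work * bs + 4.0 * np.diag(Bg)
            gains[moved] = -np.inf
            i = int(np.argmax(gains))
            s_work[i] = -s_work[i]
            moved[i] = True
            val = float(s_work @ Bg @ s_work)
            trace.append((val, s_work.copy()))
        cand_val, cand_s = max(trace, key=lambda p: p[0])
        if cand_val > best_val + 1e-12:
            best_val, best_s = cand_val, cand_s
            improved = True
    return best_s


def _split_group(W: np.ndarray, k: np.ndarray, two_m: float, idx: np.ndarray) -> list[np.ndarray]:
    """Recursively bipartition the vertex subset idx; returns list of subsets."""
    if len(idx) == 1:
        return [idx]
    B = W[np.ix_(idx, idx)] - np.outer(k[idx], k[idx]) / two_m
    Bg = B - np.diag(B.sum(axis=1))
    lead, v = _leading_eig(Bg)
    if lead <= _EIG_TOL:
        return [idx]
    s = np.where(v >= 0, 1.0, -1.0)
    s = _kl_refine(Bg, s)
    dq = float(s @ Bg @ s) / (2.0 * two_m)
    if dq <= 1e-12 or np.all(s == s[0]):
        return [idx]
    left, right = idx[s > 0], idx[s < 0]
    return _split_group(W, k, two_m, left) + _split_group(W, k, two_m, right)


def _partition_weights(W: np.ndarray) -> np.ndarray:
    """Modularity-maximizing labels for one weight matrix."""
    n = W.shape[0]
    labels = np.full(n, -1, dtype=int)
    if W.sum() <= 0:
        return np.arange(n)
    n_comp, comp = connected_components((W > 0).astype(np.int8), directed=False)
    k = W.sum(axis=1)
    two_m = W.sum()
    nxt = 0
    for c in range(n_comp):
        idx = np.where(comp == c)[0]
        for group in _split_group(W, k, two_m, idx):
            labels[group] = nxt
            nxt += 1
    return labels


def cluster_modules(
    corr: pd.DataFrame,
    s_grid=DEFAULT_S_GRID,
    t_grid=DEFAULT_T_GRID,
) -> ModulePartition:
    """Partition analytes by maximizing sigmoid-weighted modularity of |r|."""
    A = corr.to_numpy(dtype=float)
    if A.shape[0] != A.shape[1] or not np.allclose(A, A.T, atol=1e-8):
        raise ValueError("correlation matrix must be square and symmetric")
    if not np.allclose(np.diag(A), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have unit diagonal")
    abs_r = np.abs(A)
    best = None
    for s in s_grid:
        for t in t_grid:
            W = _sigmoid_weights(abs_r, s, t)
            labels = _partition_weights(W)
            q = _modularity(W, labels)
            if best is None or q > best[0] + 1e-12:
                best = (q, labels, (s, t))
    q, labels, transform = best
    return _order_partition(corr, labels, q, transform)


def _order_partition(
    corr: pd.DataFrame, labels: np.ndarray, q: float, transform
) -> ModulePartition:
    """Renumber modules by descending mean |r|; ties by size then first analyte."""
    abs_r = np.abs(corr.to_numpy())
    analytes = list(corr.index)
    stats_rows = []
    for c in np.unique(labels):
        idx = np.where(labels == c)[0]
        if len(idx) > 1:
            block = abs_r[np.ix_(idx, idx)]
            mean_r = float((block.sum() - len(idx)) / (len(idx) * (len(idx) - 1)))
        else:
            mean_r = 0.0
        stats_rows.append((c, mean_r, len(idx), analytes[idx[0]]))
    stats_rows.sort(key=lambda rec: (-rec[1], -rec[2], str(rec[3])))
    remap = {old: new for new, (old, *_rest) in enumerate(stats_rows)}
    new_labels = np.array([remap[c] for c in labels])
    mean_abs = pd.Series(
        {remap[c]: m for c, m, _sz, _a in stats_rows}, name="mean_abs_corr"
    ).sort_index()
    assignment = pd.Series(new_labels, index=pd.Index(analytes, name="analyte"), name="module")
    return ModulePartition(assignment, mean_abs, q, transform)


class ModularityClustering(BaseEstimator, ClusterMixin):
    """Sklearn-style clusterer over analytes (columns of a line-mean matrix).

    Parameters
    ----------
    corr_method : "pearson" or "spearman" correlation of line means.
    s_grid, t_grid : sigmoid transform grid searched for maximum modularity.
    precomputed : if True, ``fit`` expects a correlation matrix instead of
        line means.
    """

    def __init__(self, corr_method="pearson", s_grid=DEFAULT_S_GRID,
                 t_grid=DEFAULT_T_GRID, precomputed=False):
        self.corr_method = corr_method
        self.s_grid = s_grid
        self.t_grid = t_grid
        self.precomputed = precomputed

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        corr = X if self.precomputed else metabolite_correlations(X, self.corr_method)
        part = cluster_modules(corr, self.s_grid, self.t_grid)
        self.partition_ = part
        self.labels_ = part.assignment.to_numpy()
        self.modularity_ = part.modularity
        self.transform_params_ = part.transform
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


# ---------------------------------------------------------------------------
# Module PCA
# ---------------------------------------------------------------------------


def retained_pc_indices(
    fractions: np.ndarray, var_threshold: float = 0.04, cum_threshold: float = 0.90
) -> list[int]:
    """Apply the PC retention rule to variance fractions (descending order).

    Keep every PC with fraction > var_threshold; if those do not cumulatively
    exceed cum_threshold, append further PCs in decreasing order until the
    cumulative fraction is strictly greater than cum_threshold.
    """
    fractions = np.asarray(fractions, dtype=float)
    kept = [i for i, f in enumerate(fractions) if f > var_threshold]
    cum = float(fractions[kept].sum()) if kept else 0.0
    i = len(kept)
    # strict ">" with a float-roundoff guard so an exact boundary sum extends
    while cum <= cum_threshold + 1e-9 and i < len(fractions):
        kept.append(i)
        cum += float(fractions[i])
        i += 1
    return kept


@dataclass
class ModulePCs:
    module: int
    loadings: pd.DataFrame  # analyte x PC
    scores: pd.DataFrame  # line x PC (zero-mean columns)
    fractions: np.ndarray
    retained: list[int]


@dataclass
class ModulePCSet:
    per_module: dict[int, ModulePCs]

    def retained_scores(self) -> pd.DataFrame:
        """Line x (module, PC) matrix of all retained PC scores."""
        cols = {}
        for m in sorted(self.per_module):
            pcs = self.per_module[m]
            for i in pcs.retained:
                cols[f"mod{m}_PC{i + 1}"] = pcs.scores.iloc[:, i]
        return pd.DataFrame(cols)


def module_pca(
    line_means: pd.DataFrame,
    partition: ModulePartition,
    var_threshold: float = 0.04,
    cum_threshold: float = 0.90,
    standardize: bool = True,
) -> ModulePCSet:
    """PCA per module on (standardized) line means, with the retention rule.

    Requesting more PCs than the rank allows truncates at the rank (logged).
    Scores are zero-mean across lines; each PC's sign is fixed so its
    largest-|loading| analyte loads positively.
    """
    out: dict[int, ModulePCs] = {}
    for m in range(partition.n_modules):
        members = partition.members(m)
        sub = line_means[members].dropna(axis=0, how="any")
        Xc = sub.to_numpy(dtype=float)
        Xc = Xc - Xc.mean(axis=0)
        if standardize:
            sd = Xc.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            Xc = Xc / sd
        u, sv, vt = np.linalg.svd(Xc, full_matrices=False)
        rank = int((sv > 1e-10 * (sv[0] if sv.size else 1.0)).sum())
        max_pcs = min(len(members), max(Xc.shape[0] - 1, 1))
        if rank < max_pcs:
            logger.info("module %d rank-deficient: %d PCs available", m, rank)
        ncomp = max(rank, 1)
        var = sv[:ncomp] ** 2
        fractions = var / var.sum() if var.sum() > 0 else np.ones(ncomp) / ncomp
        loadings = vt[:ncomp].T  # analyte x PC, orthonormal columns
        scores = u[:, :ncomp] * sv[:ncomp]
        for i in range(ncomp):
            j = int(np.argmax(np.abs(loadings[:, i])))
            if loadings[j, i] < 0:
                loadings[:, i] = -loadings[:, i]
                scores[:, i] = -scores[:, i]
        retained = retained_pc_indices(fractions, var_threshold, cum_threshold)
        pc_names = [f"PC{i + 1}" for i in range(ncomp)]
        out[m] = ModulePCs(
            module=m,
            loadings=pd.DataFrame(loadings, index=members, columns=pc_names),
            scores=pd.DataFrame(scores, index=sub.index, columns=pc_names),
            fractions=fractions,
            retained=retained,
        )
    return ModulePCSet(out)


class ModulePCA(BaseEstimator, TransformerMixin):
    """Transformer: line means -> retained module-PC scores.

    ``fit(X, y)`` takes the line-mean matrix and per-analyte module labels
    (as y); ``transform`` projects a line-mean matrix onto the retained PCs
    fitted from the training lines.
    """

    def __init__(self, var_threshold=0.04, cum_threshold=0.90, standardize=True):
        self.var_threshold = var_threshold
        self.cum_threshold = cum_threshold
        self.standardize = standardize

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        if y is None:
            raise ValueError("ModulePCA.fit requires per-analyte module labels as y")
        labels = np.asarray(y)
        assignment = pd.Series(labels, index=X.columns, name="module")
        mean_abs = pd.Series({m: 0.0 for m in np.unique(labels)})
        part = ModulePartition(assignment, mean_abs, np.nan, (np.nan, np.nan))
        self.partition_ = part
        self._means = X.mean(axis=0)
        self._sds = X.std(axis=0, ddof=1).replace(0.0, 1.0)
        self.pcs_ = module_pca(
            X, part, self.var_threshold, self.cum_threshold, self.standardize
        )
        return self

    def transform(self, X):
        X = pd.DataFrame(X, columns=self._means.index)
        Z = (X - self._means) / (self._sds if self.standardize else 1.0)
        cols = {}
        for m in sorted(self.pcs_.per_module):
            pcs = self.pcs_.per_module[m]
            proj = Z[pcs.loadings.index].to_numpy() @ pcs.loadings.to_numpy()
            for i in pcs.retained:
                cols[f"mod{m}_PC{i + 1}"] = proj[:, i]
        return pd.DataFrame(cols, index=X.index)
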