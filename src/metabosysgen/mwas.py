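"""Metabolome-wide association: Spearman screens of organismal traits against
metabolites and module PCs, super-pathway breakdowns, and clustering of traits
on their correlation profiles.

The screen is deliberately liberal — Spearman rank correlation at a nominal
P < 0.05 with no multiple-testing correction — because it feeds network
assembly and fold-internal enrichment, not headline inference.
"""

from __future__ import annotations

import itertools
import logging
import math

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Exact two-sided permutation P for Spearman rho at small n.

    Enumerates all n! permutations of one rank vector; P is the fraction with
    |rho| >= |rho_obs| (observed included by construction).
    """
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    rx_c = rx - rx.mean()
    sx = math.sqrt((rx_c**2).sum())
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        ry_p = ry[list(perm)]
        ry_c = ry_p - ry_p.mean()
        sy = math.sqrt((ry_c**2).sum())
        r = float(rx_c @ ry_c / (sx * sy)) if sx > 0 and sy > 0 else 0.0
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def spearman_screen(
    traits: pd.DataFrame,
    features: pd.DataFrame,
    alpha: float = 0.05,
    exact_max_n: int = 0,
) -> pd.DataFrame:
    """Spearman correlation of every trait against every feature column.

    Rows with a missing value in either member of a pair are dropped pairwise;
    pairs with fewer than 5 complete lines, or a constant member, are skipped
    with a log message. P-values use the t approximation, or exact permutation
    enumeration when n <= exact_max_n.

    Returns columns: trait, feature, rho, p, n, significant (p < alpha).
    """
    records = []
    for trait in traits.columns:
        for feat in features.columns:
            pair = pd.concat(
                [traits[trait], features[feat]], axis=1, join="inner"
            ).dropna()
            n = len(pair)
            if n < 5:
                logger.info("skip %s~%s: only %d complete pairs", trait, feat, n)
                continue
            x = pair.iloc[:, 0].to_numpy(dtype=float)
            y = pair.iloc[:, 1].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                logger.info("skip %s~%s: constant values", trait, feat)
                continue
            rho, p = stats.spearmanr(x, y)
            if n <= exact_max_n:
                p = _spearman_exact_p(x, y, rho)
            records.append(
                {"trait": trait, "feature": feat, "rho": float(rho), "p": float(p), "n": n}
            )
    out = pd.DataFrame(records, columns=["trait", "feature", "rho", "p", "n"])
    out["significant"] = out["p"] < alpha
    return out


def superpathway_table(
    screen: pd.DataFrame, annotation: pd.DataFrame
) -> pd.DataFrame:
    """Trait x super-pathway counts of significant metabolites.

    Unannotated analytes are counted under "unknown" (warned). Row sums equal
    each trait's significant-metabolite count.
    """
    sig = screen[screen["significant"]]
    if sig.empty:
        return pd.DataFrame()
    ann = dict(zip(annotation["metabolite"], annotation["super_pathway"]))
    missing = set(sig["feature"]) - set(ann)
    if missing:
        logger.warning("%d analytes lack super-pathway annotation", len(missing))
    tab = sig.assign(super_pathway=sig["feature"].map(ann).fillna("unknown"))
    return tab.pivot_table(
        index="trait", columns="super_pathway", values="feature",
        aggfunc="nunique", fill_value=0,
    )


def trait_profiles(screen: pd.DataFrame, zero_nonsignificant: bool = True) -> pd.DataFrame:
    """Trait x feature matrix of signed rho (0 where non-significant).

    Traits with an all-zero profile are excluded with a warning.
    """
    rho = screen.pivot_table(index="trait", columns="feature", values="rho").fillna(0.0)
    if zero_nonsignificant:
        sig = screen.pivot_table(
            index="trait", columns="feature", values="significant", aggfunc="first"
        ).fillna(False).astype(bool)
        rho = rho.where(sig, 0.0)
    keep = (rho != 0).any(axis=1)
    dropped = list(rho.index[~keep])
    if dropped:
        logger.warning("traits with all-zero profiles excluded: %s", dropped)
    return rho[keep]


def cluster_traits(
    screen: pd.DataFrame,
    cut_height: float | None = None,
    n_clusters: int | None = None,
    linkage_method: str = "average",
    zero_nonsignificant: bool = True,
) -> tuple[np.ndarray, pd.Series, pd.DataFrame]:
    """Hierarchically cluster traits on their signed correlation profiles.

    Distance between two traits is 1 - Pearson correlation of their profiles;
    linkage is average by default. Returns (linkage matrix, cluster labels at
    the requested cut, profile matrix). With neither cut_height nor
    n_clusters, every trait is labelled 1 (single tree, no cut).
    """
    prof = trait_profiles(screen, zero_nonsignificant)
    if len(prof) < 2:
        labels = pd.Series(np.ones(len(prof), dtype=int), index=prof.index)
        return np.empty((0, 4)), labels, prof
    c = np.corrcoef(prof.to_numpy())
    c = np.nan_to_num(c, nan=0.0)
    d = 1.0 - c
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(squareform(d, checks=False), method=linkage_method)
    if n_clusters is not None:
        lab = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    elif cut_height is not None:
        lab = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
    else:
        lab = np.ones(len(prof), dtype=int)
    return Z, pd.Series(lab, index=prof.index, name="cluster"), prof


def dendrogram_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Newick string for a scipy linkage matrix (branch lengths from heights)."""
    from skbio.tree import TreeNode

    if len(Z) == 0:
        return f"({labels[0]});" if len(labels) == 1 else ";"
    tree = TreeNode.from_linkage_matrix(Z, labels)
    return str(tree).strip()
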