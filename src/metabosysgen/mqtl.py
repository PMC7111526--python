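"""Association mapping of line-level phenotypes on inbred-panel genotypes.

Genotypes are two homozygous classes coded {0, 1}. With unrelated,
inversion-free, Wolbachia-free lines the association model reduces to
ordinary least squares of the phenotype line value on the genotype class —
equivalently a pooled-variance two-sample t-test. Variants are kept when the
minor class contains at least ``min_minor_lines`` lines (4 of 40 is a minor
allele frequency of 0.1), and genome-wide significance uses a Bonferroni
threshold alpha / n_tests.

Hits are annotated against a gene model (1-based closed intervals); variants
outside all genes are single-linkage merged into intergenic regions when
within 2 kb of each other.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def filter_variants(genotypes: pd.DataFrame, min_minor_lines: int = 4) -> list:
    """Variant ids whose minor-class line count (over non-missing lines) is
    at least ``min_minor_lines``. Monomorphic variants are dropped."""
    g = genotypes.to_numpy(dtype=float)
    finite = np.isfinite(g)
    if not np.isin(g[finite], (0.0, 1.0)).all():
        raise ValueError("genotype entries must be 0, 1 or missing")
    n_one = np.nansum(g, axis=0)
    n_called = finite.sum(axis=0)
    minor = np.minimum(n_one, n_called - n_one)
    keep = minor >= min_minor_lines
    return list(genotypes.columns[keep])


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Genome-wide significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def map_associations(
    phenotype: pd.Series,
    genotypes: pd.DataFrame,
    variants: list | None = None,
    min_minor_lines: int = 4,
    phenotype_id: str = "",
) -> pd.DataFrame:
    """OLS of a line-level phenotype on each variant's genotype class.

    Effect is the coded-1 minus coded-0 class mean difference (so inverting
    the coding flips the sign and leaves P unchanged), with a two-sided t
    P-value on n - 2 degrees of freedom. Lines with missing phenotype or
    genotype are excluded per variant; a variant is skipped (logged) if either
    class then has fewer than ``min_minor_lines`` lines. Records are sorted by
    P.
    """
    if variants is None:
        variants = list(genotypes.columns)
    common = genotypes.index.intersection(phenotype.dropna().index)
    g = genotypes.loc[common, variants].to_numpy(dtype=float)
    y = phenotype.loc[common].to_numpy(dtype=float)

    if np.nanstd(y) == 0:
        logger.warning("phenotype %r constant: all P = 1", phenotype_id)

    called = np.isfinite(g)
    g0 = np.where(called, g, 0.0)
    n1 = (g0 * called).sum(axis=0)
    n = called.sum(axis=0)
    n0 = n - n1
    ok = (np.minimum(n0, n1) >= min_minor_lines) & (n >= 2 * min_minor_lines)
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.info("map_associations: %d variants skipped (class below minimum)", n_skipped)

    sum1 = (g0 * y[:, None] * called).sum(axis=0)
    sumy = (y[:, None] * called).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean1 = sum1 / n1
        mean0 = (sumy - sum1) / n0
        sq = ((y[:, None] - np.where(g0 == 1, mean1, mean0)) ** 2 * called).sum(axis=0)
        dfree = n - 2
        s2 = sq / dfree
        se = np.sqrt(s2 * (1.0 / n0 + 1.0 / n1))
        tstat = (mean1 - mean0) / se
    p = 2.0 * stats.t.sf(np.abs(tstat), dfree)
    p = np.where(se == 0, np.where(mean1 != mean0, 0.0, 1.0), p)
    if np.nanstd(y) == 0:
        p = np.ones_like(p)

    out = pd.DataFrame(
        {
            "variant": variants,
            "phenotype": phenotype_id or (phenotype.name or "phenotype"),
            "effect": mean1 - mean0,
            "se": se,
            "p": p,
            "n_lines": n,
            "n_minor": np.minimum(n0, n1).astype(int),
        }
    )[ok]
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)


def map_many(
    phenotypes: pd.DataFrame,
    genotypes: pd.DataFrame,
    variants: list | None = None,
    threshold: float | None = None,
    min_minor_lines: int = 4,
) -> pd.DataFrame:
    """Association scan for every phenotype column; optionally keep P <= threshold."""
    frames = []
    for col in phenotypes.columns:
        rec = map_associations(
            phenotypes[col], genotypes, variants, min_minor_lines, phenotype_id=str(col)
        )
        if threshold is not None:
            rec = rec[rec["p"] <= threshold]
        frames.append(rec)
    if not frames:
        return pd.DataFrame(columns=["variant", "phenotype", "effect", "se", "p", "n_lines", "n_minor"])
    return pd.concat(frames, ignore_index=True)


def top_n_threshold(records: pd.DataFrame, n: int) -> tuple[pd.DataFrame, float]:
    """Top-n records by P with the implied relaxed threshold reported.

    Mirrors matching a fixed-size hit set by relaxing the P-value cutoff; ties
    at the boundary are included.
    """
    if records.empty or n <= 0:
        return records.iloc[0:0], float("nan")
    srt = records.sort_values("p", kind="mergesort")
    cut = float(srt["p"].iloc[min(n, len(srt)) - 1])
    return srt[srt["p"] <= cut].reset_index(drop=True), cut


@dataclass(frozen=True)
class VariantLocus:
    variant: str
    chrom: str
    pos: int


def parse_variant_id(vid: str) -> VariantLocus:
    """Parse "chrom_pos_class" variant ids (e.g. "2L_12345_SNP")."""
    chrom, pos, _cls = vid.rsplit("_", 2)
    return VariantLocus(vid, chrom, int(pos))


def annotate_hits(
    hits: pd.DataFrame,
    gene_model: pd.DataFrame,
    merge_distance: int = 2000,
    site_classes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Annotate hit variants with genes or merged intergenic regions.

    gene_model columns: chrom, start, end, gene (1-based closed intervals).
    A variant inside a gene span is labelled with that gene (all overlapping
    genes, comma-joined, site class from ``site_classes`` when provided);
    variants in no gene are intergenic and are single-linkage merged into one
    region when within ``merge_distance`` bp of each other on a chromosome.
    """
    if hits.empty:
        out = hits.copy()
        out["annotation"] = pd.Series(dtype=str)
        out["region"] = pd.Series(dtype=str)
        return out
    loci = pd.DataFrame([parse_variant_id(v).__dict__ for v in hits["variant"].unique()])
    gene_labels, regions = {}, {}
    site_map = {}
    if site_classes is not None:
        site_map = dict(zip(site_classes["variant"], site_classes["site_class"]))

    for chrom, chrom_loci in loci.groupby("chrom"):
        genes = gene_model[gene_model["chrom"] == chrom]
        inter = []
        for _, row in chrom_loci.iterrows():
            inside = genes[(genes["start"] <= row.pos) & (row.pos <= genes["end"])]
            if len(inside):
                label = ",".join(sorted(inside["gene"]))
                sc = site_map.get(row.variant, "gene_body")
                gene_labels[row.variant] = f"{label}|{sc}" if site_classes is not None else label
            else:
                inter.append((row.pos, row.variant))
        inter.sort()
        region_i = 0
        prev = None
        for pos, vid in inter:
            if prev is None or pos - prev > merge_distance:
                region_i += 1
            regions[vid] = f"{chrom}:region_{region_i}"
            prev = pos

    out = hits.copy()
    out["annotation"] = out["variant"].map(gene_labels).fillna("intergenic")
    out["region"] = out["variant"].map(regions)
    return out


def pleiotropy_summary(hits: pd.DataFrame) -> dict:
    """Pleiotropy summary of a hit list over (variant, phenotype) pairs.

    Returns per-variant metabolite counts, the percentage of variants
    associated with exactly one metabolite, and the mean/median number of
    mQTLs per metabolite.
    """
    if hits.empty:
        return {
            "n_variants": 0,
            "n_phenotypes": 0,
            "per_variant": pd.Series(dtype=int),
            "pct_single_phenotype": float("nan"),
            "per_phenotype": pd.Series(dtype=int),
            "mean_mqtl_per_phenotype": float("nan"),
            "median_mqtl_per_phenotype": float("nan"),
        }
    pairs = hits[["variant", "phenotype"]].drop_duplicates()
    per_variant = pairs.groupby("variant")["phenotype"].nunique()
    per_pheno = pairs.groupby("phenotype")["variant"].nunique()
    return {
        "n_variants": int(len(per_variant)),
        "n_phenotypes": int(len(per_pheno)),
        "per_variant": per_variant,
        "pct_single_phenotype": float(100.0 * (per_variant == 1).mean()),
        "per_phenotype": per_pheno,
        "mean_mqtl_per_phenotype": float(per_pheno.mean()),
        "median_mqtl_per_phenotype": float(per_pheno.median()),
    }
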