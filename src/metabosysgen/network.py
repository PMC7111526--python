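"""Integrated variant-transcript-metabolite-trait networks.

For one focal trait and sex: metabolites correlated with the trait (Spearman,
nominal P < 0.05) are linked to transcripts at |rho| > 0.45; each metabolite's
mQTLs are then tested against its linked transcripts, keeping variant-gene
pairs below the metabolite-specific Bonferroni threshold 0.05 / (that
metabolite's mQTL count) — these are the meQTLs. Nodes are typed (metabolite
with super pathway, gene, variant) and flagged when directly associated with
the focal trait at nominal P < 0.05; correlation edges carry the sign of rho.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .mqtl import map_associations, parse_variant_id

logger = logging.getLogger(__name__)


def select_trait_metabolites(screen: pd.DataFrame, trait: str, alpha: float = 0.05) -> list[str]:
    """Metabolites whose Spearman P against the trait is below alpha."""
    sub = screen[(screen["trait"] == trait) & (screen["p"] < alpha)]
    return sorted(sub["feature"].unique())


def link_transcripts(
    metabolites: list[str],
    metabolite_line_means: pd.DataFrame,
    transcript_line_means: pd.DataFrame,
    rho_threshold: float = 0.45,
    min_pairs: int = 5,
) -> pd.DataFrame:
    """(gene, metabolite, rho) pairs with Spearman |rho| > rho_threshold.

    Lines missing from either table are dropped pairwise; pairs with fewer
    than ``min_pairs`` complete lines are skipped (logged).
    """
    records = []
    for met in metabolites:
        if met not in metabolite_line_means.columns:
            continue
        for gene in transcript_line_means.columns:
            pair = pd.concat(
                [metabolite_line_means[met], transcript_line_means[gene]],
                axis=1, join="inner",
            ).dropna()
            if len(pair) < min_pairs:
                logger.info("skip %s~%s: %d complete pairs", gene, met, len(pair))
                continue
            rho, p = stats.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1])
            if np.isfinite(rho) and abs(rho) > rho_threshold:
                records.append(
                    {"gene": gene, "metabolite": met, "rho": float(rho), "p": float(p)}
                )
    return pd.DataFrame(records, columns=["gene", "metabolite", "rho", "p"])


def find_meqtls(
    mqtl_hits: pd.DataFrame,
    links: pd.DataFrame,
    transcript_line_means: pd.DataFrame,
    genotypes: pd.DataFrame,
    alpha: float = 0.05,
    min_minor_lines: int = 4,
) -> pd.DataFrame:
    """Variants associated with both a metabolite and a linked transcript.

    For each metabolite with m mQTLs, each of those variants is tested against
    each transcript linked to that metabolite (same OLS as mQTL mapping); a
    variant-gene pair is kept when P < alpha / m — the metabolite-specific
    Bonferroni rule. Metabolites with zero mQTLs are skipped.
    """
    records = []
    for met, met_hits in mqtl_hits.groupby("phenotype"):
        met_links = links[links["metabolite"] == met]
        if met_links.empty:
            continue
        variants = sorted(met_hits["variant"].unique())
        threshold = alpha / len(variants)
        for gene in sorted(met_links["gene"].unique()):
            rec = map_associations(
                transcript_line_means[gene], genotypes, variants,
                min_minor_lines=min_minor_lines, phenotype_id=gene,
            )
            sig = rec[rec["p"] < threshold]
            for _, row in sig.iterrows():
                records.append(
                    {
                        "variant": row["variant"],
                        "gene": gene,
                        "metabolite": met,
                        "effect": row["effect"],
                        "p": float(row["p"]),
                        "threshold": threshold,
                    }
                )
    out = pd.DataFrame(
        records, columns=["variant", "gene", "metabolite", "effect", "p", "threshold"]
    )
    assert (out["p"] < out["threshold"]).all(), "meQTL above its metabolite-specific threshold"
    return out.drop_duplicates(subset=["variant", "gene", "metabolite"]).reset_index(drop=True)


def _sign(x: float) -> str:
    return "positive" if x > 0 else "negative"


def assemble_network(
    trait: str,
    sex: str,
    metabolites: list[str],
    links: pd.DataFrame,
    meqtls: pd.DataFrame,
    mqtl_hits: pd.DataFrame,
    trait_line_means: pd.Series | None = None,
    metabolite_line_means: pd.DataFrame | None = None,
    transcript_line_means: pd.DataFrame | None = None,
    genotypes: pd.DataFrame | None = None,
    annotation: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> nx.Graph:
    """Build the typed, signed multi-omic graph for one trait and sex.

    Nodes: selected metabolites (super pathway attribute), genes linked to
    them, and meQTL variants. Edges: gene-metabolite correlation (sign and
    rho weight), variant-gene and variant-metabolite association edges.
    Nodes directly associated/correlated with the focal trait at nominal
    P < alpha are flagged. Isolated nodes are removed; node and edge insertion
    order is sorted, so identical inputs give identical GraphML bytes.
    """
    g = nx.Graph(trait=trait, sex=sex)
    ann = {}
    if annotation is not None:
        ann = dict(zip(annotation["metabolite"], annotation["super_pathway"]))

    met_set = sorted(metabolites)
    keep_links = links[links["metabolite"].isin(met_set)]
    keep_meqtls = meqtls[meqtls["metabolite"].isin(met_set)]

    for met in met_set:
        g.add_node(met, node_type="metabolite", super_pathway=ann.get(met, "unknown"),
                   trait_flag=True)  # selected metabolites correlate with the trait by construction
    for gene in sorted(keep_links["gene"].unique()):
        g.add_node(gene, node_type="gene", trait_flag=False)
    for var in sorted(keep_meqtls["variant"].unique()):
        g.add_node(var, node_type="variant", trait_flag=False)

    for _, row in keep_links.sort_values(["gene", "metabolite"]).iterrows():
        g.add_edge(row["gene"], row["metabolite"], edge_type="correlation",
                   sign=_sign(row["rho"]), weight=float(row["rho"]), p=float(row["p"]))
    for _, row in keep_meqtls.sort_values(["variant", "gene"]).iterrows():
        g.add_edge(row["variant"], row["gene"], edge_type="variant_gene",
                   p=float(row["p"]), weight=float(abs(row["effect"])))
        met_rec = mqtl_hits[
            (mqtl_hits["variant"] == row["variant"]) & (mqtl_hits["phenotype"] == row["metabolite"])
        ]
        if len(met_rec):
            g.add_edge(row["variant"], row["metabolite"], edge_type="variant_metabolite",
                       p=float(met_rec["p"].iloc[0]), weight=float(abs(met_rec["effect"].iloc[0])))

    # direct trait associations for genes and variants
    if trait_line_means is not None:
        for gene in sorted(keep_links["gene"].unique()):
            if transcript_line_means is None or gene not in transcript_line_means:
                continue
            pair = pd.concat([trait_line_means, transcript_line_means[gene]], axis=1, join="inner").dropna()
            if len(pair) >= 5:
                _, p = stats.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1])
                if p < alpha:
                    g.nodes[gene]["trait_flag"] = True
                    g.nodes[gene]["trait_p"] = float(p)
        if genotypes is not None and len(keep_meqtls):
            variants = sorted(keep_meqtls["variant"].unique())
            rec = map_associations(trait_line_means, genotypes, variants, phenotype_id=trait)
            for _, row in rec[rec["p"] < alpha].iterrows():
                g.nodes[row["variant"]]["trait_flag"] = True
                g.nodes[row["variant"]]["trait_p"] = float(row["p"])

    g.remove_nodes_from(list(nx.isolates(g)))
    return g


def classify_cis_trans(
    meqtls: pd.DataFrame, gene_model: pd.DataFrame, window: int = 1000
) -> pd.Series:
    """Label each meQTL record cis or trans relative to its linked gene.

    cis iff the variant lies within the gene body extended by ``window`` bp on
    both sides (same chromosome); genes absent from the model get "unknown".
    """
    gm = gene_model.set_index("gene")
    labels = []
    for _, row in meqtls.iterrows():
        if row["gene"] not in gm.index:
            labels.append("unknown")
            continue
        loc = parse_variant_id(row["variant"])
        rec = gm.loc[row["gene"]]
        if (
            loc.chrom == rec["chrom"]
            and rec["start"] - window <= loc.pos <= rec["end"] + window
        ):
            labels.append("cis")
        else:
            labels.append("trans")
    return pd.Series(labels, index=meqtls.index, name="cis_trans")


def write_graphml(g: nx.Graph, path) -> None:
    nx.write_graphml(g, path)


def edge_list(g: nx.Graph) -> pd.DataFrame:
    """Flat, deterministically ordered edge table of an integrated network."""
    rows = [
        {"source": u, "target": v, **data}
        for u, v, data in sorted(g.edges(data=True), key=lambda e: (str(e[0]), str(e[1])))
    ]
    return pd.DataFrame(rows)
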