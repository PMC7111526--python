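"""Integrated-network assembly: selection thresholds, the |rho| > 0.45
transcript rule, metabolite-specific Bonferroni meQTLs, cis/trans labels,
and bit-for-bit reproducibility."""

import io

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from metabosysgen import mqtl, mwas, network, quantgen
from metabosysgen.synthetic import simulate_panel

from conftest import chain_config


def screen_row(trait, feature, rho, p):
    return {"trait": trait, "feature": feature, "rho": rho, "p": p, "n": 40,
            "significant": p < 0.05}


class TestSelection:
    def test_nominal_threshold_boundary(self):
        screen = pd.DataFrame([
            screen_row("t", "m_in", 0.4, 0.049),
            screen_row("t", "m_out", 0.4, 0.051),
        ])
        assert network.select_trait_metabolites(screen, "t") == ["m_in"]

    def test_empty_selection_gives_empty_network(self):
        g = network.assemble_network(
            "t", "F", [], pd.DataFrame(columns=["gene", "metabolite", "rho", "p"]),
            pd.DataFrame(columns=["variant", "gene", "metabolite", "effect", "p", "threshold"]),
            pd.DataFrame(columns=["variant", "phenotype", "effect", "p"]),
        )
        assert g.number_of_nodes() == 0


class TestLinkTranscripts:
    def make_pair(self, rho, n=40, seed=0):
        r = np.random.default_rng(seed)
        x = r.standard_normal(n)
        # construct a pair with approximately the requested Spearman rho by mixing
        y = rho * x + np.sqrt(max(1 - rho**2, 0)) * r.standard_normal(n)
        idx = [f"L{i}" for i in range(n)]
        return (pd.DataFrame({"met": x}, index=idx), pd.DataFrame({"gene": y}, index=idx))

    def test_threshold_rule_kept_and_dropped(self):
        # exact control: use monotone transforms to pin the Spearman value
        idx = [f"L{i}" for i in range(10)]
        x = pd.DataFrame({"met": np.arange(10.0)}, index=idx)
        strong = pd.DataFrame({"gene": np.argsort(np.argsort(
            [0, 1, 2, 3, 4, 5, 6, 7, 9, 8]))}, index=idx)  # rho ~ 0.988
        weak = pd.DataFrame({"gene": np.random.default_rng(3).permutation(10).astype(float)}, index=idx)
        links = network.link_transcripts(["met"], x, strong)
        assert len(links) == 1 and links.iloc[0]["rho"] > 0.45
        from scipy import stats
        while abs(stats.spearmanr(x["met"], weak["gene"]).statistic) > 0.44:
            weak["gene"] = np.random.default_rng(4).permutation(10).astype(float)
        assert network.link_transcripts(["met"], x, weak).empty

    def test_negative_rho_kept_with_sign(self):
        met, gene = self.make_pair(-0.9)
        links = network.link_transcripts(["met"], met, gene)
        assert len(links) == 1 and links.iloc[0]["rho"] < -0.45

    def test_too_few_pairs_skipped(self):
        met, gene = self.make_pair(0.9, n=4)
        assert network.link_transcripts(["met"], met, gene).empty


class TestMeqtls:
    def test_metabolite_specific_threshold_arithmetic(self):
        # one metabolite with 10 mQTLs -> per-test threshold 0.005
        r = np.random.default_rng(0)
        idx = [f"L{i}" for i in range(40)]
        g = pd.DataFrame(
            {f"v{i}": (r.random(40) < 0.5).astype(float) for i in range(10)}, index=idx
        )
        hits = pd.DataFrame({"variant": [f"v{i}" for i in range(10)],
                             "phenotype": "met", "effect": 1.0, "p": 1e-9})
        # transcript strongly driven by v0 only
        tr = pd.DataFrame({"gene": 3.0 * g["v0"] + 0.1 * r.standard_normal(40)}, index=idx)
        links = pd.DataFrame([{"gene": "gene", "metabolite": "met", "rho": 0.9, "p": 1e-5}])
        out = network.find_meqtls(hits, links, tr, g)
        assert np.allclose(out["threshold"], 0.05 / 10)
        assert "v0" in set(out["variant"])

    def test_single_mqtl_threshold_is_alpha(self):
        r = np.random.default_rng(1)
        idx = [f"L{i}" for i in range(40)]
        g = pd.DataFrame({"v0": (r.random(40) < 0.5).astype(float)}, index=idx)
        hits = pd.DataFrame({"variant": ["v0"], "phenotype": "met", "effect": 1.0, "p": 1e-9})
        tr = pd.DataFrame({"gene": 3.0 * g["v0"] + 0.1 * r.standard_normal(40)}, index=idx)
        links = pd.DataFrame([{"gene": "gene", "metabolite": "met", "rho": 0.9, "p": 1e-5}])
        out = network.find_meqtls(hits, links, tr, g)
        assert np.allclose(out["threshold"], 0.05)

    def test_null_family_wise_false_link_rate(self):
        # no variant-gene effect: per-metabolite familywise error <= alpha
        false_hits = 0
        n_sims = 400
        for seed in range(n_sims):
            r = np.random.default_rng(seed)
            idx = [f"L{i}" for i in range(40)]
            g = pd.DataFrame(
                {f"v{i}": (r.random(40) < 0.5).astype(float) for i in range(5)}, index=idx
            )
            hits = pd.DataFrame({"variant": [f"v{i}" for i in range(5)],
                                 "phenotype": "met", "effect": 1.0, "p": 1e-9})
            tr = pd.DataFrame({"gene": r.standard_normal(40)}, index=idx)
            links = pd.DataFrame([{"gene": "gene", "metabolite": "met", "rho": 0.5, "p": 1e-3}])
            if len(network.find_meqtls(hits, links, tr, g)):
                false_hits += 1
        assert false_hits / n_sims <= 0.08  # alpha = 0.05 plus binomial noise


class TestAssembly:
    def test_planted_chain_recovered_with_expected_edges(self):
        cfg = chain_config(seed=21)
        panel = simulate_panel(cfg)
        lm = quantgen.line_means(panel.metabolome, "F")
        screen = mwas.spearman_screen(panel.traits["F"], lm)
        mets = network.select_trait_metabolites(screen, "focal")
        assert "met_0001" in mets
        links = network.link_transcripts(mets, lm, panel.transcripts["F"])
        kept = mqtl.filter_variants(panel.genotypes)
        hits = mqtl.map_many(lm[mets], panel.genotypes, kept,
                             threshold=mqtl.bonferroni_threshold(len(kept)))
        meqtls = network.find_meqtls(hits, links, panel.transcripts["F"], panel.genotypes)
        g = network.assemble_network(
            "focal", "F", mets, links, meqtls, hits,
            trait_line_means=panel.traits["F"]["focal"],
            transcript_line_means=panel.transcripts["F"],
            genotypes=panel.genotypes, annotation=panel.annotation,
        )
        v = cfg.mqtl_spec[0].variant
        vid = panel.genotypes.columns[v]
        assert g.has_edge(vid, "gene_0001")
        assert g.has_edge(vid, "met_0001")
        assert g.has_edge("gene_0001", "met_0001")
        corr_edge = g.edges["gene_0001", "met_0001"]
        assert corr_edge["sign"] in ("positive", "negative")
        assert (corr_edge["weight"] > 0) == (corr_edge["sign"] == "positive")

    def test_graph_reproducible_bit_for_bit(self):
        cfg = chain_config(seed=22)
        panel = simulate_panel(cfg)
        lm = quantgen.line_means(panel.metabolome, "F")
        screen = mwas.spearman_screen(panel.traits["F"], lm)
        mets = network.select_trait_metabolites(screen, "focal")
        links = network.link_transcripts(mets, lm, panel.transcripts["F"])
        kept = mqtl.filter_variants(panel.genotypes)
        hits = mqtl.map_many(lm[mets] if mets else lm, panel.genotypes, kept, threshold=1e-5)
        meqtls = network.find_meqtls(hits, links, panel.transcripts["F"], panel.genotypes)
        blobs = []
        for _ in range(2):
            g = network.assemble_network("focal", "F", mets, links, meqtls, hits,
                                         annotation=panel.annotation)
            buf = io.BytesIO()
            nx.write_graphml(g, buf)
            blobs.append(buf.getvalue())
        assert blobs[0] == blobs[1]


class TestCisTrans:
    gm = pd.DataFrame({"chrom": ["2L"], "start": [10_000], "end": [20_000], "gene": ["gA"]})

    def rec(self, vid, gene="gA"):
        return pd.DataFrame([{"variant": vid, "gene": gene, "metabolite": "m",
                              "effect": 1.0, "p": 1e-4, "threshold": 0.05}])

    @pytest.mark.parametrize(
        "vid,expected",
        [
            ("2L_15000_SNP", "cis"),      # inside the gene body
            ("3R_15000_SNP", "trans"),    # different chromosome
            ("2L_9001_SNP", "cis"),       # 999 bp upstream, window 1 kb
            ("2L_8999_SNP", "trans"),     # 1001 bp upstream
        ],
    )
    def test_window_arithmetic(self, vid, expected):
        out = network.classify_cis_trans(self.rec(vid), self.gm, window=1000)
        assert out.iloc[0] == expected

    def test_unknown_gene(self):
        out = network.classify_cis_trans(self.rec("2L_15000_SNP", gene="nope"), self.gm)
        assert out.iloc[0] == "unknown"
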