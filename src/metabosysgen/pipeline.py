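"""End-to-end orchestration: simulate -> variance components -> modules ->
mQTL -> MWAS -> network -> prediction, with a JSON manifest of every output.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, modules, mqtl, mwas, network, prediction, quantgen
from .synthetic import SEXES, SimulationConfig, SyntheticPanel, simulate_panel

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: Path
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    fdr: float = 0.05
    nominal_alpha: float = 0.05
    rho_threshold: float = 0.45
    min_minor_lines: int = 4
    intergenic_merge: int = 2000
    pc_var_threshold: float = 0.04
    pc_cum_threshold: float = 0.90
    enrichment_thresholds: tuple = prediction.DEFAULT_ENRICHMENT_THRESHOLDS
    gwas_alpha: float = 0.05
    run_prediction: bool = True

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        for name in ("fdr", "nominal_alpha", "gwas_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if not 0 < self.pc_cum_threshold <= 1:
            raise ValueError("pc_cum_threshold must be in (0,1]")


def run_pipeline(cfg: PipelineConfig, panel: SyntheticPanel | None = None) -> dict:
    """Run every stage on a (simulated) panel; returns the output manifest."""
    t0 = time.time()
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "seed": cfg.sim.seed, "outputs": {}}

    def record(stage: str, path: Path) -> None:
        manifest["outputs"][str(path.relative_to(out))] = io.file_checksum(path)
        manifest["stages"].setdefault(stage, []).append(str(path.relative_to(out)))

    def stage_time(stage: str, start: float) -> None:
        manifest["stages"].setdefault("timings", {})
        manifest["stages"]["timings"][stage] = round(time.time() - start, 3)

    # --- simulate -----------------------------------------------------------
    ts = time.time()
    if panel is None:
        panel = simulate_panel(cfg.sim)
    io.write_genotypes_tsv(panel.genotypes, out / "genotypes.tsv")
    record("simulate", out / "genotypes.tsv")
    io.write_tsv(panel.metabolome, out / "metabolome.tsv", index=False)
    record("simulate", out / "metabolome.tsv")
    io.write_tsv(panel.annotation, out / "annotation.tsv", index=False)
    record("simulate", out / "annotation.tsv")
    for sex in SEXES:
        io.write_tsv(panel.transcripts[sex], out / f"transcripts_{sex}.tsv")
        record("simulate", out / f"transcripts_{sex}.tsv")
        io.write_tsv(panel.traits[sex], out / f"traits_{sex}.tsv")
        record("simulate", out / f"traits_{sex}.tsv")
    stage_time("simulate", ts)

    # --- variance components ------------------------------------------------
    ts = time.time()
    vc_full = quantgen.variance_component_table(panel.metabolome, scope="full", fdr=cfg.fdr)
    io.write_tsv(vc_full, out / "varcomp_full.tsv", index=False)
    record("varcomp", out / "varcomp_full.tsv")
    variable: dict[str, list[str]] = {}
    line_means: dict[str, pd.DataFrame] = {}
    for sex in SEXES:
        vc_sex = quantgen.variance_component_table(panel.metabolome, scope=sex, fdr=cfg.fdr)
        io.write_tsv(vc_sex, out / f"varcomp_{sex}.tsv", index=False)
        record("varcomp", out / f"varcomp_{sex}.tsv")
        variable[sex] = list(vc_sex[vc_sex["variable"]]["analyte"])
        line_means[sex] = quantgen.line_means(panel.metabolome, sex)
        io.write_tsv(line_means[sex], out / f"line_means_{sex}.tsv")
        record("varcomp", out / f"line_means_{sex}.tsv")
    manifest["mean_H2"] = float(vc_full["H2"].mean())
    stage_time("varcomp", ts)

    # --- modules + PCs ------------------------------------------------------
    ts = time.time()
    partitions, pc_scores = {}, {}
    for sex in SEXES:
        lm_var = line_means[sex][variable[sex]] if variable[sex] else line_means[sex]
        corr = modules.metabolite_correlations(lm_var)
        part = modules.cluster_modules(corr)
        partitions[sex] = part
        pcs = modules.module_pca(lm_var, part, cfg.pc_var_threshold, cfg.pc_cum_threshold)
        pc_scores[sex] = pcs.retained_scores()
        io.write_tsv(
            pd.DataFrame({"module": part.assignment,
                          "mean_abs_corr": part.assignment.map(part.mean_abs_corr)}),
            out / f"modules_{sex}.tsv",
        )
        record("modules", out / f"modules_{sex}.tsv")
        io.write_tsv(pc_scores[sex], out / f"module_pcs_{sex}.tsv")
        record("modules", out / f"module_pcs_{sex}.tsv")
    stage_time("modules", ts)

    # --- mQTL mapping -------------------------------------------------------
    ts = time.time()
    kept = mqtl.filter_variants(panel.genotypes, cfg.min_minor_lines)
    threshold = mqtl.bonferroni_threshold(len(kept) * 1, cfg.gwas_alpha)
    hits = {}
    for sex in SEXES:
        lm_var = line_means[sex][variable[sex]] if variable[sex] else line_means[sex]
        hits[sex] = mqtl.map_many(lm_var, panel.genotypes, kept, threshold=threshold,
                                  min_minor_lines=cfg.min_minor_lines)
        io.write_tsv(hits[sex], out / f"mqtl_hits_{sex}.tsv", index=False)
        record("mqtl", out / f"mqtl_hits_{sex}.tsv")
    manifest["bonferroni_threshold"] = threshold
    manifest["n_variants_tested"] = len(kept)
    stage_time("mqtl", ts)

    # --- MWAS ---------------------------------------------------------------
    ts = time.time()
    screens = {}
    for sex in SEXES:
        feats = pd.concat([line_means[sex], pc_scores[sex]], axis=1)
        screens[sex] = mwas.spearman_screen(panel.traits[sex], feats, alpha=cfg.nominal_alpha)
        io.write_tsv(screens[sex], out / f"mwas_{sex}.tsv", index=False)
        record("mwas", out / f"mwas_{sex}.tsv")
        met_screen = screens[sex][screens[sex]["feature"].isin(line_means[sex].columns)]
        sp = mwas.superpathway_table(met_screen, panel.annotation)
        io.write_tsv(sp, out / f"superpathways_{sex}.tsv")
        record("mwas", out / f"superpathways_{sex}.tsv")
        if panel.traits[sex].shape[1] >= 2:
            Z, labels, prof = mwas.cluster_traits(screens[sex])
            if len(Z):
                newick = mwas.dendrogram_newick(Z, list(prof.index))
                (out / f"trait_dendrogram_{sex}.nwk").write_text(newick + "\n")
                record("mwas", out / f"trait_dendrogram_{sex}.nwk")
    stage_time("mwas", ts)

    # --- networks -----------------------------------------------------------
    ts = time.time()
    for sex in SEXES:
        met_screen = screens[sex][screens[sex]["feature"].isin(line_means[sex].columns)]
        for trait in panel.traits[sex].columns:
            mets = network.select_trait_metabolites(met_screen, trait, cfg.nominal_alpha)
            links = network.link_transcripts(
                mets, line_means[sex], panel.transcripts[sex], cfg.rho_threshold
            )
            meqtls = network.find_meqtls(
                hits[sex][hits[sex]["phenotype"].isin(mets)], links,
                panel.transcripts[sex], panel.genotypes,
                alpha=cfg.nominal_alpha, min_minor_lines=cfg.min_minor_lines,
            )
            g = network.assemble_network(
                trait, sex, mets, links, meqtls, hits[sex],
                trait_line_means=panel.traits[sex][trait],
                metabolite_line_means=line_means[sex],
                transcript_line_means=panel.transcripts[sex],
                genotypes=panel.genotypes,
                annotation=panel.annotation,
                alpha=cfg.nominal_alpha,
            )
            path = out / f"network_{trait}_{sex}.graphml"
            network.write_graphml(g, path)
            record("network", path)
    stage_time("network", ts)

    # --- prediction ---------------------------------------------------------
    if cfg.run_prediction:
        ts = time.time()
        summary = {}
        for sex in SEXES:
            for trait in panel.traits[sex].columns:
                y = panel.traits[sex][trait].dropna()
                cv_all = prediction.loocv_blup(y, line_means[sex].fillna(line_means[sex].mean()),
                                               tag="metabolites")
                enriched = prediction.mwas_enriched_loocv(
                    y, line_means[sex].fillna(line_means[sex].mean()),
                    thresholds=cfg.enrichment_thresholds,
                )
                summary[f"{trait}_{sex}"] = {
                    "blup_all_metabolites": cv_all.accuracy,
                    **{f"mwas_blup_P<{x}": enriched[x].accuracy for x in enriched},
                }
        io.write_json(summary, out / "prediction_accuracy.json")
        record("predict", out / "prediction_accuracy.json")
        manifest["prediction"] = summary
        stage_time("predict", ts)

    manifest["runtime_s"] = round(time.time() - t0, 3)
    io.write_json(
        {k: v for k, v in manifest.items() if k != "prediction"} | {"prediction": manifest.get("prediction", {})},
        out / "manifest.json",
    )
    return manifest
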