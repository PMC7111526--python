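"""Synthetic inbred-panel generator with recorded ground truth.

Emulates a DGRP-style design: fully inbred lines (two homozygous genotype
classes, no heterozygotes), both sexes, replicate pools per line x sex, a few
hundred metabolites with line / sex / line-by-sex / error variance components,
block-modular correlation structure among metabolites, sparse planted mQTL and
eQTL effects, and organismal traits that are noisy linear functions of a small
metabolite subset.

Every random draw flows from a single integer seed; identical configs and
seeds produce identical panels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

SEXES = ("F", "M")


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class QtlEffect:
    """A planted variant -> phenotype effect, in residual-SD units."""

    variant: int
    target: int
    effect: float


@dataclass(frozen=True)
class TraitSpec:
    """A trait built as a weighted sum of metabolite line means plus noise."""

    metabolites: tuple[int, ...]
    weights: tuple[float, ...]
    h2: float
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.metabolites) != len(self.weights):
            raise ConfigurationError("trait metabolites and weights differ in length")
        if not 0.0 <= self.h2 <= 1.0:
            raise ConfigurationError(f"trait h2 must be in [0,1], got {self.h2}")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic panel.

    Defaults mirror the study design this generator emulates: 40 inbred lines,
    two sexes, three replicate pools per line x sex, ~200 metabolites with mean
    broad-sense heritability 0.43, and a minor-allele floor of 10% of lines.
    """

    n_lines: int = 40
    n_variants: int = 1000
    maf_min: float = 0.1
    n_metabolites: int = 200
    module_spec: tuple[tuple[int, float], ...] = ()
    h2_target: float = 0.43
    sex_effect_sd: float = 1.0
    lxs_fraction: float = 0.25
    n_reps: int = 3
    mqtl_spec: tuple[QtlEffect, ...] = ()
    eqtl_spec: tuple[QtlEffect, ...] = ()
    n_genes: int = 100
    trait_spec: tuple[TraitSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 2:
            raise ConfigurationError("need at least 2 lines")
        if not 0.0 < self.maf_min <= 0.5:
            raise ConfigurationError("maf_min must be in (0, 0.5]")
        if math.ceil(self.maf_min * self.n_lines) < 1:
            raise ConfigurationError("maf_min * n_lines must be >= 1")
        if math.ceil(self.maf_min * self.n_lines) > self.n_lines // 2:
            raise ConfigurationError(
                f"maf_min={self.maf_min} infeasible for n_lines={self.n_lines}: "
                "minimum minor count exceeds n_lines/2"
            )
        if not 0.0 <= self.h2_target < 1.0:
            raise ConfigurationError("h2_target must be in [0,1)")
        if not 0.0 <= self.lxs_fraction <= 1.0:
            raise ConfigurationError("lxs_fraction must be in [0,1]")
        if sum(size for size, _ in self.module_spec) > self.n_metabolites:
            raise ConfigurationError("module sizes sum beyond n_metabolites")
        for size, rho in self.module_spec:
            if not 0.0 <= rho < 1.0:
                raise ConfigurationError(f"module correlation must be in [0,1), got {rho}")
            if size < 1:
                raise ConfigurationError("module size must be >= 1")
        for q in self.mqtl_spec:
            if not (0 <= q.variant < self.n_variants and 0 <= q.target < self.n_metabolites):
                raise ConfigurationError(f"mQTL index out of range: {q}")
        for q in self.eqtl_spec:
            if not (0 <= q.variant < self.n_variants and 0 <= q.target < self.n_genes):
                raise ConfigurationError(f"eQTL index out of range: {q}")
        for t in self.trait_spec:
            for j in t.metabolites:
                if not 0 <= j < self.n_metabolites:
                    raise ConfigurationError(f"trait metabolite index {j} out of range")

    @property
    def line_ids(self) -> list[str]:
        return [f"line_{i + 1:03d}" for i in range(self.n_lines)]

    @property
    def metabolite_ids(self) -> list[str]:
        return [f"met_{j + 1:04d}" for j in range(self.n_metabolites)]

    @property
    def gene_ids(self) -> list[str]:
        return [f"gene_{j + 1:04d}" for j in range(self.n_genes)]


@dataclass
class PanelTruth:
    """Ground truth recorded while simulating: planted effects and realized
    per-metabolite variance components."""

    module_of: np.ndarray  # metabolite -> module id (-1: unassigned)
    mqtl: tuple[QtlEffect, ...]
    eqtl: tuple[QtlEffect, ...]
    traits: tuple[TraitSpec, ...]
    line_effects: np.ndarray  # n_lines x n_metabolites (common line effect)
    lxs_effects: np.ndarray  # n_lines x 2 x n_metabolites
    sigma2_line: np.ndarray  # realized var of line effects, per metabolite
    sigma2_lxs: np.ndarray
    sigma2_error: np.ndarray
    h2_realized: np.ndarray


@dataclass
class SyntheticPanel:
    config: SimulationConfig
    genotypes: pd.DataFrame  # lines x variants, {0,1}
    metabolome: pd.DataFrame  # tidy: line, sex, replicate, metabolite, abundance
    transcripts: dict[str, pd.DataFrame]  # sex -> lines x genes
    traits: dict[str, pd.DataFrame]  # sex -> lines x traits
    annotation: pd.DataFrame  # metabolite -> super_pathway, sub_pathway
    truth: PanelTruth


SUPER_PATHWAYS = (
    "lipid",
    "amino acid",
    "carbohydrate",
    "nucleotide",
    "energy",
    "xenobiotics",
    "cofactors and vitamins",
    "peptide",
)


def simulate_genotypes(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate a lines x variants matrix of homozygous genotype classes.

    Each variant's minor-class line count is drawn uniformly between
    ceil(maf_min * n_lines) and floor(n_lines / 2), and the minor lines are a
    uniform random subset — so every variant satisfies the minor-class floor
    by construction.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    lo = math.ceil(cfg.maf_min * cfg.n_lines)
    hi = cfg.n_lines // 2
    counts = rng.integers(lo, hi + 1, size=cfg.n_variants)
    g = np.zeros((cfg.n_lines, cfg.n_variants), dtype=np.int8)
    for v, c in enumerate(counts):
        carriers = rng.choice(cfg.n_lines, size=c, replace=False)
        g[carriers, v] = 1
    pos = np.sort(rng.choice(np.arange(1, 20_000_000), size=cfg.n_variants, replace=False))
    ids = [f"2L_{p}_SNP" for p in pos]
    return pd.DataFrame(g, index=cfg.line_ids, columns=ids)


def _module_assignments(cfg: SimulationConfig) -> np.ndarray:
    module_of = np.full(cfg.n_metabolites, -1, dtype=int)
    start = 0
    for m, (size, _rho) in enumerate(cfg.module_spec):
        module_of[start : start + size] = m
        start += size
    return module_of


def _correlated_line_residuals(
    cfg: SimulationConfig, module_of: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance line residuals; exchangeable correlation within modules."""
    u = np.empty((cfg.n_lines, cfg.n_metabolites))
    z_indep = rng.standard_normal((cfg.n_lines, cfg.n_metabolites))
    shared = rng.standard_normal((cfg.n_lines, max(len(cfg.module_spec), 1)))
    for j in range(cfg.n_metabolites):
        m = module_of[j]
        if m < 0:
            u[:, j] = z_indep[:, j]
        else:
            rho = cfg.module_spec[m][1]
            # exchangeable corr: one shared factor per module
            u[:, j] = math.sqrt(rho) * shared[:, m] + math.sqrt(1.0 - rho) * z_indep[:, j]
    return u


def simulate_metabolome(
    genotypes: pd.DataFrame, cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, PanelTruth]:
    """Simulate replicate-level metabolite abundances plus ground truth.

    Per metabolite m the model is

        Y_lsr = mu_m + sexeff_m * s + a_lm + b_lsm + e_lsrm

    with a_lm = planted mQTL contributions + module-correlated polygenic
    residual, b_lsm an independent line-by-sex deviation, and e iid error with
    unit variance. Variances are scaled so the expected broad-sense
    heritability (sigma2_L + sigma2_LxS over total) equals ``h2_target``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    n_l, n_m = cfg.n_lines, cfg.n_metabolites
    module_of = _module_assignments(cfg)

    sigma2_e = 1.0
    h2 = cfg.h2_target
    sigma2_g = h2 / (1.0 - h2) * sigma2_e if h2 > 0 else 0.0
    sigma2_lxs_t = cfg.lxs_fraction * sigma2_g
    sigma2_line_t = (1.0 - cfg.lxs_fraction) * sigma2_g

    g = genotypes.to_numpy(dtype=float)
    qtl_part = np.zeros((n_l, n_m))
    for q in cfg.mqtl_spec:
        qtl_part[:, q.target] += q.effect * math.sqrt(sigma2_e) * g[:, q.variant]

    resid = _correlated_line_residuals(cfg, module_of, rng)
    line_eff = np.empty_like(qtl_part)
    for j in range(n_m):
        var_q = qtl_part[:, j].var(ddof=1)
        scale = math.sqrt(max(sigma2_line_t - var_q, 0.0))
        line_eff[:, j] = qtl_part[:, j] - qtl_part[:, j].mean() + scale * resid[:, j]

    lxs_eff = math.sqrt(sigma2_lxs_t) * rng.standard_normal((n_l, 2, n_m))
    mu = 10.0 + rng.standard_normal(n_m)
    sex_eff = cfg.sex_effect_sd * rng.standard_normal(n_m)

    rows_line, rows_sex, rows_rep = [], [], []
    abun = np.empty((n_l * 2 * cfg.n_reps, n_m))
    i = 0
    for l in range(n_l):
        for s, sex in enumerate(SEXES):
            base = mu + (sex_eff if sex == "M" else 0.0) + line_eff[l] + lxs_eff[l, s]
            for r in range(cfg.n_reps):
                abun[i] = base + math.sqrt(sigma2_e) * rng.standard_normal(n_m)
                rows_line.append(cfg.line_ids[l])
                rows_sex.append(sex)
                rows_rep.append(r + 1)
                i += 1

    wide = pd.DataFrame(abun, columns=cfg.metabolite_ids)
    wide.insert(0, "replicate", rows_rep)
    wide.insert(0, "sex", rows_sex)
    wide.insert(0, "line", rows_line)
    tidy = wide.melt(
        id_vars=["line", "sex", "replicate"], var_name="metabolite", value_name="abundance"
    )

    s2_line = line_eff.var(axis=0, ddof=1)
    s2_lxs = lxs_eff.reshape(-1, n_m).var(axis=0, ddof=1)
    s2_err = np.full(n_m, sigma2_e)
    truth = PanelTruth(
        module_of=module_of,
        mqtl=cfg.mqtl_spec,
        eqtl=cfg.eqtl_spec,
        traits=cfg.trait_spec,
        line_effects=line_eff,
        lxs_effects=lxs_eff,
        sigma2_line=s2_line,
        sigma2_lxs=s2_lxs,
        sigma2_error=s2_err,
        h2_realized=(s2_line + s2_lxs) / (s2_line + s2_lxs + s2_err),
    )
    return tidy, truth


def simulate_transcripts(
    genotypes: pd.DataFrame, cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> dict[str, pd.DataFrame]:
    """Simulate per-sex line-mean transcript matrices with planted eQTLs.

    Genetic effects are shared between sexes; residual line variation is sex
    specific with unit variance.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    g = genotypes.to_numpy(dtype=float)
    genetic = np.zeros((cfg.n_lines, cfg.n_genes))
    for q in cfg.eqtl_spec:
        genetic[:, q.target] += q.effect * g[:, q.variant]
    out: dict[str, pd.DataFrame] = {}
    for sex in SEXES:
        noise = rng.standard_normal((cfg.n_lines, cfg.n_genes))
        out[sex] = pd.DataFrame(
            genetic + noise, index=pd.Index(cfg.line_ids, name="line"), columns=cfg.gene_ids
        )
    return out


def simulate_traits(
    metabolite_line_means: dict[str, pd.DataFrame],
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, pd.DataFrame]:
    """Simulate per-sex organismal traits as noisy linear functions of
    metabolite line means.

    Noise variance is set so var(signal) / var(trait) equals the trait's h2
    (computed on the realized signal); h2 = 0 yields pure noise and an exactly
    linear trait requires h2 = 1 - eps via zero-variance signal handling.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 3)
    out: dict[str, pd.DataFrame] = {}
    for sex in SEXES:
        lm = metabolite_line_means[sex]
        cols = {}
        for k, spec in enumerate(cfg.trait_spec):
            sig = np.zeros(len(lm.index))
            for j, w in zip(spec.metabolites, spec.weights):
                sig = sig + w * lm.iloc[:, j].to_numpy()
            v = sig.var(ddof=1)
            if spec.h2 >= 1.0 or v == 0.0:
                noise_sd = 0.0
            elif spec.h2 == 0.0:
                sig = np.zeros_like(sig)
                noise_sd = 1.0
            else:
                noise_sd = math.sqrt(v * (1.0 - spec.h2) / spec.h2)
            name = spec.name or f"trait_{k + 1}"
            cols[name] = sig + noise_sd * rng.standard_normal(len(sig))
        out[sex] = pd.DataFrame(cols, index=lm.index.copy())
    return out


def simulate_annotation(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Assign each metabolite a super pathway; metabolites sharing a module get
    the same super pathway (modules reflect shared biochemistry)."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 4)
    module_of = _module_assignments(cfg)
    module_path = rng.choice(len(SUPER_PATHWAYS), size=max(len(cfg.module_spec), 1))
    idx = np.where(
        module_of >= 0,
        module_path[np.clip(module_of, 0, None)],
        rng.integers(0, len(SUPER_PATHWAYS), size=cfg.n_metabolites),
    )
    return pd.DataFrame(
        {
            "metabolite": cfg.metabolite_ids,
            "super_pathway": [SUPER_PATHWAYS[i] for i in idx],
            "sub_pathway": [f"sub_{i}" for i in idx],
        }
    )


def simulate_panel(cfg: SimulationConfig) -> SyntheticPanel:
    """Generate a complete synthetic panel from one config and seed."""
    genotypes = simulate_genotypes(cfg)
    metabolome, truth = simulate_metabolome(genotypes, cfg)
    transcripts = simulate_transcripts(genotypes, cfg)
    lm = {
        sex: (
            metabolome[metabolome["sex"] == sex]
            .pivot_table(index="line", columns="metabolite", values="abundance", aggfunc="mean")
            .reindex(index=cfg.line_ids, columns=cfg.metabolite_ids)
        )
        for sex in SEXES
    }
    traits = simulate_traits(lm, cfg)
    annotation = simulate_annotation(cfg)
    return SyntheticPanel(
        config=cfg,
        genotypes=genotypes,
        metabolome=metabolome,
        transcripts=transcripts,
        traits=traits,
        annotation=annotation,
        truth=truth,
    )
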