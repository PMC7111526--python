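"""File readers and writers for the pipeline's interchange formats.

Tidy TSV is the canonical format throughout; a minimal VCF subset is accepted
for genotypes (inbred lines: homozygous GTs collapse to {0, 1}, anything else
becomes missing). Coordinates are 1-based closed in memory; BED-like inputs
(0-based half-open) are converted at the boundary. All writes are atomic
(temp file + rename).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def _atomic_write(path: Path, writer) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    try:
        writer(tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    _atomic_write(Path(path), lambda tmp: df.to_csv(tmp, sep="\t", index=index))


def read_genotypes_tsv(path) -> pd.DataFrame:
    """Lines x variants TSV with {0,1,NA} entries; first column = line id."""
    g = pd.read_csv(path, sep="\t", index_col=0)
    vals = g.to_numpy(dtype=float)
    ok = np.isin(vals[np.isfinite(vals)], (0.0, 1.0)).all()
    if not ok:
        raise ValueError("genotype TSV entries must be 0, 1 or missing")
    return g


def write_genotypes_tsv(genotypes: pd.DataFrame, path) -> None:
    write_tsv(genotypes, path)


def read_genotypes_vcf(path, lines: list[str] | None = None) -> pd.DataFrame:
    """Minimal VCF reader for inbred panels.

    GT 0/0 (or 0|0) -> 0, 1/1 -> 1; heterozygous or partially missing calls
    become missing (counted and logged). Multi-allelic records are skipped
    with a warning. Returns a lines x variants matrix with "chrom_pos_ref/alt"
    variant ids.
    """
    samples: list[str] = []
    records: dict[str, list[float]] = {}
    n_het = 0
    n_multi = 0
    with open(path) as fh:
        for raw in fh:
            if raw.startswith("##"):
                continue
            if raw.startswith("#CHROM"):
                parts = raw.rstrip("\n").split("\t")
                if len(parts) < 10 or parts[:9] != [
                    "#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT",
                ]:
                    raise ValueError("malformed VCF header line")
                samples = parts[9:]
                continue
            if not samples:
                raise ValueError("VCF data before #CHROM header")
            parts = raw.rstrip("\n").split("\t")
            chrom, pos, _id, ref, alt = parts[0], parts[1], parts[2], parts[3], parts[4]
            if "," in alt:
                n_multi += 1
                continue
            fmt = parts[8].split(":")
            gt_i = fmt.index("GT")
            calls = []
            for sample in parts[9:]:
                gt = sample.split(":")[gt_i].replace("|", "/")
                if gt == "0/0":
                    calls.append(0.0)
                elif gt == "1/1":
                    calls.append(1.0)
                else:
                    if gt not in ("./.", "."):
                        n_het += 1
                    calls.append(np.nan)
            records[f"{chrom}_{pos}_{ref}/{alt}"] = calls
    if n_multi:
        logger.warning("skipped %d multi-allelic VCF records", n_multi)
    if n_het:
        logger.warning("%d heterozygous/half-missing GTs set to missing", n_het)
    g = pd.DataFrame(records, index=samples)
    if lines is not None:
        g = g.loc[lines]
    return g


def write_genotypes_vcf(genotypes: pd.DataFrame, path) -> None:
    """Write a minimal VCF; variant ids must parse as chrom_pos_class."""

    def _write(tmp):
        with open(tmp, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
            fh.write("\t".join(genotypes.index) + "\n")
            for vid in genotypes.columns:
                chrom, pos, _cls = str(vid).rsplit("_", 2)
                calls = [
                    "./." if not np.isfinite(v) else ("1/1" if v == 1 else "0/0")
                    for v in genotypes[vid].to_numpy(dtype=float)
                ]
                fh.write(f"{chrom}\t{pos}\t{vid}\tA\tT\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n")

    _atomic_write(Path(path), _write)


def read_replicate_table(path) -> pd.DataFrame:
    tbl = pd.read_csv(path, sep="\t")
    from .quantgen import validate_replicate_table

    return validate_replicate_table(tbl)


def read_line_means(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_gene_model(path, zero_based: bool = False) -> pd.DataFrame:
    """chrom/start/end/gene TSV; BED-like 0-based half-open converted to
    1-based closed when ``zero_based``."""
    gm = pd.read_csv(path, sep="\t")
    need = {"chrom", "start", "end", "gene"}
    if not need.issubset(gm.columns):
        # headerless BED-like
        gm = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "gene"])
    if zero_based:
        gm = gm.assign(start=gm["start"] + 1)
    return gm


def write_json(obj, path) -> None:
    _atomic_write(Path(path), lambda tmp: Path(tmp).write_text(json.dumps(obj, indent=2, sort_keys=True)))


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
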