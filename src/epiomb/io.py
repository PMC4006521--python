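"""File formats, interval filtering and run manifests.

Genotype dialects
-----------------
* ``native`` — TSV, one row per sample: ``sample_id``, ``phenotype`` (1 =
  case, 0 = control), then one column per SNP with additive codes 0/1/2 and
  ``NA`` for missing.  Round-trips exactly.
* ``plink-additive`` — the ``.raw``-style recoded layout: whitespace
  delimited with a ``FID IID PAT MAT SEX PHENOTYPE`` preamble and per-SNP
  allele-dosage columns.  Phenotypes in 1/2 coding (2 = case) or 0/1 coding
  are both accepted.

Interval filtering
------------------
Intervals are 0-based half-open internally; BED files are read as-is.  Gene
intervals can be expanded strand-aware (a fixed promoter margin upstream of
the transcription start and a shorter margin past the termination site), the
standard "within or near a gene" SNP screen.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .simulate import GenotypeDataset

__all__ = [
    "IntervalSet",
    "read_genotypes",
    "write_genotypes",
    "read_bed",
    "expand_gene_intervals",
    "filter_snps_by_intervals",
    "write_manifest",
]

logger = logging.getLogger(__name__)

DIALECTS = ("native", "plink-additive")
MISSING_TOKEN = "NA"


# ---------------------------------------------------------------------------
# genotype files


def write_genotypes(dataset: GenotypeDataset, path: str | Path) -> None:
    """Write a dataset in the native TSV dialect."""
    path = Path(path)
    g = dataset.genotypes.astype(object)
    g[dataset.genotypes < 0] = MISSING_TOKEN
    df = pd.DataFrame(g, columns=dataset.snp_ids)
    df.insert(0, "phenotype", dataset.phenotype.astype(int))
    df.insert(0, "sample_id", [f"s{i}" for i in range(dataset.n_samples)])
    df.to_csv(path, sep="\t", index=False)


def _read_native(path: Path) -> GenotypeDataset:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "phenotype" not in df.columns:
        raise ValueError(f"{path}: phenotype column absent")
    snp_cols = [c for c in df.columns if c not in ("sample_id", "phenotype")]
    phenotype = df["phenotype"].astype(int).to_numpy()
    if not set(np.unique(phenotype)) <= {0, 1}:
        raise ValueError(f"{path}: phenotype codes must be 0 (control) or 1 (case)")
    geno = np.full((len(df), len(snp_cols)), -1, dtype=np.int8)
    for j, c in enumerate(snp_cols):
        col = df[c]
        valid = col != MISSING_TOKEN
        vals = pd.to_numeric(col[valid], errors="coerce")
        if vals.isna().any():
            bad = int(np.flatnonzero(vals.isna().to_numpy())[0])
            raise ValueError(f"{path}: malformed genotype in column {c!r} near data row {bad + 1}")
        if not set(vals.unique()) <= {0, 1, 2}:
            raise ValueError(f"{path}: unknown genotype code in column {c!r}")
        geno[valid.to_numpy(), j] = vals.to_numpy(dtype=np.int8)
    return GenotypeDataset(
        genotypes=geno, phenotype=phenotype.astype(np.int8), snp_ids=snp_cols
    )


def _read_plink_additive(path: Path) -> GenotypeDataset:
    df = pd.read_csv(path, sep=r"\s+", dtype=str, keep_default_na=False)
    preamble = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    if df.columns.tolist()[: len(preamble)] != preamble:
        raise ValueError(f"{path}: expected a PLINK-additive header starting {preamble}")
    snp_cols = df.columns.tolist()[len(preamble):]
    ph_raw = pd.to_numeric(df["PHENOTYPE"], errors="coerce")
    if ph_raw.isna().any():
        raise ValueError(f"{path}: non-numeric phenotype")
    vals = set(ph_raw.unique())
    if vals <= {1.0, 2.0}:
        phenotype = (ph_raw == 2).astype(np.int8).to_numpy()  # 2 = case
    elif vals <= {0.0, 1.0}:
        phenotype = ph_raw.astype(np.int8).to_numpy()
    else:
        raise ValueError(f"{path}: unsupported phenotype coding {sorted(vals)}")
    geno = np.full((len(df), len(snp_cols)), -1, dtype=np.int8)
    for j, c in enumerate(snp_cols):
        col = df[c]
        valid = ~col.isin([MISSING_TOKEN, "nan"]) & col.notna()
        vals_j = pd.to_numeric(col[valid], errors="coerce")
        if vals_j.isna().any() or not set(vals_j.unique()) <= {0, 1, 2}:
            raise ValueError(f"{path}: unknown genotype code in column {c!r}")
        geno[valid.to_numpy(), j] = vals_j.to_numpy(dtype=np.int8)
    # strip the _A allele suffix PLINK appends to SNP ids
    snp_ids = [c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols]
    return GenotypeDataset(genotypes=geno, phenotype=phenotype, snp_ids=snp_ids)


def read_genotypes(path: str | Path, dialect: str = "native") -> GenotypeDataset:
    """Read a case-control genotype matrix in the given dialect."""
    path = Path(path)
    if dialect == "native":
        return _read_native(path)
    if dialect == "plink-additive":
        return _read_plink_additive(path)
    raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


# ---------------------------------------------------------------------------
# intervals


@dataclass
class IntervalSet:
    """Genomic intervals, 0-based half-open, optionally stranded."""

    intervals: pd.DataFrame  # columns: chrom, start, end[, name, strand]

    def __post_init__(self) -> None:
        df = self.intervals
        required = {"chrom", "start", "end"}
        if not required <= set(df.columns):
            raise ValueError(f"interval frame needs columns {sorted(required)}")
        if (df["start"] >= df["end"]).any():
            raise ValueError("intervals must satisfy start < end")

    def __len__(self) -> int:
        return len(self.intervals)


def read_bed(path: str | Path) -> IntervalSet:
    """Read a BED3/BED6 file (0-based half-open, as BED is defined)."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return IntervalSet(intervals=df)


def expand_gene_intervals(
    genes: IntervalSet, upstream: int = 2000, downstream: int = 500
) -> IntervalSet:
    """Extend gene intervals by a promoter/terminator margin, strand-aware.

    On the + strand the start moves ``upstream`` bases left and the end
    ``downstream`` bases right; on the - strand the roles are mirrored.
    Negative starts are clipped to 0 (logged).
    """
    df = genes.intervals.copy()
    if "strand" not in df.columns:
        raise ValueError("strand column required for strand-aware expansion")
    plus = df["strand"] == "+"
    minus = df["strand"] == "-"
    if not (plus | minus).all():
        raise ValueError("every interval needs strand '+' or '-'")
    df.loc[plus, "start"] -= upstream
    df.loc[plus, "end"] += downstream
    df.loc[minus, "start"] -= downstream
    df.loc[minus, "end"] += upstream
    clipped = df["start"] < 0
    if clipped.any():
        logger.info("clipped %d expanded interval starts at 0", int(clipped.sum()))
        df.loc[clipped, "start"] = 0
    return IntervalSet(intervals=df)


def filter_snps_by_intervals(
    dataset: GenotypeDataset, intervals: IntervalSet
) -> list[int]:
    """Indices of SNPs whose position falls inside at least one interval.

    Positions are 0-based; interval ends are exclusive.  SNPs without
    coordinates are excluded (logged).
    """
    if dataset.snp_chrom is None or dataset.snp_pos is None:
        raise ValueError("dataset carries no SNP coordinates")
    trees: dict[str, IntervalTree] = {}
    for row in intervals.intervals.itertuples(index=False):
        trees.setdefault(str(row.chrom), IntervalTree()).addi(row.start, row.end)
    retained = []
    n_missing = 0
    for j, (chrom, pos) in enumerate(zip(dataset.snp_chrom, dataset.snp_pos)):
        if chrom is None or pos is None or (isinstance(pos, float) and np.isnan(pos)):
            n_missing += 1
            continue
        tree = trees.get(str(chrom))
        if tree is not None and tree.overlaps_point(int(pos)):
            retained.append(j)
    if n_missing:
        logger.info("excluded %d SNPs without coordinates", n_missing)
    return retained


# ---------------------------------------------------------------------------
# run manifests


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    command: str,
    params: dict,
    inputs: dict[str, str | Path] | None = None,
) -> dict:
    """Write a machine-readable run manifest (command, params, input digests).

    The manifest carries everything needed to reproduce the run bit-for-bit:
    the command name, all parameters including seeds, and a sha256 digest of
    each input file.
    """
    manifest = {
        "command": command,
        "params": params,
        "inputs": {str(k): _digest(v) for k, v in (inputs or {}).items()},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
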