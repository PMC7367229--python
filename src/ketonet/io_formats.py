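"""Readers and writers for on-disk artifacts plus shared domain types.

All tables are TSV with ``#``-prefixed metadata lines.  Coordinates are
BED-convention 0-based half-open internally; GWAS positions are read as
1-based and converted on load (and converted back on write).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__

logger = logging.getLogger("ketonet")

STATES = ("H_Pre", "H_Post", "K_Pre", "K_Post")
BIO_INDICATORS = ("BHBA", "TC", "TG", "HDL", "LDL", "Ca", "INS")

UNASSIGNED = "unassigned"


class FormatError(ValueError):
    """Structurally invalid input file or in-memory table."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Non-negative integer gene × sample read counts."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # (n_genes, n_samples) integer

    def __post_init__(self) -> None:
        self.gene_ids = list(map(str, self.gene_ids))
        self.sample_ids = list(map(str, self.sample_ids))
        self.counts = np.asarray(self.counts)
        dupg = _duplicates(self.gene_ids)
        if dupg:
            raise FormatError(f"duplicate gene ids: {sorted(dupg)}")
        dups = _duplicates(self.sample_ids)
        if dups:
            raise FormatError(f"duplicate sample ids: {sorted(dups)}")
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes × {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            frac = np.asarray(self.counts, dtype=float)
            bad = np.argwhere(frac != np.floor(frac))
            if bad.size:
                g, s = bad[0]
                raise FormatError(
                    f"non-integer count at gene {self.gene_ids[g]!r}, "
                    f"sample {self.sample_ids[s]!r}: {frac[g, s]}"
                )
            self.counts = frac.astype(np.int64)
        neg = np.argwhere(self.counts < 0)
        if neg.size:
            g, s = neg[0]
            raise FormatError(
                f"negative count at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}: {self.counts[g, s]}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, genes: Sequence[str]) -> "CountMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in genes]
        return CountMatrix(list(genes), list(self.sample_ids), self.counts[rows])


@dataclass
class GeneAnnotation:
    """Per-gene coordinates and lengths (0-based half-open intervals)."""

    table: pd.DataFrame  # columns: gene_id, chrom, start, end, length_bp

    REQUIRED = ("gene_id", "chrom", "start", "end", "length_bp")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"gene annotation missing columns: {missing}")
        t = self.table
        dup = t["gene_id"][t["gene_id"].duplicated()]
        if len(dup):
            raise FormatError(f"duplicate gene ids in annotation: {sorted(set(dup))}")
        if (t["start"] >= t["end"]).any():
            bad = t.loc[t["start"] >= t["end"], "gene_id"].iloc[0]
            raise FormatError(f"start >= end for gene {bad!r}")
        if (t["length_bp"] <= 0).any():
            bad = t.loc[t["length_bp"] <= 0, "gene_id"].iloc[0]
            raise FormatError(f"non-positive length_bp for gene {bad!r}")
        self.table = t.reset_index(drop=True)

    def lengths_for(self, gene_ids: Sequence[str]) -> np.ndarray:
        s = self.table.set_index("gene_id")["length_bp"]
        missing = [g for g in gene_ids if g not in s.index]
        if missing:
            raise FormatError(f"genes missing from annotation: {missing[:5]}")
        return s.loc[list(gene_ids)].to_numpy(dtype=float)

    @property
    def chroms(self) -> set[str]:
        return set(self.table["chrom"].astype(str))


@dataclass
class SampleInfo:
    """Physiological state and bio-indicator levels per sample."""

    table: pd.DataFrame  # columns: sample_id, state, <bio indicators...>

    def __post_init__(self) -> None:
        if "sample_id" not in self.table.columns or "state" not in self.table.columns:
            raise FormatError("sample info requires 'sample_id' and 'state' columns")
        bad_states = set(self.table["state"]) - set(STATES)
        if bad_states:
            raise FormatError(f"unknown states {sorted(bad_states)}; expected {STATES}")
        dup = self.table["sample_id"][self.table["sample_id"].duplicated()]
        if len(dup):
            raise FormatError(f"duplicate sample ids: {sorted(set(dup))}")
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].astype(str).tolist()

    @property
    def indicator_columns(self) -> list[str]:
        return [c for c in self.table.columns if c not in ("sample_id", "state")]

    def aligned_to(self, sample_ids: Sequence[str]) -> "SampleInfo":
        t = self.table.set_index("sample_id")
        missing = [s for s in sample_ids if s not in t.index]
        if missing:
            raise FormatError(f"samples missing from sample info: {missing}")
        return SampleInfo(t.loc[list(sample_ids)].reset_index())

    def state_indicators(self) -> pd.DataFrame:
        """One-vs-rest 1/0 indicator column per physiological state."""
        out = {}
        for st in STATES:
            out[st] = (self.table["state"] == st).astype(float).to_numpy()
        return pd.DataFrame(out, index=self.sample_ids)


@dataclass
class GwasSummary:
    """Genome-ordered per-SNP effect estimates and p-values for one trait.

    ``pos`` is stored 0-based internally; files use 1-based positions.
    """

    table: pd.DataFrame  # columns: snp_id, chrom, pos, effect_b, pvalue
    trait: str = "trait"

    REQUIRED = ("snp_id", "chrom", "pos", "effect_b", "pvalue")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"GWAS summary missing columns: {missing}")
        t = self.table
        p = t["pvalue"].to_numpy(dtype=float)
        if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
            bad = t["snp_id"].iloc[int(np.argmax((p <= 0) | (p > 1) | ~np.isfinite(p)))]
            raise FormatError(f"p-value outside (0,1] at SNP {bad!r}")
        key = t[["chrom", "pos", "snp_id"]].apply(tuple, axis=1)
        if key.duplicated().any():
            raise FormatError("duplicate (chrom, pos, snp_id) records")
        if not t[["chrom", "pos"]].equals(
            t[["chrom", "pos"]].sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        ):
            logger.info("GWAS summary not sorted by (chrom, pos); sorting")
            t = t.sort_values(["chrom", "pos"], kind="mergesort")
        self.table = t.reset_index(drop=True)

    @property
    def n_snps(self) -> int:
        return len(self.table)

    @property
    def effects(self) -> np.ndarray:
        return self.table["effect_b"].to_numpy(dtype=float)

    @property
    def chroms(self) -> set[str]:
        return set(self.table["chrom"].astype(str))


# ---------------------------------------------------------------------------
# metadata header
# ---------------------------------------------------------------------------


def config_hash(config: Mapping | None) -> str:
    """Stable short hash of a (nested) configuration mapping."""
    import json

    payload = json.dumps(config, sort_keys=True, default=str) if config else ""
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def metadata_lines(seed: int | None = None, cfg_hash: str | None = None) -> list[str]:
    lines = [f"# ketonet_version={__version__}"]
    if cfg_hash is not None:
        lines.append(f"# config_hash={cfg_hash}")
    if seed is not None:
        lines.append(f"# seed={seed}")
    return lines


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    *,
    index: bool = False,
    seed: int | None = None,
    cfg_hash: str | None = None,
    float_format: str = "%.10g",
) -> None:
    """Write a TSV with the standard '#' metadata header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in metadata_lines(seed=seed, cfg_hash=cfg_hash):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=index, float_format=float_format)


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_count_matrix(path: str | Path) -> CountMatrix:
    """Read a gene × sample count TSV (first column gene ids, header samples).

    Duplicate ids and negative or non-integer counts are hard errors.
    """
    df = read_table(path, dtype={0: str})
    if df.shape[1] < 2:
        raise FormatError(f"{path}: count matrix needs gene-id column plus samples")
    gene_col = df.columns[0]
    genes = df[gene_col].astype(str).tolist()
    values = df.drop(columns=[gene_col])
    try:
        counts = values.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric count value ({exc})") from exc
    return CountMatrix(genes, [str(c) for c in values.columns], counts)


def write_count_matrix(cm: CountMatrix, path: str | Path, **meta) -> None:
    df = cm.to_frame()
    df.index.name = "gene_id"
    write_table(df, path, index=True, **meta)


def read_gene_annotation(path: str | Path) -> GeneAnnotation:
    df = read_table(path, dtype={"gene_id": str, "chrom": str})
    return GeneAnnotation(df)


def write_gene_annotation(annot: GeneAnnotation, path: str | Path, **meta) -> None:
    write_table(annot.table, path, **meta)


def read_sample_info(path: str | Path) -> SampleInfo:
    df = read_table(path, dtype={"sample_id": str, "state": str})
    return SampleInfo(df)


def write_sample_info(info: SampleInfo, path: str | Path, **meta) -> None:
    write_table(info.table, path, **meta)


def read_gwas_summary(path: str | Path, trait: str | None = None) -> GwasSummary:
    """Read per-SNP summary statistics; converts 1-based file positions to 0-based."""
    df = read_table(path, dtype={"snp_id": str, "chrom": str})
    missing = [c for c in GwasSummary.REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: GWAS summary missing columns {missing}")
    df = df.copy()
    df["pos"] = df["pos"].astype(np.int64) - 1
    if (df["pos"] < 0).any():
        raise FormatError(f"{path}: position < 1 in 1-based input")
    return GwasSummary(df, trait=trait or Path(path).stem)


def write_gwas_summary(gwas: GwasSummary, path: str | Path, **meta) -> None:
    df = gwas.table.copy()
    df["pos"] = df["pos"].astype(np.int64) + 1  # back to 1-based on disk
    write_table(df, path, **meta)


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    """Write BED6 (chrom, start, end, name, score, strand) without header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = ["chrom", "start", "end", "name"]
    df = intervals[cols].copy()
    df["score"] = 0
    df["strand"] = "."
    df.to_csv(path, sep="\t", index=False, header=False)


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for it in items:
        if it in seen:
            dup.add(it)
        seen.add(it)
    return dup
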