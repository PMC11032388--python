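"""Readers and writers for the on-disk formats the pipeline touches.

All tabular files are tab-separated UTF-8 with ``.`` for missing values;
all genomic coordinates are 0-based half-open (BED convention) everywhere
in the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = "."

VALID_GROUPS = ("tumour", "control")
VALID_EVIDENCE = ("validated", "predicted")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


class CountMatrix:
    """Non-negative integer feature-by-sample count table.

    Parameters
    ----------
    counts
        DataFrame with unique feature ids as index and unique sample ids
        as columns; every cell a finite non-negative integer.
    """

    def __init__(self, counts: pd.DataFrame):
        if counts.index.has_duplicates:
            dup = counts.index[counts.index.duplicated()][0]
            raise FormatError(f"duplicate feature id: {dup!r}")
        if counts.columns.has_duplicates:
            dup = counts.columns[counts.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        if counts.shape[1] < 2:
            raise FormatError("count matrix needs at least 2 samples")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("count matrix contains non-numeric cells")
        if not np.all(np.isfinite(values)):
            raise FormatError("count matrix contains non-finite cells")
        if np.any(values < 0) or np.any(values != np.floor(values)):
            i, j = np.argwhere((values < 0) | (values != np.floor(values)))[0]
            raise FormatError(
                f"invalid count {values[i, j]!r} at feature "
                f"{counts.index[i]!r}, sample {counts.columns[j]!r}"
            )
        self.counts = counts.astype(np.int64)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_features(self, keep: Iterable[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(keep)])

    def __eq__(self, other) -> bool:
        return isinstance(other, CountMatrix) and self.counts.equals(other.counts)

    def __repr__(self) -> str:
        return f"CountMatrix({self.shape[0]} features x {self.shape[1]} samples)"


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    id: str = ""

    def __post_init__(self):
        if self.start < 0:
            raise FormatError(f"negative start in interval {self.id!r}")
        if self.end <= self.start:
            raise FormatError(
                f"interval {self.id!r}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in ("+", "-", "."):
            raise FormatError(f"invalid strand {self.strand!r} in interval {self.id!r}")

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class SampleMetadata:
    """Per-sample annotations: group, plus optional HPV status and location."""

    def __init__(self, table: pd.DataFrame):
        if "sample_id" in table.columns:
            table = table.set_index("sample_id")
        if table.index.has_duplicates:
            raise FormatError("duplicate sample ids in metadata")
        if "group" not in table.columns:
            raise FormatError("metadata must have a 'group' column")
        bad = set(table["group"]) - set(VALID_GROUPS)
        if bad:
            raise FormatError(f"unknown group value(s): {sorted(bad)}")
        self.table = table

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def group_samples(self, group: str) -> list[str]:
        return list(self.table.index[self.table["group"] == group])

    def check_matches(self, cm: CountMatrix) -> None:
        if set(self.sample_ids) != set(cm.sample_ids):
            raise FormatError("metadata sample ids do not match count matrix")
        for g in VALID_GROUPS:
            if not self.group_samples(g):
                raise FormatError(f"group {g!r} has no samples")


@dataclass
class GeneSetCollection:
    """GMT-style mapping of term id to (term name, member genes)."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, term_id: str) -> list[str]:
        return self.sets[term_id][1]

    def items(self):
        return self.sets.items()


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_count_matrix(path) -> CountMatrix:
    """Read a TSV count matrix (first column feature ids, header sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    try:
        numeric = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-numeric count cell ({exc})") from exc
    return CountMatrix(numeric)


def write_count_matrix(cm: CountMatrix, path) -> None:
    write_table(cm.counts.reset_index(names="feature_id"), path)


def read_sample_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[MISSING], keep_default_na=False)
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: metadata must have a 'sample_id' column")
    return SampleMetadata(df)


def read_bed_intervals(path) -> list[GenomicInterval]:
    """Read BED3+ intervals (chrom, start, end[, name, score, strand])."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED line has <3 fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 else f"interval_{lineno}"
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(GenomicInterval(chrom, start, end, strand, name))
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed_intervals(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id}\t0\t{iv.strand}\n")


def read_gene_annotation(path) -> pd.DataFrame:
    """Read the 4-column gene annotation TSV (gene_id, chrom, strand, tss)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    required = {"gene_id", "chrom", "strand", "tss"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: gene annotation needs columns {sorted(required)}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"{path}: duplicate gene_id {dup!r}")
    bad = set(df["strand"]) - {"+", "-"}
    if bad:
        raise FormatError(f"{path}: gene strand must be + or -, got {sorted(bad)}")
    if (df["tss"] < 0).any():
        raise FormatError(f"{path}: negative TSS")
    return df.reset_index(drop=True)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file (term, description, tab-separated members)."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs >=3 fields")
            term, desc, members = fields[0], fields[1], fields[2:]
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"{path}:{lineno}: term {term!r} has no members")
            deduped = list(dict.fromkeys(members))
            sets[term] = (desc, deduped)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for term, (desc, members) in collection.items():
            fh.write("\t".join([term, desc, *members]) + "\n")


def read_interactions(path) -> pd.DataFrame:
    """Read the miRNA-gene interaction TSV (mirna_id, gene_id, evidence)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"mirna_id", "gene_id", "evidence"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: interaction table needs columns {sorted(required)}")
    bad = set(df["evidence"]) - set(VALID_EVIDENCE)
    if bad:
        raise FormatError(f"{path}: unknown evidence value(s): {sorted(bad)}")
    n_before = len(df)
    df = df.drop_duplicates(subset=["mirna_id", "gene_id", "evidence"]).reset_index(drop=True)
    if len(df) < n_before:
        logger.warning(
            "%s: dropped %d duplicate interaction row(s)", path, n_before - len(df)
        )
    return df


def read_beta_matrix(path, clip: float = 0.001) -> pd.DataFrame:
    """Read a CpG-by-sample beta-value TSV, clipping into (0, 1).

    Values must lie in [0, 1] on disk; they are clipped to
    ``[clip, 1 - clip]`` on import so the M-value transform is defined.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise FormatError(f"{path}: duplicate CpG ids")
    values = df.to_numpy(dtype=float)
    if np.any(~np.isfinite(values)) or np.any(values < 0) or np.any(values > 1):
        raise FormatError(f"{path}: beta values must be finite and within [0, 1]")
    return df.clip(lower=clip, upper=1.0 - clip)


# ---------------------------------------------------------------------------
# canonical TSV writer
# ---------------------------------------------------------------------------


def write_table(df: pd.DataFrame, path) -> None:
    """Write a DataFrame as canonical TSV: tabs, LF endings, '.' for missing."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING, lineterminator="\n")


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[MISSING], keep_default_na=False, **kwargs)
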