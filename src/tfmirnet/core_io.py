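"""Domain types, interval arithmetic, and readers/writers for the pipeline's file formats.

All genomic coordinates are held internally as 0-based half-open intervals
(BED convention).  Formats that are natively 1-based (e.g. Ensembl-exported
TSS tables) declare their base in the file and are converted on load, so no
off-by-one conversion ever happens downstream of a reader.

Chromosome names are matched by exact string equality; an optional
normalization map ("1" -> "chr1") can be applied at load time to reconcile
Ensembl- and UCSC-style naming.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_STRANDS = {"+", "-", "."}
VALID_BIOTYPES = {"protein_coding", "ncRNA", "pri_mirna"}


class ParseError(ValueError):
    """Raised when an input file violates its declared format."""


class ValidationError(ValueError):
    """Raised when parsed values violate a domain invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"strand must be one of {VALID_STRANDS}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Peak:
    """A peak call: an interval plus its -log10(p) score and optional summit."""

    interval: GenomicInterval
    neg_log10_p: float
    summit_offset: int | None = None
    fold_enrichment: float | None = None

    def __post_init__(self) -> None:
        if self.neg_log10_p < 0:
            raise ValidationError("neg_log10_p must be >= 0")
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < len(self.interval)
        ):
            raise ValidationError("summit_offset out of [0, end-start)")


@dataclass(frozen=True)
class TSSRecord:
    """A transcription start site for a transcript, ncRNA or pri-miRNA."""

    feature_id: str
    chrom: str
    position: int  # 0-based
    strand: str
    biotype: str
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValidationError("TSS position must be >= 0")
        if self.biotype not in VALID_BIOTYPES:
            raise ValidationError(f"biotype must be one of {VALID_BIOTYPES}")
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"strand must be one of {VALID_STRANDS}")


BASE_ORDER = "ACGT"


@dataclass(frozen=True)
class PFMMatrix:
    """A position frequency matrix (counts) with background and pseudocount."""

    matrix_id: str
    counts: np.ndarray  # shape (4, L), rows A,C,G,T
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = 0.8

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "background", bg)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValidationError("counts must have shape (4, L)")
        if (counts < 0).any():
            raise ValidationError("counts must be non-negative")
        if (counts.sum(axis=0) <= 0).any():
            raise ValidationError("every column must have a positive total")
        if abs(bg.sum() - 1.0) > 1e-9:
            raise ValidationError("background must sum to 1")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PFMMatrix):
            return NotImplemented
        return (
            self.matrix_id == other.matrix_id
            and self.counts.shape == other.counts.shape
            and np.allclose(self.counts, other.counts)
            and np.allclose(self.background, other.background)
            and math.isclose(self.pseudocount, other.pseudocount)
        )


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------


def interval_overlap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Overlap length in bp between two intervals (0 if different chromosomes).

    Strand is ignored: promoter windows are symmetric, so binding assignment
    is strand-blind throughout the pipeline.
    """
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


# ---------------------------------------------------------------------------
# narrowPeak / BED
# ---------------------------------------------------------------------------


def _apply_chrom_map(chrom: str, chrom_map: Mapping[str, str] | None) -> str:
    if chrom_map is not None:
        return chrom_map.get(chrom, chrom)
    return chrom


def read_narrowpeak(
    path: str | Path, chrom_map: Mapping[str, str] | None = None
) -> list[Peak]:
    """Read an ENCODE narrowPeak (10-column BED6+4) file.

    Column 8 (1-based) is -log10(p); column 10 is the summit offset from the
    peak start (-1 meaning "not called", mapped to None).
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise ParseError(
                    f"{path}: line {lineno}: expected >= 10 tab-separated "
                    f"narrowPeak fields, got {len(fields)}"
                )
            try:
                chrom = _apply_chrom_map(fields[0], chrom_map)
                start, end = int(fields[1]), int(fields[2])
                name = fields[3]
                strand = fields[5] if fields[5] in VALID_STRANDS else "."
                neg_log10_p = float(fields[7])
                summit = int(fields[9])
                fold = float(fields[6])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if start < 0:
                raise ValidationError(
                    f"{path}: line {lineno}: negative start coordinate {start}"
                )
            interval = GenomicInterval(chrom, start, end, strand, name)
            peaks.append(
                Peak(
                    interval=interval,
                    neg_log10_p=neg_log10_p,
                    summit_offset=None if summit < 0 else summit,
                    fold_enrichment=fold if fold >= 0 else None,
                )
            )
    return peaks


def write_narrowpeak(peaks: Iterable[Peak], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        for pk in peaks:
            iv = pk.interval
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        str(iv.start),
                        str(iv.end),
                        iv.name or ".",
                        "0",
                        iv.strand,
                        f"{pk.fold_enrichment if pk.fold_enrichment is not None else -1:g}",
                        f"{pk.neg_log10_p:g}",
                        "-1",
                        str(pk.summit_offset if pk.summit_offset is not None else -1),
                    ]
                )
                + "\n"
            )


def read_bed6(
    path: str | Path, chrom_map: Mapping[str, str] | None = None
) -> list[GenomicInterval]:
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected >= 3 BED fields"
                )
            try:
                chrom = _apply_chrom_map(fields[0], chrom_map)
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            name = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 and fields[5] in VALID_STRANDS else "."
            if start < 0:
                raise ValidationError(
                    f"{path}: line {lineno}: negative start coordinate {start}"
                )
            out.append(GenomicInterval(chrom, start, end, strand, name))
    return out


def write_bed6(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# Chromosome sizes / TSS catalog
# ---------------------------------------------------------------------------


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 columns")
            try:
                sizes[fields[0]] = int(fields[1])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


TSS_COLUMNS = [
    "feature_id",
    "gene_id",
    "chrom",
    "tss",
    "strand",
    "biotype",
    "coordinate_base",
]


def read_tss_table(
    path: str | Path, chrom_map: Mapping[str, str] | None = None
) -> list[TSSRecord]:
    """Read a TSS catalog TSV.

    The per-row ``coordinate_base`` column (0 or 1) declares the file's
    convention; 1-based positions are converted to 0-based on load.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in TSS_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing TSS catalog columns {missing}")
    records: list[TSSRecord] = []
    for row in df.itertuples(index=False):
        base = int(row.coordinate_base)
        if base not in (0, 1):
            raise ParseError(f"{path}: coordinate_base must be 0 or 1, got {base}")
        pos = int(row.tss) - base
        gene_id = None if pd.isna(row.gene_id) else str(row.gene_id)
        records.append(
            TSSRecord(
                feature_id=str(row.feature_id),
                chrom=_apply_chrom_map(str(row.chrom), chrom_map),
                position=pos,
                strand=str(row.strand),
                biotype=str(row.biotype),
                gene_id=gene_id,
            )
        )
    return records


def write_tss_table(records: Iterable[TSSRecord], path: str | Path) -> None:
    rows = [
        {
            "feature_id": r.feature_id,
            "gene_id": r.gene_id if r.gene_id is not None else "",
            "chrom": r.chrom,
            "tss": r.position,
            "strand": r.strand,
            "biotype": r.biotype,
            "coordinate_base": 0,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=TSS_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Count matrices / DE tables / target maps
# ---------------------------------------------------------------------------


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a features x samples matrix (first column = feature id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ValidationError(f"{path}: negative values in count/expression matrix")
    return df


def write_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="feature_id")


def read_feature_lengths(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected 2 columns (feature_id, length)")
    lengths = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(int)))
    if any(v <= 0 for v in lengths.values()):
        raise ValidationError(f"{path}: feature lengths must be > 0")
    return lengths


def write_feature_lengths(lengths: Mapping[str, int], path: str | Path) -> None:
    pd.DataFrame(
        {"feature_id": list(lengths), "length": list(lengths.values())}
    ).to_csv(path, sep="\t", index=False)


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read an externally produced DE table (feature_id, log2fc, pvalue, fdr[, status])."""
    df = pd.read_csv(path, sep="\t")
    required = {"feature_id", "log2fc", "pvalue", "fdr"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing DE table columns {sorted(missing)}")
    return df


def read_target_map(path: str | Path) -> set[tuple[str, str]]:
    """Read a TargetScan-style predicted-target TSV (mature_id, gene_id[, score])."""
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    if len(cols) < 2:
        raise ParseError(f"{path}: expected at least 2 columns (mature_id, gene_id)")
    return set(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def write_target_map(pairs: Iterable[tuple[str, str]], path: str | Path) -> None:
    rows = sorted(set(pairs))
    pd.DataFrame(rows, columns=["mature_id", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# JASPAR PFM
# ---------------------------------------------------------------------------


def read_pfm(path: str | Path) -> PFMMatrix:
    """Read a JASPAR-format PFM (">ID name" header, bracketed A/C/G/T rows).

    Background defaults to uniform 0.25 per base.
    """
    try:
        with open(path) as fh:
            motif = motifs.read(fh, "jaspar")
    except Exception as exc:  # biopython raises assorted exceptions on bad input
        raise ParseError(f"{path}: not a valid JASPAR PFM: {exc}") from exc
    counts = np.array([motif.counts[b] for b in BASE_ORDER], dtype=float)
    if counts.size == 0 or counts.shape[1] == 0:
        raise ParseError(f"{path}: JASPAR PFM has no count columns")
    matrix_id = motif.matrix_id if getattr(motif, "matrix_id", None) else motif.name
    return PFMMatrix(matrix_id=str(matrix_id), counts=counts)


def write_pfm(pfm: PFMMatrix, path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(f">{pfm.matrix_id} {pfm.matrix_id}\n")
        for i, base in enumerate(BASE_ORDER):
            row = " ".join(f"{v:g}" for v in pfm.counts[i])
            fh.write(f"{base}  [ {row} ]\n")
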