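"""Promoter catalog construction.

A putative promoter is the +/-2500 bp window around a transcript or
pri-miRNA TSS (clipped to chromosome bounds).  Promoters are built
per-transcript; gene-level "bound" calls are made later by merging the hits
of all transcript promoters of a gene.  Mature miRNAs attach to the
promoters of their pri-miRNA precursors.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core_io import (
    GenomicInterval,
    ParseError,
    TSSRecord,
    ValidationError,
)

DEFAULT_HALFWIDTH = 2500


@dataclass(frozen=True)
class PromoterRegion:
    """A TSS-derived window carrying its parent feature identity."""

    interval: GenomicInterval
    parent_id: str  # transcript or pri-miRNA id
    gene_id: str | None
    biotype: str
    halfwidth: int = DEFAULT_HALFWIDTH

    def __post_init__(self) -> None:
        if not self.parent_id:
            raise ValidationError("parent_id must be non-empty")
        if len(self.interval) > 2 * self.halfwidth:
            raise ValidationError("promoter window longer than 2*halfwidth")

    @property
    def group_id(self) -> str:
        """Key used when merging hits: owning gene for transcripts, else parent."""
        return self.gene_id if self.gene_id else self.parent_id


@dataclass(frozen=True)
class MatureMiRNARecord:
    """A mature miRNA (-5p/-3p arm) and the precursors it derives from."""

    mature_id: str
    precursor_ids: tuple[str, ...]
    arm: str  # "5p" or "3p"

    def __post_init__(self) -> None:
        if not self.precursor_ids:
            raise ValidationError(f"{self.mature_id}: precursor_ids must be non-empty")
        if self.arm not in {"5p", "3p"}:
            raise ValidationError("arm must be '5p' or '3p'")


def build_promoters(
    tss: Sequence[TSSRecord],
    chrom_sizes: Mapping[str, int],
    halfwidth: int = DEFAULT_HALFWIDTH,
) -> list[PromoterRegion]:
    """One window [max(0, pos-halfwidth), min(chrom_len, pos+halfwidth)) per TSS.

    Input order is preserved and identical windows are not deduplicated.
    The window is strand-symmetric, so strand only travels along as metadata.
    """
    if halfwidth <= 0:
        raise ValidationError("halfwidth must be > 0")
    out: list[PromoterRegion] = []
    for rec in tss:
        if rec.chrom not in chrom_sizes:
            raise ValidationError(f"{rec.feature_id}: unknown chromosome {rec.chrom}")
        chrom_len = chrom_sizes[rec.chrom]
        if rec.position >= chrom_len:
            raise ValidationError(
                f"{rec.feature_id}: TSS {rec.position} beyond chromosome "
                f"{rec.chrom} length {chrom_len}"
            )
        start = max(0, rec.position - halfwidth)
        end = min(chrom_len, rec.position + halfwidth)
        out.append(
            PromoterRegion(
                interval=GenomicInterval(
                    rec.chrom, start, end, rec.strand, rec.feature_id
                ),
                parent_id=rec.feature_id,
                gene_id=rec.gene_id,
                biotype=rec.biotype,
                halfwidth=halfwidth,
            )
        )
    return out


def map_mature_to_promoters(
    matures: Sequence[MatureMiRNARecord],
    promoters: Sequence[PromoterRegion],
) -> tuple[dict[str, list[PromoterRegion]], set[str]]:
    """Map each mature miRNA to the union of its precursors' promoters.

    Returns (mapping, flagged) where ``flagged`` holds mature ids whose
    precursors are all absent from the promoter catalog (empty mapping).
    """
    by_parent: dict[str, list[PromoterRegion]] = {}
    for prom in promoters:
        if prom.biotype == "pri_mirna":
            by_parent.setdefault(prom.parent_id, []).append(prom)
    mapping: dict[str, list[PromoterRegion]] = {}
    flagged: set[str] = set()
    for mat in matures:
        proms: list[PromoterRegion] = []
        seen: set[int] = set()
        for pre in mat.precursor_ids:
            for prom in by_parent.get(pre, []):
                if id(prom) not in seen:
                    seen.add(id(prom))
                    proms.append(prom)
        mapping[mat.mature_id] = proms
        if not proms:
            flagged.add(mat.mature_id)
    return mapping, flagged


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

MATURE_MAP_COLUMNS = ["mature_id", "precursor_id", "arm"]


def read_mature_map(path: str | Path) -> list[MatureMiRNARecord]:
    """Read a mature<->precursor map TSV (one row per mature/precursor pair)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MATURE_MAP_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing mature map columns {missing}")
    grouped: dict[str, tuple[list[str], str]] = {}
    for row in df.itertuples(index=False):
        mature = str(row.mature_id)
        pre_list, _ = grouped.setdefault(mature, ([], str(row.arm)))
        pre_list.append(str(row.precursor_id))
    return [
        MatureMiRNARecord(mature_id=m, precursor_ids=tuple(pres), arm=arm)
        for m, (pres, arm) in grouped.items()
    ]


def write_mature_map(matures: Iterable[MatureMiRNARecord], path: str | Path) -> None:
    rows = [
        {"mature_id": m.mature_id, "precursor_id": pre, "arm": m.arm}
        for m in matures
        for pre in m.precursor_ids
    ]
    pd.DataFrame(rows, columns=MATURE_MAP_COLUMNS).to_csv(path, sep="\t", index=False)


def promoters_to_bed(promoters: Sequence[PromoterRegion]) -> list[GenomicInterval]:
    return [p.interval for p in promoters]
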