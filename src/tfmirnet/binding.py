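"""Peak-to-promoter assignment, histone-mark annotation and PWM motif scanning.

The binding rule: a peak counts for a promoter iff its -log10(p) score
exceeds ``min_neglog10p`` AND its overlap with the promoter window exceeds
``min_overlap`` bp; both inequalities are strict.  Hits are then merged per
gene (a gene is bound if any of its transcript promoters collects a passing
peak), or per pri-miRNA for miRNA promoters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core_io import GenomicInterval, Peak, PFMMatrix, ValidationError, BASE_ORDER
from .promoters import PromoterRegion

DEFAULT_MIN_NEGLOG10P = 3.0
DEFAULT_MIN_OVERLAP = 100


@dataclass(frozen=True)
class MotifHit:
    """A PWM match inside a promoter sequence.

    ``position`` is the window start on the forward strand of the scanned
    sequence regardless of hit strand; ``rel_score`` rescales the log-odds
    score to [0, 1] between the minimum and maximum attainable window scores.
    """

    position: int
    strand: str
    score: float  # log2-odds (bits)
    rel_score: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.rel_score <= 1.0 + 1e-12):
            raise ValidationError("rel_score must lie in [0, 1]")


@dataclass
class PromoterBindingAnnotation:
    """Merged binding state for one gene or one pri-miRNA/mature miRNA."""

    parent_id: str
    gene_or_mature_id: str
    bound: bool
    n_passing_peaks: int
    best_peak: Peak | None
    total_overlap: int
    h3k27ac: bool = False
    h3k4me3: bool = False
    motif_hits: list[MotifHit] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.bound != (self.n_passing_peaks >= 1):
            raise ValidationError("bound must equal n_passing_peaks >= 1")


# ---------------------------------------------------------------------------
# Peak assignment
# ---------------------------------------------------------------------------


def _chrom_index(
    intervals: Sequence[GenomicInterval],
) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Group intervals by chromosome: (sorted starts, ends, original indices)."""
    by_chrom: dict[str, list[int]] = {}
    for i, iv in enumerate(intervals):
        by_chrom.setdefault(iv.chrom, []).append(i)
    index = {}
    for chrom, idxs in by_chrom.items():
        starts = np.array([intervals[i].start for i in idxs])
        order = np.argsort(starts, kind="stable")
        idx_arr = np.array(idxs)[order]
        index[chrom] = (
            starts[order],
            np.array([intervals[i].end for i in idx_arr]),
            idx_arr,
        )
    return index


def _overlap_pairs(
    peaks: Sequence[Peak], promoters: Sequence[PromoterRegion]
) -> list[tuple[int, int, int]]:
    """All (peak index, promoter index, overlap bp) pairs with overlap > 0."""
    prom_index = _chrom_index([p.interval for p in promoters])
    max_len_by_chrom = {
        chrom: int((ends - starts).max())
        for chrom, (starts, ends, _) in prom_index.items()
    }
    pairs: list[tuple[int, int, int]] = []
    for pi, peak in enumerate(peaks):
        iv = peak.interval
        if iv.chrom not in prom_index:
            continue
        starts, ends, idxs = prom_index[iv.chrom]
        lo = int(np.searchsorted(starts, iv.start - max_len_by_chrom[iv.chrom]))
        hi = int(np.searchsorted(starts, iv.end))
        if lo >= hi:
            continue
        ov = np.minimum(ends[lo:hi], iv.end) - np.maximum(starts[lo:hi], iv.start)
        for k in np.nonzero(ov > 0)[0]:
            pairs.append((pi, int(idxs[lo + k]), int(ov[k])))
    return pairs


def assign_peaks(
    peaks: Sequence[Peak],
    promoters: Sequence[PromoterRegion],
    min_neglog10p: float = DEFAULT_MIN_NEGLOG10P,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> list[PromoterBindingAnnotation]:
    """Assign peaks to promoters and merge hits at the gene level.

    Filtering is per peak-promoter pair (strict ``> min_neglog10p`` and
    ``> min_overlap``) and happens before the gene-level merge.  A peak
    overlapping several promoters of the same gene is counted once, with its
    maximal overlap.  ``best_peak`` maximises (score, overlap, leftmost start).

    One annotation is returned per group (gene id for transcript promoters,
    parent id otherwise), including unbound groups.
    """
    if min_neglog10p < 0 or min_overlap < 0:
        raise ValidationError("thresholds must be >= 0")

    group_of: list[str] = [p.group_id for p in promoters]
    groups: dict[str, str] = {}  # group -> representative parent id
    for prom in promoters:
        groups.setdefault(prom.group_id, prom.parent_id)

    # group -> peak index -> (max overlap for that peak within the group)
    merged: dict[str, dict[int, int]] = {g: {} for g in groups}
    for pi, qi, ov in _overlap_pairs(peaks, promoters):
        if peaks[pi].neg_log10_p > min_neglog10p and ov > min_overlap:
            g = group_of[qi]
            prev = merged[g].get(pi, 0)
            if ov > prev:
                merged[g][pi] = ov

    annotations: list[PromoterBindingAnnotation] = []
    for g, parent in groups.items():
        hits = merged[g]
        if hits:
            best_pi = min(
                hits,
                key=lambda pi: (
                    -peaks[pi].neg_log10_p,
                    -hits[pi],
                    peaks[pi].interval.start,
                ),
            )
            annotations.append(
                PromoterBindingAnnotation(
                    parent_id=parent,
                    gene_or_mature_id=g,
                    bound=True,
                    n_passing_peaks=len(hits),
                    best_peak=peaks[best_pi],
                    total_overlap=sum(hits.values()),
                )
            )
        else:
            annotations.append(
                PromoterBindingAnnotation(
                    parent_id=parent,
                    gene_or_mature_id=g,
                    bound=False,
                    n_passing_peaks=0,
                    best_peak=None,
                    total_overlap=0,
                )
            )
    return annotations


def bound_ids(annotations: Sequence[PromoterBindingAnnotation]) -> set[str]:
    return {a.gene_or_mature_id for a in annotations if a.bound}


# ---------------------------------------------------------------------------
# Histone marks
# ---------------------------------------------------------------------------


def mark_flags(
    promoters: Sequence[PromoterRegion],
    mark_peaks: Sequence[Peak],
    min_overlap: int = 1,
) -> np.ndarray:
    """Per-promoter boolean: does any mark peak overlap by >= min_overlap bp?"""
    flags = np.zeros(len(promoters), dtype=bool)
    for _, qi, ov in _overlap_pairs(mark_peaks, promoters):
        if ov >= min_overlap:
            flags[qi] = True
    return flags


def annotate_marks(
    promoters: Sequence[PromoterRegion],
    h3k27ac_peaks: Sequence[Peak],
    h3k4me3_peaks: Sequence[Peak],
    min_overlap: int = 1,
) -> list[tuple[bool, bool]]:
    """(H3K27ac, H3K4me3) presence per promoter; any-overlap decision."""
    k27 = mark_flags(promoters, h3k27ac_peaks, min_overlap)
    k4 = mark_flags(promoters, h3k4me3_peaks, min_overlap)
    return list(zip(k27.tolist(), k4.tolist()))


def marks_for_groups(
    promoters: Sequence[PromoterRegion],
    flags: Sequence[tuple[bool, bool]],
    grouping: Mapping[str, Sequence[PromoterRegion]] | None = None,
) -> dict[str, tuple[bool, bool]]:
    """OR the per-promoter flags over a grouping (e.g. mature -> promoters).

    Without an explicit grouping, promoters group by their ``group_id``.
    """
    flag_of = {id(p): f for p, f in zip(promoters, flags)}
    out: dict[str, tuple[bool, bool]] = {}
    if grouping is None:
        grouping = {}
        tmp: dict[str, list[PromoterRegion]] = {}
        for p in promoters:
            tmp.setdefault(p.group_id, []).append(p)
        grouping = tmp
    for key, proms in grouping.items():
        k27 = any(flag_of.get(id(p), (False, False))[0] for p in proms)
        k4 = any(flag_of.get(id(p), (False, False))[1] for p in proms)
        out[key] = (k27, k4)
    return out


# ---------------------------------------------------------------------------
# PWM scanning
# ---------------------------------------------------------------------------

_BASE_INDEX = {b: i for i, b in enumerate(BASE_ORDER)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def pwm_log_odds(pfm: PFMMatrix) -> np.ndarray:
    """Log2-odds matrix from counts: log2(p_hat(b,j) / bg(b)).

    p_hat(b,j) = (count(b,j) + pseudocount*bg(b)) / (colsum(j) + pseudocount).
    """
    if pfm.pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0")
    colsum = pfm.counts.sum(axis=0)
    p_hat = (pfm.counts + pfm.pseudocount * pfm.background[:, None]) / (
        colsum[None, :] + pfm.pseudocount
    )
    return np.log2(p_hat / pfm.background[:, None])


def pwm_consensus(pwm: np.ndarray) -> str:
    return "".join(BASE_ORDER[i] for i in pwm.argmax(axis=0))


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    """Map A,C,G,T -> 0..3 and anything else (N) -> 4."""
    arr = np.full(len(seq), 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        arr[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = idx
    return arr


def _window_scores(codes: np.ndarray, pwm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scores of all length-m windows; second array flags windows containing N."""
    m = pwm.shape[1]
    n_win = len(codes) - m + 1
    padded = np.vstack([pwm, np.zeros((1, m))])  # row 4 = placeholder for N
    windows = np.lib.stride_tricks.sliding_window_view(codes, m)
    scores = padded[windows, np.arange(m)].sum(axis=1)
    has_n = (windows == 4).any(axis=1)
    return scores, has_n


def scan_promoter(
    sequence: str,
    pwm: np.ndarray,
    rel_threshold: float = 0.80,
) -> list[MotifHit]:
    """Scan both strands of a sequence with a log-odds PWM.

    rel_score = (score - min) / (max - min) where min/max are the least and
    greatest attainable window scores; a window is a hit iff
    rel_score >= rel_threshold.  Windows containing N are skipped.  Minus
    strand hits are reported at their forward-strand window start.
    """
    if not (0.0 < rel_threshold <= 1.0):
        raise ValidationError("rel_threshold must lie in (0, 1]")
    sequence = sequence.upper()
    m = pwm.shape[1]
    if len(sequence) < m:
        return []
    smax = pwm.max(axis=0).sum()
    smin = pwm.min(axis=0).sum()
    span = smax - smin
    if span <= 0:  # degenerate flat matrix: every window attains the max
        span = 1.0
        smin = smax - 1.0

    hits: list[MotifHit] = []
    for strand, seq in (("+", sequence), ("-", reverse_complement(sequence))):
        codes = _encode(seq)
        scores, has_n = _window_scores(codes, pwm)
        rel = (scores - smin) / span
        for j in np.nonzero((rel >= rel_threshold) & ~has_n)[0]:
            pos = int(j) if strand == "+" else len(sequence) - m - int(j)
            hits.append(
                MotifHit(
                    position=pos,
                    strand=strand,
                    score=float(scores[j]),
                    rel_score=float(min(rel[j], 1.0)),
                )
            )
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits
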