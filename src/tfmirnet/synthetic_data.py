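"""Synthetic study generator with a planted ground-truth regulatory network.

The generator lays out a toy genome (genes on chr1, pri-miRNAs on chr2 with
non-colliding promoter windows), plants a TF-driven network — promoter-bound
miRNAs that are differentially expressed on knockdown and repress target
genes so that fold-change signs oppose — and emits every input the analysis
pipeline consumes: TSS catalog, chromosome sizes, narrowPeak files for the
TF and two histone marks, promoter sequences with embedded motifs, a JASPAR
PFM, two-condition negative-binomial count matrices, a precursor->mature
map and a predicted-target map.

Counts follow a mean-dispersion NB parameterisation (variance = mu +
alpha*mu^2) with log-normal baseline means; planted features have their
silenced-condition mean scaled by 2^effect.  Replicate numbers default to
two per condition for mRNA and three for miRNA, matching the emulated study
design.  One global seed drives a fixed substream per generator component,
so components can be regenerated independently and reproducibly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import networkx as nx

from .core_io import (
    GenomicInterval,
    Peak,
    PFMMatrix,
    TSSRecord,
    ValidationError,
    write_chrom_sizes,
    write_counts,
    write_fasta,
    write_feature_lengths,
    write_narrowpeak,
    write_pfm,
    write_target_map,
    write_tss_table,
)
from .network import MiRNATargetMap, edges_of_type
from .promoters import MatureMiRNARecord, write_mature_map

# fixed substream tags (second word of the rng seed vector)
_SS_ANNOTATION = 11
_SS_TRUTH = 23
_SS_CHIP = 37
_SS_SEQ = 41
_SS_COUNTS = 53
_SS_TARGETS = 67

TF_LABEL = "TFEB"

#: E-box-like consensus used for the built-in synthetic PFM.
_MOTIF_CONSENSUS = "GTCACGTGAC"


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study; defaults emulate the study design."""

    n_genes: int = 2000
    n_mirnas: int = 100  # pri-miRNA precursors (two mature arms each)
    n_mrna_reps: int = 2  # replicates per condition, mRNA-seq
    n_mirna_reps: int = 3  # replicates per condition, miRNA-seq
    nb_dispersion: float = 0.1
    gene_meanlog: float = 5.0
    gene_sdlog: float = 1.5
    mirna_meanlog: float = 5.5
    mirna_sdlog: float = 1.2
    planted_mean_floor: float = 200.0
    frac_deg: float = 0.05  # fraction of genes with a direct planted effect
    frac_dem: float = 0.10  # fraction of precursors planted (both arms)
    effect_min: float = 1.5
    effect_max: float = 3.0
    targets_per_dem: int = 5
    repression_coupling: float = 1.0  # scales |dem effect| on the target
    frac_deg_bound: float = 0.25
    frac_target_bound: float = 0.5
    frac_extra_bound_genes: float = 0.30
    frac_extra_bound_mirnas: float = 0.30
    frac_active_marks: float = 0.5
    frac_shared_mature: float = 0.10  # precursor pairs sharing a 5p mature
    frac_second_transcript: float = 0.20
    decoy_peak_rate: float = 0.2  # decoys of each kind per promoter group
    target_decoy_rate: float = 2.0  # decoy pairs per planted repression edge
    gene_spacing: int = 12000
    promoter_halfwidth: int = 2500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 0 or self.n_mirnas < 0:
            raise ValidationError("feature counts must be >= 0")
        if self.n_mrna_reps < 1 or self.n_mirna_reps < 1:
            raise ValidationError("need >= 1 replicate per condition")
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be > 0")
        if self.gene_spacing < 2 * self.promoter_halfwidth + 1000:
            raise ValidationError(
                "gene_spacing too small: promoter windows would collide"
            )

    @classmethod
    def strong_signal(cls, seed: int = 1) -> "SimulationConfig":
        """The noise-free recovery regime: large effects, low dispersion,
        no decoys, and binding restricted to the planted network."""
        return cls(
            nb_dispersion=0.05,
            effect_min=2.0,
            effect_max=3.0,
            frac_deg_bound=0.5,
            frac_target_bound=1.0,
            frac_extra_bound_genes=0.0,
            frac_extra_bound_mirnas=0.0,
            frac_shared_mature=0.0,
            decoy_peak_rate=0.0,
            target_decoy_rate=0.0,
            seed=seed,
        )


@dataclass
class SyntheticTruth:
    """The planted ground truth used for recovery scoring."""

    bound_gene_promoters: set[str]
    bound_mirna_promoters: set[str]  # pri-miRNA ids
    planted_degs: dict[str, float]  # gene -> signed log2 effect
    planted_dems: dict[str, float]  # mature -> signed log2 effect
    repression_edges: set[tuple[str, str]]  # (mature, gene)
    motif_carriers: set[str]  # pri-miRNA ids with an embedded motif
    dem_precursors: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(e == 0 for e in self.planted_degs.values()):
            raise ValidationError("planted gene effects must be nonzero")
        if any(e == 0 for e in self.planted_dems.values()):
            raise ValidationError("planted miRNA effects must be nonzero")
        bad = {m for m, _ in self.repression_edges} - set(self.planted_dems)
        if bad:
            raise ValidationError(f"repression edges from non-planted matures: {bad}")

    def bound_dem_matures(self) -> set[str]:
        return {
            m
            for m, pres in self.dem_precursors.items()
            if any(p in self.bound_mirna_promoters for p in pres)
        }


@dataclass
class SyntheticBundle:
    """Everything one simulated study produces, in memory."""

    config: SimulationConfig
    tss: list[TSSRecord]
    chrom_sizes: dict[str, int]
    matures: list[MatureMiRNARecord]
    gene_lengths: dict[str, int]
    tf_peaks: list[Peak]
    h3k27ac_peaks: list[Peak]
    h3k4me3_peaks: list[Peak]
    mirna_promoter_seqs: dict[str, str]
    pfm: PFMMatrix
    gene_counts: pd.DataFrame
    arm_counts: pd.DataFrame
    gene_condition: dict[str, str]
    mirna_condition: dict[str, str]
    target_map: MiRNATargetMap
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------


def _gene_id(i: int) -> str:
    return f"G{i:05d}"


def _pri_id(i: int) -> str:
    return f"PRI-{i:04d}"


def generate_annotation(
    cfg: SimulationConfig,
) -> tuple[list[TSSRecord], dict[str, int], list[MatureMiRNARecord], dict[str, int]]:
    """Lay out gene and pri-miRNA TSSs on two chromosomes.

    Features are spaced so promoter windows never collide; a fraction of
    genes get a second transcript with a jittered TSS (windows of the same
    gene may then overlap, which the gene-level merge must handle).
    """
    rng = np.random.default_rng([_SS_ANNOTATION, cfg.seed])
    margin = 2 * cfg.promoter_halfwidth
    tss: list[TSSRecord] = []
    chrom_sizes = {
        "chr1": margin + max(cfg.n_genes, 1) * cfg.gene_spacing + margin,
        "chr2": margin + max(cfg.n_mirnas, 1) * cfg.gene_spacing + margin,
    }
    gene_lengths: dict[str, int] = {}
    for i in range(cfg.n_genes):
        gid = _gene_id(i)
        pos = margin + i * cfg.gene_spacing
        strand = "+" if rng.random() < 0.5 else "-"
        tss.append(
            TSSRecord(
                feature_id=f"{gid}.t1",
                chrom="chr1",
                position=pos,
                strand=strand,
                biotype="protein_coding",
                gene_id=gid,
            )
        )
        if rng.random() < cfg.frac_second_transcript:
            jitter = int(rng.integers(-1000, 1001))
            tss.append(
                TSSRecord(
                    feature_id=f"{gid}.t2",
                    chrom="chr1",
                    position=max(0, pos + jitter),
                    strand=strand,
                    biotype="protein_coding",
                    gene_id=gid,
                )
            )
        gene_lengths[gid] = int(rng.integers(500, 5001))
    for i in range(cfg.n_mirnas):
        pid = _pri_id(i)
        pos = margin + i * cfg.gene_spacing
        tss.append(
            TSSRecord(
                feature_id=pid,
                chrom="chr2",
                position=pos,
                strand="+" if rng.random() < 0.5 else "-",
                biotype="pri_mirna",
                gene_id=None,
            )
        )

    matures: list[MatureMiRNARecord] = []
    shared_pool = list(range(cfg.n_mirnas))
    n_shared_pairs = int(cfg.frac_shared_mature * cfg.n_mirnas / 2)
    shared_pairs: list[tuple[int, int]] = []
    if n_shared_pairs > 0 and cfg.n_mirnas >= 2 * n_shared_pairs:
        chosen = rng.choice(shared_pool, size=2 * n_shared_pairs, replace=False)
        shared_pairs = [
            (int(chosen[2 * k]), int(chosen[2 * k + 1])) for k in range(n_shared_pairs)
        ]
    in_pair = {i for pair in shared_pairs for i in pair}
    for i in range(cfg.n_mirnas):
        if i in in_pair:
            continue
        matures.append(
            MatureMiRNARecord(f"miR-{i:04d}-5p", (_pri_id(i),), "5p")
        )
        matures.append(
            MatureMiRNARecord(f"miR-{i:04d}-3p", (_pri_id(i),), "3p")
        )
    for a, b in shared_pairs:
        lo, hi = min(a, b), max(a, b)
        matures.append(
            MatureMiRNARecord(
                f"miR-{lo:04d}s-5p", (_pri_id(lo), _pri_id(hi)), "5p"
            )
        )
        for i in (lo, hi):
            matures.append(
                MatureMiRNARecord(f"miR-{i:04d}-3p", (_pri_id(i),), "3p")
            )
    matures.sort(key=lambda m: m.mature_id)
    return tss, chrom_sizes, matures, gene_lengths


# ---------------------------------------------------------------------------
# Truth
# ---------------------------------------------------------------------------


def generate_truth(
    cfg: SimulationConfig,
    matures: Sequence[MatureMiRNARecord],
) -> SyntheticTruth:
    """Plant the ground-truth network.

    DEMs are planted per precursor (both arms, precursors with shared
    matures excluded so mature and promoter identities stay one-to-one);
    every planted precursor's promoter is TF-bound.  Each planted mature
    represses a disjoint set of target genes with effect
    -sign(dem) * |dem effect| * coupling, so sign opposition holds in
    expectation.  Additional genes carry direct planted effects.
    """
    rng = np.random.default_rng([_SS_TRUTH, cfg.seed])
    gene_ids = [_gene_id(i) for i in range(cfg.n_genes)]
    single_pre = [
        m for m in matures if len(m.precursor_ids) == 1
    ]
    pre_to_matures: dict[str, list[MatureMiRNARecord]] = {}
    for m in single_pre:
        pre_to_matures.setdefault(m.precursor_ids[0], []).append(m)
    eligible_pre = sorted(
        p for p, ms in pre_to_matures.items() if len(ms) == 2
    )
    n_dem_pre = min(int(round(cfg.frac_dem * cfg.n_mirnas)), len(eligible_pre))
    dem_pre = sorted(
        rng.choice(eligible_pre, size=n_dem_pre, replace=False).tolist()
    ) if n_dem_pre else []

    planted_dems: dict[str, float] = {}
    dem_precursors: dict[str, tuple[str, ...]] = {}
    for pre in dem_pre:
        for m in pre_to_matures[pre]:
            effect = float(rng.uniform(cfg.effect_min, cfg.effect_max))
            if rng.random() < 0.5:
                effect = -effect
            planted_dems[m.mature_id] = effect
            dem_precursors[m.mature_id] = m.precursor_ids

    all_pre = sorted({p for m in matures for p in m.precursor_ids})
    other_pre = [p for p in all_pre if p not in set(dem_pre)]
    n_extra_mirna = int(round(cfg.frac_extra_bound_mirnas * len(other_pre)))
    extra_mirna = (
        rng.choice(other_pre, size=n_extra_mirna, replace=False).tolist()
        if n_extra_mirna
        else []
    )
    bound_mirna = set(dem_pre) | set(extra_mirna)

    # repression targets: disjoint gene sets per planted mature
    pool = list(gene_ids)
    rng.shuffle(pool)
    repression_edges: set[tuple[str, str]] = set()
    planted_degs: dict[str, float] = {}
    target_genes: list[str] = []
    for mature_id in sorted(planted_dems):
        for _ in range(cfg.targets_per_dem):
            if not pool:
                raise ValidationError("genome too small for requested repression targets")
            g = pool.pop()
            repression_edges.add((mature_id, g))
            planted_degs[g] = (
                -np.sign(planted_dems[mature_id])
                * abs(planted_dems[mature_id])
                * cfg.repression_coupling
            )
            target_genes.append(g)

    n_deg = min(int(round(cfg.frac_deg * cfg.n_genes)), len(pool))
    direct_degs = [pool.pop() for _ in range(n_deg)]
    for g in direct_degs:
        effect = float(rng.uniform(cfg.effect_min, cfg.effect_max))
        if rng.random() < 0.5:
            effect = -effect
        planted_degs[g] = effect

    bound_genes: set[str] = set()
    n_target_bound = int(round(cfg.frac_target_bound * len(target_genes)))
    if n_target_bound:
        bound_genes |= set(
            rng.choice(target_genes, size=n_target_bound, replace=False).tolist()
        )
    n_deg_bound = int(round(cfg.frac_deg_bound * len(direct_degs)))
    if n_deg_bound:
        bound_genes |= set(
            rng.choice(direct_degs, size=n_deg_bound, replace=False).tolist()
        )
    n_extra_genes = int(round(cfg.frac_extra_bound_genes * len(pool)))
    if n_extra_genes:
        bound_genes |= set(
            rng.choice(pool, size=n_extra_genes, replace=False).tolist()
        )

    return SyntheticTruth(
        bound_gene_promoters=bound_genes,
        bound_mirna_promoters=bound_mirna,
        planted_degs=planted_degs,
        planted_dems=planted_dems,
        repression_edges=repression_edges,
        motif_carriers=set(dem_pre),
        dem_precursors=dem_precursors,
    )


# ---------------------------------------------------------------------------
# ChIP peaks
# ---------------------------------------------------------------------------


def _first_tss(tss: Sequence[TSSRecord]) -> dict[str, TSSRecord]:
    """First TSS record per group id (gene id, or feature id for pri-miRNAs)."""
    out: dict[str, TSSRecord] = {}
    for rec in tss:
        key = rec.gene_id if rec.gene_id else rec.feature_id
        out.setdefault(key, rec)
    return out


def generate_chip(
    cfg: SimulationConfig,
    truth: SyntheticTruth,
    tss: Sequence[TSSRecord],
) -> tuple[list[Peak], list[Peak], list[Peak]]:
    """TF and histone-mark narrowPeak records.

    Every bound promoter gets one passing peak (400 bp centred on the TSS,
    score well above the cut-off).  Decoy TF peaks come in three kinds, each
    violating one acceptance rule: sub-threshold score inside a promoter,
    sub-threshold overlap at a window edge, or an intergenic placement.
    """
    rng = np.random.default_rng([_SS_CHIP, cfg.seed])
    anchors = _first_tss(tss)
    bound_ids = sorted(truth.bound_gene_promoters | truth.bound_mirna_promoters)
    tf_peaks: list[Peak] = []
    for k, key in enumerate(bound_ids):
        rec = anchors[key]
        start = max(0, rec.position - 200)
        tf_peaks.append(
            Peak(
                interval=GenomicInterval(
                    rec.chrom, start, rec.position + 200, ".", f"tf_peak_{k}"
                ),
                neg_log10_p=round(float(rng.uniform(5.0, 50.0)), 4),
                summit_offset=200,
                fold_enrichment=round(float(rng.uniform(2.0, 20.0)), 4),
            )
        )

    all_ids = sorted(anchors)
    n_decoys = int(round(cfg.decoy_peak_rate * len(all_ids)))
    hw = cfg.promoter_halfwidth
    leftmost: dict[str, int] = {}
    for rec in tss:
        key = rec.gene_id if rec.gene_id else rec.feature_id
        leftmost[key] = min(leftmost.get(key, rec.position), rec.position)
    for k in range(n_decoys):
        key = all_ids[int(rng.integers(len(all_ids)))]
        rec = anchors[key]
        # kind 1: good overlap, sub-threshold score
        tf_peaks.append(
            Peak(
                interval=GenomicInterval(
                    rec.chrom,
                    max(0, rec.position - 150),
                    rec.position + 250,
                    ".",
                    f"decoy_lowscore_{k}",
                ),
                neg_log10_p=round(float(rng.uniform(0.5, 2.9)), 4),
                fold_enrichment=1.0,
            )
        )
        # kind 2: good score, overlap of only 80 bp at the leftmost window
        # edge (windows of sibling transcripts start further right, so the
        # overlap with any window of the group stays <= 80 bp)
        edge = leftmost[key] - hw
        if edge - 320 >= 0:
            tf_peaks.append(
                Peak(
                    interval=GenomicInterval(
                        rec.chrom, edge - 320, edge + 80, ".", f"decoy_shortov_{k}"
                    ),
                    neg_log10_p=round(float(rng.uniform(5.0, 50.0)), 4),
                    fold_enrichment=2.0,
                )
            )
        # kind 3: good score, intergenic (gaps are > window + peak width)
        mid = rec.position + cfg.gene_spacing // 2
        tf_peaks.append(
            Peak(
                interval=GenomicInterval(
                    rec.chrom, mid - 200, mid + 200, ".", f"decoy_intergenic_{k}"
                ),
                neg_log10_p=round(float(rng.uniform(5.0, 50.0)), 4),
                fold_enrichment=2.0,
            )
        )

    active = set(bound_ids)
    rest = [i for i in all_ids if i not in active]
    n_active_extra = int(round(cfg.frac_active_marks * len(rest)))
    if n_active_extra:
        active |= set(rng.choice(rest, size=n_active_extra, replace=False).tolist())
    k27: list[Peak] = []
    k4: list[Peak] = []
    for k, key in enumerate(sorted(active)):
        rec = anchors[key]
        for marks, tag in ((k27, "k27ac"), (k4, "k4me3")):
            marks.append(
                Peak(
                    interval=GenomicInterval(
                        rec.chrom,
                        max(0, rec.position - 500),
                        rec.position + 500,
                        ".",
                        f"{tag}_{k}",
                    ),
                    neg_log10_p=round(float(rng.uniform(5.0, 50.0)), 4),
                    fold_enrichment=round(float(rng.uniform(2.0, 10.0)), 4),
                )
            )
    return tf_peaks, k27, k4


# ---------------------------------------------------------------------------
# Sequences and PFM
# ---------------------------------------------------------------------------


def make_default_pfm(matrix_id: str = "SYN0001.1") -> PFMMatrix:
    """A sharp synthetic E-box-style PFM (consensus GTCACGTGAC)."""
    counts = np.full((4, len(_MOTIF_CONSENSUS)), 5.0)
    for j, base in enumerate(_MOTIF_CONSENSUS):
        counts["ACGT".index(base), j] = 85.0
    return PFMMatrix(matrix_id=matrix_id, counts=counts)


def generate_sequences(
    cfg: SimulationConfig,
    truth: SyntheticTruth,
    tss: Sequence[TSSRecord],
) -> tuple[dict[str, str], PFMMatrix]:
    """Random pri-miRNA promoter sequences; motif carriers get the consensus
    embedded at a random offset (forward strand)."""
    rng = np.random.default_rng([_SS_SEQ, cfg.seed])
    pfm = make_default_pfm()
    motif = _MOTIF_CONSENSUS
    seqs: dict[str, str] = {}
    length = 2 * cfg.promoter_halfwidth
    base_bytes = np.frombuffer(b"ACGT", dtype=np.uint8)
    for rec in tss:
        if rec.biotype != "pri_mirna":
            continue
        seq = base_bytes[rng.integers(0, 4, size=length)].tobytes().decode()
        if rec.feature_id in truth.motif_carriers:
            offset = int(rng.integers(100, length - len(motif) - 100))
            seq = seq[:offset] + motif + seq[offset + len(motif):]
        seqs[rec.feature_id] = seq
    return seqs, pfm


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    n = 1.0 / dispersion
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def generate_counts(
    cfg: SimulationConfig,
    truth: SyntheticTruth,
    matures: Sequence[MatureMiRNARecord],
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str], dict[str, str]]:
    """Two-condition NB count matrices for genes and precursor arms.

    Returns (gene_counts, arm_counts, gene_condition, mirna_condition).
    ``arm_counts`` has one row per (precursor, mature) pair so the mature
    aggregation step has real work to do.
    """
    rng = np.random.default_rng([_SS_COUNTS, cfg.seed])
    gene_ids = [_gene_id(i) for i in range(cfg.n_genes)]

    g_samples_c = [f"wt_{r + 1}" for r in range(cfg.n_mrna_reps)]
    g_samples_s = [f"sh_{r + 1}" for r in range(cfg.n_mrna_reps)]
    gene_condition = {**{s: "control" for s in g_samples_c}, **{s: "silenced" for s in g_samples_s}}

    base = rng.lognormal(cfg.gene_meanlog, cfg.gene_sdlog, size=len(gene_ids))
    for i, g in enumerate(gene_ids):
        if g in truth.planted_degs:
            base[i] = max(base[i], cfg.planted_mean_floor)
    effect = np.array([truth.planted_degs.get(g, 0.0) for g in gene_ids])
    mu_c = np.tile(base[:, None], (1, cfg.n_mrna_reps))
    mu_s = np.tile((base * 2.0 ** effect)[:, None], (1, cfg.n_mrna_reps))
    counts = np.concatenate(
        [
            _nb_draw(rng, mu_c, cfg.nb_dispersion),
            _nb_draw(rng, mu_s, cfg.nb_dispersion),
        ],
        axis=1,
    )
    gene_counts = pd.DataFrame(
        counts, index=gene_ids, columns=g_samples_c + g_samples_s
    )

    m_samples_c = [f"wt_{r + 1}" for r in range(cfg.n_mirna_reps)]
    m_samples_s = [f"sh_{r + 1}" for r in range(cfg.n_mirna_reps)]
    mirna_condition = {**{s: "control" for s in m_samples_c}, **{s: "silenced" for s in m_samples_s}}

    rows = []
    mature_base: dict[str, float] = {}
    for m in matures:
        b = float(rng.lognormal(cfg.mirna_meanlog, cfg.mirna_sdlog))
        if m.mature_id in truth.planted_dems:
            b = max(b, cfg.planted_mean_floor)
        mature_base[m.mature_id] = b
    for m in sorted(matures, key=lambda r: r.mature_id):
        eff = truth.planted_dems.get(m.mature_id, 0.0)
        for pre in m.precursor_ids:
            mu_ctrl = np.full(cfg.n_mirna_reps, mature_base[m.mature_id])
            mu_sil = mu_ctrl * 2.0 ** eff
            vals = np.concatenate(
                [
                    _nb_draw(rng, mu_ctrl, cfg.nb_dispersion),
                    _nb_draw(rng, mu_sil, cfg.nb_dispersion),
                ]
            )
            rows.append(
                {
                    "precursor_id": pre,
                    "mature_id": m.mature_id,
                    **dict(zip(m_samples_c + m_samples_s, vals.tolist())),
                }
            )
    arm_counts = pd.DataFrame(rows)
    return gene_counts, arm_counts, gene_condition, mirna_condition


# ---------------------------------------------------------------------------
# Target map
# ---------------------------------------------------------------------------


def generate_target_map(
    cfg: SimulationConfig,
    truth: SyntheticTruth,
    matures: Sequence[MatureMiRNARecord],
) -> MiRNATargetMap:
    """All planted repression edges plus random decoy pairs."""
    rng = np.random.default_rng([_SS_TARGETS, cfg.seed])
    pairs = set(truth.repression_edges)
    n_decoys = int(round(cfg.target_decoy_rate * len(truth.repression_edges)))
    mature_ids = sorted({m.mature_id for m in matures})
    gene_ids = [_gene_id(i) for i in range(cfg.n_genes)]
    attempts = 0
    while len(pairs) < len(truth.repression_edges) + n_decoys and attempts < 50 * max(n_decoys, 1):
        attempts += 1
        if not mature_ids or not gene_ids:
            break
        m = mature_ids[int(rng.integers(len(mature_ids)))]
        g = gene_ids[int(rng.integers(len(gene_ids)))]
        if (m, g) not in truth.repression_edges:
            pairs.add((m, g))
    return MiRNATargetMap(pairs=pairs)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def simulate(cfg: SimulationConfig) -> SyntheticBundle:
    """Generate one fully self-consistent synthetic study."""
    tss, chrom_sizes, matures, gene_lengths = generate_annotation(cfg)
    truth = generate_truth(cfg, matures)
    tf_peaks, k27, k4 = generate_chip(cfg, truth, tss)
    seqs, pfm = generate_sequences(cfg, truth, tss)
    gene_counts, arm_counts, gene_cond, mirna_cond = generate_counts(cfg, truth, matures)
    target_map = generate_target_map(cfg, truth, matures)
    return SyntheticBundle(
        config=cfg,
        tss=tss,
        chrom_sizes=chrom_sizes,
        matures=matures,
        gene_lengths=gene_lengths,
        tf_peaks=tf_peaks,
        h3k27ac_peaks=k27,
        h3k4me3_peaks=k4,
        mirna_promoter_seqs=seqs,
        pfm=pfm,
        gene_counts=gene_counts,
        arm_counts=arm_counts,
        gene_condition=gene_cond,
        mirna_condition=mirna_cond,
        target_map=target_map,
        truth=truth,
    )


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the full input bundle as plain-text files; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tss": outdir / "tss_catalog.tsv",
        "chrom_sizes": outdir / "chrom.sizes",
        "mature_map": outdir / "mature_map.tsv",
        "gene_lengths": outdir / "gene_lengths.tsv",
        "tf_peaks": outdir / "tf_peaks.narrowPeak",
        "h3k27ac_peaks": outdir / "h3k27ac.narrowPeak",
        "h3k4me3_peaks": outdir / "h3k4me3.narrowPeak",
        "promoter_fasta": outdir / "mirna_promoters.fa",
        "pfm": outdir / "motif.jaspar",
        "gene_counts": outdir / "gene_counts.tsv",
        "arm_counts": outdir / "mirna_arm_counts.tsv",
        "target_map": outdir / "target_map.tsv",
        "conditions": outdir / "conditions.json",
        "truth": outdir / "truth.json",
    }
    write_tss_table(bundle.tss, paths["tss"])
    write_chrom_sizes(bundle.chrom_sizes, paths["chrom_sizes"])
    write_mature_map(bundle.matures, paths["mature_map"])
    write_feature_lengths(bundle.gene_lengths, paths["gene_lengths"])
    write_narrowpeak(bundle.tf_peaks, paths["tf_peaks"])
    write_narrowpeak(bundle.h3k27ac_peaks, paths["h3k27ac_peaks"])
    write_narrowpeak(bundle.h3k4me3_peaks, paths["h3k4me3_peaks"])
    write_fasta(bundle.mirna_promoter_seqs, paths["promoter_fasta"])
    write_pfm(bundle.pfm, paths["pfm"])
    write_counts(bundle.gene_counts, paths["gene_counts"])
    bundle.arm_counts.to_csv(paths["arm_counts"], sep="\t", index=False)
    write_target_map(bundle.target_map.pairs, paths["target_map"])
    with open(paths["conditions"], "w") as fh:
        json.dump(
            {"mrna": bundle.gene_condition, "mirna": bundle.mirna_condition},
            fh,
            indent=1,
            sort_keys=True,
        )
    with open(paths["truth"], "w") as fh:
        json.dump(truth_to_dict(bundle.truth), fh, indent=1, sort_keys=True)
    return paths


def truth_to_dict(truth: SyntheticTruth) -> dict:
    return {
        "bound_gene_promoters": sorted(truth.bound_gene_promoters),
        "bound_mirna_promoters": sorted(truth.bound_mirna_promoters),
        "planted_degs": dict(sorted(truth.planted_degs.items())),
        "planted_dems": dict(sorted(truth.planted_dems.items())),
        "repression_edges": sorted(map(list, truth.repression_edges)),
        "motif_carriers": sorted(truth.motif_carriers),
        "dem_precursors": {
            m: list(p) for m, p in sorted(truth.dem_precursors.items())
        },
    }


def truth_from_dict(d: Mapping) -> SyntheticTruth:
    return SyntheticTruth(
        bound_gene_promoters=set(d["bound_gene_promoters"]),
        bound_mirna_promoters=set(d["bound_mirna_promoters"]),
        planted_degs=dict(d["planted_degs"]),
        planted_dems=dict(d["planted_dems"]),
        repression_edges={(m, g) for m, g in d["repression_edges"]},
        motif_carriers=set(d["motif_carriers"]),
        dem_precursors={m: tuple(p) for m, p in d.get("dem_precursors", {}).items()},
    )


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------


def _prf(inferred: set, expected: set) -> dict[str, float | None]:
    tp = len(inferred & expected)
    precision = tp / len(inferred) if inferred else None
    recall = tp / len(expected) if expected else None
    return {"precision": precision, "recall": recall}


def score_recovery(
    inferred: nx.DiGraph,
    truth: SyntheticTruth,
    tf_label: str = TF_LABEL,
) -> dict[str, dict[str, float | None]]:
    """Precision/recall of an inferred bound network against the planted one.

    Expected edges are derived from the truth restricted to TF-bound
    promoters (the bound network's universe): TF->mature for bound planted
    DEMs, mature->gene for planted repression edges whose two endpoints are
    bound, and TF->gene for the bound targets of those edges.
    """
    bound_dems = truth.bound_dem_matures()
    exp_tf_mirna = {(tf_label, m) for m in bound_dems}
    exp_repress = {
        (m, g)
        for m, g in truth.repression_edges
        if m in bound_dems and g in truth.bound_gene_promoters
    }
    exp_tf_gene = {(tf_label, g) for _, g in exp_repress}
    return {
        "tf_binds_mirna": _prf(edges_of_type(inferred, "tf_binds_mirna"), exp_tf_mirna),
        "mirna_represses_gene": _prf(
            edges_of_type(inferred, "mirna_represses_gene"), exp_repress
        ),
        "tf_binds_gene": _prf(edges_of_type(inferred, "tf_binds_gene"), exp_tf_gene),
    }
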