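"""End-to-end orchestration: filters -> DE -> binding -> anti-correlation -> networks.

The pipeline consumes a YAML config naming every input file plus the
threshold set, runs the stages in a fixed order, writes all intermediate
tables, the two exported networks and a JSON run report, and is
byte-deterministic given identical inputs.

Stage order: promoter catalog; gene expression filter + DE; miRNA
aggregation + filter + DE; peak-to-promoter binding and mark/motif
annotation; anti-correlation edge selection; network assembly and export.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .binding import (
    PromoterBindingAnnotation,
    annotate_marks,
    assign_peaks,
    bound_ids,
    marks_for_groups,
    pwm_log_odds,
    scan_promoter,
)
from .core_io import (
    Peak,
    PFMMatrix,
    TSSRecord,
    ValidationError,
    read_chrom_sizes,
    read_counts,
    read_de_table,
    read_fasta,
    read_feature_lengths,
    read_narrowpeak,
    read_pfm,
    read_target_map,
    read_tss_table,
)
from .diffexpr import (
    DEResult,
    Thresholds,
    adjust_and_classify,
    de_results_from_frame,
    classify_de,
    de_test,
    normalize_counts,
    write_de_table,
)
from .expression import (
    ExpressionMatrix,
    aggregate_mature_mirna,
    compute_tpm,
    filter_expressed_genes,
    filter_expressed_mirnas,
)
from .network import (
    MiRNATargetMap,
    anticorrelated_target_set,
    build_networks,
    export_network,
    select_anticorrelated,
)
from .promoters import (
    MatureMiRNARecord,
    PromoterRegion,
    build_promoters,
    map_mature_to_promoters,
    promoters_to_bed,
    read_mature_map,
)

logger = logging.getLogger("tfmirnet")


@dataclass
class PipelineConfig:
    """Paths, thresholds and conventions for one pipeline run."""

    tss: str = ""
    chrom_sizes: str = ""
    mature_map: str = ""
    tf_peaks: str = ""
    gene_counts: str = ""
    gene_lengths: str = ""
    arm_counts: str = ""
    target_map: str = ""
    conditions: str = ""  # JSON: {"mrna": {sample: condition}, "mirna": {...}}
    h3k27ac_peaks: str | None = None
    h3k4me3_peaks: str | None = None
    promoter_fasta: str | None = None
    pfm: str | None = None
    de_mode: str = "internal"  # or "external"
    gene_de_table: str | None = None
    mirna_de_table: str | None = None
    chrom_map: dict[str, str] | None = None
    tf_label: str = "TFEB"
    outdir: str = "tfmirnet_out"
    seed: int = 0
    thresholds: Thresholds = field(default_factory=Thresholds)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        thr = raw.pop("thresholds", {}) or {}
        cfg = cls(**raw, thresholds=Thresholds(**thr))
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


_REQUIRED_PATH_KEYS = (
    "tss",
    "chrom_sizes",
    "mature_map",
    "tf_peaks",
    "gene_counts",
    "gene_lengths",
    "arm_counts",
    "target_map",
    "conditions",
)


def validate_config(cfg: PipelineConfig) -> list[str]:
    """Return the list of problems; empty iff the config is runnable."""
    problems: list[str] = []
    for key in _REQUIRED_PATH_KEYS:
        value = getattr(cfg, key)
        if not value:
            problems.append(f"missing required input path: {key}")
        elif not Path(value).exists():
            problems.append(f"{key}: file not found: {value}")
    for key in ("h3k27ac_peaks", "h3k4me3_peaks", "promoter_fasta", "pfm",
                "gene_de_table", "mirna_de_table"):
        value = getattr(cfg, key)
        if value and not Path(value).exists():
            problems.append(f"{key}: file not found: {value}")
    if cfg.de_mode not in ("internal", "external"):
        problems.append(f"de_mode must be internal or external, got {cfg.de_mode!r}")
    if cfg.de_mode == "external":
        if not cfg.gene_de_table:
            problems.append("external DE mode requires gene_de_table")
        if not cfg.mirna_de_table:
            problems.append("external DE mode requires mirna_de_table")
    thr = cfg.thresholds
    for name in ("gene_fdr", "mirna_fdr"):
        v = getattr(thr, name)
        if not (0.0 < v < 1.0):
            problems.append(f"thresholds.{name} must lie in (0, 1)")
    return problems


# ---------------------------------------------------------------------------
# Run report
# ---------------------------------------------------------------------------


@dataclass
class RunReport:
    """Counts at every stage plus a config echo."""

    counts: dict[str, int]
    version: str = __version__
    config_echo: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "version": self.version,
                    "counts": dict(sorted(self.counts.items())),
                    "config": self.config_echo,
                },
                fh,
                indent=1,
                sort_keys=True,
            )
            fh.write("\n")


def venn_identities(report: RunReport) -> list[str]:
    """Check the additive/containment identities the strata must satisfy.

    Returns a list of violations (empty = all identities hold).
    """
    c = report.counts
    checks = [
        ("DEG up + down == DEG total", c["n_degs_up"] + c["n_degs_down"] == c["n_degs"]),
        (
            "DEG bound + unbound == DEG total",
            c["n_degs_bound"] + c["n_degs_unbound"] == c["n_degs"],
        ),
        ("DEM up + down == DEM total", c["n_dems_up"] + c["n_dems_down"] == c["n_dems"]),
        (
            "DEM bound + unbound == DEM total",
            c["n_dems_bound"] + c["n_dems_unbound"] == c["n_dems"],
        ),
        (
            "bound target stratum + unbound == DEG target stratum",
            c["n_anticorr_deg_bound"] + c["n_anticorr_deg_unbound"]
            == c["n_anticorr_deg_targets"],
        ),
        (
            "DEG target stratum <= anti-correlated set",
            c["n_anticorr_deg_targets"] <= c["n_anticorr_targets"],
        ),
        (
            "DEG target stratum <= DEG total",
            c["n_anticorr_deg_targets"] <= c["n_degs"],
        ),
        ("DEG total <= expressed genes", c["n_degs"] <= c["n_expressed_genes"]),
        ("DEM total <= expressed miRNAs", c["n_dems"] <= c["n_expressed_mirnas"]),
    ]
    return [name for name, ok in checks if not ok]


# ---------------------------------------------------------------------------
# Integration (in-memory core)
# ---------------------------------------------------------------------------


@dataclass
class IntegrationResult:
    promoters: list[PromoterRegion]
    gene_annotations: list[PromoterBindingAnnotation]
    mature_bound: dict[str, bool]
    gene_de: list[DEResult]  # all expressed genes, classified
    mirna_de: list[DEResult]  # all expressed matures, classified
    dems_bound: list[DEResult]
    anticorr_targets: set[str]
    anticorr_deg_targets: set[str]
    edges: list[tuple[str, str]]
    network_all: "object"
    network_bound: "object"
    mature_marks: dict[str, tuple[bool, bool]]
    dem_motif_best: dict[str, float]
    report: RunReport


def run_integration(
    tss: Sequence[TSSRecord],
    chrom_sizes: Mapping[str, int],
    matures: Sequence[MatureMiRNARecord],
    gene_lengths: Mapping[str, int],
    tf_peaks: Sequence[Peak],
    gene_counts: pd.DataFrame,
    gene_condition: Mapping[str, str],
    arm_counts: pd.DataFrame,
    mirna_condition: Mapping[str, str],
    target_map: MiRNATargetMap,
    thresholds: Thresholds = Thresholds(),
    h3k27ac_peaks: Sequence[Peak] = (),
    h3k4me3_peaks: Sequence[Peak] = (),
    promoter_seqs: Mapping[str, str] | None = None,
    pfm: PFMMatrix | None = None,
    tf_label: str = "TFEB",
    gene_de_external: Sequence[DEResult] | None = None,
    mirna_de_external: Sequence[DEResult] | None = None,
) -> IntegrationResult:
    """Run the full integration on in-memory inputs."""
    thr = thresholds

    # --- promoters -------------------------------------------------------
    promoters = build_promoters(tss, chrom_sizes, halfwidth=thr.halfwidth)
    mature_promoters, flagged = map_mature_to_promoters(matures, promoters)
    logger.info("promoters: %d windows (%d matures without promoter)",
                len(promoters), len(flagged))

    # --- gene expression and DE -----------------------------------------
    counts_mx = ExpressionMatrix(gene_counts, "raw_counts", dict(gene_condition))
    tpm = compute_tpm(counts_mx, gene_lengths)
    expressed_genes = filter_expressed_genes(tpm, thr.min_tpm)
    if gene_de_external is not None:
        gene_expr_de = [r for r in gene_de_external if r.feature_id in expressed_genes]
        fdr_known = all(not np.isnan(r.fdr) for r in gene_expr_de)
        gene_de = (
            classify_de(gene_expr_de, thr.gene_lfc, thr.gene_fdr)
            if fdr_known
            else adjust_and_classify(gene_expr_de, thr.gene_lfc, thr.gene_fdr)
        )
    else:
        sub = gene_counts.loc[sorted(expressed_genes)]
        gene_de = adjust_and_classify(
            de_test(sub, gene_condition), thr.gene_lfc, thr.gene_fdr
        )
    degs = [r for r in gene_de if r.status != "ns"]
    logger.info("genes: %d expressed, %d DEGs", len(expressed_genes), len(degs))

    # --- miRNA aggregation and DE ---------------------------------------
    agg_raw = aggregate_mature_mirna(arm_counts, "raw_counts", mirna_condition)
    norm = ExpressionMatrix(
        normalize_counts(agg_raw.data.round().astype(int)),
        "normalized_counts",
        dict(mirna_condition),
    )
    expressed_matures = filter_expressed_mirnas(norm, thr.min_mirna_count)
    if mirna_de_external is not None:
        mirna_expr_de = [
            r for r in mirna_de_external if r.feature_id in expressed_matures
        ]
        fdr_known = all(not np.isnan(r.fdr) for r in mirna_expr_de)
        mirna_de = (
            classify_de(mirna_expr_de, thr.mirna_lfc, thr.mirna_fdr)
            if fdr_known
            else adjust_and_classify(mirna_expr_de, thr.mirna_lfc, thr.mirna_fdr)
        )
    else:
        sub = agg_raw.data.loc[sorted(expressed_matures)].round().astype(int)
        mirna_de = adjust_and_classify(
            de_test(sub, mirna_condition), thr.mirna_lfc, thr.mirna_fdr
        )
    dems = [r for r in mirna_de if r.status != "ns"]
    logger.info("miRNAs: %d expressed matures, %d DEMs", len(expressed_matures), len(dems))

    # --- binding ---------------------------------------------------------
    annotations = assign_peaks(
        tf_peaks, promoters, thr.min_neglog10p, thr.min_overlap
    )
    bound_groups = bound_ids(annotations)
    mature_bound = {
        m.mature_id: any(
            p.parent_id in bound_groups for p in mature_promoters[m.mature_id]
        )
        for m in matures
    }
    pri_groups = {p.group_id for p in promoters if p.biotype == "pri_mirna"}
    gene_bound = {
        a.gene_or_mature_id: a.bound
        for a in annotations
        if a.gene_or_mature_id not in pri_groups
    }
    flags = annotate_marks(promoters, h3k27ac_peaks, h3k4me3_peaks)
    mature_marks = marks_for_groups(promoters, flags, mature_promoters)
    logger.info("binding: %d bound promoter groups", len(bound_groups))

    dems_bound = [d for d in dems if mature_bound.get(d.feature_id, False)]

    # --- motif annotation -------------------------------------------------
    dem_motif_best: dict[str, float] = {}
    if promoter_seqs is not None and pfm is not None:
        pwm = pwm_log_odds(pfm)
        for dem in dems_bound:
            best = 0.0
            for prom in mature_promoters[dem.feature_id]:
                seq = promoter_seqs.get(prom.parent_id)
                if seq is None:
                    continue
                hits = scan_promoter(seq, pwm, thr.pwm_rel_threshold)
                if hits:
                    best = max(best, max(h.rel_score for h in hits))
            dem_motif_best[dem.feature_id] = best

    # --- anti-correlation and networks -----------------------------------
    anticorr = anticorrelated_target_set(dems_bound, gene_de, target_map)
    deg_ids = {r.feature_id for r in degs}
    anticorr_deg = anticorr & deg_ids
    edges = select_anticorrelated(dems_bound, degs, target_map)
    bound_map: dict[str, bool] = {**gene_bound, **mature_bound}
    gene_status = {r.feature_id: r.status for r in gene_de}
    net_all, net_bound = build_networks(
        tf_label, dems_bound, edges, bound_map, gene_status
    )
    logger.info(
        "network: %d anti-correlated targets (%d DEGs); all=%d nodes, bound=%d nodes",
        len(anticorr), len(anticorr_deg), net_all.number_of_nodes(),
        net_bound.number_of_nodes(),
    )

    # --- report -----------------------------------------------------------
    unique_windows = {
        (p.interval.chrom, p.interval.start, p.interval.end) for p in promoters
    }
    gene_group_ids = set(gene_bound)
    counts = {
        "n_promoters_raw": len(promoters),
        "n_promoters_unique": len(unique_windows),
        "n_genes_total": len(gene_group_ids),
        "n_matures_total": len(matures),
        "n_expressed_genes": len(expressed_genes),
        "n_expressed_mirnas": len(expressed_matures),
        "n_bound_genes": sum(gene_bound.values()),
        "n_bound_matures": sum(mature_bound.values()),
        "n_degs": len(degs),
        "n_degs_up": sum(r.status == "up" for r in degs),
        "n_degs_down": sum(r.status == "down" for r in degs),
        "n_degs_bound": sum(gene_bound.get(r.feature_id, False) for r in degs),
        "n_degs_unbound": sum(not gene_bound.get(r.feature_id, False) for r in degs),
        "n_dems": len(dems),
        "n_dems_up": sum(r.status == "up" for r in dems),
        "n_dems_down": sum(r.status == "down" for r in dems),
        "n_dems_bound": len(dems_bound),
        "n_dems_unbound": len(dems) - len(dems_bound),
        "n_dems_bound_with_motif": sum(
            1 for v in dem_motif_best.values() if v >= thr.pwm_rel_threshold
        ),
        "n_dems_both_marks": sum(
            1
            for d in dems
            if mature_marks.get(d.feature_id, (False, False)) == (True, True)
        ),
        "n_anticorr_targets": len(anticorr),
        "n_anticorr_deg_targets": len(anticorr_deg),
        "n_anticorr_deg_bound": sum(
            gene_bound.get(g, False) for g in anticorr_deg
        ),
        "n_anticorr_deg_unbound": sum(
            not gene_bound.get(g, False) for g in anticorr_deg
        ),
        "n_network_all_nodes": net_all.number_of_nodes(),
        "n_network_all_edges": net_all.number_of_edges(),
        "n_network_bound_nodes": net_bound.number_of_nodes(),
        "n_network_bound_edges": net_bound.number_of_edges(),
    }
    report = RunReport(counts=counts)

    return IntegrationResult(
        promoters=promoters,
        gene_annotations=annotations,
        mature_bound=mature_bound,
        gene_de=gene_de,
        mirna_de=mirna_de,
        dems_bound=dems_bound,
        anticorr_targets=anticorr,
        anticorr_deg_targets=anticorr_deg,
        edges=edges,
        network_all=net_all,
        network_bound=net_bound,
        mature_marks=mature_marks,
        dem_motif_best=dem_motif_best,
        report=report,
    )


# ---------------------------------------------------------------------------
# File-level driver
# ---------------------------------------------------------------------------


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Load inputs named in the config, run the integration, write outputs."""
    problems = validate_config(cfg)
    if problems:
        raise ValidationError("; ".join(problems))
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        tss = read_tss_table(cfg.tss, cfg.chrom_map)
        chrom_sizes = read_chrom_sizes(cfg.chrom_sizes)
        matures = read_mature_map(cfg.mature_map)
        gene_lengths = read_feature_lengths(cfg.gene_lengths)
        tf_peaks = read_narrowpeak(cfg.tf_peaks, cfg.chrom_map)
        k27 = read_narrowpeak(cfg.h3k27ac_peaks, cfg.chrom_map) if cfg.h3k27ac_peaks else []
        k4 = read_narrowpeak(cfg.h3k4me3_peaks, cfg.chrom_map) if cfg.h3k4me3_peaks else []
        gene_counts = read_counts(cfg.gene_counts)
        arm_counts = pd.read_csv(cfg.arm_counts, sep="\t")
        with open(cfg.conditions) as fh:
            conditions = json.load(fh)
        target_map = MiRNATargetMap(pairs=read_target_map(cfg.target_map))
        seqs = read_fasta(cfg.promoter_fasta) if cfg.promoter_fasta else None
        pfm = read_pfm(cfg.pfm) if cfg.pfm else None
        gene_de_ext = (
            de_results_from_frame(read_de_table(cfg.gene_de_table))
            if cfg.de_mode == "external" and cfg.gene_de_table
            else None
        )
        mirna_de_ext = (
            de_results_from_frame(read_de_table(cfg.mirna_de_table))
            if cfg.de_mode == "external" and cfg.mirna_de_table
            else None
        )

        result = run_integration(
            tss=tss,
            chrom_sizes=chrom_sizes,
            matures=matures,
            gene_lengths=gene_lengths,
            tf_peaks=tf_peaks,
            gene_counts=gene_counts,
            gene_condition=conditions["mrna"],
            arm_counts=arm_counts,
            mirna_condition=conditions["mirna"],
            target_map=target_map,
            thresholds=cfg.thresholds,
            h3k27ac_peaks=k27,
            h3k4me3_peaks=k4,
            promoter_seqs=seqs,
            pfm=pfm,
            tf_label=cfg.tf_label,
            gene_de_external=gene_de_ext,
            mirna_de_external=mirna_de_ext,
        )
        _write_outputs(result, cfg, outdir)
        return result.report
    finally:
        logger.removeHandler(handler)
        handler.close()


def _write_outputs(result: IntegrationResult, cfg: PipelineConfig, outdir: Path) -> None:
    from .core_io import write_bed6

    write_bed6(promoters_to_bed_sorted(result.promoters), outdir / "promoters.bed")
    write_de_table(result.gene_de, outdir / "gene_de.tsv")
    write_de_table(result.mirna_de, outdir / "mirna_de.tsv")
    _write_binding_table(result, outdir / "binding_annotations.tsv")
    for net, stem in ((result.network_all, "network_all"), (result.network_bound, "network_bound")):
        export_network(net, outdir / stem, "sif")
        export_network(net, outdir / stem, "graphml")
        export_network(net, outdir / stem, "tsv")
    with open(outdir / "anticorrelated_targets.tsv", "w", newline="\n") as fh:
        fh.write("gene_id\tis_deg\n")
        for g in sorted(result.anticorr_targets):
            fh.write(f"{g}\t{str(g in result.anticorr_deg_targets).lower()}\n")
    result.report.config_echo = {
        k: v for k, v in asdict(cfg).items() if k != "thresholds"
    } | {"thresholds": asdict(cfg.thresholds)}
    result.report.to_json(outdir / "report.json")


def promoters_to_bed_sorted(promoters: Sequence[PromoterRegion]):
    return sorted(
        promoters_to_bed(promoters),
        key=lambda iv: (iv.chrom, iv.start, iv.end, iv.name),
    )


def _write_binding_table(result: IntegrationResult, path: Path) -> None:
    rows = []
    for a in sorted(result.gene_annotations, key=lambda a: a.gene_or_mature_id):
        rows.append(
            {
                "id": a.gene_or_mature_id,
                "bound": a.bound,
                "n_passing_peaks": a.n_passing_peaks,
                "best_peak_score": a.best_peak.neg_log10_p if a.best_peak else "",
                "total_overlap": a.total_overlap,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
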