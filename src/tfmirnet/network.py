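"""Anti-correlation edge selection and TF-rooted network assembly/export.

Edges between a miRNA and a predicted target gene are retained only when
their log2 fold changes have strictly opposite signs (the sign-opposition
rule): miRNA up & gene down, or miRNA down & gene up.  A zero fold change
on either side never forms an edge.

Two networks are assembled: ``network_all`` links the TF to its
promoter-bound differentially expressed miRNAs and those miRNAs to all
sign-opposed targets; ``network_bound`` restricts the gene layer to genes
whose own promoters are TF-bound (and adds the corresponding TF->gene
edges).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx

from .core_io import ValidationError
from .diffexpr import DEResult

EDGE_TYPES = {"tf_binds_mirna", "tf_binds_gene", "mirna_represses_gene"}
NODE_TYPES = {"tf", "mirna", "gene"}


@dataclass
class MiRNATargetMap:
    """A set of predicted (mature miRNA, target gene) pairs."""

    pairs: set[tuple[str, str]]
    scores: dict[tuple[str, str], float] = field(default_factory=dict)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.pairs

    def targets_of(self, mature_id: str) -> set[str]:
        return {g for m, g in self.pairs if m == mature_id}


def _opposed(lfc_mirna: float, lfc_gene: float) -> bool:
    return (lfc_mirna > 0 and lfc_gene < 0) or (lfc_mirna < 0 and lfc_gene > 0)


def select_anticorrelated(
    dems: Sequence[DEResult],
    degs: Sequence[DEResult],
    targets: MiRNATargetMap,
) -> list[tuple[str, str]]:
    """(mature, gene) edges: pair predicted AND fold-change signs opposed."""
    gene_lfc = {g.feature_id: g.log2fc for g in degs}
    edges: list[tuple[str, str]] = []
    by_mirna: dict[str, set[str]] = {}
    for m, g in targets.pairs:
        by_mirna.setdefault(m, set()).add(g)
    for dem in dems:
        for g in sorted(by_mirna.get(dem.feature_id, ())):
            if g in gene_lfc and _opposed(dem.log2fc, gene_lfc[g]):
                edges.append((dem.feature_id, g))
    edges.sort()
    return edges


def anticorrelated_target_set(
    dems: Sequence[DEResult],
    gene_table: Sequence[DEResult],
    targets: MiRNATargetMap,
) -> set[str]:
    """Union over the DEMs of sign-opposed predicted targets.

    ``gene_table`` is the full expressed-gene DE table (not only classified
    DEGs); intersecting the result with the DEG id set gives the
    differential stratum.
    """
    return {g for _, g in select_anticorrelated(dems, gene_table, targets)}


def build_networks(
    tf_label: str,
    dems_bound: Sequence[DEResult],
    edges: Sequence[tuple[str, str]],
    bound: Mapping[str, bool],
    gene_status: Mapping[str, str] | None = None,
) -> tuple[nx.DiGraph, nx.DiGraph]:
    """Assemble (network_all, network_bound).

    ``dems_bound`` are the differentially expressed miRNAs whose promoters
    carry a TF binding event; each must appear in ``bound`` with value True.
    ``bound`` also answers, for gene nodes, whether the gene's own promoter
    is TF-bound (missing genes default to unbound).
    """
    gene_status = gene_status or {}
    for dem in dems_bound:
        if dem.feature_id not in bound:
            raise ValidationError(f"DEM {dem.feature_id} lacks a binding annotation")
        if not bound[dem.feature_id]:
            raise ValidationError(f"DEM {dem.feature_id} is not promoter-bound")

    net_all = nx.DiGraph(name="network_all")
    net_all.add_node(tf_label, type="tf", status="ns", tf_bound=False)
    dem_status = {d.feature_id: d.status for d in dems_bound}
    for dem in dems_bound:
        net_all.add_node(dem.feature_id, type="mirna", status=dem.status, tf_bound=True)
        net_all.add_edge(tf_label, dem.feature_id, etype="tf_binds_mirna")
    dem_ids = set(dem_status)
    for m, g in edges:
        if m not in dem_ids:
            continue
        net_all.add_node(
            g,
            type="gene",
            status=gene_status.get(g, "ns"),
            tf_bound=bool(bound.get(g, False)),
        )
        net_all.add_edge(m, g, etype="mirna_represses_gene")

    net_bound = nx.DiGraph(name="network_bound")
    keep = [
        n
        for n, d in net_all.nodes(data=True)
        if d["type"] != "gene" or d["tf_bound"]
    ]
    net_bound.add_nodes_from((n, dict(net_all.nodes[n])) for n in keep)
    kept = set(keep)
    net_bound.add_edges_from(
        (u, v, dict(d)) for u, v, d in net_all.edges(data=True) if u in kept and v in kept
    )
    for n, d in net_bound.nodes(data=True):
        if d["type"] == "gene":
            net_bound.add_edge(tf_label, n, etype="tf_binds_gene")
    return net_all, net_bound


def edges_of_type(graph: nx.DiGraph, etype: str) -> set[tuple[str, str]]:
    if etype not in EDGE_TYPES:
        raise ValidationError(f"unknown edge type {etype}")
    return {(u, v) for u, v, d in graph.edges(data=True) if d.get("etype") == etype}


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

EXPORT_FORMATS = {"sif", "graphml", "tsv"}


def export_network(graph: nx.DiGraph, out_prefix: str | Path, fmt: str) -> list[Path]:
    """Write the network in SIF, GraphML or node/edge TSV form.

    Ordering is deterministic (lexicographic) in every format.
    Returns the written paths.
    """
    if fmt not in EXPORT_FORMATS:
        raise ValidationError(f"unknown format {fmt!r}; available: {sorted(EXPORT_FORMATS)}")
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    edges = sorted(
        (u, d.get("etype", "edge"), v) for u, v, d in graph.edges(data=True)
    )
    if fmt == "sif":
        path = out_prefix.with_suffix(".sif")
        with open(path, "w", newline="\n") as fh:
            for u, rel, v in edges:
                fh.write(f"{u}\t{rel}\t{v}\n")
        return [path]
    if fmt == "graphml":
        path = out_prefix.with_suffix(".graphml")
        ordered = nx.DiGraph(name=graph.name)
        ordered.add_nodes_from(
            (n, dict(graph.nodes[n])) for n in sorted(graph.nodes)
        )
        ordered.add_edges_from((u, v, {"etype": rel}) for u, rel, v in edges)
        nx.write_graphml(ordered, path)
        return [path]
    nodes_path = Path(f"{out_prefix}_nodes.tsv")
    edges_path = Path(f"{out_prefix}_edges.tsv")
    with open(nodes_path, "w", newline="\n") as fh:
        fh.write("node\ttype\tstatus\ttf_bound\n")
        for n in sorted(graph.nodes):
            d = graph.nodes[n]
            fh.write(
                f"{n}\t{d.get('type', '')}\t{d.get('status', '')}\t"
                f"{str(bool(d.get('tf_bound', False))).lower()}\n"
            )
    with open(edges_path, "w", newline="\n") as fh:
        fh.write("source\tetype\ttarget\n")
        for u, rel, v in edges:
            fh.write(f"{u}\t{rel}\t{v}\n")
    return [nodes_path, edges_path]


def import_graphml(path: str | Path) -> nx.DiGraph:
    return nx.read_graphml(path)
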