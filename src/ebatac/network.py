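"""TF-loop-TF regulatory network construction and hub ranking.

An edge runs from TF t to gene u when a called loop connects one of t's
motif-bearing peaks to a peak overlapping u's TSS window.  Per cell
group, the edge weight is

    W(t, u | g) = max(0, mean ILS of supporting loops in g)
                * max(0, mean consistency of t over g's cells),

so an edge requires both an active chromatin connection and a TF whose
gene and binding activity agree in that group.  Candidate TF regulators
are ranked by weighted out-degree (self-edges excluded from the sum);
the TF->TF subnetwork keeps only edges whose target is itself a TF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .consistency import ConsistencyMatrix
from .io import EdgeRecord, GeneModel, MotifHitTable, PeakInterval
from .loops import Loop


@dataclass
class CandidateEdge:
    source_tf: str
    target_gene: str
    loops: list[Loop] = field(default_factory=list)

    @property
    def is_self_edge(self) -> bool:
        return self.source_tf == self.target_gene


def tss_proximal_peaks(
    peaks: list[PeakInterval], genes: list[GeneModel], window: int = 2000
) -> dict[str, set[str]]:
    """Peaks overlapping [TSS - window, TSS + window) for each gene."""
    out: dict[str, set[str]] = {}
    for g in genes:
        lo, hi = g.tss - window, g.tss + window
        out[g.gene_id] = {
            p.peak_id
            for p in peaks
            if p.contig == g.contig and p.start < hi and p.end > lo
        }
    return out


def candidate_edges(
    motif_hits: MotifHitTable,
    loops: list[Loop],
    tss_map: dict[str, set[str]],
) -> list[CandidateEdge]:
    """TF -> gene edges supported by >= 1 loop joining a motif peak to a TSS peak."""
    peak_tfs: dict[str, list[str]] = {}
    for i, m in enumerate(motif_hits.motif_ids):
        tf = motif_hits.motif_to_tf[m]
        for j in np.flatnonzero(motif_hits.values[i]):
            peak_tfs.setdefault(motif_hits.peak_ids[j], []).append(tf)
    peak_genes: dict[str, list[str]] = {}
    for gene, pset in tss_map.items():
        for p in pset:
            peak_genes.setdefault(p, []).append(gene)

    support: dict[tuple[str, str], list[Loop]] = {}
    for loop in loops:
        for motif_anchor, tss_anchor in (
            (loop.anchor_a, loop.anchor_b),
            (loop.anchor_b, loop.anchor_a),
        ):
            for tf in peak_tfs.get(motif_anchor, ()):
                for gene in peak_genes.get(tss_anchor, ()):
                    support.setdefault((tf, gene), [])
                    if loop not in support[(tf, gene)]:
                        support[(tf, gene)].append(loop)
    return [
        CandidateEdge(tf, gene, loop_list)
        for (tf, gene), loop_list in sorted(support.items())
    ]


def edge_weights(
    candidates: list[CandidateEdge],
    loop_signals: pd.DataFrame,
    consistency: ConsistencyMatrix,
    group: str,
    group_barcodes: list[str],
) -> list[EdgeRecord]:
    """Weight candidate edges for one cell group; zero-weight edges drop."""
    if group not in loop_signals.columns:
        raise ValueError(f"group {group!r} missing from the loop-signal table")
    if not group_barcodes:
        raise ValueError(f"group {group!r} has no cells")
    bc_index = {b: i for i, b in enumerate(consistency.barcodes)}
    cols = [bc_index[b] for b in group_barcodes]
    ils = loop_signals[group]
    edges: list[EdgeRecord] = []
    for cand in candidates:
        if cand.source_tf not in consistency.tf_names:
            continue
        mean_ils = float(np.mean([ils[l.loop_id] for l in cand.loops]))
        tf_cons = float(consistency.row(cand.source_tf)[cols].mean())
        weight = max(0.0, mean_ils) * max(0.0, tf_cons)
        if weight > 0:
            edges.append(
                EdgeRecord(cand.source_tf, cand.target_gene, weight, len(cand.loops), group)
            )
    return edges


def build_network(edges: list[EdgeRecord], genes: list[GeneModel]) -> nx.DiGraph:
    """Directed graph of weighted edges with is_tf flags on the nodes."""
    is_tf = {g.gene_id: g.is_tf for g in genes}
    graph = nx.DiGraph()
    for e in edges:
        if graph.has_edge(e.source_tf, e.target_gene):
            raise ValueError(
                f"duplicate edge {e.source_tf} -> {e.target_gene} in group {e.group}"
            )
        graph.add_edge(
            e.source_tf, e.target_gene,
            weight=e.weight, n_loops=e.n_loops, group=e.group,
            self_edge=e.source_tf == e.target_gene,
        )
    for node in graph.nodes:
        graph.nodes[node]["is_tf"] = bool(is_tf.get(node, True))
    return graph


def tf_tf_network(edges: list[EdgeRecord], genes: list[GeneModel]) -> nx.DiGraph:
    """Subnetwork keeping only edges whose target is a TF gene."""
    is_tf = {g.gene_id: g.is_tf for g in genes}
    kept = [e for e in edges if is_tf.get(e.target_gene, False)]
    return build_network(kept, genes)


def weighted_out_degree(network: nx.DiGraph) -> list[tuple[str, float]]:
    """Sources ranked by summed outgoing weight (self-edges excluded)."""
    degree: dict[str, float] = {n: 0.0 for n in network.nodes}
    for u, v, data in network.edges(data=True):
        if u != v:
            degree[u] += data.get("weight", 0.0)
    return sorted(degree.items(), key=lambda it: (-it[1], it[0]))
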