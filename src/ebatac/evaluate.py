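"""Recovery metrics of a synthetic pipeline run against its ground truth.

These functions read a finished run directory (a synthetic run carries
its own truth_* tables) and quantify how well each analysis stage
recovered what the generator planted: cluster/label agreement, marker-TF
consistency as a cell-type detector, pseudotime ordering, loop calls
versus planted enhancer-promoter loops, and regulatory-network edges
versus planted regulons.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.metrics import adjusted_rand_score, roc_auc_score

from .cluster import MarkerPanel
from .simulate import GERM_LAYERS, POOL_TYPES

#: simulator type label -> cluster annotation label
ANNOTATION_FOR_TYPE = {
    "ESC": "ESC", "END": "END", "MES": "MES", "ECT": "ECT",
    "EC_END": "EC-END", "EC_MES": "EC-MES", "EC_ECT": "EC-ECT",
}


def _truth(run_dir: Path) -> pd.DataFrame:
    return pd.read_csv(Path(run_dir) / "truth_cells.tsv", sep="\t", index_col="barcode")


def _clusters(run_dir: Path) -> pd.DataFrame:
    return pd.read_csv(Path(run_dir) / "clusters.tsv", sep="\t", index_col="barcode")


def _consistency(run_dir: Path):
    from scipy.io import mmread

    run_dir = Path(run_dir)
    values = np.asarray(mmread(str(run_dir / "consistency.mtx")).todense())
    tfs = (run_dir / "consistency.rows.txt").read_text().split()
    cells = (run_dir / "consistency.cols.txt").read_text().split()
    return values, tfs, cells


def qc_metrics(run_dir: Path) -> dict:
    qc = pd.read_csv(Path(run_dir) / "qc_report.tsv", sep="\t")
    return {
        "pass_fraction": float(qc["passed"].mean()),
        "n_cells": int(len(qc)),
        "median_fragments": float(qc["n_fragments"].median()),
        "median_tss_enrichment": float(qc["tss_enrichment"].median()),
    }


def clustering_metrics(run_dir: Path) -> dict:
    """ARI of k-means labels against planted types; recovered annotations."""
    truth = _truth(run_dir)
    clusters = _clusters(run_dir)
    joined = clusters.join(truth[["cell_type"]], how="inner")
    ari = adjusted_rand_score(joined["cell_type"], joined["cluster"])
    annotations = sorted(set(clusters["annotation"]))
    recalls = {}
    for t, ann in ANNOTATION_FOR_TYPE.items():
        members = joined[joined["cell_type"] == t]
        if len(members):
            recalls[t] = float((members["annotation"] == ann).mean())
    return {
        "ari": float(ari),
        "annotations": annotations,
        "n_annotated_populations": len([a for a in annotations if a != "unassigned"]),
        "per_population_recall": recalls,
        "n_cells": int(len(joined)),
    }


def consistency_metrics(run_dir: Path, panel: MarkerPanel | None = None) -> dict:
    """Marker consistency as a home-type detector, and EC intermediacy."""
    panel = panel or MarkerPanel()
    values, tfs, cells = _consistency(run_dir)
    truth = _truth(run_dir).loc[cells]
    cell_type = truth["cell_type"].to_numpy()
    pure = ~pd.Series(cell_type).str.startswith("EC_").to_numpy()
    aurocs: dict[str, float] = {}
    for home, marker_tfs in panel.sets.items():
        for tf in marker_tfs:
            if tf not in tfs:
                continue
            row = values[tfs.index(tf)][pure]
            labels = (cell_type[pure] == home).astype(int)
            aurocs[tf] = float(roc_auc_score(labels, row))
    ec_between: dict[str, bool] = {}
    for layer in GERM_LAYERS:
        rows = [tfs.index(tf) for tf in panel.sets[layer] if tf in tfs]

        def mean_in(ct: str) -> float:
            cols = np.flatnonzero(cell_type == ct)
            return float(values[np.ix_(rows, cols)].mean())

        ec_between[layer] = mean_in("ESC") < mean_in(f"EC_{layer}") < mean_in(layer)
    return {
        "auroc": aurocs,
        "min_auroc": min(aurocs.values()),
        "ec_between": ec_between,
        "n_ec_intermediate": int(sum(ec_between.values())),
    }


def pseudotime_metrics(run_dir: Path) -> dict:
    """Spearman of inferred vs planted pseudotime, and mean-order checks."""
    truth = _truth(run_dir)
    pt = pd.read_csv(Path(run_dir) / "pseudotime.tsv", sep="\t")
    clusters = _clusters(run_dir)
    spearman: dict[str, float] = {}
    order_ok: dict[str, bool] = {}
    for layer, sub in pt.groupby("lineage"):
        rho = spearmanr(
            sub["pseudotime"], truth.loc[sub["barcode"], "pseudotime"]
        ).statistic
        spearman[layer] = float(rho)
        ann = clusters.loc[sub["barcode"], "annotation"].to_numpy()
        means = {
            a: float(sub["pseudotime"].to_numpy()[ann == a].mean())
            for a in ("ESC", f"EC-{layer}", layer)
        }
        order_ok[layer] = means["ESC"] < means[f"EC-{layer}"] < means[layer]
    return {
        "spearman": spearman,
        "min_spearman": min(spearman.values()),
        "order_ok": order_ok,
    }


def loop_metrics(run_dir: Path) -> dict:
    """Called loops vs planted enhancer-promoter loops."""
    run_dir = Path(run_dir)
    called = pd.read_csv(run_dir / "loops.tsv", sep="\t")
    truth = pd.read_csv(run_dir / "truth_loops.tsv", sep="\t")
    called_set = set(zip(called["anchor_a"], called["anchor_b"]))
    true_set = set(zip(truth["peak_a"], truth["peak_b"]))
    tp = len(called_set & true_set)
    return {
        "precision": tp / len(called_set) if called_set else 0.0,
        "recall": tp / len(true_set) if true_set else 0.0,
        "n_called": len(called_set),
        "n_true": len(true_set),
    }


def network_metrics(run_dir: Path) -> dict:
    """Planted-regulon edge recovery per pure group and master-TF ranking.

    For each pure population the relevant planted edges are those whose
    source TF belongs to that population's program; the master TF of a
    germ layer is the planted TF with the largest regulon, and its rank
    is taken in the group's TF->TF network weighted out-degree list.
    """
    run_dir = Path(run_dir)
    edges = pd.read_csv(run_dir / "network_edges.tsv", sep="\t")
    regulons = pd.read_csv(run_dir / "truth_regulons.tsv", sep="\t")
    tf_types = pd.read_csv(run_dir / "truth_tf_types.tsv", sep="\t")
    degree = pd.read_csv(run_dir / "outdegree.tsv", sep="\t")
    tf_type = dict(zip(tf_types["tf"], tf_types["type"]))
    truth_edges = set(zip(regulons["tf"], regulons["target"]))

    precision: dict[str, float] = {}
    recall: dict[str, float] = {}
    for group in POOL_TYPES:
        pred = set(
            zip(
                edges.loc[edges["group"] == group, "source"],
                edges.loc[edges["group"] == group, "target"],
            )
        )
        group_truth = {(t, u) for (t, u) in truth_edges if tf_type.get(t) == group}
        tp = len(pred & group_truth)
        precision[group] = tp / len(pred) if pred else 0.0
        recall[group] = tp / len(group_truth) if group_truth else 0.0

    sizes = regulons.groupby("tf").size()
    master_rank: dict[str, int] = {}
    for layer in GERM_LAYERS:
        layer_tfs = [t for t, ty in tf_type.items() if ty == layer]
        master = sizes.loc[[t for t in layer_tfs if t in sizes.index]].idxmax()
        ranked = degree[(degree["group"] == layer) & (degree["network"] == "tf")]
        hit = ranked.loc[ranked["gene"] == master, "rank"]
        master_rank[layer] = int(hit.iloc[0]) if len(hit) else len(ranked) + 1
    return {
        "precision": precision,
        "recall": recall,
        "min_precision": min(precision.values()),
        "min_recall": min(recall.values()),
        "master_rank": master_rank,
        "worst_master_rank": max(master_rank.values()),
    }
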