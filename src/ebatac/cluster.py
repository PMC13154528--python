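"""K-means on marker-TF consistency scores and cluster annotation.

Clustering runs on the consistency submatrix of a small panel of
well-known lineage marker TFs (k = 7 by default: ESC, three germ layers
and three expected intermediates).  A cluster is annotated from which
marker sets are elevated (mean consistency above ``tau``): ESC alone ->
ESC; one germ layer alone -> that layer; ESC plus one germ layer -> the
"early committed" intermediate EC-<layer>; anything else -> unassigned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .consistency import ConsistencyMatrix

DEFAULT_PANEL: dict[str, list[str]] = {
    "ESC": ["POU5F1", "NANOG"],
    "END": ["SOX17", "GATA6", "FOXA2"],
    "MES": ["EOMES", "TBXT", "MESP1", "MIXL1"],
    "ECT": ["TFAP2A", "GRHL2", "PAX6", "NEUROD1"],
}

#: gene-symbol aliases accepted in marker tables (brachyury is listed as
#: either T or TBXT depending on the annotation vintage)
MARKER_ALIASES = {"T": "TBXT"}

ANNOTATIONS = ("ESC", "END", "MES", "ECT", "EC-END", "EC-MES", "EC-ECT", "unassigned")


@dataclass
class MarkerPanel:
    """Marker TFs per cell type; a TF may appear in only one set."""

    sets: dict[str, list[str]] = field(
        default_factory=lambda: {t: list(v) for t, v in DEFAULT_PANEL.items()}
    )

    def __post_init__(self) -> None:
        self.sets = {
            t: [MARKER_ALIASES.get(tf, tf) for tf in tfs] for t, tfs in self.sets.items()
        }
        if any(not tfs for tfs in self.sets.values()):
            raise ValueError("marker sets must be non-empty")
        flat = [tf for tfs in self.sets.values() for tf in tfs]
        if len(flat) != len(set(flat)):
            raise ValueError("a marker TF may appear in only one set")
        if "ESC" not in self.sets:
            raise ValueError("the panel must include an ESC marker set")

    @property
    def all_tfs(self) -> list[str]:
        return [tf for tfs in self.sets.values() for tf in tfs]

    @property
    def germ_layers(self) -> list[str]:
        return [t for t in self.sets if t != "ESC"]


@dataclass
class ClusterLabeling:
    cluster_of: dict[str, int]          # cell -> cluster id (1..k)
    annotation_of_cluster: dict[int, str]

    def annotation_of(self, barcode: str) -> str:
        return self.annotation_of_cluster[self.cluster_of[barcode]]

    def cells_with_annotation(self, annotation: str) -> list[str]:
        return [b for b, c in self.cluster_of.items()
                if self.annotation_of_cluster[c] == annotation]


def kmeans_consistency(
    C_markers: ConsistencyMatrix,
    k: int = 7,
    seed: int = 0,
    n_init: int = 50,
    max_iter: int = 300,
) -> np.ndarray:
    """Cluster cells on marker consistency (Lloyd + k-means++, best of n_init).

    Returns cluster ids in 1..k, deterministic given the seed.
    """
    if C_markers.values.size == 0:
        raise ValueError("empty consistency matrix")
    n_cells = C_markers.values.shape[1]
    if k > n_cells:
        raise ValueError(f"k={k} exceeds the {n_cells} cells available")
    km = KMeans(
        n_clusters=k, init="k-means++", n_init=n_init, max_iter=max_iter,
        random_state=seed,
    )
    return km.fit_predict(C_markers.values.T) + 1


def annotate_clusters(
    C: ConsistencyMatrix,
    clusters: np.ndarray,
    panel: MarkerPanel | None = None,
    tau: float = 0.25,
) -> ClusterLabeling:
    """Annotate clusters from which marker sets show elevated consistency."""
    panel = panel or MarkerPanel()
    clusters = np.asarray(clusters)
    annotation: dict[int, str] = {}
    for cid in sorted(set(clusters.tolist())):
        member = clusters == cid
        elevated = set()
        for t, tfs in panel.sets.items():
            rows = [C.tf_names.index(tf) for tf in tfs if tf in C.tf_names]
            if not rows:
                continue
            if float(C.values[np.ix_(rows, np.flatnonzero(member))].mean()) > tau:
                elevated.add(t)
        layers = elevated & set(panel.germ_layers)
        if elevated == {"ESC"}:
            annotation[cid] = "ESC"
        elif len(elevated) == 1 and len(layers) == 1:
            annotation[cid] = next(iter(layers))
        elif elevated == {"ESC"} | layers and len(layers) == 1:
            annotation[cid] = f"EC-{next(iter(layers))}"
        else:
            annotation[cid] = "unassigned"
    return ClusterLabeling(
        {b: int(c) for b, c in zip(C.barcodes, clusters)}, annotation
    )


def composition_by_stage(
    labeling: ClusterLabeling, stages: dict[str, str]
) -> pd.DataFrame:
    """Stage x annotation cell proportions; every row sums to 1."""
    missing = [b for b in labeling.cluster_of if b not in stages]
    if missing:
        raise ValueError(f"cells without a stage: {missing[:5]}")
    rows = [
        {"stage": stages[b], "annotation": labeling.annotation_of(b)}
        for b in labeling.cluster_of
    ]
    df = pd.DataFrame(rows)
    table = (
        df.groupby(["stage", "annotation"]).size().unstack(fill_value=0).sort_index()
    )
    return table.div(table.sum(axis=1), axis=0)


def specific_tfs(
    C: ConsistencyMatrix, clusters: np.ndarray, n: int = 10
) -> dict[int, list[tuple[str, float]]]:
    """Per cluster, TFs ranked by mean consistency inside minus outside.

    Ties break alphabetically; if n exceeds the TF count everything is
    returned with a warning.
    """
    clusters = np.asarray(clusters)
    if n > len(C.tf_names):
        warnings.warn(
            f"n={n} exceeds the {len(C.tf_names)} TFs available; returning all"
        )
        n = len(C.tf_names)
    out: dict[int, list[tuple[str, float]]] = {}
    for cid in sorted(set(clusters.tolist())):
        inside = clusters == cid
        diff = C.values[:, inside].mean(axis=1) - C.values[:, ~inside].mean(axis=1) \
            if (~inside).any() else C.values[:, inside].mean(axis=1)
        ranked = sorted(zip(C.tf_names, diff), key=lambda it: (-it[1], it[0]))
        out[int(cid)] = [(tf, float(s)) for tf, s in ranked[:n]]
    return out
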