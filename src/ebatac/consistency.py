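"""The per-TF, per-cell consistency score.

A TF contributes to a cell's identity only when two independent chromatin
readouts agree: the accessibility of the TF's own gene (gene activity)
and the accessibility of its binding sites genome-wide (motif deviation).
Both tracks are smoothed over each cell's k nearest neighbors in the LSI
embedding, standardized per feature, and combined with a signed geometric
mean that is zero whenever the two z-scores disagree in sign:

    C[t, c] = sign(z_g) * sqrt(z_g * z_b)   if z_g * z_b > 0, else 0.

The same combiner quantifies inferred loop signals (see
:mod:`ebatac.loops`); |C| <= max(|z_g|, |z_b|) and C = z when both
tracks equal z.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .matrices import EmbeddingMatrix


@dataclass(frozen=True)
class TFMap:
    """TF name -> (gene-activity row id, binding-activity motif id)."""

    entries: dict[str, tuple[str, str]]

    def __iter__(self):
        return iter(self.entries.items())


@dataclass
class ConsistencyMatrix:
    values: np.ndarray  # TFs x cells
    tf_names: list[str]
    barcodes: list[str]
    excluded_tfs: list[str] = field(default_factory=list)

    def restrict(self, tfs: list[str]) -> "ConsistencyMatrix":
        present = [t for t in tfs if t in self.tf_names]
        rows = [self.tf_names.index(t) for t in present]
        return ConsistencyMatrix(
            self.values[rows], present, list(self.barcodes), list(self.excluded_tfs)
        )

    def row(self, tf: str) -> np.ndarray:
        return self.values[self.tf_names.index(tf)]


def neighbor_indices(embedding: EmbeddingMatrix, k: int) -> np.ndarray:
    """Each cell's k nearest cells (self included; ties by barcode order)."""
    coords = embedding.coords
    n = coords.shape[0]
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} cells available")
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    # stable sort on distance keeps column (= barcode) order for ties
    order = np.argsort(d2, axis=1, kind="stable")
    return order[:, :k]


def knn_smooth(values: np.ndarray, embedding: EmbeddingMatrix, k: int = 10) -> np.ndarray:
    """Replace each cell's value by the mean over its k nearest cells."""
    values = np.asarray(values, dtype=np.float64)
    if values.shape[1] != embedding.coords.shape[0]:
        raise ValueError(
            f"matrix has {values.shape[1]} cells but embedding has "
            f"{embedding.coords.shape[0]} rows"
        )
    nn = neighbor_indices(embedding, k)
    return values[:, nn].mean(axis=2)


def standardize_rows(values: np.ndarray, sd_floor: float = 1e-6) -> np.ndarray:
    """Z-score each row; rows with (near-)zero spread map to all zeros."""
    values = np.asarray(values, dtype=np.float64)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    return (values - mean) / np.maximum(sd, sd_floor)


def signed_geometric_mean(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """sign(a) * sqrt(a*b) where a and b agree in sign, else 0 (symmetric)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    prod = a * b
    return np.where(prod > 0, np.sign(a) * np.sqrt(np.abs(prod)), 0.0)


def consistency(
    gene_z: np.ndarray,
    binding_z: np.ndarray,
    tf_map: TFMap,
    gene_ids: list[str],
    motif_ids: list[str],
    barcodes: list[str],
) -> ConsistencyMatrix:
    """Combine standardized gene-activity and binding-activity z-scores.

    TFs missing either row are excluded with a warning and listed in the
    result's metadata.
    """
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    motif_index = {m: i for i, m in enumerate(motif_ids)}
    rows, names, excluded = [], [], []
    for tf, (gene, motif) in tf_map:
        if gene not in gene_index or motif not in motif_index:
            excluded.append(tf)
            continue
        zg = gene_z[gene_index[gene]]
        zb = binding_z[motif_index[motif]]
        rows.append(signed_geometric_mean(zg, zb))
        names.append(tf)
    if excluded:
        warnings.warn(f"TFs missing a gene or motif row: {excluded}")
    values = np.vstack(rows) if rows else np.zeros((0, len(barcodes)))
    return ConsistencyMatrix(values, names, list(barcodes), excluded)
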