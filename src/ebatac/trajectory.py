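"""Supervised LDA embedding, per-lineage pseudotime, binned TF profiles.

The Fisher discriminant directions come from the generalized eigenproblem
Sb w = lambda Sw w with the within-class scatter ridge-regularized by
gamma = 1e-3 * trace(Sw) / n_features.  Pseudotime for a lineage X is the
scalar projection of its member cells (annotated ESC, EC-X or X) onto the
unit axis from the ESC centroid to the X centroid in LDA space, min-max
rescaled to [0, 1], then split into equal-width bins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .cluster import ClusterLabeling
from .consistency import ConsistencyMatrix
from .matrices import EmbeddingMatrix


@dataclass
class LineageSpec:
    """One germ-layer trajectory: which annotations belong and which TFs to profile."""

    lineage: str                       # END, MES or ECT
    profile_tfs: list[str] = field(default_factory=list)

    @property
    def members(self) -> tuple[str, str, str]:
        return ("ESC", f"EC-{self.lineage}", self.lineage)


@dataclass
class PseudotimeAssignment:
    lineage: str
    pt: dict[str, float]               # cell -> [0, 1]
    bin_of: dict[str, int]             # cell -> 1..n_bins
    n_bins: int


def lda_embed(
    features: ConsistencyMatrix | np.ndarray,
    labels: np.ndarray,
    n_components: int,
    barcodes: list[str] | None = None,
) -> EmbeddingMatrix:
    """Fisher LDA of cells (rows of feature matrix transposed).

    Directions are unit-norm with the largest-magnitude loading positive;
    the embedding is the centered data projected on them.
    """
    if isinstance(features, ConsistencyMatrix):
        barcodes = list(features.barcodes)
        X = features.values.T
    else:
        X = np.asarray(features, dtype=np.float64)
        barcodes = barcodes if barcodes is not None else [str(i) for i in range(len(X))]
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise ValueError("LDA needs at least 2 classes")
    if n_components > len(classes) - 1:
        raise ValueError(
            f"n_components={n_components} exceeds n_classes-1={len(classes) - 1}"
        )
    n, d = X.shape
    mu = X.mean(axis=0)
    Sw = np.zeros((d, d))
    Sb = np.zeros((d, d))
    for c in classes:
        Xc = X[labels == c]
        if len(Xc) < 2:
            raise ValueError(
                f"class {c} has {len(Xc)} cell(s); merge it with a neighbor"
            )
        mc = Xc.mean(axis=0)
        Sw += (Xc - mc).T @ (Xc - mc)
        Sb += len(Xc) * np.outer(mc - mu, mc - mu)
    gamma = 1e-3 * np.trace(Sw) / d
    Sw_reg = Sw + gamma * np.eye(d)
    eigvals, eigvecs = scipy.linalg.eigh(Sb, Sw_reg)
    order = np.argsort(eigvals)[::-1][:n_components]
    W = eigvecs[:, order]
    W = W / np.linalg.norm(W, axis=0, keepdims=True)
    for j in range(W.shape[1]):
        i = int(np.argmax(np.abs(W[:, j])))
        if W[i, j] < 0:
            W[:, j] = -W[:, j]
    coords = (X - mu) @ W
    return EmbeddingMatrix(
        coords=coords,
        barcodes=barcodes,
        depth_flagged=np.zeros(W.shape[1], dtype=bool),
        singular_values=np.sqrt(np.maximum(eigvals[order], 0.0)),
        loadings=W,
    )


def pt_to_bin(pt: float, n_bins: int) -> int:
    """bin = ceil(pt * n_bins), with pt = 0 mapped to bin 1."""
    return max(1, math.ceil(pt * n_bins))


def lineage_pseudotime(
    embedding: EmbeddingMatrix,
    labeling: ClusterLabeling,
    spec: LineageSpec,
    n_bins: int = 10,
) -> PseudotimeAssignment:
    """Project lineage members on the ESC -> lineage centroid axis."""
    index = {b: i for i, b in enumerate(embedding.barcodes)}
    groups = {
        a: [index[b] for b in labeling.cells_with_annotation(a) if b in index]
        for a in spec.members
    }
    for a in spec.members:
        if len(groups[a]) < 2:
            raise ValueError(f"annotation {a} has fewer than 2 cells in the embedding")
    esc_centroid = embedding.coords[groups["ESC"]].mean(axis=0)
    x_centroid = embedding.coords[groups[spec.lineage]].mean(axis=0)
    axis = x_centroid - esc_centroid
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise ValueError("ESC and lineage centroids coincide; axis is degenerate")
    axis = axis / norm
    member_idx = sorted(i for idxs in groups.values() for i in idxs)
    proj = embedding.coords[member_idx] @ axis
    lo, hi = proj.min(), proj.max()
    if hi - lo < 1e-12:
        raise ValueError("all member cells project to a single point")
    pt = (proj - lo) / (hi - lo)
    cells = [embedding.barcodes[i] for i in member_idx]
    return PseudotimeAssignment(
        lineage=spec.lineage,
        pt={b: float(p) for b, p in zip(cells, pt)},
        bin_of={b: pt_to_bin(float(p), n_bins) for b, p in zip(cells, pt)},
        n_bins=n_bins,
    )


def bin_profile(
    C: ConsistencyMatrix,
    assignment: PseudotimeAssignment,
    spec: LineageSpec,
    n_bins: int = 10,
) -> tuple[pd.DataFrame, pd.Series]:
    """Mean consistency of the profiled TFs per pseudotime bin.

    Empty bins are reported as missing (NaN), never as zero.  Also
    returns per-bin member-cell counts.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    tfs = [tf for tf in spec.profile_tfs if tf in C.tf_names]
    index = {b: i for i, b in enumerate(C.barcodes)}
    bins = list(range(1, n_bins + 1))
    profile = pd.DataFrame(np.nan, index=tfs, columns=bins)
    counts = pd.Series(0, index=bins, dtype=int)
    members_by_bin: dict[int, list[int]] = {b: [] for b in bins}
    for cell, b in assignment.bin_of.items():
        if cell in index:
            members_by_bin[b].append(index[cell])
            counts[b] += 1
    for b, cols in members_by_bin.items():
        if cols:
            for tf in tfs:
                profile.loc[tf, b] = float(C.row(tf)[cols].mean())
    return profile, counts
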