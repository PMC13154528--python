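"""Co-accessibility loop prediction and inferred loop signals (ILS).

Cells are first aggregated into metacells (small k-means groups in the
LSI embedding) to stabilize sparse peak signals.  Candidate peak pairs
within a genomic distance window are scored by the Pearson correlation
of their depth-normalized log signals across metacells; pairs above a
threshold are called loops.  The per-group inferred loop signal of a
loop is the signed geometric mean of its two anchors' smoothed,
standardized signals averaged over the group's cells — the same
combiner as the TF consistency score, zero when the anchors disagree
in sign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .consistency import signed_geometric_mean
from .io import CountMatrix, PeakInterval
from .matrices import EmbeddingMatrix


@dataclass(frozen=True)
class Loop:
    """A predicted peak-peak chromatin connection (anchors in coordinate order)."""

    anchor_a: str
    anchor_b: str
    distance: int
    coaccessibility: float = float("nan")

    @property
    def loop_id(self) -> str:
        return f"{self.anchor_a}|{self.anchor_b}"


def make_metacells(
    embedding: EmbeddingMatrix, target_size: int = 10, seed: int = 0
) -> np.ndarray:
    """Partition cells into ceil(n / target_size) k-means groups."""
    n = embedding.coords.shape[0]
    if target_size < 2:
        raise ValueError(f"target_size must be >= 2, got {target_size}")
    if n < 2 * target_size:
        raise ValueError(f"need at least 2*target_size={2 * target_size} cells, got {n}")
    k = math.ceil(n / target_size)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(embedding.coords)


def candidate_pairs(
    peaks: list[PeakInterval], min_dist: int = 1000, max_dist: int = 500_000
) -> list[Loop]:
    """Same-contig peak pairs with midpoint distance in [min_dist, max_dist]."""
    if min_dist >= max_dist:
        raise ValueError(f"min_dist {min_dist} >= max_dist {max_dist}")
    keys = [(p.contig, p.start) for p in peaks]
    if keys != sorted(keys):
        raise ValueError("peaks must be sorted by (contig, start)")
    pairs: list[Loop] = []
    for i, a in enumerate(peaks):
        for j in range(i + 1, len(peaks)):
            b = peaks[j]
            if b.contig != a.contig:
                break
            d = abs(b.midpoint - a.midpoint)
            if d > max_dist and b.start - a.end > max_dist:
                break
            if min_dist <= d <= max_dist:
                pairs.append(Loop(a.peak_id, b.peak_id, d))
    return pairs


def metacell_signal(counts: CountMatrix, metacells: np.ndarray, scale: float = 1e4) -> np.ndarray:
    """Depth-normalized log1p mean accessibility per peak per metacell."""
    metacells = np.asarray(metacells)
    groups = sorted(set(metacells.tolist()))
    X = counts.values
    sig = np.zeros((X.shape[0], len(groups)))
    for gi, g in enumerate(groups):
        cols = np.flatnonzero(metacells == g)
        m = np.asarray(X[:, cols].mean(axis=1)).ravel()
        total = m.sum()
        sig[:, gi] = np.log1p(m * scale / total) if total > 0 else 0.0
    return sig


def coaccessibility(
    counts: CountMatrix, metacells: np.ndarray, pairs: list[Loop]
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation of each pair's anchor signals across metacells.

    The per-metacell mean signal over all peaks is removed first: small
    or shallow metacells carry a shared technical offset (the concave
    log1p transform biases noisy means), and without this correction
    every background-peak pair inherits a spurious positive correlation.
    Returns (r, zero_variance_flags); anchors with zero variance get
    r = 0 and a flag.
    """
    metacells = np.asarray(metacells)
    n_groups = len(set(metacells.tolist()))
    if n_groups < 3:
        raise ValueError(f"need >= 3 metacells, got {n_groups}")
    sig = metacell_signal(counts, metacells)
    raw_constant = sig.std(axis=1) == 0  # no accessibility variation at all
    sig = sig - sig.mean(axis=0, keepdims=True)
    centered = sig - sig.mean(axis=1, keepdims=True)
    ss = (centered**2).sum(axis=1)
    index = {p: i for i, p in enumerate(counts.peak_ids)}
    if not len(pairs):
        return np.zeros(0), np.zeros(0, dtype=bool)
    ia = np.array([index[p.anchor_a] for p in pairs], dtype=int)
    ib = np.array([index[p.anchor_b] for p in pairs], dtype=int)
    num = (centered[ia] * centered[ib]).sum(axis=1)
    denom = np.sqrt(ss[ia] * ss[ib])
    flagged = (denom == 0) | raw_constant[ia] | raw_constant[ib]
    r = np.where(flagged, 0.0, num / np.where(denom == 0, 1.0, denom))
    return r, flagged


def call_loops(pairs: list[Loop], r: np.ndarray, threshold: float = 0.35) -> list[Loop]:
    """Keep candidate pairs with co-accessibility >= threshold."""
    return [
        Loop(p.anchor_a, p.anchor_b, p.distance, float(ri))
        for p, ri in zip(pairs, r)
        if ri >= threshold
    ]


def loop_signal(
    peak_z: np.ndarray,
    peak_ids: list[str],
    loops: list[Loop],
    groups: dict[str, str],
    barcodes: list[str],
) -> pd.DataFrame:
    """Inferred loop signal per loop per cell group.

    ``peak_z`` is the smoothed, standardized peak x cell matrix; for each
    loop and group the two anchors' mean z over the group's cells are
    combined with the signed geometric mean.
    """
    index = {p: i for i, p in enumerate(peak_ids)}
    group_names = sorted(set(groups.values()))
    bc_index = {b: i for i, b in enumerate(barcodes)}
    cols_of = {
        g: [bc_index[b] for b in barcodes if groups.get(b) == g] for g in group_names
    }
    empty = [g for g, cols in cols_of.items() if not cols]
    if empty:
        raise ValueError(f"groups with no cells: {empty}")
    ia = np.array([index[l.anchor_a] for l in loops], dtype=int)
    ib = np.array([index[l.anchor_b] for l in loops], dtype=int)
    table = np.zeros((len(loops), len(group_names)))
    for gi, g in enumerate(group_names):
        za = peak_z[ia][:, cols_of[g]].mean(axis=1) if len(loops) else np.zeros(0)
        zb = peak_z[ib][:, cols_of[g]].mean(axis=1) if len(loops) else np.zeros(0)
        table[:, gi] = signed_geometric_mean(za, zb)
    return pd.DataFrame(table, index=[l.loop_id for l in loops], columns=group_names)
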