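"""The three per-cell signal matrices the analysis runs on.

* :func:`tfidf_lsi` — TF-IDF weighting + truncated SVD (LSI), the
  standard scATAC embedding.  The weighted matrix is centered per peak
  before decomposition, so retained components are exactly zero-mean and
  mutually orthogonal; components that merely track sequencing depth
  (|Pearson r| > 0.9 against log10 depth) are flagged and dropped.
* :func:`gene_activity` — accessibility near each gene's TSS with an
  exponential distance decay, depth-normalized and log-transformed; a
  chromatin proxy for expression.
* :func:`motif_deviations` — per-cell motif accessibility deviation
  z-scores against GC- and accessibility-matched background peak sets
  (a bias-corrected motif enrichment in the chromVAR family).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .io import CountMatrix, GeneModel, MotifHitTable, PeakInterval


@dataclass
class EmbeddingMatrix:
    """Cells x components coordinates with per-component depth flags."""

    coords: np.ndarray
    barcodes: list[str]
    depth_flagged: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))
    singular_values: np.ndarray | None = None
    loadings: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.coords.shape[1]


@dataclass
class GeneActivityMatrix:
    values: np.ndarray  # genes x cells, nonnegative (normalized, log1p)
    gene_ids: list[str]
    barcodes: list[str]


@dataclass
class BindingActivityMatrix:
    values: np.ndarray  # motifs x cells, deviation z-scores
    motif_ids: list[str]
    tf_names: list[str]
    barcodes: list[str]
    excluded_motifs: list[str] = field(default_factory=list)
    raw_deviations: np.ndarray | None = None  # y = (o - e) / e, pre-correction


def tfidf_lsi(
    counts: CountMatrix,
    n_components: int = 30,
    binarize: bool = True,
    depth_corr_threshold: float = 0.9,
) -> EmbeddingMatrix:
    """LSI embedding of cells: TF-IDF, per-peak centering, truncated SVD."""
    X = counts.values.astype(np.float64)
    if X.nnz == 0:
        raise ValueError("cannot embed an all-zero count matrix")
    if n_components >= min(X.shape):
        raise ValueError(
            f"n_components={n_components} must be < min(dims)={min(X.shape)}"
        )
    B = X.copy()
    if binarize:
        B.data = np.ones_like(B.data)
    cell_totals = np.asarray(B.sum(axis=0)).ravel()
    if (cell_totals == 0).any():
        warnings.warn("cells with zero counts produce all-zero embedding rows")
    tf = B.multiply(1.0 / np.maximum(cell_totals, 1.0)[None, :])
    n_cells = X.shape[1]
    df = np.asarray((B > 0).sum(axis=1)).ravel()
    idf = np.log(1.0 + n_cells / (1.0 + df))
    M = (sp.diags(idf) @ tf.tocsr()).toarray()
    M = M - M.mean(axis=1, keepdims=True)  # zero-mean components by construction

    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    tol = 1e-12 * (S[0] if len(S) else 1.0)
    rank = int((S > tol).sum())
    if rank < n_components:
        warnings.warn(
            f"matrix rank {rank} < requested {n_components} components; "
            "returning the achievable rank"
        )
    k = min(n_components, rank)
    # deterministic sign: largest-|loading| of each left-singular vector positive
    for j in range(k):
        i = int(np.argmax(np.abs(U[:, j])))
        if U[i, j] < 0:
            U[:, j] = -U[:, j]
            Vt[j, :] = -Vt[j, :]
    coords = Vt[:k].T * S[:k]

    depth = np.log10(np.maximum(np.asarray(X.sum(axis=0)).ravel(), 1.0))
    flagged = np.zeros(k, dtype=bool)
    for j in range(k):
        col = coords[:, j]
        if col.std() > 0 and depth.std() > 0:
            r = float(np.corrcoef(col, depth)[0, 1])
            flagged[j] = abs(r) > depth_corr_threshold
    kept = ~flagged
    if k and not kept.any():
        warnings.warn("every LSI component tracks depth; embedding is empty")
    return EmbeddingMatrix(
        coords=coords[:, kept],
        barcodes=list(counts.barcodes),
        depth_flagged=flagged,
        singular_values=S[:k][kept],
        loadings=U[:, :k][:, kept],
    )


def gene_activity(
    counts: CountMatrix,
    peaks: list[PeakInterval],
    genes: list[GeneModel],
    decay_bp: int = 5000,
    max_dist: int = 100_000,
    scale: float = 1e4,
    normalize: bool = True,
) -> GeneActivityMatrix:
    """Distance-decayed accessibility around each TSS, normalized per cell.

    raw A[g, c] = sum over peaks with |midpoint - TSS_g| <= max_dist of
    exp(-|midpoint - TSS_g| / decay_bp) * X[p, c]; each cell is then
    scaled to ``scale`` total and log1p-transformed.  ``normalize=False``
    returns the raw A, which is linear in the counts.
    """
    peak_by_id = {p.peak_id: p for p in peaks}
    mids = np.array([peak_by_id[pid].midpoint for pid in counts.peak_ids])
    pcontig = np.array([peak_by_id[pid].contig for pid in counts.peak_ids], dtype=object)

    rows, cols, vals = [], [], []
    for gi, g in enumerate(genes):
        on_contig = np.flatnonzero(pcontig == g.contig)
        d = np.abs(mids[on_contig] - g.tss)
        near = on_contig[d <= max_dist]
        if near.size:
            rows.extend([gi] * near.size)
            cols.extend(near.tolist())
            vals.extend(np.exp(-np.abs(mids[near] - g.tss) / decay_bp).tolist())
    W = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(genes), len(counts.peak_ids))
    )
    if W.nnz == 0:
        raise ValueError("no gene has any peak within max_dist")
    A = np.asarray((W @ counts.values).todense(), dtype=np.float64)
    if not normalize:
        return GeneActivityMatrix(A, [g.gene_id for g in genes], list(counts.barcodes))
    totals = A.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} cells have zero gene-activity total")
    A = np.log1p(A / np.where(zero, 1.0, totals)[None, :] * scale)
    A[:, zero] = 0.0
    return GeneActivityMatrix(A, [g.gene_id for g in genes], list(counts.barcodes))


def background_peak_sets(
    peaks_gc: np.ndarray,
    mean_accessibility: np.ndarray,
    n_background: int,
    n_neighbors: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample bias-matched background peaks.

    For each peak, its ``n_neighbors`` nearest peaks in standardized
    (gc_fraction, log1p mean accessibility) space form the candidate
    pool; one is drawn uniformly per background iteration.  Returns an
    (n_background, n_peaks) array of peak indices.
    """
    feats = np.column_stack([peaks_gc, np.log1p(mean_accessibility)])
    mu = feats.mean(axis=0)
    sd = feats.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (feats - mu) / sd
    n_peaks = len(Z)
    d2 = ((Z[:, None, :] - Z[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)  # a peak never backgrounds itself
    k = min(n_neighbors, n_peaks - 1)
    order = np.argsort(d2, axis=1, kind="stable")[:, :k]
    picks = rng.integers(0, k, size=(n_background, n_peaks))
    return order[np.arange(n_peaks)[None, :], picks]


def motif_deviations(
    counts: CountMatrix,
    motif_hits: MotifHitTable,
    peaks: list[PeakInterval],
    n_background: int = 50,
    n_neighbors: int = 50,
    seed: int = 0,
) -> BindingActivityMatrix:
    """Bias-corrected motif deviation z-scores per cell.

    observed o[m, c] = counts in the motif's peaks; expected
    e[m, c] = T_c * f_m with f_m the motif's share of all peak counts;
    raw deviation y = (o - e) / e (0 where e = 0).  z standardizes y
    against ``n_background`` matched background draws.
    """
    peak_by_id = {p.peak_id: p for p in peaks}
    gc = np.array([peak_by_id[pid].gc_fraction for pid in counts.peak_ids])
    if np.isnan(gc).any():
        raise ValueError("gc_fraction required for all peaks (background matching)")
    if motif_hits.peak_ids != counts.peak_ids:
        raise ValueError("motif table and count matrix must share the peak axis")

    H = np.asarray(motif_hits.values, dtype=np.float64)
    keep = H.sum(axis=1) > 0
    excluded = [m for m, k in zip(motif_hits.motif_ids, keep) if not k]
    if excluded:
        warnings.warn(f"excluding motifs with zero member peaks: {excluded}")
    H = H[keep]
    motif_ids = [m for m, k in zip(motif_hits.motif_ids, keep) if k]

    X = np.asarray(counts.values.todense(), dtype=np.float64)
    peak_totals = X.sum(axis=1)
    cell_totals = X.sum(axis=0)
    grand = peak_totals.sum()

    def raw_deviation(mapping: np.ndarray | None) -> np.ndarray:
        Hm = H if mapping is None else H  # membership fixed; peaks remapped
        Xm = X if mapping is None else X[mapping]
        pt = peak_totals if mapping is None else peak_totals[mapping]
        o = Hm @ Xm
        f = (Hm @ pt) / grand
        e = np.outer(f, cell_totals)
        with np.errstate(divide="ignore", invalid="ignore"):
            y = np.where(e > 0, (o - e) / e, 0.0)
        return y

    y_obs = raw_deviation(None)
    rng = np.random.default_rng(seed)
    bg_index = background_peak_sets(
        gc, X.mean(axis=1), n_background, n_neighbors, rng
    )
    bg = np.stack([raw_deviation(bg_index[i]) for i in range(n_background)])
    z = (y_obs - bg.mean(axis=0)) / (bg.std(axis=0, ddof=1) + 1e-6)
    return BindingActivityMatrix(
        z,
        motif_ids,
        [motif_hits.motif_to_tf[m] for m in motif_ids],
        list(counts.barcodes),
        excluded_motifs=excluded,
        raw_deviations=y_obs,
    )
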