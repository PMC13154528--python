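"""Brute-force oracles for LSI, gene activity and motif deviations."""

import numpy as np
import pytest
import scipy.sparse as sp

from ebatac.io import CountMatrix, MotifHitTable
from ebatac.matrices import gene_activity, motif_deviations, tfidf_lsi
from conftest import toy_counts, toy_genes, toy_peaks


# ------------------------------------------------------------------- LSI

def lsi_oracle(X: np.ndarray, n_components: int, binarize: bool = True):
    """Full-SVD reimplementation of the documented LSI recipe."""
    B = (X > 0).astype(float) if binarize else X.astype(float)
    tf = B / np.maximum(B.sum(axis=0), 1.0)[None, :]
    idf = np.log(1.0 + X.shape[1] / (1.0 + (B > 0).sum(axis=1)))
    M = idf[:, None] * tf
    M = M - M.mean(axis=1, keepdims=True)
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    k = min(n_components, int((S > 1e-12 * S[0]).sum()))
    for j in range(k):
        i = int(np.argmax(np.abs(U[:, j])))
        if U[i, j] < 0:
            U[:, j] *= -1
            Vt[j] *= -1
    coords = Vt[:k].T * S[:k]
    depth = np.log10(np.maximum(X.sum(axis=0), 1.0))
    keep = []
    for j in range(k):
        r = np.corrcoef(coords[:, j], depth)[0, 1] if coords[:, j].std() > 0 else 0.0
        keep.append(abs(r) <= 0.9)
    return coords[:, keep]


def test_small_embedding_matches_full_svd_oracle():
    X = np.array([[3, 0, 1], [0, 2, 2], [5, 1, 0], [0, 0, 4]])
    counts = CountMatrix(sp.csr_matrix(X), ["p0", "p1", "p2", "p3"], ["a", "b", "c"])
    emb = tfidf_lsi(counts, n_components=2)
    expected = lsi_oracle(X, 2)
    assert emb.coords.shape == expected.shape
    np.testing.assert_allclose(emb.coords, expected, atol=1e-8)


def test_embedding_components_are_orthogonal_and_centered():
    rng = np.random.default_rng(0)
    counts = toy_counts(rng, 40, 25)
    emb = tfidf_lsi(counts, n_components=10)
    gram = emb.coords.T @ emb.coords
    np.testing.assert_allclose(gram - np.diag(np.diag(gram)), 0, atol=1e-8)
    norms = np.linalg.norm(emb.coords, axis=0)
    assert (np.abs(emb.coords.mean(axis=0)) < 1e-8 * np.maximum(norms, 1)).all()


def test_identical_cells_are_flagged_degenerate():
    X = np.tile([[1], [0], [2], [1]], (1, 5))
    counts = CountMatrix(sp.csr_matrix(X), [f"p{i}" for i in range(4)], [f"c{i}" for i in range(5)])
    with pytest.warns(UserWarning, match="rank"):
        emb = tfidf_lsi(counts, n_components=3)
    assert emb.coords.shape[1] == 0


def test_all_zero_matrix_is_rejected():
    counts = CountMatrix(sp.csr_matrix((4, 3)), [f"p{i}" for i in range(4)], list("abc"))
    with pytest.raises(ValueError, match="all-zero"):
        tfidf_lsi(counts, n_components=2)


def test_too_many_components_is_rejected():
    rng = np.random.default_rng(1)
    with pytest.raises(ValueError, match="n_components"):
        tfidf_lsi(toy_counts(rng, 6, 4), n_components=4)


# ------------------------------------------------------------- gene activity

def activity_oracle(X, peaks, genes, decay=5000, max_dist=100_000, scale=1e4):
    raw = np.zeros((len(genes), X.shape[1]))
    for gi, g in enumerate(genes):
        for pi, p in enumerate(peaks):
            d = abs((p.start + p.end) // 2 - g.tss)
            if p.contig == g.contig and d <= max_dist:
                raw[gi] += np.exp(-d / decay) * X[pi]
    totals = raw.sum(axis=0)
    out = np.log1p(raw / np.where(totals == 0, 1, totals)[None, :] * scale)
    out[:, totals == 0] = 0
    return raw, out


def test_gene_activity_matches_direct_formula():
    rng = np.random.default_rng(2)
    peaks = toy_peaks(6, spacing=4000)
    genes = toy_genes(3, spacing=9000)
    counts = toy_counts(rng, 6, 5)
    raw_expected, norm_expected = activity_oracle(
        np.asarray(counts.values.todense()), peaks, genes
    )
    raw = gene_activity(counts, peaks, genes, normalize=False)
    np.testing.assert_allclose(raw.values, raw_expected, atol=1e-8)
    norm = gene_activity(counts, peaks, genes)
    np.testing.assert_allclose(norm.values, norm_expected, atol=1e-8)


def test_peak_at_tss_and_distance_weights():
    # peaks at distance 0 and 5000 from the TSS with counts 2 and 3
    from ebatac.io import GeneModel, PeakInterval

    peaks = [
        PeakInterval("at_tss", "chr1", 900, 1100, 0.5),      # midpoint 1000
        PeakInterval("one_tau", "chr1", 5900, 6100, 0.5),    # midpoint 6000
        PeakInterval("far", "chr1", 200_000, 200_200, 0.5),  # beyond max_dist
    ]
    genes = [GeneModel("G", "chr1", 1000, "+"), GeneModel("H", "chr1", 98_900, "+")]
    X = np.array([[2], [3], [7]])
    counts = CountMatrix(sp.csr_matrix(X), [p.peak_id for p in peaks], ["c"])
    raw = gene_activity(counts, peaks, genes, normalize=False)
    assert raw.values[0, 0] == pytest.approx(2 + 3 * np.exp(-1))
    # the far peak's midpoint is 101100 bp from H: outside the 100 kb window;
    # the two near peaks contribute with their decayed weights
    assert raw.values[1, 0] == pytest.approx(
        3 * np.exp(-92_900 / 5000) + 2 * np.exp(-97_900 / 5000)
    )


def test_gene_activity_raw_is_linear_in_counts():
    rng = np.random.default_rng(3)
    peaks = toy_peaks(5)
    genes = toy_genes(4)
    c1, c2 = toy_counts(rng, 5, 6), toy_counts(rng, 5, 6)
    both = CountMatrix(c1.values + c2.values, c1.peak_ids, c1.barcodes)
    summed = gene_activity(both, peaks, genes, normalize=False).values
    parts = (
        gene_activity(c1, peaks, genes, normalize=False).values
        + gene_activity(c2, peaks, genes, normalize=False).values
    )
    np.testing.assert_allclose(summed, parts, atol=1e-10)


def test_no_peak_in_range_is_rejected():
    rng = np.random.default_rng(4)
    counts = toy_counts(rng, 3, 2)
    genes = toy_genes(2, contig="chrOther")
    with pytest.raises(ValueError, match="max_dist"):
        gene_activity(counts, toy_peaks(3), genes)


# ---------------------------------------------------------- motif deviations

def deviation_oracle(X, gc, hits, n_background, n_neighbors, seed):
    """Independent re-derivation of the deviation z-score protocol.

    Protocol: features (gc, log1p mean accessibility) standardized;
    each peak's candidate pool is its n_neighbors nearest other peaks
    (stable order); rng = default_rng(seed) draws an
    (n_background, n_peaks) integer matrix indexing into the pools.
    """
    n_peaks, _ = X.shape
    feats = np.column_stack([gc, np.log1p(X.mean(axis=1))])
    zf = (feats - feats.mean(axis=0)) / np.where(feats.std(axis=0) == 0, 1, feats.std(axis=0))
    pools = []
    for p in range(n_peaks):
        d = ((zf - zf[p]) ** 2).sum(axis=1)
        d[p] = np.inf
        order = np.argsort(d, kind="stable")
        pools.append(order[: min(n_neighbors, n_peaks - 1)])
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, len(pools[0]), size=(n_background, n_peaks))

    peak_totals = X.sum(axis=1)
    cell_totals = X.sum(axis=0)
    grand = peak_totals.sum()

    def dev(index):
        Xm, pt = X[index], peak_totals[index]
        o = hits @ Xm
        e = np.outer((hits @ pt) / grand, cell_totals)
        return np.where(e > 0, (o - e) / e, 0.0)

    y = dev(np.arange(n_peaks))
    bg = np.stack([dev(np.array([pools[p][picks[i, p]] for p in range(n_peaks)]))
                   for i in range(n_background)])
    return (y - bg.mean(axis=0)) / (bg.std(axis=0, ddof=1) + 1e-6)


def test_deviation_z_matches_brute_force_oracle():
    rng = np.random.default_rng(5)
    X = rng.poisson(4.0, size=(4, 3)).astype(float)
    X[X.sum(axis=1) == 0, 0] = 1
    gc = np.array([0.35, 0.5, 0.65, 0.4])
    peaks = toy_peaks(4)
    peaks = [type(p)(p.peak_id, p.contig, p.start, p.end, g) for p, g in zip(peaks, gc)]
    hits = np.array([[1, 0, 1, 0]])
    table = MotifHitTable(hits, ["M1"], [p.peak_id for p in peaks], {"M1": "TF1"})
    counts = CountMatrix(sp.csr_matrix(X), [p.peak_id for p in peaks], list("abc"))
    result = motif_deviations(counts, table, peaks, n_background=5, seed=9)
    expected = deviation_oracle(X, gc, hits.astype(float), 5, 50, 9)
    np.testing.assert_allclose(result.values, expected, atol=1e-6)


def test_saturating_motif_with_uniform_peaks_scores_zero():
    # identical peak rows make every background set exactly expectation-matching
    X = np.tile([[2.0, 5.0, 1.0]], (6, 1))
    peaks = toy_peaks(6)
    table = MotifHitTable(
        np.ones((1, 6), dtype=int), ["M"], [p.peak_id for p in peaks], {"M": "TF"}
    )
    counts = CountMatrix(sp.csr_matrix(X), [p.peak_id for p in peaks], list("abc"))
    z = motif_deviations(counts, table, peaks, n_background=5, seed=0).values
    np.testing.assert_allclose(z, 0.0, atol=1e-12)


def test_per_cell_scaling_leaves_deviations_unchanged():
    # rank-1 counts keep the motif's expected fraction f fixed when one
    # cell is rescaled, so o and e scale together exactly
    rng = np.random.default_rng(6)
    X = np.outer(rng.integers(1, 9, size=8).astype(float), rng.integers(1, 6, size=4))
    peaks = toy_peaks(8)
    table = MotifHitTable(
        (rng.random((2, 8)) < 0.5).astype(int) | np.eye(2, 8, dtype=int),
        ["M1", "M2"], [p.peak_id for p in peaks], {"M1": "A", "M2": "B"},
    )
    base = motif_deviations(
        CountMatrix(sp.csr_matrix(X), [p.peak_id for p in peaks], list("wxyz")),
        table, peaks, n_background=7, seed=3,
    ).raw_deviations
    X2 = X.copy()
    X2[:, 1] *= 5  # per-cell scale change: o and e scale together
    scaled = motif_deviations(
        CountMatrix(sp.csr_matrix(X2), [p.peak_id for p in peaks], list("wxyz")),
        table, peaks, n_background=7, seed=3,
    ).raw_deviations
    np.testing.assert_allclose(scaled[:, 1], base[:, 1], atol=1e-9)


def test_permuting_cells_permutes_columns():
    rng = np.random.default_rng(7)
    X = rng.poisson(3.0, size=(6, 5)).astype(float) + 1
    peaks = toy_peaks(6)
    table = MotifHitTable(
        np.array([[1, 1, 0, 0, 1, 0]]), ["M"], [p.peak_id for p in peaks], {"M": "T"}
    )
    perm = [3, 0, 4, 1, 2]
    a = motif_deviations(
        CountMatrix(sp.csr_matrix(X), [p.peak_id for p in peaks], list("abcde")),
        table, peaks, n_background=6, seed=1,
    ).values
    b = motif_deviations(
        CountMatrix(sp.csr_matrix(X[:, perm]), [p.peak_id for p in peaks],
                    [list("abcde")[i] for i in perm]),
        table, peaks, n_background=6, seed=1,
    ).values
    np.testing.assert_allclose(b, a[:, perm], atol=1e-9)


def test_empty_motif_is_excluded_with_warning():
    rng = np.random.default_rng(8)
    X = rng.poisson(3.0, size=(4, 3)).astype(float) + 1
    peaks = toy_peaks(4)
    table = MotifHitTable(
        np.array([[1, 1, 0, 0], [0, 0, 0, 0]]),
        ["M1", "M0"], [p.peak_id for p in peaks], {"M1": "A", "M0": "B"},
    )
    counts = CountMatrix(sp.csr_matrix(X), [p.peak_id for p in peaks], list("abc"))
    with pytest.warns(UserWarning, match="zero member peaks"):
        result = motif_deviations(counts, table, peaks, n_background=5, seed=0)
    assert result.motif_ids == ["M1"] and result.excluded_motifs == ["M0"]
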