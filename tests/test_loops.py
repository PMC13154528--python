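"""Metacells, candidate pairs, co-accessibility and inferred loop signals."""

import numpy as np
import pytest
import scipy.sparse as sp

from ebatac.io import CountMatrix, PeakInterval
from ebatac.loops import (
    Loop,
    call_loops,
    candidate_pairs,
    coaccessibility,
    loop_signal,
    make_metacells,
)
from ebatac.matrices import EmbeddingMatrix
from conftest import toy_counts, toy_peaks


def embedding_of(coords):
    coords = np.asarray(coords, dtype=float)
    return EmbeddingMatrix(coords, [f"c{i}" for i in range(len(coords))])


# ---------------------------------------------------------------- metacells

def test_minimum_cells_give_exactly_two_groups():
    rng = np.random.default_rng(0)
    emb = embedding_of(rng.normal(size=(20, 2)))
    groups = make_metacells(emb, target_size=10, seed=1)
    assert len(groups) == 20
    assert len(set(groups.tolist())) == 2


def test_metacells_partition_every_cell():
    rng = np.random.default_rng(1)
    emb = embedding_of(rng.normal(size=(57, 3)))
    groups = make_metacells(emb, target_size=10, seed=1)
    assert groups.shape == (57,)
    assert (groups >= 0).all()


def test_well_separated_blobs_are_never_mixed():
    rng = np.random.default_rng(2)
    blob_a = rng.normal(loc=0.0, scale=0.1, size=(30, 2))
    blob_b = rng.normal(loc=50.0, scale=0.1, size=(30, 2))
    emb = embedding_of(np.vstack([blob_a, blob_b]))
    groups = make_metacells(emb, target_size=10, seed=3)
    assert not set(groups[:30].tolist()) & set(groups[30:].tolist())


def test_metacell_preconditions():
    emb = embedding_of(np.zeros((5, 1)))
    with pytest.raises(ValueError, match="target_size"):
        make_metacells(emb, target_size=1)
    with pytest.raises(ValueError, match="2\\*target_size"):
        make_metacells(emb, target_size=10)


# ----------------------------------------------------------- candidate pairs

def pairs_oracle(peaks, min_dist, max_dist):
    out = set()
    for i, a in enumerate(peaks):
        for j, b in enumerate(peaks):
            if i < j and a.contig == b.contig:
                d = abs(a.midpoint - b.midpoint)
                if min_dist <= d <= max_dist:
                    out.add((a.peak_id, b.peak_id))
    return out


def test_window_edges():
    far = [PeakInterval("a", "c", 0, 200), PeakInterval("b", "c", 600_000, 600_200)]
    assert candidate_pairs(far) == []
    near = [PeakInterval("a", "c", 0, 200), PeakInterval("b", "c", 50_000, 50_200)]
    assert len(candidate_pairs(near)) == 1


def test_pair_enumeration_matches_brute_force():
    rng = np.random.default_rng(3)
    starts = np.sort(rng.integers(0, 2_000_000, size=6))
    peaks = [PeakInterval(f"p{i}", "chr1", int(s), int(s) + 300) for i, s in enumerate(starts)]
    got = {(l.anchor_a, l.anchor_b) for l in candidate_pairs(peaks)}
    assert got == pairs_oracle(peaks, 1000, 500_000)
    # distances agree too
    mids = {p.peak_id: p.midpoint for p in peaks}
    for l in candidate_pairs(peaks):
        assert l.distance == abs(mids[l.anchor_a] - mids[l.anchor_b])


def test_pair_preconditions():
    peaks = toy_peaks(3)
    with pytest.raises(ValueError, match="min_dist"):
        candidate_pairs(peaks, min_dist=100, max_dist=100)
    with pytest.raises(ValueError, match="sorted"):
        candidate_pairs(peaks[::-1])


# ---------------------------------------------------------- co-accessibility

def coaccessibility_oracle(X, metacells, pairs, peak_ids):
    """Direct evaluation of the documented two-way-centered correlation."""
    groups = sorted(set(metacells))
    sig = np.zeros((X.shape[0], len(groups)))
    for gi, g in enumerate(groups):
        m = X[:, np.asarray(metacells) == g].mean(axis=1)
        sig[:, gi] = np.log1p(m * 1e4 / m.sum())
    sig = sig - sig.mean(axis=0, keepdims=True)
    index = {p: i for i, p in enumerate(peak_ids)}
    out = []
    for pair in pairs:
        a = sig[index[pair.anchor_a]]
        b = sig[index[pair.anchor_b]]
        out.append(float(np.corrcoef(a, b)[0, 1]))
    return np.array(out)


def test_correlation_matches_direct_formula():
    rng = np.random.default_rng(4)
    counts = toy_counts(rng, 6, 25, lam=4.0)
    metacells = np.repeat(np.arange(5), 5)
    pairs = [Loop("p0", "p1", 10_000), Loop("p2", "p5", 30_000), Loop("p1", "p4", 30_000)]
    r, flagged = coaccessibility(counts, metacells, pairs)
    expected = coaccessibility_oracle(
        np.asarray(counts.values.todense(), float), metacells, pairs, counts.peak_ids
    )
    np.testing.assert_allclose(r, expected, atol=1e-10)
    assert not flagged.any()


def test_identical_anchor_rows_correlate_perfectly():
    rng = np.random.default_rng(5)
    X = rng.poisson(5.0, size=(4, 30)).astype(float)
    X[1] = X[0]
    counts = CountMatrix(sp.csr_matrix(X), [f"p{i}" for i in range(4)], [f"c{j}" for j in range(30)])
    r, flagged = coaccessibility(counts, np.repeat(np.arange(6), 5), [Loop("p0", "p1", 1)])
    assert r[0] == pytest.approx(1.0)


def test_constant_anchor_is_flagged_zero():
    rng = np.random.default_rng(6)
    X = rng.poisson(5.0, size=(3, 30)).astype(float)
    X[1] = 0.0  # never accessible: no co-accessibility evidence
    counts = CountMatrix(sp.csr_matrix(X), ["p0", "p1", "p2"], [f"c{j}" for j in range(30)])
    r, flagged = coaccessibility(counts, np.repeat(np.arange(6), 5), [Loop("p0", "p1", 1)])
    assert flagged[0] and r[0] == 0.0


def test_too_few_metacells_rejected():
    rng = np.random.default_rng(7)
    counts = toy_counts(rng, 3, 4)
    with pytest.raises(ValueError, match="metacells"):
        coaccessibility(counts, np.array([0, 0, 1, 1]), [])


# ------------------------------------------------------------------ calling

def test_threshold_filtering():
    pairs = [Loop("a", "b", 1), Loop("c", "d", 1), Loop("e", "f", 1)]
    r = np.array([0.2, 0.4, 0.9])
    assert len(call_loops(pairs, r, threshold=1.01)) == 0
    assert len(call_loops(pairs, r, threshold=-1.0)) == 3
    called = call_loops(pairs, r, threshold=0.35)
    assert [(l.anchor_a, l.coaccessibility) for l in called] == [("c", 0.4), ("e", 0.9)]


# ------------------------------------------------------------------- signal

def test_loop_signal_combiner_and_symmetry():
    peak_z = np.array([
        [1.0, 1.0, -1.0, -1.0],
        [1.0, 1.0, -1.0, 3.0],
    ])
    groups = {"c0": "g1", "c1": "g1", "c2": "g2", "c3": "g2"}
    loops = [Loop("pA", "pB", 1)]
    table = loop_signal(peak_z, ["pA", "pB"], loops, groups, ["c0", "c1", "c2", "c3"])
    assert table.loc["pA|pB", "g1"] == pytest.approx(1.0)       # means 1 and 1
    assert table.loc["pA|pB", "g2"] == 0.0                      # means -1 and +1
    swapped = loop_signal(peak_z[::-1], ["pB", "pA"], loops, groups, ["c0", "c1", "c2", "c3"])
    assert swapped.loc["pA|pB", "g1"] == table.loc["pA|pB", "g1"]


def test_loop_signal_rejects_empty_group():
    with pytest.raises(ValueError, match="no cells"):
        loop_signal(np.ones((2, 2)), ["a", "b"], [], {"c0": "g1", "zz": "g2"}, ["c0", "c1"])


def test_planted_loop_signal_is_highest_in_active_group(default_run):
    """A planted loop's ILS peaks in the population whose program owns it."""
    import pandas as pd

    signals = pd.read_csv(default_run / "loop_signal.tsv", sep="\t", index_col=0)
    truth = pd.read_csv(default_run / "truth_loops.tsv", sep="\t")
    regulons = pd.read_csv(default_run / "truth_regulons.tsv", sep="\t")
    tf_types = pd.read_csv(default_run / "truth_tf_types.tsv", sep="\t")
    tf_type = dict(zip(tf_types["tf"], tf_types["type"]))
    target_type = {t: tf_type[tf] for tf, t in zip(regulons["tf"], regulons["target"])}
    pure = [g for g in ("ESC", "END", "MES", "ECT") if g in signals.columns]
    checked = 0
    for a, b in zip(truth["peak_a"], truth["peak_b"]):
        loop_id = f"{a}|{b}"
        gene = b.rsplit("_", 1)[0]
        home = target_type.get(gene)
        if loop_id in signals.index and home in pure:
            row = signals.loc[loop_id, pure]
            assert row.idxmax() == home
            checked += 1
    assert checked > 50
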