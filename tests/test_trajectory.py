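"""Fisher LDA, centroid-axis pseudotime and binned consistency profiles."""

import numpy as np
import pandas as pd
import pytest
import scipy.linalg

from ebatac.cluster import ClusterLabeling
from ebatac.consistency import ConsistencyMatrix
from ebatac.matrices import EmbeddingMatrix
from ebatac.trajectory import (
    LineageSpec,
    PseudotimeAssignment,
    bin_profile,
    lda_embed,
    lineage_pseudotime,
    pt_to_bin,
)


# ----------------------------------------------------------------------- LDA

def lda_oracle(X, labels, n_components):
    """Dense generalized-eigensolver reimplementation."""
    classes = sorted(set(labels))
    mu = X.mean(axis=0)
    d = X.shape[1]
    Sw = np.zeros((d, d))
    Sb = np.zeros((d, d))
    for c in classes:
        Xc = X[np.asarray(labels) == c]
        mc = Xc.mean(axis=0)
        Sw += (Xc - mc).T @ (Xc - mc)
        Sb += len(Xc) * np.outer(mc - mu, mc - mu)
    Sw += 1e-3 * np.trace(Sw) / d * np.eye(d)
    vals, vecs = scipy.linalg.eig(np.linalg.inv(Sw) @ Sb)
    order = np.argsort(vals.real)[::-1][:n_components]
    W = vecs[:, order].real
    W /= np.linalg.norm(W, axis=0, keepdims=True)
    for j in range(W.shape[1]):
        if W[np.argmax(np.abs(W[:, j])), j] < 0:
            W[:, j] *= -1
    return W


def test_directions_match_dense_eigensolver():
    rng = np.random.default_rng(0)
    centers = np.array([[0.0, 0.0], [3.0, 1.0], [-1.0, 4.0]])
    labels = np.repeat([1, 2, 3], 15)
    X = centers[labels - 1] + rng.normal(scale=0.7, size=(45, 2))
    emb = lda_embed(X, labels, n_components=2)
    expected = lda_oracle(X, labels, 2)
    np.testing.assert_allclose(emb.loadings, expected, atol=1e-6)


def test_separating_feature_dominates_first_component():
    rng = np.random.default_rng(1)
    X = rng.normal(scale=0.3, size=(40, 4))
    X[:20, 0] += 5.0  # classes differ only on feature 0
    labels = np.array([1] * 20 + [2] * 20)
    emb = lda_embed(X, labels, n_components=1)
    assert np.argmax(np.abs(emb.loadings[:, 0])) == 0
    assert emb.loadings[0, 0] > 0  # sign convention


def test_lda_is_deterministic():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(30, 3))
    labels = np.repeat([1, 2, 3], 10)
    a = lda_embed(X, labels, 2)
    b = lda_embed(X, labels, 2)
    np.testing.assert_array_equal(a.coords, b.coords)


def test_lda_input_validation():
    X = np.zeros((4, 2))
    with pytest.raises(ValueError, match="2 classes"):
        lda_embed(X, np.ones(4), 1)
    with pytest.raises(ValueError, match="n_classes-1"):
        lda_embed(X, np.array([1, 1, 2, 2]), 2)
    with pytest.raises(ValueError, match="merge"):
        lda_embed(X, np.array([1, 1, 2, 3]), 1)


# ----------------------------------------------------------------- pseudotime

def labeled_embedding():
    coords = np.array(
        [[0.0, 0], [0.5, 0], [4.0, 0], [5.0, 0], [9.0, 0], [10.0, 0]], dtype=float
    )
    cells = [f"c{i}" for i in range(6)]
    emb = EmbeddingMatrix(coords, cells)
    labeling = ClusterLabeling(
        {c: i // 2 + 1 for i, c in enumerate(cells)},
        {1: "ESC", 2: "EC-END", 3: "END"},
    )
    return emb, labeling


def test_pseudotime_endpoints_and_monotone_groups():
    emb, labeling = labeled_embedding()
    a = lineage_pseudotime(emb, labeling, LineageSpec("END"))
    assert a.pt["c0"] == 0.0 and a.pt["c5"] == 1.0
    assert a.pt["c0"] < a.pt["c2"] < a.pt["c4"]


def test_reversing_the_axis_flips_pseudotime():
    emb, labeling = labeled_embedding()
    forward = lineage_pseudotime(emb, labeling, LineageSpec("END"))
    flipped_labeling = ClusterLabeling(
        labeling.cluster_of, {1: "END", 2: "EC-END", 3: "ESC"}
    )
    backward = lineage_pseudotime(emb, flipped_labeling, LineageSpec("END"))
    for cell in forward.pt:
        assert backward.pt[cell] == pytest.approx(1 - forward.pt[cell])


def test_coincident_centroids_are_rejected():
    coords = np.zeros((6, 2))
    emb = EmbeddingMatrix(coords, [f"c{i}" for i in range(6)])
    labeling = ClusterLabeling(
        {f"c{i}": i // 2 + 1 for i in range(6)}, {1: "ESC", 2: "EC-END", 3: "END"}
    )
    with pytest.raises(ValueError, match="degenerate"):
        lineage_pseudotime(emb, labeling, LineageSpec("END"))


def test_bin_mapping_convention():
    assert pt_to_bin(0.0, 10) == 1
    assert pt_to_bin(0.1, 10) == 1
    assert pt_to_bin(0.1000001, 10) == 2
    assert pt_to_bin(1.0, 10) == 10


# ---------------------------------------------------------------- bin profile

def eight_cell_assignment():
    pt = {f"c{i}": v for i, v in enumerate([0.0, 0.05, 0.3, 0.35, 0.5, 0.8, 0.9, 1.0])}
    return PseudotimeAssignment(
        "END", pt, {c: pt_to_bin(v, 4) for c, v in pt.items()}, 4
    )


def test_bin_profile_matches_direct_averaging():
    values = np.arange(16, dtype=float).reshape(2, 8)
    C = ConsistencyMatrix(values, ["A", "B"], [f"c{i}" for i in range(8)])
    assignment = eight_cell_assignment()
    profile, counts = bin_profile(C, assignment, LineageSpec("END", ["A", "B"]), n_bins=4)
    # bins: c0,c1 -> 1; c2,c3 -> 2; c4 -> 2; c5 -> 4; c6,c7 -> 4
    assert counts.tolist() == [2, 3, 0, 3]
    assert profile.loc["A", 1] == pytest.approx(values[0, :2].mean())
    assert profile.loc["A", 2] == pytest.approx(values[0, 2:5].mean())
    assert np.isnan(profile.loc["A", 3])
    assert profile.loc["B", 4] == pytest.approx(values[1, 5:].mean())
    assert counts.sum() == len(assignment.pt)


def test_single_occupied_bin_is_global_mean():
    values = np.array([[1.0, 3.0, 5.0]])
    C = ConsistencyMatrix(values, ["A"], ["c0", "c1", "c2"])
    assignment = PseudotimeAssignment("END", {c: 0.05 for c in C.barcodes},
                                      {c: 1 for c in C.barcodes}, 5)
    profile, counts = bin_profile(C, assignment, LineageSpec("END", ["A"]), n_bins=5)
    assert profile.loc["A", 1] == pytest.approx(3.0)
    assert profile.loc["A", 2:].isna().all()


def test_too_few_bins_is_rejected():
    C = ConsistencyMatrix(np.zeros((1, 2)), ["A"], ["c0", "c1"])
    assignment = PseudotimeAssignment("END", {"c0": 0.1, "c1": 0.9}, {"c0": 1, "c1": 1}, 1)
    with pytest.raises(ValueError, match="n_bins"):
        bin_profile(C, assignment, LineageSpec("END", ["A"]), n_bins=1)


# --------------------------------------------------- planted-data properties

def test_marker_profiles_are_monotone_along_trajectories(default_run):
    """ESC markers fall and lineage markers rise along each lineage
    after 3-bin moving-average smoothing."""
    from ebatac.cluster import MarkerPanel

    panel = MarkerPanel()
    for layer in ("END", "MES", "ECT"):
        profile = pd.read_csv(
            default_run / f"bin_profile_{layer}.tsv", sep="\t", index_col=0
        )
        tf_rows = profile.drop(index="cell_count")

        def smoothed(tfs):
            series = tf_rows.loc[[t for t in tfs if t in tf_rows.index]].mean(axis=0)
            return series.rolling(3, center=True, min_periods=1).mean().to_numpy()

        esc = smoothed(panel.sets["ESC"])
        lin = smoothed(panel.sets[layer])
        assert (np.diff(esc) <= 1e-9).all(), f"ESC profile not non-increasing in {layer}"
        assert (np.diff(lin) >= -1e-9).all(), f"{layer} profile not non-decreasing"
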