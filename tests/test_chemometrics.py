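"""PCA, UPGMA clustering, Q2/DQ2 and PLS-DA validation schemes."""

import numpy as np
import pandas as pd
import pytest

import mae_lipidomics as ml

# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def test_pca_explained_variance_complete_and_ordered():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(15, 6))
    m = ml.pca(X)
    pct = m.explained_variance_pct
    assert np.all(pct >= 0)
    assert np.all(np.diff(pct) <= 1e-9)
    assert pct.sum() == pytest.approx(100.0)


def test_pca_reconstruction_and_orthogonal_scores():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(12, 5))
    m = ml.pca(X)
    assert np.allclose(m.reconstruct(), m.pretreat(X), atol=1e-8)
    gram = m.scores.to_numpy().T @ m.scores.to_numpy()
    assert np.allclose(gram - np.diag(np.diag(gram)), 0.0, atol=1e-8)


def test_pca_sign_convention_largest_loading_positive():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(20, 4))
    m = ml.pca(X)
    for comp in m.loadings.columns:
        col = m.loadings[comp].to_numpy()
        assert col[np.argmax(np.abs(col))] > 0


def test_pca_direction_matches_eigendecomposition_oracle():
    """On y = 2x + noise, PC1 aligns with (1,2)/sqrt(5) within 5 degrees."""
    rng = np.random.default_rng(3)
    x = rng.normal(size=300)
    X = np.column_stack([x, 2 * x + rng.normal(0, 0.05, 300)])
    m = ml.pca(X, center=True, scale=False)
    v = m.loadings["PC1"].to_numpy()
    # oracle: leading eigenvector of the covariance matrix
    w, V = np.linalg.eigh(np.cov(X.T))
    lead = V[:, np.argmax(w)]
    target = np.array([1, 2]) / np.sqrt(5)
    for vec in (v, lead):
        angle = np.degrees(np.arccos(np.clip(abs(vec @ target), -1, 1)))
        assert angle < 5


def test_pca_input_validation():
    with pytest.raises(ValueError):
        ml.pca(np.array([[1.0, 2.0]]))  # one sample
    bad = np.ones((5, 3))
    bad[0, 0] = np.nan
    with pytest.raises(ValueError):
        ml.pca(bad)
    with pytest.raises(ValueError):
        ml.pca(np.column_stack([np.arange(5.0), np.ones(5)]), scale=True)


# ---------------------------------------------------------------------------
# UPGMA / HCA
# ---------------------------------------------------------------------------


def _naive_upgma(X):
    """O(n^3) oracle: average pairwise squared Euclidean distance between
    clusters, recomputed from scratch at every merge."""
    def d2(a, b):
        return float(np.sum((X[a] - X[b]) ** 2))

    clusters = [[i] for i in range(len(X))]
    heights = []
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                h = np.mean([d2(a, b) for a in clusters[i] for b in clusters[j]])
                if best is None or h < best[0]:
                    best = (h, i, j)
        h, i, j = best
        heights.append(h)
        merges.append((frozenset(clusters[i]), frozenset(clusters[j])))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [clusters[i] + clusters[j]]
    return heights, merges


@pytest.mark.parametrize("n,p,seed", [(6, 3, 0), (12, 4, 1), (20, 5, 2)])
def test_upgma_equals_naive_oracle(n, p, seed):
    rng = np.random.default_rng(seed)
    X = rng.uniform(size=(n, p))
    tree = ml.hca_average_linkage(X)
    oracle_heights, _ = _naive_upgma(X)
    assert np.allclose(sorted(tree.heights), sorted(oracle_heights), rtol=1e-10)


def test_upgma_heights_monotone_and_count():
    rng = np.random.default_rng(4)
    X = rng.uniform(size=(18, 6))
    tree = ml.hca_average_linkage(X)
    assert len(tree.heights) == 17
    assert np.all(np.diff(tree.heights) >= -1e-12)


def test_identical_samples_merge_at_height_zero():
    X = np.array([[0.2, 0.4], [0.2, 0.4], [0.9, 0.9]])
    tree = ml.hca_average_linkage(X)
    assert tree.heights[0] == pytest.approx(0.0)


def test_cut_tree_extremes_and_monotone_sweep():
    rng = np.random.default_rng(5)
    X = rng.uniform(size=(10, 3))
    tree = ml.hca_average_linkage(X)
    assert len(set(tree.cut(tree.heights[0] / 2))) == 10
    assert len(set(tree.cut(tree.heights[-1] * 1.01))) == 1
    counts = [len(set(tree.cut(h))) for h in np.linspace(0, tree.heights[-1] * 1.1, 40)]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_three_separated_blobs_recovered_at_largest_gap():
    rng = np.random.default_rng(6)
    centers = np.array([[0.1, 0.1], [0.5, 0.9], [0.9, 0.2]])
    labels = np.repeat([0, 1, 2], 8)
    X = centers[labels] + rng.normal(0, 0.02, size=(24, 2))
    tree = ml.hca_average_linkage(X)
    gaps = np.diff(tree.heights)
    cut = tree.heights[np.argmax(gaps)] * 1.0001
    got = tree.cut(cut)
    assert len(set(got)) == 3
    # clusters coincide with generator labels up to renaming
    for lab in (0, 1, 2):
        assert len(set(got[labels == lab])) == 1


def test_newick_export_is_parseable_ultrametric():
    import dendropy

    rng = np.random.default_rng(7)
    X = rng.uniform(size=(8, 3))
    tree = ml.hca_average_linkage(X, labels=[f"s{i}" for i in range(8)])
    t = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
    assert {l.taxon.label for l in t.leaf_node_iter()} == {f"s{i}" for i in range(8)}
    depths = [l.distance_from_root() for l in t.leaf_node_iter()]
    assert np.allclose(depths, tree.heights[-1] / 2, atol=1e-9)


# ---------------------------------------------------------------------------
# Q2 / DQ2
# ---------------------------------------------------------------------------


def test_q2_dq2_perfect_prediction():
    y = np.array([1, 0, 1, 0])
    q2, dq2 = ml.compute_q2_dq2(y, y.astype(float))
    assert q2 == pytest.approx(1.0) and dq2 == pytest.approx(1.0)


def test_overshoot_zeroed_only_for_dq2():
    """y=1 predicted 1.5 contributes 0.25 to PRESS but 0 to PRESS_D."""
    y = np.array([1.0, 0.0])
    f = np.array([1.5, 0.0])
    q2, dq2 = ml.compute_q2_dq2(y, f)
    tss = 0.5
    assert q2 == pytest.approx(1 - 0.25 / tss)
    assert dq2 == pytest.approx(1.0)
    assert dq2 > q2


def test_dq2_dominates_q2_on_random_draws():
    rng = np.random.default_rng(8)
    for _ in range(1000):
        y = rng.integers(0, 2, size=12).astype(float)
        if y.min() == y.max():
            continue
        f = rng.normal(0.5, 1.0, size=12)
        q2, dq2 = ml.compute_q2_dq2(y, f)
        assert dq2 >= q2 - 1e-12


def test_q2_rejects_constant_truth():
    with pytest.raises(ValueError):
        ml.compute_q2_dq2(np.ones(5), np.ones(5))
    with pytest.raises(ValueError):
        ml.compute_q2_dq2(np.array([0, 2, 1]), np.zeros(3))


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------


def _separable(n_per=12, seed=9, spread=0.05):
    rng = np.random.default_rng(seed)
    centers = {"A": [0, 0, 0, 0], "B": [5, 5, 0, 0], "C": [0, 0, 5, 5]}
    X, y = [], []
    for lab, c in centers.items():
        X.append(np.asarray(c) + rng.normal(0, spread, size=(n_per, 4)))
        y += [lab] * n_per
    return np.vstack(X), np.array(y)


def test_double_cv_perfect_on_separable_classes():
    X, y = _separable()
    rep = ml.plsda_double_cv(X, y, seed=0)
    for stat in ("Accuracy", "Sensitivity", "Specificity"):
        assert (rep.stats.loc[stat] == 1.0).all()
    assert (rep.stats.loc["Q2"] > 0.8).all()


def test_double_cv_rmsecv_matches_residual_bookkeeping():
    """RMSECV equals sqrt(PRESS/n) accumulated by hand from the held-out
    predictions."""
    X, y = _separable(spread=0.8)
    rep = ml.plsda_double_cv(X, y, seed=1)
    preds = rep.predictions
    for cls in rep.classes:
        truth = (preds["true"] == cls).astype(float).to_numpy()
        fhat = preds[f"yhat_{cls}"].to_numpy()
        press = np.sum((truth - fhat) ** 2)
        assert rep.stats.loc["RMSECV", cls] == pytest.approx(np.sqrt(press / len(truth)))
        q2, dq2 = ml.compute_q2_dq2(truth, fhat)
        assert rep.stats.loc["Q2", cls] == pytest.approx(q2)
        assert rep.stats.loc["DQ2", cls] == pytest.approx(dq2)


def test_label_permutation_null_q2_nonpositive(screening):
    """Cross-validated Q2 under randomly permuted labels averages <= 0."""
    X = screening.drop(columns=["sample_id", "solvent"])
    y = screening["solvent"].to_numpy()
    rng = np.random.default_rng(10)
    q2s = []
    for _ in range(20):
        perm = rng.permutation(y)
        rep = ml.plsda_double_cv(X, perm, seed=0)
        q2s.append(rep.stats.loc["Q2"].mean())
    assert np.mean(q2s) <= 0.0


def test_bootstrap_deterministic_and_close_to_double_cv():
    X, y = _separable()
    b1 = ml.plsda_bootstrap(X, y, B=200, seed=3)
    b2 = ml.plsda_bootstrap(X, y, B=200, seed=3)
    pd.testing.assert_frame_equal(b1.stats, b2.stats)  # bit-identical rerun
    assert (b1.stats.loc["Accuracy"] >= 0.95).all()
    dcv = ml.plsda_double_cv(X, y, seed=3)
    diff = (b1.stats.loc["Accuracy"] - dcv.stats.loc["Accuracy"]).abs()
    assert (diff <= 0.1).all()


def test_plsda_input_validation():
    X, y = _separable()
    with pytest.raises(ValueError):
        ml.plsda_double_cv(X, np.array(["A"] * len(y)))
    with pytest.raises(ValueError):
        ml.plsda_bootstrap(X, y, B=10)
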