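"""Representational similarity, MDS, and permutation nulls."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from facecontext import rsa
from facecontext.rsa import (FeatureMatrix, ToyReluNet, UnsupportedSchemeError,
                             extract_features, label_permutation_test,
                             make_category_features, mds_embedding,
                             pair_similarity, weight_shuffle_test,
                             within_between_summary, zscore_features)


def _labels(n_per, cats=("faces", "bodies", "houses")):
    return np.repeat(cats, n_per)


def test_pixel_layer_feature_count():
    images = np.zeros((5, 8, 8, 3))
    labels = np.array(list("abcde"))
    (pixel,) = extract_features(images, labels)
    assert pixel.layer == "pixel"
    assert pixel.data.shape == (5, 192)


def test_identical_images_identical_rows(rng):
    img = rng.uniform(size=(4, 4))
    images = np.stack([img, img, rng.uniform(size=(4, 4))])
    (pixel,) = extract_features(images, np.array(list("aab")))
    assert np.array_equal(pixel.data[0], pixel.data[1])
    assert not np.array_equal(pixel.data[0], pixel.data[2])


def test_random_projection_preserves_cluster_similarity(rng):
    centers = rng.normal(0, 8, size=(3, 10))
    X = np.vstack([c + rng.normal(0, 1, size=(6, 10)) for c in centers])
    labels = _labels(6)
    net = ToyReluNet([10, 60], seed=0)
    fm = extract_features(X, labels, net)[1]
    sim = pair_similarity(zscore_features(fm)).values
    within, between = [], []
    for i in range(18):
        for j in range(i + 1, 18):
            (within if labels[i] == labels[j] else between).append(sim[i, j])
    assert np.mean(within) > np.mean(between) + 0.3


def test_zscore_standardizes_and_drops_constant(rng):
    X = rng.normal(size=(10, 4))
    X[:, 2] = 7.0
    z = zscore_features(FeatureMatrix(X, np.arange(10).astype(str), "L"))
    assert z.data.shape == (10, 3)
    assert np.allclose(z.data.mean(axis=0), 0.0, atol=1e-12)
    assert np.allclose(z.data.std(axis=0), 1.0, atol=1e-12)


def test_zscore_hand_computed():
    X = np.array([[1.0, 0.0], [2.0, 2.0], [3.0, 4.0]])
    z = zscore_features(FeatureMatrix(X, np.array(list("abc")), "L"))
    expected = np.array([[-1.0, -1.0], [0.0, 0.0], [1.0, 1.0]]) \
        / np.sqrt(2 / 3)
    assert np.allclose(z.data, expected)


def test_similarity_metrics_basic_values():
    X = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
    fm = FeatureMatrix(X, np.array(list("abc")), "L")
    sp = pair_similarity(fm, "spearman").values
    assert sp[0, 1] == pytest.approx(1.0)
    assert sp[0, 2] == pytest.approx(-1.0)
    pe = pair_similarity(fm, "pearson").values
    assert pe[0, 1] == pytest.approx(1.0)
    d = pair_similarity(fm, "neg_sq_euclidean").values
    assert d[0, 1] == pytest.approx(0.0)
    assert d[0, 2] == pytest.approx(-8.0)
    with pytest.raises(ValueError):
        pair_similarity(fm, "cosine")


def test_spearman_matches_per_pair_oracle(rng):
    from scipy import stats
    X = rng.normal(size=(20, 15))
    fm = FeatureMatrix(X, np.arange(20).astype(str), "L")
    sim = pair_similarity(fm, "spearman").values
    for i in range(0, 20, 3):
        for j in range(i + 1, 20, 4):
            rho = stats.spearmanr(X[i], X[j]).statistic
            assert sim[i, j] == pytest.approx(rho, abs=1e-12)


def test_spearman_invariant_under_monotone_transform(rng):
    X = rng.normal(size=(8, 12))
    fm = FeatureMatrix(X, np.arange(8).astype(str), "L")
    fm_t = FeatureMatrix(np.exp(X) + X ** 3, fm.labels, "L")
    assert np.allclose(pair_similarity(fm).values,
                       pair_similarity(fm_t).values, atol=1e-12)


def test_within_between_blocked_structure():
    n = 4
    labels = _labels(n, ("faces", "bodies"))
    sim = np.zeros((8, 8))
    sim[:4, :4] = 1.0
    sim[4:, 4:] = 1.0
    np.fill_diagonal(sim, 1.0)
    s = rsa.SimilarityMatrix(sim, labels, "spearman", "L")
    out = within_between_summary(s)
    assert out.loc["faces", "faces"] == 1.0
    assert out.loc["bodies", "bodies"] == 1.0
    assert out.loc["faces", "bodies"] == 0.0


def test_within_between_matches_pair_enumeration(rng):
    labels = _labels(3)
    vals = rng.normal(size=(9, 9))
    vals = (vals + vals.T) / 2
    s = rsa.SimilarityMatrix(vals, labels, "pearson", "L")
    out = within_between_summary(s)
    pairs = [(i, j) for i in range(9) for j in range(i + 1, 9)
             if labels[i] == "faces" and labels[j] == "faces"]
    manual = np.mean([vals[i, j] for i, j in pairs])
    assert out.loc["faces", "faces"] == pytest.approx(manual)
    cross = np.mean([vals[i, j] for i in range(9) for j in range(9)
                     if labels[i] == "faces" and labels[j] == "bodies"])
    assert out.loc["faces", "bodies"] == pytest.approx(cross)


def test_relabeling_leaves_pooled_mean_unchanged(rng):
    labels = _labels(3)
    vals = rng.normal(size=(9, 9))
    vals = (vals + vals.T) / 2
    s = rsa.SimilarityMatrix(vals, labels, "pearson", "L")
    perm = rng.permutation(9)
    s2 = rsa.SimilarityMatrix(vals, labels[perm], "pearson", "L")
    iu = np.triu_indices(9, 1)

    def pooled(summary, labs):
        tot, n = 0.0, 0
        for i, j in zip(*iu):
            tot += vals[i, j]
            n += 1
        return tot / n

    assert pooled(within_between_summary(s), labels) == pytest.approx(
        pooled(within_between_summary(s2), labels[perm]))


def test_mds_equilateral_and_round_trip(rng):
    # three mutually equidistant points embed as an equilateral triangle
    X = np.eye(3)
    fm = FeatureMatrix(X, np.array(list("abc")), "L")
    emb = mds_embedding(fm)
    d = cdist(emb, emb)
    iu = np.triu_indices(3, 1)
    assert np.allclose(d[iu], d[iu][0], atol=1e-9)
    # planar points recovered up to rigid motion
    P = rng.normal(size=(15, 2))
    emb2 = mds_embedding(FeatureMatrix(P, np.arange(15).astype(str), "L"))
    assert np.allclose(cdist(emb2, emb2), cdist(P, P), atol=1e-8)
    # global translation leaves embedded distances unchanged
    emb3 = mds_embedding(FeatureMatrix(P + 5.0, np.arange(15).astype(str), "L"))
    assert np.allclose(cdist(emb3, emb3), cdist(P, P), atol=1e-8)


def test_label_permutation_requires_permutations_and_faces():
    fm = make_category_features(5, 16, seed=0)
    with pytest.raises(ValueError):
        label_permutation_test(fm, n_permutations=0)
    bad = FeatureMatrix(fm.data, np.repeat("bodies", fm.data.shape[0]), "L")
    with pytest.raises(ValueError):
        label_permutation_test(bad, n_permutations=10)


def test_label_permutation_detects_blocked_structure():
    fm = make_category_features(20, 64, face_body_shared=3.0, seed=0)
    null = label_permutation_test(fm, n_permutations=300, seed=1)
    assert null.observed["faces_vs_bodies"] > null.upper["faces_vs_bodies"]
    for key in null.observed:
        assert null.lower[key] <= null.null_mean[key] <= null.upper[key]


def test_label_permutation_seed_reproducible():
    fm = make_category_features(8, 32, seed=2)
    n1 = label_permutation_test(fm, 100, seed=5)
    n2 = label_permutation_test(fm, 100, seed=5)
    assert n1.upper == n2.upper and n1.lower == n2.lower


def test_weight_shuffle_preserves_multiset_and_changes_order(rng):
    net = ToyReluNet([10, 7, 4], seed=0)
    shuffled = net.with_shuffled_weights(rng)
    for w0, w1 in zip(net.weights, shuffled.weights):
        assert np.array_equal(np.sort(w0.ravel()), np.sort(w1.ravel()))
        assert not np.array_equal(w0, w1)


def test_weight_shuffle_requires_mutable_weights():
    fm_imgs = np.zeros((6, 2, 2))
    with pytest.raises(UnsupportedSchemeError):
        weight_shuffle_test(None, fm_imgs, _labels(2), 10, 0)


def _trained_toy_setup(rng):
    """Faces load on input dim 0, bodies on dim 1; the 'trained' first-layer
    unit sums both dims, merging the two categories."""
    n_per, n_feat = 8, 20
    labels = _labels(n_per, ("faces", "bodies", "houses", "tools"))
    X = rng.normal(0, 1, size=(4 * n_per, n_feat))
    X[:n_per, 0] += 4.0
    X[n_per:2 * n_per, 1] += 4.0
    X[2 * n_per:3 * n_per, 2] += 4.0
    X[3 * n_per:, 3] += 4.0
    net = ToyReluNet([n_feat, 6], seed=1)
    W = 0.2 * rng.normal(size=(n_feat, 6))
    W[0, 0] = W[1, 0] = 3.0       # the face+body unit
    W[2, 1] = 3.0
    W[3, 2] = 3.0
    net.weights = [W]
    return net, X, labels


def test_weight_shuffle_null_differs_from_trained_toy(rng):
    net, X, labels = _trained_toy_setup(rng)
    nulls = weight_shuffle_test(net, X, labels, n_permutations=60, seed=3)
    null = nulls["relu1"]
    assert null.observed["faces_vs_bodies"] > null.upper["faces_vs_bodies"]


def test_weight_shuffle_seed_reproducible(rng):
    net, X, labels = _trained_toy_setup(rng)
    n1 = weight_shuffle_test(net, X, labels, n_permutations=20, seed=9)
    n2 = weight_shuffle_test(net, X, labels, n_permutations=20, seed=9)
    assert n1["relu1"].upper == n2["relu1"].upper


def test_make_category_features_shapes_and_labels():
    fm = make_category_features(40, 64, seed=0)
    assert fm.data.shape == (240, 64)
    values, counts = np.unique(fm.labels, return_counts=True)
    assert len(values) == 6 and (counts == 40).all()
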