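import numpy as np
import pandas as pd
import pytest
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from smlmnet import (zscore_features, xmeans_cluster, silhouette_by_group,
                     match_groups, class_proportions)


def gaussian_groups(rng, k=4, n=50, d=28, sep=10.0):
    centers = rng.normal(0, sep, size=(k, d))
    X = np.vstack([c + rng.normal(0, 1.0, size=(n, d)) for c in centers])
    labels = np.repeat(np.arange(k), n)
    return X, labels, centers


# ---------------------------------------------------------------- z-scoring

def test_zscore_closed_form():
    Z, mu, sd = zscore_features(np.array([[1.0], [2.0], [3.0]]))
    assert np.allclose(Z.ravel(), np.array([-1, 0, 1]) / np.sqrt(2 / 3))
    assert mu[0] == 2.0 and sd[0] == pytest.approx(np.sqrt(2 / 3))


def test_zscore_idempotent_and_standard(rng):
    X = rng.normal(5, 3, size=(100, 28))
    Z, _, _ = zscore_features(X)
    assert np.abs(Z.mean(axis=0)).max() < 1e-12
    assert np.abs(Z.std(axis=0) - 1).max() < 1e-12
    Z2, _, _ = zscore_features(Z)
    assert np.allclose(Z2, Z, atol=1e-9)


def test_zscore_needs_two_rows():
    with pytest.raises(ValueError):
        zscore_features(np.ones((1, 5)))


# ------------------------------------------------------------------ X-means

def test_single_gaussian_stays_one_group(rng):
    X = rng.normal(size=(100, 5))
    ga = xmeans_cluster(X, 1, 10, seed=0)
    assert ga.K == 1
    assert len(ga.bic_trace) >= 1


def test_two_clusters_match_plain_kmeans(rng):
    X, truth, _ = gaussian_groups(rng, k=2, n=60, d=5)
    ga = xmeans_cluster(X, 1, 10, seed=0)
    assert ga.K == 2
    km = KMeans(2, n_init=10, random_state=0).fit(X)
    assert adjusted_rand_score(ga.labels, km.labels_) == 1.0
    assert adjusted_rand_score(ga.labels, truth) == 1.0


def test_k_respects_bounds(rng):
    X = rng.normal(size=(60, 4))
    ga = xmeans_cluster(X, 2, 3, seed=1)
    assert 2 <= ga.K <= 3
    # centroids are means of member vectors
    for j in range(ga.K):
        assert np.allclose(ga.centroids[j], X[ga.labels == j].mean(axis=0))


def test_labels_stable_under_row_permutation(rng):
    X, _, _ = gaussian_groups(rng, k=3, n=40, d=6)
    ga = xmeans_cluster(X, 1, 10, seed=5)
    perm = rng.permutation(len(X))
    gp = xmeans_cluster(X[perm], 1, 10, seed=5)
    assert adjusted_rand_score(ga.labels, gp.labels[np.argsort(perm)]) == 1.0


def test_xmeans_errors():
    with pytest.raises(ValueError):
        xmeans_cluster(np.zeros((3, 2)), kmin=5, kmax=10)


# -------------------------------------------------------------- silhouettes

def test_silhouette_high_for_separated_clusters(rng):
    X, labels, _ = gaussian_groups(rng, k=2, n=50, d=5, sep=50.0)
    sil = silhouette_by_group(X, labels)
    assert all(v > 0.95 for v in sil.values())


def test_silhouette_near_zero_for_random_labels(rng):
    X = rng.normal(size=(100, 5))
    means = []
    for _ in range(50):
        labels = rng.integers(0, 2, size=100)
        if np.unique(labels).size < 2:
            continue
        sil = silhouette_by_group(X, labels)
        means.append(np.mean(list(sil.values())))
    assert abs(np.mean(means)) < 0.05


def test_silhouette_negative_for_misassigned_duplicates():
    X = np.array([[0.0, 0], [0, 0], [0, 0], [10, 0]])
    labels = np.array([0, 1, 1, 0])
    sil = silhouette_by_group(X, labels)
    assert sil[0] < 0  # the (0,0) point labelled 0 sits inside cluster 1


def test_silhouette_undefined_for_one_group(rng):
    assert silhouette_by_group(rng.normal(size=(10, 3)), np.zeros(10)) is None


# ----------------------------------------------------------- class matching

def reference_frame(centroids, names=("caveolae", "S2", "S1B", "S1A")):
    return pd.DataFrame(centroids, index=list(names)[:len(centroids)])


def test_match_identity(rng):
    C = rng.normal(size=(4, 28))
    cm = match_groups(C, reference_frame(C))
    assert [cm.mapping[g] for g in range(4)] == ["caveolae", "S2", "S1B", "S1A"]
    assert np.allclose(np.diag(cm.distances.to_numpy()), 0.0)
    assert not cm.many_to_one


def test_match_recovers_permutation(rng):
    C = rng.normal(size=(4, 28))
    perm = [2, 0, 3, 1]
    cm = match_groups(C[perm], reference_frame(C))
    names = ["caveolae", "S2", "S1B", "S1A"]
    assert [cm.mapping[g] for g in range(4)] == [names[p] for p in perm]


def test_match_tie_takes_lowest_index_class():
    ref = reference_frame(np.array([[1.0, 0], [-1.0, 0]]), names=("A", "B"))
    with pytest.warns(UserWarning, match="equidistant"):
        cm = match_groups(np.array([[0.0, 0.0]]), ref)
    assert cm.mapping[0] == "A"
    assert cm.ties


def test_match_dimension_mismatch():
    with pytest.raises(ValueError, match="dimension"):
        match_groups(np.zeros((2, 3)), reference_frame(np.zeros((2, 4)),
                                                       names=("A", "B")))


# -------------------------------------------------------------- proportions

def test_proportions_one_per_class():
    df = pd.DataFrame({"cell_id": ["c1"] * 4,
                       "class": ["caveolae", "S2", "S1B", "S1A"]})
    props = class_proportions(df)
    row = props.set_index("cell_id").loc["c1"]
    assert np.allclose(row.to_numpy(dtype=float), 0.25)


def test_proportions_sum_to_one(rng):
    df = pd.DataFrame({
        "cell_id": rng.choice(["c1", "c2", "c3"], size=200),
        "class": rng.choice(["caveolae", "S2", "S1B", "S1A"], size=200),
        "condition": "wt"})
    props = class_proportions(df)
    sums = props.drop(columns=["cell_id", "condition"]).sum(axis=1)
    assert np.allclose(sums, 1.0)


def test_proportions_recover_generative_mixture(rng):
    p = np.array([0.3, 0.3, 0.2, 0.2])
    names = np.array(["caveolae", "S2", "S1B", "S1A"])
    n = 400
    df = pd.DataFrame({"cell_id": "c1",
                       "class": rng.choice(names, size=n, p=p)})
    props = class_proportions(df).set_index("cell_id").loc["c1"]
    for name, pi in zip(names, p):
        se = np.sqrt(pi * (1 - pi) / n)
        assert abs(props[name] - pi) < 4 * se
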