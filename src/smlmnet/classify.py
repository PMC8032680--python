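"""Unsupervised blob-group discovery and reference-class matching.

Blob feature vectors are z-scored, grouped by X-means (k-means with
BIC-guided recursive centroid splitting), diagnosed with silhouettes,
and each discovered group is assigned the reference class (caveolae, S2,
S1B or S1A) whose 28-feature centroid lies at the smallest Euclidean
distance in the standardized feature space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

__all__ = ["zscore_features", "xmeans_cluster", "silhouette_by_group",
           "match_groups", "class_proportions", "GroupAssignment", "ClassMap"]

SIGMA_FLOOR = 1e-12


def zscore_features(matrix: np.ndarray | pd.DataFrame
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standardize columns to mean 0, sd 1.

    Returns ``(Z, mean, std)``; the scaling parameters project reference
    centroids into the same space.  Constant columns get a floored sd.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("z-scoring needs a 2D matrix with at least 2 rows")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd < SIGMA_FLOOR, SIGMA_FLOOR, sd)
    return (X - mu) / sd, mu, sd


@dataclass
class GroupAssignment:
    """Result of X-means group discovery in z-scored feature space."""

    labels: np.ndarray
    K: int
    bic_trace: list = field(default_factory=list)  # (K, BIC) per round
    centroids: np.ndarray | None = None
    silhouette: dict | None = None


def _bic(X: np.ndarray, labels: np.ndarray, centers: np.ndarray) -> float:
    """Spherical-Gaussian identical-variance BIC of a k-means model."""
    n, d = X.shape
    K = len(centers)
    if n <= K:
        return -np.inf
    rss = float(((X - centers[labels]) ** 2).sum())
    sigma2 = max(rss / (d * (n - K)), SIGMA_FLOOR)
    counts = np.bincount(labels, minlength=K).astype(float)
    counts = counts[counts > 0]
    loglik = (float((counts * np.log(counts / n)).sum())
              - 0.5 * n * d * np.log(2.0 * np.pi * sigma2)
              - 0.5 * d * (n - K))
    n_params = (K - 1) + K * d + 1
    return loglik - 0.5 * n_params * np.log(n)


def _kmeans(X: np.ndarray, k: int, seed: int, init="k-means++", n_init=10):
    km = KMeans(n_clusters=k, init=init, n_init=n_init, random_state=seed)
    km.fit(X)
    return km.labels_, km.cluster_centers_


def xmeans_cluster(matrix: np.ndarray, kmin: int = 1, kmax: int = 10,
                   seed: int = 0) -> GroupAssignment:
    """X-means: start at ``kmin`` centroids and recursively 2-split each
    one, accepting a split iff the local BIC of the two-child model exceeds
    the parent's, until no split is accepted or ``kmax`` is reached.

    Deterministic given ``seed`` (k-means++ with 10 restarts inside).
    """
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    if not (1 <= kmin <= kmax):
        raise ValueError("require 1 <= kmin <= kmax")
    if n < kmin:
        raise ValueError(f"{n} blobs cannot support kmin={kmin}")
    kmax = min(kmax, n)
    ss = np.random.SeedSequence(seed)
    seeds = iter(ss.generate_state(10_000) % (2 ** 31))

    labels, centers = _kmeans(X, kmin, int(next(seeds)))
    trace = [(kmin, _bic(X, labels, centers))]
    while len(centers) < kmax:
        new_centers = []
        split_any = False
        for j in range(len(centers)):
            members = X[labels == j]
            if len(members) < 4 or len(centers) + (1 if split_any else 0) >= kmax:
                new_centers.append(centers[j])
                continue
            parent_bic = _bic(members, np.zeros(len(members), dtype=int),
                              members.mean(axis=0, keepdims=True))
            sub_labels, sub_centers = _kmeans(members, 2, int(next(seeds)))
            if np.unique(sub_labels).size < 2:
                new_centers.append(centers[j])
                continue
            child_bic = _bic(members, sub_labels, sub_centers)
            if child_bic > parent_bic and len(new_centers) + (
                    len(centers) - j - 1) + 2 <= kmax:
                new_centers.extend(sub_centers)
                split_any = True
            else:
                new_centers.append(centers[j])
        if not split_any:
            break
        centers = np.asarray(new_centers)
        # improve-params pass: full k-means from the refined structure
        labels, centers = _kmeans(X, len(centers), int(next(seeds)),
                                  init=centers, n_init=1)
        trace.append((len(centers), _bic(X, labels, centers)))
    K = len(centers)
    centroids = np.vstack([X[labels == j].mean(axis=0) for j in range(K)])
    return GroupAssignment(labels=labels, K=K, bic_trace=trace,
                           centroids=centroids)


def silhouette_by_group(matrix: np.ndarray, labels: np.ndarray
                        ) -> dict[int, float] | None:
    """Mean silhouette per group, in [-1, 1]; None when K < 2 (undefined)."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        return None
    s = silhouette_samples(np.asarray(matrix, dtype=float), labels)
    return {int(g): float(s[labels == g].mean()) for g in np.unique(labels)}


@dataclass
class ClassMap:
    """Group -> reference-class assignment by minimal Euclidean distance."""

    mapping: dict[int, str]
    distances: pd.DataFrame  # groups x reference classes
    ties: list = field(default_factory=list)
    many_to_one: bool = False


def match_groups(group_centroids: np.ndarray,
                 reference_centroids: pd.DataFrame) -> ClassMap:
    """Map each discovered group to the nearest reference class centroid.

    ``reference_centroids`` is indexed by class name with one feature per
    column, expressed in (or already projected into) the same standardized
    feature space as the group centroids.  Equidistant ties resolve to the
    lowest-index class with a warning; many-to-one mappings are allowed
    but flagged.
    """
    G = np.atleast_2d(np.asarray(group_centroids, dtype=float))
    R = reference_centroids.to_numpy(dtype=float)
    if G.shape[1] != R.shape[1]:
        raise ValueError(
            f"dimension mismatch: groups have {G.shape[1]} features, "
            f"reference has {R.shape[1]}")
    D = cdist(G, R)
    classes = list(reference_centroids.index)
    mapping: dict[int, str] = {}
    ties = []
    for g in range(len(G)):
        row = D[g]
        best = int(np.argmin(row))
        tied = np.flatnonzero(np.isclose(row, row[best]))
        if tied.size > 1:
            ties.append((g, [classes[t] for t in tied]))
            warnings.warn(
                f"group {g} equidistant to classes {[classes[t] for t in tied]}; "
                f"choosing {classes[best]!r}")
        mapping[g] = classes[best]
    many = len(set(mapping.values())) < len(mapping)
    if many:
        warnings.warn("many-to-one group->class mapping")
    dist_df = pd.DataFrame(D, index=range(len(G)), columns=classes)
    return ClassMap(mapping, dist_df, ties, many)


def class_proportions(assignments: pd.DataFrame,
                      class_col: str = "class",
                      cell_col: str = "cell_id") -> pd.DataFrame:
    """Per-cell fraction of blobs in each class (rows sum to 1).

    ``assignments`` needs one row per blob with cell and class columns; an
    optional ``condition`` column is carried through.
    """
    if assignments.empty:
        warnings.warn("no blobs to compute proportions from")
        return pd.DataFrame()
    keys = [cell_col]
    if "condition" in assignments.columns:
        keys = ["condition", cell_col]  # cell ids are unique per condition
    counts = (assignments.groupby(keys + [class_col], observed=True)
              .size().unstack(fill_value=0))
    props = counts.div(counts.sum(axis=1), axis=0)
    return props.reset_index()
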