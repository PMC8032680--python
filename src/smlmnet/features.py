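"""The 28-descriptor blob feature vector.

Each segmented blob is summarized by 28 named real values covering four
families:

* localization distribution — node count, per-axis extents, covariance
  eigenvalues, enclosing-ellipsoid volume and point density;
* anisotropy — the Westin linear/planar/spherical partition of the
  covariance eigenvalue triple (summing to 1) and fractional anisotropy;
* distance-to-centroid statistics;
* network features of the proximity graph at the configured radius —
  edge count, degree statistics, density, greedy-modularity community
  structure, mean clustering coefficient and characteristic path length —
  plus the convex (shrink-0) hull volume.

The registry is data-driven: the names and their order are fixed in
``FEATURE_NAMES`` so the feature set can be versioned or swapped without
touching the extraction code.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx
from scipy.spatial import cKDTree, ConvexHull, QhullError

from .preprocess import PointCloud
from .segmentation import Blob

__all__ = ["FEATURE_NAMES", "compute_features", "feature_table",
           "westin_measures", "EIGENVALUE_FLOOR"]

#: Ordered names of the 28 blob descriptors.
FEATURE_NAMES: tuple[str, ...] = (
    "n_nodes",
    "range_x", "range_y", "range_z",
    "pca_lambda1", "pca_lambda2", "pca_lambda3",
    "ellipsoid_volume",
    "point_density",
    "fractional_anisotropy",
    "linear_anisotropy",
    "planar_anisotropy",
    "spherical_anisotropy",
    "dist_centroid_mean", "dist_centroid_median",
    "dist_centroid_std", "dist_centroid_max",
    "n_edges",
    "degree_mean", "degree_median", "degree_std", "degree_max",
    "network_density",
    "modularity",
    "n_modules",
    "clustering_coeff_mean",
    "char_path_length",
    "hull_volume_s0",
)

assert len(FEATURE_NAMES) == 28

#: Floor applied to covariance eigenvalues of degenerate (coplanar or
#: collinear) blobs, in nm^2.
EIGENVALUE_FLOOR = 1e-6

#: Features that are *not* invariant under rigid rotation (axis-aligned
#: extents); everything else is rotation- and translation-invariant.
ROTATION_VARIANT = ("range_x", "range_y", "range_z")


def westin_measures(lambdas: np.ndarray) -> dict[str, float]:
    """Westin linear/planar/spherical partition and fractional anisotropy
    of a sorted (descending) eigenvalue triple."""
    l1, l2, l3 = lambdas
    total = l1 + l2 + l3
    lin = (l1 - l2) / total
    pla = 2.0 * (l2 - l3) / total
    sph = 3.0 * l3 / total
    lbar = total / 3.0
    fa = np.sqrt(1.5) * np.sqrt(((lambdas - lbar) ** 2).sum()) \
        / np.sqrt((lambdas ** 2).sum())
    return {"linear_anisotropy": float(lin), "planar_anisotropy": float(pla),
            "spherical_anisotropy": float(sph), "fractional_anisotropy": float(fa)}


def _graph_features(xyz: np.ndarray, proximity: float) -> dict[str, float]:
    n = len(xyz)
    tree = cKDTree(xyz)
    pairs = tree.query_pairs(proximity, output_type="ndarray")
    G = nx.Graph()
    G.add_nodes_from(range(n))
    G.add_edges_from(map(tuple, pairs))
    degrees = np.array([G.degree(i) for i in range(n)], dtype=float)
    n_edges = G.number_of_edges()
    density = 2.0 * n_edges / (n * (n - 1)) if n > 1 else 0.0
    if n_edges > 0:
        communities = nx.community.greedy_modularity_communities(G)
        modularity = nx.community.modularity(G, communities)
        n_modules = len(communities)
        clustering = nx.average_clustering(G)
    else:
        modularity, n_modules, clustering = 0.0, n, 0.0
    comps = max(nx.connected_components(G), key=len)
    if len(comps) > 1:
        cpl = nx.average_shortest_path_length(G.subgraph(comps))
    else:
        cpl = 0.0
    return {"n_edges": float(n_edges),
            "degree_mean": float(degrees.mean()),
            "degree_median": float(np.median(degrees)),
            "degree_std": float(degrees.std(ddof=1)) if n > 1 else 0.0,
            "degree_max": float(degrees.max()),
            "network_density": float(density),
            "modularity": float(modularity),
            "n_modules": float(n_modules),
            "clustering_coeff_mean": float(clustering),
            "char_path_length": float(cpl)}


def _hull_volume(xyz: np.ndarray) -> float:
    try:
        return float(ConvexHull(xyz).volume)
    except QhullError:
        try:
            return float(ConvexHull(xyz, qhull_options="QJ").volume)
        except QhullError:
            return 0.0


def compute_features(blob: Blob | np.ndarray, cloud: PointCloud | None = None,
                     proximity: float = 50.0) -> tuple[np.ndarray, dict]:
    """Compute the 28 descriptors of one blob.

    Parameters
    ----------
    blob : a :class:`Blob` (with ``cloud`` supplying the node coordinates)
        or directly an (n, 3) coordinate array.
    proximity : radius of the blob's proximity graph, nm.

    Returns
    -------
    (vector, flags) : the 28-vector ordered as :data:`FEATURE_NAMES`, and a
        dict of degeneracy flags (e.g. ``eigenvalue_floored``).
    """
    if isinstance(blob, Blob):
        if cloud is None:
            raise ValueError("a PointCloud is required alongside a Blob")
        xyz = cloud.xyz[blob.node_indices]
    else:
        xyz = np.asarray(blob, dtype=float)
    n = len(xyz)
    if n < 2:
        raise ValueError("a blob needs at least 2 nodes for feature extraction")
    flags: dict[str, bool] = {}
    vals: dict[str, float] = {"n_nodes": float(n)}
    rng_xyz = xyz.max(axis=0) - xyz.min(axis=0)
    vals["range_x"], vals["range_y"], vals["range_z"] = map(float, rng_xyz)
    cov = np.cov(xyz.T)
    lambdas = np.linalg.eigvalsh(cov)[::-1]
    if (lambdas < EIGENVALUE_FLOOR).any():
        flags["eigenvalue_floored"] = True
    lambdas = np.maximum(lambdas, EIGENVALUE_FLOOR)
    vals["pca_lambda1"], vals["pca_lambda2"], vals["pca_lambda3"] = map(float, lambdas)
    # ellipsoid semi-axes 2*sqrt(lambda): ~95% of a Gaussian's mass
    semi = 2.0 * np.sqrt(lambdas)
    vals["ellipsoid_volume"] = float(4.0 / 3.0 * np.pi * semi.prod())
    vals["point_density"] = float(n / vals["ellipsoid_volume"])
    vals.update(westin_measures(lambdas))
    d = np.linalg.norm(xyz - xyz.mean(axis=0), axis=1)
    vals["dist_centroid_mean"] = float(d.mean())
    vals["dist_centroid_median"] = float(np.median(d))
    vals["dist_centroid_std"] = float(d.std(ddof=1))
    vals["dist_centroid_max"] = float(d.max())
    vals.update(_graph_features(xyz, proximity))
    vals["hull_volume_s0"] = _hull_volume(xyz)
    if vals["hull_volume_s0"] == 0.0:
        flags["degenerate_hull"] = True
    vec = np.array([vals[name] for name in FEATURE_NAMES])
    return vec, flags


def feature_table(blobs: list[Blob], cloud: PointCloud,
                  proximity: float = 50.0) -> pd.DataFrame:
    """One row per blob, columns ``blob_id`` + the 28 named features."""
    rows = []
    for blob in blobs:
        vec, _ = compute_features(blob, cloud, proximity)
        rows.append([blob.blob_id, *vec])
    return pd.DataFrame(rows, columns=["blob_id", *FEATURE_NAMES])
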