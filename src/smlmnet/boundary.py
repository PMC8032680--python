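"""Shrink-factor blob boundaries, enclosed volumes and representatives.

A blob boundary is a watertight surface through a subset of the blob's own
nodes that envelops all of them.  Its tightness is set by a shrink factor
s in [0, 1]: s = 0 gives the convex hull (the most convex), s = 1 the
tightest single-region boundary still enveloping every point (the most
indented), and intermediate s interpolates monotonically.

Implementation: from the Delaunay triangulation of the points, simplices
removable without breaking single-region envelopment are exactly those
whose circumradius exceeds the critical alpha (the smallest circumradius
threshold at which the kept complex stays face-connected and covers every
input point).  Those removable simplices, ordered by descending
circumradius, form the candidate set; shrink s removes the leading
fraction s of them.  Volume is the sum of the kept simplex volumes, which
equals the signed-tetrahedron sum over the resulting surface.

Near-equal circumradii (relative difference < 1e-9) are treated as ties
and share a threshold, so symmetric configurations — e.g. the eight
corners of a cube, whose six tetrahedra share one circumsphere — are
never partially carved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay, QhullError
from scipy.stats import skew

__all__ = ["BoundaryMesh", "DegenerateGeometryError", "pca_project",
           "boundary_mesh", "boundary_2d_xy", "select_representative",
           "volume_variance"]

RADIUS_RTOL = 1e-9


class DegenerateGeometryError(ValueError):
    """The points do not span the dimension required for a boundary."""


# ---------------------------------------------------------------------------
# PCA canonical projection
# ---------------------------------------------------------------------------

def pca_project(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, dict]:
    """Centre and rotate a blob into its principal axes.

    Axes are covariance eigenvectors ordered by descending eigenvalue, so
    PC1 is the direction of highest localization variance.  Sign
    convention: each axis is oriented so the skewness of the projected
    coordinates is >= 0; at (numerical) zero skew, the axis is flipped so
    its first nonzero component is positive.

    Returns ``(projected, rotation, flags)`` with ``projected = (points -
    mean) @ rotation`` and degeneracy flags for collinear/coplanar input.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3 or len(X) < 3:
        raise ValueError("pca_project expects >= 3 points in 3D")
    centered = X - X.mean(axis=0)
    cov = centered.T @ centered / max(len(X) - 1, 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    flags = {}
    rank = int((evals > 1e-9 * max(evals[0], 1e-30)).sum())
    if rank < 3:
        flags["degenerate"] = "collinear" if rank <= 1 else "coplanar"
    proj = centered @ evecs
    for ax in range(3):
        s = skew(proj[:, ax])
        if abs(s) > 1e-9:
            sign = np.sign(s)
        else:
            nz = np.flatnonzero(np.abs(evecs[:, ax]) > 1e-12)
            sign = np.sign(evecs[nz[0], ax]) if nz.size else 1.0
        evecs[:, ax] *= sign
        proj[:, ax] *= sign
    return proj, evecs, flags


# ---------------------------------------------------------------------------
# Alpha-complex machinery (shared by 2D and 3D)
# ---------------------------------------------------------------------------

def _circumradii(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Circumradius of each d-simplex in R^d (inf for degenerate ones)."""
    d = points.shape[1]
    p0 = points[simplices[:, 0]]
    rel = points[simplices[:, 1:]] - p0[:, None, :]  # (m, d, d)
    rhs = 0.5 * np.einsum("mij,mij->mi", rel, rel)
    radii = np.full(len(simplices), np.inf)
    dets = np.abs(np.linalg.det(rel))
    scale = np.abs(rel).max(axis=(1, 2)) ** d + 1e-300
    ok = dets > 1e-12 * scale
    if ok.any():
        centers = np.linalg.solve(rel[ok], rhs[ok][..., None])[..., 0]
        radii[ok] = np.sqrt(np.einsum("mi,mi->m", centers, centers))
    # degenerate (near-flat) simplices: least-squares circumcentre, which
    # reduces to the in-plane circumcircle in the coplanar-cocircular limit
    for i in np.flatnonzero(~ok):
        center = np.linalg.lstsq(rel[i], rhs[i], rcond=None)[0]
        radii[i] = float(np.linalg.norm(center))
    bad = ~np.isfinite(radii)
    if bad.any():
        finite_max = radii[~bad].max() if (~bad).any() else 1.0
        radii[bad] = 2.0 * finite_max
    return radii


def _simplex_volumes(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    d = points.shape[1]
    rel = points[simplices[:, 1:]] - points[simplices[:, 0]][:, None, :]
    from math import factorial
    return np.abs(np.linalg.det(rel)) / factorial(d)


def _connected(neigh: np.ndarray, kept: np.ndarray) -> bool:
    """Face-connectivity of the kept simplices of a Delaunay complex."""
    idx = np.flatnonzero(kept)
    if idx.size <= 1:
        return idx.size == 1
    pos = -np.ones(len(kept), dtype=int)
    pos[idx] = np.arange(idx.size)
    nb = neigh[idx]                                  # (k, d+1)
    src = np.repeat(np.arange(idx.size), nb.shape[1])
    dst = nb.ravel()
    ok = (dst >= 0) & kept[np.clip(dst, 0, None)]
    graph = coo_matrix((np.ones(ok.sum()), (src[ok], pos[dst[ok]])),
                       shape=(idx.size, idx.size))
    n_comp, _ = connected_components(graph, directed=False)
    return n_comp == 1


def _covers_all(simplices: np.ndarray, kept: np.ndarray, n_points: int) -> bool:
    if not kept.any():
        return False
    return np.unique(simplices[kept]).size == n_points


class _AlphaComplex:
    """Delaunay triangulation with the shrink-factor removal order."""

    def __init__(self, points: np.ndarray):
        points = np.asarray(points, dtype=float)
        d = points.shape[1]
        centered = points - points.mean(axis=0)
        rank = np.linalg.matrix_rank(centered, tol=1e-9 * (np.abs(centered).max() + 1e-30))
        if rank < d:
            kind = {1: "collinear", 2: "coplanar"}.get(rank, f"rank-{rank}")
            raise DegenerateGeometryError(
                f"points are {kind}; a {d}D boundary needs full-rank input")
        try:
            self.tri = Delaunay(points)
        except QhullError as err:
            raise DegenerateGeometryError(f"triangulation failed: {err}") from err
        self.points = points
        self.simplices = self.tri.simplices
        self.neigh = self.tri.neighbors
        self.volumes = _simplex_volumes(points, self.simplices)
        radii = _circumradii(points, self.simplices)
        # cluster near-equal radii into shared threshold levels
        order = np.argsort(radii, kind="stable")
        levels = np.zeros(len(radii), dtype=int)
        level = 0
        prev = radii[order[0]]
        for i in order:
            if radii[i] - prev > RADIUS_RTOL * max(prev, 1.0):
                level += 1
                prev = radii[i]
            levels[i] = level
        self.radii = radii
        self.levels = levels
        self.alpha_crit_level = self._critical_level()
        removable = np.flatnonzero(self.levels > self.alpha_crit_level)
        key = np.lexsort((removable, -self.radii[removable]))
        self.removal_order = removable[key]

    def _critical_level(self) -> int:
        n_points = len(self.points)
        # coverage is monotone in the level: the smallest level covering
        # every vertex is max over vertices of min over incident simplices
        d1 = self.simplices.shape[1]
        vertex_min = np.full(n_points, np.iinfo(np.int64).max)
        np.minimum.at(vertex_min, self.simplices.ravel(),
                      np.repeat(self.levels, d1))
        start = int(vertex_min.max())
        for lvl in range(start, int(self.levels.max()) + 1):
            kept = self.levels <= lvl
            if (_covers_all(self.simplices, kept, n_points)
                    and _connected(self.neigh, kept)):
                return lvl
        return int(self.levels.max())  # full complex always qualifies

    def kept_at(self, s: float) -> np.ndarray:
        if not (0.0 <= s <= 1.0):
            raise ValueError("shrink factor must lie in [0, 1]")
        m = int(round(s * len(self.removal_order)))
        kept = np.ones(len(self.simplices), dtype=bool)
        kept[self.removal_order[:m]] = False
        return kept

    def boundary_facets(self, kept: np.ndarray) -> np.ndarray:
        """Facets belonging to exactly one kept simplex."""
        facets = []
        for i in np.flatnonzero(kept):
            simplex = self.simplices[i]
            for j, nb in enumerate(self.neigh[i]):
                if nb < 0 or not kept[nb]:
                    facets.append(np.delete(simplex, j))
        return (np.asarray(facets, dtype=int)
                if facets else np.zeros((0, self.points.shape[1]), dtype=int))


# ---------------------------------------------------------------------------
# 3D boundary
# ---------------------------------------------------------------------------

@dataclass
class BoundaryMesh:
    """Watertight triangle mesh through a subset of the blob's nodes."""

    shrink: float
    vertices: np.ndarray          # the input points (faces index into these)
    faces: np.ndarray             # (m, 3) triangle vertex indices
    volume: float                 # enclosed volume, nm^3
    single_region: bool = True
    flags: dict = field(default_factory=dict)


def boundary_mesh(points: np.ndarray, s: float) -> BoundaryMesh:
    """Shrink-factor boundary of a 3D point set (>= 4 non-coplanar points).

    ``s = 0`` is the convex hull; ``s = 1`` the tightest single-region
    boundary enveloping all points; volume is non-increasing in ``s``.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("boundary_mesh expects an (n, 3) array")
    if len(points) < 4:
        raise DegenerateGeometryError("a 3D boundary needs at least 4 points")
    ac = _AlphaComplex(points)
    kept = ac.kept_at(s)
    volume = float(ac.volumes[kept].sum())
    faces = ac.boundary_facets(kept)
    return BoundaryMesh(shrink=float(s), vertices=points, faces=faces,
                        volume=volume,
                        single_region=_connected(ac.neigh, kept))


@dataclass
class Boundary2D:
    shrink: float
    polygon: np.ndarray  # (m, 2) vertices ordered counter-clockwise
    area: float
    single_region: bool = True


def boundary_2d_xy(points: np.ndarray, s: float) -> Boundary2D:
    """Shrink-factor boundary of the XY projection of a point set.

    Same shrink semantics as :func:`boundary_mesh`, on 2D triangles.  The
    returned polygon is the outer boundary loop ordered counter-clockwise.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] < 2:
        raise ValueError("boundary_2d_xy expects (n, >=2) coordinates")
    pts2 = pts[:, :2]
    if len(pts2) < 3:
        raise DegenerateGeometryError("a 2D boundary needs at least 3 points")
    ac = _AlphaComplex(pts2)
    kept = ac.kept_at(s)
    area = float(ac.volumes[kept].sum())
    edges = ac.boundary_facets(kept)
    polygon = _walk_outer_loop(pts2, edges)
    return Boundary2D(shrink=float(s), polygon=polygon, area=area,
                      single_region=_connected(ac.neigh, kept))


def _walk_outer_loop(points: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Order boundary edges into loops; return the largest loop CCW."""
    if len(edges) == 0:
        return np.zeros((0, 2))
    adj: dict[int, list[int]] = {}
    for a, b in edges:
        adj.setdefault(int(a), []).append(int(b))
        adj.setdefault(int(b), []).append(int(a))
    unused = {tuple(sorted(map(int, e))) for e in map(tuple, edges)}
    loops = []
    while unused:
        a, b = next(iter(unused))
        loop = [a, b]
        unused.discard((min(a, b), max(a, b)))
        while True:
            cur, prev = loop[-1], loop[-2]
            nxt = None
            for cand in adj[cur]:
                key = (min(cur, cand), max(cur, cand))
                if cand != prev and key in unused:
                    nxt = cand
                    unused.discard(key)
                    break
            if nxt is None or nxt == loop[0]:
                break
            loop.append(nxt)
        loops.append(loop)
    loop = max(loops, key=lambda lp: abs(_signed_area(points[lp])))
    coords = points[loop]
    if _signed_area(coords) < 0:
        coords = coords[::-1]
    return coords


def _signed_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


# ---------------------------------------------------------------------------
# Representatives and volume variance
# ---------------------------------------------------------------------------

def select_representative(features_z: pd.DataFrame, n: int = 10,
                          cell_col: str = "cell_id") -> pd.DataFrame:
    """Top-n blobs per cell closest to the condition-average feature vector.

    ``features_z`` must hold z-scored feature columns (condition-wide
    scaling) plus ``blob_id`` and the cell column.  Distances are Euclidean
    to the mean of all blobs; ties break by blob_id.  Cells with fewer
    than n blobs return all of them with a warning.

    Returns a DataFrame (cell_id, blob_id, distance, rank) ordered by
    ascending distance within each cell.
    """
    feat_cols = [c for c in features_z.columns
                 if c not in (cell_col, "blob_id", "condition")]
    X = features_z[feat_cols].to_numpy(dtype=float)
    center = X.mean(axis=0)
    dist = np.linalg.norm(X - center, axis=1)
    out = features_z[[cell_col, "blob_id"]].copy()
    out["distance"] = dist
    rows = []
    for cell, grp in out.groupby(cell_col, sort=True):
        grp = grp.sort_values(["distance", "blob_id"], kind="stable")
        if len(grp) < n:
            warnings.warn(f"cell {cell!r} has only {len(grp)} blobs (< {n})")
        top = grp.head(n).copy()
        top["rank"] = np.arange(1, len(top) + 1)
        rows.append(top)
    if not rows:
        return pd.DataFrame(columns=[cell_col, "blob_id", "distance", "rank"])
    return pd.concat(rows, ignore_index=True)


def volume_variance(blob_points: dict, representatives: pd.DataFrame,
                    shrink_factors=(0.0, 0.5, 1.0),
                    class_of: dict | None = None,
                    cell_col: str = "cell_id") -> pd.DataFrame:
    """Mean and unbiased sample variance of boundary volumes.

    ``blob_points`` maps blob_id -> (n, 3) node coordinates;
    ``representatives`` is the output of :func:`select_representative`.
    One row per (cell, [class,] shrink factor); groups with < 2 blobs get
    NaN variance and a flag.
    """
    volumes = {}
    for bid in representatives["blob_id"]:
        pts = blob_points[bid]
        ac = _AlphaComplex(np.asarray(pts, dtype=float))
        volumes[bid] = {float(s): float(ac.volumes[ac.kept_at(s)].sum())
                        for s in shrink_factors}
    rows = []
    reps = representatives.copy()
    if class_of is not None:
        reps["class"] = reps["blob_id"].map(class_of)
        group_cols = [cell_col, "class"]
    else:
        group_cols = [cell_col]
    for keys, grp in reps.groupby(group_cols, sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        for s in shrink_factors:
            vols = np.array([volumes[b][float(s)] for b in grp["blob_id"]])
            row = dict(zip(group_cols, keys))
            row.update(shrink=float(s), n_blobs=len(vols),
                       mean_volume=float(vols.mean()),
                       var_volume=float(vols.var(ddof=1)) if len(vols) > 1
                       else np.nan,
                       variance_defined=len(vols) > 1)
            rows.append(row)
    return pd.DataFrame(rows)
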