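import numpy as np
import pandas as pd
import pytest
from scipy.spatial import ConvexHull
from scipy.spatial.transform import Rotation
from scipy.stats import mannwhitneyu

from smlmnet import (pca_project, boundary_mesh, boundary_2d_xy,
                     select_representative, volume_variance,
                     DegenerateGeometryError)
from smlmnet.boundary import _AlphaComplex, _covers_all, _signed_area

CUBE = np.array([[x, y, z] for x in (0, 100.0) for y in (0, 100.0)
                 for z in (0, 100.0)])


def notched_box(step=10.0):
    g = np.arange(0, 100.0 + step / 2, step)
    pts = np.array([[x, y, z] for x in g for y in g for z in g
                    if not (40 < x < 60 and z > 40)])
    true_volume = 100.0 ** 3 - 20.0 * 100.0 * 60.0
    return pts, true_volume


# ------------------------------------------------------------------- PCA

def test_pca_axes_ordered_by_variance(rng):
    pts = rng.normal(size=(200, 3)) * np.array([30.0, 10.0, 3.0])
    proj, rot, flags = pca_project(pts)
    v = proj.var(axis=0)
    assert v[0] >= v[1] >= v[2]
    assert "degenerate" not in flags
    # rotation is orthonormal and projection is centred
    assert np.allclose(rot.T @ rot, np.eye(3), atol=1e-12)
    assert np.allclose(proj.mean(axis=0), 0.0, atol=1e-9)


def test_pca_axis_aligned_is_identity_up_to_sign(rng):
    pts = rng.normal(size=(300, 3)) * np.array([50.0, 20.0, 5.0])
    _, rot, _ = pca_project(pts)
    assert np.allclose(np.abs(rot), np.eye(3), atol=0.1)


def test_pca_rotated_blob_projects_identically(rng):
    pts = rng.normal(size=(100, 3)) * np.array([40.0, 15.0, 6.0])
    p1, _, _ = pca_project(pts)
    for seed in range(3):
        R = Rotation.random(random_state=seed).as_matrix()
        p2, _, _ = pca_project(pts @ R.T)
        assert np.allclose(p1, p2, atol=1e-8)


# ------------------------------------------------------------- 3D boundary

@pytest.mark.parametrize("s", [0.0, 0.25, 0.5, 1.0])
def test_cube_volume_constant_in_s(s):
    # all six Delaunay tetrahedra of a cube share one circumsphere, so no
    # simplex is removable without the others: the hull persists at every s
    mesh = boundary_mesh(CUBE, s)
    assert mesh.volume == pytest.approx(1e6, rel=1e-9)
    assert mesh.single_region


def test_tetrahedron_is_its_own_boundary():
    tet = np.array([[0, 0, 0], [100.0, 0, 0], [0, 100.0, 0], [0, 0, 100.0]])
    for s in (0.0, 1.0):
        assert boundary_mesh(tet, s).volume == pytest.approx(1e6 / 6, rel=1e-9)


def test_notched_solid_carved_at_s1():
    pts, true_volume = notched_box()
    hull = ConvexHull(pts).volume
    v0 = boundary_mesh(pts, 0.0).volume
    v1 = boundary_mesh(pts, 1.0).volume
    assert abs(v0 - hull) / hull < 1e-6
    assert v1 < v0
    assert abs(v1 - true_volume) / true_volume < 0.10


def test_volume_monotone_and_enveloping(rng):
    for _ in range(5):
        pts = rng.normal(size=(60, 3)) * np.array([50.0, 30.0, 20.0])
        ac = _AlphaComplex(pts)
        vols = []
        for s in (0.0, 0.25, 0.5, 0.75, 1.0):
            kept = ac.kept_at(s)
            # envelopment: every input point stays a vertex of the complex
            assert _covers_all(ac.simplices, kept, len(pts))
            vols.append(ac.volumes[kept].sum())
        assert all(a >= b - 1e-9 for a, b in zip(vols, vols[1:]))
        assert vols[0] == pytest.approx(ConvexHull(pts).volume, rel=1e-6)


def test_mesh_is_watertight(rng):
    pts = rng.normal(size=(50, 3)) * 40.0
    mesh = boundary_mesh(pts, 1.0)
    edge_count = {}
    for f in mesh.faces:
        for e in ((f[0], f[1]), (f[0], f[2]), (f[1], f[2])):
            key = tuple(sorted(e))
            edge_count[key] = edge_count.get(key, 0) + 1
    assert set(edge_count.values()) == {2}


def test_degenerate_input_named():
    gx, gy = np.meshgrid(np.arange(4.0), np.arange(4.0))
    flat = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(16)])
    with pytest.raises(DegenerateGeometryError, match="coplanar"):
        boundary_mesh(flat, 0.0)
    line = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
    with pytest.raises(DegenerateGeometryError, match="collinear"):
        boundary_mesh(line, 0.0)
    with pytest.raises(ValueError):
        boundary_mesh(np.random.default_rng(0).normal(size=(10, 3)), 1.5)


# ------------------------------------------------------------- 2D boundary

def test_unit_square_area():
    sq = np.array([[0.0, 0], [1, 0], [1, 1], [0, 1]])
    b = boundary_2d_xy(sq, 0.0)
    assert b.area == pytest.approx(1.0, rel=1e-12)
    assert _signed_area(b.polygon) > 0  # counter-clockwise


def test_L_shape_area_tightens(rng):
    g = np.arange(0, 1.001, 0.1)
    pts = np.array([[x, y] for x in g for y in g if not (x > 0.5 and y > 0.5)])
    a0 = boundary_2d_xy(pts, 0.0).area
    a1 = boundary_2d_xy(pts, 1.0).area
    assert a1 <= a0
    assert abs(a1 - 0.75) / 0.75 < 0.10


def test_2d_accepts_3d_points_via_xy_projection(rng):
    pts = rng.normal(size=(40, 3)) * np.array([30.0, 20.0, 5.0])
    b = boundary_2d_xy(pts, 0.0)
    assert b.area == pytest.approx(ConvexHull(pts[:, :2]).volume, rel=1e-6)


# ------------------------------------------------- representatives, volumes

def zframe(dists, cell="c1"):
    """Blobs whose z-scored vectors sit at given distances from the mean."""
    rows = []
    for i, d in enumerate(dists):
        rows.append({"cell_id": cell, "blob_id": i, "f1": d, "f2": 0.0})
    return pd.DataFrame(rows)


def test_representative_matches_brute_force(rng):
    df = pd.DataFrame(rng.normal(size=(15, 4)),
                      columns=["f1", "f2", "f3", "f4"])
    df["cell_id"] = "c1"
    df["blob_id"] = np.arange(15)
    reps = select_representative(df, n=5)
    X = df[["f1", "f2", "f3", "f4"]].to_numpy()
    d = np.linalg.norm(X - X.mean(axis=0), axis=1)
    expected = np.argsort(d, kind="stable")[:5]
    assert list(reps["blob_id"]) == list(expected)
    assert list(reps["rank"]) == [1, 2, 3, 4, 5]


def test_representative_ties_break_by_blob_id():
    df = zframe([1.0] * 6)
    reps = select_representative(df, n=3)
    assert list(reps["blob_id"]) == [0, 1, 2]


def test_representative_small_cell_warns_and_n0():
    df = zframe([0.1, 0.2])
    with pytest.warns(UserWarning, match="only 2 blobs"):
        reps = select_representative(df, n=10)
    assert len(reps) == 2
    assert select_representative(df, n=0).empty


def test_volume_variance_closed_form():
    tet = np.array([[0, 0, 0], [100.0, 0, 0], [0, 100.0, 0], [0, 0, 100.0]])
    pts = {0: tet, 1: tet * 2.0}
    reps = pd.DataFrame({"cell_id": ["c1", "c1"], "blob_id": [0, 1],
                         "distance": [0.0, 0.0], "rank": [1, 2]})
    out = volume_variance(pts, reps, shrink_factors=(0.0,))
    v1, v2 = 1e6 / 6, 8e6 / 6
    m = (v1 + v2) / 2
    row = out.iloc[0]
    assert row["mean_volume"] == pytest.approx(m, rel=1e-9)
    assert row["var_volume"] == pytest.approx((v1 - m) ** 2 + (v2 - m) ** 2,
                                              rel=1e-9)


def test_volume_variance_identical_blobs_zero():
    tet = np.array([[0, 0, 0], [100.0, 0, 0], [0, 100.0, 0], [0, 0, 100.0]])
    reps = pd.DataFrame({"cell_id": "c1", "blob_id": [0, 1],
                         "distance": 0.0, "rank": [1, 2]})
    out = volume_variance({0: tet, 1: tet.copy()}, reps,
                          shrink_factors=(0.0, 0.5, 1.0))
    assert np.allclose(out["var_volume"], 0.0)


def test_single_blob_variance_flagged():
    tet = np.array([[0, 0, 0], [100.0, 0, 0], [0, 100.0, 0], [0, 0, 100.0]])
    reps = pd.DataFrame({"cell_id": "c1", "blob_id": [0],
                         "distance": [0.0], "rank": [1]})
    out = volume_variance({0: tet}, reps, shrink_factors=(0.0,))
    assert not out["variance_defined"].iloc[0]
    assert np.isnan(out["var_volume"].iloc[0])


def _cell_blob(rng, protrude):
    """One synthetic blob: a 60 nm shell, optionally with a loose outer layer."""
    n = 50
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1)[:, None]
    r = np.full(n, 60.0)
    if protrude:
        k = rng.uniform(size=n) < 0.3
        r[k] += rng.uniform(0, 50.0, size=k.sum())
    else:
        r *= 0.8
    return v * r[:, None] + rng.normal(0, 5.0, size=(n, 3))


def test_indented_blobs_have_higher_tight_volume_variance():
    """Blobs with protruding outer layers vary more in tight-boundary
    volume than compact blobs (the qualitative WT vs mutant effect)."""
    rng = np.random.default_rng(42)
    wt_vars, mut_vars = [], []
    for _ in range(20):
        for protrude, acc in ((True, wt_vars), (False, mut_vars)):
            vols = [boundary_mesh(_cell_blob(rng, protrude), 1.0).volume
                    for _ in range(8)]
            acc.append(np.var(vols, ddof=1))
    stat = mannwhitneyu(wt_vars, mut_vars, alternative="greater")
    assert stat.pvalue < 0.05
    assert np.median(wt_vars) > np.median(mut_vars)
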