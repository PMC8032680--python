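import numpy as np
import pytest
from scipy.spatial.distance import pdist

from smlmnet import (EventList, correct_drift, iterative_merge, denoise_filter,
                     DriftCorrectionError, PointCloud, simulate_cell)
from smlmnet.simulate import recovery_spec
from dataclasses import replace


def _events(xyz, frames=None):
    xyz = np.asarray(xyz, dtype=float)
    if frames is None:
        frames = np.arange(len(xyz))
    return EventList(np.asarray(frames), xyz)


@pytest.mark.parametrize("points,threshold,expected_nodes,expected_xyz", [
    # two events 10 nm apart merge to their midpoint with weight 2
    ([[0, 0, 0], [10, 0, 0]], 20.0, 1, [[5, 0, 0]]),
    # 25 nm apart at a 20 nm threshold: unchanged
    ([[0, 0, 0], [25, 0, 0]], 20.0, 2, [[0, 0, 0], [25, 0, 0]]),
    # five collinear events spaced 15 nm chain into one node at the centre
    ([[0, 0, 0], [15, 0, 0], [30, 0, 0], [45, 0, 0], [60, 0, 0]],
     20.0, 1, [[30, 0, 0]]),
    # distance exactly at the threshold counts as an edge (closed rule)
    ([[0, 0, 0], [20, 0, 0]], 20.0, 1, [[10, 0, 0]]),
])
def test_merge_small_cases(points, threshold, expected_nodes, expected_xyz):
    cloud = iterative_merge(_events(points), threshold)
    assert len(cloud) == expected_nodes
    got = cloud.xyz[np.lexsort(cloud.xyz.T)]
    assert np.allclose(got, np.asarray(expected_xyz, dtype=float))
    assert cloud.weights.sum() == len(points)
    assert cloud.meta["merge_iterations"] <= 3


def test_merge_invariants_on_simulated_cell(small_spec):
    ev, _, _ = simulate_cell(small_spec, seed=3)
    cloud = iterative_merge(ev, 20.0)
    # mass conservation
    assert cloud.weights.sum() == len(ev)
    # post-merge minimum pairwise distance exceeds the threshold
    assert pdist(cloud.xyz).min() > 20.0
    # idempotence: merging the merged nodes changes nothing
    again = iterative_merge(cloud.xyz, 20.0)
    assert len(again) == len(cloud)
    assert np.allclose(again.xyz, cloud.xyz)
    # provenance maps every event to a node
    assert cloud.source.shape == (len(ev),)
    assert np.all(cloud.source >= 0) and cloud.source.max() == len(cloud) - 1


def test_merge_empty_input():
    cloud = iterative_merge(np.zeros((0, 3)), 20.0)
    assert len(cloud) == 0


def test_molecule_count_recovery_seed_exact():
    """With molecules >= threshold + blink spread apart and sigma <=
    threshold/4, merging recovers the exact molecule count in >= 95% of
    seeds."""
    spec = replace(recovery_spec(), sigma_lateral_nm=3.0, sigma_axial_nm=3.0)
    hits = 0
    for seed in range(20):
        ev, _, mol = simulate_cell(spec, seed=seed)
        cloud = iterative_merge(ev, 20.0)
        hits += len(cloud) == len(mol)
    assert hits >= 19


def test_denoise_separates_cluster_from_background():
    retained_cluster, retained_bg = [], []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        cluster = rng.normal(size=(100, 3))
        cluster = 50.0 * cluster / np.linalg.norm(cluster, axis=1)[:, None] \
            * rng.uniform(0, 1, size=(100, 1)) ** (1 / 3) + 2000.0
        bg = rng.uniform(0, 4000.0, size=(20, 3))
        xyz = np.vstack([cluster, bg])
        cloud = PointCloud(xyz, np.ones(len(xyz)),
                           meta={"roi": np.array([[0.0] * 3, [4000.0] * 3])})
        out = denoise_filter(cloud, proximity=50.0, null_reps=10,
                             retain_quantile=0.95, rng=rng)
        kept = set(out.meta["kept_indices"].tolist())
        retained_cluster.append(np.mean([i in kept for i in range(100)]))
        retained_bg.append(np.mean([100 + i in kept for i in range(20)]))
    assert np.mean(retained_cluster) >= 0.90
    assert 1.0 - np.mean(retained_bg) >= 0.90


def test_denoise_self_null_retention_matches_quantile():
    """A uniform cloud filtered against its own null keeps roughly the
    (1 - retain_quantile) tail of the degree distribution."""
    fracs = []
    for seed in range(5):
        rng = np.random.default_rng(seed)
        xyz = rng.uniform(0, 1000.0, size=(1000, 3))
        cloud = PointCloud(xyz, np.ones(1000),
                           meta={"roi": np.array([[0.0] * 3, [1000.0] * 3])})
        out = denoise_filter(cloud, proximity=170.0, null_reps=10,
                             retain_quantile=0.95, rng=rng)
        fracs.append(out.meta["denoise_retained_fraction"])
    assert 0.01 <= np.mean(fracs) <= 0.10


def test_denoise_never_invents_nodes(rng):
    xyz = rng.uniform(0, 500.0, size=(50, 3))
    cloud = PointCloud(xyz, np.ones(50))
    out = denoise_filter(cloud, proximity=100.0, rng=rng)
    # every retained node is one of the input nodes
    in_rows = {tuple(r) for r in xyz}
    assert all(tuple(r) in in_rows for r in out.xyz)


def test_denoise_tiny_cloud_passthrough():
    cloud = PointCloud(np.zeros((1, 3)), np.ones(1))
    with pytest.warns(UserWarning):
        out = denoise_filter(cloud, proximity=50.0)
    assert out is cloud


def test_drift_zero_is_identity(small_spec):
    spec = replace(small_spec, n_fiducials=2, n_frames=500)
    ev, fid, _ = simulate_cell(spec, seed=1)
    out = correct_drift(ev, fid)
    assert np.allclose(out.xyz, ev.xyz, atol=1e-9)
    assert out.meta["drift_rms_nm"] < 1e-9


def test_drift_linear_recovered_within_5pct(small_spec):
    spec = replace(small_spec, n_fiducials=3, n_frames=1000,
                   drift_nm_per_frame=(0.5, 0.0, 0.0),
                   sigma_lateral_nm=10.0)
    ev, fid, _ = simulate_cell(spec, seed=2)
    out = correct_drift(ev, fid)
    # recovered displacement = raw - corrected; regress its x on frame
    est = ev.xyz - out.xyz
    slope = np.polyfit(ev.frame, est[:, 0], 1)[0]
    assert abs(slope - 0.5) / 0.5 < 0.05
    assert out.meta["n_fiducial_tracks"] >= 1


def test_drift_single_frame_unchanged():
    ev = _events([[0, 0, 0], [100, 0, 0]], frames=[5, 5])
    fid = _events([[500, 500, 0], [500, 500, 0]], frames=[0, 1])
    out = correct_drift(ev, fid)
    assert np.array_equal(out.xyz, ev.xyz)


def test_drift_requires_fiducials():
    ev = _events([[0, 0, 0]])
    with pytest.raises(DriftCorrectionError, match="no-drift-correction"):
        correct_drift(ev, None)
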