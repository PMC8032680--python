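"""End-to-end orchestration: event lists in, summary tables out.

``run_pipeline`` drives every stage for a set of cells grouped by
condition: drift correction (when fiducials are provided), 20 nm
iterative blink merging, network denoising, mean-shift segmentation,
28-feature extraction, per-condition X-means grouping with reference
class matching, per-cell class proportions, shrink-factor boundary
volumes of the representative blobs, and Welch comparisons between
conditions.  Outputs are deterministic functions of (inputs, config,
seed).
"""

from __future__ import annotations

import logging
import os
import sys
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .io import EventList, read_eventlist
from .preprocess import correct_drift, iterative_merge, denoise_filter, PointCloud
from .segmentation import Blob, mean_shift_segment
from .features import FEATURE_NAMES, feature_table
from .classify import (zscore_features, xmeans_cluster, silhouette_by_group,
                       match_groups, class_proportions)
from .boundary import select_representative, volume_variance
from .stats import per_cell_means, compare_conditions
from .simulate import SimulationSpec, simulate_cell

__all__ = ["PipelineError", "CellResult", "process_cell", "run_pipeline",
           "majority_truth_class", "reference_from_simulation",
           "OUTPUT_TABLES"]

log = logging.getLogger(__name__)

OUTPUT_TABLES = ("blobs.tsv", "features.tsv", "assignments.tsv",
                 "proportions.tsv", "boundary_volumes.tsv", "comparison.tsv")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cell."""


@dataclass
class CellResult:
    condition: str
    cell_id: str
    cloud: PointCloud
    blobs: list
    labels: np.ndarray
    features: pd.DataFrame  # blob_id + 28 feature columns


def process_cell(events: EventList, config: PipelineConfig,
                 fiducials: EventList | None = None,
                 rng: np.random.Generator | None = None,
                 condition: str = "", cell_id: str = "") -> CellResult:
    """Run preprocessing, segmentation and feature extraction on one cell."""
    stage = "drift"
    try:
        if fiducials is not None and config.drift_correction:
            events = correct_drift(events, fiducials,
                                   window=config.drift_window_frames)
        stage = "merge"
        cloud = iterative_merge(events, config.merge_threshold_nm)
        stage = "denoise"
        cloud = denoise_filter(cloud, config.network_proximity_nm,
                               config.null_reps, config.retain_quantile,
                               rng=rng)
        stage = "segment"
        blobs, labels = mean_shift_segment(cloud, config.meanshift_bandwidth_nm,
                                           config.min_blob_size)
        stage = "features"
        feats = feature_table(blobs, cloud, config.network_proximity_nm)
    except Exception as err:
        raise PipelineError(
            f"stage {stage!r} failed for cell {cell_id!r} "
            f"(condition {condition!r}): {err}") from err
    return CellResult(condition, cell_id, cloud, blobs, labels, feats)


def _blob_uid(condition: str, cell_id: str, local_id: int) -> str:
    return f"{condition}|{cell_id}|{local_id}"


def majority_truth_class(result: CellResult, event_blob_labels: np.ndarray,
                         blob_classes: dict[int, str]) -> dict[str, str]:
    """Ground-truth class of each segmented blob by majority vote over the
    generative blob labels of its merged events (0 -> 'background').

    Requires the cell to have been processed with event->node provenance
    (``cloud.source``), as produced by the standard pipeline.
    """
    source = result.cloud.source
    if source is None:
        raise ValueError("point cloud lacks event->node provenance")
    out: dict[str, str] = {}
    for blob in result.blobs:
        node_set = set(blob.node_indices.tolist())
        ev = np.flatnonzero(np.isin(source, list(node_set)))
        truth = event_blob_labels[ev]
        vals, counts = np.unique(truth, return_counts=True)
        winner = int(vals[np.argmax(counts)])
        out[_blob_uid(result.condition, result.cell_id, blob.blob_id)] = (
            "background" if winner == 0 else blob_classes[winner])
    return out


def _classify_condition(features: pd.DataFrame, config: PipelineConfig,
                        reference: pd.DataFrame | None, seed: int):
    """X-means + reference matching for one condition's feature matrix."""
    X = features[list(FEATURE_NAMES)].to_numpy(dtype=float)
    Z, mu, sd = zscore_features(X)
    ga = xmeans_cluster(Z, config.kmin, config.kmax, seed=seed)
    ga.silhouette = silhouette_by_group(Z, ga.labels)
    if reference is not None:
        ref_z = (reference[list(FEATURE_NAMES)].to_numpy(dtype=float) - mu) / sd
        ref_df = pd.DataFrame(ref_z, index=reference.index,
                              columns=list(FEATURE_NAMES))
        cmap = match_groups(ga.centroids, ref_df)
        classes = np.array([cmap.mapping[g] for g in ga.labels])
    else:
        cmap = None
        classes = np.array([f"group{g}" for g in ga.labels])
    zdf = pd.DataFrame(Z, columns=list(FEATURE_NAMES), index=features.index)
    return ga, cmap, classes, zdf


def run_pipeline(config: PipelineConfig, manifest: pd.DataFrame,
                 outdir: str | os.PathLike,
                 reference: pd.DataFrame | None = None,
                 dialect: dict | None = None) -> dict[str, pd.DataFrame]:
    """Run the full analysis over a manifest of event-list files.

    ``manifest`` needs columns condition, cell_id, path and optionally
    fiducial_path.  Writes the six output tables to ``outdir`` and returns
    them as DataFrames keyed by file name.
    """
    config.validate()
    os.makedirs(outdir, exist_ok=True)
    handler = logging.FileHandler(os.path.join(outdir, "run.log"), mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("smlmnet")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    if not any(isinstance(h, logging.StreamHandler) and h.stream is sys.stderr
               for h in root.handlers):
        root.addHandler(logging.StreamHandler(sys.stderr))
    log.info("resolved config: %s", config.to_dict())
    try:
        return _run(config, manifest, outdir, reference, dialect)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config, manifest, outdir, reference, dialect):
    manifest = manifest.sort_values(["condition", "cell_id"]).reset_index(drop=True)
    if manifest.empty:
        raise PipelineError("manifest is empty")
    results: list[CellResult] = []
    blob_rows, feat_rows = [], []
    blob_points: dict[str, np.ndarray] = {}
    for i, row in manifest.iterrows():
        cond, cell = str(row["condition"]), str(row["cell_id"])
        try:
            events = read_eventlist(row["path"], dialect)
            fid = None
            fp = row.get("fiducial_path")
            if isinstance(fp, str) and fp:
                fid = read_eventlist(fp, dialect)
        except Exception as err:
            raise PipelineError(
                f"stage 'read' failed for cell {cell!r} "
                f"(condition {cond!r}): {err}") from err
        rng = np.random.default_rng([config.random_seed, i])
        res = process_cell(events, config, fid, rng, cond, cell)
        log.info("cell %s/%s: %d events -> %d nodes -> %d blobs",
                 cond, cell, len(events), len(res.cloud), len(res.blobs))
        results.append(res)
        for blob in res.blobs:
            uid = _blob_uid(cond, cell, blob.blob_id)
            blob_rows.append({"blob_id": uid, "condition": cond,
                              "cell_id": cell, "n_nodes": blob.n_nodes,
                              "centroid_x": blob.centroid[0],
                              "centroid_y": blob.centroid[1],
                              "centroid_z": blob.centroid[2]})
            blob_points[uid] = res.cloud.xyz[blob.node_indices]
        feats = res.features.copy()
        feats.insert(0, "cell_id", cell)
        feats.insert(0, "condition", cond)
        feats["blob_id"] = [_blob_uid(cond, cell, b) for b in feats["blob_id"]]
        feat_rows.append(feats)

    blobs_df = pd.DataFrame(blob_rows)
    features_df = (pd.concat(feat_rows, ignore_index=True)
                   if feat_rows else pd.DataFrame())
    if features_df.empty or len(features_df) < 2:
        raise PipelineError("too few blobs segmented to analyse")

    # --- grouping, matching, representatives per condition ---------------
    assign_rows, rep_rows, vol_rows = [], [], []
    if config.cluster_per_condition:
        cond_groups = list(features_df.groupby("condition", sort=True))
    else:
        cond_groups = [("all", features_df)]
    for cond, feats in cond_groups:
        ga, cmap, classes, zdf = _classify_condition(
            feats, config, reference, seed=config.random_seed)
        log.info("condition %s: K=%d groups, BIC trace %s", cond, ga.K,
                 ga.bic_trace)
        block = feats[["blob_id", "condition", "cell_id"]].copy()
        block["group"] = ga.labels
        block["class"] = classes
        sil = ga.silhouette or {}
        block["group_silhouette"] = [sil.get(int(g), np.nan) for g in ga.labels]
        if cmap is not None:
            block["match_distance"] = [
                cmap.distances.loc[g, c]
                for g, c in zip(ga.labels, classes)]
        assign_rows.append(block)
        zrep = zdf.copy()
        zrep["blob_id"] = feats["blob_id"].to_numpy()
        zrep["cell_id"] = feats["cell_id"].to_numpy()
        reps = select_representative(zrep, config.top_n_representative)
        reps.insert(0, "condition", cond)
        rep_rows.append(reps)
        class_of = dict(zip(block["blob_id"], block["class"]))
        if not reps.empty:
            vols = volume_variance(blob_points, reps, config.shrink_factors,
                                   class_of=class_of)
            vols.insert(0, "condition", cond)
            vol_rows.append(vols)

    assignments_df = pd.concat(assign_rows, ignore_index=True)
    volumes_df = (pd.concat(vol_rows, ignore_index=True)
                  if vol_rows else pd.DataFrame())
    proportions_df = class_proportions(assignments_df)

    # --- condition comparison (cell is the experimental unit) ------------
    merged = features_df.merge(assignments_df[["blob_id", "class"]], on="blob_id")
    comparison_df = pd.DataFrame()
    n_cond = merged["condition"].nunique()
    cells_per_cond = merged.groupby("condition")["cell_id"].nunique()
    if n_cond == 2 and (cells_per_cond >= 2).all():
        cm_global = per_cell_means(merged)
        cm_class = per_cell_means(merged, by_class=True)
        by_class = compare_conditions(cm_class)
        by_class = by_class[by_class["scope"] != "global"]
        comparison_df = pd.concat([compare_conditions(cm_global), by_class],
                                  ignore_index=True)
    else:
        log.info("skipping condition comparison (need 2 conditions with "
                 ">= 2 cells each; have %s)", cells_per_cond.to_dict())

    tables = {"blobs.tsv": blobs_df, "features.tsv": features_df,
              "assignments.tsv": assignments_df,
              "proportions.tsv": proportions_df,
              "boundary_volumes.tsv": volumes_df,
              "comparison.tsv": comparison_df}
    for name, df in tables.items():
        df.to_csv(os.path.join(outdir, name), sep="\t", index=False)
    return tables


def reference_from_simulation(spec: SimulationSpec, config: PipelineConfig,
                              n_cells: int = 3, seed: int = 0) -> pd.DataFrame:
    """Reference class centroids from a labelled synthetic calibration scene.

    Simulates ``n_cells`` cells, runs them through preprocessing,
    segmentation and feature extraction, assigns each segmented blob its
    majority ground-truth class, and returns per-class mean feature
    vectors (raw feature space, one row per class).
    """
    frames = []
    for c in range(n_cells):
        events, fid, truth = simulate_cell(spec, seed=seed + c)
        rng = np.random.default_rng([seed, c])
        res = process_cell(events, config, fid, rng, "calibration", f"cal{c}")
        classes = majority_truth_class(
            res, events.meta["blob_label"], truth.blob_classes)
        feats = res.features.copy()
        feats["class"] = [
            classes[_blob_uid("calibration", f"cal{c}", b)]
            for b in feats["blob_id"]]
        frames.append(feats[feats["class"] != "background"])
    allf = pd.concat(frames, ignore_index=True)
    ref = allf.groupby("class")[list(FEATURE_NAMES)].mean()
    ref.index.name = "class"
    return ref
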