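"""Tabular I/O for SMLM event lists and pipeline manifests.

The event list is the raw product of an SMLM acquisition: one row per
localization with its camera frame index, 3D position and (optionally)
photon count.  Vendor exports differ only in column naming and units, so
reading goes through a small *dialect* mapping instead of hard-coding any
vendor schema.  All internal coordinates are nanometres.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EventList",
    "EventListFormatError",
    "EventListParseError",
    "DEFAULT_DIALECT",
    "read_eventlist",
    "write_eventlist",
    "read_manifest",
]


class EventListFormatError(ValueError):
    """A required column is missing from an event-list file."""


class EventListParseError(ValueError):
    """A cell in an event-list file could not be parsed as a number."""


#: Default column mapping: logical field -> file header.  ``scale`` converts
#: file coordinate units to nm (1.0 = file already in nm); ``sep`` is the
#: field delimiter.
DEFAULT_DIALECT = {
    "frame": "frame",
    "x": "x[nm]",
    "y": "y[nm]",
    "z": "z[nm]",
    "intensity": "intensity",
    "scale": 1.0,
    "sep": "\t",
}


@dataclass
class EventList:
    """Per-frame localizations with coordinates in nm.

    Attributes
    ----------
    frame : (n,) int array of camera frame indices.
    xyz : (n, 3) float array of positions in nm.
    intensity : optional (n,) float array of photon-count units.
    meta : free-form provenance (source file, drift-corrected flag, ...).
    """

    frame: np.ndarray
    xyz: np.ndarray
    intensity: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frame = np.asarray(self.frame, dtype=np.int64)
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must be an (n, 3) array")
        if self.frame.shape[0] != self.xyz.shape[0]:
            raise ValueError("frame and xyz lengths differ")
        if self.intensity is not None:
            self.intensity = np.asarray(self.intensity, dtype=float)
        if len(self) and not np.isfinite(self.xyz).all():
            raise ValueError("coordinates must be finite")
        if len(self) and (self.frame < 0).any():
            raise ValueError("frame indices must be non-negative")

    def __len__(self) -> int:
        return self.xyz.shape[0]

    @property
    def roi(self) -> np.ndarray:
        """Axis-aligned bounding box, shape (2, 3): [min; max] per axis."""
        if "roi" in self.meta:
            return np.asarray(self.meta["roi"], dtype=float)
        if len(self) == 0:
            return np.zeros((2, 3))
        return np.vstack([self.xyz.min(axis=0), self.xyz.max(axis=0)])

    def sorted_by_frame(self) -> "EventList":
        order = np.argsort(self.frame, kind="stable")
        return EventList(
            self.frame[order],
            self.xyz[order],
            None if self.intensity is None else self.intensity[order],
            dict(self.meta),
        )


def _dialect(dialect: dict | None) -> dict:
    d = dict(DEFAULT_DIALECT)
    if dialect:
        d.update(dialect)
    return d


def read_eventlist(path: str | os.PathLike, dialect: dict | None = None) -> EventList:
    """Read a delimited-text event list.

    Parameters
    ----------
    path : file path.
    dialect : optional column-mapping overrides (see :data:`DEFAULT_DIALECT`).

    Raises
    ------
    EventListFormatError
        if a required column (frame, x, y, z) is absent.
    EventListParseError
        if a coordinate cell is not numeric; the message cites the 1-based
        data-row number of the first offending cell.
    """
    d = _dialect(dialect)
    df = pd.read_csv(path, sep=d["sep"], float_precision="round_trip")
    for key in ("frame", "x", "y", "z"):
        if d[key] not in df.columns:
            raise EventListFormatError(
                f"event list {path!s} is missing required column {d[key]!r} "
                f"(mapped from {key!r})"
            )
    cols = {}
    for key in ("frame", "x", "y", "z"):
        raw = df[d[key]]
        num = pd.to_numeric(raw, errors="coerce")
        bad = num.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise EventListParseError(
                f"non-numeric value {raw.iloc[row - 1]!r} in column {d[key]!r} "
                f"at row {row} of {path!s}"
            )
        cols[key] = num.to_numpy()
    scale = float(d["scale"])
    xyz = np.column_stack([cols["x"], cols["y"], cols["z"]]) * scale
    intensity = None
    if d.get("intensity") and d["intensity"] in df.columns:
        intensity = pd.to_numeric(df[d["intensity"]], errors="coerce").to_numpy()
    return EventList(cols["frame"].astype(np.int64), xyz, intensity,
                     meta={"source": str(path)})


def write_eventlist(events: EventList, path: str | os.PathLike,
                    dialect: dict | None = None) -> str:
    """Write an event list as headered delimited text (full float precision,
    so a read/write roundtrip reproduces the records exactly)."""
    d = _dialect(dialect)
    data = {d["frame"]: events.frame,
            d["x"]: events.xyz[:, 0],
            d["y"]: events.xyz[:, 1],
            d["z"]: events.xyz[:, 2]}
    if events.intensity is not None:
        data[d["intensity"]] = events.intensity
    pd.DataFrame(data).to_csv(path, sep=d["sep"], index=False)
    return str(path)


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    """Read a pipeline manifest: one row per cell with columns
    ``condition``, ``cell_id``, ``path`` and optional ``fiducial_path``.
    Relative paths are resolved against the manifest's directory."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("condition", "cell_id", "path"):
        if col not in df.columns:
            raise EventListFormatError(f"manifest {path!s} is missing column {col!r}")
    base = os.path.dirname(os.path.abspath(path))

    def resolve(p):
        if isinstance(p, str) and p and not os.path.isabs(p):
            return os.path.join(base, p)
        return p

    df["path"] = df["path"].map(resolve)
    if "fiducial_path" in df.columns:
        df["fiducial_path"] = df["fiducial_path"].map(resolve)
    return df
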