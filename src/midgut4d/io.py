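"""Readers and writers for movie stacks, track tables and annotations.

Conventions
-----------
Coordinates live in a right-handed physical space measured in µm, with
x-y the image plane and z the optical axis.  Frame indices are 0-based;
times are minutes from movie start.  Tabular data are comma-separated
UTF-8 CSV with a header row and "." decimals.

Track table schema (one row per living cell per frame)::

    movie_id, cell_id, frame, t_min, x_um, y_um, z_um, volume_um3,
    cfp_raw, gfp_raw, rfp_raw[, label]

Ring tables hold one row per ring vertex per frame
(``movie_id, event_id, frame, t_min, vertex_index, x_um, y_um, z_um``);
plane tables are identical but with ``point_index`` (three basal reference
points per frame).  Image stacks are ImageJ-compatible TIFF with the voxel
size recorded in the file metadata; in memory stacks are canonical
``(t, c, z, y, x)`` arrays.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "MovieMeta",
    "NucleusTrack",
    "TRACK_COLUMNS",
    "read_tracks",
    "write_tracks",
    "tracks_from_table",
    "read_rings",
    "write_rings",
    "read_planes",
    "write_planes",
    "read_volume",
    "write_volume",
    "load_config",
    "write_json",
    "read_json",
    "get_logger",
]

TRACK_COLUMNS = [
    "movie_id",
    "cell_id",
    "frame",
    "t_min",
    "x_um",
    "y_um",
    "z_um",
    "volume_um3",
    "cfp_raw",
    "gfp_raw",
    "rfp_raw",
]

_log = logging.getLogger("midgut4d")


def get_logger() -> logging.Logger:
    return _log


@dataclass(frozen=True)
class MovieMeta:
    """Acquisition metadata of one movie."""

    movie_id: str
    frame_interval: float           # minutes
    n_frames: int
    voxel_size: tuple = (1.0, 1.0, 1.0)  # (z, y, x) µm
    channel_names: tuple = ("cfp", "gfp", "rfp")

    @property
    def duration_min(self) -> float:
        return self.frame_interval * self.n_frames

    @property
    def duration_hr(self) -> float:
        return self.duration_min / 60.0

    def __post_init__(self):
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")


@dataclass
class NucleusTrack:
    """One cell's per-frame centroid, volume and raw channel intensities."""

    cell_id: int
    movie_id: str
    frames: np.ndarray
    t_min: np.ndarray
    centroids: np.ndarray            # (n, 3) x, y, z in µm
    volumes: np.ndarray              # µm³
    intensities: dict = field(default_factory=dict)  # channel -> (n,) raw
    label: str | None = None

    @property
    def first_frame(self) -> int:
        return int(self.frames[0])

    @property
    def last_frame(self) -> int:
        return int(self.frames[-1])

    @property
    def has_gaps(self) -> bool:
        return bool(np.any(np.diff(self.frames) != 1))


# ---------------------------------------------------------------------------
# Track tables
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, columns, what: str):
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing required column(s): {missing}")


def read_tracks(path) -> tuple[list[NucleusTrack], MovieMeta]:
    """Read a track CSV into per-cell tracks plus inferred movie metadata.

    Rows are grouped by ``cell_id`` and sorted by ``frame``.  Duplicate
    (cell_id, frame) rows raise; gaps between a track's first and last
    frame are permitted but logged.
    """
    df = pd.read_csv(path)
    return tracks_from_table(df)


def tracks_from_table(df: pd.DataFrame) -> tuple[list[NucleusTrack], MovieMeta]:
    """Build :class:`NucleusTrack` objects from an in-memory track table."""
    _require_columns(df, TRACK_COLUMNS, "track table")
    dup = df.duplicated(subset=["movie_id", "cell_id", "frame"])
    if dup.any():
        key = df.loc[dup.idxmax(), ["movie_id", "cell_id", "frame"]].tolist()
        raise ValueError(f"duplicated (cell_id, frame) row: {key}")

    movie_ids = df["movie_id"].unique()
    movie_id = str(movie_ids[0]) if len(movie_ids) == 1 else "multi"
    frames = np.sort(df["frame"].unique())
    times = df.sort_values("frame")["t_min"].to_numpy(dtype=float)
    interval = float(np.median(np.diff(np.unique(df["t_min"])))) if len(frames) > 1 else 1.0

    tracks = []
    for (mid, cid), grp in df.groupby(["movie_id", "cell_id"], sort=True):
        grp = grp.sort_values("frame")
        fr = grp["frame"].to_numpy(dtype=int)
        if np.any(np.diff(fr) <= 0):
            raise ValueError(f"non-monotonic frames for cell {cid}")
        track = NucleusTrack(
            cell_id=int(cid),
            movie_id=str(mid),
            frames=fr,
            t_min=grp["t_min"].to_numpy(dtype=float),
            centroids=grp[["x_um", "y_um", "z_um"]].to_numpy(dtype=float),
            volumes=grp["volume_um3"].to_numpy(dtype=float),
            intensities={
                ch: grp[f"{ch}_raw"].to_numpy(dtype=float)
                for ch in ("cfp", "gfp", "rfp")
            },
            label=(str(grp["label"].iloc[0]) if "label" in grp.columns else None),
        )
        if track.has_gaps:
            _log.warning("track %s has missing frames", cid)
        tracks.append(track)

    meta = MovieMeta(
        movie_id=movie_id,
        frame_interval=interval,
        n_frames=int(frames.max()) + 1 if len(frames) else 0,
    )
    return tracks, meta


def write_tracks(df: pd.DataFrame, path) -> None:
    """Write a track table CSV (schema-checked, stable column order)."""
    _require_columns(df, TRACK_COLUMNS, "track table")
    cols = TRACK_COLUMNS + [c for c in df.columns if c not in TRACK_COLUMNS]
    df[cols].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Ring and plane annotation tables
# ---------------------------------------------------------------------------

def _read_point_table(path, index_col: str) -> dict:
    df = pd.read_csv(path)
    _require_columns(
        df,
        ["movie_id", "event_id", "frame", "t_min", index_col, "x_um", "y_um", "z_um"],
        "annotation table",
    )
    events = {}
    for eid, grp in df.groupby("event_id", sort=True):
        frames = np.sort(grp["frame"].unique())
        t_min = np.array(
            [grp.loc[grp["frame"] == f, "t_min"].iloc[0] for f in frames], dtype=float
        )
        n_pts = int(grp[index_col].max()) + 1
        pts = np.full((len(frames), n_pts, 3), np.nan)
        for (f, k), row in grp.set_index(["frame", index_col]).iterrows():
            fi = int(np.searchsorted(frames, f))
            pts[fi, int(k)] = [row["x_um"], row["y_um"], row["z_um"]]
        if np.isnan(pts).any():
            raise ValueError(f"event {eid}: missing vertex rows")
        events[eid] = {"frames": frames, "t_min": t_min, "points": pts}
    return events


def _write_point_table(events: dict, movie_id: str, index_col: str, path) -> None:
    rows = []
    for eid, ev in events.items():
        for fi, frame in enumerate(ev["frames"]):
            for k, (x, y, z) in enumerate(ev["points"][fi]):
                rows.append(
                    {
                        "movie_id": movie_id,
                        "event_id": eid,
                        "frame": int(frame),
                        "t_min": float(ev["t_min"][fi]),
                        index_col: k,
                        "x_um": x,
                        "y_um": y,
                        "z_um": z,
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_rings(path) -> dict:
    """Read ring-vertex tables: event_id -> {frames, t_min, points (f, v, 3)}."""
    return _read_point_table(path, "vertex_index")


def write_rings(events: dict, movie_id: str, path) -> None:
    _write_point_table(events, movie_id, "vertex_index", path)


def read_planes(path) -> dict:
    """Read basal-plane reference tables: event_id -> {frames, t_min, points}."""
    events = _read_point_table(path, "point_index")
    for eid, ev in events.items():
        if ev["points"].shape[1] != 3:
            raise ValueError(f"event {eid}: planes need exactly 3 reference points")
    return events


def write_planes(events: dict, movie_id: str, path) -> None:
    _write_point_table(events, movie_id, "point_index", path)


# ---------------------------------------------------------------------------
# Mitosis annotations
# ---------------------------------------------------------------------------

def write_mitoses(records, events_path, spindles_path, planes_path) -> None:
    """Write mitosis annotations as three CSVs.

    ``events``: one row per mitosis (endpoints, mother/daughter/enteroblast
    positions, longitudinal axis); ``spindles``: one row per spindle pole
    per frame; ``planes``: basal-plane reference points per frame keyed by
    cell_id (the plane triangle is reported relative to its first frame's
    reference points, one triple per annotated frame).
    """
    from .divisions import MitosisRecord  # local import to avoid a cycle

    ev_rows, sp_rows, plane_events = [], [], {}
    for rec in records:
        if not isinstance(rec, MitosisRecord):
            raise TypeError("expected MitosisRecord")
        row = {
            "movie_id": rec.movie_id,
            "cell_id": rec.cell_id,
            "t_condense_min": rec.t_condense,
            "t_decondense_min": rec.t_decondense,
        }
        for name, vec in (("long_axis", rec.long_axis), ("mother", rec.mother)):
            if vec is not None:
                row.update({f"{name}_{a}": float(v) for a, v in zip("xyz", vec)})
        if rec.daughters is not None:
            for d in range(2):
                row.update(
                    {f"d{d + 1}_{a}": float(v) for a, v in zip("xyz", rec.daughters[d])}
                )
        if rec.enteroblasts is not None:
            for e in range(len(rec.enteroblasts)):
                row.update(
                    {
                        f"eb{e + 1}_{a}": float(v)
                        for a, v in zip("xyz", rec.enteroblasts[e])
                    }
                )
        ev_rows.append(row)

        times = sorted(rec.poles)
        frames, t_min, pts = [], [], []
        for fi, t in enumerate(times):
            for p in range(2):
                sp_rows.append(
                    {
                        "movie_id": rec.movie_id,
                        "cell_id": rec.cell_id,
                        "frame": fi,
                        "t_min": t,
                        "pole_index": p,
                        "x_um": rec.poles[t][p][0],
                        "y_um": rec.poles[t][p][1],
                        "z_um": rec.poles[t][p][2],
                    }
                )
            plane = rec.planes[t]
            u = plane.normal
            # store the reference point and two in-plane offsets as 3 points
            seed = np.array([1.0, 0.0, 0.0])
            if abs(np.dot(seed, u)) > 0.9:
                seed = np.array([0.0, 1.0, 0.0])
            b1 = seed - np.dot(seed, u) * u
            b1 /= np.linalg.norm(b1)
            b2 = np.cross(u, b1)
            pts.append(np.stack([plane.point, plane.point + 3 * b1, plane.point + 3 * b2]))
            frames.append(fi)
            t_min.append(t)
        plane_events[rec.cell_id] = {
            "frames": np.array(frames),
            "t_min": np.array(t_min, dtype=float),
            "points": np.stack(pts),
        }

    pd.DataFrame(ev_rows).to_csv(events_path, index=False)
    pd.DataFrame(sp_rows).to_csv(spindles_path, index=False)
    movie_id = records[0].movie_id if records else ""
    _write_point_table(plane_events, movie_id, "point_index", planes_path)


def read_mitoses(events_path, spindles_path, planes_path) -> list:
    """Inverse of :func:`write_mitoses`.

    The reconstructed planes pass through the stored reference points; the
    normal is re-derived (and re-oriented toward the spindle midpoint plus
    its original apical side is not recoverable, but all reported angles
    are folded to [0, 90] so the sign is immaterial).
    """
    from .divisions import MitosisRecord
    from .extrusion import fit_basal_plane

    events = pd.read_csv(events_path)
    spindles = pd.read_csv(spindles_path)
    planes = _read_point_table(planes_path, "point_index")

    records = []
    for _, row in events.iterrows():
        cid = int(row["cell_id"])
        rec = MitosisRecord(
            cell_id=cid,
            movie_id=str(row["movie_id"]),
            t_condense=float(row["t_condense_min"]),
            t_decondense=float(row["t_decondense_min"]),
        )
        if "long_axis_x" in row and pd.notna(row.get("long_axis_x")):
            rec.long_axis = np.array([row[f"long_axis_{a}"] for a in "xyz"], dtype=float)
        if "mother_x" in row and pd.notna(row.get("mother_x")):
            rec.mother = np.array([row[f"mother_{a}"] for a in "xyz"], dtype=float)
        if "d1_x" in row and pd.notna(row.get("d1_x")):
            rec.daughters = np.array(
                [[row[f"d{d}_{a}"] for a in "xyz"] for d in (1, 2)], dtype=float
            )
        ebs = []
        for e in (1, 2):
            if f"eb{e}_x" in row and pd.notna(row.get(f"eb{e}_x")):
                ebs.append([row[f"eb{e}_{a}"] for a in "xyz"])
        if ebs:
            rec.enteroblasts = np.array(ebs, dtype=float)

        sp = spindles[spindles["cell_id"] == cid].sort_values(["t_min", "pole_index"])
        plane_ev = planes[cid]
        for fi, (t, grp) in enumerate(sp.groupby("t_min", sort=True)):
            poles = grp.sort_values("pole_index")[["x_um", "y_um", "z_um"]].to_numpy()
            rec.poles[float(t)] = poles
            p1, p2, p3 = plane_ev["points"][fi]
            rec.planes[float(t)] = fit_basal_plane(p1, p2, p3)
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Image stacks
# ---------------------------------------------------------------------------

CANONICAL_AXES = "TCZYX"


def write_volume(path, stack: np.ndarray, voxel_size_um) -> None:
    """Write a (t, c, z, y, x) stack as ImageJ-compatible TIFF.

    The voxel size (z, y, x in µm) is stored in the file metadata (z as the
    ImageJ ``spacing``, y/x via the TIFF resolution tags).
    """
    stack = np.asarray(stack)
    if stack.ndim != 5:
        raise ValueError("stack must be 5D (t, c, z, y, x)")
    vz, vy, vx = (float(v) for v in voxel_size_um)
    # ImageJ hyperstacks are stored TZCYX.
    tifffile.imwrite(
        path,
        np.ascontiguousarray(np.moveaxis(stack, 1, 2)),
        imagej=True,
        resolution=(1.0 / vx, 1.0 / vy),
        metadata={"spacing": vz, "unit": "um", "axes": "TZCYX"},
    )


def read_volume(path, axes: str | None = None, voxel_size_um=None):
    """Read an image stack into canonical (t, c, z, y, x) order.

    ``axes`` overrides the axis order recorded in the file (a permutation
    of "TCZYX"; missing axes are treated as length-1).  ``voxel_size_um``
    overrides the (z, y, x) voxel size; if neither the file metadata nor
    the override provides one, an error is raised.

    Returns ``(stack, voxel_size)``.
    """
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        file_axes = axes or series.axes
        file_axes = file_axes.upper().replace("S", "C").replace("Q", "")
        if sorted(file_axes) != sorted(set(file_axes)) or any(
            a not in CANONICAL_AXES for a in file_axes
        ):
            raise ValueError(
                f"unrecognized axis order {file_axes!r}; pass axes= explicitly"
            )
        if len(file_axes) != data.ndim:
            raise ValueError("axis annotation does not match array rank")

        # Expand to all five axes, then permute to canonical order.
        for a in CANONICAL_AXES:
            if a not in file_axes:
                data = data[np.newaxis]
                file_axes = a + file_axes
        order = [file_axes.index(a) for a in CANONICAL_AXES]
        data = np.transpose(data, order)

        if voxel_size_um is None:
            ij = tif.imagej_metadata or {}
            spacing = ij.get("spacing")
            page = tif.pages[0]
            xres = page.tags.get("XResolution")
            yres = page.tags.get("YResolution")
            if spacing is None or xres is None or yres is None:
                raise ValueError(
                    "no voxel size in file metadata; pass voxel_size_um="
                )
            vx = xres.value[1] / xres.value[0]
            vy = yres.value[1] / yres.value[0]
            voxel_size_um = (float(spacing), float(vy), float(vx))
    return data, tuple(float(v) for v in voxel_size_um)


# ---------------------------------------------------------------------------
# Config and JSON results
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    """Load a YAML (or JSON) configuration file into a dict."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a key-value mapping")
    return cfg


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        return super().default(o)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
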