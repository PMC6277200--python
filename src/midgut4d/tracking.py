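"""Frame-to-frame linking of nuclear detections, and progenitor pairing.

Nuclei move little between time points relative to their spacing (frame
intervals of 5-15 min), so a deterministic mutual-nearest-neighbour linker
is adequate: detections in consecutive frames are linked when each is the
other's nearest neighbour and their separation does not exceed a
displacement gate.  Unmatched detections terminate or start tracks.  Ties
are broken by (distance, lower detection index), so linking is fully
reproducible.

Two esg-positive progenitors form a *pair* at a frame when they are
mutually closer to each other than to any other progenitor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = ["LinkConfig", "link_tracks", "find_progenitor_pairs"]


@dataclass(frozen=True)
class LinkConfig:
    """Linking parameters: gate in µm per frame; gap closing unsupported."""

    max_displacement: float = 5.0
    allow_gap: int = 0

    def __post_init__(self):
        if self.max_displacement <= 0:
            raise ValueError("max_displacement must be positive")
        if self.allow_gap != 0:
            raise ValueError("gap closing is not implemented")


def _mutual_nn_links(prev: np.ndarray, cur: np.ndarray, gate: float):
    """Mutual-nearest-neighbour matches between two point sets.

    Returns a list of (i_prev, i_cur) with distance <= gate, chosen
    greedily by (distance, i_prev, i_cur).
    """
    if len(prev) == 0 or len(cur) == 0:
        return []
    d = cdist(prev, cur)
    nn_fwd = np.argmin(d, axis=1)   # prev -> cur
    nn_bwd = np.argmin(d, axis=0)   # cur -> prev
    candidates = []
    for i in range(len(prev)):
        j = nn_fwd[i]
        if nn_bwd[j] == i and d[i, j] <= gate:
            candidates.append((float(d[i, j]), i, int(j)))
    candidates.sort()
    used_prev, used_cur, links = set(), set(), []
    for _, i, j in candidates:
        if i in used_prev or j in used_cur:
            continue
        links.append((i, j))
        used_prev.add(i)
        used_cur.add(j)
    return links


def link_tracks(detections: pd.DataFrame, config: LinkConfig = LinkConfig()) -> pd.DataFrame:
    """Link per-frame detections into tracks.

    ``detections`` must carry ``frame`` and centroid columns
    ``x_um, y_um, z_um`` (any other columns are carried through).  Returns
    a copy with a ``cell_id`` column; detections sharing a cell_id form one
    track.  A detection that jumps farther than the gate starts a new
    track.
    """
    required = {"frame", "x_um", "y_um", "z_um"}
    missing = required - set(detections.columns)
    if missing:
        raise ValueError(f"detections missing columns: {sorted(missing)}")
    out = detections.sort_values("frame", kind="stable").reset_index(drop=True).copy()
    out["cell_id"] = -1

    next_id = 0
    frames = sorted(out["frame"].unique())
    prev_idx = np.array([], dtype=int)
    pos_cols = ["x_um", "y_um", "z_um"]
    for f_i, frame in enumerate(frames):
        cur_idx = out.index[out["frame"] == frame].to_numpy()
        if f_i == 0 or (frames[f_i - 1] != frame - 1 and not np.isclose(frames[f_i - 1], frame - 1)):
            links = []
        else:
            prev_pts = out.loc[prev_idx, pos_cols].to_numpy(dtype=float)
            cur_pts = out.loc[cur_idx, pos_cols].to_numpy(dtype=float)
            links = _mutual_nn_links(prev_pts, cur_pts, config.max_displacement)
        linked_cur = set()
        for i, j in links:
            out.loc[cur_idx[j], "cell_id"] = out.loc[prev_idx[i], "cell_id"]
            linked_cur.add(j)
        for j, row in enumerate(cur_idx):
            if j not in linked_cur:
                out.loc[row, "cell_id"] = next_id
                next_id += 1
        prev_idx = cur_idx
    return out


def find_progenitor_pairs(positions: pd.DataFrame) -> list[tuple[int, int]]:
    """Mutual-nearest-neighbour pairs among esg-positive cells at one frame.

    ``positions`` holds one row per progenitor (stem or enteroblast) at a
    single frame, with ``cell_id`` and centroid columns.  Two cells pair if
    each is the other's nearest progenitor; each cell appears in at most
    one pair.  Fewer than two progenitors yield an empty list.
    """
    if len(positions) < 2:
        return []
    pts = positions[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    ids = positions["cell_id"].to_numpy()
    d = cdist(pts, pts)
    np.fill_diagonal(d, np.inf)
    nn = np.argmin(d, axis=1)
    pairs = []
    for i in range(len(ids)):
        j = nn[i]
        if i < j and nn[j] == i:
            pairs.append((int(ids[i]), int(ids[j])))
    return pairs
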