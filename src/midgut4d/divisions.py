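"""Stem-cell mitosis kinetics and division orientation.

Mitoses are annotated events: nuclear condensation marks the start,
decondensation of the two daughter chromosome sets marks the end, and
spindle poles are inferred per frame from condensed-chromosome morphology.
Division orientation is measured in three reference frames:

* horizontal-vertical (hv): angle between the spindle axis and the basal
  epithelial plane; 0° = horizontal (in-plane), 90° = vertical.
* longitudinal-circumferential (lc): in-plane angle between the
  daughter-daughter axis and the gut tube's long axis; 0° = longitudinal,
  90° = circumferential.
* enteroblast-relative (eb): angle between the axis from a flanking
  enteroblast to the nearer daughter (D1) and the D1-to-D2 axis;
  0° = division parallel to the enteroblast axis.

All axes are undirected, so every angle is folded into [0°, 90°].

The mitotic index is T_M / T_SC: total observed mitosis time divided by
total stem-cell "screen time" (per movie, stem-cell count at t = 0 times
movie duration, summed over movies).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .extrusion import BasalPlane

__all__ = [
    "MitosisRecord",
    "mitosis_duration",
    "mitotic_index",
    "angle_hv",
    "angle_lc",
    "angle_eb",
    "reorientation_events",
]


@dataclass
class MitosisRecord:
    """Annotations for one stem-cell division.

    ``poles`` maps frame time (min) to a (2, 3) array of spindle-pole
    positions; ``planes`` maps frame time to the local :class:`BasalPlane`.
    ``enteroblasts`` holds 0, 1 or 2 contacting enteroblast nuclear
    positions; ``mother`` is the mother nuclear position pre-division.
    ``long_axis`` is the local longitudinal unit vector of the tube.
    """

    cell_id: int
    t_condense: float | None = None      # minutes
    t_decondense: float | None = None    # minutes
    poles: dict = field(default_factory=dict)
    planes: dict = field(default_factory=dict)
    daughters: np.ndarray | None = None  # (2, 3) positions at cytokinesis
    enteroblasts: np.ndarray | None = None  # (k, 3), k in {0, 1, 2}
    mother: np.ndarray | None = None
    long_axis: np.ndarray | None = None
    movie_id: str = ""


def mitosis_duration(record: MitosisRecord) -> float:
    """Duration of mitosis in minutes (decondensation - condensation)."""
    if record.t_condense is None or record.t_decondense is None:
        raise ValueError("mitosis record is missing a condensation endpoint")
    if record.t_decondense <= record.t_condense:
        raise ValueError("decondensation must come after condensation")
    return float(record.t_decondense - record.t_condense)


def mitotic_index(
    mitosis_durations_min,
    movies,
    stem_estimate_fraction: float = 0.20,
) -> float:
    """Mitotic index T_M / T_SC (dimensionless fraction).

    Parameters
    ----------
    mitosis_durations_min : sequence of float
        Durations of all observed mitoses, minutes.
    movies : sequence of dict
        One entry per movie with ``duration_min`` and either
        ``stem_count_t0`` (preferred) or ``total_cells_t0``, in which case
        the stem count is estimated as ``stem_estimate_fraction`` of total.
    """
    t_m = float(np.sum(mitosis_durations_min)) if len(mitosis_durations_min) else 0.0
    t_sc = 0.0
    for movie in movies:
        if "stem_count_t0" in movie and movie["stem_count_t0"] is not None:
            n_stem = float(movie["stem_count_t0"])
        elif "total_cells_t0" in movie:
            n_stem = stem_estimate_fraction * float(movie["total_cells_t0"])
        else:
            raise ValueError("movie entry needs stem_count_t0 or total_cells_t0")
        t_sc += n_stem * float(movie["duration_min"])
    if t_sc <= 0:
        raise ValueError("total stem-cell screen time T_SC is zero")
    return t_m / t_sc


def _fold_degrees(angle: float) -> float:
    """Fold an undirected-axis angle into [0, 90] degrees."""
    angle = angle % 180.0
    return 180.0 - angle if angle > 90.0 else angle


def _axis_angle(v1, v2) -> float:
    """Angle in degrees between two undirected axes, in [0, 90]."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("zero-length vector has no direction")
    cosang = abs(np.dot(v1, v2) / (n1 * n2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def angle_hv(poles, plane: BasalPlane) -> float:
    """Horizontal-vertical spindle angle, degrees in [0, 90].

    The spindle-pole vector is the difference of the two pole positions; the
    reported angle is that between the spindle axis and the basal plane,
    i.e. 90° minus the angle to the plane normal.  0° = horizontal.
    """
    poles = np.asarray(poles, dtype=float)
    spindle = poles[1] - poles[0]
    if np.linalg.norm(spindle) == 0:
        raise ValueError("spindle poles coincide")
    to_normal = _axis_angle(spindle, plane.normal)
    return _fold_degrees(90.0 - to_normal)


def angle_lc(daughter1, daughter2, long_axis, plane: BasalPlane | None = None) -> float:
    """Longitudinal-circumferential division angle, degrees in [0, 90].

    Angle between the daughter-daughter axis and the tube's longitudinal
    axis.  If ``plane`` is given, both vectors are first projected into the
    epithelial plane, mirroring measurement on planar projections;
    0° = longitudinal, 90° = circumferential.
    """
    d1 = np.asarray(daughter1, dtype=float)
    d2 = np.asarray(daughter2, dtype=float)
    axis = np.asarray(long_axis, dtype=float)
    dd = d2 - d1
    if np.linalg.norm(dd) == 0:
        raise ValueError("daughter positions coincide")
    if plane is not None:
        n = plane.normal
        dd = dd - np.dot(dd, n) * n
        axis = axis - np.dot(axis, n) * n
        if np.linalg.norm(dd) == 0 or np.linalg.norm(axis) == 0:
            raise ValueError("vector degenerate after in-plane projection")
    return _axis_angle(dd, axis)


def angle_eb(
    daughters,
    enteroblasts,
    mother=None,
    tie_tolerance_um: float = 1e-9,
) -> tuple[float, dict]:
    """Division angle relative to a flanking enteroblast, degrees in [0, 90].

    The reference enteroblast is the sole contacting enteroblast or, when
    two are present, the one whose nucleus lay closer to the mother stem
    cell before division (``mother`` required then).  D1 is the daughter
    closer to the reference enteroblast.  The angle is measured between the
    enteroblast-to-D1 vector and the D1-to-D2 vector; 0° means the division
    axis points along the enteroblast axis.

    Returns ``(angle, info)`` where ``info`` records the reference
    enteroblast index, the D1 index, and whether the daughter choice was an
    equidistance tie (broken deterministically toward the lower index).
    """
    daughters = np.asarray(daughters, dtype=float)
    ebs = np.atleast_2d(np.asarray(enteroblasts, dtype=float))
    if ebs.shape[0] == 0:
        raise ValueError("at least one enteroblast position is required")
    if ebs.shape[0] > 1:
        if mother is None:
            raise ValueError("mother position required to pick between two enteroblasts")
        mother = np.asarray(mother, dtype=float)
        ref_idx = int(np.argmin(np.linalg.norm(ebs - mother, axis=1)))
    else:
        ref_idx = 0
    eb = ebs[ref_idx]

    dists = np.linalg.norm(daughters - eb, axis=1)
    tie = bool(abs(dists[0] - dists[1]) <= tie_tolerance_um)
    d1_idx = 0 if tie else int(np.argmin(dists))
    d1, d2 = daughters[d1_idx], daughters[1 - d1_idx]
    if np.allclose(d1, d2):
        raise ValueError("daughter positions coincide")

    angle = _axis_angle(d1 - eb, d2 - d1)
    return angle, {"reference_eb": ref_idx, "d1": d1_idx, "tie": tie}


def reorientation_events(hv_angles_deg, threshold_deg: float = 15.0) -> int:
    """Count frame-to-frame re-orientations of at least ``threshold_deg``.

    A re-orientation is an absolute change in the horizontal-vertical angle
    between consecutive frames of at least the threshold.
    """
    angles = np.asarray(hv_angles_deg, dtype=float)
    if angles.ndim != 1 or len(angles) < 2:
        raise ValueError("need at least two per-frame angles")
    return int(np.sum(np.abs(np.diff(angles)) >= threshold_deg))
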