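"""Morphometry of apical enterocyte extrusion.

An extruding enterocyte is outlined basally by a junctional ring of
E-cadherin (typically six-sided).  Over several hours the ring closes to a
point while the cell's nucleus is ejected apically into the gut lumen and
then recoils.  This module measures that process from annotated ring
vertices and basal-plane reference points:

* cross-sectional ring area by centroid-fan triangulation,
* the ring's 2D "footprint" projected onto the basal plane,
* signed orthogonal distance of a point (ring centroid, nucleus) from the
  basal plane,
* decomposition of an area time series into alternating constriction and
  relaxation/stabilization pulses (the "ratchet"), and
* onset/peak/recoil kinetics of apical nuclear travel.

All coordinates are physical micrometres; times are minutes from movie
start.  Apical is the positive side of a basal plane's unit normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BasalPlane",
    "PulseSegment",
    "PulseDecomposition",
    "NuclearTravel",
    "fit_basal_plane",
    "ring_area",
    "ring_centroid",
    "ring_footprint",
    "plane_distance",
    "detect_pulses",
    "nuclear_travel",
]

_COLLINEAR_TOL = 1e-9


@dataclass(frozen=True)
class BasalPlane:
    """A plane through the basal epithelial surface.

    Attributes
    ----------
    point : (3,) array
        A reference point on the plane (µm).
    normal : (3,) array
        Unit normal.  By convention it points apically (into the lumen,
        away from the objective-side tissue); orient it with
        :meth:`oriented_toward` if the acquisition geometry requires.
    """

    point: np.ndarray
    normal: np.ndarray

    def oriented_toward(self, apical_point) -> "BasalPlane":
        """Return a copy whose normal points toward ``apical_point``."""
        apical_point = np.asarray(apical_point, dtype=float)
        if np.dot(self.normal, apical_point - self.point) < 0:
            return BasalPlane(self.point, -self.normal)
        return self


def fit_basal_plane(p1, p2, p3) -> BasalPlane:
    """Fit a plane through three reference points on the basal surface.

    The normal is the unit cross product of (p2 - p1) and (p3 - p1).
    Raises ``ValueError`` for (near-)collinear points.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    p3 = np.asarray(p3, dtype=float)
    n = np.cross(p2 - p1, p3 - p1)
    norm = np.linalg.norm(n)
    scale = max(np.linalg.norm(p2 - p1) * np.linalg.norm(p3 - p1), 1.0)
    if norm <= _COLLINEAR_TOL * scale:
        raise ValueError("basal-plane reference points are collinear")
    return BasalPlane(point=p1, normal=n / norm)


def ring_centroid(vertices) -> np.ndarray:
    """Vertex centroid of a ring (mean of its ordered vertices)."""
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[0] < 3 or v.shape[1] != 3:
        raise ValueError("ring requires >= 3 vertices of shape (n, 3)")
    return v.mean(axis=0)


def ring_area(vertices) -> float:
    """Cross-sectional area of a junctional ring, in µm².

    The polygon is triangulated about its vertex centroid; each component
    triangle contributes half the magnitude of the cross product of the two
    vectors from the centroid to adjacent vertices.  Exact for planar convex
    polygons; well-defined (and non-negative) for slightly non-planar rings.
    """
    v = np.asarray(vertices, dtype=float)
    c = ring_centroid(v)
    a = v - c
    b = np.roll(v, -1, axis=0) - c
    return float(0.5 * np.linalg.norm(np.cross(a, b), axis=1).sum())


def _plane_basis(plane: BasalPlane):
    """A fixed orthonormal in-plane basis (u, v) with u x v = normal."""
    n = plane.normal
    seed = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(seed, n)) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    u = seed - np.dot(seed, n) * n
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v


def ring_footprint(vertices, plane: BasalPlane) -> np.ndarray:
    """Orthogonal projection of ring vertices onto the basal plane.

    Returns an (n, 2) array of coordinates in a fixed orthonormal in-plane
    basis, preserving vertex order.  This is the epithelial-plane
    "footprint" of the ring.
    """
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 3:
        raise ValueError("vertices must have shape (n, 3)")
    u, w = _plane_basis(plane)
    rel = v - plane.point
    return np.stack([rel @ u, rel @ w], axis=1)


def plane_distance(point, plane: BasalPlane) -> float:
    """Signed orthogonal distance from a point to the basal plane (µm).

    Computed as the dot product of the plane's unit normal with the vector
    from the plane reference point to ``point``.  Positive values are on
    the apical side.
    """
    point = np.asarray(point, dtype=float)
    return float(np.dot(plane.normal, point - plane.point))


# ---------------------------------------------------------------------------
# Ratchet pulse decomposition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PulseSegment:
    """One constriction or relaxation/stabilization interval of ring closure."""

    kind: str              # "constriction" or "relaxation"
    start: float           # minutes
    end: float             # minutes
    rate: float            # mean dA/dt over the segment, µm²/min (signed)

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class PulseDecomposition:
    """Alternating pulse segments plus per-kind summaries."""

    segments: list
    constriction_time: float       # cumulative minutes
    relaxation_time: float         # cumulative minutes
    mean_constriction_rate: float  # µm²/min (signed, negative)
    mean_relaxation_rate: float    # µm²/min (signed)

    @property
    def n_constrictions(self) -> int:
        return sum(1 for s in self.segments if s.kind == "constriction")

    @property
    def n_relaxations(self) -> int:
        return sum(1 for s in self.segments if s.kind == "relaxation")


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; the window is truncated at the ends."""
    if window <= 1:
        return y.astype(float)
    half = window // 2
    out = np.empty_like(y, dtype=float)
    for i in range(len(y)):
        lo = max(0, i - half)
        hi = min(len(y), i + half + 1)
        out[i] = y[lo:hi].mean()
    return out


def detect_pulses(
    t_min,
    area_um2,
    smoothing_window: int = 3,
    rate_epsilon: float | None = None,
    min_segment_intervals: int = 2,
) -> PulseDecomposition:
    """Decompose a ring-area series into ratchet pulses.

    The series is smoothed with a centered moving average, the rate dA/dt is
    computed on each inter-frame interval of the smoothed series, and
    intervals are labelled constriction where the rate is below
    ``-rate_epsilon`` and relaxation/stabilization otherwise.  Adjacent
    same-kind intervals are merged; residual segments shorter than
    ``min_segment_intervals`` frame intervals are absorbed into their
    neighbours (which keeps single-interval noise flickers from splitting a
    pulse), so the returned segments strictly alternate in kind.

    ``rate_epsilon`` defaults to 5% of the maximum absolute smoothed rate,
    a dead band that treats near-flat stretches as stabilization.

    Segment mean rates are computed from the raw (unsmoothed) series between
    the segment boundary times.

    Parameters
    ----------
    t_min, area_um2 : 1D sequences
        Strictly increasing times (minutes) and ring areas (µm²), >= 3 points.
    """
    t = np.asarray(t_min, dtype=float)
    a = np.asarray(area_um2, dtype=float)
    if t.ndim != 1 or t.shape != a.shape or len(t) < 3:
        raise ValueError("need >= 3 (time, area) pairs of equal length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if smoothing_window > len(t):
        raise ValueError("smoothing window exceeds series length")

    smooth = _moving_average(a, smoothing_window)
    rates = np.diff(smooth) / np.diff(t)
    if rate_epsilon is None:
        rate_epsilon = 0.05 * float(np.max(np.abs(rates))) if np.any(rates) else 0.0

    # Per-interval labels: True = constriction.
    labels = rates < -rate_epsilon

    # Run-length encode, then absorb runs shorter than the minimum duration.
    runs = []  # (label, start_interval, n_intervals)
    i = 0
    while i < len(labels):
        j = i
        while j < len(labels) and labels[j] == labels[i]:
            j += 1
        runs.append([bool(labels[i]), i, j - i])
        i = j
    changed = True
    while changed and len(runs) > 1:
        changed = False
        lengths = [r[2] for r in runs]
        k = int(np.argmin(lengths))
        if lengths[k] < min_segment_intervals:
            runs[k][0] = not runs[k][0]  # flip, then re-merge neighbours
            merged = []
            for r in runs:
                if merged and merged[-1][0] == r[0]:
                    merged[-1][2] += r[2]
                else:
                    merged.append(r)
            # recompute starts
            pos = 0
            for r in merged:
                r[1] = pos
                pos += r[2]
            runs = merged
            changed = True

    segments = []
    for is_con, start_iv, n_iv in runs:
        i0, i1 = start_iv, start_iv + n_iv
        rate = (a[i1] - a[i0]) / (t[i1] - t[i0])
        segments.append(
            PulseSegment(
                kind="constriction" if is_con else "relaxation",
                start=float(t[i0]),
                end=float(t[i1]),
                rate=float(rate),
            )
        )

    con = [s for s in segments if s.kind == "constriction"]
    rel = [s for s in segments if s.kind == "relaxation"]
    t_con = sum(s.duration for s in con)
    t_rel = sum(s.duration for s in rel)
    mean_con = (
        sum(s.rate * s.duration for s in con) / t_con if t_con > 0 else float("nan")
    )
    mean_rel = (
        sum(s.rate * s.duration for s in rel) / t_rel if t_rel > 0 else float("nan")
    )
    return PulseDecomposition(
        segments=segments,
        constriction_time=float(t_con),
        relaxation_time=float(t_rel),
        mean_constriction_rate=float(mean_con),
        mean_relaxation_rate=float(mean_rel),
    )


# ---------------------------------------------------------------------------
# Nuclear travel kinetics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NuclearTravel:
    """Apical travel of the extruding cell's nucleus.

    ``start`` is the time point at which apical movement is first apparent:
    the frame immediately preceding the first persistent excursion of the
    smoothed distance above baseline.  ``peak`` is the time of maximal
    apical displacement.  ``recoil`` is the drop from the peak back to the
    final resting plateau.
    """

    event: bool
    t_min: np.ndarray = field(default=None)
    distance_um: np.ndarray = field(default=None)
    start: float = float("nan")       # minutes
    peak: float = float("nan")        # minutes
    duration: float = float("nan")    # minutes
    peak_distance: float = float("nan")   # µm
    recoil: float = float("nan")          # µm


def nuclear_travel(
    t_min,
    distance_um,
    baseline_frames: int = 10,
    onset_min_excursion_um: float = 0.5,
    persistence_frames: int = 2,
    smoothing_window: int = 3,
    plateau_frames: int = 5,
) -> NuclearTravel:
    """Measure onset, peak and recoil of apical nuclear travel.

    Parameters
    ----------
    t_min, distance_um : 1D sequences
        Times (minutes) and signed apical distances of the nuclear centroid
        from the basal plane (µm).
    baseline_frames : int
        Number of initial frames defining the pre-rise baseline (median).
    onset_min_excursion_um : float
        Floor on the onset threshold above baseline; the threshold is
        ``baseline + max(2 * 1.4826 * MAD, onset_min_excursion_um)``.
    persistence_frames : int
        Consecutive frames the smoothed distance must stay above threshold.

    Returns a :class:`NuclearTravel`; ``event=False`` flags a flat series in
    which no persistent apical excursion was found.
    """
    t = np.asarray(t_min, dtype=float)
    d = np.asarray(distance_um, dtype=float)
    if t.shape != d.shape or t.ndim != 1 or len(t) < persistence_frames + 2:
        raise ValueError("need a 1D series longer than persistence_frames + 1")

    smooth = _moving_average(d, smoothing_window)
    base = smooth[: max(1, min(baseline_frames, len(smooth) - 1))]
    baseline = float(np.median(base))
    mad = float(np.median(np.abs(base - np.median(base))))
    threshold = baseline + max(2.0 * 1.4826 * mad, onset_min_excursion_um)

    above = smooth > threshold
    onset_idx = None
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= persistence_frames:
            onset_idx = i - persistence_frames + 1
            break
    if onset_idx is None:
        return NuclearTravel(event=False, t_min=t, distance_um=d)

    # Movement is "first apparent" on the frame from which the excursion
    # departs, i.e. the last frame at or below threshold before onset.
    start_idx = max(0, onset_idx - 1)
    peak_idx = int(np.argmax(d))
    plateau = float(np.median(d[-min(plateau_frames, len(d)):]))
    return NuclearTravel(
        event=True,
        t_min=t,
        distance_um=d,
        start=float(t[start_idx]),
        peak=float(t[peak_idx]),
        duration=float(t[peak_idx] - t[start_idx]),
        peak_distance=float(d[peak_idx]),
        recoil=float(d[peak_idx] - plateau),
    )
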