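"""Notch-reporter fate dynamics: the normalized GFP:RFP metric and its uses.

Notch transcriptional activation in midgut progenitors is read out by a
nuclear GFP reporter against a ubiquitous nuclear RFP reference.  The
normalized GFP:RFP metric makes this comparable across cells, depths and
movies: within each movie, each channel's raw single-cell intensities are
divided by that movie's maximum, and the per-cell, per-frame ratio of the
two normalized intensities is taken.  Pooled over progenitors the metric is
bimodal — a sharp low mode (stem-like cells, negligible reporter signal)
and a broad high mode (enteroblasts) — and the local density minimum
between the modes defines the fate threshold separating the two states.

This module implements ratio normalization, kernel-density threshold
estimation, benchmark validation against known (pre-mitotic) stem cells,
persistent-crossing transition calling, inter-nuclear-distance contact
classification for sibling pairs, and bleed-over flagging of frames where
a bright neighbour contaminates a cell's measured GFP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import gaussian_kde

__all__ = [
    "NotchConfig",
    "ContactThresholds",
    "RatioSeries",
    "TransitionEvent",
    "normalize_ratios",
    "ratio_series",
    "estimate_threshold",
    "benchmark_stem_fraction",
    "detect_transition",
    "detect_transitions",
    "internuclear_distance",
    "classify_contact",
    "sibling_contact_timeline",
    "flag_bleedover",
]

PROGENITOR_LABELS = ("stem", "enteroblast")


@dataclass(frozen=True)
class NotchConfig:
    """Parameters of the fate metric.

    ``eb_threshold`` is the GFP:RFP value separating stem-like cells from
    enteroblasts; it is normally estimated from the pooled distribution
    (:func:`estimate_threshold`) and is imaging-system specific.  The
    fallback default corresponds to the reference acquisition conditions.
    """

    eb_threshold: float = 0.17
    persistence_frames: int = 3
    baseline_window: int = 6
    density_grid: float = 0.001
    ratio_clip: float = 2.0

    def __post_init__(self):
        if self.eb_threshold <= 0:
            raise ValueError("eb_threshold must be positive")
        if self.persistence_frames < 1:
            raise ValueError("persistence_frames must be >= 1")


@dataclass(frozen=True)
class ContactThresholds:
    """Inter-nuclear distance cut-offs for inferring sibling contact."""

    contact_max: float = 6.0       # µm; below this, inferred contact
    separation_min: float = 15.5   # µm; above this, inferred separation

    def __post_init__(self):
        if not 0 < self.contact_max < self.separation_min:
            raise ValueError("require 0 < contact_max < separation_min")


@dataclass
class RatioSeries:
    """Per-cell time series of normalized GFP:RFP values."""

    cell_id: int
    movie_id: str
    t_min: np.ndarray
    ratio: np.ndarray
    valid: np.ndarray  # bool per frame


@dataclass(frozen=True)
class TransitionEvent:
    """One stem-to-enteroblast transition called from a ratio series."""

    cell_id: int
    baseline_value: float
    baseline_time_min: float
    crossing_time_min: float
    final_ratio: float

    @property
    def duration_min(self) -> float:
        return self.crossing_time_min - self.baseline_time_min

    @property
    def duration_hr(self) -> float:
        return self.duration_min / 60.0


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_ratios(
    tracks: pd.DataFrame,
    progenitors_only: bool = True,
    movie_col: str = "movie_id",
) -> pd.DataFrame:
    """Compute the normalized GFP:RFP metric for each cell at each frame.

    Within each movie, ``gfp_raw`` and ``rfp_raw`` are each divided by the
    maximum of that channel over all cells and frames of the movie; the
    returned frame adds ``gfp_norm``, ``rfp_norm``, ``ratio`` and a boolean
    ``valid`` column.  Frames with zero RFP are flagged invalid (their
    ratio is NaN, never infinity).  The metric is invariant to any
    per-movie multiplicative gain.

    With ``progenitors_only`` and a ``label`` column present, the output is
    restricted to esg-positive (stem / enteroblast) cells, which are the
    cells the reporter is meaningful for.
    """
    required = {movie_col, "cell_id", "frame", "gfp_raw", "rfp_raw"}
    missing = required - set(tracks.columns)
    if missing:
        raise ValueError(f"track table is missing columns: {sorted(missing)}")
    out = tracks.copy()
    if progenitors_only and "label" in out.columns:
        out = out[out["label"].isin(PROGENITOR_LABELS)].copy()

    for col in ("gfp", "rfp"):
        maxima = tracks.groupby(movie_col)[f"{col}_raw"].max()
        if (maxima <= 0).any():
            raise ValueError(f"movie with non-positive maximum {col} intensity")
        out[f"{col}_norm"] = out[f"{col}_raw"].to_numpy() / out[movie_col].map(
            maxima
        ).to_numpy()

    rfp = out["rfp_norm"].to_numpy()
    valid = rfp > 0
    ratio = np.full(len(out), np.nan)
    ratio[valid] = out["gfp_norm"].to_numpy()[valid] / rfp[valid]
    out["ratio"] = ratio
    out["valid"] = valid
    return out


def ratio_series(ratios: pd.DataFrame) -> list[RatioSeries]:
    """Split a normalized table into per-cell :class:`RatioSeries`."""
    series = []
    for (movie_id, cell_id), grp in ratios.groupby(["movie_id", "cell_id"], sort=True):
        grp = grp.sort_values("frame")
        series.append(
            RatioSeries(
                cell_id=int(cell_id),
                movie_id=str(movie_id),
                t_min=grp["t_min"].to_numpy(dtype=float),
                ratio=grp["ratio"].to_numpy(dtype=float),
                valid=grp["valid"].to_numpy(dtype=bool),
            )
        )
    return series


# ---------------------------------------------------------------------------
# Threshold estimation and benchmark validation
# ---------------------------------------------------------------------------

def estimate_threshold(
    pooled_ratios,
    config: NotchConfig = NotchConfig(),
) -> tuple[float, tuple[float, float]]:
    """Estimate the fate threshold from the pooled ratio distribution.

    A Gaussian kernel density (Silverman bandwidth) is evaluated on a
    regular grid over [0, clip]; the two highest local maxima are taken as
    the stem and enteroblast modes and the threshold is the location of the
    minimum density between them.

    Returns ``(threshold, (low_mode, high_mode))``.  Raises ``ValueError``
    if the density has no interior minimum between two modes (unimodal
    distribution).
    """
    values = np.asarray(pooled_ratios, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < 100:
        raise ValueError("need >= 100 pooled ratio values")
    values = np.clip(values, 0.0, config.ratio_clip)

    grid = np.arange(0.0, values.max() + config.density_grid, config.density_grid)
    density = gaussian_kde(values, bw_method="silverman")(grid)

    interior = np.arange(1, len(grid) - 1)
    is_max = (density[interior] >= density[interior - 1]) & (
        density[interior] > density[interior + 1]
    )
    peaks = interior[is_max]
    # Endpoints count as modes if density falls away from them.
    if density[0] > density[1]:
        peaks = np.concatenate([[0], peaks])
    if density[-1] > density[-2]:
        peaks = np.concatenate([peaks, [len(grid) - 1]])
    if len(peaks) < 2:
        raise ValueError("pooled ratio density is unimodal; no threshold exists")

    top2 = peaks[np.argsort(density[peaks])[-2:]]
    lo, hi = int(top2.min()), int(top2.max())
    if hi - lo < 2:
        raise ValueError("modes are adjacent; no interior minimum")
    between = np.arange(lo + 1, hi)
    cut = between[int(np.argmin(density[between]))]
    return float(grid[cut]), (float(grid[lo]), float(grid[hi]))


def benchmark_stem_fraction(
    ratios: pd.DataFrame,
    premitotic: dict,
    threshold: float,
) -> dict:
    """Validate the threshold against ratios of known stem cells.

    Cells observed to divide are stem cells independent of their reporter
    level; their ratios at all frames strictly before nuclear condensation
    form the benchmark collection.  ``premitotic`` maps cell_id to the
    condensation time (minutes).  Returns the fraction of benchmark values
    below ``threshold`` plus counts.
    """
    values = []
    n_cells = 0
    for cell_id, t_condense in premitotic.items():
        grp = ratios[(ratios["cell_id"] == cell_id) & (ratios["t_min"] < t_condense)]
        grp = grp[grp["valid"]]
        if len(grp):
            values.append(grp["ratio"].to_numpy())
            n_cells += 1
    if not values:
        raise ValueError("no pre-mitotic frames found for any benchmark cell")
    pooled = np.concatenate(values)
    return {
        "fraction_below": float(np.mean(pooled < threshold)),
        "n_values": int(len(pooled)),
        "n_cells": n_cells,
    }


# ---------------------------------------------------------------------------
# Transition calling
# ---------------------------------------------------------------------------

def _persistent_crossing(above: np.ndarray, persistence: int) -> int | None:
    """First index at which ``above`` stays True for ``persistence`` frames."""
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= persistence:
            return i - persistence + 1
    return None


def detect_transition(
    series: RatioSeries,
    config: NotchConfig = NotchConfig(),
    threshold: float | None = None,
) -> dict:
    """Call a stem-to-enteroblast transition on one ratio series.

    A cell transitions if its GFP:RFP rises persistently from below to at
    least the threshold: the crossing frame is the first frame at or above
    threshold that is followed by ``persistence_frames`` consecutive
    at-or-above frames (itself included).  The baseline is the last
    pre-rise local minimum before the crossing; its value is the median of
    up to ``baseline_window`` frames ending there, and the transition
    duration runs from that frame (end of the flat baseline) to the
    crossing.  Invalid (bleed-over) frames are excluded.

    Returns a dict with keys ``event`` (:class:`TransitionEvent` or None),
    ``status`` in {"transition", "no_transition", "already_enteroblast"},
    and ``reversions``, the times of persistent falls from above to below
    the threshold.
    """
    thr = config.eb_threshold if threshold is None else threshold
    keep = series.valid & np.isfinite(series.ratio)
    t = series.t_min[keep]
    r = series.ratio[keep]
    if len(r) < config.persistence_frames + 1:
        raise ValueError("series too short for transition calling")

    above = r >= thr
    below = ~above

    reversions = []
    seen_above = False
    run = 0
    for i in range(len(r)):
        if above[i]:
            seen_above = True
            run = 0
        else:
            run = run + 1 if seen_above else 0
            if run == config.persistence_frames:
                reversions.append(float(t[i - config.persistence_frames + 1]))
                seen_above = False
                run = 0

    if above.all():
        return {"event": None, "status": "already_enteroblast", "reversions": reversions}

    cross = _persistent_crossing(above, config.persistence_frames)
    if cross is None or cross == 0:
        # Never crossed persistently, or started above (no below-to-above rise).
        return {"event": None, "status": "no_transition", "reversions": reversions}

    # Baseline: the end of the flat pre-rise stretch.  The lowest rolling
    # median before the crossing defines the baseline level; the baseline
    # frame is the last pre-crossing frame still at that level, within a
    # band set by a trend-robust noise estimate (second differences), so
    # noise dips on the rising limb are not mistaken for the baseline.
    tol = 1e-9
    w = config.baseline_window
    roll_med = np.array(
        [np.median(r[max(0, i - w + 1) : i + 1]) for i in range(cross)]
    )
    floor = float(roll_med.min())
    if floor >= thr:
        return {"event": None, "status": "no_transition", "reversions": reversions}
    d2 = np.diff(r[:cross], n=2)
    sigma = 1.4826 * float(np.median(np.abs(d2))) / np.sqrt(6.0) if len(d2) else 0.0
    at_level = (roll_med <= floor + max(2.0 * sigma / np.sqrt(w), tol)) & (
        r[:cross] <= floor + max(2.0 * sigma, tol)
    )
    if not at_level.any():
        return {"event": None, "status": "no_transition", "reversions": reversions}
    m = int(np.flatnonzero(at_level)[-1])
    baseline_value = float(roll_med[m])
    if baseline_value >= thr:
        return {"event": None, "status": "no_transition", "reversions": reversions}

    event = TransitionEvent(
        cell_id=series.cell_id,
        baseline_value=baseline_value,
        baseline_time_min=float(t[m]),
        crossing_time_min=float(t[cross]),
        final_ratio=float(r[-1]),
    )
    return {"event": event, "status": "transition", "reversions": reversions}


def detect_transitions(
    series_list,
    config: NotchConfig = NotchConfig(),
    threshold: float | None = None,
) -> list[TransitionEvent]:
    """Call transitions over many cells; returns the events found."""
    events = []
    for series in series_list:
        try:
            result = detect_transition(series, config, threshold)
        except ValueError:
            continue
        if result["event"] is not None:
            events.append(result["event"])
    return events


# ---------------------------------------------------------------------------
# Contact inference
# ---------------------------------------------------------------------------

def internuclear_distance(c1, c2) -> float:
    """Euclidean distance between two nuclear centroids, µm."""
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    return float(np.linalg.norm(c2 - c1))


def classify_contact(distance_um: float, thresholds: ContactThresholds = ContactThresholds()) -> str:
    """Infer sibling contact state from inter-nuclear distance.

    Distances below ``contact_max`` imply contact; above ``separation_min``
    imply separation; the closed interval between them (both boundaries
    included) is indeterminate.
    """
    if distance_um < 0:
        raise ValueError("distance cannot be negative")
    if distance_um < thresholds.contact_max:
        return "contact"
    if distance_um > thresholds.separation_min:
        return "separated"
    return "indeterminate"


def _collapse_states(states):
    """Run-length collapse dropping indeterminate frames."""
    collapsed = []
    for s in states:
        if s == "indeterminate":
            continue
        if not collapsed or collapsed[-1] != s:
            collapsed.append(s)
    return collapsed


def summarize_contact_states(t_min, states) -> dict:
    """Summaries of a per-frame contact-state sequence.

    * ``longest_separation_min``: span of the longest maximal run of
      separated frames (first to last frame of the run), minutes.
    * ``separated_ge_1h``: whether any separation run spans >= 60 min.
    * ``alternations``: state changes between contact and separated after
      collapsing runs and ignoring indeterminate frames.
    * ``permanent_separation``: the pair is separated at the end and never
      regains contact afterwards (final collapsed state is separated).
    """
    t = np.asarray(t_min, dtype=float)
    states = list(states)
    longest = 0.0
    i = 0
    while i < len(states):
        if states[i] == "separated":
            j = i
            while j < len(states) and states[j] == "separated":
                j += 1
            longest = max(longest, float(t[j - 1] - t[i]))
            i = j
        else:
            i += 1
    collapsed = _collapse_states(states)
    alternations = max(0, len(collapsed) - 1)
    return {
        "longest_separation_min": longest,
        "separated_ge_1h": bool(longest >= 60.0),
        "alternations": int(alternations),
        "permanent_separation": bool(collapsed and collapsed[-1] == "separated"),
    }


def sibling_contact_timeline(
    track1: pd.DataFrame,
    track2: pd.DataFrame,
    thresholds: ContactThresholds = ContactThresholds(),
) -> dict:
    """Per-frame contact states of a sibling pair tracked from birth.

    ``track1`` / ``track2`` are per-frame tables with ``frame``, ``t_min``
    and centroid columns ``x_um, y_um, z_um``; only their common frames
    (from the shared birth frame on) are used.  Returns the per-frame
    distances and states plus the summaries of
    :func:`summarize_contact_states`.
    """
    merged = track1.merge(track2, on="frame", suffixes=("_1", "_2"))
    if merged.empty:
        raise ValueError("sibling tracks share no frames")
    merged = merged.sort_values("frame")
    p1 = merged[["x_um_1", "y_um_1", "z_um_1"]].to_numpy(dtype=float)
    p2 = merged[["x_um_2", "y_um_2", "z_um_2"]].to_numpy(dtype=float)
    dist = np.linalg.norm(p2 - p1, axis=1)
    t = merged["t_min_1"].to_numpy(dtype=float)
    states = [classify_contact(d, thresholds) for d in dist]
    summary = summarize_contact_states(t, states)
    return {
        "frame": merged["frame"].to_numpy(),
        "t_min": t,
        "distance_um": dist,
        "state": states,
        **summary,
    }


# ---------------------------------------------------------------------------
# Bleed-over flagging
# ---------------------------------------------------------------------------

def flag_bleedover(
    ratios: pd.DataFrame,
    high_ratio_threshold: float = 0.5,
    proximity_um: float = 4.0,
) -> pd.DataFrame:
    """Invalidate frames where a bright neighbour can contaminate a cell.

    When a cell's nuclear surface collides with that of a high-GFP
    neighbour, the neighbour's signal bleeds into the cell's measured
    intensities and its ratio spikes artifactually.  Any frame in which a
    cell lies within ``proximity_um`` of another cell whose ratio exceeds
    ``high_ratio_threshold`` is marked invalid in the returned copy; the
    ratio values themselves are retained.
    """
    required = {"frame", "cell_id", "x_um", "y_um", "z_um", "ratio", "valid"}
    missing = required - set(ratios.columns)
    if missing:
        raise ValueError(f"normalized table is missing columns: {sorted(missing)}")
    out = ratios.reset_index(drop=True).copy()
    flagged = np.zeros(len(out), dtype=bool)
    pos_cols = ["x_um", "y_um", "z_um"]
    for _, sub in out.groupby("frame"):
        pts = sub[pos_cols].to_numpy(dtype=float)
        hot = (sub["ratio"].to_numpy() > high_ratio_threshold) & sub["valid"].to_numpy()
        if not hot.any():
            continue
        near = cdist(pts, pts) <= proximity_um
        np.fill_diagonal(near, False)  # a hot cell is not its own neighbour
        flagged[sub.index.to_numpy()] = (near & hot[None, :]).any(axis=1)
    out.loc[flagged, "valid"] = False
    out["bleedover"] = flagged
    return out
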