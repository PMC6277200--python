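"""Synthetic 4D midgut movies with known ground truth.

The generator emulates the data structure of tracked-nuclei exports from a
long-term movie of the adult fly midgut: a curved epithelial monolayer of
nuclei on a cylindrical tube surface, ~20% stem cells, raw three-channel
nuclear intensities whose normalized GFP:RFP ratio is bimodal (a sharp
stem mode and a broad enteroblast mode), mitoses lasting tens of minutes
with per-frame scheduled spindle orientations, ratcheted extrusion-ring
closures over several hours with apical nuclear ejection and recoil,
enteroblast transitions with scheduled crossing times, and sibling pairs
with scheduled contact dynamics.

Every generated event carries a complete ground-truth record so each
downstream measurement can be validated as a parameter-recovery exercise.
Identical configurations (including the seed) give identical outputs.

The intensity model is ``raw = movie_gain * (normalized * channel_base +
noise)``; the gain differs between movies so that cross-movie
normalization is genuinely exercised.  One calibration frame per channel
per movie is pinned to the channel maximum so that normalized intensities
span exactly [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .divisions import MitosisRecord
from .extrusion import fit_basal_plane

__all__ = [
    "SimConfig",
    "MitosisSpec",
    "ExtrusionSpec",
    "TransitionSpec",
    "SiblingPairSpec",
    "GroundTruth",
    "generate_tracks",
    "generate_extrusion_event",
    "generate_mitosis_event",
    "render_volume",
]

CHANNEL_BASE = {"cfp": 150.0, "gfp": 180.0, "rfp": 200.0}
RATIO_CAP = 1.6          # upper truncation of target GFP:RFP draws
POLE_SEPARATION = 6.0    # µm between scheduled spindle poles
DAUGHTER_SEPARATION = 6.0
CONTACT_DISTANCES = {"contact": 4.0, "indeterminate": 10.0, "separated": 20.0}


@dataclass(frozen=True)
class MitosisSpec:
    """One scheduled stem-cell division.

    ``angle_schedule`` lists (hv, lc) degree pairs, one per mitotic frame
    from condensation to decondensation inclusive; its length fixes the
    mitotic duration as ``(len - 1) * frame_interval``.
    """

    t_condense_min: float
    angle_schedule: tuple          # ((hv, lc), ...)
    cell_index: int | None = None  # stem cell to divide; auto if None
    n_enteroblasts: int = 0        # 0, 1 or 2 contacting enteroblasts


@dataclass(frozen=True)
class ExtrusionSpec:
    """One scheduled single-enterocyte extrusion."""

    start_time_min: float = 0.0
    closure_duration_min: float = 360.0
    n_pulses: int = 8
    initial_area_um2: float = 80.0
    peak_nuclear_displacement_um: float = 12.0


@dataclass(frozen=True)
class TransitionSpec:
    """One scheduled stem-to-enteroblast transition (ratio ramp)."""

    baseline_end_min: float
    crossing_min: float
    baseline_ratio: float = 0.05
    final_ratio: float = 0.40
    threshold: float = 0.17
    cell_index: int | None = None


@dataclass(frozen=True)
class SiblingPairSpec:
    """A sibling pair born in-movie with a scheduled contact sequence.

    ``states`` lists (state, n_frames) with state in
    {"contact", "indeterminate", "separated"}.
    """

    birth_frame: int
    states: tuple  # (("contact", 5), ("separated", 10), ...)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a synthetic movie.

    Defaults emulate the reference acquisition: 7.5 min frame intervals,
    ~12 hr movies, a tube of radius 35 µm, cell-type fractions with 20%
    stem cells, and GFP:RFP modes at 0.015 (stem) and 0.528 (enteroblast).
    """

    rng_seed: int = 0
    movie_id: str = "sim0"
    n_cells: int = 60
    stem_fraction: float = 0.20
    ee_fraction: float = 0.10
    ec_fraction: float = 0.55
    frame_interval: float = 7.5       # minutes
    n_frames: int = 96
    tube_radius: float = 35.0         # µm
    cell_spacing: float = 18.0        # µm, mean nearest-neighbour spacing
    margin: float = 10.0              # µm padding around the tube
    voxel_size: tuple = (1.0, 1.0, 1.0)   # (z, y, x) µm
    motion_sd: float = 0.25           # µm per frame, on-surface random walk
    ratio_modes: tuple = (0.015, 0.528)
    ratio_mode_sds: tuple = (0.010, 0.120)
    intensity_noise_sd: float = 0.01  # fraction of channel base, additive
    gain: float = 1.0                 # per-movie multiplicative gain
    quota_mode: bool = True           # exact type quotas (else binomial)
    mitoses: tuple = ()
    extrusions: tuple = ()
    transitions: tuple = ()
    sibling_pairs: tuple = ()

    def __post_init__(self):
        fracs = (self.stem_fraction, self.ee_fraction, self.ec_fraction)
        if any(not 0 <= f <= 1 for f in fracs) or sum(fracs) > 1 + 1e-12:
            raise ValueError("type fractions must lie in [0, 1] and sum to <= 1")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if any(m < 0 for m in self.ratio_modes):
            raise ValueError("ratio modes must be non-negative")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")

    @property
    def tube_length(self) -> float:
        """Axial tube length giving ~cell_spacing² surface area per cell."""
        area = self.n_cells * self.cell_spacing**2 * 1.05
        return max(60.0, area / (2 * math.pi * self.tube_radius))

    @property
    def axis_center(self) -> np.ndarray:
        """Tube axis offset: (y, z) of the cylinder axis, µm."""
        c = self.tube_radius + self.margin
        return np.array([c, c])

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class GroundTruth:
    """Complete truth records for every generated cell and event."""

    labels: dict = field(default_factory=dict)          # cell_id -> type
    ratio_targets: dict = field(default_factory=dict)   # cell_id -> per-frame target
    mitoses: list = field(default_factory=list)
    extrusions: list = field(default_factory=list)
    transitions: list = field(default_factory=list)
    sibling_pairs: list = field(default_factory=list)
    calibration: dict = field(default_factory=dict)     # channel -> (cell, frame)


# ---------------------------------------------------------------------------
# Geometry helpers: cells live on a cylinder (axis along x)
# ---------------------------------------------------------------------------

def _embed(config: SimConfig, axial: np.ndarray, arc: np.ndarray) -> np.ndarray:
    """Map unrolled (axial, arc) surface coordinates to 3D µm positions."""
    theta = arc / config.tube_radius
    cy, cz = config.axis_center
    x = axial + config.margin
    y = cy + config.tube_radius * np.cos(theta)
    z = cz + config.tube_radius * np.sin(theta)
    return np.stack([x, y, z], axis=-1)


def _local_frame(config: SimConfig, arc: float):
    """(longitudinal, circumferential, apical) unit vectors at a surface point."""
    theta = arc / config.tube_radius
    lon = np.array([1.0, 0.0, 0.0])
    circ = np.array([0.0, -math.sin(theta), math.cos(theta)])
    apical = np.array([0.0, -math.cos(theta), -math.sin(theta)])  # inward
    return lon, circ, apical


def _seed_positions(config: SimConfig, rng: np.random.Generator, n: int):
    """Jittered-grid seed positions in unrolled (axial, arc) coordinates."""
    circumference = 2 * math.pi * config.tube_radius
    length = config.tube_length
    n_arc = max(1, int(round(circumference / config.cell_spacing)))
    n_ax = max(1, math.ceil(n / n_arc))
    ax_step = length / n_ax
    arc_step = circumference / n_arc
    pts = []
    for i in range(n_ax):
        for j in range(n_arc):
            pts.append(((i + 0.5) * ax_step, (j + 0.5 + 0.5 * (i % 2)) * arc_step))
    pts = np.array(pts)
    order = rng.permutation(len(pts))[:n]
    chosen = pts[order]
    jitter = rng.uniform(-0.05, 0.05, size=chosen.shape) * np.array(
        [ax_step, arc_step]
    )
    return chosen + jitter


# ---------------------------------------------------------------------------
# Type quotas and ratio targets
# ---------------------------------------------------------------------------

def _assign_labels(config: SimConfig, rng: np.random.Generator) -> list:
    n = config.n_cells
    if config.quota_mode:
        n_stem = int(round(config.stem_fraction * n))
        n_ee = int(round(config.ee_fraction * n))
        n_ec = int(round(config.ec_fraction * n))
        n_eb = n - n_stem - n_ee - n_ec
        if n_eb < 0:
            raise ValueError("type quotas exceed n_cells")
        labels = (
            ["stem"] * n_stem + ["enteroendocrine"] * n_ee
            + ["enterocyte"] * n_ec + ["enteroblast"] * n_eb
        )
    else:
        eb_frac = 1 - config.stem_fraction - config.ee_fraction - config.ec_fraction
        labels = list(
            rng.choice(
                ["stem", "enteroendocrine", "enterocyte", "enteroblast"],
                size=n,
                p=[config.stem_fraction, config.ee_fraction, config.ec_fraction, eb_frac],
            )
        )
    rng.shuffle(labels)
    return labels


def _truncated_normal(rng, loc, scale, lo, hi, size):
    out = rng.normal(loc, scale, size=size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(loc, scale, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _draw_volume(label: str, rng) -> float:
    # EC nuclei are polyploid (> 113 µm³ by construction); all others diploid.
    if label == "enterocyte":
        return float(rng.uniform(140.0, 240.0))
    return float(rng.uniform(45.0, 95.0))


def _target_ratio_center(label: str, config: SimConfig, rng) -> float:
    lo_mode, hi_mode = config.ratio_modes
    lo_sd, hi_sd = config.ratio_mode_sds
    if label == "enteroblast":
        return float(_truncated_normal(rng, hi_mode, hi_sd, 0.0, RATIO_CAP, 1)[0])
    return float(_truncated_normal(rng, lo_mode, lo_sd, 0.0, RATIO_CAP, 1)[0])


# ---------------------------------------------------------------------------
# Track generation
# ---------------------------------------------------------------------------

def _check_event_overlap(config: SimConfig, assignments: dict):
    """Reject schedules that give one cell two overlapping events."""
    for cell, intervals in assignments.items():
        intervals = sorted(intervals)
        for (a0, a1), (b0, b1) in zip(intervals, intervals[1:]):
            if b0 < a1:
                raise ValueError(
                    f"cell {cell} has overlapping scheduled events "
                    f"({a0}-{a1} and {b0}-{b1} min)"
                )


def generate_tracks(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a tracked-nuclei table and its ground truth.

    One row per living cell per frame with the track-table schema of
    :mod:`midgut4d.io`.  Nuclei sit on the tube surface and follow a
    bounded random walk in unrolled surface coordinates; stem/EB/EC/EE
    labels follow the configured fractions (exact quotas by default); raw
    intensities are constructed so that the normalized GFP:RFP of stem
    cells clusters at the low mode and of enteroblasts at the high mode.
    Scheduled mitoses, transitions and sibling pairs are embedded and
    recorded in the returned :class:`GroundTruth`.
    """
    rng = np.random.default_rng(config.rng_seed)
    truth = GroundTruth()
    times = config.times()
    n_frames = config.n_frames

    labels = _assign_labels(config, rng)
    seeds = _seed_positions(config, rng, config.n_cells)

    # Bounded random walk on the unrolled surface.
    steps = rng.normal(0.0, config.motion_sd, size=(n_frames - 1, config.n_cells, 2))
    coords = np.empty((n_frames, config.n_cells, 2))
    coords[0] = seeds
    circumference = 2 * math.pi * config.tube_radius
    for f in range(1, n_frames):
        coords[f] = coords[f - 1] + steps[f - 1]
        coords[f, :, 0] = np.clip(coords[f, :, 0], 0.0, config.tube_length)
        coords[f, :, 1] %= circumference

    volumes = np.array([_draw_volume(lab, rng) for lab in labels])
    ratio_centers = np.array(
        [_target_ratio_center(lab, config, rng) for lab in labels]
    )

    # Per-frame target ratios: slow jitter around the per-cell centre.
    jitter_sd = 0.2 * np.where(
        np.array(labels) == "enteroblast",
        config.ratio_mode_sds[1],
        config.ratio_mode_sds[0],
    )
    ratio = np.clip(
        ratio_centers[None, :]
        + rng.normal(0.0, 1.0, size=(n_frames, config.n_cells)) * jitter_sd[None, :],
        0.0,
        RATIO_CAP,
    )

    # --- event cell assignment -------------------------------------------
    stem_ids = [i for i, lab in enumerate(labels) if lab == "stem"]
    assigned: set[int] = set()
    occupancy: dict[int, list] = {}

    def _claim(spec_index, explicit, t0, t1, kind):
        if explicit is not None:
            cell = explicit
        else:
            free = [c for c in stem_ids if c not in assigned]
            if not free:
                raise ValueError(f"not enough stem cells to host {kind} events")
            cell = free[0]
        assigned.add(cell)
        occupancy.setdefault(cell, []).append((t0, t1))
        return cell

    transition_cells = []
    for spec in config.transitions:
        cell = _claim(None, spec.cell_index, spec.baseline_end_min,
                      spec.crossing_min, "transition")
        transition_cells.append((cell, spec))

    mitosis_cells = []
    for spec in config.mitoses:
        duration = (len(spec.angle_schedule) - 1) * config.frame_interval
        cell = _claim(None, spec.cell_index, spec.t_condense_min,
                      spec.t_condense_min + duration, "mitosis")
        mitosis_cells.append((cell, spec))
    _check_event_overlap(config, occupancy)

    # --- transition ramps override ratio targets --------------------------
    for cell, spec in transition_cells:
        if not spec.baseline_end_min < spec.crossing_min:
            raise ValueError("transition crossing must come after the baseline")
        slope = (spec.threshold - spec.baseline_ratio) / (
            spec.crossing_min - spec.baseline_end_min
        )
        r = np.full(n_frames, spec.baseline_ratio)
        rising = times > spec.baseline_end_min
        r[rising] = spec.baseline_ratio + slope * (times[rising] - spec.baseline_end_min)
        r = np.minimum(r, spec.final_ratio)
        ratio[:, cell] = r
        truth.transitions.append(
            {
                "cell_id": cell,
                "baseline_time_min": float(spec.baseline_end_min),
                "crossing_time_min": float(spec.crossing_min),
                "baseline_ratio": float(spec.baseline_ratio),
                "threshold": float(spec.threshold),
            }
        )

    # --- assemble per-cell frame ranges -----------------------------------
    alive = np.ones((n_frames, config.n_cells), dtype=bool)
    extra_rows = []  # daughters and siblings appended as new cells
    next_id = config.n_cells

    positions = _embed(config, coords[:, :, 0], coords[:, :, 1])

    for cell, spec in mitosis_cells:
        record, daughters, decondense_frame = generate_mitosis_event(
            config, spec, cell, coords[:, cell, :].mean(axis=0)
        )
        truth.mitoses.append(
            {
                "record": record,
                "spec": spec,
                "cell_id": cell,
                "duration_min": (len(spec.angle_schedule) - 1) * config.frame_interval,
            }
        )
        # Mother track ends at decondensation; daughters are new cells.
        if decondense_frame < n_frames - 1:
            alive[decondense_frame + 1 :, cell] = False
            for d_pos in daughters:
                d_id = next_id
                next_id += 1
                truth.labels[d_id] = "stem"
                for f in range(decondense_frame + 1, n_frames):
                    drift = rng.normal(0.0, config.motion_sd, size=3)
                    d_pos = d_pos + drift
                    extra_rows.append(
                        (d_id, f, d_pos.copy(), float(rng.uniform(45, 95)),
                         config.ratio_modes[0], "stem")
                    )

    for pair_idx, spec in enumerate(config.sibling_pairs):
        state_seq = []
        for state, count in spec.states:
            if state not in CONTACT_DISTANCES:
                raise ValueError(f"unknown contact state {state!r}")
            state_seq.extend([state] * int(count))
        id1, id2 = next_id, next_id + 1
        next_id += 2
        anchor_ax = config.tube_length * (0.2 + 0.6 * (pair_idx / max(1, len(config.sibling_pairs))))
        anchor_arc = 0.0
        lon = np.array([1.0, 0.0, 0.0])
        center = _embed(config, np.array([anchor_ax]), np.array([anchor_arc]))[0]
        frames_used = []
        for k, state in enumerate(state_seq):
            f = spec.birth_frame + k
            if f >= n_frames:
                break
            d = CONTACT_DISTANCES[state]
            p1 = center - 0.5 * d * lon
            p2 = center + 0.5 * d * lon
            extra_rows.append((id1, f, p1, 70.0, config.ratio_modes[0], "stem"))
            extra_rows.append((id2, f, p2, 70.0, config.ratio_modes[0], "stem"))
            frames_used.append((f, state))
        truth.labels[id1] = "stem"
        truth.labels[id2] = "stem"
        truth.sibling_pairs.append(
            {
                "cell_ids": (id1, id2),
                "birth_frame": int(spec.birth_frame),
                "states": [s for _, s in frames_used],
                "frames": [f for f, _ in frames_used],
            }
        )

    # --- intensities -------------------------------------------------------
    rows = []
    label_arr = list(labels)
    for cell in range(config.n_cells):
        truth.labels[cell] = label_arr[cell]
        truth.ratio_targets[cell] = ratio[:, cell].copy()
    base_rfp = rng.uniform(0.35, 0.90, size=config.n_cells)

    cells_frames = []  # (cell_id, frame, position, volume, target_ratio, label)
    for cell in range(config.n_cells):
        for f in range(n_frames):
            if alive[f, cell]:
                cells_frames.append(
                    (
                        cell,
                        f,
                        positions[f, cell],
                        volumes[cell],
                        ratio[f, cell],
                        label_arr[cell],
                    )
                )
    cells_frames.extend(extra_rows)
    cells_frames.sort(key=lambda r: (r[1], r[0]))

    n_rows = len(cells_frames)
    rfp_n = np.empty(n_rows)
    tgt = np.empty(n_rows)
    for i, (cell, f, _pos, _vol, r, _lab) in enumerate(cells_frames):
        base = base_rfp[cell] if cell < config.n_cells else 0.6
        rfp_n[i] = np.clip(base + rng.normal(0.0, 0.02), 0.05, 1.0)
        tgt[i] = r

    # Pin one calibration frame per channel to the channel maximum, so the
    # per-movie maxima are attained and normalized ratios equal the targets.
    i_rfp = int(np.argmax(rfp_n))
    rfp_n[i_rfp] = 1.0
    gfp_n = np.clip(tgt * rfp_n, 0.0, 1.0)
    i_gfp = int(np.argmax(gfp_n))
    gfp_n[i_gfp] = 1.0
    truth.calibration = {
        "rfp": (cells_frames[i_rfp][0], cells_frames[i_rfp][1]),
        "gfp": (cells_frames[i_gfp][0], cells_frames[i_gfp][1]),
    }

    cfp_n = np.array(
        [
            np.clip(0.5 + 0.4 * rng.random(), 0.05, 1.0)
            if lab in ("stem", "enteroblast")
            else 0.02
            for (_c, _f, _p, _v, _r, lab) in cells_frames
        ]
    )

    noise = {
        ch: rng.normal(0.0, config.intensity_noise_sd * CHANNEL_BASE[ch], size=n_rows)
        if config.intensity_noise_sd > 0
        else np.zeros(n_rows)
        for ch in CHANNEL_BASE
    }

    for i, (cell, f, pos, vol, _r, lab) in enumerate(cells_frames):
        rows.append(
            {
                "movie_id": config.movie_id,
                "cell_id": cell,
                "frame": f,
                "t_min": times[f],
                "x_um": pos[0],
                "y_um": pos[1],
                "z_um": pos[2],
                "volume_um3": vol,
                "cfp_raw": max(
                    0.0, config.gain * (cfp_n[i] * CHANNEL_BASE["cfp"] + noise["cfp"][i])
                ),
                "gfp_raw": max(
                    0.0, config.gain * (gfp_n[i] * CHANNEL_BASE["gfp"] + noise["gfp"][i])
                ),
                "rfp_raw": max(
                    0.0, config.gain * (rfp_n[i] * CHANNEL_BASE["rfp"] + noise["rfp"][i])
                ),
                "label": lab,
            }
        )
    table = pd.DataFrame(rows)
    return table, truth


# ---------------------------------------------------------------------------
# Mitosis events
# ---------------------------------------------------------------------------

def generate_mitosis_event(
    config: SimConfig,
    spec: MitosisSpec,
    cell_id: int = 0,
    surface_coord=None,
) -> tuple[MitosisRecord, list, int]:
    """Construct a mitosis with exactly the scheduled per-frame angles.

    Spindle poles are placed on the local tangent frame of the tube so
    that the horizontal-vertical and longitudinal-circumferential angles
    at each mitotic frame equal ``spec.angle_schedule``.  Returns
    ``(record, daughter_positions, decondense_frame)``.
    """
    if len(spec.angle_schedule) < 2:
        raise ValueError("angle schedule needs at least two frames")
    duration = (len(spec.angle_schedule) - 1) * config.frame_interval
    span = (config.n_frames - 1) * config.frame_interval
    if not config.frame_interval <= duration <= span:
        raise ValueError("mitosis duration outside the movie span")
    for hv, lc in spec.angle_schedule:
        if not (0 <= hv <= 90 and 0 <= lc <= 90):
            raise ValueError("scheduled angles must lie in [0, 90] degrees")

    if surface_coord is None:
        surface_coord = np.array([config.tube_length / 2, 0.0])
    axial, arc = float(surface_coord[0]), float(surface_coord[1])
    lon, circ, apical = _local_frame(config, arc)
    center = _embed(config, np.array([axial]), np.array([arc]))[0]

    # Basal-plane reference triangle on the local tangent plane.
    plane_pts = (
        center + 3.0 * lon,
        center - 1.5 * lon + 2.5 * circ,
        center - 1.5 * lon - 2.5 * circ,
    )

    record = MitosisRecord(
        cell_id=cell_id,
        t_condense=spec.t_condense_min,
        t_decondense=spec.t_condense_min + duration,
        mother=center.copy(),
        long_axis=lon.copy(),
        movie_id=config.movie_id,
    )

    v_final = None
    for k, (hv, lc) in enumerate(spec.angle_schedule):
        t = spec.t_condense_min + k * config.frame_interval
        hv_r, lc_r = math.radians(hv), math.radians(lc)
        in_plane = math.cos(lc_r) * lon + math.sin(lc_r) * circ
        v = math.cos(hv_r) * in_plane + math.sin(hv_r) * apical
        poles = np.stack(
            [center - 0.5 * POLE_SEPARATION * v, center + 0.5 * POLE_SEPARATION * v]
        )
        record.poles[t] = poles
        plane = fit_basal_plane(*plane_pts).oriented_toward(center + apical)
        record.planes[t] = plane
        v_final = v

    daughters = [
        center - 0.5 * DAUGHTER_SEPARATION * v_final,
        center + 0.5 * DAUGHTER_SEPARATION * v_final,
    ]
    record.daughters = np.stack(daughters)

    if spec.n_enteroblasts:
        hv_f, lc_f = spec.angle_schedule[-1]
        lc_r = math.radians(lc_f)
        eb_axis = math.cos(lc_r) * lon + math.sin(lc_r) * circ
        ebs = [center + 7.0 * eb_axis]
        if spec.n_enteroblasts == 2:
            ebs.append(center - 8.0 * eb_axis)
        record.enteroblasts = np.stack(ebs)

    decondense_frame = int(round(record.t_decondense / config.frame_interval))
    return record, daughters, decondense_frame


# ---------------------------------------------------------------------------
# Extrusion events
# ---------------------------------------------------------------------------

def _pulse_schedule(spec: ExtrusionSpec, frame_interval: float):
    """Segment boundaries (frame counts and areas) of a ratcheted closure.

    Constriction pulses alternate with relaxation pulses; relaxations
    regain part of the preceding drop, and constriction rates exceed
    relaxation rates while the net change closes the ring to ~2% of its
    initial area.
    """
    n = spec.n_pulses
    if n < 1:
        raise ValueError("n_pulses must be >= 1")
    n_intervals = int(round(spec.closure_duration_min / frame_interval))
    if n_intervals < 2:
        raise ValueError("closure_duration must span at least 2 frames")
    n_relax = n - 1
    min_needed = 3 * n_relax + 2 * n
    if n_intervals < min_needed:
        raise ValueError(
            f"{n} pulses need >= {min_needed} frame intervals; got {n_intervals}"
        )

    # Interval allocation: relaxation time roughly matches constriction time
    # (each relaxation >= 3 intervals, each constriction >= 2), mirroring the
    # observation that cumulative constriction and stabilization times are
    # similar while constriction proceeds at the faster rate.
    if n_relax:
        relax_len = max(3, n_intervals // (2 * n_relax))
        while relax_len > 3 and n_intervals - n_relax * relax_len < 2 * n:
            relax_len -= 1
        rem = n_intervals - n_relax * relax_len
    else:
        relax_len = 0
        rem = n_intervals
    base, extra = divmod(rem, n)
    con_lengths = [base + (1 if i < extra else 0) for i in range(n)]
    seg_lengths = []
    for i in range(n):
        seg_lengths.append(con_lengths[i])
        if i < n_relax:
            seg_lengths.append(relax_len)

    a0 = spec.initial_area_um2
    a_end = 0.02 * a0
    drop_total = a0 - a_end
    # Relaxations regain gamma * net drop in total; gamma is set so the mean
    # constriction rate is ~1.4x the mean relaxation rate (and capped so the
    # area never undershoots its final value).
    if n_relax:
        t_con = float(rem)
        t_rel = float(n_relax * relax_len)
        denom = 1.4 * t_con - t_rel
        gamma = t_rel / denom if denom > 0 else float(n - 1)
        gamma = min(max(gamma, 0.5), float(n - 1))
    else:
        gamma = 0.0
    delta = (1 + gamma) * drop_total / n            # per-constriction drop
    regain = gamma * drop_total / n_relax if n_relax else 0.0

    areas = [a0]
    kinds = []
    for i, seg_len in enumerate(seg_lengths):
        kind = "constriction" if i % 2 == 0 else "relaxation"
        change = -delta if kind == "constriction" else regain
        areas.append(areas[-1] + change)
        kinds.append(kind)
    areas[-1] = a_end  # absorb rounding
    return seg_lengths, areas, kinds


def generate_extrusion_event(
    config: SimConfig,
    spec: ExtrusionSpec,
    event_id: str = "ext0",
    area_noise_sd_fraction: float = 0.0,
    rng: np.random.Generator | None = None,
):
    """Generate one ratcheted ring closure with apical nuclear ejection.

    Returns ``(ring_event, plane_event, nucleus, truth)``: ring and plane
    annotation events in the table layout of :mod:`midgut4d.io`, a
    per-frame nucleus table (t_min, distance from the basal plane, 3D
    position), and the ground-truth schedule (segment times, kinds,
    rates, nuclear rise/peak times).
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    seg_lengths, areas, kinds = _pulse_schedule(spec, config.frame_interval)
    n_intervals = sum(seg_lengths)
    frame0 = int(round(spec.start_time_min / config.frame_interval))
    frames = np.arange(frame0, frame0 + n_intervals + 1)
    t = frames * config.frame_interval

    # Piecewise-linear area at frame times.
    boundaries = np.cumsum([0] + seg_lengths)
    area = np.empty(n_intervals + 1)
    for s, (b0, b1) in enumerate(zip(boundaries, boundaries[1:])):
        seg_frames = np.arange(b0, b1 + 1)
        area[b0 : b1 + 1] = np.interp(seg_frames, [b0, b1], [areas[s], areas[s + 1]])
    truth_rates = [
        (areas[s + 1] - areas[s]) / (seg_lengths[s] * config.frame_interval)
        for s in range(len(seg_lengths))
    ]
    if area_noise_sd_fraction > 0:
        noisy = area + rng.normal(
            0.0, area_noise_sd_fraction * spec.initial_area_um2, size=area.shape
        )
        area_out = np.maximum(noisy, 0.0)
    else:
        area_out = area

    # Geometry: hexagonal ring on the tangent plane at arc 0, mid-tube.
    axial = config.tube_length / 2
    lon, circ, apical = _local_frame(config, 0.0)
    center = _embed(config, np.array([axial]), np.array([0.0]))[0]
    plane_pts = np.stack(
        [center + 4.0 * lon, center - 2.0 * lon + 3.5 * circ, center - 2.0 * lon - 3.5 * circ]
    )

    n_vertices = 6
    ring_pts = np.empty((len(frames), n_vertices, 3))
    # The ring itself advances slowly apically during closure.
    ring_apical = np.linspace(0.0, 3.0, len(frames))
    for fi in range(len(frames)):
        rho = math.sqrt(2 * max(area_out[fi], 1e-9) / (3 * math.sqrt(3)))
        for v in range(n_vertices):
            ang = 2 * math.pi * v / n_vertices
            ring_pts[fi, v] = (
                center
                + rho * (math.cos(ang) * lon + math.sin(ang) * circ)
                + ring_apical[fi] * apical
            )

    # Nuclear travel: flat, rapid apical ejection, deeper penetration, recoil.
    rise_start = spec.start_time_min + 0.30 * spec.closure_duration_min
    peak_time = spec.start_time_min + 0.65 * spec.closure_duration_min
    recoil_end = spec.start_time_min + 0.90 * spec.closure_duration_min
    plateau = 0.5 * spec.peak_nuclear_displacement_um
    knots_t = [t[0], rise_start, peak_time, recoil_end, t[-1]]
    knots_d = [0.0, 0.0, spec.peak_nuclear_displacement_um, plateau, plateau]
    dist = np.interp(t, knots_t, knots_d)
    nucleus = pd.DataFrame(
        {
            "frame": frames,
            "t_min": t,
            "distance_um": dist,
            "x_um": center[0] + dist * apical[0],
            "y_um": center[1] + dist * apical[1],
            "z_um": center[2] + dist * apical[2],
        }
    )

    ring_event = {"frames": frames, "t_min": t, "points": ring_pts}
    plane_event = {
        "frames": frames,
        "t_min": t,
        "points": np.repeat(plane_pts[None], len(frames), axis=0),
    }
    seg_times = t[0] + np.asarray(boundaries) * config.frame_interval
    truth = {
        "event_id": event_id,
        "n_pulses": spec.n_pulses,
        "segment_times_min": seg_times.tolist(),
        "segment_kinds": kinds,
        "segment_rates": truth_rates,
        "area_initial": spec.initial_area_um2,
        "area_final": float(area[-1]),
        "nuclear_rise_start_min": float(rise_start),
        "nuclear_peak_min": float(peak_time),
        "nuclear_travel_duration_min": float(peak_time - rise_start),
        "nuclear_recoil_um": float(spec.peak_nuclear_displacement_um - plateau),
        "apical_direction": apical.tolist(),
    }
    return ring_event, plane_event, nucleus, truth


# ---------------------------------------------------------------------------
# Volume rendering
# ---------------------------------------------------------------------------

# Amplitude of a rendered nucleus per channel, by cell type.
_RENDER_AMPLITUDE = {
    "rfp": {lab: 200.0 for lab in ("stem", "enteroblast", "enterocyte", "enteroendocrine")},
    "cfp": {"stem": 180.0, "enteroblast": 180.0},
    "gfp": {"enteroblast": 180.0},
}
# With threshold = amplitude / 2, a Gaussian blob's thresholded support has
# radius 1.1774 sigma; sigma is chosen so that support volume ~ nominal.
_SIGMA_FACTOR = math.sqrt(2 * math.log(2.0))


def render_volume(
    frame_table: pd.DataFrame,
    config: SimConfig,
    noise_sd: float = 5.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one frame's nuclei as 3D Gaussian blobs, per channel.

    ``frame_table`` holds one row per cell at a single frame with centroid,
    ``volume_um3`` and ``label`` columns.  Each nucleus becomes an
    isotropic Gaussian whose half-maximum isosurface encloses the nominal
    nuclear volume, added to the channels its type expresses.  Gaussian
    read noise of ``noise_sd`` is added per voxel.  Returns a
    (c, z, y, x) float32 stack ordered (cfp, gfp, rfp).

    Raises if any centroid falls outside the rendering field.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed + 101)
    vz, vy, vx = config.voxel_size
    extent_y = extent_z = 2 * (config.tube_radius + config.margin)
    extent_x = config.tube_length + 2 * config.margin
    shape = (
        int(math.ceil(extent_z / vz)),
        int(math.ceil(extent_y / vy)),
        int(math.ceil(extent_x / vx)),
    )
    channels = ("cfp", "gfp", "rfp")
    stack = np.zeros((len(channels),) + shape, dtype=np.float32)

    if len(frame_table):
        pos = frame_table[["z_um", "y_um", "x_um"]].to_numpy(dtype=float)
        lims = np.array([extent_z, extent_y, extent_x])
        bad = np.any((pos < 0) | (pos >= lims), axis=1)
        if bad.any():
            ids = frame_table.loc[bad, "cell_id"].tolist()
            raise ValueError(f"centroids outside the rendering field: cells {ids}")

    for _, row in frame_table.iterrows():
        r_um = (3.0 * row["volume_um3"] / (4.0 * math.pi)) ** (1.0 / 3.0)
        sigma = r_um / _SIGMA_FACTOR
        cz, cy, cx = row["z_um"] / vz, row["y_um"] / vy, row["x_um"] / vx
        sz, sy, sx = sigma / vz, sigma / vy, sigma / vx
        reach = 3.0
        z0, z1 = max(0, int(cz - reach * sz)), min(shape[0], int(cz + reach * sz) + 2)
        y0, y1 = max(0, int(cy - reach * sy)), min(shape[1], int(cy + reach * sy) + 2)
        x0, x1 = max(0, int(cx - reach * sx)), min(shape[2], int(cx + reach * sx) + 2)
        zz = (np.arange(z0, z1) - cz) / sz
        yy = (np.arange(y0, y1) - cy) / sy
        xx = (np.arange(x0, x1) - cx) / sx
        blob = np.exp(
            -0.5
            * (
                zz[:, None, None] ** 2
                + yy[None, :, None] ** 2
                + xx[None, None, :] ** 2
            )
        ).astype(np.float32)
        for ci, ch in enumerate(channels):
            amp = _RENDER_AMPLITUDE[ch].get(row["label"])
            if amp:
                stack[ci, z0:z1, y0:y1, x0:x1] += amp * blob

    if noise_sd > 0:
        stack += rng.normal(0.0, noise_sd, size=stack.shape).astype(np.float32)
        np.maximum(stack, 0.0, out=stack)
    return stack
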