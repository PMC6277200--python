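"""Nucleus segmentation and combinatorial cell typing.

Cell identity in the fate-sensor genotype is encoded by three nuclear
markers: a ubiquitous RFP on all nuclei, a progenitor CFP on stem cells and
enteroblasts, and a Notch-reporter GFP on enteroblasts.  Channel-mask
arithmetic separates the populations:

* stem cells  = CFP AND NOT GFP
* enteroblasts = GFP
* mature cells = RFP AND NOT CFP

and mature cells split by nuclear volume: small (diploid, <= 113 µm³)
nuclei are enteroendocrine, large (polyploid, > 113 µm³) nuclei are
enterocytes.

Segmentation itself is intensity thresholding of a single channel followed
by connected-component labelling with a minimum-volume filter; centroids
are intensity-weighted and reported in physical µm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "TypingConfig",
    "CELL_TYPES",
    "segment_nuclei",
    "mask_populations",
    "classify_mature",
    "extract_intensities",
    "type_detections",
]

CELL_TYPES = ("stem", "enteroblast", "enterocyte", "enteroendocrine")


@dataclass(frozen=True)
class TypingConfig:
    """Segmentation and size-filter parameters.

    ``ee_volume_max`` is the nuclear-volume boundary (µm³) separating
    diploid enteroendocrine nuclei from polyploid enterocyte nuclei among
    esg-negative cells; the boundary itself is enteroendocrine.
    """

    ee_volume_max: float = 113.0
    threshold_method: str = "automatic"  # "automatic" (Otsu) or "fixed"
    fixed_thresholds: dict = field(default_factory=dict)  # channel -> value
    min_component_volume: float = 10.0   # µm³
    connectivity: int = 26               # 6 or 26 neighbourhood in 3D

    def __post_init__(self):
        if self.ee_volume_max <= 0:
            raise ValueError("ee_volume_max must be positive")
        if self.min_component_volume < 0:
            raise ValueError("min_component_volume must be >= 0")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")
        if self.threshold_method not in ("automatic", "fixed"):
            raise ValueError("threshold_method must be 'automatic' or 'fixed'")


def _binary_structure(connectivity: int):
    return ndimage.generate_binary_structure(3, 1 if connectivity == 6 else 3)


def _channel_threshold(volume: np.ndarray, config: TypingConfig, channel: str) -> float:
    if config.threshold_method == "fixed":
        try:
            return float(config.fixed_thresholds[channel])
        except KeyError:
            raise ValueError(f"no fixed threshold configured for channel {channel!r}")
    if volume.max() == volume.min():
        return float(volume.max())  # flat image -> empty foreground
    return float(threshold_otsu(volume))


def segment_nuclei(
    volume: np.ndarray,
    voxel_size_um,
    config: TypingConfig = TypingConfig(),
    channel: str = "rfp",
) -> tuple[pd.DataFrame, np.ndarray]:
    """Segment nuclei in a single-channel z-stack.

    Parameters
    ----------
    volume : (z, y, x) array
        Raw intensities of one channel at one time point.
    voxel_size_um : (z, y, x) triple
        Physical voxel dimensions, µm.

    Returns
    -------
    (table, labels)
        ``table`` has one row per retained component with ``label``,
        intensity-weighted centroid ``x_um, y_um, z_um`` and
        ``volume_um3`` (voxel count times voxel volume); ``labels`` is the
        filtered label image.  An all-background volume yields an empty
        table, not an error.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError("expected a 3D (z, y, x) volume")
    vz, vy, vx = (float(v) for v in voxel_size_um)
    if min(vz, vy, vx) <= 0:
        raise ValueError("voxel dimensions must be positive")
    voxel_vol = vz * vy * vx

    thr = _channel_threshold(volume, config, channel)
    mask = volume > thr
    labels, n = ndimage.label(mask, structure=_binary_structure(config.connectivity))
    if n == 0:
        return (
            pd.DataFrame(columns=["label", "x_um", "y_um", "z_um", "volume_um3"]),
            labels,
        )

    counts = np.bincount(labels.ravel())[1:]
    keep = np.flatnonzero(counts * voxel_vol >= config.min_component_volume) + 1
    remap = np.zeros(n + 1, dtype=labels.dtype)
    remap[keep] = np.arange(1, len(keep) + 1)
    labels = remap[labels]

    idx = np.arange(1, len(keep) + 1)
    coms = ndimage.center_of_mass(volume.astype(float), labels, idx)
    kept_counts = np.bincount(labels.ravel(), minlength=len(keep) + 1)[1:]
    table = pd.DataFrame(
        {
            "label": idx,
            "x_um": [c[2] * vx for c in coms],
            "y_um": [c[1] * vy for c in coms],
            "z_um": [c[0] * vz for c in coms],
            "volume_um3": kept_counts * voxel_vol,
        }
    )
    return table, labels


def mask_populations(cfp_mask, gfp_mask, rfp_mask) -> dict:
    """Channel-mask arithmetic separating the three marked populations.

    stem = CFP AND NOT GFP; enteroblast = GFP; mature = RFP AND NOT CFP.
    For the fate-sensor genotype (every CFP+ voxel is RFP+) the three masks
    are mutually exclusive and partition the labelled foreground.
    """
    cfp = np.asarray(cfp_mask, dtype=bool)
    gfp = np.asarray(gfp_mask, dtype=bool)
    rfp = np.asarray(rfp_mask, dtype=bool)
    if not (cfp.shape == gfp.shape == rfp.shape):
        raise ValueError("channel masks must share a shape")
    return {
        "stem_mask": cfp & ~gfp,
        "eb_mask": gfp,
        "mature_mask": rfp & ~cfp,
    }


def classify_mature(volume_um3: float, config: TypingConfig = TypingConfig()) -> str:
    """Size-filter an esg-negative nucleus into enteroendocrine/enterocyte.

    Volumes at or below ``ee_volume_max`` (default 113 µm³) are
    enteroendocrine; larger nuclei are enterocyte.
    """
    if volume_um3 <= 0:
        raise ValueError("nuclear volume must be positive")
    return "enteroendocrine" if volume_um3 <= config.ee_volume_max else "enterocyte"


def extract_intensities(labels: np.ndarray, channels: dict) -> pd.DataFrame:
    """Mean raw intensity of each labelled component in each channel.

    ``channels`` maps channel name to a stack of the same shape as
    ``labels``.  Returns one row per label with a ``{name}_raw`` column per
    channel.
    """
    labels = np.asarray(labels)
    present = np.unique(labels)
    present = present[present > 0]
    out = pd.DataFrame({"label": present.astype(int)})
    for name, stack in channels.items():
        stack = np.asarray(stack)
        if stack.shape != labels.shape:
            raise ValueError(f"channel {name!r} shape differs from label image")
        means = ndimage.mean(stack, labels=labels, index=present)
        out[f"{name}_raw"] = np.asarray(means, dtype=float)
    return out


def type_detections(
    detections: pd.DataFrame,
    cfp_threshold: float,
    gfp_threshold: float,
    config: TypingConfig = TypingConfig(),
) -> pd.DataFrame:
    """Assign a cell-type label to each detection from its mean intensities.

    Applies the population logic of :func:`mask_populations` at the level
    of whole nuclei (CFP/GFP positivity by threshold on the mean), then the
    nuclear-size filter for mature cells.  Requires ``cfp_raw``,
    ``gfp_raw`` and ``volume_um3`` columns.
    """
    out = detections.copy()
    cfp_pos = out["cfp_raw"].to_numpy() > cfp_threshold
    gfp_pos = out["gfp_raw"].to_numpy() > gfp_threshold
    labels = []
    for cp, gp, vol in zip(cfp_pos, gfp_pos, out["volume_um3"].to_numpy()):
        if gp:
            labels.append("enteroblast")
        elif cp:
            labels.append("stem")
        else:
            labels.append(classify_mature(vol, config))
    out["label"] = labels
    return out
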