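"""Threshold-based multi-sequence lesion compartmentalization.

Reproduces the semiautomated workflow: lesion voxels are those whose
intensity exceeds the normal-bone-marrow reference (control VOI mean +
k·SD) — on both the contrast-enhanced T1W and the T2W volume for T1C+,
on the T2W volume only for T2W+ — and the perilesional compartment is the
2-mm isotropic expansion of the combined lesion restricted to voxels that
look like normal marrow on both sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import Compartment

__all__ = [
    "ControlStats",
    "CompartmentLabelmap",
    "control_stats",
    "segment_lesion",
    "perilesional_shell",
    "compose_labelmap",
]

# relative SD floor so the normal-appearance band is well defined even on
# noiseless (zero-variance) control regions
_SD_FLOOR_REL = 1e-9


@dataclass(frozen=True)
class ControlStats:
    """Mean/SD of the control-VOI intensities for one sequence, with the
    mask they were computed over.  SD is the sample (ddof=1) definition."""

    mean: float
    sd: float
    n: int
    mask: np.ndarray

    def threshold(self, k: float) -> float:
        return self.mean + k * self.sd

    def band(self, k: float) -> tuple[float, float]:
        sd = max(self.sd, _SD_FLOOR_REL * max(abs(self.mean), 1.0))
        return self.mean - k * sd, self.mean + k * sd


@dataclass
class CompartmentLabelmap:
    """Integer labelmap {0 bg, 1 T1C+, 2 T2W+, 3 PL, 4 C} plus the
    provenance of the thresholds that produced it."""

    labels: np.ndarray
    meta: dict


def control_stats(volume: np.ndarray, control_mask: np.ndarray) -> ControlStats:
    """Mean/SD of a sequence over the control VOI."""
    vol = np.asarray(volume, dtype=float)
    mask = np.asarray(control_mask, dtype=bool)
    if mask.shape != vol.shape:
        raise ValueError("control mask does not match the volume grid")
    vals = vol[mask]
    if vals.size == 0:
        raise ValueError("control mask is empty")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return ControlStats(mean=float(vals.mean()), sd=sd, n=int(vals.size), mask=mask)


def segment_lesion(
    t1c_volume: np.ndarray,
    t2w_volume: np.ndarray,
    stats_t1c: ControlStats,
    stats_t2w: ControlStats,
    k: float = 2.0,
    min_component_voxels: int = 5,
) -> dict[str, np.ndarray]:
    """Threshold the two sequences into disjoint T1C+ and T2W+ masks.

    A voxel is T1C+ iff it exceeds mean + k·SD of the control on *both*
    sequences (enhancing and hyperintense); T2W+ iff only the T2W
    criterion holds.  Connected components of the combined lesion smaller
    than ``min_component_voxels`` are discarded — the programmatic stand-in
    for the manual cleanup step of a semiautomated workflow, suppressing
    isolated threshold crossings in normal marrow.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    t1c = np.asarray(t1c_volume, dtype=float)
    t2w = np.asarray(t2w_volume, dtype=float)
    if t1c.shape != t2w.shape:
        raise ValueError("volumes must share a grid")
    hot_t1c = t1c > stats_t1c.threshold(k)
    hot_t2w = t2w > stats_t2w.threshold(k)
    combined = hot_t2w  # lesion voxels are T2W-hyperintense in both classes
    if min_component_voxels > 1 and combined.any():
        lab, n = ndimage.label(combined)
        sizes = np.bincount(lab.ravel())
        keep = np.flatnonzero(sizes >= min_component_voxels)
        combined = np.isin(lab, keep[keep > 0])
    return {"T1C+": combined & hot_t1c, "T2W+": combined & ~hot_t1c}


def perilesional_shell(
    lesion_masks: dict[str, np.ndarray],
    spacing: tuple[float, float, float],
    radius_mm: float,
    t1c_volume: np.ndarray,
    t2w_volume: np.ndarray,
    stats_t1c: ControlStats,
    stats_t2w: ControlStats,
    k: float = 2.0,
) -> np.ndarray:
    """2-mm (by default) isotropic expansion of the combined lesion,
    restricted to normal-appearing voxels on both sequences.

    Distances are Euclidean in physical units (mm); a voxel joins the
    shell when its center lies within ``radius_mm`` of a lesion voxel
    center, it is not itself lesion, and both its intensities fall within
    mean ± k·SD of the control.
    """
    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    combined = np.zeros_like(next(iter(lesion_masks.values())), dtype=bool)
    for m in lesion_masks.values():
        combined |= np.asarray(m, dtype=bool)
    if not combined.any():
        return np.zeros_like(combined)
    dist = ndimage.distance_transform_edt(~combined, sampling=spacing)
    shell = (dist <= radius_mm + 1e-12) & ~combined
    lo1, hi1 = stats_t1c.band(k)
    lo2, hi2 = stats_t2w.band(k)
    t1c = np.asarray(t1c_volume, dtype=float)
    t2w = np.asarray(t2w_volume, dtype=float)
    normal = (t1c >= lo1) & (t1c <= hi1) & (t2w >= lo2) & (t2w <= hi2)
    return shell & normal


def compose_labelmap(
    masks: dict[str, np.ndarray],
    control_mask: np.ndarray,
    meta: dict | None = None,
) -> CompartmentLabelmap:
    """Merge the compartment masks with precedence T1C+ > T2W+ > PL > C."""
    control = np.asarray(control_mask, dtype=bool)
    for name in ("T1C+", "T2W+"):
        if name in masks and np.any(np.asarray(masks[name], dtype=bool) & control):
            raise ValueError(f"control mask overlaps the {name} lesion mask")
    labels = np.zeros(control.shape, dtype=np.int16)
    order = [("C", control, Compartment.CONTROL),
             ("PL", masks.get("PL"), Compartment.PL),
             ("T2W+", masks.get("T2W+"), Compartment.T2W),
             ("T1C+", masks.get("T1C+"), Compartment.T1C)]
    for _, mask, code in order:  # later assignments take precedence
        if mask is not None:
            labels[np.asarray(mask, dtype=bool)] = int(code)
    return CompartmentLabelmap(labels=labels, meta=dict(meta or {}))
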