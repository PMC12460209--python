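"""Lesion stratification: T2W/T1C mismatch classification, 40-voxel
probing-site VOIs, and region-mean extraction into the lesion table."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .config import COMPARTMENT_NAMES, Compartment

__all__ = [
    "classify_mismatch",
    "place_site_voi",
    "extract_region_means",
    "DEFAULT_VOI_VOXELS",
]

DEFAULT_VOI_VOXELS = 40  # ~ mean lesion volume per probing site (about 37 voxels)


def classify_mismatch(
    t1c_volumes,
    t2w_volumes,
    mode: str = "reference_range",
    level: float = 0.95,
) -> np.ndarray:
    """Flag lesions whose T2W+ volume exceeds the cohort 95% interval of
    T1C+ volumes.

    ``mode='reference_range'`` (default) takes the upper bound as
    mean + z·SD of the T1C+ volumes — a per-lesion exceedance criterion;
    ``mode='ci_mean'`` uses mean + z·SD/sqrt(n), the confidence interval
    of the mean.  Both are scale-invariant.  Requires >= 2 lesions.
    """
    from scipy.stats import norm

    v1 = np.asarray(t1c_volumes, dtype=float)
    v2 = np.asarray(t2w_volumes, dtype=float)
    if v1.ndim != 1 or v1.shape != v2.shape:
        raise ValueError("need matching 1-D arrays of per-lesion volumes")
    if v1.size < 2:
        raise ValueError(
            "mismatch classification needs >= 2 lesions: the 95% interval "
            "requires dispersion across the cohort")
    z = norm.ppf(0.5 + level / 2.0)
    sd = np.std(v1, ddof=1)
    if mode == "reference_range":
        upper = v1.mean() + z * sd
    elif mode == "ci_mean":
        upper = v1.mean() + z * sd / np.sqrt(v1.size)
    else:
        raise ValueError("mode must be 'reference_range' or 'ci_mean'")
    return v2 > upper


def place_site_voi(
    lesion_mask: np.ndarray,
    site_anchor,
    n_voxels: int = DEFAULT_VOI_VOXELS,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> tuple[np.ndarray, bool]:
    """VOI of the ``n_voxels`` lesion voxels nearest the probing-site anchor.

    Distances are Euclidean in physical units; ties are broken by
    lexicographic voxel index.  If the lesion holds fewer voxels, all are
    taken and the shortfall flag is returned True.
    """
    mask = np.asarray(lesion_mask, dtype=bool)
    if not mask.any():
        raise ValueError("lesion mask is empty")
    if n_voxels < 1:
        raise ValueError("n_voxels must be >= 1")
    anchor = np.asarray(site_anchor, dtype=float)
    if anchor.shape != (mask.ndim,) or np.any(anchor < 0) or np.any(
            anchor > np.asarray(mask.shape) - 1):
        raise ValueError("anchor must be a voxel coordinate inside the volume")
    idx = np.argwhere(mask)
    d = np.linalg.norm((idx - anchor) * np.asarray(spacing), axis=1)
    order = np.lexsort(tuple(idx.T[::-1]) + (d,))  # distance, then i, j, k
    take = order[: min(n_voxels, idx.shape[0])]
    voi = np.zeros_like(mask)
    voi[tuple(idx[take].T)] = True
    return voi, idx.shape[0] < n_voxels


def extract_region_means(
    maps: dict[str, np.ndarray],
    regions: dict[str, np.ndarray] | np.ndarray,
) -> pd.DataFrame:
    """Arithmetic mean of each map over each region's valid voxels.

    ``regions`` is either a dict of boolean masks or an integer labelmap
    (non-zero analysis codes are turned into masks).  Rows carry the
    region name, voxel count, per-map means and the per-map count of valid
    (finite) voxels; empty or all-NaN regions yield NaN means with a
    warning.
    """
    if isinstance(regions, np.ndarray):
        labs = regions
        regions = {
            COMPARTMENT_NAMES[Compartment(code)]: labs == code
            for code in np.unique(labs) if 0 < code <= int(Compartment.CONTROL)
        }
    rows = []
    for name, mask in regions.items():
        mask = np.asarray(mask, dtype=bool)
        row = {"region": name, "n_voxels": int(mask.sum())}
        for map_name, vol in maps.items():
            vals = np.asarray(vol, dtype=float)[mask]
            finite = np.isfinite(vals)
            row[f"n_valid_{map_name}"] = int(finite.sum())
            if finite.any():
                row[map_name] = float(vals[finite].mean())
            else:
                row[map_name] = np.nan
                warnings.warn(f"region {name!r} has no valid voxels for {map_name!r}")
        rows.append(row)
    return pd.DataFrame(rows)
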