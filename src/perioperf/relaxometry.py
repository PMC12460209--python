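"""Baseline T1/M0 mapping from the variable-flip-angle series.

Per voxel the spoiled gradient-echo equation is linearized: plotting
S/tan(a) against S/sin(a) over flip angles gives a line with slope
E1 = exp(-TR/T1), so T1 = -TR / ln(slope) and M0 follows from the
intercept.  Voxels whose slope falls outside (0, 1) are masked invalid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .models import spgr_signal

__all__ = ["T1M0Maps", "fit_vfa_t1"]


@dataclass
class T1M0Maps:
    """Fitted baseline maps: ``t1`` (ms), ``m0`` (signal units), boolean
    validity ``mask``.  Invalid voxels carry NaN."""

    t1: np.ndarray
    m0: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        if not (self.t1.shape == self.m0.shape == self.mask.shape):
            raise ValueError("map shapes must match")


def fit_vfa_t1(
    vfa_signals: np.ndarray,
    flips_deg,
    tr_ms: float,
    nonlinear_refine: bool = False,
) -> T1M0Maps:
    """Fit T1 and M0 maps from a variable-flip-angle SPGR series.

    Parameters
    ----------
    vfa_signals
        Array of shape ``(n_flips, ...)`` — one volume per flip angle, all
        co-registered on the same grid.
    flips_deg
        Flip angles in degrees, one per volume, at least two distinct.
    tr_ms
        Repetition time in ms.
    nonlinear_refine
        Refine valid voxels with a nonlinear least-squares fit of the full
        SPGR equation, seeded from the linear solution.
    """
    sig = np.asarray(vfa_signals, dtype=float)
    flips = np.asarray(flips_deg, dtype=float)
    if flips.ndim != 1 or flips.size < 2 or np.unique(flips).size < 2:
        raise ValueError("need at least two distinct flip angles")
    if sig.shape[0] != flips.size:
        raise ValueError("first axis of vfa_signals must match number of flip angles")
    if tr_ms <= 0:
        raise ValueError("tr must be positive")

    shape = sig.shape[1:]
    s = sig.reshape(flips.size, -1)
    a = np.deg2rad(flips)[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        y = s / np.sin(a)
        x = s / np.tan(a)
        n = flips.size
        sx, sy = x.sum(0), y.sum(0)
        sxx, sxy = (x * x).sum(0), (x * y).sum(0)
        denom = n * sxx - sx * sx
        slope = (n * sxy - sx * sy) / denom
        intercept = (sy - slope * sx) / n
        t1 = -tr_ms / np.log(slope)
        m0 = intercept / (1.0 - slope)

    valid = (
        np.isfinite(slope) & (slope > 0) & (slope < 1)
        & np.isfinite(intercept) & (intercept > 0)
        & (np.abs(s).sum(0) > 0)
    )
    t1 = np.where(valid, t1, np.nan)
    m0 = np.where(valid, m0, np.nan)

    if nonlinear_refine:
        idx = np.flatnonzero(valid)
        for i in idx:
            res = least_squares(
                lambda p, yi=s[:, i]: spgr_signal(p[0], p[1], tr_ms, flips) - yi,
                x0=[m0[i], t1[i]],
                bounds=([0, 1e-3], [np.inf, 1e5]),
            )
            m0[i], t1[i] = res.x

    return T1M0Maps(
        t1=t1.reshape(shape), m0=m0.reshape(shape), mask=valid.reshape(shape)
    )
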