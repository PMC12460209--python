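"""Dynamic-series kinetics: rigid motion correction, signal-to-concentration
conversion, voxelwise standard Tofts fitting and the 90-s AUC map.

The Tofts fit is solved by variable projection: for fixed kep = Ktrans/Ve
the model is linear in Ktrans, so the fit reduces to a 1-D search over kep
(coarse log grid, then vectorized golden-section refinement).  The search is
deterministic and shares its exponential-convolution quadrature with the
forward model, which makes noiseless round trips exact to solver tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

from .aif import parker_aif
from .config import AcquisitionConfig, AIFParams
from .models import expconv

__all__ = [
    "ConcentrationSeries",
    "ParameterMaps",
    "AIFSamples",
    "sample_aif",
    "detect_bolus_arrival",
    "rigid_motion_correct",
    "signal_to_concentration",
    "fit_tofts",
    "compute_auc",
]

KTRANS_MAX = 10.0   # min^-1, fit upper bound
VE_MIN = 1e-3
KEP_GRID = np.geomspace(2e-3, 300.0, 90)  # min^-1 coarse search grid


@dataclass
class ConcentrationSeries:
    """Tissue concentration (mM) on the dynamic frame grid.

    ``conc`` has time on the last axis; ``t_s`` are frame times in s;
    ``arrival_index`` is the first post-bolus frame; ``qc`` counts voxel
    frames masked during conversion.
    """

    conc: np.ndarray
    t_s: np.ndarray
    arrival_index: int
    mask: np.ndarray | None = None
    qc: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t_s) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if self.conc.shape[-1] != self.t_s.size:
            raise ValueError("last axis of conc must match the time grid")


@dataclass
class ParameterMaps:
    """Fitted kinetic maps aligned to the dynamic grid.

    ``ktrans`` in min^-1, ``ve`` as a fraction, ``auc`` dimensionless
    (filled by :func:`compute_auc`), ``residual`` the fit residual norm,
    ``mask`` the valid-fit mask, ``at_bounds`` nonzero where a parameter
    was clamped at its bound (1: ve at 1, 2: ktrans at upper bound).
    """

    ktrans: np.ndarray
    ve: np.ndarray
    residual: np.ndarray
    mask: np.ndarray
    at_bounds: np.ndarray
    auc: np.ndarray | None = None


@dataclass(frozen=True)
class AIFSamples:
    """An AIF evaluated on a fine grid that contains the frame times."""

    t_min: np.ndarray        # fine grid, minutes
    cp: np.ndarray           # mM on the fine grid
    frame_index: np.ndarray  # indices of the frame times within t_min

    @property
    def cp_frames(self) -> np.ndarray:
        return self.cp[self.frame_index]


def sample_aif(
    params: AIFParams,
    frame_times_s: np.ndarray,
    oversample_s: float = 1.0,
    hematocrit: float | None = None,
) -> AIFSamples:
    """Evaluate the population AIF on a fine grid containing the frame times.

    The fine grid (default 1-s spacing) resolves the bolus peak, which the
    ~12-s frame interval undersamples; the convolution quadrature then uses
    the fine curve and reads off tissue values at the frames.
    """
    ft = np.asarray(frame_times_s, dtype=float)
    fine = np.arange(ft[0], ft[-1] + oversample_s / 2, oversample_s)
    t_all = np.union1d(fine, ft)
    cp = parker_aif(t_all / 60.0, params, hematocrit=hematocrit)
    frame_index = np.searchsorted(t_all, ft)
    return AIFSamples(t_min=t_all / 60.0, cp=cp, frame_index=frame_index)


def detect_bolus_arrival(aif_curve: np.ndarray, frac: float = 0.05) -> int:
    """First sample index where the AIF exceeds ``frac`` of its peak."""
    c = np.asarray(aif_curve, dtype=float)
    peak = c.max()
    if peak <= 0:
        raise ValueError("AIF curve has no positive peak")
    return int(np.argmax(c >= frac * peak))


# ---------------------------------------------------------------------------
# motion correction


def rigid_motion_correct(
    dynamic: np.ndarray,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Rigidly align every dynamic frame to the first frame.

    Uses a correlation-metric rigid (Euler 3-D) registration; returns the
    corrected series and one 6-vector (rotations rad, translations mm) per
    frame.  Constant frames get the identity transform with a warning.
    """
    dyn = np.asarray(dynamic, dtype=float)
    if dyn.ndim != 4 or dyn.shape[-1] < 2:
        raise ValueError("dynamic must be 4-D with at least 2 frames")

    def to_img(vol: np.ndarray) -> sitk.Image:
        img = sitk.GetImageFromArray(np.ascontiguousarray(vol.T))
        img.SetSpacing(tuple(float(s) for s in spacing[::-1]))
        return img

    fixed = to_img(dyn[..., 0])
    out = np.empty_like(dyn)
    out[..., 0] = dyn[..., 0]
    params_log: list[np.ndarray] = [np.zeros(6)]
    for f in range(1, dyn.shape[-1]):
        vol = dyn[..., f]
        if np.ptp(vol) == 0:
            warnings.warn(f"frame {f} is constant; identity transform used")
            out[..., f] = vol
            params_log.append(np.zeros(6))
            continue
        moving = to_img(vol)
        tx = sitk.CenteredTransformInitializer(
            fixed, moving, sitk.Euler3DTransform(),
            sitk.CenteredTransformInitializerFilter.GEOMETRY)
        reg = sitk.ImageRegistrationMethod()
        reg.SetMetricAsCorrelation()
        reg.SetInterpolator(sitk.sitkLinear)
        reg.SetOptimizerAsRegularStepGradientDescent(
            learningRate=1.0, minStep=1e-5, numberOfIterations=200,
            relaxationFactor=0.6)
        reg.SetOptimizerScalesFromPhysicalShift()
        reg.SetInitialTransform(tx, inPlace=True)
        final = reg.Execute(fixed, moving)
        res = sitk.Resample(moving, fixed, final, sitk.sitkLinear, 0.0)
        corrected = sitk.GetArrayFromImage(res).T
        # keep the correction only if it did not reduce similarity to frame 1
        if _ncc(corrected, dyn[..., 0]) >= _ncc(vol, dyn[..., 0]):
            out[..., f] = corrected
            params_log.append(np.asarray(final.GetParameters()))
        else:
            out[..., f] = vol
            params_log.append(np.zeros(6))
    return out, params_log


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return float(a @ b / denom) if denom > 0 else 1.0


# ---------------------------------------------------------------------------
# signal -> concentration


def signal_to_concentration(
    dynamic: np.ndarray,
    t1m0,
    acq: AcquisitionConfig,
    arrival_index: int | None = None,
) -> ConcentrationSeries:
    """Invert the SPGR equation frame by frame to tissue concentration.

    The equilibrium magnetization is re-anchored on the pre-contrast mean of
    each voxel's own dynamic signal (with the fitted baseline T1), which
    removes scaling differences between the VFA and dynamic acquisitions.
    C(t) = (R1(t) - R1_0) / r1 in mM with R1 in s^-1.
    """
    dyn = np.asarray(dynamic, dtype=float)
    nb = acq.baseline_frames if arrival_index is None else arrival_index
    if nb < 1:
        raise ValueError("need at least one baseline frame")
    t1 = np.asarray(t1m0.t1, dtype=float)
    valid0 = np.asarray(t1m0.mask, dtype=bool) & np.isfinite(t1) & (t1 > 0)

    a = np.deg2rad(acq.flip_dynamic)
    tr = acq.tr_dynamic
    with np.errstate(invalid="ignore", divide="ignore"):
        e10 = np.exp(-tr / t1)
        s_base = dyn[..., :nb].mean(axis=-1)
        # effective M0 sin(a) anchored on the baseline signal
        m0sin = s_base * (1.0 - np.cos(a) * e10) / (1.0 - e10)
        s = dyn
        e1 = (m0sin[..., None] - s) / (m0sin[..., None] - np.cos(a) * s)
        ok = valid0[..., None] & np.isfinite(e1) & (e1 > 0) & (e1 < 1)
        r1 = -np.log(np.where(ok, e1, 0.5)) / tr * 1000.0  # s^-1
        r10 = (1000.0 / t1)[..., None]
        conc = np.where(ok, (r1 - r10) / acq.relaxivity_r1, np.nan)

    qc = {
        "invalid_voxel_frames": int(np.sum(~ok & valid0[..., None])),
        "invalid_t1_voxels": int(np.sum(~valid0)),
    }
    return ConcentrationSeries(
        conc=conc, t_s=acq.frame_times, arrival_index=nb,
        mask=valid0, qc=qc,
    )


# ---------------------------------------------------------------------------
# Tofts fit (variable projection over kep)


def fit_tofts(
    conc: ConcentrationSeries | np.ndarray,
    aif: AIFSamples,
    t_s: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    n_refine: int = 36,
) -> ParameterMaps:
    """Voxelwise standard Tofts fit of a concentration series against an AIF.

    Bounds: Ktrans in [0, 10] min^-1, Ve in (1e-3, 1].  The nonlinear
    parameter kep is searched on a fixed log grid and refined by golden
    section (deterministic); Ktrans is profiled out linearly.  Voxels whose
    Ve estimate exceeds 1 are refit on the Ve = 1 boundary and flagged.
    """
    if isinstance(conc, ConcentrationSeries):
        curves = conc.conc
        t_s = conc.t_s
        if mask is None:
            mask = conc.mask
    else:
        curves = np.asarray(conc, dtype=float)
    shape = curves.shape[:-1]
    nt = curves.shape[-1]
    y_all = curves.reshape(-1, nt)
    vmask = (
        np.ones(y_all.shape[0], dtype=bool) if mask is None
        else np.asarray(mask, dtype=bool).reshape(-1)
    )
    vmask = vmask & np.isfinite(y_all).all(axis=1)
    y = np.nan_to_num(y_all[vmask])
    n = y.shape[0]

    kt_out = np.full(y_all.shape[0], np.nan)
    ve_out = np.full(y_all.shape[0], np.nan)
    res_out = np.full(y_all.shape[0], np.nan)
    bound_out = np.zeros(y_all.shape[0], dtype=np.uint8)
    ok_out = np.zeros(y_all.shape[0], dtype=bool)

    if n:
        tmin, cp, fidx = aif.t_min, aif.cp, aif.frame_index
        if fidx.size != nt:
            raise ValueError("AIF frame grid does not match the series")
        yss = np.einsum("ij,ij->i", y, y)

        # coarse grid: basis shared across voxels
        basis = expconv(tmin, cp, KEP_GRID)[:, fidx]          # (K, T)
        bb = np.einsum("kj,kj->k", basis, basis)
        by = basis @ y.T                                       # (K, N)
        ktg = np.maximum(by, 0.0) / bb[:, None]
        rsq = yss[None, :] - ktg * ktg * bb[:, None]
        best = np.argmin(rsq, axis=0)

        lo = np.log(KEP_GRID[np.maximum(best - 1, 0)])
        hi = np.log(KEP_GRID[np.minimum(best + 1, KEP_GRID.size - 1)])
        kep, ktrans, resid = _golden_kep(tmin, cp, fidx, y, yss, lo, hi, n_refine)

        ve = np.where(ktrans > 0, ktrans / kep, np.nan)
        at_bound = np.zeros(n, dtype=np.uint8)

        # Ve > 1 is non-physical: refit on the Ve = 1 boundary (kep == ktrans)
        over = ktrans / np.where(kep > 0, kep, np.inf) > 1.0
        if np.any(over):
            kb, rb = _golden_boundary(tmin, cp, fidx, y[over], yss[over], n_refine)
            ktrans[over] = kb
            ve[over] = 1.0
            resid[over] = rb
            at_bound[over] |= 1
        hi_k = ktrans >= KTRANS_MAX
        ktrans = np.minimum(ktrans, KTRANS_MAX)
        at_bound[hi_k] |= 2

        zero = ktrans <= 0
        ve[zero] = np.nan

        idx = np.flatnonzero(vmask)
        kt_out[idx] = ktrans
        ve_out[idx] = ve
        res_out[idx] = np.sqrt(np.maximum(resid, 0.0))
        bound_out[idx] = at_bound
        ok_out[idx] = ~zero

    return ParameterMaps(
        ktrans=kt_out.reshape(shape),
        ve=ve_out.reshape(shape),
        residual=res_out.reshape(shape),
        mask=ok_out.reshape(shape),
        at_bounds=bound_out.reshape(shape),
    )


def _golden_kep(tmin, cp, fidx, y, yss, lo, hi, n_iter):
    """Vectorized golden-section minimization of the projection residual
    over log kep, one bracket per voxel, one basis evaluation per step."""
    gr = (np.sqrt(5.0) - 1.0) / 2.0

    def r_of(logk):
        b = expconv(tmin, cp, np.exp(logk))[:, fidx]
        bb = np.einsum("ij,ij->i", b, b)
        by = np.einsum("ij,ij->i", b, y)
        kt = np.maximum(by, 0.0) / np.where(bb > 0, bb, 1.0)
        return yss - kt * kt * bb, kt

    a, b = lo.copy(), hi.copy()
    c = b - gr * (b - a)
    d = a + gr * (b - a)
    fc, _ = r_of(c)
    fd, _ = r_of(d)
    for _ in range(n_iter):
        left = fc < fd
        a = np.where(left, a, c)
        b = np.where(left, d, b)
        # surviving interior point and its value
        keep_x = np.where(left, c, d)
        keep_f = np.where(left, fc, fd)
        new_x = np.where(left, b - gr * (b - a), a + gr * (b - a))
        new_f, _ = r_of(new_x)
        c = np.where(left, new_x, keep_x)
        fc = np.where(left, new_f, keep_f)
        d = np.where(left, keep_x, new_x)
        fd = np.where(left, keep_f, new_f)
    logk = (a + b) / 2.0
    resid, kt = r_of(logk)
    return np.exp(logk), kt, resid


def _golden_boundary(tmin, cp, fidx, y, yss, n_iter):
    """Golden-section fit of Ct = k * conv(cp, exp(-k t)) (Ve = 1 boundary)."""
    gr = (np.sqrt(5.0) - 1.0) / 2.0

    def r_of(logk):
        k = np.exp(logk)
        b = expconv(tmin, cp, k)[:, fidx] * k[:, None]
        d = y - b
        return np.einsum("ij,ij->i", d, d)

    a = np.full(y.shape[0], np.log(1e-4))
    b = np.full(y.shape[0], np.log(KTRANS_MAX))
    c = b - gr * (b - a)
    d = a + gr * (b - a)
    fc, fd = r_of(c), r_of(d)
    for _ in range(n_iter):
        left = fc < fd
        b = np.where(left, d, b)
        a = np.where(left, a, c)
        c = b - gr * (b - a)
        d = a + gr * (b - a)
        fc, fd = r_of(c), r_of(d)
    logk = (a + b) / 2.0
    return np.exp(logk), r_of(logk)


# ---------------------------------------------------------------------------
# AUC


def _window_integral(y: np.ndarray, t: np.ndarray, t0: float, t1: float) -> np.ndarray:
    """Trapezoidal integral of each row of ``y`` over [t0, t1], with linear
    interpolation at the window ends."""
    if t0 < t[0] - 1e-9 or t1 > t[-1] + 1e-9:
        raise ValueError("integration window exceeds the time grid")
    inner = (t > t0) & (t < t1)
    ts = np.concatenate(([t0], t[inner], [t1]))
    y0 = np.array([np.interp(t0, t, row) for row in np.atleast_2d(y)])
    y1 = np.array([np.interp(t1, t, row) for row in np.atleast_2d(y)])
    ys = np.concatenate([y0[:, None], np.atleast_2d(y)[:, inner], y1[:, None]], axis=1)
    return np.trapezoid(ys, ts, axis=1)


def compute_auc(
    series: ConcentrationSeries | np.ndarray,
    aif_curve: np.ndarray,
    window_s: float = 90.0,
    t_s: np.ndarray | None = None,
    aif_t_s: np.ndarray | None = None,
    arrival_index: int | None = None,
    normalize: bool = True,
) -> np.ndarray:
    """Area under the enhancement curve over ``window_s`` after bolus arrival.

    The voxel curve integral is divided by the AIF integral over the same
    window (``normalize=True``, the default), giving the dimensionless index;
    ``normalize=False`` returns the raw curve integral.  Arrival defaults to
    the first sample where the AIF reaches 5% of its peak.
    """
    if isinstance(series, ConcentrationSeries):
        curves, t = series.conc, series.t_s
    else:
        curves = np.asarray(series, dtype=float)
        if t_s is None:
            raise ValueError("t_s required when series is a bare array")
        t = np.asarray(t_s, dtype=float)
    aif_curve = np.asarray(aif_curve, dtype=float)
    ta = t if aif_t_s is None else np.asarray(aif_t_s, dtype=float)
    if arrival_index is None:
        arrival_index = detect_bolus_arrival(aif_curve)
    t0 = float(ta[arrival_index])
    t1 = t0 + float(window_s)
    if t1 > t[-1] + 1e-9 or t1 > ta[-1] + 1e-9:
        raise ValueError("AUC window exceeds the acquired series")

    shape = curves.shape[:-1]
    flat = np.nan_to_num(curves.reshape(-1, curves.shape[-1]))
    num = _window_integral(flat, t, t0, t1)
    if not normalize:
        return num.reshape(shape)
    den = _window_integral(aif_curve[None, :], ta, t0, t1)[0]
    if den <= 0:
        raise ValueError("AIF integral over the window is not positive")
    return (num / den).reshape(shape)
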