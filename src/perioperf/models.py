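"""Forward signal models: spoiled gradient-echo steady state and the
standard two-compartment exchange (Tofts) tissue model.

The exchange convolution uses an exponential-kernel recursion on the
discrete grid that is exact for piecewise-linear plasma concentration,
so forward simulation and model fitting share one quadrature.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["spgr_signal", "tofts_forward", "expconv"]


def spgr_signal(m0, t1_ms, tr_ms, flip_deg):
    """Steady-state spoiled gradient-echo signal.

    S = M0 sin(a) (1 - E1) / (1 - cos(a) E1), E1 = exp(-TR/T1).
    Arrays broadcast; T1 in ms, TR in ms, flip in degrees.
    """
    t1 = np.asarray(t1_ms, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("t1 must be positive")
    if tr_ms <= 0:
        raise ValueError("tr must be positive")
    flip = np.asarray(flip_deg, dtype=float)
    if np.any(flip <= 0) or np.any(flip >= 180):
        raise ValueError("flip angle must lie in (0, 180) degrees")
    a = np.deg2rad(flip)
    e1 = np.exp(-tr_ms / t1)
    return np.asarray(m0) * np.sin(a) * (1.0 - e1) / (1.0 - np.cos(a) * e1)


@njit(cache=True)
def _expconv_kernel(t, cp, keps, out):  # pragma: no cover - numba
    # out[j, i] = int_0^{t_i} cp(tau) exp(-keps[j] (t_i - tau)) dtau
    # exact for cp piecewise linear on t; series for small kep*dt
    n = t.shape[0]
    for j in range(keps.shape[0]):
        k = keps[j]
        f = 0.0
        out[j, 0] = 0.0
        for i in range(n - 1):
            dt = t[i + 1] - t[i]
            x = k * dt
            e = math.exp(-x)
            if x > 1e-5:
                i0 = (1.0 - (1.0 + x) * e) / (k * x)
                i1 = (1.0 - e) / k - i0
            else:
                i0 = dt * (0.5 - x / 3.0 + x * x / 8.0)
                i1 = dt * (0.5 - x / 6.0 + x * x / 24.0)
            f = e * f + cp[i] * i0 + cp[i + 1] * i1
            out[j, i + 1] = f


def expconv(t_min: np.ndarray, cp: np.ndarray, keps) -> np.ndarray:
    """Convolution of ``cp`` with ``exp(-kep t)`` for one or many kep.

    Parameters are on a common clock: ``t_min`` in minutes, ``keps`` in
    min^-1.  Returns shape ``(len(keps), len(t))`` (or 1-D for scalar kep).
    """
    t = np.ascontiguousarray(t_min, dtype=np.float64)
    c = np.ascontiguousarray(cp, dtype=np.float64)
    if t.shape != c.shape or t.ndim != 1:
        raise ValueError("t and cp must be matching 1-D arrays")
    scalar = np.isscalar(keps) or np.ndim(keps) == 0
    k = np.atleast_1d(np.asarray(keps, dtype=np.float64))
    out = np.empty((k.size, t.size))
    _expconv_kernel(t, c, k, out)
    return out[0] if scalar else out


def tofts_forward(ktrans: float, ve: float, cp: np.ndarray, t_min: np.ndarray) -> np.ndarray:
    """Tissue concentration under the standard exchange model.

    Ct(t) = Ktrans * int_0^t Cp(tau) exp(-(Ktrans/Ve)(t - tau)) dtau,
    with Ktrans in min^-1, Ve a fraction in (0, 1], t in minutes and
    Cp/Ct in mM.
    """
    if not np.isfinite(ktrans) or ktrans < 0:
        raise ValueError("ktrans must be finite and >= 0")
    if ktrans == 0:
        return np.zeros_like(np.asarray(t_min, dtype=float))
    if not (0 < ve <= 1):
        raise ValueError("ve must lie in (0, 1] when ktrans > 0")
    cp = np.asarray(cp, dtype=float)
    if np.any(cp < 0):
        raise ValueError("cp must be non-negative")
    return ktrans * expconv(t_min, cp, ktrans / ve)
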