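"""Population arterial input function (bi-Gaussian plus sigmoid-gated washout)."""

from __future__ import annotations

import numpy as np

from .config import AIFParams

__all__ = ["parker_aif"]


def parker_aif(
    t_min: np.ndarray,
    params: AIFParams | None = None,
    hematocrit: float | None = None,
) -> np.ndarray:
    """Evaluate the population blood-concentration curve on a time grid.

    Parameters
    ----------
    t_min
        Time grid in minutes, non-decreasing and non-negative.
    params
        Curve parameters; defaults to the published population values.
    hematocrit
        If given, the whole-blood curve is divided by ``1 - hematocrit`` to
        yield plasma concentration.  Default ``None`` uses the curve as
        plasma concentration directly, the common population-AIF convention.

    Returns
    -------
    Concentration in mM, zero before ``params.onset_delay``.
    """
    params = params or AIFParams()
    t = np.asarray(t_min, dtype=float)
    if t.ndim != 1:
        raise ValueError("time grid must be 1-D")
    if np.any(~np.isfinite(t)) or np.any(t < 0) or np.any(np.diff(t) < 0):
        raise ValueError("time grid must be finite, non-negative and non-decreasing")

    # shift so the bolus arrives at onset_delay (given in seconds)
    ts = t - params.onset_delay / 60.0
    cb = np.zeros_like(ts)
    pos = ts > 0
    tp = ts[pos]
    for a, tc, sig in ((params.a1, params.t1, params.sigma1),
                       (params.a2, params.t2, params.sigma2)):
        cb[pos] += a / (sig * np.sqrt(2.0 * np.pi)) * np.exp(
            -((tp - tc) ** 2) / (2.0 * sig**2))
    cb[pos] += params.alpha * np.exp(-params.beta * tp) / (
        1.0 + np.exp(-params.s * (tp - params.tau)))
    if hematocrit is not None:
        if not (0 <= hematocrit < 1):
            raise ValueError("hematocrit must lie in [0, 1)")
        cb = cb / (1.0 - hematocrit)
    return np.maximum(cb, 0.0)
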