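"""Protocol constants and shared domain types.

Units are stated per field and kept consistent across the package:
times at the sequence level in ms (TR) or s (dynamic timing), kinetic
quantities in minutes (Ktrans, kep in min^-1), concentrations in mM,
lengths in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

__all__ = [
    "Compartment",
    "COMPARTMENT_NAMES",
    "AcquisitionConfig",
    "AIFParams",
]


class Compartment(IntEnum):
    """Fixed label enumeration for the compartment labelmap.

    The first five codes are the analysis compartments; TOOTH and BONE
    are phantom-scene codes that segmentation treats as background.
    """

    BACKGROUND = 0
    T1C = 1      # contrast-enhancing lesion core
    T2W = 2      # T2-hyperintense, non-enhancing rim
    PL = 3       # perilesional 2-mm shell, normal-appearing
    CONTROL = 4  # distant normal bone marrow
    TOOTH = 5
    BONE = 6


COMPARTMENT_NAMES = {
    Compartment.BACKGROUND: "background",
    Compartment.T1C: "T1C+",
    Compartment.T2W: "T2W+",
    Compartment.PL: "PL",
    Compartment.CONTROL: "C",
    Compartment.TOOTH: "tooth",
    Compartment.BONE: "bone",
}


@dataclass(frozen=True)
class AcquisitionConfig:
    """Scanner/protocol constants for the dynamic VIBE protocol.

    Defaults follow the dental DCE protocol this package models:
    TR 4.47 ms, dynamic flip 15 deg, VFA flips 5/8/11/14/17 deg,
    42 dynamic cycles over 509 s, 0.9 mm isotropic perfusion voxels,
    0.1 mmol/kg gadoterate meglumine.
    """

    tr_dynamic: float = 4.47          # ms
    flip_dynamic: float = 15.0        # degrees
    flip_vfa: tuple[float, ...] = (5.0, 8.0, 11.0, 14.0, 17.0)  # degrees
    n_cycles: int = 42
    total_dynamic_time: float = 509.0  # s
    voxel_spacing: tuple[float, float, float] = (0.9, 0.9, 0.9)  # mm
    relaxivity_r1: float = 3.5        # L mmol^-1 s^-1, gadoterate at 3 T
    dose: float = 0.1                 # mmol/kg
    auc_window: float = 90.0          # s
    baseline_frames: int = 3          # pre-bolus frames

    def __post_init__(self) -> None:
        if self.tr_dynamic <= 0 or self.total_dynamic_time <= 0:
            raise ValueError("times must be strictly positive")
        if not (0 < self.flip_dynamic < 180):
            raise ValueError("flip_dynamic must lie in (0, 180) degrees")
        if self.n_cycles < 2:
            raise ValueError("need at least 2 dynamic cycles")
        flips = np.asarray(self.flip_vfa, dtype=float)
        if flips.size < 2 or np.any(np.diff(flips) <= 0) or np.any(flips <= 0):
            raise ValueError("flip_vfa must be >= 2 strictly increasing positive angles")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be positive")
        if self.relaxivity_r1 <= 0 or self.dose <= 0:
            raise ValueError("relaxivity and dose must be positive")
        if not (0 < self.auc_window <= self.total_dynamic_time):
            raise ValueError("auc_window must be positive and <= total dynamic time")
        if not (0 <= self.baseline_frames < self.n_cycles):
            raise ValueError("baseline_frames must be in [0, n_cycles)")

    @property
    def cycle_duration(self) -> float:
        """Frame interval in s (total dynamic time / number of cycles)."""
        return self.total_dynamic_time / self.n_cycles

    @property
    def frame_times(self) -> np.ndarray:
        """Dynamic frame times in s, first frame at t = 0."""
        return np.arange(self.n_cycles) * self.cycle_duration

    @property
    def bolus_onset(self) -> float:
        """Contrast arrival time in s (after the baseline frames)."""
        return self.baseline_frames * self.cycle_duration


@dataclass(frozen=True)
class AIFParams:
    """Population arterial input function parameters (bi-Gaussian + sigmoidal
    washout), with the published population values as defaults.

    Amplitudes a1, a2 in mmol·min, centers/widths in min, washout alpha in
    mmol, decay beta in min^-1, sigmoid steepness s in min^-1 and center tau
    in min.  onset_delay (s) shifts the whole curve to the bolus arrival.
    """

    a1: float = 0.809
    a2: float = 0.330
    t1: float = 0.17046
    t2: float = 0.365
    sigma1: float = 0.0563
    sigma2: float = 0.132
    alpha: float = 1.050
    beta: float = 0.1685
    s: float = 38.078
    tau: float = 0.483
    onset_delay: float = 0.0  # s

    def __post_init__(self) -> None:
        vals = (self.a1, self.a2, self.t1, self.t2, self.sigma1, self.sigma2,
                self.alpha, self.beta, self.s, self.tau, self.onset_delay)
        if not np.all(np.isfinite(vals)):
            raise ValueError("AIF parameters must be finite")
        if self.sigma1 <= 0 or self.sigma2 <= 0 or self.s <= 0:
            raise ValueError("widths and sigmoid steepness must be positive")
        if self.onset_delay < 0:
            raise ValueError("onset_delay must be non-negative")
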