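"""Synthetic digital phantoms of periodontal bone lesions.

A phantom is a 3-D jaw-like scene — bone block, tooth cylinder, an
enhancing lesion core (T1C+) with a T2-hyperintense non-enhancing rim
(T2W+), its 2-mm perilesional shell (PL) and a distant control region (C)
— with known voxelwise Ktrans/Ve/T1/M0 ground truth, rendered through the
spoiled gradient-echo acquisition model of the dental DCE protocol
(variable-flip-angle baselines, 42-cycle dynamic series, structural T2W
and contrast-enhanced T1W volumes, a CBCT-like density map).

Two design constraints are solved numerically rather than chosen:

* the control compartment's baseline T1 is set so that its 90-s
  enhancement AUC equals the perilesional one even though the perilesional
  Ktrans/Ve are elevated (the AUC-matched condition);
* the M0 of the normal-appearing compartments (PL, T2W+ rim) is set so
  their post-contrast structural intensity equals the control's, keeping
  them "normal-appearing" on contrast-enhanced T1W by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import brentq

from .aif import parker_aif
from .config import AcquisitionConfig, AIFParams, Compartment
from .kinetics import AIFSamples, _window_integral, detect_bolus_arrival, sample_aif
from .models import expconv, spgr_signal

__all__ = [
    "CompartmentSpec",
    "PhantomTruth",
    "CohortDesign",
    "generate_phantom",
    "render_acquisition",
    "enhancement_auc",
    "solve_matched_control_t1",
    "build_subject",
    "SITES",
]

SITES = ("mb", "b", "db", "ml", "l", "dl")  # six probing sites per tooth


@dataclass(frozen=True)
class CompartmentSpec:
    """One phantom compartment: a label, a geometry and its tissue truth.

    ``geometry`` is one of
    ``{"kind": "ellipsoid", "center_mm": (x,y,z), "radii_mm": (rx,ry,rz)}``,
    ``{"kind": "cylinder", "center_mm": (x,y), "radius_mm": r, "z_mm": (z0,z1)}``,
    ``{"kind": "shell", "around": (labels...), "radius_mm": r}`` (an
    isotropic expansion of previously painted labels, physical distance), or
    ``{"kind": "fill"}`` (everything still unpainted).
    Units: Ktrans min^-1, Ve fraction, T1 ms, M0/T2W/CBCT arbitrary units.
    """

    name: str
    label: int
    geometry: dict
    ktrans: float
    ve: float
    t1: float
    m0: float
    t2w: float
    cbct: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.ve <= 1.0):
            raise ValueError(f"{self.name}: ve must lie in [0, 1]")
        if self.ktrans < 0:
            raise ValueError(f"{self.name}: ktrans must be >= 0")
        if self.ktrans > 0 and self.ve == 0:
            raise ValueError(f"{self.name}: ve = 0 with ktrans > 0 is undefined")
        if self.t1 <= 0:
            raise ValueError(f"{self.name}: t1 must be positive")


@dataclass
class PhantomTruth:
    """Ground truth emitted by the simulator: the compartment labelmap,
    voxelwise kinetic/relaxometric maps, probing-site anchors and the
    per-site clinical flags (all synthetic)."""

    labels: np.ndarray
    ktrans: np.ndarray
    ve: np.ndarray
    t1: np.ndarray
    m0: np.ndarray
    t2w: np.ndarray
    cbct: np.ndarray
    spacing: tuple[float, float, float]
    seed: int
    site_anchors: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["tooth", "site", "i", "j", "k"]))
    clinical: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["tooth", "site", "bop", "bone_loss"]))

    def compartment_mask(self, label: int) -> np.ndarray:
        return self.labels == int(label)


def _grid_mm(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _paint_mask(spec: CompartmentSpec, shape, spacing, labels: np.ndarray) -> np.ndarray:
    g = spec.geometry
    kind = g["kind"]
    extent = [(n - 1) * s for n, s in zip(shape, spacing)]
    if kind == "ellipsoid":
        c, r = g["center_mm"], g["radii_mm"]
        for ci, ri, ei in zip(c, r, extent):
            if ci - ri < -1e-9 or ci + ri > ei + 1e-9:
                raise ValueError(f"{spec.name}: ellipsoid outside the field of view")
        xx, yy, zz = _grid_mm(shape, spacing)
        return ((xx - c[0]) / r[0]) ** 2 + ((yy - c[1]) / r[1]) ** 2 + (
            (zz - c[2]) / r[2]) ** 2 <= 1.0 + 1e-12
    if kind == "cylinder":
        (cx, cy), r = g["center_mm"], g["radius_mm"]
        z0, z1 = g["z_mm"]
        if cx - r < -1e-9 or cx + r > extent[0] + 1e-9 or cy - r < -1e-9 \
                or cy + r > extent[1] + 1e-9 or z0 < -1e-9 or z1 > extent[2] + 1e-9:
            raise ValueError(f"{spec.name}: cylinder outside the field of view")
        xx, yy, zz = _grid_mm(shape, spacing)
        return (((xx - cx) / r) ** 2 + ((yy - cy) / r) ** 2 <= 1.0 + 1e-12) \
            & (zz >= z0) & (zz <= z1)
    if kind == "shell":
        core = np.isin(labels, g["around"])
        if not core.any():
            return np.zeros(shape, dtype=bool)
        dist = ndimage.distance_transform_edt(~core, sampling=spacing)
        return (dist <= g["radius_mm"] + 1e-12) & ~core
    if kind == "fill":
        return np.ones(shape, dtype=bool)
    raise ValueError(f"unknown geometry kind {kind!r}")


def generate_phantom(
    specs: list[CompartmentSpec],
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float] = (0.9, 0.9, 0.9),
    seed: int = 0,
    background: CompartmentSpec | None = None,
) -> PhantomTruth:
    """Paint compartments into a voxel grid and populate the truth maps.

    Specs are painted in list order with first-wins precedence; ``shell``
    geometries see only labels painted before them.  A spec that realizes
    no voxel raises.  ``background`` supplies truth values for unpainted
    voxels (defaults to non-enhancing soft tissue).
    """
    if background is None:
        background = CompartmentSpec(
            "background", Compartment.BACKGROUND, {"kind": "fill"},
            ktrans=0.0, ve=0.0, t1=900.0, m0=400.0, t2w=95.0, cbct=30.0)
    labels = np.full(shape, -1, dtype=np.int16)
    maps = {k: np.zeros(shape) for k in ("ktrans", "ve", "t1", "m0", "t2w", "cbct")}

    for spec in list(specs) + [background]:
        mask = _paint_mask(spec, shape, spacing, np.where(labels < 0, 0, labels))
        mask &= labels < 0
        if spec is not background and not mask.any():
            raise ValueError(f"compartment {spec.name!r} realizes no voxel")
        labels[mask] = spec.label
        for k in maps:
            maps[k][mask] = getattr(spec, k)
    labels[labels < 0] = background.label
    return PhantomTruth(labels=labels.astype(np.int16), spacing=tuple(spacing),
                        seed=seed, **maps)


# ---------------------------------------------------------------------------
# acquisition rendering


def _rician(rng: np.random.Generator, signal: np.ndarray, sd: float) -> np.ndarray:
    """Magnitude of the signal with complex Gaussian channel noise."""
    if sd == 0:
        return signal.copy()
    re = signal + rng.normal(0.0, sd, signal.shape)
    im = rng.normal(0.0, sd, signal.shape)
    return np.hypot(re, im)


def render_acquisition(
    truth: PhantomTruth,
    acq: AcquisitionConfig,
    aif: AIFParams,
    noise_sd: float = 0.0,
    motion: np.ndarray | None = None,
    seed: int = 0,
    struct_noise_sd: float | None = None,
    cbct_noise_sd: float | None = None,
) -> dict:
    """Render the full synthetic dataset from a ground-truth phantom.

    Returns a dict with ``vfa`` (n_flips, X, Y, Z), ``dynamic``
    (X, Y, Z, n_cycles), ``t2w``, ``t1c`` (post-contrast structural) and
    ``cbct`` volumes, plus the ``AIFSamples`` used.  ``motion`` is an
    optional (n_cycles, 3) array of per-frame voxel shifts applied to the
    dynamic frames.  Deterministic under a fixed seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape != (acq.n_cycles, 3):
            raise ValueError("motion must have one (dx,dy,dz) shift per cycle")
    rng = np.random.default_rng(seed)
    if struct_noise_sd is None:
        struct_noise_sd = noise_sd * 8.0
    if cbct_noise_sd is None:
        cbct_noise_sd = noise_sd * 12.0

    shape = truth.labels.shape
    aifs = sample_aif(aif, acq.frame_times)
    kt = truth.ktrans.reshape(-1)
    ve = truth.ve.reshape(-1)
    t1 = truth.t1.reshape(-1)
    m0 = truth.m0.reshape(-1)

    ct_frames = np.zeros((kt.size, acq.n_cycles))
    active = kt > 0
    if active.any():
        kep = kt[active] / ve[active]
        conv = expconv(aifs.t_min, aifs.cp, kep)[:, aifs.frame_index]
        ct_frames[active] = kt[active, None] * conv

    r1 = 1000.0 / t1[:, None] + acq.relaxivity_r1 * ct_frames  # s^-1
    t1_t = 1000.0 / r1
    dynamic = spgr_signal(m0[:, None], t1_t, acq.tr_dynamic, acq.flip_dynamic)
    dynamic = _rician(rng, dynamic, noise_sd).reshape(*shape, acq.n_cycles)
    if motion is not None:
        for f in range(acq.n_cycles):
            if np.any(motion[f]):
                dynamic[..., f] = ndimage.shift(
                    dynamic[..., f], motion[f], order=1, mode="nearest")

    vfa = np.stack([
        _rician(rng, spgr_signal(m0, t1, acq.tr_dynamic, f), noise_sd).reshape(shape)
        for f in acq.flip_vfa
    ])

    # post-contrast structural T1W from the end-of-acquisition concentration
    t1_post = 1000.0 / (1000.0 / t1 + acq.relaxivity_r1 * ct_frames[:, -1])
    t1c = _rician(rng, spgr_signal(m0, t1_post, acq.tr_dynamic, acq.flip_dynamic),
                  noise_sd).reshape(shape)
    t2w = _rician(rng, truth.t2w.reshape(-1).copy(), struct_noise_sd).reshape(shape)
    cbct = truth.cbct + rng.normal(0.0, cbct_noise_sd, shape)

    return {"vfa": vfa, "dynamic": dynamic, "t2w": t2w, "t1c": t1c,
            "cbct": cbct, "aif_samples": aifs}


# ---------------------------------------------------------------------------
# design solvers


def enhancement_auc(
    ktrans: float, ve: float, t1_ms: float,
    acq: AcquisitionConfig, aifs: AIFSamples,
) -> float:
    """Noise-free 90-s AUC of the relative-enhancement signal curve,
    normalized by the AIF integral over the same window."""
    ct = ktrans * expconv(aifs.t_min, aifs.cp, ktrans / ve)[aifs.frame_index] \
        if ktrans > 0 else np.zeros(aifs.frame_index.size)
    t1_t = 1000.0 / (1000.0 / t1_ms + acq.relaxivity_r1 * ct)
    s = spgr_signal(1.0, t1_t, acq.tr_dynamic, acq.flip_dynamic)
    s0 = s[:acq.baseline_frames].mean()
    enh = s / s0 - 1.0
    i0 = detect_bolus_arrival(aifs.cp)
    t0 = aifs.t_min[i0] * 60.0
    t_frames = aifs.t_min[aifs.frame_index] * 60.0
    num = _window_integral(enh[None, :], t_frames, t0, t0 + acq.auc_window)[0]
    den = _window_integral(aifs.cp[None, :], aifs.t_min * 60.0, t0,
                           t0 + acq.auc_window)[0]
    return float(num / den)


def _expected_auc(ktrans, ve, t1_ms, acq, aifs, jitter_sd, nodes=7):
    """Expectation of the enhancement AUC when Ktrans and Ve are jointly
    scaled by a log-normal factor (Gauss–Hermite quadrature)."""
    if jitter_sd <= 0:
        return enhancement_auc(ktrans, ve, t1_ms, acq, aifs)
    x, w = np.polynomial.hermite.hermgauss(nodes)
    f = np.exp(np.sqrt(2.0) * jitter_sd * x)
    vals = [enhancement_auc(ktrans * fi, min(ve * fi, 0.95), t1_ms, acq, aifs)
            for fi in f]
    return float(np.sum(w * np.asarray(vals)) / np.sqrt(np.pi))


def solve_matched_control_t1(
    pl_ktrans: float, pl_ve: float, pl_t1: float,
    c_ktrans: float, c_ve: float,
    acq: AcquisitionConfig, aif: AIFParams,
    jitter_sd: float = 0.0,
    bracket: tuple[float, float] = (300.0, 6000.0),
) -> float:
    """Baseline T1 (ms) of the control compartment such that its
    enhancement AUC equals the perilesional one.

    The control has lower Ktrans but, on the relative-enhancement scale, a
    longer baseline T1 raises sensitivity to a given concentration — the
    baseline-T1 confound of the semiquantitative AUC that this design
    exploits to decouple AUC from permeability.  With ``jitter_sd`` > 0 the
    match is taken in expectation over the cohort's log-normal
    between-subject scaling of Ktrans/Ve (the AUC response is mildly
    nonlinear, so matching at the design point alone would leave a small
    systematic offset)."""
    aifs = sample_aif(aif, acq.frame_times)
    target = _expected_auc(pl_ktrans, pl_ve, pl_t1, acq, aifs, jitter_sd)

    def f(t1c):
        return _expected_auc(c_ktrans, c_ve, t1c, acq, aifs, jitter_sd) - target

    return float(brentq(f, *bracket, xtol=1e-6))


def _matched_m0(
    ref_signal: float, ktrans: float, ve: float, t1_ms: float,
    acq: AcquisitionConfig, aifs: AIFSamples,
) -> float:
    """M0 that makes a compartment's post-contrast structural T1W intensity
    equal ``ref_signal`` (keeps it normal-appearing by construction)."""
    ct_end = (ktrans * expconv(aifs.t_min, aifs.cp, ktrans / ve)[aifs.frame_index][-1]
              if ktrans > 0 else 0.0)
    t1_post = 1000.0 / (1000.0 / t1_ms + acq.relaxivity_r1 * ct_end)
    return float(ref_signal / spgr_signal(1.0, t1_post, acq.tr_dynamic,
                                          acq.flip_dynamic))


# ---------------------------------------------------------------------------
# cohort design


@dataclass(frozen=True)
class CohortDesign:
    """Design parameters of the default synthetic cohort.

    Compartment means qualitatively mirror the regional ordering of the
    study this package models (T1C+ >> PL > C for Ktrans/Ve; PL AUC matched
    to C by construction); they are design inputs, not estimates of patient
    values.  Ktrans in min^-1, T1 in ms, intensities arbitrary units.
    """

    n_subjects: int = 19
    shape: tuple[int, int, int] = (26, 26, 16)
    spacing: tuple[float, float, float] = (0.9, 0.9, 0.9)
    # lesion core (T1C+)
    t1c_ktrans: float = 1.3
    t1c_ve: float = 0.5
    t1c_t1: float = 900.0
    t1c_m0: float = 500.0
    t1c_t2w: float = 220.0
    t1c_cbct: float = 120.0
    # T2-hyperintense non-enhancing rim (T2W+)
    t2w_ktrans: float = 0.06
    t2w_ve: float = 0.30
    t2w_t1: float = 1200.0
    t2w_t2w: float = 200.0
    t2w_cbct: float = 170.0
    # perilesional shell (PL): permeability elevated over control
    pl_ktrans: float = 0.32
    pl_ve: float = 0.34
    pl_t1: float = 700.0
    pl_t2w: float = 100.0
    pl_cbct: float = 195.0
    # distant control (C): baseline T1 solved for the AUC-matched condition
    c_ktrans: float = 0.16
    c_ve: float = 0.17
    c_m0: float = 500.0
    c_t2w: float = 100.0
    c_cbct: float = 200.0
    # scene
    bone_t1: float = 900.0
    bone_m0: float = 450.0
    lesion_radius_mm: float = 2.7
    rim_mm: float = 1.2
    rim_mismatch_mm: float = 3.2
    shell_radius_mm: float = 2.0
    control_radius_mm: float = 2.7
    # clinical effect structure
    p_mismatch: float = 0.35
    bop_prevalence: float = 0.5
    bop_ktrans_factor: float = 2.0
    bop_ve_factor: float = 1.8
    p_bone_loss: float = 0.5
    bone_loss_cbct_factor: float = 0.6
    # between-subject variability (log-normal sigma)
    subject_sd: float = 0.15
    compartment_sd: float = 0.10
    # acquisition noise (Gaussian channel SD, dynamic-signal units)
    noise_sd: float = 0.4


def build_subject(
    design: CohortDesign,
    acq: AcquisitionConfig,
    seed: int,
    control_t1: float | None = None,
    aif: AIFParams | None = None,
) -> PhantomTruth:
    """Draw one subject's phantom from the cohort design.

    A global log-normal subject factor scales Ktrans/Ve in every
    compartment; each compartment adds independent log-normal jitter.  The
    T1C+ core is split into six angular probing-site sectors; BOP-positive
    sectors get elevated Ktrans/Ve.  Bone-loss and mismatch (thick rim)
    states are drawn per lesion.
    """
    rng = np.random.default_rng(seed)
    aif = aif or AIFParams(onset_delay=acq.bolus_onset)
    aifs = sample_aif(aif, acq.frame_times)
    if control_t1 is None:
        control_t1 = solve_matched_control_t1(
            design.pl_ktrans, design.pl_ve, design.pl_t1,
            design.c_ktrans, design.c_ve, acq, aif,
            jitter_sd=np.hypot(design.subject_sd, design.compartment_sd))

    g = float(np.exp(rng.normal(0.0, design.subject_sd)))
    jit = {name: float(np.exp(rng.normal(0.0, design.compartment_sd)))
           for name in ("t1c", "t2w", "pl", "c")}
    mismatch = bool(rng.random() < design.p_mismatch)
    bone_loss = bool(rng.random() < design.p_bone_loss)
    bop = rng.random(len(SITES)) < design.bop_prevalence

    ext = [(n - 1) * s for n, s in zip(design.shape, design.spacing)]
    lesion_c = (ext[0] / 2, ext[1] * 0.38, ext[2] / 2)
    rim = design.rim_mismatch_mm if mismatch else design.rim_mm
    r0 = design.lesion_radius_mm
    cbct_core = design.t1c_cbct * (design.bone_loss_cbct_factor if bone_loss else 1.0)

    # control reference structural signal (post-contrast, at its own Ct_end)
    ct_end_c = design.c_ktrans * g * jit["c"] * expconv(
        aifs.t_min, aifs.cp,
        (design.c_ktrans * g * jit["c"]) / min(design.c_ve * g * jit["c"], 0.95)
    )[aifs.frame_index][-1]
    t1_post_c = 1000.0 / (1000.0 / control_t1 + acq.relaxivity_r1 * ct_end_c)
    ref_signal = design.c_m0 * spgr_signal(1.0, t1_post_c, acq.tr_dynamic,
                                           acq.flip_dynamic)

    kt_pl = design.pl_ktrans * g * jit["pl"]
    ve_pl = min(design.pl_ve * g * jit["pl"], 0.95)
    kt_rim = design.t2w_ktrans * g * jit["t2w"]
    ve_rim = min(design.t2w_ve * g * jit["t2w"], 0.95)
    m0_pl = _matched_m0(ref_signal, kt_pl, ve_pl, design.pl_t1, acq, aifs)
    m0_rim = _matched_m0(ref_signal, kt_rim, ve_rim, design.t2w_t1, acq, aifs)
    m0_bone = _matched_m0(ref_signal, 0.0, 1.0, design.bone_t1, acq, aifs)

    specs = [
        CompartmentSpec(
            "T1C+", Compartment.T1C,
            {"kind": "ellipsoid", "center_mm": lesion_c, "radii_mm": (r0, r0, r0)},
            ktrans=design.t1c_ktrans * g * jit["t1c"],
            ve=min(design.t1c_ve * g * jit["t1c"], 0.95),
            t1=design.t1c_t1, m0=design.t1c_m0, t2w=design.t1c_t2w,
            cbct=cbct_core),
        CompartmentSpec(
            "T2W+", Compartment.T2W,
            {"kind": "ellipsoid", "center_mm": lesion_c,
             "radii_mm": (r0 + rim, r0 + rim, r0 + rim)},
            ktrans=kt_rim, ve=ve_rim, t1=design.t2w_t1, m0=m0_rim,
            t2w=design.t2w_t2w, cbct=design.t2w_cbct),
        CompartmentSpec(
            "tooth", Compartment.TOOTH,
            {"kind": "cylinder", "center_mm": (ext[0] / 2, ext[1] * 0.68),
             "radius_mm": 2.2, "z_mm": (0.0, ext[2])},
            ktrans=0.0, ve=0.0, t1=300.0, m0=80.0, t2w=30.0, cbct=250.0),
        CompartmentSpec(
            "PL", Compartment.PL,
            {"kind": "shell", "around": (int(Compartment.T1C), int(Compartment.T2W)),
             "radius_mm": design.shell_radius_mm},
            ktrans=kt_pl, ve=ve_pl, t1=design.pl_t1, m0=m0_pl,
            t2w=design.pl_t2w, cbct=design.pl_cbct),
        CompartmentSpec(
            "C", Compartment.CONTROL,
            {"kind": "ellipsoid",
             "center_mm": (ext[0] * 0.78, ext[1] * 0.82, ext[2] / 2),
             "radii_mm": (design.control_radius_mm,) * 3},
            ktrans=design.c_ktrans * g * jit["c"],
            ve=min(design.c_ve * g * jit["c"], 0.95),
            t1=control_t1, m0=design.c_m0, t2w=design.c_t2w, cbct=design.c_cbct),
        CompartmentSpec(
            "bone", Compartment.BONE, {"kind": "fill"},
            ktrans=0.0, ve=0.0, t1=design.bone_t1, m0=m0_bone,
            t2w=100.0, cbct=200.0),
    ]
    truth = generate_phantom(specs, design.shape, design.spacing, seed=seed)

    # split the lesion core into six angular probing-site sectors;
    # BOP-positive sectors carry elevated permeability
    core = truth.labels == Compartment.T1C
    idx = np.argwhere(core)
    centers = idx * np.asarray(design.spacing)
    ang = np.arctan2(centers[:, 1] - lesion_c[1], centers[:, 0] - lesion_c[0])
    sector = np.floor((ang + np.pi) / (2 * np.pi / len(SITES))).astype(int) % len(SITES)
    anchors, clin = [], []
    for s_id, site in enumerate(SITES):
        sel = idx[sector == s_id]
        if sel.size:
            anchor = sel[np.argmin(np.linalg.norm(
                (sel - sel.mean(0)) * np.asarray(design.spacing), axis=1))]
        else:  # degenerate sector: fall back to the core centroid voxel
            anchor = idx[0]
        anchors.append({"tooth": 1, "site": site,
                        "i": int(anchor[0]), "j": int(anchor[1]), "k": int(anchor[2])})
        clin.append({"tooth": 1, "site": site, "bop": int(bop[s_id]),
                     "bone_loss": int(bone_loss)})
        if bop[s_id]:
            sub = tuple(sel.T)
            truth.ktrans[sub] *= design.bop_ktrans_factor
            truth.ve[sub] = np.minimum(truth.ve[sub] * design.bop_ve_factor, 0.95)
    truth.site_anchors = pd.DataFrame(anchors)
    truth.clinical = pd.DataFrame(clin)
    return truth
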