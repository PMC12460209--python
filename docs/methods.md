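# Methods

`perioperf` implements a dynamic contrast-enhanced (DCE) perfusion MRI
analysis of periodontal bone lesions and validates it end to end on
synthetic digital-phantom cohorts.  This note documents the models, the
design choices that were genuinely open, the numerical machinery, and what
the synthetic validation does and does not establish.

## Kinetic model

Tissue concentration follows the standard Tofts two-compartment exchange
model

    Ct(t) = Ktrans ∫₀ᵗ Cp(τ) · exp(−(Ktrans/Ve)(t−τ)) dτ,

with `Ktrans` (min⁻¹) the plasma→interstitium volume transfer constant,
`Ve` the extravascular extracellular volume fraction, and `Cp` the plasma
concentration.  `Cp` is the Parker population arterial input function
(bi-Gaussian bolus plus sigmoid-gated exponential washout) with the
published population parameters hard-coded in `AIFParams`; the curve is
used as plasma concentration directly (no hematocrit correction), with an
optional hematocrit division for users who prefer whole-blood scaling.

The convolution is evaluated with an exponential-kernel recursion that is
exact for piecewise-linear `Cp` (coefficients switch to a Taylor series
below `kep·Δt = 10⁻⁵` for stability).  Because the dynamic frame interval
(509 s / 42 ≈ 12.1 s) undersamples the bolus peak, the AIF is always
evaluated on a 1-s auxiliary grid that contains the frame times; tissue
curves are read off at the frames.

## Signal model and T1 mapping

All T1-weighted volumes use the spoiled gradient-echo steady state
`S = M0 sin α (1−E1)/(1−cos α E1)`, `E1 = exp(−TR/T1)`, with TR 4.47 ms
and dynamic flip 15°.  Baseline T1/M0 come from the five-flip-angle
(5–17°) series via the linearized DESPOT1 fit (line through
`(S/tan α, S/sin α)`); voxels with slope outside (0, 1) are masked.  A
nonlinear refinement exists behind a flag but the linear fit is the
default: it is deterministic, fast, and exact on noiseless data.  No B1
correction is applied.  Concentration inversion re-anchors `M0 sin α` on
each voxel's own pre-contrast dynamic mean (default 3 baseline frames),
then `C(t) = (R1(t) − R1₀)/r1` with relaxivity r1 = 3.5 L·mmol⁻¹·s⁻¹
(gadoterate at 3 T, configurable) — this makes the conversion immune to
scaling differences between the VFA and dynamic acquisitions.

## Voxelwise fitting

The Tofts fit is solved by variable projection: for fixed
`kep = Ktrans/Ve` the model is linear in `Ktrans`, so the problem reduces
to a 1-D search over `kep`.  A fixed 90-point log grid on
[2·10⁻³, 300] min⁻¹ (whose basis curves are shared across all voxels)
brackets the optimum; a vectorized golden-section refinement (36 steps,
one basis evaluation per step, numba kernel) polishes it to solver
precision.  Bounds are `Ktrans ∈ [0, 10]` min⁻¹ and `Ve ∈ (10⁻³, 1]`;
voxels whose unconstrained `Ve` exceeds 1 are refit on the `Ve = 1`
boundary and flagged, as are `Ktrans` ceiling hits.  The procedure is
fully deterministic — identical inputs give bit-identical maps — and the
noiseless round trip recovers truth to ~10⁻⁶ relative, far inside the
0.5% tolerance the tests assert.

## AUC

The 90-s area under the curve integrates the relative-enhancement signal
curve (`S/S₀ − 1`) from bolus arrival (first sample where the AIF reaches
5% of its peak, configurable) over the window, by trapezoid with linear
interpolation at the window ends, and divides by the AIF integral over
the same window.  This yields the dimensionless magnitudes clinical
reports print.  When fed a concentration series instead, a tissue curve
identical to the AIF gives exactly 1.  A raw (unnormalized) mode exists
behind a flag.  Note the deliberate asymmetry: AUC is computed from the
*signal* curve and therefore inherits the baseline-T1 sensitivity
confound of the semiquantitative index, whereas Ktrans/Ve are fitted on
*concentration* and do not — this distinction is what the end-to-end
power experiment exploits.

## Segmentation

Compartments follow the two-sequence threshold rule: a voxel is lesion if
its T2W intensity exceeds the control VOI mean + k·SD (sample SD); it is
T1C+ if it additionally exceeds the contrast-enhanced T1W threshold,
otherwise T2W+.  `k = 2` by default — the conventional hyperintensity
criterion for marrow; clinical workflows of this kind rarely pin the
exact multiplier, so it is configurable.  Connected components of the combined lesion smaller than 5
voxels are discarded, standing in for the manual cleanup of a
semiautomated workflow (with mean+2SD thresholds ~2% of normal marrow
voxels cross by chance as isolated speckle).  The perilesional (PL)
compartment is the 2-mm isotropic expansion of the combined lesion —
Euclidean distance transform in physical millimetres, not voxel counts
(2 mm ≈ 2.22 voxels at 0.9 mm) — restricted to voxels within mean ± k·SD
of control on *both* sequences.  The SD carries a 10⁻⁹ relative floor so
the band stays well defined on noiseless (zero-variance) phantoms.
Labelmap composition uses precedence T1C+ > T2W+ > PL > C.  Control VOI
placement is an input (in the phantom pipeline, the ground-truth control
region stands in for the reader-placed VOI), and lesion masks exclude it.

## Stratification

* **Mismatch**: a lesion is mismatch-positive when its T2W+ volume exceeds
  the cohort 95% interval of T1C+ volumes.  A "95% interval of
  lesion volumes" admits two readings; the default takes it as a
  reference range (mean + 1.96·SD — a per-lesion exceedance criterion),
  with the CI-of-the-mean reading behind a flag.  Both are
  scale-invariant.
* **Site VOIs**: 40 voxels per probing site (rounded up from the
  typical mean lesion volume per site, ~37 voxels at 0.9 mm), taken as the lesion voxels nearest the
  site anchor in physical distance, ties broken lexicographically;
  smaller lesions contribute all voxels with a shortfall flag.
* **Region means** are arithmetic means over valid (finite) voxels, with
  per-region valid-voxel accounting.

## Statistics

`compare_regions` screens each region with Shapiro–Wilk (α = 0.05) and
chooses Friedman + Dunn when any region is non-normal, else one-way
repeated-measures ANOVA + Dunnett-versus-control.  Friedman uses
mid-ranks with the standard tie correction and, for tables small enough
to enumerate (n ≤ 6, k ≤ 4), the *exact* within-row permutation null
computed by convolving per-row rank-sum distributions; larger tables use
the χ² reference.  Dunn contrasts are rank-mean z statistics with
SE = √(k(k+1)/6n); the family is versus-control by default (all-pairs
available) and the multiplicity adjustment Holm step-down (Bonferroni
available) — tools differ in the adjustment they attach to Dunn's
contrasts, and Holm controls the same family-wise error at uniformly
better power than Bonferroni.  The
repeated-measures Dunnett contrast uses paired differences against
control with a max-|T| multivariate-t adjustment whose correlation is
estimated from the difference vectors (fixed QMC seed for
repeatability); adjusted p-values are clipped to ≥ raw and made monotone.
Null calibration of the auto-mode omnibus over 1000 normal replicates of
a 19 × 4 table sits at ~0.05 (asserted within [0.035, 0.065]).
Dichotomies use the paired two-tailed t-test (BOP, within subject) or the
two-sample t / exact Mann–Whitney U.  Agreement uses Shrout–Fleiss
ICC(2,1) — two-way random effects, single measure, absolute agreement —
with the F-based 95% CI (all six forms exposed); the implementation
delegates to `pingouin`, while the tests verify it against hand-computed
ANOVA mean squares.

## Synthetic cohort design

Each subject is a 26×26×16 voxel (0.9 mm isotropic) jaw-like scene: a
bone block, a tooth cylinder, a spherical enhancing lesion core (T1C+)
with a concentric T2-hyperintense non-enhancing rim (T2W+), the derived
2-mm PL shell, and a distant spherical control region.  Default design
means: T1C+ Ktrans 1.3 min⁻¹ / Ve 0.50; T2W+ 0.06 / 0.30; PL 0.32 /
0.34; control 0.16 / 0.17.  Between-subject variability is log-normal —
a global factor (σ = 0.15) on all Ktrans/Ve plus independent
per-compartment jitter (σ = 0.10).  Six angular probing-site sectors per
lesion carry Bernoulli(0.5) bleeding-on-probing flags; positive sectors
have Ktrans ×2.0 and Ve ×1.8, mirroring the roughly two-fold BOP
contrast reported clinically.  Mismatch subjects (p = 0.35) get a 3.2-mm
rim instead of 1.2 mm; bone-loss lesions (p = 0.5) get reduced CBCT
density.  Acquisition noise is complex-Gaussian before magnitude
(Rician), channel SD 0.4 in dynamic-signal units (baseline SNR ≈ 40);
the Gaussian approximation of the concentration-level noise is adequate
above SNR 5.  Rendering is bit-deterministic under a fixed seed.

Two constraints are *solved*, not chosen:

1. **AUC-matched control.**  The control compartment's baseline T1 is
   found by Brent's method so that its expected enhancement AUC equals
   the perilesional one — expectation taken over the log-normal jitter by
   Gauss–Hermite quadrature, because the AUC response to parameter
   scaling is mildly nonlinear and a design-point match alone leaves a
   systematic offset the paired test at n = 19 can detect.  The solved
   control T1 (~1250 ms) is *longer* than the PL T1 (700 ms), which is
   physiologically inverted for marrow; it is accepted as the price of
   the matched-AUC condition in a synthetic design and is the one place
   the phantom trades realism for an identifiable property.
2. **Normal-appearing intensities.**  PL and rim M0 are solved so their
   post-contrast structural T1W intensity equals the control's exactly,
   making them normal-appearing by construction (and making noiseless
   segmentation recover truth with Dice 1.0).

What the phantoms do **not** emulate: partial-volume mixing at
compartment borders, B1/B0 inhomogeneity, k-space/Dixon reconstruction
effects, spatially correlated noise, individual AIF variation, motion
beyond rigid shifts, and anatomically realistic marrow T1 in the control
(see above).  Passing tests therefore demonstrate that the *pipeline*
recovers designed effects through the full measurement chain — not that
patient data would show these effect sizes.

## Pipeline and problem sizes

The orchestrated run per subject: simulate → (optional) rigid motion
correction → VFA T1 map → threshold segmentation (two readers at k = 2.0
and 2.5, the second feeding the ICC) → concentration conversion → Tofts
fit restricted to the labelled compartments → AUC → region means, site
VOIs and cohort statistics.  Motion correction defaults to `auto`:
SimpleITK Euler-3D registration runs only when motion was injected
(synthetic volumes are generated aligned); it is always exercised in its
own tests.  The default cohort is 19 subjects; the end-to-end power
experiment uses 50 seeded cohorts of 19 — sizes chosen so the full
validation runs comfortably on a single CPU while keeping every
statistical branch populated.  Every output carries the configuration
hash and seed; reruns with the same seed are bit-identical.

## Known limitations

* The standard Tofts model omits a plasma-volume term (vp); strongly
  vascularized voxels map part of vp into Ktrans/Ve.
* The exact Friedman null is enumerated only for small tables; at n = 19
  the χ² reference is used (adequate, slightly conservative).
* The repeated-measures Dunnett adjustment relies on a QMC integration of
  the multivariate t; p-values are repeatable (fixed seed) but carry
  ~10⁻⁴ integration noise, handled by the monotonicity clipping.
* Mismatch and bone-loss group comparisons are between-lesion (one lesion
  per synthetic subject), whereas a multi-tooth cohort would allow
  within-subject pairing.
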