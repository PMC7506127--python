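# Methods

This note documents the models, conventions and numerical choices
behind `mrplanqa`, and what its synthetic tests do and do not establish
about real treatment plans.

## Grid and geometry conventions

All masks and dose grids share one axis-aligned voxel lattice,
by default 108 × 108 × 36 voxels at 1 × 1 × 3 mm (head-and-neck CT
convention: 1-mm in-plane pixels, 3-mm slices).  Voxel (0, 0, 0) has its
centre at the grid origin; coordinates are voxel centres in mm.  Doses
are absorbed dose in Gy; masks are boolean.  A single common grid is
used for masks and dose because the derived 1-mm shells are sub-voxel
objects — resampling a coarser dose grid onto them would dominate the
very quantities being measured.

## Derived structures

* **Distance transforms** use `scipy.ndimage.distance_transform_edt`
  with anisotropic sampling.  Grid edges count as exterior.
  `distance_to_complement` and `expand_margin`/`normal_tissue` work on
  voxel-centre distances with closed thresholds (`<=`); normal tissue
  uses strict `>` ("more than 1 cm from the PTV"), so NT and the 10-mm
  PTV expansion partition the body exactly.
* **Millimetre shells** (skin = first 1 mm under the body outline,
  interface = first 1 mm of tissue outside each air cavity) are
  thresholded on a *partial-volume depth*: the distance transform is
  evaluated on a 2× refined sub-lattice and mean-pooled back, so a voxel
  with an exposed corner counts as shallower than one shielded on all
  faces.  A plain voxel-centre threshold snaps to whole voxel layers and
  misstates the shell volume of smooth bodies by ±20 % (rasterization
  staircase); the refined depth tracks the analytic surface-times-
  thickness volume of spheres and cylinders to ≈ 12 % and 5 %
  respectively, while still being reproducible by an exhaustive
  nearest-neighbour computation on the refined lattice.
* On a 1 × 1 × 3 mm grid a 1-mm shell therefore contains a single
  in-plane voxel layer and no purely axial (superior/inferior) layer,
  matching slice-wise contouring practice; whether end slices of a scan
  belong to the skin is a convention — here they do not.

## DVH and plan metrics

Cumulative DVHs are built from the in-mask voxel-dose multiset on a
0.01-Gy bin grid; the curve is 1.0 at 0 Gy and non-increasing.
`dose_at_volume` interpolates linearly down the cumulative curve and
breaks plateau ties toward the higher dose (the "hottest q %" reading:
a two-voxel structure at 10/20 Gy has D50 = 20 Gy).  `volume_at_dose`
interpolates on the dose axis.  Both agree with direct voxel-multiset
computation within one bin width (tested on 200 random grids).

Dmax is the single hottest in-mask voxel (the convention of the TPS
being emulated; users comparing with near-max conventions should use
D2 %).  Dmean is the arithmetic in-mask mean.  HI = (D2 − D98)/D50 is
reported as a fraction (the scoring intervals 0–0.2/0–0.3 are on this
scale).  CI is the van't Riet index with the treated volume clipped to
the body, because MC dose grids deposit dose in the surrounding air;
both high-dose targets are evaluated against the same 69.96-Gy isodose.
Parotids are scored on the union of both lobes.

## Plan-quality metric

Each of 15 submetrics is mapped linearly from its evaluation interval
[M_il, M_iu] onto 0–10 points — upward for Vp and CI, downward for HI
and the OAR dose limits — and clamped outside the interval (the printed
linear form is unbounded; the fixed 0–10 point range implies
saturation).  All submetrics carry equal weight; the total is their sum,
0–150.  The default interval table covers three targets (coverage,
conformity, homogeneity) and six OAR dose limits; such tables are partly
cohort-adapted in practice, so the table is a user-replaceable input
(YAML/JSON) with the default shipped in code.

## Comparison statistics

Summaries report the mean with the **population** standard deviation
(÷ n — the convention of the reference cohort's printed 82.2 ± 7.0; the
sample form is available via an option) and the midpoint median.

The Wilcoxon signed-rank test follows the asymptotic form SPSS prints:
differences d = b − a, zeros dropped, |d| mid-ranked, W = the smaller
signed-rank sum, tie-corrected variance, **no continuity correction**,
two-sided normal p.  z is computed from the positive-rank sum so it
flips sign when the samples are swapped.  On the embedded reference
columns this reproduces W = 0 → z = −2.803 → p = 0.005 and W = 9 →
z = −1.886 → p = 0.059 exactly as printed.  The normal approximation
tracks the exact sign-flip distribution within 0.05 across the whole
range for n ≥ 10 and in the significance tail for smaller n; below
five nonzero differences the result is flagged unreliable.  With fewer
than two nonzero differences p is NaN.  No multiple-testing correction
is applied (each metric is tested at α = 0.05, matching the analysis
being mirrored).  Presentation rounding is half-away-from-zero, one
decimal for scores/doses and three for p.

## Synthetic phantom and dose model

The generator's purpose is the *downstream metric structure* — DVH
shapes, shell doses, score ordering — not transport physics.

**Anatomy.**  A circular-cylinder body (radius 45 mm, jittered
42–48 mm per patient), a larynx/trachea air column (r = 7 mm), a
naso/oropharyngeal air pocket, an ellipsoidal tumour-bed target partly
wrapping the airway, a nodal target, brain stem, spinal cord, two
parotids and a thyroid.  The PTV is the 8-mm expansion of the target
union, clipped to tissue (targets never include air: prescribed dose is
deposited in tissue only).  Geometry is deterministic given the spec;
cohort variability (radii ±15 %, centres ±3 mm, cavity size ±10 %,
interface-shift direction) is drawn from per-patient seeds derived from
the master seed via `numpy` seed sequences.

**Beams.**  Nine equiangular in-plane beams.  Per beam: exponential
depth attenuation (μ = 0.0015 mm⁻¹) with a short build-up region
(dd(s) = e^(−μs)(1 − 0.4·e^(−s/2 mm))), a soft rectangular port
conformed to the target projection (3-mm margin, 3-mm Gaussian
penumbra), and a partially transmitting shielding strip over the spinal
cord projection (transmission 0.3) emulating cord-sparing segments.

**Optimizer proxy.**  A flat-fluence nine-beam sum cannot
simultaneously deliver homogeneous target coverage, a conformal
prescription isodose and a spared cord — that is precisely what inverse
optimization does.  Three corrections stand in for it: (i) target
voxels are pulled to their own prescription level (scaled by 1.015 so
the target medians sit ~1.5 % above prescription, inside the 2 %
normalisation band, and V_Rx lands at 92–95 %; the residual in-target
texture is the MC-like noise), (ii) outside the PTV, dose above a
conformal envelope 1.05·D_PTV·e^(−d/8 mm) is suppressed by 85 %
(crossfire-plateau removal), (iii) the cord strip above.  All constants
were calibrated once on the default phantom and frozen.  Each plan
condition receives an independent multiplicative Gaussian noise
realisation of relative σ = 1 % (the MC statistical uncertainty per
calculation), truncated at zero dose.

**1.5-T perturbation.**  Phenomenological ERE model, identity when all
amplitudes vanish:

* *Skin boost* A·e^(−d/λ), λ = 5 mm, where d is the lateral depth below
  the body outline (scan end slices carry no skin — the anatomy
  continues), applied in alternating 40° azimuthal sectors (5 of 9,
  ≈ 56 % of the circumference).  The sectoring makes the boost
  non-uniform, so the maximum-dose increase exceeds the mean increase,
  as observed at beam-exit skin.  Default amplitudes 3.76 Gy
  (recalculated) and 2.70 Gy (reoptimized) were fixed by dividing the
  target shell shifts of 1.81 and 1.30 Gy by the default phantom's
  shell attenuation-and-sector factor (0.481); the expected shift for
  any phantom/parameters is exposed as
  `expected_skin_dmean_increase`, and a 20-patient cohort recovers it
  within 10 %.
* *Interface shift*: within the 1-mm shell of each cavity, dose moves
  from one side of the cavity (relative to a per-patient random in-plane
  direction) to the other.  The per-voxel shift is ±B capped at the
  local dose (the effect redistributes locally deposited dose, and a
  voxel cannot lose more than it carries) and recentred so the
  two-sided shell mean is conserved exactly; a literal ±B addition
  would bias the shell mean wherever the local dose falls below B once
  doses are floored at zero.  Defaults: B = 2.0 Gy (recalculated),
  1.5 Gy (reoptimized).
* *Coverage degradation*: the recalculated condition scales the
  PTV-region dose by (1 − 0.03); reoptimization sets it to zero.

**Known limitations.**  With the generator's tight in-target DVH, the
3 % degradation collapses V_Rx far more steeply than clinical plans
degrade (the score drop is ≈ 45 points against the ≈ 14 reported
clinically), and absolute plan scores run higher (≈ 123 vs ≈ 82)
because the synthetic OARs are better spared than real anatomy allows.
The per-patient *ordering* — every recalculated plan scores below its
no-field plan, reoptimization recovers most of the gap — and the
skin/interface dose-shift magnitudes are the properties the generator
is calibrated to reproduce.  In the recalculated contrast the larynx
interface mean also reflects the coverage degradation, because the
airway lies partly inside the target — consistent with the larynx being
the one interface reported as changed; the interface-cancellation
property is therefore assessed on the reoptimized contrast, which
isolates the antisymmetric mechanism.  Passing tests show the pipeline
is correct on data with this statistical structure; they cannot certify
behaviour on features the generator lacks (real segment shapes,
heterogeneous densities, true ERE physics, organ deformation).

## Degenerate inputs and numerics

Empty masks are rejected wherever a statistic is undefined; an empty
cavity yields an empty shell.  CI is defined as 0 when no voxel reaches
the prescription.  A single-patient cohort runs end-to-end with the
statistics stage skipped.  DVH bins are closed on the left
(fraction ≥ edge); Dq ties resolve to the higher dose.  All randomness
flows from explicit integer seeds (master seed → per-patient →
per-condition via `numpy.random.SeedSequence`); a fixed seed reproduces
every artifact bit-for-bit, which the manifest's SHA-256 checksums
verify.

## Problem sizes

The default phantom grid (108 × 108 × 36 ≈ 4.2 × 10⁵ voxels) and
10-patient cohorts keep a full simulate→score→compare cycle around
20 seconds on one CPU; oracle suites run on grids ≤ 40³ where
exhaustive nearest-neighbour and voxel-multiset brute force are exact
and fast.
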