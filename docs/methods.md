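# Methods

## Signal model and the vascular-fraction score

A blood-pool contrast agent raises the signal of blood by some amount
ΔS_blood between the pre- and post-contrast acquisitions. If a voxel's
compartmental blood content plus leaked contrast amounts to a fraction *f*
of pure blood, its signal change is *f*·ΔS_blood. The score

    VF(v) = (I_post(v) − I_pre(v)) / (S_blood,post − S_blood,pre)

therefore estimates *f* per voxel, with VF ≈ 0 for intact-barrier tissue
with negligible blood volume and VF ≈ 1 for pure blood. The normalization
makes VF invariant under global rescaling of the scanner gain and under a
common additive offset, which the pipeline's property tests assert exactly.

The blood reference signal is the **median** over a designated blood-pool
label (≥ 20 voxels required). The median is robust to inflow and
partial-volume edge voxels; the mean is available via configuration. A
non-positive blood signal change is an error, not a silent sign flip.
Negative VF values are legitimate noise around zero and are never clipped.

This is a single steady-state ratio, valid because the agent's
intravascular half-life (~15 h) is long compared to a session. Kinetic
(Ktrans-style) leakage-rate modelling and absolute cerebral-blood-volume
calibration are deliberately out of scope.

## Regional summary: the histogram mode

Each subject contributes one value per atlas region: the mode of the VF
values over the region's voxels. The mode (rather than the mean) discounts
the skewed upper tail contributed by intra-regional vessels. Since the mode
of a continuous sample needs an estimator, the default is a fixed-width
histogram:

- bin width 0.005 on the fraction scale, edges anchored at integer
  boundaries so bin centers are comparable across subjects and regions;
- the center of the maximal-count bin wins; ties break toward the bin
  nearest the sample median, then toward the lower center — fully
  deterministic;
- a Gaussian-KDE alternative (Silverman bandwidth, argmax on a 0.005 grid)
  is available behind `estimator="kde"` for sensitivity analyses.

Monte-Carlo characterization (this repository's tests): for a Normal
sample with SD 0.028 the estimator's absolute error has a 95th percentile
of ≈ 0.018 at 500 voxels and ≈ 0.028 at 50 voxels; across a phantom cohort
the mean absolute error stays below `bin_width + 3·(σ_voxel/ΔS_blood)/√n`.
Regions below 20 voxels are excluded with a logged warning.

## Group comparison

Per region, control and diabetic regional modes are compared with a
two-sided Wilcoxon rank-sum test:

- **exact** p by complete enumeration of rank assignments when the combined
  sample is tie-free and ≤ 20 observations (always the case for untied
  7-vs-8 cohorts; the smallest attainable two-sided p is 2/C(15,7) ≈
  0.00031);
- otherwise midranks with the tie-corrected, continuity-corrected normal
  approximation (mode values are quantized to the bin grid, so ties across
  subjects are common and expected).

Significance is called at raw p < α (default 0.05); Benjamini–Hochberg
q-values are computed across all analyzed regions and reported alongside so
the false-discovery burden of a 173-region screen is visible, but they do
not drive the significance flag. Two-sided testing is the conservative
default; the direction of each group difference is reported separately.
Output tables are ranked by ascending p. The exact path is validated
against a from-scratch enumeration oracle for every sample-size pair up to
8-vs-8, and its null rejection rate at α = 0.05 with 7-vs-8 continuous data
is 0.0401 (the attainable level of the discrete exact test, computed by
full enumeration) — the empirical calibration test asserts the
0.05 ± 0.015 band over 10⁴ replicates.

## Synthetic phantom cohorts

Real acquisitions for this design are not publicly available, so validation
runs on simulated cohorts with known ground truth. The generator inverts
the VF score:

- **Geometry.** An ellipsoidal "brain" (semi-axes 0.42 of each grid extent)
  is partitioned into 173 parcels by seeded centroidal Voronoi relaxation
  (5 Lloyd iterations), giving roughly equal parcels of ≥ 50 voxels; a
  tubular blood-pool structure sits outside the brain. Geometry is label
  bookkeeping only — no anatomical realism is attempted or needed by the
  analysis stages.
- **Subjects.** Per region *r*, a subject-level fraction
  f_r ~ Normal(group mean, max(group SD, 0.005)) truncated to [0, 1.2] is
  drawn; every voxel of *r* gets post = pre + f_r·ΔS_blood plus independent
  Gaussian voxel noise (SD 2 signal units on both volumes, baseline 100,
  ΔS_blood 100). Blood-pool voxels use f = 1 exactly. The truncation bound
  1.2 (not 1.0) keeps sampling symmetric for near-blood regions such as the
  pineal gland (means 0.86–0.90), avoiding mode bias at the boundary.
- **Calibration.** The group means/SDs come from the packaged regional
  reference statistics: per-region control/diabetic mean and SD of the
  regional mode from a 7-control/8-diabetic rat study of type 2 diabetes.
  SDs printed as 0.00 are rounded values, replaced by a floor of 0.005.
  Default cohort sizes are those of that design (7 control, 8 diabetic);
  the default grid is 64³, with 48³ used for replicate sweeps (the methods
  are resolution-agnostic; these sizes give ~470 and ~220 voxels per region
  respectively).

What the phantom does **not** emulate: Rician MR noise, partial-volume
mixing at parcel borders, B1 inhomogeneity, motion, vessel-induced
intra-regional skew, or batch effects between imaging sessions. Passing
phantom tests therefore demonstrates correctness of the estimators and the
statistical pipeline under the stated generative model, not robustness to
every artifact of real acquisitions.

A known consequence of calibrating to across-animal SDs of *measured*
modes: the simulated measured mode carries the estimator's own sampling
noise (SD ≈ 0.01 at ~200–500 voxels per region) on top of the injected
subject-level SD, so the simulated across-animal spread is mildly inflated
— by √(SD² + 0.01²)/SD, i.e. ~40% for regions with printed SD 0.01 —
relative to the reference tables. This costs a few borderline regions their
significance in any given replicate. More fundamentally, resimulating a
two-group comparison from its own summary statistics does not reproduce
every borderline call: regions whose reference p-values lie between 0.01
and 0.05 have well under 100% power when redrawn at n = 7 vs 8, so the
expected significant count in a calibrated replicate sits several regions
below the reference count of 147/173 (≈ 141–142 in the noise-free limit,
137–144 observed across seeds with imaging noise). The replicate sweep in
`scripts/acceptance.py` reports the significant percentage attained by 80%
of replicates (typically 78–80%) rather than a single best draw.

## Alignment stage

A deliberately simple 6-DOF rigid stage exists so imperfectly aligned real
data can be handled and so the pipeline contract is complete: exhaustive
search over a caller-supplied grid of translations/rotations maximizing
normalized cross-correlation, initialized at the center-of-mass
translation, with a `weak` flag when the peak correlation is below 0.2.
Labels are resampled nearest-neighbour (never interpolated; label sets can
shrink but never grow), intensities trilinearly. Scaling and nonlinear
warps are excluded. Phantom cohorts are generated pre-aligned, where the
estimated transform is the identity and running with or without the stage
yields identical regional tables (asserted in tests); `--skip-align` (the
default) bypasses the stage.

## Dosimetry helpers

Injected stock volume = body_mass · blood_fraction · target_conc /
(1000 · stock_conc), with blood assumed 7% of body mass at unit density
(g ≈ ml): a 400 g rat needs 0.933 ml of 6 mg Fe/ml stock for a 200 µg
Fe/ml starting blood concentration (= 3.58 mM Fe). Geometry helper: a
cubic field of view of 30 mm over a 180³ matrix gives 167 µm isotropic
voxels. Concentration decay over a session is neglected (long half-life).

## Numerical and I/O choices

- NIfTI-1 for all volumes; voxel size carried in µm; orientation/affine
  content beyond voxel size is passed through, never interpreted.
- Labels are unsigned 16-bit; background 0, regions 1–173, blood pool 999
  (configurable, collision-checked).
- Volumes are validated at load: finite, non-negative, 3D.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); per-subject seeds derive from the cohort
  seed, so cohorts are bit-reproducible and CSV outputs rerun identically.
- Degenerate cases: zero group SD with zero floor draws the mean exactly;
  constant samples return their value to within half a bin; 1-vs-1 cohorts
  yield p = 1 everywhere (the exact-test floor), hence an empty significant
  table.

## Limitations

- Mode-recovery accuracy degrades below ~100 voxels per region; the 20-voxel
  floor only guards against degenerate extractions.
- The exact test's discreteness makes the effective level 0.040, not 0.050,
  at 7-vs-8 — slightly conservative.
- The phantom's equal-size Voronoi parcels do not reproduce the large
  dynamic range of real anatomical region sizes; per-region power in real
  data varies more than in simulation.
- Batch structure (e.g. cohorts imaged in separate sessions) is not
  modeled or adjusted for.
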