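# Methods

This note documents the models, conventions and numerical choices behind
`ligcect`: what each stage computes, what the synthetic generators emulate,
and where the design was genuinely open.

## 1. Tensile analysis

### Stress, strain and the zero-load length

Stress is engineering stress, force over the elliptical cross-section
π·w·t/4 (mm² → N/mm² = MPa). Strain is engineering strain relative to the
zero-load length, defined operationally as the clamp-to-clamp length at
which a 0.05 MPa tensile preload is first reached during loading.

`find_zero_load_length` implements the plain convention: the first upward
crossing of the preload, linearly interpolated between samples. On noisy
traces this convention is unusable as-is — with stress noise around 0.1 MPa
(2% of a ~5 MPa ramp peak) a naive first crossing triggers far too early —
so the trace-level helper `zero_load_length_from_test` locates a coarse
crossing on lightly smoothed stress (0.15 s moving average) and refines it
by least-squares fitting a toe+linear loading model to the whole ramp:
a quadratic toe of fixed width 2% strain joining continuously into a line
of slope E. The toe width is an analysis convention, not a fitted
parameter: for compliant post-overstrain samples the toe curvature is too
weak relative to noise to identify jointly with the crossing position
(the two trade off along a ridge). The fitted shift may be negative
because the coarse crossing can trigger early. If the fit fails or leaves
more than half the signal variance unexplained, the smoothed crossing is
used directly.

### Young's modulus

Least-squares slope of stress vs. strain over the 4–8% strain window of
the 8% ramp. The window excludes the toe; both bounds are configurable
(`modulus_window`). Fits with r² < 0.5 are flagged `low_quality`. At least
10 samples must fall in the window.

### Stress relaxation

The 600 s hold is fit with σ(t) = σ_eq + A₁·e^(−t/θ₁) + A₂·e^(−t/θ₂),
t = 0 at the ramp end (the hold segment's first sample). Trust-region
least squares (`scipy.optimize.curve_fit`, method `trf`) with
non-negativity bounds on all parameters, tolerances 1e-12, and a 3×3
multi-start grid θ₁ ∈ {1, 3, 10} s × θ₂ ∈ {60, 120, 300} s; the best SSE
wins and θ₁ < θ₂ is enforced by a post-fit swap. A flat hold returns the
mean stress with a `degenerate` flag; an amplitude below 0.1% of the total
flags its time constant `unidentifiable` (a single-exponential input
yields A₂ ≈ 0 with `theta2_unidentifiable`). The peak-to-equilibrium ratio
is (σ_eq + A₁ + A₂)/σ_eq ≥ 1, with equality iff both amplitudes vanish.

### Phase shift

Strain and stress over the sinusoid segment are each fit by linear least
squares to a + b·sin(2πft) + c·cos(2πft) after discarding the first
(transient) cycle; γ = phase(strain) − phase(stress) in degrees, wrapped
into (−90, 90). The estimator is invariant to time origin and additive
stress offset. At least five cycles must be present. Precision is
information-limited: the phase error scales as (noise/amplitude)·√(2/N),
so at high frequency (few samples) and noise comparable to the stress
amplitude no estimator can do better than ~1°; under the documented test
condition (noise at 5% of the stress amplitude, 10 cycles) the median
error is below 0.2° at every protocol frequency.

### Yield detection

On the 16% overstrain ramp, the tangent modulus over a moving 1%-strain
window is compared against 70% of the pre-damage linear modulus (threshold
configurable). The scan starts past the toe (4% strain), runs on lightly
smoothed stress (0.4% strain moving average), and requires three
consecutive sub-threshold windows at half-window stride, so isolated noise
excursions do not trigger. The coarse detection is then refined as the
intersection of straight lines fit to the raw data strictly before and
after it — exact for a bilinear curve — and the yield stress is read off
the pre-yield line (chord interpolation across the kink would bias it).
A curve whose tangent never drops below threshold gets a `no_yield` flag.

### Damage parameters

Dσ = 1 − σ_peak,post/σ_peak,pre and Dε = 1 − σ_eq,post/σ_eq,pre use the
relaxation-fit peak σ_eq + A₁ + A₂ rather than the raw trace maximum: the
fit-based peak refers both tests to the same model quantity and is robust
to transient spikes at the ramp–hold transition. λε is the relative
increase of the preload-determined zero-load length. Values outside [0, 1]
(possible under noise, or for an undamaged pair) are flagged, never
clipped, so a null comparison keeps its sign structure.

## 2. Quantitative CECT

### Calibration

A linear map sends the mean over the water-tube ROI to 0 HU and the mean
over the air ROI to −1000 HU. Estimating these means from finite noisy
ROIs leaves a common-mode offset of order noise/√(n_ROI) (~0.5 HU on the
default phantom); region statistics quoted against generator truth must
account for it or bypass calibration.

### Tissue segmentation (k = 2)

Voxel intensities are clustered with k-means (k = 2, 10 restarts, fixed
seed, fit on a deterministic ≤100k-voxel subsample, assignment by
threshold at the center midpoint — exact for 1-D k-means). Tissue is the
higher-mean cluster. A guard rejects volumes whose two clusters are
separated by less than 4 pooled within-cluster SDs (an all-background
volume splits its own noise). Per-slice cleanup follows: morphological
closing then opening with a Euclidean disk of radius 10 px (implemented
via distance transforms, so the disk is exact and the operation fast),
boundary shrink by 10 px, removal of connected areas under 2000 px.
Finally the largest 3D connected component is kept — this is what drops
the water tube, which is smaller than the sample by construction. The
10 px shrink means the measured mask is a deliberately conservative core;
Dice against truth is therefore evaluated against the identically shrunk
truth mask.

### Bulk partition and uptake kinetics

partition(t) = (mean HU over the tissue mask at t − native tissue mean) /
bath HU, with water at 0 HU post-calibration so the bath value is already
the attenuation above water. Subtracting the native scan isolates
contrast-induced attenuation; it is switchable off (`subtract_native`).
The bath is the initial bath attenuation; no co-registration between
timepoints is attempted (bulk means only). Because the mask is shrunk
10 px, a structured sample (fascicle/IFM levels differing) yields a bulk
partition referred to the core's regional mix — on default phantoms this
biases P_max ≈ 3% low relative to the whole-cross-section truth; τ is
unaffected.

The two-parameter fit of P_max·(1 − e^(−t/τ)) uses positivity bounds,
initialization P_max⁰ = last partition and τ⁰ = interpolated time of first
reaching 0.632·P_max⁰, with a multi-start over scaled τ⁰. The fitted curve
evaluated at t = τ equals 63.2% of P_max by construction of the model. The
fit is scale-equivariant (scaling the data scales P_max, leaves τ). The
worst-case dilution error is partition/ratio for a bath `ratio` times the
sample volume (mass balance), ≈ 2.5% at partition 2.49 and ratio 100.

## 3. Structural segmentation (k = 3)

Per-slice k-means on attenuation values within the tissue mask, labels
renumbered 1..3 by ascending cluster mean. The fascicle mask is the tissue
minus cluster 3 (set difference on masks, not intensity subtraction, since
the downstream use is a mask); the IFM is the remainder. This works when
fascicles dominate the cross-section: k-means then spends two clusters on
the fascicle mode and the brightest cluster is the nanoparticle-rich IFM.
A slice with fewer distinct values than k but more than one is grouped by
value with the brightest group keeping the top label (so a noiseless
two-level phantom segments exactly); a constant slice is degenerate. A
fully uniform volume returns an empty fascicle mask with a warning; more
than 10% (but not all) degenerate slices is an error listing them. A 3D
mode (single clustering of the whole volume) is available but off by
default. Manual ROIs — per-slice rectangles or polygons from a JSON
sidecar — are accepted by `roi_stats` as a reproducible stand-in for
hand-drawn regions. Label ordering is canonical (by mean), and the
segmentation is equivariant under positive-scale affine intensity maps.

## 4. Statistics

**Wilcoxon signed-rank, exact.** Zero differences are dropped; |d| gets
average (mid) ranks. The null distribution of the positive-rank sum W⁺
over all 2ⁿ sign assignments, conditional on the observed ranks, is
computed by dynamic programming (mid-ranks doubled to integers, one
convolution per rank) — identical to brute-force enumeration at any n, in
O(n²·max-rank) time. Two-sided p = min(1, 2·min(P(W⁺≤w), P(W⁺≥w))). Exact
up to n = 25; beyond that a tie-corrected normal approximation. Fewer than
5 non-zero differences flags `underpowered`. Under a symmetric null the
test is conservative: empirical type-I error ≈ 0.04 at nominal 0.05 for
n = 11 (discreteness of the exact distribution).

**Spearman.** ρ is the Pearson correlation of mid-rank vectors. For n ≤ 8
the two-sided p is exact by enumerating all n! permutations of one rank
vector (conditional on observed ranks, so ties are consistent); above,
the t-approximation t = ρ√((n−2)/(1−ρ²)). ρ is invariant under strictly
monotone transforms of either input.

**Correlation screen.** Every biomechanical parameter × {P_max, τ} × agent.
Control and damaged rows are pooled except for the damage-specific
parameters (Dσ, Dε, λε, ε_yield, σ_yield), which exist only for the
damaged group and are screened damaged-only. Significance at p < 0.05 per
test with no multiple-testing correction by design (a Benjamini–Hochberg
option exists downstream of the returned table but is off by default).

## 5. Synthetic data: what it emulates, what it does not

### Tensile traces

The generator emits the full protocol — five preconditioning blocks of ten
6%-strain cycles at 2%/s, a re-zero dwell, the 8% ramp at 8%/s, the 600 s
hold, four sinusoid blocks (six cycles each), and for damaged samples the
16% ramp, 2 s hold, return, and post-damage repeats — at 100 Hz (≥50
samples per cycle at 2 Hz, chosen for phase-estimation accuracy).

Segment stress models are **piecewise and exact**: the ramp follows the
quadratic-toe (2% strain) + linear curve with slope exactly E; the hold
follows the two-exponential exactly from its first sample; sinusoidal
stress lags strain by exactly γ with amplitude E·(strain amplitude).
Consequences accepted by design: relaxation during the ramp is not
modeled, so the ramp apex and the hold's σ(0) differ (a stress
discontinuity at the transition), which is why damage parameters use
fit-based peaks. Lengths are emitted relative to the preload-crossing
zero-load length (the trace's measured crossing recovers the true length
exactly at zero noise), with 2% strain of sub-preload slack before each
ramp so the crossing is observable. Ramps begin at the slack position like
a real displacement-controlled device.

Damage in a single generated test scales every stress-like parameter by
(1 − d), making Dσ = Dε = d and λε = residual_strain exact truths. In
cohorts, a `DamageEffect` applies independent per-parameter ratios
(defaults: the damaged/healthy reference group-mean ratios), and the
generator records the implied Dσ/Dε derived from the constructed pre/post
models as truth. Reference parameter means are **not mutually consistent**
under any single piecewise-linear model (e.g. a linear ramp at the healthy
E cannot end at the hold peak implied by the peak-to-equilibrium ratio,
and the linear model's stress at 12% strain exceeds the quoted mean yield
stress), so dependent truths — yield stress, Dσ, Dε — are always derived
from the generator's own model rather than set to quoted means.

Noise is additive Gaussian on the stress channel only (displacement is
device-controlled). The cohort default is 2% of the per-sample ramp peak.
Not emulated: drift, grip slippage, hysteresis in preconditioning,
strain-rate-dependent toe shape, plasticity beyond the bilinear yield.

### CT phantoms

Cross-sections are greedy random circle packings (radii log-uniform over
diameters [max(50, 3·voxel), 500] µm, largest-first, ≥1 voxel IFM gaps)
inside a disk of tissue, extruded along z, with an off-sample water tube
and air background, plus water/air reference ROI boxes. Largest-first
packing makes fascicles the majority phase (~60–70% of the cross-section)
with thin IFM seams — the regime in which the k = 3 rule isolates the IFM
as the brightest cluster, and a realistic rendering of ligament
architecture. Region attenuations rise from a common native baseline
(50 HU) to their equilibrium values (reference: 603 HU fascicle, 795 HU
IFM for the nanoparticle; homogeneous for iodixanol) with a single time
constant; the bath attenuation is derived so the bulk partition saturates
exactly at P_max. Gaussian noise (default 22 HU) is added everywhere; by
default the export is on an uncalibrated linear scale (gain 0.8, offset
900) so HU calibration is genuinely exercised. Not emulated: beam
hardening, scatter, partial-volume blur, anisotropic or radially graded
diffusion, timepoint-to-timepoint motion.

### Cohorts

Per ligament: a lognormal random effect on every mechanical parameter
(CVs set to the healthy-group SD/mean reference ratios, e.g. 0.38 for E),
small within-ligament jitter between the paired control/damaged members
(15% of the ligament-level CVs), the damage effect (with 10% lognormal
jitter on its ratios) applied to the damaged member's post-overstrain
state, and per-agent uptake truths drawn around the reference means
(iodixanol 0.81 ± 0.06 / 0.82 ± 0.20 h; nanoparticle 2.49 ± 0.90 /
5.38 ± 1.36 h) with no group effect on uptake — matching the observed
absence of control/damaged partition differences. All generators are pure
functions of (parameters, seed); per-subsample child seeds are drawn below
2³¹ so volumes can be regenerated lazily instead of stored.

## 6. Pipeline and problem sizes

`run_pipeline` executes simulate → mechanics → cect → segment → report,
writing per-stage CSVs, a parameter summary (group means ± SD with paired
Wilcoxon p), an uptake summary and per-timepoint partition curves, the
correlation screen, and a manifest with SHA-256 checksums of every output.
Identical configurations reproduce byte-identical data files.

Default sizes, chosen to keep a full run in minutes on one CPU while
preserving the study's structure: cohort phantoms are (24, 128, 128)
voxels — the 128-px cross-section is the smallest in which the sample disk
survives the 10 px shrink and 2000 px area filter — with structural
segmentation run on the first two nanoparticle subsamples (mirroring the
two samples selected for qualitative assessment); segmentation validation
phantoms use 8–12 slices of the same cross-section (fascicles are
extruded, so additional slices add no structural information); Monte-Carlo
recovery suites use 50 trace seeds, 500 uptake replicates and 10,000 null
cohorts.

## 7. Known limitations

- The toe model (quadratic, fixed 2% width) is a convention shared by the
  generator and the zero-load refinement; on real data the toe width would
  need calibration, and the refinement falls back to the smoothed-crossing
  estimate when the model fits poorly.
- Phase-shift estimates at noise comparable to the stress amplitude are
  CRLB-limited (see §1); damaged-sample phase shifts at 1–2 Hz in noisy
  cohorts carry degree-scale uncertainty.
- k = 3 structural segmentation assumes fascicle-majority cross-sections
  and two well-separated attenuation modes; a volume of uniform or
  continuum attenuation yields an empty or arbitrary fascicle mask (the
  motivation for the manual-ROI path).
- Bulk partition through the shrunk mask refers to the sample core (≈3%
  P_max bias on structured phantoms); no voxelwise diffusion mapping is
  attempted.
- Passing tests on phantoms demonstrates correctness of the estimators
  under the generator's assumptions, not robustness to physics the
  phantoms omit (beam hardening, motion, partial volume).
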