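# ligcect

Structural and functional evaluation of ligament microdamage from tensile
testing and contrast-enhanced micro-CT (CECT), with synthetic data
generators that make every step of the pipeline testable against known
ground truth.

## The problem

Minor overloads (sprains) can microdamage a ligament without any visible
tear, and such damage is hard to see with clinical imaging. Two
complementary probes can reveal it:

- **Tensile viscoelastics.** A dumbbell sample is preloaded to 0.05 MPa to
  define its zero-load length, preconditioned, ramped to 8% strain at 8%/s,
  held for 10 min, and driven sinusoidally (0.5% amplitude at 0.1, 0.5, 1
  and 2 Hz). Overstraining to 16% induces microdamage; repeating the 8%
  protocol afterwards quantifies it.
- **CECT.** The sample is immersed in a contrast agent — neutral iodixanol
  (small, reflects porosity) or a cationic Ta₂O₅ nanoparticle (larger,
  positively charged, accumulates in the elastin/proteoglycan-rich
  interfascicular matrix, IFM) — and micro-CT-scanned at several immersion
  times. The attenuation gain, normalized to the bath, gives the bulk
  partition; the nanoparticle also renders the fascicle/IFM architecture
  visible.

## Models and statistics

Stress relaxation during the hold is fit with a two-term Prony-type decay

    σ(t) = σ_eq + A₁·exp(−t/θ₁) + A₂·exp(−t/θ₂),      θ₁ < θ₂,

and the ramp slope over the 4–8% strain window gives the Young's modulus E.
Sinusoidal stress lags strain by the phase shift γ (an energy-dissipation
measure). Damage is summarized by Dσ = 1 − σ_peak,post/σ_peak,pre,
Dε = 1 − σ_eq,post/σ_eq,pre, the residual strain λε (relative increase of
the preload-determined zero-load length), and the yield point (ε_yield,
σ_yield) where the tangent modulus on the 16% ramp drops below 70% of E.

Contrast uptake follows first-order kinetics

    Partition(t) = P_max · [1 − exp(−t/τ)],

where P_max is the equilibrium partition and τ the diffusion time constant
(time to 63.2% of equilibrium). Volumes are Hounsfield-calibrated against
water/air reference ROIs, the sample is separated from background by k = 2
intensity clustering with morphological cleanup, and fascicles are
separated from the IFM by per-slice k = 3 clustering (fascicles = tissue
minus the brightest cluster).

Group comparisons use the exact Wilcoxon signed-rank test (paired
control/damaged samples from the same ligament); biomechanics-vs-uptake
associations use Spearman's rank correlation, pooled over groups except for
the damage-specific parameters, with significance at p < 0.05.

## Worked example

Generate a noise-free overstrained test at the healthy reference
parameters and extract everything:

```python
from ligcect.synthetic import MechGroundTruth, Protocol, gen_tensile_test
from ligcect.mechanics import analyze_test

test, truth = gen_tensile_test(MechGroundTruth(), Protocol(damaged=True), seed=0)
res = analyze_test(test)
```

prints (via the fields of `res`):

```
E          =   70.10 MPa  (r^2 = 1.0000)
sigma_eq   =   1.713 MPa   ratio_PE = 1.80
A1, theta1 =   0.880 MPa,   2.56 s
A2, theta2 =   0.490 MPa, 137.18 s
gamma(0.1 Hz) = 4.13 deg
D_sigma = 0.82   D_epsilon = 0.82   lambda_eps = 0.040
yield: strain 0.120, stress 8.09 MPa
```

i.e. the fits recover the generator truth exactly: a 70 MPa modulus, a
peak-to-equilibrium ratio of 1.80, fast (2.56 s) and slow (137 s)
relaxation, a 4.13° phase lag at 0.1 Hz, and the imposed damage (82% peak
stress loss, 4% residual strain, yield at 12% strain).

Uptake fitting on a noisy nanoparticle series:

```python
from ligcect.synthetic import gen_diffusion_series
from ligcect.cect import fit_uptake

series = gen_diffusion_series(2.49, 5.38, [3, 8, 22, 46, 72],
                              noise_sd=0.05, seed=1)
fit = fit_uptake(series)
# Pmax = 2.49 (249%), tau = 5.17 h, rmse = 0.037
```

The nanoparticle equilibrates at 249% of bath concentration (charge-driven
accumulation can exceed 100%) with a ~5 h time constant — about three
times the iodixanol partition (81%, τ ≈ 0.8 h).

The full pipeline — simulate a paired n = 11 cohort, analyze every trace
and phantom series, and write group summary tables, partition curves,
correlation screen and a checksummed manifest — runs as

```bash
ligcect run-all --n 11 --seed 1 --out run/
```

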