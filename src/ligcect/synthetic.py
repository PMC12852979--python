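"""Synthetic data with known ground truth.

Generators for (1) tensile traces following the ramp-hold-sinusoid protocol,
with an optional 16% overstrain block that induces modulus loss and residual
strain; (2) first-order exponential contrast-uptake series; (3) 3D micro-CT
phantoms containing circle-packed fascicles in an interfascicular matrix
(IFM), a water calibration tube and air background, evolving by exponential
uptake kinetics; and (4) full paired control/damaged cohorts emulating the
study's statistical structure.

All generators are pure functions of their parameters and a seed.  Segment
stress models are piecewise: the ramp follows a toe-then-linear elastic
curve with slope exactly E, the hold follows the two-exponential relaxation
exactly, and sinusoidal stress lags strain by exactly gamma, so every
downstream fit has an exact generator truth (relaxation during the ramp is
not modeled and the ramp-to-hold stress transition is discontinuous).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .cect import DiffusionSeries
from .io import (
    AGENT_TIMEPOINTS_H,
    CTVolume,
    Geometry,
    Segment,
    StudyRow,
    StudyTable,
    TensileTest,
    ValidationError,
)

# ---------------------------------------------------------------------------
# ground truth containers
# ---------------------------------------------------------------------------

_DEFAULT_GAMMA = {0.1: 4.13, 0.5: 3.27, 1.0: 3.08, 2.0: 2.95}


@dataclass(frozen=True)
class MechGroundTruth:
    """True viscoelastic and damage parameters behind a generated trace.

    Defaults are reference group means for healthy bovine cruciate ligament:
    modulus ~70 MPa, fast/slow relaxation (A1, theta1; A2, theta2), a
    peak-to-equilibrium ratio of 1.80 (fixing sigma_eq), and phase shifts of
    3-4 degrees across 0.1-2 Hz.
    """

    E_MPa: float = 70.10
    sigma_eq_MPa: float = (0.88 + 0.49) / 0.80  # peak/equilibrium ratio 1.80
    A1_MPa: float = 0.88
    theta1_s: float = 2.56
    A2_MPa: float = 0.49
    theta2_s: float = 137.18
    gamma_deg: Mapping[float, float] = field(
        default_factory=lambda: dict(_DEFAULT_GAMMA)
    )
    yield_strain: float = 0.12
    yield_stress_MPa: float | None = None  # derived from the ramp model
    damage_fraction: float = 0.82
    residual_strain: float = 0.04

    def __post_init__(self) -> None:
        if min(self.E_MPa, self.sigma_eq_MPa, self.A1_MPa, self.A2_MPa) < 0:
            raise ValidationError("moduli and amplitudes must be >= 0")
        if not self.theta1_s < self.theta2_s:
            raise ValidationError("theta1 (fast) must be smaller than theta2 (slow)")
        for f, g in self.gamma_deg.items():
            if not 0.0 < g < 90.0:
                raise ValidationError(f"gamma at {f} Hz must lie in (0, 90)")
        if not 0.0 <= self.damage_fraction < 1.0:
            raise ValidationError("damage_fraction must lie in [0, 1)")

    @property
    def sigma_peak_MPa(self) -> float:
        return self.sigma_eq_MPa + self.A1_MPa + self.A2_MPa


#: reference group means for the post-overstrain (damaged) state
DAMAGED_REFERENCE = MechGroundTruth(
    E_MPa=22.13,
    sigma_eq_MPa=(0.11 + 0.06) / 0.44,  # peak/equilibrium ratio 1.44
    A1_MPa=0.11,
    theta1_s=2.25,
    A2_MPa=0.06,
    theta2_s=120.58,
    gamma_deg={0.1: 3.55, 0.5: 3.01, 1.0: 3.15, 2.0: 3.20},
)

CONTROL_REFERENCE = MechGroundTruth()


@dataclass(frozen=True)
class DamageEffect:
    """Multiplicative map from a healthy truth to its post-overstrain state.

    Default ratios are the damaged/healthy reference group means; the
    residual strain and yield point are set directly.  ``variability_cv``
    adds ligament-level lognormal jitter to the ratios in cohort generation.
    """

    modulus_ratio: float = 22.13 / 70.10
    sigma_eq_ratio: float = ((0.11 + 0.06) / 0.44) / ((0.88 + 0.49) / 0.80)
    A1_ratio: float = 0.11 / 0.88
    theta1_ratio: float = 2.25 / 2.56
    A2_ratio: float = 0.06 / 0.49
    theta2_ratio: float = 120.58 / 137.18
    gamma_ratio: Mapping[float, float] = field(
        default_factory=lambda: {
            0.1: 3.55 / 4.13, 0.5: 3.01 / 3.27, 1.0: 3.15 / 3.08, 2.0: 3.20 / 2.95,
        }
    )
    residual_strain: float = 0.04
    yield_strain: float = 0.12
    variability_cv: float = 0.10

    @classmethod
    def null(cls) -> "DamageEffect":
        """No-op damage: identical pre/post state (a null cohort)."""
        return cls(
            modulus_ratio=1.0, sigma_eq_ratio=1.0, A1_ratio=1.0, theta1_ratio=1.0,
            A2_ratio=1.0, theta2_ratio=1.0,
            gamma_ratio={f: 1.0 for f in _DEFAULT_GAMMA},
            residual_strain=0.0, yield_strain=0.12, variability_cv=0.0,
        )

    def apply(self, truth: MechGroundTruth, rng: np.random.Generator | None = None,
              ) -> MechGroundTruth:
        def jitter() -> float:
            if rng is None or self.variability_cv <= 0:
                return 1.0
            sd = math.sqrt(math.log(1.0 + self.variability_cv**2))
            return float(np.exp(rng.normal(-0.5 * sd**2, sd)))

        theta1 = truth.theta1_s * self.theta1_ratio * jitter()
        theta2 = truth.theta2_s * self.theta2_ratio * jitter()
        if theta1 >= theta2:
            theta1 = 0.5 * theta2
        gamma = {
            f: min(89.0, max(0.1, g * self.gamma_ratio.get(f, 1.0) * jitter()))
            for f, g in truth.gamma_deg.items()
        }
        return replace(
            truth,
            E_MPa=truth.E_MPa * self.modulus_ratio * jitter(),
            sigma_eq_MPa=truth.sigma_eq_MPa * self.sigma_eq_ratio * jitter(),
            A1_MPa=truth.A1_MPa * self.A1_ratio * jitter(),
            theta1_s=theta1,
            A2_MPa=truth.A2_MPa * self.A2_ratio * jitter(),
            theta2_s=theta2,
            gamma_deg=gamma,
            residual_strain=self.residual_strain * (jitter() if self.residual_strain else 1.0),
            yield_strain=self.yield_strain,
        )


@dataclass
class CTGroundTruth:
    """Phantom ground truth: region masks, attenuations and uptake kinetics.

    ``mu_fascicle_HU``/``mu_ifm_HU`` are the equilibrium (t -> inf) region
    attenuations; the native (pre-immersion) tissue sits at
    ``native_mu_HU``.  ``bath_hu`` is derived so the bulk tissue partition
    saturates exactly at ``Pmax_true``.
    """

    fascicle_mask: np.ndarray | None = None
    ifm_mask: np.ndarray | None = None
    mu_fascicle_HU: float = 603.0
    mu_ifm_HU: float = 795.0
    noise_sd_HU: float = 22.0
    Pmax_true: float = 2.49
    tau_true_h: float = 5.38
    timepoints_h: tuple[float, ...] = AGENT_TIMEPOINTS_H["Ta2O5-cNP"]
    native_mu_HU: float = 50.0
    bath_hu: float | None = None
    agent: str = "Ta2O5-cNP"

    def __post_init__(self) -> None:
        if not (self.Pmax_true > 0 and self.tau_true_h > 0):
            raise ValidationError("Pmax_true and tau_true_h must be > 0")
        if self.fascicle_mask is not None and self.ifm_mask is not None:
            f = np.asarray(self.fascicle_mask, dtype=bool)
            i = np.asarray(self.ifm_mask, dtype=bool)
            if np.any(f & i):
                raise ValidationError("fascicle and IFM masks must be disjoint")

    @property
    def tissue_mask(self) -> np.ndarray:
        return np.asarray(self.fascicle_mask, bool) | np.asarray(self.ifm_mask, bool)


def ct_truth_for_agent(
    agent: str,
    pmax: float,
    tau_h: float,
    noise_sd_hu: float = 22.0,
    native_mu_hu: float = 50.0,
) -> CTGroundTruth:
    """Phantom truth scaled to a subsample's (Pmax, tau).

    The cationic nanoparticle concentrates in the IFM (reference equilibrium
    attenuations 603 HU fascicle / 795 HU IFM at Pmax 2.49); neutral
    iodixanol distributes homogeneously (equal region attenuations, bath
    ~600 HU above water).
    """
    if agent == "iodixanol":
        amp = pmax * 600.0
        mu_f = mu_i = native_mu_hu + amp
    else:
        scale = pmax / 2.49
        mu_f = native_mu_hu + (603.0 - native_mu_hu) * scale
        mu_i = native_mu_hu + (795.0 - native_mu_hu) * scale
    return CTGroundTruth(
        mu_fascicle_HU=mu_f,
        mu_ifm_HU=mu_i,
        noise_sd_HU=noise_sd_hu,
        Pmax_true=pmax,
        tau_true_h=tau_h,
        timepoints_h=AGENT_TIMEPOINTS_H[agent],
        native_mu_HU=native_mu_hu,
        agent=agent,
    )


# ---------------------------------------------------------------------------
# tensile test protocol and trace generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Protocol:
    """Tensile protocol constants (strains as fractions, rates per second)."""

    damaged: bool = False
    sample_rate_hz: float = 100.0
    precondition_blocks: int = 5
    precondition_cycles: int = 10
    precondition_strain: float = 0.06
    precondition_rate: float = 0.02
    ramp_strain: float = 0.08
    ramp_rate: float = 0.08
    hold_s: float = 600.0
    sinusoid_amplitude: float = 0.005
    frequencies: tuple[float, ...] = (0.1, 0.5, 1.0, 2.0)
    sinusoid_cycles: int = 6
    overstrain: float = 0.16
    overstrain_hold_s: float = 2.0
    rezero_s: float = 1.0
    ramp_slack_strain: float = 0.02  # sub-preload lead-in before each ramp
    toe_strain: float = 0.02
    preload_mpa: float = 0.05
    post_yield_slope_fraction: float = 0.3
    dynamic_modulus_factor: float = 1.0


DEFAULT_GEOMETRY = Geometry(width_mm=4.28, thickness_mm=3.42, clamp_length_mm=19.6)


def _preload_strain(e_mpa: float, toe: float, preload: float) -> float:
    """Strain offset at which the toe curve reaches the preload stress."""
    return math.sqrt(2.0 * preload * toe / e_mpa)


def _elastic_stress(
    eps: np.ndarray,
    e_mpa: float,
    toe: float,
    eps_star: float,
    yield_strain: float | None = None,
    post_fraction: float = 0.3,
) -> np.ndarray:
    """Toe-then-linear elastic curve, measured from the preload crossing.

    ``eps`` is strain relative to the preload-determined zero-load length, so
    stress equals the preload at eps = 0 and the linear-region slope is
    exactly ``e_mpa``.  An optional bilinear yield kink reduces the tangent
    to ``post_fraction * e_mpa`` above ``yield_strain``.
    """
    u = np.asarray(eps, dtype=float) + eps_star
    sig = np.where(
        u < toe, e_mpa * u**2 / (2.0 * toe), e_mpa * (u - toe / 2.0)
    )
    sig = np.where(u <= 0.0, 0.0, sig)
    if yield_strain is not None:
        s_y = e_mpa * (yield_strain + eps_star - toe / 2.0)
        sig = np.where(
            eps > yield_strain,
            s_y + post_fraction * e_mpa * (eps - yield_strain),
            sig,
        )
    return sig


def yield_stress_truth(truth: MechGroundTruth, protocol: Protocol) -> float:
    """Model yield stress implied by (E, yield_strain) and the toe shape."""
    eps_star = _preload_strain(truth.E_MPa, protocol.toe_strain, protocol.preload_mpa)
    return truth.E_MPa * (truth.yield_strain + eps_star - protocol.toe_strain / 2.0)


class _TraceBuilder:
    def __init__(self, rate_hz: float):
        self.dt = 1.0 / rate_hz
        self.t0 = 0.0
        self.chunks_len: list[np.ndarray] = []
        self.chunks_sig: list[np.ndarray] = []
        self.times: list[np.ndarray] = []
        self.segments: list[Segment] = []

    def add(self, label: str, lengths: np.ndarray, stresses: np.ndarray) -> None:
        n = len(lengths)
        if n == 0:
            return
        t = self.t0 + np.arange(n) * self.dt
        self.times.append(t)
        self.chunks_len.append(np.asarray(lengths, dtype=float))
        self.chunks_sig.append(np.asarray(stresses, dtype=float))
        t_end = self.t0 + n * self.dt
        self.segments.append(Segment(label, self.t0, t_end))
        self.t0 = t_end


def _n_samples(duration_s: float, rate: float) -> int:
    return max(1, int(round(duration_s * rate)))


def gen_tensile_test(
    truth: MechGroundTruth,
    protocol: Protocol | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    geometry: Geometry = DEFAULT_GEOMETRY,
    sample_id: str = "S1",
    post_truth: MechGroundTruth | None = None,
) -> tuple[TensileTest, MechGroundTruth]:
    """Generate a full protocol trace for one sample.

    For a damaged protocol the post-overstrain segments follow
    ``post_truth``; when not supplied it is derived from ``truth`` by scaling
    every stress-like parameter (and hence the modulus) by
    ``1 - damage_fraction``, so the damage metrics have the exact truths
    ``D_sigma = D_epsilon = damage_fraction`` and
    ``lambda_epsilon = residual_strain``.  Gaussian noise of SD ``noise_sd``
    (MPa) is added to the stress channel only; displacement is
    device-controlled and exact.

    Returns the trace and the truth with the derived yield stress filled in.
    """
    protocol = protocol or Protocol()
    if protocol.damaged and truth.damage_fraction == 0 and post_truth is None:
        pass  # a zero-damage overstrain run is legitimate (null cohort)
    rng = np.random.default_rng(seed)
    p = protocol
    rate = p.sample_rate_hz
    toe = p.toe_strain

    l0 = geometry.clamp_length_mm
    eps_star = _preload_strain(truth.E_MPa, toe, p.preload_mpa)

    def elastic(eps, tr, es, **kw):
        return _elastic_stress(eps, tr.E_MPa, toe, es, **kw)

    b = _TraceBuilder(rate)

    # --- preconditioning: triangular cycles to 6% strain -------------------
    slack = p.ramp_slack_strain
    cyc_up = np.linspace(
        -(eps_star + slack), p.precondition_strain,
        _n_samples((p.precondition_strain + eps_star + slack) / p.precondition_rate,
                   rate),
        endpoint=False,
    )
    cyc = np.concatenate([cyc_up, cyc_up[::-1]])
    pre_eps = np.tile(cyc, p.precondition_blocks * p.precondition_cycles)
    b.add("preconditioning", l0 * (1 + pre_eps), elastic(pre_eps, truth, eps_star))

    # --- rezero dwell at the slack position --------------------------------
    n_rz = _n_samples(p.rezero_s, rate)
    b.add("rezero", np.full(n_rz, l0 * (1 - eps_star - slack)), np.zeros(n_rz))

    def ramp_hold_sin(prefix: str, tr: MechGroundTruth, l0_block: float,
                      es: float) -> None:
        ramp_eps = np.linspace(
            -(es + slack), p.ramp_strain,
            _n_samples((p.ramp_strain + es + slack) / p.ramp_rate, rate),
            endpoint=False,
        )
        b.add(prefix + "ramp8", l0_block * (1 + ramp_eps), elastic(ramp_eps, tr, es))
        t_hold = np.arange(_n_samples(p.hold_s, rate)) / rate
        sig_hold = (
            tr.sigma_eq_MPa
            + tr.A1_MPa * np.exp(-t_hold / tr.theta1_s)
            + tr.A2_MPa * np.exp(-t_hold / tr.theta2_s)
        )
        b.add(prefix + "hold8", np.full(t_hold.size, l0_block * (1 + p.ramp_strain)),
              sig_hold)
        for f in p.frequencies:
            t_sin = np.arange(_n_samples(p.sinusoid_cycles / f, rate)) / rate
            omega = 2 * math.pi * f
            eps_sin = p.ramp_strain + p.sinusoid_amplitude * np.sin(omega * t_sin)
            gamma = math.radians(tr.gamma_deg[f])
            amp = p.dynamic_modulus_factor * tr.E_MPa * p.sinusoid_amplitude
            sig_sin = tr.sigma_eq_MPa + amp * np.sin(omega * t_sin - gamma)
            b.add(f"{prefix}sinusoid@{f:g}", l0_block * (1 + eps_sin), sig_sin)

    ramp_hold_sin("", truth, l0, eps_star)

    derived = replace(truth, yield_stress_MPa=yield_stress_truth(truth, p))
    if p.damaged:
        if post_truth is None:
            s = 1.0 - truth.damage_fraction
            post_truth = replace(
                truth,
                E_MPa=truth.E_MPa * s,
                sigma_eq_MPa=truth.sigma_eq_MPa * s,
                A1_MPa=truth.A1_MPa * s,
                A2_MPa=truth.A2_MPa * s,
            )
        lam = truth.residual_strain
        l0_post = l0 * (1 + lam)
        es_post = _preload_strain(post_truth.E_MPa, toe, p.preload_mpa)

        # 16% overstrain ramp with a bilinear yield kink, then a short hold
        ramp16_eps = np.linspace(
            p.ramp_strain, p.overstrain,
            _n_samples((p.overstrain - p.ramp_strain) / p.ramp_rate, rate),
            endpoint=False,
        )
        sig16 = elastic(ramp16_eps, truth, eps_star,
                        yield_strain=truth.yield_strain,
                        post_fraction=p.post_yield_slope_fraction)
        b.add("ramp16", l0 * (1 + ramp16_eps), sig16)
        sig_end = elastic(np.array([p.overstrain]), truth, eps_star,
                          yield_strain=truth.yield_strain,
                          post_fraction=p.post_yield_slope_fraction)[0]
        n_h2 = _n_samples(p.overstrain_hold_s, rate)
        b.add("hold2s", np.full(n_h2, l0 * (1 + p.overstrain)),
              np.full(n_h2, sig_end))

        # return toward the (new, longer) slack length
        l_end = l0_post * (1 - es_post - slack)
        n_ret = _n_samples((l0 * (1 + p.overstrain) - l_end) / (l0 * p.ramp_rate), rate)
        lengths_ret = np.linspace(l0 * (1 + p.overstrain), l_end, n_ret, endpoint=False)
        eps_ret_post = lengths_ret / l0_post - 1.0
        b.add("return", lengths_ret, elastic(eps_ret_post, post_truth, es_post))

        ramp_hold_sin("post_", post_truth, l0_post, es_post)

    time = np.concatenate(b.times)
    stress = np.concatenate(b.chunks_sig)
    if noise_sd > 0:
        stress = stress + rng.normal(0.0, noise_sd, size=stress.size)
    area = math.pi * geometry.width_mm * geometry.thickness_mm / 4.0
    lengths = np.concatenate(b.chunks_len)
    test = TensileTest(
        time=time,
        displacement=lengths - l0,
        force=stress * area,
        segments=b.segments,
        geometry=geometry,
        sample_id=sample_id,
        group="damaged" if p.damaged else "control",
    )
    return test, derived


# ---------------------------------------------------------------------------
# diffusion series
# ---------------------------------------------------------------------------

def gen_diffusion_series(
    pmax: float,
    tau_h: float,
    timepoints_h: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    agent: str = "none",
    sample_id: str = "",
) -> DiffusionSeries:
    """First-order uptake series ``Pmax (1 - exp(-t/tau))`` plus noise."""
    if pmax <= 0 or tau_h <= 0:
        raise ValidationError("Pmax and tau must be > 0")
    t = np.asarray(timepoints_h, dtype=float)
    part = pmax * (1.0 - np.exp(-t / tau_h))
    if noise_sd > 0:
        part = part + np.random.default_rng(seed).normal(0, noise_sd, t.size)
    return DiffusionSeries(timepoints_h=t, partition=part, agent=agent,
                           sample_id=sample_id)


# ---------------------------------------------------------------------------
# CT phantom
# ---------------------------------------------------------------------------

def _pack_fascicles(
    rng: np.random.Generator,
    sample_radius_vox: float,
    voxel_um: float,
    diameter_um: tuple[float, float] = (50.0, 500.0),
    gap_vox: float = 1.0,
    max_failures: int = 400,
) -> list[tuple[float, float, float]]:
    """Greedy random circle packing inside a disk, >= 1 voxel IFM gaps.

    Radii are drawn log-uniformly over the admissible diameter range (the
    lower bound is raised to 3 voxels so no fascicle is sub-resolution) and
    attempted largest-first, which yields a fascicle-dominated cross-section
    with thin IFM seams.
    """
    d_lo = max(diameter_um[0], 3.0 * voxel_um)
    d_hi = min(diameter_um[1], 1.2 * sample_radius_vox * voxel_um)
    if d_lo > d_hi:
        raise ValidationError(
            f"fascicle diameter range [{d_lo:.0f}, {d_hi:.0f}] um is empty at "
            f"{voxel_um} um voxels"
        )
    radii = np.exp(rng.uniform(np.log(d_lo), np.log(d_hi), size=600)) / 2.0 / voxel_um
    radii = np.sort(radii)[::-1]
    placed: list[tuple[float, float, float]] = []
    failures = 0
    for r in radii:
        if failures > max_failures:
            break
        ok = False
        for _ in range(60):
            rho = sample_radius_vox - r - gap_vox
            if rho <= 0:
                break
            a = rng.uniform(0, 2 * math.pi)
            rad = rho * math.sqrt(rng.uniform())
            cy, cx = rad * math.sin(a), rad * math.cos(a)
            if all(
                math.hypot(cy - y0, cx - x0) >= r + r0 + gap_vox
                for y0, x0, r0 in placed
            ):
                placed.append((cy, cx, r))
                ok = True
                break
        failures = 0 if ok else failures + 1
    return placed


def gen_ct_phantom(
    shape: tuple[int, int, int] = (48, 128, 128),
    voxel_um: float = 16.99,
    truth: CTGroundTruth | None = None,
    seed: int = 0,
    *,
    sample_radius_frac: float = 0.33,
    fascicle_circles: Sequence[tuple[float, float, float]] | None = None,
    emit: str = "raw",
    raw_gain: float = 0.8,
    raw_offset: float = 900.0,
    sample_id: str = "P1",
) -> tuple[CTVolume, list[CTVolume], CTGroundTruth]:
    """Generate a native scan plus an immersion time series of phantoms.

    The cross-section is a disk of tissue (circle-packed fascicles in IFM)
    extruded along z, with an off-sample water tube and air background.
    Region attenuation rises from the native baseline toward the equilibrium
    region values by ``1 - exp(-t/tau)``; the bath attenuation is derived so
    the bulk tissue partition saturates exactly at ``Pmax_true``.  With
    ``emit='raw'`` intensities are exported on an uncalibrated linear scale
    (``raw = HU * raw_gain + raw_offset``) for the calibration step to undo;
    ``emit='hu'`` exports calibrated HU directly.

    Returns (native volume, timepoint volumes, truth with masks and bath).
    """
    truth = truth or CTGroundTruth()
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    cy, cx = ny / 2.0, nx * 0.45
    r_sample = sample_radius_frac * min(ny, nx)

    yy, xx = np.mgrid[0:ny, 0:nx]
    sample2d = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_sample**2

    if fascicle_circles is None:
        fascicle_circles = _pack_fascicles(rng, r_sample, voxel_um)
    fasc2d = np.zeros((ny, nx), dtype=bool)
    for fy, fx, fr in fascicle_circles:
        if 2 * fr * voxel_um < 3.0 * voxel_um - 1e-9:
            raise ValidationError("fascicle diameter below 3 voxels")
        fasc2d |= (yy - (cy + fy)) ** 2 + (xx - (cx + fx)) ** 2 <= fr**2
    fasc2d &= sample2d
    ifm2d = sample2d & ~fasc2d

    # water calibration tube (smaller than the sample) and reference ROIs
    ty, tx, tr_ = ny * 0.15, nx * 0.8, 0.08 * min(ny, nx)
    water2d = (yy - ty) ** 2 + (xx - tx) ** 2 <= tr_**2

    fascicle_mask = np.broadcast_to(fasc2d, shape).copy()
    ifm_mask = np.broadcast_to(ifm2d, shape).copy()
    water_mask = np.broadcast_to(water2d, shape).copy()

    hw = max(2, int(tr_ / 2))
    water_roi = np.zeros(shape, dtype=bool)
    water_roi[:, int(ty) - hw:int(ty) + hw, int(tx) - hw:int(tx) + hw] = True
    air_roi = np.zeros(shape, dtype=bool)
    air_roi[:, 2:max(8, ny // 12), 2:max(8, nx // 12)] = True
    if (air_roi & (water_mask | sample2d[None, :, :])).any():
        raise ValidationError("air ROI overlaps the sample or tube")

    # bath derived so the bulk partition saturates exactly at Pmax_true
    n_f, n_i = int(fasc2d.sum()), int(ifm2d.sum())
    if n_i == 0:
        raise ValidationError("IFM is empty: fascicles fill the whole sample")
    amp_f = truth.mu_fascicle_HU - truth.native_mu_HU
    amp_i = truth.mu_ifm_HU - truth.native_mu_HU
    amp_tissue = (n_f * amp_f + n_i * amp_i) / (n_f + n_i)
    bath_hu = amp_tissue / truth.Pmax_true

    def build(timepoint_h: float | None) -> CTVolume:
        hu = np.full(shape, -1000.0, dtype=np.float64)
        hu[water_mask] = 0.0
        if timepoint_h is None:
            uptake = 0.0
        else:
            uptake = 1.0 - math.exp(-timepoint_h / truth.tau_true_h)
        hu[fascicle_mask] = truth.native_mu_HU + amp_f * uptake
        hu[ifm_mask] = truth.native_mu_HU + amp_i * uptake
        if truth.noise_sd_HU > 0:
            hu += rng.normal(0.0, truth.noise_sd_HU, size=shape)
        if emit == "raw":
            data = hu * raw_gain + raw_offset
            calibrated = False
        else:
            data = hu
            calibrated = True
        return CTVolume(
            intensities=data.astype(np.float32),
            voxel_size_um=voxel_um,
            calibrated=calibrated,
            water_roi=water_roi,
            air_roi=air_roi,
            timepoint_h=timepoint_h,
            agent=truth.agent,
            bath_hu=bath_hu,
            sample_id=sample_id,
        )

    native = build(None)
    series = [build(float(t)) for t in truth.timepoints_h]
    truth_out = replace(
        truth, fascicle_mask=fascicle_mask, ifm_mask=ifm_mask, bath_hu=bath_hu
    )
    return native, series, truth_out


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

#: per-parameter coefficient of variation of the ligament-level random
#: effects (reference healthy-group SD/mean ratios)
LIGAMENT_CV = {
    "E_MPa": 26.67 / 70.10,
    "sigma_eq_MPa": 0.30,
    "A1_MPa": 0.33 / 0.88,
    "theta1_s": 0.78 / 2.56,
    "A2_MPa": 0.18 / 0.49,
    "theta2_s": 14.35 / 137.18,
    "gamma": 0.15,
}

#: reference (mean, SD) of the uptake parameters per agent
AGENT_UPTAKE_REFERENCE = {
    "iodixanol": {"Pmax": (0.81, 0.06), "tau_h": (0.82, 0.20)},
    "Ta2O5-cNP": {"Pmax": (2.49, 0.90), "tau_h": (5.38, 1.36)},
}


@dataclass(frozen=True)
class CohortNoise:
    """Measurement noise levels applied across a synthetic cohort."""

    mech_stress_sd_frac: float = 0.02   # x peak ramp stress, per sample
    ct_noise_sd_hu: float = 22.0
    partition_sd: float = 0.03          # used by the volume-free CT mode


def _lognormal(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Lognormal draw with the requested mean and coefficient of variation."""
    if cv <= 0:
        return mean
    s2 = math.log(1.0 + cv**2)
    return float(np.exp(rng.normal(math.log(mean) - 0.5 * s2, math.sqrt(s2))))


def _jitter_truth(truth: MechGroundTruth, rng: np.random.Generator,
                  cv_scale: float = 1.0) -> MechGroundTruth:
    def draw(value: float, key: str) -> float:
        return _lognormal(rng, value, LIGAMENT_CV[key] * cv_scale)

    theta1 = draw(truth.theta1_s, "theta1_s")
    theta2 = draw(truth.theta2_s, "theta2_s")
    if theta1 >= theta2:
        theta1 = 0.5 * theta2
    gamma = {
        f: min(89.0, _lognormal(rng, g, LIGAMENT_CV["gamma"] * cv_scale))
        for f, g in truth.gamma_deg.items()
    }
    return replace(
        truth,
        E_MPa=draw(truth.E_MPa, "E_MPa"),
        sigma_eq_MPa=draw(truth.sigma_eq_MPa, "sigma_eq_MPa"),
        A1_MPa=draw(truth.A1_MPa, "A1_MPa"),
        theta1_s=theta1,
        A2_MPa=draw(truth.A2_MPa, "A2_MPa"),
        theta2_s=theta2,
        gamma_deg=gamma,
        yield_strain=float(np.clip(rng.normal(truth.yield_strain, 0.01), 0.09, 0.15)),
    )


def gen_cohort(
    n_ligaments: int = 11,
    control_truth: MechGroundTruth | None = None,
    damage_effect: DamageEffect | None = None,
    noise: CohortNoise | None = None,
    seed: int = 0,
    *,
    protocol: Protocol | None = None,
    agents: tuple[str, ...] = ("iodixanol", "Ta2O5-cNP"),
    ct_shape: tuple[int, int, int] | None = None,
) -> StudyTable:
    """Generate a paired control/damaged cohort with full ground truth.

    Per ligament: a ligament-level random effect on the healthy truth, two
    subsamples (control and damaged) with small within-ligament jitter, the
    damage effect applied to the damaged member's post-overstrain state, and
    per-agent uptake truths drawn around the reference means.  CT phantoms
    are attached only when ``ct_shape`` is given (they are bulky); otherwise
    the per-subsample CT truths and derived seeds allow downstream stages to
    regenerate volumes deterministically.
    """
    if n_ligaments < 2:
        raise ValidationError("need at least 2 ligaments")
    control_truth = control_truth or MechGroundTruth()
    damage_effect = damage_effect or DamageEffect()
    noise = noise or CohortNoise()
    base_protocol = protocol or Protocol()
    rng = np.random.default_rng(seed)

    rows: list[StudyRow] = []
    traces: dict = {}
    volumes: dict = {}
    truth: dict = {"mech": {}, "cect": {}, "seed": seed}

    for i in range(n_ligaments):
        lig = f"L{i + 1:02d}"
        lig_truth = _jitter_truth(control_truth, rng)
        lig_uptake = {
            agent: {
                "Pmax": _lognormal(rng, ref["Pmax"][0], ref["Pmax"][1] / ref["Pmax"][0]),
                "tau_h": _lognormal(rng, ref["tau_h"][0], ref["tau_h"][1] / ref["tau_h"][0]),
            }
            for agent, ref in AGENT_UPTAKE_REFERENCE.items()
            if agent in agents
        }
        for group in ("control", "damaged"):
            member_truth = _jitter_truth(lig_truth, rng, cv_scale=0.15)
            damaged = group == "damaged"
            proto = replace(base_protocol, damaged=damaged)
            post_truth = damage_effect.apply(member_truth, rng) if damaged else None
            peak = _elastic_stress(
                np.array([proto.ramp_strain]), member_truth.E_MPa, proto.toe_strain,
                _preload_strain(member_truth.E_MPa, proto.toe_strain, proto.preload_mpa),
            )[0]
            trace_seed = int(rng.integers(0, 2**31 - 1))
            test, filled = gen_tensile_test(
                member_truth, proto,
                noise_sd=noise.mech_stress_sd_frac * peak,
                seed=trace_seed,
                sample_id=f"{lig}-{group}",
                post_truth=post_truth,
            )
            traces[(lig, group)] = test
            mech_entry = {"pre": filled, "post": post_truth}
            if damaged:
                mech_entry["damage"] = {
                    "D_sigma": 1.0 - post_truth.sigma_peak_MPa / member_truth.sigma_peak_MPa,
                    "D_epsilon": 1.0 - post_truth.sigma_eq_MPa / member_truth.sigma_eq_MPa,
                    "lambda_epsilon": post_truth.residual_strain,
                    "yield_strain": member_truth.yield_strain,
                    "yield_stress": filled.yield_stress_MPa,
                }
            truth["mech"][(lig, group)] = mech_entry

            for agent in agents:
                base = lig_uptake[agent]
                pmax = _lognormal(rng, base["Pmax"], 0.05)
                tau = _lognormal(rng, base["tau_h"], 0.05)
                ct_seed = int(rng.integers(0, 2**31 - 1))
                ct_truth = ct_truth_for_agent(
                    agent, pmax, tau, noise_sd_hu=noise.ct_noise_sd_hu
                )
                rows.append(StudyRow(ligament_id=lig, group=group, agent=agent))
                truth["cect"][(lig, group, agent)] = {
                    "Pmax": pmax,
                    "tau_h": tau,
                    "seed": ct_seed,
                    "ct_truth": ct_truth,
                }
                if ct_shape is not None:
                    native, series, filled_ct = gen_ct_phantom(
                        shape=ct_shape, truth=ct_truth, seed=ct_seed,
                        sample_id=f"{lig}-{group}-{agent}",
                    )
                    volumes[(lig, group, agent)] = [native, *series]
                    truth["cect"][(lig, group, agent)]["ct_truth"] = filled_ct

    return StudyTable(rows=rows, traces=traces, volumes=volumes, truth=truth)


__all__ = [
    "AGENT_UPTAKE_REFERENCE",
    "CONTROL_REFERENCE",
    "CohortNoise",
    "CTGroundTruth",
    "DAMAGED_REFERENCE",
    "DamageEffect",
    "DEFAULT_GEOMETRY",
    "LIGAMENT_CV",
    "MechGroundTruth",
    "Protocol",
    "ct_truth_for_agent",
    "gen_cohort",
    "gen_ct_phantom",
    "gen_diffusion_series",
    "gen_tensile_test",
    "yield_stress_truth",
]
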