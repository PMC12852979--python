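import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from ligcect.io import ValidationError
from ligcect.mechanics import (
    RelaxationFit,
    StressStrainSeries,
    compute_young_modulus,
    damage_parameters,
    detect_yield,
    elliptical_area,
    find_zero_load_length,
    fit_relaxation,
    fit_sinusoid_phase,
)

HSETTINGS = settings(max_examples=30, deadline=None, derandomize=True)


class TestEllipticalArea:
    def test_reference_values(self):
        assert elliptical_area(4, 3) == pytest.approx(9.4248, abs=1e-4)
        d = 2.5
        assert elliptical_area(d, d) == pytest.approx(math.pi * d**2 / 4)

    def test_matches_quadrature_oracle(self):
        for w in (1.0, 2.5, 5.0):
            for t in (1.0, 3.3, 5.0):
                # ellipse area by numeric integration of the upper half-curve
                half, _ = quad(
                    lambda x: (t / 2) * math.sqrt(max(0.0, 1 - (2 * x / w) ** 2)),
                    -w / 2, w / 2,
                )
                assert elliptical_area(w, t) == pytest.approx(2 * half, abs=1e-9)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            elliptical_area(0, 1)


class TestZeroLoadLength:
    def test_exact_sample_hit(self):
        lengths = np.array([20.0, 20.5, 21.0])
        stress = np.array([0.0, 0.05, 0.10])
        assert find_zero_load_length(lengths, stress) == 20.5

    def test_linear_interpolated_midpoint(self):
        lengths = np.linspace(20, 21, 11)
        stress = np.linspace(0, 0.1, 11) + 1e-9  # no exact hit
        assert find_zero_load_length(lengths, stress) == pytest.approx(20.5, abs=1e-6)

    def test_preload_never_reached(self):
        with pytest.raises(ValidationError, match="preload"):
            find_zero_load_length(np.array([20.0, 21.0]), np.array([0.0, 0.01]))

    def test_recovers_generator_truth(self, damaged_analysis_clean):
        from ligcect.synthetic import DEFAULT_GEOMETRY

        l0 = DEFAULT_GEOMETRY.clamp_length_mm
        assert damaged_analysis_clean["zero_load_length_mm"] == pytest.approx(
            l0, rel=1e-4
        )
        assert damaged_analysis_clean["post_zero_load_length_mm"] == pytest.approx(
            l0 * 1.04, rel=1e-4
        )


class TestYoungModulus:
    def test_exact_linear_curve(self):
        eps = np.linspace(0, 0.08, 200)
        series = StressStrainSeries(np.arange(200.0), eps, 50.0 * eps)
        res = compute_young_modulus(series)
        assert res.E == pytest.approx(50.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_too_few_window_samples(self):
        eps = np.linspace(0, 0.02, 50)
        with pytest.raises(ValidationError, match="window"):
            compute_young_modulus(StressStrainSeries(np.arange(50.0), eps, eps))

    def test_pure_noise_flagged_low_quality(self):
        rng = np.random.default_rng(0)
        eps = np.linspace(0.0, 0.08, 400)
        series = StressStrainSeries(np.arange(400.0), eps, rng.normal(0, 1, 400))
        res = compute_young_modulus(series)
        assert res.low_quality and res.r_squared < 0.2

    def test_recovers_toe_plus_linear_truth(self, damaged_analysis_clean):
        assert damaged_analysis_clean["pre"]["modulus"].E == pytest.approx(
            70.10, rel=1e-3
        )


class TestRelaxationFit:
    def test_constant_hold_degenerate(self):
        series = StressStrainSeries(
            np.arange(600.0), np.full(600, 0.08), np.full(600, 2.0)
        )
        fit = fit_relaxation(series)
        assert fit.sigma_eq == pytest.approx(2.0)
        assert fit.A1 == 0.0 and fit.A2 == 0.0
        assert "degenerate" in fit.flags
        assert fit.ratio_pe == pytest.approx(1.0)

    def test_noiseless_reference_means_recovered(self, damaged_analysis_clean):
        fit = damaged_analysis_clean["pre"]["relaxation"]
        for got, want in (
            (fit.A1, 0.88), (fit.theta1, 2.56), (fit.A2, 0.49),
            (fit.theta2, 137.18), (fit.ratio_pe, 1.80),
        ):
            assert got == pytest.approx(want, rel=1e-3)

    def test_single_exponential_flags_unidentifiable_theta2(self):
        t = np.arange(0, 600.0, 0.1)
        stress = 1.5 + 0.8 * np.exp(-t / 3.0)
        fit = fit_relaxation(StressStrainSeries(t, np.full(t.size, 0.08), stress))
        assert fit.A2 < 1e-3
        assert "theta2_unidentifiable" in fit.flags

    @given(scale=st.floats(0.1, 50.0))
    @HSETTINGS
    def test_scaling_equivariance(self, scale):
        t = np.arange(0, 601.0, 0.5)
        stress = 1.7 + 0.9 * np.exp(-t / 2.5) + 0.5 * np.exp(-t / 130.0)
        base = fit_relaxation(StressStrainSeries(t, np.full(t.size, 0.08), stress))
        scaled = fit_relaxation(
            StressStrainSeries(t, np.full(t.size, 0.08), scale * stress)
        )
        assert scaled.sigma_eq == pytest.approx(scale * base.sigma_eq, rel=1e-6)
        assert scaled.A1 == pytest.approx(scale * base.A1, rel=1e-4)
        assert scaled.theta1 == pytest.approx(base.theta1, rel=1e-4)
        assert scaled.theta2 == pytest.approx(base.theta2, rel=1e-4)
        assert scaled.ratio_pe == pytest.approx(base.ratio_pe, rel=1e-6)

    def test_ratio_pe_at_least_one_iff_amplitudes(self, damaged_analysis_clean):
        fit = damaged_analysis_clean["pre"]["relaxation"]
        assert fit.ratio_pe >= 1.0
        assert fit.ratio_pe > 1.0  # A1 + A2 > 0 here


def _sinusoid_series(f, gamma_deg, n_cycles=8, rate=100.0, noise=0.0, seed=0,
                     t0=0.0, stress_offset=1.7):
    t = t0 + np.arange(int(n_cycles / f * rate)) / rate
    om = 2 * math.pi * f
    strain = 0.08 + 0.005 * np.sin(om * (t - t0))
    stress = stress_offset + 0.35 * np.sin(om * (t - t0) - math.radians(gamma_deg))
    if noise:
        stress = stress + np.random.default_rng(seed).normal(0, noise, t.size)
    return StressStrainSeries(t, strain, stress)


class TestSinusoidPhase:
    def test_reference_phase_exact(self):
        fit = fit_sinusoid_phase(_sinusoid_series(0.1, 4.13), 0.1)
        assert fit.gamma_deg == pytest.approx(4.13, abs=1e-6)

    def test_elastic_limit_zero_phase(self):
        t = np.arange(0, 60, 0.01)
        strain = 0.08 + 0.005 * np.sin(2 * math.pi * 0.5 * t)
        fit = fit_sinusoid_phase(
            StressStrainSeries(t, strain, 40.0 * strain), 0.5
        )
        assert fit.gamma_deg == pytest.approx(0.0, abs=1e-9)

    def test_invariant_to_time_origin_and_offset(self):
        a = fit_sinusoid_phase(_sinusoid_series(1.0, 3.08), 1.0)
        b = fit_sinusoid_phase(
            _sinusoid_series(1.0, 3.08, t0=123.4, stress_offset=9.9), 1.0
        )
        assert a.gamma_deg == pytest.approx(b.gamma_deg, abs=1e-9)

    def test_too_few_cycles_rejected(self):
        with pytest.raises(ValidationError, match="cycles"):
            fit_sinusoid_phase(_sinusoid_series(0.1, 4.0, n_cycles=3), 0.1)

    def test_noisy_recovery_within_point2_degrees(self):
        # noise at 5% of the stress amplitude, 10 cycles
        errs = [
            fit_sinusoid_phase(
                _sinusoid_series(2.0, 2.95, n_cycles=10, noise=0.05 * 0.35, seed=s),
                2.0,
            ).gamma_deg - 2.95
            for s in range(40)
        ]
        assert np.median(np.abs(errs)) < 0.2


class TestYieldDetection:
    @staticmethod
    def _bilinear(e_lin=70.0, kink=0.12, post_frac=0.5):
        eps = np.linspace(0.0, 0.16, 400)
        stress = np.where(
            eps <= kink, e_lin * eps, e_lin * kink + post_frac * e_lin * (eps - kink)
        )
        return StressStrainSeries(np.arange(400.0), eps, stress), e_lin

    def test_bilinear_kink_recovered_exactly(self):
        series, e_lin = self._bilinear(kink=0.12)
        res = detect_yield(series, e_lin)
        assert not res.no_yield
        assert res.yield_strain == pytest.approx(0.12, abs=1e-9)
        assert res.yield_stress == pytest.approx(70.0 * 0.12, rel=1e-9)

    def test_perfectly_linear_no_yield(self):
        eps = np.linspace(0.0, 0.16, 400)
        series = StressStrainSeries(np.arange(400.0), eps, 70.0 * eps)
        res = detect_yield(series, 70.0)
        assert res.no_yield and math.isnan(res.yield_strain)

    def test_generator_truth_recovered(self, damaged_trace_clean,
                                       damaged_analysis_clean):
        _, truth = damaged_trace_clean
        res = damaged_analysis_clean["yield"]
        assert res.yield_strain == pytest.approx(0.12, rel=1e-3)
        assert res.yield_stress == pytest.approx(truth.yield_stress_MPa, rel=1e-3)


class TestDamageParameters:
    @staticmethod
    def _fit(sigma_eq, a1, a2):
        return RelaxationFit(
            sigma_eq=sigma_eq, A1=a1, theta1=2.5, A2=a2, theta2=130.0,
            ratio_pe=(sigma_eq + a1 + a2) / sigma_eq, rmse=0.0,
        )

    def test_peak_reduction_arithmetic(self):
        pre = self._fit(3.8, 0.8, 0.4)   # peak 5.0
        post = self._fit(0.7, 0.15, 0.05)  # peak 0.9
        d = damage_parameters(pre, post, 20.0, 20.0)
        assert d.D_sigma == pytest.approx(1 - 0.9 / 5.0)  # 0.82

    def test_identity_gives_zeros(self):
        fit = self._fit(2.0, 0.5, 0.3)
        d = damage_parameters(fit, fit, 20.0, 20.0)
        assert d.D_sigma == 0.0 and d.D_epsilon == 0.0 and d.lambda_epsilon == 0.0
        assert not d.flags

    def test_residual_strain_from_lengths(self):
        fit = self._fit(2.0, 0.5, 0.3)
        d = damage_parameters(fit, fit, 20.0, 20.8)
        assert d.lambda_epsilon == pytest.approx(0.04)

    def test_generator_truth_recovered(self, damaged_trace_clean,
                                       damaged_analysis_clean):
        _, truth = damaged_trace_clean
        d = damaged_analysis_clean["damage"]
        assert d.D_sigma == pytest.approx(truth.damage_fraction, rel=1e-3)
        assert d.D_epsilon == pytest.approx(truth.damage_fraction, rel=1e-3)
        assert d.lambda_epsilon == pytest.approx(truth.residual_strain, rel=1e-2)
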