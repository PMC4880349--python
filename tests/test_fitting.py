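"""Harmonic regression, degree of polarization, contrast and gating."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import curve_fit

from polstripe.fitting import (
    SinusoidFit,
    critical_r,
    degree_of_polarization,
    fit_sinusoid,
    fit_sinusoid_stack,
    michelson,
    phase_difference,
    significance_gate,
    wrap_phase_difference,
)
from polstripe.scene import class_luminance

from .conftest import PROTOCOL


def sinusoid(angles, b, d, phase):
    return class_luminance(angles, b, d, phase)


class TestFitSinusoid:
    def test_exact_recovery_of_known_sinusoid(self):
        lum = sinusoid(PROTOCOL, b=100.0, d=0.3, phase=10.0)
        fit = fit_sinusoid(PROTOCOL, lum)
        assert fit.amplitude_a == pytest.approx(30.0, abs=1e-10)
        assert fit.baseline_b == pytest.approx(100.0, abs=1e-10)
        assert fit.phase_deg == pytest.approx(10.0, abs=1e-10)
        assert fit.fit_r == pytest.approx(1.0, abs=1e-12)
        assert fit.degree_d == pytest.approx(0.3, abs=1e-12)

    def test_constant_series_gives_zero_amplitude(self):
        fit = fit_sinusoid(PROTOCOL, np.full(7, 50.0))
        assert fit.amplitude_a == pytest.approx(0.0, abs=1e-10)
        assert fit.baseline_b == pytest.approx(50.0)
        assert fit.degree_d == pytest.approx(0.0, abs=1e-12)

    def test_horizontal_polarization_phase_convention(self):
        """Luminance peaking at filter ±90° means horizontally polarized
        light and must fit with phase −45° under the field convention."""
        lum = 100.0 - 30.0 * np.cos(2 * np.radians(PROTOCOL))
        fit = fit_sinusoid(PROTOCOL, lum)
        assert fit.phase_deg == pytest.approx(-45.0, abs=1e-9)
        # and the orthogonal, vertical case lands at +45°
        fit_v = fit_sinusoid(PROTOCOL, 100.0 + 30.0 * np.cos(2 * np.radians(PROTOCOL)))
        assert fit_v.phase_deg == pytest.approx(45.0, abs=1e-9)

    def test_phase_reported_on_half_open_domain(self):
        for true_phase in (-90.0, -45.0, 0.0, 33.3, 89.0):
            fit = fit_sinusoid(PROTOCOL, sinusoid(PROTOCOL, 80.0, 0.4, true_phase))
            assert -90.0 <= fit.phase_deg < 90.0
            assert wrap_phase_difference(fit.phase_deg, true_phase) == pytest.approx(0.0, abs=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="4 samples"):
            fit_sinusoid(np.array([-90.0, 0.0, 90.0]), np.array([1.0, 2.0, 1.0]))

    def test_rank_deficient_angles_rejected(self):
        # ±90° are the same filter position (180° period): only 2 distinct angles
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_sinusoid(np.array([-90.0, -90.0, 0.0, 90.0]), np.array([1.0, 1.0, 2.0, 1.0]))

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        b=st.floats(10.0, 1000.0),
        d=st.floats(0.01, 0.95),
        phase=st.floats(-90.0, 89.9),
    )
    def test_matches_nonlinear_least_squares(self, b, d, phase):
        """Closed-form harmonic regression equals an iterative multi-start
        nonlinear fit of the same model at the optimum."""
        rng = np.random.default_rng(int(b * 100 + d * 1000) % 2**31)
        lum = sinusoid(PROTOCOL, b, d, phase) + rng.normal(0, 0.02 * b, 7)
        fit = fit_sinusoid(PROTOCOL, lum)

        def model(theta, a, ph, base):
            return a * np.sin(2 * np.radians(theta + ph)) + base

        best = None
        for ph0 in (-60.0, -20.0, 20.0, 60.0):
            try:
                popt, _ = curve_fit(model, PROTOCOL, lum, p0=[b * d, ph0, b], maxfev=20000)
            except RuntimeError:
                continue
            rss = float(np.sum((model(PROTOCOL, *popt) - lum) ** 2))
            if best is None or rss < best[0]:
                best = (rss, popt)
        assert best is not None
        rss_harm = float(np.sum((fit.predict(PROTOCOL) - lum) ** 2))
        assert rss_harm <= best[0] + 1e-8
        a_nl, ph_nl, b_nl = best[1]
        assert fit.amplitude_a == pytest.approx(abs(a_nl), abs=1e-6)
        assert fit.baseline_b == pytest.approx(b_nl, abs=1e-6)

    def test_stack_fit_matches_scalar_fit(self):
        rng = np.random.default_rng(3)
        L = np.column_stack([sinusoid(PROTOCOL, 100, 0.2, p) + rng.normal(0, 2, 7) for p in (-60, 0, 45)])
        out = fit_sinusoid_stack(PROTOCOL, L)
        for j in range(3):
            f = fit_sinusoid(PROTOCOL, L[:, j])
            assert out["a"][j] == pytest.approx(f.amplitude_a, abs=1e-10)
            assert out["phase_deg"][j] == pytest.approx(f.phase_deg, abs=1e-10)
            assert out["degree_d"][j] == pytest.approx(f.degree_d, abs=1e-12)
            assert out["fit_r"][j] == pytest.approx(f.fit_r, abs=1e-12)


class TestDegreeOfPolarization:
    def test_fully_polarized_when_fitted_minimum_is_zero(self):
        fit = fit_sinusoid(PROTOCOL, sinusoid(PROTOCOL, 100.0, 1.0, -45.0))
        assert fit.degree_d == pytest.approx(1.0, abs=1e-12)

    def test_unpolarized_when_constant(self):
        fit = fit_sinusoid(PROTOCOL, np.full(7, 123.0))
        assert fit.degree_d == pytest.approx(0.0, abs=1e-12)

    def test_direct_arithmetic(self):
        # a=30, b=100 → Lmax=130, Lmin=70 → d = 60/200
        fit = SinusoidFit(amplitude_a=30, baseline_b=100, phase_deg=0, fit_r=1, n_points=7, degree_d=0)
        assert degree_of_polarization(fit) == pytest.approx(0.300)

    def test_negative_implied_luminance_clips_with_warning(self):
        fit = SinusoidFit(amplitude_a=120, baseline_b=100, phase_deg=0, fit_r=1, n_points=7, degree_d=0)
        with pytest.warns(UserWarning, match="negative luminance"):
            assert degree_of_polarization(fit) == 1.0
        assert fit.clipped

    def test_scale_invariance(self):
        """Degree is an exposure-independent luminance ratio."""
        lum = sinusoid(PROTOCOL, 100.0, 0.25, 30.0)
        d1 = fit_sinusoid(PROTOCOL, lum).degree_d
        d2 = fit_sinusoid(PROTOCOL, 7.3 * lum).degree_d
        assert d1 == pytest.approx(d2, abs=1e-12)


class TestCriticalR:
    def test_published_gate_constant(self):
        """The alpha=0.05, df=6 critical correlation rounds to 0.71."""
        assert critical_r(0.05, 6) == pytest.approx(0.707, abs=5e-4)

    def test_monotone_decreasing_in_df(self):
        vals = [critical_r(0.05, df) for df in (1, 2, 6, 20, 100, 1000)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert vals[0] > critical_r(0.05, 6)
        assert vals[-1] < 0.1

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            critical_r(0.0, 6)
        with pytest.raises(ValueError):
            critical_r(0.05, 0)


def _fit_with(r, n=7):
    return SinusoidFit(amplitude_a=1, baseline_b=10, phase_deg=0, fit_r=r, n_points=n, degree_d=0.1)


class TestSignificanceGate:
    def test_both_above_passes(self):
        assert significance_gate(_fit_with(0.9), _fit_with(0.8)) is True

    def test_one_below_fails(self):
        assert significance_gate(_fit_with(0.9), _fit_with(0.5)) is False

    def test_exactly_at_threshold_fails(self):
        rc = critical_r(0.05, 6)
        assert significance_gate(_fit_with(rc), _fit_with(0.99)) is False

    def test_gate_null_pass_rate_matches_beta_distribution(self):
        """Calibration of the published criterion under pure noise.

        fit_r is the correlation between a 3-parameter fit and its own
        data, so under the null its square follows Beta(p/2, (n−1−p)/2)
        with p = 2 harmonic regressors and n = 7, i.e. Beta(1, 2) — the
        exact closed-form null, an independent oracle for the Monte-
        Carlo pass rate. Consequence worth knowing: a single class
        passes r > 0.707 for ≈25% of pure-noise series (the printed
        df = 6 treats fit_r as a bivariate correlation, which it is
        not), and the both-classes gate passes ≈ 6%, so the gate is a
        fit-quality filter rather than an alpha-level test."""
        from scipy.stats import beta

        rng = np.random.default_rng(42)
        n_rep = 4000
        L = 100.0 + rng.normal(0, 2.0, size=(7, n_rep))
        r = fit_sinusoid_stack(PROTOCOL, L)["fit_r"]
        rc = critical_r(0.05, 6)
        frac = float(np.mean(r > rc))
        expected = float(beta.sf(rc**2, 1.0, 2.0))
        assert expected == pytest.approx((1 - rc**2) ** 2, abs=1e-12)
        assert frac == pytest.approx(expected, abs=3 * np.sqrt(expected * (1 - expected) / n_rep))
        # both independent classes must pass, squaring the null rate
        r2 = fit_sinusoid_stack(PROTOCOL, 100.0 + rng.normal(0, 2.0, size=(7, n_rep)))["fit_r"]
        both = float(np.mean((r > rc) & (r2 > rc)))
        assert both == pytest.approx(expected**2, abs=0.02)


class TestPhaseDifference:
    def test_equal_phases(self):
        b, w = _fit_with(0.9), _fit_with(0.9)
        b.phase_deg, w.phase_deg = -45.0, -45.0
        significance_gate(b, w)
        assert phase_difference(b, w) == pytest.approx(0.0)

    def test_wraparound_on_180_period(self):
        # brute-force oracle: min over k of |pb − pw + 180k|
        pb, pw = 80.0, -80.0
        oracle = min(abs(pb - pw + 180 * k) for k in (-2, -1, 0, 1, 2))
        assert abs(wrap_phase_difference(pb, pw)) == pytest.approx(oracle)
        assert oracle == pytest.approx(20.0)

    def test_antipodal_is_max_magnitude(self):
        assert wrap_phase_difference(0.0, 90.0) == pytest.approx(-90.0)

    def test_ungated_fits_rejected(self):
        b, w = _fit_with(0.9), _fit_with(0.2)
        significance_gate(b, w)
        with pytest.raises(ValueError, match="significance gate"):
            phase_difference(b, w)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(pb=st.floats(-90, 89.9), pw=st.floats(-90, 89.9))
    def test_wrap_matches_bruteforce(self, pb, pw):
        oracle = min((abs(pb - pw + 180 * k) for k in range(-3, 4)))
        assert abs(wrap_phase_difference(pb, pw)) == pytest.approx(oracle, abs=1e-9)


class TestMichelson:
    def test_basic_values(self):
        assert michelson(150.0, 50.0) == pytest.approx(0.5)
        assert michelson(80.0, 80.0) == 0.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            michelson(0.0, 0.0)


class TestParameterRecovery:
    def test_recovery_accuracy_and_phase_degradation(self):
        """At 2% noise, the degree is recovered within ±0.02 and the phase
        within ±5° (median absolute error) for d ≥ 0.1; the phase error
        inflates as d → 0, which is the rationale for gating phases."""
        rng = np.random.default_rng(123)
        b, n_rep = 100.0, 200
        med_phase_err = {}
        for d in (0.05, 0.1, 0.2, 0.4):
            for phase in (-90.0, -45.0, 0.0, 45.0):
                clean = sinusoid(PROTOCOL, b, d, phase)
                L = clean[:, None] + rng.normal(0, 0.02 * b, size=(7, n_rep))
                out = fit_sinusoid_stack(PROTOCOL, L)
                d_err = np.median(np.abs(out["degree_d"] - d))
                p_err = np.median(np.abs([wrap_phase_difference(p, phase) for p in out["phase_deg"]]))
                med_phase_err.setdefault(d, []).append(p_err)
                if d >= 0.1:
                    assert d_err <= 0.02, f"d={d} phase={phase}: degree error {d_err}"
                    assert p_err <= 5.0, f"d={d} phase={phase}: phase error {p_err}"
        assert np.mean(med_phase_err[0.05]) > np.mean(med_phase_err[0.4])
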