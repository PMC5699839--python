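"""Unit tests of segmentation, exponential fitting and parameter extraction."""

import math

import numpy as np
import pytest

from capdec.circuit import (
    CircuitParams,
    CurrentTrace,
    StimulusProtocol,
    add_thermal_noise,
    fusion_tau2,
    simulate_fusion_current,
    simulate_square_wave,
    simulate_step,
    time_constant,
)
from capdec.fitting import (
    FitResult3,
    analyze_square_record,
    charge_integral,
    circuit_from_fit,
    fit_five_element,
    fit_three_element,
    optimal_period,
    per_period_means,
    segment_half_periods,
    standard_procedure_fit,
    thermal_limit,
)


def _orbit_record(params, v_stim=0.08, f_samp=1e5, n_periods=3, halfs_per_tau=6.0):
    tau = time_constant(params)
    n_half = max(8, round(halfs_per_tau * tau * f_samp))
    warm = 6
    prot = StimulusProtocol(
        v_stim=v_stim, t_s=2 * n_half / f_samp, f_samp=f_samp,
        n_periods=warm + n_periods,
    )
    x = simulate_square_wave(params, prot)
    n = n_periods * 2 * n_half
    return CurrentTrace(x.samples[-n:], x.dt), prot.with_periods(n_periods)


class TestSegmentation:
    def test_folded_segments_identical_in_steady_state(self):
        p = CircuitParams(50e-12, 200e6, 5e6)
        tr, prot = _orbit_record(p)
        segs = segment_half_periods(tr, prot)
        ref = segs[0].samples
        for s in segs[1:]:
            assert np.allclose(s.samples, ref, rtol=1e-9)

    def test_first_half_period_dropped(self):
        p = CircuitParams(50e-12, 200e6, 5e6)
        tr, prot = _orbit_record(p, n_periods=2)
        segs = segment_half_periods(tr, prot)
        assert [s.index for s in segs] == [1, 2, 3]

    def test_too_few_half_periods_rejected(self):
        p = CircuitParams(50e-12, 200e6, 5e6)
        tr, prot = _orbit_record(p, n_periods=2)
        short = CurrentTrace(tr.samples[: prot.samples_per_half], tr.dt)
        with pytest.raises(Exception):
            segment_half_periods(short, prot)


class TestThreeElementFit:
    def test_recovers_generator_parameters(self):
        """A noiseless single-step transient is recovered far inside 1e-6."""
        p = CircuitParams(50e-12, 200e6, 5e6)
        tau = time_constant(p)
        v = 0.08
        tr = simulate_step(p, v, 12 * tau, 1e-5)
        fit = fit_three_element(tr)
        assert fit.converged
        i_s = v / (p.r_m + p.r_a)
        i_p = v / p.r_a - i_s
        assert fit.i_s == pytest.approx(i_s, rel=1e-9)
        assert fit.i_p == pytest.approx(i_p, rel=1e-9)
        assert fit.tau == pytest.approx(tau, rel=1e-9)

    def test_pure_resistor_flagged_not_raised(self):
        tr = CurrentTrace(np.full(64, 2e-9), dt=1e-5)
        fit = fit_three_element(tr)
        assert not fit.converged
        assert math.isnan(fit.tau)

    def test_blanking_excludes_head_samples(self):
        p = CircuitParams(50e-12, 200e6, 5e6)
        tau = time_constant(p)
        tr = simulate_step(p, 0.08, 12 * tau, 1e-5)
        spoiled = tr.samples.copy()
        spoiled[:6] = 1.0  # corrupt the first 60 us
        fit = fit_three_element(CurrentTrace(spoiled, tr.dt), blank_head=60e-6)
        assert fit.converged
        assert fit.tau == pytest.approx(tau, rel=1e-9)

    def test_noise_robustness(self):
        p = CircuitParams(50e-12, 200e6, 5e6)
        tau = time_constant(p)
        tr = simulate_step(p, 0.08, 12 * tau, 1e-5)
        noisy = add_thermal_noise(tr, p.r_a, seed=3)
        fit = fit_three_element(noisy)
        assert fit.converged
        assert fit.tau == pytest.approx(tau, rel=0.05)


class TestCircuitFromFit:
    def test_closed_form_round_trip(self):
        """Theoretical (I_P, I_S, tau) values invert exactly to the circuit."""
        p = CircuitParams(140e-12, 500e6, 4e6)
        v = 0.08
        tau = time_constant(p)
        i_s = v / (p.r_m + p.r_a)
        i_p = v / p.r_a - i_s
        est = circuit_from_fit(FitResult3(i_p=i_p, i_s=i_s, tau=tau, sse=0.0), v)
        assert est.r_a == pytest.approx(p.r_a, rel=1e-12)
        assert est.r_m == pytest.approx(p.r_m, rel=1e-12)
        assert est.c_m == pytest.approx(p.c_m, rel=1e-12)

    def test_high_membrane_resistance_limit(self):
        """R_M -> infinity: R_A = V/I_P and C_M = tau / R_A."""
        v, r_a, c_m = 0.08, 5e6, 50e-12
        r_m = 1e13
        tau = c_m * r_m * r_a / (r_m + r_a)
        i_s = v / (r_m + r_a)
        i_p = v / r_a - i_s
        est = circuit_from_fit(FitResult3(i_p=i_p, i_s=i_s, tau=tau, sse=0.0), v)
        assert est.r_a == pytest.approx(v / (i_p + i_s), rel=1e-12)
        assert est.c_m == pytest.approx(tau / est.r_a, rel=1e-5)

    def test_nonphysical_fit_flagged(self):
        est = circuit_from_fit(
            FitResult3(i_p=1e-9, i_s=-1e-10, tau=1e-4, sse=0.0), 0.08
        )
        assert not est.physical
        assert math.isnan(est.r_m)


class TestChargeIntegral:
    def test_flat_segment_is_zero(self):
        tr = CurrentTrace(np.full(32, 4e-9), dt=1e-5)
        assert charge_integral(tr, 4e-9) == 0.0

    def test_matches_analytic_capacitive_charge(self):
        """Q_C approximates C_M * V * (R_M/(R_M+R_A))^2; the discrete sum
        carries an O(dt/tau) Riemann correction."""
        p = CircuitParams(140e-12, 500e6, 4e6)
        tau = time_constant(p)
        v = 0.08
        dt = 1e-5
        tr = simulate_step(p, v, 20 * tau, dt)
        i_s = v / (p.r_m + p.r_a)
        q = charge_integral(tr, i_s)
        analytic = p.c_m * v * (p.r_m / (p.r_m + p.r_a)) ** 2
        assert q == pytest.approx(analytic, rel=0.02)
        # exact discrete closed form: geometric sum of the sampled transient
        n = len(tr)
        amp = v / p.r_a - i_s
        exact = dt * amp * (1 - math.exp(-n * dt / tau)) / (1 - math.exp(-dt / tau))
        assert q == pytest.approx(exact, rel=1e-10)


class TestFiveElementFit:
    def _fusion_trace(self, i_p2, tau2, sigma=0.0, seed=0):
        base = (0.1e-9, 2e-9, 150e-6)
        tr = simulate_fusion_current(base, i_p2, tau2, 6 * tau2, 1e-5)
        if sigma > 0:
            rng = np.random.default_rng(seed)
            tr = CurrentTrace(tr.samples + rng.normal(0, sigma, len(tr)), tr.dt)
        return base, tr

    def test_recovery_at_high_snr(self):
        """Slow-component amplitude and time constant within 1 % at a
        slow-amplitude-to-noise ratio of 100 per repeat, fitting the averaged
        response as in bandwidth-reduced operation (16 repeats ~ a 50 Hz
        analysis bandwidth at ~1 kHz stimulation)."""
        from capdec.transfer import average_records

        i_p2, tau2 = 0.2e-9, 1e-3
        base = (0.1e-9, 2e-9, 150e-6)
        clean = simulate_fusion_current(base, i_p2, tau2, 8 * tau2, 1e-5)
        rng = np.random.default_rng(4)
        reps = [
            CurrentTrace(
                clean.samples + rng.normal(0, i_p2 / 100, len(clean)), clean.dt
            )
            for _ in range(16)
        ]
        tr = average_records(reps)
        seed_fit = fit_three_element(tr)
        fit = fit_five_element(tr, seed_fit, c_v=100e-15)
        assert fit.converged
        assert fit.i_p2 == pytest.approx(i_p2, rel=0.01)
        assert fit.tau2 == pytest.approx(tau2, rel=0.01)
        assert fit.g_p == pytest.approx(100e-15 / tau2, rel=0.01)

    def test_model_selection_prefers_simple_model_without_fusion(self):
        base, tr = self._fusion_trace(0.0, 1e-3, sigma=2e-12, seed=5)
        seed_fit = fit_three_element(tr)
        fit = fit_five_element(tr, seed_fit, c_v=100e-15)
        assert not fit.preferred

    def test_cv_estimated_from_slow_charge(self):
        i_p2, tau2 = 0.2e-9, 1e-3
        _, tr = self._fusion_trace(i_p2, tau2)
        fit = fit_five_element(tr, fit_three_element(tr), v_stim=0.08)
        assert fit.c_v == pytest.approx(i_p2 * tau2 / 0.08, rel=1e-6)

    def test_pore_conductance_trajectory(self):
        """A rising pore conductance at fixed vesicle capacitance produces a
        monotone G_p trajectory; tau2 = C_v / G_p throughout."""
        c_v = 100e-15
        g_true = np.linspace(0.1e-9, 0.5e-9, 5)
        g_est = []
        for g in g_true:
            tau2 = fusion_tau2(c_v, g)
            _, tr = self._fusion_trace(0.15e-9, tau2)
            fit = fit_five_element(tr, fit_three_element(tr), c_v=c_v)
            g_est.append(fit.g_p)
        assert np.allclose(g_est, g_true, rtol=1e-3)
        assert np.all(np.diff(g_est) > 0)


class TestAnalyzeSquareRecord:
    def test_exact_recovery_from_orbit_record(self):
        """The re-referencing convention makes the parameter extraction exact
        on undistorted records in periodic steady state."""
        p = CircuitParams(140e-12, 500e6, 4e6)
        tr, prot = _orbit_record(p)
        df = analyze_square_record(tr, prot)
        assert np.allclose(df.c_m, p.c_m, rtol=1e-10)
        assert np.allclose(df.r_m, p.r_m, rtol=1e-10)
        assert np.allclose(df.r_a, p.r_a, rtol=1e-10)

    def test_exact_even_at_short_half_periods(self):
        """Unlike tail-level referencing, the fitted-boundary convention has
        no settling bias: even 3-tau half-periods are recovered exactly."""
        p = CircuitParams(140e-12, 500e6, 4e6)
        tr, prot = _orbit_record(p, halfs_per_tau=3.0)
        df = analyze_square_record(tr, prot)
        assert np.allclose(df.c_m, p.c_m, rtol=1e-9)
        assert np.allclose(df.r_m, p.r_m, rtol=1e-9)

    def test_per_period_means_average_half_periods(self):
        p = CircuitParams(50e-12, 200e6, 5e6)
        tr, prot = _orbit_record(p, n_periods=3)
        df = analyze_square_record(tr, prot)
        means = per_period_means(df)
        assert len(means) >= 2
        assert np.allclose(means.c_m, p.c_m, rtol=1e-10)


class TestStandardProcedure:
    def test_consistent_with_direct_fit_on_undistorted_record(self):
        """On a reconstructed (undistorted) record with zero-time 0 the
        standard blank-and-extrapolate path agrees with the direct analysis
        up to the finite-settling amplitude bias ~e^-6."""
        p = CircuitParams(50e-12, 200e6, 5e6)
        tr, prot = _orbit_record(p)
        std, t_z, _ = standard_procedure_fit(
            tr, prot, zero_time_grid=np.array([0.0])
        )
        assert t_z == 0.0
        ref = analyze_square_record(tr, prot)
        assert np.allclose(std.tau, ref.tau, rtol=1e-9)
        assert np.allclose(std.i_s, ref.i_s, rtol=1e-9)
        assert np.allclose(std.c_m, ref.c_m, rtol=0.01)

    def test_requires_half_period_longer_than_blanking(self):
        p = CircuitParams(5e-12, 2e9, 2e6)  # tau ~ 10 us
        tr, prot = _orbit_record(p)
        with pytest.raises(Exception):
            standard_procedure_fit(tr, prot)


class TestClosedForms:
    def test_optimal_period(self):
        assert optimal_period(62e-6) == pytest.approx(0.744e-3, rel=1e-12)
        assert optimal_period(1e-3) == pytest.approx(12e-3, rel=1e-12)

    def test_optimal_period_linear(self):
        taus = np.array([20e-6, 100e-6, 1e-3])
        periods = np.array([optimal_period(t) for t in taus])
        assert np.allclose(periods / taus, 12.0)

    def test_thermal_limit_scalings(self):
        base = thermal_limit(50e-12, 5e6, 0.02, 50.0)
        assert thermal_limit(50e-12, 5e6, 0.04, 50.0) == pytest.approx(base / 2)
        assert thermal_limit(50e-12, 5e6, 0.02, 200.0) == pytest.approx(base * 2)
        assert thermal_limit(50e-12, 20e6, 0.02, 50.0) == pytest.approx(base * 2)

    def test_thermal_limit_closed_form_over_cell_sizes(self):
        """sigma_C_M = C_M sqrt(4kTBR_A)/V over the hardware-model range."""
        from scipy import constants

        for c_m_pf in (4.7, 10, 22, 33, 68, 101, 160):
            got = thermal_limit(c_m_pf * 1e-12, 4.7e6, 0.02, 50.0, t_abs=296.15)
            expected = (
                c_m_pf * 1e-12
                * math.sqrt(4 * constants.k * 296.15 * 50.0 * 4.7e6)
                / 0.02
            )
            assert got == pytest.approx(expected, rel=1e-12)
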