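"""Tests of pulse-volume formulas, stiffness regression and the grid search."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oscillobp import (
    ATM_MMHG,
    ArteryModel,
    CuffModel,
    Envelope,
    PressureWaveform,
    artery_volume,
    estimate_pressures,
    extract_envelope,
    fit_stiffness,
    predicted_envelope,
    pulse_volume,
    simulate_run,
    sum_of_squares,
)

ARTERY = ArteryModel(a=0.11, b=0.03, Va0=0.3)


def known_stiffness(a, b):
    """StiffnessFit carrying externally known exponents (no regression)."""
    from oscillobp import StiffnessFit

    return StiffnessFit(
        a_hat=a,
        b_hat=b,
        slope_head=-a,
        slope_tail=b,
        log_k1=0.0,
        log_k3=0.0,
        n_head=0,
        n_tail=0,
        head_indices=np.array([], dtype=int),
        tail_indices=np.array([], dtype=int),
    )


def synth_envelope(pressures, sbp, dbp, a, b, scale=1.0):
    """Envelope generated exactly from the model's predicted amplitudes."""
    pressures = np.asarray(pressures, float)
    amps = scale * predicted_envelope(pressures, sbp, dbp, a, b)
    return Envelope(pressures=pressures, amplitudes=amps, beat_indices=np.arange(len(pressures)))


class TestPulseVolume:
    def test_domain_formulas_equal_volume_differences(self):
        """The three closed-form domain expressions are algebraically identical
        to differences of the volume law (scan across all domains)."""
        Pt = np.linspace(-100.0, 100.0, 2001)
        for PP in (10.0, 40.0, 80.0):
            direct = pulse_volume(Pt, PP, ARTERY)
            ref = artery_volume(Pt + PP, ARTERY) - artery_volume(Pt, ARTERY)
            assert np.max(np.abs(direct - ref)) < 1e-12

    @given(Pt=st.floats(-150.0, 150.0), PP=st.floats(1.0, 100.0))
    @settings(deadline=None, max_examples=200)
    def test_identity_property(self, Pt, PP):
        ref = artery_volume(Pt + PP, ARTERY) - artery_volume(Pt, ARTERY)
        assert pulse_volume(Pt, PP, ARTERY) == pytest.approx(ref, abs=1e-12)

    def test_continuous_across_domain_boundaries(self):
        PP = 40.0
        for edge in (-PP, 0.0):
            lo = pulse_volume(edge - 1e-9, PP, ARTERY)
            hi = pulse_volume(edge + 1e-9, PP, ARTERY)
            assert abs(lo - hi) < 1e-9

    def test_vanishes_as_pulse_pressure_shrinks(self):
        assert pulse_volume(-20.0, 1e-9, ARTERY) == pytest.approx(0.0, abs=1e-9)

    def test_rejects_non_positive_pulse_pressure(self):
        with pytest.raises(ValueError):
            pulse_volume(-20.0, 0.0, ARTERY)

    def test_swing_maximal_in_straddling_domain(self):
        """The nadir giving the largest swing lies strictly inside (-PP, 0)."""
        Pt = np.linspace(-120.0, 60.0, 18001)
        dv = pulse_volume(Pt, 40.0, ARTERY)
        best = Pt[np.argmax(dv)]
        assert -40.0 < best < 0.0

    def test_swing_slope_extremal_at_systolic_and_diastolic_points(self):
        """d(swing)/d(nadir) is maximal where cuff pressure equals SBP
        (nadir + PP = 0) and minimal where it equals DBP (nadir = 0)."""
        PP = 40.0
        Pt = np.linspace(-100.0, 60.0, 16001)
        dv = pulse_volume(Pt, PP, ARTERY)
        slope = np.gradient(dv, Pt)
        assert Pt[np.argmax(slope)] == pytest.approx(-PP, abs=0.05)
        assert Pt[np.argmin(slope)] == pytest.approx(0.0, abs=0.05)


class TestFitStiffness:
    def log_linear_envelope(self, a=0.11, b=0.03, peak_pressure=90.0, peak_amp=2.5):
        """Tent in log space: exact exponentials on both flanks, peak near MAP."""
        P = np.arange(150.0, 30.0, -2.25)
        k1 = peak_amp * np.exp(a * peak_pressure)
        k3 = peak_amp * np.exp(-b * peak_pressure)
        amps = np.minimum(k1 * np.exp(-a * P), k3 * np.exp(b * P))
        return Envelope(pressures=P, amplitudes=amps, beat_indices=np.arange(P.size))

    def test_exact_on_log_linear_data(self):
        env = self.log_linear_envelope()
        fit = fit_stiffness(env)
        assert fit.a_hat == pytest.approx(0.11, abs=1e-10)
        assert fit.b_hat == pytest.approx(0.03, abs=1e-10)
        # intercepts are the lumped constants: ln k1 = ln(peak) + a*P_peak
        assert fit.log_k1 == pytest.approx(np.log(2.5) + 0.11 * 90.0, abs=1e-8)
        assert fit.log_k3 == pytest.approx(np.log(2.5) - 0.03 * 90.0, abs=1e-8)

    def test_inflection_method_close_to_height_rule(self):
        env = self.log_linear_envelope()
        fit = fit_stiffness(env, method="inflection")
        assert fit.a_hat == pytest.approx(0.11, rel=0.1)
        assert fit.b_hat == pytest.approx(0.03, rel=0.15)

    def test_head_range_error_names_the_range(self):
        # the very first beat already exceeds a third of the peak height,
        # so the rising-side regression has a single point
        P = np.arange(150.0, 30.0, -2.25)
        rise = np.linspace(1.0, 2.5, 27)
        fall = 2.5 * np.exp(0.03 * (P[27:] - P[26]))
        amps = np.concatenate([rise, fall])
        env = Envelope(pressures=P, amplitudes=amps, beat_indices=np.arange(P.size))
        with pytest.raises(ValueError, match="head"):
            fit_stiffness(env)

    def test_non_positive_amplitudes_dropped(self):
        env = self.log_linear_envelope()
        amps = env.amplitudes.copy()
        amps[5] = 0.0
        env2 = Envelope(pressures=env.pressures, amplitudes=amps, beat_indices=env.beat_indices)
        fit = fit_stiffness(env2)
        assert fit.n_dropped == 1
        assert fit.a_hat == pytest.approx(0.11, abs=1e-6)

    def test_normal_simulation_recovers_constants(self, normal_envelope):
        """Noise-free standard run: regression estimates land near the true
        exponents a = 0.110, b = 0.030."""
        fit = fit_stiffness(normal_envelope)
        assert fit.a_hat == pytest.approx(0.11, abs=0.01)
        assert fit.b_hat == pytest.approx(0.03, abs=0.005)


class TestPredictedEnvelope:
    def test_identity_with_pulse_volume(self):
        P = np.linspace(30.0, 150.0, 500)
        cuff = CuffModel(V0=300.0)
        y = predicted_envelope(P, 120.0, 80.0, 0.11, 0.03, cuff)
        artery = ArteryModel(a=0.11, b=0.03, Va0=1.0)
        ref = pulse_volume(80.0 - P, 40.0, artery) * (P + ATM_MMHG) / 300.0
        assert np.allclose(y, ref, rtol=0, atol=1e-14)

    def test_vanishes_as_candidate_pair_collapses(self):
        P = np.linspace(30.0, 150.0, 100)
        y = predicted_envelope(P, 100.0 + 1e-8, 100.0, 0.11, 0.03)
        assert np.max(y) < 1e-6

    def test_peak_strictly_between_dbp_and_sbp(self):
        P = np.arange(30.0, 150.0, 0.1)
        y = predicted_envelope(P, 120.0, 80.0, 0.11, 0.03)
        assert 80.0 < P[np.argmax(y)] < 120.0

    def test_rejects_inverted_candidates(self):
        with pytest.raises(ValueError):
            predicted_envelope(100.0, 80.0, 120.0, 0.11, 0.03)


class TestSumOfSquares:
    P_BEATS = np.arange(146.0, 32.0, -2.25)

    def test_zero_at_generating_pressures(self):
        env = synth_envelope(self.P_BEATS, 120.0, 80.0, 0.11, 0.03)
        assert sum_of_squares(env, 120.0, 80.0, 0.11, 0.03) == pytest.approx(0.0, abs=1e-24)

    def test_invariant_to_amplitude_rescaling(self):
        a = synth_envelope(self.P_BEATS, 120.0, 80.0, 0.11, 0.03, scale=1.0)
        b = synth_envelope(self.P_BEATS, 120.0, 80.0, 0.11, 0.03, scale=137.5)
        ss_a = sum_of_squares(a, 110.0, 70.0, 0.11, 0.03)
        ss_b = sum_of_squares(b, 110.0, 70.0, 0.11, 0.03)
        assert ss_a == pytest.approx(ss_b, rel=1e-12)

    def test_wrong_candidates_fit_worse(self, normal_envelope):
        """Shifting the candidate pair 10 mmHg off the truth inflates the misfit."""
        fit = fit_stiffness(normal_envelope)
        ss_true = sum_of_squares(normal_envelope, 120.0, 80.0, fit.a_hat, fit.b_hat)
        ss_low = sum_of_squares(normal_envelope, 110.0, 70.0, fit.a_hat, fit.b_hat)
        ss_high = sum_of_squares(normal_envelope, 130.0, 90.0, fit.a_hat, fit.b_hat)
        assert ss_low > ss_true
        assert ss_high > ss_true

    def test_degenerate_prediction_returns_inf_sentinel(self):
        env = synth_envelope(self.P_BEATS, 120.0, 80.0, 0.11, 0.03)
        # candidates so far above the cuff range that both volume terms
        # saturate and the predicted envelope underflows to identically zero
        ss = sum_of_squares(env, 5.0e4, 4.0e4, 0.11, 0.03)
        assert ss == float("inf")


class TestEstimatePressures:
    def test_exact_recovery_of_synthesized_envelope(self):
        """With the generating exponents given, an envelope synthesized at grid
        candidates is recovered exactly (SS = 0 at the truth)."""
        P = np.arange(146.0, 32.0, -2.25)
        env = synth_envelope(P, 117.0, 83.0, 0.11, 0.03)
        res = estimate_pressures(env, stiffness=known_stiffness(0.11, 0.03))
        assert (res.SBP_hat, res.DBP_hat) == (117.0, 83.0)
        assert res.ss_min == pytest.approx(0.0, abs=1e-20)

    def test_normal_scenario_grid_minimum(self, normal_estimate):
        res = normal_estimate
        assert res.SBP_hat == pytest.approx(119.0, abs=1.0)
        assert res.DBP_hat == pytest.approx(80.0, abs=1.0)

    def test_peak_pressure_bracketed(self, normal_estimate, normal_envelope):
        assert res_brackets(normal_estimate, normal_envelope)

    def test_grid_bounds_extend_beyond_support(self, normal_estimate, normal_envelope):
        assert normal_estimate.dbp_grid[0] <= normal_envelope.pressures.min() - 9.0
        assert normal_estimate.sbp_grid[-1] >= normal_envelope.pressures.max() + 9.0

    def test_surface_has_single_minimum_basin(self, normal_estimate):
        """Noise-free misfit surface shows one target-like basin: a unique
        strict local minimum over the feasible grid."""
        ss = normal_estimate.ss_surface
        n_min = 0
        for i in range(ss.shape[0]):
            for j in range(ss.shape[1]):
                if not np.isfinite(ss[i, j]):
                    continue
                neigh = []
                for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    ii, jj = i + di, j + dj
                    if 0 <= ii < ss.shape[0] and 0 <= jj < ss.shape[1]:
                        neigh.append(ss[ii, jj])
                if neigh and ss[i, j] < min(neigh):
                    n_min += 1
        assert n_min == 1

    def test_deterministic_across_runs(self, normal_envelope):
        r1 = estimate_pressures(normal_envelope)
        r2 = estimate_pressures(normal_envelope)
        assert (r1.SBP_hat, r1.DBP_hat, r1.a_hat, r1.b_hat) == (
            r2.SBP_hat,
            r2.DBP_hat,
            r2.a_hat,
            r2.b_hat,
        )
        assert np.array_equal(r1.ss_surface, r2.ss_surface)

    def test_noise_robust_recovery_with_harmonic_amplitudes(self):
        """Seeded measurement noise (sd 0.02 mmHg) moves the recovered
        pressures by at most 3 mmHg when the noise-rejecting amplitude
        estimator is used."""
        artery, cuff, w = ArteryModel(), CuffModel(), PressureWaveform()
        for seed in (1, 2):
            rec = simulate_run(artery, cuff, w, noise_sd=0.02, seed=seed)
            env = extract_envelope(rec, amp_method="harmonic")
            res = estimate_pressures(env, cuff)
            assert abs(res.SBP_hat - 119.0) <= 3.0
            assert abs(res.DBP_hat - 80.0) <= 3.0


def res_brackets(res, env):
    return res.SBP_hat >= env.P_max >= res.DBP_hat
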