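"""Fluorescence pipeline operations and voltage-trace event detection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dfgaba import (
    Calibration,
    FluorescenceRecording,
    SyntheticScenario,
    average_epochs,
    detect_network_burst,
    detect_sle,
    detrend_polynomial,
    dff_event,
    dff_to_voltage,
    estimate_df_gabaa,
    in_vivo_dff,
    moving_average,
    render_recording,
    select_peri_sle_probe,
    subtract_background,
)
from dfgaba.traces import TraceError


class TestSubtractBackground:
    def test_zero_background_is_identity(self):
        roi = np.array([1.0, 2.0, 3.0])
        assert np.allclose(subtract_background(roi, np.zeros(3), 5), roi)

    def test_constant_background_shifts_by_constant(self):
        roi = np.linspace(10, 20, 50)
        out = subtract_background(roi, np.full(50, 4.0), 7)
        assert np.allclose(out, roi - 4.0)

    def test_roi_equal_background_cancels(self):
        rng = np.random.default_rng(0)
        trace = 100 + rng.normal(0, 1, 200)
        out = subtract_background(trace, trace, 1)
        assert np.allclose(out, 0.0)

    def test_length_mismatch(self):
        with pytest.raises(TraceError):
            subtract_background(np.zeros(5), np.zeros(6))


class TestDetrend:
    def test_polynomial_removed_exactly(self):
        x = np.linspace(0, 1, 200)
        trace = 3 - 2 * x + 5 * x**3
        resid = detrend_polynomial(trace, order=3)
        assert np.allclose(resid, 0.0, atol=1e-9)

    def test_pulse_on_ramp_survives_when_excluded(self):
        """A square pulse excluded from an order-1 fit is preserved while
        the underlying ramp is removed."""
        n = 200
        x = np.arange(n, dtype=float)
        ramp = 0.05 * x + 10
        pulse = np.zeros(n)
        pulse[80:120] = 2.0
        exclude = pulse > 0
        resid = detrend_polynomial(ramp + pulse, order=1, exclude_mask=exclude)
        assert np.allclose(resid[~exclude], 0.0, atol=1e-8)
        assert np.allclose(resid[exclude], 2.0, atol=1e-8)

    def test_order_zero_is_mean_subtraction(self):
        trace = np.array([1.0, 2.0, 3.0, 10.0])
        exclude = np.array([False, False, False, True])
        resid = detrend_polynomial(trace, order=0, exclude_mask=exclude)
        assert np.allclose(resid, trace - 2.0)

    def test_trendless_trace_is_untouched(self):
        rng = np.random.default_rng(1)
        trace = 50 + rng.normal(0, 1e-12, 300)
        resid = detrend_polynomial(trace, order=9)
        assert np.allclose(resid + 50, trace, atol=1e-6)

    def test_underdetermined_fit_names_requirement(self):
        with pytest.raises(TraceError, match="underdetermined"):
            detrend_polynomial(np.arange(5.0), order=9)


class TestMovingAverage:
    def test_identity_cases(self):
        trace = np.array([3.0, 3.0, 3.0, 3.0])
        assert np.allclose(moving_average(trace, 7), trace)
        rng = np.random.default_rng(2)
        noisy = rng.normal(size=20)
        assert np.allclose(moving_average(noisy, 1), noisy)

    def test_impulse_response_is_uniform_plateau(self):
        impulse = np.zeros(31)
        impulse[15] = 1.0
        out = moving_average(impulse, 7)
        assert np.allclose(out[12:19], 1.0 / 7.0)
        assert np.allclose(out[:12], 0.0)
        assert np.allclose(out[19:], 0.0)


class TestDffEvent:
    def test_flat_trace(self):
        trace = np.full(20, 7.0)
        base = np.arange(20) < 10
        resp = ~base
        assert dff_event(trace, base, resp, "mean") == 0.0
        assert dff_event(trace, base, resp, "extremum") == 0.0

    def test_mean_mode_ratio(self):
        trace = np.concatenate([np.full(10, 100.0), np.full(10, 101.0)])
        base = np.arange(20) < 10
        assert dff_event(trace, base, ~base, "mean") == pytest.approx(0.01)

    def test_extremum_picks_larger_deviation(self):
        trace = np.concatenate([np.full(10, 100.0), [97.0, 100.0, 100.0]])
        base = np.arange(13) < 10
        assert dff_event(trace, base, ~base, "extremum") == pytest.approx(-0.03)

    def test_zero_baseline_rejected(self):
        trace = np.concatenate([np.zeros(5), np.ones(5)])
        base = np.arange(10) < 5
        with pytest.raises(TraceError, match="baseline"):
            dff_event(trace, base, ~base)


class TestAverageEpochs:
    def test_identical_epochs_average_to_one_epoch(self):
        trace = np.tile(np.array([0.0, 0.0, 5.0, 5.0]), 5)
        slices = [(4 * k + 2, 4 * k + 4) for k in range(5)]
        stim, base = average_epochs(trace, slices)
        assert np.allclose(stim, 5.0)
        assert np.allclose(base, 0.0)

    def test_noise_variance_reduced_n_fold(self):
        rng = np.random.default_rng(3)
        n_epochs, span, reps = 8, 50, 400
        ratios = []
        for _ in range(reps):
            trace = rng.normal(0, 1, n_epochs * 2 * span)
            slices = [(2 * span * k + span, 2 * span * (k + 1)) for k in range(n_epochs)]
            stim, _ = average_epochs(trace, slices)
            ratios.append(stim.var())
        assert np.mean(ratios) == pytest.approx(1.0 / n_epochs, rel=0.1)

    def test_single_epoch_passthrough(self):
        trace = np.arange(10.0)
        stim, base = average_epochs(trace, [(5, 8)])
        assert np.allclose(stim, trace[5:8])
        assert np.allclose(base, trace[2:5])

    def test_unequal_epochs_rejected(self):
        with pytest.raises(TraceError, match="unequal"):
            average_epochs(np.arange(20.0), [(2, 5), (8, 12)])


class TestInVivoDff:
    def test_flat_background_reduces_to_mean_mode(self):
        roi = np.concatenate([np.full(10, 100.0), np.full(10, 102.0)])
        bg = np.full(20, 30.0)
        flank = np.arange(20) < 10
        assert in_vivo_dff(roi, bg, ~flank, flank) == pytest.approx(0.02)

    def test_shared_contamination_cancels_exactly(self):
        flank = np.arange(20) < 10
        artefact = np.concatenate([np.zeros(10), np.full(10, 7.0)])
        roi = np.full(20, 100.0) + artefact
        bg = np.full(20, 25.0) + artefact
        assert in_vivo_dff(roi, bg, ~flank, flank) == pytest.approx(0.0, abs=1e-12)

    def test_signal_plus_artefact_arithmetic(self):
        # ROI: +2% signal plus a +1% (of ROI baseline) shared artefact
        flank = np.arange(20) < 10
        roi = np.concatenate([np.full(10, 100.0), np.full(10, 103.0)])
        bg = np.concatenate([np.full(10, 40.0), np.full(10, 41.0)])
        assert in_vivo_dff(roi, bg, ~flank, flank) == pytest.approx(0.02)


class TestCalibration:
    def test_printed_slope_gives_5_42_mV_per_percent(self):
        cal = Calibration(slope_percent_per_mV=0.1845)
        assert abs(dff_to_voltage(0.01, cal)) == pytest.approx(5.42, abs=0.01)

    def test_sign_and_linearity(self):
        cal = Calibration()
        assert dff_to_voltage(0.0, cal) == 0.0
        assert dff_to_voltage(0.01, cal) < 0  # brighter -> hyperpolarized
        assert dff_to_voltage(-0.01, cal) == pytest.approx(-dff_to_voltage(0.01, cal))


class TestEstimateRoundTrip:
    @pytest.mark.parametrize("true_df", [-15.0, -6.0, 0.0, 9.0, 15.0])
    def test_noiseless_recovery(self, fast_scenario, true_df):
        rec, _ = render_recording(fast_scenario(true_df))
        est = estimate_df_gabaa(rec, mode="in-vitro")
        assert est.df_gabaa_mV == pytest.approx(true_df, abs=0.1)

    def test_zero_gain_recording_estimates_zero(self, fast_scenario):
        sc = fast_scenario(-6.0, calibration=Calibration(slope_percent_per_mV=1e-9))
        rec, _ = render_recording(sc)
        est = estimate_df_gabaa(rec, cal=Calibration(), mode="in-vitro")
        assert est.df_gabaa_mV == pytest.approx(0.0, abs=0.05)

    def test_puff_mode_recovers_extremum(self, fast_scenario):
        sc = fast_scenario(-8.0, n_epochs=1, first_onset_s=3.0,
                           epoch_duration_s=2.0, duration_s=10.0,
                           stimulus_kind="agonist_puff")
        rec, _ = render_recording(sc)
        est = estimate_df_gabaa(rec, mode="puff")
        # the extremum rides the polynomial interpolated across the excluded
        # response gap, which wiggles at the 0.1% level under bleaching
        assert est.df_gabaa_mV == pytest.approx(-8.0, abs=0.6)

    def test_in_vivo_mode_cancels_shared_artefact(self, fast_scenario):
        # no background pedestal in the ROI so F0S is pure indicator signal;
        # the shared artefact appears in both traces and must cancel
        # onset placed off the frame grid: a frame exactly at onset samples
        # zero deflection by construction
        sc = fast_scenario(-5.0, n_epochs=1, first_onset_s=9.98,
                           epoch_duration_s=2.0, duration_s=25.0,
                           bleach_rate_per_s=0.0, background_photons=0.0,
                           artefact_amplitude=2000.0, artefact_window=(9.98, 13.0))
        rec, _ = render_recording(sc)
        est = estimate_df_gabaa(rec, mode="in-vivo")
        assert est.df_gabaa_mV == pytest.approx(-5.0, abs=0.1)

    @given(scale=st.floats(0.2, 5.0))
    @settings(max_examples=10, deadline=None)
    def test_photon_scale_invariance(self, scale):
        """Scaling every count by c > 0 leaves dF/F0 and DF unchanged."""
        sc = SyntheticScenario(true_df_mV=-6.0, tau_on_s=1e-3, tau_off_s=1e-3,
                               shot_noise=False)
        rec, _ = render_recording(sc)
        ref = estimate_df_gabaa(rec, mode="in-vitro").df_gabaa_mV
        scaled = FluorescenceRecording(
            times=rec.times, roi=rec.roi * scale, background=rec.background * scale,
            stimulus_windows=rec.stimulus_windows, frame_rate_hz=rec.frame_rate_hz,
        )
        est = estimate_df_gabaa(scaled, mode="in-vitro").df_gabaa_mV
        assert est == pytest.approx(ref, abs=1e-9)


class TestEventDetection:
    def test_flat_trace_has_no_events(self):
        rng = np.random.default_rng(4)
        v = -65 + rng.normal(0, 0.5, 2000)
        assert detect_sle(v, 50.0) == []
        assert detect_network_burst(v, 50.0) == []

    def test_sle_duration_rule_boundaries(self):
        rate = 50.0
        v = np.full(3000, -65.0)
        v[:500] += np.tile([0.5, -0.5], 250)           # baseline with spread
        sd = v[:500].std()
        v[1000:1200] = -65 + 3 * sd + 5                # 4 s: too short
        assert detect_sle(v, rate, baseline_span=(0.0, 10.0)) == []
        v[1500:2000] = -65 + 3 * sd + 5                # 10 s at 3 SD
        events = detect_sle(v, rate, baseline_span=(0.0, 10.0))
        assert len(events) == 1
        start, end = events[0]
        assert start == pytest.approx(30.0, abs=0.1)
        assert end == pytest.approx(40.0, abs=0.1)

    def test_network_burst_threshold_and_duration(self):
        rate = 100.0
        base = np.full(1000, -65.0)

        def with_plateau(amp, n):
            v = base.copy()
            v[500 : 500 + n] += amp
            return v

        assert detect_network_burst(with_plateau(9.0, 500), rate) == []
        assert detect_network_burst(with_plateau(12.0, 20), rate) == []   # 200 ms
        events = detect_network_burst(with_plateau(12.0, 40), rate)      # 400 ms
        assert len(events) == 1

    def test_short_trace_rejected(self):
        with pytest.raises(TraceError):
            detect_sle(np.zeros(10), 10.0)


class TestPeriSleProbe:
    SLE = [(100.0, 130.0)]

    def test_pre_phase_window_selection(self):
        assert select_peri_sle_probe([(88.0, 90.0)], self.SLE, "pre") == (88.0, 90.0)
        assert select_peri_sle_probe([(78.0, 80.0)], self.SLE, "pre") is None

    def test_post_phase_contamination_rejection(self):
        burst = [(134.0, 137.0)]
        assert (
            select_peri_sle_probe([(135.0, 137.0)], self.SLE, "post",
                                  contaminated_intervals=burst)
            is None
        )
        assert select_peri_sle_probe(
            [(140.0, 142.0)], self.SLE, "post", contaminated_intervals=burst
        ) == (140.0, 142.0)

    def test_during_phase_near_cessation(self):
        assert select_peri_sle_probe([(120.0, 122.0)], self.SLE, "during") == (120.0, 122.0)
        assert select_peri_sle_probe([(105.0, 107.0)], self.SLE, "during") is None
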