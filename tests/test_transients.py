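"""Peak detection, decay fitting, cumulative load and decay-impact algebra."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from striacal import preprocess, synth, transients
from striacal.errors import InputError, ParameterError
from striacal.preprocess import StimulusProtocol
from striacal.rois import DffTrace
from striacal.transients import (
    analyze_trace,
    compute_rms,
    cumulative_load,
    decay_impact,
    detect_peaks,
    fit_decay,
    peak_amplitude_simple,
    pulse_windows,
)

DT = 0.01


def make_trace(values, dt=DT, f0=300.0):
    values = np.asarray(values, dtype=float)
    return DffTrace(values=values, time=np.arange(values.size) * dt, f0_value=f0)


def exp_trace(a, tau, pulse_time=1.5, duration=6.0, dt=DT):
    t = np.arange(0, duration, dt)
    v = np.where(t >= pulse_time, a * np.exp(-(t - pulse_time) / tau), 0.0)
    return DffTrace(values=v, time=t, f0_value=300.0)


class TestComputeRms:
    def test_zero_noise_baseline(self):
        trace = exp_trace(0.5, 1.0)
        assert compute_rms(trace, StimulusProtocol([1.5])) == 0.0

    def test_alternating_samples_closed_form(self):
        c = 0.37
        values = c * (-1.0) ** np.arange(400)
        rms = compute_rms(make_trace(values), StimulusProtocol([2.0]))
        assert rms == pytest.approx(c, rel=1e-9)

    def test_unit_white_noise(self, rng):
        values = rng.normal(0, 1, 400)
        rms = compute_rms(make_trace(values), StimulusProtocol([2.0]))
        # the 0.9-s window holds ~90 samples; SE of the RMS is ~1/sqrt(2n)
        assert abs(rms - 1.0) < 0.25

    def test_window_outside_trace_errors(self):
        with pytest.raises(InputError):
            compute_rms(make_trace(np.zeros(50)), StimulusProtocol([0.5]))


def oracle_detect(trace, protocol, rms, mult=5.0):
    """Independent exhaustive scan of every sample in every pulse window."""
    results = []
    t, v = trace.time, trace.values
    times = list(protocol.pulse_times)
    for k, tk in enumerate(times):
        end = times[k + 1] if k + 1 < len(times) else tk + protocol.post_window
        base_sel = [
            i for i in range(len(t))
            if tk - 0.204 - 1e-12 <= t[i] <= tk - 0.104 + 1e-12
        ]
        baseline = float(np.mean([v[i] for i in base_sel])) if base_sel else 0.0
        best, best_i = -np.inf, None
        for i in range(len(t)):
            if tk + 1e-12 < t[i] <= end + 1e-12 and v[i] > best:
                best, best_i = v[i], i
        if best_i is None:
            results.append((False, 0.0))
            continue
        amp = best - baseline
        results.append((amp >= mult * rms, amp))
    return results


class TestDetectPeaks:
    def test_noiseless_amplitude_recovery(self):
        trace = exp_trace(0.5, 2.0)
        protocol = StimulusProtocol([1.5], post_window=2.0)
        peaks = detect_peaks(trace, protocol, rms=0.001)
        assert len(peaks) == 1
        assert peaks[0].detected
        # the search window opens just after the pulse, so the first sampled
        # frame carries one frame-interval of decay
        assert peaks[0].amplitude == pytest.approx(0.5 * math.exp(-DT / 2.0))

    def test_non_responder_has_zero_peaks(self, train_protocol):
        noise = synth.NoiseParams(seed=21)
        trace = synth.simulate_roi_trace(
            synth.KineticsParams(responder=False), train_protocol, noise
        )
        metrics = analyze_trace(trace, train_protocol)
        assert not metrics.responder
        assert sum(p.detected for p in metrics.peaks) == 0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_window_scan(self, seed):
        rng = np.random.default_rng(seed)
        protocol = StimulusProtocol([1.5, 2.5, 3.5], post_window=1.0)
        values = rng.normal(0, 0.02, 460)
        values += np.where(
            np.arange(460) * DT >= 2.5,
            rng.uniform(0, 0.3) * np.exp(-(np.arange(460) * DT - 2.5) / 0.4),
            0.0,
        )
        trace = make_trace(values)
        rms = compute_rms(trace, protocol)
        peaks = detect_peaks(trace, protocol, rms)
        expected = oracle_detect(trace, protocol, rms)
        for p, (det, amp) in zip(peaks, expected):
            assert p.detected == det
            assert p.amplitude == pytest.approx(amp, abs=1e-12)


class TestPeakAmplitudeSimple:
    def test_noiseless_model_evaluation(self):
        trace = exp_trace(0.8, 0.7)
        # window (t0+10 ms, t0+70 ms]: first sampled frame is 20 ms after the
        # pulse, and the decaying transient is maximal there
        expected = 0.8 * math.exp(-0.02 / 0.7)
        assert peak_amplitude_simple(trace, 1.5) == pytest.approx(expected)

    def test_blockade_suppresses_amplitude(self, single_pulse_protocol):
        noise = synth.NoiseParams(seed=3)
        rng = np.random.default_rng(99)
        control = synth.simulate_roi_trace(
            synth.KineticsParams(), single_pulse_protocol, noise, rng=rng
        )
        blocked = synth.simulate_roi_trace(
            synth.KineticsParams(responder=False), single_pulse_protocol, noise,
            rng=rng,
        )
        a_ctrl = peak_amplitude_simple(control, 1.5)
        a_block = peak_amplitude_simple(blocked, 1.5)
        assert a_block / a_ctrl < 0.05

    def test_window_outside_trace_errors(self):
        with pytest.raises(InputError):
            peak_amplitude_simple(make_trace(np.zeros(10)), 5.0)


class TestFitDecay:
    def test_noiseless_exact_recovery(self):
        trace = exp_trace(1.0, 2.0, duration=12.0)
        protocol = StimulusProtocol([1.5], post_window=10.0)
        peaks = detect_peaks(trace, protocol, rms=1e-6)
        fit = fit_decay(trace, peaks[0])
        assert fit.tau == pytest.approx(2.0, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.tau_valid

    @pytest.mark.parametrize("a", [0.1, 0.5, 2.0])
    @pytest.mark.parametrize("tau", [0.2, 0.7, 3.0])
    def test_grid_recovery_at_machine_precision(self, a, tau):
        duration = max(6.0, 1.5 + 8 * tau)
        trace = exp_trace(a, tau, duration=duration)
        protocol = StimulusProtocol([1.5], post_window=duration - 1.6)
        fit = fit_decay(trace, detect_peaks(trace, protocol, rms=1e-9)[0])
        assert abs(fit.tau - tau) / tau <= 1e-6
        assert abs(fit.fit_a - a) / a <= 1e-6

    def test_heavy_noise_fit_is_discarded(self, rng):
        trace = exp_trace(0.3, 0.7)
        noisy = trace.replace_values(trace.values + rng.normal(0, 0.05, trace.values.size))
        protocol = StimulusProtocol([1.5], post_window=3.0)
        rms = compute_rms(noisy, protocol)
        fit = fit_decay(noisy, detect_peaks(noisy, protocol, rms)[0])
        assert fit.r_squared < 0.990
        assert not fit.tau_valid

    def test_truncated_segment_is_flagged(self):
        # tau=2 s, next pulse after 1 s: 20% of the peak is never reached
        trace = exp_trace(0.5, 2.0, duration=4.0)
        protocol = StimulusProtocol([1.5], post_window=1.0)
        fit = fit_decay(trace, detect_peaks(trace, protocol, rms=1e-9)[0],
                        end_time=2.5)
        assert fit.truncated
        assert fit.tau == pytest.approx(2.0, rel=1e-6)

    def test_train_taus_recover_ground_truth(self, train_protocol, noiseless):
        kin = synth.KineticsParams(amplitude_a=0.3, tau=0.7)
        trace = synth.simulate_roi_trace(kin, train_protocol, noiseless)
        metrics = analyze_trace(trace, train_protocol)
        for fit in metrics.fits:
            assert fit is not None
            assert fit.tau == pytest.approx(0.7, rel=5e-3)


class TestCumulativeLoad:
    def test_zero_trace(self, train_protocol):
        trace = make_trace(np.zeros(1300))
        np.testing.assert_array_equal(
            cumulative_load(trace, train_protocol), 0.0
        )

    def test_matches_brute_force_sample_sum(self, rng, train_protocol):
        trace = make_trace(rng.normal(0, 0.1, 1300))
        loads = cumulative_load(trace, train_protocol)
        t1 = train_protocol.pulse_times[0]
        for k, tk in enumerate(train_protocol.pulse_times):
            acc = 0.0
            for i, ti in enumerate(trace.time):
                if t1 - 1e-12 <= ti <= tk + 1.0 + 1e-12:
                    acc += abs(trace.values[i]) * DT
            assert loads[k] == pytest.approx(acc)

    def test_single_pulse_total_area_approaches_a_tau(self):
        a, tau = 1.0, 0.2
        trace = exp_trace(a, tau, duration=8.0)
        protocol = StimulusProtocol([1.5], post_window=6.0)
        load = cumulative_load(trace, protocol, window_after=6.0)[0]
        # rectangle rule on a sampled exponential: a*dt/(1-exp(-dt/tau)) -> a*tau
        assert load == pytest.approx(a * tau, rel=0.03)
        assert load == pytest.approx(a * DT / (1 - math.exp(-DT / tau)), rel=1e-6)

    def test_nondecreasing_across_pulses(self, train_protocol, rng):
        trace = make_trace(np.abs(rng.normal(0, 0.1, 1300)))
        loads = cumulative_load(trace, train_protocol)
        assert np.all(np.diff(loads) >= 0)

    def test_short_trace_errors(self, train_protocol):
        with pytest.raises(InputError):
            cumulative_load(make_trace(np.zeros(500)), train_protocol)


class TestDecayImpact:
    def test_closed_forms(self):
        assert decay_impact(2.0, 1 / math.e).time_above == pytest.approx(2.0)
        assert decay_impact(3.0, 0.5).time_above == pytest.approx(3 * math.log(2))
        assert decay_impact(1.7, 0.2).area_total == 1.7

    def test_quadrature_matches_area(self):
        for tau in (0.2, 0.7, 2.0, 5.0):
            numeric, _ = quad(lambda t: math.exp(-t / tau), 0, 50 * tau)
            assert abs(numeric - decay_impact(tau, 0.5).area_total) / tau <= 1e-3

    def test_ratios_equal_tau_ratio(self):
        d1, d2 = decay_impact(1.2, 0.3), decay_impact(3.6, 0.3)
        assert d2.area_total / d1.area_total == pytest.approx(3.0)
        assert d2.time_above / d1.time_above == pytest.approx(3.0)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ParameterError):
            decay_impact(1.0, 1.0)
        with pytest.raises(ParameterError):
            decay_impact(-1.0, 0.5)


class TestAnalyzeTrace:
    def test_full_train_metrics(self, train_protocol):
        noise = synth.NoiseParams(seed=17)
        kin = synth.KineticsParams()
        trace = synth.simulate_roi_trace(kin, train_protocol, noise)
        m = analyze_trace(trace, train_protocol)
        assert m.responder
        assert len(m.peaks) == 10
        assert np.all(np.diff(m.cumulative_load) > 0)
        amp_truth, _ = synth.roi_ground_truth(kin)
        detected = [p.amplitude for p in m.peaks if p.detected]
        assert np.mean(detected) == pytest.approx(amp_truth, rel=0.15)

    def test_windows_partition_the_train(self, train_protocol):
        w = pulse_windows(train_protocol)
        assert len(w) == 10
        for (s0, e0), (s1, _) in zip(w, w[1:]):
            assert e0 == s1
        assert w[-1][1] == pytest.approx(train_protocol.pulse_times[-1] + 1.0)
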