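"""Stimulus-locked transient metrics: peaks, decay fits, cumulative load.

Detection follows the RMS-threshold protocol: baseline noise is the RMS over
[-1000, -104] ms relative to the first stimulus, and a per-pulse peak counts
as detected when its amplitude over the local baseline crosses 5×RMS.  Decay
time constants come from an unconstrained least-squares fit of
F(t) = a·exp(-t/τ) to the 80%→20% segment of the falling phase, and fits
with r² < 0.990 are discarded.  Cumulative calcium load is the running
integral of |ΔF/F0| from the first stimulus to 1 s after each pulse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import InputError, ParameterError
from .preprocess import StimulusProtocol, gaussian_filter_time
from .rois import DffTrace

#: detection threshold in units of baseline RMS noise
RMS_MULTIPLIER = 5.0
#: minimum r^2 for a decay fit to be kept
R2_MIN = 0.990
#: RMS window relative to the first stimulus, s
RMS_WINDOW = (-1.000, -0.104)
#: local pre-pulse baseline window relative to each pulse, s; the end point
#: keeps the same 104-ms guard as the RMS window so that Gaussian smoothing
#: of the stimulus-locked rise cannot leak backwards into the baseline
BASELINE_WINDOW = (-0.204, -0.104)
#: decay-fit segment limits, fractions of peak amplitude
FIT_UPPER_FRACTION = 0.8
FIT_LOWER_FRACTION = 0.2


@dataclass
class PulsePeak:
    """Peak candidate for one pulse of the train."""

    pulse_index: int
    pulse_time: float
    detected: bool
    amplitude: float  # peak minus local baseline, ΔF/F0 units
    peak_time: float
    baseline: float
    window: tuple[float, float]


@dataclass
class DecayFit:
    """Single-exponential fit of one transient's falling phase."""

    tau: float
    fit_a: float
    r_squared: float
    tau_valid: bool
    truncated: bool = False
    message: str = ""


@dataclass
class DecayImpact:
    """Closed-form consequences of a decay time constant.

    For a unit-peak exponential, the total area under the transient is τ and
    the time spent above a fractional threshold is τ·ln(1/threshold); both
    scale linearly in τ, so ratios of these quantities equal the τ ratio.
    """

    area_total: float  # s
    time_above: float  # s
    threshold: float


@dataclass
class TransientMetrics:
    """Per-dendrite, per-pulse metrics of one stimulus train."""

    peaks: list[PulsePeak]
    fits: list[DecayFit | None]
    cumulative_load: np.ndarray
    rms_noise: float

    @property
    def responder(self) -> bool:
        """A dendrite with no detected peak across the train is a non-responder."""
        return any(p.detected for p in self.peaks)


def compute_rms(
    trace: DffTrace,
    protocol: StimulusProtocol,
    window: tuple[float, float] = RMS_WINDOW,
) -> float:
    """RMS deviation from the window mean over [t1-1.000 s, t1-0.104 s]."""
    t1 = float(protocol.pulse_times[0])
    lo, hi = t1 + window[0], t1 + window[1]
    t = trace.time
    if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
        raise InputError("RMS window extends outside the trace")
    sel = (t >= lo - 1e-12) & (t <= hi + 1e-12)
    v = trace.values[sel]
    if v.size < 2:
        raise InputError("RMS window contains fewer than 2 samples")
    return float(np.sqrt(np.mean((v - v.mean()) ** 2)))


def _local_baseline(trace: DffTrace, pulse_time: float,
                    window: tuple[float, float] = BASELINE_WINDOW) -> float:
    """Mean of the trace over the 100 ms window just before a pulse.

    Before the first pulse this is the tail of the ΔF/F0 baseline (≈ 0); for
    later pulses it is the residual of the preceding decay, so amplitudes are
    per-pulse increments.
    """
    sel = (trace.time >= pulse_time + window[0] - 1e-12) & (
        trace.time <= pulse_time + window[1] + 1e-12
    )
    if not np.any(sel):
        return 0.0
    return float(trace.values[sel].mean())


def pulse_windows(
    protocol: StimulusProtocol, post_last: float | None = None
) -> list[tuple[float, float]]:
    """Per-pulse search windows: (t_k, t_{k+1}], last pulse (t_n, t_n + post]."""
    if post_last is None:
        post_last = protocol.post_window
    times = protocol.pulse_times
    out = []
    for k, tk in enumerate(times):
        end = times[k + 1] if k + 1 < len(times) else tk + post_last
        out.append((float(tk), float(end)))
    return out


def detect_peaks(
    trace: DffTrace,
    protocol: StimulusProtocol,
    rms: float,
    threshold_multiplier: float = RMS_MULTIPLIER,
    baseline_mode: str = "local",
) -> list[PulsePeak]:
    """Per-pulse maxima, flagged detected when they cross 5×RMS over baseline.

    ``baseline_mode='local'`` references each pulse to the trace level just
    before it (amplitudes are increments); ``'global'`` references everything
    to the pre-train baseline of 0 on the ΔF/F0 scale.
    """
    if baseline_mode not in ("local", "global"):
        raise ParameterError("baseline_mode must be 'local' or 'global'")
    t = trace.time
    peaks: list[PulsePeak] = []
    for k, (start, end) in enumerate(pulse_windows(protocol)):
        sel = np.nonzero((t > start + 1e-12) & (t <= end + 1e-12))[0]
        baseline = (
            _local_baseline(trace, start) if baseline_mode == "local" else 0.0
        )
        if sel.size == 0:
            peaks.append(
                PulsePeak(k, start, False, 0.0, start, baseline, (start, end))
            )
            continue
        i_max = sel[np.argmax(trace.values[sel])]
        amplitude = float(trace.values[i_max] - baseline)
        detected = amplitude >= threshold_multiplier * rms
        peaks.append(
            PulsePeak(
                pulse_index=k,
                pulse_time=start,
                detected=bool(detected),
                amplitude=amplitude,
                peak_time=float(t[i_max]),
                baseline=baseline,
                window=(start, end),
            )
        )
    return peaks


def peak_amplitude_simple(
    trace: DffTrace,
    pulse_time: float,
    window: tuple[float, float] = (0.010, 0.070),
) -> float:
    """Highest point in (pulse+10 ms, pulse+70 ms], relative to baseline 0.

    Used when a transient may be absent (channel-blockade conditions and
    single-pixel profiles), where the RMS detector has nothing to detect.
    """
    t = trace.time
    lo, hi = pulse_time + window[0], pulse_time + window[1]
    if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
        raise InputError("amplitude window extends outside the trace")
    sel = (t > lo + 1e-12) & (t <= hi + 1e-12)
    if not np.any(sel):
        raise InputError("amplitude window contains no samples")
    return float(np.max(trace.values[sel]))


def _interp_crossing(t0, v0, t1, v1, level) -> float:
    if v1 == v0:
        return float(t0)
    return float(t0 + (level - v0) * (t1 - t0) / (v1 - v0))


def fit_decay(
    trace: DffTrace,
    peak: PulsePeak,
    end_time: float | None = None,
    r2_min: float = R2_MIN,
    min_samples: int = 5,
) -> DecayFit:
    """Unconstrained fit of a·exp(-t/τ) to the 80%→20% falling segment.

    The segment runs from the *last* downward crossing of 0.8×amplitude to
    the *first* crossing of 0.2×amplitude after the peak (crossing times by
    linear interpolation; the last-0.8/first-0.2 rule resolves multi-crossing
    noise).  ``end_time`` bounds the segment (next pulse); if 20% is never
    reached the fit is performed on the truncated segment and flagged.  The
    trace is expected to be re-filtered at 5 Hz by the caller.  τ is kept
    only when r² >= ``r2_min`` on the fitted segment.

    The fit is referenced to the ΔF/F0 zero, not to the per-pulse local
    baseline: the two-parameter model has no offset term, and within a train
    the superposed trace decays toward zero, so subtracting the pre-pulse
    residual would make every late-pulse decay look artificially fast.
    """
    t = trace.time
    v = trace.values
    if end_time is None:
        end_time = float(t[-1])
    i_peak = int(np.argmin(np.abs(t - peak.peak_time)))
    # refine to the local maximum of this (possibly re-filtered) trace
    lo = max(0, i_peak - 5)
    hi_idx = min(len(t), i_peak + 6)
    i_peak = lo + int(np.argmax(v[lo:hi_idx]))
    amp = float(v[i_peak])
    if amp <= 0:
        return DecayFit(np.nan, np.nan, np.nan, False, message="non-positive peak")

    upper = FIT_UPPER_FRACTION * amp
    lower = FIT_LOWER_FRACTION * amp
    i_end = int(np.searchsorted(t, end_time + 1e-12))
    seg = slice(i_peak, i_end)
    ts, vs = t[seg], v[seg]
    if ts.size < 2:
        return DecayFit(np.nan, np.nan, np.nan, False, message="segment too short")

    down_upper = np.nonzero((vs[:-1] >= upper) & (vs[1:] < upper))[0]
    if down_upper.size == 0:
        t80 = float(ts[0])
    else:
        i = int(down_upper[-1])
        t80 = _interp_crossing(ts[i], vs[i], ts[i + 1], vs[i + 1], upper)
    below_lower = np.nonzero((vs[:-1] >= lower) & (vs[1:] < lower))[0]
    below_lower = below_lower[ts[below_lower] >= t80 - 1e-12]
    truncated = below_lower.size == 0
    if truncated:
        t20 = float(ts[-1])
    else:
        i = int(below_lower[0])
        t20 = _interp_crossing(ts[i], vs[i], ts[i + 1], vs[i + 1], lower)

    sel = (t >= t80 - 1e-12) & (t <= t20 + 1e-12)
    tf, vf = t[sel], v[sel]
    if tf.size < min_samples:
        return DecayFit(
            np.nan, np.nan, np.nan, False, truncated=truncated,
            message=f"only {tf.size} samples in the 80-20% segment",
        )

    # time origin at the peak so 'a' is the back-extrapolated peak amplitude
    tr = tf - t[i_peak]
    pos = vf > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(tr[pos], np.log(vf[pos]), 1)
        tau0 = -1.0 / slope if slope < 0 else trace.frame_interval * tf.size
        a0 = math.exp(intercept)
    else:
        tau0, a0 = trace.frame_interval * tf.size, amp

    def model(tt, a, tau):
        return a * np.exp(-tt / tau)

    try:
        popt, _ = curve_fit(
            model, tr, vf, p0=(a0, max(tau0, 1e-3)), maxfev=10000
        )
    except RuntimeError as exc:
        return DecayFit(
            np.nan, np.nan, np.nan, False, truncated=truncated,
            message=f"fit did not converge: {exc}",
        )
    a_hat, tau_hat = float(popt[0]), float(popt[1])
    resid = vf - model(tr, *popt)
    ss_tot = float(np.sum((vf - vf.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    valid = bool(r2 >= r2_min and tau_hat > 0)
    return DecayFit(tau_hat, a_hat, r2, valid, truncated=truncated)


def cumulative_load(
    trace: DffTrace, protocol: StimulusProtocol, window_after: float = 1.0
) -> np.ndarray:
    """∫|ΔF/F0| from the first stimulus to ``window_after`` s past each pulse.

    Rectangle rule at the frame interval; absolute values, no normalization.
    The result is in ΔF/F0·s; divide by the frame interval for the
    samples-summed (frames) convention.
    """
    t = trace.time
    dt = trace.frame_interval
    t1 = float(protocol.pulse_times[0])
    last_end = float(protocol.pulse_times[-1]) + window_after
    if t[-1] + dt / 2 < last_end:
        raise InputError(
            f"trace ends at {t[-1]:g} s; need data to {last_end:g} s"
        )
    absv = np.abs(trace.values)
    out = np.empty(protocol.n_pulses)
    for k, tk in enumerate(protocol.pulse_times):
        sel = (t >= t1 - 1e-12) & (t <= tk + window_after + 1e-12)
        out[k] = absv[sel].sum() * dt
    return out


def decay_impact(tau: float, threshold: float) -> DecayImpact:
    """Area(∞) = τ and time-above-threshold T = τ·ln(1/threshold)."""
    if tau <= 0:
        raise ParameterError("tau must be positive")
    if not 0.0 < threshold < 1.0:
        raise ParameterError("threshold must lie strictly between 0 and 1")
    return DecayImpact(
        area_total=float(tau),
        time_above=float(tau * math.log(1.0 / threshold)),
        threshold=float(threshold),
    )


def analyze_trace(
    trace: DffTrace,
    protocol: StimulusProtocol,
    detection_cutoff: float = 15.0,
    fitting_cutoff: float = 5.0,
    threshold_multiplier: float = RMS_MULTIPLIER,
    r2_min: float = R2_MIN,
    baseline_mode: str = "local",
) -> TransientMetrics:
    """Full per-dendrite analysis of an unfiltered ΔF/F0 ROI trace.

    The trace is Gaussian-filtered at 15 Hz for RMS/peak detection and
    cumulative load, and re-filtered at 5 Hz for the decay fits.
    """
    dt = trace.frame_interval
    t15 = trace.replace_values(gaussian_filter_time(trace.values, detection_cutoff, dt))
    t5 = trace.replace_values(gaussian_filter_time(trace.values, fitting_cutoff, dt))

    rms = compute_rms(t15, protocol)
    peaks = detect_peaks(
        t15, protocol, rms, threshold_multiplier=threshold_multiplier,
        baseline_mode=baseline_mode,
    )
    fits: list[DecayFit | None] = []
    windows = pulse_windows(protocol)
    for k, peak in enumerate(peaks):
        # stop the fit segment 104 ms before the next pulse so the smoothed
        # rise of the following transient cannot contaminate the tail
        end = windows[k][1] - (abs(BASELINE_WINDOW[1]) if k + 1 < len(peaks) else 0.0)
        fits.append(
            fit_decay(t5, peak, end_time=end, r2_min=r2_min)
            if peak.detected
            else None
        )
    load = cumulative_load(t15, protocol)
    return TransientMetrics(peaks=peaks, fits=fits, cumulative_load=load,
                            rms_noise=rms)


def metrics_to_frame(
    metrics: list[TransientMetrics], ids: list | None = None
) -> pd.DataFrame:
    """Tidy table: one row per dendrite × pulse."""
    rows = []
    for j, m in enumerate(metrics):
        dendrite = ids[j] if ids is not None else j
        for k, peak in enumerate(m.peaks):
            fit = m.fits[k]
            rows.append(
                {
                    "dendrite_id": dendrite,
                    "pulse": k + 1,
                    "detected": peak.detected,
                    "amplitude": peak.amplitude,
                    "peak_time": peak.peak_time,
                    "tau": fit.tau if fit else np.nan,
                    "fit_a": fit.fit_a if fit else np.nan,
                    "r_squared": fit.r_squared if fit else np.nan,
                    "tau_valid": bool(fit.tau_valid) if fit else False,
                    "cumulative_load": m.cumulative_load[k],
                    "rms_noise": m.rms_noise,
                    "responder": m.responder,
                }
            )
    return pd.DataFrame(rows)
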