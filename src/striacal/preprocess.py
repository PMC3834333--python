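"""Raw-stack preprocessing: dark subtraction, baseline F0 and ΔF/F0.

The processing order mirrors the acquisition pipeline of a shuttered EMCCD
recording: the mean shutter-closed (dark) frame is subtracted from every
frame, the baseline F0 is the pixelwise mean over the 1 s immediately
preceding the first stimulus, and the signal is expressed as the fold change
(F - F0)/F0 = ΔF/F0.  No photobleach correction is applied anywhere in the
pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .errors import InputError, ParameterError, ProcessingError, ProtocolError

#: camera pixel pitch in the object plane, μm per pixel
DEFAULT_PIXEL_SIZE = 1.18
#: acquisition frame interval, s (100 frames/s)
DEFAULT_FRAME_INTERVAL = 0.01


@dataclass
class StimulusProtocol:
    """Field-stimulation timing: pulse onsets plus analysis windows.

    Parameters
    ----------
    pulse_times:
        Stimulus onset times in seconds, strictly increasing.
    frequency:
        Nominal train frequency in Hz (metadata; 1 Hz in the reference
        protocol of 10 pulses).
    pre_window:
        Length of the pre-stimulus baseline window used for F0, s.
    post_window:
        Analysis window after the last pulse, s.
    """

    pulse_times: np.ndarray
    frequency: float | None = None
    pre_window: float = 1.0
    post_window: float = 1.0

    def __post_init__(self) -> None:
        self.pulse_times = np.asarray(self.pulse_times, dtype=float)
        if self.pulse_times.ndim != 1 or self.pulse_times.size == 0:
            raise ProtocolError("pulse_times must be a non-empty 1-D sequence")
        if np.any(np.diff(self.pulse_times) <= 0):
            raise ProtocolError("pulse_times must be strictly increasing")
        if self.pre_window <= 0 or self.post_window <= 0:
            raise ProtocolError("pre_window and post_window must be positive")

    @property
    def n_pulses(self) -> int:
        return int(self.pulse_times.size)

    def to_dict(self) -> dict:
        return {
            "pulse_times": self.pulse_times.tolist(),
            "frequency": self.frequency,
            "pre_window": self.pre_window,
            "post_window": self.post_window,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        return cls(
            pulse_times=np.asarray(d["pulse_times"], dtype=float),
            frequency=d.get("frequency"),
            pre_window=d.get("pre_window", 1.0),
            post_window=d.get("post_window", 1.0),
        )

    @classmethod
    def train(
        cls,
        n_pulses: int = 10,
        frequency: float = 1.0,
        first_pulse: float = 1.5,
        pre_window: float = 1.0,
        post_window: float = 1.0,
    ) -> "StimulusProtocol":
        """Regular train, default 10 pulses at 1 Hz."""
        times = first_pulse + np.arange(n_pulses) / frequency
        return cls(times, frequency=frequency, pre_window=pre_window,
                   post_window=post_window)


@dataclass
class ImageStack:
    """Time-lapse fluorescence stack (frames × rows × cols, camera counts).

    ``dark_frames`` are shutter-closed images acquired with the same camera
    settings; their pixelwise mean is the background to subtract.
    """

    data: np.ndarray
    frame_interval: float = DEFAULT_FRAME_INTERVAL
    pixel_size: float = DEFAULT_PIXEL_SIZE
    dark_frames: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise InputError("stack data must be frames × rows × cols with >=1 frame")
        if self.frame_interval <= 0:
            raise InputError("frame_interval must be positive")
        if self.dark_frames is not None:
            self.dark_frames = np.asarray(self.dark_frames, dtype=float)
            if self.dark_frames.ndim != 3 or (
                self.dark_frames.shape[1:] != self.data.shape[1:]
            ):
                raise InputError("dark frames must match the stack's spatial shape")

    @property
    def n_frames(self) -> int:
        return int(self.data.shape[0])

    @property
    def time(self) -> np.ndarray:
        """Time axis in seconds; frame i is taken at i*frame_interval."""
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class DffStack:
    """ΔF/F0 stack with its baseline map and time axis.

    ``valid`` marks pixels where F0 > 0; ΔF/F0 is NaN elsewhere and those
    pixels are excluded from all downstream extraction.
    """

    dff: np.ndarray
    f0: np.ndarray
    time: np.ndarray
    frame_interval: float
    pixel_size: float = DEFAULT_PIXEL_SIZE
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.asarray(self.f0) > 0


def subtract_dark(stack: ImageStack) -> ImageStack:
    """Subtract the mean dark (shutter-closed) frame from every frame.

    Negative values are kept: clipping would bias the baseline estimate.
    """
    if stack.dark_frames is None or stack.dark_frames.shape[0] < 1:
        raise InputError("stack carries no dark frames")
    dark_mean = stack.dark_frames.mean(axis=0)
    return ImageStack(
        data=stack.data - dark_mean,
        frame_interval=stack.frame_interval,
        pixel_size=stack.pixel_size,
        dark_frames=stack.dark_frames,
    )


def compute_f0(
    stack: ImageStack, protocol: StimulusProtocol, window: float | None = None
) -> np.ndarray:
    """Pixelwise baseline: mean over [t1 - window, t1) before the first pulse.

    ``window`` defaults to the protocol's pre_window (1 s in the reference
    protocol).
    """
    if window is None:
        window = protocol.pre_window
    t1 = float(protocol.pulse_times[0])
    if t1 - window < -1e-9:
        raise InputError(
            f"need {window:g} s of data before the first pulse at {t1:g} s"
        )
    t = stack.time
    sel = (t >= t1 - window - 1e-12) & (t < t1 - 1e-12)
    n_needed = int(round(window / stack.frame_interval))
    if sel.sum() < max(1, n_needed):
        raise InputError(
            f"only {int(sel.sum())} pre-stimulus frames available, "
            f"{n_needed} required for a {window:g}-s baseline window"
        )
    return stack.data[sel].mean(axis=0)


def compute_dff(stack: ImageStack, f0: np.ndarray) -> DffStack:
    """Elementwise (F - F0)/F0; pixels with F0 <= 0 are marked invalid."""
    f0 = np.asarray(f0, dtype=float)
    valid = f0 > 0
    if not np.any(valid):
        raise ProcessingError("no pixel has a positive baseline; field of view empty")
    safe_f0 = np.where(valid, f0, 1.0)
    dff = (stack.data - f0) / safe_f0
    dff[:, ~valid] = np.nan
    return DffStack(
        dff=dff,
        f0=f0,
        time=stack.time,
        frame_interval=stack.frame_interval,
        pixel_size=stack.pixel_size,
        valid=valid,
    )


def gaussian_sigma_from_cutoff(cutoff_hz: float) -> float:
    """Kernel σ (seconds) whose -3 dB amplitude point is at ``cutoff_hz``.

    The Gaussian transfer function is exp(-2 π² f² σ²); setting it to 1/√2 at
    f = f_c gives σ = sqrt(ln 2) / (2 π f_c).
    """
    if cutoff_hz <= 0:
        raise ParameterError("cutoff must be positive")
    return np.sqrt(np.log(2.0)) / (2.0 * np.pi * cutoff_hz)


def gaussian_filter_time(
    values: np.ndarray, cutoff_hz: float, frame_interval: float
) -> np.ndarray:
    """Gaussian low-pass along the first axis with unit DC gain.

    ``cutoff_hz`` is the -3 dB amplitude point of the realized filter.  The
    kernel is normalized, so constant traces pass unchanged and the trace
    integral is preserved.
    """
    nyquist = 0.5 / frame_interval
    if cutoff_hz >= nyquist:
        raise ParameterError(
            f"cutoff {cutoff_hz:g} Hz must be below the Nyquist frequency "
            f"{nyquist:g} Hz"
        )
    sigma_samples = gaussian_sigma_from_cutoff(cutoff_hz) / frame_interval
    return gaussian_filter1d(
        np.asarray(values, dtype=float), sigma_samples, axis=0, mode="nearest"
    )
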