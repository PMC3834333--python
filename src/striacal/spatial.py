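"""Subcellular gradients of peak amplitude and normalized F0 along pixel paths.

Each single-pixel trace along a nucleus→soma→dendrite path yields one peak
amplitude (highest point 10-70 ms after the stimulus) and one baseline F0;
F0 is normalized to the profile's own maximum.  Group comparisons run one
two-tailed log-t-test per position, uncorrected by default to mirror the
per-parameter testing convention, with Benjamini-Hochberg available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind

from .errors import InputError
from .preprocess import StimulusProtocol, gaussian_filter_time
from .rois import DffTrace
from .transients import RMS_MULTIPLIER, peak_amplitude_simple


@dataclass
class SpatialProfile:
    """Per-pixel amplitude and normalized F0 along one path."""

    position: np.ndarray  # pixel index from the nucleus center (0 = nucleus)
    region: np.ndarray  # nucleus | soma | dendrite per pixel
    peak_amplitude: np.ndarray  # ΔF/F0
    f0_norm: np.ndarray  # F0 / max(F0), in [0, 1]
    neuron_id: str | int | None = None
    decay_peaks: bool | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=int)
        self.peak_amplitude = np.asarray(self.peak_amplitude, dtype=float)
        self.f0_norm = np.asarray(self.f0_norm, dtype=float)
        self.region = np.asarray(self.region, dtype=object)
        if np.any(np.diff(self.position) <= 0):
            raise InputError("profile positions must be strictly increasing")
        if np.any(self.f0_norm < -1e-12) or np.any(self.f0_norm > 1 + 1e-12):
            raise InputError("normalized F0 must lie in [0, 1]")

    def truncate(self, n: int) -> "SpatialProfile":
        """Prefix of the profile; extraction commutes with path truncation
        except that F0 is re-normalized to the prefix maximum."""
        f0 = self.f0_norm[:n]
        return SpatialProfile(
            self.position[:n], self.region[:n], self.peak_amplitude[:n],
            f0 / f0.max(), self.neuron_id, self.decay_peaks,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "neuron_id": self.neuron_id,
                "position": self.position,
                "region": self.region,
                "amplitude": self.peak_amplitude,
                "f0_norm": self.f0_norm,
            }
        )


def normalize_f0(f0: np.ndarray) -> np.ndarray:
    """Scale a baseline profile to its maximum; idempotent by construction."""
    f0 = np.asarray(f0, dtype=float)
    m = f0.max()
    if m <= 0:
        raise InputError("profile has no positive baseline to normalize")
    return f0 / m


def has_decay_phase_peaks(
    trace: DffTrace,
    peak_time: float,
    rms: float,
    threshold_multiplier: float = RMS_MULTIPLIER,
    envelope_cutoff: float = 2.0,
) -> bool:
    """Local discrete peaks during the decay phase, 5×RMS over the envelope.

    The decay envelope is a heavy (2 Hz) Gaussian smoothing of the trace;
    any post-peak local maximum of the residual exceeding 5×RMS counts as a
    discrete event (e.g. an elementary release event riding the decay).
    """
    t = trace.time
    after = t > peak_time + 1e-12
    if after.sum() < 3:
        return False
    envelope = gaussian_filter_time(trace.values, envelope_cutoff,
                                    trace.frame_interval)
    resid = (trace.values - envelope)[after]
    interior = (resid[1:-1] > resid[:-2]) & (resid[1:-1] >= resid[2:])
    return bool(np.any(resid[1:-1][interior] > threshold_multiplier * rms))


def profile_from_path(
    traces: list[DffTrace],
    protocol: StimulusProtocol,
    rms: float | None = None,
    neuron_id=None,
) -> SpatialProfile:
    """Per-pixel amplitude (10-70 ms rule) and max-normalized F0 profile."""
    if not traces:
        raise InputError("no traces supplied")
    t1 = float(protocol.pulse_times[0])
    amps = np.array([peak_amplitude_simple(tr, t1) for tr in traces])
    f0 = np.array([tr.f0_value for tr in traces])
    positions = np.array(
        [tr.position if tr.position is not None else i
         for i, tr in enumerate(traces)]
    )
    regions = np.array(
        [tr.label if tr.label is not None else "dendrite" for tr in traces],
        dtype=object,
    )
    decay_peaks = None
    if rms is not None:
        i_ref = int(np.argmax(amps))
        peak_t = t1 + 0.04  # nominal peak inside the 10-70 ms window
        decay_peaks = any(
            has_decay_phase_peaks(tr, peak_t, rms) for tr in (traces[i_ref],)
        )
    return SpatialProfile(
        position=positions,
        region=regions,
        peak_amplitude=amps,
        f0_norm=normalize_f0(f0),
        neuron_id=neuron_id,
        decay_peaks=decay_peaks,
    )


def _collect(profiles: list[SpatialProfile], positions: np.ndarray, attr: str):
    """Values of one attribute per profile, linearly interpolated onto a
    common position grid (profiles with identical grids pass through)."""
    out = np.full((len(profiles), positions.size), np.nan)
    for i, p in enumerate(profiles):
        vals = getattr(p, attr)
        out[i] = np.interp(positions, p.position, vals,
                           left=np.nan, right=np.nan)
    return out


def compare_profiles(
    group_a: list[SpatialProfile],
    group_b: list[SpatialProfile],
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Per-position means ± SEM and two-tailed log-t-tests between groups.

    Positions where any value is non-positive fall back to a plain t-test on
    the raw scale (column ``test``).  Mismatched position grids are aligned
    by interpolation onto the overlapping integer positions.  The returned
    frame also carries each group's fraction of profiles with discrete
    decay-phase peaks (constant columns).
    """
    if not group_a or not group_b:
        raise InputError("both groups must be non-empty")
    lo = max(min(p.position.min() for p in g) for g in (group_a, group_b))
    hi = min(max(p.position.max() for p in g) for g in (group_a, group_b))
    if hi < lo:
        raise InputError("profile position ranges do not overlap")
    positions = np.arange(lo, hi + 1)

    amp_a = _collect(group_a, positions, "peak_amplitude")
    amp_b = _collect(group_b, positions, "peak_amplitude")

    rows = []
    for j, pos in enumerate(positions):
        a = amp_a[:, j][~np.isnan(amp_a[:, j])]
        b = amp_b[:, j][~np.isnan(amp_b[:, j])]
        if a.size < 2 or b.size < 2:
            rows.append((pos, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, "none"))
            continue
        if np.all(a > 0) and np.all(b > 0):
            t_stat, p_val = ttest_ind(np.log(a), np.log(b))
            test = "t_log"
        else:
            t_stat, p_val = ttest_ind(a, b)
            test = "t_raw"
        rows.append(
            (pos, a.mean(), a.std(ddof=1) / np.sqrt(a.size),
             b.mean(), b.std(ddof=1) / np.sqrt(b.size),
             float(t_stat), float(p_val), test)
        )
    df = pd.DataFrame(
        rows,
        columns=["position", "mean_a", "sem_a", "mean_b", "sem_b", "t", "p", "test"],
    )
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        ok = df["p"].notna()
        adj = np.full(len(df), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = multipletests(df.loc[ok, "p"], method="fdr_bh")[1]
        df["p_adj"] = adj
        df["significant"] = df["p_adj"] < alpha
    else:
        df["significant"] = df["p"] < alpha

    def peak_fraction(group):
        flags = [p.decay_peaks for p in group if p.decay_peaks is not None]
        return float(np.mean(flags)) if flags else np.nan

    df["decay_peak_fraction_a"] = peak_fraction(group_a)
    df["decay_peak_fraction_b"] = peak_fraction(group_b)
    return df
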