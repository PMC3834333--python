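"""Marker-positivity classification via a simultaneous confidence-band threshold.

Because unspecific staining grows with cell size, a fixed intensity cutoff
would misclassify large cells.  Instead, negative-control intensities (primary
antibody omitted) are regressed on log10 somatic area and the upper limit of
the 95% *uniform* (simultaneous) confidence band of that regression — the
Working-Hotelling/Scheffé two-parameter band, halfwidth
sqrt(2·F_0.95(2, n-2)) · SE(fit at x) — is used as the positivity threshold.
Cell types follow the marker logic: medium spiny neuron = GAD65+/DARPP-32+,
GABAergic interneuron = GAD65+/DARPP-32-, cholinergic = (GAD65- or
VGAT-)/VAChT+.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import f as f_dist

from .errors import FitError, InputError, ParameterError

CELL_TYPES = ("MSN", "GABA_interneuron", "cholinergic", "unclassified")
#: somatic-area range (μm²) of calcium responders, used to gate summaries
DEFAULT_AREA_GATE = (158.0, 537.0)
RUNNING_AVERAGE_WINDOW = 7


def somatic_intensity(image: np.ndarray, line: np.ndarray) -> float:
    """Peak of the 7-pixel running average of a line profile through the soma.

    ``line`` is an ordered (N, 2) array of (row, col) pixel coordinates; the
    smoothing suppresses single-pixel spikes (e.g. perimeter nerve terminals)
    before the maximum is taken.
    """
    line = np.asarray(line, dtype=int)
    if line.ndim != 2 or line.shape[0] < RUNNING_AVERAGE_WINDOW:
        raise InputError(
            f"line must contain at least {RUNNING_AVERAGE_WINDOW} pixels"
        )
    image = np.asarray(image, dtype=float)
    profile = image[line[:, 0], line[:, 1]]
    kernel = np.full(RUNNING_AVERAGE_WINDOW, 1.0 / RUNNING_AVERAGE_WINDOW)
    smoothed = np.convolve(profile, kernel, mode="valid")
    return float(smoothed.max())


@dataclass
class BandModel:
    """OLS line of intensity on log10(area) with its simultaneous 95% band."""

    slope: float
    intercept: float
    residual_sd: float
    n_control: int
    x_mean: float
    sxx: float
    confidence: float = 0.95
    marker: str | None = None

    @property
    def critical_factor(self) -> float:
        """sqrt(2·F_conf(2, n-2)): the Scheffé scaling of the pointwise SE."""
        return float(
            np.sqrt(2.0 * f_dist.ppf(self.confidence, 2, self.n_control - 2))
        )

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def se_fit(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.residual_sd * np.sqrt(
            1.0 / self.n_control + (x - self.x_mean) ** 2 / self.sxx
        )

    def band_halfwidth(self, x) -> np.ndarray:
        return self.critical_factor * self.se_fit(x)

    def upper_limit(self, x) -> np.ndarray:
        """The positivity threshold as a function of log10(area)."""
        return self.predict(x) + self.band_halfwidth(x)

    def lower_limit(self, x) -> np.ndarray:
        """Computed and reported for completeness; not used as a threshold."""
        return self.predict(x) - self.band_halfwidth(x)

    def contains_line(self, intercept: float, slope: float) -> bool:
        """Whether a given line lies inside the band at *every* x.

        sup_x [(δ0 + δ1·(x - x̄))² / SE²(x)] has the closed form
        n·δ0² + Sxx·δ1² over the residual variance, where δ0 is the deviation
        at x̄ and δ1 the slope deviation; containment everywhere is that
        supremum staying below the squared critical factor.
        """
        d0 = (self.intercept + self.slope * self.x_mean) - (
            intercept + slope * self.x_mean
        )
        d1 = self.slope - slope
        if self.residual_sd == 0:
            return d0 == 0 and d1 == 0
        stat = (self.n_control * d0**2 + self.sxx * d1**2) / self.residual_sd**2
        return bool(stat <= self.critical_factor**2)

    def to_dict(self) -> dict:
        return {
            "marker": self.marker,
            "slope": self.slope,
            "intercept": self.intercept,
            "residual_sd": self.residual_sd,
            "n_control": self.n_control,
            "x_mean": self.x_mean,
            "sxx": self.sxx,
            "confidence": self.confidence,
            "band": "Working-Hotelling/Scheffe simultaneous band",
            "x_variable": "log10(somatic area, um^2)",
        }


def fit_band_xy(
    x: np.ndarray,
    y: np.ndarray,
    confidence: float = 0.95,
    min_controls: int = 10,
    marker: str | None = None,
) -> BandModel:
    """Fit the band from raw (log10 area, intensity) control pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InputError("x and y must have equal length")
    if x.size < min_controls:
        raise FitError(
            f"{x.size} control records; at least {min_controls} required"
        )
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx <= 0:
        raise FitError("control areas have zero variance; band is undefined")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return BandModel(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        residual_sd=float(np.sqrt(res.mse_resid)),
        n_control=int(x.size),
        x_mean=float(x.mean()),
        sxx=sxx,
        confidence=confidence,
        marker=marker,
    )


def fit_band(
    controls: pd.DataFrame,
    marker: str,
    confidence: float = 0.95,
    min_controls: int = 10,
) -> BandModel:
    """Band fit for one marker channel from negative-control records.

    ``controls`` must carry ``area_um2`` and the marker intensity column; if a
    ``primary_antibody_present`` column exists, only antibody-absent rows are
    used.  Controls are pooled across genotypes/conditions by the caller.
    """
    if "primary_antibody_present" in controls:
        controls = controls.loc[~controls["primary_antibody_present"].astype(bool)]
    if marker not in controls:
        raise InputError(f"controls carry no {marker!r} column")
    return fit_band_xy(
        np.log10(controls["area_um2"].to_numpy()),
        controls[marker].to_numpy(),
        confidence=confidence,
        min_controls=min_controls,
        marker=marker,
    )


def _call_type(pos: dict[str, bool | None]) -> str:
    gad = pos.get("GAD65")
    darpp = pos.get("DARPP32")
    vacht = pos.get("VAChT")
    vgat = pos.get("VGAT")
    if gad is True and darpp is True:
        return "MSN"
    if gad is True and darpp is False:
        return "GABA_interneuron"
    if vacht is True and (gad is False or vgat is False):
        return "cholinergic"
    return "unclassified"


def classify(records: pd.DataFrame, bands: dict[str, BandModel]) -> pd.DataFrame:
    """Per-marker positivity calls and the resulting cell type per record.

    A marker is positive iff its intensity strictly exceeds the band's upper
    limit at that cell's log10 area (ties are negative).  Records missing a
    marker channel keep a missing call for it and may end up unclassified;
    they are flagged, not dropped.
    """
    if "area_um2" not in records:
        raise InputError("records must carry 'area_um2'")
    out = records.copy()
    x = np.log10(out["area_um2"].to_numpy(dtype=float))
    for marker, band in bands.items():
        if marker not in out:
            out[f"{marker}_positive"] = pd.array([None] * len(out), dtype="boolean")
            continue
        intensity = out[marker].to_numpy(dtype=float)
        calls = intensity > band.upper_limit(x)
        calls = pd.array(calls, dtype="boolean")
        calls[np.isnan(intensity)] = None
        out[f"{marker}_positive"] = calls
    types = []
    for _, row in out.iterrows():
        pos = {
            m: (None if pd.isna(row.get(f"{m}_positive")) else bool(row[f"{m}_positive"]))
            for m in bands
        }
        types.append(_call_type(pos))
    out["cell_type"] = types
    return out


def population_summary(
    calls: pd.DataFrame,
    area_gate: tuple[float, float] | None = DEFAULT_AREA_GATE,
    group_col: str | None = None,
) -> pd.DataFrame:
    """Counts and percentages per cell type among area-gated cells.

    One row per class (× group when ``group_col`` is given); the denominator
    is the number of gated cells in the group.  An empty gate yields an empty
    table (with a warning), not an error.
    """
    if calls.empty:
        raise InputError("no classification calls supplied")
    gated = calls
    if area_gate is not None:
        lo, hi = area_gate
        gated = calls.loc[
            (calls["area_um2"] >= lo) & (calls["area_um2"] <= hi)
        ]
    if gated.empty:
        import warnings

        warnings.warn("no cells inside the area gate", stacklevel=2)
        return pd.DataFrame(
            columns=["group", "cell_type", "count", "total", "percent"]
        )
    groups = gated.groupby(group_col) if group_col else [("all", gated)]
    rows = []
    for name, g in groups:
        total = len(g)
        for ct in CELL_TYPES:
            count = int((g["cell_type"] == ct).sum())
            rows.append(
                {
                    "group": name,
                    "cell_type": ct,
                    "count": count,
                    "total": total,
                    "percent": 100.0 * count / total,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ResponderSummary:
    fraction: float
    n_responders: int
    n_gated: int
    gate: float

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction


def responder_fraction(
    areas: np.ndarray,
    responded: np.ndarray,
    gate: float | str = "auto",
) -> ResponderSummary:
    """Fraction of responders among cells at or above the size gate.

    ``gate='auto'`` sets the lower bound to the smallest somatic area among
    responders (the reference rule: no neuron below the smallest responder
    size ever responded); a float applies an explicit bound.  Adding
    non-responders below the gate cannot change the reported fraction.
    """
    areas = np.asarray(areas, dtype=float)
    responded = np.asarray(responded, dtype=bool)
    if areas.size == 0 or areas.size != responded.size:
        raise InputError("areas and responded flags must be equal-length, non-empty")
    if isinstance(gate, str):
        if gate != "auto":
            raise ParameterError("gate must be 'auto' or a number")
        if not responded.any():
            raise InputError("no responders: the size gate is undefined")
        gate_value = float(areas[responded].min())
    else:
        gate_value = float(gate)
    in_gate = areas >= gate_value
    n_gated = int(in_gate.sum())
    n_resp = int((responded & in_gate).sum())
    return ResponderSummary(
        fraction=n_resp / n_gated if n_gated else float("nan"),
        n_responders=n_resp,
        n_gated=n_gated,
        gate=gate_value,
    )
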