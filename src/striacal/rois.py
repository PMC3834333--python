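"""Dendritic ROI placement, single-pixel paths, and trace extraction.

Three contiguous 2×2-pixel ROIs are placed on a dendrite with the most
proximal pixel 6 pixels (~7 μm at 1.18 μm/pixel) from the soma-dendrite
border, and their 12 member pixels are averaged into one ΔF/F0 trace.  A
dendrite is rejected — not an error — when it is 12 pixels long or shorter,
when the 2-pixel ROI extent exceeds the local dendrite width, or when the ROI
span touches an annotated branch point.  Averaging is always performed on
ΔF/F0 values (not raw counts), so it commutes with nothing upstream and does
not need to.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .preprocess import DffStack

#: most proximal ROI pixel, measured in centerline pixels from the border
ROI_PROXIMAL_OFFSET = 6
#: each ROI is a 2x2 pixel square
ROI_EDGE = 2
N_ROIS = 3
#: dendrites this long or shorter (in centerline pixels) are not analyzed
MIN_DENDRITE_PIXELS = 12


@dataclass
class DffTrace:
    """Uniformly sampled ΔF/F0 time series from one ROI set or one pixel."""

    values: np.ndarray
    time: np.ndarray
    f0_value: float
    label: str | None = None
    position: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        if self.values.shape != self.time.shape:
            raise InputError("trace values and time axis differ in length")
        if self.time.size >= 2 and np.any(np.diff(self.time) <= 0):
            raise InputError("trace time axis must be strictly increasing")

    @property
    def frame_interval(self) -> float:
        if self.time.size < 2:
            raise InputError("single-sample trace has no frame interval")
        return float(self.time[1] - self.time[0])

    def replace_values(self, values: np.ndarray) -> "DffTrace":
        return DffTrace(values, self.time, self.f0_value, self.label, self.position)


@dataclass
class RoiSet:
    """Three contiguous 2×2 ROIs on one dendrite.

    ``rois`` holds, per ROI, the (row, col) coordinates of its 4 member
    pixels; ``distance_to_soma`` is the centerline distance (pixels) from the
    soma-dendrite border to the most proximal ROI pixel.
    """

    rois: list[np.ndarray]
    dendrite_id: int
    distance_to_soma: int = ROI_PROXIMAL_OFFSET
    dendrite_width: float | None = None

    def __post_init__(self) -> None:
        if len(self.rois) != N_ROIS:
            raise InputError(f"an ROI set must contain exactly {N_ROIS} ROIs")
        self.rois = [np.asarray(r, dtype=int) for r in self.rois]
        for r in self.rois:
            if r.shape != (ROI_EDGE * ROI_EDGE, 2):
                raise InputError("each ROI must list its 4 member pixels as (4, 2)")

    @property
    def pixels(self) -> np.ndarray:
        """All 12 member pixels, shape (12, 2)."""
        return np.concatenate(self.rois, axis=0)

    def to_dict(self) -> dict:
        return {
            "rois": [r.tolist() for r in self.rois],
            "dendrite_id": self.dendrite_id,
            "distance_to_soma": self.distance_to_soma,
            "dendrite_width": self.dendrite_width,
            "coords": "0-based (row, col)",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RoiSet":
        return cls(
            rois=[np.asarray(r, dtype=int) for r in d["rois"]],
            dendrite_id=int(d["dendrite_id"]),
            distance_to_soma=int(d.get("distance_to_soma", ROI_PROXIMAL_OFFSET)),
            dendrite_width=d.get("dendrite_width"),
        )


@dataclass
class RoiRejection:
    """A dendrite excluded from ROI analysis, with the rule that fired."""

    dendrite_id: int
    reason: str  # too_short | too_narrow | branch_point

    VALID_REASONS = ("too_short", "too_narrow", "branch_point")

    def __post_init__(self) -> None:
        if self.reason not in self.VALID_REASONS:
            raise InputError(f"unknown rejection reason {self.reason!r}")


@dataclass
class PixelPath:
    """Ordered single-pixel path from the nucleus center into a dendrite."""

    coords: np.ndarray  # (N, 2) int, 0-based (row, col)
    labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=int)
        if self.coords.ndim != 2 or self.coords.shape[0] == 0:
            raise InputError("pixel path must be a non-empty (N, 2) array")
        steps = np.abs(np.diff(self.coords, axis=0))
        if steps.size and np.any(steps.max(axis=1) > 1):
            raise InputError("pixel path must be 8-connected")
        if self.labels is None:
            self.labels = np.array(["dendrite"] * len(self.coords), dtype=object)
        else:
            self.labels = np.asarray(self.labels, dtype=object)
            if self.labels.shape[0] != self.coords.shape[0]:
                raise InputError("one label per path pixel required")

    def __len__(self) -> int:
        return int(self.coords.shape[0])

    def to_dict(self) -> dict:
        return {
            "coords": self.coords.tolist(),
            "labels": list(self.labels),
            "coords_convention": "0-based (row, col)",
        }


def place_rois(geom, dendrite_id: int, pixel_size: float | None = None):
    """Place the 3×(2×2) ROI set on a dendrite, or reject it with a reason.

    Placement is purely geometric and deterministic: ROIs are laid end-to-end
    along the centerline starting 6 pixels distal to the soma-dendrite
    border, each square axis-aligned to the dominant local direction of the
    dendrite.  Returns a :class:`RoiSet` or a :class:`RoiRejection`.
    """
    if dendrite_id < 0 or dendrite_id >= len(geom.dendrites):
        raise InputError(f"geometry has no dendrite {dendrite_id}")
    if pixel_size is None:
        pixel_size = geom.pixel_size
    path = np.asarray(geom.dendrites[dendrite_id], dtype=int)
    border = int(geom.soma_dendrite_borders[dendrite_id])
    widths = np.asarray(geom.dendrite_widths[dendrite_id], dtype=float)

    n_dendrite = len(path) - border
    if n_dendrite <= MIN_DENDRITE_PIXELS:
        return RoiRejection(dendrite_id, "too_short")

    start = border + ROI_PROXIMAL_OFFSET
    span = np.arange(start, start + N_ROIS * ROI_EDGE)
    roi_extent_um = ROI_EDGE * pixel_size
    if np.min(widths[span]) < roi_extent_um:
        return RoiRejection(dendrite_id, "too_narrow")

    branch_points = getattr(geom, "branch_points", None)
    if branch_points:
        bp = set(branch_points[dendrite_id] or ())
        if bp.intersection(span.tolist()):
            return RoiRejection(dendrite_id, "branch_point")

    # dominant local direction over the ROI span decides the square alignment
    delta = path[span[-1]] - path[span[0]]
    along_rows = abs(delta[0]) >= abs(delta[1])
    rois = []
    for k in range(N_ROIS):
        anchor = path[span[2 * k]]
        nxt = path[span[2 * k + 1]]
        if along_rows:
            r0 = min(anchor[0], nxt[0])
            c0 = anchor[1]
        else:
            r0 = anchor[0]
            c0 = min(anchor[1], nxt[1])
        members = np.array(
            [[r0 + i, c0 + j] for i in range(ROI_EDGE) for j in range(ROI_EDGE)]
        )
        rois.append(members)
    return RoiSet(
        rois=rois,
        dendrite_id=dendrite_id,
        distance_to_soma=ROI_PROXIMAL_OFFSET,
        dendrite_width=float(widths[span].mean()),
    )


def extract_roi_trace(dff: DffStack, rois: RoiSet) -> DffTrace:
    """Average ΔF/F0 over the 12 member pixels, frame by frame.

    ``f0_value`` is the mean baseline over the same pixels; all ROIs are 2×2,
    so ROI-equal and pixel-equal weighting coincide.
    """
    px = rois.pixels
    n_rows, n_cols = dff.dff.shape[1:]
    if np.any(px < 0) or np.any(px[:, 0] >= n_rows) or np.any(px[:, 1] >= n_cols):
        raise InputError("ROI extends outside the image bounds")
    if not np.all(dff.valid[px[:, 0], px[:, 1]]):
        raise InputError("ROI covers pixels with invalid (non-positive) baseline")
    values = dff.dff[:, px[:, 0], px[:, 1]].mean(axis=1)
    f0_value = float(dff.f0[px[:, 0], px[:, 1]].mean())
    return DffTrace(values=values, time=dff.time, f0_value=f0_value)


def extract_path_traces(dff: DffStack, path: PixelPath) -> list[DffTrace]:
    """One unaveraged ΔF/F0 trace per path pixel, ordered along the path."""
    if len(path) == 0:
        raise InputError("empty pixel path")
    n_rows, n_cols = dff.dff.shape[1:]
    c = path.coords
    if np.any(c < 0) or np.any(c[:, 0] >= n_rows) or np.any(c[:, 1] >= n_cols):
        raise InputError("path extends outside the image bounds")
    traces = []
    for i, ((r, col), label) in enumerate(zip(c, path.labels)):
        traces.append(
            DffTrace(
                values=dff.dff[:, r, col],
                time=dff.time,
                f0_value=float(dff.f0[r, col]),
                label=str(label),
                position=i,
            )
        )
    return traces


def path_from_geometry(geom, dendrite_id: int) -> PixelPath:
    """Nucleus→soma→dendrite single-pixel path from a synthetic geometry."""
    path = np.asarray(geom.dendrites[dendrite_id], dtype=int)
    border = int(geom.soma_dendrite_borders[dendrite_id])
    center = np.asarray(geom.nucleus_center, dtype=float)
    dist = np.hypot(path[:, 0] - center[0], path[:, 1] - center[1])
    labels = np.empty(len(path), dtype=object)
    labels[:] = "soma"
    labels[dist <= geom.nucleus_radius_px] = "nucleus"
    labels[border:] = "dendrite"
    return PixelPath(coords=path, labels=labels)


def save_rois(rois: RoiSet | list[RoiSet], path: str) -> None:
    items = rois if isinstance(rois, list) else [rois]
    with open(path, "w") as fh:
        json.dump([r.to_dict() for r in items], fh, indent=2)


def load_rois(path: str) -> list[RoiSet]:
    """Import manually placed ROI sets (blinded-placement workflow)."""
    with open(path) as fh:
        data = json.load(fh)
    return [RoiSet.from_dict(d) for d in data]


def trace_to_csv(trace: DffTrace, path: str) -> None:
    import pandas as pd

    pd.DataFrame(
        {"time_s": trace.time, "dff": trace.values,
         "f0": np.full(trace.time.shape, trace.f0_value)}
    ).to_csv(path, index=False)
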