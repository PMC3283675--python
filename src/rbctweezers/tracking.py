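"""Video reduction: position tracks -> terminal velocity, frames -> cell length.

The instrument records two kinds of raw observation: the position of a
migrating cell over time (electrophoresis sweeps) and bright-field
frames of a cell elongating under drag. This module reduces both to the
scalars the estimators consume, mirroring what the original video
analysis software produced.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .errors import (
    AmbiguousSceneError,
    DegenerateTrackError,
    InsufficientDataError,
    NoCellFoundError,
)

__all__ = [
    "TrackSeries",
    "FrameStack",
    "VelocityFit",
    "terminal_velocity",
    "segment_cell",
    "cell_length",
    "read_frame_stack",
    "write_frame_stack",
    "read_tracks_csv",
    "write_tracks_csv",
]

#: Fraction of leading samples dropped before the velocity fit. At cell
#: Reynolds numbers the terminal speed is reached within milliseconds, so
#: the discarded transient is a recapture/camera artifact, not physics.
DEFAULT_TRANSIENT_FRACTION = 0.1


@dataclass(frozen=True)
class TrackSeries:
    """Signed displacement of one cell along the motion axis over time."""

    timestamps: np.ndarray  # s, strictly increasing
    positions: np.ndarray  # m
    frame_interval: float | None = None  # s, metadata only

    def __post_init__(self) -> None:
        t = np.asarray(self.timestamps, dtype=float)
        x = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "timestamps", t)
        object.__setattr__(self, "positions", x)
        if t.shape != x.shape or t.ndim != 1:
            raise InsufficientDataError("timestamps and positions must be equal-length 1-D")
        if t.size < 3:
            raise InsufficientDataError(f"need >= 3 samples, got {t.size}")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(x))):
            raise DegenerateTrackError("non-finite values in track")
        if np.any(np.diff(t) <= 0):
            raise DegenerateTrackError("timestamps must be strictly increasing")


@dataclass(frozen=True)
class FrameStack:
    """A stack of same-shape grayscale frames with pixel calibration."""

    frames: np.ndarray  # (n_frames, h, w)
    pixel_size: float  # m per pixel
    timestamps: np.ndarray | None = None  # s

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 3:
            raise InsufficientDataError(f"frames must be (n, h, w), got shape {frames.shape}")
        if self.pixel_size <= 0:
            raise InsufficientDataError(f"pixel_size must be positive, got {self.pixel_size}")
        object.__setattr__(self, "frames", frames)


@dataclass(frozen=True)
class VelocityFit:
    """OLS velocity estimate with fit diagnostics."""

    velocity: float  # m/s, slope of position vs time
    stderr: float  # m/s, standard error of the slope
    residual_rms: float  # m
    pearson_r: float
    n_used: int


def terminal_velocity(
    track: TrackSeries, transient_fraction: float = DEFAULT_TRANSIENT_FRACTION
) -> VelocityFit:
    """Terminal velocity as the OLS slope of position vs. time.

    The leading ``transient_fraction`` of samples is discarded (trap
    release / recapture transient); at least 3 samples must remain.
    """
    if not 0 <= transient_fraction < 1:
        raise InsufficientDataError(f"transient_fraction must be in [0, 1), got {transient_fraction}")
    n = track.timestamps.size
    start = int(math.floor(n * transient_fraction))
    t = track.timestamps[start:]
    x = track.positions[start:]
    if t.size < 3:
        raise InsufficientDataError(f"only {t.size} samples left after transient cut")
    if t[-1] == t[0]:
        raise DegenerateTrackError("zero time span")

    slope, intercept = np.polyfit(t, x, 1)
    resid = x - (slope * t + intercept)
    dof = t.size - 2
    rss = float(resid @ resid)
    sxx = float(np.sum((t - t.mean()) ** 2))
    stderr = math.sqrt(rss / dof / sxx) if dof > 0 and sxx > 0 else float("nan")
    if np.ptp(x) == 0:  # constant position: r undefined, report 0
        r = 0.0
    else:
        r = float(np.corrcoef(t, x)[0, 1])
    return VelocityFit(
        velocity=float(slope),
        stderr=stderr,
        residual_rms=math.sqrt(rss / t.size),
        pearson_r=r,
        n_used=int(t.size),
    )


def segment_cell(frame: np.ndarray, threshold: float | str = "otsu"):
    """Segment the single bright cell in ``frame``.

    ``threshold`` is either ``"otsu"`` (automatic) or a float quantile in
    (0, 1) of the intensity distribution. Returns
    ``(mask, centroid_rc, major_axis_length_px)`` for the largest
    connected component. Raises :class:`NoCellFoundError` on an empty
    mask and :class:`AmbiguousSceneError` when a second component is
    comparable in size (> 50% of the largest).
    """
    frame = np.asarray(frame, dtype=float)
    if np.ptp(frame) == 0:
        raise NoCellFoundError("flat frame, nothing to segment")
    if threshold == "otsu":
        thr = threshold_otsu(frame)
    else:
        thr = float(np.quantile(frame, float(threshold)))
    mask = frame > thr
    if not mask.any():
        raise NoCellFoundError("empty mask after thresholding")
    labels = label(mask)
    props = sorted(regionprops(labels), key=lambda p: p.area, reverse=True)
    if len(props) > 1 and props[1].area > 0.5 * props[0].area:
        raise AmbiguousSceneError(
            f"two comparable objects (areas {props[0].area}, {props[1].area})"
        )
    cell = props[0]
    return labels == cell.label, cell.centroid, float(cell.axis_major_length)


def cell_length(stack: FrameStack, threshold: float | str = "otsu") -> np.ndarray:
    """Per-frame cell length in metres: equivalent-ellipse major axis x pixel size."""
    lengths = np.empty(stack.frames.shape[0])
    for i, frame in enumerate(stack.frames):
        _, _, major_px = segment_cell(frame, threshold)
        lengths[i] = major_px * stack.pixel_size
    return lengths


def steady_state_length(lengths: np.ndarray) -> float:
    """Steady-state length for one velocity step: median over its frames
    (robust to isolated segmentation blips)."""
    lengths = np.asarray(lengths, dtype=float)
    if lengths.size == 0:
        raise InsufficientDataError("no frame lengths to aggregate")
    return float(np.median(lengths))


# ---------------------------------------------------------------------------
# File interfaces: multi-page TIFF + JSON sidecar, track tables as CSV.

def write_frame_stack(stack: FrameStack, tiff_path: str | Path) -> None:
    """Write a grayscale multi-page TIFF plus a ``<name>.json`` sidecar."""
    tiff_path = Path(tiff_path)
    tifffile.imwrite(tiff_path, stack.frames)
    sidecar = {"pixel_size_m": stack.pixel_size}
    if stack.timestamps is not None:
        sidecar["timestamps_s"] = list(map(float, stack.timestamps))
    tiff_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_frame_stack(tiff_path: str | Path) -> FrameStack:
    tiff_path = Path(tiff_path)
    frames = tifffile.imread(tiff_path)
    if frames.ndim == 2:
        frames = frames[None]
    meta = json.loads(tiff_path.with_suffix(".json").read_text())
    ts = meta.get("timestamps_s")
    return FrameStack(
        frames=frames,
        pixel_size=float(meta["pixel_size_m"]),
        timestamps=None if ts is None else np.asarray(ts, dtype=float),
    )


def write_tracks_csv(tracks: dict[tuple[str, str], TrackSeries], path: str | Path) -> None:
    """Write tracks keyed by (cell_id, step_id) with columns cell_id, step_id, t_s, x_m."""
    rows = []
    for (cell_id, step_id), track in tracks.items():
        for t, x in zip(track.timestamps, track.positions):
            rows.append({"cell_id": cell_id, "step_id": step_id, "t_s": t, "x_m": x})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_tracks_csv(path: str | Path) -> dict[tuple[str, str], TrackSeries]:
    df = pd.read_csv(path, dtype={"cell_id": str, "step_id": str})
    out: dict[tuple[str, str], TrackSeries] = {}
    for (cell_id, step_id), grp in df.groupby(["cell_id", "step_id"], sort=True):
        grp = grp.sort_values("t_s")
        out[(cell_id, step_id)] = TrackSeries(
            timestamps=grp["t_s"].to_numpy(), positions=grp["x_m"].to_numpy()
        )
    return out
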