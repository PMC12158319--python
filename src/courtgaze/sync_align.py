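"""Temporal fusion of gaze / eye-state streams onto the scene-frame timeline.

The scene camera is the slowest stream (30 Hz), so every other stream is
resampled onto it: for each scene frame the gaze sample and eye-state sample
with the smallest absolute timestamp difference are attached, provided that
difference is within a tolerance (default: half the scene frame period).
Nearest-neighbour matching is used rather than interpolation — pupil
diameter in particular is never interpolated across gaps.  Ties in |dt| are
broken toward the earlier sample for determinism.

Gaze pixels are also normalized to the unit square by dividing by the scene
dimensions; off-frame points are kept un-clamped (flagged ``on_frame=False``)
so they remain inspectable but are excluded from AOI tests downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .neon_io import DeviceSpec, RecordingSession

logger = logging.getLogger("courtgaze")


@dataclass(frozen=True)
class AlignmentConfig:
    """Frame rate and matching tolerance for stream fusion.

    ``tolerance_ns`` defaults to half the frame period at ``rate`` Hz
    (~16.7 ms at 30 Hz): a sample farther than half a frame from every frame
    timestamp belongs to no frame.
    """

    rate: float = 30.0
    tolerance_ns: int | None = None

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        if self.tolerance_ns is not None and self.tolerance_ns <= 0:
            raise ValueError("tolerance_ns must be > 0")

    @property
    def effective_tolerance_ns(self) -> int:
        if self.tolerance_ns is not None:
            return self.tolerance_ns
        return round(1e9 / self.rate / 2)


@dataclass
class AlignedRecord:
    """One scene frame's fused snapshot of gaze and pupil state."""

    frame_index: int
    frame_timestamp: int
    gaze_px_x: float = math.nan
    gaze_px_y: float = math.nan
    gaze_norm_x: float = math.nan
    gaze_norm_y: float = math.nan
    confidence: float = math.nan
    pupil_diameter: float = math.nan
    on_frame: bool = False

    @property
    def has_gaze(self) -> bool:
        return math.isfinite(self.gaze_px_x) and math.isfinite(self.gaze_px_y)


def normalize_gaze(
    x: float, y: float, device: DeviceSpec
) -> tuple[float, float, bool]:
    """Map pixel gaze to the unit square; report whether it lies on-frame.

    Off-frame points are returned un-clamped with ``on_frame=False``.
    Non-finite input propagates with ``on_frame=False``.
    """
    if not (math.isfinite(x) and math.isfinite(y)):
        return (math.nan, math.nan, False)
    nx = x / device.scene_width
    ny = y / device.scene_height
    on = (0.0 <= nx <= 1.0) and (0.0 <= ny <= 1.0)
    return (nx, ny, on)


def _nearest_indices(
    frame_ts: np.ndarray, sample_ts: np.ndarray, tolerance_ns: int
) -> np.ndarray:
    """Index of the nearest sample per frame, -1 when none is within tolerance.

    Ties in |dt| resolve to the earlier sample.
    """
    out = np.full(len(frame_ts), -1, dtype=np.int64)
    if len(sample_ts) == 0:
        return out
    right = np.searchsorted(sample_ts, frame_ts, side="left")
    left = np.clip(right - 1, 0, len(sample_ts) - 1)
    right = np.clip(right, 0, len(sample_ts) - 1)
    dl = np.abs(frame_ts - sample_ts[left])
    dr = np.abs(sample_ts[right] - frame_ts)
    # tie (dl == dr) chooses left, the earlier sample
    pick = np.where(dr < dl, right, left)
    dist = np.minimum(dl, dr)
    ok = dist <= tolerance_ns
    out[ok] = pick[ok]
    return out


def align_streams(
    session: RecordingSession, cfg: AlignmentConfig | None = None
) -> list[AlignedRecord]:
    """Fuse gaze and eye-state samples onto the scene-frame timeline.

    Returns exactly one record per scene frame, ordered by frame index;
    missing data never drops a frame, it only leaves fields NaN.
    """
    cfg = cfg or AlignmentConfig(rate=session.device.scene_rate)
    if session.n_frames == 0:
        raise ValueError("session has no world timestamps; nothing to align to")
    tol = cfg.effective_tolerance_ns

    frame_ts = session.world["timestamp"].to_numpy()
    gaze_ts = session.gaze["timestamp"].to_numpy()
    eye_ts = session.eye_states["timestamp"].to_numpy()

    gi = _nearest_indices(frame_ts, gaze_ts, tol)
    ei = _nearest_indices(frame_ts, eye_ts, tol)

    gx = session.gaze["x"].to_numpy(dtype=float)
    gy = session.gaze["y"].to_numpy(dtype=float)
    gc = session.gaze["confidence"].to_numpy(dtype=float)
    pd_mm = session.eye_states["pupil_diameter"].to_numpy(dtype=float)

    records: list[AlignedRecord] = []
    n_missing_gaze = 0
    for k in range(len(frame_ts)):
        rec = AlignedRecord(
            frame_index=int(session.world["frame_index"].iloc[k]),
            frame_timestamp=int(frame_ts[k]),
        )
        if gi[k] >= 0:
            rec.gaze_px_x = gx[gi[k]]
            rec.gaze_px_y = gy[gi[k]]
            rec.confidence = gc[gi[k]]
            rec.gaze_norm_x, rec.gaze_norm_y, rec.on_frame = normalize_gaze(
                rec.gaze_px_x, rec.gaze_px_y, session.device
            )
        else:
            n_missing_gaze += 1
        if ei[k] >= 0 and math.isfinite(pd_mm[ei[k]]):
            rec.pupil_diameter = float(pd_mm[ei[k]])
        records.append(rec)
    if n_missing_gaze:
        logger.info(
            "alignment: %d/%d frames have no gaze sample within %.1f ms",
            n_missing_gaze,
            len(frame_ts),
            tol / 1e6,
        )
    return records


def aligned_to_dataframe(records: Sequence[AlignedRecord]) -> pd.DataFrame:
    """One row per frame; writable as CSV for inspection."""
    return pd.DataFrame(
        {
            "frame_index": [r.frame_index for r in records],
            "frame_timestamp": [r.frame_timestamp for r in records],
            "gaze_px_x": [r.gaze_px_x for r in records],
            "gaze_px_y": [r.gaze_px_y for r in records],
            "gaze_norm_x": [r.gaze_norm_x for r in records],
            "gaze_norm_y": [r.gaze_norm_y for r in records],
            "confidence": [r.confidence for r in records],
            "pupil_diameter": [r.pupil_diameter for r in records],
            "on_frame": [r.on_frame for r in records],
        }
    )


def write_aligned_csv(records: Sequence[AlignedRecord], path: str | Path) -> Path:
    path = Path(path)
    aligned_to_dataframe(records).to_csv(path, index=False)
    return path
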