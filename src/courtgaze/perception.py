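"""Person detection and clothing segmentation contracts, mocks, and mask math.

The pipeline needs two perception capabilities per scene frame: (1) person
bounding boxes (a pretrained object detector in production), and (2) a binary
upper-clothing mask for a cropped person patch (a pretrained clothing
segmenter in production).  Both live behind small backend contracts so the
rest of the pipeline is independent of any model weights.  The test suite and
the synthetic-data path use mock backends driven by ground-truth sidecars,
which makes end-to-end runs exact by construction.

The crop / mask arithmetic is deliberately plain: a crop copies the half-open
box region, and masking is element-wise multiplication (clothing pixels kept,
everything else zeroed) before color extraction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Protocol, Sequence, runtime_checkable

import numpy as np
from PIL import Image, ImageDraw

logger = logging.getLogger("courtgaze")


@dataclass(frozen=True)
class BoundingBox:
    """A detected person in pixel space, half-open: x_max/y_max exclusive."""

    x_min: int
    y_min: int
    x_max: int
    y_max: int
    class_label: str = "person"
    confidence: float = 1.0
    track_id: int | None = None

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(f"degenerate box {self}")

    @property
    def width(self) -> int:
        return self.x_max - self.x_min

    @property
    def height(self) -> int:
        return self.y_max - self.y_min

    @property
    def area(self) -> int:
        return self.width * self.height

    def contains(self, x: float, y: float) -> bool:
        return self.x_min <= x < self.x_max and self.y_min <= y < self.y_max

    def clipped(self, frame_width: int, frame_height: int) -> "BoundingBox | None":
        """Intersect with the frame rectangle; None if nothing remains."""
        x0 = max(self.x_min, 0)
        y0 = max(self.y_min, 0)
        x1 = min(self.x_max, frame_width)
        y1 = min(self.y_max, frame_height)
        if x0 >= x1 or y0 >= y1:
            return None
        return BoundingBox(x0, y0, x1, y1, self.class_label, self.confidence, self.track_id)


@dataclass
class BinaryMask:
    """Per-pixel {0,1} mask with the same geometry as the crop it came from."""

    values: np.ndarray  # uint8, shape (height, width)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("mask values must be strictly binary")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def support(self) -> int:
        return int(self.values.sum())


@runtime_checkable
class DetectorBackend(Protocol):
    """frame -> person boxes capability."""

    name: str
    deterministic: bool

    def detect(self, frame: np.ndarray, frame_index: int | None = None) -> list[BoundingBox]:
        ...


@runtime_checkable
class SegmenterBackend(Protocol):
    """person crop -> binary upper-clothing mask capability."""

    name: str
    deterministic: bool

    def segment(self, patch: np.ndarray) -> BinaryMask:
        ...


# ---------------------------------------------------------------------------
# Core operations


def detect_persons(
    frame: np.ndarray, backend: DetectorBackend, *, frame_index: int | None = None
) -> list[BoundingBox]:
    """Run the detector, keep class "person", clip to frame, sort by confidence.

    A backend failure on a single frame is logged and yields an empty list —
    one bad frame never aborts a run.
    """
    if frame.size == 0:
        raise ValueError("empty frame")
    h, w = frame.shape[:2]
    try:
        raw = backend.detect(frame, frame_index)
    except Exception:
        logger.warning("detector backend %s failed on frame %s; skipping",
                       getattr(backend, "name", "?"), frame_index, exc_info=True)
        return []
    boxes = []
    for b in raw:
        if b.class_label != "person":
            continue
        clipped = b.clipped(w, h)
        if clipped is not None:
            boxes.append(clipped)
    boxes.sort(key=lambda b: (-b.confidence, b.x_min, b.y_min))
    return boxes


def crop(frame: np.ndarray, box: BoundingBox) -> np.ndarray:
    """Copy the half-open box region out of the frame."""
    h, w = frame.shape[:2]
    if not (0 <= box.x_min < box.x_max <= w and 0 <= box.y_min < box.y_max <= h):
        raise ValueError(f"box {box} not within {w}x{h} frame; clip it first")
    return frame[box.y_min : box.y_max, box.x_min : box.x_max].copy()


def segment_clothing(patch: np.ndarray, backend: SegmenterBackend) -> BinaryMask:
    """Segment upper clothing in a person crop; failure yields an empty mask."""
    if patch.size == 0:
        raise ValueError("empty patch")
    try:
        mask = backend.segment(patch)
    except Exception:
        logger.warning("segmenter backend %s failed; returning empty mask",
                       getattr(backend, "name", "?"), exc_info=True)
        return BinaryMask(np.zeros(patch.shape[:2], dtype=np.uint8))
    if mask.values.shape != patch.shape[:2]:
        raise ValueError(
            f"segmenter returned {mask.values.shape} mask for {patch.shape[:2]} patch"
        )
    return mask


def apply_mask(patch: np.ndarray, mask: BinaryMask) -> np.ndarray:
    """Element-wise multiply: keep patch pixels under the mask, zero elsewhere."""
    if mask.values.shape != patch.shape[:2]:
        raise ValueError(
            f"mask {mask.values.shape} does not match patch {patch.shape[:2]}"
        )
    m = mask.values
    if patch.ndim == 3:
        m = m[:, :, None]
    return (patch * m).astype(patch.dtype)


# ---------------------------------------------------------------------------
# Mock backends (ground-truth sidecar driven)


def load_sidecar(recording_dir: str | Path) -> dict:
    """Load the ground-truth sidecar JSON emitted next to a synthetic recording."""
    path = Path(recording_dir) / "ground_truth.json"
    with open(path) as fh:
        return json.load(fh)


def _sidecar_boxes(frame_entry: Mapping) -> list[BoundingBox]:
    return [
        BoundingBox(
            x_min=int(b["x_min"]),
            y_min=int(b["y_min"]),
            x_max=int(b["x_max"]),
            y_max=int(b["y_max"]),
            class_label="person",
            confidence=float(b.get("confidence", 1.0)),
            track_id=b.get("track_id"),
        )
        for b in frame_entry["boxes"]
    ]


class MockDetector:
    """Detector that replays ground-truth boxes from a sidecar.

    Reproduces the sidecar exactly, so end-to-end tests have a zero-error
    perception stage.
    """

    name = "mock-detector"
    deterministic = True

    def __init__(self, sidecar: Mapping):
        self._frames = {int(f["frame_index"]): f for f in sidecar["frames"]}

    def detect(self, frame: np.ndarray, frame_index: int | None = None) -> list[BoundingBox]:
        if frame_index is None:
            raise ValueError("MockDetector needs frame_index")
        entry = self._frames.get(frame_index)
        return _sidecar_boxes(entry) if entry else []


class NullDetector:
    """Detector that never finds anyone (degenerate-path testing)."""

    name = "null-detector"
    deterministic = True

    def detect(self, frame: np.ndarray, frame_index: int | None = None) -> list[BoundingBox]:
        return []


class MockSegmenter:
    """Segmenter exploiting the synthetic rendering convention.

    Synthetic players are drawn as a box whose top ``upper_fraction`` is the
    solid jersey and whose bottom is shorts/skin, over a uniform court color.
    Upper clothing in a crop is therefore exactly: rows in the top fraction
    whose pixel differs from the court background.  On synthetic frames this
    reproduces the painted jersey region with zero error.
    """

    name = "mock-segmenter"
    deterministic = True

    def __init__(self, background_rgb: Sequence[int], upper_fraction: float = 0.5):
        self.background = np.asarray(background_rgb, dtype=np.uint8)
        self.upper_fraction = float(upper_fraction)

    def segment(self, patch: np.ndarray) -> BinaryMask:
        h = patch.shape[0]
        top = int(round(h * self.upper_fraction))
        not_bg = (patch != self.background[None, None, :]).any(axis=2)
        mask = np.zeros(patch.shape[:2], dtype=np.uint8)
        mask[:top] = not_bg[:top]
        return BinaryMask(mask)


class EmptySegmenter:
    """Segmenter that finds no clothing anywhere (degenerate-path testing)."""

    name = "empty-segmenter"
    deterministic = True

    def segment(self, patch: np.ndarray) -> BinaryMask:
        return BinaryMask(np.zeros(patch.shape[:2], dtype=np.uint8))


# ---------------------------------------------------------------------------
# Overlay writer


def annotate_frame(
    frame: np.ndarray,
    boxes: Sequence[BoundingBox],
    gaze_px: tuple[float, float] | None,
    *,
    box_color: tuple[int, int, int] = (255, 0, 0),
    gaze_color: tuple[int, int, int] = (0, 255, 255),
    gaze_radius: int = 6,
) -> np.ndarray:
    """Draw detection boxes (red) and the gaze point (cyan dot) on a frame."""
    im = Image.fromarray(frame).convert("RGB")
    draw = ImageDraw.Draw(im)
    for b in boxes:
        draw.rectangle([b.x_min, b.y_min, b.x_max - 1, b.y_max - 1], outline=box_color, width=2)
    if gaze_px is not None and all(np.isfinite(gaze_px)):
        x, y = gaze_px
        draw.ellipse(
            [x - gaze_radius, y - gaze_radius, x + gaze_radius, y + gaze_radius],
            fill=gaze_color,
        )
    return np.asarray(im)
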