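"""Readers and writers for the Neon wearable eye-tracker CSV export family.

A recording directory holds one CSV per data stream plus the scene-camera
frames.  Four streams are mandatory (``world_timestamps``, ``gaze``,
``3d_eye_states``, ``events``); four more are optional and are parsed but not
analyzed (``fixations``, ``saccades``, ``blinks``, ``imu``).  Column headers
drift between export versions, so each stream accepts both the current
Pupil Cloud dialect (e.g. ``timestamp [ns]``, ``gaze x [px]``) and a minimal
dialect (``timestamp``, ``x``, ``y``, ...); the mapping is configurable.

All timestamps are held internally as int64 nanoseconds on the device clock.
Float inputs that look like seconds are converted on read, which keeps the
downstream nearest-neighbour alignment free of float-equality pitfalls.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image

logger = logging.getLogger("courtgaze")

MANDATORY_STREAMS = ("world_timestamps", "gaze", "3d_eye_states", "events")
OPTIONAL_STREAMS = ("fixations", "saccades", "blinks", "imu")

#: canonical column -> accepted header spellings, per stream
DEFAULT_COLUMN_DIALECTS: dict[str, dict[str, tuple[str, ...]]] = {
    "world_timestamps": {"timestamp": ("timestamp [ns]", "timestamp")},
    "gaze": {
        "timestamp": ("timestamp [ns]", "timestamp"),
        "x": ("gaze x [px]", "x"),
        "y": ("gaze y [px]", "y"),
        "confidence": ("confidence", "worn"),
    },
    "3d_eye_states": {
        "timestamp": ("timestamp [ns]", "timestamp"),
        "pupil_left": ("pupil diameter left [mm]", "pupil_left"),
        "pupil_right": ("pupil diameter right [mm]", "pupil_right"),
        "pupil_diameter": ("pupil diameter [mm]", "diameter", "pupil_diameter"),
    },
    "events": {
        "timestamp": ("timestamp [ns]", "timestamp"),
        "name": ("name", "event"),
    },
}

#: columns that must resolve for a stream to parse (others are optional)
_REQUIRED_CANONICAL: dict[str, tuple[str, ...]] = {
    "world_timestamps": ("timestamp",),
    "gaze": ("timestamp", "x", "y"),
    "3d_eye_states": ("timestamp",),
    "events": ("timestamp", "name"),
}

_FRAME_PATTERNS = ("*.png", "*.jpg", "*.jpeg")


@dataclass(frozen=True)
class DeviceSpec:
    """Geometry and sampling rates of the head-mounted tracker.

    Defaults mirror the Neon hardware: a 1600x1200 px scene (point-of-view)
    camera at 30 Hz and 200 Hz eye cameras.
    """

    scene_width: int = 1600
    scene_height: int = 1200
    scene_rate: float = 30.0
    eye_rate: float = 200.0

    def __post_init__(self) -> None:
        for name in ("scene_width", "scene_height", "scene_rate", "eye_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"DeviceSpec.{name} must be > 0")

    @property
    def frame_period_ns(self) -> int:
        return round(1e9 / self.scene_rate)


class FrameStore:
    """Accessor mapping frame_index -> RGB image array for a frame directory."""

    def __init__(self, directory: Path):
        self.directory = Path(directory)
        files: list[Path] = []
        for pat in _FRAME_PATTERNS:
            files.extend(self.directory.glob(pat))
        self.files = sorted(files)
        if not self.files:
            raise FileNotFoundError(f"no frame images found in {self.directory}")

    def __len__(self) -> int:
        return len(self.files)

    def __getitem__(self, frame_index: int) -> np.ndarray:
        if not 0 <= frame_index < len(self.files):
            raise IndexError(f"frame {frame_index} not in store of {len(self.files)}")
        with Image.open(self.files[frame_index]) as im:
            return np.asarray(im.convert("RGB"))


@dataclass
class RecordingSession:
    """Parsed recording: per-stream tables, frame accessor, device metadata.

    ``world`` has columns (frame_index, timestamp); ``gaze`` has
    (timestamp, x, y, confidence); ``eye_states`` has (timestamp,
    pupil_diameter [, pupil_left, pupil_right]); ``events`` has
    (timestamp, name).  Optional streams are retained verbatim.
    """

    device: DeviceSpec
    world: pd.DataFrame
    gaze: pd.DataFrame
    eye_states: pd.DataFrame
    events: pd.DataFrame
    fixations: pd.DataFrame = field(default_factory=pd.DataFrame)
    saccades: pd.DataFrame = field(default_factory=pd.DataFrame)
    blinks: pd.DataFrame = field(default_factory=pd.DataFrame)
    imu: pd.DataFrame = field(default_factory=pd.DataFrame)
    frames: FrameStore | None = None
    path: Path | None = None

    @property
    def n_frames(self) -> int:
        return len(self.world)


def _to_ns(values: pd.Series, *, stream: str) -> pd.Series:
    """Convert a timestamp column to int64 nanoseconds.

    Floats below 1e12 are interpreted as seconds on the device clock.
    """
    arr = pd.to_numeric(values, errors="raise")
    if arr.dtype.kind == "f":
        finite = arr.dropna()
        if len(finite) and finite.abs().max() < 1e12:
            arr = arr * 1e9
        arr = arr.round()
    return arr.astype("int64")


def _check_monotonic(ts: pd.Series, stream: str) -> None:
    diff = np.diff(ts.to_numpy())
    bad = np.nonzero(diff <= 0)[0]
    if bad.size:
        row = int(bad[0]) + 1
        raise ValueError(
            f"{stream}: timestamps not strictly increasing at row {row} "
            f"(value {int(ts.iloc[row])} after {int(ts.iloc[row - 1])})"
        )


def _resolve_columns(
    df: pd.DataFrame, stream: str, dialects: Mapping[str, Mapping[str, Sequence[str]]]
) -> pd.DataFrame:
    mapping = dialects.get(stream)
    if mapping is None:
        return df
    rename: dict[str, str] = {}
    for canonical, candidates in mapping.items():
        for cand in candidates:
            if cand in df.columns:
                rename[cand] = canonical
                break
    out = df.rename(columns=rename)
    missing = [c for c in _REQUIRED_CANONICAL.get(stream, ()) if c not in out.columns]
    if missing:
        raise ValueError(
            f"{stream}.csv: cannot resolve required column(s) {missing}; "
            f"headers present: {list(df.columns)}"
        )
    return out


def _read_stream(
    path: Path, stream: str, dialects: Mapping[str, Mapping[str, Sequence[str]]]
) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pandas raises with row context where it can
        raise ValueError(f"{path.name}: unparseable CSV ({exc})") from exc
    df = _resolve_columns(df, stream, dialects)
    if "timestamp" in df.columns:
        df["timestamp"] = _to_ns(df["timestamp"], stream=stream)
        _check_monotonic(df["timestamp"], stream)
    return df


def read_session(
    recording_dir: str | Path,
    device: DeviceSpec | None = None,
    *,
    column_dialects: Mapping[str, Mapping[str, Sequence[str]]] | None = None,
    require_frames: bool = True,
) -> RecordingSession:
    """Parse and validate a Neon-dialect recording directory.

    Parameters
    ----------
    recording_dir:
        Directory holding the stream CSVs and a ``frames/`` subdirectory (or
        frame images at top level).
    device:
        Scene/eye camera geometry; defaults to the Neon hardware values.
    column_dialects:
        Override of the header-spelling map, per stream.
    require_frames:
        If False, a missing frame source yields ``frames=None`` instead of an
        error (useful for stream-only workflows).

    Raises
    ------
    FileNotFoundError
        A mandatory stream file is absent (the message names it).
    ValueError
        Non-monotonic timestamps or an unparseable row.
    """
    recording_dir = Path(recording_dir)
    device = device or DeviceSpec()
    dialects = column_dialects or DEFAULT_COLUMN_DIALECTS

    tables: dict[str, pd.DataFrame] = {}
    for stream in MANDATORY_STREAMS:
        path = recording_dir / f"{stream}.csv"
        if not path.exists():
            raise FileNotFoundError(f"mandatory stream file missing: {stream}.csv")
        tables[stream] = _read_stream(path, stream, dialects)
    for stream in OPTIONAL_STREAMS:
        path = recording_dir / f"{stream}.csv"
        if path.exists():
            tables[stream] = _read_stream(path, stream, dialects)
        else:
            logger.info("optional stream %s.csv absent; continuing without it", stream)
            tables[stream] = pd.DataFrame()

    world = tables["world_timestamps"]
    if "frame_index" not in world.columns:
        world = world.assign(frame_index=np.arange(len(world), dtype=np.int64))
    world = world[["frame_index", "timestamp"]].copy()
    world["frame_index"] = world["frame_index"].astype("int64")
    if len(world) and not np.array_equal(
        world["frame_index"].to_numpy(), np.arange(len(world))
    ):
        raise ValueError("world_timestamps: frame_index must be contiguous from 0")

    gaze = tables["gaze"]
    if "confidence" not in gaze.columns:
        gaze = gaze.assign(confidence=1.0)
    gaze = gaze[["timestamp", "x", "y", "confidence"]].copy()
    gaze["confidence"] = gaze["confidence"].astype(float)
    conf = gaze["confidence"].dropna()
    if len(conf) and ((conf < 0) | (conf > 1)).any():
        row = int(np.nonzero(((conf < 0) | (conf > 1)).to_numpy())[0][0])
        raise ValueError(f"gaze: confidence outside [0, 1] at row {row}")

    eye = tables["3d_eye_states"].copy()
    eye = _combine_pupil_columns(eye)

    events = tables["events"][["timestamp", "name"]].copy()
    if events["name"].isna().any() or (events["name"].astype(str) == "").any():
        raise ValueError("events: empty event name")

    frames: FrameStore | None = None
    frame_dir = recording_dir / "frames"
    try:
        frames = FrameStore(frame_dir if frame_dir.is_dir() else recording_dir)
    except FileNotFoundError:
        if require_frames:
            raise FileNotFoundError(
                f"no frame source found under {recording_dir} (expected a frames/ "
                "directory of PNG/JPEG images)"
            ) from None
    if frames is not None and len(frames) < len(world):
        raise ValueError(
            f"frame store has {len(frames)} images but world_timestamps lists "
            f"{len(world)} frames"
        )

    return RecordingSession(
        device=device,
        world=world,
        gaze=gaze,
        eye_states=eye,
        events=events,
        fixations=tables["fixations"],
        saccades=tables["saccades"],
        blinks=tables["blinks"],
        imu=tables["imu"],
        frames=frames,
        path=recording_dir,
    )


def _combine_pupil_columns(eye: pd.DataFrame) -> pd.DataFrame:
    """Average left/right pupil diameters into one per-sample value.

    When only one eye is present its value is used; a missing value stays NaN
    (distinguishable from zero, which would be invalid anyway).
    """
    if "pupil_diameter" not in eye.columns:
        if "pupil_left" in eye.columns or "pupil_right" in eye.columns:
            left = eye.get("pupil_left", pd.Series(np.nan, index=eye.index))
            right = eye.get("pupil_right", pd.Series(np.nan, index=eye.index))
            eye["pupil_diameter"] = (
                pd.concat([left.astype(float), right.astype(float)], axis=1).mean(axis=1)
            )
        else:
            raise ValueError("3d_eye_states.csv: no pupil diameter column resolvable")
    eye["pupil_diameter"] = eye["pupil_diameter"].astype(float)
    valid = eye["pupil_diameter"].dropna()
    if len(valid) and (valid <= 0).any():
        row = int(np.nonzero((valid <= 0).to_numpy())[0][0])
        raise ValueError(f"3d_eye_states: non-positive pupil diameter at row {row}")
    keep = ["timestamp", "pupil_diameter"] + [
        c for c in ("pupil_left", "pupil_right") if c in eye.columns
    ]
    return eye[keep]


# ---------------------------------------------------------------------------
# Writing


def write_session(session: RecordingSession, out_dir: str | Path) -> Path:
    """Write a session back to disk in the canonical Cloud header dialect.

    Frames are copied only as a manifest reference (the source frame files are
    not duplicated); streams round-trip losslessly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    session.world.rename(columns={"timestamp": "timestamp [ns]"}).to_csv(
        out_dir / "world_timestamps.csv", index=False
    )
    session.gaze.rename(
        columns={"timestamp": "timestamp [ns]", "x": "gaze x [px]", "y": "gaze y [px]"}
    ).to_csv(out_dir / "gaze.csv", index=False)
    eye = session.eye_states.rename(
        columns={
            "timestamp": "timestamp [ns]",
            "pupil_left": "pupil diameter left [mm]",
            "pupil_right": "pupil diameter right [mm]",
            "pupil_diameter": "pupil diameter [mm]",
        }
    )
    eye.to_csv(out_dir / "3d_eye_states.csv", index=False)
    session.events.rename(columns={"timestamp": "timestamp [ns]"}).to_csv(
        out_dir / "events.csv", index=False
    )
    for stream in OPTIONAL_STREAMS:
        df: pd.DataFrame = getattr(session, stream)
        if len(df):
            df.rename(columns={"timestamp": "timestamp [ns]"}).to_csv(
                out_dir / f"{stream}.csv", index=False
            )
    return out_dir


ASSIGNMENT_COLUMNS = [
    "frame_index",
    "frame_timestamp",
    "hit",
    "team",
    "color_r",
    "color_g",
    "color_b",
    "n_pixels",
    "pupil_diameter",
]


def write_outputs(
    assignments: Iterable,
    features: pd.DataFrame | None,
    out_dir: str | Path,
    *,
    annotated_frames: Mapping[int, np.ndarray] | None = None,
) -> dict:
    """Write per-frame assignments, the feature table, and optional overlays.

    Returns a manifest dict (also saved as ``manifest.json``) listing every
    file written.  ``assignments`` is a sequence of
    :class:`~courtgaze.gaze_features.TeamAssignment`.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory not writable: {out_dir} ({exc})") from exc

    written: list[str] = []

    rows = []
    for a in assignments:
        color = a.color.dominant if a.color is not None else (np.nan,) * 3
        rows.append(
            {
                "frame_index": a.frame_index,
                "frame_timestamp": a.frame_timestamp,
                "hit": a.hit,
                "team": a.team,
                "color_r": color[0],
                "color_g": color[1],
                "color_b": color[2],
                "n_pixels": a.color.n_pixels if a.color is not None else 0,
                "pupil_diameter": a.pupil_diameter,
            }
        )
    adf = pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS)
    apath = out_dir / "assignments.csv"
    adf.to_csv(apath, index=False)
    written.append(apath.name)

    if features is not None:
        fpath = out_dir / "feature_table.csv"
        features.to_csv(fpath, index=False)
        written.append(fpath.name)

    if annotated_frames:
        fdir = out_dir / "annotated"
        fdir.mkdir(exist_ok=True)
        for idx, img in sorted(annotated_frames.items()):
            p = fdir / f"frame_{idx:05d}.png"
            Image.fromarray(img).save(p)
            written.append(f"annotated/{p.name}")

    manifest = {"out_dir": str(out_dir), "files": written}
    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    manifest["files"] = written + [mpath.name]
    return manifest


def read_assignments(path: str | Path) -> pd.DataFrame:
    """Re-read an assignments CSV written by :func:`write_outputs`."""
    df = pd.read_csv(path)
    missing = [c for c in ASSIGNMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"assignment CSV missing columns {missing}")
    return df


def sessions_equal(a: RecordingSession, b: RecordingSession, *, rtol: float = 1e-9) -> bool:
    """Field-for-field stream equality (integers exact, reals to ``rtol``)."""
    for name in ("world", "gaze", "eye_states", "events"):
        da: pd.DataFrame = getattr(a, name)
        db: pd.DataFrame = getattr(b, name)
        if list(da.columns) != list(db.columns) or len(da) != len(db):
            return False
        for col in da.columns:
            xa, xb = da[col].to_numpy(), db[col].to_numpy()
            if xa.dtype.kind in "iu":
                if not np.array_equal(xa, xb):
                    return False
            elif xa.dtype.kind == "f":
                if not np.allclose(xa, xb, rtol=rtol, equal_nan=True):
                    return False
            else:
                if not (xa == xb).all():
                    return False
    return True
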