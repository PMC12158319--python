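"""Dynamic-AOI gaze assignment, gaze-event segmentation, and feature tables.

A detected player's bounding box acts as a *dynamic* area of interest: a
gaze sample counts as "observing" that player exactly when it falls inside
the box on the same frame.  Per-frame team labels then come from the jersey
color of the gazed player, and runs of consecutive same-team frames form
*gaze events* — this package's operational unit for "number of gazes".
Finally, expert phase annotations (who is attacking when) slice the frames
into attack/defense cells per observed team, over which gaze counts and
pupil-diameter statistics are aggregated into the feature table that the
statistical layer consumes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .neon_io import RecordingSession
from .perception import (
    BoundingBox,
    DetectorBackend,
    SegmenterBackend,
    apply_mask,
    crop,
    detect_persons,
    segment_clothing,
)
from .sync_align import AlignedRecord
from .team_color import (
    TEAM_A,
    TEAM_B,
    UNKNOWN,
    ColorObservation,
    TeamPalette,
    classify_team,
    extract_dominant_color,
)

logger = logging.getLogger("courtgaze")

NONE_LABEL = "none"
OBSERVER_ROLES = ("lead_referee", "trail_referee", "coach_A", "coach_B")
PHASES = ("attack", "defense")


@dataclass(frozen=True)
class AOIHit:
    """Result of testing one frame's gaze against that frame's boxes."""

    frame_index: int
    box: BoundingBox | None = None

    @property
    def hit(self) -> bool:
        return self.box is not None


@dataclass
class TeamAssignment:
    """Per-frame outcome of the full gaze→player→jersey-color chain."""

    frame_index: int
    frame_timestamp: int
    hit: bool
    team: str  # A | B | unknown | none
    color: ColorObservation | None = None
    pupil_diameter: float = math.nan

    def __post_init__(self) -> None:
        if (self.team == NONE_LABEL) != (not self.hit):
            raise ValueError("team must be 'none' exactly when hit is False")


@dataclass(frozen=True)
class GazeEvent:
    """Maximal run of consecutive frames assigned to the same team."""

    team: str  # A | B
    start_frame: int
    end_frame: int  # inclusive

    @property
    def duration_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


@dataclass(frozen=True)
class PhaseSegment:
    """Expert annotation: during [start_ts, end_ts), ``attacking_team`` attacks.

    The phase of an *observed* team inside the span is derived: attack if it
    is the attacking team, defense otherwise.
    """

    start_ts: int
    end_ts: int
    attacking_team: str  # A | B
    observer_role: str = "coach_A"

    def __post_init__(self) -> None:
        if self.start_ts >= self.end_ts:
            raise ValueError("phase segment must have start_ts < end_ts")
        if self.attacking_team not in (TEAM_A, TEAM_B):
            raise ValueError("attacking_team must be 'A' or 'B'")

    def phase_of(self, team_observed: str) -> str:
        return "attack" if team_observed == self.attacking_team else "defense"

    def contains(self, ts: int) -> bool:
        return self.start_ts <= ts < self.end_ts


def validate_phase_plan(phases: Sequence[PhaseSegment]) -> None:
    ordered = sorted(phases, key=lambda p: p.start_ts)
    for prev, cur in zip(ordered, ordered[1:]):
        if cur.start_ts < prev.end_ts:
            raise ValueError(
                f"phase segments overlap: [{prev.start_ts},{prev.end_ts}) and "
                f"[{cur.start_ts},{cur.end_ts})"
            )


def read_phases_csv(path: str | Path) -> list[PhaseSegment]:
    """Read a phase-annotation CSV (start_ts, end_ts, attacking_team[, observer_role])."""
    df = pd.read_csv(path)
    segments = [
        PhaseSegment(
            start_ts=int(row.start_ts),
            end_ts=int(row.end_ts),
            attacking_team=str(row.attacking_team),
            observer_role=str(getattr(row, "observer_role", "coach_A")),
        )
        for row in df.itertuples()
    ]
    validate_phase_plan(segments)
    return segments


def write_phases_csv(phases: Sequence[PhaseSegment], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "start_ts": [p.start_ts for p in phases],
            "end_ts": [p.end_ts for p in phases],
            "attacking_team": [p.attacking_team for p in phases],
            "observer_role": [p.observer_role for p in phases],
        }
    ).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# AOI assignment


def assign_gaze_to_box(record: AlignedRecord, boxes: Sequence[BoundingBox]) -> AOIHit:
    """Pick the box containing the gaze point, if any.

    Among containing boxes the smallest-area one wins (the most specific
    dynamic AOI); ties break by higher confidence, then first-listed order.
    Off-frame or missing gaze never hits.
    """
    if not record.on_frame or not record.has_gaze:
        return AOIHit(frame_index=record.frame_index)
    containing = [
        (b.area, -b.confidence, i, b)
        for i, b in enumerate(boxes)
        if b.contains(record.gaze_px_x, record.gaze_px_y)
    ]
    if not containing:
        return AOIHit(frame_index=record.frame_index)
    containing.sort(key=lambda t: t[:3])
    return AOIHit(frame_index=record.frame_index, box=containing[0][3])


# ---------------------------------------------------------------------------
# Full per-frame classification chain


def classify_frames(
    session: RecordingSession,
    aligned: Sequence[AlignedRecord],
    detector: DetectorBackend,
    segmenter: SegmenterBackend,
    palette: TeamPalette,
) -> list[TeamAssignment]:
    """Run detect → AOI → crop → segment → mask → color → team on every frame.

    Any per-frame stage failure degrades that frame to ``unknown`` (if the
    AOI hit stood) or ``none`` (if not) and is logged; the run never aborts
    because of a single frame.
    """
    if session.frames is None:
        raise ValueError("session has no frame source; cannot run perception")
    assignments: list[TeamAssignment] = []
    for rec in aligned:
        team = NONE_LABEL
        hit = False
        color: ColorObservation | None = None
        try:
            frame = session.frames[rec.frame_index]
            boxes = detect_persons(frame, detector, frame_index=rec.frame_index)
            aoi = assign_gaze_to_box(rec, boxes)
            if aoi.hit:
                hit = True
                team = UNKNOWN
                patch = crop(frame, aoi.box)
                mask = segment_clothing(patch, segmenter)
                if mask.support > 0:
                    masked = apply_mask(patch, mask)
                    color = extract_dominant_color(
                        masked, mask, frame_index=rec.frame_index
                    )
                    team = classify_team(color, palette)
        except Exception:
            logger.warning(
                "frame %d: classification stage failed; marking %s",
                rec.frame_index,
                UNKNOWN if hit else NONE_LABEL,
                exc_info=True,
            )
            team = UNKNOWN if hit else NONE_LABEL
            color = None
        assignments.append(
            TeamAssignment(
                frame_index=rec.frame_index,
                frame_timestamp=rec.frame_timestamp,
                hit=hit,
                team=team,
                color=color,
                pupil_diameter=rec.pupil_diameter,
            )
        )
    return assignments


# ---------------------------------------------------------------------------
# Gaze-event segmentation (run-length over team labels)


def segment_gaze_events(
    assignments: Sequence[TeamAssignment], min_event_frames: int = 2
) -> list[GazeEvent]:
    """Maximal runs of consecutive same-team frames, A/B only.

    ``unknown`` and ``none`` frames break runs; runs shorter than
    ``min_event_frames`` (default 2, ≈67 ms at 30 Hz) are discarded as
    single-frame flicker.
    """
    events: list[GazeEvent] = []
    run_team: str | None = None
    run_start = 0
    prev_frame = None

    def flush(end_frame: int) -> None:
        nonlocal run_team
        if run_team in (TEAM_A, TEAM_B):
            ev = GazeEvent(team=run_team, start_frame=run_start, end_frame=end_frame)
            if ev.duration_frames >= min_event_frames:
                events.append(ev)
        run_team = None

    for a in assignments:
        contiguous = prev_frame is not None and a.frame_index == prev_frame + 1
        if a.team != run_team or not contiguous:
            if prev_frame is not None:
                flush(prev_frame)
            run_team = a.team if a.team in (TEAM_A, TEAM_B) else None
            run_start = a.frame_index
        prev_frame = a.frame_index
    if prev_frame is not None:
        flush(prev_frame)
    return events


# ---------------------------------------------------------------------------
# Feature table


FEATURE_COLUMNS = [
    "observer_role",
    "team_observed",
    "phase",
    "gaze_event_count",
    "gaze_frame_count",
    "pupil_mean",
    "pupil_sd",
]


def _phase_at(phases: Sequence[PhaseSegment], ts: int, team: str) -> str | None:
    for seg in phases:
        if seg.contains(ts):
            return seg.phase_of(team)
    return None


def build_feature_table(
    assignments: Sequence[TeamAssignment],
    events: Sequence[GazeEvent],
    phases: Sequence[PhaseSegment],
    *,
    observer_role: str = "coach_A",
) -> pd.DataFrame:
    """Aggregate per (team_observed, phase): gaze counts and pupil statistics.

    - ``gaze_event_count``: events whose *start frame* timestamp falls in a
      span giving the event's team that phase;
    - ``gaze_frame_count``: frames so labeled;
    - ``pupil_mean``/``pupil_sd``: over the pupil diameters of those frames
      (missing diameters excluded; sd is the sample s.d., NaN for n<2);
    - a ``Total`` row per phase sums counts and pools diameters across teams.

    Empty cells keep zero counts and NaN pupil statistics.
    """
    validate_phase_plan(phases)
    ts_by_frame = {a.frame_index: a.frame_timestamp for a in assignments}

    frame_cells: dict[tuple[str, str], list[float]] = {
        (t, p): [] for t in (TEAM_A, TEAM_B) for p in PHASES
    }
    event_counts: dict[tuple[str, str], int] = {
        (t, p): 0 for t in (TEAM_A, TEAM_B) for p in PHASES
    }

    for a in assignments:
        if a.team in (TEAM_A, TEAM_B):
            phase = _phase_at(phases, a.frame_timestamp, a.team)
            if phase is not None:
                frame_cells[(a.team, phase)].append(a.pupil_diameter)

    for ev in events:
        start_ts = ts_by_frame.get(ev.start_frame)
        if start_ts is None:
            continue
        phase = _phase_at(phases, start_ts, ev.team)
        if phase is not None:
            event_counts[(ev.team, phase)] += 1

    def stats(diams: list[float]) -> tuple[float, float]:
        vals = np.array([d for d in diams if math.isfinite(d)], dtype=float)
        if len(vals) == 0:
            return (math.nan, math.nan)
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        return (mean, sd)

    rows = []
    for phase in PHASES:
        pooled: list[float] = []
        for team in (TEAM_A, TEAM_B):
            diams = frame_cells[(team, phase)]
            mean, sd = stats(diams)
            rows.append(
                {
                    "observer_role": observer_role,
                    "team_observed": team,
                    "phase": phase,
                    "gaze_event_count": event_counts[(team, phase)],
                    "gaze_frame_count": len(diams),
                    "pupil_mean": mean,
                    "pupil_sd": sd,
                }
            )
            pooled.extend(diams)
        mean, sd = stats(pooled)
        rows.append(
            {
                "observer_role": observer_role,
                "team_observed": "Total",
                "phase": phase,
                "gaze_event_count": sum(
                    event_counts[(t, phase)] for t in (TEAM_A, TEAM_B)
                ),
                "gaze_frame_count": len(pooled),
                "pupil_mean": mean,
                "pupil_sd": sd,
            }
        )
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)
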