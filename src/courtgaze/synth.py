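"""Synthetic recording generator: frames, export CSVs, phases, ground truth.

Emulates a head-mounted tracker recording of a two-team court game so the
whole pipeline is testable without any real footage: players are solid
shapes on a uniform court background (the top half of each player box is the
jersey — the "upper clothing" the segmenter isolates), gaze follows a
scripted plan of player/background targets at the eye-camera rate with
optional pixel noise and dropout, and pupil diameter follows a baseline plus
a configurable defensive-phase shift plus Gaussian noise.

Everything the generator writes is also described in a ground-truth sidecar
(JSON): true boxes and jersey rectangles per frame, the intended gazed team
per frame, and the feature table implied by the plan.  Under ideal settings
(zero noise, zero dropout, mock perception backends) the pipeline must
reproduce that sidecar exactly; the sidecar is computed by direct recounting
here, independent of the pipeline code paths it validates.

Defaults model the study conditions: a 1600×1200 @ 30 Hz scene camera with
200 Hz eye cameras, white (Team A) vs navy (Team B) jerseys, clip lengths of
a few seconds to minutes, and pupil diameters in the 3–5 mm range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .gaze_features import PhaseSegment
from .neon_io import DeviceSpec

DEFAULT_T0_NS = 1_700_000_000_000_000_000
COURT_COLOR = (193, 154, 107)  # hardwood tan
SHORTS_COLOR = (70, 70, 70)
TEAM_A_COLOR = (255, 255, 255)  # white / light
TEAM_B_COLOR = (0, 0, 128)  # navy / dark
UPPER_FRACTION = 0.5  # jersey occupies the top half of the player box


@dataclass(frozen=True)
class PlayerSpec:
    """One synthetic player: team, jersey color, linear (reflecting) motion.

    Motion reflects inside the lane ``[x_lo, x_hi) × [y_lo, y_hi)`` (defaults:
    the whole frame).  The default cast gives every player a disjoint lane so
    boxes never overlap and the intended gaze target is unambiguous.
    """

    team: str  # A | B
    color: tuple[int, int, int]
    x0: float
    y0: float
    vx: float = 0.0
    vy: float = 0.0
    width: int = 100
    height: int = 300
    x_lo: float = 0.0
    x_hi: float | None = None
    y_lo: float = 0.0
    y_hi: float | None = None

    def box_at(self, frame: int, device: DeviceSpec) -> tuple[int, int, int, int]:
        """Integer half-open box at a frame, reflecting off the lane edges."""

        def bounce(p0: float, v: float, lo: float, hi: float) -> float:
            span = hi - lo
            if span <= 0:
                return lo
            x = (p0 - lo + v * frame) % (2 * span)
            return lo + (2 * span - x if x > span else x)

        x_hi = (self.x_hi if self.x_hi is not None else device.scene_width) - self.width
        y_hi = (self.y_hi if self.y_hi is not None else device.scene_height) - self.height
        x = bounce(self.x0, self.vx, self.x_lo, x_hi)
        y = bounce(self.y0, self.vy, self.y_lo, y_hi)
        x_min, y_min = int(round(x)), int(round(y))
        return (x_min, y_min, x_min + self.width, y_min + self.height)


@dataclass(frozen=True)
class PupilModel:
    """Pupil diameter generator, in millimetres.

    ``defense_shift_mm`` is added whenever the observer's own team is
    defending (attacking_team differs from the observer's team), modelling
    the higher cognitive load reported for defensive phases.
    """

    baseline_mm: float = 3.6
    defense_shift_mm: float = 0.3
    noise_sd_mm: float = 0.05


@dataclass
class SceneScript:
    """Full description of a synthetic recording; a pure function of its fields."""

    seed: int = 7
    n_frames: int = 90
    device: DeviceSpec = field(default_factory=DeviceSpec)
    players: list[PlayerSpec] | None = None
    gaze_plan: list[tuple[int, int, int | None]] | None = None  # (start, end incl, player idx | None)
    phase_plan: list[PhaseSegment] | None = None
    pupil: PupilModel = field(default_factory=PupilModel)
    gaze_noise_px: float = 0.0
    dropout_rate: float = 0.0
    observer_role: str = "coach_A"
    min_event_frames: int = 2
    t0_ns: int = DEFAULT_T0_NS

    @property
    def frame_period_ns(self) -> int:
        return round(1e9 / self.device.scene_rate)

    @property
    def eye_period_ns(self) -> int:
        return round(1e9 / self.device.eye_rate)

    @property
    def observer_team(self) -> str:
        return "B" if self.observer_role.endswith("B") else "A"


def default_players(device: DeviceSpec) -> list[PlayerSpec]:
    """Two players per team in disjoint vertical lanes, slow drifting motion."""
    w, h = device.scene_width, device.scene_height
    pw, ph = max(8, w // 16), max(16, h // 4)
    teams = ("A", "B", "A", "B")
    colors = (TEAM_A_COLOR, TEAM_B_COLOR, TEAM_A_COLOR, TEAM_B_COLOR)
    players = []
    margin = 0.04 * w  # keeps the background gaze anchor outside every lane
    lane_w = (w - margin) / 4
    speeds = ((1.1, 0.4), (-0.8, 0.6), (0.9, -0.5), (-1.2, 0.3))
    for i in range(4):
        x_lo = margin + i * lane_w
        x_hi = margin + (i + 1) * lane_w
        players.append(
            PlayerSpec(
                team=teams[i],
                color=colors[i],
                x0=x_lo + 0.3 * (lane_w - pw),
                y0=(0.15 + 0.2 * i) * (h - ph),
                vx=speeds[i][0],
                vy=speeds[i][1],
                width=pw,
                height=ph,
                x_lo=x_lo,
                x_hi=x_hi,
            )
        )
    return players


def default_gaze_plan(
    rng: np.random.Generator, n_frames: int, n_players: int
) -> list[tuple[int, int, int | None]]:
    """Spans of 4–8 frames; 80% target a player, 20% the background."""
    plan: list[tuple[int, int, int | None]] = []
    f = 0
    while f < n_frames:
        span = int(rng.integers(4, 9))
        end = min(f + span - 1, n_frames - 1)
        target = int(rng.integers(n_players)) if rng.random() < 0.8 else None
        plan.append((f, end, target))
        f = end + 1
    return plan


def default_phase_plan(script: SceneScript) -> list[PhaseSegment]:
    """Four equal spans alternating the attacking team A, B, A, B."""
    period = script.frame_period_ns
    bounds = [round(script.n_frames * k / 4) for k in range(5)]
    segments = []
    for k in range(4):
        if bounds[k] == bounds[k + 1]:
            continue
        segments.append(
            PhaseSegment(
                start_ts=script.t0_ns + bounds[k] * period,
                end_ts=script.t0_ns + bounds[k + 1] * period,
                attacking_team="A" if k % 2 == 0 else "B",
                observer_role=script.observer_role,
            )
        )
    return segments


def _nearest_grid_index(offset_ns: int, period_ns: int, n: int) -> int:
    """Nearest multiple of period_ns to offset_ns, ties toward the earlier."""
    k = offset_ns // period_ns
    d_lo = offset_ns - k * period_ns
    d_hi = (k + 1) * period_ns - offset_ns
    k = k if d_lo <= d_hi else k + 1
    return int(min(max(k, 0), n - 1))


def _validate_script(script: SceneScript) -> SceneScript:
    if script.n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    players = script.players or default_players(script.device)
    for p in players:
        if p.team not in ("A", "B"):
            raise ValueError(f"player team must be A or B, got {p.team}")
        if p.width > script.device.scene_width or p.height > script.device.scene_height:
            raise ValueError("player larger than the frame")
    rng = np.random.default_rng(script.seed)
    plan = script.gaze_plan or default_gaze_plan(rng, script.n_frames, len(players))
    covered = -1
    for start, end, target in plan:
        if start != covered + 1 or end < start:
            raise ValueError("gaze_plan spans must tile [0, n_frames) contiguously")
        if target is not None and not 0 <= target < len(players):
            raise ValueError(f"gaze_plan target {target} out of range")
        covered = end
    if covered != script.n_frames - 1:
        raise ValueError("gaze_plan does not cover all frames")
    phases = script.phase_plan or default_phase_plan(script)
    span_start = script.t0_ns
    span_end = script.t0_ns + script.n_frames * script.frame_period_ns
    ordered = sorted(phases, key=lambda s: s.start_ts)
    if ordered[0].start_ts > span_start or ordered[-1].end_ts < span_end:
        raise ValueError("phase_plan does not cover the recording span")
    for a, b in zip(ordered, ordered[1:]):
        if b.start_ts < a.end_ts:
            raise ValueError("phase_plan segments overlap")
    return replace(script, players=players, gaze_plan=plan, phase_plan=ordered)


def _render_frame(
    script: SceneScript, boxes: Sequence[dict], path: Path
) -> None:
    w, h = script.device.scene_width, script.device.scene_height
    img = np.empty((h, w, 3), dtype=np.uint8)
    img[:] = COURT_COLOR
    for b in boxes:
        x0, y0, x1, y1 = b["x_min"], b["y_min"], b["x_max"], b["y_max"]
        jy = b["jersey"][3]
        img[y0:jy, x0:x1] = b["color"]
        img[jy:y1, x0:x1] = SHORTS_COLOR
    Image.fromarray(img).save(path)


def _truth_feature_table(
    frame_team: Sequence[str | None],
    frame_diameter: Sequence[float],
    frame_ts: Sequence[int],
    phases: Sequence[PhaseSegment],
    min_event_frames: int,
    observer_role: str,
) -> list[dict]:
    """Direct recount of the feature table from the per-frame truth.

    Kept independent of the pipeline's aggregation code so end-to-end tests
    compare two separately derived tables.
    """

    def phase_of(ts: int, team: str) -> str | None:
        for seg in phases:
            if seg.start_ts <= ts < seg.end_ts:
                return "attack" if team == seg.attacking_team else "defense"
        return None

    n = len(frame_team)
    # events: maximal same-team runs, counted at their start frame's phase
    event_counts: dict[tuple[str, str], int] = {}
    i = 0
    while i < n:
        team = frame_team[i]
        j = i
        while j + 1 < n and frame_team[j + 1] == team:
            j += 1
        if team in ("A", "B") and (j - i + 1) >= min_event_frames:
            ph = phase_of(frame_ts[i], team)
            if ph is not None:
                event_counts[(team, ph)] = event_counts.get((team, ph), 0) + 1
        i = j + 1

    rows = []
    for phase in ("attack", "defense"):
        pooled: list[float] = []
        total_events = 0
        for team in ("A", "B"):
            diams = [
                frame_diameter[k]
                for k in range(n)
                if frame_team[k] == team and phase_of(frame_ts[k], team) == phase
            ]
            pooled.extend(diams)
            count = event_counts.get((team, phase), 0)
            total_events += count
            rows.append(
                {
                    "observer_role": observer_role,
                    "team_observed": team,
                    "phase": phase,
                    "gaze_event_count": count,
                    "gaze_frame_count": len(diams),
                    "pupil_mean": float(np.mean(diams)) if diams else math.nan,
                    "pupil_sd": float(np.std(diams, ddof=1)) if len(diams) > 1 else (0.0 if diams else math.nan),
                }
            )
        rows.append(
            {
                "observer_role": observer_role,
                "team_observed": "Total",
                "phase": phase,
                "gaze_event_count": total_events,
                "gaze_frame_count": len(pooled),
                "pupil_mean": float(np.mean(pooled)) if pooled else math.nan,
                "pupil_sd": float(np.std(pooled, ddof=1)) if len(pooled) > 1 else (0.0 if pooled else math.nan),
            }
        )
    return rows


def generate_session(script: SceneScript, out_dir: str | Path) -> tuple[Path, dict]:
    """Write a complete synthetic recording; return (directory, ground truth).

    Emits the scene frames, the eight export CSVs at the scene/eye rates, a
    phase-annotation CSV, and the ground-truth sidecar (also saved as
    ``ground_truth.json``).  Fully reproducible from ``script.seed``.
    """
    script = _validate_script(script)
    out_dir = Path(out_dir)
    frames_dir = out_dir / "frames"
    frames_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(script.seed)
    device = script.device
    period = script.frame_period_ns
    eye_period = script.eye_period_ns
    t0 = script.t0_ns

    # per-frame geometry and plan lookup
    target_of_frame: list[int | None] = [None] * script.n_frames
    for start, end, target in script.gaze_plan:
        for f in range(start, end + 1):
            target_of_frame[f] = target

    frame_ts = [t0 + f * period for f in range(script.n_frames)]
    frame_entries: list[dict] = []
    for f in range(script.n_frames):
        boxes = []
        for tid, p in enumerate(script.players):
            x0, y0, x1, y1 = p.box_at(f, device)
            boxes.append(
                {
                    "x_min": x0,
                    "y_min": y0,
                    "x_max": x1,
                    "y_max": y1,
                    "team": p.team,
                    "color": list(p.color),
                    "track_id": tid,
                    "confidence": 1.0,
                    "jersey": [x0, y0, x1, y0 + int(round((y1 - y0) * UPPER_FRACTION))],
                }
            )
        target = target_of_frame[f]
        if target is not None:
            b = boxes[target]
            gaze_px = [(b["x_min"] + b["x_max"]) / 2.0, (b["y_min"] + b["y_max"]) / 2.0]
            gazed_team = script.players[target].team
        else:
            gaze_px = [device.scene_width * 0.01, device.scene_height * 0.01]
            gazed_team = None
        frame_entries.append(
            {
                "frame_index": f,
                "boxes": boxes,
                "gazed_team": gazed_team,
                "gazed_track": target,
                "gaze_px": gaze_px,
            }
        )
        _render_frame(script, boxes, frames_dir / f"frame_{f:05d}.png")

    # eye-rate grids
    n_eye = round(script.n_frames * device.eye_rate / device.scene_rate)
    eye_ts = [t0 + k * eye_period for k in range(n_eye)]
    nearest_frame = [
        _nearest_grid_index(ts - t0, period, script.n_frames) for ts in eye_ts
    ]

    # phases active at each eye sample (for the pupil defensive shift)
    def own_team_defending(ts: int) -> bool:
        for seg in script.phase_plan:
            if seg.start_ts <= ts < seg.end_ts:
                return seg.attacking_team != script.observer_team
        return False

    pupil_values = [
        script.pupil.baseline_mm
        + (script.pupil.defense_shift_mm if own_team_defending(ts) else 0.0)
        + rng.normal(0.0, script.pupil.noise_sd_mm)
        for ts in eye_ts
    ]

    gaze_rows = []
    for k, ts in enumerate(eye_ts):
        if script.dropout_rate > 0 and rng.random() < script.dropout_rate:
            continue
        gx, gy = frame_entries[nearest_frame[k]]["gaze_px"]
        if script.gaze_noise_px > 0:
            gx += rng.normal(0.0, script.gaze_noise_px)
            gy += rng.normal(0.0, script.gaze_noise_px)
        gaze_rows.append((ts, gx, gy, 0.99))

    # --- write the export CSVs (Cloud header dialect)
    pd.DataFrame({"timestamp [ns]": frame_ts}).to_csv(
        out_dir / "world_timestamps.csv", index=False
    )
    pd.DataFrame(
        gaze_rows, columns=["timestamp [ns]", "gaze x [px]", "gaze y [px]", "confidence"]
    ).to_csv(out_dir / "gaze.csv", index=False)
    pd.DataFrame(
        {
            "timestamp [ns]": eye_ts,
            "pupil diameter left [mm]": pupil_values,
            "pupil diameter right [mm]": pupil_values,
        }
    ).to_csv(out_dir / "3d_eye_states.csv", index=False)

    end_ts = t0 + script.n_frames * period
    event_rows = [(t0, "recording.begin")]
    for seg in script.phase_plan:
        event_rows.append((seg.start_ts, f"phase.attacking_team_{seg.attacking_team}"))
    event_rows.append((end_ts, "recording.end"))
    event_rows.sort(key=lambda r: r[0])
    dedup = []
    for ts, name in event_rows:  # events share phase boundaries; keep ts strictly increasing
        if dedup and ts <= dedup[-1][0]:
            ts = dedup[-1][0] + 1
        dedup.append((ts, name))
    pd.DataFrame(dedup, columns=["timestamp [ns]", "name"]).to_csv(
        out_dir / "events.csv", index=False
    )

    # minimal plausible optional streams
    mid = t0 + (script.n_frames // 2) * period
    pd.DataFrame(
        {"timestamp [ns]": [t0 + period, mid], "duration [ms]": [180.0, 220.0]}
    ).to_csv(out_dir / "fixations.csv", index=False)
    pd.DataFrame(
        {"timestamp [ns]": [t0 + 2 * period, mid + period], "amplitude [deg]": [4.2, 6.8]}
    ).to_csv(out_dir / "saccades.csv", index=False)
    pd.DataFrame({"timestamp [ns]": [mid], "duration [ms]": [120.0]}).to_csv(
        out_dir / "blinks.csv", index=False
    )
    pd.DataFrame(
        {"timestamp [ns]": [t0, mid], "gyro x [deg/s]": [0.1, -0.2]}
    ).to_csv(out_dir / "imu.csv", index=False)

    pd.DataFrame(
        {
            "start_ts": [s.start_ts for s in script.phase_plan],
            "end_ts": [s.end_ts for s in script.phase_plan],
            "attacking_team": [s.attacking_team for s in script.phase_plan],
            "observer_role": [s.observer_role for s in script.phase_plan],
        }
    ).to_csv(out_dir / "phases.csv", index=False)

    # --- ground truth
    frame_team = [e["gazed_team"] for e in frame_entries]
    frame_diam = [
        pupil_values[_nearest_grid_index(ts - t0, eye_period, n_eye)] for ts in frame_ts
    ]
    truth_table = _truth_feature_table(
        frame_team,
        frame_diam,
        frame_ts,
        script.phase_plan,
        script.min_event_frames,
        script.observer_role,
    )
    ground_truth = {
        "court_color": list(COURT_COLOR),
        "upper_fraction": UPPER_FRACTION,
        "observer_role": script.observer_role,
        "min_event_frames": script.min_event_frames,
        "team_colors": {"A": list(TEAM_A_COLOR), "B": list(TEAM_B_COLOR)},
        "frames": frame_entries,
        "frame_pupil_mm": frame_diam,
        "phases": [
            {
                "start_ts": s.start_ts,
                "end_ts": s.end_ts,
                "attacking_team": s.attacking_team,
                "observer_role": s.observer_role,
            }
            for s in script.phase_plan
        ],
        "feature_table": truth_table,
    }
    import json

    (out_dir / "ground_truth.json").write_text(json.dumps(ground_truth))
    return out_dir, ground_truth


# ---------------------------------------------------------------------------
# Null / effect generators for the statistical layer


@dataclass(frozen=True)
class EffectConfig:
    """Gaussian 2 (coach) × 2 (phase) generator for ANOVA calibration.

    Observations decompose as subject intercept + fixed effects + residual.
    Subject and residual variances each take half the unit total variance
    (intra-class correlation 0.5 — per-subject baselines are stable relative
    to within-subject noise, as is typical for pupillometry).  Effect sizes
    are expressed in units of the total s.d.
    """

    n_per_group: int = 8
    phase_shift_sd: float = 0.0  # added to the defense phase, all subjects
    coach_shift_sd: float = 0.0  # added to the second coach group
    interaction_sd: float = 0.0  # opposite-sign phase shifts per group
    subject_sd: float = 1.0 / math.sqrt(2.0)
    residual_sd: float = 1.0 / math.sqrt(2.0)

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need n_per_group >= 2")

    @property
    def total_sd(self) -> float:
        return math.hypot(self.subject_sd, self.residual_sd)


def generate_long_dataset(cfg: EffectConfig, rng: np.random.Generator) -> pd.DataFrame:
    """One balanced long-format dataset: 2 groups × n subjects × 2 phases."""
    rows = []
    sd = cfg.total_sd
    subject = 0
    for gi, coach in enumerate(("A", "B")):
        for _ in range(cfg.n_per_group):
            intercept = rng.normal(0.0, cfg.subject_sd)
            for pi, phase in enumerate(("attack", "defense")):
                value = intercept + rng.normal(0.0, cfg.residual_sd)
                if pi == 1:
                    value += cfg.phase_shift_sd * sd
                if gi == 1:
                    value += cfg.coach_shift_sd * sd
                if pi == 1:
                    value += (1 if gi == 0 else -1) * cfg.interaction_sd * sd / 2.0
                rows.append(
                    {
                        "subject_id": subject,
                        "coach": coach,
                        "phase": phase,
                        "value": value,
                    }
                )
            subject += 1
    return pd.DataFrame(rows)


def generate_null_and_effect_datasets(
    cfg: EffectConfig, n_replicates: int, seed: int
) -> list[pd.DataFrame]:
    """Seeded replicate draws under ``cfg`` (null when all shifts are zero)."""
    rng = np.random.default_rng(seed)
    return [generate_long_dataset(cfg, rng) for _ in range(n_replicates)]
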