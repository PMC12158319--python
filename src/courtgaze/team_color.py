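"""Jersey color extraction and team classification.

Team sports with distinctly colored uniforms (ideally one light, one dark)
allow each detected player to be assigned to a team from clothing color
alone.  This module takes the masked clothing crop produced by the
perception stage and:

1. extracts a dominant color — the channel-wise median over mask-support
   pixels only, which is robust to jersey numbers and trim;
2. classifies it against a two-team reference palette in CIELAB space:
   the nearer reference wins if its ΔE*ab distance is within a match
   threshold; otherwise a light/dark fallback assigns by L* lightness,
   with a dead band around the split returning ``unknown``.

The fallback assigns the light side to whichever team's *reference* color is
lighter, so swapping the two palette entries swaps every label (a symmetry
the tests rely on).  Observations supported by too few pixels are never
trusted: tiny crops at long range carry unreliable color.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from skimage.color import deltaE_cie76, rgb2lab

from .perception import BinaryMask

TEAM_A = "A"
TEAM_B = "B"
UNKNOWN = "unknown"


def srgb_to_lab(rgb: Sequence[float]) -> np.ndarray:
    """Convert one sRGB triple (0..255) to CIELAB."""
    arr = np.asarray(rgb, dtype=float).reshape(1, 1, 3) / 255.0
    return rgb2lab(arr)[0, 0]


def delta_e(rgb1: Sequence[float], rgb2: Sequence[float]) -> float:
    """Perceptual ΔE*ab (CIE76) between two sRGB triples."""
    return float(deltaE_cie76(srgb_to_lab(rgb1), srgb_to_lab(rgb2)))


@dataclass(frozen=True)
class TeamPalette:
    """Reference jersey colors and matching thresholds for the two teams.

    Defaults mirror a white (light, Team A) vs navy (dark, Team B) pairing.
    ``match_threshold`` is the maximum ΔE*ab for a direct reference match;
    ``lightness_split``/``lightness_dead_band`` drive the L* fallback.
    """

    team_a_ref: tuple[int, int, int] = (255, 255, 255)
    team_b_ref: tuple[int, int, int] = (0, 0, 128)
    match_threshold: float = 25.0
    lightness_split: float = 50.0
    lightness_dead_band: float = 5.0
    min_pixels: int = 25
    labels: tuple[str, str] = (TEAM_A, TEAM_B)

    def __post_init__(self) -> None:
        d = delta_e(self.team_a_ref, self.team_b_ref)
        if d <= 2 * self.match_threshold:
            raise ValueError(
                f"palette references too similar (ΔE={d:.1f} ≤ "
                f"2×threshold={2 * self.match_threshold:.1f}); teams must wear "
                "distinctly different colors"
            )

    def swapped(self) -> "TeamPalette":
        return TeamPalette(
            team_a_ref=self.team_b_ref,
            team_b_ref=self.team_a_ref,
            match_threshold=self.match_threshold,
            lightness_split=self.lightness_split,
            lightness_dead_band=self.lightness_dead_band,
            min_pixels=self.min_pixels,
            labels=self.labels,
        )


@dataclass(frozen=True)
class ColorObservation:
    """Dominant color of one masked clothing crop."""

    dominant: tuple[float, float, float]
    n_pixels: int
    frame_index: int = -1

    def __post_init__(self) -> None:
        if self.n_pixels < 1:
            raise ValueError("a valid color observation needs n_pixels >= 1")


def extract_dominant_color(
    masked_patch: np.ndarray, mask: BinaryMask, *, frame_index: int = -1
) -> ColorObservation:
    """Channel-wise median color over mask-support pixels.

    Zeros outside the mask never contribute: only pixels where the mask is 1
    enter the median.
    """
    if mask.values.shape != masked_patch.shape[:2]:
        raise ValueError("mask geometry does not match patch")
    support = mask.values.astype(bool)
    n = int(support.sum())
    if n == 0:
        raise ValueError("no clothing pixels (empty mask support)")
    pixels = masked_patch[support].reshape(n, -1).astype(float)
    dominant = tuple(float(v) for v in np.median(pixels, axis=0))
    return ColorObservation(dominant=dominant, n_pixels=n, frame_index=frame_index)


def classify_team(obs: ColorObservation, palette: TeamPalette) -> str:
    """Map a color observation to ``"A"``, ``"B"`` or ``"unknown"``.

    Stage 1: nearest palette reference in CIELAB, accepted when its ΔE*ab is
    within the match threshold (an exact tie between references is ambiguous
    and returns unknown).  Stage 2 (fallback): split on L* lightness — the
    lighter half goes to the team with the lighter reference, the darker half
    to the other, and L* within the dead band returns unknown.  Observations
    with fewer than ``palette.min_pixels`` support pixels return unknown.
    """
    if obs.n_pixels < palette.min_pixels:
        return UNKNOWN
    if not all(np.isfinite(obs.dominant)):
        return UNKNOWN
    lab = srgb_to_lab(obs.dominant)
    lab_a = srgb_to_lab(palette.team_a_ref)
    lab_b = srgb_to_lab(palette.team_b_ref)
    d_a = float(np.linalg.norm(lab - lab_a))
    d_b = float(np.linalg.norm(lab - lab_b))
    label_a, label_b = palette.labels

    if min(d_a, d_b) <= palette.match_threshold:
        if d_a == d_b:
            return UNKNOWN
        return label_a if d_a < d_b else label_b

    # fallback: light/dark split tied to the *references'* lightness
    l_star = float(lab[0])
    if abs(l_star - palette.lightness_split) <= palette.lightness_dead_band:
        return UNKNOWN
    if lab_a[0] == lab_b[0]:
        return UNKNOWN
    light_label = label_a if lab_a[0] > lab_b[0] else label_b
    dark_label = label_b if light_label == label_a else label_a
    return light_label if l_star > palette.lightness_split else dark_label


def calibrate_palette(
    samples_a: Sequence[ColorObservation],
    samples_b: Sequence[ColorObservation],
    *,
    match_threshold: float = 25.0,
    lightness_split: float = 50.0,
    lightness_dead_band: float = 5.0,
    min_pixels: int = 25,
) -> TeamPalette:
    """Build a palette from labeled sample observations.

    References are the per-team medians of the sample dominant colors;
    thresholds stay at their configured defaults.
    """
    if not samples_a or not samples_b:
        raise ValueError("need at least one labeled sample per team")
    ref_a = tuple(float(v) for v in np.median([s.dominant for s in samples_a], axis=0))
    ref_b = tuple(float(v) for v in np.median([s.dominant for s in samples_b], axis=0))
    return TeamPalette(
        team_a_ref=ref_a,
        team_b_ref=ref_b,
        match_threshold=match_threshold,
        lightness_split=lightness_split,
        lightness_dead_band=lightness_dead_band,
        min_pixels=min_pixels,
    )


# ---------------------------------------------------------------------------
# Palette file I/O (YAML)


def load_palette(path: str | Path) -> TeamPalette:
    """Load a palette YAML: team_a/team_b color triples plus thresholds."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    kwargs = {}
    if "team_a" in raw:
        kwargs["team_a_ref"] = tuple(raw["team_a"])
    if "team_b" in raw:
        kwargs["team_b_ref"] = tuple(raw["team_b"])
    for key in ("match_threshold", "lightness_split", "lightness_dead_band", "min_pixels"):
        if key in raw:
            kwargs[key] = raw[key]
    return TeamPalette(**kwargs)


def save_palette(palette: TeamPalette, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "team_a": [float(v) for v in palette.team_a_ref],
        "team_b": [float(v) for v in palette.team_b_ref],
        "match_threshold": palette.match_threshold,
        "lightness_split": palette.lightness_split,
        "lightness_dead_band": palette.lightness_dead_band,
        "min_pixels": palette.min_pixels,
    }
    path.write_text(yaml.safe_dump(payload))
    return path
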