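"""Statistical layer: two-sample t-tests and the 2×2 mixed-design ANOVA.

The study design behind the feature tables compares observers (lead vs trail
referee) with unpaired t-tests, and coaches with a 2×2 mixed-design ANOVA:
game phase (attack/defense) as the within-subjects factor, coach as the
between-subjects factor, the annotated clip being the observation unit.
Significance is judged at α = 0.05 with p ≤ α.

The t statistic (Welch by default, Student optional) and the classical
mixed-model sums-of-squares decomposition are computed here from first
principles; scipy supplies only the t and F distributions.  For two groups
the between effect is tested against subjects-within-groups (df_den = N−2)
and the within main effect and interaction against the phase×subjects
residual (also df_den = N−2 with two phase levels).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps



@dataclass(frozen=True)
class StatConfig:
    alpha: float = 0.05
    t_variant: str = "welch"  # welch | student

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.t_variant not in ("welch", "student"):
            raise ValueError("t_variant must be 'welch' or 'student'")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int


@dataclass(frozen=True)
class EffectResult:
    F: float
    df_num: int
    df_den: int
    p: float
    ss_effect: float
    ss_error: float
    degenerate: bool = False  # zero error SS: F undefined, reported as 0 with p=1


@dataclass(frozen=True)
class AnovaResult:
    """F tests for the between, within, and interaction effects."""

    between: EffectResult
    within: EffectResult
    interaction: EffectResult
    n_subjects: int


def t_test(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    cfg: StatConfig | None = None,
) -> TTestResult:
    """Two-sided unpaired t-test; Welch–Satterthwaite df by default.

    Identical samples give t = 0, p = 1.  Degenerate inputs (n < 2 or zero
    variance in both samples with equal means excepted — zero *pooled*
    variance with unequal means is still an error) raise with the condition
    named.
    """
    cfg = cfg or StatConfig()
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError(f"need at least 2 observations per sample (got {na}, {nb})")
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if ma == mb:
            return TTestResult(0.0, float(na + nb - 2), 1.0, ma, mb, 0.0, 0.0, na, nb)
        raise ValueError("zero variance in both samples with unequal means")

    if cfg.t_variant == "welch":
        se2 = va / na + vb / nb
        t = (ma - mb) / math.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    else:
        df = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        t = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * sps.t.sf(abs(t), df)
    return TTestResult(
        t=float(t), df=float(df), p=float(p),
        mean_a=float(ma), mean_b=float(mb),
        sd_a=float(math.sqrt(va)), sd_b=float(math.sqrt(vb)),
        n_a=na, n_b=nb,
    )


# ---------------------------------------------------------------------------
# 2×2 mixed-design ANOVA


def _long_to_wide(data: pd.DataFrame) -> pd.DataFrame:
    required = {"subject_id", "coach", "phase", "value"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"long-format data missing columns {sorted(missing)}")
    phases = sorted(data["phase"].unique())
    if len(phases) != 2:
        raise ValueError(f"need exactly 2 phase levels, got {phases}")
    counts = data.groupby(["subject_id", "phase"]).size()
    if (counts != 1).any():
        bad = counts[counts != 1].index[0]
        raise ValueError(
            f"unbalanced within-subject data: subject {bad[0]} has "
            f"{counts[bad]} values for phase {bad[1]} (need exactly 1)"
        )
    wide = data.pivot_table(
        index=["subject_id", "coach"], columns="phase", values="value", aggfunc="first"
    )
    if wide.isna().any().any():
        sub = wide[wide.isna().any(axis=1)].index[0][0]
        raise ValueError(f"subject {sub} is missing a phase observation")
    return wide


def mixed_anova_2x2(data: pd.DataFrame, cfg: StatConfig | None = None) -> AnovaResult:
    """Classical mixed-model SS decomposition for 2 groups × 2 phases.

    ``data`` is long format with columns (subject_id, coach, phase, value);
    each subject contributes exactly one value per phase.  Groups may be
    unbalanced in subject count, but each subject must be complete.

    Degenerate inputs with zero error SS (e.g. all values identical) report
    F = 0, p = 1 and flag the effect as degenerate.
    """
    wide = _long_to_wide(data)
    groups = wide.index.get_level_values("coach")
    levels = sorted(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 coach groups, got {levels}")
    n_per = [int((groups == g).sum()) for g in levels]
    if min(n_per) < 2:
        raise ValueError("need at least 2 subjects per coach group")

    y = wide.to_numpy(dtype=float)  # (N, 2) subjects × phases
    n_subj, n_phase = y.shape
    grand = y.mean()

    subj_means = y.mean(axis=1)
    group_masks = [np.asarray(groups == g) for g in levels]
    group_means = np.array([y[m].mean() for m in group_masks])
    phase_means = y.mean(axis=0)

    # between-subjects stratum
    ss_group = sum(
        n_per[i] * n_phase * (group_means[i] - grand) ** 2 for i in range(2)
    )
    ss_subj_within = sum(
        n_phase * ((subj_means[m] - group_means[i]) ** 2).sum()
        for i, m in enumerate(group_masks)
    )
    df_between_err = n_subj - 2

    # within-subjects stratum
    ss_phase = n_subj * ((phase_means - grand) ** 2).sum()
    cell_means = np.vstack([y[m].mean(axis=0) for m in group_masks])  # (2 groups, 2 phases)
    ss_inter = sum(
        n_per[i] * (cell_means[i, j] - group_means[i] - phase_means[j] + grand) ** 2
        for i in range(2)
        for j in range(n_phase)
    )
    ss_total = ((y - grand) ** 2).sum()
    ss_within_err = ss_total - ss_group - ss_subj_within - ss_phase - ss_inter
    ss_within_err = max(ss_within_err, 0.0)  # guard tiny negative round-off
    df_within_err = (n_subj - 2) * (n_phase - 1)

    def effect(ss_eff: float, ss_err: float, df_num: int, df_den: int) -> EffectResult:
        if ss_err <= 0:
            return EffectResult(0.0, df_num, df_den, 1.0, ss_eff, ss_err, degenerate=True)
        F = (ss_eff / df_num) / (ss_err / df_den)
        p = float(sps.f.sf(F, df_num, df_den))
        return EffectResult(float(F), df_num, df_den, p, ss_eff, ss_err)

    return AnovaResult(
        between=effect(ss_group, ss_subj_within, 1, df_between_err),
        within=effect(ss_phase, ss_within_err, 1, df_within_err),
        interaction=effect(ss_inter, ss_within_err, 1, df_within_err),
        n_subjects=n_subj,
    )


def anova_to_dataframe(result: AnovaResult) -> pd.DataFrame:
    rows = []
    for name in ("between", "within", "interaction"):
        e: EffectResult = getattr(result, name)
        rows.append(
            {
                "effect": name,
                "F": e.F,
                "df_num": e.df_num,
                "df_den": e.df_den,
                "p": e.p,
                "degenerate": e.degenerate,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Report tables (mean ± s.d. per condition plus p-values)


REPORT_METRICS = ("DIA", "GAZE")
REPORT_TEAMS = ("Team A", "Team B", "Total")


def report_tables(
    observations: pd.DataFrame,
    cfg: StatConfig | None = None,
) -> pd.DataFrame:
    """Condition-comparison table: one row per metric × observed team.

    ``observations`` is long format with columns (metric ∈ {DIA, GAZE},
    team ∈ {Team A, Team B, Total}, condition ∈ two levels, value) where each
    row is one clip-level measurement.  The output row carries mean ± s.d.
    per condition, the two-sided p, and a significance marker (p ≤ α).
    Rows whose cells cannot be tested (fewer than two values on either side)
    are emitted with missing markers.
    """
    cfg = cfg or StatConfig()
    required = {"metric", "team", "condition", "value"}
    if not required <= set(observations.columns):
        raise ValueError(f"observations need columns {sorted(required)}")
    conditions = sorted(observations["condition"].unique())
    if len(conditions) != 2:
        raise ValueError(f"need exactly 2 conditions, got {conditions}")
    c1, c2 = conditions
    rows = []
    for metric in REPORT_METRICS:
        for team in REPORT_TEAMS:
            cell = observations[
                (observations["metric"] == metric) & (observations["team"] == team)
            ]
            if cell.empty:
                continue
            va = cell.loc[cell["condition"] == c1, "value"].to_numpy(dtype=float)
            vb = cell.loc[cell["condition"] == c2, "value"].to_numpy(dtype=float)
            row = {
                "metric": metric,
                "team": team,
                f"mean_{c1}": va.mean() if len(va) else math.nan,
                f"sd_{c1}": va.std(ddof=1) if len(va) > 1 else math.nan,
                f"mean_{c2}": vb.mean() if len(vb) else math.nan,
                f"sd_{c2}": vb.std(ddof=1) if len(vb) > 1 else math.nan,
            }
            try:
                res = t_test(va, vb, cfg)
                row["p"] = res.p
                row["significant"] = res.p <= cfg.alpha
            except ValueError:
                row["p"] = math.nan
                row["significant"] = False
            rows.append(row)
    columns = [
        "metric", "team",
        f"mean_{c1}", f"sd_{c1}", f"mean_{c2}", f"sd_{c2}",
        "p", "significant",
    ]
    return pd.DataFrame(rows, columns=columns)
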