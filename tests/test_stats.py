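import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from courtgaze.stats import (
    StatConfig,
    anova_to_dataframe,
    mixed_anova_2x2,
    report_tables,
    t_test,
)
from courtgaze.synth import EffectConfig, generate_long_dataset


class TestTTest:
    def test_identical_samples_null(self):
        r = t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == 0.0
        assert r.p == pytest.approx(1.0)

    def test_large_shift_detected(self):
        a = [1.0, 2.0, 3.0]
        b = [11.0, 12.0, 13.0]
        r = t_test(a, b)
        # closed-form Welch t from means/sds
        expected_t = (np.mean(a) - np.mean(b)) / math.sqrt(
            np.var(a, ddof=1) / 3 + np.var(b, ddof=1) / 3
        )
        assert r.t == pytest.approx(expected_t)
        assert abs(r.t) > 10 and r.p < 0.001

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 2, 14)
        r1, r2 = t_test(a, b), t_test(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)
        assert r1.df == pytest.approx(r2.df)

    @pytest.mark.parametrize("variant", ["welch", "student"])
    def test_matches_reference_implementation(self, variant):
        rng = np.random.default_rng(5)
        cfg = StatConfig(t_variant=variant)
        for _ in range(25):
            a = rng.normal(0, 1, int(rng.integers(3, 20)))
            b = rng.normal(0.3, 1.7, int(rng.integers(3, 20)))
            r = t_test(a, b, cfg)
            ref = sps.ttest_ind(a, b, equal_var=(variant == "student"))
            assert r.t == pytest.approx(ref.statistic, abs=1e-10)
            assert r.p == pytest.approx(ref.pvalue, abs=1e-10)
            assert r.df == pytest.approx(ref.df, abs=1e-10)

    def test_degenerate_inputs_named(self):
        with pytest.raises(ValueError, match="at least 2"):
            t_test([1.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="zero variance"):
            t_test([1.0, 1.0], [2.0, 2.0])


def long_data(values_by_cell, n_per_group):
    """values_by_cell[(coach, phase)] -> per-subject values."""
    rows = []
    sid = 0
    for coach in ("A", "B"):
        for s in range(n_per_group):
            for phase in ("attack", "defense"):
                rows.append(
                    {
                        "subject_id": sid,
                        "coach": coach,
                        "phase": phase,
                        "value": values_by_cell[(coach, phase)][s],
                    }
                )
            sid += 1
    return pd.DataFrame(rows)


def brute_force_mixed_ss(df):
    """Cell/subject-means SS oracle for the 2x2 mixed design."""
    wide = df.pivot_table(index=["subject_id", "coach"], columns="phase", values="value")
    y = wide.to_numpy()
    groups = wide.index.get_level_values("coach").to_numpy()
    grand = y.mean()
    ss = {}
    levels = sorted(set(groups))
    ss["group"] = sum(
        2 * (y[groups == g].size // 2) * (y[groups == g].mean() - grand) ** 2
        for g in levels
    )
    ss["subj"] = sum(
        2 * (y[i].mean() - y[groups == groups[i]].mean()) ** 2 for i in range(len(y))
    )
    ss["phase"] = sum(len(y) * (y[:, j].mean() - grand) ** 2 for j in range(2))
    ss["inter"] = sum(
        (groups == g).sum()
        * (
            y[groups == g][:, j].mean()
            - y[groups == g].mean()
            - y[:, j].mean()
            + grand
        )
        ** 2
        for g in levels
        for j in range(2)
    )
    ss["total"] = ((y - grand) ** 2).sum()
    ss["werr"] = ss["total"] - ss["group"] - ss["subj"] - ss["phase"] - ss["inter"]
    return ss


class TestMixedAnova:
    def test_all_equal_degenerate(self):
        df = long_data(
            {(c, p): [5.0] * 4 for c in "AB" for p in ("attack", "defense")}, 4
        )
        r = mixed_anova_2x2(df)
        for eff in (r.between, r.within, r.interaction):
            assert eff.degenerate
            assert eff.F == 0.0 and eff.p == 1.0

    def test_pure_interaction_dominates_and_df(self):
        # opposite phase shifts per coach group, near-zero noise
        rng = np.random.default_rng(4)
        n = 8
        eps = 1e-6
        cells = {
            ("A", "attack"): 1.0 + eps * rng.normal(size=n),
            ("A", "defense"): -1.0 + eps * rng.normal(size=n),
            ("B", "attack"): -1.0 + eps * rng.normal(size=n),
            ("B", "defense"): 1.0 + eps * rng.normal(size=n),
        }
        r = mixed_anova_2x2(long_data(cells, n))
        assert r.n_subjects == 16
        assert r.within.df_den == 14  # N_subjects - 2
        assert r.interaction.df_den == 14
        assert r.interaction.F > 1e6 * max(r.within.F, 1.0)
        ss = brute_force_mixed_ss(long_data(cells, n))
        assert r.interaction.ss_effect == pytest.approx(ss["inter"], rel=1e-9)

    def test_matches_ss_oracle_on_random_instances(self):
        rng = np.random.default_rng(29)
        for _ in range(20):
            n = int(rng.integers(2, 20))  # up to 40 subjects
            cells = {
                (c, p): rng.normal(rng.normal(), 1.0, n)
                for c in "AB"
                for p in ("attack", "defense")
            }
            df = long_data(cells, n)
            r = mixed_anova_2x2(df)
            ss = brute_force_mixed_ss(df)
            assert r.between.ss_effect == pytest.approx(ss["group"], rel=1e-9)
            assert r.between.ss_error == pytest.approx(ss["subj"], rel=1e-9)
            assert r.within.ss_effect == pytest.approx(ss["phase"], rel=1e-9)
            assert r.interaction.ss_effect == pytest.approx(ss["inter"], rel=1e-9)
            assert r.within.ss_error == pytest.approx(ss["werr"], rel=1e-9, abs=1e-12)

    def test_matches_reference_mixed_anova(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(29)
        df = generate_long_dataset(EffectConfig(phase_shift_sd=0.5), rng)
        r = mixed_anova_2x2(df)
        ref = pg.mixed_anova(
            data=df, dv="value", within="phase", subject="subject_id", between="coach"
        ).set_index("Source")
        assert r.between.F == pytest.approx(ref.loc["coach", "F"], abs=1e-8)
        assert r.within.F == pytest.approx(ref.loc["phase", "F"], abs=1e-8)
        assert r.interaction.F == pytest.approx(ref.loc["Interaction", "F"], abs=1e-8)
        assert r.within.p == pytest.approx(ref.loc["phase", "p_unc"], abs=1e-8)

    def test_unbalanced_within_rejected(self):
        df = long_data(
            {(c, p): [1.0, 2.0] for c in "AB" for p in ("attack", "defense")}, 2
        )
        df = df.drop(index=0)
        with pytest.raises(ValueError, match="missing a phase|unbalanced"):
            mixed_anova_2x2(df)

    def test_anova_dataframe_shape(self):
        rng = np.random.default_rng(7)
        df = generate_long_dataset(EffectConfig(), rng)
        adf = anova_to_dataframe(mixed_anova_2x2(df))
        assert list(adf["effect"]) == ["between", "within", "interaction"]
        assert (adf["df_num"] == 1).all()


def make_observations(rng, n=6):
    rows = []
    for metric in ("DIA", "GAZE"):
        for team in ("Team A", "Team B", "Total"):
            base = 4.0 if metric == "DIA" else 50.0
            for cond in ("attack", "defense"):
                shift = 0.5 if cond == "defense" else 0.0
                for _ in range(n):
                    rows.append(
                        {
                            "metric": metric,
                            "team": team,
                            "condition": cond,
                            "value": base + shift + rng.normal(0, 0.3),
                        }
                    )
    return pd.DataFrame(rows)


class TestReportTables:
    def test_six_rows_layout(self):
        rng = np.random.default_rng(31)
        table = report_tables(make_observations(rng))
        assert len(table) == 6  # DIA/GAZE x Team A/Team B/Total
        assert {"p", "significant"} <= set(table.columns)

    def test_empty_observations_header_only(self):
        empty = pd.DataFrame(columns=["metric", "team", "condition", "value"])
        empty["condition"] = pd.Series(dtype=str)
        with pytest.raises(ValueError, match="2 conditions"):
            report_tables(empty)
        two = pd.DataFrame(
            {
                "metric": ["DIA", "DIA"],
                "team": ["Team A", "Team A"],
                "condition": ["attack", "defense"],
                "value": [1.0, 2.0],
            }
        )
        table = report_tables(two)  # one value per side: emitted with NaN p
        assert len(table) == 1
        assert math.isnan(table["p"].iloc[0])

    def test_round_trip_values(self, tmp_path):
        rng = np.random.default_rng(33)
        obs = make_observations(rng)
        table = report_tables(obs)
        p = tmp_path / "report.csv"
        table.to_csv(p, index=False)
        back = pd.read_csv(p)
        for col in table.columns:
            if back[col].dtype.kind == "f":
                assert np.allclose(back[col], table[col], equal_nan=True)
        # means in the table equal the input cell means
        cell = obs[(obs.metric == "DIA") & (obs.team == "Team A") & (obs.condition == "attack")]
        row = back[(back.metric == "DIA") & (back.team == "Team A")].iloc[0]
        assert row["mean_attack"] == pytest.approx(cell["value"].mean())
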