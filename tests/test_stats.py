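"""Statistical layer: within-subject ANOVA, Wilcoxon, correlation, t test, outlier rule."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from actionselect.stats import (
    DegenerateDataError,
    anova_rm,
    outlier_sensitivity,
    pearson_r,
    two_sample_t,
    wilcoxon_signed_rank,
)


def brute_force_rm_f(df, dv="y"):
    """Independent oracle: within-subject F values from sequential OLS
    residual sums over dummy-coded nested models (balanced design)."""

    def dummies(values):
        levels = sorted(pd.unique(values))
        return np.column_stack([(values == lv).astype(float) for lv in levels[1:]])

    def interact(A, B):
        return np.column_stack([a * b for a, b in itertools.product(A.T, B.T)]) if A.size and B.size else np.empty((len(A), 0))

    y = df[dv].to_numpy(float)
    one = np.ones((len(df), 1))
    S = dummies(df["subject"].to_numpy())
    A = dummies(df["condition"].to_numpy())
    B = dummies(df["day"].to_numpy())
    AB = interact(A, B)
    AS = interact(A, S)
    BS = interact(B, S)

    def rss(*parts):
        X = np.hstack([one, *parts])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    ss_a = rss(S) - rss(S, A)
    ss_b = rss(S, A) - rss(S, A, B)
    ss_ab = rss(S, A, B) - rss(S, A, B, AB)
    ss_as = rss(S, A, B, AB) - rss(S, A, B, AB, AS)
    ss_bs = rss(S, A, B, AB, AS) - rss(S, A, B, AB, AS, BS)
    ss_res = rss(S, A, B, AB, AS, BS)
    s, a, b = df["subject"].nunique(), df["condition"].nunique(), df["day"].nunique()
    df_a, df_b, df_ab = a - 1, b - 1, (a - 1) * (b - 1)
    df_as, df_bs, df_res = df_a * (s - 1), df_b * (s - 1), df_ab * (s - 1)
    return {
        "condition": (ss_a / df_a) / (ss_as / df_as),
        "day": (ss_b / df_b) / (ss_bs / df_bs),
        "condition:day": (ss_ab / df_ab) / (ss_res / df_res),
    }


def random_design(rng, s=6, a=2, b=4):
    rows = [
        {"subject": i, "condition": c, "day": d, "y": rng.normal()}
        for i in range(s)
        for c in range(a)
        for d in range(b)
    ]
    return pd.DataFrame(rows)


class TestAnovaRm:
    def test_matches_brute_force_oracle_on_random_designs(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            df = random_design(rng)
            mine = anova_rm(df, "y")
            oracle = brute_force_rm_f(df)
            for eff, f_ref in oracle.items():
                assert mine.F(eff) == pytest.approx(f_ref, abs=1e-8)

    def test_matches_statsmodels(self):
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(7)
        df = random_design(rng, s=8)
        mine = anova_rm(df, "y")
        ref = AnovaRM(df, "y", "subject", within=["condition", "day"]).fit().anova_table
        for eff in ("condition", "day", "condition:day"):
            assert mine.F(eff) == pytest.approx(ref.loc[eff, "F Value"], rel=1e-10)
            assert mine.p(eff) == pytest.approx(ref.loc[eff, "Pr > F"], rel=1e-8)

    def test_additive_cells_give_zero_interaction(self):
        rows = []
        for s in range(5):
            for c in range(2):
                for d in range(4):
                    rows.append(
                        {"subject": s, "condition": c, "day": d, "y": 1.0 * c + 0.5 * d + 0.1 * s}
                    )
        res = anova_rm(pd.DataFrame(rows), "y")
        assert res.effect("condition:day")["ss"] == pytest.approx(0.0, abs=1e-12)
        assert res.F("condition:day") == 0.0

    def test_constant_dv_all_zero_ss(self):
        df = random_design(np.random.default_rng(0))
        df["y"] = 3.14
        res = anova_rm(df, "y")
        assert (res.table["ss"] < 1e-12).all()

    def test_missing_cell_names_offender(self):
        df = random_design(np.random.default_rng(1))
        df = df[~((df["subject"] == 2) & (df["condition"] == 1) & (df["day"] == 3))]
        with pytest.raises(ValueError, match="2"):
            anova_rm(df, "y")

    def test_single_factor_day_effect(self):
        rng = np.random.default_rng(3)
        rows = [
            {"subject": s, "day": d, "rt_cost": 0.5 - 0.05 * d + rng.normal(0, 0.02)}
            for s in range(8)
            for d in (1, 2, 3, 4)
        ]
        res = anova_rm(pd.DataFrame(rows), "rt_cost", factors=("day",))
        assert res.effect("day")["df"] == 3
        assert res.effect("day")["error_df"] == 21
        assert res.p("day") < 0.001

    def test_gg_epsilon_bounds(self):
        df = random_design(np.random.default_rng(5), s=10)
        res = anova_rm(df, "y", gg_correction=True)
        day = res.effect("day")
        assert 1 / 3 - 1e-9 <= day["gg_epsilon"] <= 1.0
        assert day["p_gg"] >= day["p"] - 1e-12


class TestWilcoxon:
    def test_three_positive_differences_exact_quarter(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert res.method == "wilcoxon-exact"
        assert res.p_two_sided == pytest.approx(0.25)

    def test_identical_samples_degenerate(self):
        with pytest.raises(DegenerateDataError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    def test_exact_matches_scipy_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(3, 13))
            a = rng.normal(0.4, 1.0, n)
            d = a  # vs zeros
            if np.any(d == 0) or len(np.unique(np.abs(d))) < n:
                continue
            mine = wilcoxon_signed_rank(a, np.zeros(n), mode="exact")
            ref = sps.wilcoxon(a, mode="exact")
            assert mine.p_two_sided == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approx_close_to_exact_at_n12(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = rng.normal(0.5, 1.0, 12)
            exact = wilcoxon_signed_rank(a, np.zeros(12), mode="exact")
            approx = wilcoxon_signed_rank(a, np.zeros(12), mode="approx")
            assert abs(approx.p_two_sided - exact.p_two_sided) < 0.02

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        st.lists(
            st.floats(-5, 5).filter(lambda v: abs(v) > 1e-6),
            min_size=3,
            max_size=10,
        )
    )
    def test_sign_flip_symmetry(self, diffs):
        a = np.asarray(diffs)
        p1 = wilcoxon_signed_rank(a, np.zeros_like(a), mode="exact").p_two_sided
        p2 = wilcoxon_signed_rank(-a, np.zeros_like(a), mode="exact").p_two_sided
        assert p1 == pytest.approx(p2)

    def test_large_n_uses_approx(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.3, 1.0, 30)
        assert wilcoxon_signed_rank(a, np.zeros(30)).method == "wilcoxon-approx"


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1).statistic == pytest.approx(1.0)
        assert pearson_r(x, -x).statistic == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        x = np.array([1.0, 2.0, 4.0, 4.5, 7.0, 9.0])
        y = np.array([0.3, 0.1, 0.8, 0.9, 0.6, 1.4])
        r = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert pearson_r(x, y).statistic == pytest.approx(r, abs=1e-12)

    def test_zero_variance_degenerate(self):
        with pytest.raises(DegenerateDataError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestTwoSampleT:
    def test_identical_groups(self):
        res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_two_sided == pytest.approx(1.0)

    def test_pooled_matches_hand_formula(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        sp2 = (a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / 4
        t_ref = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        res = two_sample_t(a, b, variant="pooled")
        assert res.statistic == pytest.approx(t_ref, abs=1e-10)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0, 2.0], [3.0, 4.0], variant="student")

    def test_constant_unequal_groups_degenerate(self):
        with pytest.raises(DegenerateDataError):
            two_sample_t([1.0, 1.0], [2.0, 2.0])


class TestOutlierRule:
    def test_single_extreme_subject_flagged(self):
        values = pd.Series({i: 0.3 for i in range(15)} | {15: 3.0})
        report = outlier_sensitivity(values, analysis=lambda kept: len(kept))
        assert report.flagged == [15]
        assert report.original == 16 and report.reanalysis == 15

    def test_no_outlier_reuses_original(self):
        values = pd.Series({i: v for i, v in enumerate([0.3, 0.4, 0.5, 0.45, 0.35])})
        calls = []

        def analysis(kept):
            calls.append(tuple(kept))
            return "result"

        report = outlier_sensitivity(values, analysis)
        assert report.flagged == []
        assert report.reanalysis is report.original
        assert len(calls) == 1

    def test_rule_is_one_sided_high_by_default(self):
        values = pd.Series({0: -3.0} | {i: 0.3 for i in range(1, 16)})
        assert outlier_sensitivity(values, lambda k: None).flagged == []
        assert outlier_sensitivity(values, lambda k: None, two_sided=True).flagged == [0]
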