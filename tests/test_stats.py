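"""Nested ANOVA / Tukey: exact equivalences, calibration, power."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import cryptmorph as cm
from cryptmorph.stats import (
    DesignError,
    depth_twoway_anova,
    per_cohort_depth_tests,
    per_depth_cohort_tests,
    simulate_depth_table,
    simulate_nested_table,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


class TestNestedOneWay:
    def test_balanced_equals_oneway_on_mouse_means(self, rng):
        """For balanced nesting the image-level nested F is the mouse-mean F."""
        tab = simulate_nested_table(rng, n_cohorts=4, mice_per_cohort=3,
                                    images_per_mouse=6)
        res = cm.nested_oneway_anova(tab)
        mm = tab.groupby(["cohort", "mouse"])["value"].mean()
        groups = [mm[c].to_numpy() for c in sorted(tab["cohort"].unique())]
        ref = sps.f_oneway(*groups)
        t = res["cohort"]
        assert t.F == pytest.approx(ref.statistic, rel=1e-10)
        assert t.p == pytest.approx(ref.pvalue, rel=1e-10)
        assert (t.df_num, t.df_den) == (3, 8)

    def test_identical_responses_degenerate(self):
        tab = pd.DataFrame(
            dict(cohort=list("aabb") * 2, mouse=["m1", "m2"] * 4, value=3.0)
        )
        res = cm.nested_oneway_anova(tab)
        assert res.degenerate and np.isnan(res["cohort"].p)

    def test_single_mouse_cohort_errors(self):
        tab = pd.DataFrame(
            dict(
                cohort=["a", "a", "a", "b", "b"],
                mouse=["m1", "m2", "m2", "m1", "m1"],
                value=[1.0, 2.0, 3.0, 4.0, 5.0],
            )
        )
        with pytest.raises(DesignError, match="single mouse"):
            cm.nested_oneway_anova(tab)

    def test_mouse_ids_scoped_within_cohort(self, rng):
        """Reusing mouse labels across cohorts must not merge strata."""
        tab = simulate_nested_table(rng, 3, 4, 5)  # mouse ids m0..m3 per cohort
        res = cm.nested_oneway_anova(tab)
        assert res["cohort"].df_den == 3 * 4 - 3

    def test_unbalanced_strata_sum_to_total(self, rng):
        tab = simulate_nested_table(rng, 3, 4, 5).iloc[:-7]
        res = cm.nested_oneway_anova(tab)
        vals = tab["value"].iloc[: len(tab)]
        ss_total = float(((vals - vals.mean()) ** 2).sum())
        assert sum(ss for ss, _ in res.strata.values()) == pytest.approx(ss_total)

    def test_permutation_p_agrees_with_anova(self, rng):
        """Cohort-label permutation p is close to the parametric p."""
        tab = simulate_nested_table(rng, 4, 6, 4, cohort_effects={0: 0.8})
        obs = cm.nested_oneway_anova(tab)["cohort"].F
        mice = tab[["cohort", "mouse"]].drop_duplicates().reset_index(drop=True)
        count = 0
        n_perm = 500
        for _ in range(n_perm):
            perm = mice.copy()
            perm["new_cohort"] = rng.permutation(perm["cohort"].to_numpy())
            merged = tab.merge(perm, on=["cohort", "mouse"])
            merged = merged.drop(columns="cohort").rename(
                columns={"new_cohort": "cohort"}
            )
            if cm.nested_oneway_anova(merged)["cohort"].F >= obs:
                count += 1
        p_perm = (count + 1) / (n_perm + 1)
        assert abs(p_perm - cm.nested_oneway_anova(tab)["cohort"].p) < 0.05


class TestTukey:
    def test_two_groups_equal_pooled_t_test(self, rng):
        tab = simulate_nested_table(rng, 2, 5, 4)
        tk = cm.tukey_posthoc(tab)
        mm = tab.groupby(["cohort", "mouse"])["value"].mean()
        t_ref = sps.ttest_ind(mm["c0"], mm["c1"])
        (c,) = tk.comparisons
        assert c.q == pytest.approx(abs(t_ref.statistic) * np.sqrt(2), rel=1e-9)
        assert c.p_adj == pytest.approx(t_ref.pvalue, rel=1e-9)

    def test_identical_group_means_all_ns(self):
        tab = pd.DataFrame(
            dict(
                cohort=np.repeat(["a", "b", "c"], 4),
                mouse=np.tile(["m1", "m1", "m2", "m2"], 3),
                value=np.tile([1.0, 2.0, 3.0, 4.0], 3),
            )
        )
        tk = cm.tukey_posthoc(tab)
        assert all(c.flag == "ns" for c in tk.comparisons)
        assert all(c.mean_diff == 0 for c in tk.comparisons)

    def test_adjusted_p_not_below_unadjusted(self, rng):
        """For >2 groups the studentized-range p dominates the pooled-t p."""
        tab = simulate_nested_table(rng, 4, 4, 5, cohort_effects={0: 1.0})
        tk = cm.tukey_posthoc(tab)
        for c in tk.comparisons:
            p_unadj = 2 * sps.t.sf(c.q / np.sqrt(2), tk.df_error)
            assert c.p_adj >= p_unadj - 1e-12

    def test_matches_statsmodels_on_mouse_means(self, rng):
        statsmodels = pytest.importorskip("statsmodels.stats.multicomp")
        tab = simulate_nested_table(rng, 3, 6, 4, cohort_effects={1: 1.0})
        mm = tab.groupby(["cohort", "mouse"])["value"].mean().reset_index()
        ref = statsmodels.pairwise_tukeyhsd(mm["value"], mm["cohort"])
        tk = cm.tukey_posthoc(tab)
        got = {frozenset((c.group_i, c.group_j)): c.p_adj for c in tk.comparisons}
        for row, p_ref in zip(ref._results_table.data[1:], ref.pvalues):
            assert got[frozenset((str(row[0]), str(row[1])))] == pytest.approx(
                p_ref, abs=1e-6
            )

    def test_flag_convention(self):
        assert cm.significance_flag(0.03) == "*"
        assert cm.significance_flag(0.005) == "**"
        assert cm.significance_flag(0.2) == "ns"
        assert cm.significance_flag(float("nan")) == "ns"


class TestDepthTwoWay:
    def test_single_depth_reduces_to_nested_oneway(self, rng):
        tab = simulate_depth_table(rng)
        sub = tab[tab["depth_um"] == 60.0]
        res = depth_twoway_anova(sub)
        ref = cm.nested_oneway_anova(sub)
        assert [f.name for f in res.factors] == ["cohort"]
        assert res["cohort"].F == pytest.approx(ref["cohort"].F)

    def test_missing_depth_plane_listed(self, rng):
        tab = simulate_depth_table(rng)
        broken = tab.drop(
            tab[
                (tab["cohort"] == "c0") & (tab["mouse"] == "m0")
                & (tab["stack"] == "s0") & (tab["depth_um"] == 60.0)
            ].index
        )
        with pytest.raises(DesignError, match="c0/m0/s0"):
            depth_twoway_anova(broken)

    def test_strata_decompose_total_ss(self, rng):
        tab = simulate_depth_table(rng)
        res = depth_twoway_anova(tab)
        v = tab["value"]
        ss_total = float(((v - v.mean()) ** 2).sum())
        assert sum(ss for ss, _ in res.strata.values()) == pytest.approx(ss_total)
        n = len(tab)
        assert sum(df for _, df in res.strata.values()) == n - 1

    def test_null_depth_rejection_near_alpha(self, rng):
        reps, rej = 1200, 0
        for _ in range(reps):
            res = depth_twoway_anova(simulate_depth_table(rng))
            if res["depth"].p < 0.05:
                rej += 1
        assert 0.03 <= rej / reps <= 0.07

    def test_localized_shift_detected_with_power(self, rng):
        """A 2-SD cohort shift at one depth is caught by that depth's contrast."""
        sd_tot = np.hypot(np.hypot(0.5, 0.3), 1.0)
        detected = 0
        reps = 120
        for _ in range(reps):
            tab = simulate_depth_table(
                rng, shift=2 * sd_tot, shift_cohort=0, shift_depth=40.0
            )
            _, tukey40 = per_depth_cohort_tests(tab)[40.0]
            if any(
                c.flag != "ns" and "c0" in (c.group_i, c.group_j)
                for c in tukey40.comparisons
            ):
                detected += 1
        assert detected / reps > 0.8

    def test_per_cohort_depth_contrasts(self, rng):
        tab = simulate_depth_table(rng, n_cohorts=2)
        out = per_cohort_depth_tests(tab)
        assert set(out) == {"c0", "c1"}
        anova, tukey = out["c0"]
        assert anova["depth"].df_num == 4
        assert len(tukey.comparisons) == 10  # 5 choose 2 depth pairs


class TestFeatureScreen:
    def _summaries(self, rng):
        rows = []
        for c in range(3):
            for m in range(3):
                for i in range(3):
                    row = dict(cohort=f"c{c}", mouse=f"m{m}", image=i)
                    for feat in cm.FEATURE_COLUMNS:
                        row[f"{feat}_mean"] = rng.normal()
                        row[f"{feat}_sd"] = abs(rng.normal())
                    rows.append(row)
        return pd.DataFrame(rows)

    def test_fourteen_screen_rows(self, rng):
        anova_df, tukey_df = cm.run_feature_screen(self._summaries(rng))
        assert len(anova_df) == 14  # 7 features x {mean, sd}
        assert len(tukey_df) == 14 * 3  # 3 cohorts -> 3 pairs each

    def test_screen_deterministic(self, rng):
        s = self._summaries(rng)
        a1, t1 = cm.run_feature_screen(s)
        a2, t2 = cm.run_feature_screen(s)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_null_screen_flag_rate_near_alpha(self):
        rng = np.random.default_rng(7)
        flags = total = 0
        for _ in range(40):
            _, tukey_df = cm.run_feature_screen(self._summaries(rng))
            flags += int((tukey_df["flag"] != "ns").sum())
            total += len(tukey_df)
        # Tukey protects the familywise rate per screen, so the per-pair
        # rate under the null sits at or below alpha
        assert flags / total <= 0.07
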