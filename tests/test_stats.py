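"""Group statistics: branch selection, post hocs, regressions, BH."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from propriomap.stats import (
    bh_correct, choose_and_run_anova, compare_metric_by_impairment,
    compare_taskscores_by_lesion, regress_metric_on_taskscore,
    regression_table, sidak_adjust,
)


class TestAnovaBranching:
    def test_identical_groups_give_f_zero_p_one(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        res = choose_and_run_anova({"a": g, "b": g.copy()})
        assert res.F == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_classical_branch_matches_reference_anova(self):
        rng = np.random.default_rng(0)
        groups = {k: rng.normal(i * 0.5, 1.0, 12) for i, k in enumerate("abc")}
        res = choose_and_run_anova(groups)
        ref = sps.f_oneway(*groups.values())
        assert res.method == "anova_sidak"
        assert res.F == pytest.approx(ref.statistic, abs=1e-6)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-6)

    def test_unequal_variances_select_welch(self):
        rng = np.random.default_rng(1)
        groups = {
            "a": rng.normal(0, 1, 15),
            "b": rng.normal(0, 10, 15),
            "c": rng.normal(0, 1, 15),
        }
        res = choose_and_run_anova(groups)
        assert res.method == "welch_games_howell"
        assert res.levene_p < 0.05
        # Welch denominator df never exceeds the classical one
        assert res.df2 <= 42

    def test_welch_f_equals_classical_f_under_equal_variances(self):
        """With equal group variances and sizes, Welch's F equals the
        classical F divided by its small-sample denominator correction;
        the two agree in the large-n limit."""
        rng = np.random.default_rng(2)
        k, n = 3, 12
        raw = [rng.normal(m, 1.0, n) for m in (0.0, 0.4, 0.9)]
        # force exactly equal sample variances
        groups = [(g - g.mean()) / g.std(ddof=1) + g.mean() for g in raw]
        res = choose_and_run_anova(
            {c: g for c, g in zip("abc", groups)}, method="welch"
        )
        classical = sps.f_oneway(*groups).statistic
        w = np.array([n / g.var(ddof=1) for g in groups])
        correction = 1.0 + (2.0 * (k - 2) / (k**2 - 1)) * sum(
            (1 - wi / w.sum()) ** 2 / (n - 1) for wi in w
        )
        assert res.F == pytest.approx(classical / correction, abs=1e-6)
        # and the correction vanishes with n
        big = [rng.normal(m, 1.0, 4000) for m in (0.0, 0.05, 0.1)]
        big = [(g - g.mean()) / g.std(ddof=1) + g.mean() for g in big]
        res_big = choose_and_run_anova({c: g for c, g in zip("abc", big)}, method="welch")
        assert res_big.F == pytest.approx(sps.f_oneway(*big).statistic, rel=2e-3)

    def test_games_howell_two_groups_equals_welch_t(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 12), rng.normal(1, 3, 9)
        res = choose_and_run_anova({"a": a, "b": b}, method="welch")
        welch_t = sps.ttest_ind(a, b, equal_var=False)
        assert res.posthoc["p_adj"].iloc[0] == pytest.approx(welch_t.pvalue, abs=1e-9)

    def test_single_observation_group_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            choose_and_run_anova({"a": np.array([1.0]), "b": np.array([1.0, 2.0])})


class TestSidak:
    @given(st.floats(0, 1), st.floats(0, 1), st.integers(1, 20))
    @settings(derandomize=True, max_examples=100)
    def test_monotone_and_bounded_by_bonferroni(self, p1, p2, m):
        lo, hi = sorted((p1, p2))
        assert sidak_adjust(lo, m) <= sidak_adjust(hi, m)
        assert sidak_adjust(p1, m) <= min(1.0, m * p1) + 1e-12


class TestLesionGroupComparisons:
    def test_planted_coupling_separates_lesioned_from_controls(self, study, study_scores):
        from propriomap.synthetic import TRACTS
        from propriomap.tracts import (
            MaskVolume, assign_lesion_groups, lesion_overlap, overlaps_to_frame,
        )
        vox = study.config.grid.voxel_size_mm
        results = []
        for pid in study.stroke_ids:
            hemi = study.demographics[pid].lesioned_hemisphere
            lesion = MaskVolume(study.lesion_masks[pid], vox)
            for tract in TRACTS:
                from propriomap.tracts import build_template
                tpl = build_template(
                    [MaskVolume(m, vox) for m in study.control_tract_masks[(tract, hemi)]],
                    study.config.agreement_k, tract=tract, hemisphere=hemi,
                )
                results.append(lesion_overlap(tpl, lesion, pid))
        groups = assign_lesion_groups(overlaps_to_frame(results))
        res = compare_taskscores_by_lesion(
            study_scores["task_score"], groups, study.control_ids, "AF"
        )
        task = study_scores["task_score"]
        lesioned_ids = groups[(groups["tract"] == "AF") & groups["lesioned"]]["participant"]
        assert task.loc[lesioned_ids].mean() > task.loc[study.control_ids].mean()
        pair = res.posthoc[
            res.posthoc[["A", "B"]].apply(set, axis=1) == {"lesioned", "control"}
        ]
        assert float(pair["p_adj"].iloc[0]) < 0.05

    def test_empty_group_rejected(self, study_scores, study):
        groups = pd.DataFrame(
            [
                {"participant": p, "tract": "AF", "lesioned": True}
                for p in study.stroke_ids
            ]
        )
        with pytest.raises(ValueError, match="empty group"):
            compare_taskscores_by_lesion(
                study_scores["task_score"], groups, study.control_ids, "AF"
            )

    def test_null_rejection_rate_near_alpha(self):
        """Zero lesion-deficit coupling: the 3-group comparison rejects at
        roughly the nominal rate across 200 null replicates."""
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 200
        for _ in range(reps):
            groups = {
                "lesioned": rng.normal(1.0, 0.8, 8),
                "non_lesioned": rng.normal(1.0, 0.8, 18),
                "control": rng.normal(1.0, 0.8, 7),
            }
            res = choose_and_run_anova(groups)
            rejections += res.p < 0.05
        assert rejections / reps <= 1.5 * 0.05


class TestMetricByImpairment:
    @staticmethod
    def make_metric(fa_by_group):
        rng = np.random.default_rng(11)
        rows, impaired = [], {}
        pid = 0
        for imp in (True, False):
            for _ in range(8):
                p = f"S{pid:03d}"; pid += 1
                impaired[p] = imp
                for role in ("lesioned", "non_lesioned"):
                    rows.append({
                        "participant": p, "tract": "AF", "hemisphere": "R",
                        "hemisphere_role": role,
                        "FA": fa_by_group[("impaired" if imp else "unimpaired", role)]
                        + rng.normal(0, 0.01),
                    })
        controls = []
        for _ in range(7):
            p = f"C{pid:03d}"; pid += 1
            controls.append(p)
            impaired[p] = False
            for hemi in ("L", "R"):
                rows.append({
                    "participant": p, "tract": "AF", "hemisphere": hemi,
                    "hemisphere_role": hemi,
                    "FA": fa_by_group["control"] + rng.normal(0, 0.01),
                })
        return pd.DataFrame(rows), pd.Series(impaired), controls

    def test_planted_decrement_gives_lowest_group_mean(self):
        fa = {
            ("impaired", "lesioned"): 0.35,
            ("impaired", "non_lesioned"): 0.45,
            ("unimpaired", "lesioned"): 0.45,
            ("unimpaired", "non_lesioned"): 0.45,
            "control": 0.45,
        }
        metric, impaired, controls = self.make_metric(fa)
        res = compare_metric_by_impairment(metric, impaired, controls, "AF")
        assert res.p < 0.01
        means = {
            g: metric[metric["hemisphere_role"].eq(r) & metric["participant"].isin(
                [p for p in impaired.index if impaired[p] == i and p not in controls]
            )]["FA"].mean()
            for g, (i, r) in {
                "imp_les": (True, "lesioned"), "imp_non": (True, "non_lesioned"),
            }.items()
        }
        assert means["imp_les"] < means["imp_non"]

    def test_null_control_hemispheres_not_different(self):
        fa = {k: 0.45 for k in (
            ("impaired", "lesioned"), ("impaired", "non_lesioned"),
            ("unimpaired", "lesioned"), ("unimpaired", "non_lesioned"))}
        fa["control"] = 0.45
        metric, impaired, controls = self.make_metric(fa)
        res = compare_metric_by_impairment(metric, impaired, controls, "AF")
        pair = res.posthoc[
            res.posthoc[["A", "B"]].apply(set, axis=1) == {"control_L", "control_R"}
        ]
        assert float(pair["p_adj"].iloc[0]) > 0.05

    def test_missing_hemisphere_rejected(self):
        fa = {k: 0.45 for k in (
            ("impaired", "lesioned"), ("impaired", "non_lesioned"),
            ("unimpaired", "lesioned"), ("unimpaired", "non_lesioned"))}
        fa["control"] = 0.45
        metric, impaired, controls = self.make_metric(fa)
        metric = metric[metric["hemisphere_role"] != "L"]
        with pytest.raises(ValueError, match="missing hemisphere"):
            compare_metric_by_impairment(metric, impaired, controls, "AF")


class TestRegression:
    def test_planted_slope_recovered_within_2se(self):
        rng = np.random.default_rng(5)
        fa = rng.normal(0.45, 0.05, 26)
        task = 12.0 - 20.0 * fa + rng.normal(0, 1, 26)
        res = regress_metric_on_taskscore(fa, task, "FA_AF")
        se = 1.0 / (fa.std() * np.sqrt(26))
        assert abs(res.slope - (-20.0)) < 2 * se

    def test_null_slope_p_uniform(self):
        rng = np.random.default_rng(6)
        ps = []
        for _ in range(200):
            x = rng.normal(0, 1, 26)
            y = rng.normal(0, 1, 26)
            ps.append(regress_metric_on_taskscore(x, y).p)
        # uniformity: KS against U(0,1) should not reject wildly
        assert sps.kstest(ps, "uniform").pvalue > 0.01
        assert np.mean(np.array(ps) < 0.05) < 0.12

    def test_two_points_interpolate_with_flag(self):
        res = regress_metric_on_taskscore([0.0, 1.0], [1.0, 3.0])
        assert res.degenerate and np.isnan(res.p)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            regress_metric_on_taskscore([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_regression_table_families(self):
        rng = np.random.default_rng(8)
        rows = []
        pids = [f"S{i}" for i in range(26)]
        task = pd.Series(rng.normal(2, 1, 26), index=pids)
        for tract in ("AF", "MdLF"):
            for pid in pids:
                rows.append({
                    "participant": pid, "tract": tract,
                    "FA": rng.normal(0.45, 0.05),
                    "MD": rng.normal(7.5e-4, 5e-5),
                    "volume_mm3": rng.normal(12000, 2000),
                })
        tbl = regression_table(pd.DataFrame(rows), task)
        assert len(tbl) == 6  # 2 tracts x 3 metric families
        assert set(tbl["metric"]) == {"FA", "MD", "volume_mm3"}


class TestBH:
    def bh_bruteforce(self, ps, q):
        m = len(ps)
        order = np.argsort(ps)
        flags = np.zeros(m, dtype=bool)
        kmax = 0
        for rank, idx in enumerate(order, start=1):
            if ps[idx] <= q * rank / m:
                kmax = rank
        for rank, idx in enumerate(order, start=1):
            if rank <= kmax:
                flags[idx] = True
        return flags

    def test_all_ones_give_no_flags(self):
        assert not bh_correct([1.0] * 5).any()

    def test_worked_example_matches_stepup(self):
        ps = [0.001, 0.011, 0.012, 0.04, 0.2]
        assert np.array_equal(bh_correct(ps, 0.05), self.bh_bruteforce(ps, 0.05))

    def test_single_p_reduces_to_raw_comparison(self):
        assert bh_correct([0.04], 0.05)[0]
        assert not bh_correct([0.06], 0.05)[0]

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    @settings(derandomize=True, max_examples=80)
    def test_matches_bruteforce_enumeration(self, ps):
        assert np.array_equal(bh_correct(ps, 0.05), self.bh_bruteforce(ps, 0.05))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_correct([0.5, 1.2])
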