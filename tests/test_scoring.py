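"""Scoring chain: raw parameters, normative fit, z/zeta, Task Score."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from propriomap.scoring import (
    PARAMETERS, IMPAIRMENT_CUTOFF, NormativeModel, compute_parameter_scores,
    fit_normative_model, score_cohort, task_score, z_score_parameters,
    zeta_transform,
)
from propriomap.synthetic import (
    CovariateModel, DeficitProfile, Demographics, IDENTITY_PROFILE,
    gen_target_layout, simulate_exam, simulate_normative_cohort,
)

DEMO = Demographics(age=60.0, sex="F", handedness="R")
LAYOUT = gen_target_layout()


def make_exam(transform, rng_seed=0):
    """Identity exam whose *mirrored* matches are modified by ``transform``."""
    ex = simulate_exam(LAYOUT, IDENTITY_PROFILE, DEMO, np.random.default_rng(rng_seed))
    t = ex.trials
    mirrored = np.column_stack([-t["matched_x"], t["matched_y"]])
    new = np.apply_along_axis(transform, 1, mirrored)
    t["matched_x"], t["matched_y"] = -new[:, 0], new[:, 1]
    return ex


class TestParameterScores:
    def test_perfect_matching_is_all_zero_error(self):
        ex = simulate_exam(LAYOUT, IDENTITY_PROFILE, DEMO, np.random.default_rng(1))
        s = compute_parameter_scores(ex)
        assert s["abs_err_x"] == s["abs_err_y"] == 0
        assert s["var_x"] == s["var_y"] == 0
        assert s["shift_x"] == s["shift_y"] == 0
        assert s["contract_x"] == s["contract_y"] == 1

    def test_uniform_displacement_maps_to_shift_and_abs_err(self):
        ex = make_exam(lambda p: p + np.array([2.0, 0.0]))
        s = compute_parameter_scores(ex)
        assert s["shift_x"] == pytest.approx(2.0)
        assert s["abs_err_x"] == pytest.approx(2.0)
        assert s["var_x"] == pytest.approx(0.0, abs=1e-12)
        assert s["contract_x"] == pytest.approx(1.0)
        assert s["shift_y"] == pytest.approx(0.0, abs=1e-12)

    def test_scaling_about_centroid_maps_to_contraction(self):
        centroid = np.zeros(2)  # layout centred at origin
        ex = make_exam(lambda p: centroid + 0.5 * (p - centroid))
        s = compute_parameter_scores(ex)
        assert s["contract_x"] == pytest.approx(0.5)
        assert s["contract_y"] == pytest.approx(0.5)
        assert s["shift_x"] == pytest.approx(0.0, abs=1e-12)
        assert s["shift_y"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_bruteforce_recomputation(self):
        prof = DeficitProfile((0.8, 1.2), (0.8, 1.1), (1.5, -0.5), 0.05)
        ex = simulate_exam(LAYOUT, prof, DEMO, np.random.default_rng(3))
        s = compute_parameter_scores(ex)
        # independent per-trial / per-target loops
        rows = list(ex.trials.itertuples(index=False))
        for axis, tkey, mkey in (("x", "target_x", "matched_x"), ("y", "target_y", "matched_y")):
            mirrored = [
                (-getattr(r, mkey) if axis == "x" else getattr(r, mkey)) for r in rows
            ]
            targets = [getattr(r, tkey) for r in rows]
            errs = [m - t for m, t in zip(mirrored, targets)]
            assert s[f"abs_err_{axis}"] == pytest.approx(np.mean(np.abs(errs)))
            assert s[f"shift_{axis}"] == pytest.approx(np.mean(errs))
            by_target = {}
            for r, m in zip(rows, mirrored):
                by_target.setdefault(r.target_index, []).append(m)
            sds = [np.std(v, ddof=1) for v in by_target.values()]
            assert s[f"var_{axis}"] == pytest.approx(np.mean(sds))
            means = {k: np.mean(v) for k, v in by_target.items()}
            tmap = {r.target_index: getattr(r, tkey) for r in rows}
            expect = (max(means.values()) - min(means.values())) / (
                max(tmap.values()) - min(tmap.values())
            )
            assert s[f"contract_{axis}"] == pytest.approx(expect)

    def test_single_trial_per_target_rejected(self):
        ex = simulate_exam(LAYOUT, IDENTITY_PROFILE, DEMO, np.random.default_rng(4),
                           n_blocks=1)
        with pytest.raises(ValueError, match="2 trials"):
            compute_parameter_scores(ex)


class TestNormativeFit:
    def test_small_cohort_rejected(self):
        exams, _ = simulate_normative_cohort(50, rng=np.random.default_rng(0))
        with pytest.raises(ValueError, match="n >= 50"):
            fit_normative_model(exams[:10])

    def test_self_scoring_is_calibrated(self, norm_model):
        """On the fitting cohort itself z-scores are mean 0, SD 1 and the
        RSS stage is standard normal by construction."""
        exams, _ = simulate_normative_cohort(200, rng=np.random.default_rng(17))
        scores = score_cohort(exams, norm_model)
        for p in PARAMETERS:
            assert abs(scores[f"z_{p}"].mean()) < 0.05
            assert scores[f"z_{p}"].std() == pytest.approx(1.0, abs=0.05)
        assert (scores["task_score"] < IMPAIRMENT_CUTOFF).mean() > 0.9

    def test_zero_covariate_cohort_has_small_age_coefficient(self):
        cov = CovariateModel(age_noise_slope=0.0, sex_noise_delta=0.0)
        exams, _ = simulate_normative_cohort(300, cov, np.random.default_rng(8))
        model = fit_normative_model(exams)
        assert abs(model.parameters["var_x"].coefficients["age"]) < 0.004

    def test_planted_age_coefficient_recovered(self):
        """Age slope on matching noise propagates into the variability
        parameter's fitted age coefficient (within 2 SE at n=500)."""
        slope = 0.02
        # lapse-free so the planted slope is exactly c4 * slope
        cov = CovariateModel(age_noise_slope=slope, lapse_rate=0.0)
        exams, _ = simulate_normative_cohort(500, cov, np.random.default_rng(9))
        model = fit_normative_model(exams)
        # var_x estimates the per-axis noise SD scaled by the finite-sample
        # SD bias factor c4(6) for n=6 trials per target
        from scipy.special import gamma
        c4 = np.sqrt(2 / 5) * gamma(3.0) / gamma(2.5)
        expected = slope * c4
        ages = np.array([e.demographics.age for e in exams])
        resid_sd = model.parameters["var_x"].residual_sd
        se = resid_sd / (ages.std() * np.sqrt(len(ages)))
        got = model.parameters["var_x"].coefficients["age"]
        assert abs(got - expected) < 2 * se

    def test_json_round_trip_preserves_scores(self, norm_model, tmp_path):
        path = tmp_path / "model.json"
        norm_model.to_json(path)
        clone = NormativeModel.from_json(path)
        exams, _ = simulate_normative_cohort(50, rng=np.random.default_rng(30))
        a = score_cohort(exams, norm_model)
        b = score_cohort(exams, clone)
        assert np.allclose(a["task_score"], b["task_score"])


class TestZAndZeta:
    def test_z_is_residual_in_sd_units(self, norm_model):
        pm = norm_model.parameters["abs_err_x"]
        raw = {p: 1.0 for p in PARAMETERS}
        raw["abs_err_x"] = pm.predict(DEMO)
        z = z_score_parameters(raw, DEMO, norm_model)
        assert z["abs_err_x"] == pytest.approx(0.0)
        raw["abs_err_x"] = pm.predict(DEMO) + pm.residual_sd
        z = z_score_parameters(raw, DEMO, norm_model)
        assert z["abs_err_x"] == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "z,sided,expected",
        [
            (0.0, "two_sided", 0.0),
            (0.0, "one_sided_high", norm.ppf(0.75)),  # ~0.6745
            (norm.ppf(0.95), "one_sided_high", norm.ppf(0.975)),  # ~1.96
            (-3.0, "two_sided", 3.0),
        ],
    )
    def test_zeta_reference_points(self, z, sided, expected):
        assert zeta_transform(z, sided) == pytest.approx(expected, abs=1e-9)

    def test_zeta_extreme_z_stays_finite_and_asymptotic(self):
        for z in (10.0, 50.0, 300.0):
            zeta = zeta_transform(z, "one_sided_high")
            assert np.isfinite(zeta)
            assert zeta == pytest.approx(np.sqrt(z * z + 2 * np.log(2)), rel=1e-3)

    @given(st.floats(-8, 8), st.floats(0.001, 3))
    @settings(derandomize=True, max_examples=60)
    def test_one_sided_zeta_strictly_increasing(self, z, dz):
        assert zeta_transform(z + dz, "one_sided_high") > zeta_transform(z, "one_sided_high")


class TestTaskScore:
    def test_zero_zetas_hit_the_floor(self, norm_model):
        res = task_score(np.zeros(8), norm_model)
        assert res.rss == 0.0
        assert res.task_score == pytest.approx(0.0, abs=0.05)
        assert not res.impaired

    def test_impairment_flag_is_inclusive_at_cutoff(self, norm_model, study_scores):
        assert (study_scores["impaired"] == (study_scores["task_score"] >= 1.96)).all()

    def test_monotone_in_each_zeta(self, norm_model):
        rng = np.random.default_rng(0)
        for _ in range(50):
            zetas = rng.uniform(0, 4, 8)
            idx = rng.integers(8)
            bumped = zetas.copy()
            bumped[idx] += rng.uniform(0.1, 2)
            assert (
                task_score(bumped, norm_model).task_score
                >= task_score(zetas, norm_model).task_score
            )

    def test_doubling_noise_raises_median_task_score(self, norm_model):
        lay = gen_target_layout()
        med = []
        for sd in (1.0, 2.0):
            rng = np.random.default_rng(13)
            exams = [
                simulate_exam(lay, DeficitProfile((sd, sd)), DEMO, rng, f"P{i}")
                for i in range(40)
            ]
            med.append(score_cohort(exams, norm_model)["task_score"].median())
        assert med[1] > med[0]
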