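"""Growth-model fitting, inversion, and correlation statistics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from chplanimetry import (
    BoneAgeLinearModel,
    SimulationConfig,
    categorize_correlation,
    compare_correlations,
    estimate_bone_age,
    fit_growth_model,
    pearson_r_ci,
    predict_area,
    reference_models,
    simulate_cohort,
)
from chplanimetry.growth import load_models, save_models


def _ch_truth(cohort):
    wide = (
        cohort.truth.pivot_table(
            index=["subject_id", "hand"], columns="bone", values="true_area_mm2"
        )
        .dropna()
        .reset_index()
    )
    wide["ch"] = wide["capitate"] + wide["hamate"]
    return wide.merge(
        cohort.subjects[["subject_id", "sex", "age_months"]], on="subject_id"
    )


class TestFit:
    def test_exact_line(self):
        x = np.array([1.0, 5.0, 9.0, 20.0])
        m = fit_growth_model(x, 2 * x + 1)
        assert m.intercept_ == pytest.approx(1.0, abs=1e-10)
        assert m.slope_ == pytest.approx(2.0, abs=1e-12)
        assert m.residual_sd_ == pytest.approx(0.0, abs=1e-10)

    def test_zero_noise_cohort_recovers_config_coefficients(self):
        cfg = SimulationConfig(
            seed=5, n_subjects=800, noise_cv=0.0, single_hand_rate=0.0
        )
        data = _ch_truth(simulate_cohort(cfg))
        # below ~7 months the latent mean is floored at the visibility
        # threshold, so the exact-line identity holds from 12 months up
        data = data[data.age_months >= 12]
        for sex in ("male", "female"):
            sub = data[(data.sex == sex) & (data.hand == "left")]
            for bone in ("capitate", "hamate"):
                m = fit_growth_model(sub.age_months, sub[bone])
                coef = cfg.growth_coefficients[sex][bone]
                assert m.slope_ == pytest.approx(coef.slope, abs=1e-9)
                assert m.intercept_ == pytest.approx(coef.intercept, abs=1e-7)

    def test_parameter_recovery_single_seed(self):
        """Generating slope falls inside the fit's own 95 % slope CI."""
        cfg = SimulationConfig(seed=7, n_subjects=5000)
        data = _ch_truth(simulate_cohort(cfg))
        sub = data[(data.sex == "male") & (data.hand == "left")]
        m = fit_growth_model(sub.age_months, sub.ch)
        gen_slope = sum(
            cfg.growth_coefficients["male"][b].slope for b in ("capitate", "hamate")
        )
        (lo, hi), _ = m.coef_ci()
        assert lo < gen_slope < hi

    def test_robust_ses_match_statsmodels_hc1(self, rng):
        """Hand-rolled HC1 sandwich SEs agree with statsmodels."""
        import statsmodels.api as sm

        x = rng.uniform(1, 180, 250)
        y = 3.0 * x - 10.0 + rng.normal(0, 0.2 * np.abs(3.0 * x), 250)
        m = fit_growth_model(x, y)
        res = sm.OLS(y, sm.add_constant(x)).fit(cov_type="HC1")
        assert m.intercept_se_robust_ == pytest.approx(res.bse[0], rel=1e-8)
        assert m.slope_se_robust_ == pytest.approx(res.bse[1], rel=1e-8)
        assert m.slope_se_ == pytest.approx(
            sm.OLS(y, sm.add_constant(x)).fit().bse[1], rel=1e-8
        )

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_growth_model([1, 2], [1, 2])
        with pytest.raises(ValueError, match="constant age"):
            fit_growth_model([5, 5, 5], [1, 2, 3])


class TestOlsAdditivity:
    def test_printed_reference_slopes_add(self):
        ref = reference_models()
        assert round(
            ref[("male", "capitate")].slope_ + ref[("male", "hamate")].slope_, 4
        ) == round(ref[("male", "CH")].slope_, 4)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_additivity_on_random_data(self, seed):
        """Least-squares linearity: fit(cap + ham) = fit(cap) + fit(ham)."""
        rng = np.random.default_rng(seed)
        age = rng.uniform(1, 180, 300)
        cap = 1.8 * age - 6.6 + rng.normal(0, 15, 300)
        ham = 1.25 * age - 7.3 + rng.normal(0, 12, 300)
        mc, mh, ms = (fit_growth_model(age, y) for y in (cap, ham, cap + ham))
        assert ms.slope_ == pytest.approx(mc.slope_ + mh.slope_, abs=1e-10)
        assert ms.intercept_ == pytest.approx(mc.intercept_ + mh.intercept_, abs=1e-10)


class TestPredictAndInvert:
    def test_reference_predictions(self):
        ref = reference_models()
        assert predict_area(ref[("male", "CH")], 75) == pytest.approx(
            215.9434, abs=1e-4
        )
        assert predict_area(ref[("female", "CH")], 60) == pytest.approx(
            144.8493, abs=1e-4
        )

    def test_root_of_line_predicts_zero(self):
        m = BoneAgeLinearModel.from_coefficients(-10.0, 2.0)
        assert predict_area(m, 5.0) == pytest.approx(0.0, abs=1e-12)

    def test_out_of_range_age_warns_but_computes(self):
        m = reference_models()[("male", "CH")]
        with pytest.warns(UserWarning, match="extrapolating"):
            val = predict_area(m, 250)
        assert val == pytest.approx(-13.3391 + 3.0571 * 250, abs=1e-6)

    @pytest.mark.parametrize("t", [12.0, 75.0, 180.0])
    def test_inversion_round_trip(self, t):
        m = reference_models()[("male", "CH")]
        est = estimate_bone_age(m, predict_area(m, t))
        assert est.estimated_age_months == pytest.approx(t, abs=1e-9)
        assert not est.clamped

    def test_reference_inversion_value(self):
        est = estimate_bone_age(reference_models()[("male", "CH")], 216.94)
        assert est.estimated_age_months == pytest.approx(75.33, abs=0.01)

    def test_negative_root_clamped_to_zero(self):
        m = BoneAgeLinearModel.from_coefficients(50.0, 2.0)
        est = estimate_bone_age(m, 0.0)  # raw would be -25 months
        assert est.estimated_age_months == 0.0 and est.clamped

    def test_nonpositive_slope_rejected(self):
        m = BoneAgeLinearModel.from_coefficients(1.0, -2.0)
        with pytest.raises(ValueError, match="slope"):
            m.estimate_age(100.0)


class TestCorrelation:
    def test_perfect_line_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            r, ci = pearson_r_ci([1, 2, 3, 4], [2, 4, 6, 8])
        assert r == pytest.approx(1.0) and ci == (r, r)

    def test_hand_computed_r(self):
        with pytest.warns(UserWarning, match="n = 3"):
            r, _ = pearson_r_ci([1, 2, 3], [1, 2, 4])
        assert r == pytest.approx(0.9820, abs=1e-4)

    def test_ci_matches_independent_implementation(self, rng):
        """Fisher-z interval agrees with pingouin's correlation CI."""
        import pingouin as pg

        x = rng.normal(size=200)
        y = 0.8 * x + rng.normal(size=200)
        r, (lo, hi) = pearson_r_ci(x, y)
        res = pg.corr(x, y)
        assert r == pytest.approx(float(res["r"].iloc[0]), abs=1e-10)
        ci = res["CI95"].iloc[0]
        assert lo == pytest.approx(ci[0], abs=5e-3)
        assert hi == pytest.approx(ci[1], abs=5e-3)

    def test_closed_form_halfwidth(self):
        from chplanimetry.growth import pearson_r_ci_from_r

        lo, hi = pearson_r_ci_from_r(0.97, 403)
        z = np.arctanh(0.97)
        half = 1.959963984540054 / np.sqrt(400)
        assert lo == pytest.approx(np.tanh(z - half), abs=1e-12)
        assert hi == pytest.approx(np.tanh(z + half), abs=1e-12)

    def test_compare_equal_correlations(self):
        z, p = compare_correlations(0.9, 100, 0.9, 100)
        assert z == 0.0 and p == 1.0

    def test_compare_hand_computed(self):
        z, p = compare_correlations(0.9, 100, 0.8, 100)
        assert z == pytest.approx(2.6027, abs=1e-3)
        assert p == pytest.approx(2 * (1 - 0.9953), abs=1e-3)

    def test_compare_antisymmetry(self):
        z1, _ = compare_correlations(0.95, 242, 0.91, 149)
        z2, _ = compare_correlations(0.91, 149, 0.95, 242)
        assert z1 == pytest.approx(-z2, rel=1e-12)

    def test_compare_rejects_invalid(self):
        with pytest.raises(ValueError):
            compare_correlations(1.0, 100, 0.5, 100)
        with pytest.raises(ValueError):
            compare_correlations(0.5, 3, 0.5, 100)

    @pytest.mark.parametrize(
        "r, cat",
        [
            (0.9702, "strong"),
            (0.30, "weak"),
            (0.5, "moderate"),
            (0.7, "moderate"),
            (-0.85, "strong"),
            (0.0, "weak"),
        ],
    )
    def test_categorize(self, r, cat):
        assert categorize_correlation(r) == cat

    @given(
        st.floats(-0.99, 0.99),
        st.floats(0.1, 10.0),
        st.floats(-50.0, 50.0),
    )
    def test_r_invariant_to_positive_affine_rescaling(self, rho, scale, shift):
        rng = np.random.default_rng(17)
        x = rng.normal(size=60)
        y = rho * x + np.sqrt(max(1 - rho**2, 1e-6)) * rng.normal(size=60)
        r1, _ = pearson_r_ci(x, y)
        r2, _ = pearson_r_ci(x, scale * y + shift)
        assert r1 == pytest.approx(r2, abs=1e-10)


def test_noise_ladder_r_increases_as_noise_shrinks():
    """Cohort age-area correlation rises monotonically toward 1 as noise → 0."""
    ladders = [0.8, 0.4, 0.2, 0.1, 0.02]
    mean_r = []
    for cv in ladders:
        rs = []
        for seed in range(20):
            cfg = SimulationConfig(
                seed=seed, n_subjects=400, noise_cv=cv, single_hand_rate=0.0
            )
            data = _ch_truth(simulate_cohort(cfg))
            sub = data[(data.sex == "male") & (data.hand == "left")]
            rs.append(np.corrcoef(sub.age_months, sub.ch)[0, 1])
        mean_r.append(np.mean(rs))
    assert all(a < b for a, b in zip(mean_r, mean_r[1:]))
    assert mean_r[-1] > 0.999


def test_model_json_round_trip(tmp_path):
    cfg = SimulationConfig(seed=3, n_subjects=300)
    data = _ch_truth(simulate_cohort(cfg))
    sub = data[(data.sex == "male") & (data.hand == "left")]
    m = fit_growth_model(sub.age_months, sub.ch, sex="male", target="CH")
    path = tmp_path / "models.json"
    save_models([m], path)
    (loaded,) = load_models(path)
    assert loaded.slope_ == m.slope_
    assert loaded.intercept_ == m.intercept_
    assert loaded.r_ci_ == tuple(m.r_ci_)
    assert loaded.sex == "male" and loaded.target == "CH"
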