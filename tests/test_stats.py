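import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from conftest import make_demographics
from eegbattery.stats import (
    DESIGNATED_TERMS,
    MODELS,
    assign_age_tertiles,
    build_design,
    compute_gvif,
    count_fits,
    effect_table,
    fit_models,
    lrt_age_quadratic,
    partial_eta2_type3,
    remove_outliers,
)
from oracles import eta2_type3_oracle


class TestAgeTertiles:
    def test_balanced_9_and_9(self):
        demo = make_demographics(18, seed=2, diagnoses=("AD", "ASD"))
        grouping = assign_age_tertiles(demo)
        merged = demo.set_index("participant_id").join(grouping.labels)
        counts = merged.groupby(["diagnosis", "age_group"]).size()
        assert (counts == 3).all()

    def test_10_cases_split_max_imbalance_one(self):
        rows = make_demographics(30, seed=3, diagnoses=("AD", "ASD", "CON"))
        extra = make_demographics(1, seed=99, diagnoses=("AD",))
        extra["participant_id"] = ["p999"]
        demo = pd.concat([rows, extra], ignore_index=True)  # 11 AD
        grouping = assign_age_tertiles(demo)
        merged = demo.set_index("participant_id").join(grouping.labels)
        ad_counts = merged[merged.diagnosis == "AD"].groupby("age_group").size()
        assert ad_counts.max() - ad_counts.min() <= 1

    def test_tertiles_ordered_by_age_within_group(self):
        demo = make_demographics(60, seed=4)
        grouping = assign_age_tertiles(demo)
        merged = demo.set_index("participant_id").join(grouping.labels)
        for diag in ("AD", "ASD"):
            sub = merged[merged.diagnosis == diag]
            young_max = sub[sub.age_group == "youngest"]["age_months"].max()
            old_min = sub[sub.age_group == "oldest"]["age_months"].min()
            assert young_max < old_min

    def test_con_assigned_by_boundaries(self):
        demo = make_demographics(90, seed=5)
        grouping = assign_age_tertiles(demo)
        b1, b2 = grouping.boundaries
        merged = demo.set_index("participant_id").join(grouping.labels)
        con = merged[merged.diagnosis == "CON"]
        assert (con[con.age_months <= b1]["age_group"] == "youngest").all()
        assert (con[con.age_months > b2]["age_group"] == "oldest").all()

    def test_deterministic(self):
        demo = make_demographics(45, seed=6)
        a = assign_age_tertiles(demo)
        b = assign_age_tertiles(demo.sample(frac=1.0, random_state=0))
        assert a.labels.sort_index().equals(b.labels.sort_index())

    def test_too_few_cases_rejected(self):
        demo = make_demographics(4, seed=0, diagnoses=("AD", "CON"))
        with pytest.raises(ValueError, match="at least 3"):
            assign_age_tertiles(demo)


class TestRemoveOutliers:
    def test_constant_values_none_removed(self):
        keep, counts = remove_outliers(np.ones(20), np.array(["CON"] * 20))
        assert keep.all()
        assert counts == {"autistic": 0, "neurotypical": 0}

    def test_single_extreme_value_removed(self, rng):
        values = np.concatenate([rng.standard_normal(99), [1e6]])
        diag = np.array(["AD"] * 50 + ["CON"] * 50)
        keep, counts = remove_outliers(values, diag)
        assert not keep[-1]
        assert keep[:-1].all()
        assert counts == {"autistic": 0, "neurotypical": 1}

    def test_matches_direct_rule(self, rng):
        values = rng.standard_normal(50) * 3
        diag = np.array(["ASD", "CON"] * 25)
        keep, _ = remove_outliers(values, diag)
        med = np.median(values)
        mad = np.median(np.abs(values - med))
        expected = np.abs(values - med) <= 3.5 * 1.4826 * mad
        np.testing.assert_array_equal(keep, expected)

    def test_minimum_size(self):
        with pytest.raises(ValueError, match="10"):
            remove_outliers(np.ones(5), np.array(["CON"] * 5))


class TestLRT:
    def test_linear_noiseless_keeps_linear(self):
        age = np.linspace(10, 200, 40)
        use, lr, p = lrt_age_quadratic(2.0 + 0.1 * age, age)
        assert not use

    def test_quadratic_noiseless_selects_quadratic(self):
        age = np.linspace(10, 200, 40)
        use, lr, p = lrt_age_quadratic(1.0 + 0.01 * (age - 100) ** 2, age)
        assert use and p < 1e-10

    def test_statistic_matches_hand_computation(self, rng):
        age = rng.uniform(10, 200, 50)
        y = 0.5 * age + 0.002 * (age - 100) ** 2 + rng.standard_normal(50) * 20
        _, lr, p = lrt_age_quadratic(y, age)
        a = age - age.mean()
        x0 = np.column_stack([np.ones(50), a])
        x1 = np.column_stack([np.ones(50), a, a**2 - (a**2).mean()])
        rss0 = np.sum((y - x0 @ np.linalg.lstsq(x0, y, rcond=None)[0]) ** 2)
        rss1 = np.sum((y - x1 @ np.linalg.lstsq(x1, y, rcond=None)[0]) ** 2)
        assert lr == pytest.approx(50 * np.log(rss0 / rss1), rel=1e-10)
        assert p == pytest.approx(sps.chi2.sf(lr, 1), rel=1e-10)


class TestModelsAndEta2:
    def test_pure_diagnosis_shift_gives_eta2_one(self):
        demo = make_demographics(60, seed=7)
        shift = demo["diagnosis"].map({"AD": 1.0, "ASD": 0.0, "CON": -1.0}).to_numpy()
        fits = fit_models(shift, demo, use_age2=False)
        eta2, p = partial_eta2_type3(fits["M1"], "Diagnosis")
        assert eta2 == pytest.approx(1.0, abs=1e-9)

    def test_zero_effect_orthogonal_noiseless_gives_zero(self):
        demo = make_demographics(60, seed=8)
        age = demo["age_months"].to_numpy()
        y = (age - age.mean()) * 2.0  # depends on Age only
        fits = fit_models(y, demo, use_age2=False)
        eta2_age, _ = partial_eta2_type3(fits["M1"], "Age")
        assert eta2_age == pytest.approx(1.0, abs=1e-9)

    def test_eta2_matches_qr_projection_oracle(self, rng):
        demo = make_demographics(80, seed=9)
        y = rng.standard_normal(80)
        fits = fit_models(y, demo, use_age2=True)
        for model in MODELS:
            fit = fits[model]
            for term in DESIGNATED_TERMS[model]:
                ours, _ = partial_eta2_type3(fit, term)
                expected = eta2_type3_oracle(y, fit.x, fit.term_cols[term])
                assert ours == pytest.approx(expected, abs=1e-10)

    def test_eta2_matches_statsmodels_type3_anova(self, rng):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        demo = make_demographics(90, seed=10)
        df = demo.copy()
        df["y"] = rng.standard_normal(90)
        df["age_c"] = df.age_months - df.age_months.mean()
        df["iq_c"] = df.iq - df.iq.mean()
        sm_fit = smf.ols(
            "y ~ age_c + C(sex, Sum) + iq_c + C(diagnosis, Sum)", data=df
        ).fit()
        table = anova_lm(sm_fit, typ=3)
        ss_diag = table.loc["C(diagnosis, Sum)", "sum_sq"]
        ss_res = table.loc["Residual", "sum_sq"]
        expected = ss_diag / (ss_diag + ss_res)
        fits = fit_models(df["y"].to_numpy(), demo, use_age2=False)
        ours, _ = partial_eta2_type3(fits["M1"], "Diagnosis")
        assert ours == pytest.approx(expected, rel=1e-8)

    def test_one_df_term_matches_t_statistic_identity(self, rng):
        demo = make_demographics(70, seed=11)
        y = rng.standard_normal(70)
        fits = fit_models(y, demo, use_age2=False)
        fit = fits["M1"]
        eta2, _ = partial_eta2_type3(fit, "IQ")
        # eta2 = t²/(t² + df_res) for a single-df term
        xtx_inv = np.linalg.inv(fit.x.T @ fit.x)
        j = fit.term_cols["IQ"][0]
        sigma2 = fit.rss / fit.df_resid
        t2 = fit.beta[j] ** 2 / (sigma2 * xtx_inv[j, j])
        assert eta2 == pytest.approx(t2 / (t2 + fit.df_resid), rel=1e-8)

    def test_balanced_orthogonal_design_type3_equals_sequential(self):
        # 2x2-balanced sex/diagnosis sub-design with centred age constant
        rows = []
        i = 0
        for diag in ("AD", "ASD", "CON"):
            for sex in ("F", "M"):
                for _ in range(10):
                    rows.append(
                        {"participant_id": f"p{i:03d}", "age_months": 100.0 + (i % 2),
                         "sex": sex, "iq": 100.0, "diagnosis": diag, "dataset": "t"}
                    )
                    i += 1
        demo = pd.DataFrame(rows)
        rng = np.random.default_rng(12)
        y = rng.standard_normal(len(demo))
        x, term_cols = build_design(demo.drop(columns="iq").assign(iq=100.0), "M1", False)
        # drop IQ (constant -> not estimable); rebuild manually
        keep_terms = {t: c for t, c in term_cols.items() if t != "IQ"}
        cols = [0] + [j for t in keep_terms.values() for j in t]
        x2 = x[:, sorted(set(cols))]
        # sequential SS for Diagnosis (last term added) == type-III SS here
        remap = {}
        new_idx = {old: new for new, old in enumerate(sorted(set(cols)))}
        for t, c in keep_terms.items():
            remap[t] = [new_idx[j] for j in c]
        from eegbattery.stats import ModelFit, _ols_rss

        rss_full, beta, rank = _ols_rss(x2, y)
        fit = ModelFit("M1", x2, y, remap, beta, rss_full, rank)
        eta2_t3, _ = partial_eta2_type3(fit, "Diagnosis")
        seq_cols = [j for t, c in remap.items() if t != "Diagnosis" for j in c]
        rss_before, _, _ = _ols_rss(x2[:, [0] + sorted(seq_cols)], y)
        ss_seq = rss_before - rss_full
        assert eta2_t3 == pytest.approx(ss_seq / (ss_seq + rss_full), rel=1e-8)

    def test_null_monte_carlo_matches_f_tail(self, rng):
        # P(eta2 > c) under the null for the 2-df Diagnosis term vs F closed form
        n, reps, c = 100, 2000, 0.035
        demo = make_demographics(n, seed=13)
        exceed = 0
        for _ in range(reps):
            y = rng.standard_normal(n)
            fits = fit_models(y, demo, use_age2=False)
            eta2, _ = partial_eta2_type3(fits["M1"], "Diagnosis")
            exceed += eta2 > c
        k = fits["M1"].x.shape[1]
        df_res = n - k
        f_crit = (c / (1 - c)) * (df_res / 2)
        expected = sps.f.sf(f_crit, 2, df_res)
        assert exceed / reps == pytest.approx(expected, abs=0.02)


class TestGVIF:
    def test_orthogonal_predictors_give_one(self):
        n = 400
        demo = make_demographics(n, seed=14)
        y = np.zeros(n)
        fits = fit_models(y, demo, use_age2=False)
        # constructed demographics are random, so GVIF ~ 1 but not exactly;
        # build an exactly orthogonal design instead
        x = np.column_stack([np.ones(n), np.tile([1, -1], n // 2), np.repeat([1, -1], n // 2)])
        from eegbattery.stats import ModelFit, _ols_rss

        rss, beta, rank = _ols_rss(x, y)
        fit = ModelFit("M1", x, y, {"A": [1], "B": [2]}, beta, rss, rank)
        gvif = compute_gvif(fit)
        assert gvif["A"] == pytest.approx(1.0, abs=1e-10)
        assert gvif["B"] == pytest.approx(1.0, abs=1e-10)

    def test_correlated_pair_closed_form(self):
        # two continuous predictors with r = 0.6 -> VIF 1.5625, adjusted 1.25
        n = 5000
        rng = np.random.default_rng(15)
        a = rng.standard_normal(n)
        b = 0.6 * a + np.sqrt(1 - 0.36) * rng.standard_normal(n)
        # enforce exact sample correlation via whitening + recoloring
        from numpy.linalg import cholesky

        raw = np.column_stack([a, b])
        raw = raw - raw.mean(axis=0)
        cov = np.cov(raw, rowvar=False)
        white = raw @ np.linalg.inv(cholesky(cov)).T
        target = np.array([[1.0, 0.6], [0.6, 1.0]])
        xy = white @ cholesky(target).T
        x = np.column_stack([np.ones(n), xy])
        from eegbattery.stats import ModelFit, _ols_rss

        y = np.zeros(n)
        rss, beta, rank = _ols_rss(x, y)
        fit = ModelFit("M1", x, y, {"A": [1], "B": [2]}, beta, rss, rank)
        gvif = compute_gvif(fit)
        assert gvif["A"] ** 2 == pytest.approx(1.5625, rel=1e-8)
        assert gvif["A"] == pytest.approx(1.25, rel=1e-8)

    def test_duplicated_predictor_rejected(self):
        n = 50
        rng = np.random.default_rng(16)
        a = rng.standard_normal(n)
        x = np.column_stack([np.ones(n), a, a])
        from eegbattery.stats import ModelFit, _ols_rss

        y = np.zeros(n)
        rss, beta, rank = _ols_rss(x, y)
        fit = ModelFit("M1", x, y, {"A": [1], "B": [2]}, beta, rss, rank)
        with pytest.raises(ValueError, match="aliased"):
            compute_gvif(fit)


@pytest.fixture(scope="module")
def small_sweep(cohort_demo, registry):
    from eegbattery.cohort import simulate_feature_table

    sub = registry.subset(10)
    features = simulate_feature_table(cohort_demo, sub, seed=17)
    grouping = assign_age_tertiles(cohort_demo)
    return effect_table(features, cohort_demo, grouping), sub


class TestEffectTable:
    def test_record_and_fit_counts(self, small_sweep):
        effects, sub = small_sweep
        assert len(effects) == len(sub) * 3 * 7  # designated-term rows
        assert count_fits(effects) == len(sub) * 3 * 4

    def test_eta2_bounds_and_no_errors(self, small_sweep):
        effects, _ = small_sweep
        assert (effects["error"] == "").all()
        valid = effects["eta2"].dropna()
        assert ((valid >= 0) & (valid <= 1)).all()

    def test_sweep_is_deterministic(self, cohort_demo, registry):
        from eegbattery.cohort import simulate_feature_table

        sub = registry.subset(5)
        features = simulate_feature_table(cohort_demo, sub, seed=18)
        grouping = assign_age_tertiles(cohort_demo)
        a = effect_table(features, cohort_demo, grouping)
        b = effect_table(features, cohort_demo, grouping)
        pd.testing.assert_frame_equal(a, b)

    def test_injected_age_effect_recovered(self, cohort_demo, registry):
        from eegbattery.cohort import FeatureEffect, FeatureEffects, simulate_feature_table

        sub = registry.subset(12)
        eff = FeatureEffects(effects=[FeatureEffect(age_beta=0.8)])  # all variables
        features = simulate_feature_table(cohort_demo, sub, eff, seed=19)
        grouping = assign_age_tertiles(cohort_demo)
        effects = effect_table(features, cohort_demo, grouping)
        age_rows = effects[effects.term == "Age"]
        assert (age_rows["eta2"] > 0.035).mean() > 0.9

    def test_failures_recorded_not_raised(self, cohort_demo, registry):
        from eegbattery.cohort import simulate_feature_table

        sub = registry.subset(3)
        features = simulate_feature_table(cohort_demo, sub, seed=20)
        features.iloc[:, 1] = np.nan  # first variable entirely missing
        grouping = assign_age_tertiles(cohort_demo)
        effects = effect_table(features, cohort_demo, grouping)
        broken = effects[effects.variable == features.columns[1]]
        assert (broken["error"] != "").all()
        assert broken["eta2"].isna().all()
        ok = effects[effects.variable != features.columns[1]]
        assert (ok["error"] == "").all()
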