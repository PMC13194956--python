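"""Mixed-model estimation and small-sample inference.

The headline checks compare this package's REML estimates, Satterthwaite
degrees of freedom, type III F-tests and Tukey-adjusted ring contrasts
against values computed once with the reference mixed-model stack
(lme4/lmerTest/emmeans) on the identical simulated datasets; those
reference numbers are frozen below.
"""

import numpy as np
import pandas as pd
import pytest

from rezr.stats import (
    describe,
    fit_location_model,
    fit_ring_model,
    fit_va_model,
    pairwise_group_contrasts,
    ring_contrasts,
)
from rezr.synthetic import CohortSimSpec, generate_cohort, generate_va_cohort


@pytest.fixture(scope="module")
def location_fit(study_cohort):
    table, _ = study_cohort
    return fit_location_model(table.rename(columns={"rezr": "outer_ring"}), "outer_ring")


@pytest.fixture(scope="module")
def ring_sim():
    spec = CohortSimSpec(
        group_sizes=(17, 33, 14),
        n_patients=44,
        location_means={"central_1mm": 1.0, "inner_ring": 1.148, "outer_ring": 1.278},
        group_effects={"noDR": 0.0, "NPDR": -0.05, "PDR": -0.15},
        group_location_effects={
            ("NPDR", "central_1mm"): 0.168,
            ("NPDR", "inner_ring"): 0.036,
            ("PDR", "central_1mm"): 0.105,
            ("PDR", "inner_ring"): 0.01,
        },
        patient_sd=0.02**0.5,
        eye_sd=0.05,
        residual_sd=0.1,
        scans_per_eye=3,
        seed=11,
    )
    table, _ = generate_cohort(spec)
    return table.rename(columns={"region": "ring"})


@pytest.fixture(scope="module")
def ring_fit(ring_sim):
    return fit_ring_model(ring_sim)


# reference-stack (lme4_1.1-37 / lmerTest_3.1-3 / emmeans) values for the
# exact datasets built by the fixtures above
_LOCATION_REFERENCE = {
    # name: (estimate, se, satterthwaite df)
    "Intercept": (1.20826179, 0.19441757, 37.5005),
    "group[NPDR]": (-0.05338945, 0.06573682, 37.9036),
    "group[PDR]": (-0.16616839, 0.08394017, 37.7263),
    "duration": (-0.00546972, 0.00314417, 36.9046),
    "age": (0.00175866, 0.00317357, 38.5306),
    "gender[female]": (0.06667928, 0.06825339, 38.6263),
    "eye_side[left]": (-0.02749301, 0.02604925, 22.7713),
}


class TestLocationModelAgainstReferenceStack:
    def test_fixed_effects_and_satterthwaite_df(self, location_fit):
        for name, (est, se, df) in _LOCATION_REFERENCE.items():
            row = location_fit.params.loc[name]
            assert row["estimate"] == pytest.approx(est, abs=2e-6)
            assert row["se"] == pytest.approx(se, rel=1e-4)
            assert row["df"] == pytest.approx(df, rel=2e-3)

    def test_type_iii_group_ftest(self, location_fit):
        f = location_fit.ftests.loc["group"]
        assert f["F"] == pytest.approx(2.07277, rel=1e-4)
        assert f["df_den"] == pytest.approx(37.4071, rel=2e-3)
        assert f["p"] == pytest.approx(0.140051, abs=2e-4)

    def test_variance_components(self, location_fit):
        assert location_fit.vc["patient_var"] == pytest.approx(0.02324889, rel=1e-3)
        assert location_fit.vc["residual_var"] == pytest.approx(0.00753324, rel=1e-3)

    def test_counts_reported(self, location_fit):
        assert (location_fit.n_eyes, location_fit.n_patients) == (64, 44)
        assert location_fit.n_dropped == 0


class TestGroupContrasts:
    def test_linearity_identity_exact(self, location_fit):
        cons = {c.label: c for c in pairwise_group_contrasts(location_fit)}
        assert cons["PDR - NPDR"].estimate == pytest.approx(
            cons["PDR - noDR"].estimate - cons["NPDR - noDR"].estimate, abs=1e-12
        )

    def test_gating_flag_follows_overall_ftest(self, location_fit):
        gated = location_fit.ftests.loc["group", "p"] >= 0.05
        assert all(c.gated == gated for c in pairwise_group_contrasts(location_fit))

    def test_ci_contains_estimate(self, location_fit):
        for c in pairwise_group_contrasts(location_fit):
            assert c.ci_low <= c.estimate <= c.ci_high


class TestRingModelAgainstReferenceStack:
    def test_type_iii_ftests(self, ring_fit):
        assert ring_fit.ftests.loc["ring", "F"] == pytest.approx(152.04196, rel=1e-3)
        assert ring_fit.ftests.loc["group", "F"] == pytest.approx(2.82989, rel=1e-3)
        assert ring_fit.ftests.loc["group", "df_den"] == pytest.approx(38.557, rel=5e-3)
        assert ring_fit.ftests.loc["ring:group", "F"] == pytest.approx(10.32824, rel=1e-3)
        assert ring_fit.ftests.loc["ring:group", "p"] == pytest.approx(
            4.7817e-08, rel=1e-2
        )

    def test_variance_components_with_nesting(self, ring_fit):
        assert ring_fit.vc["patient_var"] == pytest.approx(0.02127307, rel=1e-3)
        assert ring_fit.vc["eye_var"] == pytest.approx(0.00326157, rel=1e-3)
        assert ring_fit.vc["residual_var"] == pytest.approx(0.01029940, rel=1e-3)

    def test_tukey_ring_contrasts(self, ring_fit):
        cons = {c.label: c for c in ring_contrasts(ring_fit)}
        c = cons["central_1mm - inner_ring (noDR)"]
        assert c.estimate == pytest.approx(-0.15045853, abs=2e-6)
        assert c.se == pytest.approx(0.02009722, rel=1e-4)
        assert c.df == pytest.approx(506.0, rel=5e-3)
        c = cons["central_1mm - inner_ring (NPDR)"]
        assert c.p == pytest.approx(0.0374, abs=5e-4)
        assert c.ci_low == pytest.approx(-0.06945288, abs=5e-5)
        assert c.ci_high == pytest.approx(-0.00163918, abs=5e-5)
        c = cons["central_1mm - inner_ring (PDR)"]
        assert c.p == pytest.approx(0.0280, abs=5e-4)

    def test_tukey_p_never_below_unadjusted(self, ring_fit):
        tukey = {c.label: c.p for c in ring_contrasts(ring_fit, adjustment="tukey")}
        plain = {c.label: c.p for c in ring_contrasts(ring_fit, adjustment="none")}
        for label in tukey:
            assert tukey[label] >= plain[label] - 1e-12


class TestModelBehaviour:
    def test_zero_variance_components_agree_with_ols(self):
        """One independent eye per patient: the mixed fit collapses to OLS."""
        import statsmodels.formula.api as smf

        spec = CohortSimSpec(
            group_sizes=(20, 20, 20),
            n_patients=60,
            location_means={"outer_ring": 1.3},
            group_effects={"noDR": 0.0, "NPDR": -0.1, "PDR": -0.3},
            patient_sd=0.0,
            residual_sd=0.1,
            scans_per_eye=1,
            seed=21,
        )
        table, _ = generate_cohort(spec)
        wide = table.rename(columns={"rezr": "outer_ring"})
        fit = fit_location_model(wide, "outer_ring")
        ols = smf.ols(
            "outer_ring ~ C(dr_stage, Treatment('noDR')) + duration + age "
            "+ C(gender, Treatment('male')) + C(eye_side, Treatment('right'))",
            wide,
        ).fit()
        for mixed_name, ols_name in (
            ("group[NPDR]", "C(dr_stage, Treatment('noDR'))[T.NPDR]"),
            ("group[PDR]", "C(dr_stage, Treatment('noDR'))[T.PDR]"),
            ("age", "age"),
        ):
            assert fit.params.loc[mixed_name, "estimate"] == pytest.approx(
                ols.params[ols_name], abs=1e-3
            )

    def test_constant_response_degenerates_to_zero_contrasts(self):
        spec = CohortSimSpec(
            group_sizes=(5, 5, 5),
            n_patients=15,
            location_means={"outer_ring": 1.0},
            patient_sd=0.0,
            residual_sd=0.0,
            scans_per_eye=1,
            seed=1,
        )
        table, _ = generate_cohort(spec)
        fit = fit_location_model(table.rename(columns={"rezr": "outer_ring"}), "outer_ring")
        assert fit.ftests.loc["group", "F"] == 0.0
        assert any("degenerate" in w for w in fit.warnings)
        assert all(c.estimate == 0.0 for c in pairwise_group_contrasts(fit))

    def test_single_group_raises(self):
        spec = CohortSimSpec(
            group_sizes=(10, 0, 0), n_patients=10, scans_per_eye=1, seed=2
        )
        table, _ = generate_cohort(spec)
        with pytest.raises(ValueError, match="two DR groups"):
            fit_location_model(table.rename(columns={"rezr": "outer_ring"}), "outer_ring")

    def test_complete_case_attrition_reported(self, study_cohort):
        table, _ = study_cohort
        wide = table.rename(columns={"rezr": "outer_ring"}).copy()
        drop_pat = wide["patient_id"].unique()[:6]
        wide.loc[wide["patient_id"].isin(drop_pat), "duration"] = np.nan
        fit = fit_location_model(wide, "outer_ring")
        assert fit.n_dropped > 0
        assert fit.n_eyes == 64 - fit.n_dropped
        assert fit.n_patients == 38

    def test_nested_term_vanishes_when_eye_variance_is_zero(self):
        """With no eye-level variance the nested fit matches a flat fit."""
        from rezr.stats import _GROUP_TERM, _RING_TERM, _fit_mixed

        spec = CohortSimSpec(
            group_sizes=(34, 33, 33),
            n_patients=75,
            location_means={"central_1mm": 1.0, "inner_ring": 1.13, "outer_ring": 1.26},
            patient_sd=0.15,
            eye_sd=0.0,
            residual_sd=0.1,
            scans_per_eye=3,
            seed=31,
        )
        table, _ = generate_cohort(spec)
        table = table.rename(columns={"region": "ring"})
        nested = fit_ring_model(table)
        formula = nested.formula
        flat = _fit_mixed(
            table.dropna(subset=["rezr"]), formula, "rezr", {"group": _GROUP_TERM}, nest_eye=False
        )
        for name in nested.params.index:
            assert nested.params.loc[name, "estimate"] == pytest.approx(
                flat.params.loc[name, "estimate"], abs=1e-3
            )


class TestVAModel:
    def test_univariable_slope_recovered(self):
        ests = []
        for seed in range(25):
            eyes, _ = generate_va_cohort(slope=-0.171, seed=seed)
            fit = fit_va_model(eyes, predictor="total")
            ests.append(fit.params.loc["rezr_total", "estimate"])
        assert np.mean(ests) == pytest.approx(-0.171, abs=0.05)

    def test_uncorrelated_predictor_centred_at_zero(self):
        ests = []
        for seed in range(25):
            eyes, _ = generate_va_cohort(slope=0.0, seed=100 + seed)
            fit = fit_va_model(eyes, predictor="total")
            ests.append(fit.params.loc["rezr_total", "estimate"])
        assert abs(np.mean(ests)) < 0.05

    def test_confounding_attenuates_multivariable_slope(self):
        """Effect routed through age: adjusting pulls the slope towards 0."""
        rng = np.random.default_rng(77)
        n = 200
        age = rng.normal(62, 9, n)
        rezr = 1.2 - 0.01 * (age - 62) + rng.normal(0, 0.1, n)
        logmar = 0.005 * (age - 62) + rng.normal(0, 0.05, n)
        eyes = pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(n)],
                "eye_id": [f"E{i}" for i in range(n)],
                "rezr_total": rezr,
                "bcva_logmar": logmar,
                "age": age,
                "duration": rng.normal(15, 8, n),
                "dr_stage": rng.choice(["noDR", "NPDR", "PDR"], n),
            }
        )
        uni = fit_va_model(eyes, predictor="total")
        multi = fit_va_model(eyes, predictor="total", multivariable=True)
        slope_uni = uni.params.loc["rezr_total", "estimate"]
        slope_multi = multi.params.loc["rezr_total", "estimate"]
        assert uni.params.loc["rezr_total", "p"] < 0.05
        assert abs(slope_multi) < abs(slope_uni)


class TestDescribe:
    def test_symmetric_metric_takes_mean_sd_branch(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {"dr_stage": ["noDR"] * 50 + ["PDR"] * 50, "age": rng.normal(60, 9, 100)}
        )
        out = describe(df, metric_cols=("age",))
        assert out.loc[out["variable"] == "age", "summary"].iloc[0] == "mean ± SD"

    def test_skewed_metric_takes_median_iqr_branch(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {
                "dr_stage": ["noDR"] * 50 + ["PDR"] * 50,
                "bcva_logmar": rng.exponential(0.1, 100),
            }
        )
        out = describe(df, metric_cols=("bcva_logmar",))
        assert "median" in out["summary"].iloc[0]

    def test_categorical_counts_match_direct_tabulation(self):
        df = pd.DataFrame(
            {
                "dr_stage": ["noDR"] * 4 + ["PDR"] * 6,
                "gender": ["female", "male", "male", "male"] + ["female"] * 3 + ["male"] * 3,
            }
        )
        out = describe(df, categorical_cols=("gender",)).set_index("variable")
        assert out.loc["gender = female", "noDR"] == "1 (25%)"
        assert out.loc["gender = female", "PDR"] == "3 (50%)"
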