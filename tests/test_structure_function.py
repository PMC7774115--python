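"""Structure-function mixed models: transforms, R^2, LRT, AIC selection
and the abnormal-RPE-E subset analysis."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import statsmodels.api as sm

from drusensf import faf_mpod, normative
from drusensf.structure_function import (
    FULL_TERMS,
    SFModelFit,
    abnormal_threshold,
    fit_multivariable,
    fit_sf_model,
    fit_univariable,
    fixed_effect_r2,
    flag_abnormal,
    likelihood_ratio_test,
    log_transform_predictors,
    reduced_terms_without,
    stepwise_aic_reduction,
    subset_analysis,
    univariable_table,
)
from drusensf.synthetic_data import (
    NormativeTruth,
    SFTruth,
    SimConfig,
    simulate_location_records,
)


def _records(df_dict):
    return pd.DataFrame(df_dict)


class TestLogTransform:
    def test_reference_values(self):
        df = _records(
            {
                "rpe_e_mean_um": [100.0, 0.0],
                "prr_mean": [1.0, 10.0],
                "gaf_mean": [1000.0, 1.0],
            }
        )
        out = log_transform_predictors(df)
        assert out["log_rpe_e"].tolist() == [2.0, 0.0]  # 0 clamped to 1 um
        assert out["log_prr"].tolist() == [0.0, 1.0]
        assert out["log_gaf"].tolist() == [3.0, 0.0]
        assert out.attrs["n_clamped_rpe_e"] == 1

    def test_negative_predictor_rejected(self):
        df = _records(
            {"rpe_e_mean_um": [-1.0], "prr_mean": [1.0], "gaf_mean": [1.0]}
        )
        with pytest.raises(ValueError):
            log_transform_predictors(df)


class _FakeFit:
    def __init__(self, yhat):
        self.yhat = np.asarray(yhat, dtype=float)

    def predict_fixed(self, records):
        return self.yhat


class TestFixedEffectR2:
    def test_hand_arithmetic(self):
        rec = _records({"sl_db": [1.0, 2.0, 3.0]})
        assert fixed_effect_r2(_FakeFit([1.0, 2.0, 4.0]), rec) == 0.5

    def test_perfect_prediction(self):
        rec = _records({"sl_db": [1.0, 2.0, 3.0]})
        assert fixed_effect_r2(_FakeFit([1.0, 2.0, 3.0]), rec) == 1.0

    def test_mean_prediction(self):
        rec = _records({"sl_db": [1.0, 2.0, 3.0]})
        assert fixed_effect_r2(_FakeFit([2.0, 2.0, 2.0]), rec) == 0.0

    def test_zero_variance_rejected(self):
        rec = _records({"sl_db": [2.0, 2.0]})
        with pytest.raises(ValueError):
            fixed_effect_r2(_FakeFit([2.0, 2.0]), rec)


def _exact_records(slope=3.0, n=40):
    rng = np.random.default_rng(0)
    x = rng.uniform(1.0, 2.0, n)
    return log_transform_predictors(
        _records(
            {
                "eye_id": np.repeat(["a", "b"], n // 2),
                "rpe_e_mean_um": np.full(n, 2.0),
                "prr_mean": x,
                "gaf_mean": np.full(n, 1000.0),
                "sl_db": slope * np.log10(x),
            }
        )
    )


class TestUnivariable:
    def test_exact_regime_recovers_slope(self):
        fit = fit_univariable(_exact_records(slope=3.0), "prr")
        assert fit.params["log_prr"] == pytest.approx(3.0, abs=1e-6)
        assert fit.r2_fixed == pytest.approx(1.0, abs=1e-9)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError):
            fit_univariable(_exact_records(), "gaf")

    def test_unknown_predictor_rejected(self):
        with pytest.raises(ValueError):
            fit_univariable(_exact_records(), "thickness")

    def test_permuted_predictor_kills_r2(self, cohort_records):
        _, _, drusen = cohort_records
        mes = drusen[drusen["test_type"] == "mesopic"].copy()
        rng = np.random.default_rng(4)
        mes["rpe_e_mean_um"] = rng.permutation(
            mes["rpe_e_mean_um"].to_numpy()
        )
        mes = log_transform_predictors(mes)
        fit = fit_univariable(mes, "rpe_e")
        assert abs(fit.r2_fixed) < 0.01

    def test_r2_monotone_in_effect_size(self):
        """Univariable R^2 grows with the generating slope at fixed noise."""
        r2 = []
        for b in (2.0, 6.0, 12.0):
            cfg = SimConfig(
                random_seed=31, n_healthy=0, n_drusen=20,
                sf_truth=SFTruth(rpe_e=0.0, prr=b, gaf=0.0),
            )
            rec = simulate_location_records(
                cfg, seed=31, cohorts=("drusen",), test_types=("mesopic",)
            )
            rec["sl_db"] = rec["sensitivity_db"] - (
                cfg.normative_truth.fixed_effects(
                    "mesopic",
                    rec["eccentricity_deg"].to_numpy(),
                    rec["age_years"].to_numpy(),
                )
            )
            fit = fit_univariable(log_transform_predictors(rec), "prr")
            r2.append(fit.r2_fixed)
        assert r2[0] < r2[1] < r2[2]

    def test_cohort_slopes_near_truth(self, cohort_records):
        cfg, _, drusen = cohort_records
        table = univariable_table(
            drusen[drusen["test_type"] == "mesopic"]
        )
        row = table.set_index("predictor")
        assert row.loc["rpe_e", "slope"] == pytest.approx(
            cfg.sf_truth.rpe_e, abs=0.3
        )
        assert row.loc["prr", "slope"] == pytest.approx(
            cfg.sf_truth.prr, rel=0.3
        )


class TestMultivariable:
    def test_term_structure(self, cohort_records):
        _, _, drusen = cohort_records
        fit = fit_multivariable(drusen[drusen["test_type"] == "mesopic"])
        assert fit.terms == FULL_TERMS
        assert len(fit.params) == 8  # intercept + 7 terms
        assert fit.aic == pytest.approx(
            2 * (len(fit.params) + 2) - 2 * fit.llf
        )

    def test_single_eye_collapses_to_ols(self):
        rng = np.random.default_rng(2)
        n = 200
        rec = log_transform_predictors(
            _records(
                {
                    "eye_id": ["only"] * n,
                    "rpe_e_mean_um": rng.uniform(2, 100, n),
                    "prr_mean": rng.uniform(1.0, 1.6, n),
                    "gaf_mean": rng.uniform(700, 1000, n),
                    "sl_db": rng.normal(0, 1, n),
                }
            )
        )
        rec["sl_db"] += -2.0 * rec["log_rpe_e"] + 5.0 * rec["log_prr"]
        terms = ["log_rpe_e", "log_prr", "log_gaf"]
        fit = fit_sf_model(rec, terms)
        X = sm.add_constant(rec[terms].to_numpy())
        ols = sm.OLS(rec["sl_db"].to_numpy(), X).fit()
        np.testing.assert_allclose(fit.params.to_numpy(), ols.params,
                                   atol=1e-4)

    def test_duplicated_records_keep_estimates(self, cohort_records):
        _, _, drusen = cohort_records
        mes = drusen[drusen["test_type"] == "mesopic"]
        doubled = pd.concat([mes, mes], ignore_index=True)
        f1 = fit_sf_model(mes, ["log_rpe_e", "log_prr", "log_gaf"])
        f2 = fit_sf_model(doubled, ["log_rpe_e", "log_prr", "log_gaf"])
        # optimizer tolerance, not a model difference
        np.testing.assert_allclose(
            f1.params.to_numpy(), f2.params.to_numpy(), rtol=0.01,
            atol=0.05,
        )

    def test_collinear_terms_rejected(self):
        rec = _exact_records()
        rec["log_gaf"] = rec["log_prr"]
        with pytest.raises(ValueError, match="collinear"):
            fit_sf_model(rec, ["log_prr", "log_gaf"])


class TestLikelihoodRatio:
    def test_identical_models_give_null_result(self, cohort_records):
        _, _, drusen = cohort_records
        mes = drusen[drusen["test_type"] == "mesopic"]
        fit = fit_sf_model(mes, ["log_rpe_e"])
        stat, df, p = likelihood_ratio_test(fit, fit)
        assert stat == 0.0 and df == 0 and p == 1.0

    def test_non_nested_rejected(self, cohort_records):
        _, _, drusen = cohort_records
        mes = drusen[drusen["test_type"] == "mesopic"]
        f1 = fit_sf_model(mes, ["log_rpe_e"])
        f2 = fit_sf_model(mes, ["log_prr"])
        with pytest.raises(ValueError):
            likelihood_ratio_test(f1, f2)

    def test_reduced_terms_drop_predictor_block(self):
        red = reduced_terms_without(FULL_TERMS, "prr")
        assert red == ["log_rpe_e", "log_gaf", "log_rpe_e:log_gaf"]

    def test_strong_effect_detected(self, cohort_records):
        _, _, drusen = cohort_records
        mes = drusen[drusen["test_type"] == "mesopic"]
        full = fit_multivariable(mes)
        red = fit_sf_model(mes, reduced_terms_without(FULL_TERMS, "rpe_e"))
        stat, df, p = likelihood_ratio_test(full, red)
        assert df == 4
        assert p < 0.001


class TestStepwiseAic:
    def test_interaction_model_selected(self):
        cfg = SimConfig(
            random_seed=0,
            sf_truth=SFTruth(rpe_e=-2.5, prr=8.0, gaf=4.0,
                             rpe_prr_interaction=-6.0),
        )
        rec = faf_mpod.compensate_records(
            simulate_location_records(cfg, seed=0)
        )
        healthy = rec[rec["cohort"] == "healthy"]
        models = {"mesopic": normative.fit_normative(healthy, "mesopic")}
        drusen = log_transform_predictors(
            normative.apply_normative(
                rec[(rec["cohort"] == "drusen")
                    & (rec["test_type"] == "mesopic")],
                models,
            )
        )
        full = fit_multivariable(drusen)
        sel, trace = stepwise_aic_reduction(full, drusen)
        assert set(sel.terms) == {
            "log_rpe_e", "log_prr", "log_gaf", "log_rpe_e:log_prr"
        }
        aics = [a for _, a in trace]
        assert all(b < a for a, b in zip(aics, aics[1:]))

    def test_pure_noise_selects_far_smaller_models(self):
        """Backward AIC prunes most terms on a structure-free response.

        Exact intercept-only selection is capped by AIC's per-term
        overfitting probability (a chi-square(1) deviance exceeds the
        2-point penalty ~16% of the time), so the assertion targets the
        pruning, not a guaranteed empty model.
        """
        sizes = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 600
            rec = log_transform_predictors(
                _records(
                    {
                        "eye_id": np.repeat(
                            [f"e{i}" for i in range(15)], n // 15
                        ),
                        "rpe_e_mean_um": rng.uniform(2, 100, n),
                        "prr_mean": rng.uniform(1.0, 1.6, n),
                        "gaf_mean": rng.uniform(700, 1000, n),
                        "sl_db": rng.normal(0, 1.5, n),
                    }
                )
            )
            full = fit_multivariable(rec)
            sel, _ = stepwise_aic_reduction(full, rec)
            sizes.append(len(sel.terms))
        assert np.mean(sizes) < len(FULL_TERMS) / 2
        assert min(sizes) == 0  # intercept-only reached

    def test_marginality_respected(self, cohort_records):
        _, _, drusen = cohort_records
        mes = drusen[drusen["test_type"] == "mesopic"]
        full = fit_multivariable(mes)
        _, trace = stepwise_aic_reduction(full, mes)
        for terms, _ in trace:
            for t in terms:
                parts = set(t.split(":"))
                for sub in parts:
                    assert sub in terms  # every main kept under marginality


class TestAbnormalSubset:
    def test_constant_pool_and_strict_inequality(self):
        thr = abnormal_threshold(np.full(50, 7.0))
        assert thr == 7.0
        flags = flag_abnormal(
            _records({"rpe_e_mean_um": [7.0, 7.0001]}), thr
        )["abnormal"]
        assert flags.tolist() == [False, True]

    def test_percentile_convention(self):
        assert abnormal_threshold(np.arange(1.0, 101.0)) == pytest.approx(
            95.05
        )

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            abnormal_threshold([])

    def test_healthy_flag_rate_near_five_percent(self, cohort_records):
        _, healthy, _ = cohort_records
        vals = healthy["rpe_e_mean_um"].to_numpy()
        thr = abnormal_threshold(vals)
        assert np.mean(vals > thr) == pytest.approx(0.05, abs=0.005)

    def test_threshold_below_all_values_keeps_full_set(self, cohort_records):
        _, _, drusen = cohort_records
        mes = drusen[drusen["test_type"] == "mesopic"]
        res = subset_analysis(mes, threshold=-1.0,
                              terms=["log_rpe_e", "log_prr", "log_gaf"])
        r = res["mesopic"]
        assert r.fit_abnormal.n_records == r.fit_all.n_records
        assert r.r2_ratio == pytest.approx(1.0, abs=1e-9)

    def test_localized_loss_enriches_r2(self):
        """When elevation hurts sensitivity only above a hinge (loss
        localized to drusen), restricting to abnormal locations
        strengthens the mesopic structure-function fit on average."""
        cfg = SimConfig(sf_localized=True)
        diffs = []
        for seed in (7, 100, 101):
            rec = faf_mpod.compensate_records(
                simulate_location_records(cfg, seed=seed)
            )
            healthy = rec[rec["cohort"] == "healthy"]
            models = {
                "mesopic": normative.fit_normative(healthy, "mesopic")
            }
            drusen = log_transform_predictors(
                normative.apply_normative(
                    rec[(rec["cohort"] == "drusen")
                        & (rec["test_type"] == "mesopic")],
                    models,
                )
            )
            thr = abnormal_threshold(healthy["rpe_e_mean_um"].to_numpy())
            res = subset_analysis(drusen, thr)["mesopic"]
            diffs.append(res.fit_abnormal.r2_fixed - res.fit_all.r2_fixed)
        assert np.mean(diffs) > 0.0
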