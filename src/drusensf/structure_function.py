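"""Mixed-model structure-function analysis of sensitivity loss.

Sensitivity loss (dB deviation from the normative fixed-effects
prediction) is regressed on the log10-transformed structural predictors
(RPE elevation, photoreceptor reflectivity ratio, green
autofluorescence) with a per-eye random intercept, by maximum
likelihood. The module provides the univariable fits, the full
three-way-interaction multivariable fit, the fixed-effect R^2,
likelihood-ratio tests for dropping one predictor with all its
interactions, marginality-respecting backward AIC reduction, and the
abnormal-RPE-E subset analysis against the healthy 95th percentile.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._mixed import MixedFit, design_matrix, fit_mixed_ml

logger = logging.getLogger(__name__)

PREDICTORS = ("rpe_e", "prr", "gaf")
LOG_COLUMNS = {
    "rpe_e": ("rpe_e_mean_um", "log_rpe_e"),
    "prr": ("prr_mean", "log_prr"),
    "gaf": ("gaf_mean", "log_gaf"),
}
#: log10 guards against zero-valued predictors (um for RPE-E, raw units
#: otherwise); values below the guard are clamped before the log.
DEFAULT_EPSILON = {"rpe_e": 1.0, "prr": 1e-3, "gaf": 1e-3}

#: Full-interaction fixed-effect structure (3 mains, 3 two-way, 1 three-way).
FULL_TERMS = [
    "log_rpe_e",
    "log_prr",
    "log_gaf",
    "log_rpe_e:log_prr",
    "log_rpe_e:log_gaf",
    "log_prr:log_gaf",
    "log_rpe_e:log_prr:log_gaf",
]


@dataclass
class SFModelFit:
    """One structure-function mixed-model fit."""

    terms: list[str]
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    re_var: float
    resid_var: float
    llf: float
    aic: float
    n_records: int
    n_eyes: int
    r2_fixed: float

    @classmethod
    def from_mixed(cls, fit: MixedFit, r2: float) -> "SFModelFit":
        return cls(
            terms=fit.terms,
            params=fit.params,
            bse=fit.bse,
            pvalues=fit.pvalues,
            re_var=fit.re_var,
            resid_var=fit.resid_var,
            llf=fit.llf,
            aic=fit.aic,
            n_records=fit.n_records,
            n_eyes=fit.n_groups,
            r2_fixed=r2,
        )

    def predict_fixed(self, records: pd.DataFrame) -> np.ndarray:
        X = design_matrix(records, self.terms)
        return X.to_numpy() @ self.params.reindex(X.columns).to_numpy()

    def confint(self, level: float = 0.95) -> pd.DataFrame:
        z = stats.norm.ppf(0.5 + level / 2.0)
        return pd.DataFrame(
            {"lower": self.params - z * self.bse,
             "upper": self.params + z * self.bse}
        )


def log_transform_predictors(
    records: pd.DataFrame, epsilon: dict[str, float] | None = None
) -> pd.DataFrame:
    """Add log10 predictor columns, clamping small values at the guard.

    Negative predictor values are an error; values below the per-predictor
    epsilon are clamped to it before the log10 and the clamp count logged.
    """
    eps = dict(DEFAULT_EPSILON)
    if epsilon is not None:
        eps.update(epsilon)
    out = records.copy()
    for name, (src, dst) in LOG_COLUMNS.items():
        v = out[src].to_numpy(dtype=float)
        if np.any(v < 0):
            raise ValueError(f"negative values in predictor {src}")
        n_clamped = int(np.sum(v < eps[name]))
        if n_clamped:
            logger.info("clamped %d %s values below %g", n_clamped, src,
                        eps[name])
        out[dst] = np.log10(np.maximum(v, eps[name]))
        out.attrs[f"n_clamped_{name}"] = n_clamped
    return out


def fixed_effect_r2(fit, records: pd.DataFrame,
                    response: str = "sl_db") -> float:
    """R^2 of the fixed-effects-only prediction.

    ``1 - sum((y - yhat_fixed)^2) / sum((y - ybar)^2)``, with random
    intercepts excluded from the prediction. Equals 1 for a perfect fit
    and 0 when the fixed effects do no better than the response mean.
    """
    y = records[response].to_numpy(dtype=float)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("response has zero variance")
    yhat = fit.predict_fixed(records)
    return 1.0 - float(np.sum((y - yhat) ** 2)) / sst


def fit_sf_model(
    records: pd.DataFrame,
    terms: list[str],
    response: str = "sl_db",
) -> SFModelFit:
    """ML random-intercept fit of the sensitivity loss on given terms."""
    fit = fit_mixed_ml(records, response, terms)
    sf = SFModelFit.from_mixed(fit, 0.0)
    sf.r2_fixed = fixed_effect_r2(sf, records, response)
    return sf


def fit_univariable(
    records: pd.DataFrame, predictor: str, response: str = "sl_db"
) -> SFModelFit:
    """SL ~ one log10 predictor + (random intercept | eye)."""
    if predictor not in PREDICTORS:
        raise ValueError(f"predictor must be one of {PREDICTORS}")
    col = LOG_COLUMNS[predictor][1]
    if records["eye_id"].nunique() < 2 or len(records) < 3:
        raise ValueError("need >= 2 eyes and >= 3 records")
    if records[col].nunique() < 2:
        raise ValueError(f"predictor {col} is constant")
    return fit_sf_model(records, [col], response)


def fit_multivariable(
    records: pd.DataFrame, response: str = "sl_db"
) -> SFModelFit:
    """Full-interaction multivariable fit (8 fixed-effect terms)."""
    return fit_sf_model(records, list(FULL_TERMS), response)


def reduced_terms_without(terms: list[str], predictor: str) -> list[str]:
    """Drop a predictor's main effect and every interaction containing it."""
    col = LOG_COLUMNS[predictor][1]
    return [t for t in terms if col not in t.split(":")]


def likelihood_ratio_test(
    full: SFModelFit, reduced: SFModelFit
) -> tuple[float, int, float]:
    """Chi-square LRT of two nested ML fits on identical records."""
    if not set(reduced.terms) <= set(full.terms):
        raise ValueError("reduced model terms are not nested in full")
    if full.n_records != reduced.n_records:
        raise ValueError("fits must use identical records")
    df = len(full.terms) - len(reduced.terms)
    if df < 0:
        raise ValueError("full model has fewer terms than reduced")
    stat = max(2.0 * (full.llf - reduced.llf), 0.0)
    p = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
    return stat, df, p


def _droppable(terms: list[str]) -> list[str]:
    """Terms removable under marginality: not part of any retained
    higher-order interaction."""
    out = []
    for t in terms:
        parts = set(t.split(":"))
        in_higher = any(
            o != t and parts < set(o.split(":")) for o in terms
        )
        if not in_higher:
            out.append(t)
    return out


def stepwise_aic_reduction(
    full_fit: SFModelFit,
    records: pd.DataFrame,
    response: str = "sl_db",
) -> tuple[SFModelFit, list[tuple[tuple[str, ...], float]]]:
    """Backward elimination over fixed-effect terms by AIC.

    At each step every droppable term (marginality respected: a main
    effect stays while any of its interactions remain) is tentatively
    removed; the drop lowering the AIC most is kept. Stops at a local AIC
    minimum. The random intercept is never dropped. Returns the selected
    fit and the (terms, AIC) trace of accepted models.
    """
    current = full_fit
    trace = [(tuple(current.terms), current.aic)]
    while True:
        best = None
        for t in _droppable(current.terms):
            cand_terms = [x for x in current.terms if x != t]
            cand = fit_sf_model(records, cand_terms, response)
            if best is None or cand.aic < best.aic:
                best = cand
        if best is None or best.aic >= current.aic:
            return current, trace
        current = best
        trace.append((tuple(current.terms), current.aic))


def abnormal_threshold(
    healthy_rpe_e_values, percentile: float = 95.0
) -> float:
    """Healthy-cohort RPE-E percentile (linear interpolation convention).

    A location counts as abnormal only when its RPE-E is strictly greater
    than the returned threshold.
    """
    v = np.asarray(healthy_rpe_e_values, dtype=float)
    if v.size == 0:
        raise ValueError("empty healthy RPE-E pool")
    return float(np.percentile(v, percentile))


def flag_abnormal(records: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Add the strict-inequality ``abnormal`` flag."""
    out = records.copy()
    out["abnormal"] = out["rpe_e_mean_um"].to_numpy(dtype=float) > threshold
    return out


@dataclass
class SubsetResult:
    fit_all: SFModelFit
    fit_abnormal: SFModelFit
    r2_ratio: float


def subset_analysis(
    records: pd.DataFrame,
    threshold: float,
    terms: list[str] | None = None,
    response: str = "sl_db",
) -> dict[str, SubsetResult]:
    """Refit per test on all locations vs. abnormal-RPE-E locations only.

    Returns, per test type present in the records, both fits and the
    ratio of the abnormal-subset fixed-effect R^2 to the all-locations
    one.
    """
    if terms is None:
        terms = list(FULL_TERMS)
    out = {}
    for t in sorted(records["test_type"].unique()):
        df = records[records["test_type"] == t]
        sub = df[df["rpe_e_mean_um"] > threshold]
        if sub["eye_id"].nunique() < 2:
            raise ValueError(
                f"too few abnormal records for test {t!r} "
                f"({sub['eye_id'].nunique()} eyes)"
            )
        fit_all = fit_sf_model(df, terms, response)
        fit_sub = fit_sf_model(sub, terms, response)
        ratio = (fit_sub.r2_fixed / fit_all.r2_fixed
                 if fit_all.r2_fixed != 0 else np.inf)
        out[t] = SubsetResult(fit_all, fit_sub, float(ratio))
    return out


def univariable_table(
    records: pd.DataFrame, response: str = "sl_db"
) -> pd.DataFrame:
    """Predictor-by-test table of univariable R^2 and p values."""
    rows = []
    for t in sorted(records["test_type"].unique()):
        df = records[records["test_type"] == t]
        for p in PREDICTORS:
            fit = fit_univariable(df, p, response)
            col = LOG_COLUMNS[p][1]
            rows.append(
                {
                    "test_type": t,
                    "predictor": p,
                    "slope": float(fit.params[col]),
                    "r2_fixed": fit.r2_fixed,
                    "p_value": float(fit.pvalues[col]),
                    "n_records": fit.n_records,
                }
            )
    return pd.DataFrame(rows)
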