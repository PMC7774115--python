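"""Per-test normative sensitivity models and the sensitivity loss.

Three model forms, fitted on the healthy cohort with a per-eye random
intercept (maximum likelihood):

* mesopic and scotopic red: ``sensitivity ~ eccentricity + age``
* scotopic cyan: ``sensitivity ~ ln(ecc) + ln(ecc)^2`` (no age term; the
  rod-density dip toward the fovea needs the log-quadratic shape, and
  age carries no significant effect for this stimulus)

Only the fixed effects serve as the normative reference; patient
sensitivity loss is the observed (MP-compensated for cyan) sensitivity
minus that fixed-effects prediction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._mixed import fit_mixed_ml

MODEL_FORMS = {
    "mesopic": "linear_ecc_age",
    "scotopic_red": "linear_ecc_age",
    "scotopic_cyan": "log_ecc_quadratic",
}


@dataclass
class NormativeModel:
    """Fitted normative reference for one test type."""

    test_type: str
    coefficients: dict[str, float]
    re_var: float  # between-eye random-intercept variance, dB^2
    resid_var: float  # residual variance, dB^2
    n_eyes: int
    n_locations: int
    standard_errors: dict[str, float] | None = None  # Wald SEs

    @property
    def form(self) -> str:
        return MODEL_FORMS[self.test_type]

    def __post_init__(self) -> None:
        if self.test_type not in MODEL_FORMS:
            raise ValueError(f"unknown test type {self.test_type!r}")
        expected = (
            {"Intercept", "eccentricity_deg", "age_years"}
            if self.form == "linear_ecc_age"
            else {"Intercept", "log_ecc", "log_ecc_sq"}
        )
        if set(self.coefficients) != expected:
            raise ValueError(
                f"coefficients {set(self.coefficients)} do not match the "
                f"{self.form} form ({expected})"
            )
        if self.re_var < 0 or self.resid_var < 0:
            raise ValueError("variances must be non-negative")

    def to_json(self) -> str:
        return json.dumps(
            {
                "test_type": self.test_type,
                "form": self.form,
                "coefficients": self.coefficients,
                "re_var": self.re_var,
                "resid_var": self.resid_var,
                "n_eyes": self.n_eyes,
                "n_locations": self.n_locations,
                "standard_errors": self.standard_errors,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "NormativeModel":
        d = json.loads(text)
        return cls(
            test_type=d["test_type"],
            coefficients=d["coefficients"],
            re_var=d["re_var"],
            resid_var=d["resid_var"],
            n_eyes=d["n_eyes"],
            n_locations=d["n_locations"],
            standard_errors=d.get("standard_errors"),
        )


def _with_log_ecc(records: pd.DataFrame) -> pd.DataFrame:
    out = records.copy()
    ecc = out["eccentricity_deg"].to_numpy(dtype=float)
    if np.any(ecc <= 0):
        raise ValueError("eccentricity must be positive (log undefined)")
    out["log_ecc"] = np.log(ecc)
    out["log_ecc_sq"] = out["log_ecc"] ** 2
    return out


def fit_normative(records: pd.DataFrame, test_type: str) -> NormativeModel:
    """Fit the normative mixed model for one test on healthy records.

    ``records`` must hold one row per tested location with the standard
    columns; cyan rows must already be MP-compensated. Rows of other test
    types are ignored.
    """
    if test_type not in MODEL_FORMS:
        raise ValueError(f"unknown test type {test_type!r}")
    df = records[records["test_type"] == test_type]
    if df["eye_id"].nunique() < 2:
        raise ValueError("need records from at least 2 eyes")
    if MODEL_FORMS[test_type] == "linear_ecc_age":
        terms = ["eccentricity_deg", "age_years"]
    else:
        df = _with_log_ecc(df)
        terms = ["log_ecc", "log_ecc_sq"]
    fit = fit_mixed_ml(df, "sensitivity_db", terms)
    return NormativeModel(
        test_type=test_type,
        coefficients={k: float(v) for k, v in fit.params.items()},
        re_var=max(fit.re_var, 0.0),
        resid_var=max(fit.resid_var, 0.0),
        n_eyes=fit.n_groups,
        n_locations=fit.n_records,
        standard_errors={k: float(v) for k, v in fit.bse.items()},
    )


def predict_normative(model: NormativeModel, eccentricity, age=None):
    """Fixed-effects-only expected sensitivity, dB.

    The per-eye random intercept is never applied: the normative
    reference is the population-level prediction.
    """
    ecc = np.asarray(eccentricity, dtype=float)
    if np.any(ecc <= 0):
        raise ValueError("eccentricity must be positive")
    c = model.coefficients
    if model.form == "linear_ecc_age":
        if age is None:
            raise ValueError("this model form requires age")
        return (
            c["Intercept"]
            + c["eccentricity_deg"] * ecc
            + c["age_years"] * np.asarray(age, dtype=float)
        )
    le = np.log(ecc)
    return c["Intercept"] + c["log_ecc"] * le + c["log_ecc_sq"] * le**2


def sensitivity_loss(observed, expected):
    """SL = observed - expected; negative values indicate a loss."""
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if not (np.all(np.isfinite(obs)) and np.all(np.isfinite(exp))):
        raise ValueError("observed and expected must be finite")
    return obs - exp


def apply_normative(
    records: pd.DataFrame, models: dict[str, NormativeModel]
) -> pd.DataFrame:
    """Add ``expected_db`` and ``sl_db`` columns to a record table."""
    out = records.copy()
    out["expected_db"] = np.nan
    for t, model in models.items():
        sel = out["test_type"] == t
        if not sel.any():
            continue
        out.loc[sel, "expected_db"] = predict_normative(
            model,
            out.loc[sel, "eccentricity_deg"].to_numpy(),
            out.loc[sel, "age_years"].to_numpy(),
        )
    # plain subtraction here: rows whose test type has no model keep NaN
    out["sl_db"] = out["sensitivity_db"] - out["expected_db"]
    return out
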