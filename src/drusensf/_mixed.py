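"""Shared random-intercept mixed-model fitting on explicit design matrices.

All fits use maximum likelihood (not REML) so that likelihood-ratio
tests and AIC comparisons across fixed-effect structures are valid
without refitting. Interaction columns are plain products of their main
columns. Degenerate cases (a single grouping level, a vanishing random
intercept variance) are allowed: the mixed fit then collapses toward
ordinary least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM


def design_matrix(data: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    """Intercept + named columns; ``a:b`` terms are columnwise products."""
    out = pd.DataFrame({"Intercept": np.ones(len(data))}, index=data.index)
    for t in terms:
        parts = t.split(":")
        col = data[parts[0]].to_numpy(dtype=float).copy()
        for p in parts[1:]:
            col = col * data[p].to_numpy(dtype=float)
        out[t] = col
    return out


@dataclass
class MixedFit:
    """Result of one ML random-intercept fit."""

    terms: list[str]
    params: pd.Series  # fixed effects, incl. Intercept
    bse: pd.Series
    pvalues: pd.Series  # Wald z
    re_var: float  # random-intercept variance
    resid_var: float
    llf: float
    n_records: int
    n_groups: int

    @property
    def k_params(self) -> int:
        """Fixed effects + random-intercept variance + residual variance."""
        return len(self.params) + 2

    @property
    def aic(self) -> float:
        return 2.0 * self.k_params - 2.0 * self.llf

    def predict_fixed(self, data: pd.DataFrame) -> np.ndarray:
        """Fixed-effects-only prediction (random intercepts never applied)."""
        X = design_matrix(data, self.terms)
        return X.to_numpy() @ self.params.reindex(X.columns).to_numpy()


def fit_mixed_ml(
    data: pd.DataFrame,
    response: str,
    terms: list[str],
    group: str = "eye_id",
) -> MixedFit:
    """ML random-intercept fit of ``response ~ 1 + terms`` grouped by eye."""
    X = design_matrix(data, terms)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient fixed-effect design ({rank} < {X.shape[1]}); "
            f"collinear terms among {list(X.columns)}"
        )
    y = data[response].to_numpy(dtype=float)
    groups = data[group].to_numpy()
    if len(np.unique(groups)) < 2:
        # a single eye cannot identify the random intercept: the mixed fit
        # degenerates to ordinary least squares with zero intercept variance
        import statsmodels.api as sm

        ols = sm.OLS(y, X.to_numpy()).fit()
        return MixedFit(
            terms=list(terms),
            params=pd.Series(ols.params, index=X.columns),
            bse=pd.Series(ols.bse, index=X.columns),
            pvalues=pd.Series(ols.pvalues, index=X.columns),
            re_var=0.0,
            resid_var=float(np.mean(ols.resid**2)),
            llf=float(ols.llf),
            n_records=len(y),
            n_groups=1,
        )
    # standardize the non-intercept columns for conditioning; the fit is an
    # exact linear reparametrization, mapped back afterwards
    Xn = X.to_numpy(dtype=float)
    p = Xn.shape[1]
    centers = Xn[:, 1:].mean(axis=0)
    scales = Xn[:, 1:].std(axis=0)
    scales[scales == 0] = 1.0
    Xs = Xn.copy()
    Xs[:, 1:] = (Xs[:, 1:] - centers) / scales
    A = np.eye(p)
    A[0, 1:] = -centers / scales
    A[1:, 1:] = np.diag(1.0 / scales)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(y, Xs, groups=groups)
        try:
            res = model.fit(reml=False)
            if not np.all(np.isfinite(res.params)):
                raise ValueError("non-finite parameters")
        except Exception:
            res = model.fit(reml=False, method="powell")
    beta = A @ np.asarray(res.fe_params)
    cov = A @ np.asarray(res.cov_params())[:p, :p] @ A.T
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.inf)
    params = pd.Series(beta, index=X.columns)
    bse = pd.Series(se, index=X.columns)
    pvalues = pd.Series(2.0 * stats.norm.sf(np.abs(z)), index=X.columns)
    return MixedFit(
        terms=list(terms),
        params=params,
        bse=bse,
        pvalues=pvalues,
        re_var=float(np.asarray(res.cov_re)[0, 0]),
        resid_var=float(res.scale),
        llf=float(res.llf),
        n_records=len(y),
        n_groups=len(np.unique(groups)),
    )
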