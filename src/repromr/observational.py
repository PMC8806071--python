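"""Observational arm: covariate adjustment with rank-based inverse-normal
transformation, logistic exposure-outcome models, and fractional-polynomial
closed-test model selection with AIC comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .nonlinear import FP_POWER_GRID, _fp_basis

__all__ = [
    "AdjustedExposure", "FitComparison", "adjust_and_int", "logistic_or",
    "mfp_closed_test", "FractionalPolynomialLogit",
]


class ObservationalError(ValueError):
    pass


@dataclass
class AdjustedExposure:
    """Covariate-adjusted, rank-inverse-normal-transformed exposure
    (unitless; mean ~ 0, SD ~ 1)."""

    values: np.ndarray
    covariates_used: list
    offset: float

    def __len__(self):
        return self.values.size


def rank_inverse_normal(x, offset: float = 0.375) -> np.ndarray:
    """Blom-style rank-based inverse normal transform.

    Phi^-1((rank - offset) / (n - 2*offset + 1)), with ties sharing the
    average rank.
    """
    x = np.asarray(x, float)
    n = x.size
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - offset) / (n - 2.0 * offset + 1.0))


def adjust_and_int(exposure, covariates=None, *, offset: float = 0.375
                   ) -> AdjustedExposure:
    """Residualise the exposure on covariates, then apply the rank-based
    inverse normal transform.

    ``covariates`` is a DataFrame (categorical columns are dummy-coded) or
    None for no adjustment.  Rank order of the residuals is preserved.
    """
    x = np.asarray(exposure, float)
    if x.size < 10:
        raise ObservationalError("need n >= 10")
    if np.ptp(x) == 0:
        raise ObservationalError("constant exposure")
    used = []
    if covariates is not None and len(covariates.columns):
        cov = pd.get_dummies(covariates, drop_first=True, dtype=float)
        used = list(cov.columns)
        X = sm.add_constant(cov.to_numpy(float))
        x = sm.OLS(x, X).fit().resid
    return AdjustedExposure(rank_inverse_normal(x, offset), used, offset)


def logistic_or(outcome, exposure, covariates=None) -> dict:
    """Maximum-likelihood logistic regression of a binary outcome on a
    (transformed) exposure; returns OR per 1 SD with 95% CI and p-value.
    """
    y = np.asarray(outcome, float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ObservationalError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ObservationalError("both outcome classes must be present")
    x = exposure.values if isinstance(exposure, AdjustedExposure) else np.asarray(exposure, float)
    cols = [x]
    if covariates is not None:
        cov = pd.get_dummies(covariates, drop_first=True, dtype=float)
        cols.extend(cov[c].to_numpy(float) for c in cov.columns)
    X = sm.add_constant(np.column_stack(cols))
    try:
        fit = sm.Logit(y, X).fit(disp=0)
    except Exception as err:          # pragma: no cover - separation path
        raise ObservationalError(f"logistic fit failed: {err}") from err
    if not np.isfinite(fit.bse[1]) or fit.bse[1] > 1e3:
        raise ObservationalError("complete separation suspected")
    beta, se = fit.params[1], fit.bse[1]
    z = stats.norm.ppf(0.975)
    return {"beta": float(beta), "se": float(se),
            "or": float(np.exp(beta)),
            "ci_low": float(np.exp(beta - z * se)),
            "ci_high": float(np.exp(beta + z * se)),
            "pvalue": float(2 * stats.norm.sf(abs(beta / se))),
            "aic": float(fit.aic)}


@dataclass
class FitComparison:
    """AIC comparison across candidate models; ``selected`` attains the
    minimum AIC."""

    aic: dict

    @property
    def selected(self) -> str:
        return min(self.aic, key=self.aic.get)

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame(sorted(self.aic.items()), columns=["model", "aic"])
        df["selected"] = df["model"] == self.selected
        return df


class FractionalPolynomialLogit:
    """Fractional-polynomial logistic model with closed-test selection.

    The closed test proceeds on deviance differences with the conventional
    degrees of freedom (each estimated power counts one):

    1. best FP2 vs covariate-only null on 4 df — overall association; if not
       significant the null model is selected;
    2. best FP2 vs linear on 3 df — evidence of non-linearity; if not
       significant the linear model is selected;
    3. best FP2 vs best FP1 on 2 df — degree; FP1 if not significant.

    The exposure is shifted to be strictly positive when required by the
    log/negative powers.
    """

    def __init__(self, outcome, exposure, covariates=None, *,
                 powers_set=FP_POWER_GRID):
        self.y = np.asarray(outcome, float)
        x = np.asarray(exposure, float)
        self.shift = 0.0
        if x.min() <= 0:
            self.shift = 1.0 - x.min()
        self.x = x + self.shift
        self.powers_set = tuple(powers_set)
        if covariates is not None:
            cov = pd.get_dummies(covariates, drop_first=True, dtype=float)
            self.Z = cov.to_numpy(float)
        else:
            self.Z = np.empty((self.y.size, 0))

    def _deviance(self, fp_powers):
        cols = [np.ones_like(self.x)]
        if fp_powers:
            cols.append(_fp_basis(self.x, fp_powers))
        if self.Z.shape[1]:
            cols.append(self.Z)
        X = np.column_stack(cols)
        fit = sm.GLM(self.y, X, family=sm.families.Binomial()).fit()
        return float(fit.deviance), float(fit.aic), fit

    def fit(self, *, alpha: float = 0.05):
        dev_null, aic_null, _ = self._deviance(())
        dev_lin, aic_lin, fit_lin = self._deviance((1.0,))
        fp1 = {p: self._deviance((p,)) for p in self.powers_set}
        best_p1 = min(fp1, key=lambda p: fp1[p][0])
        pairs = [(p, q) for i, p in enumerate(self.powers_set)
                 for q in self.powers_set[i:]]
        fp2 = {pq: self._deviance(pq) for pq in pairs}
        best_p2 = min(fp2, key=lambda pq: fp2[pq][0])
        dev_fp1, aic_fp1, fit_fp1 = fp1[best_p1]
        dev_fp2, aic_fp2, fit_fp2 = fp2[best_p2]

        p_overall = float(stats.chi2.sf(max(dev_null - dev_fp2, 0), 4))
        p_nonlin = float(stats.chi2.sf(max(dev_lin - dev_fp2, 0), 3))
        p_degree = float(stats.chi2.sf(max(dev_fp1 - dev_fp2, 0), 2))

        if p_overall >= alpha:
            selected, powers, fit = "null", (), None
        elif p_nonlin >= alpha:
            selected, powers, fit = "linear", (1.0,), fit_lin
        elif p_degree >= alpha:
            selected, powers, fit = "fp1", (best_p1,), fit_fp1
        else:
            selected, powers, fit = "fp2", best_p2, fit_fp2

        comparison = FitComparison({"null": aic_null, "linear": aic_lin,
                                    f"fp1{best_p1}": aic_fp1,
                                    f"fp2{best_p2}": aic_fp2})
        return FPClosedTestResults(selected, powers, fit, comparison,
                                   p_overall, p_nonlin, p_degree, self.shift)


@dataclass
class FPClosedTestResults:
    selected: str
    powers: tuple
    model_fit: object
    comparison: FitComparison
    p_overall: float
    p_nonlinearity: float
    p_degree: float
    shift: float

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame([
            ("selected", self.selected),
            ("powers", str(self.powers)),
            ("p_overall", self.p_overall),
            ("p_nonlinearity", self.p_nonlinearity),
            ("p_degree", self.p_degree),
            ("min_aic_model", self.comparison.selected),
        ], columns=["statistic", "value"])


def mfp_closed_test(outcome, exposure, covariates=None, *,
                    powers_set=FP_POWER_GRID, alpha: float = 0.05):
    """Functional wrapper: fractional-polynomial closed-test selection."""
    return FractionalPolynomialLogit(outcome, exposure, covariates,
                                     powers_set=powers_set).fit(alpha=alpha)
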