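"""Two-sample Mendelian randomisation estimators and diagnostics.

Implements the estimator stack used for summary-data MR of a (possibly
binary) outcome on a continuous exposure: the per-SNP Wald ratio, the
inverse-variance-weighted (IVW) estimator, MR-Egger regression, the weighted
median estimator, heterogeneity statistics (Cochran's Q for IVW and Q' for
Egger), the Rucker model-selection framework, the Steiger directionality
test, a binary-outcome power approximation, and the two-estimate
heterogeneity z-test.

The model-level entry point is :class:`TwoSampleMR`, built from a
:class:`~repromr.sumstats.HarmonizedInstruments`; ``fit()`` returns a
:class:`TwoSampleMRResults` carrying one :class:`MRResult` per method plus
the Rucker selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import HarmonizedInstruments

__all__ = [
    "MRResult", "SteigerResult", "RuckerDecision",
    "wald_ratio", "ivw", "mr_egger", "weighted_median",
    "rucker_select", "steiger", "power_binary", "het_between",
    "TwoSampleMR", "TwoSampleMRResults",
]

Z95 = stats.norm.ppf(0.975)


class MRError(ValueError):
    pass


@dataclass
class MRResult:
    """Causal-effect estimate from one summary-data MR method.

    ``beta`` is the causal slope: log OR per 1 SD of exposure for a binary
    outcome.  ``or_``/``ci_low``/``ci_high`` are the exponentiated point
    estimate and 95% bounds.  ``q`` is Cochran's Q about the fitted model
    (Q for IVW, Q' for Egger).  Intercept fields are populated by Egger only.
    """

    method: str
    beta: float
    se: float
    pvalue: float
    n_snps: int
    q: float | None = None
    q_df: int | None = None
    q_pvalue: float | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pvalue: float | None = None

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.beta - Z95 * self.se))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.beta + Z95 * self.se))

    def as_row(self) -> dict:
        return {
            "method": self.method, "beta": self.beta, "se": self.se,
            "pvalue": self.pvalue, "or": self.or_, "ci_low": self.ci_low,
            "ci_high": self.ci_high, "n_snps": self.n_snps, "q": self.q,
            "q_df": self.q_df, "q_pvalue": self.q_pvalue,
            "intercept": self.intercept, "intercept_se": self.intercept_se,
            "intercept_pvalue": self.intercept_pvalue,
        }


@dataclass
class SteigerResult:
    r2_exposure: float
    r2_outcome: float
    direction_ok: bool
    pvalue: float


@dataclass
class RuckerDecision:
    selected: str                 # "ivw" | "egger"
    q_ivw: float
    q_egger: float
    q_ratio: float                # Q' / Q
    q_pvalue: float
    q_diff_pvalue: float
    intercept_pvalue: float | None

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def _two_sided_p(z):
    return float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# estimators

def wald_ratio(bx: float, sx: float, by: float, sy: float, *,
               second_order: bool = False) -> MRResult:
    """Single-SNP causal estimate: by/bx.

    First-order SE ``sy/|bx|`` by default; ``second_order=True`` adds the
    exposure-uncertainty term sqrt(sy^2/bx^2 + by^2 sx^2 / bx^4).
    """
    if bx == 0:
        raise MRError("Wald ratio undefined for bx = 0")
    beta = by / bx
    if second_order:
        se = float(np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4))
    else:
        se = sy / abs(bx)
    return MRResult("wald", float(beta), float(se), _two_sided_p(beta / se), 1)


def ivw(instruments: HarmonizedInstruments, *,
        random_effects: bool = False) -> MRResult:
    """Inverse-variance-weighted estimate.

    Weighted (1/sy^2) regression of outcome effects on exposure effects
    through the origin.  Fixed-effect by default: the residual scale is held
    at 1, so the SE is 1/sqrt(sum w bx^2).  ``random_effects=True`` inflates
    the SE by sqrt(max(1, Q/df)) (multiplicative random-effects model).
    A single SNP degrades to the Wald ratio.
    """
    bx, sx, by, sy = instruments.arrays()
    n = bx.size
    if n < 1:
        raise MRError("IVW needs at least one SNP")
    if n == 1:
        return wald_ratio(bx[0], sx[0], by[0], sy[0])
    w = 1.0 / sy**2
    denom = np.sum(w * bx**2)
    beta = float(np.sum(w * bx * by) / denom)
    se = float(1.0 / np.sqrt(denom))
    q = float(np.sum(w * (by - beta * bx) ** 2))
    q_df = n - 1
    if random_effects:
        se *= float(np.sqrt(max(1.0, q / q_df)))
    return MRResult("ivw", beta, se, _two_sided_p(beta / se), n,
                    q=q, q_df=q_df, q_pvalue=float(stats.chi2.sf(q, q_df)))


def mr_egger(instruments: HarmonizedInstruments, *,
             random_effects: bool = False) -> MRResult:
    """MR-Egger regression: weighted fit of by on bx with an intercept.

    SNP orientation is first fixed so every exposure effect is non-negative
    (flipping the sign of both bx and by where needed); the intercept then
    estimates average directional pleiotropy and the slope a
    pleiotropy-adjusted causal effect.  Q' is the weighted residual sum of
    squares on n-2 df.
    """
    bx, sx, by, sy = instruments.arrays()
    n = bx.size
    if n < 3:
        raise MRError("MR-Egger needs at least 3 SNPs")
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(n), bx])
    xtw = X.T * w
    cov = np.linalg.inv(xtw @ X)          # residual scale fixed at 1
    coef = cov @ (xtw @ by)
    resid = by - X @ coef
    q = float(np.sum(w * resid**2))
    q_df = n - 2
    icpt_se, slope_se = np.sqrt(np.diag(cov))
    if random_effects:
        infl = float(np.sqrt(max(1.0, q / q_df)))
        icpt_se, slope_se = icpt_se * infl, slope_se * infl
    icpt, slope = coef
    return MRResult(
        "egger", float(slope), float(slope_se),
        _two_sided_p(slope / slope_se), n,
        q=q, q_df=q_df, q_pvalue=float(stats.chi2.sf(q, q_df)),
        intercept=float(icpt), intercept_se=float(icpt_se),
        intercept_pvalue=_two_sided_p(icpt / icpt_se))


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median (cumulative weight 0.5)."""
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w) - 0.5 * w
    cw /= np.sum(w)
    return float(np.interp(0.5, cw, v))


def weighted_median(instruments: HarmonizedInstruments, *,
                    n_boot: int = 5000, seed: int) -> MRResult:
    """Weighted median of per-SNP Wald ratios.

    Weights are the inverse variances of the first-order ratio SEs.
    Consistent when up to half the instrument weight comes from invalid
    (pleiotropic) SNPs.  The SE is estimated by a seeded parametric
    bootstrap: (bx, by) resampled from normal errors around their estimates.
    """
    bx, sx, by, sy = instruments.arrays()
    n = bx.size
    if n < 3:
        raise MRError("weighted median needs at least 3 SNPs")
    theta = by / bx
    w = (bx / sy) ** 2               # 1 / se(ratio)^2, first order
    est = _weighted_median(theta, w)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bxs = bx + sx * rng.standard_normal(n)
        bys = by + sy * rng.standard_normal(n)
        boots[i] = _weighted_median(bys / bxs, (bxs / sy) ** 2)
    se = float(np.std(boots, ddof=1))
    return MRResult("weighted_median", est, se, _two_sided_p(est / se), n)


# ---------------------------------------------------------------------------
# diagnostics

def rucker_select(ivw_res: MRResult, egger_res: MRResult, *,
                  alpha_q: float = 0.05) -> RuckerDecision:
    """Rucker framework: choose between IVW and MR-Egger.

    If the IVW Q shows no significant heterogeneity, IVW is retained (the
    more powerful model).  Otherwise Egger is preferred only when the Q - Q'
    reduction is significant on 1 df *and* the Egger intercept is significant
    — i.e. when the extra intercept genuinely absorbs directional pleiotropy;
    otherwise IVW is kept despite heterogeneity.
    """
    q, q_df = ivw_res.q, ivw_res.q_df
    qp, qp_df = egger_res.q, egger_res.q_df
    q_p = float(stats.chi2.sf(q, q_df))
    q_diff = max(q - qp, 0.0)
    q_diff_p = float(stats.chi2.sf(q_diff, 1))
    if q_p >= alpha_q:
        selected = "ivw"
    elif q_diff_p < alpha_q and (egger_res.intercept_pvalue or 1.0) < alpha_q:
        selected = "egger"
    else:
        selected = "ivw"
    return RuckerDecision(selected, q, qp, qp / q if q > 0 else np.nan,
                          q_p, q_diff_p, egger_res.intercept_pvalue)


def _per_snp_r2(beta, se, n, eaf, trait_type):
    """Per-SNP variance explained.

    For a variance-standardised continuous trait with known EAF:
    r^2 = 2 f (1-f) beta^2.  Fallback (binary traits or missing EAF):
    t^2 / (t^2 + n - 2) from the t-statistic.
    """
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    if trait_type == "continuous" and eaf is not None and not np.any(np.isnan(eaf)):
        f = np.asarray(eaf, float)
        return 2.0 * f * (1.0 - f) * beta**2
    if n is None or np.any(np.isnan(np.asarray(n, float))):
        raise MRError("per-SNP r^2 not computable: need eaf (continuous) or n")
    t2 = (beta / se) ** 2
    return t2 / (t2 + np.asarray(n, float) - 2.0)


def steiger(instruments: HarmonizedInstruments, *, n_exposure: float,
            n_outcome: float, exposure_type: str = "continuous",
            outcome_type: str = "binary",
            eaf_outcome=None) -> SteigerResult:
    """MR-Steiger directionality test.

    Compares the variance the instrument explains in the exposure versus in
    the outcome; the causal direction exposure -> outcome is supported when
    the former is larger.  The p-value is from the z-comparison of the two
    Fisher-transformed multiple correlations.
    """
    d = instruments.df
    r2_x = float(np.sum(_per_snp_r2(d["bx"], d["sx"], n_exposure,
                                    d["eaf"].to_numpy(float), exposure_type)))
    r2_y = float(np.sum(_per_snp_r2(d["by"], d["sy"], n_outcome,
                                    eaf_outcome, outcome_type)))
    r2_x, r2_y = min(r2_x, 1.0), min(r2_y, 1.0)
    zx = np.arctanh(np.sqrt(r2_x))
    zy = np.arctanh(np.sqrt(r2_y))
    z = (zx - zy) / np.sqrt(1.0 / (n_exposure - 3) + 1.0 / (n_outcome - 3))
    return SteigerResult(r2_x, r2_y, bool(r2_x > r2_y), _two_sided_p(z))


def power_binary(n: float, case_fraction: float, r2_instrument: float,
                 or_true: float, alpha: float = 0.05) -> float:
    """Approximate power of two-sample MR with a binary outcome.

    Uses the normal-test approximation with the log-OR standard error
    1/sqrt(n * r2 * phi * (1-phi)), where phi is the case fraction of the
    outcome GWAS and r2 the exposure variance explained by the instrument.
    Returns the two-sided rejection probability; equals alpha when the true
    OR is 1.
    """
    b = abs(np.log(or_true))
    se = 1.0 / np.sqrt(n * r2_instrument * case_fraction * (1.0 - case_fraction))
    z_a = stats.norm.ppf(1.0 - alpha / 2.0)
    return float(stats.norm.sf(z_a - b / se) + stats.norm.cdf(-z_a - b / se))


def het_between(beta1: float, se1: float, beta2: float, se2: float):
    """Heterogeneity z-test between two independent estimates.

    Returns (z, p); z = (b1 - b2)/sqrt(se1^2 + se2^2), two-sided normal p.
    """
    if se1 <= 0 or se2 <= 0:
        raise MRError("SEs must be positive")
    z = (beta1 - beta2) / np.sqrt(se1**2 + se2**2)
    return float(z), _two_sided_p(z)


# ---------------------------------------------------------------------------
# model / results wrappers

class TwoSampleMR:
    """Two-sample MR model over a harmonised instrument set.

    Parameters
    ----------
    instruments : HarmonizedInstruments
    random_effects : bool
        Multiplicative random-effects SEs for IVW/Egger (default fixed-effect).

    Examples
    --------
    >>> res = TwoSampleMR(instruments).fit(seed=7)
    >>> res.selected                    # Rucker-selected method label
    >>> print(res.summary())
    """

    def __init__(self, instruments: HarmonizedInstruments, *,
                 random_effects: bool = False):
        self.instruments = instruments
        self.random_effects = random_effects

    def fit(self, methods=("ivw", "egger", "weighted_median"), *,
            alpha_q: float = 0.05, n_boot: int = 5000,
            seed: int | None = None) -> "TwoSampleMRResults":
        results: dict[str, MRResult] = {}
        n = self.instruments.n_snps
        if "ivw" in methods:
            results["ivw"] = ivw(self.instruments, random_effects=self.random_effects)
        if "egger" in methods and n >= 3:
            results["egger"] = mr_egger(self.instruments,
                                        random_effects=self.random_effects)
        if "weighted_median" in methods and n >= 3:
            if seed is None:
                raise MRError("weighted_median requires a seed")
            results["weighted_median"] = weighted_median(
                self.instruments, n_boot=n_boot, seed=seed)
        rucker = None
        if "ivw" in results and "egger" in results:
            rucker = rucker_select(results["ivw"], results["egger"], alpha_q=alpha_q)
        return TwoSampleMRResults(self.instruments, results, rucker)


@dataclass
class TwoSampleMRResults:
    instruments: HarmonizedInstruments
    results: dict = field(default_factory=dict)
    rucker: RuckerDecision | None = None

    @property
    def selected(self) -> str:
        return self.rucker.selected if self.rucker else "ivw"

    @property
    def selected_result(self) -> MRResult:
        return self.results[self.selected]

    def summary(self) -> pd.DataFrame:
        rows = [r.as_row() for r in self.results.values()]
        df = pd.DataFrame(rows)
        df.insert(0, "exposure", self.instruments.exposure_label)
        df.insert(1, "outcome", self.instruments.outcome_label)
        df["rucker_selected"] = df["method"] == self.selected
        return df
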