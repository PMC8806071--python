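"""Multivariable MR and two-step mediation analysis.

Two-step MR decomposes the total genetically predicted effect ``c`` of an
exposure on a (binary) outcome into an indirect path through a mediator —
the product of the exposure-to-mediator effect ``a`` (SD per SD, univariable
MR) and the mediator-to-outcome effect ``b`` (log OR per SD, from
multivariable MR adjusted for the exposure) — and a direct effect.  The
proportion mediated is ``a*b/c`` with a first-order delta-method standard
error treating a, b and c as independent:

    se^2 = (b*se_a/c)^2 + (a*se_b/c)^2 + (a*b*se_c/c^2)^2

Confidence bounds are truncated to [0, 1] at the reporting layer only.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import HarmonizedInstruments
from .pipeline import bh_fdr

__all__ = [
    "MVMRResult", "MediationResult", "MultivariableMR",
    "mvmr_ivw", "two_step_mediation", "or_from_log", "mediation_grid",
    "load_printed_mediation_inputs",
]

Z95 = stats.norm.ppf(0.975)


class MediationError(ValueError):
    pass


@dataclass
class MVMRResult:
    """Per-exposure conditional effects from multivariable MR."""

    exposures: list
    beta: np.ndarray
    se: np.ndarray
    pvalue: np.ndarray
    n_snps: int
    conditional_f: np.ndarray | None = None

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "exposure": self.exposures, "beta": self.beta, "se": self.se,
            "pvalue": self.pvalue,
        })
        if self.conditional_f is not None:
            df["conditional_f"] = self.conditional_f
        df["n_snps"] = self.n_snps
        return df

    def for_exposure(self, label: str) -> tuple[float, float, float]:
        i = self.exposures.index(label)
        return float(self.beta[i]), float(self.se[i]), float(self.pvalue[i])


class MultivariableMR:
    """Multivariable MR model: outcome effects regressed jointly on several
    exposures' SNP effects (weights 1/sy^2, no intercept).

    Parameters
    ----------
    exposure_effects : pandas.DataFrame
        One column per exposure; rows are SNPs (union of all instruments,
        harmonised to a common effect allele and to the outcome).
    by, sy : array-like
        Outcome effects and SEs for the same SNPs.
    """

    def __init__(self, exposure_effects: pd.DataFrame, by, sy):
        self.X = exposure_effects
        self.by = np.asarray(by, float)
        self.sy = np.asarray(sy, float)
        if len(self.X) != self.by.size:
            raise MediationError("exposure matrix and outcome effects differ in length")
        if len(self.X) < self.X.shape[1] + 1:
            raise MediationError("need at least (n_exposures + 1) SNPs")

    def fit(self) -> MVMRResult:
        Xm = self.X.to_numpy(float)
        w = 1.0 / self.sy**2
        xtw = Xm.T * w
        gram = xtw @ Xm
        cond = np.linalg.cond(gram)
        if not np.isfinite(cond) or cond > 1e10:
            # name the offending exposures via pairwise correlation
            corr = np.corrcoef(Xm, rowvar=False)
            np.fill_diagonal(corr, 0.0)
            i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
            raise MediationError(
                f"rank-deficient exposure matrix: {self.X.columns[i]!r} and "
                f"{self.X.columns[j]!r} are collinear")
        cov = np.linalg.inv(gram)            # residual scale fixed at 1
        beta = cov @ (xtw @ self.by)
        se = np.sqrt(np.diag(cov))
        p = 2.0 * stats.norm.sf(np.abs(beta / se))
        # conditional instrument strength: F of each exposure's effects after
        # regressing out the co-included exposures (weighted)
        k = Xm.shape[1]
        cond_f = np.empty(k)
        for col in range(k):
            others = np.delete(Xm, col, axis=1)
            if others.shape[1] == 0:
                resid = Xm[:, col]
            else:
                ow = others * w[:, None]
                gamma = np.linalg.lstsq(ow.T @ others, ow.T @ Xm[:, col], rcond=None)[0]
                resid = Xm[:, col] - others @ gamma
            cond_f[col] = np.sum(w * resid**2) / max(len(resid) - k, 1)
        return MVMRResult(list(self.X.columns), beta, se, p, len(self.X),
                          conditional_f=cond_f)


def mvmr_ivw(exposure_effects: pd.DataFrame, by, sy) -> MVMRResult:
    """Functional form of :class:`MultivariableMR` (IVW weighting)."""
    return MultivariableMR(exposure_effects, by, sy).fit()


# ---------------------------------------------------------------------------
# two-step mediation

@dataclass
class MediationResult:
    """Product-of-coefficients mediation decomposition.

    All effects on the log-OR scale for binary outcomes.  ``proportion`` and
    its CI are raw (untruncated); ``proportion_ci_reported`` truncates to
    [0, 1] for presentation, matching the convention of reporting "0%" lower
    bounds.
    """

    c: float
    se_c: float
    a: float
    se_a: float
    b: float
    se_b: float
    direct: float | None = None
    se_direct: float | None = None

    @property
    def indirect(self) -> float:
        return self.a * self.b

    @property
    def proportion(self) -> float:
        return self.indirect / self.c

    @property
    def proportion_se(self) -> float:
        a, b, c = self.a, self.b, self.c
        return float(np.sqrt((b * self.se_a / c) ** 2
                             + (a * self.se_b / c) ** 2
                             + (a * b * self.se_c / c**2) ** 2))

    @property
    def proportion_ci(self) -> tuple[float, float]:
        half = Z95 * self.proportion_se
        return (self.proportion - half, self.proportion + half)

    @property
    def proportion_ci_reported(self) -> tuple[float, float]:
        lo, hi = self.proportion_ci
        return (min(max(lo, 0.0), 1.0), min(max(hi, 0.0), 1.0))

    def as_row(self) -> dict:
        lo, hi = self.proportion_ci_reported
        return {
            "total_c": self.c, "se_c": self.se_c,
            "mediator_outcome_b": self.b, "se_b": self.se_b,
            "exposure_mediator_a": self.a, "se_a": self.se_a,
            "indirect": self.indirect,
            "proportion_pct": round(100.0 * self.proportion, 1),
            "ci_low_pct": round(100.0 * lo, 1),
            "ci_high_pct": round(100.0 * hi, 1),
        }


def two_step_mediation(a: float, se_a: float, b: float, se_b: float,
                       c: float, se_c: float, *,
                       direct: float | None = None,
                       se_direct: float | None = None) -> MediationResult:
    """Mediation by the product of coefficients.

    ``a``: exposure -> mediator (univariable MR); ``b``: mediator -> outcome
    conditional on the exposure (multivariable MR); ``c``: total exposure ->
    outcome effect.  Proportion mediated = a*b/c with the 3-term independent
    delta-method SE.
    """
    if c == 0:
        raise MediationError("proportion mediated undefined: total effect is 0")
    return MediationResult(c=c, se_c=se_c, a=a, se_a=se_a, b=b, se_b=se_b,
                           direct=direct, se_direct=se_direct)


def or_from_log(log_or: float) -> float:
    """Odds ratio from a log odds ratio."""
    if not np.isfinite(log_or):
        raise MediationError("log OR must be finite")
    return float(np.exp(log_or))


def mediation_grid(triples: pd.DataFrame, *, gate_fdr: float = 0.05,
                   gate_p: float = 0.05) -> pd.DataFrame:
    """Apply the mediation significance gates across a set of
    exposure-mediator-outcome triples and compute mediation where they pass.

    ``triples`` columns: exposure, mediator, outcome, a, se_a, b, se_b,
    c, se_c.  Gates: (i) the total effect c must be significant at
    FDR < ``gate_fdr`` (BH across the exposure-outcome family in the input);
    (ii) the a and b path estimates must each be significant at unadjusted
    p < ``gate_p``.  Skipped triples are returned with a ``skip_reason``.
    """
    df = triples.copy()
    for col in ("a", "b", "c"):
        df[f"p_{col}"] = 2.0 * stats.norm.sf(np.abs(df[col] / df[f"se_{col}"]))
    # FDR over the distinct exposure-outcome total effects
    totals = df.drop_duplicates(["exposure", "outcome"])[["exposure", "outcome", "p_c"]]
    totals = totals.assign(q_c=bh_fdr(totals["p_c"].to_numpy()))
    df = df.merge(totals[["exposure", "outcome", "q_c"]], on=["exposure", "outcome"])

    rows = []
    for rec in df.itertuples(index=False):
        row = {"exposure": rec.exposure, "mediator": rec.mediator,
               "outcome": rec.outcome}
        if rec.q_c >= gate_fdr:
            row["skip_reason"] = "total effect not significant"
        elif rec.p_a >= gate_p:
            row["skip_reason"] = "exposure-mediator path not significant"
        elif rec.p_b >= gate_p:
            row["skip_reason"] = "mediator-outcome path not significant"
        else:
            med = two_step_mediation(rec.a, rec.se_a, rec.b, rec.se_b,
                                     rec.c, rec.se_c)
            row.update(med.as_row())
            row["skip_reason"] = ""
        rows.append(row)
    return pd.DataFrame(rows)


def two_step_from_sumstats(exposure, mediator, outcome, *,
                           p_threshold: float = 5e-9) -> MediationResult:
    """Run the full two-step mediation MR from three summary-statistics
    tables.

    Step 1 — the total effect ``c`` (exposure -> outcome) and the
    exposure -> mediator effect ``a`` are estimated by univariable IVW using
    the exposure's genome-wide significant instruments.  Step 2 — the
    conditional mediator -> outcome effect ``b`` comes from multivariable MR
    over the *combined* instrument set (exposure instruments plus the
    mediator's own instruments), regressing outcome effects jointly on both
    traits' per-SNP effects.
    """
    from .mr import ivw
    from .sumstats import harmonize

    inst_x = exposure.select_instruments(p_threshold)
    if not len(inst_x):
        raise MediationError("no genome-wide significant exposure instruments")
    c_res = ivw(harmonize(inst_x, outcome))
    a_res = ivw(harmonize(inst_x, mediator))

    inst_m = mediator.select_instruments(p_threshold)
    union = pd.concat([inst_x.df["variant_id"], inst_m.df["variant_id"]]
                      ).drop_duplicates()
    frames = {}
    for name, table in (("exposure", exposure), ("mediator", mediator),
                        ("outcome", outcome)):
        frames[name] = table.df.set_index("variant_id").reindex(union)
    keep = ~pd.concat([f["beta"].isna() for f in frames.values()], axis=1
                      ).any(axis=1)
    X = pd.DataFrame({"exposure": frames["exposure"].loc[keep, "beta"],
                      "mediator": frames["mediator"].loc[keep, "beta"]})
    mv = MultivariableMR(X, frames["outcome"].loc[keep, "beta"],
                         frames["outcome"].loc[keep, "se"]).fit()
    b, se_b, _ = mv.for_exposure("mediator")
    direct, se_direct, _ = mv.for_exposure("exposure")
    return two_step_mediation(a_res.beta, a_res.se, b, se_b,
                              c_res.beta, c_res.se,
                              direct=direct, se_direct=se_direct)


def load_printed_mediation_inputs() -> pd.DataFrame:
    """Packaged worked-example path coefficients for the mediation analysis
    of obesity traits on reproductive outcomes (exposure-outcome log OR and
    SE, mediator-outcome log OR and SE, exposure-mediator beta and SE)."""
    with resources.files("repromr.data").joinpath("mediation_paths.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
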