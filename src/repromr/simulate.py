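"""Synthetic individual-level cohorts and two-sample GWAS summary statistics
with known ground truth.

The generative model mirrors the causal chain probed by the pipeline:
unlinked biallelic SNPs (dosages 0/1/2 at frequencies drawn from a
configurable range) build a continuous exposure with heritability ``h2``;
an optional mediator is a linear function of the exposure; and a binary
outcome follows a logistic model

    logit P(Y=1) = alpha + theta_direct * X + b * M + nonlinear(X) + G_inv @ delta

where ``delta`` are direct (pleiotropic) SNP effects on a configurable
fraction of invalid instruments and ``alpha`` is solved numerically to hit
the target prevalence.  Effect alleles are oriented to be
exposure-increasing, as GWAS index variants are reported, so directional
pleiotropy genuinely biases the IVW estimator.  Everything is reproducible
from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special

from .sumstats import CANONICAL_COLUMNS, SummaryStatsTable, normal_p

__all__ = [
    "SimulationConfig", "SyntheticCohort", "simulate_cohort",
    "cohort_to_sumstats", "gwas", "simulate_summary_instruments",
    "benchmark_suite", "BENCHMARK_SCENARIOS",
]


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters for one synthetic cohort.

    ``theta_direct`` is the direct exposure effect on the outcome logit
    (log OR per SD of exposure); with a mediator the total causal effect is
    ``theta_direct + a * b``.  ``nonlinear`` is ``None`` or
    ``("quadratic", coef)`` / ``("threshold", coef, cutpoint)`` adding
    ``coef * (X^2 - 1)`` or ``coef * max(X - cutpoint, 0)`` to the logit.
    """

    n_individuals: int = 100_000
    n_snps: int = 200
    maf_range: tuple = (0.05, 0.5)
    h2: float = 0.04                      # exposure variance explained by SNPs
    theta_direct: float = 0.0             # log OR per SD exposure (direct)
    a: float = 0.0                        # exposure -> mediator (SD per SD)
    b: float = 0.0                        # mediator -> outcome (log OR per SD)
    n_snps_mediator: int = 0              # mediator-specific instruments
    h2_mediator: float = 0.0              # mediator variance from its own SNPs
    pleiotropy_mean: float = 0.0          # direct SNP -> outcome effects
    pleiotropy_sd: float = 0.0
    fraction_invalid: float = 0.0
    prevalence: float = 0.05
    nonlinear: tuple | None = None
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 1):
            raise SimulationError("maf_range must lie in (0, 1)")
        if not 0 < self.prevalence < 1:
            raise SimulationError("prevalence must lie in (0, 1)")
        if not 0 <= self.fraction_invalid <= 1:
            raise SimulationError("fraction_invalid must lie in [0, 1]")
        if not 0 <= self.h2 < 1:
            raise SimulationError("h2 must lie in [0, 1)")
        if self.a**2 + self.h2_mediator >= 1:
            raise SimulationError(
                "a^2 + h2_mediator must be < 1 for a unit-variance mediator")

    @property
    def theta_total(self) -> float:
        return self.theta_direct + self.a * self.b

    @property
    def proportion_mediated(self) -> float:
        return self.a * self.b / self.theta_total if self.theta_total else np.nan


@dataclass
class SyntheticCohort:
    """Individual-level synthetic data with its ground truth."""

    genotypes: np.ndarray                 # (n, m) int8 dosages
    maf: np.ndarray
    snp_ids: list
    exposure: np.ndarray                  # SD units
    mediator: np.ndarray | None
    outcome: np.ndarray                   # 0/1
    invalid_snps: np.ndarray              # boolean mask
    pleiotropy: np.ndarray                # per-SNP direct outcome effects
    snp_effects: np.ndarray               # per-allele exposure effects (truth)
    mediator_effects: np.ndarray          # per-allele direct mediator effects
    config: SimulationConfig

    @property
    def score(self) -> np.ndarray:
        """Weighted allele score built from the (externally known) per-SNP
        exposure weights, as an individual-level genetic instrument."""
        return (self.genotypes - 2.0 * self.maf) @ self.snp_effects

    @property
    def n(self) -> int:
        return self.exposure.size

    @property
    def prevalence(self) -> float:
        return float(self.outcome.mean())

    def truth(self) -> dict:
        c = self.config
        return {"theta_direct": c.theta_direct, "theta_total": c.theta_total,
                "a": c.a, "b": c.b, "h2": c.h2,
                "proportion_mediated": c.proportion_mediated,
                "prevalence": c.prevalence,
                "fraction_invalid": c.fraction_invalid}

    def frame(self) -> pd.DataFrame:
        d = {"score": self.score, "exposure": self.exposure,
             "outcome": self.outcome}
        if self.mediator is not None:
            d["mediator"] = self.mediator
        return pd.DataFrame(d)


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw a cohort under ``config`` (bit-reproducible from its seed)."""
    c = config
    rng = np.random.default_rng(c.seed)
    n = c.n_individuals
    m = c.n_snps + c.n_snps_mediator     # exposure SNPs first, mediator SNPs after
    maf = rng.uniform(*c.maf_range, size=m)
    G = rng.binomial(2, maf, size=(n, m)).astype(np.int8)
    Gc = G - 2.0 * maf                    # centred dosages

    # per-SNP exposure effects: magnitudes drawn half-normal (effect allele
    # oriented exposure-increasing), scaled so the genetic variance is h2
    beta = np.zeros(m)
    raw = np.abs(rng.standard_normal(c.n_snps))
    mafx = maf[:c.n_snps]
    beta[:c.n_snps] = raw * np.sqrt(
        c.h2 / np.sum(raw**2 * 2.0 * mafx * (1.0 - mafx)))
    exposure = Gc @ beta + rng.normal(0.0, np.sqrt(1.0 - c.h2), size=n)

    mediator = None
    gamma = np.zeros(m)
    eta = c.theta_direct * exposure
    if c.a or c.b or c.n_snps_mediator:
        if c.n_snps_mediator:
            rawm = np.abs(rng.standard_normal(c.n_snps_mediator))
            mafm = maf[c.n_snps:]
            gamma[c.n_snps:] = rawm * np.sqrt(
                c.h2_mediator / np.sum(rawm**2 * 2.0 * mafm * (1.0 - mafm)))
        noise_sd = np.sqrt(1.0 - c.a**2 - c.h2_mediator)
        mediator = c.a * exposure + Gc @ gamma + rng.normal(0.0, noise_sd, size=n)
        eta = eta + c.b * mediator

    invalid = np.zeros(m, dtype=bool)
    delta = np.zeros(m)
    if c.fraction_invalid > 0:
        # pleiotropy afflicts the exposure instrument, not mediator SNPs
        k = int(round(c.fraction_invalid * c.n_snps))
        invalid[rng.choice(c.n_snps, size=k, replace=False)] = True
        delta[invalid] = rng.normal(c.pleiotropy_mean, c.pleiotropy_sd,
                                    size=invalid.sum())
        eta = eta + Gc @ delta

    if c.nonlinear is not None:
        kind = c.nonlinear[0]
        if kind == "quadratic":
            eta = eta + c.nonlinear[1] * (exposure**2 - 1.0)
        elif kind == "threshold":
            _, coef, cut = c.nonlinear
            eta = eta + coef * np.maximum(exposure - cut, 0.0)
        else:
            raise SimulationError(f"unknown nonlinear spec {kind!r}")

    def mean_prev(alpha):
        return special.expit(alpha + eta).mean() - c.prevalence

    try:
        alpha = optimize.brentq(mean_prev, -40.0, 40.0)
    except ValueError as err:
        raise SimulationError(
            f"target prevalence {c.prevalence} unattainable") from err
    outcome = (rng.random(n) < special.expit(alpha + eta)).astype(np.int8)

    return SyntheticCohort(G, maf, [f"rs{i+1}" for i in range(m)], exposure,
                           mediator, outcome, invalid, delta, beta, gamma, c)


# ---------------------------------------------------------------------------
# summary statistics from a cohort

_EFFECT_OTHER = ("A", "G")                # arbitrary fixed allele coding


def _linear_gwas(G, maf, y):
    n = G.shape[0]
    Gc = G - G.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", Gc, Gc)
    beta = (Gc.T @ yc) / sxx
    rss = np.sum(yc**2) - beta**2 * sxx
    sigma2 = rss / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    return beta, se


def _logistic_score_gwas(G, maf, y):
    """Score-based one-step logistic estimates (valid for modest effects;
    fast enough for 10^5 individuals x hundreds of SNPs)."""
    ybar = y.mean()
    Gc = G - G.mean(axis=0)
    v = ybar * (1.0 - ybar)
    sxx = np.einsum("ij,ij->j", Gc, Gc)
    beta = (Gc.T @ (y - ybar)) / (v * sxx)
    se = 1.0 / np.sqrt(v * sxx)
    return beta, se


def _logistic_ml_gwas(G, maf, y):
    m = G.shape[1]
    beta = np.empty(m)
    se = np.empty(m)
    for j in range(m):
        X = sm.add_constant(G[:, j].astype(float))
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        beta[j], se[j] = fit.params[1], fit.bse[1]
    return beta, se


def gwas(cohort: SyntheticCohort, trait: str, idx=None, *,
         exact_ml: bool = False, label: str | None = None) -> SummaryStatsTable:
    """Per-SNP association scan of one cohort trait on a subset of
    individuals.  Continuous traits use ordinary least squares per SNP;
    the binary outcome uses logistic score regression (``exact_ml=True``
    switches to per-SNP maximum likelihood)."""
    idx = slice(None) if idx is None else idx
    G = cohort.genotypes[idx].astype(np.float64)
    if trait == "exposure":
        y, binary = cohort.exposure[idx], False
    elif trait == "mediator":
        if cohort.mediator is None:
            raise SimulationError("cohort has no mediator")
        y, binary = cohort.mediator[idx], False
    elif trait == "outcome":
        y, binary = cohort.outcome[idx].astype(float), True
    else:
        raise SimulationError(f"unknown trait {trait!r}")
    n = G.shape[0]
    if binary:
        beta, se = (_logistic_ml_gwas if exact_ml else _logistic_score_gwas)(
            G, cohort.maf, y)
    else:
        beta, se = _linear_gwas(G, cohort.maf, y)
    df = pd.DataFrame({
        "variant_id": cohort.snp_ids,
        "effect_allele": _EFFECT_OTHER[0],
        "other_allele": _EFFECT_OTHER[1],
        "eaf": cohort.maf,
        "beta": beta,
        "se": se,
        "pvalue": normal_p(beta, se),
        "n": n,
    })[CANONICAL_COLUMNS]
    return SummaryStatsTable(label or trait, df,
                             "binary" if binary else "continuous",
                             provenance=f"synthetic gwas (n={n})")


def cohort_to_sumstats(cohort: SyntheticCohort, *, split: str = "two-sample",
                       exact_ml: bool = False) -> dict:
    """GWAS summary statistics for every cohort trait.

    ``two-sample`` computes continuous-trait (exposure, mediator) scans on
    the first half of the cohort and the outcome scan on the disjoint second
    half, emulating non-overlapping GWAS sources; ``one-sample`` uses all
    individuals for everything and flags the provenance accordingly.
    """
    n = cohort.n
    if split == "two-sample":
        first, second = np.arange(n // 2), np.arange(n // 2, n)
    elif split == "one-sample":
        first = second = np.arange(n)
    else:
        raise SimulationError(f"unknown split {split!r}")
    out = {"exposure": gwas(cohort, "exposure", first, exact_ml=exact_ml)}
    if cohort.mediator is not None:
        out["mediator"] = gwas(cohort, "mediator", first, exact_ml=exact_ml)
    out["outcome"] = gwas(cohort, "outcome", second, exact_ml=exact_ml)
    if split == "one-sample":
        for t in out.values():
            t.provenance += "|one-sample"
    return out


# ---------------------------------------------------------------------------
# summary-level simulation (fast path for calibration studies)

def simulate_summary_instruments(n_snps: int, *, theta: float = 0.0,
                                 seed: int, bx_mean: float = 0.05,
                                 bx_sd: float = 0.01, sx: float = 0.005,
                                 sy: float = 0.02,
                                 pleiotropy_mean: float = 0.0,
                                 pleiotropy_sd: float = 0.0,
                                 fraction_invalid: float = 0.0):
    """Draw a harmonised instrument set directly at the summary level.

    True exposure effects are positive (half-normal-shifted around
    ``bx_mean``); observed bx and by carry independent normal errors with
    the stated SEs; a fraction of SNPs receives direct (pleiotropic) outcome
    effects.  Returns a :class:`~repromr.sumstats.HarmonizedInstruments`.
    """
    from .sumstats import HarmonizedInstruments

    rng = np.random.default_rng(seed)
    bx_true = np.abs(rng.normal(bx_mean, bx_sd, size=n_snps))
    delta = np.zeros(n_snps)
    k = int(round(fraction_invalid * n_snps))
    if k:
        which = rng.choice(n_snps, size=k, replace=False)
        delta[which] = rng.normal(pleiotropy_mean, pleiotropy_sd, size=k)
    bx = bx_true + sx * rng.standard_normal(n_snps)
    by = theta * bx_true + delta + sy * rng.standard_normal(n_snps)
    df = pd.DataFrame({
        "variant_id": [f"rs{i+1}" for i in range(n_snps)],
        "bx": bx, "sx": sx, "by": by, "sy": sy, "eaf": 0.3,
    })
    return HarmonizedInstruments("exposure", "outcome", df)


# ---------------------------------------------------------------------------
# canonical benchmark scenarios

BENCHMARK_SCENARIOS = ("null", "linear_theta0.25", "invalid30_directional",
                       "mediation_phi0.5", "ushape")


def benchmark_suite(seed: int) -> dict:
    """Named canonical scenarios with documented ground truth.

    * ``null`` — no causal chain at all; estimator type-I error benchmark.
    * ``linear_theta0.25`` — constant causal log OR 0.25 per SD exposure,
      200 valid SNPs; recovery benchmark.
    * ``invalid30_directional`` — 30% of instruments carry directional
      pleiotropy; IVW is biased, the weighted median is not (much).
    * ``mediation_phi0.5`` — half the total effect flows through the
      mediator (a=0.5, b=0.4, direct 0.2).
    * ``ushape`` — U-shaped logit (quadratic term 0.15) with no linear
      direct effect; non-linearity detection benchmark.
    """
    base = SimulationConfig(seed=seed)
    return {
        "null": base,
        "linear_theta0.25": replace(base, theta_direct=0.25),
        "invalid30_directional": replace(
            base, theta_direct=0.25, fraction_invalid=0.30,
            pleiotropy_mean=0.01, pleiotropy_sd=0.002),
        "mediation_phi0.5": replace(base, theta_direct=0.2, a=0.5, b=0.4,
                                    n_snps_mediator=100, h2_mediator=0.1),
        "ushape": replace(base, nonlinear=("quadratic", 0.15)),
    }
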