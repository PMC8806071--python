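"""GWAS summary statistics: reading, validation, allele harmonisation and
fixed-effect meta-analysis.

A summary-statistics table holds one association record per variant for a
single trait: effect/other allele, effect-allele frequency (EAF), per-allele
effect (``beta``, SD units for continuous traits or log odds ratio for binary
traits), its standard error, p-value and sample size.  Harmonisation aligns
an outcome table to the effect alleles of an exposure table so that per-SNP
effect pairs (b_x, b_y) refer to the same allele — the precondition for every
two-sample Mendelian-randomisation estimator downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SummaryStatsTable",
    "HarmonizedInstruments",
    "InstrumentDiagnostics",
    "CANONICAL_COLUMNS",
    "GENOME_WIDE_SIG",
    "read_sumstats",
    "write_sumstats",
    "validate_records",
    "harmonize",
    "meta_analyze_fixed_ivw",
    "instrument_f",
    "normal_p",
]

#: Canonical column order for sumstats TSV output.
CANONICAL_COLUMNS = [
    "variant_id", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n",
]

#: Default genome-wide significance threshold for instrument selection
#: (stricter than 5e-8 to reflect densely imputed GWAS).
GENOME_WIDE_SIG = 5e-9

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_VALID_ALLELES = frozenset(_COMPLEMENT)


def normal_p(beta, se):
    """Two-sided normal p-value for beta/se.

    Input p-value columns are advisory only; p-values are recomputed from
    beta and se wherever needed for internal consistency.
    """
    z = np.asarray(beta, dtype=float) / np.asarray(se, dtype=float)
    return 2.0 * stats.norm.sf(np.abs(z))


class SumstatsError(ValueError):
    """Configuration or validation failure in summary-statistics handling."""


@dataclass
class SummaryStatsTable:
    """Per-variant GWAS association records for one trait.

    Parameters
    ----------
    trait_label : str
        Human-readable trait name.
    df : pandas.DataFrame
        Canonical columns (``CANONICAL_COLUMNS``); ``eaf`` and ``n`` may be NaN.
    trait_type : {"continuous", "binary"}
    provenance : str
        Free-text source tag.
    rejected : pandas.DataFrame
        Rows that failed validation, with a ``reason`` column.  Collected,
        never silently dropped.
    """

    trait_label: str
    df: pd.DataFrame
    trait_type: str = "continuous"
    provenance: str = ""
    rejected: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=CANONICAL_COLUMNS + ["reason"])
    )

    def __post_init__(self):
        if self.trait_type not in ("continuous", "binary"):
            raise SumstatsError(f"unknown trait_type {self.trait_type!r}")
        dup = self.df["variant_id"].duplicated()
        if dup.any():
            raise SumstatsError(
                "duplicate variant_id: " + ", ".join(self.df.loc[dup, "variant_id"].head(5))
            )

    def __len__(self):
        return len(self.df)

    def select_instruments(self, p_threshold: float = GENOME_WIDE_SIG) -> "SummaryStatsTable":
        """Subset to genome-wide significant variants (p recomputed from beta/se)."""
        p = normal_p(self.df["beta"], self.df["se"])
        sub = self.df.loc[p < p_threshold].reset_index(drop=True)
        return SummaryStatsTable(self.trait_label, sub, self.trait_type,
                                 provenance=f"{self.provenance}|p<{p_threshold:g}")


@dataclass
class HarmonizedInstruments:
    """Allele-aligned per-SNP exposure/outcome effect pairs.

    ``df`` columns: variant_id, bx, sx, by, sy, eaf (exposure EAF; NaN if
    unknown).  ``dropped`` lists (variant_id, reason) for instruments that
    could not be aligned.
    """

    exposure_label: str
    outcome_label: str
    df: pd.DataFrame
    dropped: list = field(default_factory=list)

    def __post_init__(self):
        if len(self.df):
            if (self.df["sx"] <= 0).any() or (self.df["sy"] <= 0).any():
                raise SumstatsError("nonpositive SE in harmonized set")

    def __len__(self):
        return len(self.df)

    @property
    def n_snps(self) -> int:
        return len(self.df)

    def arrays(self):
        """(bx, sx, by, sy) as float arrays."""
        d = self.df
        return (d["bx"].to_numpy(float), d["sx"].to_numpy(float),
                d["by"].to_numpy(float), d["sy"].to_numpy(float))

    def dropped_sidecar(self, path):
        """Write the dropped-variant report as a JSON sidecar."""
        Path(path).write_text(json.dumps(
            [{"variant_id": v, "reason": r} for v, r in self.dropped], indent=1))


@dataclass
class InstrumentDiagnostics:
    n_snps: int
    f_statistic: float
    variance_explained: float | None = None


# ---------------------------------------------------------------------------
# reading / validation

_DEFAULT_DIALECT = {c: c for c in CANONICAL_COLUMNS}


def validate_records(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a canonical-column frame into (valid, rejected-with-reason)."""
    reasons = pd.Series("", index=df.index)

    def flag(mask, reason):
        nonlocal reasons
        mask = mask & (reasons == "")
        reasons[mask] = reason

    ea = df["effect_allele"].astype(str).str.upper()
    oa = df["other_allele"].astype(str).str.upper()
    flag(~ea.isin(_VALID_ALLELES) | ~oa.isin(_VALID_ALLELES), "invalid allele")
    flag(ea == oa, "identical alleles")
    beta = pd.to_numeric(df["beta"], errors="coerce")
    se = pd.to_numeric(df["se"], errors="coerce")
    flag(beta.isna() | se.isna(), "unparseable beta/se")
    flag(se <= 0, "nonpositive SE")
    eaf = pd.to_numeric(df["eaf"], errors="coerce")
    flag(df["eaf"].notna() & (eaf.isna() | (eaf < 0) | (eaf > 1)), "eaf outside [0,1]")
    pval = pd.to_numeric(df["pvalue"], errors="coerce")
    flag(df["pvalue"].notna() & (pval.isna() | (pval < 0) | (pval > 1)), "pvalue outside [0,1]")

    bad = reasons != ""
    rejected = df.loc[bad].copy()
    rejected["reason"] = reasons[bad]
    good = df.loc[~bad].copy()
    good["effect_allele"] = ea[~bad]
    good["other_allele"] = oa[~bad]
    for c in ("eaf", "beta", "se", "pvalue", "n"):
        good[c] = pd.to_numeric(good[c], errors="coerce")
    return good.reset_index(drop=True), rejected.reset_index(drop=True)


def read_sumstats(path, dialect: Mapping[str, str] | None = None, *,
                  trait_label: str | None = None, trait_type: str = "continuous",
                  sep: str = "\t") -> SummaryStatsTable:
    """Read a delimited summary-statistics file.

    ``dialect`` maps canonical field names to the column names used in the
    file (e.g. ``{"beta": "b", "se": "stderr"}``); unmapped fields default to
    their canonical names.  ``eaf``, ``pvalue`` and ``n`` are optional and
    filled with NaN when absent.  Rows failing validation are collected on
    the returned table's ``rejected`` attribute with a reason.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=sep, dtype=str)
    mapping = dict(_DEFAULT_DIALECT)
    if dialect:
        mapping.update(dialect)
    rename = {src: canon for canon, src in mapping.items() if src in raw.columns}
    df = raw.rename(columns=rename)
    mandatory = ["variant_id", "effect_allele", "other_allele", "beta", "se"]
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise SumstatsError(f"{path.name}: missing mandatory column(s) {missing}; "
                            f"map them via the dialect")
    for c in ("eaf", "pvalue", "n"):
        if c not in df.columns:
            df[c] = np.nan
    df = df[CANONICAL_COLUMNS]
    good, rejected = validate_records(df)
    return SummaryStatsTable(trait_label or path.stem, good, trait_type,
                             provenance=str(path), rejected=rejected)


def write_sumstats(table: SummaryStatsTable, path, sep: str = "\t") -> None:
    table.df[CANONICAL_COLUMNS].to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# harmonisation

def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT[ea] == oa


def _ambiguous_eaf(eaf: float, window: float) -> bool:
    # min(eaf, 1-eaf) within `window` of 0.5  <=>  |eaf - 0.5| <= window
    return abs(eaf - 0.5) <= window


def harmonize(exposure: SummaryStatsTable, outcome: SummaryStatsTable, *,
              palindrome_policy: str = "drop", eaf_window: float = 0.08,
              ) -> HarmonizedInstruments:
    """Align outcome effects to the exposure's effect alleles.

    For each exposure instrument found in the outcome table:

    * same effect/other alleles — outcome effect kept as is;
    * alleles swapped — outcome beta negated, outcome EAF complemented;
    * strand flip (both alleles complementary to the exposure's) — resolved
      by complementing before comparison, effects unchanged;
    * strand flip plus swap — resolved, beta negated.

    Palindromic SNPs (A/T or C/G) cannot be strand-resolved from alleles
    alone.  Policy ``"drop"`` (default) drops them when the exposure or
    outcome EAF is missing or ambiguous (minor-allele frequency within
    ``eaf_window`` of 0.5) and otherwise infers strand by comparing which
    side of 0.5 the two frequencies fall on.  Policy ``"infer-by-eaf"``
    always infers from the frequencies when both are present, dropping only
    missing-EAF palindromes.

    Instruments absent from the outcome table are recorded in ``dropped``.
    """
    if palindrome_policy not in ("drop", "infer-by-eaf"):
        raise SumstatsError(f"unknown palindrome_policy {palindrome_policy!r}")

    out_idx = outcome.df.set_index("variant_id")
    rows, dropped = [], []
    for rec in exposure.df.itertuples(index=False):
        vid = rec.variant_id
        if vid not in out_idx.index:
            dropped.append((vid, "absent from outcome"))
            continue
        o = out_idx.loc[vid]
        ea_x, oa_x = rec.effect_allele, rec.other_allele
        ea_y, oa_y = o["effect_allele"], o["other_allele"]
        by, sy = float(o["beta"]), float(o["se"])
        eaf_y = float(o["eaf"]) if pd.notna(o["eaf"]) else np.nan
        eaf_x = float(rec.eaf) if pd.notna(rec.eaf) else np.nan

        if _is_palindromic(ea_x, oa_x):
            if {ea_y, oa_y} != {ea_x, oa_x}:
                dropped.append((vid, "allele mismatch"))
                continue
            if np.isnan(eaf_x) or np.isnan(eaf_y):
                dropped.append((vid, "palindromic, missing frequency"))
                continue
            if palindrome_policy == "drop" and (
                    _ambiguous_eaf(eaf_x, eaf_window) or _ambiguous_eaf(eaf_y, eaf_window)):
                dropped.append((vid, "palindromic, ambiguous frequency"))
                continue
            # strand inferred by frequency: effect alleles labelled the same
            # and frequencies on the same side of 0.5 -> same strand

            same_label = ea_y == ea_x
            freq_for_ea_x = eaf_y if same_label else 1.0 - eaf_y
            same_strand = (eaf_x - 0.5) * (freq_for_ea_x - 0.5) > 0
            if not same_label:
                by, eaf_y = -by, 1.0 - eaf_y
            if not same_strand:
                # outcome reported on the opposite strand: its "same" label
                # actually refers to the complementary (other) allele
                by, eaf_y = -by, 1.0 - eaf_y
        else:
            if (ea_y, oa_y) == (ea_x, oa_x):
                pass
            elif (ea_y, oa_y) == (oa_x, ea_x):
                by, eaf_y = -by, 1.0 - eaf_y
            elif (ea_y, oa_y) == (_COMPLEMENT[ea_x], _COMPLEMENT[oa_x]):
                pass  # strand flip only
            elif (ea_y, oa_y) == (_COMPLEMENT[oa_x], _COMPLEMENT[ea_x]):
                by, eaf_y = -by, 1.0 - eaf_y
            else:
                dropped.append((vid, "allele mismatch"))
                continue

        rows.append((vid, float(rec.beta), float(rec.se), by, sy, eaf_x))

    if not rows and all(r == "absent from outcome" for _, r in dropped):
        raise SumstatsError(
            f"no overlapping instruments between {exposure.trait_label!r} "
            f"and {outcome.trait_label!r}")
    df = pd.DataFrame(rows, columns=["variant_id", "bx", "sx", "by", "sy", "eaf"])
    return HarmonizedInstruments(exposure.trait_label, outcome.trait_label, df, dropped)


# ---------------------------------------------------------------------------
# fixed-effect IVW meta-analysis

def meta_analyze_fixed_ivw(tables: Sequence[SummaryStatsTable], *,
                           trait_label: str | None = None) -> SummaryStatsTable:
    """Fixed-effect inverse-variance-weighted meta-analysis across studies.

    Per variant shared across studies (aligned to the first study carrying it
    via the harmonisation allele rules): pooled beta = sum(b_i/se_i^2) /
    sum(1/se_i^2), pooled se = 1/sqrt(sum(1/se_i^2)), p from a two-sided
    normal test.  Variants present in a single study are carried through and
    flagged ``single_source`` in the output provenance column ``n_studies``.
    """
    if not tables:
        raise SumstatsError("need at least one table")
    if len(tables) == 1:
        t = tables[0]
        return SummaryStatsTable(trait_label or t.trait_label, t.df.copy(),
                                 t.trait_type, provenance="meta(1 study)")

    # reference alleles: first table in which each variant appears
    ref: dict[str, tuple] = {}
    contrib: dict[str, list] = {}
    for t in tables:
        for rec in t.df.itertuples(index=False):
            vid = rec.variant_id
            ea, oa = rec.effect_allele, rec.other_allele
            beta, se = float(rec.beta), float(rec.se)
            eaf = float(rec.eaf) if pd.notna(rec.eaf) else np.nan
            if vid not in ref:
                ref[vid] = (ea, oa, eaf, rec.n)
                contrib[vid] = [(beta, se)]
                continue
            rea, roa = ref[vid][0], ref[vid][1]
            if (ea, oa) == (rea, roa) or (ea, oa) == (_COMPLEMENT[rea], _COMPLEMENT[roa]):
                contrib[vid].append((beta, se))
            elif (ea, oa) == (roa, rea) or (ea, oa) == (_COMPLEMENT[roa], _COMPLEMENT[rea]):
                contrib[vid].append((-beta, se))
            # irreconcilable alleles: skip this study's record

    rows = []
    for vid, (ea, oa, eaf, n) in ref.items():
        betas = np.array([b for b, _ in contrib[vid]])
        ses = np.array([s for _, s in contrib[vid]])
        w = 1.0 / ses**2
        pooled_b = float(np.sum(w * betas) / np.sum(w))
        pooled_se = float(1.0 / np.sqrt(np.sum(w)))
        rows.append((vid, ea, oa, eaf, pooled_b, pooled_se,
                     float(normal_p(pooled_b, pooled_se)), n, len(betas)))
    df = pd.DataFrame(rows, columns=CANONICAL_COLUMNS + ["n_studies"])
    df["single_source"] = df["n_studies"] == 1
    return SummaryStatsTable(trait_label or tables[0].trait_label, df,
                             tables[0].trait_type,
                             provenance=f"meta({len(tables)} studies)")


# ---------------------------------------------------------------------------
# instrument strength

def instrument_f(betas: Iterable[float], ses: Iterable[float], *,
                 eafs: Iterable[float] | None = None) -> InstrumentDiagnostics:
    """Instrument strength: mean per-SNP (beta/se)^2 over the instrument.

    When effect-allele frequencies are supplied, the variance explained is
    additionally reported as sum of per-SNP r^2 = 2 f (1-f) beta^2 (for a
    variance-standardised continuous trait).
    """
    b = np.asarray(list(betas), dtype=float)
    s = np.asarray(list(ses), dtype=float)
    if b.size == 0:
        raise SumstatsError("empty instrument")
    if (s <= 0).any():
        raise SumstatsError("nonpositive SE")
    f_stat = float(np.mean((b / s) ** 2))
    r2 = None
    if eafs is not None:
        f = np.asarray(list(eafs), dtype=float)
        r2 = float(np.sum(2.0 * f * (1.0 - f) * b**2))
    return InstrumentDiagnostics(n_snps=int(b.size), f_statistic=f_stat,
                                 variance_explained=r2)
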