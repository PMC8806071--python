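"""Analysis-grid orchestration: harmonise, estimate with every method,
Rucker-select, and FDR-correct across an exposure x outcome grid.

``run_grid`` reproduces the study layout — each cell of the grid gets IVW,
MR-Egger and weighted-median estimates, the Rucker-selected method, Q/Q'
heterogeneity diagnostics, the Egger intercept test, an optional Steiger
directionality flag, and a Benjamini-Hochberg q-value computed across the
grid family.  A reverse mode swaps exposure and outcome roles.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import sumstats as ss
from .sumstats import SummaryStatsTable, harmonize

logger = logging.getLogger("repromr")

__all__ = ["bh_fdr", "run_grid", "AnalysisGrid"]


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values.

    q_(i) = min_{j >= i} ( p_(j) * m / j ), capped at 1; preserves input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be 1-D")
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class AnalysisGrid:
    """Results over an exposures x outcomes grid."""

    exposures: list
    outcomes: list
    cells: pd.DataFrame            # one row per (exposure, outcome, method)
    selected: pd.DataFrame         # one row per cell: selected method + q-value
    manifest: dict = field(default_factory=dict)

    @property
    def n_tests(self) -> int:
        return len(self.exposures) * len(self.outcomes)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.cells.to_csv(outdir / "mr_all_methods.tsv", sep="\t", index=False)
        self.selected.to_csv(outdir / "mr_selected.tsv", sep="\t", index=False)
        (outdir / "manifest.json").write_text(json.dumps(self.manifest, indent=1,
                                                         sort_keys=True))


def run_grid(exposures: Mapping[str, SummaryStatsTable],
             outcomes: Mapping[str, SummaryStatsTable], *,
             seed: int, methods=("ivw", "egger", "weighted_median"),
             alpha_q: float = 0.05, n_boot: int = 5000,
             palindrome_policy: str = "drop", eaf_window: float = 0.08,
             reverse: bool = False,
             sample_sizes: Mapping[str, float] | None = None) -> AnalysisGrid:
    """Run the full two-sample MR grid.

    Each exposure table should already be restricted to its instruments
    (e.g. via :meth:`SummaryStatsTable.select_instruments`).  ``reverse=True``
    swaps the roles of the two collections (reverse MR).  ``sample_sizes``
    maps trait labels to GWAS sample sizes for the Steiger test; cells
    without both sizes carry a NaN Steiger flag.
    """
    from .mr import TwoSampleMR, steiger  # deferred: avoid import cycle

    if reverse:
        exposures, outcomes = outcomes, exposures
    exp_labels, out_labels = list(exposures), list(outcomes)
    all_rows, sel_rows = [], []
    dropped_counts = {}
    for i, (e_label, e_tab) in enumerate(exposures.items()):
        for j, (o_label, o_tab) in enumerate(outcomes.items()):
            try:
                inst = harmonize(e_tab, o_tab, palindrome_policy=palindrome_policy,
                                 eaf_window=eaf_window)
            except ss.SumstatsError as err:
                raise ss.SumstatsError(
                    f"grid cell ({e_label}, {o_label}): {err}") from err
            dropped_counts[f"{e_label}|{o_label}"] = len(inst.dropped)
            cell_seed = seed + 7919 * i + 104729 * j
            res = TwoSampleMR(inst).fit(methods=methods, alpha_q=alpha_q,
                                        n_boot=n_boot, seed=cell_seed)
            summ = res.summary()
            all_rows.append(summ)
            chosen = res.selected_result
            sel = {"exposure": e_label, "outcome": o_label,
                   "method": res.selected, "beta": chosen.beta, "se": chosen.se,
                   "pvalue": chosen.pvalue, "or": chosen.or_,
                   "ci_low": chosen.ci_low, "ci_high": chosen.ci_high,
                   "n_snps": chosen.n_snps,
                   "q_ivw": res.rucker.q_ivw if res.rucker else np.nan,
                   "q_egger": res.rucker.q_egger if res.rucker else np.nan,
                   "egger_intercept_p": (res.rucker.intercept_pvalue
                                         if res.rucker else np.nan)}
            if sample_sizes and e_label in sample_sizes and o_label in sample_sizes:
                st = steiger(inst, n_exposure=sample_sizes[e_label],
                             n_outcome=sample_sizes[o_label],
                             exposure_type=e_tab.trait_type,
                             outcome_type=o_tab.trait_type)
                sel["steiger_ok"] = st.direction_ok
            else:
                sel["steiger_ok"] = np.nan
            sel_rows.append(sel)
            logger.info("cell (%s, %s): %s selected, %d SNPs, %d dropped",
                        e_label, o_label, res.selected, chosen.n_snps,
                        len(inst.dropped))

    selected = pd.DataFrame(sel_rows)
    selected["fdr_q"] = bh_fdr(selected["pvalue"].to_numpy())
    cells = pd.concat(all_rows, ignore_index=True)
    manifest = {"seed": seed, "methods": list(methods), "alpha_q": alpha_q,
                "n_boot": n_boot, "reverse": reverse,
                "exposures": exp_labels, "outcomes": out_labels,
                "dropped_per_cell": dropped_counts}
    return AnalysisGrid(exp_labels, out_labels, cells, selected, manifest)
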