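import numpy as np
import pandas as pd
import pytest

from repromr.sumstats import (CANONICAL_COLUMNS, SummaryStatsTable, normal_p)


def make_table(label, beta, se, *, eaf=0.3, effect="A", other="G",
               binary=False, variant_ids=None, n=50_000):
    """Build a valid SummaryStatsTable from effect arrays."""
    beta = np.atleast_1d(np.asarray(beta, float))
    se = np.broadcast_to(np.asarray(se, float), beta.shape)
    m = beta.size
    df = pd.DataFrame({
        "variant_id": variant_ids or [f"rs{i+1}" for i in range(m)],
        "effect_allele": effect, "other_allele": other,
        "eaf": eaf, "beta": beta, "se": se,
        "pvalue": normal_p(beta, se), "n": n,
    })[CANONICAL_COLUMNS]
    return SummaryStatsTable(label, df, "binary" if binary else "continuous")


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def instruments():
    """A 20-SNP harmonised set with true slope 0.3 and mild noise."""
    from repromr.simulate import simulate_summary_instruments
    return simulate_summary_instruments(20, theta=0.3, seed=11)
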