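import numpy as np
import pandas as pd
import pytest
from scipy import stats

from twostepmr import HarmonizedSet, SimScenario, simulate_summary_stats


def make_hset(beta_exp, se_exp, beta_out, se_out) -> HarmonizedSet:
    """Harmonized set straight from effect arrays (alleles already aligned)."""
    beta_exp = np.asarray(beta_exp, dtype=float)
    k = beta_exp.size
    table = pd.DataFrame({
        "variant_id": [f"v{i:03d}" for i in range(k)],
        "chrom": "1",
        "pos": 1_000_000 * (np.arange(k) + 1),
        "effect_allele": "A",
        "other_allele": "G",
        "beta_exp": beta_exp,
        "se_exp": np.broadcast_to(np.asarray(se_exp, float), (k,)).copy(),
        "beta_out": np.asarray(beta_out, dtype=float),
        "se_out": np.broadcast_to(np.asarray(se_out, float), (k,)).copy(),
        "eaf_exp": 0.3,
        "eaf_out": 0.3,
        "action": "kept",
    })
    return HarmonizedSet(table=table, n_matched=k)


def summary_frame(rows: list[dict]) -> pd.DataFrame:
    """Summary-statistics frame from per-variant dicts with defaults."""
    defaults = dict(chrom="1", pos=1_000_000, effect_allele="A",
                    other_allele="G", eaf=0.3, beta=0.1, se=0.02, n=10_000)
    out = []
    for i, row in enumerate(rows):
        rec = dict(defaults, variant_id=f"v{i:03d}", pos=1_000_000 * (i + 1))
        rec.update(row)
        if "pval" not in rec:
            try:
                rec["pval"] = float(
                    2.0 * stats.norm.sf(abs(rec["beta"] / rec["se"])))
            except (TypeError, ZeroDivisionError):
                rec["pval"] = 0.5  # invalid beta/se: let the reader judge
        out.append(rec)
    df = pd.DataFrame(out)
    return df[["variant_id", "chrom", "pos", "effect_allele", "other_allele",
               "eaf", "beta", "se", "pval", "n"]]


@pytest.fixture(scope="session")
def default_triple():
    """One realisation of the default causal-chain scenario."""
    return simulate_summary_stats(SimScenario(seed=11))


@pytest.fixture(scope="session")
def null_scenario():
    return SimScenario(beta1_true=0.0, beta2_true=0.0, beta_direct_true=0.0,
                       seed=7)
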