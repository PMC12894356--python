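"""Selection of independent, strong genetic instruments.

Instrument selection follows the usual three-stage recipe for summary-data
MR: a genome-wide significance filter (with an optional relaxed fallback
threshold when too few variants survive), greedy LD clumping against an
r-squared matrix, and a per-variant F-statistic filter against weak
instruments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8
RELAXED_P = 1e-6
DEFAULT_R2_LIMIT = 0.001
DEFAULT_WINDOW_KB = 10_000
DEFAULT_F_MIN = 10.0


class NoInstrumentsError(ValueError):
    """No variant passes the instrument-selection thresholds."""


@dataclass
class InstrumentSet:
    """Selected instruments with full provenance of each exclusion."""

    table: pd.DataFrame                 # selected records incl. F column
    p_threshold_used: float
    r2_limit: float
    window_kb: float
    f_min: float
    provenance: list[str] = field(default_factory=list)

    @property
    def n_snps(self) -> int:
        return len(self.table)


def f_statistic(beta, se):
    """Single-SNP instrument-strength F, the squared Wald z: (beta/se)^2."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be > 0")
    return (beta / se) ** 2


def select_by_pvalue(
    records: pd.DataFrame,
    primary_p: float = GENOME_WIDE_P,
    fallback_p: float | None = RELAXED_P,
    min_snps: int = 1,
) -> tuple[pd.DataFrame, float, list[str]]:
    """Significance filter with a relaxed fallback threshold.

    Variants with p < ``primary_p`` are selected; if fewer than ``min_snps``
    survive and ``fallback_p`` is given, the selection is redone at the
    relaxed threshold and the relaxation is recorded in the provenance log.

    Returns (selected records, threshold used, provenance lines).
    """
    provenance: list[str] = []
    selected = records[records["pval"] < primary_p]
    threshold = primary_p
    if len(selected) < min_snps and fallback_p is not None and fallback_p > primary_p:
        selected = records[records["pval"] < fallback_p]
        threshold = fallback_p
        msg = (f"p-threshold relaxed from {primary_p:g} to {fallback_p:g} "
               f"({len(selected)} variant(s) at relaxed threshold)")
        provenance.append(msg)
        logger.info(msg)
    if len(selected) == 0:
        raise NoInstrumentsError(
            f"no instruments: no variant with p < {threshold:g}")
    return selected.reset_index(drop=True), threshold, provenance


def clump(
    records: pd.DataFrame,
    ld_matrix: pd.DataFrame | None,
    r2_limit: float = DEFAULT_R2_LIMIT,
    window_kb: float = DEFAULT_WINDOW_KB,
) -> pd.DataFrame:
    """Greedy LD clumping by ascending p-value.

    Sort variants by (p-value, variant_id); accept the best remaining; drop
    every other variant on the same chromosome within ``window_kb`` whose
    r-squared with an accepted variant exceeds ``r2_limit``; repeat.  Pairs
    absent from ``ld_matrix`` are treated as unlinked (r2 = 0) and logged.
    The variant_id tie-break makes the result invariant to input row order.
    """
    if len(records) == 0:
        return records.copy()
    df = records.sort_values(
        ["pval", "variant_id"], kind="mergesort").reset_index(drop=True)

    vids = df["variant_id"].to_numpy()
    chroms = df["chrom"].to_numpy()
    pos = df["pos"].to_numpy(dtype=float)
    window_bp = window_kb * 1_000

    in_ld = np.zeros(len(df), dtype=bool)  # known LD-matrix rows/cols
    r2_sub = None
    if ld_matrix is not None:
        known = [i for i, v in enumerate(vids)
                 if v in ld_matrix.index and v in ld_matrix.columns]
        in_ld[known] = True
        if known:
            kv = vids[known]
            r2_sub = pd.DataFrame(
                ld_matrix.loc[kv, kv].to_numpy(dtype=float),
                index=kv, columns=kv)

    missing_pairs = 0
    accepted: list[int] = []
    removed = np.zeros(len(df), dtype=bool)
    for i in range(len(df)):
        if removed[i]:
            continue
        accepted.append(i)
        near = (~removed) & (chroms == chroms[i]) \
            & (np.abs(pos - pos[i]) <= window_bp)
        near[: i + 1] = False
        if not near.any():
            continue
        idx = np.flatnonzero(near)
        if r2_sub is not None and in_ld[i]:
            covered = idx[in_ld[idx]]
            missing_pairs += len(idx) - len(covered)
            if len(covered):
                r2 = r2_sub.loc[vids[i], vids[covered]].to_numpy(dtype=float)
                removed[covered[r2 > r2_limit]] = True
        elif ld_matrix is not None:
            missing_pairs += len(idx)

    if missing_pairs:
        logger.info("clump: %d pairs missing from LD matrix treated as r2=0",
                    missing_pairs)
    return df.iloc[accepted].reset_index(drop=True)


def select_instruments(
    records: pd.DataFrame,
    ld_matrix: pd.DataFrame | None = None,
    primary_p: float = GENOME_WIDE_P,
    fallback_p: float | None = RELAXED_P,
    min_snps: int = 1,
    r2_limit: float = DEFAULT_R2_LIMIT,
    window_kb: float = DEFAULT_WINDOW_KB,
    f_min: float = DEFAULT_F_MIN,
) -> InstrumentSet:
    """Full instrument-selection pipeline: p filter, clump, F filter."""
    selected, threshold, provenance = select_by_pvalue(
        records, primary_p=primary_p, fallback_p=fallback_p, min_snps=min_snps)

    clumped = clump(selected, ld_matrix, r2_limit=r2_limit, window_kb=window_kb)
    n_clumped_away = len(selected) - len(clumped)
    if n_clumped_away:
        provenance.append(f"{n_clumped_away} variant(s) removed by LD clumping "
                          f"(r2 > {r2_limit:g} within {window_kb:g} kb)")

    clumped = clumped.copy()
    clumped["f_stat"] = f_statistic(clumped["beta"], clumped["se"])
    strong = clumped[clumped["f_stat"] > f_min].reset_index(drop=True)
    n_weak = len(clumped) - len(strong)
    if n_weak:
        provenance.append(f"{n_weak} weak instrument(s) removed (F <= {f_min:g})")
    if len(strong) == 0:
        raise NoInstrumentsError("no instruments: all removed by clumping/F filter")
    return InstrumentSet(
        table=strong, p_threshold_used=threshold, r2_limit=r2_limit,
        window_kb=window_kb, f_min=f_min, provenance=provenance)
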