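"""Reading, validation and allele harmonization of GWAS summary statistics.

Two-sample MR combines per-variant effects measured in different cohorts,
which may report them relative to different effect alleles or on opposite
strands.  :func:`harmonize` aligns every shared variant to a single effect
allele, flipping outcome effect signs where the allele labels are swapped,
resolving strand flips by complementing, and handling palindromic (A/T, C/G)
variants by allele-frequency inference or conservative removal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import SUMMARY_COLUMNS

logger = logging.getLogger(__name__)

DEFAULT_PALINDROMIC_EAF_LIMIT = 0.42

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_VALID_ALLELES = frozenset("ACGT")


class SummaryStatsError(ValueError):
    """Malformed or unusable summary statistics input."""


class NoOverlapError(SummaryStatsError):
    """Exposure and outcome share no variants."""


def read_summary_stats(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    sep: str = "\t",
) -> pd.DataFrame:
    """Read a delimited summary-statistics file into the canonical layout.

    Parameters
    ----------
    path
        Delimited text file with one variant per row.
    column_map
        Mapping from canonical names (``variant_id``, ``chrom``, ``pos``,
        ``effect_allele``, ``other_allele``, ``eaf``, ``beta``, ``se``,
        ``pval``, ``n``) to the column names used in the file; identity by
        default.  ``eaf`` and ``n`` are optional; the rest are mandatory.

    Returns
    -------
    DataFrame with canonical columns.  Rows violating basic invariants
    (non-positive SE, identical alleles, non-ACGT alleles, p outside (0, 1])
    are dropped with a logged reason; the number skipped is exposed in
    ``df.attrs["n_skipped"]``.
    """
    path = Path(path)
    if not path.exists():
        raise SummaryStatsError(f"summary statistics file not found: {path}")
    column_map = column_map or {}
    raw = pd.read_csv(path, sep=sep, dtype={
        column_map.get("chrom", "chrom"): str,
        column_map.get("variant_id", "variant_id"): str,
    })

    rename = {src: canon for canon, src in column_map.items()}
    raw = raw.rename(columns=rename)

    mandatory = ["variant_id", "chrom", "pos", "effect_allele", "other_allele",
                 "beta", "se", "pval"]
    missing = [c for c in mandatory if c not in raw.columns]
    if missing:
        raise SummaryStatsError(
            f"{path}: missing mandatory column(s) {missing}; "
            f"present: {list(raw.columns)}"
        )
    if "eaf" not in raw.columns:
        raw["eaf"] = np.nan
    if "n" not in raw.columns:
        raw["n"] = np.nan

    df = raw[SUMMARY_COLUMNS].copy()
    df["effect_allele"] = df["effect_allele"].str.upper()
    df["other_allele"] = df["other_allele"].str.upper()
    for col in ("pos", "eaf", "beta", "se", "pval", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    bad = pd.Series(False, index=df.index)
    reasons = []
    checks = [
        (~np.isfinite(df["beta"]) | ~np.isfinite(df["se"]), "unparsable beta/se"),
        (df["se"] <= 0, "non-positive se"),
        (df["effect_allele"] == df["other_allele"], "identical alleles"),
        (~df["effect_allele"].isin(_VALID_ALLELES)
         | ~df["other_allele"].isin(_VALID_ALLELES), "non-ACGT allele"),
        ((df["pval"] <= 0) | (df["pval"] > 1) | ~np.isfinite(df["pval"]),
         "p-value outside (0, 1]"),
    ]
    for mask, reason in checks:
        mask = mask.fillna(True) & ~bad
        for line in df.index[mask]:
            reasons.append((int(line) + 2, reason))  # +2: header and 1-basing
        bad |= mask

    if reasons:
        for line_no, reason in reasons:
            logger.warning("%s line %d skipped: %s", path.name, line_no, reason)
    out = df[~bad].reset_index(drop=True)
    out.attrs["n_skipped"] = int(bad.sum())
    out.attrs["source"] = str(path)
    return out


@dataclass
class HarmonizedSet:
    """Exposure/outcome effect pairs aligned to a common effect allele.

    ``table`` has one row per retained variant with columns ``variant_id``,
    ``effect_allele``, ``other_allele``, ``beta_exp``, ``se_exp``,
    ``beta_out``, ``se_out``, ``eaf_exp``, ``eaf_out``, ``action``.
    ``dropped`` records every matched-but-removed variant with a reason code.
    """

    table: pd.DataFrame
    dropped: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["variant_id", "reason"]))
    n_matched: int = 0

    @property
    def n_snps(self) -> int:
        return len(self.table)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.table)


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT.get(ea) == oa


def _eaf_informative(eaf: float, limit: float) -> bool:
    return np.isfinite(eaf) and (eaf < limit or eaf > 1.0 - limit)


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindromic_eaf_limit: float = DEFAULT_PALINDROMIC_EAF_LIMIT,
) -> HarmonizedSet:
    """Align exposure and outcome effects to the exposure's effect allele.

    Matching is by ``variant_id``.  For each shared variant:

    * same allele pair -> kept unchanged;
    * effect/other alleles swapped -> outcome beta sign-flipped, eaf
      reflected to 1-eaf;
    * strand flip of a non-palindromic pair (outcome alleles are the
      base complements) -> resolved by complementing, then the two rules
      above apply;
    * palindromic variants (A/T or C/G) are kept only when both allele
      frequencies fall on the same side of 0.5 **and** both lie outside
      ``[limit, 1-limit]``; the outcome is sign-flipped if the frequencies
      disagree in orientation after strand alignment.  Missing eaf on either
      side drops the variant (conservative);
    * anything else is dropped as incompatible.

    Raises
    ------
    NoOverlapError
        if the two files share no variant identifiers.
    """
    exp = exposure.set_index("variant_id", drop=False)
    out = outcome.set_index("variant_id", drop=False)
    shared = exp.index.intersection(out.index)
    if len(shared) == 0:
        raise NoOverlapError("no overlapping instruments between exposure and outcome")

    kept_rows = []
    dropped_rows = []
    limit = float(palindromic_eaf_limit)

    for vid in shared:
        e = exp.loc[vid]
        o = out.loc[vid]
        e_ea, e_oa = e["effect_allele"], e["other_allele"]
        o_ea, o_oa = o["effect_allele"], o["other_allele"]
        beta_out, eaf_out = float(o["beta"]), float(o["eaf"])
        action = "kept"

        if _is_palindromic(e_ea, e_oa):
            eaf_exp = float(e["eaf"])
            if {o_ea, o_oa} != {e_ea, e_oa}:
                dropped_rows.append((vid, "incompatible-alleles"))
                continue
            if not (_eaf_informative(eaf_exp, limit)
                    and _eaf_informative(eaf_out, limit)):
                dropped_rows.append((vid, "palindromic-ambiguous"))
                continue
            if o_ea != e_ea:  # reported against the other label
                beta_out, eaf_out = -beta_out, 1.0 - eaf_out
                action = "sign-flipped"
            if (eaf_exp < 0.5) != (eaf_out < 0.5):
                # frequencies disagree: outcome is on the opposite strand,
                # which for a palindromic variant swaps the allele roles
                beta_out, eaf_out = -beta_out, 1.0 - eaf_out
                action = "sign-flipped"
        else:
            if {o_ea, o_oa} == {_COMPLEMENT.get(e_ea), _COMPLEMENT.get(e_oa)} \
                    and {o_ea, o_oa} != {e_ea, e_oa}:
                o_ea = _COMPLEMENT[o_ea]
                o_oa = _COMPLEMENT[o_oa]
                action = "strand-flipped"
            if (o_ea, o_oa) == (e_ea, e_oa):
                pass
            elif (o_ea, o_oa) == (e_oa, e_ea):
                beta_out = -beta_out
                if np.isfinite(eaf_out):
                    eaf_out = 1.0 - eaf_out
                action = "sign-flipped" if action == "kept" else "strand+sign-flipped"
            else:
                dropped_rows.append((vid, "incompatible-alleles"))
                continue

        kept_rows.append({
            "variant_id": vid,
            "chrom": e["chrom"],
            "pos": e["pos"],
            "effect_allele": e_ea,
            "other_allele": e_oa,
            "beta_exp": float(e["beta"]),
            "se_exp": float(e["se"]),
            "pval_exp": float(e["pval"]),
            "beta_out": beta_out,
            "se_out": float(o["se"]),
            "eaf_exp": float(e["eaf"]),
            "eaf_out": eaf_out,
            "action": action,
        })

    table = pd.DataFrame(kept_rows)
    dropped = pd.DataFrame(dropped_rows, columns=["variant_id", "reason"])
    if len(dropped):
        for _, row in dropped.iterrows():
            logger.info("harmonize: %s dropped (%s)", row["variant_id"], row["reason"])
    return HarmonizedSet(table=table, dropped=dropped, n_matched=len(shared))


def read_ld_matrix(path: str | Path) -> pd.DataFrame:
    """Read a variant-by-variant r-squared matrix written as labelled TSV."""
    ld = pd.read_csv(path, sep="\t", index_col="variant_id")
    ld.columns.name = None
    return ld
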