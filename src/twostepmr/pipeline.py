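"""Exposure-wide MR screen, FDR correction, and the full two-step framework.

Stage 1 screens every exposure in a manifest against the outcome (instrument
selection, harmonization, primary Wald/IVW estimate, secondary estimators
when the instrument count permits, sensitivity battery) and applies
Benjamini-Hochberg FDR across the screen.  Stage 2 runs two-step mediation
MR for every significant exposure x significant mediator pair.  Stage 3
classifies effect directions between exposures and mediators and runs the
reverse MR of the outcome on the exposures.  All stages are deterministic
given the config and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from statsmodels.stats.multitest import multipletests

from . import instruments as instr
from . import mediation as med
from . import mr
from .io import harmonize, read_ld_matrix, read_summary_stats

logger = logging.getLogger(__name__)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Step-up formula q_(i) = min over j>=i of p_(j)*m/j, i.e. p_(i)*m/i with a
    cumulative minimum applied from the largest rank downwards, capped at 1.
    Empty input yields an empty array.
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    if np.any((pvals <= 0) | (pvals > 1) | ~np.isfinite(pvals)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


@dataclass
class TraitSpec:
    """One exposure or mediator entry of the manifest."""

    trait_id: str
    path: Path
    primary_p: float = instr.GENOME_WIDE_P
    fallback_p: float | None = instr.RELAXED_P


@dataclass
class ScreenConfig:
    """Declarative configuration for a screen or full-framework run."""

    exposures: list[TraitSpec]
    outcome_path: Path
    mediators: list[TraitSpec] = field(default_factory=list)
    ld_matrix_path: Path | None = None
    fdr_alpha: float = 0.05
    r2_limit: float = instr.DEFAULT_R2_LIMIT
    window_kb: float = instr.DEFAULT_WINDOW_KB
    f_min: float = instr.DEFAULT_F_MIN
    min_snps: int = 1
    n_boot: int = 1000
    n_presso_sim: int = 1000
    seed: int = 0
    output_dir: Path = Path("twostepmr_out")

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_alpha < 1.0:
            raise ValueError("fdr_alpha must lie in (0, 1)")

    @property
    def instrument_kw(self) -> dict:
        return dict(r2_limit=self.r2_limit, window_kb=self.window_kb,
                    f_min=self.f_min, min_snps=self.min_snps)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScreenConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = path.parent

        def _traits(section) -> list[TraitSpec]:
            out = []
            for trait_id, entry in (section or {}).items():
                if isinstance(entry, str):
                    entry = {"path": entry}
                fb = entry.get("fallback_p", instr.RELAXED_P)
                out.append(TraitSpec(
                    trait_id=trait_id, path=base / entry["path"],
                    primary_p=float(entry.get("primary_p", instr.GENOME_WIDE_P)),
                    fallback_p=None if fb is None else float(fb)))
            return out

        inst = raw.get("instruments", {})
        ld = raw.get("ld_matrix")
        return cls(
            exposures=_traits(raw.get("exposures")),
            mediators=_traits(raw.get("mediators")),
            outcome_path=base / raw["outcome"],
            ld_matrix_path=None if ld is None else base / ld,
            fdr_alpha=float(raw.get("fdr_alpha", 0.05)),
            r2_limit=float(inst.get("r2_limit", instr.DEFAULT_R2_LIMIT)),
            window_kb=float(inst.get("window_kb", instr.DEFAULT_WINDOW_KB)),
            f_min=float(inst.get("f_min", instr.DEFAULT_F_MIN)),
            min_snps=int(inst.get("min_snps", 1)),
            n_boot=int(raw.get("n_boot", 1000)),
            n_presso_sim=int(raw.get("n_presso_sim", 1000)),
            seed=int(raw.get("seed", 0)),
            output_dir=Path(raw.get("output_dir", "twostepmr_out")),
        )


_SCREEN_COLUMNS = [
    "exposure", "outcome", "status", "method", "n_snps", "p_threshold",
    "beta", "se", "ci_low", "ci_high", "pval", "or_", "or_low", "or_high",
    "egger_beta", "weighted_median_beta", "weighted_mode_beta",
    "q", "q_pval", "egger_intercept_pval", "presso_pval", "qval",
    "significant", "note",
]


def screen_one(exposure_stats: pd.DataFrame, outcome_stats: pd.DataFrame,
               ld_matrix=None, primary_p: float = instr.GENOME_WIDE_P,
               fallback_p: float | None = instr.RELAXED_P,
               seed: int = 0, n_boot: int = 1000, n_presso_sim: int = 1000,
               **instrument_kw) -> dict:
    """Screen a single exposure against the outcome; returns one report row."""
    ivs = instr.select_instruments(
        exposure_stats, ld_matrix, primary_p=primary_p, fallback_p=fallback_p,
        **instrument_kw)
    h = harmonize(ivs.table, outcome_stats)
    if h.n_snps == 0:
        raise instr.NoInstrumentsError("all instruments lost in harmonization")
    est = mr.primary_estimate(h)
    or_, (or_lo, or_hi) = mr.to_odds_ratio(est)
    row = {
        "status": "ok", "method": est.method, "n_snps": est.n_snps,
        "p_threshold": ivs.p_threshold_used,
        "beta": est.beta, "se": est.se,
        "ci_low": est.ci_low, "ci_high": est.ci_high, "pval": est.pval,
        "or_": or_, "or_low": or_lo, "or_high": or_hi,
        "egger_beta": None, "weighted_median_beta": None,
        "weighted_mode_beta": None,
        "note": "; ".join(ivs.provenance),
    }
    if h.n_snps >= 3:
        row["egger_beta"] = mr.egger(h).beta
        row["weighted_median_beta"] = mr.weighted_median(
            h, n_boot=n_boot, seed=seed).beta
        row["weighted_mode_beta"] = mr.weighted_mode(
            h, n_boot=n_boot, seed=seed).beta
    sens = mr.sensitivity_report(h, n_sim=n_presso_sim, seed=seed)
    row.update(q=sens["cochran_q"], q_pval=sens["q_pval"],
               egger_intercept_pval=sens["egger_intercept_pval"],
               presso_pval=sens["presso_pval"])
    return row


def run_screen(config: ScreenConfig, outcome_stats: pd.DataFrame | None = None,
               ld_matrix=None) -> pd.DataFrame:
    """Run the stage-1 exposure-wide screen with BH FDR across exposures.

    Per-exposure failures (missing files, no instruments, no overlap) are
    recorded in the report row and do not abort the run.  FDR is computed
    over the successful rows of this manifest only, treating the manifest as
    one testing family.
    """
    if outcome_stats is None:
        outcome_stats = read_summary_stats(config.outcome_path)
    if ld_matrix is None and config.ld_matrix_path is not None:
        ld_matrix = read_ld_matrix(config.ld_matrix_path)

    rows = []
    for spec in config.exposures:
        row = {"exposure": spec.trait_id, "outcome": "outcome"}
        try:
            stats_df = read_summary_stats(spec.path)
            row.update(screen_one(
                stats_df, outcome_stats, ld_matrix,
                primary_p=spec.primary_p, fallback_p=spec.fallback_p,
                seed=config.seed, n_boot=config.n_boot,
                n_presso_sim=config.n_presso_sim, **config.instrument_kw))
        except Exception as err:  # isolation: one bad exposure never kills the run
            logger.warning("screen: exposure %s failed: %s", spec.trait_id, err)
            row.update(status="error", note=str(err))
        rows.append(row)

    report = pd.DataFrame(rows).reindex(columns=_SCREEN_COLUMNS)
    if report.empty:
        logger.warning("screen: empty exposure manifest")
        return report
    ok = report["status"] == "ok"
    report["qval"] = np.nan
    if ok.any():
        report.loc[ok, "qval"] = bh_fdr(report.loc[ok, "pval"].to_numpy())
    report["significant"] = (report["qval"] < config.fdr_alpha).fillna(False)
    return report


def run_full_framework(config: ScreenConfig, write: bool = True) -> dict:
    """Run the three-stage framework and (optionally) write all tables.

    Returns a dict with keys ``exposure_screen``, ``mediator_screen``,
    ``mediation`` (Table-1-style rows), ``direction`` and ``manifest``.
    """
    outcome_stats = read_summary_stats(config.outcome_path)
    ld_matrix = (read_ld_matrix(config.ld_matrix_path)
                 if config.ld_matrix_path is not None else None)

    exp_screen = run_screen(config, outcome_stats, ld_matrix)
    med_config = ScreenConfig(
        exposures=config.mediators, outcome_path=config.outcome_path,
        ld_matrix_path=config.ld_matrix_path, fdr_alpha=config.fdr_alpha,
        r2_limit=config.r2_limit, window_kb=config.window_kb,
        f_min=config.f_min, min_snps=config.min_snps, n_boot=config.n_boot,
        n_presso_sim=config.n_presso_sim, seed=config.seed,
        output_dir=config.output_dir)
    med_screen = run_screen(med_config, outcome_stats, ld_matrix)
    med_screen = med_screen.rename(columns={"exposure": "mediator"})

    exposures = {s.trait_id: s for s in config.exposures}
    mediators = {s.trait_id: s for s in config.mediators}
    sig_exp = exp_screen.loc[exp_screen["significant"], "exposure"].tolist()
    sig_med = med_screen.loc[med_screen["significant"], "mediator"].tolist()

    mediation_rows = []
    direction_rows = []
    for e_id in sig_exp:
        e_stats = read_summary_stats(exposures[e_id].path)
        for m_id in sig_med:
            m_stats = read_summary_stats(mediators[m_id].path)
            kw = dict(primary_p=exposures[e_id].primary_p,
                      fallback_p=exposures[e_id].fallback_p,
                      **config.instrument_kw)
            try:
                res = med.run_mediation(
                    e_stats, m_stats, outcome_stats, ld_matrix,
                    n_boot=config.n_boot, seed=config.seed, instrument_kw=kw)
                mediation_rows.append(med.mediation_table_row(
                    e_id, m_id, "outcome", res))
            except (instr.NoInstrumentsError, mr.InsufficientInstrumentsError) as err:
                logger.warning("mediation %s x %s failed: %s", e_id, m_id, err)
                mediation_rows.append({
                    "exposure": e_id, "mediator": m_id, "outcome": "outcome",
                    "beta_total": np.nan, "note": str(err)})
            # stage 3a: direction between exposure and mediator
            d = med.direction_screen(e_stats, m_stats, ld_matrix,
                                     alpha=config.fdr_alpha,
                                     instrument_kw=config.instrument_kw)
            direction_rows.append({
                "trait_a": e_id, "trait_b": m_id,
                "classification": d["classification"],
                "a_to_b_status": d["status"]["a_to_b"],
                "b_to_a_status": d["status"]["b_to_a"]})

    # stage 3b: reverse MR, outcome as exposure of each screened trait
    for e_id in sig_exp or [s.trait_id for s in config.exposures][:1]:
        e_stats = read_summary_stats(exposures[e_id].path)
        d = med.direction_screen(outcome_stats, e_stats, ld_matrix,
                                 alpha=config.fdr_alpha,
                                 instrument_kw=config.instrument_kw)
        direction_rows.append({
            "trait_a": "outcome", "trait_b": e_id,
            "classification": d["classification"],
            "a_to_b_status": d["status"]["a_to_b"],
            "b_to_a_status": d["status"]["b_to_a"]})

    mediation_table = pd.DataFrame(mediation_rows)
    direction_table = pd.DataFrame(direction_rows)
    manifest = {
        "seed": config.seed, "fdr_alpha": config.fdr_alpha,
        "n_exposures": len(config.exposures),
        "n_mediators": len(config.mediators),
        "significant_exposures": sig_exp,
        "significant_mediators": sig_med,
        "instruments": config.instrument_kw,
    }

    result = {"exposure_screen": exp_screen, "mediator_screen": med_screen,
              "mediation": mediation_table, "direction": direction_table,
              "manifest": manifest}
    if write:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        exp_screen.to_csv(out / "exposure_screen.tsv", sep="\t", index=False,
                          float_format="%.10g")
        med_screen.to_csv(out / "mediator_screen.tsv", sep="\t", index=False,
                          float_format="%.10g")
        mediation_table.to_csv(out / "mediation.tsv", sep="\t", index=False,
                               float_format="%.10g")
        direction_table.to_csv(out / "direction.tsv", sep="\t", index=False,
                               float_format="%.10g")
        with open(out / "run_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return result
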