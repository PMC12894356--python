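"""Two-step mediation Mendelian randomization.

Quantifies how much of an exposure's effect on a binary outcome is
transmitted through a candidate mediator.  The two legs are estimated from
summary statistics with the exposure's instruments (leg 1, beta1:
exposure -> mediator) and the mediator's instruments (leg 2, beta2:
mediator -> outcome); the mediated (indirect) effect is the product
beta1 * beta2 with a Sobel (product-of-coefficients, first-order delta
method) standard error, and the mediated proportion is the indirect effect
divided by the total exposure -> outcome effect.  Proportions are reported
unclipped: with noisy totals they can legitimately exceed 100%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import instruments as instr
from . import mr
from .io import harmonize
from .mr import MREstimate, Z95

UNSTABLE_TOTAL_Z = 3.0  # |beta_total| < 3*se flags the proportion unstable


@dataclass
class MediationResult:
    """Total, step, and mediated effects for one exposure/mediator pair."""

    beta_total: MREstimate
    beta1: MREstimate
    beta2: MREstimate
    mediated_effect: float
    mediated_se: float
    mediated_ci: tuple[float, float]
    mediated_pval: float
    mediated_proportion: float | None       # as a fraction, not %
    proportion_ci: tuple[float, float] | None
    proportion_stable: bool

    def __post_init__(self) -> None:
        prod = self.beta1.beta * self.beta2.beta
        assert abs(self.mediated_effect - prod) <= 1e-12 * max(1.0, abs(prod))


def mediated_effect(beta1: float, se1: float, beta2: float, se2: float
                    ) -> tuple[float, float, tuple[float, float], float]:
    """Product-of-coefficients indirect effect with Sobel SE.

    effect = beta1*beta2; se = sqrt(beta1^2 se2^2 + beta2^2 se1^2); normal
    95% CI; two-sided p.  Returns (effect, se, (lo, hi), pval).
    """
    if se1 <= 0 or se2 <= 0 or not all(np.isfinite([beta1, se1, beta2, se2])):
        raise ValueError("betas must be finite and SEs positive")
    effect = beta1 * beta2
    se = float(np.sqrt(beta1 ** 2 * se2 ** 2 + beta2 ** 2 * se1 ** 2))
    if se == 0.0:
        pval = 1.0 if effect == 0.0 else 0.0
    else:
        pval = float(2.0 * stats.norm.sf(abs(effect) / se))
    ci = (effect - Z95 * se, effect + Z95 * se)
    return float(effect), se, ci, pval


def mediated_proportion(effect: float, effect_se: float, beta_total: float,
                        total_se: float, n_boot: int = 1000, seed: int = 0
                        ) -> tuple[float | None, tuple[float, float] | None, bool]:
    """Proportion mediated = indirect effect / total effect, bootstrap CI.

    The CI is a percentile parametric bootstrap: the indirect and total
    effects are drawn independently from their normal approximations and the
    ratio's 2.5/97.5 percentiles taken.  When the total effect is weak
    (|beta_total| < 3*total_se) the ratio distribution is too heavy-tailed
    to summarize; the proportion is flagged unstable and no CI is returned.

    Returns (proportion, (lo, hi) or None, stable flag); proportion is a
    fraction (multiply by 100 to report %), and is None when the total
    effect is numerically zero.
    """
    if total_se <= 0 or effect_se < 0:
        raise ValueError("SEs must be positive")
    if abs(beta_total) < 1e-12:
        return None, None, False
    prop = float(effect / beta_total)
    if abs(beta_total) < UNSTABLE_TOTAL_Z * total_se:
        return prop, None, False
    rng = np.random.default_rng(seed)
    eff_b = rng.normal(effect, effect_se, size=n_boot)
    tot_b = rng.normal(beta_total, total_se, size=n_boot)
    ratio = eff_b / tot_b
    lo, hi = np.percentile(ratio, [2.5, 97.5])
    return prop, (float(lo), float(hi)), True


def _single_trait_mr(exposure_stats: pd.DataFrame, outcome_stats: pd.DataFrame,
                     ld_matrix=None, leg: str = "", **instrument_kw) -> MREstimate:
    """Instrument, harmonize and estimate one exposure -> outcome leg."""
    try:
        ivs = instr.select_instruments(exposure_stats, ld_matrix, **instrument_kw)
    except instr.NoInstrumentsError as err:
        raise instr.NoInstrumentsError(
            f"{leg or 'leg'}: {err}") from err
    h = harmonize(ivs.table, outcome_stats)
    if h.n_snps == 0:
        raise instr.NoInstrumentsError(
            f"{leg or 'leg'}: all instruments lost in harmonization")
    return mr.primary_estimate(h)


def run_mediation(exposure_stats: pd.DataFrame, mediator_stats: pd.DataFrame,
                  outcome_stats: pd.DataFrame, ld_matrix=None,
                  n_boot: int = 1000, seed: int = 0,
                  instrument_kw: dict | None = None,
                  mediator_instrument_ids=None) -> MediationResult:
    """Full two-step mediation MR for one exposure/mediator/outcome triple.

    Leg 1 regresses the mediator on the exposure's instruments; leg 2 the
    outcome on the mediator's instruments (unadjusted for the exposure — the
    summary-data approximation of the controlled mediator effect); the total
    effect uses the exposure's instruments against the outcome.  Each leg
    follows the Wald-ratio/IVW selection rule.

    ``mediator_instrument_ids`` optionally restricts leg-2 instrument
    selection to the mediator's own loci (the cis-QTL convention for
    protein mediators), excluding variants whose mediator association is
    transmitted through an upstream trait.
    """
    kw = instrument_kw or {}
    beta1 = _single_trait_mr(exposure_stats, mediator_stats, ld_matrix,
                             leg="exposure->mediator", **kw)
    leg2_source = mediator_stats
    if mediator_instrument_ids is not None:
        leg2_source = mediator_stats[
            mediator_stats["variant_id"].isin(set(mediator_instrument_ids))]
    beta2 = _single_trait_mr(leg2_source, outcome_stats, ld_matrix,
                             leg="mediator->outcome", **kw)
    total = _single_trait_mr(exposure_stats, outcome_stats, ld_matrix,
                             leg="exposure->outcome", **kw)

    eff, se, ci, pval = mediated_effect(beta1.beta, beta1.se,
                                        beta2.beta, beta2.se)
    prop, prop_ci, stable = mediated_proportion(
        eff, se, total.beta, total.se, n_boot=n_boot, seed=seed)
    return MediationResult(
        beta_total=total, beta1=beta1, beta2=beta2,
        mediated_effect=eff, mediated_se=se, mediated_ci=ci,
        mediated_pval=pval, mediated_proportion=prop,
        proportion_ci=prop_ci, proportion_stable=stable)


def direction_screen(trait_a_stats: pd.DataFrame, trait_b_stats: pd.DataFrame,
                     ld_matrix=None, alpha: float = 0.05,
                     instrument_kw: dict | None = None) -> dict:
    """Bidirectional MR between two traits; classify the causal direction.

    Runs a -> b with a's instruments and b -> a with b's, then classifies as
    ``a->b``, ``b->a``, ``bidirectional`` or ``null`` from which directions
    are significant at ``alpha``.  A direction with no instruments is
    reported ``untestable`` (distinct from a tested null).
    """
    kw = instrument_kw or {}
    results: dict = {"a_to_b": None, "b_to_a": None}
    status: dict[str, str] = {}
    for key, (src, dst) in {
        "a_to_b": (trait_a_stats, trait_b_stats),
        "b_to_a": (trait_b_stats, trait_a_stats),
    }.items():
        try:
            est = _single_trait_mr(src, dst, ld_matrix, leg=key, **kw)
            results[key] = est
            status[key] = "significant" if est.pval < alpha else "null"
        except instr.NoInstrumentsError:
            status[key] = "untestable"

    sig_ab = status["a_to_b"] == "significant"
    sig_ba = status["b_to_a"] == "significant"
    if sig_ab and sig_ba:
        label = "bidirectional"
    elif sig_ab:
        label = "a->b"
    elif sig_ba:
        label = "b->a"
    elif "untestable" in status.values():
        label = "untestable"
    else:
        label = "null"
    return {"classification": label, "status": status, "estimates": results}


def mediation_table_row(exposure: str, mediator: str, outcome: str,
                        res: MediationResult) -> dict:
    """Flatten a MediationResult into one report row (proportion in %)."""
    def _ci(e: MREstimate) -> str:
        return f"{e.beta:.2f} ({e.ci_low:.2f}, {e.ci_high:.2f})"

    prop_pct = (None if res.mediated_proportion is None
                else 100.0 * res.mediated_proportion)
    prop_ci = (None if res.proportion_ci is None else
               f"({100 * res.proportion_ci[0]:.2f}%, {100 * res.proportion_ci[1]:.2f}%)")
    return {
        "exposure": exposure, "mediator": mediator, "outcome": outcome,
        "beta_total": res.beta_total.beta, "beta_total_ci": _ci(res.beta_total),
        "beta1": res.beta1.beta, "beta1_ci": _ci(res.beta1),
        "beta2": res.beta2.beta, "beta2_ci": _ci(res.beta2),
        "mediation_effect": res.mediated_effect,
        "mediation_effect_ci": (f"{res.mediated_ci[0]:.2f}, "
                                f"{res.mediated_ci[1]:.2f}"),
        "mediation_proportion_pct": prop_pct,
        "mediation_proportion_ci": prop_ci,
        "proportion_stable": res.proportion_stable,
        "pval": res.mediated_pval,
    }
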