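"""Monte-Carlo validation experiments on the synthetic causal chain.

These drive the package's own quality checks: type-I-error calibration of
the IVW and MR-PRESSO tests under the no-effect scenario, confidence-
interval coverage for the two mediation legs and the mediated proportion
under the default chain, and recovery of planted directional pleiotropy by
the MR-Egger intercept.  Every experiment derives per-replicate seeds from
one master seed, so results are exactly reproducible.
"""

from __future__ import annotations

import numpy as np

from . import mr
from .instruments import select_instruments
from .io import harmonize
from .mediation import run_mediation
from .synthetic import SimScenario, simulate_summary_stats

NULL_SCENARIO_KW = dict(beta1_true=0.0, beta2_true=0.0, beta_direct_true=0.0)


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def _harmonized_exposure_outcome(scenario: SimScenario):
    triple = simulate_summary_stats(scenario)
    ivs = select_instruments(triple.exposure_stats, triple.ld_matrix)
    return harmonize(ivs.table, triple.outcome_stats), triple


def ivw_null_rejection_rate(n_reps: int = 2000, seed: int = 0,
                            alpha: float = 0.05, mode: str = "random"
                            ) -> float:
    """Fraction of null-scenario replicates where IVW rejects at alpha."""
    rejections = 0
    for s in _child_seeds(seed, n_reps):
        sc = SimScenario(seed=int(s), **NULL_SCENARIO_KW)
        h, _ = _harmonized_exposure_outcome(sc)
        rejections += mr.ivw(h, mode=mode).pval < alpha
    return rejections / n_reps


def presso_null_rejection_rate(n_reps: int = 500, n_sim: int = 1000,
                               seed: int = 0, alpha: float = 0.05) -> float:
    """Fraction of null replicates where the MR-PRESSO global test rejects."""
    rejections = 0
    for s in _child_seeds(seed, n_reps):
        sc = SimScenario(seed=int(s), **NULL_SCENARIO_KW)
        h, _ = _harmonized_exposure_outcome(sc)
        gp, _ = mr.mr_presso(h, n_sim=n_sim, seed=int(s) ^ 0x5EED)
        rejections += gp < alpha
    return rejections / n_reps


def chain_recovery(n_reps: int = 200, seed: int = 0, n_boot: int = 500,
                   scenario_kw: dict | None = None) -> dict:
    """CI coverage of beta1, beta2 and the mediated proportion.

    Runs the full two-step mediation pipeline on fresh replicates of the
    default chain scenario and records whether each 95% interval covers its
    generating value.  Returns the three empirical coverage fractions plus
    the mean point estimates.
    """
    kw = scenario_kw or {}
    cover1 = cover2 = cover_prop = 0
    n_prop = 0
    est1, est2, props = [], [], []
    for s in _child_seeds(seed, n_reps):
        sc = SimScenario(seed=int(s), **kw)
        true_prop = sc.beta1_true * sc.beta2_true / sc.total_effect_true
        triple = simulate_summary_stats(sc)
        res = run_mediation(triple.exposure_stats, triple.mediator_stats,
                            triple.outcome_stats, triple.ld_matrix,
                            n_boot=n_boot, seed=int(s) ^ 0xB007)
        cover1 += res.beta1.ci_low <= sc.beta1_true <= res.beta1.ci_high
        cover2 += res.beta2.ci_low <= sc.beta2_true <= res.beta2.ci_high
        est1.append(res.beta1.beta)
        est2.append(res.beta2.beta)
        if res.proportion_ci is not None:
            n_prop += 1
            lo, hi = res.proportion_ci
            cover_prop += lo <= true_prop <= hi
            props.append(res.mediated_proportion)
    return {
        "coverage_beta1": cover1 / n_reps,
        "coverage_beta2": cover2 / n_reps,
        "coverage_proportion": cover_prop / max(n_prop, 1),
        "n_proportion_stable": n_prop,
        "mean_beta1": float(np.mean(est1)),
        "mean_beta2": float(np.mean(est2)),
        "mean_proportion": float(np.mean(props)) if props else float("nan"),
        "n_reps": n_reps,
    }


def ivw_total_effect_recovery(n_reps: int = 500, seed: int = 0,
                              scenario_kw: dict | None = None) -> dict:
    """Mean IVW estimate of the total effect over replicates.

    With balanced (or absent) pleiotropy the mean estimate must sit within
    Monte-Carlo error of the scenario's generating total effect.
    """
    kw = scenario_kw or {}
    estimates = []
    truth = SimScenario(**kw).total_effect_true
    for s in _child_seeds(seed, n_reps):
        h, _ = _harmonized_exposure_outcome(SimScenario(seed=int(s), **kw))
        estimates.append(mr.ivw(h, mode="fixed").beta)
    estimates = np.asarray(estimates)
    return {
        "mean_estimate": float(estimates.mean()),
        "true_total": float(truth),
        "mc_se": float(estimates.std(ddof=1) / np.sqrt(n_reps)),
        "n_reps": n_reps,
    }


def egger_intercept_recovery(n_reps: int = 200, seed: int = 0,
                             pleiotropy_mean: float = 0.02) -> dict:
    """Mean MR-Egger intercept under planted directional pleiotropy.

    A constant pleiotropic offset added to every instrument's outcome effect
    must surface as the Egger intercept.  The offset is planted on the null
    causal chain so that regression dilution of the slope (sampling noise in
    the exposure effects violating the no-measurement-error condition)
    cannot leak a fraction of a non-null causal effect into the intercept;
    that leakage is a known property of MR-Egger, not of this
    implementation."""
    intercepts = []
    for s in _child_seeds(seed, n_reps):
        sc = SimScenario(seed=int(s), pleiotropy_mean=pleiotropy_mean,
                         pleiotropy_sd=0.0, **NULL_SCENARIO_KW)
        h, _ = _harmonized_exposure_outcome(sc)
        intercepts.append(mr.egger(h).intercept)
    intercepts = np.asarray(intercepts)
    return {
        "mean_intercept": float(intercepts.mean()),
        "planted": float(pleiotropy_mean),
        "mc_se": float(intercepts.std(ddof=1) / np.sqrt(n_reps)),
        "n_reps": n_reps,
    }


def cochran_q_power(n_reps: int = 200, seed: int = 0,
                    extra_ratio_sd: float = 0.05, alpha: float = 0.05
                    ) -> float:
    """Rejection rate of Cochran's Q under per-SNP ratio heterogeneity,
    planted as balanced pleiotropy of the given SD on the outcome effects."""
    rejections = 0
    for s in _child_seeds(seed, n_reps):
        sc = SimScenario(seed=int(s), pleiotropy_mean=0.0,
                         pleiotropy_sd=extra_ratio_sd, **NULL_SCENARIO_KW)
        h, _ = _harmonized_exposure_outcome(sc)
        _, _, p = mr.cochran_q(h)
        rejections += p < alpha
    return rejections / n_reps
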