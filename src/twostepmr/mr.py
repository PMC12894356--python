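"""Causal-effect estimators and sensitivity battery for two-sample MR.

All estimators operate on a harmonized exposure/outcome effect table.  The
working quantity is the per-variant Wald ratio rho_i = beta_out_i /
beta_exp_i with inverse-variance weight w_i = beta_exp_i^2 / se_out_i^2
(first-order weights, ignoring exposure-side uncertainty, the standard
summary-data convention).  IVW is then the weighted mean of the ratios,
identically a zero-intercept weighted regression of outcome on exposure
effects with weights 1/se_out^2.

Estimators
----------
wald_ratio       single-instrument ratio estimate
ivw              fixed- or multiplicative-random-effects inverse-variance
                 weighted estimate
egger            weighted regression with a free intercept (directional
                 pleiotropy estimate)
weighted_median  majority-valid estimator, bootstrap SE
weighted_mode    plurality-valid (kernel density mode) estimator, bootstrap SE

Sensitivity
-----------
cochran_q        heterogeneity of the per-variant ratios
leave_one_out    influence of each single variant on the IVW estimate
mr_presso        simulation-based global pleiotropy test with per-variant
                 outlier flagging
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import HarmonizedSet

Z95 = stats.norm.ppf(0.975)


class InsufficientInstrumentsError(ValueError):
    """Fewer variants than the estimator's minimum."""


class UndefinedRatioError(ValueError):
    """Wald ratio undefined because the exposure effect is zero."""


@dataclass
class MREstimate:
    """One estimator's causal effect with normal-theory inference."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")


def to_odds_ratio(est: MREstimate) -> tuple[float, tuple[float, float]]:
    """Exponentiate a log-odds estimate to an odds ratio with 95% CI."""
    return float(np.exp(est.beta)), (float(np.exp(est.ci_low)),
                                     float(np.exp(est.ci_high)))


def _table(h) -> pd.DataFrame:
    return h.table if isinstance(h, HarmonizedSet) else h


def _arrays(h):
    t = _table(h)
    return (t["beta_exp"].to_numpy(float), t["se_exp"].to_numpy(float),
            t["beta_out"].to_numpy(float), t["se_out"].to_numpy(float))


def _ratios_weights(h):
    bx, _, by, sy = _arrays(h)
    if np.any(bx == 0):
        raise UndefinedRatioError("undefined ratio: exposure beta is zero")
    rho = by / bx
    w = bx ** 2 / sy ** 2
    return rho, w


def _normal_estimate(method, beta, se, k, **kw) -> MREstimate:
    pval = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else (
        1.0 if beta == 0 else 0.0)
    return MREstimate(method=method, beta=float(beta), se=float(se),
                      ci_low=float(beta - Z95 * se),
                      ci_high=float(beta + Z95 * se),
                      pval=float(pval), n_snps=int(k), **kw)


def wald_ratio(h) -> MREstimate:
    """Single-instrument causal estimate beta_out/beta_exp.

    SE is first order, se_out/|beta_exp|, which ignores exposure-side noise;
    adequate when the instrument is strong (F >> 10).
    """
    t = _table(h)
    if len(t) != 1:
        raise InsufficientInstrumentsError(
            f"wald_ratio needs exactly 1 variant, got {len(t)}")
    bx, _, by, sy = (float(v[0]) for v in _arrays(h))
    if bx == 0:
        raise UndefinedRatioError("undefined ratio: exposure beta is zero")
    return _normal_estimate("wald_ratio", by / bx, sy / abs(bx), 1)


def ivw(h, mode: str = "random") -> MREstimate:
    """Inverse-variance-weighted estimate over per-variant Wald ratios.

    ``mode="fixed"`` uses se = (sum w)^-1/2.  ``mode="random"`` applies the
    multiplicative random-effects correction: the SE is inflated by
    sqrt(max(1, Q/(k-1))), never deflated, so under homogeneity the two
    flavours coincide.
    """
    rho, w = _ratios_weights(h)
    k = rho.size
    if k < 2:
        raise InsufficientInstrumentsError(f"ivw needs >= 2 variants, got {k}")
    beta = float(np.sum(w * rho) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    label = "ivw_fe"
    if mode == "random":
        q = float(np.sum(w * (rho - beta) ** 2))
        se *= float(np.sqrt(max(1.0, q / (k - 1))))
        label = "ivw_re"
    elif mode != "fixed":
        raise ValueError(f"unknown ivw mode {mode!r}")
    return _normal_estimate(label, beta, se, k)


def egger(h) -> MREstimate:
    """MR-Egger: weighted regression of outcome on exposure effects with a
    free intercept.

    The slope is the causal estimate under the InSIDE assumption; the
    intercept estimates average directional pleiotropy.  Variants are
    oriented so all exposure effects are non-negative before fitting, and
    SEs carry a multiplicative overdispersion factor floored at 1.
    """
    bx, _, by, sy = _arrays(h)
    k = bx.size
    if k < 3:
        raise InsufficientInstrumentsError(f"egger needs >= 3 variants, got {k}")
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    x = bx * flip
    y = by * flip
    w = 1.0 / sy ** 2

    # closed-form weighted least squares with intercept
    sw, swx, swy = np.sum(w), np.sum(w * x), np.sum(w * y)
    sxx = np.sum(w * x * x)
    sxy = np.sum(w * x * y)
    denom = sw * sxx - swx ** 2
    slope = (sw * sxy - swx * swy) / denom
    intercept = (swy - slope * swx) / sw
    resid = y - intercept - slope * x
    rss = float(np.sum(w * resid ** 2))
    phi = max(1.0, rss / (k - 2))  # overdispersion floored at 1
    se_slope = float(np.sqrt(phi * sw / denom))
    se_int = float(np.sqrt(phi * sxx / denom))
    int_p = float(2.0 * stats.norm.sf(abs(intercept) / se_int))
    return _normal_estimate("egger", slope, se_slope, k,
                            intercept=float(intercept),
                            intercept_se=se_int, intercept_pval=int_p)


def _weighted_median_point(rho: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(rho, kind="mergesort")
    rho_s = rho[order]
    w_s = w[order] / np.sum(w)
    # mid-point cumulative weights; linear interpolation at the 0.5 crossing
    cum = np.cumsum(w_s) - 0.5 * w_s
    if cum[0] >= 0.5:
        return float(rho_s[0])
    if cum[-1] <= 0.5:
        return float(rho_s[-1])
    idx = int(np.searchsorted(cum, 0.5))
    lo, hi = idx - 1, idx
    frac = (0.5 - cum[lo]) / (cum[hi] - cum[lo])
    return float(rho_s[lo] + frac * (rho_s[hi] - rho_s[lo]))


def weighted_median(h, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted-median estimator: consistent if >=50% of weight is valid.

    SE by parametric bootstrap: exposure and outcome effects are redrawn
    from normal(beta, se) and the weighted median recomputed.
    """
    t = _table(h)
    k = len(t)
    if k < 3:
        raise InsufficientInstrumentsError(
            f"weighted_median needs >= 3 variants, got {k}")
    rho, w = _ratios_weights(h)
    beta = _weighted_median_point(rho, w)

    bx, sx, by, sy = _arrays(h)
    rng = np.random.default_rng(seed)
    bx_b = rng.normal(bx, sx, size=(n_boot, k))
    by_b = rng.normal(by, sy, size=(n_boot, k))
    bx_b[bx_b == 0] = np.finfo(float).tiny
    boots = np.empty(n_boot)
    for b in range(n_boot):
        rho_b = by_b[b] / bx_b[b]
        w_b = bx_b[b] ** 2 / sy ** 2
        boots[b] = _weighted_median_point(rho_b, w_b)
    se = float(np.std(boots, ddof=1))
    return _normal_estimate("weighted_median", beta, se, k)


def _mode_point(rho, w, bandwidth_factor):
    w = w / np.sum(w)
    center = _weighted_median_point(rho, w)
    mad = _weighted_median_point(np.abs(rho - center), w)
    scale = 1.4826 * mad
    h_bw = bandwidth_factor * 0.9 * scale * rho.size ** (-0.2)
    h_bw = max(h_bw, 1e-8 * max(1.0, float(np.max(np.abs(rho)))))  # guard
    grid = np.linspace(np.min(rho) - 3 * h_bw, np.max(rho) + 3 * h_bw, 512)
    dens = np.sum(
        w[:, None] * np.exp(-0.5 * ((grid[None, :] - rho[:, None]) / h_bw) ** 2),
        axis=0)
    return float(grid[int(np.argmax(dens))])


def weighted_mode(h, bandwidth_factor: float = 1.0, n_boot: int = 1000,
                  seed: int = 0) -> MREstimate:
    """Weighted-mode estimator: peak of the kernel-smoothed ratio density.

    Consistent if the largest group of variants sharing a ratio is valid.
    Bandwidth is ``bandwidth_factor`` times a weighted-MAD-based normal
    scale, guarded away from zero.
    """
    t = _table(h)
    k = len(t)
    if k < 3:
        raise InsufficientInstrumentsError(
            f"weighted_mode needs >= 3 variants, got {k}")
    rho, w = _ratios_weights(h)
    beta = _mode_point(rho, w, bandwidth_factor)

    bx, sx, by, sy = _arrays(h)
    rng = np.random.default_rng(seed)
    bx_b = rng.normal(bx, sx, size=(n_boot, k))
    by_b = rng.normal(by, sy, size=(n_boot, k))
    bx_b[bx_b == 0] = np.finfo(float).tiny
    boots = np.empty(n_boot)
    for b in range(n_boot):
        rho_b = by_b[b] / bx_b[b]
        w_b = bx_b[b] ** 2 / sy ** 2
        boots[b] = _mode_point(rho_b, w_b, bandwidth_factor)
    se = float(np.std(boots, ddof=1))
    return _normal_estimate("weighted_mode", beta, se, k)


def cochran_q(h) -> tuple[float, int, float]:
    """Heterogeneity of the ratio estimates around the fixed-effect IVW.

    Returns (Q, df, p) with Q = sum w_i (rho_i - beta_ivw)^2, df = k-1,
    p from the chi-square upper tail.
    """
    rho, w = _ratios_weights(h)
    k = rho.size
    if k < 2:
        raise InsufficientInstrumentsError(f"cochran_q needs >= 2 variants, got {k}")
    beta = np.sum(w * rho) / np.sum(w)
    q = float(np.sum(w * (rho - beta) ** 2))
    df = k - 1
    return q, df, float(stats.chi2.sf(q, df))


def leave_one_out(h) -> pd.DataFrame:
    """IVW re-estimates dropping one variant at a time.

    Flags variants whose removal flips the sign of the estimate or moves it
    outside the full-set 95% CI.
    """
    t = _table(h)
    k = len(t)
    if k < 3:
        raise InsufficientInstrumentsError(
            f"leave_one_out needs >= 3 variants, got {k}")
    full = ivw(h, mode="fixed")
    rows = []
    for i in range(k):
        sub = t.drop(t.index[i])
        est = ivw(sub, mode="fixed")
        flagged = (np.sign(est.beta) != np.sign(full.beta)) or not (
            full.ci_low <= est.beta <= full.ci_high)
        rows.append({
            "dropped_variant": t.iloc[i]["variant_id"],
            "beta": est.beta, "se": est.se,
            "ci_low": est.ci_low, "ci_high": est.ci_high,
            "pval": est.pval, "influential": bool(flagged),
        })
    return pd.DataFrame(rows)


def mr_presso(h, n_sim: int = 1000, seed: int = 0,
              outlier_alpha: float = 0.05) -> tuple[float, list[int]]:
    """Simulation-based global pleiotropy test with outlier detection.

    The observed weighted residual sum of squares of the IVW fit (expected
    outcome effect for variant i taken from the leave-one-out IVW estimate,
    so a variant cannot mask itself) is ranked against ``n_sim`` parametric
    replicates in which outcome effects are redrawn from
    normal(expected_i, se_out_i).  The global p-value is the rank-based
    upper-tail probability.  Per-variant outlier p-values compare each
    observed squared standardized residual with its simulated distribution,
    Bonferroni-corrected at ``outlier_alpha``.

    Returns (global_pval, sorted outlier row indices into ``h.table``).
    """
    t = _table(h)
    k = len(t)
    if k < 4:
        raise InsufficientInstrumentsError(f"mr_presso needs >= 4 variants, got {k}")
    bx, _, by, sy = _arrays(h)
    w = 1.0 / sy ** 2
    wx2 = (bx ** 2) * w

    def _loo_resid2(y):
        # weighted squared residual of each variant against the IVW slope
        # re-fitted without it, so a variant cannot mask itself;
        # y may be a (n_sim, k) matrix of simulated outcome effects
        wxy = bx * y * w
        slope_loo = (wxy.sum(axis=-1, keepdims=y.ndim > 1) - wxy) \
            / (np.sum(wx2) - wx2)
        return (y - slope_loo * bx) ** 2 * w

    resid2 = _loo_resid2(by)
    rss_obs = float(np.sum(resid2))

    # simulate outcome effects under the fitted no-pleiotropy model and
    # push them through the same leave-one-out residual computation, so the
    # null distribution carries the same estimation noise as the observed
    slope_fit = float(np.sum(bx * by * w) / np.sum(wx2))
    rng = np.random.default_rng(seed)
    by_sim = rng.normal(slope_fit * bx, sy, size=(n_sim, k))
    resid2_sim = _loo_resid2(by_sim)
    rss_sim = np.sum(resid2_sim, axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))

    p_var = (1 + np.sum(resid2_sim >= resid2, axis=0)) / (n_sim + 1)
    outliers = np.flatnonzero(p_var < outlier_alpha / k)
    return global_p, sorted(int(i) for i in outliers)


def sensitivity_report(h, n_sim: int = 1000, seed: int = 0) -> dict:
    """Run the full sensitivity battery on a harmonized set.

    Components requiring more variants than available are reported as None.
    """
    t = _table(h)
    k = len(t)
    out: dict = {"n_snps": k, "cochran_q": None, "q_df": None, "q_pval": None,
                 "egger_intercept": None, "egger_intercept_se": None,
                 "egger_intercept_pval": None, "leave_one_out": None,
                 "presso_pval": None, "presso_outliers": None}
    if k >= 2:
        q, df, p = cochran_q(h)
        out.update(cochran_q=q, q_df=df, q_pval=p)
    if k >= 3:
        e = egger(h)
        out.update(egger_intercept=e.intercept,
                   egger_intercept_se=e.intercept_se,
                   egger_intercept_pval=e.intercept_pval)
        out["leave_one_out"] = leave_one_out(h)
    if k >= 4:
        gp, oi = mr_presso(h, n_sim=n_sim, seed=seed)
        out.update(presso_pval=gp, presso_outliers=oi)
    return out


def primary_estimate(h, mode: str = "random",
                     wald_if_single: bool = True) -> MREstimate:
    """Estimator-selection rule for the screen: Wald ratio for a single
    instrument, IVW otherwise."""
    t = _table(h)
    if len(t) == 0:
        raise InsufficientInstrumentsError("no variants in harmonized set")
    if len(t) == 1:
        if not wald_if_single:
            raise InsufficientInstrumentsError("single variant, Wald disabled")
        return wald_ratio(h)
    return ivw(h, mode=mode)
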