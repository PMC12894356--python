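"""Estimator correctness against closed forms and independent oracles."""

import numpy as np
import pytest
import statsmodels.api as sm

from twostepmr import (
    InsufficientInstrumentsError,
    UndefinedRatioError,
    cochran_q,
    egger,
    ivw,
    leave_one_out,
    mr_presso,
    primary_estimate,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
    weighted_mode,
)

from conftest import make_hset


def _random_hset(seed=0, k=12, slope=0.4, intercept=0.0, noise=0.03):
    rng = np.random.default_rng(seed)
    bx = np.abs(rng.normal(0.25, 0.05, k))
    by = intercept + slope * bx + rng.normal(0.0, noise, k)
    return make_hset(bx, 0.03, by, noise)


# ------------------------------------------------------------ wald ratio

def test_wald_ratio_arithmetic():
    est = wald_ratio(make_hset([0.2], [0.01], [0.1], [0.02]))
    assert est.beta == pytest.approx(0.5)
    assert est.se == pytest.approx(0.1)
    assert est.method == "wald_ratio" and est.n_snps == 1


def test_wald_ratio_null_outcome():
    est = wald_ratio(make_hset([0.2], [0.01], [0.0], [0.02]))
    assert est.beta == 0.0 and est.pval == pytest.approx(1.0)


def test_wald_ratio_invariant_to_allele_sign_flip():
    a = wald_ratio(make_hset([0.2], [0.01], [0.1], [0.02]))
    b = wald_ratio(make_hset([-0.2], [0.01], [-0.1], [0.02]))
    assert a.beta == pytest.approx(b.beta)
    assert a.se == pytest.approx(b.se)


def test_wald_ratio_zero_exposure_beta_rejected():
    with pytest.raises(UndefinedRatioError):
        wald_ratio(make_hset([0.0], [0.01], [0.1], [0.02]))


def test_wald_ratio_requires_single_variant():
    with pytest.raises(InsufficientInstrumentsError):
        wald_ratio(make_hset([0.2, 0.3], 0.01, [0.1, 0.1], 0.02))


# ------------------------------------------------------------------- ivw

def test_ivw_homogeneous_ratios_fixed_equals_random():
    h = make_hset([0.1, 0.2, 0.4], 0.01, [0.05, 0.10, 0.20], 0.01)
    fe, re = ivw(h, "fixed"), ivw(h, "random")
    assert fe.beta == pytest.approx(0.5)
    assert re.beta == pytest.approx(fe.beta)
    assert re.se == pytest.approx(fe.se)  # Q < df: no inflation
    q, df, p = cochran_q(h)
    assert q == pytest.approx(0.0, abs=1e-20) and p == pytest.approx(1.0)


def test_ivw_two_variant_closed_form():
    """Spec fixture: equals the zero-intercept WLS fit through the origin."""
    bx = np.array([0.1, 0.2])
    by = np.array([0.05, 0.20])
    sy = np.array([0.01, 0.01])
    est = ivw(make_hset(bx, 0.01, by, sy), "fixed")
    w = 1.0 / sy**2
    beta_wls = np.sum(w * bx * by) / np.sum(w * bx**2)
    assert est.beta == pytest.approx(beta_wls, rel=1e-12)
    assert est.se == pytest.approx(np.sum(bx**2 / sy**2) ** -0.5, rel=1e-12)


@pytest.mark.parametrize("seed", range(5))
def test_ivw_matches_statsmodels_wls_through_origin(seed):
    h = _random_hset(seed)
    t = h.table
    fit = sm.WLS(t["beta_out"], t["beta_exp"],
                 weights=1.0 / t["se_out"]**2).fit()
    est = ivw(h, "fixed")
    assert est.beta == pytest.approx(fit.params.iloc[0], rel=1e-10)


def test_ivw_random_never_deflates_se():
    h = _random_hset(3, noise=0.08)
    assert ivw(h, "random").se >= ivw(h, "fixed").se


def test_ivw_requires_two_variants():
    with pytest.raises(InsufficientInstrumentsError):
        ivw(make_hset([0.2], 0.01, [0.1], 0.02))


# ----------------------------------------------------------------- egger

def test_egger_perfect_linear_fit_is_exact():
    bx = np.array([0.1, 0.2, 0.3])
    by = 0.02 + 0.5 * bx  # exactly collinear
    est = egger(make_hset(bx, 0.01, by, 0.02))
    assert est.beta == pytest.approx(0.5, rel=1e-10)
    assert est.intercept == pytest.approx(0.02, rel=1e-10)


@pytest.mark.parametrize("seed", range(4))
def test_egger_matches_statsmodels_wls_with_intercept(seed):
    h = _random_hset(seed, intercept=0.02)
    t = h.table
    w = 1.0 / t["se_out"]**2
    fit = sm.WLS(t["beta_out"], sm.add_constant(t["beta_exp"]),
                 weights=w).fit()
    est = egger(h)
    assert est.intercept == pytest.approx(fit.params.iloc[0], rel=1e-10)
    assert est.beta == pytest.approx(fit.params.iloc[1], rel=1e-10)
    # SEs agree once the overdispersion floor is accounted for
    scale_floor = np.sqrt(max(1.0, fit.scale) / fit.scale)
    assert est.se == pytest.approx(fit.bse.iloc[1] * scale_floor, rel=1e-10)


def test_egger_orientation_invariance():
    """Flipping the reported allele of some variants (sign of both betas)
    must not change the Egger fit."""
    h = _random_hset(7)
    flipped = h.table.copy()
    flipped.loc[::2, ["beta_exp", "beta_out"]] *= -1.0
    a, b = egger(h), egger(make_hset(
        flipped["beta_exp"], flipped["se_exp"],
        flipped["beta_out"], flipped["se_out"]))
    assert a.beta == pytest.approx(b.beta, rel=1e-12)
    assert a.intercept == pytest.approx(b.intercept, rel=1e-12)


def test_egger_with_zero_intercept_constraint_reproduces_ivw():
    """Cross-check: the free-intercept fit collapses onto IVW when the
    intercept is constrained to zero (here: data demeaned so the WLS
    intercept estimate is numerically zero)."""
    h = _random_hset(9)
    t = h.table
    w = 1.0 / t["se_out"]**2
    fit0 = sm.WLS(t["beta_out"], t["beta_exp"], weights=w).fit()
    assert ivw(h, "fixed").beta == pytest.approx(fit0.params.iloc[0],
                                                 rel=1e-10)


def test_egger_requires_three_variants():
    with pytest.raises(InsufficientInstrumentsError):
        egger(make_hset([0.1, 0.2], 0.01, [0.05, 0.1], 0.02))


# ------------------------------------------------------- weighted median

def test_weighted_median_equal_weights_is_plain_median():
    h = make_hset([0.1, 0.1, 0.1], 0.01, [0.1, 0.2, 0.9], 0.02)
    assert weighted_median(h, n_boot=50, seed=1).beta == pytest.approx(2.0)


def test_weighted_median_dominating_weight_wins():
    # first variant carries >50% of total weight => estimate is its ratio
    h = make_hset([1.0, 0.05, 0.05], 0.01, [0.3, 0.04, 0.045], 0.02)
    est = weighted_median(h, n_boot=50, seed=1)
    assert est.beta == pytest.approx(0.3, abs=0.01)


def _median_oracle(rho, w):
    """Independent cumulative-weight interpolation (brute force)."""
    order = np.argsort(rho)
    rho, w = np.asarray(rho)[order], np.asarray(w)[order] / np.sum(w)
    cum = np.cumsum(w) - 0.5 * w
    for i in range(1, len(rho)):
        if cum[i] >= 0.5:
            return rho[i - 1] + (0.5 - cum[i - 1]) * \
                (rho[i] - rho[i - 1]) / (cum[i] - cum[i - 1])
    return rho[-1]


@pytest.mark.parametrize("seed", range(5))
def test_weighted_median_matches_interpolation_oracle(seed):
    h = _random_hset(seed, k=5, noise=0.05)
    t = h.table
    rho = (t["beta_out"] / t["beta_exp"]).to_numpy()
    w = (t["beta_exp"]**2 / t["se_out"]**2).to_numpy()
    est = weighted_median(h, n_boot=50, seed=2)
    assert est.beta == pytest.approx(_median_oracle(rho, w), rel=1e-12)


def test_weighted_median_bootstrap_deterministic_with_seed():
    h = _random_hset(11)
    a = weighted_median(h, n_boot=200, seed=5)
    b = weighted_median(h, n_boot=200, seed=5)
    assert a.se == b.se


# --------------------------------------------------------- weighted mode

def test_weighted_mode_degenerate_ratios():
    h = make_hset([0.1, 0.2, 0.3], 0.01, [0.05, 0.10, 0.15], 0.02)
    est = weighted_mode(h, n_boot=20, seed=1)
    assert est.beta == pytest.approx(0.5, abs=1e-6)  # zero-bandwidth guard


def test_weighted_mode_finds_cluster_not_outlier():
    bx = np.full(5, 0.1)
    by = np.array([0.05, 0.051, 0.049, 0.05, 0.5])  # 4 @ 0.5, outlier @ 5
    est = weighted_mode(make_hset(bx, 0.01, by, 0.02), n_boot=20, seed=1)
    assert est.beta == pytest.approx(0.5, abs=0.05)


def test_weighted_mode_requires_three_variants():
    with pytest.raises(InsufficientInstrumentsError):
        weighted_mode(make_hset([0.1, 0.2], 0.01, [0.05, 0.1], 0.02))


# ------------------------------------------------------------- cochran q

def test_cochran_q_two_variant_closed_form():
    """For k=2, Q is the squared standardized difference of the ratios."""
    bx = np.array([0.1, 0.2])
    by = np.array([0.05, 0.26])
    sy = np.array([0.01, 0.03])
    rho = by / bx
    var = (sy / bx) ** 2
    q_oracle = (rho[0] - rho[1]) ** 2 / (var[0] + var[1])
    q, df, p = cochran_q(make_hset(bx, 0.01, by, sy))
    assert q == pytest.approx(q_oracle, rel=1e-12)
    assert df == 1


# --------------------------------------------------------- leave one out

def test_leave_one_out_homogeneous_reestimates_equal_full():
    h = make_hset([0.1, 0.2, 0.4, 0.25], 0.01,
                  [0.05, 0.10, 0.20, 0.125], 0.01)
    tab = leave_one_out(h)
    assert len(tab) == 4
    np.testing.assert_allclose(tab["beta"], 0.5, rtol=1e-12)
    assert not tab["influential"].any()


def test_leave_one_out_flags_planted_outlier():
    bx = np.full(8, 0.25)
    by = np.full(8, 0.1)
    by[3] = 0.4  # one wildly deviant ratio
    tab = leave_one_out(make_hset(bx, 0.01, by, 0.01))
    assert tab.loc[3, "influential"]
    assert tab["influential"].sum() == 1


# ------------------------------------------------------------- mr presso

def test_mr_presso_deterministic_and_calibration_sane():
    h = _random_hset(17, k=10)
    p1, o1 = mr_presso(h, n_sim=400, seed=9)
    p2, o2 = mr_presso(h, n_sim=400, seed=9)
    assert p1 == p2 and o1 == o2
    assert 0.0 < p1 <= 1.0


def test_mr_presso_detects_planted_pleiotropic_outlier():
    bx = np.full(10, 0.25)
    by = 0.4 * bx + 0.0
    by = by.copy()
    by[4] += 10 * 0.02  # offset of 10x the outcome SE
    p, outliers = mr_presso(make_hset(bx, 0.01, by, 0.02),
                            n_sim=1000, seed=3)
    assert 4 in outliers
    assert p < 0.05


def test_mr_presso_requires_four_variants():
    with pytest.raises(InsufficientInstrumentsError):
        mr_presso(make_hset([0.1, 0.2, 0.3], 0.01, [0.1, 0.1, 0.1], 0.02))


# ------------------------------------------------------------ reporting

def test_to_odds_ratio_identity_and_monotonicity():
    est = primary_estimate(make_hset([0.2], [0.01], [0.0], [0.02]))
    or0, _ = to_odds_ratio(est)
    assert or0 == pytest.approx(1.0)
    a = to_odds_ratio(primary_estimate(
        make_hset([0.2], [0.01], [0.05], [0.02])))[0]
    b = to_odds_ratio(primary_estimate(
        make_hset([0.2], [0.01], [0.10], [0.02])))[0]
    assert b > a


def test_to_odds_ratio_reproduces_reported_transform():
    """log-odds 0.433 with CI (0.239, 0.620) maps to OR 1.54 (1.27, 1.86)."""
    est = wald_ratio(make_hset([1.0], [1e-6], [0.4318], [0.0974]))
    or_, (lo, hi) = to_odds_ratio(est)
    assert round(or_, 2) == 1.54
    assert round(lo, 2) == 1.27
    assert round(hi, 2) == 1.86


# ------------------------------------------------- shared properties

@pytest.mark.parametrize("estimator", [
    lambda h: ivw(h, "fixed"),
    lambda h: ivw(h, "random"),
    egger,
    lambda h: weighted_median(h, n_boot=100, seed=4),
    lambda h: weighted_mode(h, n_boot=20, seed=4),
])
@pytest.mark.parametrize("c", [2.5, 0.3])
def test_estimators_equivariant_to_exposure_rescaling(estimator, c):
    """Scaling exposure effects (and SEs) by c scales the causal estimate
    by 1/c: the estimate is per SD of exposure, whatever the SD units."""
    h = _random_hset(23, k=8)
    t = h.table
    scaled = make_hset(c * t["beta_exp"], c * t["se_exp"],
                       t["beta_out"], t["se_out"])
    a, b = estimator(h), estimator(scaled)
    assert b.beta == pytest.approx(a.beta / c, rel=1e-9)


def test_primary_estimate_selection_rule():
    single = make_hset([0.2], [0.01], [0.1], [0.02])
    multi = make_hset([0.2, 0.3], 0.01, [0.1, 0.15], 0.02)
    assert primary_estimate(single).method == "wald_ratio"
    assert primary_estimate(multi).method == "ivw_re"
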