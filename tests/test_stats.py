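"""Effect estimators and tests: closed-form oracles, enumeration oracles,
simulation recovery, and the frozen worked examples."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyexpress import stats
from polyexpress.stats import (bin_comparison, bonferroni, carrier_effect,
                               carrier_effect_pgs_adjusted, extreme_bin_logistic,
                               pgs_effect_in_carriers, power_correlation, signs_test,
                               tertile_summary, z_diff)
from polyexpress.synth import simulate_standardized_trait

# ---------------------------------------------------------------------------
# carrier effect
# ---------------------------------------------------------------------------


def test_carrier_effect_equals_difference_of_group_means():
    z = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 15.0])
    c = np.array([0, 0, 0, 1, 1, 1])
    est = carrier_effect(z, c)
    assert est.beta == pytest.approx(12.0 - 2.0, abs=1e-10)
    # closed-form two-sample OLS standard error
    resid_var = (np.var(z[:3], ddof=0) * 3 + np.var(z[3:], ddof=0) * 3) / (6 - 2)
    assert est.se == pytest.approx(math.sqrt(resid_var * (1 / 3 + 1 / 3)), abs=1e-10)
    assert est.ci_low < est.beta < est.ci_high


def test_carrier_effect_requires_both_groups():
    with pytest.raises(ValueError):
        carrier_effect(np.ones(5), np.ones(5))


def test_null_shift_rarely_exceeds_three_se():
    hits = 0
    for rep in range(20):
        rng = np.random.default_rng(500 + rep)
        z, _, c = simulate_standardized_trait(2000, 0.2, rng, np.zeros(50))
        est = carrier_effect(z, c)
        hits += abs(est.beta) < 3 * est.se
    assert hits >= 19


def test_carrier_shift_recovery_is_unbiased():
    """Means over replicates land within 2 Monte-Carlo SE of the planted
    Table-1-scale shifts (reduced control cohort for speed)."""
    for shift, n_car in [(-1.91, 19), (2.49, 146)]:
        betas = []
        for rep in range(60):
            rng = np.random.default_rng(7000 + rep)
            z, _, c = simulate_standardized_trait(4000, 0.0799, rng,
                                                  np.full(n_car, shift))
            betas.append(carrier_effect(z, c).beta)
        mc_se = np.std(betas, ddof=1) / np.sqrt(len(betas))
        assert abs(np.mean(betas) - shift) < 2 * mc_se + 1e-3


# ---------------------------------------------------------------------------
# PGS effect within carriers
# ---------------------------------------------------------------------------


def test_pgs_effect_recovery_and_spearman_rank_invariance():
    rng = np.random.default_rng(11)
    g = rng.standard_normal(146)
    z = 0.55 * g + np.sqrt(1 - 0.55**2) * rng.standard_normal(146)
    mask = np.ones(146, dtype=bool)
    est = pgs_effect_in_carriers(z, g, mask)
    assert est.beta == pytest.approx(0.55, abs=3 * est.se)
    # a monotone transform of the trait leaves Spearman untouched
    est2 = pgs_effect_in_carriers(np.exp(z), g, mask)
    assert est2.spearman_rho == pytest.approx(est.spearman_rho, abs=1e-12)
    assert est2.beta != pytest.approx(est.beta, abs=1e-3)


def test_pgs_effect_degenerate_inputs():
    with pytest.raises(ValueError):
        pgs_effect_in_carriers(np.ones(10), np.ones(10), np.ones(10, dtype=bool))
    with pytest.raises(ValueError):
        pgs_effect_in_carriers(np.ones(10), np.arange(10.0), np.zeros(10, dtype=bool))


def test_pgs_adjustment_shrinks_confounded_carrier_effect():
    rng = np.random.default_rng(23)
    n, n_car = 4000, 200
    g = rng.standard_normal(n + n_car)
    carrier = np.r_[np.zeros(n), np.ones(n_car)]
    g[carrier == 1] += 1.0  # carriers enriched for a high polygenic score
    z = 0.5 * g + 1.0 * carrier + rng.standard_normal(n + n_car)
    raw = carrier_effect(z, carrier)
    adj = carrier_effect_pgs_adjusted(z, carrier, g)
    assert adj.beta < raw.beta
    assert adj.beta == pytest.approx(1.0, abs=3 * adj.se)


def test_pgs_adjustment_tightens_standard_errors():
    hits = 0
    for rep in range(20):
        rng = np.random.default_rng(900 + rep)
        z, g, c = simulate_standardized_trait(3000, 0.2171, rng, np.full(50, 1.0))
        raw = carrier_effect(z, c)
        adj = carrier_effect_pgs_adjusted(z, c, g)
        hits += adj.se <= raw.se
    assert hits >= 18


# ---------------------------------------------------------------------------
# percentile-bin comparison and tertiles
# ---------------------------------------------------------------------------


def test_equivalent_percentile_exact_match():
    rng = np.random.default_rng(3)
    bins = np.repeat(np.arange(1, 101), 10)
    z = bins / 100 + rng.normal(0, 1e-9, bins.size)  # bin 60 mean ~ 0.60
    carrier = np.zeros(bins.size + 4, dtype=bool)
    carrier[-4:] = True
    z = np.r_[z, [0.60, 0.60, 0.60, 0.60]]
    bins = np.r_[bins, [0, 0, 0, 0]]
    est = bin_comparison(z, bins, carrier, 50)
    assert est.equivalent_percentile == 60


def test_45x_sits_below_the_bottom_percentile_bin():
    """A -1.91 SD carrier group lies below even the 1st percentile bin of
    the polygenic distribution (negative contrast)."""
    neg = 0
    for rep in range(10):
        rng = np.random.default_rng(1200 + rep)
        from polyexpress.pgs import percentile_bins
        import pandas as pd
        z, g, c = simulate_standardized_trait(10000, 0.2171, rng, np.full(19, -1.91))
        idx = [f"s{i}" for i in range(z.size)]
        ref_ids = [idx[i] for i in range(10000)]
        bins = percentile_bins(pd.Series(g, index=idx), ref_ids).to_numpy()
        bins[c == 1] = 0
        est = bin_comparison(z, bins, c == 1, 1)
        neg += est.beta < 0
    assert neg >= 9


def test_tail_matched_shift_maps_to_extreme_percentile():
    """A carrier shift equal to sqrt(r2) x the top-bin conditional mean of
    the polygenic value is equivalent to the >= 99th percentile bin."""
    r2 = 0.2171
    shift = np.sqrt(r2) * 2.665
    hits = 0
    for rep in range(10):
        rng = np.random.default_rng(2200 + rep)
        from polyexpress.pgs import percentile_bins
        import pandas as pd
        z, g, c = simulate_standardized_trait(20000, r2, rng, np.full(100, shift))
        idx = [f"s{i}" for i in range(z.size)]
        bins = percentile_bins(pd.Series(g, index=idx), idx[:20000]).to_numpy()
        bins[c == 1] = 0
        est = bin_comparison(z, bins, c == 1, 100)
        hits += est.equivalent_percentile >= 99
    assert hits >= 9


def test_tertile_summary_constant_and_planted_configuration():
    out = tertile_summary(np.ones(9), np.repeat([1, 2, 3], 3))
    assert (out["mean"] == 1).all() and (out["sem"] == 0).all()

    # carrier group with shift 0.64 and within-group polygenic slope 0.54:
    # the favourable tertile returns to the population mean
    t1_means, t31 = [], []
    for rep in range(100):
        rng = np.random.default_rng(3100 + rep)
        g = rng.standard_normal(58)
        z = 0.64 + 0.54 * g + np.sqrt(1 - 0.54**2) * rng.standard_normal(58)
        t = np.searchsorted(np.quantile(g, [1 / 3, 2 / 3]), g) + 1
        out = tertile_summary(z, t).set_index("tertile")
        t1_means.append(out.loc[1, "mean"])
        t31.append(out.loc[3, "mean"] - out.loc[1, "mean"])
    sem = np.std(t1_means, ddof=1)
    assert abs(np.mean(t1_means)) < 2 * sem
    # outer-tertile gap ~ 2.19 x slope (Gaussian conditional means)
    assert np.mean(t31) == pytest.approx(2.195 * 0.54, rel=0.15)


def test_tertile_summary_rejects_empty_tertile():
    with pytest.raises(ValueError):
        tertile_summary(np.ones(4), [1, 1, 2, 2])


# ---------------------------------------------------------------------------
# signs test, Bonferroni, power, coefficient equality
# ---------------------------------------------------------------------------


def _signs_oracle(k, n):
    """Brute-force two-tailed binomial p at 1/2: total mass of outcomes no
    more probable than the observed one."""
    pmf = [math.comb(n, j) / 2**n for j in range(n + 1)]
    return min(1.0, sum(p for p in pmf if p <= pmf[k] + 1e-12))


def test_signs_test_worked_examples():
    assert signs_test(11, 11) == pytest.approx(9.765625e-4, abs=1e-12)
    assert signs_test(1, 1) == pytest.approx(1.0)
    assert signs_test(8, 10) == pytest.approx(0.109375, abs=1e-12)


def test_signs_test_matches_enumeration_for_all_small_n():
    for n in range(1, 13):
        for k in range(n + 1):
            assert signs_test(k, n) == pytest.approx(_signs_oracle(k, n), abs=1e-12)
    with pytest.raises(ValueError):
        signs_test(5, 3)


@given(p=st.floats(1e-12, 1.0), m=st.integers(1, 20))
@settings(max_examples=60, derandomize=True, deadline=None)
def test_bonferroni_bounds(p, m):
    q = bonferroni(p, m)
    assert p <= q <= 1.0
    assert q == pytest.approx(min(1.0, m * p))


def test_bonferroni_worked_examples():
    assert bonferroni(1.33e-3, 4) == pytest.approx(5.32e-3, rel=1e-9)
    assert bonferroni(9.28e-4, 3) == pytest.approx(2.784e-3, rel=1e-9)
    assert bonferroni(0.5, 4) == 1.0


def test_power_worked_values_and_limits():
    assert power_correlation(0.22, 44).power == pytest.approx(0.90, abs=0.005)
    assert power_correlation(0.08, 146).power == pytest.approx(0.94, abs=0.005)
    assert power_correlation(1e-12, 1000).power == pytest.approx(0.05, abs=1e-3)
    with pytest.raises(ValueError):
        power_correlation(1.2, 44)
    with pytest.raises(ValueError):
        power_correlation(0.2, 3)


def test_power_strictly_increasing_in_n_and_r2():
    grid_n = [10, 20, 50, 100, 500]
    p_n = [power_correlation(0.1, n).power for n in grid_n]
    assert all(a < b for a, b in zip(p_n, p_n[1:]))
    grid_r2 = [0.01, 0.05, 0.1, 0.3, 0.6]
    p_r = [power_correlation(r, 50).power for r in grid_r2]
    assert all(a < b for a, b in zip(p_r, p_r[1:]))


def test_z_diff_worked_example_and_antisymmetry():
    res = z_diff(0.46, 0.005, 0.55, 0.19)
    assert res.z_diff == pytest.approx(-0.4735, abs=5e-4)
    assert res.p == pytest.approx(0.636, abs=2e-3)
    eq = z_diff(0.4, 0.1, 0.4, 0.2)
    assert eq.z_diff == 0 and eq.p == 1
    flipped = z_diff(0.55, 0.19, 0.46, 0.005)
    assert flipped.z_diff == pytest.approx(-res.z_diff)
    assert flipped.p == pytest.approx(res.p)
    assert np.sign(res.z_diff) == np.sign(res.beta_neg - res.beta_pos)


# ---------------------------------------------------------------------------
# extreme-bin logistic
# ---------------------------------------------------------------------------


def test_logistic_matches_contingency_cross_product():
    y = np.r_[np.ones(30), np.zeros(70), np.ones(10), np.zeros(90)]
    x = np.r_[np.ones(100), np.zeros(100)]
    est = extreme_bin_logistic(y, x)
    expect = (30 * 90) / (70 * 10)
    assert est.beta == pytest.approx(expect, abs=1e-8)


def test_logistic_null_ci_covers_one():
    hits = 0
    for rep in range(20):
        rng = np.random.default_rng(4300 + rep)
        y = rng.random(3000) < 0.4
        x = rng.random(3000) < 0.01
        est = extreme_bin_logistic(y.astype(float), x.astype(float))
        hits += est.ci_low <= 1.0 <= est.ci_high
    assert hits >= 17


def test_logistic_recovers_planted_odds_ratio():
    from scipy.special import expit, logit
    ors = []
    for rep in range(30):
        rng = np.random.default_rng(5100 + rep)
        top = rng.random(30000) < 0.01
        p = expit(logit(0.41) + np.log(3.0) * top)
        y = rng.random(30000) < p
        ors.append(extreme_bin_logistic(y.astype(float), top.astype(float)).beta)
    assert np.mean(ors) == pytest.approx(3.0, abs=0.15)


def test_logistic_separation_detected():
    y = np.r_[np.ones(20), np.zeros(20)]
    x = np.r_[np.ones(20), np.zeros(20)]
    with pytest.raises(ValueError):
        extreme_bin_logistic(y, x)
    with pytest.raises(ValueError):
        extreme_bin_logistic(np.ones(10), np.r_[np.ones(5), np.zeros(5)])
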