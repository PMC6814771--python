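"""Effect-size estimation and hypothesis tests for variable expressivity.

Everything operates on pre-adjusted, standardized traits (SD units):

* carrier effects — OLS of z on a carrier indicator, optionally adjusted
  for the trait's polygenic score;
* polygenic effects within carriers — OLS of z on the standardized PGS
  restricted to one carrier group, plus Spearman rank correlation;
* percentile-bin equivalence — the bin of variant-negative individuals
  whose mean trait best matches a carrier group's mean, and the OLS
  contrast of carriers against a chosen bin;
* a two-tailed exact binomial signs test for direction concordance;
* per-trait Bonferroni correction;
* power for a correlation of known R^2 via the Fisher-z approximation,
  lambda = atanh(sqrt(R^2)) * sqrt(n - 3);
* equality of two regression coefficients estimated in disjoint groups
  (normal test with pooled squared standard errors);
* logistic models for outcome odds in the extreme PGS bin.

Confidence intervals use the normal multiplier 1.959964 throughout; at the
cohort sizes involved the difference from Student's t is negligible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from scipy import stats as sps

Z95 = 1.959964


@dataclass
class EffectEstimate:
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    r2: float | None = None
    spearman_rho: float | None = None
    spearman_p: float | None = None
    equivalent_percentile: int | None = None


@dataclass
class InteractionResult:
    z_diff: float
    p: float
    beta_neg: float
    beta_pos: float
    se_neg: float
    se_pos: float


@dataclass
class PowerResult:
    r2: float
    n: int
    alpha: float
    power: float


def _ols_effect(y: np.ndarray, x: np.ndarray, covar: np.ndarray | None = None) -> EffectEstimate:
    """OLS of y on x (plus optional covariates); reports the x coefficient
    with normal-approximation CI and two-tailed p."""
    X = x.reshape(-1, 1) if covar is None else np.column_stack([x, covar])
    model = sm.OLS(y, sm.add_constant(X, prepend=True)).fit()
    beta, se = float(model.params[1]), float(model.bse[1])
    p = float(2 * sps.norm.sf(abs(beta / se))) if se > 0 else np.nan
    return EffectEstimate(beta, se, beta - Z95 * se, beta + Z95 * se,
                          p, int(len(y)), r2=float(model.rsquared))


def carrier_effect(z: np.ndarray, carrier_flag: np.ndarray) -> EffectEstimate:
    """Mean standardized-trait displacement of carriers vs non-carriers."""
    z = np.asarray(z, dtype=float)
    c = np.asarray(carrier_flag, dtype=float)
    if c.sum() < 2 or (1 - c).sum() < 2:
        raise ValueError("need at least 2 carriers and 2 non-carriers")
    return _ols_effect(z, c)


def carrier_effect_pgs_adjusted(z, carrier_flag, pgs) -> EffectEstimate:
    """Carrier effect with the trait's polygenic score as a covariate."""
    z = np.asarray(z, dtype=float)
    c = np.asarray(carrier_flag, dtype=float)
    if c.sum() < 2 or (1 - c).sum() < 2:
        raise ValueError("need at least 2 carriers and 2 non-carriers")
    return _ols_effect(z, c, np.asarray(pgs, dtype=float).reshape(-1, 1))


def pgs_effect_in_carriers(z, pgs, carrier_mask) -> EffectEstimate:
    """Per-SD polygenic effect on the trait within one carrier group, with
    Spearman rank correlation alongside the linear fit."""
    mask = np.asarray(carrier_mask, dtype=bool)
    if mask.sum() < 3:
        raise ValueError("need at least 3 carriers")
    zc = np.asarray(z, dtype=float)[mask]
    pc = np.asarray(pgs, dtype=float)[mask]
    if np.std(pc) == 0:
        raise ValueError("constant PGS among carriers")
    est = _ols_effect(zc, pc)
    rho, sp = sps.spearmanr(pc, zc)
    est.spearman_rho, est.spearman_p = float(rho), float(sp)
    return est


def bin_comparison(z, bins, carrier_mask, k: int) -> EffectEstimate:
    """Contrast a carrier group against percentile bin k of the
    variant-negative population, and report the equivalent percentile (the
    bin whose mean trait is closest to the carrier mean)."""
    z = np.asarray(z, dtype=float)
    bins = np.asarray(bins)
    carrier = np.asarray(carrier_mask, dtype=bool)
    in_bin = (bins == k) & ~carrier
    if in_bin.sum() == 0:
        raise ValueError(f"percentile bin {k} is empty")
    if carrier.sum() == 0:
        raise ValueError("carrier group is empty")
    sel = in_bin | carrier
    est = carrier_effect(z[sel], carrier[sel].astype(float))
    carrier_mean = z[carrier].mean()
    bin_ids = np.unique(bins[~carrier & (bins > 0)])
    means = np.array([z[(bins == b) & ~carrier].mean() for b in bin_ids])
    est.equivalent_percentile = int(bin_ids[np.argmin(np.abs(means - carrier_mean))])
    return est


def tertile_summary(z, tertile) -> pd.DataFrame:
    """Mean and standard error of the mean per PGS tertile."""
    df = pd.DataFrame({"z": np.asarray(z, dtype=float), "tertile": np.asarray(tertile)})
    if df.groupby("tertile").size().min() < 1 or df["tertile"].nunique() < 3:
        raise ValueError("every tertile must be non-empty")
    g = df.groupby("tertile")["z"]
    out = pd.DataFrame({
        "mean": g.mean(),
        "sem": g.std(ddof=1).fillna(0.0) / np.sqrt(g.size()),
        "n": g.size(),
    })
    return out.reset_index()


def signs_test(n_positive: int, n_total: int) -> float:
    """Two-tailed exact binomial test of direction concordance at p=1/2."""
    if not 0 <= n_positive <= n_total:
        raise ValueError("need 0 <= n_positive <= n_total")
    return float(sps.binomtest(n_positive, n_total, 0.5).pvalue)


def bonferroni(p: float, m: int) -> float:
    """Per-trait Bonferroni correction, capped at 1."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p)


def power_correlation(r2: float, n: int, alpha: float = 0.05) -> PowerResult:
    """Power to detect a correlation explaining ``r2`` at sample size n.

    Fisher-z approximation without small-sample bias correction:
    lambda = atanh(sqrt(r2)) * sqrt(n - 3);
    power = Phi(lambda - z_{1-a/2}) + Phi(-lambda - z_{1-a/2}).
    """
    if not 0 < r2 < 1:
        raise ValueError("r2 must lie in (0, 1)")
    if n < 4:
        raise ValueError("n must be >= 4")
    lam = np.arctanh(np.sqrt(r2)) * np.sqrt(n - 3)
    zc = sps.norm.ppf(1 - alpha / 2)
    power = float(sps.norm.cdf(lam - zc) + sps.norm.cdf(-lam - zc))
    return PowerResult(r2, n, alpha, power)


def z_diff(beta_neg: float, se_neg: float, beta_pos: float, se_pos: float) -> InteractionResult:
    """Equality test of the polygenic coefficient between carrier-negative
    and carrier-positive models (disjoint groups, normal statistic)."""
    if se_neg <= 0 or se_pos <= 0:
        raise ValueError("standard errors must be positive")
    z = (beta_neg - beta_pos) / np.sqrt(se_neg**2 + se_pos**2)
    return InteractionResult(float(z), float(2 * sps.norm.sf(abs(z))),
                             beta_neg, beta_pos, se_neg, se_pos)


def extreme_bin_logistic(outcome_flag, in_top_bin_flag, covariates=None) -> EffectEstimate:
    """Odds of the outcome for membership in the extreme PGS bin.

    Maximum-likelihood logistic regression; the estimate is reported as an
    odds ratio with a Wald 95% CI.  Raises on perfect separation.
    """
    y = np.asarray(outcome_flag, dtype=float)
    x = np.asarray(in_top_bin_flag, dtype=float)
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    X = x.reshape(-1, 1) if covariates is None else np.column_stack([x, covariates])
    try:
        fit = sm.Logit(y, sm.add_constant(X, prepend=True)).fit(disp=0)
    except Exception as exc:  # PerfectSeparationError and friends
        raise ValueError(f"logistic fit failed (possible separation): {exc}") from exc
    beta, se = float(fit.params[1]), float(fit.bse[1])
    if not np.isfinite(se) or se > 50:
        raise ValueError("separation suspected: unbounded coefficient standard error")
    p = float(2 * sps.norm.sf(abs(beta / se)))
    return EffectEstimate(float(np.exp(beta)), se,
                          float(np.exp(beta - Z95 * se)), float(np.exp(beta + Z95 * se)),
                          p, int(len(y)))
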