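"""Univariable two-sample MR estimators and their diagnostics.

Implements the Wald ratio, multiplicative random-effects IVW, MR-Egger
(with the I2_GX no-measurement-error statistic and SIMEX correction),
the weighted median, Cochran's and Ruecker's Q heterogeneity statistics,
leave-one-out re-estimation, and per-SNP (funnel-plot) tables.

Conventions
-----------
* IVW weights are first-order, 1/se_out^2 (exposure uncertainty ignored
  in the weights, as in the standard primary analysis).
* Random-effects IVW uses a multiplicative overdispersion factor floored
  at 1, so the random-effects SE is never narrower than fixed-effect.
* MR-Egger internally orients every SNP so its exposure beta is
  non-negative (required for identifiability of the intercept); its SEs
  carry the same multiplicative overdispersion treatment (floored at 1).
* All confidence intervals are normal-theory 95%; p-values are two-sided
  normal (chi-square upper tail for Q statistics).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import HarmonizedSet

Z975 = stats.norm.ppf(0.975)


class EstimationError(ValueError):
    """The estimator's preconditions are not met."""


@dataclass
class MREstimate:
    """One method's causal estimate on the beta (log-OR / unit) scale."""

    method: str
    n_snps: int
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    outcome_binary: bool = True

    @property
    def or_scale(self) -> tuple:
        """(OR, lower, upper): elementwise exp of the beta-scale entries."""
        return (np.exp(self.beta), np.exp(self.ci_low), np.exp(self.ci_high))


@dataclass
class HeterogeneityResult:
    """A Q-type heterogeneity statistic with its chi-square p-value."""

    statistic: float
    df: int
    pval: float
    kind: str = "cochran_q"


@dataclass
class EggerFit:
    """MR-Egger slope, pleiotropy intercept, Ruecker's Q, and I2_GX."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_pval: float
    i2_gx: float
    rucker_q: HeterogeneityResult


def _estimate(method, n_snps, beta, se, outcome_binary) -> MREstimate:
    beta = float(beta)
    se = float(se)
    p = float(2.0 * stats.norm.sf(abs(beta / se))) if se > 0 else 0.0
    return MREstimate(
        method=method,
        n_snps=int(n_snps),
        beta=beta,
        se=se,
        ci_low=beta - Z975 * se,
        ci_high=beta + Z975 * se,
        pval=p,
        outcome_binary=outcome_binary,
    )


def wald_ratio(bx: float, sex: float, by: float, sey: float,
               outcome_binary: bool = True) -> MREstimate:
    """Single-instrument causal estimate by/bx with first-order delta SE."""
    if bx == 0:
        raise EstimationError("Wald ratio undefined for bx = 0")
    return _estimate("wald", 1, by / bx, sey / abs(bx), outcome_binary)


def ivw(h: HarmonizedSet, random_effects: bool = True) -> MREstimate:
    """Inverse-variance-weighted estimate.

    theta = sum(w * bx * by) / sum(w * bx^2) with w = 1/se_out^2;
    fixed-effect SE is (sum w bx^2)^(-1/2); under multiplicative random
    effects the SE is inflated by sqrt(max(1, Q/(L-1))).  A single SNP
    degenerates to the Wald ratio.
    """
    L = len(h)
    if L < 1:
        raise EstimationError("IVW needs at least one SNP")
    if L == 1:
        return wald_ratio(h.beta_exp[0], h.se_exp[0], h.beta_out[0],
                          h.se_out[0], h.outcome_binary)
    w = 1.0 / h.se_out**2
    denom = float(np.sum(w * h.beta_exp**2))
    theta = float(np.sum(w * h.beta_exp * h.beta_out)) / denom
    se = denom**-0.5
    method = "ivw_re" if random_effects else "ivw_fe"
    if random_effects:
        q = float(np.sum(w * (h.beta_out - theta * h.beta_exp) ** 2))
        se *= np.sqrt(max(1.0, q / (L - 1)))
    return _estimate(method, L, theta, se, h.outcome_binary)


def cochran_q(h: HarmonizedSet, theta: float) -> HeterogeneityResult:
    """Cochran's Q about a given pooled estimate.

    Q = sum_j w_j (ratio_j - theta)^2 with w_j = (bx_j / se_out_j)^2,
    which equals sum_j (by_j - theta * bx_j)^2 / se_out_j^2.
    """
    L = len(h)
    if L < 2:
        raise EstimationError("Cochran's Q needs at least two SNPs")
    q = float(np.sum((h.beta_out - theta * h.beta_exp) ** 2 / h.se_out**2))
    df = L - 1
    return HeterogeneityResult(q, df, float(stats.chi2.sf(q, df)), "cochran_q")


def _wls_line(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Closed-form weighted least squares of y on (1, x).

    Works on stacked inputs: the last axis indexes observations.  Returns
    (intercept, slope, var_intercept, var_slope, q_resid) with variances
    unscaled (i.e. for unit residual variance on the weighted scale).
    """
    W = w.sum(axis=-1)
    sx = (w * x).sum(axis=-1)
    sy = (w * y).sum(axis=-1)
    sxx = (w * x * x).sum(axis=-1)
    sxy = (w * x * y).sum(axis=-1)
    det = W * sxx - sx**2
    slope = (W * sxy - sx * sy) / det
    intercept = (sxx * sy - sx * sxy) / det
    resid = y - intercept[..., None] - slope[..., None] * x
    q = (w * resid**2).sum(axis=-1)
    return intercept, slope, sxx / det, W / det, q


def egger(h: HarmonizedSet) -> EggerFit:
    """MR-Egger regression with multiplicative overdispersion.

    SNPs are oriented so the exposure beta is non-negative, then
    beta_out is regressed on beta_exp with an intercept, weights
    1/se_out^2.  The slope is the pleiotropy-adjusted causal estimate,
    the intercept the average directional pleiotropy.  Also returns
    Ruecker's Q' (df = L-2) and the NOME statistic
    I2_GX = (Q_GX - (L-1)) / Q_GX.
    """
    L = len(h)
    if L < 3:
        raise EstimationError("MR-Egger needs at least three SNPs")
    sign = np.where(h.beta_exp < 0, -1.0, 1.0)
    x = h.beta_exp * sign
    y = h.beta_out * sign
    w = 1.0 / h.se_out**2

    a0, theta, var_a0, var_theta, q = _wls_line(x, y, w)
    dispersion = np.sqrt(max(1.0, q / (L - 2)))
    se_theta = np.sqrt(var_theta) * dispersion
    se_a0 = np.sqrt(var_a0) * dispersion

    # The intercept is the pleiotropy test statistic; its model-based SE
    # assumes heterogeneity proportional to se_out^2, which understates the
    # variance when pleiotropy is additive and weights vary.  Guard the test
    # with a heteroskedasticity-robust (sandwich) SE and report the more
    # conservative of the two.
    X = np.column_stack([np.ones(L), x])
    resid = y - a0 - theta * x
    a_inv = np.linalg.inv((X.T * w) @ X)
    meat = (X * (w**2 * resid**2)[:, None]).T @ X
    cov_sw = a_inv @ meat @ a_inv * L / (L - 2)
    se_a0 = max(se_a0, float(np.sqrt(cov_sw[0, 0])))

    slope = _estimate("egger", L, theta, se_theta, h.outcome_binary)
    p_a0 = float(2.0 * stats.norm.sf(abs(a0 / se_a0))) if se_a0 > 0 else 1.0

    wx = 1.0 / h.se_exp**2
    xbar = float(np.sum(wx * x) / np.sum(wx))
    q_gx = float(np.sum((x - xbar) ** 2 / h.se_exp**2))
    i2_gx = (q_gx - (L - 1)) / q_gx if q_gx > 0 else -np.inf

    rucker = HeterogeneityResult(float(q), L - 2,
                                 float(stats.chi2.sf(q, L - 2)), "rucker_q")
    return EggerFit(
        slope=slope,
        intercept=float(a0),
        intercept_se=float(se_a0),
        intercept_pval=p_a0,
        i2_gx=float(i2_gx),
        rucker_q=rucker,
    )


def egger_simex(
    h: HarmonizedSet,
    lambda_grid: Sequence[float] = (0.0, 0.5, 1.0, 1.5, 2.0),
    n_boot: int = 1000,
    seed: Optional[int] = None,
) -> MREstimate:
    """Simulation-extrapolation correction of the MR-Egger slope.

    For each lambda in the grid, the exposure betas are perturbed with
    extra noise of variance lambda * se_exp^2 (n_boot replicates); the
    mean Egger slope over replicates is modelled as a quadratic in
    lambda and extrapolated to lambda = -1 (zero measurement error).
    The SE combines the quadratic extrapolation of the per-lambda
    empirical slope variances (clipped at zero) with the lambda = 0
    model variance.

    The pipeline trigger for using this correction is I2_GX < 0.9.
    """
    lambda_grid = np.asarray(sorted(lambda_grid), dtype=float)
    if len(lambda_grid) < 3:
        raise EstimationError("SIMEX quadratic extrapolation needs >= 3 lambda values")
    if n_boot < 100:
        raise EstimationError("SIMEX needs at least 100 replicates")
    L = len(h)
    base = egger(h)
    rng = np.random.default_rng(seed)
    w = 1.0 / h.se_out**2

    mean_slopes = np.empty(len(lambda_grid))
    var_slopes = np.empty(len(lambda_grid))
    for i, lam in enumerate(lambda_grid):
        if lam == 0.0:
            mean_slopes[i] = base.slope.beta
            var_slopes[i] = 0.0
            continue
        eps = rng.standard_normal((n_boot, L))
        bx = h.beta_exp + np.sqrt(lam) * h.se_exp * eps
        sign = np.where(bx < 0, -1.0, 1.0)
        x = bx * sign
        y = h.beta_out * sign
        _, slopes, _, _, _ = _wls_line(x, y, np.broadcast_to(w, x.shape))
        mean_slopes[i] = slopes.mean()
        var_slopes[i] = slopes.var(ddof=1)

    coef = np.polyfit(lambda_grid, mean_slopes, 2)
    beta = float(np.polyval(coef, -1.0))
    vcoef = np.polyfit(lambda_grid, var_slopes, 2)
    var_extra = max(0.0, float(np.polyval(vcoef, -1.0)))
    se = float(np.sqrt(var_extra + base.slope.se**2))
    out = _estimate("egger_simex", L, beta, se, h.outcome_binary)
    return out


def weighted_median(
    h: HarmonizedSet,
    n_boot: int = 1000,
    seed: Optional[int] = None,
) -> MREstimate:
    """Weighted median of the Wald ratios.

    Ratios are sorted with weights w_j = bx_j^2 / se_out_j^2 (normalized);
    the estimate is the linear interpolation of the ratio at cumulative
    weight midpoint 0.5.  Valid when at least half of the total weight
    comes from valid instruments.  The SE is the standard deviation of
    the estimate over ``n_boot`` parametric-bootstrap resamples of the
    summary estimates from their normal sampling distributions.
    """
    L = len(h)
    if L < 3:
        raise EstimationError("weighted median needs at least three SNPs")
    rng = np.random.default_rng(seed)

    def _wm(bx, by):
        ratio = by / bx
        w = bx**2 / h.se_out**2
        order = np.argsort(ratio, axis=-1)
        ratio = np.take_along_axis(ratio, order, axis=-1)
        w = np.take_along_axis(np.broadcast_to(w, ratio.shape).copy(), order, axis=-1)
        wn = w / w.sum(axis=-1, keepdims=True)
        cum = np.cumsum(wn, axis=-1)
        s = cum - wn / 2.0
        if ratio.ndim == 1:
            return float(np.interp(0.5, s, ratio))
        return np.array([np.interp(0.5, s[i], ratio[i]) for i in range(len(ratio))])

    est = _wm(h.beta_exp, h.beta_out)
    bx_boot = h.beta_exp + h.se_exp * rng.standard_normal((n_boot, L))
    by_boot = h.beta_out + h.se_out * rng.standard_normal((n_boot, L))
    boots = _wm(bx_boot, by_boot)
    se = float(np.std(boots, ddof=1))
    return _estimate("weighted_median", L, est, se, h.outcome_binary)


def leave_one_out(h: HarmonizedSet, alpha: float = 0.05) -> pd.DataFrame:
    """IVW re-estimated dropping each SNP in turn.

    Flags any drop that changes the sign of the estimate or its
    significance at ``alpha`` relative to the full-set estimate.
    Returns a DataFrame with exactly L rows.
    """
    L = len(h)
    if L < 3:
        raise EstimationError("leave-one-out needs at least three SNPs")
    full = ivw(h)
    rows = []
    for j in range(L):
        mask = np.ones(L, dtype=bool)
        mask[j] = False
        est = ivw(h.subset(mask))
        rows.append(
            {
                "snp_id": h.snp_ids[j],
                "beta": est.beta,
                "se": est.se,
                "pval": est.pval,
                "sign_change": np.sign(est.beta) != np.sign(full.beta),
                "significance_change": (est.pval < alpha) != (full.pval < alpha),
            }
        )
    return pd.DataFrame(rows)


def single_snp(h: HarmonizedSet) -> pd.DataFrame:
    """Per-SNP Wald ratios with precision (funnel-plot-ready, no graphics)."""
    ratio = h.beta_out / h.beta_exp
    se = h.se_out / np.abs(h.beta_exp)
    return pd.DataFrame(
        {
            "snp_id": h.snp_ids,
            "beta": ratio,
            "se": se,
            "precision": 1.0 / se,
        }
    )
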