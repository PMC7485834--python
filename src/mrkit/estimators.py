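"""Single-exposure two-sample MR estimators and diagnostics.

Given a harmonized set of k instruments with exposure effects b_Xj (SE
se_Xj) and outcome effects b_Yj (SE se_Yj), each estimator combines the
per-SNP Wald ratios r_j = b_Yj / b_Xj into a causal-effect estimate:

* inverse-variance weighted (IVW), fixed or multiplicative random effects —
  beta = sum(w_j r_j) / sum(w_j) with w_j = b_Xj^2 / se_Yj^2; the
  multiplicative random-effects SE scales the fixed SE by
  max(1, sqrt(Q / (k - 1))) where Q is Cochran's heterogeneity statistic;
* MR-Egger — weighted regression of b_Yj on b_Xj with an intercept; a
  nonzero intercept indicates directional pleiotropy;
* weighted median — consistent when valid instruments carry >= 50% of the
  weight; SE by parametric bootstrap;
* mode-based — the maximum of a normal-kernel density over the ratios,
  consistent when the largest homogeneous cluster is valid.

Also here: the Steiger directionality test (variance explained in exposure
vs outcome) and the analytic power calculation for a binary outcome.

Betas for a binary outcome are log odds ratios; estimates are reported on
the OR scale with normal-theory 95% CIs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import (
    DataError,
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
)
from .sumstats import HarmonizedSet, effective_n

Z95 = float(stats.norm.ppf(0.975))


def _two_sided_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


@dataclass
class RatioEstimate:
    """Per-SNP Wald ratio with first-order SE and IVW weight."""

    snp_id: str
    r_j: float      # b_Y / b_X
    se_rj: float    # se_Y / |b_X|
    w_j: float      # b_X^2 / se_Y^2


@dataclass
class MrEstimate:
    method: str
    k: int
    beta: float
    se: float
    pval: float
    or_: float
    ci_low: float
    ci_high: float

    @classmethod
    def from_beta_se(cls, method: str, k: int, beta: float, se: float) -> "MrEstimate":
        return cls(
            method=method,
            k=k,
            beta=float(beta),
            se=float(se),
            pval=_two_sided_p(beta / se) if se > 0 else 0.0,
            or_=math.exp(beta),
            ci_low=math.exp(beta - Z95 * se),
            ci_high=math.exp(beta + Z95 * se),
        )


@dataclass
class HeterogeneityStat:
    Q: float
    df: int
    pval: float


@dataclass
class EggerResult:
    slope: MrEstimate
    intercept: float
    intercept_se: float
    intercept_pval: float


@dataclass
class SteigerResult:
    r2_exposure: float
    r2_outcome: float
    direction_correct: bool
    pval: float


def ratio_estimates(h: HarmonizedSet) -> list[RatioEstimate]:
    """Per-SNP Wald ratios for a single-exposure harmonized set."""
    h.require_single_exposure()
    bx = h.beta_exp[:, 0]
    if np.any(bx == 0):
        bad = h.snp_ids[bx == 0]
        raise DegenerateInstrumentError(f"zero exposure beta for {list(bad)}")
    return [
        RatioEstimate(
            snp_id=h.snp_ids[j],
            r_j=float(h.beta_out[j] / bx[j]),
            se_rj=float(h.se_out[j] / abs(bx[j])),
            w_j=float(bx[j] ** 2 / h.se_out[j] ** 2),
        )
        for j in range(h.k)
    ]


def _rw(h: HarmonizedSet):
    bx = h.beta_exp[:, 0]
    r = h.beta_out / bx
    w = bx**2 / h.se_out**2
    return r, w


def cochran_q(r: np.ndarray, w: np.ndarray, beta: float, df: int) -> HeterogeneityStat:
    q = float(np.sum(w * (r - beta) ** 2))
    return HeterogeneityStat(Q=q, df=df, pval=float(stats.chi2.sf(q, df)) if df > 0 else 1.0)


def mr_wald(h: HarmonizedSet) -> MrEstimate:
    """Single-instrument Wald ratio estimate (k = 1 only)."""
    h.require_single_exposure()
    if h.k != 1:
        raise DataError("mr_wald requires exactly one instrument")
    [re_] = ratio_estimates(h)
    return MrEstimate.from_beta_se("wald", 1, re_.r_j, re_.se_rj)


def mr_ivw(
    h: HarmonizedSet, model: str = "multiplicative_random"
) -> tuple[MrEstimate, HeterogeneityStat]:
    """Inverse-variance weighted estimate.

    ``model="fixed"`` uses se = (sum w_j)^(-1/2); ``"multiplicative_random"``
    multiplies that by max(1, sqrt(Q/(k-1))), so overdispersion widens the
    CI but underdispersion never narrows it.
    """
    h.require_single_exposure()
    if h.k < 2:
        raise InsufficientInstrumentsError("IVW requires k >= 2 (use mr_wald for k = 1)")
    if model not in ("fixed", "multiplicative_random"):
        raise DataError(f"unknown IVW model {model!r}")
    if np.any(h.beta_exp[:, 0] == 0):
        raise DegenerateInstrumentError("zero exposure beta")
    r, w = _rw(h)
    beta = float(np.sum(w * r) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    het = cochran_q(r, w, beta, h.k - 1)
    se = se_fixed
    if model == "multiplicative_random":
        se = se_fixed * max(1.0, math.sqrt(het.Q / (h.k - 1)))
    method = "ivw_fe" if model == "fixed" else "ivw_mre"
    return MrEstimate.from_beta_se(method, h.k, beta, se), het


def mr_egger(h: HarmonizedSet) -> EggerResult:
    """MR-Egger regression: weighted least squares of b_Y on b_X with an
    intercept, weights 1/se_Y^2, instruments oriented so every b_X > 0.

    The intercept estimates the average directional pleiotropic effect; the
    slope is the causal estimate.  Both SEs carry the multiplicative
    dispersion factor max(1, sqrt(Q_egger/(k-2))).
    """
    h.require_single_exposure()
    if h.k < 3:
        raise InsufficientInstrumentsError("Egger regression requires k >= 3")
    sign = np.sign(h.beta_exp[:, 0])
    if np.any(sign == 0):
        raise DegenerateInstrumentError("zero exposure beta")
    bx = h.beta_exp[:, 0] * sign
    by = h.beta_out * sign
    w = 1.0 / h.se_out**2

    X = np.column_stack([np.ones_like(bx), bx])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * by)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = by - X @ coef
    q = float(np.sum(w * resid**2))
    disp = max(1.0, math.sqrt(q / (h.k - 2)))
    cov = np.linalg.inv(xtwx) * disp**2
    se_int, se_slope = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
    return EggerResult(
        slope=MrEstimate.from_beta_se("egger", h.k, coef[1], se_slope),
        intercept=float(coef[0]),
        intercept_se=se_int,
        intercept_pval=_two_sided_p(coef[0] / se_int),
    )


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    p = weights[order] / np.sum(weights)
    s = np.cumsum(p) - 0.5 * p
    return float(np.interp(0.5, s, r))


def _parametric_bootstrap(h: HarmonizedSet, n_boot: int, seed, point_fn) -> float:
    """SE of a ratio-based estimator under normal resampling of both
    exposure and outcome betas; bit-reproducible given (seed, n_boot)."""
    rng = np.random.default_rng(seed)
    bx, sx = h.beta_exp[:, 0], h.se_exp[:, 0]
    by, sy = h.beta_out, h.se_out
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bx_s = rng.normal(bx, sx)
        by_s = rng.normal(by, sy)
        bx_s[bx_s == 0] = np.finfo(float).tiny  # guard degenerate resample
        boots[b] = point_fn(by_s / bx_s, bx_s**2 / sy**2, sy / np.abs(bx_s))
    return float(np.std(boots, ddof=1))


def mr_weighted_median(
    h: HarmonizedSet, n_boot: int = 1000, seed: int = 0
) -> MrEstimate:
    """Weighted-median estimate.

    Ratios are ordered ascending; with normalized inverse-variance weights
    p_j = (1/se_rj^2)/sum, the estimate interpolates the ratio at cumulative
    weight midpoint 0.5.  SE from a parametric bootstrap with ``n_boot``
    normal resamples of the exposure and outcome betas.
    """
    h.require_single_exposure()
    if h.k < 3:
        raise InsufficientInstrumentsError("weighted median requires k >= 3")
    ratios = np.array([re_.r_j for re_ in ratio_estimates(h)])
    inv_var = np.array([1.0 / re_.se_rj**2 for re_ in ratio_estimates(h)])
    beta = _weighted_median(ratios, inv_var)
    se = _parametric_bootstrap(
        h, n_boot, seed, lambda r, w, se_r: _weighted_median(r, 1.0 / se_r**2)
    )
    return MrEstimate.from_beta_se("weighted_median", h.k, beta, se)


def _mode_bandwidth(ratios: np.ndarray, factor: float) -> float:
    sd = float(np.std(ratios, ddof=1))
    iqr = float(np.subtract(*np.percentile(ratios, [75, 25])))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    return factor * 0.9 * spread * len(ratios) ** (-1 / 5)


def _mode_point(ratios: np.ndarray, weights: np.ndarray, bandwidth: float) -> float:
    if bandwidth == 0 or np.ptp(ratios) == 0:
        return float(ratios[0])
    p = weights / np.sum(weights)

    def neg_density(x):
        return -np.sum(p * np.exp(-0.5 * ((x - ratios) / bandwidth) ** 2))

    lo, hi = ratios.min() - 2 * bandwidth, ratios.max() + 2 * bandwidth
    grid = np.linspace(lo, hi, 2001)
    dens = (p[None, :] * np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / bandwidth) ** 2)).sum(axis=1)
    best = grid[int(np.argmax(dens))]
    step = (hi - lo) / 2000
    res = optimize.minimize_scalar(
        neg_density, bounds=(best - step, best + step), method="bounded",
        options={"xatol": 1e-13},
    )
    return float(res.x)


def mr_mode(
    h: HarmonizedSet,
    weighted: bool = True,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MrEstimate:
    """Mode-based estimate: the maximum of a normal-kernel density over the
    Wald ratios, with modified-Silverman bandwidth
    ``bandwidth_factor * 0.9 * min(sd, IQR/1.349) * k^(-1/5)``.

    With ``weighted=True`` kernels carry the normalized inverse-variance
    weights of the ratios; otherwise uniform.  If all ratios coincide the
    common value is returned.  SE by parametric bootstrap.
    """
    h.require_single_exposure()
    if h.k < 3:
        raise InsufficientInstrumentsError("mode-based estimate requires k >= 3")
    res = ratio_estimates(h)
    ratios = np.array([re_.r_j for re_ in res])
    inv_var = np.array([1.0 / re_.se_rj**2 for re_ in res])

    def point(r, w_ivw, se_r):
        wts = 1.0 / se_r**2 if weighted else np.ones_like(r)
        return _mode_point(r, wts, _mode_bandwidth(r, bandwidth_factor))

    weights = inv_var if weighted else np.ones_like(ratios)
    beta = _mode_point(ratios, weights, _mode_bandwidth(ratios, bandwidth_factor))
    se = _parametric_bootstrap(h, n_boot, seed, point)
    method = "mode_weighted" if weighted else "mode_simple"
    return MrEstimate.from_beta_se(method, h.k, beta, se)


def steiger_test(
    h: HarmonizedSet,
    n_exposure: int,
    n_outcome_case: int,
    n_outcome_control: int,
) -> SteigerResult:
    """Directionality check: do the instruments explain more variance in
    the exposure than in the outcome?

    Per-instrument variance explained uses the t-statistic transform
    r2_j = t_j^2 / (t_j^2 + n - 2); the outcome uses the effective
    case-control sample size 4/(1/ncase + 1/ncontrol).  The p-value
    compares the two aggregate correlations via Fisher's z transform.
    """
    h.require_single_exposure()
    if h.k < 1:
        raise InsufficientInstrumentsError("Steiger test requires k >= 1")
    if not n_exposure or n_exposure <= 0:
        raise DataError("n_exposure required for Steiger test")
    n_out = effective_n(n_outcome_case, n_outcome_control)

    t_x = h.beta_exp[:, 0] / h.se_exp[:, 0]
    t_y = h.beta_out / h.se_out
    r2_x = float(np.sum(t_x**2 / (t_x**2 + n_exposure - 2)))
    r2_y = float(np.sum(t_y**2 / (t_y**2 + n_out - 2)))
    r2_x = min(r2_x, 1.0 - 1e-12)
    r2_y = min(r2_y, 1.0 - 1e-12)

    z = (math.atanh(math.sqrt(r2_x)) - math.atanh(math.sqrt(r2_y))) / math.sqrt(
        1.0 / (n_exposure - 3) + 1.0 / (n_out - 3)
    )
    return SteigerResult(
        r2_exposure=r2_x,
        r2_outcome=r2_y,
        direction_correct=r2_x > r2_y,
        pval=_two_sided_p(z),
    )


def mr_power(
    n_case: int,
    n_control: int,
    r2_exposure: float,
    or_alt: float,
    alpha: float = 0.01,
) -> float:
    """Analytic power of a two-sample MR test on a binary outcome.

    With total N = n_case + n_control and case fraction phi, the IVW z
    statistic under the alternative has mean
    d = |ln(or_alt)| * sqrt(N * r2_exposure * phi * (1 - phi)); two-sided
    power at level ``alpha`` is Phi(d - z_{1-alpha/2}) + Phi(-d - z_{1-alpha/2}),
    which degenerates to alpha at or_alt = 1.
    """
    if not (0 < r2_exposure < 1):
        raise DataError("r2_exposure must lie in (0, 1)")
    if or_alt <= 0:
        raise DataError("or_alt must be positive")
    if not (0 < alpha < 1):
        raise DataError("alpha must lie in (0, 1)")
    if n_case <= 0 or n_control <= 0:
        raise DataError("sample sizes must be positive")
    n_total = n_case + n_control
    phi = n_case / n_total
    d = abs(math.log(or_alt)) * math.sqrt(n_total * r2_exposure * phi * (1 - phi))
    z_crit = float(stats.norm.ppf(1 - alpha / 2))
    return float(stats.norm.cdf(d - z_crit) + stats.norm.cdf(-d - z_crit))


def results_frame(entries, exposure: str, outcome: str) -> pd.DataFrame:
    """Tidy results table: one row per method.

    ``entries`` is an iterable of MrEstimate or (MrEstimate,
    HeterogeneityStat) pairs; heterogeneity columns are NA where absent.
    """
    rows = []
    for entry in entries:
        if isinstance(entry, tuple):
            est, het = entry
        else:
            est, het = entry, None
        rows.append(
            {
                "exposure": exposure,
                "outcome": outcome,
                "method": est.method,
                "k": est.k,
                "beta": est.beta,
                "se": est.se,
                "or": est.or_,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "pval": est.pval,
                "Q": het.Q if het else np.nan,
                "Q_df": het.df if het else np.nan,
                "Q_pval": het.pval if het else np.nan,
            }
        )
    return pd.DataFrame(rows)
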