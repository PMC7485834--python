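"""Cross-trait LD-score regression.

Under a polygenic model, the expected squared z-score of SNP j in a GWAS
of n samples is linear in its LD score l_j (the sum of squared
correlations with nearby SNPs):

    E[z_j^2] = intercept + (n h2 / M) l_j,

where M is the number of SNPs the panel represents and the intercept
captures confounding and overcounting (1 in its absence).  For two traits,

    E[z1_j z2_j] = intercept_ct + (sqrt(n1 n2) rho_g / M) l_j,

with rho_g the genetic covariance; sample overlap moves only the
cross-trait intercept, which is estimated rather than fixed.  The genetic
correlation is r_g = rho_g / sqrt(h2_1 h2_2).

Fitting follows the standard two-step scheme for univariate fits (the
intercept is estimated on the chi^2 < 30 subset, then the slope on all
SNPs with the intercept fixed), with heteroskedasticity weights frozen
from a pilot fit.  All standard errors come from a delete-one-block
jackknife over contiguous SNP blocks, computed exactly via per-block
sufficient statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import ConfigError, DataError


@dataclass
class LdScorePanel:
    """Per-SNP LD scores and the panel's total SNP count M."""

    snp_ids: list
    ld_score: np.ndarray
    M: int

    def __post_init__(self):
        self.ld_score = np.asarray(self.ld_score, dtype=float)
        if np.any(self.ld_score < 1.0 - 1e-9):
            raise DataError("LD scores must be >= 1 (a SNP tags itself)")
        if self.M < len(self.ld_score):
            raise DataError("panel M smaller than number of rows")

    def __len__(self):
        return len(self.ld_score)


@dataclass
class UnivariateLdscFit:
    h2: float
    h2_se: float
    intercept: float
    intercept_se: float


@dataclass
class LdscFit:
    h2_1: float
    h2_1_se: float
    h2_2: float
    h2_2_se: float
    intercept_1: float
    intercept_2: float
    intercept_ct: float
    intercept_ct_se: float
    rho_g: float
    rho_g_se: float
    r_g: float
    r_g_se: float
    pval: float


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test significance threshold alpha / n_tests."""
    if not (0 < alpha < 1):
        raise ConfigError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ConfigError("n_tests must be >= 1")
    return alpha / n_tests


def _block_ids(m: int, n_blocks: int) -> np.ndarray:
    """Contiguous, nearly equal-size block assignment."""
    return np.minimum((np.arange(m) * n_blocks) // m, n_blocks - 1)


def _resolve_blocks(m: int, n_blocks: int) -> int:
    if m < 3 * n_blocks:
        reduced = max(2, m // 3)
        warnings.warn(
            f"only {m} SNPs for {n_blocks} jackknife blocks; using {reduced}",
            stacklevel=3,
        )
        return reduced
    return n_blocks


class _TwoParamFit:
    """Weighted fit of y = a + b*x with delete-one-block replicates."""

    def __init__(self, x, y, w, blocks, n_blocks):
        cols = (w, w * x, w * x * x, w * y, w * x * y)
        stats_ = np.column_stack(
            [np.bincount(blocks, weights=c, minlength=n_blocks) for c in cols]
        )
        self.block_stats = stats_
        self.total = stats_.sum(axis=0)
        self.a, self.b = self._solve(self.total)
        deleted = self.total[None, :] - stats_
        self.a_del = np.empty(n_blocks)
        self.b_del = np.empty(n_blocks)
        for g in range(n_blocks):
            self.a_del[g], self.b_del[g] = self._solve(deleted[g])

    @staticmethod
    def _solve(s):
        sw, sx, sxx, sy, sxy = s
        det = sw * sxx - sx * sx
        b = (sw * sxy - sx * sy) / det
        a = (sy - b * sx) / sw
        return a, b


class _SlopeFit:
    """Weighted slope of (y - a) on x through the origin, with the offset
    a supplied per delete-one replicate (two-step combination)."""

    def __init__(self, x, y, w, blocks, n_blocks, a_full, a_del):
        cols = (w * x * x, w * x * y, w * x)
        stats_ = np.column_stack(
            [np.bincount(blocks, weights=c, minlength=n_blocks) for c in cols]
        )
        total = stats_.sum(axis=0)
        self.b = (total[1] - a_full * total[2]) / total[0]
        deleted = total[None, :] - stats_
        self.b_del = (deleted[:, 1] - a_del * deleted[:, 2]) / deleted[:, 0]


def _jackknife_se(reps: np.ndarray) -> float:
    nb = len(reps)
    return float(np.sqrt((nb - 1) / nb * np.sum((reps - reps.mean()) ** 2)))


def _univariate_machinery(z, n, panel, n_blocks, chi2_max):
    z = np.asarray(z, dtype=float)
    ell = panel.ld_score
    if len(z) != len(ell):
        raise DataError("z scores not aligned to panel")
    m = len(z)
    n_blocks = _resolve_blocks(m, n_blocks)
    blocks = _block_ids(m, n_blocks)
    y = z**2

    # pilot slope for the heteroskedasticity weights
    pilot = np.sum(ell * (y - 1.0)) / np.sum(ell**2)
    pilot = max(pilot, 0.0)
    mean_var = 2.0 * (1.0 + pilot * ell) ** 2
    w = 1.0 / (np.maximum(ell, 1.0) * mean_var)

    slope, slope_del, fit1 = _two_step_fit(ell, y, w, blocks, n_blocks, chi2_max)

    scale = panel.M / n
    return {
        "n_blocks": n_blocks,
        "blocks": blocks,
        "weights": w,
        "h2": slope * scale,
        "h2_del": slope_del * scale,
        "intercept": fit1.a,
        "intercept_del": fit1.a_del,
    }


def _two_step_fit(ell, y, w, blocks, n_blocks, chi2_max):
    """Two-step fit (intercept on the |y| < chi2_max subset, then the slope
    on all SNPs with the intercept fixed).  The cutoff only stabilizes the
    intercept when it discards a small tail; when the signal is so strong
    that the cutoff would truncate the bulk of SNPs, fall back to a
    single-step free-intercept fit, which is unbiased."""
    mask = np.abs(y) < chi2_max
    if mask.sum() < max(3 * n_blocks, 0.95 * len(y)):
        fit = _TwoParamFit(ell, y, w, blocks, n_blocks)
        return fit.b, fit.b_del, fit
    fit1 = _TwoParamFit(ell[mask], y[mask], w[mask], blocks[mask], n_blocks)
    fit2 = _SlopeFit(ell, y, w, blocks, n_blocks, fit1.a, fit1.a_del)
    return fit2.b, fit2.b_del, fit1


def univariate_ldsc(
    z,
    n: float,
    panel: LdScorePanel,
    n_blocks: int = 200,
    chi2_max: float = 30.0,
) -> UnivariateLdscFit:
    """SNP heritability and confounding intercept for one trait.

    Regresses z^2 on the LD score; the slope times M/n is h2.  SEs are
    delete-one-block jackknife estimates.
    """
    if n <= 0:
        raise DataError("sample size must be positive")
    r = _univariate_machinery(z, n, panel, n_blocks, chi2_max)
    return UnivariateLdscFit(
        h2=float(r["h2"]),
        h2_se=_jackknife_se(r["h2_del"]),
        intercept=float(r["intercept"]),
        intercept_se=_jackknife_se(r["intercept_del"]),
    )


def cross_trait_ldsc(
    z1,
    z2,
    n1: float,
    n2: float,
    panel: LdScorePanel,
    n_overlap: int = 0,
    n_blocks: int = 200,
    chi2_max: float = 30.0,
) -> LdscFit:
    """Genetic covariance and correlation between two traits.

    Three fits share one block partition: the two univariate fits give
    h2_1 and h2_2; the cross fit regresses z1*z2 on the LD score with a
    free intercept (which absorbs sample overlap — ``n_overlap`` is
    informational only).  r_g = rho_g / sqrt(h2_1 h2_2); its jackknife SE
    propagates all three fits per deleted block, and the p-value is
    normal-based on r_g / SE.
    """
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    if len(z1) != len(z2):
        raise DataError("z1 and z2 must be aligned")
    u1 = _univariate_machinery(z1, n1, panel, n_blocks, chi2_max)
    u2 = _univariate_machinery(z2, n2, panel, n_blocks, chi2_max)
    n_blocks = u1["n_blocks"]
    blocks = u1["blocks"]
    ell = panel.ld_score

    # cross weights: geometric mean of the per-trait conditional scales
    w = np.sqrt(u1["weights"] * u2["weights"])
    slope_ct, slope_ct_del, fit_ct1 = _two_step_fit(
        ell, z1 * z2, w, blocks, n_blocks, chi2_max
    )

    scale = panel.M / np.sqrt(n1 * n2)
    rho = slope_ct * scale
    rho_del = slope_ct_del * scale

    h2_1, h2_2 = float(u1["h2"]), float(u2["h2"])
    if h2_1 <= 0 or h2_2 <= 0:
        rg = np.nan
        rg_del = np.full(n_blocks, np.nan)
    else:
        rg = float(rho / np.sqrt(h2_1 * h2_2))
        denom = np.sqrt(np.clip(u1["h2_del"] * u2["h2_del"], 1e-12, None))
        rg_del = rho_del / denom
    rg_se = _jackknife_se(rg_del) if np.isfinite(rg) else np.nan
    pval = (
        float(2 * stats.norm.sf(abs(rg / rg_se)))
        if np.isfinite(rg) and rg_se > 0
        else np.nan
    )
    return LdscFit(
        h2_1=h2_1,
        h2_1_se=_jackknife_se(u1["h2_del"]),
        h2_2=h2_2,
        h2_2_se=_jackknife_se(u2["h2_del"]),
        intercept_1=float(u1["intercept"]),
        intercept_2=float(u2["intercept"]),
        intercept_ct=float(fit_ct1.a),
        intercept_ct_se=_jackknife_se(fit_ct1.a_del),
        rho_g=float(rho),
        rho_g_se=_jackknife_se(rho_del),
        r_g=rg,
        r_g_se=rg_se,
        pval=pval,
    )
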