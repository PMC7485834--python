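"""Multivariable Mendelian randomization.

With K >= 2 exposures, the per-SNP outcome effects y_j are regressed
jointly on the matrix B of exposure effects (no intercept), weighted by
the inverse outcome variance:

    beta = (B' W B)^{-1} B' W y,     W = diag(1 / se_Yj^2).

Each beta_k is the direct effect of exposure k on the outcome, holding the
other exposures fixed.  Under multiplicative random effects the covariance
is scaled by max(1, Q_A / (m - K)) where Q_A is the weighted residual sum
of squares.  Conditional instrument strength per exposure follows the
Sanderson-Windmeijer Q formulation: regress that exposure's effects on the
others' and measure the residual signal against the exposure's own SEs;
conditional F below 10 flags a weak exposure (flag only, never enforced).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    CollinearityError,
    DataError,
    InsufficientInstrumentsError,
)
from .estimators import MrEstimate, _two_sided_p
from .instruments import LdMatrix, PruneLog, ld_clump, select_significant
from .sumstats import GwasTable, HarmonizedSet, harmonize


@dataclass
class MvmrInstrumentSet:
    """Instruments for multivariable MR: complete m x K exposure effect and
    SE matrices with aligned outcome effects; m > K >= 2."""

    snp_ids: np.ndarray
    exposure_names: list
    B: np.ndarray        # (m, K) exposure betas
    se_B: np.ndarray     # (m, K) exposure SEs
    y: np.ndarray        # (m,) outcome betas
    se_y: np.ndarray     # (m,) outcome SEs

    def __post_init__(self):
        m, k = self.B.shape
        if k < 1:
            raise DataError("MVMR requires at least one exposure")
        if m <= k:
            raise InsufficientInstrumentsError(
                f"MVMR requires m > K instruments (m={m}, K={k})"
            )
        if np.isnan(self.B).any() or np.isnan(self.y).any():
            raise DataError("MVMR instrument set has missing cells")

    @property
    def m(self) -> int:
        return self.B.shape[0]

    @property
    def n_exposures(self) -> int:
        return self.B.shape[1]

    def subset(self, mask) -> "MvmrInstrumentSet":
        mask = np.asarray(mask, dtype=bool)
        return MvmrInstrumentSet(
            snp_ids=self.snp_ids[mask],
            exposure_names=list(self.exposure_names),
            B=self.B[mask],
            se_B=self.se_B[mask],
            y=self.y[mask],
            se_y=self.se_y[mask],
        )

    @classmethod
    def from_harmonized(cls, h: HarmonizedSet) -> "MvmrInstrumentSet":
        return cls(
            snp_ids=h.snp_ids,
            exposure_names=list(h.exposure_names),
            B=h.beta_exp,
            se_B=h.se_exp,
            y=h.beta_out,
            se_y=h.se_out,
        )


@dataclass
class MvmrExposureResult:
    exposure: str
    estimate: MrEstimate
    conditional_F: float
    weak: bool


@dataclass
class MvmrResult:
    exposures: list          # list[MvmrExposureResult]
    Q_A: float
    Q_df: int
    Q_pval: float

    def to_frame(self, outcome: str = "") -> pd.DataFrame:
        rows = []
        for er in self.exposures:
            est = er.estimate
            rows.append(
                {
                    "exposure": er.exposure,
                    "outcome": outcome,
                    "method": est.method,
                    "k": est.k,
                    "beta": est.beta,
                    "se": est.se,
                    "or": est.or_,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "pval": est.pval,
                    "cond_F": er.conditional_F,
                    "weak": er.weak,
                    "QA": self.Q_A,
                    "QA_df": self.Q_df,
                    "QA_pval": self.Q_pval,
                }
            )
        return pd.DataFrame(rows)


def build_mvmr_set(
    exposures,
    outcome: GwasTable,
    ld: LdMatrix,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.001,
    palindrome_eaf_window: float = 0.08,
) -> MvmrInstrumentSet:
    """Assemble a joint instrument set for several exposures.

    Union-first assembly: per exposure, take genome-wide-significant SNPs
    and LD-clump them; restrict the union to SNPs present in every exposure
    table and the outcome; re-clump the union jointly, ranking SNPs by
    their minimum p-value across exposures; harmonize to a common effect
    allele.
    """
    exposures = list(exposures)
    if len(exposures) < 2:
        raise DataError("build_mvmr_set requires >= 2 exposures")

    candidates = set()
    for table in exposures:
        sig = select_significant(table, p_threshold)
        clumped, _ = ld_clump(sig, ld, r2_threshold)
        candidates |= set(clumped.records["snp_id"])

    universe = set(outcome.snp_ids)
    for table in exposures:
        universe &= set(table.snp_ids)
    candidates &= universe
    if not candidates:
        raise InsufficientInstrumentsError("no candidate instruments after filtering")

    # joint re-clump ranked by best (minimum) p across exposures
    min_p = {}
    for table in exposures:
        ix = table.indexed()
        for snp in candidates:
            p = float(ix.loc[snp, "pval"])
            if snp not in min_p or p < min_p[snp]:
                min_p[snp] = p
    rank_frame = exposures[0].subset(candidates).records.copy()
    rank_frame["pval"] = rank_frame["snp_id"].map(min_p)
    ranked = GwasTable(exposures[0].trait_name, exposures[0].trait_type, rank_frame)
    joint, _ = ld_clump(ranked, ld, r2_threshold)
    final_ids = set(joint.records["snp_id"])

    h = harmonize(
        [t.subset(final_ids) for t in exposures],
        outcome.subset(final_ids),
        palindrome_eaf_window,
    )
    if h.k <= len(exposures):
        raise InsufficientInstrumentsError(
            f"only {h.k} instruments for {len(exposures)} exposures after harmonization"
        )
    return MvmrInstrumentSet.from_harmonized(h)


def _check_rank(s: MvmrInstrumentSet, w: np.ndarray):
    xtwx = s.B.T @ (w[:, None] * s.B)
    if np.linalg.matrix_rank(xtwx, tol=1e-10 * np.abs(xtwx).max()) < s.n_exposures:
        # name the exposures involved in the dependency via correlations
        corr = np.corrcoef(s.B.T)
        bad = set()
        k = s.n_exposures
        for i in range(k):
            for j in range(i + 1, k):
                if abs(corr[i, j]) > 1 - 1e-8:
                    bad |= {s.exposure_names[i], s.exposure_names[j]}
        if not bad:
            bad = set(s.exposure_names)
        raise CollinearityError(sorted(bad))
    return xtwx


def mvmr_fit(
    s: MvmrInstrumentSet, model: str = "multiplicative_random"
) -> MvmrResult:
    """Weighted multivariable fit (no intercept).

    Covariance is (B'WB)^{-1}, scaled by max(1, Q_A/(m-K)) under
    multiplicative random effects; Q_A is the global heterogeneity
    statistic with m - K degrees of freedom.
    """
    if model not in ("fixed", "multiplicative_random"):
        raise DataError(f"unknown MVMR model {model!r}")
    w = 1.0 / s.se_y**2
    xtwx = _check_rank(s, w)
    beta = np.linalg.solve(xtwx, s.B.T @ (w * s.y))
    resid = s.y - s.B @ beta
    q_a = float(np.sum(w * resid**2))
    df = s.m - s.n_exposures
    disp = max(1.0, math.sqrt(q_a / df)) if model == "multiplicative_random" else 1.0
    cov = np.linalg.inv(xtwx) * disp**2
    ses = np.sqrt(np.diag(cov))

    cond_f = conditional_strength(s)
    results = []
    for i, name in enumerate(s.exposure_names):
        est = MrEstimate.from_beta_se("mvmr_ivw", s.m, beta[i], ses[i])
        results.append(
            MvmrExposureResult(
                exposure=name,
                estimate=est,
                conditional_F=cond_f[name],
                weak=cond_f[name] < 10.0,
            )
        )
    return MvmrResult(
        exposures=results,
        Q_A=q_a,
        Q_df=df,
        Q_pval=float(stats.chi2.sf(q_a, df)),
    )


def conditional_strength(s: MvmrInstrumentSet) -> dict:
    """Conditional F statistic per exposure.

    For exposure k, regress B[:, k] on the remaining columns (weights
    1/se_Yj^2); the residual signal Q_strength = sum(resid_j^2 / se_Xjk^2)
    scaled by 1/(m - K + 1) is the conditional F.  F < 10 is the customary
    weak-instrument flag.
    """
    w = 1.0 / s.se_y**2
    out = {}
    m, k = s.B.shape
    for i, name in enumerate(s.exposure_names):
        target = s.B[:, i]
        others = np.delete(s.B, i, axis=1)
        if others.shape[1] == 0:
            resid = target
        else:
            xtwx = others.T @ (w[:, None] * others)
            try:
                gamma = np.linalg.solve(xtwx, others.T @ (w * target))
            except np.linalg.LinAlgError:
                gamma = np.linalg.lstsq(others * np.sqrt(w[:, None]),
                                        target * np.sqrt(w), rcond=None)[0]
            resid = target - others @ gamma
        q_strength = float(np.sum(resid**2 / s.se_B[:, i] ** 2))
        out[name] = q_strength / (m - k + 1)
    return out


def mvmr_heterogeneity_prune(
    s: MvmrInstrumentSet, q_alpha: float = 0.05
) -> tuple[MvmrInstrumentSet, PruneLog]:
    """Iteratively remove the SNP contributing most to Q_A until the
    heterogeneity test no longer rejects; never reduce below m = K + 2."""
    if s.m <= s.n_exposures + 1:
        raise InsufficientInstrumentsError("need m > K + 1 to prune")
    log = PruneLog()
    current = s
    floor = s.n_exposures + 2
    while current.m > floor:
        res = mvmr_fit(current)
        if res.Q_pval >= q_alpha:
            break
        w = 1.0 / current.se_y**2
        beta = np.array([er.estimate.beta for er in res.exposures])
        contrib = w * (current.y - current.B @ beta) ** 2
        worst = int(np.argmax(contrib))
        log.add(current.snp_ids[worst], "qa_contribution", contrib[worst])
        log.rounds += 1
        mask = np.ones(current.m, dtype=bool)
        mask[worst] = False
        current = current.subset(mask)
    return current, log
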