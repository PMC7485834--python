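"""Locus-restricted MR, cross-locus meta-analysis, and per-SNP GWAS meta.

Gene-specific MR restricts the instrument set to conditionally independent
variants lying within a window (default 100 kb) of a gene's coordinates,
runs fixed-effects IVW on those variants, and pools the per-gene estimates
across a pathway's genes with a fixed-effects inverse-variance
meta-analysis.  Conditional association statistics are trusted as mutually
independent (they come from stepwise conditional analysis), so no LD
pruning is applied inside loci.  Loci with fewer than two surviving
instruments are excluded rather than errored.

The same inverse-variance pooling kernel, applied SNP-by-SNP, provides the
fixed-effects meta-analysis of two GWASs (:func:`gwas_meta`).
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError, MissingMetadataError
from .estimators import (
    HeterogeneityStat,
    MrEstimate,
    _two_sided_p,
    mr_ivw,
)
from .sumstats import GwasTable, HarmonizedSet, harmonize, make_table


@dataclass
class LocusDefinition:
    """A gene (or multi-gene locus) span, 1-based inclusive, with a flank."""

    locus_name: str
    chrom: str
    start: int
    end: int
    flank: int = 100_000

    def __post_init__(self):
        if self.start > self.end:
            raise DataError(f"{self.locus_name}: start > end")
        if self.flank < 0:
            raise DataError(f"{self.locus_name}: negative flank")

    def window(self) -> tuple[int, int]:
        return self.start - self.flank, self.end + self.flank


@dataclass
class LocusEstimate:
    locus_name: str
    k: int
    estimate: MrEstimate
    heterogeneity: HeterogeneityStat


@dataclass
class MetaResult:
    beta: float
    se: float
    pval: float
    or_: float
    ci_low: float
    ci_high: float
    Q: float
    Q_df: int
    Q_pval: float
    n_estimates: int


def read_locus_table(path) -> list[LocusDefinition]:
    """Read a locus TSV (locus_name, chrom, start, end[, flank])."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    loci = []
    for _, row in df.iterrows():
        kwargs = {}
        if "flank" in df.columns and not pd.isna(row.get("flank")):
            kwargs["flank"] = int(row["flank"])
        loci.append(
            LocusDefinition(
                str(row["locus_name"]), str(row["chrom"]),
                int(row["start"]), int(row["end"]), **kwargs,
            )
        )
    return loci


def load_packaged_loci() -> list[LocusDefinition]:
    """The 16 core HDL/LDL pathway loci shipped with the package
    (approximate hg19 RefSeq spans; users may substitute their own table)."""
    ref = importlib.resources.files("mrkit").joinpath("data/hdl_ldl_loci.tsv")
    with importlib.resources.as_file(ref) as path:
        return read_locus_table(path)


def locus_instruments(
    conditional_table: GwasTable,
    outcome: GwasTable,
    locus: LocusDefinition,
    palindrome_eaf_window: float = 0.08,
) -> HarmonizedSet | None:
    """Conditionally independent instruments inside a locus window,
    harmonized to the outcome; None if fewer than 2 survive (the locus is
    excluded, mirroring the minimum-2-instruments rule)."""
    recs = conditional_table.records
    if recs["chrom"].isna().any() or recs["pos"].isna().any():
        raise MissingMetadataError("conditional table needs chrom and pos")
    lo, hi = locus.window()
    inside = (recs["chrom"].astype(str) == str(locus.chrom)) & (
        recs["pos"].between(lo, hi)
    )
    snps = list(recs.loc[inside, "snp_id"])
    if len(snps) < 2:
        return None
    sub = conditional_table.subset(snps)
    try:
        h = harmonize([sub], outcome, palindrome_eaf_window)
    except DataError:
        return None
    if h.k < 2:
        return None
    return h


def locus_mr(h: HarmonizedSet, locus_name: str) -> LocusEstimate:
    """Fixed-effects IVW on a locus instrument set."""
    est, het = mr_ivw(h, model="fixed")
    return LocusEstimate(locus_name=locus_name, k=h.k, estimate=est, heterogeneity=het)


def _pool(betas: np.ndarray, ses: np.ndarray):
    inv_var = 1.0 / ses**2
    beta = float(np.sum(betas * inv_var) / np.sum(inv_var))
    se = float(np.sum(inv_var) ** -0.5)
    q = float(np.sum(inv_var * (betas - beta) ** 2))
    return beta, se, q


def meta_fixed(estimates) -> MetaResult:
    """Fixed-effects inverse-variance pooling of >= 2 estimates.

    Accepts MrEstimate, LocusEstimate, or (beta, se) pairs.  Pooled
    variance is 1/sum(1/var_i); heterogeneity Q has n-1 df.
    """
    pairs = []
    for e in estimates:
        if isinstance(e, LocusEstimate):
            pairs.append((e.estimate.beta, e.estimate.se))
        elif isinstance(e, MrEstimate):
            pairs.append((e.beta, e.se))
        else:
            pairs.append((float(e[0]), float(e[1])))
    if len(pairs) < 2:
        raise DataError("meta-analysis requires at least 2 estimates")
    betas = np.array([p[0] for p in pairs])
    ses = np.array([p[1] for p in pairs])
    beta, se, q = _pool(betas, ses)
    df = len(pairs) - 1
    from .estimators import Z95

    return MetaResult(
        beta=beta,
        se=se,
        pval=_two_sided_p(beta / se),
        or_=math.exp(beta),
        ci_low=math.exp(beta - Z95 * se),
        ci_high=math.exp(beta + Z95 * se),
        Q=q,
        Q_df=df,
        Q_pval=float(stats.chi2.sf(q, df)),
        n_estimates=len(pairs),
    )


def gwas_meta(
    study_a: GwasTable,
    study_b: GwasTable,
    palindrome_eaf_window: float = 0.08,
) -> GwasTable:
    """Per-SNP fixed-effects meta-analysis of two GWASs.

    Study B is allele-aligned to study A before pooling.  SNPs present in
    only one study (or unalignable) pass through unchanged; the returned
    table carries a ``meta_status`` column (pooled / only_a / only_b /
    dropped_palindromic / dropped_mismatch).
    """
    if study_a.trait_type != study_b.trait_type:
        raise DataError("cannot meta-analyze traits of different type")
    shared = set(study_a.snp_ids) & set(study_b.snp_ids)
    out_rows = []

    if shared:
        h = harmonize(
            [study_a.subset(shared)], study_b.subset(shared), palindrome_eaf_window
        )
        b_ix = {s: j for j, s in enumerate(h.snp_ids)}
        action = dict(zip(h.actions["snp_id"], h.actions["action"]))
    else:
        b_ix, action = {}, {}

    a_ix = study_a.indexed()
    for snp in study_a.records["snp_id"]:
        row = a_ix.loc[snp].to_dict()
        row["snp_id"] = snp
        if snp in b_ix:
            j = b_ix[snp]
            ba, sa = h.beta_exp[j, 0], h.se_exp[j, 0]
            bb, sb = h.beta_out[j], h.se_out[j]
            beta, se, _ = _pool(np.array([ba, bb]), np.array([sa, sb]))
            row["beta"], row["se"] = beta, se
            row["pval"] = _two_sided_p(beta / se)
            nb = study_b.indexed().loc[snp, "n"]
            if not pd.isna(row.get("n")) and not pd.isna(nb):
                row["n"] = float(row["n"]) + float(nb)
            row["meta_status"] = "pooled"
        elif snp in shared:
            row["meta_status"] = action.get(snp, "dropped_mismatch")
        else:
            row["meta_status"] = "only_a"
        out_rows.append(row)

    b_only = [s for s in study_b.records["snp_id"] if s not in shared]
    if b_only:
        b_frame = study_b.subset(b_only).records.copy()
        b_frame["meta_status"] = "only_b"
        out_rows.extend(b_frame.to_dict("records"))

    merged = pd.DataFrame(out_rows)
    table = make_table(
        f"meta({study_a.trait_name},{study_b.trait_name})",
        study_a.trait_type,
        merged,
    )
    table.records["meta_status"] = merged["meta_status"].values
    return table


def locus_results_frame(
    locus_estimates, pooled: MetaResult | None, outcome: str
) -> pd.DataFrame:
    """Forest-plot-ready table: one row per locus plus an optional pooled
    row (locus, k, OR, CI, p)."""
    rows = []
    for le in locus_estimates:
        est = le.estimate
        rows.append(
            {
                "locus": le.locus_name,
                "outcome": outcome,
                "k": le.k,
                "beta": est.beta,
                "se": est.se,
                "or": est.or_,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "pval": est.pval,
                "Q": le.heterogeneity.Q,
                "Q_df": le.heterogeneity.df,
                "Q_pval": le.heterogeneity.pval,
            }
        )
    if pooled is not None:
        rows.append(
            {
                "locus": "pooled",
                "outcome": outcome,
                "k": pooled.n_estimates,
                "beta": pooled.beta,
                "se": pooled.se,
                "or": pooled.or_,
                "ci_low": pooled.ci_low,
                "ci_high": pooled.ci_high,
                "pval": pooled.pval,
                "Q": pooled.Q,
                "Q_df": pooled.Q_df,
                "Q_pval": pooled.Q_pval,
            }
        )
    return pd.DataFrame(rows)
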