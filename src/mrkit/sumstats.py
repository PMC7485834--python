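"""GWAS summary-statistics I/O and allele harmonization.

A :class:`GwasTable` is the unit of all I/O in mrkit: one trait's per-SNP
association statistics (rsID, alleles, effect-allele frequency, beta, SE,
p-value, sample size) held as a pandas DataFrame with a canonical column
set.  Tables from different cohorts report effects relative to arbitrary
effect alleles; :func:`harmonize` aligns one or more exposure tables and an
outcome table onto a shared orientation, sign-flipping betas where the
effect/other alleles are swapped, resolving strand flips via reverse
complements, and dropping palindromic (A/T, C/G) SNPs whose strand cannot
be inferred from allele frequencies.  The result, a :class:`HarmonizedSet`,
is the input of every MR estimator in the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import (
    DataError,
    EmptyIntersectionError,
    EmptyTableError,
    MissingMetadataError,
)

#: canonical column order for GwasTable frames and TSV output
CANONICAL_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
    "ncase",
    "ncontrol",
]

_REQUIRED = ["snp_id", "effect_allele", "other_allele", "beta", "se", "pval"]

#: header aliases recognized without an explicit column map.  Includes the
#: GCTA-COJO ".ma" dialect (SNP A1 A2 freq b se p N).
DEFAULT_ALIASES = {
    "snp_id": ["snp_id", "snp", "rsid", "markername", "id"],
    "chrom": ["chrom", "chr", "chromosome"],
    "pos": ["pos", "bp", "position", "base_pair_location"],
    "effect_allele": ["effect_allele", "a1", "allele1", "ea"],
    "other_allele": ["other_allele", "a2", "allele2", "oa", "nea"],
    "eaf": ["eaf", "freq", "af", "effect_allele_frequency", "maf"],
    "beta": ["beta", "b", "effect"],
    "se": ["se", "stderr", "standard_error"],
    "pval": ["pval", "p", "pvalue", "p_value"],
    "n": ["n", "samplesize", "n_total"],
    "ncase": ["ncase", "n_case", "ncases"],
    "ncontrol": ["ncontrol", "n_control", "ncontrols"],
}

_ACGT = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC_PAIRS = (frozenset("AT"), frozenset("CG"))


@dataclass
class ValidationReport:
    """Row-level QC accounting from :func:`read_gwas_table`."""

    n_input: int = 0
    n_valid: int = 0
    dropped: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"n_input": self.n_input, "n_valid": self.n_valid, "dropped": self.dropped},
            indent=2,
        )


@dataclass
class GwasTable:
    """One trait's per-SNP summary statistics.

    ``records`` is a DataFrame with :data:`CANONICAL_COLUMNS`; ``snp_id`` is
    unique within the table.  ``trait_type`` is ``"quantitative"`` (betas in
    SD units) or ``"binary"`` (betas are log odds ratios).
    """

    trait_name: str
    trait_type: str
    records: pd.DataFrame

    def __post_init__(self):
        if self.trait_type not in ("quantitative", "binary"):
            raise DataError(f"unknown trait_type {self.trait_type!r}")
        if self.records["snp_id"].duplicated().any():
            raise DataError(f"duplicate snp_id in table {self.trait_name!r}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def snp_ids(self) -> pd.Index:
        return pd.Index(self.records["snp_id"])

    def subset(self, snp_ids) -> "GwasTable":
        """Rows for ``snp_ids``, preserving this table's row order."""
        keep = self.records["snp_id"].isin(set(snp_ids))
        return replace(self, records=self.records.loc[keep].reset_index(drop=True))

    def indexed(self) -> pd.DataFrame:
        return self.records.set_index("snp_id")


def make_table(trait_name, trait_type, frame: pd.DataFrame) -> GwasTable:
    """Build a GwasTable from a partially filled frame, adding missing
    optional columns as NA and ordering columns canonically."""
    df = frame.copy()
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return GwasTable(trait_name, trait_type, df[CANONICAL_COLUMNS].reset_index(drop=True))


def _resolve_columns(header, column_map):
    mapping = {}
    lower = {str(c).lower(): c for c in header}
    explicit = column_map or {}
    for canon in CANONICAL_COLUMNS:
        if canon in explicit:
            src = explicit[canon]
            if src not in header:
                raise DataError(f"mapped column {src!r} not in file header")
            mapping[canon] = src
            continue
        for alias in DEFAULT_ALIASES[canon]:
            if alias in lower:
                mapping[canon] = lower[alias]
                break
    missing = [c for c in _REQUIRED if c not in mapping]
    if missing:
        raise DataError(f"could not locate required columns: {missing}")
    return mapping


def read_gwas_table(
    path,
    column_map: dict | None = None,
    trait_type: str = "quantitative",
    trait_name: str | None = None,
    sep: str | None = None,
) -> tuple[GwasTable, ValidationReport]:
    """Read a delimited summary-statistics file.

    Parameters
    ----------
    path
        Tab- or whitespace-delimited text with a header row; ``.gz`` files
        are decompressed transparently.
    column_map
        Optional mapping canonical-name -> file column name.  Columns not
        mapped are located via :data:`DEFAULT_ALIASES`.
    trait_type
        ``"quantitative"`` or ``"binary"``.
    sep
        Field separator; default splits on any whitespace.

    Returns
    -------
    (GwasTable, ValidationReport)
        Rows failing validation (missing beta/se/p, non-ACGT alleles,
        se <= 0, p outside (0, 1], eaf outside (0, 1), identical alleles,
        duplicated rsID) are dropped and counted by reason.

    Raises
    ------
    EmptyTableError
        If no row survives validation.
    """
    try:
        raw = pd.read_csv(path, sep=sep if sep is not None else r"\s+", dtype=str)
    except (OSError, pd.errors.ParserError) as exc:
        raise IOError(f"cannot read summary statistics from {path}: {exc}") from exc
    if raw.empty:
        raise EmptyTableError(f"{path}: no data rows")

    mapping = _resolve_columns(list(raw.columns), column_map)
    df = pd.DataFrame({canon: raw[src] for canon, src in mapping.items()})
    report = ValidationReport(n_input=len(df))

    for col in ("eaf", "beta", "se", "pval", "n", "ncase", "ncontrol", "pos"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper().str.strip()

    def drop(mask, reason):
        n = int(mask.sum())
        if n:
            report.dropped[reason] = report.dropped.get(reason, 0) + n
        return df.loc[~mask]

    df = drop(df[["beta", "se", "pval"]].isna().any(axis=1), "missing_beta_se_pval")
    non_snv = ~df["effect_allele"].isin(_ACGT) | ~df["other_allele"].isin(_ACGT)
    df = drop(non_snv, "non_acgt_allele")
    df = drop(df["effect_allele"] == df["other_allele"], "identical_alleles")
    df = drop(df["se"] <= 0, "nonpositive_se")
    df = drop((df["pval"] <= 0) | (df["pval"] > 1), "pval_out_of_range")
    if "eaf" in df.columns:
        bad_eaf = df["eaf"].notna() & ((df["eaf"] <= 0) | (df["eaf"] >= 1))
        df = drop(bad_eaf, "eaf_out_of_range")
    # multi-allelic rsIDs (same ID, different allele pairs) are rejected outright
    df = drop(df["snp_id"].duplicated(keep=False), "duplicated_snp_id")

    report.n_valid = len(df)
    if report.n_valid == 0:
        raise EmptyTableError(f"{path}: zero valid rows after QC ({report.dropped})")
    name = trait_name if trait_name is not None else str(path)
    return make_table(name, trait_type, df), report


def write_gwas_table(table: GwasTable, path) -> None:
    """Write the canonical TSV (fixed column order, NA for missing)."""
    table.records.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

KEPT = "kept"
FLIPPED = "flipped"
DROPPED_PALINDROMIC = "dropped_palindromic"
DROPPED_MISMATCH = "dropped_mismatch"


@dataclass
class HarmonizedSet:
    """Exposure and outcome effects aligned to a common effect allele.

    Arrays cover the retained ("kept"/"flipped") SNPs only; ``actions``
    records the decision for every shared SNP, so
    kept + flipped + dropped_palindromic + dropped_mismatch equals the size
    of the rsID intersection.
    """

    outcome_name: str
    exposure_names: list
    snp_ids: np.ndarray        # (m,) retained rsIDs
    beta_exp: np.ndarray       # (m, K)
    se_exp: np.ndarray         # (m, K)
    beta_out: np.ndarray       # (m,)
    se_out: np.ndarray         # (m,)
    actions: pd.DataFrame      # columns snp_id, action — all shared SNPs
    pval_exp: np.ndarray | None = None   # (m, K), if available
    eaf: np.ndarray | None = None        # (m,) exposure-1 effect-allele freq

    @property
    def k(self) -> int:
        """Number of retained instruments."""
        return len(self.snp_ids)

    @property
    def n_exposures(self) -> int:
        return len(self.exposure_names)

    def require_single_exposure(self):
        if self.n_exposures != 1:
            raise DataError("operation requires a single-exposure HarmonizedSet")

    def subset(self, mask) -> "HarmonizedSet":
        """Retain only instruments where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        return HarmonizedSet(
            outcome_name=self.outcome_name,
            exposure_names=list(self.exposure_names),
            snp_ids=self.snp_ids[mask],
            beta_exp=self.beta_exp[mask],
            se_exp=self.se_exp[mask],
            beta_out=self.beta_out[mask],
            se_out=self.se_out[mask],
            actions=self.actions,
            pval_exp=None if self.pval_exp is None else self.pval_exp[mask],
            eaf=None if self.eaf is None else self.eaf[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-SNP frame (one row per retained SNP)."""
        out = {"snp_id": self.snp_ids}
        for i, name in enumerate(self.exposure_names):
            out[f"beta_{name}"] = self.beta_exp[:, i]
            out[f"se_{name}"] = self.se_exp[:, i]
        out["beta_outcome"] = self.beta_out
        out["se_outcome"] = self.se_out
        return pd.DataFrame(out)


def _is_palindromic(a1: str, a2: str) -> bool:
    return frozenset((a1, a2)) in _PALINDROMIC_PAIRS


def _align_alleles(ref_ea, ref_oa, ea, oa):
    """Return 'same', 'swap' or None (irreconcilable), resolving strand
    flips via reverse complement.  Not valid for palindromic pairs."""
    if (ea, oa) == (ref_ea, ref_oa):
        return "same"
    if (ea, oa) == (ref_oa, ref_ea):
        return "swap"
    cea, coa = _COMPLEMENT[ea], _COMPLEMENT[oa]
    if (cea, coa) == (ref_ea, ref_oa):
        return "same"
    if (cea, coa) == (ref_oa, ref_ea):
        return "swap"
    return None


def harmonize(
    exposures,
    outcome: GwasTable,
    palindrome_eaf_window: float = 0.08,
) -> HarmonizedSet:
    """Align exposure and outcome tables to a shared effect allele.

    The first exposure's orientation is the reference.  For every SNP
    present (by rsID) in all exposure tables and the outcome:

    * identical allele pair, identical orientation -> kept;
    * identical pair with effect/other swapped -> beta sign-flipped and eaf
      complemented (action ``flipped``);
    * alleles that are reverse complements -> strand-flipped, then as above;
    * palindromic SNP (A/T or C/G) -> orientation inferred from effect-allele
      frequencies when every table's eaf lies outside
      ``[0.5 - w, 0.5 + w]``; otherwise dropped (``dropped_palindromic``);
    * anything else -> ``dropped_mismatch``.

    Raises
    ------
    EmptyIntersectionError
        If the tables share no SNPs.
    """
    if isinstance(exposures, GwasTable):
        exposures = [exposures]
    exposures = list(exposures)
    if not exposures:
        raise DataError("at least one exposure table required")
    for t in exposures:
        if len(t) == 0:
            raise EmptyTableError(f"exposure table {t.trait_name!r} is empty")

    shared = exposures[0].snp_ids
    for t in exposures[1:]:
        shared = shared.intersection(t.snp_ids)
    shared = shared.intersection(outcome.snp_ids)
    if len(shared) == 0:
        raise EmptyIntersectionError(
            f"no shared SNPs between exposures and outcome {outcome.trait_name!r}"
        )
    # preserve first-exposure row order for determinism
    shared_order = [s for s in exposures[0].records["snp_id"] if s in set(shared)]

    exp_ix = [t.indexed() for t in exposures]
    out_ix = outcome.indexed()
    w = float(palindrome_eaf_window)

    kept_rows = []
    actions = []
    for snp in shared_order:
        ref = exp_ix[0].loc[snp]
        ref_ea, ref_oa = ref["effect_allele"], ref["other_allele"]
        rows = [exp_ix[i].loc[snp] for i in range(1, len(exp_ix))]
        orow = out_ix.loc[snp]

        if _is_palindromic(ref_ea, ref_oa):
            eafs = [ref["eaf"]] + [r["eaf"] for r in rows] + [orow["eaf"]]
            pairs_ok = all(
                frozenset((r["effect_allele"], r["other_allele"]))
                == frozenset((ref_ea, ref_oa))
                for r in rows + [orow]
            )
            if not pairs_ok:
                actions.append((snp, DROPPED_MISMATCH))
                continue
            if any(pd.isna(e) or abs(e - 0.5) <= w for e in eafs):
                actions.append((snp, DROPPED_PALINDROMIC))
                continue
            ref_major = ref["eaf"] > 0.5
            flips = [(r["eaf"] > 0.5) != ref_major for r in rows]
            out_flip = (orow["eaf"] > 0.5) != ref_major
        else:
            aligns = [
                _align_alleles(ref_ea, ref_oa, r["effect_allele"], r["other_allele"])
                for r in rows
            ]
            out_align = _align_alleles(
                ref_ea, ref_oa, orow["effect_allele"], orow["other_allele"]
            )
            if out_align is None or any(a is None for a in aligns):
                actions.append((snp, DROPPED_MISMATCH))
                continue
            flips = [a == "swap" for a in aligns]
            out_flip = out_align == "swap"

        betas = [float(ref["beta"])]
        ses = [float(ref["se"])]
        pvals = [float(ref["pval"])]
        for r, flip in zip(rows, flips):
            betas.append(-float(r["beta"]) if flip else float(r["beta"]))
            ses.append(float(r["se"]))
            pvals.append(float(r["pval"]))
        beta_out = -float(orow["beta"]) if out_flip else float(orow["beta"])
        actions.append((snp, FLIPPED if out_flip else KEPT))
        kept_rows.append(
            (snp, betas, ses, pvals, beta_out, float(orow["se"]), ref["eaf"])
        )

    action_df = pd.DataFrame(actions, columns=["snp_id", "action"])
    if not kept_rows:
        return HarmonizedSet(
            outcome_name=outcome.trait_name,
            exposure_names=[t.trait_name for t in exposures],
            snp_ids=np.array([], dtype=object),
            beta_exp=np.empty((0, len(exposures))),
            se_exp=np.empty((0, len(exposures))),
            beta_out=np.array([]),
            se_out=np.array([]),
            actions=action_df,
            pval_exp=np.empty((0, len(exposures))),
            eaf=np.array([]),
        )

    snp_arr = np.array([r[0] for r in kept_rows], dtype=object)
    return HarmonizedSet(
        outcome_name=outcome.trait_name,
        exposure_names=[t.trait_name for t in exposures],
        snp_ids=snp_arr,
        beta_exp=np.array([r[1] for r in kept_rows], dtype=float),
        se_exp=np.array([r[2] for r in kept_rows], dtype=float),
        beta_out=np.array([r[4] for r in kept_rows], dtype=float),
        se_out=np.array([r[5] for r in kept_rows], dtype=float),
        actions=action_df,
        pval_exp=np.array([r[3] for r in kept_rows], dtype=float),
        eaf=np.array([r[6] for r in kept_rows], dtype=float),
    )


def effective_n(ncase: float, ncontrol: float) -> float:
    """Effective sample size of a case-control GWAS, 4/(1/ncase + 1/ncontrol)."""
    if not (ncase > 0 and ncontrol > 0):
        raise MissingMetadataError("case/control counts must be positive")
    return 4.0 / (1.0 / ncase + 1.0 / ncontrol)
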