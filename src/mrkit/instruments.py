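"""Genetic-instrument construction.

Instruments for two-sample MR are SNPs robustly associated with the
exposure and mutually independent.  This module provides the four
selection steps used by the pipeline: genome-wide-significance filtering
(P < 5e-8 by default), greedy LD clumping against a user-supplied r^2
matrix (r^2 < 0.001 by default), cross-trait pruning in the style of
removing instruments associated with correlated traits (P < 1e-3), and
iterative heterogeneity pruning that removes the largest contributor to
Cochran's Q until the Q test no longer rejects.

All pruning is deterministic: ties in p-value are broken by rsID, and
every removal is recorded in a :class:`PruneLog`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError, InsufficientInstrumentsError
from .sumstats import GwasTable, HarmonizedSet


@dataclass
class LdMatrix:
    """Squared-correlation matrix over a set of SNPs.

    Symmetric, unit diagonal, entries in [0, 1].
    """

    snp_ids: list
    r2: np.ndarray

    def __post_init__(self):
        self.snp_ids = list(self.snp_ids)
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.snp_ids)
        if self.r2.shape != (n, n):
            raise DataError("LD matrix shape does not match snp_ids")
        if not np.allclose(self.r2, self.r2.T, atol=1e-8):
            raise DataError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-8):
            raise DataError("LD matrix diagonal is not 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12:
            raise DataError("LD matrix entries outside [0, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def __contains__(self, snp_id) -> bool:
        return snp_id in self._index

    def pairwise(self, snp_a, snp_b) -> float:
        return float(self.r2[self._index[snp_a], self._index[snp_b]])

    @classmethod
    def identity(cls, snp_ids) -> "LdMatrix":
        """No-LD matrix (all SNPs independent)."""
        return cls(list(snp_ids), np.eye(len(list(snp_ids))))

    @classmethod
    def read_tsv(cls, path) -> "LdMatrix":
        """Read either a square TSV (rsID header row + first column) or a
        long-format TSV with columns snp_a, snp_b, r2."""
        head = pd.read_csv(path, sep="\t", nrows=1)
        if set(map(str.lower, head.columns)) >= {"snp_a", "snp_b", "r2"}:
            long = pd.read_csv(path, sep="\t")
            long.columns = [c.lower() for c in long.columns]
            snps = sorted(set(long["snp_a"]) | set(long["snp_b"]))
            idx = {s: i for i, s in enumerate(snps)}
            mat = np.eye(len(snps))
            for _, row in long.iterrows():
                i, j = idx[row["snp_a"]], idx[row["snp_b"]]
                mat[i, j] = mat[j, i] = float(row["r2"])
            return cls(snps, mat)
        square = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(square.index), square.to_numpy(dtype=float))


@dataclass
class PruneLog:
    """Ordered record of removed SNPs: (snp_id, reason, statistic)."""

    removed: list = field(default_factory=list)
    rounds: int = 0

    def add(self, snp_id, reason, statistic=np.nan):
        self.removed.append((snp_id, reason, float(statistic)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.removed, columns=["snp_id", "reason", "statistic"])

    def write_tsv(self, path):
        self.to_frame().to_csv(path, sep="\t", index=False)


def select_significant(table: GwasTable, p_threshold: float = 5e-8) -> GwasTable:
    """Keep records with pval strictly below ``p_threshold``."""
    if len(table) == 0:
        raise DataError("empty table")
    keep = table.records["pval"] < p_threshold
    out = table.records.loc[keep].reset_index(drop=True)
    return GwasTable(table.trait_name, table.trait_type, out)


def ld_clump(
    table: GwasTable, ld: LdMatrix, r2_threshold: float = 0.001
) -> tuple[GwasTable, PruneLog]:
    """Greedy p-value-ranked LD clumping.

    SNPs are sorted by ascending p-value (ties by rsID); the best remaining
    SNP is accepted and every remaining SNP with r^2 >= ``r2_threshold`` to
    it is discarded.  SNPs absent from the LD matrix are dropped up front
    (conservative: unknown LD is not assumed to be absence of LD).  The
    returned set is pairwise r^2 < threshold.
    """
    log = PruneLog()
    recs = table.records
    in_ld = recs["snp_id"].map(lambda s: s in ld)
    for snp in recs.loc[~in_ld, "snp_id"]:
        log.add(snp, "absent_from_ld_matrix")
    recs = recs.loc[in_ld]

    order = recs.sort_values(["pval", "snp_id"], kind="mergesort")
    remaining = list(order["snp_id"])
    accepted = []
    while remaining:
        best = remaining.pop(0)
        accepted.append(best)
        still = []
        for snp in remaining:
            r2 = ld.pairwise(snp, best)
            if r2 >= r2_threshold:
                log.add(snp, f"r2_with_{best}", r2)
            else:
                still.append(snp)
        remaining = still
        log.rounds += 1
    return table.subset(accepted), log


def cross_trait_prune(
    target: GwasTable, others, p_threshold: float = 1e-3
) -> tuple[GwasTable, PruneLog]:
    """Remove target instruments associated with any other trait.

    An instrument is removed if its p-value in any table of ``others`` is
    below ``p_threshold``; SNPs absent from an other-trait table are treated
    as not associated there.
    """
    log = PruneLog(rounds=1)
    drop = set()
    for other in others:
        ix = other.indexed()
        for snp in target.records["snp_id"]:
            if snp in drop or snp not in ix.index:
                continue
            p = float(ix.loc[snp, "pval"])
            if p < p_threshold:
                drop.add(snp)
                log.add(snp, f"associated_with_{other.trait_name}", p)
    keep = [s for s in target.records["snp_id"] if s not in drop]
    return target.subset(keep), log


def heterogeneity_prune(
    h: HarmonizedSet, q_alpha: float = 0.05, min_k: int = 3
) -> tuple[HarmonizedSet, PruneLog]:
    """Iteratively remove the instrument contributing most to Cochran's Q.

    At each round the IVW estimate and Q are recomputed; if the Q test
    p-value is >= ``q_alpha`` pruning stops.  Otherwise the SNP with the
    largest individual contribution w_j (r_j - beta)^2 is removed.  The set
    is never reduced below ``min_k`` instruments.
    """
    from .estimators import mr_ivw, ratio_estimates

    h.require_single_exposure()
    if h.k < min_k:
        raise InsufficientInstrumentsError(
            f"need at least {min_k} instruments, have {h.k}"
        )
    log = PruneLog()
    current = h
    while current.k > min_k:
        est, het = mr_ivw(current, model="multiplicative_random")
        if het.pval >= q_alpha:
            break
        ratios = ratio_estimates(current)
        contrib = np.array([re.w_j * (re.r_j - est.beta) ** 2 for re in ratios])
        worst = int(np.argmax(contrib))
        log.add(current.snp_ids[worst], "q_contribution", contrib[worst])
        log.rounds += 1
        mask = np.ones(current.k, dtype=bool)
        mask[worst] = False
        current = current.subset(mask)
    return current, log
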