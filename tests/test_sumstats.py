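"""Summary-statistics reading, validation and allele harmonization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mrkit.exceptions import EmptyIntersectionError, EmptyTableError
from mrkit.sumstats import (
    DROPPED_MISMATCH,
    DROPPED_PALINDROMIC,
    FLIPPED,
    KEPT,
    harmonize,
    read_gwas_table,
    write_gwas_table,
)

from conftest import toy_table


def _write_tsv(tmp_path, text, name="sumstats.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadGwasTable:
    def test_well_formed_table_passes_through(self, tmp_path):
        p = _write_tsv(
            tmp_path,
            "SNP\tA1\tA2\tfreq\tb\tse\tp\tN\n"
            "rs1\tA\tG\t0.3\t0.1\t0.01\t1e-20\t10000\n"
            "rs2\tC\tT\t0.4\t-0.05\t0.02\t1e-6\t10000\n"
            "rs3\tG\tA\t0.2\t0.02\t0.01\t0.04\t10000\n",
        )
        table, report = read_gwas_table(p, trait_name="lipid")
        assert len(table) == 3
        assert report.n_valid == 3 and report.dropped == {}
        assert list(table.records["snp_id"]) == ["rs1", "rs2", "rs3"]
        assert table.records["beta"].tolist() == [0.1, -0.05, 0.02]

    def test_zero_se_row_dropped_and_counted(self, tmp_path):
        p = _write_tsv(
            tmp_path,
            "SNP A1 A2 freq b se p N\n"
            "rs1 A G 0.3 0.1 0.0 1e-20 10000\n"
            "rs2 C T 0.4 -0.05 0.02 1e-6 10000\n",
        )
        table, report = read_gwas_table(p)
        assert len(table) == 1
        assert report.dropped == {"nonpositive_se": 1}

    def test_indel_alleles_rejected_as_non_snv(self, tmp_path):
        # hand enumeration: rs1 and rs3 violate the ACGT rule
        p = _write_tsv(
            tmp_path,
            "SNP A1 A2 freq b se p N\n"
            "rs1 I D 0.3 0.1 0.01 1e-20 10000\n"
            "rs2 C T 0.4 -0.05 0.02 1e-6 10000\n"
            "rs3 AT A 0.2 0.02 0.01 0.04 10000\n",
        )
        table, report = read_gwas_table(p)
        assert list(table.records["snp_id"]) == ["rs2"]
        assert report.dropped == {"non_acgt_allele": 2}

    def test_multiallelic_rsid_rejected(self, tmp_path):
        p = _write_tsv(
            tmp_path,
            "SNP A1 A2 freq b se p N\n"
            "rs1 A G 0.3 0.1 0.01 1e-20 10000\n"
            "rs1 A C 0.3 0.2 0.01 1e-20 10000\n"
            "rs2 C T 0.4 -0.05 0.02 1e-6 10000\n",
        )
        table, report = read_gwas_table(p)
        assert list(table.records["snp_id"]) == ["rs2"]
        assert report.dropped == {"duplicated_snp_id": 2}

    def test_all_rows_invalid_raises(self, tmp_path):
        p = _write_tsv(
            tmp_path, "SNP A1 A2 freq b se p N\nrs1 I D 0.3 0.1 0.01 0.5 10\n"
        )
        with pytest.raises(EmptyTableError):
            read_gwas_table(p)

    def test_roundtrip_through_canonical_tsv(self, tmp_path, simple_rows):
        table = toy_table("t", simple_rows)
        out = tmp_path / "canonical.tsv"
        write_gwas_table(table, out)
        back, _ = read_gwas_table(out, trait_name="t")
        pd.testing.assert_frame_equal(
            back.records[["snp_id", "beta", "se", "pval"]],
            table.records[["snp_id", "beta", "se", "pval"]],
        )

    def test_gzip_transparent(self, tmp_path):
        import gzip

        p = tmp_path / "sumstats.tsv.gz"
        with gzip.open(p, "wt") as fh:
            fh.write("SNP A1 A2 freq b se p N\nrs1 A G 0.3 0.1 0.01 1e-20 100\n")
        table, _ = read_gwas_table(p)
        assert len(table) == 1


def _exp(rows):
    return toy_table("exp", rows)


def _out(rows):
    return toy_table("out", rows, trait_type="binary")


class TestHarmonize:
    def test_swapped_alleles_flip_outcome_beta(self):
        exp = _exp([dict(snp_id="rs1", effect_allele="A", other_allele="G",
                         eaf=0.3, beta=0.1, se=0.01, pval=1e-9)])
        out = _out([dict(snp_id="rs1", effect_allele="G", other_allele="A",
                         eaf=0.7, beta=0.05, se=0.01, pval=1e-4)])
        h = harmonize([exp], out)
        assert h.k == 1
        assert h.beta_out[0] == -0.05
        assert list(h.actions["action"]) == [FLIPPED]

    def test_palindromic_near_half_frequency_dropped(self):
        exp = _exp([dict(snp_id="rs1", effect_allele="A", other_allele="T",
                         eaf=0.50, beta=0.1, se=0.01, pval=1e-9)])
        out = _out([dict(snp_id="rs1", effect_allele="A", other_allele="T",
                         eaf=0.50, beta=0.05, se=0.01, pval=1e-4)])
        h = harmonize([exp], out)
        assert h.k == 0
        assert list(h.actions["action"]) == [DROPPED_PALINDROMIC]

    def test_palindromic_informative_eaf_inferred(self):
        # outcome eaf on the opposite side of 0.5: reported for the other strand
        exp = _exp([dict(snp_id="rs1", effect_allele="A", other_allele="T",
                         eaf=0.2, beta=0.1, se=0.01, pval=1e-9)])
        out = _out([dict(snp_id="rs1", effect_allele="A", other_allele="T",
                         eaf=0.8, beta=0.05, se=0.01, pval=1e-4)])
        h = harmonize([exp], out)
        assert h.k == 1 and h.beta_out[0] == -0.05

    def test_five_snp_toy_with_strand_flip_matches_hand_resolution(self):
        # rs4 is reported on the opposite strand in the outcome (A/G vs T/C):
        # hand-resolved orientation keeps its sign; rs5 additionally has
        # effect/other swapped after the strand flip, so its beta negates.
        exp = _exp([
            dict(snp_id=f"rs{i}", effect_allele=ea, other_allele=oa,
                 eaf=f, beta=0.1 * i, se=0.01, pval=1e-9)
            for i, (ea, oa, f) in enumerate(
                [("A", "G", 0.3), ("C", "T", 0.4), ("G", "C", 0.2),
                 ("A", "G", 0.25), ("T", "G", 0.35)], start=1)
        ])
        out = _out([
            dict(snp_id="rs1", effect_allele="A", other_allele="G",
                 eaf=0.3, beta=0.01, se=0.01, pval=0.1),
            dict(snp_id="rs2", effect_allele="C", other_allele="T",
                 eaf=0.4, beta=0.02, se=0.01, pval=0.1),
            dict(snp_id="rs3", effect_allele="G", other_allele="C",
                 eaf=0.2, beta=0.03, se=0.01, pval=0.1),
            dict(snp_id="rs4", effect_allele="T", other_allele="C",
                 eaf=0.25, beta=0.04, se=0.01, pval=0.1),
            dict(snp_id="rs5", effect_allele="C", other_allele="A",
                 eaf=0.65, beta=0.05, se=0.01, pval=0.1),
        ])
        h = harmonize([exp], out)
        assert h.k == 5
        by = dict(zip(h.snp_ids, h.beta_out))
        assert by["rs1"] == 0.01
        assert by["rs2"] == 0.02
        assert by["rs3"] == 0.03      # C/G palindrome, eafs informative + agree
        assert by["rs4"] == 0.04      # strand flip only, same orientation
        assert by["rs5"] == -0.05     # strand flip + swap -> negated

    def test_irreconcilable_alleles_dropped_as_mismatch(self):
        exp = _exp([dict(snp_id="rs1", effect_allele="A", other_allele="G",
                         eaf=0.3, beta=0.1, se=0.01, pval=1e-9)])
        out = _out([dict(snp_id="rs1", effect_allele="A", other_allele="C",
                         eaf=0.3, beta=0.05, se=0.01, pval=1e-4)])
        h = harmonize([exp], out)
        assert h.k == 0
        assert list(h.actions["action"]) == [DROPPED_MISMATCH]

    def test_no_shared_snps_raises(self):
        exp = _exp([dict(snp_id="rs1", effect_allele="A", other_allele="G",
                         eaf=0.3, beta=0.1, se=0.01, pval=1e-9)])
        out = _out([dict(snp_id="rs2", effect_allele="A", other_allele="G",
                         eaf=0.3, beta=0.1, se=0.01, pval=1e-9)])
        with pytest.raises(EmptyIntersectionError):
            harmonize([exp], out)


# -- property tests ---------------------------------------------------------

_allele_pair = st.sampled_from(
    [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("A", "T"), ("C", "G")]
)


@st.composite
def _random_table_rows(draw):
    n = draw(st.integers(2, 8))
    rows = []
    for i in range(n):
        ea, oa = draw(_allele_pair)
        rows.append(
            dict(snp_id=f"rs{i}", effect_allele=ea, other_allele=oa,
                 eaf=draw(st.floats(0.05, 0.95)),
                 beta=draw(st.floats(-1, 1, allow_nan=False)),
                 se=draw(st.floats(0.01, 0.5)), pval=draw(st.floats(1e-10, 1)))
        )
    return rows


@settings(max_examples=50, deadline=None, derandomize=True)
@given(_random_table_rows())
def test_self_harmonization_is_identity_for_nonpalindromic(rows):
    """Harmonizing a table against itself keeps every non-palindromic SNP
    unchanged with action 'kept'."""
    exp = toy_table("t", rows)
    out = toy_table("t2", rows)
    h = harmonize([exp], out)
    actions = dict(zip(h.actions["snp_id"], h.actions["action"]))
    ix = exp.indexed()
    for row in rows:
        pal = frozenset((row["effect_allele"], row["other_allele"])) in (
            frozenset("AT"), frozenset("CG"))
        if not pal:
            assert actions[row["snp_id"]] == KEPT
    for snp, bo in zip(h.snp_ids, h.beta_out):
        assert bo == pytest.approx(float(ix.loc[snp, "beta"]))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(_random_table_rows())
def test_outcome_allele_flip_leaves_end_state_identical(rows):
    """Swapping the outcome's allele columns (and complementing eaf,
    negating beta) must not change any harmonized outcome beta."""
    exp = toy_table("exp", rows)
    out = toy_table("out", rows, trait_type="binary")
    flipped_rows = [
        {**r, "effect_allele": r["other_allele"], "other_allele": r["effect_allele"],
         "eaf": 1 - r["eaf"], "beta": -r["beta"]}
        for r in rows
    ]
    out_flipped = toy_table("out", flipped_rows, trait_type="binary")
    h1 = harmonize([exp], out)
    h2 = harmonize([exp], out_flipped)
    assert list(h1.snp_ids) == list(h2.snp_ids)
    np.testing.assert_allclose(h1.beta_out, h2.beta_out, atol=1e-12)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(_random_table_rows(), _random_table_rows())
def test_action_counts_partition_shared_snps(rows_a, rows_b):
    """kept + flipped + dropped_palindromic + dropped_mismatch = shared."""
    exp = toy_table("exp", rows_a)
    out = toy_table("out", rows_b, trait_type="binary")
    shared = set(exp.snp_ids) & set(out.snp_ids)
    if not shared:
        return
    h = harmonize([exp], out)
    assert len(h.actions) == len(shared)
    counts = h.actions["action"].value_counts()
    assert counts.get(KEPT, 0) + counts.get(FLIPPED, 0) == h.k
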