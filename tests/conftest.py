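import numpy as np
import pandas as pd
import pytest

from mrkit.sumstats import GwasTable, HarmonizedSet, make_table


def toy_table(name, rows, trait_type="quantitative") -> GwasTable:
    """Build a GwasTable from a list of dicts with partial columns."""
    return make_table(name, trait_type, pd.DataFrame(rows))


def toy_harmonized(bx, sx, by, sy, snp_ids=None, exposure="x", outcome="y"):
    """Single-exposure HarmonizedSet straight from arrays."""
    bx = np.asarray(bx, dtype=float)
    sx = np.asarray(sx, dtype=float)
    by = np.asarray(by, dtype=float)
    sy = np.asarray(sy, dtype=float)
    if snp_ids is None:
        snp_ids = np.array([f"rs{i + 1}" for i in range(len(bx))], dtype=object)
    else:
        snp_ids = np.asarray(snp_ids, dtype=object)
    return HarmonizedSet(
        outcome_name=outcome,
        exposure_names=[exposure],
        snp_ids=snp_ids,
        beta_exp=bx[:, None],
        se_exp=sx[:, None],
        beta_out=by,
        se_out=sy,
        actions=pd.DataFrame({"snp_id": snp_ids, "action": "kept"}),
    )


@pytest.fixture
def simple_rows():
    return [
        dict(snp_id="rs1", chrom="1", pos=1000, effect_allele="A",
             other_allele="G", eaf=0.3, beta=0.10, se=0.01, pval=1e-20, n=10000),
        dict(snp_id="rs2", chrom="1", pos=2000, effect_allele="C",
             other_allele="T", eaf=0.4, beta=-0.05, se=0.02, pval=1e-6, n=10000),
        dict(snp_id="rs3", chrom="2", pos=3000, effect_allele="G",
             other_allele="A", eaf=0.2, beta=0.02, se=0.01, pval=0.04, n=10000),
    ]
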