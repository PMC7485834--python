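"""Multivariable MR on the five-exposure lipid-style fixture.

Five correlated exposures (hdl, ldl, tg, bmi, menarche) act on a binary
outcome with direct log-OR effects (0.06, 0.04, -0.02, -0.10, -0.04).
Single-trait MR of hdl is confounded by the correlated exposures; MVMR
recovers each direct effect.
"""

import numpy as np

from mrkit import (
    LdMatrix,
    SimulationConfig,
    build_mvmr_set,
    harmonize,
    mr_ivw,
    mvmr_fit,
    mvmr_heterogeneity_prune,
    select_significant,
    simulate_gwas_pair,
)

cfg = SimulationConfig(seed=7)
study = simulate_gwas_pair(cfg)
print("true direct effects:", dict(zip(cfg.exposure_names, cfg.theta)))

# single-trait MR of hdl picks up the total genetically proxied effect
h = harmonize([select_significant(study.exposures[0])], study.outcome)
est, _ = mr_ivw(h)
print(f"\nsingle-trait hdl IVW: beta={est.beta:.3f}"
      " (total effect incl. correlated exposures, not the direct 0.06)")

ld = LdMatrix.identity(study.exposures[0].records["snp_id"])
s = build_mvmr_set(study.exposures, study.outcome, ld)
res = mvmr_fit(s)
print(f"\nMVMR on {s.m} instruments (QA p={res.Q_pval:.2f}):")
print(res.to_frame("outcome")[
    ["exposure", "beta", "se", "or", "ci_low", "ci_high", "pval", "cond_F"]
].round(4).to_string(index=False))

pruned, log = mvmr_heterogeneity_prune(s)
print(f"\ninvalidity pruning removed {len(log.removed)} SNPs; "
      "each beta above should sit within ~2 SE of its true direct effect, "
      "and cond_F >> 10 indicates strong conditional instruments.")
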