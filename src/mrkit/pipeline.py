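"""Config-driven orchestration of the analysis graph.

Each ``run_*`` function executes one analysis end-to-end from a
:class:`RunConfig` — reading inputs, filtering, harmonizing, estimating,
pruning, re-estimating — and writes a report bundle to the output
directory: tidy result TSVs (pre- and post-pruning where pruning applies),
a prune log, and a JSON manifest carrying the package version, the seed,
a hash of the resolved configuration and the count of SNPs entering and
leaving every filtering stage, so a run can be audited and reproduced
bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .exceptions import ConfigError, DataError, MissingMetadataError
from .estimators import (
    mr_egger,
    mr_ivw,
    mr_mode,
    mr_weighted_median,
    results_frame,
    steiger_test,
)
from .instruments import (
    LdMatrix,
    heterogeneity_prune,
    ld_clump,
    select_significant,
)
from .ldsc import LdScorePanel, cross_trait_ldsc
from .locus import (
    load_packaged_loci,
    locus_instruments,
    locus_mr,
    locus_results_frame,
    meta_fixed,
    read_locus_table,
)
from .mvmr import build_mvmr_set, mvmr_fit, mvmr_heterogeneity_prune
from .sumstats import harmonize, read_gwas_table, write_gwas_table
from .locus import gwas_meta

log = logging.getLogger("mrkit")

DEFAULT_ESTIMATORS = ("ivw_mre", "egger", "weighted_median", "mode_weighted")


@dataclass
class RunConfig:
    """Paths, thresholds and switches for one pipeline run."""

    exposure_paths: list = field(default_factory=list)
    outcome_path: str | None = None
    ld_path: str | None = None
    locus_path: str | None = None
    panel_path: str | None = None
    panel_m: int | None = None
    outcome_trait_type: str = "binary"
    exposure_trait_type: str = "quantitative"
    p_instrument: float = 5e-8
    r2_clump: float = 0.001
    q_alpha: float = 0.05
    cross_trait_p: float = 1e-3
    palindrome_eaf_window: float = 0.08
    estimators: tuple = DEFAULT_ESTIMATORS
    n_boot: int = 1000
    prune_heterogeneity: bool = True
    seed: int = 0
    out_dir: str = "mrkit_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _manifest(config: RunConfig, counts: dict, extra: dict | None = None) -> dict:
    doc = {
        "package": "mrkit",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "counts": counts,
    }
    if extra:
        doc.update(extra)
    return doc


def _write_manifest(doc: dict, out: Path):
    (out / "manifest.json").write_text(json.dumps(doc, indent=2, default=str))


def _load_ld(config: RunConfig, table):
    if config.ld_path:
        return LdMatrix.read_tsv(config.ld_path)
    log.info("no LD matrix supplied; assuming independent SNPs")
    return LdMatrix.identity(table.records["snp_id"])


def _read(path, trait_type, name=None):
    if name is None:
        name = Path(path).name.removesuffix(".gz").rsplit(".", 1)[0]
    table, report = read_gwas_table(path, trait_type=trait_type, trait_name=name)
    log.info("%s: %d valid rows (%s dropped)", path, len(table), report.dropped)
    return table, report


def _estimate_all(h, config: RunConfig):
    entries = []
    egger = None
    for method in config.estimators:
        if method in ("ivw_mre", "ivw_fe"):
            model = "fixed" if method == "ivw_fe" else "multiplicative_random"
            entries.append(mr_ivw(h, model=model))
        elif method == "egger":
            if h.k >= 3:
                egger = mr_egger(h)
                entries.append(egger.slope)
        elif method == "weighted_median":
            if h.k >= 3:
                entries.append(
                    mr_weighted_median(h, n_boot=config.n_boot, seed=config.seed)
                )
        elif method in ("mode_weighted", "mode_simple"):
            if h.k >= 3:
                entries.append(
                    mr_mode(
                        h,
                        weighted=method == "mode_weighted",
                        n_boot=config.n_boot,
                        seed=config.seed,
                    )
                )
        else:
            raise ConfigError(f"unknown estimator {method!r}")
    return entries, egger


def _steiger_metadata(exposure, outcome):
    n_exp = exposure.records["n"].dropna()
    ncase = outcome.records["ncase"].dropna()
    nctrl = outcome.records["ncontrol"].dropna()
    if n_exp.empty or ncase.empty or nctrl.empty:
        raise MissingMetadataError("sample sizes unavailable for Steiger test")
    return float(n_exp.median()), float(ncase.median()), float(nctrl.median())


def run_single_trait(config: RunConfig) -> dict:
    """Single-exposure MR: select -> clump -> harmonize -> estimators ->
    diagnostics -> heterogeneity pruning -> re-estimate."""
    if not config.exposure_paths or config.outcome_path is None:
        raise ConfigError("single-trait run needs one exposure and one outcome path")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    exposure, _ = _read(config.exposure_paths[0], config.exposure_trait_type)
    outcome, _ = _read(config.outcome_path, config.outcome_trait_type)
    counts = {"exposure_snps_in": len(exposure), "outcome_snps_in": len(outcome)}

    sig = select_significant(exposure, config.p_instrument)
    counts["significant"] = len(sig)
    ld = _load_ld(config, sig)
    clumped, clump_log = ld_clump(sig, ld, config.r2_clump)
    counts["after_clump"] = len(clumped)
    counts["clump_removed"] = len(clump_log.removed)

    h = harmonize([clumped], outcome, config.palindrome_eaf_window)
    counts["harmonized_kept"] = h.k
    counts["harmonization_actions"] = (
        h.actions["action"].value_counts().to_dict()
    )

    entries, egger = _estimate_all(h, config)
    pre = results_frame(entries, exposure.trait_name, outcome.trait_name)
    pre.to_csv(out / "single_trait_pre_pruning.tsv", sep="\t", index=False)

    extra = {}
    if egger is not None:
        extra["egger_intercept"] = {
            "value": egger.intercept,
            "se": egger.intercept_se,
            "pval": egger.intercept_pval,
        }
    try:
        n_exp, ncase, nctrl = _steiger_metadata(exposure, outcome)
        st = steiger_test(h, n_exp, ncase, nctrl)
        extra["steiger"] = {
            "r2_exposure": st.r2_exposure,
            "r2_outcome": st.r2_outcome,
            "direction_correct": st.direction_correct,
            "pval": st.pval,
        }
    except MissingMetadataError as exc:
        extra["steiger"] = {"skipped": str(exc)}

    if config.prune_heterogeneity and h.k >= 3:
        pruned, prune_log = heterogeneity_prune(h, q_alpha=config.q_alpha)
        counts["heterogeneity_removed"] = len(prune_log.removed)
        counts["post_pruning_k"] = pruned.k
        prune_log.write_tsv(out / "heterogeneity_prune_log.tsv")
        post_entries, _ = _estimate_all(pruned, config)
        post = results_frame(post_entries, exposure.trait_name, outcome.trait_name)
        post.to_csv(out / "single_trait_post_pruning.tsv", sep="\t", index=False)

    doc = _manifest(config, counts, extra)
    _write_manifest(doc, out)
    return doc


def run_mvmr(config: RunConfig) -> dict:
    """Multivariable MR: build joint set -> strength diagnostics -> fit ->
    invalidity pruning -> refit."""
    if len(config.exposure_paths) < 2:
        raise ConfigError("mvmr run needs >= 2 exposure paths")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    exposures = [
        _read(p, config.exposure_trait_type)[0] for p in config.exposure_paths
    ]
    outcome, _ = _read(config.outcome_path, config.outcome_trait_type)
    ld = _load_ld(config, exposures[0])

    s = build_mvmr_set(
        exposures, outcome, ld,
        p_threshold=config.p_instrument,
        r2_threshold=config.r2_clump,
        palindrome_eaf_window=config.palindrome_eaf_window,
    )
    counts = {"instruments": s.m, "exposures": s.n_exposures}
    pre = mvmr_fit(s)
    pre.to_frame(outcome.trait_name).assign(stage="pre_pruning").to_csv(
        out / "mvmr_pre_pruning.tsv", sep="\t", index=False
    )

    pruned, prune_log = mvmr_heterogeneity_prune(s, q_alpha=config.q_alpha)
    counts["invalidity_removed"] = len(prune_log.removed)
    counts["post_pruning_m"] = pruned.m
    prune_log.write_tsv(out / "mvmr_prune_log.tsv")
    post = mvmr_fit(pruned)
    post.to_frame(outcome.trait_name).assign(stage="post_pruning").to_csv(
        out / "mvmr_post_pruning.tsv", sep="\t", index=False
    )

    doc = _manifest(config, counts)
    _write_manifest(doc, out)
    return doc


def run_locus(config: RunConfig) -> dict:
    """Locus-specific fixed-effects MR with cross-locus meta-analysis."""
    if not config.exposure_paths or config.outcome_path is None:
        raise ConfigError("locus run needs a conditional exposure table and an outcome")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    conditional, _ = _read(config.exposure_paths[0], config.exposure_trait_type)
    outcome, _ = _read(config.outcome_path, config.outcome_trait_type)
    loci = (
        read_locus_table(config.locus_path)
        if config.locus_path
        else load_packaged_loci()
    )

    estimates, excluded = [], []
    for locus in loci:
        h = locus_instruments(
            conditional, outcome, locus, config.palindrome_eaf_window
        )
        if h is None:
            excluded.append(locus.locus_name)
            continue
        estimates.append(locus_mr(h, locus.locus_name))
    counts = {
        "loci_in": len(loci),
        "loci_estimated": len(estimates),
        "loci_excluded": excluded,
    }
    if not estimates:
        doc = _manifest(config, counts, {"status": "empty: all loci excluded"})
        _write_manifest(doc, out)
        return doc

    pooled = meta_fixed(estimates) if len(estimates) >= 2 else None
    frame = locus_results_frame(estimates, pooled, outcome.trait_name)
    frame.to_csv(out / "locus_mr.tsv", sep="\t", index=False)
    doc = _manifest(config, counts, {"status": "ok"})
    _write_manifest(doc, out)
    return doc


def run_gwas_meta(config: RunConfig) -> dict:
    """Per-SNP fixed-effects meta-analysis of two GWASs."""
    if len(config.exposure_paths) != 2:
        raise ConfigError("gwas-meta run needs exactly 2 study paths")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    a, _ = _read(config.exposure_paths[0], config.exposure_trait_type)
    b, _ = _read(config.exposure_paths[1], config.exposure_trait_type)
    merged = gwas_meta(a, b, config.palindrome_eaf_window)
    write_gwas_table(merged, out / "gwas_meta.tsv")
    counts = {
        "study_a": len(a),
        "study_b": len(b),
        "meta_status": merged.records["meta_status"].value_counts().to_dict(),
    }
    doc = _manifest(config, counts)
    _write_manifest(doc, out)
    return doc


def run_ldsc(config: RunConfig) -> dict:
    """Cross-trait LD-score regression from two sumstats tables aligned to
    a panel TSV (snp_id, ld_score) with total SNP count ``panel_m``."""
    if len(config.exposure_paths) != 2 or not config.panel_path:
        raise ConfigError("ldsc run needs 2 sumstats paths and a panel path")
    if not config.panel_m:
        raise ConfigError("ldsc run needs panel_m (total SNPs the panel represents)")
    import pandas as pd

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t1, _ = _read(config.exposure_paths[0], config.exposure_trait_type)
    t2, _ = _read(config.exposure_paths[1], config.exposure_trait_type)
    panel_df = pd.read_csv(config.panel_path, sep="\t")
    panel = LdScorePanel(
        snp_ids=list(panel_df["snp_id"]),
        ld_score=panel_df["ld_score"].to_numpy(),
        M=int(config.panel_m),
    )
    ix1 = t1.indexed().reindex(panel.snp_ids)
    ix2 = t2.indexed().reindex(panel.snp_ids)
    if ix1["beta"].isna().any() or ix2["beta"].isna().any():
        raise DataError("panel SNPs missing from sumstats")
    n1 = float(ix1["n"].median())
    n2 = float(ix2["n"].median())
    if not (n1 > 0 and n2 > 0):
        raise MissingMetadataError("sample-size column required for LDSC")
    fit = cross_trait_ldsc(
        (ix1["beta"] / ix1["se"]).to_numpy(),
        (ix2["beta"] / ix2["se"]).to_numpy(),
        n1, n2, panel,
    )
    doc = _manifest(config, {"panel_snps": len(panel)}, {"ldsc": asdict(fit)})
    _write_manifest(doc, out)
    return doc


def run_simulate(config: RunConfig, sim_config_path=None) -> dict:
    """Generate a synthetic study and write its tables."""
    from .simulate import SimulationConfig, simulate_gwas_pair

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = (
        SimulationConfig.from_yaml(sim_config_path)
        if sim_config_path
        else SimulationConfig(seed=config.seed)
    )
    study = simulate_gwas_pair(sim)
    for table in study.exposures:
        write_gwas_table(table, out / f"exposure_{table.trait_name}.tsv")
    write_gwas_table(study.outcome, out / "outcome.tsv")
    counts = {
        "m_snps": sim.m_snps,
        "exposures": list(sim.exposure_names),
        "realized_r2": [float(x) for x in study.true_model.realized_r2],
    }
    doc = _manifest(config, counts)
    _write_manifest(doc, out)
    return doc
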