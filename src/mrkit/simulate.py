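"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator works entirely at the summary level (no individual-level
genotypes): per-SNP true effects on K correlated exposures are drawn from
a correlated spike-and-slab, the true per-SNP effect on a binary outcome
is the causal combination sum_k theta_k * beta_jk plus an optional direct
(pleiotropic) effect, and observed betas add independent two-sample
estimation noise at the configured sample sizes:

    se_Xjk = 1 / sqrt(2 f_j (1 - f_j) n_k)                (SD-unit exposure)
    se_Yj  = 1 / sqrt(2 f_j (1 - f_j) N phi (1 - phi))    (log-OR outcome)

with f_j the effect-allele frequency, N = ncase + ncontrol and phi the
case fraction.  The spike (causal SNP set) is shared across exposures and
the slab effects are multivariate normal with the configured correlation
matrix, so the realized correlation of the true effect vectors equals the
configured one in expectation; effects are rescaled so the realized
variance explained per exposure equals h2_x exactly.  Optional LD is
block-structured: constant r^2 within consecutive blocks, with marginal
effects and correlated noise to match.

The default configuration is a five-exposure study (hdl, ldl, tg, bmi,
menarche) with HDL and triglycerides negatively correlated, causal log-OR
effects (0.06, 0.04, -0.02, -0.10, -0.04), 2,000 SNPs, exposure GWASs of
200,000 and a 120,000-case / 100,000-control outcome.

Everything is drawn from one seeded generator; identical configs produce
byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError
from .instruments import LdMatrix
from .ldsc import LdScorePanel
from .sumstats import GwasTable, make_table

_DEFAULT_NAMES = ("hdl", "ldl", "tg", "bmi", "menarche")
_DEFAULT_THETA = (0.06, 0.04, -0.02, -0.10, -0.04)
_DEFAULT_CORR = (
    (1.00, 0.20, -0.50, -0.30, 0.10),
    (0.20, 1.00, 0.30, 0.10, 0.00),
    (-0.50, 0.30, 1.00, 0.30, -0.10),
    (-0.30, 0.10, 0.30, 1.00, -0.30),
    (0.10, 0.00, -0.10, -0.30, 1.00),
)


@dataclass
class PleiotropyConfig:
    """Direct (exposure-bypassing) SNP effects on the outcome."""

    prop_invalid: float = 0.0
    mean_direct_effect: float = 0.0
    sd_direct_effect: float = 0.0
    inside_violated: bool = False

    def __post_init__(self):
        if not (0 <= self.prop_invalid <= 1):
            raise ConfigError("prop_invalid must lie in [0, 1]")
        if self.sd_direct_effect < 0:
            raise ConfigError("sd_direct_effect must be >= 0")


@dataclass
class SimulationConfig:
    m_snps: int = 2000
    maf_range: tuple = (0.05, 0.5)
    exposure_names: tuple = _DEFAULT_NAMES
    prop_causal: tuple | float = 0.05
    h2_x: tuple | float = 0.05
    effect_corr: tuple = _DEFAULT_CORR
    theta: tuple = _DEFAULT_THETA
    pleiotropy: PleiotropyConfig = field(default_factory=PleiotropyConfig)
    n_exposure: tuple | int = 200_000
    n_case: int = 120_000
    n_control: int = 100_000
    ld_block_size: int | None = None
    ld_r2: float = 0.0
    seed: int = 0

    @property
    def n_exposures(self) -> int:
        return len(self.exposure_names)

    def __post_init__(self):
        k = self.n_exposures
        if np.isscalar(self.prop_causal):
            self.prop_causal = (float(self.prop_causal),) * k
        if np.isscalar(self.h2_x):
            self.h2_x = (float(self.h2_x),) * k
        if np.isscalar(self.n_exposure):
            self.n_exposure = (int(self.n_exposure),) * k
        for name, seq in (
            ("prop_causal", self.prop_causal),
            ("h2_x", self.h2_x),
            ("n_exposure", self.n_exposure),
            ("theta", self.theta),
        ):
            if len(seq) != k:
                raise ConfigError(f"{name} length must equal number of exposures ({k})")
        if any(not (0 <= p <= 1) for p in self.prop_causal):
            raise ConfigError("prop_causal values must lie in [0, 1]")
        if any(not (0 <= h < 1) for h in self.h2_x):
            raise ConfigError("h2_x values must lie in [0, 1)")
        corr = np.asarray(self.effect_corr, dtype=float)
        if corr.shape != (k, k):
            raise ConfigError("effect_corr must be K x K")
        if not np.allclose(corr, corr.T):
            raise ConfigError("effect_corr must be symmetric")
        if np.linalg.eigvalsh(corr).min() < -1e-8:
            raise ConfigError("effect_corr must be positive semidefinite")
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 1):
            raise ConfigError("maf_range must satisfy 0 < low <= high < 1")
        if self.ld_block_size is not None and not (0 <= self.ld_r2 < 1):
            raise ConfigError("ld_r2 must lie in [0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "pleiotropy" in raw:
            raw["pleiotropy"] = PleiotropyConfig(**raw["pleiotropy"])
        for key in ("maf_range", "exposure_names", "theta", "effect_corr",
                    "prop_causal", "h2_x", "n_exposure"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(
                    tuple(v) if isinstance(v, list) else v for v in raw[key]
                )
        return cls(**raw)


@dataclass
class TrueModel:
    """Ground truth underlying one synthetic study."""

    maf: np.ndarray            # (m,)
    beta_x: np.ndarray         # (m, K) true (conditional) exposure effects
    direct_effect: np.ndarray  # (m,) pleiotropic outcome effects
    causal: np.ndarray         # (m, K) bool causal indicator
    valid: np.ndarray          # (m,) bool: no direct effect
    realized_r2: np.ndarray    # (K,) variance explained per exposure

    @property
    def true_outcome_effect(self):
        raise AttributeError("use SyntheticStudy.eta for the outcome effects")


@dataclass
class SyntheticStudy:
    config: SimulationConfig
    exposures: list            # list[GwasTable], one per exposure
    outcome: GwasTable
    true_model: TrueModel
    eta: np.ndarray            # (m,) true per-SNP log-OR on the outcome
    ld: LdMatrix | None = None  # None when no block LD was configured

    def harmonized(self, exposure: int = 0, mask=None):
        """HarmonizedSet for one exposure straight from the generator's
        arrays (all tables share one allele orientation by construction, so
        no allele reconciliation is needed).  ``mask`` selects instruments.
        """
        from .sumstats import KEPT, HarmonizedSet

        e = self.exposures[exposure].records
        o = self.outcome.records
        if mask is None:
            mask = np.ones(len(e), dtype=bool)
        mask = np.asarray(mask)
        snp_ids = e["snp_id"].to_numpy()[mask]
        return HarmonizedSet(
            outcome_name=self.outcome.trait_name,
            exposure_names=[self.exposures[exposure].trait_name],
            snp_ids=snp_ids,
            beta_exp=e["beta"].to_numpy()[mask][:, None],
            se_exp=e["se"].to_numpy()[mask][:, None],
            beta_out=o["beta"].to_numpy()[mask],
            se_out=o["se"].to_numpy()[mask],
            actions=pd.DataFrame({"snp_id": snp_ids, "action": KEPT}),
            pval_exp=e["pval"].to_numpy()[mask][:, None],
            eaf=e["eaf"].to_numpy()[mask],
        )


def _draw_effects(config: SimulationConfig, rng: np.random.Generator) -> TrueModel:
    m, k = config.m_snps, config.n_exposures
    maf = rng.uniform(*config.maf_range, size=m)
    beta = np.zeros((m, k))
    causal = np.zeros((m, k), dtype=bool)

    n_causal = [int(round(p * m)) for p in config.prop_causal]
    shared_n = min(n_causal)
    perm = rng.permutation(m)
    shared = perm[:shared_n]
    if shared_n:
        corr = np.asarray(config.effect_corr, dtype=float)
        # eigen route tolerates PSD-but-singular matrices
        vals, vecs = np.linalg.eigh(corr)
        L = vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None)))
        beta[shared] = rng.standard_normal((shared_n, k)) @ L.T
        causal[shared] = True
    cursor = shared_n
    for j in range(k):
        extra = n_causal[j] - shared_n
        if extra > 0:
            idx = perm[cursor: cursor + extra]
            cursor += extra
            beta[idx, j] = rng.standard_normal(extra)
            causal[idx, j] = True

    var_per_snp = 2.0 * maf * (1.0 - maf)
    realized = np.zeros(k)
    for j in range(k):
        if config.h2_x[j] == 0:
            beta[:, j] = 0.0
            causal[:, j] = False
            continue
        raw = float(np.sum(var_per_snp * beta[:, j] ** 2))
        if raw > 0:
            beta[:, j] *= np.sqrt(config.h2_x[j] / raw)
        realized[j] = float(np.sum(var_per_snp * beta[:, j] ** 2))

    direct = np.zeros(m)
    ple = config.pleiotropy
    union = np.where(causal.any(axis=1))[0]
    n_invalid = int(round(ple.prop_invalid * len(union)))
    if n_invalid > 0:
        invalid = rng.choice(union, size=n_invalid, replace=False)
        noise = rng.standard_normal(n_invalid)
        if ple.inside_violated and n_invalid > 1:
            strength = np.abs(beta[invalid, 0])
            s = (strength - strength.mean()) / (strength.std() or 1.0)
            mix = 0.7 * s + np.sqrt(1 - 0.49) * noise
        else:
            mix = noise
        # directional pleiotropy is defined per exposure-raising allele of
        # the first exposure; otherwise a nonzero mean would cancel under
        # the arbitrary allele orientation of a GWAS table
        orient = np.sign(beta[invalid, 0])
        orient[orient == 0] = 1.0
        direct[invalid] = orient * (
            ple.mean_direct_effect + ple.sd_direct_effect * mix
        )

    return TrueModel(
        maf=maf,
        beta_x=beta,
        direct_effect=direct,
        causal=causal,
        valid=direct == 0.0,
        realized_r2=realized,
    )


def simulate_effects(config: SimulationConfig) -> TrueModel:
    """Draw the ground-truth model only (no sampling noise)."""
    return _draw_effects(config, np.random.default_rng(config.seed))


def _ld_blocks(config: SimulationConfig):
    m, size = config.m_snps, config.ld_block_size
    starts = range(0, m, size)
    return [np.arange(s, min(s + size, m)) for s in starts]


def _build_ld_matrix(config: SimulationConfig, snp_ids) -> LdMatrix:
    m = config.m_snps
    mat = np.eye(m)
    for block in _ld_blocks(config):
        ix = np.ix_(block, block)
        sub = np.full((len(block), len(block)), config.ld_r2)
        np.fill_diagonal(sub, 1.0)
        mat[ix] = sub
    return LdMatrix(list(snp_ids), mat)


def _marginalize(values: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Marginal effects under block LD: R @ beta with r = sqrt(r2)."""
    out = values.astype(float).copy()
    r = np.sqrt(config.ld_r2)
    for block in _ld_blocks(config):
        v = values[block]
        out[block] = (1 - r) * v + r * v.sum()
    return out


def _correlated_noise(m: int, config: SimulationConfig, rng) -> np.ndarray:
    z = rng.standard_normal(m)
    if config.ld_block_size is None or config.ld_r2 == 0:
        return z
    r = np.sqrt(config.ld_r2)
    out = z.copy()
    for block in _ld_blocks(config):
        shared = rng.standard_normal()
        out[block] = np.sqrt(1 - r) * z[block] + np.sqrt(r) * shared
    return out


def _sumstats_frame(snp_ids, pos, maf, beta_hat, se, n=None, ncase=None, ncontrol=None):
    from scipy import stats as _st

    z = beta_hat / se
    df = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": "1",
            "pos": pos,
            "effect_allele": "A",
            "other_allele": "G",
            "eaf": maf,
            "beta": beta_hat,
            "se": se,
            "pval": np.maximum(2 * _st.norm.sf(np.abs(z)), np.finfo(float).tiny),
        }
    )
    if n is not None:
        df["n"] = n
    if ncase is not None:
        df["ncase"] = ncase
        df["ncontrol"] = ncontrol
    return df


def simulate_gwas_pair(config: SimulationConfig) -> SyntheticStudy:
    """Generate one synthetic two-sample study.

    Exposure and outcome sampling noise are independent (two-sample
    design); the exposure GWASs are quantitative (SD units), the outcome a
    case-control GWAS on the log-OR scale.
    """
    rng = np.random.default_rng(config.seed)
    model = _draw_effects(config, rng)
    m, k = config.m_snps, config.n_exposures
    maf = model.maf
    var_snp = 2.0 * maf * (1.0 - maf)
    snp_ids = np.array([f"rs{i + 1}" for i in range(m)], dtype=object)
    pos = np.arange(1, m + 1) * 10_000

    theta = np.asarray(config.theta, dtype=float)
    eta = model.beta_x @ theta + model.direct_effect

    with_ld = config.ld_block_size is not None and config.ld_r2 > 0
    exposures = []
    for j in range(k):
        se_x = 1.0 / np.sqrt(var_snp * config.n_exposure[j])
        true_marg = _marginalize(model.beta_x[:, j], config) if with_ld else model.beta_x[:, j]
        noise = _correlated_noise(m, config, rng) if with_ld else rng.standard_normal(m)
        beta_hat = true_marg + se_x * noise
        frame = _sumstats_frame(
            snp_ids, pos, maf, beta_hat, se_x, n=config.n_exposure[j]
        )
        exposures.append(
            make_table(config.exposure_names[j], "quantitative", frame)
        )

    n_total = config.n_case + config.n_control
    phi = config.n_case / n_total
    se_y = 1.0 / np.sqrt(var_snp * n_total * phi * (1 - phi))
    true_marg_y = _marginalize(eta, config) if with_ld else eta
    noise_y = _correlated_noise(m, config, rng) if with_ld else rng.standard_normal(m)
    beta_hat_y = true_marg_y + se_y * noise_y
    out_frame = _sumstats_frame(
        snp_ids, pos, maf, beta_hat_y, se_y,
        n=n_total, ncase=config.n_case, ncontrol=config.n_control,
    )
    outcome = make_table("outcome", "binary", out_frame)

    # a dense identity matrix at large m is pure waste; ld is None unless
    # block LD was actually requested
    ld = _build_ld_matrix(config, snp_ids) if with_ld else None
    return SyntheticStudy(
        config=config,
        exposures=exposures,
        outcome=outcome,
        true_model=model,
        eta=eta,
        ld=ld,
    )


def simulate_ldsc_panel(
    m_snps: int,
    M: int,
    h2_1: float,
    h2_2: float,
    r_g: float,
    n1: float,
    n2: float,
    n_blocks_ld: int | None = None,
    seed: int = 0,
):
    """Simulated z-scores for two traits under the LD-score model.

    LD scores are drawn from a right-skewed distribution >= 1 (optionally
    constant within ``n_blocks_ld`` consecutive blocks); per-SNP aggregate
    standardized effects are bivariate normal with variance n h2 l_j / M
    and correlation ``r_g``; sampling noise is unit normal.

    Returns (z1, z2, LdScorePanel).
    """
    if not (-1 <= r_g <= 1):
        raise ConfigError("r_g must lie in [-1, 1]")
    if not (0 <= h2_1 < 1 and 0 <= h2_2 < 1):
        raise ConfigError("heritabilities must lie in [0, 1)")
    if M < m_snps:
        raise ConfigError("M must be >= m_snps")
    rng = np.random.default_rng(seed)
    if n_blocks_ld:
        per_block = rng.gamma(shape=2.0, scale=15.0, size=n_blocks_ld)
        reps = int(np.ceil(m_snps / n_blocks_ld))
        ell = 1.0 + np.repeat(per_block, reps)[:m_snps]
    else:
        ell = 1.0 + rng.gamma(shape=2.0, scale=15.0, size=m_snps)

    cov = np.array([[1.0, r_g], [r_g, 1.0]])
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(2))
    u = rng.standard_normal((m_snps, 2)) @ L.T
    z1 = np.sqrt(n1 * h2_1 * ell / M) * u[:, 0] + rng.standard_normal(m_snps)
    z2 = np.sqrt(n2 * h2_2 * ell / M) * u[:, 1] + rng.standard_normal(m_snps)
    panel = LdScorePanel(
        snp_ids=[f"rs{i + 1}" for i in range(m_snps)], ld_score=ell, M=M
    )
    return z1, z2, panel
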