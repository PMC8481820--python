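"""Paired synthetic GWAS summary statistics under a bivariate polygenic model.

The generator emulates the data-generating process the downstream analyses
assume: a small fraction of SNPs (polygenicity pi) carries normally
distributed causal effects (variance = discoverability sigma_beta^2) on
standardized genotypes; a fraction pi12 of causal SNPs is shared between the
two traits with effect correlation rho_beta; marginal GWAS effects are the
within-block LD convolution of the causal effects; and the observed Z-scores
add LD-correlated sampling noise whose cross-trait correlation r0 models
sample overlap. An optional directional term b_xy makes trait-1 liability
causal for trait 2, so the Mendelian-randomization stage has a ground truth.

All randomness flows through named substreams of one global seed, so adding
a stage never perturbs earlier draws.

Scale conventions: se = 1/sqrt(n) and beta = z/sqrt(n) (standardized
genotype and phenotype), so SNP heritability is h2 = M * pi * sigma_beta^2.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .panel import ReferencePanel, compute_ld_scores
from .sumstats import CANONICAL_COLUMNS, SumStats

__all__ = [
    "PanelConfig",
    "SimulationConfig",
    "TruthRecord",
    "SimulatedPair",
    "make_reference_panel",
    "simulate_pair",
    "truth_summary",
    "make_gene_annotation",
    "make_gene_sets",
]


def substream(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-stage RNG derived from one global seed and a label."""
    key = zlib.crc32(label.encode())
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


@dataclass
class PanelConfig:
    """Shape of the synthetic LD reference.

    Blocks are AR(1) correlation matrices r_ij = ld_rho^|i-j|; alt-allele
    frequencies are uniform on ``af_range``. SNPs are laid out on up to 22
    chromosomes at ``spacing_bp`` intervals, blocks contiguous.
    """

    m_snps: int = 20_000
    block_size: int = 50
    ld_rho: float = 0.6
    ld_rho_range: tuple[float, float] | None = (0.0, 0.9)
    af_range: tuple[float, float] = (0.05, 0.5)
    spacing_bp: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.ld_rho < 1:
            raise ConfigError(f"ld_rho must be in [0, 1), got {self.ld_rho}")
        if self.ld_rho_range is not None:
            lo, hi = self.ld_rho_range
            if not 0 <= lo <= hi < 1:
                raise ConfigError(f"ld_rho_range must lie in [0, 1), got {self.ld_rho_range}")
        if self.m_snps < 1 or self.block_size < 1:
            raise ConfigError("m_snps and block_size must be positive")


@dataclass
class SimulationConfig:
    """Bivariate polygenic architecture of the simulated trait pair.

    pi1, pi2: per-trait causal fractions; pi12 <= min(pi1, pi2) shared.
    sigma_b1_sq, sigma_b2_sq: causal effect-size variances (standardized
    scale), so h2_i = M * pi_i * sigma_bi_sq.
    rho_beta: effect correlation among shared causal SNPs.
    n1, n2: GWAS sample sizes.
    r0: cross-trait correlation of null Z-scores induced by sample overlap.
        For two case-control studies sharing n_s controls, roughly
        r0 ~= n_s / sqrt(n1 * n2) scaled by the case/control balance of each
        study; r0 is parameterized directly because it is the quantity the
        overlap-corrected meta-analysis consumes.
    b_xy: directional causal effect of trait-1 liability on trait 2
        (0 = purely pleiotropic scenario).
    """

    pi1: float = 0.01
    pi2: float = 0.01
    pi12: float = 0.005
    sigma_b1_sq: float = 6e-4
    sigma_b2_sq: float = 6e-4
    rho_beta: float = 0.6
    n1: float = 100_000
    n2: float = 100_000
    r0: float = 0.0
    b_xy: float = 0.0
    seed: int = 0

    def validate(self, m_snps: int) -> None:
        if not 0 <= self.pi12 <= min(self.pi1, self.pi2):
            raise ConfigError("pi12 must satisfy 0 <= pi12 <= min(pi1, pi2)")
        if not -1 <= self.rho_beta <= 1:
            raise ConfigError("rho_beta must be in [-1, 1]")
        if not -1 < self.r0 < 1:
            raise ConfigError("r0 must be in (-1, 1)")
        for pi, sig, tag in ((self.pi1, self.sigma_b1_sq, "1"), (self.pi2, self.sigma_b2_sq, "2")):
            h2 = m_snps * pi * sig
            if h2 > 1:
                raise ConfigError(f"implied heritability of trait {tag} is {h2:.3f} > 1")


@dataclass
class TruthRecord:
    """Generating parameters in the units the estimators target."""

    h2_1: float
    h2_2: float
    rg_true: float
    r0: float
    b_xy: float
    causal_ids_1: list[str] = field(default_factory=list)
    causal_ids_2: list[str] = field(default_factory=list)

    @property
    def n_causal_1(self) -> int:
        return len(self.causal_ids_1)

    @property
    def n_causal_2(self) -> int:
        return len(self.causal_ids_2)


@dataclass
class SimulatedPair:
    ss1: SumStats
    ss2: SumStats
    panel: ReferencePanel
    truth: TruthRecord


# ---------------------------------------------------------------------------


def make_reference_panel(cfg: PanelConfig) -> ReferencePanel:
    """Build an AR(1)-block synthetic LD panel; deterministic given cfg.seed.

    With ``ld_rho_range`` set (the default), each block's AR(1) parameter is
    drawn uniformly from the range, giving the heterogeneous LD-score
    distribution that identifies LD-score regression; with
    ``ld_rho_range=None`` every block uses the constant ``ld_rho``.
    """
    rng = substream(cfg.seed, "panel")
    m = cfg.m_snps
    n_blocks = (m + cfg.block_size - 1) // cfg.block_size
    block_id = np.repeat(np.arange(n_blocks), cfg.block_size)[:m]

    n_chrom = min(22, n_blocks)
    blocks_per_chrom = (n_blocks + n_chrom - 1) // n_chrom
    chrom_of_block = 1 + np.arange(n_blocks) // blocks_per_chrom
    chrom = chrom_of_block[block_id]
    pos = np.empty(m, dtype=int)
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        pos[idx] = 1 + np.arange(len(idx)) * cfg.spacing_bp

    af = rng.uniform(*cfg.af_range, size=m)
    bases = np.array(list("ACGT"))
    ref_i = rng.integers(0, 4, size=m)
    alt_i = (ref_i + rng.integers(1, 4, size=m)) % 4

    variants = pd.DataFrame(
        {
            "snp_id": [f"rs{i + 1}" for i in range(m)],
            "chrom": chrom,
            "pos": pos,
            "ref_allele": bases[ref_i],
            "alt_allele": bases[alt_i],
            "af": af,
            "block_id": block_id,
        }
    )
    if cfg.ld_rho_range is None:
        rhos = np.full(n_blocks, cfg.ld_rho)
    else:
        rhos = rng.uniform(*cfg.ld_rho_range, size=n_blocks)
    blocks: dict[int, np.ndarray] = {}
    for bid in range(n_blocks):
        size = int((block_id == bid).sum())
        ii = np.arange(size)
        blocks[bid] = rhos[bid] ** np.abs(ii[:, None] - ii[None, :])
    ld_scores = compute_ld_scores(variants, blocks)
    return ReferencePanel(variants=variants, blocks=blocks, ld_scores=ld_scores)


def truth_summary(cfg: SimulationConfig, panel: ReferencePanel) -> TruthRecord:
    """Closed-form heritabilities and genetic correlation, no sampling.

    With b_xy = 0: h2_i = M pi_i sigma_bi^2 and
    rg = pi12 rho_beta / sqrt(pi1 pi2). A nonzero b_xy adds b_xy * gamma_1
    to every trait-2 joint effect, which feeds through both the trait-2
    variance and the cross-trait covariance.
    """
    cfg.validate(panel.n_snps)
    m = panel.n_snps
    s1, s2 = cfg.sigma_b1_sq, cfg.sigma_b2_sq
    cross = cfg.pi12 * cfg.rho_beta * np.sqrt(s1 * s2)
    h2_1 = m * cfg.pi1 * s1
    var2 = cfg.pi2 * s2 + cfg.b_xy**2 * cfg.pi1 * s1 + 2 * cfg.b_xy * cross
    cov = cross + cfg.b_xy * cfg.pi1 * s1
    h2_2 = m * var2
    rg = 0.0 if (h2_1 <= 0 or h2_2 <= 0) else cov / np.sqrt(cfg.pi1 * s1 * var2)
    return TruthRecord(h2_1=float(h2_1), h2_2=float(h2_2), rg_true=float(rg),
                       r0=cfg.r0, b_xy=cfg.b_xy)


def simulate_pair(cfg: SimulationConfig, panel: ReferencePanel) -> SimulatedPair:
    """Draw one paired set of summary statistics; deterministic given seeds.

    Per SNP the causal status is one of {neither, trait-1 only, trait-2
    only, both} with probabilities (1-pi1-pi2+pi12, pi1-pi12, pi2-pi12,
    pi12). Shared effects are bivariate normal with correlation rho_beta.
    With b_xy != 0 the trait-2 joint effect becomes
    gamma_2 = b_xy * gamma_1 + gamma_2_specific. Marginal effects are the
    within-block LD convolution R gamma, and
    z_i = sqrt(n_i) R gamma_i + eps_i with eps ~ N(0, R) per block and
    corr(eps_1j, eps_2j) = r0.
    """
    cfg.validate(panel.n_snps)
    m = panel.n_snps
    rng_status = substream(cfg.seed, "causal-status")
    rng_eff = substream(cfg.seed, "causal-effects")
    rng_noise = substream(cfg.seed, "noise")

    u = rng_status.uniform(size=m)
    p_both, p_1, p_2 = cfg.pi12, cfg.pi1 - cfg.pi12, cfg.pi2 - cfg.pi12
    both = u < p_both
    only1 = (u >= p_both) & (u < p_both + p_1)
    only2 = (u >= p_both + p_1) & (u < p_both + p_1 + p_2)
    causal1, causal2 = both | only1, both | only2

    g1 = np.zeros(m)
    g2_specific = np.zeros(m)
    s1, s2 = np.sqrt(cfg.sigma_b1_sq), np.sqrt(cfg.sigma_b2_sq)
    # shared causals: bivariate normal with correlation rho_beta
    nb = int(both.sum())
    z_a = rng_eff.standard_normal(nb)
    z_b = rng_eff.standard_normal(nb)
    g1[both] = s1 * z_a
    g2_specific[both] = s2 * (cfg.rho_beta * z_a + np.sqrt(1 - cfg.rho_beta**2) * z_b)
    g1[only1] = s1 * rng_eff.standard_normal(int(only1.sum()))
    g2_specific[only2] = s2 * rng_eff.standard_normal(int(only2.sum()))
    g2 = cfg.b_xy * g1 + g2_specific

    # block-wise LD convolution and correlated noise
    delta1 = np.empty(m)
    delta2 = np.empty(m)
    e1 = np.empty(m)
    e2 = np.empty(m)
    bids = panel.variants["block_id"].to_numpy()
    sorted_blocks = bool(np.all(np.diff(bids) >= 0))
    r0c = np.sqrt(1 - cfg.r0**2)
    for bid, mat in panel.blocks.items():
        if sorted_blocks:
            lo, hi = np.searchsorted(bids, [bid, bid + 1])
            idx = np.arange(lo, hi)
        else:
            idx = np.flatnonzero(bids == bid)
        chol = np.linalg.cholesky(mat + 1e-10 * np.eye(mat.shape[0]))
        delta1[idx] = mat @ g1[idx]
        delta2[idx] = mat @ g2[idx]
        a = chol @ rng_noise.standard_normal(len(idx))
        b = chol @ rng_noise.standard_normal(len(idx))
        e1[idx] = a
        e2[idx] = cfg.r0 * a + r0c * b

    z1 = np.sqrt(cfg.n1) * delta1 + e1
    z2 = np.sqrt(cfg.n2) * delta2 + e2

    truth = truth_summary(cfg, panel)
    snp_ids = panel.variants["snp_id"].to_numpy()
    truth.causal_ids_1 = list(snp_ids[causal1])
    truth.causal_ids_2 = list(snp_ids[causal2])

    ss1 = _to_sumstats(panel, z1, cfg.n1, "trait1", cfg.seed)
    ss2 = _to_sumstats(panel, z2, cfg.n2, "trait2", cfg.seed)
    return SimulatedPair(ss1=ss1, ss2=ss2, panel=panel, truth=truth)


def _to_sumstats(panel: ReferencePanel, z: np.ndarray, n: float,
                 label: str, seed: int) -> SumStats:
    v = panel.variants
    se = 1.0 / np.sqrt(n)
    df = pd.DataFrame(
        {
            "snp_id": v["snp_id"],
            "chrom": v["chrom"],
            "pos": v["pos"],
            "effect_allele": v["alt_allele"],
            "other_allele": v["ref_allele"],
            "eaf": v["af"],
            "beta": z * se,
            "se": se,
            "pval": 2.0 * stats.norm.sf(np.abs(z)),
            "z": z,
            "n": float(n),
            "n_cases": np.nan,
            "n_controls": np.nan,
        }
    )
    return SumStats(trait_label=label, table=df[CANONICAL_COLUMNS],
                    provenance=f"simulated(seed={seed})")


# ---------------------------------------------------------------------------
# synthetic annotation for the gene-based stages


def make_gene_annotation(panel: ReferencePanel, snps_per_gene: int = 25,
                         pad_bp: int = 1) -> pd.DataFrame:
    """Tile synthetic genes over the panel so every SNP falls in one gene.

    Returns a BED-like frame (gene_id, chrom, start, end, strand) with
    1-based closed intervals. Genes never span LD blocks more than the SNP
    layout does; this is a synthetic annotation for pipeline exercise, not a
    real gene map.
    """
    rows = []
    gid = 0
    for c in sorted(panel.variants["chrom"].unique()):
        sub = panel.variants[panel.variants["chrom"] == c].sort_values("pos")
        pos = sub["pos"].to_numpy()
        for i in range(0, len(pos), snps_per_gene):
            chunk = pos[i:i + snps_per_gene]
            gid += 1
            rows.append((f"GENE{gid:05d}", int(c), int(chunk[0] - pad_bp),
                         int(chunk[-1] + pad_bp), "+"))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def make_gene_sets(gene_ids: list[str], n_sets: int, set_size: int,
                   seed: int) -> dict[str, list[str]]:
    """Random gene sets (null membership) for calibration exercises."""
    rng = substream(seed, "gene-sets")
    out = {}
    for s in range(n_sets):
        members = rng.choice(gene_ids, size=min(set_size, len(gene_ids)), replace=False)
        out[f"SET{s + 1:05d}"] = sorted(members.tolist())
    return out
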