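"""Gene-based association, pleiotropic-gene prioritization, set enrichment.

SNP-level results are aggregated per gene by summing squared Z-scores over
the SNPs assigned to the gene (a symmetric window around the gene body).
Under the null the statistic S = sum z_j^2 is a mixture sum_i lambda_i
chi2_1 with lambda_i the eigenvalues of the SNPs' LD correlation matrix;
the tail is evaluated with a Satterthwaite/Brown moment-matched scaled
chi-square (exact when the LD matrix is the identity), with an optional
Monte-Carlo mode for verification on small genes.

Pleiotropic genes are prioritized by a triple threshold: genome-wide gene
significance in the cross-trait meta-analysis plus suggestive association
in both single-trait analyses. Competitive gene-set enrichment regresses
the probit-transformed gene p-value on set membership with SNP-count and
gene-length covariates, one-sided for enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import ConfigError, DataError
from .panel import ReferencePanel
from .sumstats import SumStats

logger = logging.getLogger(__name__)

__all__ = [
    "GeneAnnotation",
    "GeneResult",
    "GeneSet",
    "EnrichmentResult",
    "read_gene_annotation",
    "read_gmt",
    "assign_snps_to_genes",
    "gene_test",
    "bonferroni_threshold",
    "pleiotropy_filter",
    "geneset_enrichment",
    "gene_table",
]

_P_CLIP_LO = 1e-300
_P_CLIP_HI = 1.0 - 1e-16


@dataclass
class GeneAnnotation:
    gene_id: str
    chrom: int
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")


@dataclass
class GeneResult:
    gene_id: str
    n_snps: int
    stat: float
    pval_meta: float
    pval_a: float | None = None
    pval_b: float | None = None


@dataclass
class GeneSet:
    set_id: str
    members: list[str]

    def __post_init__(self) -> None:
        self.members = list(dict.fromkeys(self.members))


@dataclass
class EnrichmentResult:
    set_id: str
    beta_s: float
    beta_se: float
    pval: float
    n_in_set_tested: int
    pval_bonferroni: float | None = None


# ---------------------------------------------------------------------------
# I/O


def read_gene_annotation(path: str) -> list[GeneAnnotation]:
    """BED-like TSV (chrom, start, end, gene_id, strand), 1-based closed."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "gene_id"}
    if not required.issubset(df.columns):
        raise ConfigError(f"gene annotation must have columns {sorted(required)}")
    return [
        GeneAnnotation(
            gene_id=str(r.gene_id), chrom=int(r.chrom), start=int(r.start),
            end=int(r.end), strand=getattr(r, "strand", "+"),
        )
        for r in df.itertuples()
    ]


def read_gmt(path: str) -> list[GeneSet]:
    """Standard GMT: set_id <tab> description <tab> member genes..."""
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets.append(GeneSet(set_id=parts[0], members=parts[2:]))
    if not sets:
        raise DataError(f"no gene sets parsed from {path}")
    return sets


# ---------------------------------------------------------------------------
# SNP-to-gene assignment and the gene statistic


def assign_snps_to_genes(
    annotation: list[GeneAnnotation],
    ss: SumStats,
    window_kb: float = 20.0,
) -> dict[str, list[str]]:
    """Map gene_id -> SNP ids within gene.start - w <= pos <= gene.end + w.

    The window is symmetric and strand-agnostic; a SNP inside two
    overlapping windows is assigned to both genes.
    """
    w = window_kb * 1000.0
    tab = ss.table
    out: dict[str, list[str]] = {}
    by_chrom = {int(c): sub.sort_values("pos") for c, sub in tab.groupby("chrom")}
    for gene in annotation:
        sub = by_chrom.get(gene.chrom)
        if sub is None:
            continue
        pos = sub["pos"].to_numpy()
        lo = np.searchsorted(pos, gene.start - w, side="left")
        hi = np.searchsorted(pos, gene.end + w, side="right")
        if hi > lo:
            out[gene.gene_id] = sub["snp_id"].iloc[lo:hi].tolist()
    if not out:
        raise DataError("no gene received any SNP; check builds and coordinates")
    return out


def gene_test(
    z: np.ndarray,
    r_gene: np.ndarray,
    monte_carlo: int = 0,
    rng: np.random.Generator | None = None,
) -> float:
    """Gene p-value for S = sum z_j^2 against the LD-aware null.

    The null of S is sum_i lambda_i chi2_1 (lambda_i = eigenvalues of
    r_gene). Moment matching gives a scaled chi-square a*chi2_nu with
    a = Var/(2 E), nu = 2 E^2 / Var, E = trace(r_gene) and
    Var = 2 ||r_gene||_F^2; this is exact for identity LD. With
    ``monte_carlo`` > 0 the tail is instead estimated from that many draws
    of z ~ N(0, r_gene).
    """
    z = np.atleast_1d(np.asarray(z, float))
    r_gene = np.atleast_2d(np.asarray(r_gene, float))
    if r_gene.shape != (len(z), len(z)):
        raise ConfigError("z and r_gene dimensions disagree")
    eigmin = float(np.linalg.eigvalsh(r_gene).min())
    if eigmin < -1e-8:
        raise DataError(f"r_gene is not positive semi-definite (min eigenvalue {eigmin:.3g})")
    s = float(np.sum(z**2))
    if monte_carlo:
        rng = rng or np.random.default_rng(0)
        chol = np.linalg.cholesky(r_gene + 1e-10 * np.eye(len(z)))
        draws = rng.standard_normal((monte_carlo, len(z))) @ chol.T
        exceed = int(np.sum(np.sum(draws**2, axis=1) >= s))
        return (1 + exceed) / (1 + monte_carlo)
    e = float(np.trace(r_gene))
    var = 2.0 * float(np.sum(r_gene**2))
    a = var / (2.0 * e)
    nu = 2.0 * e**2 / var
    return float(stats.chi2.sf(s / a, nu))


def bonferroni_threshold(n_genes: int, alpha: float = 0.05) -> float:
    """Family-wise gene significance threshold alpha / n_genes."""
    if n_genes < 1:
        raise ConfigError("n_genes must be >= 1")
    return alpha / n_genes


def pleiotropy_filter(
    results: list[GeneResult],
    meta_threshold: float,
    per_trait_threshold: float = 1e-4,
) -> list[GeneResult]:
    """Triple-threshold prioritization of shared risk genes.

    Retains genes with pval_meta <= meta_threshold AND pval_a <= t AND
    pval_b <= t, all comparisons inclusive; genes lacking a per-trait
    p-value never pass.
    """
    out = []
    for g in results:
        if g.pval_a is None or g.pval_b is None:
            continue
        if (g.pval_meta <= meta_threshold
                and g.pval_a <= per_trait_threshold
                and g.pval_b <= per_trait_threshold):
            out.append(g)
    return out


# ---------------------------------------------------------------------------
# pipeline helper: gene table from aligned SNP sets


def gene_table(
    annotation: list[GeneAnnotation],
    ss_meta: pd.DataFrame,
    panel: ReferencePanel,
    ss_a: SumStats | None = None,
    ss_b: SumStats | None = None,
    window_kb: float = 20.0,
) -> list[GeneResult]:
    """Run the gene test per gene on meta (and optionally per-trait) Z-scores.

    ``ss_meta`` needs columns snp_id, chrom, pos, z (e.g. a MetaResult table
    with z_meta renamed to z). The same SNP assignment and LD submatrix are
    reused for all three SNP sets.
    """
    carrier = SumStats(trait_label="meta",
                       table=_as_canonical(ss_meta)) if not isinstance(ss_meta, SumStats) else ss_meta
    mapping = assign_snps_to_genes(annotation, carrier, window_kb=window_kb)
    zmeta = carrier.table.set_index("snp_id")["z"]
    za = ss_a.table.set_index("snp_id")["z"] if ss_a is not None else None
    zb = ss_b.table.set_index("snp_id")["z"] if ss_b is not None else None
    results = []
    for gene_id, snps in mapping.items():
        r = panel.ld_submatrix(snps)
        pm = gene_test(zmeta.reindex(snps).to_numpy(), r)
        pa = pb = None
        if za is not None:
            pa = gene_test(za.reindex(snps).fillna(0.0).to_numpy(), r)
        if zb is not None:
            pb = gene_test(zb.reindex(snps).fillna(0.0).to_numpy(), r)
        results.append(GeneResult(
            gene_id=gene_id, n_snps=len(snps),
            stat=float(np.sum(zmeta.reindex(snps).to_numpy() ** 2)),
            pval_meta=pm, pval_a=pa, pval_b=pb,
        ))
    return results


def _as_canonical(df: pd.DataFrame) -> pd.DataFrame:
    from .sumstats import CANONICAL_COLUMNS

    out = df.copy()
    if "z_meta" in out.columns and "z" not in out.columns:
        out = out.rename(columns={"z_meta": "z"})
    for col in CANONICAL_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    return out[CANONICAL_COLUMNS]


# ---------------------------------------------------------------------------
# competitive gene-set enrichment


def geneset_enrichment(
    results: list[GeneResult],
    sets: list[GeneSet],
    covariates: pd.DataFrame | None = None,
    annotation: list[GeneAnnotation] | None = None,
) -> list[EnrichmentResult]:
    """Competitive enrichment: probit gene Z regressed on set membership.

    Per gene, Z_g = Phi^-1(1 - p_meta) (p clipped away from 0/1). For each
    set with >= 2 tested members and >= 2 tested non-members, OLS of Z_g on
    the membership indicator plus log SNP count and log gene length;
    reported p is one-sided for a positive membership coefficient, with a
    Bonferroni-adjusted companion across tested sets.

    ``covariates`` may supply per-gene columns ``n_snps`` and ``length``
    indexed by gene_id; lengths default to the annotation span or 1.
    """
    pvals = np.array([np.clip(g.pval_meta, _P_CLIP_LO, _P_CLIP_HI) for g in results])
    if np.any(pvals != np.array([g.pval_meta for g in results])):
        logger.info("probit transform clipped %d gene p-values",
                    int(np.sum(pvals != [g.pval_meta for g in results])))
    zg = stats.norm.isf(pvals)
    gene_ids = [g.gene_id for g in results]
    n_snps = np.array([g.n_snps for g in results], dtype=float)
    if covariates is not None and "length" in covariates.columns:
        length = covariates["length"].reindex(gene_ids).to_numpy(dtype=float)
    elif annotation is not None:
        span = {a.gene_id: a.end - a.start + 1 for a in annotation}
        length = np.array([span.get(g, 1.0) for g in gene_ids], dtype=float)
    else:
        length = np.ones(len(gene_ids))
    if covariates is not None and "n_snps" in covariates.columns:
        n_snps = covariates["n_snps"].reindex(gene_ids).to_numpy(dtype=float)

    base = np.column_stack([np.log(n_snps), np.log(length)])
    # constant covariates are collinear with the intercept; drop them so the
    # membership coefficient stays identified
    keep = (base.max(axis=0) - base.min(axis=0)) > 1e-12
    base = base[:, keep]
    out = []
    for gs in sets:
        member = np.array([g in set(gs.members) for g in gene_ids], dtype=float)
        n_in = int(member.sum())
        if n_in < 2 or (len(member) - n_in) < 2:
            logger.info("set %s skipped: %d tested members", gs.set_id, n_in)
            continue
        x = sm.add_constant(np.column_stack([member, base]))
        fit = sm.OLS(zg, x).fit()
        beta, se = float(fit.params[1]), float(fit.bse[1])
        degenerate = (not np.isfinite(se)) or se == 0 or \
            fit.ssr <= 1e-12 * max(1.0, float(np.sum(zg**2)))
        if degenerate:
            p = 0.5 if abs(beta) < 1e-8 else (0.0 if beta > 0 else 1.0)
        else:
            p = float(stats.t.sf(beta / se, df=fit.df_resid))
        out.append(EnrichmentResult(
            set_id=gs.set_id, beta_s=beta, beta_se=se, pval=p, n_in_set_tested=n_in,
        ))
    for res in out:
        res.pval_bonferroni = min(1.0, res.pval * len(out))
    return out
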