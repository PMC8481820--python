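"""Overlap-aware cross-trait meta-analysis and genomic risk-locus definition.

Two GWAS with shared participants have correlated Z-scores even at null
SNPs. The weighted-Z combination used here estimates that null correlation
from SNPs with |Z| <= 1 in both studies (truncation removes non-null
effects), assembles the K x K null covariance Omega with unit diagonal,
takes Lin-Sullivan optimal weights w = Omega^-1 e / (e' Omega^-1 e), and
combines

    Z_meta = (sum_k w_k Z_k) / sqrt(sum_k w_k^2 + sum_{k!=l} w_k w_l r_kl)

so that Z_meta is standard normal at null SNPs despite the overlap.

Truncating to the central box |Z| <= t shrinks the sample correlation well
below the underlying null correlation (for t = 1, rho = 0.6 yields a
truncated correlation of about 0.25). estimate_overlap therefore inverts
the exact truncation map by Gauss-Legendre quadrature before assembling
Omega; the raw truncated-sample value is kept alongside and the inversion
can be disabled for comparison.

Significant meta-analysis SNPs are greedily clumped by LD into genomic risk
loci with LD-independent lead SNPs, mirroring the convention of standard
GWAS annotation platforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConfigError, DataError, EstimationError
from .panel import ReferencePanel

logger = logging.getLogger(__name__)

__all__ = [
    "OverlapMatrix",
    "MetaResult",
    "ClumpParams",
    "Locus",
    "estimate_overlap",
    "truncated_correlation",
    "lin_sullivan_weights",
    "meta_z",
    "genomic_inflation",
    "clump_loci",
]

#: median of the chi-square(1) distribution, the null median of z^2
CHI2_MEDIAN_1DF = 0.454936423119572


@dataclass
class OverlapMatrix:
    """Null cross-trait Z correlation and the covariance matrix built from it."""

    r_hat: float
    omega: np.ndarray
    n_snps_used: int
    truncation: float = 1.0
    r_hat_raw: float | None = None  # truncated-sample value before de-attenuation


@dataclass
class MetaResult:
    table: pd.DataFrame  # snp_id, chrom, pos, z_meta, p_meta, z per study
    weights: np.ndarray
    overlap: OverlapMatrix
    lambda_gc: float | None = None
    lambda_1000: float | None = None


@dataclass
class ClumpParams:
    p_threshold: float = 5e-8
    r2_member: float = 0.6
    r2_lead: float = 0.1
    merge_window_kb: float = 250.0

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ConfigError("p_threshold must be in (0, 1)")
        if not 0 < self.r2_lead <= self.r2_member <= 1:
            raise ConfigError("need 0 < r2_lead <= r2_member <= 1")


@dataclass
class Locus:
    chrom: int
    start: int
    end: int
    lead_snps: list[str]
    member_snps: list[str]
    min_p: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("locus start > end")


# ---------------------------------------------------------------------------
# overlap estimation


def truncated_correlation(rho: float, t: float = 1.0, n_nodes: int = 80) -> float:
    """Correlation of a standard bivariate normal restricted to |x|,|y| <= t.

    Evaluated by tensor-product Gauss-Legendre quadrature; smooth and
    strictly increasing in rho, so invertible.
    """
    x, w = np.polynomial.legendre.leggauss(n_nodes)
    x, w = x * t, w * t
    xg, yg = np.meshgrid(x, x, indexing="ij")
    wg = np.outer(w, w)
    s = np.sqrt(max(1.0 - rho**2, 1e-12))
    dens = (
        np.exp(-0.5 * xg**2) / np.sqrt(2 * np.pi)
        * np.exp(-0.5 * ((yg - rho * xg) / s) ** 2) / (np.sqrt(2 * np.pi) * s)
    )
    mass = float(np.sum(wg * dens))
    exy = float(np.sum(wg * dens * xg * yg)) / mass
    ex2 = float(np.sum(wg * dens * xg**2)) / mass
    ey2 = float(np.sum(wg * dens * yg**2)) / mass
    return exy / np.sqrt(ex2 * ey2)


def _invert_truncation(r_trunc: float, t: float) -> float:
    limit = truncated_correlation(0.999999, t)
    if abs(r_trunc) >= limit:
        return float(np.sign(r_trunc)) * 0.999999
    return float(
        optimize.brentq(lambda r: truncated_correlation(r, t) - r_trunc, -0.999999, 0.999999)
    )


def estimate_overlap(
    z1: np.ndarray,
    z2: np.ndarray,
    truncation: float = 1.0,
    deattenuate: bool = True,
) -> OverlapMatrix:
    """Estimate the null cross-trait Z correlation from truncated Z-scores.

    SNPs where either study's |Z| exceeds ``truncation`` are excluded as
    potentially non-null; the sample correlation of the survivors is then
    mapped back to the full-distribution correlation by inverting the exact
    bivariate-normal truncation map (set ``deattenuate=False`` to keep the
    raw truncated-sample correlation).
    """
    z1, z2 = np.asarray(z1, float), np.asarray(z2, float)
    if z1.shape != z2.shape:
        raise ConfigError("z1 and z2 must be aligned on the same SNP set")
    if len(z1) < 1000:
        raise DataError(f"need >= 1000 aligned SNPs, got {len(z1)}")
    keep = (np.abs(z1) <= truncation) & (np.abs(z2) <= truncation)
    n_used = int(keep.sum())
    if n_used < 100:
        raise EstimationError(f"only {n_used} SNPs survive |z| <= {truncation} truncation")
    r_raw = float(np.corrcoef(z1[keep], z2[keep])[0, 1])
    if not abs(r_raw) < 1:
        raise EstimationError(
            "truncated-sample correlation is +/-1; the two Z vectors appear "
            "to be copies — supply distinct studies"
        )
    r_hat = _invert_truncation(r_raw, truncation) if deattenuate else r_raw
    omega = np.array([[1.0, r_hat], [r_hat, 1.0]])
    return OverlapMatrix(r_hat=r_hat, omega=omega, n_snps_used=n_used,
                         truncation=truncation, r_hat_raw=r_raw)


# ---------------------------------------------------------------------------
# weighting and combination


def lin_sullivan_weights(omega: OverlapMatrix | np.ndarray) -> np.ndarray:
    """Optimal study weights w = Omega^-1 e / (e' Omega^-1 e); sums to 1."""
    mat = omega.omega if isinstance(omega, OverlapMatrix) else np.asarray(omega, float)
    e = np.ones(mat.shape[0])
    try:
        oi_e = np.linalg.solve(mat, e)
    except np.linalg.LinAlgError as exc:
        raise EstimationError(f"overlap matrix is singular: {exc}") from exc
    return oi_e / (e @ oi_e)


def meta_z(
    z_rows: np.ndarray,
    weights: np.ndarray,
    omega: OverlapMatrix | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Combine per-study Z vectors into overlap-corrected meta Z and p.

    ``z_rows`` has one row per study. The denominator
    sqrt(sum w_k^2 + sum_{k!=l} w_k w_l r_kl) equals sqrt(w' Omega w) for a
    unit-diagonal Omega, guaranteeing unit null variance.
    """
    mat = omega.omega if isinstance(omega, OverlapMatrix) else np.asarray(omega, float)
    z_rows = np.atleast_2d(np.asarray(z_rows, float))
    w = np.asarray(weights, float)
    denom_sq = float(w @ mat @ w)
    if denom_sq <= 0:
        raise EstimationError("nonpositive combined-Z variance; invalid overlap matrix")
    z_hat = (w @ z_rows) / np.sqrt(denom_sq)
    p = 2.0 * stats.norm.sf(np.abs(z_hat))
    return z_hat, p


def genomic_inflation(
    z: np.ndarray,
    n_cases: float,
    n_controls: float,
) -> tuple[float, float]:
    """Median-based genomic inflation factor and its 1,000/1,000 rescaling.

    lambda_gc = median(z^2) / 0.454936...; lambda_1000 rescales to an
    equivalent study of 1,000 cases and 1,000 controls:
    lambda_1000 = 1 + (lambda_gc - 1) * 500 * (1/n_cases + 1/n_controls).
    """
    z = np.asarray(z, float)
    if len(z) == 0:
        raise DataError("empty Z vector")
    if n_cases <= 0 or n_controls <= 0:
        raise ConfigError("case and control counts must be positive")
    lam = float(np.median(z**2) / CHI2_MEDIAN_1DF)
    lam1000 = 1.0 + (lam - 1.0) * 500.0 * (1.0 / n_cases + 1.0 / n_controls)
    return lam, lam1000


def run_meta(
    table1: pd.DataFrame,
    table2: pd.DataFrame,
    truncation: float = 1.0,
    deattenuate: bool = True,
    n_cases: float | None = None,
    n_controls: float | None = None,
) -> MetaResult:
    """Align two harmonized tables on snp_id and run the full combination."""
    merged = pd.merge(
        table1[["snp_id", "chrom", "pos", "z"]],
        table2[["snp_id", "z"]],
        on="snp_id",
        suffixes=("_1", "_2"),
    )
    overlap = estimate_overlap(
        merged["z_1"].to_numpy(), merged["z_2"].to_numpy(),
        truncation=truncation, deattenuate=deattenuate,
    )
    w = lin_sullivan_weights(overlap)
    zh, p = meta_z(
        np.vstack([merged["z_1"].to_numpy(), merged["z_2"].to_numpy()]), w, overlap
    )
    out = merged.assign(z_meta=zh, p_meta=p)
    lam = lam1000 = None
    if n_cases and n_controls:
        lam, lam1000 = genomic_inflation(zh, n_cases, n_controls)
    return MetaResult(table=out, weights=w, overlap=overlap,
                      lambda_gc=lam, lambda_1000=lam1000)


# ---------------------------------------------------------------------------
# LD clumping into genomic risk loci


def clump_loci(
    meta: MetaResult | pd.DataFrame,
    panel: ReferencePanel,
    params: ClumpParams | None = None,
) -> list[Locus]:
    """Greedy LD clumping of significant SNPs into genomic risk loci.

    Repeatedly takes the unassigned significant SNP with smallest p (ties
    broken by chrom, pos, snp_id) as a candidate lead and absorbs unassigned
    significant SNPs with r^2 >= r2_member to it. Candidate leads correlated
    at r^2 >= r2_lead with an already retained better lead are demoted: their
    clump merges into the retained lead's clump. Finally, clumps whose
    base-pair spans lie within merge_window_kb on the same chromosome merge
    into one locus. Every significant SNP lands in exactly one locus; locus
    lead lists are pairwise LD-independent at r2_lead, best p first.
    """
    params = params or ClumpParams()
    table = meta.table if isinstance(meta, MetaResult) else meta
    sig = table[table["p_meta"] <= params.p_threshold].copy()
    if sig.empty:
        logger.info("no SNP passes p <= %g; zero loci", params.p_threshold)
        return []
    sig = sig.sort_values(["p_meta", "chrom", "pos", "snp_id"], kind="mergesort")

    vinfo = panel.variants.set_index("snp_id")
    bid = vinfo["block_id"]
    members_of_block: dict[int, list[str]] = {}
    index_in_block: dict[str, int] = {}
    for b in bid.loc[sig["snp_id"]].unique():
        mem = panel.block_members(int(b))["snp_id"].tolist()
        members_of_block[int(b)] = mem
        for i, s in enumerate(mem):
            index_in_block[s] = i

    def r2(a: str, b: str) -> float:
        if a == b:
            return 1.0
        ba, bb = int(bid.loc[a]), int(bid.loc[b])
        if ba != bb:
            return 0.0
        return float(panel.blocks[ba][index_in_block[a], index_in_block[b]] ** 2)

    # pass 1: greedy clumps
    unassigned = sig["snp_id"].tolist()
    pvals = sig.set_index("snp_id")["p_meta"]
    clumps: list[dict] = []  # {"lead": snp, "members": [snps]}
    assigned: set[str] = set()
    for snp in sig["snp_id"]:
        if snp in assigned:
            continue
        members = [snp]
        assigned.add(snp)
        for other in unassigned:
            if other in assigned:
                continue
            if r2(snp, other) >= params.r2_member:
                members.append(other)
                assigned.add(other)
        clumps.append({"lead": snp, "members": members})

    # pass 2: demote leads in LD with a better retained lead
    retained: list[dict] = []
    for clump in clumps:  # clumps are in best-p-first order
        merged = False
        for kept in retained:
            if any(r2(clump["lead"], lead) >= params.r2_lead for lead in kept["leads"]):
                kept["members"].extend(clump["members"])
                merged = True
                break
        if not merged:
            retained.append({"leads": [clump["lead"]], "members": list(clump["members"])})

    # pass 3: merge clumps within merge_window_kb on the same chromosome
    spans = []
    for c in retained:
        pos = vinfo.loc[c["members"], "pos"]
        spans.append({
            "chrom": int(vinfo.loc[c["leads"][0], "chrom"]),
            "start": int(pos.min()),
            "end": int(pos.max()),
            "leads": c["leads"],
            "members": c["members"],
        })
    spans.sort(key=lambda s: (s["chrom"], s["start"]))
    window = params.merge_window_kb * 1000.0
    loci_spans: list[dict] = []
    for s in spans:
        if loci_spans and s["chrom"] == loci_spans[-1]["chrom"] and \
                s["start"] - loci_spans[-1]["end"] <= window:
            prev = loci_spans[-1]
            prev["end"] = max(prev["end"], s["end"])
            prev["leads"].extend(s["leads"])
            prev["members"].extend(s["members"])
        else:
            loci_spans.append(s)

    loci = []
    for s in loci_spans:
        leads = sorted(set(s["leads"]), key=lambda snp: (pvals.loc[snp], snp))
        members = sorted(set(s["members"]),
                         key=lambda snp: (int(vinfo.loc[snp, "pos"]), snp))
        loci.append(Locus(
            chrom=s["chrom"], start=s["start"], end=s["end"],
            lead_snps=leads, member_snps=members,
            min_p=float(pvals.loc[leads[0]]),
        ))
    loci.sort(key=lambda locus: (locus.chrom, locus.start))
    return loci
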