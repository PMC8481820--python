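"""Genetic-architecture estimation from summary statistics.

Implements the single-trait and cross-trait LD-score regressions (SNP
heritability and genetic correlation with block-jackknife standard errors),
the observed-to-liability scale conversion for case-control traits, a
Gaussian-mixture estimator of polygenicity and discoverability
("mixture-lite": no LD convolution of causal effects, the LD score enters
only the causal-component variance), and the exact binomial sign-
concordance test between two traits' genome-wide significant index SNPs.

LD-score regression background: under a polygenic model,
E[z_j^2] = 1 + n h2 l_j / M where l_j is SNP j's LD score, M the number of
SNPs and n the sample size; confounding inflates the intercept rather than
the slope. The cross-trait analogue regresses z1*z2 on l with slope
sqrt(n1 n2) rho_g / M; its intercept absorbs sample overlap.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConfigError, EstimationError
from .panel import ReferencePanel
from .sumstats import SumStats

logger = logging.getLogger(__name__)

__all__ = [
    "ArchitectureEstimate",
    "RgEstimate",
    "MixtureEstimate",
    "SignTestResult",
    "ldsc_h2",
    "ldsc_rg",
    "liability_scale",
    "mixer_em",
    "sign_concordance",
]


@dataclass
class ArchitectureEstimate:
    h2_obs: float
    h2_se: float
    intercept: float
    h2_liability: float | None = None


@dataclass
class RgEstimate:
    rg: float
    rg_se: float
    pval: float
    gencov: float
    cross_intercept: float
    out_of_range: bool = False


@dataclass
class MixtureEstimate:
    pi_hat: float
    sigma_b_sq_hat: float
    n_causal_hat: float
    loglik: float
    n_iter: int
    converged: bool
    model: str = "mixture-lite"
    loglik_history: list[float] = dataclasses.field(default_factory=list, repr=False)


@dataclass
class SignTestResult:
    n_index: int
    n_concordant: int
    pval: float


# ---------------------------------------------------------------------------
# LD-score regression


def _aligned_ld(ss: SumStats, panel: ReferencePanel) -> tuple[np.ndarray, np.ndarray]:
    tab = ss.table
    ell = panel.ld_scores.reindex(tab["snp_id"]).to_numpy()
    ok = ~np.isnan(ell)
    if not ok.all():
        logger.warning("%s: %d SNPs lack LD scores and are excluded",
                       ss.trait_label, int((~ok).sum()))
    return tab.loc[ok, "z"].to_numpy(), ell[ok]


def _wls_slope_intercept(y: np.ndarray, ell: np.ndarray) -> tuple[float, float]:
    """Weighted least squares of y on ell with 1/max(1, ell) weights."""
    w = 1.0 / np.maximum(1.0, ell)
    sw = w.sum()
    mx = (w * ell).sum() / sw
    my = (w * y).sum() / sw
    sxx = (w * (ell - mx) ** 2).sum()
    if sxx <= 0:
        raise EstimationError("LD scores are constant; regression design is degenerate")
    slope = (w * (ell - mx) * (y - my)).sum() / sxx
    return slope, my - slope * mx


def _jackknife(thetas: np.ndarray, theta_full: float) -> float:
    b = len(thetas)
    return float(np.sqrt((b - 1) / b * np.sum((thetas - thetas.mean()) ** 2)))


def _block_slices(n: int, n_blocks: int) -> list[np.ndarray]:
    return [idx for idx in np.array_split(np.arange(n), n_blocks) if len(idx)]


def ldsc_h2(
    ss: SumStats,
    panel: ReferencePanel,
    n: float,
    n_jackknife_blocks: int = 200,
) -> ArchitectureEstimate:
    """SNP heritability by LD-score regression of z^2 on l.

    The fitted slope equals n h2 / M, so h2 = slope * M / n; the intercept
    is free and reports confounding/overlap inflation. The standard error is
    a delete-one-block jackknife over contiguous genomic blocks.
    """
    if n <= 0:
        raise ConfigError("sample size n must be positive")
    z, ell = _aligned_ld(ss, panel)
    m = len(z)
    if m < n_jackknife_blocks:
        raise ConfigError(
            f"{m} SNPs is fewer than {n_jackknife_blocks} jackknife blocks"
        )
    y = z**2
    slope, intercept = _wls_slope_intercept(y, ell)
    h2 = slope * m / n

    thetas = []
    for idx in _block_slices(m, n_jackknife_blocks):
        mask = np.ones(m, dtype=bool)
        mask[idx] = False
        s, _ = _wls_slope_intercept(y[mask], ell[mask])
        thetas.append(s * m / n)
    se = _jackknife(np.asarray(thetas), h2)
    return ArchitectureEstimate(h2_obs=float(h2), h2_se=se, intercept=float(intercept))


def ldsc_rg(
    ss1: SumStats,
    ss2: SumStats,
    panel: ReferencePanel,
    n1: float,
    n2: float,
    n_jackknife_blocks: int = 200,
) -> RgEstimate:
    """Genetic correlation by cross-trait LD-score regression.

    Regresses z1*z2 on l (slope = sqrt(n1 n2) rho_g / M, free intercept
    absorbing sample overlap), divides the genetic covariance by the two
    univariate heritabilities, and jackknifes the full rg functional —
    including both univariate fits — over contiguous blocks.
    """
    merged = pd.merge(
        ss1.table[["snp_id", "z"]],
        ss2.table[["snp_id", "z"]],
        on="snp_id",
        suffixes=("_1", "_2"),
    )
    ell = panel.ld_scores.reindex(merged["snp_id"]).to_numpy()
    ok = ~np.isnan(ell)
    merged, ell = merged[ok], ell[ok]
    m = len(merged)
    if m < 1000:
        raise EstimationError(f"only {m} shared SNPs with LD scores; need >= 1000")
    z1 = merged["z_1"].to_numpy()
    z2 = merged["z_2"].to_numpy()

    def rg_functional(mask: np.ndarray) -> tuple[float, float, float]:
        s11, _ = _wls_slope_intercept(z1[mask] ** 2, ell[mask])
        s22, _ = _wls_slope_intercept(z2[mask] ** 2, ell[mask])
        s12, c12 = _wls_slope_intercept((z1 * z2)[mask], ell[mask])
        h2_1 = s11 * m / n1
        h2_2 = s22 * m / n2
        gencov = s12 * m / np.sqrt(n1 * n2)
        if h2_1 <= 0 or h2_2 <= 0:
            raise EstimationError(
                f"nonpositive heritability (h2_1={h2_1:.4g}, h2_2={h2_2:.4g}); "
                "rg undefined"
            )
        return gencov / np.sqrt(h2_1 * h2_2), gencov, c12

    full = np.ones(m, dtype=bool)
    rg, gencov, cross_int = rg_functional(full)
    thetas = []
    for idx in _block_slices(m, n_jackknife_blocks):
        mask = full.copy()
        mask[idx] = False
        thetas.append(rg_functional(mask)[0])
    se = _jackknife(np.asarray(thetas), rg)
    pval = 2.0 * stats.norm.sf(abs(rg) / se) if se > 0 else float(rg == 0)
    out_of_range = abs(rg) > 1
    if out_of_range:
        logger.warning("rg estimate %.3f outside [-1, 1]; flagged, not clamped", rg)
    return RgEstimate(rg=float(rg), rg_se=se, pval=float(pval),
                      gencov=float(gencov), cross_intercept=float(cross_int),
                      out_of_range=out_of_range)


def liability_scale(h2_obs: float, pop_prev: float, sample_prev: float) -> float:
    """Convert observed-scale case-control h2 to the liability scale.

    h2_lia = h2_obs * K^2 (1-K)^2 / (P (1-P) phi(t)^2) with K the population
    prevalence, P the sample case fraction and t the upper-K standard-normal
    quantile.
    """
    if not (0 < pop_prev < 1 and 0 < sample_prev < 1):
        raise ConfigError("prevalences must lie strictly inside (0, 1)")
    k, p = pop_prev, sample_prev
    t = stats.norm.isf(k)
    phi = stats.norm.pdf(t)
    return float(h2_obs * (k * (1 - k)) ** 2 / (p * (1 - p) * phi**2))


# ---------------------------------------------------------------------------
# polygenicity / discoverability mixture ("mixture-lite")


def mixer_em(
    ss: SumStats,
    panel: ReferencePanel,
    n: float,
    init: tuple[float, float] = (0.01, 1e-4),
    tol: float = 1e-6,
    max_iter: int = 500,
) -> MixtureEstimate:
    """EM fit of z ~ (1-pi) N(0,1) + pi N(0, 1 + n sigma_b^2 l_j).

    Expectation-conditional-maximization: the E-step computes causal
    responsibilities; pi is updated in closed form and sigma_b^2 by a
    bounded one-dimensional maximization of the expected complete-data
    log-likelihood. The observed log-likelihood is monotone non-decreasing
    across iterations; convergence when successive gains fall below tol.
    The null variance is fixed at 1 and LD enters only the causal-component
    variance — a deliberate simplification of full LD-convolution mixture
    models, labeled "mixture-lite" in outputs.
    """
    pi, sig = init
    if not (0 < pi < 1) or sig < 0:
        raise ConfigError("init must satisfy 0 < pi < 1 and sigma_b_sq >= 0")
    z, ell = _aligned_ld(ss, panel)
    z2 = z**2

    def loglik(pi_: float, sig_: float) -> float:
        v1 = 1.0 + n * sig_ * ell
        a = np.log(1 - pi_) - 0.5 * z2
        b = np.log(pi_) - 0.5 * (z2 / v1 + np.log(v1))
        hi = np.maximum(a, b)
        return float(np.sum(hi + np.log(np.exp(a - hi) + np.exp(b - hi))) -
                     0.5 * len(z) * np.log(2 * np.pi))

    ll = loglik(pi, sig)
    history = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step
        v1 = 1.0 + n * sig * ell
        log_r0 = np.log(1 - pi) - 0.5 * z2
        log_r1 = np.log(pi) - 0.5 * (z2 / v1 + np.log(v1))
        hi = np.maximum(log_r0, log_r1)
        denom = hi + np.log(np.exp(log_r0 - hi) + np.exp(log_r1 - hi))
        w = np.exp(log_r1 - denom)
        # CM-steps
        pi = float(np.clip(w.mean(), 1e-12, 1 - 1e-12))
        sw = w.sum()
        if sw > 0:
            def neg_q(log_sig: float) -> float:
                v = 1.0 + n * np.exp(log_sig) * ell
                return float(np.sum(w * (z2 / v + np.log(v))))

            res = optimize.minimize_scalar(
                neg_q, bounds=(np.log(1e-12), np.log(1.0)), method="bounded",
                options={"xatol": 1e-10},
            )
            cand = float(np.exp(res.x))
            # guard: only accept if the Q-value does not worsen (GEM property)
            if neg_q(res.x) <= neg_q(np.log(max(sig, 1e-300))):
                sig = cand
        ll_new = loglik(pi, sig)
        if ll_new + 1e-9 < ll:
            logger.warning("EM log-likelihood decreased by %.3g at iter %d", ll - ll_new, it)
        history.append(ll_new)
        if abs(ll_new - ll) < tol:
            ll = ll_new
            converged = True
            break
        ll = ll_new
    return MixtureEstimate(
        pi_hat=pi,
        sigma_b_sq_hat=sig,
        n_causal_hat=pi * len(z),
        loglik=ll,
        n_iter=it,
        converged=converged,
        loglik_history=history,
    )


# ---------------------------------------------------------------------------
# sign concordance


def sign_concordance(
    index_snps: list[tuple[str, float]],
    ss_b: SumStats,
) -> SignTestResult:
    """Exact two-sided binomial test of effect-direction sharing.

    ``index_snps`` are (snp_id, effect sign or effect size) pairs for one
    trait's genome-wide significant LD-independent SNPs; concordance counts
    how many have a same-signed Z in the other trait. Under no shared
    architecture the concordant fraction is Binomial(n, 1/2).
    """
    if not index_snps:
        raise ConfigError("no index SNPs supplied to the sign test")
    zb = ss_b.table.set_index("snp_id")["z"]
    missing = [s for s, _ in index_snps if s not in zb.index]
    if missing:
        raise ConfigError(
            f"{len(missing)} index SNPs absent from the second trait "
            f"(e.g. {missing[:3]}); harmonize both traits first"
        )
    n_conc = 0
    for snp, sign in index_snps:
        z = zb.loc[snp]
        if z == 0:
            logger.warning("index SNP %s has z=0 in the second trait; counted discordant", snp)
            continue
        if np.sign(z) == np.sign(sign):
            n_conc += 1
    pval = stats.binomtest(n_conc, len(index_snps), 0.5, alternative="two-sided").pvalue
    return SignTestResult(n_index=len(index_snps), n_concordant=n_conc, pval=float(pval))
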