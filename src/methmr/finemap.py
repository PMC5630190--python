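"""Bivariate fine mapping over an LD region and the concordance statistic.

For the variants in high LD (r^2 >= 0.8) with a sentinel mQTL, per-variant
approximate Bayes factors (Wakefield's closed form, Gaussian effect prior)
are computed separately from the SNP-methylation and SNP-trait effect
estimates.  The concordance rate — the rank of the top methylation-ranked
variant inside the trait-based ranking, divided by the region size — asks
whether the same causal variant plausibly drives both signals; a rate
below 0.05 argues against LD confounding (two distinct causal variants
travelling together).

A posterior over the number of causal variants K in {1, 2} is obtained by
exhaustive enumeration under the standard multivariate-normal z-score
model: z ~ N(0, R + v * R_S R_S') for causal set S with effect prior
variance v on the non-centrality scale, against the null z ~ N(0, R).
Priors over variants are uniform (no functional weighting).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REGION_R2 = 0.8
#: Gaussian prior variance on standardized per-allele effects (prior SD 0.2)
PRIOR_W = 0.04
CONCORDANCE_ALPHA = 0.05


@dataclass
class RegionFineMap:
    sentinel_id: str
    variant_ids: list[str]
    pos: np.ndarray
    z_meth: np.ndarray
    z_trait: np.ndarray
    log_bf_meth: np.ndarray
    log_bf_trait: np.ndarray
    posterior_meth: np.ndarray
    posterior_trait: np.ndarray
    k_posterior_meth: dict = field(default_factory=dict)
    k_posterior_trait: dict = field(default_factory=dict)
    #: slot for externally computed colocalization p-values (e.g. JLIM);
    #: never produced here, merged into reports when supplied
    external_coloc_p: float | None = None

    def __post_init__(self) -> None:
        if self.sentinel_id not in self.variant_ids:
            raise ValueError("variant list must include the sentinel")
        for post in (self.posterior_meth, self.posterior_trait):
            if abs(float(np.sum(post)) - 1.0) > 1e-9:
                raise ValueError("posterior vector does not sum to 1")


@dataclass
class ConcordanceResult:
    top_meth_variant: str
    top_trait_variant: str
    rank_of_top_meth_in_trait_ranking: int  # 1-based
    m_variants: int
    concordance_rate: float
    verdict: str  # concordant | discordant

    def __post_init__(self) -> None:
        expected = self.rank_of_top_meth_in_trait_ranking / self.m_variants
        if abs(self.concordance_rate - expected) > 1e-12:
            raise ValueError("concordance rate inconsistent with rank")


def build_region(
    sentinel: str,
    ld_r2_row: pd.Series,
    r2_min: float = REGION_R2,
) -> list[str]:
    """Sentinel plus every variant with r^2 >= ``r2_min`` against it,
    ordered deterministically by the LD row's own (positional) order."""
    if sentinel not in ld_r2_row.index:
        raise ValueError(f"sentinel {sentinel!r} absent from LD data")
    keep = [v for v, r2 in ld_r2_row.items()
            if v == sentinel or r2 >= r2_min]
    return keep


def abf(beta: float, se: float, prior_var_w: float = PRIOR_W) -> float:
    """Wakefield log approximate Bayes factor, H1 (nonzero effect with
    Gaussian prior variance W) versus H0 (zero effect).

        log BF = 0.5*log(se^2/(se^2+W)) + 0.5 * z^2 * W/(se^2+W)

    Monotone increasing in |z| at fixed se; tends to 0 as W -> 0.
    """
    if se <= 0 or prior_var_w <= 0:
        raise ValueError("se and prior variance must be positive")
    z = beta / se
    shrink = prior_var_w / (se**2 + prior_var_w)
    return float(0.5 * np.log(se**2 / (se**2 + prior_var_w))
                 + 0.5 * z**2 * shrink)


def single_variant_posteriors(log_bfs) -> np.ndarray:
    """Posterior over which single variant is causal, under a uniform
    prior: softmax of the log Bayes factors (max-subtracted)."""
    lb = np.asarray(log_bfs, dtype=float)
    if lb.size == 0:
        raise ValueError("no Bayes factors supplied")
    if not np.all(np.isfinite(lb)):
        raise ValueError("log Bayes factors must be finite")
    w = np.exp(lb - lb.max())
    return w / w.sum()


def _log_bf_sets(z: np.ndarray, R: np.ndarray, nc_var: float):
    """Log Bayes factors (vs the global null) for all single-variant and
    all variant-pair causal configurations under z ~ N(0, R + v R_S R_S').

    Closed forms: for S = {i},
        log BF = -0.5*log(1+v) + 0.5 * z_i^2 * v/(1+v);
    for S = {i, j} with LD r,
        det term  det(I + v R_SS) = (1+v)^2 - (v r)^2,
        quad term z_S' (v^-1 I + R_SS)^-1 z_S.
    """
    m = len(z)
    v = nc_var
    lbf1 = -0.5 * np.log1p(v) + 0.5 * z**2 * v / (1.0 + v)
    iu, ju = np.triu_indices(m, k=1)
    r = R[iu, ju]
    det = (1.0 + v) ** 2 - (v * r) ** 2
    a = 1.0 / v + 1.0
    det2 = a**2 - r**2  # of (v^-1 I + R_SS); > 0 whenever |r| <= 1, v > 0
    near_singular = det2 < 1e-12
    if np.any(near_singular):
        logger.warning("%d variant pair(s) near-singular; ridge applied",
                       int(near_singular.sum()))
        det2 = np.where(near_singular, det2 + 1e-4, det2)
    zi, zj = z[iu], z[ju]
    quad = (a * (zi**2 + zj**2) - 2.0 * r * zi * zj) / det2
    lbf2 = -0.5 * np.log(det) + 0.5 * quad
    return lbf1, lbf2


def k_causal_posterior(
    z_vector,
    ld_matrix,
    priors: dict[int, float] | None = None,
    nc_var: float = 100.0,
) -> dict[int, float]:
    """Posterior over the number of causal variants K in {1, 2}.

    The marginal likelihood for each K averages the configuration Bayes
    factors over all size-K subsets (uniform configuration prior within
    K); the posterior multiplies by the prior over K and normalizes.
    ``nc_var`` is the Gaussian prior variance of the causal non-centrality
    (z-scale effect; roughly n * W for standardized per-allele prior W).
    Regions are limited to 500 variants (exhaustive enumeration).
    """
    z = np.asarray(z_vector, dtype=float)
    R = np.asarray(ld_matrix, dtype=float)
    m = len(z)
    if m > 500:
        raise ValueError("region too large for exhaustive enumeration")
    if R.shape != (m, m):
        raise ValueError("LD matrix shape does not match z vector")
    if priors is None:
        priors = {1: 0.5, 2: 0.5}
    lbf1, lbf2 = _log_bf_sets(z, R, nc_var)

    def log_mean_exp(x):
        c = np.max(x)
        return c + np.log(np.mean(np.exp(x - c)))

    log_lik = {1: log_mean_exp(lbf1)}
    if m >= 2:
        log_lik[2] = log_mean_exp(lbf2)
    ks = sorted(set(priors) & set(log_lik))
    if not ks:
        raise ValueError("no K with both a prior and a likelihood")
    logpost = np.array([np.log(priors[k]) + log_lik[k] for k in ks])
    logpost -= logpost.max()
    post = np.exp(logpost)
    post /= post.sum()
    return {k: float(pk) for k, pk in zip(ks, post)}


def _ranked(ids, log_bfs, abs_z, pos):
    """Indices sorted by descending BF; ties by larger |z|, then smaller
    position, then lexicographic ID (deterministic)."""
    order = sorted(
        range(len(ids)),
        key=lambda i: (-log_bfs[i], -abs_z[i], pos[i], ids[i]),
    )
    ties = len({round(b, 12) for b in log_bfs}) < len(log_bfs)
    if ties:
        logger.info("BF ties present; deterministic tie-break applied")
    return order


def concordance(region_fm: RegionFineMap,
                alpha: float = CONCORDANCE_ALPHA) -> ConcordanceResult:
    """Concordance rate of the two fine-mapping rankings.

    rank (1-based) of the top methylation-BF variant within the
    descending trait-BF ranking, divided by the number of region
    variants.  Verdict is "concordant" iff the rate is strictly below
    ``alpha`` — note that regions smaller than 1/alpha variants can never
    be called concordant, even with perfect agreement.
    """
    ids = region_fm.variant_ids
    m = len(ids)
    abs_zm = np.abs(region_fm.z_meth)
    abs_zt = np.abs(region_fm.z_trait)
    meth_order = _ranked(ids, region_fm.log_bf_meth, abs_zm, region_fm.pos)
    trait_order = _ranked(ids, region_fm.log_bf_trait, abs_zt, region_fm.pos)
    top_meth = meth_order[0]
    rank = trait_order.index(top_meth) + 1
    rate = rank / m
    return ConcordanceResult(
        top_meth_variant=ids[top_meth],
        top_trait_variant=ids[trait_order[0]],
        rank_of_top_meth_in_trait_ranking=rank,
        m_variants=m,
        concordance_rate=rate,
        verdict="concordant" if rate < alpha else "discordant",
    )


def fine_map_region(
    sentinel_id: str,
    variant_ids: list[str],
    pos,
    beta_meth, se_meth,
    beta_trait, se_trait,
    ld_r2: pd.DataFrame,
    prior_var_w: float = PRIOR_W,
    nc_var: float | None = None,
    df: int | None = None,
) -> RegionFineMap:
    """Assemble a :class:`RegionFineMap` from per-variant marginal effect
    estimates for methylation and trait over one region.

    ``nc_var`` for the K-posterior defaults to W / median(se^2), the
    z-scale equivalent of the per-allele prior.  When the regression
    degrees of freedom ``df`` are supplied, the K-posterior is evaluated
    on the correlation scale, z* = sqrt(df) * t / sqrt(t^2 + df): for
    large standardized effects the plain t statistic overshoots the
    linear mean structure r * lambda that the multivariate z model
    assumes (residual variance shrinks at the causal variant), whereas
    the sample-correlation transform preserves it.
    """
    beta_meth = np.asarray(beta_meth, float)
    se_meth = np.asarray(se_meth, float)
    beta_trait = np.asarray(beta_trait, float)
    se_trait = np.asarray(se_trait, float)
    z_m = beta_meth / se_meth
    z_t = beta_trait / se_trait
    lbf_m = np.array([abf(b, s, prior_var_w)
                      for b, s in zip(beta_meth, se_meth)])
    lbf_t = np.array([abf(b, s, prior_var_w)
                      for b, s in zip(beta_trait, se_trait)])
    # signed LD (correlation) is not retained by an r^2 matrix; the
    # K-posterior uses |r|, which leaves the quadratic form conservative
    # for anti-correlated pairs
    sub = ld_r2.loc[variant_ids, variant_ids].to_numpy(float)
    R = np.sqrt(np.clip(sub, 0.0, 1.0))
    if df is not None:
        zk_m = np.sqrt(df) * z_m / np.sqrt(z_m**2 + df)
        zk_t = np.sqrt(df) * z_t / np.sqrt(z_t**2 + df)
    else:
        zk_m, zk_t = z_m, z_t
    if nc_var is None:
        # empirical-Bayes prior scale: the strongest signal in the region
        # sets the expected non-centrality (floored for null regions)
        nc_m = max(1.0, float(np.max(zk_m**2)) - 1.0)
        nc_t = max(1.0, float(np.max(zk_t**2)) - 1.0)
    else:
        nc_m = nc_t = nc_var
    kp_m = k_causal_posterior(zk_m, R, nc_var=nc_m)
    kp_t = k_causal_posterior(zk_t, R, nc_var=nc_t)
    return RegionFineMap(
        sentinel_id=sentinel_id,
        variant_ids=list(variant_ids),
        pos=np.asarray(pos),
        z_meth=z_m, z_trait=z_t,
        log_bf_meth=lbf_m, log_bf_trait=lbf_t,
        posterior_meth=single_variant_posteriors(lbf_m),
        posterior_trait=single_variant_posteriors(lbf_t),
        k_posterior_meth=kp_m, k_posterior_trait=kp_t,
    )
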