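"""Phenotype derivation, methylation residualization and instrument selection.

Covers the data-preparation steps upstream of association scanning and MR:
derived lipid phenotypes (Friedewald LDL/VLDL), blood-pressure averaging,
rank-based inverse-normal transformation, covariate residualization, the
cis-mQTL filter (1 Mb window, p < 1e-14, trans-associated SNPs removed
entirely) and greedy LD clumping to pairwise-independent sentinels.

Coordinates are 1-based inclusive throughout; cis distance is
|pos_SNP - pos_CpG| on the same chromosome.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

logger = logging.getLogger(__name__)

CIS_WINDOW_BP = 1_000_000
MQTL_P_MAX = 1e-14
CLUMP_R2 = 0.1

#: required columns of an mQTL summary record table
MQTL_COLUMNS = [
    "snp_id", "cpg_id", "chrom", "pos_snp", "pos_cpg",
    "beta", "se", "p", "effect_allele", "other_allele",
]


def friedewald_ldl(tc, hdl, tg):
    """Friedewald LDL cholesterol and the companion VLDL value (mmol/L).

    LDL = TC - (HDL + 0.45*TG); VLDL = TC - (HDL + LDL) = 0.45*TG.
    Negative LDL estimates are returned as NaN with a flag: the Friedewald
    approximation has broken down (typically high triglycerides) and the
    record is excluded downstream.

    Returns
    -------
    (ldl, vldl) as floats or arrays; negative-LDL entries are NaN.
    """
    tc = np.asarray(tc, dtype=float)
    hdl = np.asarray(hdl, dtype=float)
    tg = np.asarray(tg, dtype=float)
    if np.any(tc < 0) or np.any(hdl < 0) or np.any(tg < 0):
        raise ValueError("lipid concentrations cannot be negative")
    ldl = tc - (hdl + 0.45 * tg)
    vldl = tc - (hdl + ldl)
    bad = ldl < 0
    if np.any(bad):
        logger.warning("%d negative Friedewald LDL estimate(s) flagged "
                       "and set to NaN", int(np.sum(bad)))
        ldl = np.where(bad, np.nan, ldl)
        vldl = np.where(bad, np.nan, vldl)
    if ldl.ndim == 0:
        return float(ldl), float(vldl)
    return ldl, vldl


def mean_bp(reading1, reading2):
    """Mean of two blood-pressure readings (mmHg).

    A single available reading passes through with a logged note; both
    missing yields NaN.
    """
    r1 = np.asarray(reading1, dtype=float)
    r2 = np.asarray(reading2, dtype=float)
    if np.any(r1[~np.isnan(r1)] <= 0) or np.any(r2[~np.isnan(r2)] <= 0):
        raise ValueError("blood-pressure readings must be positive")
    single = np.isnan(r1) ^ np.isnan(r2)
    if np.any(single):
        logger.warning("%d sample(s) have a single BP reading; passed "
                       "through unaveraged", int(np.sum(single)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = np.nanmean(np.stack([r1, r2]), axis=0)
    return float(out) if out.ndim == 0 else out


def rank_inverse_normal(values, offset: float = 3.0 / 8.0):
    """Rank-based inverse-normal (Blom) transform.

    Maps value ranks to normal quantiles of (rank - offset)/(n + 1 - 2*offset),
    the Blom formulation for offset 3/8.  Ties share the average rank; NaNs
    are preserved.  Output has mean ~0, SD ~1, and preserves rank order, so
    any monotone transform of the input yields an identical output.
    """
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, np.nan)
    mask = ~np.isnan(x)
    n = int(mask.sum())
    if n < 2:
        raise ValueError("need at least 2 non-missing values")
    xs = x[mask]
    if np.all(xs == xs[0]):
        warnings.warn("all values identical; transform returns zeros")
        out[mask] = 0.0
        return out
    ranks = rankdata(xs, method="average")
    out[mask] = norm.ppf((ranks - offset) / (n + 1.0 - 2.0 * offset))
    return out


def residualize(matrix, covariates) -> pd.DataFrame:
    """Replace each column of ``matrix`` by its OLS residuals against the
    covariate design (intercept added).

    Residuals are orthogonal to every covariate; re-residualizing is
    idempotent.  A rank-deficient design raises, naming collinear columns.
    """
    mat = pd.DataFrame(matrix).astype(float)
    cov = pd.DataFrame(covariates).astype(float)
    if len(mat) != len(cov):
        raise ValueError("matrix and covariates differ in sample count")
    design = np.column_stack([np.ones(len(cov)), cov.to_numpy()])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify columns whose removal restores full rank
        bad = []
        for j, name in enumerate(cov.columns):
            reduced = np.delete(design, j + 1, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                bad.append(str(name))
        raise ValueError(
            f"rank-deficient covariate design; collinear columns: {bad}"
        )
    coef, *_ = np.linalg.lstsq(design, mat.to_numpy(), rcond=None)
    resid = mat.to_numpy() - design @ coef
    return pd.DataFrame(resid, index=mat.index, columns=mat.columns)


def select_cis_mqtls(
    records: pd.DataFrame,
    window_bp: int = CIS_WINDOW_BP,
    p_max: float = MQTL_P_MAX,
) -> pd.DataFrame:
    """Retain cis-mQTL records suitable as MR instruments.

    A record is cis when SNP and CpG share a chromosome and lie within
    ``window_bp`` of each other, and significant when p < ``p_max``.  SNPs
    with any significant trans association (far CpG or other chromosome)
    are removed from the instrument set entirely, keeping only SNPs
    associated with methylation at a proximal CpG alone — this limits
    pleiotropy through distal methylation pathways.  Records with missing
    coordinates are rejected with a logged count.  Idempotent.
    """
    rec = records.copy()
    missing = rec[["chrom", "pos_snp", "pos_cpg"]].isna().any(axis=1)
    # CpG on another chromosome is trans regardless of its position
    if "cpg_chrom" in rec.columns:
        missing |= rec["cpg_chrom"].isna()
        same_chrom = rec["chrom"].astype(str) == rec["cpg_chrom"].astype(str)
    else:
        same_chrom = pd.Series(True, index=rec.index)
    if missing.any():
        logger.warning("%d record(s) with missing coordinates rejected",
                       int(missing.sum()))
        rec = rec[~missing]
        same_chrom = same_chrom[~missing]
    dist = (rec["pos_snp"].astype(float) - rec["pos_cpg"].astype(float)).abs()
    significant = rec["p"] < p_max
    cis = same_chrom & (dist <= window_bp)
    keep = cis & significant
    trans_snps = set(rec.loc[significant & ~cis, "snp_id"])
    if trans_snps:
        logger.info("%d SNP(s) removed for significant trans associations",
                    len(trans_snps))
    return rec[keep & ~rec["snp_id"].isin(trans_snps)].copy()


def ld_clump(
    stats: pd.DataFrame,
    ld_r2_matrix: pd.DataFrame,
    r2_threshold: float = CLUMP_R2,
) -> list[str]:
    """Greedy LD clumping to pairwise-independent sentinel SNPs.

    Repeatedly takes the most significant remaining SNP and discards every
    SNP with r^2 >= ``r2_threshold`` against it.  Ties are broken by
    smaller p, then smaller genomic position, then lexicographic ID, so
    the result is deterministic.  Returned sentinels have pairwise
    r^2 < threshold.
    """
    if stats.empty:
        return []
    order = stats.copy()
    if "pos" not in order.columns:
        order["pos"] = 0
    # a neg_log10_p column, when present, carries significance ranking
    # past float64 p underflow; ordering is otherwise identical
    if "neg_log10_p" in order.columns:
        order["_rank_p"] = -order["neg_log10_p"]
    else:
        order["_rank_p"] = order["p"]
    order = order.sort_values(["_rank_p", "pos", "snp_id"],
                              kind="mergesort").reset_index(drop=True)
    missing = set(order["snp_id"]) - set(ld_r2_matrix.index)
    if missing:
        raise ValueError(f"LD matrix lacks variants: {sorted(missing)[:5]}")
    sentinels: list[str] = []
    alive = dict.fromkeys(order["snp_id"], True)
    for snp in order["snp_id"]:
        if not alive[snp]:
            continue
        sentinels.append(snp)
        r2 = ld_r2_matrix.loc[snp]
        for other, flag in alive.items():
            if flag and other != snp and r2.get(other, 0.0) >= r2_threshold:
                alive[other] = False
        alive[snp] = False
    return sentinels
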