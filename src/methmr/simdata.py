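"""Synthetic mQTL studies with known causal architecture.

Generates genotype/methylation/trait bundles under one of four generative
scenarios for a genetic signal shared between DNA methylation and a
cardiovascular trait:

``mediation``
    SNP -> methylation -> trait (M = a*G + e, Y = b*M + e).
``reverse``
    A polygenic trait feeds back on methylation
    (Y = sum_k beta_k*G_k + e, M = a*G_cis + c*Y + e).
``ld_confounded``
    Distinct causal variants for methylation and trait held together only
    by linkage disequilibrium (r^2 between them is a target parameter).
``pleiotropy``
    One variant with independent effects on both (M = a*G, Y = d*G).

The first and last scenarios are marginally indistinguishable by design:
single-instrument MR cannot separate them, and the framework never claims
to.

Linkage disequilibrium is produced by a Gaussian-copula haplotype model:
haplotypes are thresholded AR(1)-correlated standard normals, thresholded
at the MAF quantile, and two haplotypes are summed per sample.  The
latent-correlation -> genotype-correlation map has a closed form through
Owen's T function, which gives an exact handle on pairwise r^2 and lets
the ld_confounded scenario place its second causal variant at a requested
r^2 to the sentinel.

Effect units: per-allele effects on methylation/trait are in SD units.
Residual SDs default to the value that makes the population variance of M
and Y exactly 1, so the recorded truth parameters live on the same
standardized scale as the emitted data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import owens_t
from scipy.stats import norm

SCENARIOS = ("mediation", "reverse", "ld_confounded", "pleiotropy")

# small fixed covariate effects (SD per SD of covariate); exercised by the
# MWAS covariate adjustment but never material to any verdict
COVARIATE_EFFECT = 0.05


class ParameterError(ValueError):
    """Invalid simulation parameter."""


# ---------------------------------------------------------------------------
# latent <-> genotype correlation mapping


def genotype_corr_from_latent(latent_r: float, maf: float) -> float:
    """Correlation between two dosages whose haplotypes share latent
    correlation ``latent_r``.

    Haplotype alleles are indicators {Z < Phi^-1(maf)}; the dosage
    correlation equals the haplotype phi coefficient, computed from the
    bivariate-normal orthant probability via Owen's T (equal thresholds).
    """
    if not -1.0 < latent_r < 1.0:
        if latent_r == 1.0:
            return 1.0
        raise ParameterError(f"latent correlation {latent_r} outside (-1, 1]")
    t = norm.ppf(maf)
    a = np.sqrt((1.0 - latent_r) / (1.0 + latent_r))
    p11 = norm.cdf(t) - 2.0 * owens_t(t, a)
    return float((p11 - maf**2) / (maf * (1.0 - maf)))


def latent_for_genotype_corr(target_r: float, maf: float) -> float:
    """Inverse of :func:`genotype_corr_from_latent` (positive branch)."""
    if not 0.0 <= target_r < 1.0:
        raise ParameterError("target genotype correlation must be in [0, 1)")
    if target_r == 0.0:
        return 0.0
    return brentq(
        lambda r: genotype_corr_from_latent(r, maf) - target_r,
        0.0, 1.0 - 1e-12, xtol=1e-12,
    )


def _index_distance_for_r2(r2: float, maf: float, ld_rho: float) -> float:
    """AR(1) index distance at which the genotype r^2 equals ``r2``."""
    latent = latent_for_genotype_corr(np.sqrt(r2), maf)
    return float(np.log(latent) / np.log(ld_rho))


# ---------------------------------------------------------------------------
# config


@dataclass
class SimulationConfig:
    """Generative parameters for one synthetic study.

    Scenario-specific effects (``b``, ``c``, ``d``, ``r2_pair``) default to
    None and are resolved per scenario; setting one that the scenario does
    not use raises a warning.
    """

    scenario: str = "mediation"
    n_samples: int = 5000
    n_variants_region: int = 31
    maf: float = 0.3
    ld_rho: float = 0.999
    a: float = 0.95           # SNP -> methylation, SD per allele
    b: float | None = None    # methylation -> trait, SD per SD (mediation)
    c: float | None = None    # trait -> methylation, SD per SD (reverse)
    d: float | None = None    # direct SNP -> trait, SD per allele
    r2_pair: float | None = None  # LD between the two causal variants
    n_trait_instruments: int = 20
    trait_instrument_beta: float = 0.1
    n_gwas_samples: int = 20000  # external trait-GWAS cohort (reverse MR)
    noise_sd_m: float | None = None  # None: scale to unit total variance
    noise_sd_y: float | None = None
    seed: int = 0

    _DEFAULTS = {"b": 0.5, "c": 0.4, "d": 0.475, "r2_pair": 0.3}
    _USED = {
        "mediation": ("b",),
        "reverse": ("c",),
        "ld_confounded": ("d", "r2_pair"),
        "pleiotropy": ("d",),
    }

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ParameterError(f"unknown scenario {self.scenario!r}")
        if self.n_samples < 10:
            raise ParameterError("n_samples must be >= 10")
        if self.n_variants_region < 1:
            raise ParameterError("n_variants_region must be >= 1")
        if not 0.0 < self.maf <= 0.5:
            raise ParameterError("maf must lie in (0, 0.5]")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ParameterError("ld_rho must lie in [0, 1)")
        for name in ("a", "b", "c", "d", "r2_pair", "noise_sd_m", "noise_sd_y"):
            v = getattr(self, name)
            if v is not None and not np.isfinite(v):
                raise ParameterError(f"{name} must be finite")
        used = self._USED[self.scenario]
        for name in ("b", "c", "d", "r2_pair"):
            v = getattr(self, name)
            if name not in used and v is not None and v != 0:
                warnings.warn(
                    f"parameter {name!r} is not used by scenario "
                    f"{self.scenario!r}", stacklevel=3,
                )

    def resolved(self) -> dict:
        """Scenario-relevant parameters with defaults filled in."""
        out = {"a": self.a}
        for name in self._USED[self.scenario]:
            v = getattr(self, name)
            out[name] = self._DEFAULTS[name] if v is None else v
        return out


# ---------------------------------------------------------------------------
# containers


@dataclass
class GenotypeMatrix:
    """Additive dosages (samples x variants) plus per-variant metadata.

    ``variants`` columns: variant_id, chrom, pos (1-based), ref, alt, maf,
    role in {region, trait_instrument}.
    """

    dosages: np.ndarray
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError("dosage columns and variant metadata disagree")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def variant_ids(self) -> list[str]:
        return list(self.variants["variant_id"])

    def column(self, variant_id: str) -> np.ndarray:
        idx = self.variants.index[self.variants["variant_id"] == variant_id]
        if len(idx) == 0:
            raise KeyError(variant_id)
        return self.dosages[:, idx[0]]

    def ld_r2(self) -> pd.DataFrame:
        """Pairwise empirical r^2 between all variants."""
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(self.dosages, rowvar=False)
        r = np.nan_to_num(r, nan=0.0)
        np.fill_diagonal(r, 1.0)
        ids = self.variant_ids
        return pd.DataFrame(r**2, index=ids, columns=ids)


@dataclass
class SyntheticStudy:
    genotypes: GenotypeMatrix
    methylation: np.ndarray  # per sample, SD units
    trait: np.ndarray        # per sample, SD units
    covariates: pd.DataFrame  # age (years), sex (0/1)
    truth: dict = field(default_factory=dict)
    #: external trait-GWAS summary stats for the instruments (reverse MR
    #: is two-sample, as with published GWAS-catalog instruments)
    gwas_stats: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        n = self.genotypes.n_samples
        if not (len(self.methylation) == len(self.trait)
                == len(self.covariates) == n):
            raise ValueError("sample dimension mismatch across study arrays")


# ---------------------------------------------------------------------------
# genotype simulation


def _simulate_from_positions(
    n_samples: int,
    index_positions: np.ndarray,
    maf: float,
    ld_rho: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Dosages for variants at (possibly non-integer) AR(1) index positions.

    Latent correlation between variants i, j is ld_rho**|pos_i - pos_j|
    (a valid exponential-decay kernel for any spacing).
    """
    m = len(index_positions)
    t = norm.ppf(maf)
    if ld_rho == 0.0 or m == 1:
        latent = rng.standard_normal((2 * n_samples, m))
    else:
        dist = np.abs(index_positions[:, None] - index_positions[None, :])
        corr = ld_rho ** dist
        # tiny jitter guards Cholesky against coincident positions
        chol = np.linalg.cholesky(corr + 1e-12 * np.eye(m))
        latent = rng.standard_normal((2 * n_samples, m)) @ chol.T
    haplo = (latent < t).astype(np.int8)
    return (haplo[:n_samples] + haplo[n_samples:]).astype(np.float64)


def simulate_genotypes(
    n_samples: int,
    n_variants: int,
    maf: float,
    ld_rho: float,
    seed: int | np.random.Generator = 0,
) -> GenotypeMatrix:
    """Simulate an LD block of additive dosages in {0, 1, 2}.

    Haplotypes are zero-mean AR(1)-correlated Gaussians thresholded at the
    MAF quantile; two independent haplotypes are summed per sample.
    Adjacent-variant r^2 increases monotonically with ``ld_rho``.
    """
    if n_samples <= 0 or n_variants <= 0:
        raise ParameterError("n_samples and n_variants must be positive")
    if not 0.0 < maf <= 0.5:
        raise ParameterError("maf must lie in (0, 0.5]")
    if not 0.0 <= ld_rho < 1.0:
        raise ParameterError("ld_rho must lie in [0, 1)")
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    dosages = _simulate_from_positions(
        n_samples, np.arange(n_variants, dtype=float), maf, ld_rho, rng
    )
    variants = _region_metadata(np.arange(n_variants, dtype=float), maf)
    return GenotypeMatrix(dosages, variants)


def _region_metadata(index_positions: np.ndarray, maf: float) -> pd.DataFrame:
    base = 1_000_000
    return pd.DataFrame({
        "variant_id": [f"var{j:04d}" for j in range(len(index_positions))],
        "chrom": "1",
        "pos": (base + np.round(index_positions * 1000).astype(int) + 1),
        "ref": "A",
        "alt": "G",
        "maf": maf,
        "role": "region",
    })


# ---------------------------------------------------------------------------
# scenario simulation


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def _noise_sd(explained: float, override: float | None, label: str) -> float:
    if override is not None:
        return float(override)
    if explained >= 1.0:
        raise ParameterError(
            f"effects explain {explained:.3f} >= 1 of the variance of "
            f"{label}; reduce effect sizes or set noise_sd_{label} explicitly"
        )
    return float(np.sqrt(1.0 - explained))


def simulate_scenario(config: SimulationConfig) -> SyntheticStudy:
    """Generate one study under the configured causal architecture.

    Every scenario carries a polygenic background for the trait
    (``n_trait_instruments`` unlinked variants on chromosome 2), so the
    trait always has valid genetic instruments for reverse MR; only in
    the ``reverse`` scenario does the trait feed back on methylation.  Final methylation
    and trait vectors are standardized to unit sample variance and the
    generating parameters are recorded in ``truth``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    m = config.n_variants_region
    params = config.resolved()
    a = params["a"]
    v_g = 2.0 * config.maf * (1.0 - config.maf)

    # --- region genotypes (AR(1) LD block; sentinel in the middle)
    positions = np.arange(m, dtype=float)
    sentinel_idx = m // 2
    trait_causal_id = None
    if config.scenario == "ld_confounded":
        # append a second causal cluster whose lead variant sits at the
        # requested r^2 to the sentinel, with its own high-LD neighbours
        r2_pair = params["r2_pair"]
        if not 0.0 < r2_pair < 1.0:
            raise ParameterError("r2_pair must lie in (0, 1)")
        if config.ld_rho == 0.0:
            raise ParameterError("ld_confounded requires ld_rho > 0")
        gap = _index_distance_for_r2(r2_pair, config.maf, config.ld_rho)
        # second cluster mirrors the first, shifted so its lead variant
        # sits exactly `gap` index units from the sentinel
        positions = np.concatenate([positions, positions + gap])
        trait_causal_idx = m + sentinel_idx
    dosages = _simulate_from_positions(
        n, positions, config.maf, config.ld_rho, rng
    )
    variants = _region_metadata(positions, config.maf)
    sentinel_id = variants.loc[sentinel_idx, "variant_id"]
    if config.scenario == "ld_confounded":
        trait_causal_id = variants.loc[trait_causal_idx, "variant_id"]

    # --- unlinked polygenic trait instruments (chromosome 2)
    k = config.n_trait_instruments
    gi = rng.binomial(2, config.maf, size=(n, k)).astype(np.float64)
    inst_meta = pd.DataFrame({
        "variant_id": [f"ti{j:03d}" for j in range(k)],
        "chrom": "2",
        "pos": 5_000_000 + 50_000 * np.arange(k) + 1,
        "ref": "A",
        "alt": "G",
        "maf": config.maf,
        "role": "trait_instrument",
    })
    beta_k = np.full(k, config.trait_instrument_beta)

    # --- covariates
    age = rng.normal(7.5, 0.15, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    age_z = _standardize(age)
    sex_z = _standardize(sex)
    cov_term = COVARIATE_EFFECT * age_z + COVARIATE_EFFECT * sex_z
    v_cov = 2.0 * COVARIATE_EFFECT**2

    g_sent = dosages[:, sentinel_idx]
    poly = gi @ beta_k
    v_poly = float(np.sum(beta_k**2) * v_g)

    # --- structural equations (population variance of M and Y targeted at 1)
    if config.scenario == "mediation":
        b = params["b"]
        sd_m = _noise_sd(a**2 * v_g + v_cov, config.noise_sd_m, "m")
        meth = a * g_sent + cov_term + rng.normal(0, sd_m, n)
        # cross term: meth already contains the covariate effects
        explained_y = b**2 + v_poly + v_cov + 2.0 * b * v_cov
        sd_y = _noise_sd(explained_y, config.noise_sd_y, "y")
        trait = b * meth + poly + cov_term + rng.normal(0, sd_y, n)
    elif config.scenario == "reverse":
        c = params["c"]
        sd_y = _noise_sd(v_poly + v_cov, config.noise_sd_y, "y")
        trait = poly + cov_term + rng.normal(0, sd_y, n)
        # cross term: trait already contains the covariate effects
        explained_m = a**2 * v_g + c**2 + v_cov + 2.0 * c * v_cov
        sd_m = _noise_sd(explained_m, config.noise_sd_m, "m")
        meth = a * g_sent + c * trait + cov_term + rng.normal(0, sd_m, n)
    elif config.scenario == "ld_confounded":
        d = params["d"]
        g2 = dosages[:, trait_causal_idx]
        sd_m = _noise_sd(a**2 * v_g + v_cov, config.noise_sd_m, "m")
        meth = a * g_sent + cov_term + rng.normal(0, sd_m, n)
        sd_y = _noise_sd(d**2 * v_g + v_poly + v_cov, config.noise_sd_y, "y")
        trait = d * g2 + poly + cov_term + rng.normal(0, sd_y, n)
    else:  # pleiotropy
        d = params["d"]
        sd_m = _noise_sd(a**2 * v_g + v_cov, config.noise_sd_m, "m")
        meth = a * g_sent + cov_term + rng.normal(0, sd_m, n)
        sd_y = _noise_sd(d**2 * v_g + v_poly + v_cov, config.noise_sd_y, "y")
        trait = d * g_sent + poly + cov_term + rng.normal(0, sd_y, n)

    gwas_stats = _external_trait_gwas(config, params, beta_k, inst_meta, rng)

    all_dosages = np.concatenate([dosages, gi], axis=1)
    all_meta = pd.concat([variants, inst_meta], ignore_index=True)
    genotypes = GenotypeMatrix(all_dosages, all_meta)

    truth = {
        "scenario": config.scenario,
        "params": params,
        "sentinel_id": str(sentinel_id),
        "cpg_id": "cg_synth01",
        "cpg_chrom": "1",
        "cpg_pos": int(variants.loc[sentinel_idx, "pos"]) + 500,
        "trait_causal_id": trait_causal_id and str(trait_causal_id),
        "trait_instrument_ids": list(inst_meta["variant_id"]),
        "trait_instrument_betas": beta_k.tolist(),
        "seed": config.seed,
    }
    covariates = pd.DataFrame({"age": age, "sex": sex})
    return SyntheticStudy(
        genotypes, _standardize(meth), _standardize(trait), covariates,
        truth, gwas_stats,
    )


def _external_trait_gwas(config, params, beta_k, inst_meta, rng):
    """Instrument-trait summary stats from an independent cohort.

    Reverse MR is a two-sample analysis: instrument effects on the trait
    come from an external GWAS (as with published catalog instruments),
    which breaks the correlated-error bias that same-sample estimation of
    both stages would introduce.  The external cohort regenerates the
    trait under the same structural equations (instruments drawn without
    LD; the cis region enters only through the trait's upstream terms).
    """
    n = config.n_gwas_samples
    a = params["a"]
    v_g = 2.0 * config.maf * (1.0 - config.maf)
    gi = rng.binomial(2, config.maf, size=(n, len(beta_k))).astype(float)
    poly = gi @ beta_k
    v_poly = float(np.sum(beta_k**2) * v_g)
    cov = COVARIATE_EFFECT * (_standardize(rng.normal(7.5, 0.15, n))
                              + _standardize(rng.integers(0, 2, n)))
    v_cov = 2.0 * COVARIATE_EFFECT**2
    g_cis = rng.binomial(2, config.maf, size=n).astype(float)
    if config.scenario == "mediation":
        b = params["b"]
        sd_m = _noise_sd(a**2 * v_g + v_cov, config.noise_sd_m, "m")
        meth = a * g_cis + cov + rng.normal(0, sd_m, n)
        sd_y = _noise_sd(b**2 + v_poly + v_cov + 2 * b * v_cov,
                         config.noise_sd_y, "y")
        trait = b * meth + poly + cov + rng.normal(0, sd_y, n)
    elif config.scenario == "reverse":
        sd_y = _noise_sd(v_poly + v_cov, config.noise_sd_y, "y")
        trait = poly + cov + rng.normal(0, sd_y, n)
    else:  # ld_confounded / pleiotropy: direct SNP effect plus polygenes
        d = params["d"]
        g2 = rng.binomial(2, config.maf, size=n).astype(float)
        sd_y = _noise_sd(d**2 * v_g + v_poly + v_cov, config.noise_sd_y, "y")
        trait = d * g2 + poly + cov + rng.normal(0, sd_y, n)
    y = _standardize(trait)
    # simple per-instrument regression, vectorized
    gc = gi - gi.mean(axis=0)
    var_g = (gc**2).sum(axis=0)
    beta = (gc * y[:, None]).sum(axis=0) / var_g
    resid_var = ((y**2).sum() - beta**2 * var_g) / (n - 2)
    se = np.sqrt(resid_var / var_g)
    z = beta / se
    from scipy import stats as sps
    p = 2.0 * sps.norm.sf(np.abs(z))
    return pd.DataFrame({
        "snp_id": inst_meta["variant_id"],
        "effect_allele": inst_meta["alt"],
        "other_allele": inst_meta["ref"],
        "eaf": inst_meta["maf"],
        "beta": beta,
        "se": se,
        "p": p,
        "n": n,
        "trait_id": "trait",
    })


# ---------------------------------------------------------------------------
# bundle writer / reader


def write_study_bundle(study: SyntheticStudy, outdir: str | Path,
                       vcf: bool = False) -> dict[str, Path]:
    """Write a study as plain-text files: genotype dosage TSV, methylation
    TSV, phenotype TSV, variant metadata TSV and truth JSON (optionally a
    minimal VCF 4.2 with a DS FORMAT field)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    samples = [f"s{i:05d}" for i in range(study.genotypes.n_samples)]
    paths: dict[str, Path] = {}

    geno = pd.DataFrame(
        study.genotypes.dosages, index=samples,
        columns=study.genotypes.variant_ids,
    )
    paths["genotypes"] = outdir / "genotypes.tsv"
    geno.to_csv(paths["genotypes"], sep="\t", index_label="sample",
                float_format="%.10g")

    paths["variants"] = outdir / "variants.tsv"
    study.genotypes.variants.to_csv(paths["variants"], sep="\t", index=False)

    meth = pd.DataFrame({"sample": samples, "cg_synth01": study.methylation})
    paths["methylation"] = outdir / "methylation.tsv"
    meth.to_csv(paths["methylation"], sep="\t", index=False,
                float_format="%.10g")

    pheno = pd.DataFrame({
        "sample": samples,
        "trait": study.trait,
        "age": study.covariates["age"],
        "sex": study.covariates["sex"].astype(int),
    })
    paths["phenotypes"] = outdir / "phenotypes.tsv"
    pheno.to_csv(paths["phenotypes"], sep="\t", index=False,
                 float_format="%.10g")

    if study.gwas_stats is not None:
        paths["trait_gwas"] = outdir / "trait_gwas.tsv"
        study.gwas_stats.to_csv(paths["trait_gwas"], sep="\t", index=False,
                                float_format="%.10g")

    paths["truth"] = outdir / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(study.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")

    if vcf:
        paths["vcf"] = outdir / "study.vcf"
        _write_vcf(study, samples, paths["vcf"])
    return paths


def _write_vcf(study: SyntheticStudy, samples: list[str], path: Path) -> None:
    v = study.genotypes.variants
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                 'Description="Additive dosage">\n')
        for chrom in pd.unique(v["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        order = np.lexsort((v["pos"].to_numpy(), v["chrom"].to_numpy()))
        for j in order:
            row = v.iloc[j]
            ds = "\t".join(f"{x:g}" for x in study.genotypes.dosages[:, j])
            fh.write(f"{row.chrom}\t{row.pos}\t{row.variant_id}\t{row.ref}"
                     f"\t{row.alt}\t.\t.\t.\tDS\t{ds}\n")


def read_study_bundle(bundledir: str | Path) -> SyntheticStudy:
    """Load a bundle written by :func:`write_study_bundle`."""
    bundledir = Path(bundledir)
    geno = pd.read_csv(bundledir / "genotypes.tsv", sep="\t",
                       index_col="sample")
    variants = pd.read_csv(bundledir / "variants.tsv", sep="\t",
                           dtype={"chrom": str})
    meth = pd.read_csv(bundledir / "methylation.tsv", sep="\t")
    pheno = pd.read_csv(bundledir / "phenotypes.tsv", sep="\t")
    truth_path = bundledir / "truth.json"
    truth = {}
    if truth_path.exists():
        with open(truth_path) as fh:
            truth = json.load(fh)
    gwas_path = bundledir / "trait_gwas.tsv"
    gwas = (pd.read_csv(gwas_path, sep="\t") if gwas_path.exists() else None)
    genotypes = GenotypeMatrix(geno.to_numpy(float), variants)
    return SyntheticStudy(
        genotypes,
        meth.iloc[:, 1].to_numpy(float),
        pheno["trait"].to_numpy(float),
        pheno[["age", "sex"]].astype(float).reset_index(drop=True),
        truth,
        gwas,
    )
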