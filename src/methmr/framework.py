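"""End-to-end decision pipeline: one verdict per shared signal.

Given a study bundle (genotypes, methylation, trait, covariates), the
pipeline (1) scans for cis-mQTLs and clumps them to a sentinel, (2) tests
the sentinel against the trait with study-wide Bonferroni control,
(3) estimates the forward causal effect of methylation on the trait by
2SLS, (4) tests reverse causation with trait GWAS instruments, (5) fine
maps the sentinel's high-LD region bivariately and computes the
concordance rate, and (6) classifies the signal into one of:

    2_reverse          trait -> methylation (reverse MR p <= alpha)
    3_ld               two distinct causal variants in LD (discordant)
    1_mediation_or_4   mediation or horizontal pleiotropy — a single
                       instrument cannot separate these, and the label
                       deliberately never resolves the ambiguity
    inconclusive       required evidence missing or no rule fired

Rule precedence (reverse before concordance) follows the decision
flow of the published pipeline and is configurable off for sensitivity
analyses.  Identical config + seed reproduces every output byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import finemap as fm
from . import mr as mrmod
from . import mwas as mwasmod
from . import prep as prepmod
from .simdata import read_study_bundle

logger = logging.getLogger(__name__)

CALL_MEDIATION_OR_PLEIOTROPY = "1_mediation_or_4"
CALL_REVERSE = "2_reverse"
CALL_LD = "3_ld"
CALL_INCONCLUSIVE = "inconclusive"


@dataclass
class EvidenceBundle:
    signal_id: str
    forward_mr: mrmod.MRResult
    reverse_mr: mrmod.MRResult | None = None
    reverse_verdict: str | None = None
    concordance: fm.ConcordanceResult | None = None
    k_posterior_meth: dict | None = None
    k_posterior_trait: dict | None = None
    replication_2smr: mrmod.MRResult | None = None
    eqtl_2smr: mrmod.MRResult | None = None


@dataclass
class ExplanationCall:
    signal_id: str
    call: str
    notes: list[str] = field(default_factory=list)
    evidence: EvidenceBundle | None = None


def classify_signal(
    evidence: EvidenceBundle,
    alpha: float = 0.05,
    reverse_first: bool = True,
) -> ExplanationCall:
    """Apply the decision rules to one signal's evidence trail.

    Order: (i) reverse MR p <= alpha -> reverse causation; (ii) fine-map
    rankings discordant -> LD confounding; (iii) forward MR p <= alpha
    with reverse unlikely and rankings concordant -> mediation-or-
    pleiotropy (never resolved further); anything else -> inconclusive.
    Replication and expression 2SMR results are reported but never gate
    the call.
    """
    notes: list[str] = []
    rev, conc = evidence.reverse_mr, evidence.concordance

    def rule_reverse():
        if rev is not None and rev.p <= alpha:
            notes.append(f"reverse MR p={rev.p:.3g} <= {alpha}")
            return CALL_REVERSE
        return None

    def rule_ld():
        if conc is not None and conc.verdict == "discordant":
            notes.append(
                f"concordance rate {conc.concordance_rate:.4f} >= "
                f"{fm.CONCORDANCE_ALPHA} (rank "
                f"{conc.rank_of_top_meth_in_trait_ranking} of "
                f"{conc.m_variants})"
            )
            return CALL_LD
        return None

    rules = [rule_reverse, rule_ld] if reverse_first else [rule_ld,
                                                           rule_reverse]
    for rule in rules:
        call = rule()
        if call is not None:
            return ExplanationCall(evidence.signal_id, call, notes, evidence)

    fwd = evidence.forward_mr
    if (fwd is not None and fwd.p <= alpha
            and rev is not None and rev.p > alpha
            and conc is not None and conc.verdict == "concordant"):
        notes.append(
            f"forward MR p={fwd.p:.3g} <= {alpha}; reverse unlikely "
            f"(p={rev.p:.3g}); rankings concordant "
            f"(rate {conc.concordance_rate:.4f}); mediation and horizontal "
            f"pleiotropy remain indistinguishable with one instrument"
        )
        return ExplanationCall(evidence.signal_id,
                               CALL_MEDIATION_OR_PLEIOTROPY, notes, evidence)

    missing = [name for name, v in
               [("forward_mr", fwd), ("reverse_mr", rev),
                ("concordance", conc)] if v is None]
    if missing:
        notes.append(f"missing evidence: {', '.join(missing)}")
    else:
        notes.append("no classification rule satisfied")
    return ExplanationCall(evidence.signal_id, CALL_INCONCLUSIVE, notes,
                           evidence)


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    bundle_dir: str
    out_dir: str | None = None
    cis_window_bp: int = prepmod.CIS_WINDOW_BP
    mqtl_p_max: float = prepmod.MQTL_P_MAX
    clump_r2: float = prepmod.CLUMP_R2
    region_r2: float = fm.REGION_R2
    concordance_alpha: float = fm.CONCORDANCE_ALPHA
    alpha: float = 0.05
    prior_w: float = fm.PRIOR_W
    reverse_first: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if not Path(cfg.bundle_dir).is_dir():
            raise FileNotFoundError(cfg.bundle_dir)
        for name in ("mqtl_p_max", "clump_r2", "region_r2",
                     "concordance_alpha", "alpha"):
            v = getattr(cfg, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        return cfg


def _summary_scan(study, variant_mask, trait_col):
    """Marginal covariate-adjusted per-variant summaries as a DataFrame
    indexed by variant id, with effect/other alleles attached."""
    geno = study.genotypes
    pheno = pd.DataFrame({
        trait_col: (study.methylation if trait_col == "meth"
                    else study.trait),
        "age": study.covariates["age"].to_numpy(),
        "sex": study.covariates["sex"].to_numpy(),
    })
    from .simdata import GenotypeMatrix
    sub = GenotypeMatrix(geno.dosages[:, variant_mask],
                         geno.variants[variant_mask].reset_index(drop=True))
    res = mwasmod.run_mwas(sub, pheno, traits=[trait_col])
    meta = sub.variants.set_index("variant_id")
    res = res.set_index("snp_id")
    res["effect_allele"] = meta["alt"]
    res["other_allele"] = meta["ref"]
    res["eaf"] = meta["maf"]
    res["pos"] = meta["pos"]
    res["chrom"] = meta["chrom"]
    return res


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full decision pipeline on a study bundle.

    Returns a report dict; when ``config.out_dir`` is set, also writes
    deterministic TSV/JSON reports (association tables, a Manhattan-ready
    table, MR table, per-region fine-mapping JSON, the call table and a
    log of thresholds and dropped records).
    """
    study = read_study_bundle(config.bundle_dir)
    variants = study.genotypes.variants
    region_mask = (variants["role"] == "region").to_numpy()
    inst_mask = (variants["role"] == "trait_instrument").to_numpy()
    # out_dir is where the report lands, not an analysis parameter; it is
    # excluded so identical analyses yield byte-identical logs anywhere
    logged_cfg = {k: v for k, v in asdict(config).items() if k != "out_dir"}
    log: dict = {"config": logged_cfg, "dropped": {}}

    # --- stage 1: cis-mQTL discovery scan and LD clumping
    meth_scan = _summary_scan(study, region_mask, "meth")
    cpg_pos = study.truth.get("cpg_pos",
                              int(variants.loc[region_mask, "pos"].median()))
    records = meth_scan.reset_index().rename(columns={"pos": "pos_snp"})
    records["cpg_id"] = study.truth.get("cpg_id", "cpg")
    records["cpg_chrom"] = records["chrom"]
    records["pos_cpg"] = cpg_pos
    mqtls = prepmod.select_cis_mqtls(
        records, window_bp=config.cis_window_bp, p_max=config.mqtl_p_max
    )
    log["n_mqtls"] = int(len(mqtls))
    report: dict = {"log": log}
    if mqtls.empty:
        logger.info("no cis-mQTL passes p < %.3g; no signals to classify",
                    config.mqtl_p_max)
        report["calls"] = []
        _write_reports(report, None, None, None, None, config)
        return report

    region_ids = variants.loc[region_mask, "variant_id"].tolist()
    from .simdata import GenotypeMatrix
    region_geno = GenotypeMatrix(
        study.genotypes.dosages[:, region_mask],
        variants[region_mask].reset_index(drop=True),
    )
    ld = region_geno.ld_r2()
    sentinels = prepmod.ld_clump(
        mqtls.rename(columns={"pos_snp": "pos"}), ld,
        r2_threshold=config.clump_r2,
    )
    log["sentinels"] = sentinels
    sentinel = sentinels[0]

    # --- stage 2: sentinel x trait association (MWAS)
    trait_scan = _summary_scan(study, region_mask, "trait")
    thr = mwasmod.bonferroni_threshold(len(sentinels), 1, alpha=config.alpha)
    log["mwas_threshold"] = thr.threshold
    log["mwas_n_tests"] = thr.n_tests
    sent_assoc = trait_scan.loc[sentinel]
    mwas_pass = bool(sent_assoc["p"] < thr.threshold)
    log["mwas_pass"] = mwas_pass

    # --- stage 3: forward one-sample MR (2SLS)
    covs = study.covariates[["age", "sex"]].to_numpy(float)
    forward = mrmod.two_stage_least_squares(
        region_geno.column(sentinel), study.methylation, study.trait,
        covariates=covs, exposure_id="meth", outcome_id="trait",
        instrument_ids=[sentinel],
    )

    # --- stage 4: reverse MR with trait instruments (outside cis window);
    # instrument-trait effects come from the external GWAS table when
    # available (two-sample, as with published catalog instruments)
    inst_meth = _summary_scan(study, inst_mask, "meth").reset_index()
    if study.gwas_stats is not None:
        inst_trait = study.gwas_stats
    else:
        inst_trait = _summary_scan(study, inst_mask, "trait").reset_index()
    reverse, verdict = mrmod.reverse_mr(
        inst_trait, inst_meth, alpha=config.alpha,
        trait_id="trait", cpg_id="meth",
    )

    # --- stage 5: bivariate fine mapping over the sentinel's region
    region = fm.build_region(sentinel, ld.loc[sentinel],
                             r2_min=config.region_r2)
    ms, ts = meth_scan.loc[region], trait_scan.loc[region]
    region_fm = fm.fine_map_region(
        sentinel, region, ms["pos"].to_numpy(),
        ms["beta"].to_numpy(), ms["se"].to_numpy(),
        ts["beta"].to_numpy(), ts["se"].to_numpy(),
        ld, prior_var_w=config.prior_w,
        df=int(ms["n"].min()) - 4,  # intercept + dosage + age + sex
    )
    conc = fm.concordance(region_fm, alpha=config.concordance_alpha)

    # --- stage 6: classification
    evidence = EvidenceBundle(
        signal_id=f"{sentinel}:{study.truth.get('cpg_id', 'cpg')}:trait",
        forward_mr=forward, reverse_mr=reverse, reverse_verdict=verdict,
        concordance=conc,
        k_posterior_meth=region_fm.k_posterior_meth,
        k_posterior_trait=region_fm.k_posterior_trait,
    )
    call = classify_signal(evidence, alpha=config.alpha,
                           reverse_first=config.reverse_first)
    report.update({
        "sentinel": sentinel,
        "mwas_pass": mwas_pass,
        "calls": [call],
        "truth": study.truth,
    })
    _write_reports(report, meth_scan, trait_scan, region_fm, conc, config)
    return report


def _mr_row(res: mrmod.MRResult | None) -> dict:
    if res is None:
        return {}
    d = asdict(res)
    d["instrument_ids"] = ",".join(d["instrument_ids"])
    return d


def _write_reports(report, meth_scan, trait_scan, region_fm, conc,
                   config: PipelineConfig) -> None:
    if config.out_dir is None:
        return
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ff = "%.8g"

    def dump_json(obj, name):
        with open(out / name, "w") as fh:
            json.dump(obj, fh, indent=1, sort_keys=True, default=_jsonable)
            fh.write("\n")

    dump_json(report["log"], "log.json")
    if meth_scan is not None:
        meth_scan.reset_index().to_csv(out / "mqtl_scan.tsv", sep="\t",
                                       index=False, float_format=ff)
        trait_scan.reset_index().to_csv(out / "mwas.tsv", sep="\t",
                                        index=False, float_format=ff)
        manh = mwasmod.manhattan_table(
            trait_scan.reset_index()[mwasmod.RESULT_COLUMNS],
            trait_scan.reset_index()[["snp_id", "chrom", "pos"]]
            .rename(columns={"snp_id": "variant_id"}),
            threshold=report["log"]["mwas_threshold"],
        )
        manh.to_csv(out / "manhattan.tsv", sep="\t", index=False,
                    float_format=ff)
    calls_rows = []
    for call in report["calls"]:
        ev = call.evidence
        row = {"signal_id": call.signal_id, "call": call.call,
               "notes": "; ".join(call.notes)}
        if ev is not None:
            for tag, res in [("forward", ev.forward_mr),
                             ("reverse", ev.reverse_mr)]:
                for k, v in _mr_row(res).items():
                    row[f"{tag}_{k}"] = v
            if ev.concordance is not None:
                row.update({f"concordance_{k}": v
                            for k, v in asdict(ev.concordance).items()})
        calls_rows.append(row)
    pd.DataFrame(calls_rows).to_csv(out / "calls.tsv", sep="\t", index=False,
                                    float_format=ff)
    if region_fm is not None:
        dump_json({
            "sentinel_id": region_fm.sentinel_id,
            "variant_ids": region_fm.variant_ids,
            "z_meth": region_fm.z_meth,
            "z_trait": region_fm.z_trait,
            "log_bf_meth": region_fm.log_bf_meth,
            "log_bf_trait": region_fm.log_bf_trait,
            "posterior_meth": region_fm.posterior_meth,
            "posterior_trait": region_fm.posterior_trait,
            "k_posterior_meth": region_fm.k_posterior_meth,
            "k_posterior_trait": region_fm.k_posterior_trait,
            "concordance": asdict(conc),
        }, "finemap.json")


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return [round(float(x), 10) for x in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "__dataclass_fields__"):
        return asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
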