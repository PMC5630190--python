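#!/usr/bin/env python
"""Causal-effect estimation per scenario: forward 2SLS and reverse MR.

Forward: two-stage least squares of the trait on methylation with the
sentinel mQTL as the instrument.  Reverse: inverse-variance-weighted MR
of methylation on the trait, using the bundle's external trait-GWAS
instruments.  Also reproduces the published two-sample Wald-ratio
replication panel from its printed per-stage inputs.  Writes
results/mr_estimates.tsv and results/two_sample_replication.tsv.

What it finds: the 2SLS estimate recovers the generative effect under
mediation, matches it under pleiotropy (the documented 1-vs-4
indistinguishability), is attenuated but nonzero under LD confounding,
and is null under reverse causation — where the reverse-MR p-value, and
only there, is significant.
"""

from pathlib import Path

import pandas as pd

from methmr import mr
from methmr.framework import _summary_scan
from methmr.simdata import SCENARIOS, read_study_bundle

ROOT = Path(__file__).resolve().parent.parent
BUNDLES = ROOT / "scratch" / "bundles"
RESULTS = ROOT / "results"

# published two-sample replication rows: per-stage (beta, se) inputs
REPLICATION_PANEL = [
    ("ADIPOQ", "adiponectin", 0.982, 0.103, -0.629, 0.143),
    ("ABO", "IL-6", 0.912, 0.036, -0.245, 0.026),
    ("LEPR", "CRP", 0.682, 0.036, -0.170, 0.022),
    ("APOB", "Apo B", 0.627, 0.053, 0.098, 0.013),
    ("SORT1", "Apo B", -0.980, 0.037, -0.089, 0.012),
    ("APOA1", "Apo A1", -0.884, 0.044, 0.057, 0.013),
    ("FADS1", "TC", -0.655, 0.031, 0.047, 0.004),
    ("ADCY3", "BMI", 0.908, 0.026, 0.068, 0.007),
]


def main() -> None:
    rows = []
    for scenario in SCENARIOS:
        study = read_study_bundle(BUNDLES / scenario)
        sentinel = study.truth["sentinel_id"]
        fwd = mr.two_stage_least_squares(
            study.genotypes.column(sentinel), study.methylation,
            study.trait, study.covariates.to_numpy(float),
            exposure_id="meth", outcome_id="trait",
            instrument_ids=[sentinel])
        inst_mask = (study.genotypes.variants["role"]
                     == "trait_instrument").to_numpy()
        outcome = _summary_scan(study, inst_mask, "meth").reset_index()
        rev, verdict = mr.reverse_mr(study.gwas_stats, outcome)
        rows.append({
            "scenario": scenario,
            "forward_beta": fwd.beta, "forward_se": fwd.se,
            "forward_p": fwd.p,
            "reverse_beta": rev.beta, "reverse_se": rev.se,
            "reverse_p": rev.p, "reverse_verdict": verdict,
        })
    tab = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    tab.to_csv(RESULTS / "mr_estimates.tsv", sep="\t", index=False,
               float_format="%.4g")
    print(tab.to_string(index=False))

    rep = []
    for gene, trait, bx, sx, by, sy in REPLICATION_PANEL:
        beta, se, p = mr.wald_ratio(bx, sx, by, sy)
        rep.append({"gene": gene, "trait": trait, "cpg_effect": bx,
                    "trait_effect": by, "2smr_beta": round(beta, 3),
                    "2smr_se": round(se, 3), "p": p})
    rep = pd.DataFrame(rep)
    rep.to_csv(RESULTS / "two_sample_replication.tsv", sep="\t",
               index=False, float_format="%.4g")
    print("\ntwo-sample replication panel:")
    print(rep.to_string(index=False))


if __name__ == "__main__":
    main()
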