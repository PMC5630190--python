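#!/usr/bin/env python
"""Run the full decision pipeline on each bundle and tabulate the calls.

Executes prep -> MWAS -> forward/reverse MR -> bivariate fine mapping ->
classification end-to-end via the framework, writing the per-scenario
report directories under scratch/runs/ and the call-vs-truth table to
results/classification.tsv.

What it finds: the four verdicts recover the generating architectures —
mediation and pleiotropy both land on the deliberately joint
"1_mediation_or_4" call (a single cis instrument cannot separate them),
reverse causation on "2_reverse", LD confounding on "3_ld".
"""

from pathlib import Path

import pandas as pd

from methmr.framework import PipelineConfig, run_pipeline
from methmr.simdata import SCENARIOS

ROOT = Path(__file__).resolve().parent.parent
BUNDLES = ROOT / "scratch" / "bundles"
RUNS = ROOT / "scratch" / "runs"
RESULTS = ROOT / "results"

EXPECTED = {"mediation": "1_mediation_or_4", "reverse": "2_reverse",
            "ld_confounded": "3_ld", "pleiotropy": "1_mediation_or_4"}


def main() -> None:
    rows = []
    for scenario in SCENARIOS:
        rep = run_pipeline(PipelineConfig(
            bundle_dir=str(BUNDLES / scenario),
            out_dir=str(RUNS / scenario)))
        call = rep["calls"][0]
        ev = call.evidence
        rows.append({
            "scenario": scenario,
            "call": call.call,
            "expected": EXPECTED[scenario],
            "match": call.call == EXPECTED[scenario],
            "forward_p": ev.forward_mr.p,
            "reverse_p": ev.reverse_mr.p,
            "concordance_rate": round(
                ev.concordance.concordance_rate, 4),
        })
    tab = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    tab.to_csv(RESULTS / "classification.tsv", sep="\t", index=False,
               float_format="%.4g")
    print(tab.to_string(index=False))
    print(f"\n{int(tab['match'].sum())}/4 calls match the generating truth")


if __name__ == "__main__":
    main()
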