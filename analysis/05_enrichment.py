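#!/usr/bin/env python
"""Annotation enrichment of the lead SNPs and CpG sites.

Builds a synthetic regulatory track that covers every causal-region
position (emulating sentinels falling in regulatory peaks), a matched
control pool drawn away from the track at ~15% overlap, and tests SNP
and CpG targets separately with the exact hypergeometric tail plus the
10,000-iteration matched-resampling empirical p.  Writes
results/enrichment.json.

What it finds: with all 4 SNP and 4 CpG targets inside peaks against a
15%-overlap background, both classes are enriched with empirical
p at or near the resampling floor (~1e-4).
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from methmr import enrichment as en
from methmr.simdata import SCENARIOS, read_study_bundle

ROOT = Path(__file__).resolve().parent.parent
BUNDLES = ROOT / "scratch" / "bundles"
RESULTS = ROOT / "results"
SEED = 1


def main() -> None:
    rng = np.random.default_rng(SEED)
    targets, intervals = [], []
    for scenario in SCENARIOS:
        study = read_study_bundle(BUNDLES / scenario)
        v = study.genotypes.variants.set_index("variant_id")
        snp_pos = int(v.loc[study.truth["sentinel_id"], "pos"])
        targets.append({"id": f"{scenario}_snp", "chrom": "1",
                        "pos": snp_pos, "class": "snp"})
        targets.append({"id": f"{scenario}_cpg", "chrom": "1",
                        "pos": int(study.truth["cpg_pos"]),
                        "class": "cpg"})
        intervals.append(("1", snp_pos - 500, study.truth["cpg_pos"] + 500))
    targets = pd.DataFrame(targets)
    track = en.AnnotationTrack.from_intervals(intervals, label="peaks")

    # matched controls: ~15% land inside a peak, the rest in flanks
    pool_rows = []
    for t in targets.itertuples():
        for j in range(40):
            if rng.random() < 0.15:
                pos = int(t.pos + rng.integers(-400, 400))
            else:
                pos = int(t.pos + 10_000 + rng.integers(0, 5_000))
            pool_rows.append((t.id, f"{t.id}_c{j}", "1", pos))
    pool = pd.DataFrame(pool_rows, columns=["target_id", "control_id",
                                            "chrom", "pos"])

    payload = {}
    for cls in ("snp", "cpg"):
        sub = targets[targets["class"] == cls]
        res = en.matched_resample_enrichment(
            sub, pool[pool["target_id"].isin(sub["id"])], track,
            iterations=10_000, seed=SEED)
        payload[cls] = {
            "n_targets": res.n_targets,
            "n_overlapping": res.n_overlapping,
            "hypergeometric_p": res.hypergeometric_p,
            "empirical_p": res.empirical_p,
            "iterations": res.iterations,
        }
        print(f"{cls}: {res.n_overlapping}/{res.n_targets} in peaks, "
              f"hypergeometric p={res.hypergeometric_p:.3g}, "
              f"empirical p={res.empirical_p:.3g}")
    RESULTS.mkdir(exist_ok=True)
    with open(RESULTS / "enrichment.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


if __name__ == "__main__":
    main()
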