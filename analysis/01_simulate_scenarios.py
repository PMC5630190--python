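#!/usr/bin/env python
"""Generate one synthetic study bundle per causal architecture.

Writes four bundles (mediation, reverse causation, LD confounding,
horizontal pleiotropy) at the study's default conditions — n=5,000
samples, a 31-variant cis region in tight LD (~25 variants at r^2 >= 0.8
with the sentinel), a 0.95 SD-per-allele mQTL effect, and 20 unlinked
trait instruments backed by an external GWAS cohort — under
scratch/bundles/<scenario>/ (bundles are megabyte-scale intermediates;
the small summary tables the later steps derive from them live under
results/).
"""

from pathlib import Path

from methmr.simdata import (
    SCENARIOS,
    SimulationConfig,
    simulate_scenario,
    write_study_bundle,
)

OUT = Path(__file__).resolve().parent.parent / "scratch" / "bundles"
SEED = 1


def main() -> None:
    for scenario in SCENARIOS:
        cfg = SimulationConfig(scenario=scenario, seed=SEED)
        study = simulate_scenario(cfg)
        outdir = OUT / scenario
        write_study_bundle(study, outdir, vcf=False)
        p = study.truth["params"]
        print(f"{scenario:14s} -> {outdir}  "
              f"(n={cfg.n_samples}, params={p})")
    print("\nEach bundle: genotypes.tsv, variants.tsv, methylation.tsv, "
          "phenotypes.tsv, trait_gwas.tsv, truth.json")


if __name__ == "__main__":
    main()
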