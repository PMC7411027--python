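#!/usr/bin/env python
"""Simulate the study cohorts and write them in standard formats.

Produces one disease (liability-threshold, K = 0.1) and one quantitative
(h2 = 0.5) family-structured cohort: unrelated training individuals plus
full-sibling pairs, confound-free.  Genotypes go out as PLINK BED/BIM/FAM
and VCF, the pedigree as a FAM-style table, phenotypes as TSV, and the
generative truth (causal effects, variance components) as JSON for the
downstream parameter-recovery checks.
"""
import argparse
import json
from pathlib import Path

from sibprs import SimConfig, simulate_cohort
from sibprs import io as sio


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    args = ap.parse_args()

    for kind in ("binary", "quantitative"):
        cfg = SimConfig(
            n_families=1000, n_unrelated=8000, n_variants=4000, n_causal=100,
            h2=0.5, prevalence=0.1, seed=args.seed, trait_kind=kind,
            trait=f"sim_{kind}",
        )
        cohort = simulate_cohort(cfg)
        out = args.out / kind
        out.mkdir(parents=True, exist_ok=True)
        sio.write_plink(cohort.genotypes, cohort.pedigree, out / "cohort")
        sio.write_vcf(cohort.genotypes, out / "cohort.vcf")
        sio.write_pedigree_fam(cohort.pedigree, out / "pedigree.fam")
        sio.write_phenotypes(cohort.phenotypes, out / "phenotypes.tsv")
        truth = {
            "n_causal": cohort.truth.n_causal,
            "variance_components": cohort.truth.variance_components,
            "liability_threshold": cohort.truth.liability_threshold,
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=1))
        n = cohort.genotypes.n_samples
        n_sib = len(cohort.pedigree.sib_ids())
        print(f"{kind}: {n} individuals ({n_sib} in sibling pairs), "
              f"{cohort.genotypes.n_variants} variants -> {out}")
        if kind == "binary":
            print(f"  realized prevalence {cohort.phenotypes.values.mean():.3f} "
                  f"(target {cfg.prevalence})")


if __name__ == "__main__":
    main()
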