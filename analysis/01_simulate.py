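#!/usr/bin/env python
"""Generate the synthetic two-survey study population.

Emulates the structure of a genotyped national health survey pair: three
self-reported race-ethnicity strata, twelve SNPs in Hardy-Weinberg
equilibrium with stratum-specific coded-allele frequencies, seventeen
phenotypes (continuous biomarkers, binary diagnoses, one categorical
exposure) binned into fourteen phenotype classes, a correlated lipid-like
block, three planted effect patterns (two pleiotropic), and 5% MCAR
missingness.  Writes the genotype/phenotype TSVs, the class map, and the
planted-effect truth table under results/data/.
"""

from pathlib import Path

from survey_phewas.config import default_config
from survey_phewas.synthetic import generate_dataset, write_minimal_vcf

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 11


def main() -> None:
    cfg = default_config(seed=SEED)
    ds = generate_dataset(cfg)
    ds.write(OUT)
    write_minimal_vcf(ds, "S1", OUT / "genotypes_S1.vcf")
    n1 = sum(cfg.n_per_stratum["S1"].values())
    n2 = sum(cfg.n_per_stratum["S2"].values())
    print(f"simulated surveys S1 (n={n1}) and S2 (n={n2}), "
          f"{len(cfg.snps)} SNPs, {len(cfg.phenotypes)} phenotypes")
    print(f"planted truth: {len(ds.truth)} (snp, class, stratum) effects")
    print(ds.truth.to_string(index=False))
    print(f"wrote dataset to {OUT}")


if __name__ == "__main__":
    main()
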