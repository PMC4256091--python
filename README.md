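# survey-phewas

A phenome-wide association study (PheWAS) pipeline for paired epidemiologic
surveys — the analysis design used with genotyped NHANES data, where a
modest panel of GWAS-identified SNPs is tested against *every* available
phenotype, and significance is declared by cross-survey replication rather
than multiple-testing correction.

It is written for statistical geneticists and epidemiologists who want a
tested, reproducible implementation of that workflow: phenotype
harmonization into classes, a stratified additive-model scan, the
seven-criterion replication filter, prior-catalog classification
(replicated / related / novel), pleiotropy and cross-ancestry
generalization detection, phenotype correlation reports, and SNP → gene →
pathway network construction. Because the individual-level survey data are
restricted, the package ships a synthetic two-survey generator with planted
effects so every stage is testable end to end, plus transcriptions of the
published summary tables for bookkeeping checks.

## The method

For each SNP *s* with coded-allele dosage g ∈ {0, 1, 2}, each phenotype
measurement *y*, each survey and each self-reported race-ethnicity stratum,
the scan fits the unadjusted additive model

* continuous *y*:  y = β₀ + β·g + ε, by OLS; two-sided p from the slope's
  t statistic on n − 2 df;
* binary *y*:  logit P(y = 1) = β₀ + β·g, by maximum likelihood; Wald p.

Continuous phenotypes are analyzed both untransformed and as ln(y + 1);
categorical phenotypes are expanded into "A versus not A" indicators.
Analyses are complete-case per SNP–measurement pair, and the coded-allele
frequency (CAF) is computed on exactly the analyzed subset.

A **significant PheWAS result** is a (SNP, phenotype class, stratum) group
satisfying all seven criteria: (1) an association observed in *both*
surveys, (2) p < 0.01, (3) CAF > 0.01, (4) n > 200, (5) same stratum,
(6) same phenotype class, (7) same direction of effect. Within each survey
the lowest-p qualifying measurement is reported, and where the identical
phenotype was measured in both surveys a pooled combined-survey re-test is
attached. Retained results are classified against a prior-association
catalog, screened for pleiotropy (one SNP, ≥ 2 phenotype classes) and
generalization (same SNP–class association, same sign, ≥ 2 strata),
correlated pairwise (Pearson, pairwise-complete; partners with r > 0.6
reported; clustered |r| heatmap matrices exported), and assembled into
per-stratum networks in which only components where ≥ 2 significant SNPs'
nearest genes share a pathway/grouping are kept.

## Worked example

The numbered drivers under `analysis/` run the whole study on the default
synthetic population (two surveys of 3,600 samples in three strata, 12 SNPs,
17 phenotypes in 14 classes, three planted effect patterns of which two are
pleiotropic):

```bash
python analysis/01_simulate.py
python analysis/02_scan.py
python analysis/03_replicate_classify.py
python analysis/04_correlations.py
python analysis/05_network.py
python analysis/06_published_tables.py
```

The replication stage prints:

```
9 groups pass all seven replication criteria
  planted groups recovered: 9/12 (binary diagnoses are lower-powered by design)
  groups retained beyond the planted truth: 0
category summary: {'total': 9, 'replicated': 5, 'related': 3, 'novel': 1,
 'pleiotropic_snps': 2, 'generalized_groups': 3, 'discordant_groups': 0}
```

Every continuous planted effect is recovered (the three Diabetes groups are
planted on a binary outcome at deliberately lower power), nothing spurious
survives the filter, and the two planted pleiotropic SNPs — a lipid SNP
affecting cholesterol and triglycerides, and a urate SNP affecting uric
acid and protoporphyrin — are detected with the correct per-class signs.
The cholesterol measures planted on one latent factor exceed the r > 0.6
correlation screen (r ≈ 0.64–0.69 across strata), and the network stage
retains exactly the component where two significant SNPs' genes share the
"lipid metabolism" grouping.

The published-table driver reproduces the study's bookkeeping: pooled
% female 54.12 over n = 14,998 with sex-by-survey χ² ≈ 35.9 (p < 0.0001),
21 distinct novel result groups, and 13 pleiotropic SNPs.

The same functionality is available as a CLI
(`survey-phewas simulate | run | classify | network | report`).

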