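# Methods

## Scope and model

The package implements a cross-survey PheWAS: unadjusted additive-model
single-SNP association scans over many phenotypes, per survey and per
self-reported race-ethnicity stratum, with significance defined by
replication across two surveys instead of a multiple-testing correction.
The core contract is the seven-criterion filter — association in both
surveys, p < 0.01, coded-allele frequency > 0.01, n > 200, same stratum,
same phenotype class, same direction of effect — with all thresholds read
as strict inequalities. No covariates and no survey design weights enter
any regression; this mirrors the unadjusted design the workflow reproduces
and is a deliberate, documented limitation rather than an oversight.

## Association tests

* **Continuous measurements.** OLS of y on dosage with intercept; the
  two-sided p comes from the slope's t statistic on n − 2 df. The scan's
  hot loop is a hand-vectorized closed form: for one genotype vector
  against a matrix of phenotype columns with independent missingness, the
  per-column presence mask gives all sufficient statistics as a few matrix
  products. Columns are centered per-column before the cross-product, so
  phenotypes with large means (e.g. vitamin E in µg/dL) do not lose
  precision to cancellation. `fit_linear` exposes the same closed form for
  a single pair; the test suite checks it against `scipy.stats.linregress`
  and a textbook normal-equation oracle at 1e-10 relative error.
* **Binary measurements.** Maximum-likelihood logistic regression
  (statsmodels `Logit`, Newton, max 50 iterations, tolerance 1e-8) with a
  Wald two-sided p against the standard normal. Non-convergence and
  (quasi-)separation — SE or |β| above 100 on the coded scale — are
  flagged on the result, never raised; flagged rows can never qualify for
  replication. An independent brute-force likelihood-grid maximizer backs
  the tests.
* **Degenerate inputs.** Constant genotype, constant phenotype, fewer than
  3 complete cases, or a single outcome level yield a result flagged
  `unavailable`. p-values are floored at the smallest positive float so
  the p ∈ (0, 1] invariant holds even for astronomically strong effects.
* **CAF** is Σg / 2n on each result's analyzed (complete-case, per-survey,
  per-stratum) subset, so the frequency criterion is evaluated on exactly
  the sample the test used.

## Harmonization

Survey-specific raw phenotype names are binned into phenotype classes via
an external curated class-map table (curation is data, not code; conflicts
raise, unmapped names are excluded and listed). Continuous phenotypes are
carried in two versions — untransformed and ln(y + 1) — as distinct
measurements of one class; the +1 keeps zero-valued measurements in the
analysis, and the transform refuses negative input by name. Categorical
phenotypes become one "A versus not A" indicator per observed category,
inheriting the parent's class. A combined-survey variable exists only when
the identical raw measurement appears in both surveys; classes binned but
not harmonized are analyzable per survey only.

## Replication filter decisions

A qualifying cross-survey pair must match on transform status: a slope on
the ln scale is not comparable with one in raw units, so an ln(y+1) hit in
one survey cannot pair with an untransformed hit in the other (both
versions are separate rows of the result tables). β = 0 exactly has no
direction and never pairs. When a group contains qualifying pairs of both
signs (possible only through distinct measurements), the direction follows
the globally most significant pair member; ties break by larger n, then
lexicographic measurement name — the same tie-break used to pick each
survey's best measurement. The combined re-test attaches the lowest-p
available combined result of the group's class and is absent, not an
error, where no phenotype of the class was harmonized.

## Classification, pleiotropy, generalization

"Related" is operationalized through explicit related-group tags (e.g. one
lipid group covering total/HDL/LDL cholesterol and triglycerides) carried
in the catalog files, making a category that was originally expert
judgement reproducible and auditable. Direction agreement with the catalog
is reported but never changes a category. Pleiotropy counts distinct
phenotype classes per SNP across strata jointly; generalization requires
the same (SNP, class) direction in ≥ 2 strata, with mixed directions
reported as discordant. Classification is a pure function of (SNP, class,
catalog) — p-values and strata never enter.

## Correlations

Pearson r on pairwise-complete observations (maximizing usable n in
survey-style missingness), per survey and stratum, among phenotypes with a
retained result. The r > 0.6 partner screen uses signed r; the absolute
value enters only the heatmap export, where rows/columns are ordered by
complete-linkage hierarchical clustering on Euclidean distances between
|r| rows (unavailable cells imputed as 0 for ordering only). Cells with
fewer than 3 complete pairs or zero variance are unavailable.

## Networks

Nearest-gene annotation uses 1-based coordinates and closed gene spans;
distance is 0 inside a span, signed to the nearer boundary otherwise, ties
break lexicographically by symbol, and strand is ignored. Genomic context
strings are consumed from the annotation input, never recomputed. All
pathway/grouping sources are parsed from one GMT format with the source
recorded in the grouping name. Pruning keeps a component only when the
nearest genes of ≥ 2 significant SNPs fall in one gene–grouping-connected
cluster containing ≥ 1 grouping node: chained sharing (A–B via one
pathway, B–C via another) is retained, while SNPs linked only through a
shared phenotype-class node are not. Pruning is idempotent.

## Synthetic data generator

The generator emulates the structure of the real study — two surveys,
three strata with stratum-specific coded-allele frequencies, genotypes
drawn from Hardy–Weinberg proportions, overlapping-but-renamed phenotypes,
correlated phenotype blocks, planted (possibly pleiotropic) additive
effects, and MCAR missingness — at a reduced default size chosen for
desk-scale analysis: 1,200 samples per stratum per survey (3,600 per
survey), 12 SNPs, 17 phenotypes in 14 classes, 5% missingness. Continuous
phenotypes follow y = baseline + noise_sd · (Σ effect·g + loading·F + ε)
with F and ε standard normal, so a planted effect is expressed in units of
the phenotype's noise SD and one number is meaningful across a class's
members regardless of units; values are left-censored at 0 (assay floor).
Binary phenotypes use a logistic link on the same standardized predictor
with the intercept centered to hit the configured prevalence. Latent
factors have unit variance and unit-variance noise, so a block loading λ
gives pairwise r = λ²/(λ² + 1); loadings above 1 are legitimate and the
default cholesterol block uses λ = 1.4 (r ≈ 0.66) so the correlation
screen is exercised. One global seed expands through `SeedSequence` into
independent genotype / phenotype-noise / missingness / demographics
streams, so each component reproduces on its own. Effects act on the true
genotype; missingness only hides dosages afterwards.

What the generator does **not** emulate: linkage disequilibrium between
SNPs, population admixture, age structure, oversampling weights,
informative missingness, and measurement-error structure between a class's
member phenotypes (members differ only by scale and independent noise).
Passing tests therefore demonstrate the correctness and calibration of the
pipeline's logic, not robustness to those real-data complications.

## Problem sizes and calibration checks

The calibration studies run at sizes chosen to make their statistical
targets sharp: null p-value uniformity uses 10⁴ scan p-values (KS test);
the replication filter's null pass rate uses 2×10⁵ (SNP, class, stratum)
groups at n = 250 per stratum, where the theoretical rate is
0.01² × ½ = 5×10⁻⁵; planted-pleiotropy recovery uses 0.5 noise-SD per
allele at n = 2,000 per survey (per-survey Wald z ≈ 14, power ≈ 1 at
p < 0.01) over 20 seeds; oracle comparisons use 1,000 random OLS instances,
25 tiny logistic instances, and 1,000 random nearest-gene configurations.

## Published-table bookkeeping

The packaged `data/published_*.tsv` files transcribe printed summary tables
of the 80-SNP NHANES PheWAS (cohort counts, novel result groups, the
pleiotropic SNPs' groups with signs, nearest-gene annotations, and a
curated prior catalog with the lipid related-group). They cover the
printed results only: the full 69-group retained set lives in
supplementary material that is not redistributable here, so study-wide
totals beyond the novel count (21) and pleiotropic SNP count (13) are not
reproducible from the packaged tables; the related-group file itself is a
best-effort curation, labelled as such.

## Known limitations

Wald p-values throughout (the original analysis environment's default test
statistic is unrecorded); no LD-aware proxy matching when classifying
against the catalog; no unit conversion beyond declared metadata; plot
rendering is out of scope — the exports are tabular contracts (replication
matrix, per-SNP sun-plot tables sorted by ascending p) that any plotting
layer can consume.
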