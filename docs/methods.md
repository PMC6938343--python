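# Methods

## The detection procedure

`pleiopheno` treats pleiotropy detection as a filtering problem, not a
joint model. The unit of evidence is one association record: a single
study's test of one SNP against one phenotype response. Records flow
through four stages — significance filtering, class binning with
direction harmonization, cross-study replication, LD collapsing — plus a
permutation layer that calibrates the significance threshold for the
whole, heavily dependent test battery.

### Association scans

For each study, every variant with in-study minor coded-allele frequency
strictly greater than `maf_min` (default 0.01) is tested against every
phenotype response. Covariates are the two leading principal components
of the study's standardized dosage matrix (missing dosages mean-imputed
for the PCA only; component signs fixed so the largest-magnitude loading
is positive) and sex, which is dropped in a female-only study. Tests are
complete-case: rows missing the response, a covariate, or the genotype
are excluded per test, so per-record sample sizes vary.

* Linear fits are exact OLS. The scan path residualizes the response and
  all dosage columns on the covariate block via a QR decomposition and
  reads the genotype coefficient off the residualized cross-products;
  this equals the full normal-equations solution, and a test asserts
  agreement with an independent normal-equations oracle to 1e-10. The
  p-value is the two-sided t test with n − k degrees of freedom.
* Logistic fits are maximum likelihood via iteratively reweighted least
  squares (tolerance 1e-8 on the coefficient step, at most 50
  iterations), with Wald p-values. |β| > 15 during iteration is treated
  as separation. IRLS is implemented in the package; statsmodels serves
  only as an independent oracle in the test suite.
* Continuous responses are fit twice: raw and after y → log(y + 1)
  (natural log; the +1 keeps zero-valued measurements in the analysis).
  When a phenotype has negative values the transform is undefined and
  that response is skipped and counted in the scan manifest. Categorical
  phenotypes with L ≥ 3 labels expand into L one-vs-rest binary
  responses; a two-label categorical collapses to a single binary
  response.
* Fits that cannot proceed — monomorphic or collinear genotype, one-class
  outcome, n below `min_n` (default 10), an outcome group below
  `min_cases` (default 5), zero residual variance, separation — are
  skipped and tallied by reason in a per-study manifest. The floors are
  package defaults: the emulated studies ran tests with n as low as 13,
  and some floor is needed to avoid degenerate fits; both are
  configurable.

### Phenotype classes and polarity

Curators bin per-study phenotype labels into 30 classes. Each map entry
also carries a polarity in {+1, −1}: the harmonized direction of a record
is sign(β · polarity), so an inversely coded label ("Never hypertensive
(Y/N)") with a negative beta supports the same direction as a directly
coded one with a positive beta. Zero betas harmonize to "0" and never
support replication.

The packaged default map covers every label in the bundled
concomitant-results fixture plus representative labels for the remaining
classes. Map entries are keyed on the verbatim per-study label, including
any transform prefix the source table printed, because the fixture keeps
those labels verbatim. Polarity is curation: most flips follow label
semantics, a few are certified only by reproducing the published rows
(the certification suite pins every row's class set and direction flag),
and users can edit the TSV.

### Replication and calling

A (variant, class) pair replicates at threshold t when some harmonized
direction is supported by records with p < t from at least two distinct
studies. The default `direction_rule="concordant"` tolerates discordant
stragglers — additional sub-threshold records in the other direction —
because the published result rows themselves contain such stragglers
within replicated classes; the stricter `"unanimous"` reading (every
sub-threshold record of the pair must agree) is available as an option.
When both directions somehow qualify, the hit takes the direction with
more studies, then more records, then the smaller minimum p. A variant
with two or more replicated classes becomes a pleiotropy call;
`opposite_between_classes` is set when its class directions differ.
Expected-but-uninteresting class combinations (e.g. LDL with total
cholesterol, or white-blood-count couplings restricted to one chromosome)
are removed by configurable exclusion rules, not hard-code.

A pre-binning variant of the filter (`replicate_same_phenotype`) counts
replication for identical phenotype names across studies; both stages are
exposed because they answer different questions (the same-phenotype count
is much larger than the class-level count).

### LD collapsing

Independent signals are formed greedily: sort calls by minimum supporting
p (ties by variant id), seed a cluster with the best unassigned call, and
absorb every unassigned call whose composite LD with the seed — the
squared Pearson correlation of unphased dosage vectors — reaches `r2_min`
(default 0.80). The seed is the representative. Greedy-by-significance is
standard clumping practice; the procedure accepts any genotype source for
the r² computation (here, study genotypes; a reference panel would do).
A constant dosage vector has undefined correlation and is treated as
r² = 0, logged.

### Permutation-derived threshold

Within each study, one uniform permutation of sample labels is applied
jointly to the entire phenotype block, so genotype–genotype and
phenotype–phenotype dependence are both preserved while every
genotype–phenotype pairing is broken. Genotype-derived PCs stay with the
genotypes; sex moves with the phenotype block by default (it belongs to
the phenotype side of the pairing), controlled by `permute_sex`. Studies
are permuted independently. For each of B permuted datasets the full scan
and counting pipeline is re-run, and for each threshold two counts are
recorded: replicated (variant, class) pairs and multi-class variants.
The empirical p of an observed count uses the add-one estimator
(1 + #{b : permuted_b ≥ observed}) / (B + 1), which is never zero and is
super-uniform under the null. The reporting helper recommends the largest
threshold in the grid (default {1e-2, 1e-3, 1e-4, 1e-5}) whose
multi-class empirical p is at most α = 0.05. B defaults to 1000; the
desk-scale tests use B = 99.

### Local ancestry

Local-ancestry inference itself (LAMP-LD, ADMIXTURE) is consumed, not
re-implemented: the expected input is a samples × variants matrix of
African-derived allele copies (0/1/2, missing allowed). A locus profile
is the fraction of individuals with 0, 1 and 2 copies; the locus African
proportion is (f₁ + 2 f₂)/2; the genome-wide proportion is the mean
copy count over all entries divided by two. A locus is *admixed* when
its proportion is within `tol` of the global value, else
*African-derived* or *European-derived* by the sign of the deviation.
The source gives no numeric tolerance for "consistent with global
ancestry"; `tol = 0.10` is the default here, certified against the five
published exemplar rows (JAZF1 and TLL2 European-derived, RBKS
African-derived, PHACTR1 and B7H6 admixed at global 0.788), and it is a
flag. One published ancestry row (the SPARC locus) is internally
inconsistent with its own admixed classification and is carried in the
fixture with a note, excluded from certification.

## The synthetic generator

The generator emulates the study conditions the pipeline targets, with
defaults fixed to the emulated design:

* **Three unequal cohorts**, default n = 3430/549/2186, the third
  female-only, sharing a variant panel but not samples.
* **Two-way admixture.** Each haplotype's ancestry is a two-state Markov
  chain along position: stationary African probability `global_african`
  (default 0.788), and on each inter-variant interval a switch event with
  probability 1 − exp(−rate·distance) after which the state is redrawn
  from the stationary distribution. The default rate, 1e-7 per basepair,
  corresponds to roughly the number of generations since admixture in
  African American populations times the recombination rate; variants sit
  on a uniform 4 kb grid by default. Alleles are Bernoulli draws with
  origin-matched frequencies (defaults U(0.05, 0.5) per variant per
  origin), so within-origin genotypes are in Hardy–Weinberg proportions
  and the realized frequency is the ancestry-weighted mixture.
* **Latent class scores.** Genetic effects are specified per (variant,
  class) in standardized-dosage units; a class score is the effect sum
  plus shared class noise (`class_noise_sd`, default 0.5). A phenotype is
  polarity · loading · score plus independent noise (`noise_sd`, default
  1.0), giving classmates a correlation of about
  s²/(s² + σ²) — 0.2 at the defaults — which is what makes class-level
  replication aggregate the way it does on real data. Binary phenotypes
  are Bernoulli with logit(prevalence) + signal; categoricals bin a
  continuous latent into tertiles. Availability masks drop phenotypes
  from studies without disturbing the random stream, so masked and
  unmasked runs are comparable.
* **Determinism.** All draws flow from one `numpy` generator seeded by
  the config; the same seed reproduces every downstream number.
* **LD.** Variants are unlinked apart from optional duplicated-column
  blocks used to exercise the collapsing step; realistic LD decay is out
  of scope.

Continuous phenotypes are mean-zero latent scales, not positive lab
measurements; the log(y+1) arm of the scan is therefore exercised by unit
tests with non-negative data rather than by the synthetic benchmarks, and
the benchmarks say nothing about transform-induced differences on real
measurements. Similarly, the generator's independent variants mean the
permutation calibration here does not probe LD-induced dependence between
SNPs — only phenotype-side dependence, which the block permutation
preserves exactly.

## What the benchmarks measure

The headline numbers of the emulated study (5,424 replicated tests, 133
multi-class SNPs, the 188-vs-3 permutation comparison, reference-panel
LD collapsing to 38 signals) require controlled-access individual-level
data and are not desk-reproducible; the suite instead certifies the
procedure:

* the packaged published records reproduce all 43 table rows — class
  sets and opposite-direction flags — through the real pipeline;
* fits match independent oracles (normal equations, an independent MLE)
  to 1e-10 / 1e-6 on random instances;
* on a no-effect three-study dataset (500 SNPs, 40 phenotypes, 12
  classes, n = 3000/500/2000) scan p-values pass KS uniformity and hit
  the nominal 1% rate within Monte-Carlo error;
* the multi-class empirical p is super-uniform over 200 seeded null
  replicates at B = 99 (a small 16-SNP, 6-phenotype design keeps 20,000
  full scans tractable);
* one SNP with standardized effect 0.15 on two classes — at the default
  cohort sizes the class-level replication filter has essentially full
  power for such an effect — is called in ≥ 80% of 200 replicates with
  fitted standardized effects unbiased to within 0.02;
* greedy collapsing agrees with a hand-traced three-variant chain and
  merges duplicated columns.

## Numerical choices and edge cases

Strict inequalities follow the source conventions: records enter
replication only with p strictly below the threshold, and the frequency
filter keeps variants strictly above 1%. Dosage missingness is NaN,
always distinct from zero; allele frequencies and ancestry profiles use
non-missing entries only. The linear scan flags fits with residual sum of
squares at numerical zero as degenerate rather than reporting p = 0.
Empirical p-values use the add-one estimator, so they are never 0 and at
most 1. Cluster and call orderings are deterministic (p, then lexical),
so pipeline output is invariant to record and study order.

## Known limitations

Single-variant tests only: no mixed models or kinship adjustment, no
X/Y/mitochondrial variants, and no formal cross-phenotype statistic (the
procedure is deliberately filter-based). Class curation is by label, not
by statistical clustering of phenotypes, and the polarity mechanism is
only as good as the curation. The synthetic admixture model has no
linkage between variants and two ancestries only. The published-table
fixture inherits a handful of typographical defects from its source;
emendations are confined to restoring obvious transform prefixes and
positions and are noted in the fixture files.
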