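# pleiopheno

Cross-phenotype (pleiotropy) detection for multi-study phenome-wide
association studies (PheWAS) in admixed populations.

A PheWAS is the transpose of a GWAS: every genetic variant is tested
against hundreds of phenotypes. When several independent epidemiologic
cohorts contribute data — with different phenotype batteries, different
sample sizes, and one cohort female-only — the question "which SNPs are
associated with two or more *distinct* traits?" cannot be answered by a
single genome-wide threshold. `pleiopheno` implements the filter-based
procedure used for Metabochip PheWAS of African American cohorts:

1. **Per-study scans.** Each SNP with minor coded-allele frequency > 1% is
   tested against every available phenotype under an additive model
   (dosage *g* ∈ {0, 1, 2} of the coded allele), adjusted for the first
   two genotype-derived principal components and sex (omitted in a
   female-only study):

   - continuous *y*: OLS of *y* on (1, *g*, PC1, PC2, sex), repeated on
     log(*y* + 1); two-sided *t* test for β_g,
   - binary *y*: logistic maximum likelihood (IRLS), Wald test,
   - categorical *y*: one "A versus not A" logistic response per label.

2. **Phenotype classes.** A curated map bins per-study phenotype labels
   into 30 phenotype classes, with a coding *polarity* (±1) so that
   inversely coded labels ("Never hypertensive", "years since quit
   smoking") harmonize: the direction of a record is sign(β · polarity).

3. **Replication and pleiotropy calling.** A (variant, class) pair
   replicates when records with p < 0.01 from ≥ 2 studies share one
   harmonized direction; a variant with ≥ 2 replicated classes is a
   pleiotropy call, flagged when its classes disagree in direction.

4. **LD collapsing.** Calls are clustered greedily by composite LD
   (squared dosage correlation): the best-p unassigned call seeds a
   cluster and absorbs every call with r² ≥ 0.80 to the seed.

5. **Empirical threshold.** Within each study the whole phenotype block is
   permuted against the genotype matrix (preserving genotype–genotype and
   phenotype–phenotype correlations) and the entire analysis is re-run B
   times; the empirical p-value of an observed count C is
   (1 + #{b : C_b ≥ C}) / (B + 1).

6. **Local ancestry.** Called loci are profiled from external 0/1/2
   African-derived-allele calls and classified *admixed* when the locus
   African proportion is within 0.10 of the genome-wide average (78.8%
   here), else *African-derived* or *European-derived*.

The package ships the published concomitant-association records and
ancestry rows as fixtures, plus a synthetic multi-study generator
(two-way admixed genotypes, latent class scores, availability masks) so
the entire pipeline is testable without controlled-access cohort data.

## Worked example

```python
import numpy as np, pandas as pd
from pleiopheno.fixtures import certify_table4
from pleiopheno import simulate as sim
from pleiopheno.association import run_study_phewas
from pleiopheno.pipeline import replicate_class, detect_pleiotropy
from pleiopheno.permutation import permutation_phewas, empirical_summary

# 1. reproduce the published pleiotropy calls from the packaged records
calls, expected = certify_table4()
print(f"{len(calls)} pleiotropic variants reproduced from the packaged records")
call = next(c for c in calls if c.variant_id == "rs9349379")
print(f"rs9349379: classes={sorted(call.class_names)}, "
      f"opposite_between_classes={call.opposite_between_classes}")
call = next(c for c in calls if c.variant_id == "rs4958487")
for h in sorted(call.classes, key=lambda h: h.phenotype_class):
    print(f"rs4958487 {h.phenotype_class}: direction {h.direction}, "
          f"studies {sorted(h.studies)}, min p {h.min_p:.3g}")

# 2. synthetic three-study dataset with one injected pleiotropic SNP
cfg = sim.signal_config(effect=0.15, n_per_study=(3430, 549, 2186),
                        m_variants=20, n_phenotypes=8, n_classes=4, seed=42)
cohorts = sim.build_multistudy_dataset(cfg)
cmap = sim.class_map_from_config(cfg)
records = pd.concat([run_study_phewas(c) for c in cohorts], ignore_index=True)
calls = detect_pleiotropy(replicate_class(records, cmap, p_max=0.01))
print(f"pleiotropy calls: {[(c.variant_id, sorted(c.class_names)) for c in calls]}")

# 3. permutation-derived empirical significance
summary = permutation_phewas(cohorts, 99, cmap, np.random.default_rng(42),
                             thresholds=(1e-2, 1e-3))
report = empirical_summary(summary)
row = report["per_threshold"][0]
print(f"t=0.01: observed multiclass {row['observed_multiclass']} vs permuted "
      f"max {row['permuted_max_multiclass']} -> empirical p "
      f"{row['empirical_p_multiclass']:.3g}")
```

prints

```
43 pleiotropic variants reproduced from the packaged records
rs9349379: classes=['Diabetes', 'Hypertension', 'Smoking'], opposite_between_classes=True
rs4958487 Glucose Levels: direction +, studies ['ARIC', 'WHI'], min p 0.00129
rs4958487 Hypertension: direction +, studies ['ARIC', 'WHI'], min p 0.00665
pleiotropy calls: [('snp00000', ['class0', 'class1'])]
t=0.01: observed multiclass 1 vs permuted max 0 -> empirical p 0.01
```

The 43 variants are the published concomitant results after removing the
LDL/total-cholesterol co-memberships and the chromosome-1 white-blood-count
couplings; rs9349379 (*PHACTR1*) is the one variant with three phenotype
classes, opposite in direction between them, and rs4958487 (*SPARC*) is the
glucose/hypertension example. On the synthetic data, the injected SNP with
standardized effect 0.15 on two latent classes is the only pleiotropy
call, and no permuted dataset matches the observed multi-class count, so
its empirical p equals 1/(B+1) = 0.01.

A command-line layer mirrors this flow: `pleiopheno run --config cfg.yaml`,
`pleiopheno pleiotropy --records R.tsv`, `pleiopheno collapse`,
`pleiopheno permute --B 1000 --seed 42`.

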