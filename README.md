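# rohkin

Runs of homozygosity, inbreeding decomposition and disease association for
admixed cohorts.

`rohkin` is a toolkit for studying how genomic homozygosity relates to
disease risk in populations — such as Latin American admixed cohorts — where
inbreeding arises from a mixture of **genetic drift** (small effective
population size, isolation) and **consanguinity** (recent related matings).
It was built around a case-control analysis of gallbladder cancer (GBC) in a
Chilean cohort with Aymara–Quechua and Mapuche–Huilliche indigenous American
ancestry components, but every layer is generic.

## What it does

1. **Genotype I/O and QC** (`rohkin.genotype_io`): PLINK 1 BED/BIM/FAM
   reading/writing; exact Hardy–Weinberg test; MAF < 0.01 and HWE p < 0.001
   variant filters.
2. **ROH calling** (`rohkin.roh_caller`): the standard SNP-array sliding
   window scan — 30-SNP windows, ≤ 1 heterozygote and ≤ 5 missing calls per
   window, 5% hit threshold, segments ≥ 30 SNPs, ≥ 300 kb, ≥ 1 SNP / 30 kb,
   1 Mb maximum gap.
3. **Inbreeding coefficients** (`rohkin.inbreeding`):
   - `F_IS = (O(HOM) − E(HOM)) / (N − E(HOM))` — excess individual
     homozygosity over the Hardy–Weinberg expectation (consanguinity when
     positive);
   - `F_ROH = Σ ROH>1.5 Mb / 3 Gb` — genomic inbreeding, a proxy for the
     total inbreeding coefficient `F_IT`;
   - the drift component implied by `(1 − F_IT) = (1 − F_IS)(1 − F_ST)`;
   - six ROH length-class sums (0.3–0.5, 0.5–1, 1–2, 2–4, 4–8, ≥ 8 Mb) and
     the inbreeding-depression mean `M_F = M_0 − 2F Σ d_i p̄_i q̄_i`.
4. **Pedigree simulation** (`rohkin.pedigree_sim`): gene-dropping of
   founder-labelled haplotypes through second-cousin (F = 1/64),
   first-cousin (1/16), avuncular (1/8) and incest (1/4) pedigrees with
   Poisson recombination, yielding exact autozygous tracts.
5. **Origin classification** (`rohkin.origin`): NROH-vs-SROH geometry
   against an outbred baseline (consanguinity shifts individuals right of
   the drift diagonal) plus the three regions of the F_IS/F_ROH plane;
   one-way ANOVA of ROH burden across ancestry groups.
6. **Association** (`rohkin.association`): maximum-likelihood logistic
   regression of case status on F_ROH (per 1%) adjusted for sex, age + age²,
   education, BMI category, ancestry proportions (per percentage point) and
   a weighted gallstone-disease polygenic risk score entered as log2(score)
   (OR per doubling); interaction tests and stratified odds ratios
   (sex, age < / ≥ 60, PRS below/above median).
7. **Synthetic cohorts** (`rohkin.synthetic_cohort`): download-free
   generator reproducing the cohort's structure — six ancestry groups with
   calibrated drift (founder-pool haplotype mosaics) and consanguinity
   (pedigree routing), covariates with realistic marginals, and outcomes
   from the published logistic coefficients.

## Worked example

```python
import numpy as np
from rohkin import (default_config, generate_cohort, fit_gbc_model,
                    simulate_mating, GenomeMap)
from rohkin.association import stratified_or, forest_table

# synthetic cohort generated with the published effect sizes
cohort, truth = generate_cohort(default_config(n=20_000), seed=7)
res = fit_gbc_model(cohort)
for term in ("froh_pct", "sex_female", "log2_prs"):
    print(term, res.term(term))

offs = simulate_mating("first_cousin", GenomeMap.human22(),
                       n_offspring=1000, seed=7)
print(np.mean([o.f_auto for o in offs]))
```

prints (formatted):

```
cohort: n=20000, cases=15.3%, median F_ROH=0.0088
F_ROH per 1%                 OR 1.09 (95% CI 1.06-1.12)
female sex                   OR 3.78 (95% CI 3.40-4.21)
Mapuche-Huilliche per %      OR 1.02 (95% CI 1.02-1.02)
gallstone PRS per doubling   OR 2.86 (95% CI 2.49-3.29)
first-cousin offspring: mean autozygous fraction 0.0618 (theory 0.0625)
```

The fitted odds ratios recover the coefficients the generator planted
(female sex 3.48, PRS 2.75 per doubling, F_ROH 1.07 per 1%), and simulated
first-cousin offspring carry the analytic autozygous fraction 1/16.

A full run — genotype synthesis, QC, ROH calling, inbreeding profiles,
origin classification and association — is one command:

```sh
rohkin run --seed 1 --out-dir run1        # writes run1/summary.json
rohkin simulate --mating first_cousin --n 5000 --seed 1 --out sim.tsv
rohkin qc --bed g.bed --bim g.bim --fam g.fam --out qc
rohkin roh --bed qc.bed --bim qc.bim --fam qc.fam --out roh.tsv
```

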