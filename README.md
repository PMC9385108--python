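# survmdr

Multifactor dimensionality reduction (MDR) for censored survival and
binary outcomes: covariate-adjusted SNP–SNP interaction search with
cross-validated model selection, permutation testing, iterative
main-effect removal, and regression / Kaplan–Meier validation — plus a
synthetic-cohort generator with plantable ground-truth effects so the
whole workflow is testable end to end.

## Who this is for

Statistical geneticists and cancer epidemiologists asking whether
*combinations* of common genotypes — 1-, 2- or 3-way — separate patients
with different outcome risks, in cohorts of a few hundred subjects where
a 27-cell genotype table is far too sparse for direct modelling.

## The method

All genotype effects are measured against a covariates-only null model.
For survival data this is a Cox model (Breslow ties); each subject's
score is the martingale residual

&nbsp;&nbsp;&nbsp;&nbsp;*s<sub>i</sub>* = *δ<sub>i</sub>* − Λ̂₀(*t<sub>i</sub>*)·exp(γ̂ᵀ*z<sub>i</sub>*),

the observed minus expected event count. For a 5-year binary outcome the
scores are logistic score residuals *y<sub>i</sub>* − *p̂<sub>i</sub>*.
A cell of the {0,1,2}<sup>k</sup> dosage lattice is **high-risk** when its
training subjects' scores sum above zero, collapsing each k-SNP table to
one binary attribute. Model quality is the score-mass balanced accuracy
(mean of the positive-mass sensitivity and negative-mass specificity);
5-fold cross-validation scores every C(m,k) combination; the run-best
model is chosen by testing balanced accuracy (TBA) or by cross-validation
consistency (CVC, with its deliberately order-dependent earliest-in-file
tie-break), and 20 repeated runs form the consensus "top model". Its
significance comes from permutation of genotype rows against the joint
(outcome, covariates) rows, and significant 1-way models are iteratively
removed — together with all r² ≥ 0.8 LD partners — before the 2-/3-way
scans. See `docs/methods.md` for the full treatment.

## Worked example

Plant a pure 2-way interaction — heterozygosity-parity cells at MAF 0.5
carry a hazard ratio of 4 but leave every single SNP marginally
uninformative — and recover it:

```python
import numpy as np
from survmdr import (SimulationConfig, planted_model_presets, simulate_dataset,
                     repeated_search, permutation_test, assign_risk_groups,
                     cox_regression_validation, km_logrank)
from survmdr.pipeline import PipelineConfig, compute_scores

cfg = SimulationConfig(n_subjects=600, n_snps=20, maf_range=(0.5, 0.5), seed=7)
effect = planted_model_presets("xor2", [2, 7], np.log(4.0))
ds = simulate_dataset(cfg, effect=effect)

mask, scores = compute_scores(ds, PipelineConfig(engine="cox"))
top, runs = repeated_search(ds.geno, scores, k=2, n_runs=20, base_seed=1)
perm = permutation_test(ds.geno, scores, k=2, n_perm=200, seed=2, partition_seed=3)
group = assign_risk_groups(ds.geno, top.model)
res = cox_regression_validation(group, ds.covariates, ds.time, ds.event,
                                direction="high_vs_low")
```

Output:

```
cohort: 600 subjects, 20 SNPs, 367 events
top 2-way model: rs000003+rs000008 (frequency 20/20, mean TBA 0.784)
high-risk cells: [(0, 1), (1, 0), (1, 2), (2, 1)]
permutation p: < 0.005 (observed mean TBA 0.785)
adjusted HR (high vs low): 4.07 (95% CI 3.24-5.10, p = 6.49e-34)
log-rank p: 1.67e-37
```

The search finds exactly the planted pair (columns 2 and 7, i.e.
`rs000003`/`rs000008`) in all 20 runs; the high-risk cells are precisely
the odd-heterozygosity cells of the planted parity effect; the permutation
test puts the observed mean TBA above all 200 null values; and the
covariate-adjusted Cox fit recovers a hazard ratio close to the planted 4.

A scikit-learn-style estimator wraps the same search
(`MDRSearch(k=2, n_runs=20).fit(X, scores).predict(X)`), and a CLI covers
the file-based workflow:

```
survmdr simulate --config sim.yaml --out-prefix cohort
survmdr qc       --in cohort.raw --out cohort.qc
survmdr search   --in cohort.qc.raw --pheno cohort.pheno.tsv --k 2 --out run1/
survmdr permute  --in cohort.qc.raw --pheno cohort.pheno.tsv --k 2 --out null.tsv
survmdr run      --config pipeline.yaml --in cohort.raw --pheno cohort.pheno.tsv --out report/
```

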