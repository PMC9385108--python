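# Methods

## The problem

Single common variants rarely explain much of the variation in cancer
patient outcomes; combinations of genotypes may matter where no single SNP
does. Exhaustively testing k-SNP interactions is statistically awkward —
a 3-way scan over even 100 SNPs spans 161,700 candidate triples, each a
27-cell contingency table over a few hundred subjects. Multifactor
dimensionality reduction (MDR) addresses the sparsity by collapsing each
k-SNP genotype table to a single binary attribute (high-risk vs low-risk
cells) before any accuracy is measured. `survmdr` implements the
survival-outcome version of this programme: covariate-adjusted residual
scores drive the cell classification, cross-validation and repeated runs
select a consensus model, permutation testing calibrates its significance,
and conventional regression/Kaplan–Meier analyses validate the resulting
risk grouping.

## Residual scores (the "null model")

All genotype effects are measured against a covariates-only null model.

* **Survival engine** — a Cox proportional-hazards model of the survival
  outcome on the clinical covariates only, with Breslow tie handling and
  the Breslow step-function baseline cumulative hazard Λ̂₀. Each subject's
  score is the martingale residual

      s_i = δ_i − Λ̂₀(t_i) · exp(γ̂ᵀ z_i),

  the observed minus model-expected number of events. With the Breslow
  baseline the residuals sum to zero *identically* (for any coefficient
  vector), which the tests exploit as an exact invariant. Breslow rather
  than Efron ties: the residual algebra above only cancels with the
  Breslow baseline, and the validation fits use the same convention so
  null and validation models are comparable. Subjects with follow-up past
  the last event time use the right-constant extension of Λ̂₀.

* **Binary engine** — a logistic regression of the 5-year outcome status
  on the covariates, intercept included. Scores are the GLM score
  residuals s_i = y_i − p̂_i, which sum to zero by the intercept's score
  equation. Subjects censored alive before the 5-year horizon have
  unknown status and are excluded before the fit and from every
  downstream binary-engine stage. Raw residuals are used without
  standardisation: the classification and balanced accuracy below depend
  only on signs and relative magnitudes, which standardisation cannot
  change.

## Cell classification and balanced accuracy

For a combination of k SNPs (k = 1–3) each subject falls in one cell of
the {0,1,2}^k dosage lattice. A cell is labelled **high-risk** when the
training subjects' scores in it sum strictly above T = 0; sums at or below
zero, and cells with no training subjects, are low-risk — no evidence is
treated as no risk, which avoids inflating high-risk groups from empty
cells.

Model quality is a *score-mass* balanced accuracy. With P the total
positive score mass and N the total |negative| mass in the evaluation set,

    sensitivity = (positive mass inside high cells) / P
    specificity = (negative mass inside low cells) / N
    BA          = (sensitivity + specificity) / 2.

This weighting follows the generalized-MDR treatment of continuous scores:
a subject who did much worse than the covariates predict counts for more
than one who barely did. BA is invariant to positive rescaling of the
scores, and negating all scores flips every label and maps BA to 1 − BA
(both are property-tested). BA is undefined when an evaluation set carries
only one score sign; this is an error, not a default value.

## Cross-validation, selection strategies, consensus

Every analysis uses 5-fold cross-validation: random folds of size ⌊n/5⌋ or
⌈n/5⌉ (an event-stratified mode exists but is off by default, since plain
random partitioning is the reference behaviour). Per fold, all C(m,k)
combinations are trained on the 4/5 training scores; the fold-best is the
highest training BA, with exact ties broken to the lexicographically
earliest combination in current column order (deterministic and logged).
The fold-best's cell labels are then scored on the held-out 1/5 (TBA).

Two run-level selection strategies are provided, deliberately mirroring
the two software lineages this package generalises:

* **tba** — among the fold-best models, pick the one with the highest
  mean TBA over the folds where it was fold-best (ties: lexicographically
  smallest sorted SNP-id tuple, which is column-order invariant).
* **cvc_first_in_file** — pick the highest cross-validation consistency
  (CVC = number of folds where the combination was fold-best); ties go to
  the combination whose SNPs appear earliest in the dataset. This
  reproduces a real behaviour of the CVC-based selection lineage: under a
  CVC tie the answer depends on input column order. The package treats
  this as a property to be exposed and tested, not hidden — the
  order-dependence study constructs CVC-tie instances and verifies that
  reversing the column order always changes the cvc pick and never the
  tba pick.

The run-best combination is retrained on the full dataset to fix its cell
labels. A *top model* is the consensus of 20 independent runs with fresh
fold partitions: run-best models are grouped by (SNP ids, high-cell set)
jointly, and the most frequent group wins, with ties broken by mean TBA
and then CVC. The run-best TBA is the mean testing BA over the folds where
the model was fold-best; the aggregation is a declared choice, stamped
into the result objects.

## Permutation testing

Significance of a top model's mean TBA is assessed by permuting genotype
rows against the joint (outcome, covariates) rows. This preserves the
outcome–covariate relationship and every marginal, and tests precisely
"no genotype association given the covariates". Because the residual
scores never see genotypes, a permutation is implemented as re-linking the
fixed score vector to shuffled genotype rows — algebraically identical to
recomputing the scores from the permuted dataset, and asserted equal to
that naive route in the tests. Each permutation runs one cross-validated
search with the same fold-partition seed as the observed statistic, so
observed and null values are exchangeable under the null; p is the
fraction of null statistics at or above the observed one (zero counts are
reported as "< 1/n_perm"; an add-one variant is a flag). One search per
permutation — not 20 repeated runs — keeps 1,000-permutation analyses
tractable; the observed statistic is computed the same single-run way for
comparability. The type-I error of this construction is calibrated
empirically in the acceptance suite: with no planted effect,
Pr(p ≤ 0.05) ≈ 0.05 over 100 replicate cohorts.

## Main-effect removal and the full workflow

A SNP with a strong marginal effect can masquerade as part of spurious
higher-order interactions. The workflow therefore iterates 1-way searches:
while the 1-way top model's permutation p is below α = 0.05, the top SNP
and every SNP in high LD with it (dosage r² ≥ 0.8) are removed and the
search repeats; the first non-significant iteration ends the loop and is
recorded along with all removal iterations. Removal is gated on the
permutation p alone — an iteration can be permutation-significant but
regression-non-significant, and the workflow must still proceed past it;
a strict mode requiring both is available. The 2-way and 3-way searches
then run on the reduced SNP set. No multiple-testing correction is applied
across interaction orders; per-test permutation p-values are reported
as such.

## Genotype QC and LD

Filters: minor allele frequency ≥ 0.05 (alleles are relabelled when the
coded allele's frequency exceeds 0.5, with the swap recorded), exact
Hardy–Weinberg test p > 1e-4, missing-call rate ≤ 0 (i.e. none). The HWE
test is the Levene–Haldane exact conditional test, two-sided by
probability-mass ordering without a mid-p correction, with monomorphic
SNPs assigned p = 1. Groups of SNPs with pairwise r² = 1 are statistically
indistinguishable to a cell-based search, so each group is collapsed to
its earliest member in file order ("keep first" is a convention, declared
here because the choice is otherwise arbitrary).

All r² values are squared Pearson correlations of the 0/1/2 dosage
columns (genotype-scale LD), not EM-phased haplotype r². On unphased data
this is deterministic, invariant to coding flips, and agrees with
haplotype r² exactly at the r² = 1 screen; the dialect is recorded in the
QC report metadata.

## Synthetic cohorts

No real genotype–outcome data ships with the package; every experiment
runs on simulated cohorts that emulate the structure of a modest
colorectal-cancer cohort study:

* **Genotypes** — per-SNP HWE draws at a target MAF in [0.05, 0.5].
  LD blocks use a Gaussian copula: per haplotype, a latent equicorrelated
  normal vector across the block is thresholded at the MAF quantile; the
  latent correlation is calibrated (bivariate-normal orthant probability,
  Brent root-finding) so allele-level — hence dosage-level — pairwise r²
  hits the block target, exactly reproducing column copies at r² = 1.
  Multi-SNP blocks share one MAF, which makes the calibration exact and is
  required by the perfect-copy limit; singletons draw MAF freely.
* **Covariates** — age from a truncated normal on [20, 75] parameterised
  by its realized mean (61 by default), ordinal stage, and Bernoulli MSI /
  tumor-location / chemo / radio indicators. The emulated study's actual
  covariate distributions are not published in the available text, so
  these defaults are generic and fully exposed in `SimulationConfig`.
* **Survival** — Weibull proportional hazards
  h(t) = λρt^{ρ−1}·exp(β_g·1[cell high] + γᵀz) with λ = 0.03, ρ = 1.3
  (≈45% events within 10 years at covariate baseline), administrative
  censoring at 10 years plus exponential dropout at 0.03/year — follow-up
  and event fractions in the range typical of such registries. The 5-year
  dichotomization marks subjects censored alive before the horizon as
  excluded.
* **Planted effects** — explicit high-cell sets with a known log hazard
  ratio. Presets: dominant (carrier), recessive (homozygous minor), and
  xor2/xor3, which label a cell high when an odd number of its SNPs are
  heterozygous. At MAF 0.5 a heterozygosity indicator is a fair coin, so
  the xor parity is marginally independent of every individual dosage — a
  pure interaction with no main effect, the configuration cell-based
  search exists to detect and single-SNP scans cannot.

What passing recovery tests on these cohorts shows: the search, selection,
permutation and removal machinery behave correctly when the generative
model matches the analysis assumptions (proportional hazards, independent
subjects, clean genotypes). What they do not show: robustness to
population structure, genotyping error, non-proportional hazards,
informative censoring, or covariate misspecification — none of which the
generator emulates.

## Numerical choices and problem sizes

* Cell-mass accumulation uses one weighted `bincount` per combination
  chunk; enumeration is lexicographic and chunked, and results are
  independent of chunk size (strict-improvement comparisons across chunks,
  first-maximum within a chunk).
* Exact r² = 1 detection uses a 1e-12 tolerance on Pearson r².
* Wald confidence intervals and p-values for validation fits; hazard
  ratios for the low- vs high-risk contrast are the reciprocal
  parameterisation of the high- vs low-risk fit.
* Degenerate inputs are errors, not silent defaults: all-zero scores, a
  one-sided score mass in an evaluation fold, no events, single-class
  binary outcomes, rank-deficient designs (for Cox fits the rank check
  includes an implicit constant column, which the partial likelihood
  cannot identify).
* The benchmark experiments use cohorts of 300–2,000 subjects, 4–20 SNPs,
  200 permutations and 20–100 replicates — sizes at which each headline
  statistic is stable to within its stated tolerance while the full
  battery completes on a single CPU in minutes. The search kernel itself
  streams arbitrarily large combination sets in chunks.

## Known limitations

* k ≤ 3; no model-based MDR variants; no haplotype-aware LD or
  genome-coordinate windowed pruning; no PLINK binary parsing.
* The permutation scheme permutes genotypes against outcome+covariates
  jointly; schemes that permute residuals, or outcomes before adjustment,
  answer slightly different questions and are not implemented.
* Whether a CVC tie should compare high/low label maps in addition to SNP
  identity is ambiguous in the CVC lineage; here CVC counts fold-best
  matches on SNP identity alone, while consensus identity includes the
  label map.
* Regression validation uses the dichotomous risk-group variable only; no
  per-cell multi-level validation.
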