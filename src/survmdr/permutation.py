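"""Permutation significance for a selected MDR model.

The null hypothesis is "no genotype-outcome association given the
covariates": genotype rows are shuffled against the joint (outcome,
covariate) rows, which preserves the outcome-covariate relationship and
every marginal distribution. Because the residual scores depend only on
outcome and covariates, a permutation amounts to re-linking the fixed
score vector to permuted genotype rows — an exact algebraic shortcut over
refitting the null model per permutation (asserted against the naive route
in the tests).

Each permutation runs ONE cross-validated search with the same fold
partition seed as the observed statistic, and the p-value is the fraction
of null statistics at or above the observed run-best mean TBA.
"""

from __future__ import annotations

import numpy as np

from .mdr import cv_search
from .types import DataError, Dataset, GenotypeMatrix, PermutationResult

__all__ = ["permute_genotype_rows", "permute_dataset", "permutation_test"]


def permute_genotype_rows(dosage: np.ndarray, rng) -> np.ndarray:
    perm = rng.permutation(len(dosage))
    return dosage[perm]


def permute_dataset(dataset: Dataset, seed) -> Dataset:
    """Shuffle genotype rows against the (outcome, covariate) rows."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(dataset.n_subjects)
    geno = GenotypeMatrix(
        dosage=dataset.geno.dosage[perm].copy(),
        subject_ids=dataset.geno.subject_ids,  # subjects keep their outcome rows
        snps=dataset.geno.snps.copy(),
    )
    return dataset.with_geno(geno)


def permutation_test(
    geno,
    scores,
    k: int,
    n_perm: int = 1000,
    seed=0,
    strategy: str = "tba",
    partition_seed=0,
    threshold: float = 0.0,
    add_one: bool = False,
    engine: str = "cox",
) -> PermutationResult:
    """Permutation p-value for the run-best mean TBA at order k.

    The observed statistic and every null statistic come from a single
    cv_search with the same fold-partition seed, so observed and null are
    exchangeable under the null hypothesis. ``add_one`` switches to the
    (b+1)/(m+1) estimator; by default p = #{null >= observed} / n_perm and
    a zero count is labelled "< 1/n_perm".
    """
    if n_perm < 1:
        raise DataError("n_perm must be at least 1")
    if isinstance(geno, GenotypeMatrix):
        dosage = geno.dosage
    else:
        dosage = np.asarray(geno)
    s = np.asarray(scores, dtype=float)
    observed = cv_search(
        geno, s, k, seed=partition_seed, strategy=strategy, threshold=threshold
    ).mean_tba
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        d_perm = permute_genotype_rows(dosage, rng)
        null[b] = cv_search(
            d_perm, s, k, seed=partition_seed, strategy=strategy, threshold=threshold
        ).mean_tba
    count = int(np.sum(null >= observed))
    if add_one:
        p = (count + 1) / (n_perm + 1)
        label = f"{p:.4g}"
    else:
        p = count / n_perm
        label = f"< {1.0 / n_perm:g}" if count == 0 else f"{p:.4g}"
    return PermutationResult(
        observed=float(observed),
        null_statistics=null,
        p_value=float(p),
        p_label=label,
        n_perm=n_perm,
        seed=seed,
        engine=engine,
        k=k,
    )
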