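"""End-to-end workflow: QC, scoring, main-effect removal, multi-locus search.

The orchestration mirrors the standard MDR survival-analysis workflow:

1. genotype QC and r^2 = 1 deduplication;
2. covariates-only null model and residual scores;
3. 1-way search with permutation testing, iterated — each significant
   main-effect SNP is removed together with every SNP in high LD with it
   (r^2 >= 0.8) until the 1-way top model is no longer significant;
4. 2-way and 3-way searches with permutation testing on the reduced
   dataset, with regression/KM validation of significant models.

Main-effect removal is gated on the permutation p-value alone; the
regression summary is reported but does not gate removal (a strict mode
requiring both is available), since an iteration can be permutation-
significant yet regression-non-significant and the search must still
proceed past it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import qc as qc_mod
from .mdr import cv_search, repeated_search
from .permutation import permutation_test
from .scoring import (
    fit_cox_null,
    fit_logistic_null,
    logistic_residual_scores,
    martingale_residuals,
)
from .simulate import COVARIATE_COLUMNS
from .types import DataError, Dataset, GenotypeMatrix

__all__ = ["PipelineConfig", "IterationRecord", "PipelineReport",
           "compute_scores", "run_main_effect_iterations", "run_full_pipeline"]


@dataclass
class PipelineConfig:
    engine: str = "cox"                  # "cox" or "logistic"
    strategy: str = "tba"                # or "cvc_first_in_file"
    k_values: tuple = (2, 3)             # multi-locus orders after main-effect removal
    covariates: tuple = tuple(COVARIATE_COLUMNS)
    n_folds: int = 5
    n_runs: int = 20
    n_perm: int = 1000
    alpha: float = 0.05
    r2_threshold: float = 0.8
    maf_min: float = 0.05
    hwe_min_p: float = 1e-4
    max_missing: float = 0.0
    seed: int = 0
    strict_removal: bool = False         # require regression p < alpha too
    run_qc: bool = True
    max_iterations: int | None = None


@dataclass
class IterationRecord:
    iteration: int
    k: int
    top_model: object                    # TopModel
    permutation: object                  # PermutationResult
    regression: object | None            # RegressionSummary or None
    removed_snp_ids: list
    removed_r2: dict
    stop_reason: str                     # "", "not_significant", "regression_ns", "exhausted"

    def to_dict(self) -> dict:
        return {
            "iteration": self.iteration,
            "k": self.k,
            "top_model": self.top_model.to_dict(),
            "permutation_p": self.permutation.p_value,
            "permutation_p_label": self.permutation.p_label,
            "observed_tba": self.permutation.observed,
            "regression": None if self.regression is None else self.regression.to_dict(),
            "removed_snp_ids": list(self.removed_snp_ids),
            "removed_r2": {k: float(v) for k, v in self.removed_r2.items()},
            "stop_reason": self.stop_reason,
        }


@dataclass
class PipelineReport:
    config: dict
    qc_summary: dict
    input_hash: str
    stage_hashes: dict
    iterations: list = field(default_factory=list)       # 1-way IterationRecords
    multiway: list = field(default_factory=list)         # k=2/3 IterationRecords

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "qc_summary": self.qc_summary,
            "input_hash": self.input_hash,
            "stage_hashes": self.stage_hashes,
            "iterations": [r.to_dict() for r in self.iterations],
            "multiway": [r.to_dict() for r in self.multiway],
        }


def _analysis_arrays(dataset: Dataset, config: PipelineConfig):
    """Subject mask, covariate design and outcome arrays for the engine."""
    cov = dataset.covariates[list(config.covariates)]
    if config.engine == "cox":
        mask = np.ones(dataset.n_subjects, dtype=bool)
        return mask, cov, dataset.time, dataset.event, None
    if config.engine == "logistic":
        if dataset.status5y is None:
            raise DataError("logistic engine requires the 5-year binary outcome")
        mask = dataset.included5y.astype(bool)
        return (
            mask,
            cov.loc[mask].reset_index(drop=True),
            dataset.time[mask],
            dataset.event[mask],
            dataset.status5y[mask],
        )
    raise DataError(f"unknown engine {config.engine!r}")


def compute_scores(dataset: Dataset, config: PipelineConfig) -> tuple[np.ndarray, np.ndarray]:
    """(subject mask, score vector) for the configured engine.

    The scores depend only on outcome and covariates, so they are computed
    once and reused across main-effect iterations and permutations.
    """
    mask, cov, time, event, status = _analysis_arrays(dataset, config)
    if config.engine == "cox":
        null = fit_cox_null(time, event, cov)
        return mask, martingale_residuals(null, time, event, cov)
    null = fit_logistic_null(status, cov)
    return mask, logistic_residual_scores(null, status)


def _validate_model(model, dataset: Dataset, mask, config: PipelineConfig):
    from .validation import (
        assign_risk_groups,
        cox_regression_validation,
        logistic_regression_validation,
    )

    group = assign_risk_groups(dataset.geno, model)[mask]
    cov = dataset.covariates[list(config.covariates)].loc[mask].reset_index(drop=True)
    try:
        if config.engine == "cox":
            return cox_regression_validation(
                group, cov, dataset.time[mask], dataset.event[mask], direction="low_vs_high"
            )
        return logistic_regression_validation(
            group, cov, dataset.status5y[mask], direction="high_vs_low"
        )
    except DataError:
        return None


def run_main_effect_iterations(
    dataset: Dataset,
    config: PipelineConfig,
    scores: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, list]:
    """Iterated 1-way search with LD-aware removal of main-effect SNPs.

    Each iteration runs the repeated 1-way search and its permutation test;
    while the permutation p stays below alpha the top SNP and all its
    r^2 >= threshold LD partners are removed and the loop repeats. Every
    iteration — including the final non-significant one — is recorded.
    """
    if scores is None or mask is None:
        mask, scores = compute_scores(dataset, config)
    geno = dataset.geno
    records = []
    seeds = np.random.SeedSequence([config.seed, 1]).spawn(3)
    base_seed = int(seeds[0].generate_state(1)[0] % (2**31))
    perm_seed = int(seeds[1].generate_state(1)[0] % (2**31))
    part_seed = int(seeds[2].generate_state(1)[0] % (2**31))
    iteration = 0
    limit = config.max_iterations or geno.n_snps
    while True:
        iteration += 1
        geno_masked = GenotypeMatrix(
            dosage=geno.dosage[mask].copy(), subject_ids=geno.subject_ids[mask], snps=geno.snps.copy()
        )
        top, _ = repeated_search(
            geno_masked, scores, 1, n_runs=config.n_runs,
            base_seed=base_seed + iteration, strategy=config.strategy, n_folds=config.n_folds,
        )
        perm = permutation_test(
            geno_masked, scores, 1, n_perm=config.n_perm, seed=perm_seed + iteration,
            strategy=config.strategy, partition_seed=part_seed + iteration, engine=config.engine,
        )
        top.permutation_p = perm.p_value
        significant = perm.p_value < config.alpha
        regression = _validate_model(top.model, dataset, mask, config) if significant else None
        if config.strict_removal and significant:
            significant = regression is not None and regression.p_value < config.alpha
        if not significant:
            records.append(IterationRecord(iteration, 1, top, perm, regression, [], {},
                                           "not_significant"))
            break
        main_snp = top.model.snp_ids[0]
        partners = qc_mod.ld_partners(geno_masked, main_snp, config.r2_threshold)
        removed = [main_snp] + partners
        r2_map = {main_snp: 1.0}
        for p in partners:
            r2_map[p] = qc_mod.pairwise_r2(geno_masked, main_snp, p)
        records.append(IterationRecord(iteration, 1, top, perm, regression, removed, r2_map, ""))
        geno = geno.drop_snps(removed)
        if geno.n_snps == 0:
            records.append(IterationRecord(iteration + 1, 1, top, perm, None, [], {}, "exhausted"))
            break
        if iteration >= limit:
            break
    dataset_out = dataset.with_geno(geno)
    return dataset_out, records


def run_full_pipeline(dataset: Dataset, config: PipelineConfig) -> PipelineReport:
    """QC -> scoring -> main-effect iterations -> 2-/3-way search + validation."""
    input_hash = dataset.geno.content_hash()
    stage_hashes = {"input": input_hash}
    qc_summary = {}
    if config.run_qc:
        geno, rep1 = qc_mod.apply_qc_filters(
            dataset.geno, config.maf_min, config.hwe_min_p, config.max_missing
        )
        geno, rep2 = qc_mod.prune_duplicate_snps(geno)
        qc_summary = {**rep1.summary, **rep2.summary, "n_final": geno.n_snps}
        dataset = dataset.with_geno(geno)
        stage_hashes["post_qc"] = geno.content_hash()
    mask, scores = compute_scores(dataset, config)
    reduced, records = run_main_effect_iterations(dataset, config, scores=scores, mask=mask)
    stage_hashes["post_main_effect"] = reduced.geno.content_hash()
    multiway = []
    seeds = np.random.SeedSequence([config.seed, 2]).spawn(2)
    base_seed = int(seeds[0].generate_state(1)[0] % (2**31))
    perm_seed = int(seeds[1].generate_state(1)[0] % (2**31))
    for k in config.k_values:
        if reduced.geno.n_snps < k:
            continue
        geno_masked = GenotypeMatrix(
            dosage=reduced.geno.dosage[mask].copy(),
            subject_ids=reduced.geno.subject_ids[mask],
            snps=reduced.geno.snps.copy(),
        )
        top, _ = repeated_search(
            geno_masked, scores, k, n_runs=config.n_runs,
            base_seed=base_seed + k, strategy=config.strategy, n_folds=config.n_folds,
        )
        perm = permutation_test(
            geno_masked, scores, k, n_perm=config.n_perm, seed=perm_seed + k,
            strategy=config.strategy, partition_seed=perm_seed + 100 + k, engine=config.engine,
        )
        top.permutation_p = perm.p_value
        regression = (
            _validate_model(top.model, reduced, mask, config) if perm.p_value < config.alpha else None
        )
        multiway.append(
            IterationRecord(
                iteration=k, k=k, top_model=top, permutation=perm, regression=regression,
                removed_snp_ids=[], removed_r2={},
                stop_reason="" if perm.p_value < config.alpha else "not_significant",
            )
        )
    cfg = {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(config).items()}
    return PipelineReport(
        config=cfg,
        qc_summary=qc_summary,
        input_hash=input_hash,
        stage_hashes=stage_hashes,
        iterations=records,
        multiway=multiway,
    )
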