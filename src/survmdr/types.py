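"""Core data containers shared across the pipeline.

Genotypes are held as an additive-dosage matrix (subjects x SNPs, entries in
{0,1,2} counting minor alleles; -1 marks a missing call before QC) together
with per-SNP metadata. Risk models map multilocus genotype cells to a
high/low-risk label; everything downstream (cross-validation, permutation
testing, validation) is expressed in terms of these containers.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1

SNP_META_COLUMNS = ["snp_id", "gene", "major_allele", "minor_allele", "maf", "input_index"]


class DataError(ValueError):
    """Malformed or inconsistent input data."""


class NoEventsError(DataError):
    """Survival input contains no events; a null hazard model cannot be fit."""


class UninformativeScoresError(DataError):
    """All subject scores are exactly zero; cells cannot be classified."""


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs additive-dosage matrix with per-SNP metadata.

    Parameters
    ----------
    dosage : (n_subjects, n_snps) integer array with entries in {0, 1, 2}
        (minor-allele count) or -1 for a missing call.
    subject_ids : sequence of unique subject identifiers.
    snps : DataFrame with columns snp_id, gene, major_allele, minor_allele,
        maf, input_index. ``input_index`` records the column position in the
        originating file and is preserved under subsetting (provenance);
        tie-breaking inside the MDR search uses current column order.
    """

    dosage: np.ndarray
    subject_ids: np.ndarray
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage)
        if self.dosage.ndim != 2:
            raise DataError("dosage must be 2-D (subjects x SNPs)")
        if not np.issubdtype(self.dosage.dtype, np.integer):
            raise DataError("dosage must be integer-typed")
        bad = ~np.isin(self.dosage, (MISSING, 0, 1, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise DataError(f"invalid dosage {self.dosage[i, j]} at subject {i}, SNP column {j}")
        self.subject_ids = np.asarray(self.subject_ids)
        if len(self.subject_ids) != self.dosage.shape[0]:
            raise DataError("subject_ids length does not match dosage rows")
        if len(np.unique(self.subject_ids)) != len(self.subject_ids):
            raise DataError("duplicated subject ids")
        if not isinstance(self.snps, pd.DataFrame):
            raise DataError("snps must be a DataFrame")
        missing_cols = set(SNP_META_COLUMNS) - set(self.snps.columns)
        if missing_cols:
            raise DataError(f"snps table missing columns: {sorted(missing_cols)}")
        if len(self.snps) != self.dosage.shape[1]:
            raise DataError("snps table length does not match dosage columns")
        if self.snps["snp_id"].duplicated().any():
            dup = self.snps.loc[self.snps["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise DataError(f"duplicated SNP id {dup!r}")
        self.snps = self.snps.reset_index(drop=True)

    @property
    def n_subjects(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snps["snp_id"].to_numpy()

    def column(self, snp_id: str) -> np.ndarray:
        return self.dosage[:, self.col_index(snp_id)]

    def col_index(self, snp_id: str) -> int:
        pos = np.flatnonzero(self.snp_ids == snp_id)
        if pos.size == 0:
            raise DataError(f"unknown SNP id {snp_id!r}")
        return int(pos[0])

    def select_columns(self, cols: Sequence[int]) -> "GenotypeMatrix":
        cols = list(cols)
        return GenotypeMatrix(
            dosage=self.dosage[:, cols].copy(),
            subject_ids=self.subject_ids.copy(),
            snps=self.snps.iloc[cols].reset_index(drop=True),
        )

    def drop_snps(self, snp_ids: Iterable[str]) -> "GenotypeMatrix":
        drop = set(snp_ids)
        keep = [j for j, s in enumerate(self.snp_ids) if s not in drop]
        return self.select_columns(keep)

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.dosage.astype(np.int8).tobytes())
        h.update("|".join(map(str, self.subject_ids)).encode())
        h.update("|".join(map(str, self.snp_ids)).encode())
        return h.hexdigest()[:16]


@dataclass(frozen=True)
class RiskModel:
    """A k-SNP combination plus the high/low label of every genotype cell.

    ``high_cells`` lists the cells (tuples over {0,1,2}^k, ordered as
    ``snp_ids``) labelled high-risk; every other cell — including cells never
    observed during training — is low-risk. The classification threshold is
    zero on the summed subject scores per cell.
    """

    snp_ids: tuple
    col_indices: tuple
    high_cells: frozenset

    @property
    def k(self) -> int:
        return len(self.snp_ids)

    def labels(self) -> dict:
        return {
            cells: ("high" if cells in self.high_cells else "low")
            for cells in itertools.product((0, 1, 2), repeat=self.k)
        }

    def identity(self) -> tuple:
        """Consensus identity: SNP ids jointly with the high-cell set."""
        return (self.snp_ids, self.high_cells)


@dataclass
class FoldResult:
    fold: int
    best_combo: tuple          # snp ids
    best_cols: tuple           # column positions
    training_ba: float
    testing_ba: float
    high_cells: frozenset


@dataclass
class RunResult:
    seed: object
    fold_results: list
    best_model: RiskModel
    cvc: int
    mean_tba: float
    selection_strategy: str


@dataclass
class TopModel:
    model: RiskModel
    frequency: int
    n_runs: int
    mean_tba: float
    cvc: float
    permutation_p: float | None = None

    def to_dict(self) -> dict:
        return {
            "snp_ids": list(self.model.snp_ids),
            "high_cells": sorted(map(list, self.model.high_cells)),
            "frequency": self.frequency,
            "n_runs": self.n_runs,
            "mean_tba": self.mean_tba,
            "cvc": self.cvc,
            "permutation_p": self.permutation_p,
        }


@dataclass
class PermutationResult:
    observed: float
    null_statistics: np.ndarray
    p_value: float
    p_label: str
    n_perm: int
    seed: object
    engine: str
    k: int


@dataclass
class RegressionSummary:
    effect_type: str           # "HR" or "OR"
    estimate: float
    ci_lower: float
    ci_upper: float
    p_value: float
    direction: str             # "high_vs_low" or "low_vs_high"
    covariate_estimates: dict
    n_used: int

    def to_dict(self) -> dict:
        return {
            "effect_type": self.effect_type,
            "estimate": self.estimate,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "p_value": self.p_value,
            "direction": self.direction,
            "covariate_estimates": self.covariate_estimates,
            "n_used": self.n_used,
        }


@dataclass
class KMResult:
    """Per-group product-limit curves plus the two-sample log-rank test."""

    curves: dict               # group -> DataFrame(time, survival, at_risk)
    censor_times: dict         # group -> array of censoring times
    logrank_statistic: float
    logrank_p: float


@dataclass
class Dataset:
    """Genotypes joined with covariates and outcomes on subject order."""

    geno: GenotypeMatrix
    covariates: pd.DataFrame
    time: np.ndarray
    event: np.ndarray
    status5y: np.ndarray | None = None
    included5y: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.geno.n_subjects
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if len(self.covariates) != n or len(self.time) != n or len(self.event) != n:
            raise DataError("component lengths disagree with genotype subject count")
        if np.any(self.time <= 0):
            raise DataError("survival times must be positive")
        if self.status5y is not None:
            self.status5y = np.asarray(self.status5y)
            self.included5y = np.asarray(self.included5y)
            if len(self.status5y) != n or len(self.included5y) != n:
                raise DataError("binary outcome length mismatch")

    @property
    def n_subjects(self) -> int:
        return self.geno.n_subjects

    def subset_subjects(self, mask: np.ndarray) -> "Dataset":
        mask = np.asarray(mask, dtype=bool)
        geno = GenotypeMatrix(
            dosage=self.geno.dosage[mask].copy(),
            subject_ids=self.geno.subject_ids[mask],
            snps=self.geno.snps.copy(),
        )
        return Dataset(
            geno=geno,
            covariates=self.covariates.loc[mask].reset_index(drop=True),
            time=self.time[mask],
            event=self.event[mask],
            status5y=None if self.status5y is None else self.status5y[mask],
            included5y=None if self.included5y is None else self.included5y[mask],
        )

    def with_geno(self, geno: GenotypeMatrix) -> "Dataset":
        return replace(self, geno=geno)
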