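"""Genotype quality control and LD screening.

Filters follow the standard GWAS extraction conventions: minor allele
frequency >= 0.05, Hardy-Weinberg exact-test p > 1e-4, zero missingness,
then collapse of r^2 = 1 duplicate groups to a single representative.

r^2 here is the squared Pearson correlation of the 0/1/2 dosage columns
(genotype-scale LD). This is deterministic on unphased data, invariant to
allele-coding flips, and coincides with haplotype r^2 at the r^2 = 1
duplicate screen; the dialect is recorded in the QC report metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .types import MISSING, DataError, GenotypeMatrix

__all__ = [
    "QCReport",
    "compute_maf",
    "hwe_exact_test",
    "pairwise_r2",
    "apply_qc_filters",
    "prune_duplicate_snps",
    "ld_partners",
    "GenotypeQC",
]

R2_DIALECT = "pearson-r2 on additive dosages (genotype-scale LD)"


@dataclass
class QCReport:
    """Per-SNP QC metrics and the reason each removed SNP was removed."""

    table: pd.DataFrame        # snp_id, maf, hwe_p, missing_rate, passed, removal_reason
    summary: dict
    metadata: dict = field(default_factory=lambda: {"r2_dialect": R2_DIALECT})

    def __post_init__(self) -> None:
        reasons = self.table["removal_reason"]
        if (reasons.eq("none") != self.table["passed"]).any():
            raise DataError("removal reasons inconsistent with pass flags")


def compute_maf(column) -> tuple[float, bool]:
    """Minor-allele frequency of a dosage column.

    Returns ``(maf, swapped)``: if the coded allele's frequency exceeds 0.5
    the alleles need relabelling (dosage -> 2 - dosage) and the frequency of
    the *other* allele is reported, with ``swapped`` set.
    """
    col = np.asarray(column)
    col = col[col != MISSING]
    if col.size == 0:
        raise DataError("all-missing genotype column")
    freq = float(col.sum()) / (2.0 * col.size)
    if freq > 0.5:
        return 1.0 - freq, True
    return freq, False


@lru_cache(maxsize=4096)
def _hwe_exact(n_het: int, n_hom_minor: int, n_hom_major: int) -> float:
    """Levene-Haldane exact HWE p-value (two-sided, probability-mass ordering)."""
    n = n_het + n_hom_minor + n_hom_major
    n_minor = 2 * n_hom_minor + n_het
    if n_minor > n:  # work with the rarer allele
        n_minor = 2 * n - n_minor
    if n_minor == 0:
        return 1.0
    # log P(het = h | n, n_minor) up to a constant, over feasible h
    hs = np.arange(n_minor % 2, n_minor + 1, 2)
    from scipy.special import gammaln

    def logfact(x):
        return gammaln(np.asarray(x, dtype=float) + 1.0)

    hom_min = (n_minor - hs) // 2
    hom_maj = n - hs - hom_min
    logp = hs * np.log(2.0) + logfact(n) - logfact(hs) - logfact(hom_min) - logfact(hom_maj)
    logp -= max(logp.max(), -np.inf)
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = np.flatnonzero(hs == n_het)
    if obs.size == 0:
        raise DataError("observed genotype counts infeasible")
    p_obs = probs[obs[0]]
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-12)].sum()))


def hwe_exact_test(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Arguments are genotype counts (major homozygote, heterozygote, minor
    homozygote). Two-sided by summing the conditional probabilities of all
    heterozygote counts no more probable than the observed one; a
    monomorphic SNP returns 1.0 by convention.
    """
    counts = (n_hom_major, n_het, n_hom_minor)
    if any(c < 0 for c in counts):
        raise DataError("negative genotype counts")
    if sum(counts) < 1:
        raise DataError("empty genotype counts")
    return _hwe_exact(int(n_het), int(n_hom_minor), int(n_hom_major))


def _column_stats(dosage: np.ndarray):
    """Per-column maf (after virtual relabel), HWE p and missing rate."""
    n, m = dosage.shape
    maf = np.empty(m)
    hwe_p = np.empty(m)
    missing = np.empty(m)
    swapped = np.zeros(m, dtype=bool)
    for j in range(m):
        col = dosage[:, j]
        obs = col[col != MISSING]
        missing[j] = 1.0 - obs.size / n
        if obs.size == 0:
            maf[j], hwe_p[j] = np.nan, np.nan
            continue
        maf[j], swapped[j] = compute_maf(obs)
        n0 = int(np.sum(obs == 0))
        n1 = int(np.sum(obs == 1))
        n2 = int(np.sum(obs == 2))
        if swapped[j]:
            n0, n2 = n2, n0
        hwe_p[j] = hwe_exact_test(n0, n1, n2)
    return maf, hwe_p, missing, swapped


def pairwise_r2(geno: GenotypeMatrix, i, j) -> float:
    """Squared Pearson correlation of two dosage columns (complete cases)."""
    ci = i if isinstance(i, (int, np.integer)) else geno.col_index(i)
    cj = j if isinstance(j, (int, np.integer)) else geno.col_index(j)
    x = geno.dosage[:, ci].astype(float)
    y = geno.dosage[:, cj].astype(float)
    ok = (x != MISSING) & (y != MISSING)
    x, y = x[ok], y[ok]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("r^2 undefined for a monomorphic column")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _r2_matrix(dosage: np.ndarray) -> np.ndarray:
    x = dosage.astype(float)
    sd = x.std(axis=0)
    if np.any(sd == 0):
        raise DataError("r^2 undefined for a monomorphic column")
    r = np.corrcoef(x, rowvar=False)
    return r * r


class GenotypeQC(BaseEstimator, TransformerMixin):
    """SNP-filter transformer over additive-dosage arrays.

    fit computes per-column MAF (relabelling to the minor allele where the
    coded-allele frequency exceeds 0.5), exact HWE p and missing rate;
    transform keeps columns with MAF >= ``maf_min``, HWE p > ``hwe_min_p``
    and missing rate <= ``max_missing``, flipping relabelled columns to
    minor-allele dosage. Missing calls are encoded as -1.

    Attributes ending in an underscore are set by fit: ``maf_``, ``hwe_p_``,
    ``missing_rate_``, ``swapped_``, ``support_``.
    """

    def __init__(self, maf_min: float = 0.05, hwe_min_p: float = 1e-4, max_missing: float = 0.0):
        self.maf_min = maf_min
        self.hwe_min_p = hwe_min_p
        self.max_missing = max_missing

    def fit(self, X, y=None):
        for name in ("maf_min", "hwe_min_p", "max_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DataError(f"{name} must lie in [0, 1]")
        X = np.asarray(X)
        if X.ndim != 2:
            raise DataError("expected a 2-D dosage array")
        self.n_features_in_ = X.shape[1]
        self.maf_, self.hwe_p_, self.missing_rate_, self.swapped_ = _column_stats(X)
        reasons = np.full(X.shape[1], "none", dtype=object)
        # precedence: missing, then maf, then hwe (first failed rule is reported)
        with np.errstate(invalid="ignore"):
            reasons[(reasons == "none") & (self.missing_rate_ > self.max_missing)] = "missing"
            reasons[(reasons == "none") & ~(self.maf_ >= self.maf_min)] = "maf"
            reasons[(reasons == "none") & ~(self.hwe_p_ > self.hwe_min_p)] = "hwe"
        self.removal_reason_ = reasons
        self.support_ = reasons == "none"
        return self

    def get_support(self) -> np.ndarray:
        return self.support_

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X)
        if X.shape[1] != self.n_features_in_:
            raise DataError("feature count changed between fit and transform")
        out = X[:, self.support_].copy()
        flips = self.swapped_[self.support_]
        if flips.any():
            cols = out[:, flips]
            mask = cols != MISSING
            cols[mask] = 2 - cols[mask]
            out[:, flips] = cols
        return out


def apply_qc_filters(
    geno: GenotypeMatrix,
    maf_min: float = 0.05,
    hwe_min_p: float = 1e-4,
    max_missing: float = 0.0,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the MAF / HWE / missingness filters to a genotype matrix.

    Returns the filtered matrix (column order preserved, relabelled columns
    flipped to minor-allele dosage with alleles swapped in the metadata) and
    a complete per-SNP report. An empty result is legal.
    """
    qc = GenotypeQC(maf_min=maf_min, hwe_min_p=hwe_min_p, max_missing=max_missing).fit(geno.dosage)
    table = pd.DataFrame(
        {
            "snp_id": geno.snp_ids,
            "maf": qc.maf_,
            "hwe_p": qc.hwe_p_,
            "missing_rate": qc.missing_rate_,
            "allele_swap": qc.swapped_,
            "passed": qc.support_,
            "removal_reason": qc.removal_reason_,
        }
    )
    keep = np.flatnonzero(qc.support_)
    out = geno.select_columns(keep)
    out.dosage = qc.transform(geno.dosage)
    snps = out.snps.copy()
    swapped_kept = qc.swapped_[keep]
    if swapped_kept.any():
        maj = snps.loc[swapped_kept, "major_allele"].copy()
        snps.loc[swapped_kept, "major_allele"] = snps.loc[swapped_kept, "minor_allele"]
        snps.loc[swapped_kept, "minor_allele"] = maj
    snps["maf"] = qc.maf_[keep]
    out.snps = snps
    summary = {
        "n_input": geno.n_snps,
        "n_passed": int(qc.support_.sum()),
        "n_removed_missing": int(np.sum(qc.removal_reason_ == "missing")),
        "n_removed_maf": int(np.sum(qc.removal_reason_ == "maf")),
        "n_removed_hwe": int(np.sum(qc.removal_reason_ == "hwe")),
    }
    return out, QCReport(table=table, summary=summary)


def prune_duplicate_snps(geno: GenotypeMatrix, tol: float = 1e-12) -> tuple[GenotypeMatrix, QCReport]:
    """Collapse groups of statistically identical SNPs (r^2 = 1).

    Within each group of columns whose pairwise r^2 equals 1 (within
    ``tol``), only the earliest column in file order is retained — such SNPs
    score identically under the MDR procedure, so one representative
    suffices.
    """
    m = geno.n_snps
    reasons = np.full(m, "none", dtype=object)
    if m > 1:
        r2 = _r2_matrix(geno.dosage)
        for j in range(1, m):
            if reasons[j] != "none":
                continue
            for i in range(j):
                if reasons[i] == "none" and r2[i, j] >= 1.0 - tol:
                    reasons[j] = "duplicate_r2"
                    break
    keep = np.flatnonzero(reasons == "none")
    table = pd.DataFrame(
        {
            "snp_id": geno.snp_ids,
            "maf": geno.snps["maf"].to_numpy(),
            "hwe_p": np.nan,
            "missing_rate": 0.0,
            "passed": reasons == "none",
            "removal_reason": reasons,
        }
    )
    summary = {
        "n_input": m,
        "n_passed": len(keep),
        "n_removed_duplicate_r2": int(np.sum(reasons == "duplicate_r2")),
    }
    return geno.select_columns(keep), QCReport(table=table, summary=summary)


def ld_partners(geno: GenotypeMatrix, snp_id: str, r2_threshold: float = 0.8) -> list:
    """All other SNPs with r^2 >= threshold against ``snp_id`` (inclusive)."""
    j = geno.col_index(snp_id)
    out = []
    for i in range(geno.n_snps):
        if i == j:
            continue
        try:
            r2 = pairwise_r2(geno, i, j)
        except DataError:
            continue
        if r2 >= r2_threshold:
            out.append(str(geno.snp_ids[i]))
    return out
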