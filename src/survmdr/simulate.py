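"""Synthetic cohort generator with known ground truth.

Emulates the data structure of a modest colorectal-cancer genotype cohort:
a few hundred subjects, common SNPs (MAF >= 0.05) in Hardy-Weinberg
proportions with optional block LD, clinical covariates (age, stage, MSI
status, tumor location, chemo/radiotherapy), and right-censored survival
generated from a Weibull proportional-hazards model. Risk effects are
planted on explicit genotype cells of 1-3 SNPs so that every downstream
stage (scoring, MDR search, permutation, validation) can be tested against
a known truth.

Genotypes within an LD block are produced by a Gaussian copula: each of the
two haplotypes per subject draws a latent equicorrelated normal vector
across the block's SNPs, thresholds it at the MAF quantile to obtain allele
indicators, and the dosage is the sum over haplotypes. The latent
correlation is calibrated so the allele-level (hence dosage-level) pairwise
r^2 matches the block target; the r^2 = 1 limit yields exact column copies.
Multi-SNP blocks share a single MAF, which makes this calibration exact and
is required for the perfect-copy limit anyway; singleton SNPs draw their
MAF freely from ``maf_range``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .types import DataError, Dataset, GenotypeMatrix, SNP_META_COLUMNS

__all__ = [
    "SimulationConfig",
    "PlantedEffect",
    "planted_model_presets",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_survival",
    "dichotomize_survival",
    "simulate_dataset",
    "high_risk_indicator",
]

COVARIATE_COLUMNS = ["age", "stage", "msi", "location", "chemo", "radio"]

# allele letter pairs cycled through for synthetic SNP metadata
_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("G", "T"), ("A", "C"), ("T", "A"), ("G", "C")]


@dataclass(frozen=True)
class PlantedEffect:
    """Ground-truth risk effect on explicit genotype cells of 1-3 SNPs."""

    snp_indices: tuple
    high_cells: frozenset
    log_hazard_ratio: float
    model_name: str = "custom"

    def __post_init__(self) -> None:
        k = len(self.snp_indices)
        if not 1 <= k <= 3:
            raise DataError("planted effects cover 1-3 SNPs")
        if not np.isfinite(self.log_hazard_ratio):
            raise DataError("log hazard ratio must be finite")
        for cell in self.high_cells:
            if len(cell) != k or any(g not in (0, 1, 2) for g in cell):
                raise DataError(f"invalid genotype cell {cell!r}")


@dataclass
class SimulationConfig:
    """Knobs for the synthetic cohort.

    Defaults mirror the structure of the emulated study: ~400 subjects,
    common SNPs, mostly independent loci with optional LD blocks, clinical
    covariates with modest prognostic effects, Weibull baseline hazard giving
    roughly 45% events within a 10-year administrative follow-up window, and
    light random dropout.
    """

    n_subjects: int = 400
    n_snps: int = 100
    maf_range: tuple = (0.05, 0.5)
    ld_block_sizes: tuple = ()       # remaining SNPs are singletons
    ld_block_r2: float = 0.8         # target pairwise r^2 within each block
    age_mean: float = 61.0
    age_sd: float = 10.0
    age_range: tuple = (20.0, 75.0)
    stage_probs: tuple = (0.15, 0.30, 0.35, 0.20)
    msi_rate: float = 0.12
    location_rate: float = 0.35
    chemo_rate: float = 0.55
    radio_rate: float = 0.30
    # log-hazard effects for (age-61)/10, stage-2, msi, location, chemo, radio
    gamma: tuple = (0.25, 0.45, -0.45, 0.10, -0.35, 0.10)
    weibull_scale: float = 0.03      # lambda
    weibull_shape: float = 1.3       # rho
    censor_horizon: float = 10.0     # administrative censoring, years
    dropout_rate: float = 0.03       # exponential dropout per year
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.05 <= lo <= hi <= 0.5):
            raise DataError("maf_range must lie within [0.05, 0.5]")
        if self.n_subjects < 2 or self.n_snps < 1:
            raise DataError("need at least 2 subjects and 1 SNP")
        if sum(self.ld_block_sizes) > self.n_snps:
            raise DataError("LD blocks larger than n_snps")
        if any(b < 1 for b in self.ld_block_sizes):
            raise DataError("LD block sizes must be positive")
        if abs(sum(self.stage_probs) - 1.0) > 1e-9:
            raise DataError("stage probabilities must sum to 1")
        if min(self.weibull_scale, self.weibull_shape) <= 0:
            raise DataError("Weibull parameters must be positive")
        if self.censor_horizon < 0 or self.dropout_rate < 0:
            raise DataError("rates must be non-negative")
        if self.seed is None:
            raise DataError("seed is mandatory")


def planted_model_presets(name: str, snp_indices, log_hazard_ratio: float = np.log(2.0)) -> PlantedEffect:
    """Named ground-truth effect shapes.

    dominant/recessive act on one SNP via minor-allele carrier status. The
    xor presets label a cell high when the number of *heterozygous* SNPs in
    it is odd: at MAF 0.5 each heterozygosity indicator is a fair coin, so
    the parity is marginally independent of every single SNP's dosage —
    a pure interaction with no main effect, which is exactly the situation
    dimensionality-reduction search exists to detect.
    """
    snp_indices = tuple(int(i) for i in np.atleast_1d(snp_indices))
    k = len(snp_indices)
    cells = list(itertools.product((0, 1, 2), repeat=k))
    if name == "dominant":
        if k != 1:
            raise DataError("dominant preset is 1-way")
        high = {(1,), (2,)}
    elif name == "recessive":
        if k != 1:
            raise DataError("recessive preset is 1-way")
        high = {(2,)}
    elif name in ("xor2", "xor3"):
        want_k = 2 if name == "xor2" else 3
        if k != want_k:
            raise DataError(f"{name} preset is {want_k}-way")
        high = {c for c in cells if sum(g == 1 for g in c) % 2 == 1}
    else:
        raise DataError(f"unknown preset {name!r}")
    return PlantedEffect(snp_indices, frozenset(high), float(log_hazard_ratio), name)


@lru_cache(maxsize=256)
def _latent_correlation(maf: float, target_r2: float) -> float:
    """Latent normal correlation giving allele correlation sqrt(target_r2)."""
    if target_r2 <= 0:
        return 0.0
    if target_r2 >= 1.0 - 1e-12:
        return 1.0
    target_r = float(np.sqrt(target_r2))
    q = stats.norm.ppf(maf)
    var = maf * (1.0 - maf)

    def allele_corr(rho: float) -> float:
        p11 = stats.multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]]).cdf([q, q])
        return (p11 - maf * maf) / var

    return float(optimize.brentq(lambda r: allele_corr(r) - target_r, 0.0, 1.0 - 1e-9, xtol=1e-10))


def _block_layout(config: SimulationConfig):
    sizes = list(config.ld_block_sizes)
    sizes += [1] * (config.n_snps - sum(sizes))
    return sizes


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw HWE-consistent dosages with block LD via the Gaussian copula."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x67]))
    n = config.n_subjects
    sizes = _block_layout(config)
    cols, meta = [], []
    snp_counter = 0
    for b, size in enumerate(sizes):
        maf = float(rng.uniform(*config.maf_range))
        q = stats.norm.ppf(maf)
        rho = _latent_correlation(round(maf, 6), config.ld_block_r2) if size > 1 else 0.0
        dosage = np.zeros((n, size), dtype=np.int8)
        for _hap in range(2):
            w = rng.standard_normal((n, 1))
            e = rng.standard_normal((n, size))
            z = np.sqrt(rho) * w + np.sqrt(1.0 - rho) * e
            dosage += (z < q).astype(np.int8)
        cols.append(dosage)
        for _ in range(size):
            major, minor = _ALLELE_PAIRS[snp_counter % len(_ALLELE_PAIRS)]
            meta.append(
                {
                    "snp_id": f"rs{snp_counter + 1:06d}",
                    "gene": f"GENE{b + 1}",
                    "major_allele": major,
                    "minor_allele": minor,
                    "maf": maf,
                    "input_index": snp_counter,
                }
            )
            snp_counter += 1
    return GenotypeMatrix(
        dosage=np.concatenate(cols, axis=1),
        subject_ids=np.array([f"S{i + 1:05d}" for i in range(n)]),
        snps=pd.DataFrame(meta, columns=SNP_META_COLUMNS),
    )


def simulate_covariates(config: SimulationConfig) -> pd.DataFrame:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0]))
    n = config.n_subjects
    lo, hi = config.age_range
    # age_mean is the realized mean of the truncated normal, so solve for the
    # location parameter (asymmetric truncation shifts the mean otherwise)
    def trunc_mean(loc):
        return stats.truncnorm.mean(
            (lo - loc) / config.age_sd, (hi - loc) / config.age_sd, loc=loc, scale=config.age_sd
        )

    loc = optimize.brentq(lambda L: trunc_mean(L) - config.age_mean, lo, hi)
    a = (lo - loc) / config.age_sd
    b = (hi - loc) / config.age_sd
    age = stats.truncnorm.rvs(a, b, loc=loc, scale=config.age_sd, size=n, random_state=rng)
    stage = rng.choice([1, 2, 3, 4], size=n, p=config.stage_probs)
    return pd.DataFrame(
        {
            "age": age,
            "stage": stage,
            "msi": rng.binomial(1, config.msi_rate, size=n),
            "location": rng.binomial(1, config.location_rate, size=n),
            "chemo": rng.binomial(1, config.chemo_rate, size=n),
            "radio": rng.binomial(1, config.radio_rate, size=n),
        }
    )


def _centered_design(cov: pd.DataFrame) -> np.ndarray:
    """Design used by the generative hazard: scaled age, stage offset, binaries."""
    return np.column_stack(
        [
            (cov["age"].to_numpy() - 61.0) / 10.0,
            cov["stage"].to_numpy() - 2.0,
            cov["msi"].to_numpy(),
            cov["location"].to_numpy(),
            cov["chemo"].to_numpy(),
            cov["radio"].to_numpy(),
        ]
    )


def high_risk_indicator(geno: GenotypeMatrix, effect: PlantedEffect) -> np.ndarray:
    """1 for subjects whose genotype cell over the effect's SNPs is high-risk."""
    sub = geno.dosage[:, list(effect.snp_indices)]
    if sub.shape[1] != len(effect.snp_indices):
        raise DataError("effect SNP indices out of range")
    cells = set(effect.high_cells)
    return np.fromiter((tuple(row) in cells for row in sub), dtype=int, count=len(sub))


def simulate_survival(
    geno: GenotypeMatrix,
    cov: pd.DataFrame,
    effect: PlantedEffect | None,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Weibull proportional-hazards event times with mixed censoring.

    h(t) = lambda * rho * t^(rho-1) * exp(beta_g * 1[cell high] + gamma' z);
    censoring is the minimum of the administrative horizon and an
    exponential dropout time. Returns columns time (years) and event.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5E]))
    n = geno.n_subjects
    lp = np.zeros(n)
    if effect is not None:
        if max(effect.snp_indices) >= geno.n_snps:
            raise DataError("effect SNP indices out of range")
        lp += effect.log_hazard_ratio * high_risk_indicator(geno, effect)
    gamma = np.asarray(config.gamma, dtype=float)
    if gamma.size:
        lp += _centered_design(cov)[:, : gamma.size] @ gamma
    u = rng.uniform(size=n)
    # S(t) = exp(-lambda t^rho e^lp)  =>  T = (-log U / (lambda e^lp))^(1/rho)
    t_event = (-np.log(u) / (config.weibull_scale * np.exp(lp))) ** (1.0 / config.weibull_shape)
    if config.dropout_rate > 0:
        dropout = rng.exponential(1.0 / config.dropout_rate, size=n)
    else:
        dropout = np.full(n, np.inf)
    censor = np.minimum(config.censor_horizon, dropout)
    time = np.minimum(t_event, censor)
    event = (t_event <= censor).astype(int)
    time = np.maximum(time, 1e-9)  # keep times strictly positive at horizon ~ 0
    return pd.DataFrame({"time": time, "event": event})


def dichotomize_survival(time, event, horizon: float = 5.0):
    """Binary status at a fixed horizon, excluding early-censored subjects.

    Subjects with an event by the horizon are status 1; subjects followed at
    least to the horizon are status 0; subjects censored alive before the
    horizon have unknown status and are excluded (included = 0).
    """
    if horizon <= 0:
        raise DataError("horizon must be positive")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    status = np.zeros(len(time), dtype=int)
    included = np.ones(len(time), dtype=int)
    had_event = (event == 1) & (time <= horizon)
    status[had_event] = 1
    early_censored = (event == 0) & (time < horizon)
    included[early_censored] = 0
    status[early_censored] = 0
    return status, included


def simulate_dataset(
    config: SimulationConfig,
    effect: PlantedEffect | None = None,
    horizon: float = 5.0,
) -> Dataset:
    """Full synthetic cohort: genotypes + covariates + survival + 5y status."""
    geno = simulate_genotypes(config)
    cov = simulate_covariates(config)
    surv = simulate_survival(geno, cov, effect, config)
    status, included = dichotomize_survival(surv["time"], surv["event"], horizon)
    return Dataset(
        geno=geno,
        covariates=cov,
        time=surv["time"].to_numpy(),
        event=surv["event"].to_numpy(),
        status5y=status,
        included5y=included,
    )
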