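import numpy as np
import pandas as pd
import pytest

from survmdr import Dataset, GenotypeMatrix, SimulationConfig, simulate_dataset
from survmdr.pipeline import PipelineConfig, compute_scores
from survmdr.types import SNP_META_COLUMNS


def make_geno(dosage, snp_ids=None, mafs=None):
    """Small handmade genotype matrix for unit tests."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    ids = snp_ids or [f"rs{j + 1:03d}" for j in range(m)]
    snps = pd.DataFrame(
        {
            "snp_id": ids,
            "gene": [f"G{j}" for j in range(m)],
            "major_allele": "A",
            "minor_allele": "G",
            "maf": mafs if mafs is not None else np.nan,
            "input_index": np.arange(m),
        },
        columns=SNP_META_COLUMNS,
    )
    return GenotypeMatrix(dosage=dosage, subject_ids=np.array([f"S{i}" for i in range(n)]), snps=snps)


@pytest.fixture(scope="session")
def cohort_with_scores():
    """Moderate synthetic cohort plus its martingale-residual scores."""
    cfg = SimulationConfig(n_subjects=300, n_snps=12, seed=20240)
    ds = simulate_dataset(cfg)
    mask, scores = compute_scores(ds, PipelineConfig(engine="cox"))
    return ds, scores


@pytest.fixture
def rng():
    return np.random.default_rng(77)
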