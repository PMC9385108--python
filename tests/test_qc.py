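"""Genotype QC: MAF, exact HWE test, filters, duplicate pruning, LD."""

import numpy as np
import pytest
from scipy import stats

from survmdr import (
    DataError,
    GenotypeQC,
    SimulationConfig,
    apply_qc_filters,
    compute_maf,
    hwe_exact_test,
    ld_partners,
    pairwise_r2,
    prune_duplicate_snps,
    simulate_genotypes,
)
from conftest import make_geno


class TestMAF:
    @pytest.mark.parametrize(
        "col,expect,swap",
        [
            ([0, 0, 0, 0], 0.0, False),
            ([1, 1, 1, 1], 0.5, False),
            ([2, 2, 1, 0], 0.375, True),  # 5/8 > 0.5 forces relabel; 1 - 5/8
        ],
    )
    def test_examples(self, col, expect, swap):
        maf, swapped = compute_maf(col)
        assert maf == pytest.approx(expect)
        assert swapped is swap

    def test_all_missing_rejected(self):
        with pytest.raises(DataError):
            compute_maf(np.full(4, -1))


class TestHWEExact:
    def test_two_subject_enumeration(self):
        # feasible het counts {0, 2} have Levene probabilities 1/3 and 2/3
        assert hwe_exact_test(1, 0, 1) == pytest.approx(1 / 3)
        assert hwe_exact_test(0, 2, 0) == pytest.approx(1.0)

    def test_monomorphic_convention(self):
        assert hwe_exact_test(100, 0, 0) == 1.0
        assert hwe_exact_test(0, 0, 100) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(DataError):
            hwe_exact_test(-1, 2, 3)

    def test_agrees_with_chisquare_for_balanced_large_counts(self):
        # asymptotic-limit check against the 1-df chi-square HWE test
        for n_aa, n_het, n_bb in [(250, 500, 250), (300, 480, 220), (400, 420, 180)]:
            n = n_aa + n_het + n_bb
            p = (2 * n_aa + n_het) / (2 * n)
            exp = np.array([p * p, 2 * p * (1 - p), (1 - p) ** 2]) * n
            chi2 = (((np.array([n_aa, n_het, n_bb]) - exp) ** 2) / exp).sum()
            p_asym = stats.chi2.sf(chi2, 1)
            p_exact = hwe_exact_test(n_aa, n_het, n_bb)
            assert abs(p_exact - p_asym) <= 0.01

    def test_symmetric_in_homozygote_labels(self):
        assert hwe_exact_test(30, 40, 10) == pytest.approx(hwe_exact_test(10, 40, 30))


class TestFilters:
    def test_low_maf_removed(self):
        # MAF 2/40 = 0.05 passes (inclusive); 1/40 = 0.025 fails
        dosage = np.zeros((20, 2), dtype=np.int8)
        dosage[0, 0] = 1
        dosage[0, 1] = 1
        dosage[1, 1] = 1
        geno = make_geno(dosage)
        out, report = apply_qc_filters(geno)
        assert list(out.snp_ids) == ["rs002"]
        row = report.table.set_index("snp_id").loc["rs001"]
        assert row["removal_reason"] == "maf"

    def test_missing_call_removed_at_zero_tolerance(self):
        dosage = np.array([[0, 1], [1, -1], [1, 0], [0, 1]] * 10, dtype=np.int8)
        geno = make_geno(dosage)
        out, report = apply_qc_filters(geno, maf_min=0.0, hwe_min_p=0.0)
        assert list(out.snp_ids) == ["rs001"]
        assert report.table.iloc[1]["removal_reason"] == "missing"

    def test_hwe_violation_removed(self):
        # all heterozygotes: exact p << 1e-4 at n=100
        dosage = np.column_stack([np.ones(100), np.tile([0, 1, 1, 2], 25)]).astype(np.int8)
        geno = make_geno(dosage)
        out, report = apply_qc_filters(geno)
        assert list(out.snp_ids) == ["rs002"]
        assert report.table.iloc[0]["removal_reason"] == "hwe"

    def test_idempotent_when_all_pass(self):
        geno = simulate_genotypes(SimulationConfig(n_subjects=500, n_snps=6, seed=3))
        once, _ = apply_qc_filters(geno)
        twice, rep = apply_qc_filters(once)
        assert np.array_equal(once.dosage, twice.dosage)
        assert rep.summary["n_passed"] == once.n_snps

    def test_relabelled_column_flipped_and_alleles_swapped(self):
        dosage = np.array([[2], [2], [1], [2], [2], [1], [2], [1]], dtype=np.int8)
        geno = make_geno(dosage)
        out, report = apply_qc_filters(geno, hwe_min_p=0.0)
        assert report.table.iloc[0]["allele_swap"]
        assert np.array_equal(out.dosage[:, 0], 2 - dosage[:, 0])
        assert out.snps.iloc[0]["major_allele"] == "G"
        assert out.snps.iloc[0]["minor_allele"] == "A"

    def test_reasons_partition_removed_set(self):
        rng = np.random.default_rng(4)
        dosage = rng.integers(0, 3, size=(60, 10)).astype(np.int8)
        dosage[0, 3] = -1
        dosage[:, 5] = 0
        _, report = apply_qc_filters(make_geno(dosage))
        removed = report.table[~report.table["passed"]]
        assert (removed["removal_reason"] != "none").all()
        assert report.summary["n_passed"] + len(removed) == 10


class TestGenotypeQCTransformer:
    def test_sklearn_interface(self):
        from sklearn.base import clone

        qc = GenotypeQC(maf_min=0.1)
        assert clone(qc).get_params()["maf_min"] == 0.1
        X = np.tile([[0], [1], [2], [1]], (1, 4)).astype(np.int8)
        Xt = qc.fit(X).transform(X)
        assert Xt.shape[0] == 4
        assert qc.support_.dtype == bool

    def test_bad_threshold_rejected(self):
        with pytest.raises(DataError):
            GenotypeQC(maf_min=1.5).fit(np.zeros((4, 2), dtype=np.int8))


class TestR2AndPruning:
    def test_identical_and_flipped_columns_give_r2_one(self):
        col = np.tile([0, 1, 2, 1, 0], 8)
        geno = make_geno(np.column_stack([col, col, 2 - col]))
        assert pairwise_r2(geno, 0, 1) == pytest.approx(1.0)
        assert pairwise_r2(geno, 0, 2) == pytest.approx(1.0)

    def test_symmetry(self, rng):
        geno = make_geno(rng.integers(0, 3, size=(50, 3)))
        assert pairwise_r2(geno, 0, 2) == pytest.approx(pairwise_r2(geno, 2, 0))

    def test_monomorphic_rejected(self):
        geno = make_geno(np.column_stack([np.zeros(10), np.tile([0, 1], 5)]))
        with pytest.raises(DataError):
            pairwise_r2(geno, 0, 1)

    def test_independent_snps_low_r2(self):
        geno = simulate_genotypes(SimulationConfig(n_subjects=5000, n_snps=2, seed=5))
        assert pairwise_r2(geno, 0, 1) < 0.01

    def test_triplicate_keeps_first_in_file_order(self):
        col = np.tile([0, 1, 2, 1], 10)
        other = np.tile([0, 0, 1, 2, 1], 8)
        geno = make_geno(
            np.column_stack([col, other, col, 2 - col]),
            snp_ids=["zzz", "mid", "aaa", "bbb"],  # alphabetical order must not matter
        )
        out, report = prune_duplicate_snps(geno)
        assert list(out.snp_ids) == ["zzz", "mid"]
        reasons = report.table.set_index("snp_id")["removal_reason"]
        assert reasons["aaa"] == reasons["bbb"] == "duplicate_r2"

    def test_no_duplicates_is_identity_and_idempotent(self, rng):
        geno = make_geno(rng.integers(0, 3, size=(60, 5)))
        out, _ = prune_duplicate_snps(geno)
        again, _ = prune_duplicate_snps(out)
        assert np.array_equal(out.dosage, geno.dosage)
        assert np.array_equal(again.dosage, out.dosage)


class TestLDPartners:
    def test_exact_copy_is_partner(self):
        col = np.tile([0, 1, 2, 1], 10)
        geno = make_geno(np.column_stack([col, col]))
        assert ld_partners(geno, "rs001") == ["rs002"]

    def test_copula_block_partner_found_cross_block_absent(self):
        cfg = SimulationConfig(
            n_subjects=2000, n_snps=4, ld_block_sizes=(2,), ld_block_r2=0.9, seed=6
        )
        geno = simulate_genotypes(cfg)
        partners = ld_partners(geno, "rs000001", r2_threshold=0.8)
        assert partners == ["rs000002"]

    def test_threshold_above_one_gives_empty(self):
        col = np.tile([0, 1, 2, 1], 10)
        geno = make_geno(np.column_stack([col, col]))
        assert ld_partners(geno, "rs001", r2_threshold=1.01) == []

    def test_unknown_snp_rejected(self):
        geno = make_geno(np.zeros((4, 1), dtype=np.int8))
        with pytest.raises(DataError):
            ld_partners(geno, "nope")
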