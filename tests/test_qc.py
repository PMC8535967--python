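"""Quality control: MAF, Hardy-Weinberg exact test, and the filter cascade."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from suppscan.containers import GenotypeMatrix
from suppscan.qc import (
    EmptyAfterQCError,
    QCThresholds,
    apply_qc,
    hwe_exact_test,
    minor_allele_frequency,
)


def hwe_enumeration_oracle(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact-integer enumeration of the conditional HWE test.

    Weight of a het count h given n and the rare-allele count:
    2^h * multinomial(n; hom_rare, h, hom_common). The p-value is the
    weight-sum over configurations no more likely than observed.
    """
    n = n_hom_major + n_het + n_hom_minor
    n_rare = 2 * min(n_hom_major, n_hom_minor) + n_het
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0
    weights = {}
    for h in range(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2):
        hom_r = (n_rare - h) // 2
        weights[h] = 2 ** h * math.comb(n, h) * math.comb(n - h, hom_r)
    total = sum(weights.values())
    w_obs = weights[n_het]
    return sum(w for w in weights.values() if w <= w_obs) / total


class TestMinorAlleleFrequency:
    def test_counts_minor_alleles(self):
        assert minor_allele_frequency([0, 0, 1, 2]) == pytest.approx(0.375)

    def test_monomorphic_is_zero(self):
        assert minor_allele_frequency([0, 0, 0, 0]) == 0.0

    def test_swaps_labels_above_half(self):
        freq, swapped = minor_allele_frequency([2, 2, 2, 1], return_swapped=True)
        assert freq == pytest.approx(1 / 8)
        assert swapped

    def test_ignores_missing_entries(self):
        assert minor_allele_frequency([0, 1, np.nan, np.nan]) == pytest.approx(0.25)

    def test_all_missing_raises(self):
        with pytest.raises(ValueError, match="all-missing"):
            minor_allele_frequency([np.nan, np.nan])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.sampled_from([0, 1, 2]), min_size=1, max_size=50))
    def test_matches_direct_allele_count(self, dosages):
        count = sum(dosages)
        expected = min(count, 2 * len(dosages) - count) / (2 * len(dosages))
        assert minor_allele_frequency(dosages) == pytest.approx(expected)


class TestHWEExactTest:
    def test_monomorphic_returns_one(self):
        assert hwe_exact_test(50, 0, 0) == 1.0
        assert hwe_exact_test(0, 0, 7) == 1.0

    def test_single_rare_homozygote(self):
        # n_rare=2: configurations h=0 (weight 1) and h=2 (weight 98);
        # observed h=0 is the least likely -> p = 1/99
        assert hwe_exact_test(49, 0, 1) == pytest.approx(1 / 99, rel=1e-12)

    def test_agrees_with_chi_square_for_large_expected_counts(self):
        from scipy.stats import chi2

        counts = (160, 290, 150)
        n = sum(counts)
        p = (2 * counts[2] + counts[1]) / (2 * n)
        expected = np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2]) * n
        stat = ((np.array(counts) - expected) ** 2 / expected).sum()
        p_chi = chi2.sf(stat, df=1)
        p_exact = hwe_exact_test(*counts)
        assert p_exact == pytest.approx(p_chi, rel=0.10)

    def test_probabilities_normalize(self):
        """Perfect-HWE-looking counts give p close to 1, never above it."""
        for counts in [(25, 50, 25), (49, 42, 9), (100, 0, 100)]:
            p = hwe_exact_test(*counts)
            assert 0.0 < p <= 1.0

    def test_large_sample_no_overflow(self):
        p = hwe_exact_test(1000, 900, 299)
        assert 0.0 < p <= 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)


def _matrix(dosages, snp_ids):
    dosages = np.asarray(dosages, float)
    meta = pd.DataFrame({
        "snp_id": snp_ids,
        "chrom": "1",
        "pos": np.arange(1, len(snp_ids) + 1),
        "minor_allele": "A",
        "major_allele": "C",
    })
    ids = [f"S{i}" for i in range(dosages.shape[0])]
    return GenotypeMatrix(sample_ids=ids, snp_meta=meta, dosages=dosages)


class TestApplyQC:
    def test_low_maf_snp_excluded_with_reason(self, rng):
        # 50 samples; snp "rare" has 4 minor alleles -> MAF 0.04 < 0.05
        common = rng.binomial(2, 0.3, 50).astype(float)
        common[0] = 1.0  # guard against monomorphism
        rare = np.zeros(50)
        rare[:4] = 1.0
        g = _matrix(np.column_stack([common, rare]), ["common", "rare"])
        filtered, report = apply_qc(g)
        assert list(filtered.snp_meta["snp_id"]) == ["common"]
        row = report.snp_table.set_index("snp_id").loc["rare"]
        assert row["reasons"] == "maf"

    def test_all_pass_matrix_returned_unchanged(self, rng):
        d = rng.binomial(2, 0.4, size=(60, 3)).astype(float)
        g = _matrix(d, ["a", "b", "c"])
        filtered, report = apply_qc(g)
        np.testing.assert_array_equal(filtered.dosages, g.dosages)
        assert report.snp_table["pass"].all()
        assert report.sample_table["pass"].all()

    def test_hand_crafted_fixture_three_exclusions(self):
        """10 samples x 4 SNPs: one low-call-rate sample, one high-missing
        SNP, one HWE-violating SNP (all heterozygous; exact p = 512/48620
        = 0.0105 with 9 retained samples) -> exactly 3 exclusions."""
        nan = np.nan
        d = np.array([
            # good   hi_miss  all_het  good2
            [0,      0,       1,       1],
            [1,      1,       1,       0],
            [2,      0,       1,       1],
            [0,      1,       1,       2],
            [1,      0,       1,       1],
            [0,      2,       1,       0],
            [1,      0,       1,       1],
            [2,      1,       1,       2],
            [0,      nan,     1,       1],   # call rate 3/4: retained
            [nan,    nan,     nan,     1],   # call rate 1/4: excluded
        ], dtype=float)
        g = _matrix(d, ["good", "hi_miss", "all_het", "good2"])
        thr = QCThresholds(min_maf=0.05, max_snp_missing=0.03,
                           min_sample_call_rate=0.70, hwe_p_floor=0.05)
        filtered, report = apply_qc(g, thr)
        assert report.n_samples_retained == 9
        assert set(filtered.snp_meta["snp_id"]) == {"good", "good2"}
        snp = report.snp_table.set_index("snp_id")
        assert snp.loc["hi_miss", "reasons"] == "missing"   # 1/9 missing > 3%
        assert snp.loc["all_het", "reasons"] == "hwe"
        excluded = (~report.sample_table["pass"]).sum() + (~report.snp_table["pass"]).sum()
        assert excluded == 3

    def test_idempotent(self, default_cohort):
        once, _ = apply_qc(default_cohort.genotypes)
        twice, report = apply_qc(once)
        assert list(twice.snp_meta["snp_id"]) == list(once.snp_meta["snp_id"])
        assert twice.sample_ids == once.sample_ids
        assert report.snp_table["pass"].all()

    def test_retained_snps_satisfy_thresholds(self, default_cohort):
        thr = QCThresholds()
        filtered, report = apply_qc(default_cohort.genotypes, thr)
        retained = report.snp_table[report.snp_table["pass"]]
        assert (retained["maf"] >= thr.min_maf).all()
        assert (retained["hwe_p"] >= thr.hwe_p_floor).all()
        assert (retained["missing_frac"] <= thr.max_snp_missing).all()

    def test_empty_result_raises_with_report(self):
        g = _matrix(np.zeros((20, 2)), ["mono1", "mono2"])  # MAF 0 everywhere
        with pytest.raises(EmptyAfterQCError) as exc:
            apply_qc(g)
        assert exc.value.report.n_snps_retained == 0
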