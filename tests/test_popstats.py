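"""Allele frequencies, polymorphism indices and Hardy-Weinberg tests."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from karyopool import popstats
from karyopool.bandmap import ARMS
from karyopool.popstats import (
    HET_EXCESS,
    NO_DEVIATION,
    AlleleFrequencyTable,
    ArmGenotype,
    LarvaKaryotype,
    PopulationSample,
    allele_frequencies,
    hw_chi_square,
    hw_exact_test,
    hw_expected,
    polymorphism_summary,
    pool_census,
    quantitative_panel_means,
    sequence_key,
)

B1, B2, B3 = "p'agiB1", "p'agiB2", "p'agiB3"


def make_sample(code="TST", **arm_counts):
    counts = {arm: dict(c) for arm, c in arm_counts.items()}
    return PopulationSample(code=code, counts=counts)


def homozygous_larva(b_chromosomes=0, het_arms=()):
    genos = {}
    for arm in ARMS:
        main = f"p'agi{arm}1"
        alt = f"p'agi{arm}2"
        genos[arm] = (
            ArmGenotype(main, alt) if arm in het_arms else ArmGenotype(main, main)
        )
    return LarvaKaryotype(genos, b_chromosomes=b_chromosomes)


class TestGenotypesAndFrequencies:
    def test_genotype_sorted_and_het(self):
        g = ArmGenotype(B2, B1)
        assert g.key == (B1, B2)
        assert g.heterozygous
        assert not ArmGenotype(B1, B1).heterozygous

    def test_prefix_does_not_affect_identity(self):
        assert not ArmGenotype("h'agiC1", "p'agiC1").heterozygous
        assert sequence_key("h'agiC1") == sequence_key("p'agiC1")

    def test_symmetric_counts(self):
        s = make_sample(B={(B1, B1): 25, (B1, B2): 50, (B2, B2): 25})
        t = allele_frequencies(s)
        assert t.frequency("B", B1) == pytest.approx(0.5)
        assert t.frequency("B", B2) == pytest.approx(0.5)

    def test_monomorphic_arm(self):
        s = make_sample(B={(B2, B2): 36})
        assert allele_frequencies(s).frequency("B", B2) == 1.0

    def test_hand_arithmetic(self):
        s = make_sample(B={(B1, B2): 40, (B2, B2): 60})
        assert allele_frequencies(s).frequency("B", B1) == pytest.approx(0.2)

    @given(
        st.lists(
            st.integers(min_value=0, max_value=500), min_size=3, max_size=3
        ).filter(lambda c: sum(c) > 0)
    )
    @settings(derandomize=True, max_examples=60)
    def test_frequencies_sum_to_one(self, counts):
        c11, c12, c22 = counts
        s = make_sample(
            B={k: v for k, v in
               [((B1, B1), c11), ((B1, B2), c12), ((B2, B2), c22)] if v}
        )
        total = sum(allele_frequencies(s).freqs["B"].values())
        assert total == pytest.approx(1.0, abs=1e-12)


class TestPolymorphismSummary:
    def test_hand_counted_larvae(self):
        larvae = [
            homozygous_larva(het_arms=("B",)),
            homozygous_larva(het_arms=("B", "F")),
            homozygous_larva(),
        ]
        s = PopulationSample(code="TST", larvae=larvae)
        summary = polymorphism_summary(s)
        assert summary.pct_het_larvae == pytest.approx(66.7, abs=0.05)
        assert summary.het_inv_per_larva == pytest.approx(1.0)

    def test_all_homozygous(self):
        s = PopulationSample(code="TST", larvae=[homozygous_larva()] * 5)
        summary = polymorphism_summary(s)
        assert summary.pct_het_larvae == 0.0
        assert summary.het_inv_per_larva == 0.0

    def test_monomorphic_population_has_seven_sequences(self):
        s = PopulationSample(code="TST", larvae=[homozygous_larva()] * 3)
        summary = polymorphism_summary(s)
        assert summary.n_sequences == 7
        assert summary.n_genotypes == 7

    def test_counts_only_requires_opt_in(self):
        s = make_sample(B={(B1, B2): 4})
        with pytest.raises(ValueError):
            polymorphism_summary(s)
        assert polymorphism_summary(s, allow_counts=True).het_inv_per_larva == 1.0

    def test_b_chromosome_freq_excluded_from_het(self):
        larvae = [homozygous_larva(b_chromosomes=1), homozygous_larva()]
        summary = polymorphism_summary(PopulationSample(code="T", larvae=larvae))
        assert summary.b_chromosome_freq == pytest.approx(0.5)
        assert summary.pct_het_larvae == 0.0

    def test_panel_mean_of_identical_summaries(self):
        s = polymorphism_summary(
            PopulationSample(code="T", larvae=[homozygous_larva(het_arms=("B",))])
        )
        pct, inv = quantitative_panel_means([s, s, s])
        assert pct == s.pct_het_larvae
        assert inv == s.het_inv_per_larva

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            quantitative_panel_means([])


class TestHardyWeinberg:
    def test_expected_proportions(self):
        exp = hw_expected({B1: 0.291, B2: 0.707, B3: 0.002})
        assert 100 * exp[(B1, B2)] == pytest.approx(41.1, abs=0.05)

    def test_fixed_allele(self):
        exp = hw_expected({B1: 1.0, B2: 0.0})
        assert exp[(B1, B1)] == 1.0
        assert exp[(B1, B2)] == 0.0

    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=4))
    @settings(derandomize=True, max_examples=60)
    def test_expected_sums_to_one(self, weights):
        total = sum(weights)
        freqs = {
            f"p'agiB{i + 1}": w / total for i, w in enumerate(weights)
        }
        assert sum(hw_expected(freqs).values()) == pytest.approx(1.0)

    def test_exact_hw_counts_give_zero_chi(self):
        r = hw_chi_square({(B1, B1): 25, (B1, B2): 50, (B2, B2): 25})
        assert r.chi_square == pytest.approx(0.0)
        assert r.df == 1
        assert r.direction == NO_DEVIATION

    def test_het_excess_detected(self):
        r = hw_chi_square({(B1, B1): 10, (B1, B2): 80, (B2, B2): 10})
        assert r.chi_square == pytest.approx(36.0)
        assert r.df == 1
        assert r.p_value < 0.05
        assert r.direction == HET_EXCESS

    def test_monomorphic_skipped(self):
        r = hw_chi_square({(B1, B1): 50})
        assert not r.tested
        assert r.direction == NO_DEVIATION

    def test_relabeling_invariance(self):
        counts = {(B1, B1): 12, (B1, B2): 30, (B2, B2): 8}
        relabeled = {(B2, B2): 12, (B1, B2): 30, (B1, B1): 8}
        assert hw_chi_square(counts).chi_square == pytest.approx(
            hw_chi_square(relabeled).chi_square
        )

    def test_three_allele_df(self):
        counts = {
            (B1, B1): 5, (B1, B2): 10, (B2, B2): 5, (B1, B3): 4, (B2, B3): 4,
            (B3, B3): 2,
        }
        assert hw_chi_square(counts).df == 3

    def test_exact_test_extremes(self):
        # total heterozygote excess at n=20 is wildly improbable under HW
        assert hw_exact_test({(B1, B2): 20}) < 0.01
        # perfectly proportioned counts sit in the bulk of the distribution
        assert hw_exact_test({(B1, B1): 5, (B1, B2): 10, (B2, B2): 5}) > 0.3


class TestPoolCensus:
    def test_nonzero_rule_over_fixture_tables(self, fx):
        # the frequency tables list 16 sequences but two of them (A2, C2)
        # occur only in populations below the quantitative threshold and
        # carry zero frequency throughout
        census = pool_census(fx.tables)
        assert census.pool_size == 14
        assert census.per_population["YAR-RY"] == 7

    def test_monomorphic_population_counts_seven(self):
        t = AlleleFrequencyTable(
            "MONO", {arm: {f"p'agi{arm}1": 1.0} for arm in ARMS}
        )
        assert pool_census([t]).pool_size == 7

    def test_union_is_monotone(self, fx):
        sizes = []
        for k in range(1, len(fx.tables) + 1):
            sizes.append(pool_census(fx.tables[:k]).pool_size)
        assert sizes == sorted(sizes)
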