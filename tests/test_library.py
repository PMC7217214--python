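"""Library combinatorics: diversity, mismatch laws, primer subsets, codes."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st

from poolpcr.library import (
    AVOGADRO,
    CodeSet,
    CodeSearchBudgetError,
    InfeasibleCodeError,
    LibrarySpec,
    PrimerSpec,
    copies_per_member,
    design_code_set,
    diversity,
    enumerate_members,
    hamming,
    mismatch_distribution,
    parse_variable_region,
    primer_subset,
    sample_members,
    variable_region_to_iupac,
)
from conftest import brute_force_mismatch_pmf

PRIMER = "A" * 20


def make_spec(variable: str, name: str = "lib") -> LibrarySpec:
    return LibrarySpec.from_iupac(name, PRIMER, variable, PRIMER)


class TestDiversity:
    def test_fully_degenerate_20_exceeds_a_trillion(self):
        spec = make_spec("N" * 20)
        assert diversity(spec) == 4**20 == 1_099_511_627_776

    def test_two_degenerate_positions_give_16_species(self):
        assert diversity(make_spec("AC" * 9 + "NN")) == 16

    def test_single_sequence_has_diversity_one(self):
        assert diversity(make_spec("ACGTACGTACGTACGTACGT")) == 1

    def test_exact_big_integer_no_float_truncation(self):
        spec = make_spec("N" * 40)
        d = diversity(spec)
        assert d == 4**40 and d % 2 == 0 and d > 2**63


class TestMismatchDistribution:
    def test_one_fully_degenerate_position(self):
        dist = mismatch_distribution(make_spec("N"))
        assert dist.pmf[0] == pytest.approx(0.25)
        assert dist.pmf[1] == pytest.approx(0.75)

    def test_x2_matches_known_exact_pmf(self):
        # brute-force over all 16 x 16 ordered pairs gives 1/16, 6/16, 9/16
        dist = mismatch_distribution(make_spec("NN"))
        assert dist.pmf[0] == pytest.approx(1 / 16)
        assert dist.pmf[1] == pytest.approx(6 / 16)
        assert dist.pmf[2] == pytest.approx(9 / 16)

    @pytest.mark.parametrize(
        "variable",
        ["N", "NN", "NNN", "NNNNNN", "RYN", "NNRRYY", "MKWS", "NBV"],
    )
    def test_agrees_with_exhaustive_enumeration(self, variable):
        spec = make_spec(variable)
        expected = brute_force_mismatch_pmf(spec)
        dist = mismatch_distribution(spec)
        for m, p in expected.items():
            assert dist.pmf[m] == pytest.approx(p, abs=1e-12)

    @pytest.mark.parametrize("variable", ["NN", "RYN", "NNRRYY"])
    def test_distinct_conditioning_agrees_with_enumeration(self, variable):
        spec = make_spec(variable)
        expected = brute_force_mismatch_pmf(spec, distinct=True)
        dist = mismatch_distribution(spec, distinct_members=True)
        assert dist.pmf[0] == 0.0
        for m, p in expected.items():
            assert dist.pmf[m] == pytest.approx(p, abs=1e-12)

    def test_x20_mean_is_15(self):
        dist = mismatch_distribution(make_spec("N" * 20))
        assert dist.mean == pytest.approx(20 * 3 / 4)

    def test_x20_mean_matches_monte_carlo_sampling(self):
        spec = make_spec("N" * 20)
        n = 100_000
        a = sample_members(spec, n, seed=11)
        b = sample_members(spec, n, seed=12)
        distances = np.array([hamming(x, y) for x, y in zip(a, b)])
        se = distances.std(ddof=1) / math.sqrt(n)
        assert abs(distances.mean() - 15.0) < 3 * se

    def test_conditioning_impossible_at_diversity_one(self):
        with pytest.raises(ValueError):
            mismatch_distribution(make_spec("ACGT"), distinct_members=True)


class TestPrimerSubset:
    def test_extension_fractions_on_fully_degenerate_library(self):
        spec = make_spec("N" * 20, "X_20")
        for k in (1, 5, 10):
            frac, reduced = primer_subset(spec, PrimerSpec(PRIMER, "ACGTACGTAC"[:k]))
            assert frac == Fraction(1, 4**k)
            assert diversity(reduced) == 4 ** (20 - k)

    def test_ten_base_extension_reduces_to_4_to_10(self):
        frac, reduced = primer_subset(
            make_spec("N" * 20), PrimerSpec(PRIMER, "ACGTACGTAC")
        )
        assert diversity(reduced) == 4**10 == 1_048_576

    def test_matching_fixed_position_contributes_factor_one(self):
        spec = make_spec("A" + "N" * 9)
        frac, reduced = primer_subset(spec, PrimerSpec(PRIMER, "A"))
        assert frac == 1
        assert diversity(reduced) == diversity(spec)

    def test_mismatching_fixed_position_gives_zero_not_error(self):
        spec = make_spec("A" + "N" * 9)
        frac, reduced = primer_subset(spec, PrimerSpec(PRIMER, "G"))
        assert frac == 0
        assert reduced is None

    def test_extension_longer_than_region_rejected(self):
        with pytest.raises(ValueError):
            primer_subset(make_spec("NN"), PrimerSpec(PRIMER, "ACG"))

    @given(k=st.integers(0, 12))
    def test_reduced_diversity_complements_fraction(self, k):
        spec = make_spec("N" * 12)
        frac, reduced = primer_subset(spec, PrimerSpec(PRIMER, "A" * k))
        assert diversity(reduced) * 4**k == diversity(spec)


class TestCopiesPerMember:
    def test_single_member_equals_molecule_count(self):
        assert copies_per_member(1e-9, 10e-6, 1) == pytest.approx(6.02214076e9)

    def test_medium_diversity_leaves_thousands_of_copies(self):
        copies = copies_per_member(1e-9, 10e-6, 4**10)
        assert copies == pytest.approx(6.02214076e9 / 4**10)
        assert 5000 < copies < 6000

    def test_high_diversity_leaves_under_one_copy(self):
        assert copies_per_member(1e-9, 10e-6, 4**20) < 1

    def test_zero_diversity_rejected(self):
        with pytest.raises(ValueError):
            copies_per_member(1e-9, 10e-6, 0)


class TestCodeDesign:
    def test_ten_by_twenty_distance_16_verified_independently(self):
        codes = design_code_set(10, 20, 16, seed=7)
        members = codes.members
        assert len(members) == 10 and len(set(members)) == 10
        pair_min = min(
            sum(a != b for a, b in zip(members[i], members[j]))
            for i in range(10)
            for j in range(i + 1, 10)
        )
        assert pair_min >= 16
        assert codes.min_pairwise_distance == pair_min

    def test_full_length_distance_code_is_constructed(self):
        codes = design_code_set(4, 4, 4, seed=1)
        for i, j, d in codes.pairwise_distances():
            assert d == 4

    def test_distance_beyond_length_is_infeasible(self):
        with pytest.raises(InfeasibleCodeError):
            design_code_set(2, 2, 3, seed=0)

    def test_plotkin_bound_rejects_oversized_requests(self):
        # at L=20, d=16 the quaternary Plotkin cap is 16 words
        with pytest.raises(InfeasibleCodeError):
            design_code_set(17, 20, 16, seed=0)

    def test_exhausted_budget_raises_retryable_error(self):
        with pytest.raises(CodeSearchBudgetError):
            design_code_set(16, 20, 16, seed=0, max_tries=20)

    def test_seed_determinism(self):
        assert design_code_set(6, 12, 6, seed=5).members == design_code_set(
            6, 12, 6, seed=5
        ).members

    def test_code_set_recomputes_distance_rather_than_trusting(self):
        cs = CodeSet(("AAAA", "AATT"), min_pairwise_distance=99)
        assert cs.min_pairwise_distance == 2


class TestHammingAndSampling:
    def test_hamming_basics(self):
        assert hamming("ACGT", "ACGT") == 0
        assert hamming("AAAA", "TTTT") == 4
        with pytest.raises(ValueError):
            hamming("AC", "ACG")

    def test_sampling_is_uniform_per_position(self):
        spec = make_spec("NN")
        members = sample_members(spec, 100_000, seed=3)
        for pos in range(2):
            for base in "ACGT":
                freq = sum(m[pos] == base for m in members) / len(members)
                assert abs(freq - 0.25) < 0.01

    def test_sampling_reproducible_and_degenerate_cases(self):
        spec = make_spec("ACGT")
        assert set(sample_members(spec, 50, seed=1)) == {"ACGT"}
        spec2 = make_spec("NNNN")
        assert sample_members(spec2, 20, seed=9) == sample_members(spec2, 20, seed=9)


@st.composite
def variable_regions(draw):
    size = draw(st.integers(1, 12))
    return tuple(
        frozenset(draw(st.sets(st.sampled_from("ACGT"), min_size=1, max_size=4)))
        for _ in range(size)
    )


class TestIupacRoundTrip:
    @given(region=variable_regions())
    def test_serialize_parse_is_lossless(self, region):
        assert parse_variable_region(variable_region_to_iupac(region)) == region

    def test_unknown_symbol_rejected(self):
        with pytest.raises(ValueError):
            parse_variable_region("ACGU")

    def test_enumeration_matches_diversity(self):
        spec = make_spec("RYN")
        members = list(enumerate_members(spec))
        assert len(members) == len(set(members)) == diversity(spec) == 16
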