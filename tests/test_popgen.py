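import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ampligeno.popgen_stats import (
    UndefinedLocusError,
    allele_frequencies,
    effective_alleles,
    expected_het,
    hwe_exact_test,
    locus_summary,
    observed_het,
    pic,
    round2,
    summarize_all,
)
from bruteforce import biallelic_hwe_pvalue


def matrix_from_calls(calls, locus="L1"):
    rows = [
        {
            "sample": f"s{i}",
            "locus": locus,
            "allele1": a,
            "allele2": b,
            "status": "called",
        }
        for i, (a, b) in enumerate(calls)
    ]
    return pd.DataFrame(rows)


# the biallelic reference configuration: 32 diploids, 13 heterozygotes,
# 4 minor homozygotes -> allele frequencies 43/64 and 21/64
REF_CALLS = [(44, 48)] * 13 + [(48, 48)] * 4 + [(44, 44)] * 15


class TestFrequencies:
    def test_minor_allele_in_two_heterozygotes(self):
        calls = [(18, 18)] * 30 + [(18, 20)] * 2
        assert allele_frequencies(calls) == {18: 62 / 64, 20: 2 / 64}

    def test_single_heterozygous_individual(self):
        assert allele_frequencies([(1, 2)]) == {1: 0.5, 2: 0.5}

    def test_matches_bruteforce_tally(self, rng):
        alleles = [10, 12, 14, 16]
        calls = [tuple(sorted(rng.choice(alleles, size=2))) for _ in range(50)]
        freqs = allele_frequencies(calls)
        flat = [x for c in calls for x in c]
        for a in set(flat):
            assert freqs[a] == pytest.approx(flat.count(a) / len(flat))
        assert sum(freqs.values()) == pytest.approx(1.0)

    def test_all_missing_is_undefined(self):
        with pytest.raises(UndefinedLocusError):
            allele_frequencies([])


class TestHetAndPic:
    def test_reference_locus_values(self):
        freqs = allele_frequencies(REF_CALLS)
        assert observed_het(REF_CALLS) == pytest.approx(13 / 32)
        assert expected_het(freqs) == pytest.approx(0.44091796875)
        assert effective_alleles(freqs) == pytest.approx(1.788646288, abs=1e-8)
        assert pic(freqs) == pytest.approx(0.343713641, abs=1e-8)

    def test_het_extremes(self):
        assert observed_het([(1, 1), (2, 2)]) == 0.0
        assert observed_het([(1, 2), (3, 4)]) == 1.0

    def test_even_biallelic_closed_forms(self):
        freqs = {16: 0.5, 19: 0.5}
        assert expected_het(freqs) == 0.5
        assert effective_alleles(freqs) == 2.0
        assert pic(freqs) == pytest.approx(0.375)

    def test_monomorphic_limits(self):
        freqs = {20: 1.0}
        assert expected_het(freqs) == 0.0
        assert effective_alleles(freqs) == 1.0
        assert pic(freqs) == 0.0

    def test_pic_matches_double_sum_for_uniform_alleles(self):
        for k in range(2, 7):
            freqs = {i: 1 / k for i in range(k)}
            ps = list(freqs.values())
            direct = (
                1
                - sum(p * p for p in ps)
                - sum(
                    2 * ps[i] ** 2 * ps[j] ** 2
                    for i in range(k)
                    for j in range(i + 1, k)
                )
            )
            assert pic(freqs) == pytest.approx(direct)

    @given(
        st.lists(st.floats(0.01, 1.0), min_size=1, max_size=6).map(
            lambda ws: {i: w / sum(ws) for i, w in enumerate(ws)}
        )
    )
    def test_identities(self, freqs):
        """He == 1 - 1/Ae exactly, and PIC never exceeds He."""
        he = expected_het(freqs)
        ae = effective_alleles(freqs)
        assert he == pytest.approx(1 - 1 / ae, abs=1e-12)
        assert pic(freqs) <= he + 1e-12
        assert 1.0 <= ae <= len(freqs) + 1e-12


class TestExactHWE:
    def test_two_heterozygote_configuration_gives_p_one(self):
        calls = [(18, 18)] * 30 + [(18, 20)] * 2
        # both attainable tables are no more probable than the observed
        assert hwe_exact_test(calls) == pytest.approx(1.0)

    def test_single_heterozygote_individual(self):
        assert hwe_exact_test([(1, 2)]) == pytest.approx(1.0)

    def test_all_heterozygous_extreme_matches_bruteforce(self):
        calls = [(1, 2)] * 32
        p = hwe_exact_test(calls)
        assert p == pytest.approx(biallelic_hwe_pvalue(0, 32, 0), rel=1e-9)
        assert p < 0.01

    @pytest.mark.parametrize(
        "n_AA,n_Aa,n_aa", [(30, 2, 0), (10, 12, 10), (20, 4, 8), (5, 25, 2)]
    )
    def test_biallelic_enumeration_matches_independent_formula(self, n_AA, n_Aa, n_aa):
        calls = [(1, 1)] * n_AA + [(1, 2)] * n_Aa + [(2, 2)] * n_aa
        assert hwe_exact_test(calls) == pytest.approx(
            biallelic_hwe_pvalue(n_AA, n_Aa, n_aa), rel=1e-9
        )

    def test_monomorphic_is_undefined(self):
        assert math.isnan(hwe_exact_test([(5, 5)] * 10))

    def test_monte_carlo_agrees_with_enumeration(self):
        # triallelic locus where both paths are feasible
        calls = (
            [(1, 1)] * 6 + [(1, 2)] * 7 + [(2, 2)] * 3 + [(1, 3)] * 4 + [(2, 3)] * 2
        )
        p_exact = hwe_exact_test(calls)
        reps = 40_000
        p_mc = hwe_exact_test(calls, mc_reps=reps, seed=5, max_tables=0)
        se = math.sqrt(p_exact * (1 - p_exact) / reps)
        assert abs(p_mc - p_exact) < 3 * se + 2 / reps

    def test_rejection_rate_is_conservative_under_hwe(self, rng):
        """Sampling genotypes under random mating, the exact test rejects
        at alpha=0.05 no more often than alpha (plus Monte Carlo slack)."""
        R, n, p_freq = 250, 32, 0.3
        rejections = 0
        for _ in range(R):
            g = rng.binomial(1, p_freq, size=(n, 2)) + 1
            calls = [tuple(sorted(pair)) for pair in g]
            if len({a for c in calls for a in c}) < 2:
                continue
            if hwe_exact_test(calls) <= 0.05:
                rejections += 1
        assert rejections / R <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / R)


class TestSummaries:
    def test_summary_matches_direct_formulas(self):
        matrix = matrix_from_calls(REF_CALLS)
        s = locus_summary(matrix, "L1")
        freqs = allele_frequencies(REF_CALLS)
        assert s.n == 32 and s.Ao == 2
        assert s.Ho == observed_het(REF_CALLS)
        assert s.He == expected_het(freqs)
        assert s.Ae == effective_alleles(freqs)
        assert s.PIC == pic(freqs)
        assert s.He == pytest.approx(1 - 1 / s.Ae)
        assert not s.monomorphic

    def test_reference_locus_rounds_to_reported_cells(self):
        s = locus_summary(matrix_from_calls(REF_CALLS), "L1")
        assert (round2(s.Ho), round2(s.He), round2(s.Ae), round2(s.PIC)) == (
            0.41,
            0.44,
            1.79,
            0.34,
        )

    def test_monomorphic_locus_flagged(self):
        matrix = matrix_from_calls([(20, 20)] * 10)
        table = summarize_all(matrix)
        row = table[table["locus"] == "L1"].iloc[0]
        assert row["note"] == "Monomorphic"
        assert row["Ao"] == 1
        assert math.isnan(row["HWE_p"])

    def test_mean_row_covers_polymorphic_loci_only(self):
        matrix = pd.concat(
            [
                matrix_from_calls(REF_CALLS, "L1"),
                matrix_from_calls([(20, 20)] * 32, "L2"),
                matrix_from_calls([(10, 12)] * 16 + [(10, 10)] * 16, "L3"),
            ]
        )
        table = summarize_all(matrix)
        mean = table[table["locus"] == "Mean"].iloc[0]
        assert "2 polymorphic" in mean["note"]
        l1 = locus_summary(matrix, "L1")
        l3 = locus_summary(matrix, "L3")
        assert mean["Ho"] == round2((l1.Ho + l3.Ho) / 2)
        assert mean["Ao"] == round2((l1.Ao + l3.Ao) / 2)

    def test_empty_matrix_gives_empty_report(self):
        empty = pd.DataFrame(columns=["sample", "locus", "allele1", "allele2", "status"])
        assert len(summarize_all(empty)) == 0

    def test_he_ae_identity_holds_for_random_matrices(self, rng):
        for _ in range(20):
            k = int(rng.integers(2, 6))
            alleles = list(range(10, 10 + 2 * k, 2))
            calls = [tuple(sorted(rng.choice(alleles, size=2))) for _ in range(30)]
            s = locus_summary(matrix_from_calls(calls), "L1", mc_reps=2000, seed=1)
            assert s.He == pytest.approx(1 - 1 / s.Ae, abs=1e-12)
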