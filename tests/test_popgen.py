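"""Diversity, divergence, site counting and Tajima's D."""

import math

import numpy as np
import pytest

from mkpop import (
    HaplotypeAlignment,
    count_sites,
    divergence,
    pairwise_diversity,
    tajima_d,
    tajima_p_coalescent,
    watterson_theta,
)
from mkpop.codon import codon_sites, pathway_differences
from mkpop.popgen import (
    _simulate_neutral_d,
    harmonic,
    jukes_cantor,
    synonymous_segregating_sites,
    tajima_d_from_counts,
)

from conftest import random_alignment


def _aln(ingroup, outgroup=("ATG",)):
    return HaplotypeAlignment("t", tuple(ingroup), tuple(outgroup))


class TestSiteCounting:
    def test_phe_codon_enumeration(self):
        # TTT: of its nine single-base changes only TTT->TTC is synonymous
        s, n = codon_sites("TTT")
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(8 / 3)

    def test_met_has_no_synonymous_sites(self):
        assert codon_sites("ATG") == (0.0, 3.0)

    def test_average_over_haplotypes(self):
        aln = _aln(["TTT", "TTC"], ["TTT"])
        sites = count_sites(aln)
        assert sites.L_s == pytest.approx(1 / 3)
        assert sites.L_n == pytest.approx(8 / 3)

    @pytest.mark.parametrize("seed", range(8))
    def test_site_classes_sum_to_three_per_codon(self, seed):
        aln = random_alignment(seed)
        sites = count_sites(aln)
        n_cols = len(aln.codon_columns())
        assert sites.L_s + sites.L_n == pytest.approx(3 * n_cols)

    def test_pathway_average_of_two_hit_codon(self):
        # ATG->ACA: via ACG (nonsyn then syn) or via ATA (nonsyn then
        # nonsyn); equal weights give (0.5, 1.5)
        assert pathway_differences("ATG", "ACA") == pytest.approx((0.5, 1.5))


class TestPairwiseDiversity:
    def test_one_synonymous_difference(self):
        # 50 Lys codons (L_s = 50/3 per hap) -- use an exact small case:
        # haplotypes differing by one synonymous change
        h1 = "AAA" * 25
        h2 = "AAG" + "AAA" * 24
        aln = _aln([h1, h2], [h1])
        pi_s, pi_a = pairwise_diversity(aln)
        sites = count_sites(aln)
        assert pi_s == pytest.approx(1 / sites.L_s)
        assert pi_a == 0.0

    def test_identical_haplotypes(self):
        aln = _aln(["ATGAAA"] * 3, ["ATGAAA"])
        assert pairwise_diversity(aln) == (0.0, 0.0)

    def test_three_haplotypes_against_pair_enumeration(self):
        # brute-force oracle: average the per-pair pathway counts directly
        haps = ["ATGAAAGGGTTTCCC", "ATGAAGGGGTTCCCC", "ATAAAAGGGTTTCCA"]
        aln = _aln(haps, [haps[0]])
        sd = nd = 0.0
        pairs = [(0, 1), (0, 2), (1, 2)]
        for i, j in pairs:
            for k in range(0, 15, 3):
                s, n = pathway_differences(haps[i][k : k + 3], haps[j][k : k + 3])
                sd += s
                nd += n
        sites = count_sites(aln)
        pi_s, pi_a = pairwise_diversity(aln)
        assert pi_s == pytest.approx(sd / len(pairs) / sites.L_s)
        assert pi_a == pytest.approx(nd / len(pairs) / sites.L_n)

    def test_needs_two_ingroup_haplotypes(self):
        with pytest.raises(ValueError, match=">=2 ingroup"):
            pairwise_diversity(_aln(["ATG"]))

    @pytest.mark.parametrize("seed", [3, 11])
    def test_invariant_to_haplotype_order(self, seed):
        aln = random_alignment(seed)
        rev = HaplotypeAlignment(
            aln.locus_id,
            tuple(reversed(aln.ingroup_haplotypes)),
            aln.outgroup_haplotypes,
        )
        assert pairwise_diversity(aln) == pytest.approx(pairwise_diversity(rev))


class TestDivergence:
    def test_single_synonymous_difference_jc(self):
        # Lys->Lys (AAA->AAG) in a 25-codon background
        ing = "AAA" * 25
        out = "AAG" + "AAA" * 24
        aln = _aln([ing], [out])
        sites = count_sites(aln)
        ks, ka = divergence(aln)
        assert ka == 0.0
        assert ks == pytest.approx(jukes_cantor(1 / sites.L_s))

    def test_single_nonsynonymous_difference_jc(self):
        ing = "AAA" * 25
        out = "ACA" + "AAA" * 24  # Lys->Thr
        aln = _aln([ing], [out])
        sites = count_sites(aln)
        ks, ka = divergence(aln)
        assert ks == 0.0
        assert ka == pytest.approx(jukes_cantor(1 / sites.L_n))

    def test_identical_species_samples(self):
        aln = _aln(["ATGAAA"] * 2, ["ATGAAA"])
        assert divergence(aln) == (0.0, 0.0)

    def test_saturated_proportion_reported_missing(self):
        # every Lys codon replaced synonymously: raw p_s = 25/L_s > 3/4
        ing = "AAA" * 25
        out = "AAG" * 25
        with pytest.warns(UserWarning, match="JC correction undefined"):
            ks, _ = divergence(_aln([ing], [out]))
        assert math.isnan(ks)


class TestWattersonTheta:
    def test_harmonic_sum_example(self):
        assert watterson_theta(3, 4, 1.0) == pytest.approx(3 / (1 + 0.5 + 1 / 3))

    def test_no_segregating_sites(self):
        assert watterson_theta(0, 12, 100.0) == 0.0

    def test_pair_of_haplotypes(self):
        assert watterson_theta(5, 2, 100.0) == pytest.approx(0.05)

    def test_requires_two_haplotypes(self):
        with pytest.raises(ValueError, match="n >= 2"):
            watterson_theta(1, 1, 100.0)


def _oracle_tajima(n, S, pi):
    """Independent transcription of the 1989 formulas."""
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


class TestTajimaD:
    def test_hand_case(self):
        assert tajima_d_from_counts(4, 3, 1.5) == pytest.approx(-0.754, abs=5e-4)

    def test_matches_closed_form_oracle_on_random_triples(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(4, 40))
            S = int(rng.integers(1, 60))
            pi = float(rng.uniform(0, 2 * S))
            assert tajima_d_from_counts(n, S, pi) == pytest.approx(
                _oracle_tajima(n, S, pi), abs=1e-9
            )

    def test_monomorphic_locus_is_missing(self):
        aln = _aln(["ATGAAA"] * 4, ["ATGAAA"])
        assert math.isnan(tajima_d(aln).D)

    def test_three_haplotypes_always_give_zero(self):
        # at n=3 every biallelic site contributes 2/3 to pi, so pi equals
        # S/a1 identically and D vanishes
        aln = _aln(["AAAAAA", "AAGAAA", "AAAAAG"], ["AAAAAA"])
        res = tajima_d(aln)
        assert res.S == 2
        assert res.D == pytest.approx(0.0, abs=1e-12)

    def test_needs_three_haplotypes(self):
        with pytest.raises(ValueError, match="n=2 < 3"):
            tajima_d(_aln(["ATG", "ATG"]))

    def test_synonymous_sites_only(self):
        # one syn (AAA/AAG) and one nonsyn (AAA/ACA) segregating codon
        aln = _aln(["AAAAAA", "AAGAAA", "AAAACA", "AAAAAA"], ["AAAAAA"])
        assert synonymous_segregating_sites(aln) == 1


class TestCoalescentNull:
    def test_mean_d_near_zero(self):
        rng = np.random.default_rng(7)
        sims = _simulate_neutral_d(10, 20, 2000, rng)
        assert abs(sims.mean()) < 0.15

    def test_extreme_observations_have_vanishing_p(self):
        assert tajima_p_coalescent(10, 20, 50.0, reps=500, seed=1) == 0.0
        assert tajima_p_coalescent(10, 20, -50.0, reps=500, seed=1) == 0.0

    def test_null_observation_has_moderate_p(self):
        p = tajima_p_coalescent(10, 20, 0.01, reps=2000, seed=1)
        assert 0.3 < p < 0.7

    def test_large_positive_d_is_significant(self):
        # strongly positive skews (intermediate-frequency excess) are rare
        # under the neutral null
        p = tajima_p_coalescent(11, 30, 2.29, reps=2000, seed=2)
        assert p < 0.03

    def test_rep_floor(self):
        with pytest.raises(ValueError, match="reps"):
            tajima_p_coalescent(10, 20, 1.0, reps=50)


class TestHarmonic:
    @pytest.mark.parametrize("n,expected", [(1, 0.0), (2, 1.0), (4, 1 + 0.5 + 1 / 3)])
    def test_values(self, n, expected):
        assert harmonic(n) == pytest.approx(expected)
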