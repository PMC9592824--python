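"""Segregating sites, nucleotide diversity, and Tajima's D against
brute-force and exact-fraction oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from tas2rpop import (
    compute_diversity,
    nucleotide_diversity,
    segregating_sites,
    tajima_constants,
    tajimas_d,
)
from tas2rpop.annotation import Consequence, VariantRecord
from tas2rpop.diversity import diversity_from_counts, tajimas_d_from_summaries

from conftest import matrix_from_haplotypes
from oracles import brute_force_pi_total, exact_tajimas_d, random_haplotype_matrix


class TestSegregatingSites:
    def test_monomorphic_matrix_has_zero_s(self):
        m = matrix_from_haplotypes(np.zeros((3, 6), dtype=int))
        assert segregating_sites(m) == (0, 0, 0)

    def test_indels_excluded_from_s(self):
        hap = np.array([[0, 1, 0, 1]] * 4)
        cons = [Consequence.NONSYNONYMOUS] * 4
        m = matrix_from_haplotypes(hap, consequences=cons)
        m.variants[3].alt = "GA"  # make the last row an indel
        S, S_ns, S_syn = segregating_sites(m)
        assert S == 3 and S_ns == 3 and S_syn == 0

    def test_ns_syn_split_leaves_stop_classes_out(self):
        hap = np.array([[0, 1, 0, 1]] * 3)
        cons = [Consequence.NONSYNONYMOUS, Consequence.SYNONYMOUS, Consequence.STOP_GAINED]
        m = matrix_from_haplotypes(hap, consequences=cons)
        S, S_ns, S_syn = segregating_sites(m)
        assert (S, S_ns, S_syn) == (3, 1, 1)
        assert S_ns + S_syn <= S

    def test_multiallelic_position_counts_once(self, small_manifest):
        # two alt rows at the same position
        from tas2rpop import GenotypeMatrix

        variants = [
            VariantRecord(chrom="1", pos=5, ref="C", alt="A"),
            VariantRecord(chrom="1", pos=5, ref="C", alt="T"),
        ]
        dosages = np.array([[1, 0, 0], [0, 1, 0]])
        hap_counts = np.array([[1, 6], [1, 6]])
        m = GenotypeMatrix(variants, dosages, hap_counts, ["a", "b", "c"])
        assert segregating_sites(m)[0] == 1


class TestNucleotideDiversity:
    def test_identical_haplotypes_give_zero(self):
        m = matrix_from_haplotypes(np.ones((4, 8), dtype=int))
        assert nucleotide_diversity(m, 100) == 0.0

    def test_three_haplotype_example_enumerated(self):
        # one site, one haplotype of 4 differs (diploid pairing needs even n)
        hap = np.array([[1, 0, 0, 0]])
        m = matrix_from_haplotypes(hap)
        # pairs: (1,0),(1,0),(1,0),(0,0),(0,0),(0,0) -> mean diff 3/6 = 1/2
        assert nucleotide_diversity(m, 10) == pytest.approx(0.05)

    def test_matches_brute_force_pair_enumeration(self, rng):
        for _ in range(50):
            hap = random_haplotype_matrix(rng)
            if hap.shape[1] % 2:
                hap = hap[:, :-1]
            if hap.shape[1] < 4:
                continue
            m = matrix_from_haplotypes(hap)
            L = 37
            expected = float(brute_force_pi_total(hap)) / L
            assert nucleotide_diversity(m, L) == pytest.approx(expected, abs=1e-12)

    def test_doubling_length_halves_pi(self, rng):
        hap = random_haplotype_matrix(rng)
        hap = hap[:, : (hap.shape[1] // 2) * 2]
        m = matrix_from_haplotypes(hap)
        assert nucleotide_diversity(m, 200) == pytest.approx(nucleotide_diversity(m, 100) / 2)

    def test_multiallelic_site_uses_full_heterozygosity(self):
        from tas2rpop import GenotypeMatrix

        # 6 haplotypes: 2 carry alt1, 1 carries alt2, 3 reference
        variants = [
            VariantRecord(chrom="1", pos=5, ref="C", alt="A"),
            VariantRecord(chrom="1", pos=5, ref="C", alt="T"),
        ]
        dosages = np.array([[2, 0, 0], [0, 1, 0]])
        hap_counts = np.array([[2, 6], [1, 6]])
        m = GenotypeMatrix(variants, dosages, hap_counts, ["a", "b", "c"])
        # direct: 1 - (2/6)^2 - (1/6)^2 - (3/6)^2 = 22/36; unbiased x 6/5
        expected = (22 / 36) * (6 / 5)
        assert nucleotide_diversity(m, 1) == pytest.approx(expected, abs=1e-12)


class TestTajimasD:
    def test_singleton_excess_drives_d_negative(self):
        n = 40
        hap = np.zeros((12, n), dtype=int)
        for i in range(12):
            hap[i, i % n] = 1  # every site a singleton
        m = matrix_from_haplotypes(hap)
        assert tajimas_d(m) < 0

    def test_undefined_when_no_segregating_sites(self):
        m = matrix_from_haplotypes(np.zeros((3, 8), dtype=int))
        assert tajimas_d(m) is None

    def test_matches_exact_fraction_oracle(self, rng):
        for _ in range(50):
            hap = random_haplotype_matrix(rng, max_hap=8, max_sites=5)
            if hap.shape[1] % 2:
                hap = hap[:, :-1]
            if hap.shape[1] < 4:
                continue
            m = matrix_from_haplotypes(hap)
            expected = exact_tajimas_d(hap)
            assert tajimas_d(m) == pytest.approx(expected, abs=1e-10)

    def test_constants_against_exact_fractions(self):
        from fractions import Fraction

        n = 10
        c = tajima_constants(n)
        a1 = sum(Fraction(1, i) for i in range(1, n))
        assert c["a1"] == pytest.approx(float(a1), abs=1e-14)
        assert c["b1"] == pytest.approx(float(Fraction(n + 1, 3 * (n - 1))), abs=1e-14)

    def test_missing_data_sites_dropped(self, tiny_vcf, tiny_panel_text):
        from tas2rpop import GeneRegion, extract_region_genotypes, read_sample_panel

        manifest = read_sample_panel(tiny_panel_text)
        m = extract_region_genotypes(tiny_vcf, GeneRegion("G", "7", 1, 1000, None, None), manifest)
        d_all = tajimas_d(m)
        # dropping the missing-data site by hand gives the same answer
        keep = m.hap_counts[:, 1] == 6
        d_manual = tajimas_d(m.take_sites(keep))
        assert d_all == pytest.approx(d_manual)


class TestInvariances:
    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000))
    def test_sample_and_site_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        hap = random_haplotype_matrix(rng)
        hap = hap[:, : (hap.shape[1] // 2) * 2]
        m = matrix_from_haplotypes(hap)
        base = (segregating_sites(m)[0], nucleotide_diversity(m, 50), tajimas_d(m))

        perm_sites = rng.permutation(hap.shape[0])
        m_sites = matrix_from_haplotypes(hap[perm_sites])
        perm_samples = rng.permutation(hap.shape[1] // 2)
        hap_pairs = hap.reshape(hap.shape[0], -1, 2)[:, perm_samples].reshape(hap.shape)
        m_samples = matrix_from_haplotypes(hap_pairs)

        for other in (m_sites, m_samples):
            got = (segregating_sites(other)[0], nucleotide_diversity(other, 50), tajimas_d(other))
            assert got[0] == base[0]
            assert got[1] == pytest.approx(base[1], abs=1e-12)
            if base[2] is None:
                assert got[2] is None
            else:
                assert got[2] == pytest.approx(base[2], abs=1e-10)

    def test_fast_counts_path_agrees_with_matrix_path(self, rng):
        hap = random_haplotype_matrix(rng, max_hap=12, max_sites=20)
        if hap.shape[1] % 2:
            hap = hap[:, :-1]
        n = hap.shape[1]
        m = matrix_from_haplotypes(hap)
        S_fast, pi_fast, d_fast = diversity_from_counts(hap.sum(axis=1), n, 77)
        assert S_fast == segregating_sites(m)[0]
        assert pi_fast == pytest.approx(nucleotide_diversity(m, 77), abs=1e-12)
        assert d_fast == pytest.approx(tajimas_d(m), abs=1e-10)
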