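"""Weir-Cockerham F_ST against an exact-fraction oracle, plus PCA checks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tas2rpop import SampleManifest, genotype_pca, wc_components_per_site, wc_fst_weighted
from tas2rpop.annotation import Consequence
from tas2rpop.differentiation import fst_from_pop_counts, theta_site

from conftest import matrix_from_haplotypes
from oracles import exact_wc_theta


def manifest_for(n_samples, n_pops, super_map=None):
    entries = []
    for i in range(n_samples):
        pop = f"P{i % n_pops}"
        sup = super_map[pop] if super_map else "SUP1"
        entries.append((f"S{i:03d}", pop, sup))
    return SampleManifest(entries)


class TestComponents:
    def test_identical_frequencies_give_nonpositive_theta(self):
        a, b, c = wc_components_per_site([10, 10], [20, 20])
        assert theta_site(a, b, c) <= 1e-12

    def test_fixed_differences_give_theta_one(self):
        a, b, c = wc_components_per_site([20, 0], [20, 20])
        assert theta_site(a, b, c) == pytest.approx(1.0)

    def test_matches_exact_fraction_oracle(self):
        a, b, _ = wc_components_per_site([10, 2], [20, 20])
        ea, eb, etheta = exact_wc_theta([10, 2], [20, 20])
        assert a == pytest.approx(ea, abs=1e-12)
        assert b == pytest.approx(eb, abs=1e-12)
        assert theta_site(a, b, 0.0) == pytest.approx(etheta, abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        counts=st.lists(
            st.tuples(st.integers(0, 30), st.integers(2, 30)).filter(lambda t: t[0] <= t[1]),
            min_size=2, max_size=6,
        )
    )
    def test_oracle_agreement_on_random_population_counts(self, counts):
        alts = [c[0] for c in counts]
        tots = [c[1] for c in counts]
        a, b, _ = wc_components_per_site(alts, tots)
        ea, eb, _ = exact_wc_theta(alts, tots)
        assert a == pytest.approx(ea, abs=1e-10)
        assert b == pytest.approx(eb, abs=1e-10)

    def test_single_population_rejected(self):
        with pytest.raises(ValueError):
            wc_components_per_site([5], [10])

    def test_empty_population_excluded(self):
        a1, b1, _ = wc_components_per_site([5, 0, 3], [10, 0, 10])
        a2, b2, _ = wc_components_per_site([5, 3], [10, 10])
        assert (a1, b1) == (a2, b2)


class TestWeightedFst:
    def test_single_site_equals_its_theta(self, rng):
        hap = (rng.random((1, 12)) < 0.4).astype(np.int8)
        while hap.sum() in (0, 12):
            hap = (rng.random((1, 12)) < 0.4).astype(np.int8)
        m = matrix_from_haplotypes(hap)
        manifest = manifest_for(6, 2)
        res = wc_fst_weighted(m, manifest)
        assert res.theta_weighted == pytest.approx(res.per_site[0][4])

    def test_ratio_of_sums_not_mean_of_ratios(self, rng):
        hap = (rng.random((8, 24)) < rng.uniform(0.2, 0.8, (8, 1))).astype(np.int8)
        m = matrix_from_haplotypes(hap)
        manifest = manifest_for(12, 3)
        res = wc_fst_weighted(m, manifest)
        sum_a = sum(r[1] for r in res.per_site)
        sum_den = sum(r[1] + r[2] + r[3] for r in res.per_site)
        assert res.theta_weighted == pytest.approx(sum_a / sum_den)
        mean_of_ratios = np.nanmean([r[4] for r in res.per_site])
        # the two aggregations genuinely differ on heterogeneous sites
        assert res.theta_weighted != pytest.approx(mean_of_ratios, abs=1e-6)

    def test_population_label_permutation_invariance(self, rng):
        hap = (rng.random((6, 24)) < 0.5).astype(np.int8)
        m = matrix_from_haplotypes(hap)
        base = wc_fst_weighted(m, manifest_for(12, 3)).theta_weighted
        relabeled = SampleManifest(
            [(s, {"P0": "X", "P1": "Y", "P2": "Z"}[p], sup)
             for s, p, sup in manifest_for(12, 3).entries]
        )
        assert wc_fst_weighted(m, relabeled).theta_weighted == pytest.approx(base)

    def test_one_population_pooling_degenerate(self, rng):
        hap = (rng.random((4, 12)) < 0.5).astype(np.int8)
        m = matrix_from_haplotypes(hap)
        with pytest.raises(ValueError):
            wc_fst_weighted(m, manifest_for(6, 1))

    def test_consequence_filters_partition_sites(self, rng):
        hap = (rng.random((10, 24)) < 0.5).astype(np.int8)
        cons = [Consequence.NONSYNONYMOUS if i % 2 else Consequence.SYNONYMOUS for i in range(10)]
        m = matrix_from_haplotypes(hap, consequences=cons)
        manifest = manifest_for(12, 2)
        all_res = wc_fst_weighted(m, manifest, site_filter="all")
        ns_res = wc_fst_weighted(m, manifest, site_filter="nonsynonymous")
        syn_res = wc_fst_weighted(m, manifest, site_filter="synonymous")
        assert ns_res.n_sites_used + syn_res.n_sites_used == all_res.n_sites_used

    def test_superpop_grouping_changes_unit(self, rng):
        hap = (rng.random((6, 24)) < 0.5).astype(np.int8)
        m = matrix_from_haplotypes(hap)
        super_map = {"P0": "A", "P1": "A", "P2": "B", "P3": "B"}
        manifest = manifest_for(12, 4, super_map)
        pop_res = wc_fst_weighted(m, manifest, grouping="population")
        sup_res = wc_fst_weighted(m, manifest, grouping="superpop")
        assert pop_res.grouping != sup_res.grouping

    def test_negative_estimates_not_clamped(self):
        # equal frequencies in equal-sized populations -> slightly negative a
        alt = np.array([[6], [6]]).T
        tot = np.array([[12], [12]]).T
        theta = fst_from_pop_counts(np.array([[6, 6]]), np.array([[12, 12]]))
        assert theta < 0


class TestPCA:
    def test_two_clusters_separate_on_pc1(self):
        hap = np.zeros((20, 24), dtype=np.int8)
        hap[:, 12:] = 1  # half the haplotypes carry all alt alleles
        m = matrix_from_haplotypes(hap)
        res = genotype_pca(m)
        pc1 = res.coords[:, 0]
        assert (pc1[:6] * pc1[6:] < 0).all()  # opposite signs by cluster
        assert res.var_explained[0] > 0.9

    def test_duplicated_sample_gets_identical_coordinates(self, rng):
        hap = (rng.random((12, 24)) < 0.5).astype(np.int8)
        hap[:, 2:4] = hap[:, 0:2]  # sample 1 duplicates sample 0
        m = matrix_from_haplotypes(hap)
        res = genotype_pca(m)
        np.testing.assert_allclose(res.coords[0], res.coords[1], atol=1e-8)

    def test_orthogonal_scores_and_bounded_variance(self, rng):
        hap = (rng.random((30, 40)) < rng.uniform(0.1, 0.9, (30, 1))).astype(np.int8)
        m = matrix_from_haplotypes(hap)
        res = genotype_pca(m, n_components=5)
        gram = res.coords.T @ res.coords
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8
        assert np.all(np.diff(res.var_explained) <= 1e-12)
        assert 0 < res.var_explained.sum() <= 1 + 1e-12

    def test_monomorphic_subset_is_error(self):
        hap = np.zeros((3, 8), dtype=np.int8)
        m = matrix_from_haplotypes(hap)
        with pytest.raises(ValueError):
            genotype_pca(m)
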