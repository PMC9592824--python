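"""Window tiling, windowed statistics, and empirical percentile calls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tas2rpop import (
    NullDistribution,
    pe_percentile,
    read_sample_panel,
    tile_windows,
    window_statistics,
)
from tas2rpop.io import read_mask
from tas2rpop.null import read_null, write_null


class TestTiling:
    def test_exact_tiling_without_mask(self):
        windows = tile_windows({"1": 10_000}, 1000)
        assert len(windows) == 10
        assert windows[0].start == 1 and windows[0].end == 1000
        assert windows[-1].end == 10_000

    def test_any_mask_overlap_drops_window(self):
        mask = read_mask("1\t2000\t3000\n")
        windows = tile_windows({"1": 10_000}, 1000, mask)
        assert len(windows) == 9
        assert all(not (w.start == 2001) for w in windows)

    def test_partial_tail_window_dropped(self):
        assert len(tile_windows({"1": 10_500}, 1000)) == 10

    def test_single_base_overlap_still_drops(self):
        mask = read_mask("1\t1999\t2000\n")  # last base of window 2
        windows = tile_windows({"1": 10_000}, 1000, mask)
        assert len(windows) == 9

    def test_overlap_fraction_threshold_configurable(self):
        mask = read_mask("1\t1999\t2000\n")
        windows = tile_windows({"1": 10_000}, 1000, mask, max_mask_overlap=0.01)
        assert len(windows) == 10

    def test_tiny_windows_rejected(self):
        with pytest.raises(ValueError):
            tile_windows({"1": 1000}, 50)


class TestPercentile:
    def test_below_minimum_is_low_outlier(self):
        null = NullDistribution("pi", np.array([1.0, 2.0, 3.0]))
        call = pe_percentile(null, 0.5)
        assert call.pe == 0.0 and call.flag == "low_outlier"

    def test_counting_with_ties(self):
        null = NullDistribution("pi", np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert pe_percentile(null, 3.5).pe == pytest.approx(60.0)
        assert pe_percentile(null, 3.5).flag == "none"
        # ties count toward the percentile
        assert pe_percentile(null, 3.0).pe == pytest.approx(60.0)

    def test_above_maximum_is_high_outlier(self):
        null = NullDistribution("pi", np.array([1.0, 2.0, 3.0]))
        call = pe_percentile(null, 10.0)
        assert call.pe == 100.0 and call.flag == "high_outlier"

    def test_five_ninetyfive_flag_boundaries(self):
        null = NullDistribution("tajima_d", np.arange(100, dtype=float))
        assert pe_percentile(null, 3.5).flag == "low_outlier"   # pe = 4
        assert pe_percentile(null, 4.5).flag == "none"          # pe = 5 (not < 5)
        assert pe_percentile(null, 94.5).flag == "none"         # pe = 95 (not > 95)
        assert pe_percentile(null, 95.5).flag == "high_outlier" # pe = 96

    def test_non_finite_observed_rejected(self):
        null = NullDistribution("pi", np.array([1.0]))
        with pytest.raises(ValueError):
            pe_percentile(null, float("nan"))

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000))
    def test_percentile_monotone_in_observed(self, seed):
        rng = np.random.default_rng(seed)
        null = NullDistribution("pi", rng.normal(size=50))
        obs = np.sort(rng.normal(size=10))
        pes = [pe_percentile(null, o).pe for o in obs]
        assert all(a <= b for a, b in zip(pes, pes[1:]))


class TestNullDistribution:
    def test_values_sorted_and_provenance_conserved(self):
        null = NullDistribution("fst", np.array([3.0, 1.0, 2.0]),
                                n_windows_total=5, n_windows_dropped=2)
        np.testing.assert_array_equal(null.values, [1.0, 2.0, 3.0])
        assert null.n_windows_dropped + len(null) == null.n_windows_total

    def test_non_finite_values_rejected(self):
        with pytest.raises(ValueError):
            NullDistribution("pi", np.array([1.0, np.nan]))

    def test_inconsistent_provenance_rejected(self):
        with pytest.raises(ValueError):
            NullDistribution("pi", np.array([1.0]), n_windows_total=5, n_windows_dropped=1)

    def test_tsv_round_trip(self, tmp_path):
        null = NullDistribution("tajima_d", np.array([-2.0, -1.5, 0.25]),
                                n_windows_total=4, n_windows_dropped=1, mask_id="m1")
        path = tmp_path / "null.tsv"
        write_null(null, path)
        again = read_null(path)
        assert again.statistic == "tajima_d"
        assert again.mask_id == "m1"
        np.testing.assert_array_equal(again.values, null.values)
        assert again.n_windows_dropped == 1


class TestWindowStatistics:
    def test_windowed_null_from_synthetic_vcf(self, tmp_path):
        from tas2rpop import SimConfig, simulate_loci, write_bundle

        bundle = simulate_loci(SimConfig(seed=5, n_loci=6, mask_interval_bp=0))
        paths = write_bundle(bundle, tmp_path)
        manifest = read_sample_panel(paths["panel"])
        lengths = {loc.chrom: loc.length for loc in bundle.loci}
        windows = tile_windows(lengths, 1000)
        null = window_statistics(paths["vcf"], windows, manifest, "tajima_d")
        assert null.n_windows_total == len(windows)
        assert len(null) + null.n_windows_dropped == len(windows)
        # oracle recomputation per window from the in-memory haplotypes
        from tas2rpop.diversity import diversity_from_counts
        from tas2rpop import locus_matrix

        expected = []
        for i, loc in enumerate(bundle.loci):
            snp = np.array([v.is_snp for v in loc.variants])
            in_window = (loc.positions >= 1) & (loc.positions <= 1000) & snp
            counts = loc.alt_counts[in_window]
            n = loc.haplotypes.shape[1]
            _, _, d = diversity_from_counts(counts, n, 1000)
            if d is not None:
                expected.append(d)
        np.testing.assert_allclose(null.values, np.sort(expected), atol=1e-10)

    def test_all_monomorphic_windows_give_empty_null_error(self, tmp_path):
        vcf = tmp_path / "mono.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1,length=2000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\n"
            "1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0|0\t0|0\n"
        )
        manifest = read_sample_panel("#sample\tpop\tsuper_pop\nA\tP1\tS1\nB\tP2\tS1\n")
        windows = tile_windows({"1": 2000}, 1000)
        with pytest.raises(ValueError, match="empty null"):
            window_statistics(vcf, windows, manifest, "tajima_d")
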