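import numpy as np
import pytest
from hypothesis import given, strategies as st

from fcbwas import meta
from fcbwas.connectivity import AtlasSpec, link_index
from fcbwas.site_stats import SiteLinkResult
from oracles import flood_fill_clusters, stouffer_brute


def _site_result(signed_z, site_id="s", n_pat=10, n_con=10):
    z = np.asarray(signed_z, dtype=float)
    return SiteLinkResult(
        site_id=site_id,
        t_statistic=z.copy(),
        df=n_pat + n_con - 2,
        p_two_tailed=np.full(z.shape, 0.5),
        signed_z=z,
        mean_diff=z * 0.1,
        var_diff=np.full(z.shape, 0.01),
        n_patients=n_pat,
        n_controls=n_con,
    )


class TestStouffer:
    def test_single_site_identity_for_any_weight(self):
        assert meta.stouffer_combine([1.5], [7.0]) == pytest.approx(1.5, abs=1e-12)

    def test_equal_weights_equal_z_closed_form(self):
        for k in (2, 3, 5):
            z = meta.stouffer_combine([0.8] * k, [1.0] * k)
            assert z == pytest.approx(np.sqrt(k) * 0.8, abs=1e-12)

    def test_two_site_example(self):
        # (2*sqrt(40) + 1*sqrt(60)) / sqrt(100) = 2.0395077...
        z = meta.stouffer_combine([2.0, 1.0], [np.sqrt(40), np.sqrt(60)])
        assert z == pytest.approx(2.039508, abs=1e-6)
        assert z == pytest.approx(stouffer_brute([2.0, 1.0], [np.sqrt(40), np.sqrt(60)]), abs=1e-12)

    def test_nonfinite_site_z_flags_link_missing(self):
        z = meta.stouffer_combine(np.array([[1.0, np.nan], [1.0, 1.0]]), [1, 1])
        assert np.isfinite(z[0]) and np.isnan(z[1])

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(ValueError):
            meta.stouffer_combine([1.0, 1.0], [1.0, 0.0])

    @given(
        st.lists(st.floats(-4, 4), min_size=2, max_size=6),
        st.floats(0.1, 50),
    )
    def test_weight_scale_invariance(self, zs, c):
        w = np.arange(1.0, len(zs) + 1)
        a = meta.stouffer_combine(zs, w)
        b = meta.stouffer_combine(zs, c * w)
        assert a == pytest.approx(b, abs=1e-9)

    @given(st.lists(st.floats(-4, 4), min_size=1, max_size=6))
    def test_matches_brute_force(self, zs):
        w = np.sqrt(np.arange(2.0, len(zs) + 2))
        assert meta.stouffer_combine(zs, w) == pytest.approx(
            stouffer_brute(zs, w), abs=1e-10
        )


class TestBonferroni:
    def test_whole_brain_threshold_two_sig_figs(self):
        alpha = meta.bonferroni_threshold(1_134_570_430)
        assert f"{alpha:.1e}" == "4.4e-11"

    def test_single_link(self):
        assert meta.bonferroni_threshold(1) == 0.05

    def test_region_level_90_nodes(self):
        assert meta.bonferroni_threshold(4005) == pytest.approx(1.2484e-5, rel=1e-4)


class TestCombineSites:
    def test_single_site_reduction_is_exact(self):
        site = _site_result([1.2, -0.5, 3.0])
        combined = meta.combine_sites([site])
        assert np.array_equal(combined.site_zs[0], site.signed_z)
        assert np.allclose(combined.combined_z, site.signed_z)

    def test_weights_schemes_differ_only_by_profile(self):
        sites = [_site_result([2.0, 1.0], "a", 20, 20), _site_result([1.0, 2.0], "b", 30, 30)]
        zs = meta.combine_sites(sites, weights="sqrt_n").combined_z
        zn = meta.combine_sites(sites, weights="n").combined_z
        # literal sample-size weighting tilts toward the larger site
        assert not np.allclose(zs, zn)
        w = np.array([np.sqrt(40), np.sqrt(60)])
        assert zs[0] == pytest.approx(stouffer_brute([2.0, 1.0], w), abs=1e-12)

    def test_direction_and_significance_flags(self):
        sites = [_site_result([6.0, -6.0, 0.1]) for _ in range(3)]
        combined = meta.combine_sites(sites)
        assert list(combined.direction) == [1, -1, 1]
        assert combined.significant[0] and combined.significant[1]
        assert not combined.significant[2]
        assert np.all((combined.combined_p > 0) & (combined.combined_p <= 1))


class TestMA:
    def test_no_significant_links_zero_map(self):
        ma = meta.compute_ma(np.ones(10), 0.05, 5)
        assert np.all(ma.counts == 0)

    def test_toy_counts_match_brute_force(self):
        # sub-alpha links: (0,1), (0,2), (3,4) -> MA = (2,1,1,1,1)
        p = np.ones(10)
        for i, j in [(0, 1), (0, 2), (3, 4)]:
            p[link_index(i, j, 5)] = 1e-6
        ma = meta.compute_ma(p, 0.05, 5)
        assert list(ma.counts) == [2, 1, 1, 1, 1]

    def test_all_links_significant(self):
        ma = meta.compute_ma(np.zeros(15) + 1e-9, 0.05, 6)
        assert np.all(ma.counts == 5)

    def test_conservation_invariant(self, rng):
        p = rng.uniform(0, 1, 45)
        ma = meta.compute_ma(p, 0.3, 10)
        assert ma.counts.sum() == 2 * (p < 0.3).sum()


class TestClusters:
    AFFINE = np.diag([3.0, 3.0, 3.0, 1.0])

    def test_single_voxel_below_min_size(self):
        vol = np.zeros((8, 8, 8), dtype=int)
        vol[4, 4, 4] = 5
        assert meta.extract_clusters(vol, self.AFFINE, min_size=20) == []

    def test_solid_block_matches_flood_fill_oracle(self):
        vol = np.zeros((9, 9, 9), dtype=int)
        vol[3:6, 3:6, 3:6] = np.arange(27).reshape(3, 3, 3) + 1
        clusters = meta.extract_clusters(vol, self.AFFINE, min_size=20)
        oracle = flood_fill_clusters(vol)
        assert len(clusters) == 1 and len(oracle) == 1
        assert clusters[0].size == 27 == len(oracle[0])
        assert vol[clusters[0].peak_voxel] == 27
        expect_mm = (self.AFFINE @ [*clusters[0].peak_voxel, 1.0])[:3]
        assert np.allclose(clusters[0].peak_mm, expect_mm)

    def test_two_separated_blocks(self):
        vol = np.zeros((10, 10, 10), dtype=int)
        vol[0:3, 0:3, 0:3] = 2
        vol[6:9, 6:9, 6:9] = 7
        for scheme in (6, 18, 26):
            clusters = meta.extract_clusters(
                vol, self.AFFINE, min_size=20, connectivity=scheme
            )
            assert len(clusters) == 2
            assert clusters[0].peak_ma == 7  # sorted by peak MA

    def test_empty_map(self):
        assert meta.extract_clusters(np.zeros((5, 5, 5)), self.AFFINE) == []

    def test_ma_to_volume_paints_regions(self):
        labels = np.zeros((2, 2, 2), dtype=int)
        labels[0] = 1
        labels[1] = 2
        atlas = AtlasSpec(label_volume=labels, affine=np.eye(4))
        from fcbwas.meta import MAMap, ma_to_volume

        vol = ma_to_volume(MAMap(counts=np.array([3, 9]), alpha=0.05), atlas)
        assert np.all(vol[0] == 3) and np.all(vol[1] == 9)


class TestManhattan:
    def test_no_links_under_cutoff(self):
        table = meta.manhattan_export(np.ones(6), np.array([1, 1, 2, 2]), 4)
        assert len(table) == 0

    def test_single_link_neg_log10(self):
        p = np.ones(6)
        p[link_index(0, 2, 4)] = 1e-8
        table = meta.manhattan_export(p, np.array([5, 5, 9, 9]), 4)
        assert len(table) == 1
        assert table.iloc[0]["neg_log10_p"] == pytest.approx(8.0)
        assert (table.iloc[0]["region_a"], table.iloc[0]["region_b"]) == (5, 9)

    def test_background_nodes_excluded(self):
        p = np.full(6, 1e-8)
        table = meta.manhattan_export(p, np.array([0, 1, 1, 2]), 4)
        # links touching node 0 (region 0) are dropped
        assert len(table) == 3
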