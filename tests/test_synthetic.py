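import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.diagnostic import acorr_ljungbox

from fcbwas.connectivity import fisher_z, link_index
from fcbwas.synthetic import (
    SimulationConfig,
    default_effect_map,
    make_atlas,
    read_cohort,
    region_link_matrix,
    simulate_cohort,
    write_cohort,
)


class TestConfigValidation:
    def test_invalid_ar1_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(ar1_coefficient=1.0)

    def test_effect_region_outside_atlas_rejected(self):
        with pytest.raises(ValueError, match="atlas"):
            SimulationConfig(effect_map=[(1, 99, 0.3)])

    def test_excessive_delta_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(effect_map=[(1, 2, 2.5)])

    def test_untileable_grid_rejected(self):
        with pytest.raises(ValueError, match="tile"):
            SimulationConfig(grid_shape=(7, 7, 7), n_regions=8, effect_map=[])

    def test_default_effect_map_mixed_sign_on_hub(self):
        em = default_effect_map(5, 27)
        assert len(em) == 10
        assert all(5 in (a, b) for a, b, _ in em)
        signs = {np.sign(d) for _, _, d in em}
        assert signs == {1.0, -1.0}


class TestAtlasTiling:
    def test_labels_cover_grid(self):
        atlas = make_atlas((12, 12, 12), 27)
        assert atlas.label_volume.min() == 1
        assert set(np.unique(atlas.label_volume)) == set(range(1, 28))
        # equal-size blocks
        assert np.all(np.bincount(atlas.label_volume.ravel())[1:] == 12**3 // 27)

    def test_affine_centers_grid(self):
        atlas = make_atlas((12, 12, 12), 27, voxel_size_mm=3.0)
        corner = atlas.affine @ [0, 0, 0, 1]
        assert np.allclose(corner[:3], -3.0 * 11 / 2)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = SimulationConfig(n_sites=1, n_patients=3, n_controls=3, n_timepoints=60)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        assert np.array_equal(a.region_series, b.region_series)
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)

    def test_subject_streams_stable_under_count_change(self):
        base = dict(n_sites=1, n_controls=3, n_timepoints=60)
        small = simulate_cohort(SimulationConfig(n_patients=3, **base))
        large = simulate_cohort(SimulationConfig(n_patients=5, **base))
        # the first three patients are unchanged when more are added
        assert np.array_equal(small.region_series[:3], large.region_series[:3])


@pytest.fixture(scope="module")
def big_cohort():
    cfg = SimulationConfig(
        n_sites=1,
        n_patients=110,
        n_controls=110,
        site_shift_sd=0.0,
        covariate_effects={},
        ar1_coefficient=0.0,
        seed=21,
    )
    cohort = simulate_cohort(cfg)
    return cohort, region_link_matrix(cohort)


class TestGeneratorMoments:
    """Monte-Carlo checks of the generator against its own target moments."""

    def test_planted_links_shift_by_delta(self, big_cohort):
        cohort, links = big_cohort
        pat = (cohort.phenotypes["group"] == "patient").to_numpy()
        n = cohort.config.n_regions
        se = np.sqrt(2.0 / pat.sum()) / np.sqrt(cohort.config.n_timepoints - 3)
        for a, b, dz in cohort.config.effect_map:
            col = links[:, link_index(a - 1, b - 1, n)]
            diff = col[pat].mean() - col[~pat].mean()
            assert diff == pytest.approx(dz, abs=3 * se)

    def test_null_links_stay_at_baseline(self, big_cohort):
        cohort, links = big_cohort
        n = cohort.config.n_regions
        planted = {
            link_index(a - 1, b - 1, n) for a, b, _ in cohort.config.effect_map
        }
        controls = (cohort.phenotypes["group"] == "control").to_numpy()
        se = 1.0 / np.sqrt((cohort.config.n_timepoints - 3) * controls.sum())
        null_cols = [k for k in range(links.shape[1]) if k not in planted]
        means = links[controls][:, null_cols].mean(axis=0)
        # allow a small Fisher-z bias term on top of 3 SE
        within = np.abs(means - cohort.config.baseline_z) < 3 * se + 2e-3
        assert within.mean() > 0.95

    def test_empty_effect_map_gives_uniform_group_p(self):
        from fcbwas.site_stats import site_link_test
        from scipy import stats

        cfg = SimulationConfig(
            n_sites=1, n_patients=40, n_controls=40, effect_map=[],
            covariate_effects={}, seed=3,
        )
        cohort = simulate_cohort(cfg)
        links = region_link_matrix(cohort)
        groups = (cohort.phenotypes["group"] == "patient").to_numpy().astype(int)
        res = site_link_test(links, groups)
        assert stats.kstest(res.p_two_tailed, "uniform").pvalue > 0.01


def test_white_noise_series_pass_ljung_box_screen():
    cfg = SimulationConfig(
        n_sites=1, n_patients=3, n_controls=3, ar1_coefficient=0.0,
        covariate_effects={}, effect_map=[], seed=5,
    )
    cohort = simulate_cohort(cfg)
    rejections = []
    for subj in range(cohort.n_subjects):
        for region in range(cohort.config.n_regions):
            p = acorr_ljungbox(cohort.region_series[subj, region], lags=[10])[
                "lb_pvalue"
            ].iloc[0]
            rejections.append(p < 0.05)
    rate = np.mean(rejections)  # 162 series, nominal 5%
    assert rate < 0.05 + 3 * np.sqrt(0.05 * 0.95 / len(rejections))


def test_ar1_raises_lag_one_autocorrelation():
    cfg = SimulationConfig(n_sites=1, n_patients=3, n_controls=3, seed=5,
                           ar1_coefficient=0.5, effect_map=[])
    cohort = simulate_cohort(cfg)
    x = cohort.region_series[0]
    ac = np.mean([np.corrcoef(r[:-1], r[1:])[0, 1] for r in x])
    assert ac == pytest.approx(0.5, abs=0.12)


def test_truth_table_identifies_every_planted_link(effect_cohort):
    truth = effect_cohort.truth
    assert len(truth) == len(effect_cohort.config.effect_map)
    recorded = {(a, b, d) for a, b, d in truth.itertuples(index=False)}
    assert recorded == set(effect_cohort.config.effect_map)
    assert set(truth.columns) == {"region_a", "region_b", "delta_z"}


class TestRoundTrip:
    def _small_cfg(self, **kw):
        return SimulationConfig(
            n_sites=2, n_patients=3, n_controls=3, grid_shape=(6, 6, 6),
            n_regions=8, n_timepoints=40, seed=9, effect_map=[(1, 2, 0.3)], **kw
        )

    def test_region_level_round_trip(self, tmp_path):
        cohort = simulate_cohort(self._small_cfg())
        write_cohort(cohort, tmp_path)
        back = read_cohort(tmp_path)
        z0 = region_link_matrix(cohort)
        z1 = region_link_matrix(back)
        assert np.abs(z0 - z1).max() < 1e-6
        pd.testing.assert_frame_equal(cohort.truth, back.truth)

    def test_voxel_level_round_trip_within_float32(self, tmp_path):
        cohort = simulate_cohort(self._small_cfg(), level="voxel")
        write_cohort(cohort, tmp_path)
        back = read_cohort(tmp_path)
        assert np.allclose(back.images[0], cohort.images[0], atol=1e-5)
        assert np.array_equal(back.atlas.label_volume, cohort.atlas.label_volume)

    def test_missing_directory_errors_before_writing(self, tmp_path):
        cohort = simulate_cohort(self._small_cfg())
        missing = tmp_path / "nope"
        with pytest.raises(FileNotFoundError):
            write_cohort(cohort, missing)
        assert not missing.exists()

    def test_manifest_lists_each_subject_once(self, tmp_path):
        import json

        cohort = simulate_cohort(self._small_cfg())
        manifest = json.loads(write_cohort(cohort, tmp_path).read_text())
        ids = [s["subject_id"] for s in manifest["subjects"]]
        assert sorted(ids) == sorted(cohort.phenotypes["subject_id"])
        assert len(set(ids)) == cohort.n_subjects


def test_voxel_series_correlate_with_region_latents():
    cfg = SimulationConfig(
        n_sites=1, n_patients=3, n_controls=3, grid_shape=(6, 6, 6),
        n_regions=8, n_timepoints=80, seed=2, effect_map=[],
    )
    cohort = simulate_cohort(cfg, level="voxel")
    from fcbwas.connectivity import extract_region_series

    extracted = extract_region_series(cohort.images[0], cohort.atlas)
    # voxel noise (SD 1) averages down over 27 voxels/region
    for r in range(8):
        c = np.corrcoef(extracted[r], cohort.region_series[0, r])[0, 1]
        assert c > 0.9


def test_clinical_coupling_plants_within_site_correlation():
    cfg = SimulationConfig(
        n_sites=2, n_patients=60, n_controls=5, effect_map=[(1, 2, 0.0)],
        covariate_effects={}, clinical_coupling=[(1, 2, "panss_neg", 0.5)], seed=13,
    )
    cohort = simulate_cohort(cfg)
    links = region_link_matrix(cohort)
    pat = (cohort.phenotypes["group"] == "patient").to_numpy()
    col = links[pat, link_index(0, 1, cfg.n_regions)]
    scores = cohort.phenotypes.loc[pat, "panss_neg"].to_numpy()
    sites = cohort.phenotypes.loc[pat, "site"].to_numpy()
    rs = [
        np.corrcoef(col[sites == s], scores[sites == s])[0, 1]
        for s in np.unique(sites)
    ]
    assert np.mean(rs) == pytest.approx(0.5, abs=0.25)
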