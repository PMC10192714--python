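"""Synthetic nuclei, foci placement and colony tables."""

import numpy as np
import pytest

from nucleodyn import (
    SceneConfig,
    add_foci,
    apply_noise,
    detect_foci,
    make_colony_table,
    make_nucleus,
    normalize_dapi,
    render_pcna,
)
from nucleodyn.errors import InputError, PlacementError
from nucleodyn.geometry import normalized_radial_map
from nucleodyn.synth import PHASE_RENDER_DEFAULTS


class TestMakeNucleus:
    def test_noise_free_image_is_flat_in_nucleoplasm(self, plain_scene):
        s = plain_scene
        assert np.all(s.image[s.analysis_mask] == s.config.background)
        assert np.all(s.image[~s.nucleus_mask] == 0)

    def test_masks_are_consistent(self, plain_scene):
        s = plain_scene
        assert not np.any(s.nucleoli_mask & ~s.nucleus_mask)
        assert s.nucleoli_mask.sum() > 0

    def test_seed_determinism(self):
        a = make_nucleus(seed=3)
        b = make_nucleus(seed=3)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.nucleoli_mask, b.nucleoli_mask)

    def test_nucleoli_area_ratio_within_bounds(self):
        cfg = SceneConfig()
        for seed in range(25):
            s = make_nucleus(cfg, seed=seed)
            ratio = s.nucleoli_mask.sum() / s.nucleus_mask.sum()
            assert cfg.nucleoli_area_ratio[0] <= ratio <= cfg.nucleoli_area_ratio[1]

    def test_oversized_nucleus_rejected(self):
        with pytest.raises(Exception):
            SceneConfig(shape=(64, 64))


class TestAddFoci:
    def test_zero_foci_is_identity(self, plain_scene):
        before = plain_scene.image.copy()
        out = add_foci(plain_scene, 0)
        assert np.array_equal(out.image, before)
        assert out.foci_truth == []

    def test_single_bright_focus_detected_once(self, plain_scene):
        add_foci(plain_scene, 1, radius_px=(3, 3), amplitude=(10, 10), seed=5)
        report = detect_foci(plain_scene.image, plain_scene.nucleus_mask,
                             plain_scene.nucleoli_mask)
        assert report.n_foci == 1
        assert report.i_r_foci > 1

    def test_truth_centres_inside_nucleus(self, plain_scene):
        add_foci(plain_scene, 8, seed=2)
        for f in plain_scene.foci_truth:
            assert plain_scene.nucleus_mask[int(round(f.row)), int(round(f.col))]

    def test_peripheral_placement_is_in_outer_shell(self, plain_scene):
        add_foci(plain_scene, 6, placement="peripheral", seed=9)
        r_norm = normalized_radial_map(plain_scene.nucleus_mask)
        for f in plain_scene.foci_truth:
            assert r_norm[int(round(f.row)), int(round(f.col))] > plain_scene.config.shell_threshold

    def test_minimum_distance_respected(self, plain_scene):
        add_foci(plain_scene, 10, seed=4)
        foci = plain_scene.foci_truth
        for i in range(len(foci)):
            for j in range(i + 1, len(foci)):
                d = np.hypot(foci[i].row - foci[j].row, foci[i].col - foci[j].col)
                assert d >= plain_scene.config.min_dist_factor * (
                    foci[i].radius_px + foci[j].radius_px)

    def test_impossible_packing_raises(self, plain_scene):
        with pytest.raises(PlacementError):
            add_foci(plain_scene, 500, radius_px=(6, 6), seed=1, max_tries_per_focus=20)

    def test_negative_count_rejected(self, plain_scene):
        with pytest.raises(InputError):
            add_foci(plain_scene, -1)


class TestNoise:
    def test_noise_matches_requested_snr(self):
        cfg = SceneConfig(snr=5.0)
        s = apply_noise(make_nucleus(cfg, seed=1), seed=2)
        vals = s.image[s.analysis_mask]
        snr = vals.mean() / vals.std()
        assert snr == pytest.approx(5.0, rel=0.1)

    def test_noise_free_config_is_passthrough(self, plain_scene):
        assert apply_noise(plain_scene) is plain_scene

    def test_noise_is_seed_deterministic(self):
        cfg = SceneConfig(snr=5.0)
        a = apply_noise(make_nucleus(cfg, seed=1), seed=7)
        b = apply_noise(make_nucleus(cfg, seed=1), seed=7)
        assert np.array_equal(a.image, b.image)


class TestRenderPCNA:
    def test_g_phase_has_no_foci(self):
        s = render_pcna("G", seed=1)
        assert s.foci_truth == [] and s.phase_truth == "G"

    def test_es_counts_in_configured_range(self):
        lo, hi = PHASE_RENDER_DEFAULTS["ES"]["n"]
        for seed in (1, 2, 3):
            s = render_pcna("ES", seed=seed)
            assert lo <= len(s.foci_truth) <= hi

    def test_ls_foci_are_at_least_twice_es_radius(self):
        es_hi = PHASE_RENDER_DEFAULTS["ES"]["radius_px"][1]
        s = render_pcna("LS", seed=4)
        for f in s.foci_truth:
            assert f.radius_px >= 1.5 * es_hi

    def test_ms_foci_all_in_boundary_regions(self):
        s = render_pcna("MS", seed=5)
        assert all(f.placement == "boundary" for f in s.foci_truth)

    def test_unknown_phase_rejected(self):
        with pytest.raises(InputError):
            render_pcna("S", seed=0)

    def test_render_determinism(self):
        a = render_pcna("ES", seed=11)
        b = render_pcna("ES", seed=11)
        assert np.array_equal(a.image, b.image)
        assert a.foci_truth == b.foci_truth


class TestColonyTable:
    def test_all_g1_colony_without_jitter_is_constant(self):
        t = make_colony_table(3, 5, phase_mix={"G1": 1.0}, gain_jitter=0.0,
                              dapi_cv=0.0, seed=0)
        assert np.allclose(t["integrated_dapi"], 1.0)

    def test_normalized_colony_means_are_one(self):
        t = make_colony_table(6, 12, seed=3)
        norm = normalize_dapi(t)
        means = norm.groupby("colony_id")["i_dapi_normalized"].mean()
        assert np.allclose(means, 1.0, atol=1e-12)

    def test_mean_normalized_dapi_ordered_across_s_phase(self):
        t = normalize_dapi(make_colony_table(20, 50, seed=9))
        means = t.groupby("phase_truth")["i_dapi_normalized"].mean()
        assert means["ES"] < means["MS"] < means["LS"]

    def test_bad_phase_mix_rejected(self):
        with pytest.raises(Exception):
            make_colony_table(2, 5, phase_mix={"G1": 0.5, "XX": 0.5})

    def test_table_determinism(self):
        a = make_colony_table(4, 10, seed=5)
        b = make_colony_table(4, 10, seed=5)
        assert a.equals(b)
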