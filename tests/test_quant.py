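"""Image metrics: CV, focus detection, stack averaging, DAPI and contrasts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucleodyn import (
    add_foci,
    average_stack,
    compare_groups,
    compute_cv,
    detect_foci,
    make_nucleus,
    normalize_dapi,
)
import pandas as pd

from nucleodyn.errors import DegenerateInputError, InputError


def square_region(values):
    """A 2x2 image fully inside the nucleus mask."""
    img = np.asarray(values, dtype=float).reshape(2, 2)
    mask = np.ones((2, 2), dtype=bool)
    return img, mask


class TestCV:
    def test_uniform_image_has_zero_cv(self):
        img, mask = square_region([7, 7, 7, 7])
        assert compute_cv(img, mask) == 0.0

    def test_hand_computed_cv(self):
        img, mask = square_region([1, 1, 3, 3])  # mean 2, population SD 1
        assert compute_cv(img, mask) == pytest.approx(0.5, abs=1e-15)

    def test_bright_nucleolus_excluded(self, plain_scene):
        s = plain_scene
        s.image[s.nucleoli_mask] = 10 * s.config.background
        assert compute_cv(s.image, s.nucleus_mask, s.nucleoli_mask) == 0.0

    def test_empty_region_raises(self):
        img = np.ones((4, 4))
        with pytest.raises(DegenerateInputError):
            compute_cv(img, np.zeros((4, 4), dtype=bool))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(1e-3, 1e4))
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(0)
        img = rng.uniform(1, 5, (32, 32))
        mask = np.ones((32, 32), dtype=bool)
        assert compute_cv(img * c, mask) == pytest.approx(compute_cv(img, mask), abs=1e-12)


class TestDetectFoci:
    def test_uniform_image_yields_no_foci(self, plain_scene):
        report = detect_foci(plain_scene.image, plain_scene.nucleus_mask,
                             plain_scene.nucleoli_mask)
        assert report.n_foci == 0 and report.i_r_foci is None

    def test_resolution_sized_focus_retained(self):
        s = make_nucleus(seed=21)
        add_foci(s, 1, radius_px=(5.0, 5.0), amplitude=(10, 10), seed=1)  # 2x resolution
        report = detect_foci(s.image, s.nucleus_mask, s.nucleoli_mask, resolution_px=2.5)
        assert report.n_foci == 1
        assert report.i_r_foci > 1
        assert report.foci[0].area_px2 >= np.pi * 1.25**2

    def test_subresolution_focus_rejected(self):
        s = make_nucleus(seed=21)
        add_foci(s, 1, radius_px=(0.75, 0.75), amplitude=(10, 10), seed=1)
        report = detect_foci(s.image, s.nucleus_mask, s.nucleoli_mask, resolution_px=2.5)
        assert report.n_foci == 0

    def test_count_monotone_in_resolution(self):
        s = make_nucleus(seed=22)
        add_foci(s, 6, radius_px=(2.0, 4.0), amplitude=(6, 10), seed=2)
        counts = [
            detect_foci(s.image, s.nucleus_mask, s.nucleoli_mask, resolution_px=r).n_foci
            for r in (1.0, 2.5, 4.0, 8.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_detection_scale_invariant(self):
        s = make_nucleus(seed=23)
        add_foci(s, 4, seed=3)
        r1 = detect_foci(s.image, s.nucleus_mask, s.nucleoli_mask)
        r2 = detect_foci(s.image * 37.5, s.nucleus_mask, s.nucleoli_mask)
        assert r1.n_foci == r2.n_foci
        assert r1.i_r_foci == pytest.approx(r2.i_r_foci, abs=1e-12)
        assert r1.cv == pytest.approx(r2.cv, abs=1e-12)

    def test_truth_count_recovered(self):
        s = make_nucleus(seed=24)
        add_foci(s, 9, radius_px=(2.5, 3.5), amplitude=(5, 10), seed=4)
        report = detect_foci(s.image, s.nucleus_mask, s.nucleoli_mask)
        assert report.n_foci == 9
        assert len(report.foci) == 9


class TestNormalizeDapi:
    def test_hand_example(self):
        t = pd.DataFrame({"colony_id": [0, 0, 0], "cell_id": list("abc"),
                          "integrated_dapi": [100.0, 200.0, 300.0]})
        out = normalize_dapi(t)
        assert list(out["i_dapi_normalized"]) == [0.5, 1.0, 1.5]

    def test_single_cell_colony_normalizes_to_one(self):
        t = pd.DataFrame({"colony_id": [0], "cell_id": ["a"], "integrated_dapi": [123.0]})
        assert normalize_dapi(t)["i_dapi_normalized"].iloc[0] == 1.0

    def test_per_colony_gain_invariance(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame({
            "colony_id": np.repeat([0, 1], 10),
            "cell_id": [f"c{i}" for i in range(20)],
            "integrated_dapi": rng.uniform(50, 150, 20),
        })
        base = normalize_dapi(t)["i_dapi_normalized"]
        t2 = t.copy()
        t2.loc[t2.colony_id == 1, "integrated_dapi"] *= 7.3
        scaled = normalize_dapi(t2)["i_dapi_normalized"]
        assert np.allclose(base, scaled, atol=1e-12)

    def test_nonpositive_values_rejected(self):
        t = pd.DataFrame({"colony_id": [0, 0], "cell_id": ["a", "b"],
                          "integrated_dapi": [1.0, 0.0]})
        with pytest.raises(InputError):
            normalize_dapi(t)


class TestAverageStack:
    def test_identical_frames_average_to_themselves(self):
        img = np.arange(12.0).reshape(3, 4)
        assert np.array_equal(average_stack([img] * 5), img)

    def test_two_frame_mean(self):
        a = np.zeros((2, 2))
        b = np.full((2, 2), 2.0)
        assert np.array_equal(average_stack([a, b]), np.ones((2, 2)))

    def test_noise_reduction_scales_with_sqrt_k(self):
        rng = np.random.default_rng(1)
        frames = [rng.poisson(100, (64, 64)).astype(float) for _ in range(25)]
        sd1 = frames[0].std()
        sd25 = average_stack(frames).std()
        assert sd25 == pytest.approx(sd1 / 5, rel=0.2)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InputError):
            average_stack([np.zeros((2, 2)), np.zeros((3, 3))])


class TestCompareGroups:
    def test_identical_groups_are_not_significant(self):
        vals = np.tile(np.arange(20.0), 2)
        labels = ["a"] * 20 + ["b"] * 20
        res = compare_groups(vals, labels, n_permutations=10_000, seed=0)
        assert res["p_value"].iloc[0] >= 0.9

    def test_ten_sigma_shift_is_significant(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 20)
        b = rng.normal(10, 1, 20)
        res = compare_groups(np.concatenate([a, b]), ["a"] * 20 + ["b"] * 20,
                             n_permutations=10_000, seed=0)
        assert res["p_value"].iloc[0] <= 0.001

    def test_null_p_values_are_roughly_uniform(self):
        rng = np.random.default_rng(3)
        ps = []
        for rep in range(100):
            vals = rng.normal(0, 1, 24)
            res = compare_groups(vals, ["a"] * 12 + ["b"] * 12,
                                 n_permutations=200, seed=rep)
            ps.append(res["p_value"].iloc[0])
        ps = np.asarray(ps)
        assert 0.25 < (ps < 0.5).mean() < 0.75  # median near 0.5
        assert (ps < 0.05).mean() < 0.15

    def test_adjacent_contrast_structure(self):
        vals = np.concatenate([np.zeros(5), np.ones(5), np.full(5, 2.0)])
        labels = ["G"] * 5 + ["ES"] * 5 + ["MS"] * 5
        res = compare_groups(vals, labels, order=["G", "ES", "MS"],
                             n_permutations=100, seed=0)
        assert list(res["contrast"]) == ["ES vs G", "MS vs ES"]

    def test_small_groups_rejected(self):
        with pytest.raises(InputError):
            compare_groups([1.0, 2.0, 3.0, 4.0], ["a", "a", "b", "b"])
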