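"""Scene generator: ground-truth exactness, determinism, class rules."""

import json

import numpy as np
import pytest

from stumprot.segquality import BoundingBox
from stumprot.simdata import (
    RotClass,
    SceneParams,
    class_from_ratio,
    default_class_mix,
    generate_dataset,
    generate_scenes,
    load_dataset,
    rbr_ratio,
    render_scene,
)


class TestClassFromRatio:
    @pytest.mark.parametrize(
        "r, expected",
        [
            (0.0, RotClass.NO_ROT),
            (1e-6, RotClass.ROT_LT_50),
            (0.49, RotClass.ROT_LT_50),
            (0.50, RotClass.ROT_GE_50),
            (1.0, RotClass.ROT_GE_50),
        ],
    )
    def test_boundaries(self, r, expected):
        assert class_from_ratio(r) is expected

    @pytest.mark.parametrize("r", [-0.1, 1.1])
    def test_out_of_range(self, r):
        with pytest.raises(ValueError):
            class_from_ratio(r)

    def test_severity_ordering(self):
        assert RotClass.NO_ROT < RotClass.ROT_LT_50 < RotClass.ROT_GE_50


class TestRbrRatio:
    def test_full_rot(self):
        m = np.ones((10, 20), dtype=bool)
        assert rbr_ratio(m, m) == 1.0

    def test_pixel_count_ratio(self):
        stump = np.zeros((20, 20), dtype=bool)
        stump[:10, :20] = True  # 200 pixels
        rot = np.zeros_like(stump)
        rot[:5, :10] = True  # 50 pixels
        assert rbr_ratio(rot, stump) == 0.25

    def test_empty_rot(self):
        stump = np.ones((5, 5), dtype=bool)
        assert rbr_ratio(np.zeros_like(stump), stump) == 0.0

    def test_empty_stump_rejected(self):
        with pytest.raises(ValueError):
            rbr_ratio(np.zeros((3, 3), bool), np.zeros((3, 3), bool))

    def test_rot_outside_stump_rejected(self):
        stump = np.zeros((4, 4), bool)
        stump[0, 0] = True
        rot = np.zeros((4, 4), bool)
        rot[3, 3] = True
        with pytest.raises(ValueError):
            rbr_ratio(rot, stump)


class TestRenderScene:
    def test_zero_target_gives_no_rot(self, small_scene_params):
        from dataclasses import replace
        scene = render_scene(replace(small_scene_params, target_rbr_ratio=0.0, seed=3))
        assert scene.rot_mask.sum() == 0
        assert scene.rot_class is RotClass.NO_ROT

    def test_high_target_hits_band_and_class(self):
        scene = render_scene(SceneParams(target_rbr_ratio=0.7, seed=1))
        assert 0.68 <= scene.rbr_ratio <= 0.72
        assert scene.rot_class is RotClass.ROT_GE_50

    def test_bit_identical_under_same_seed(self, small_scene_params):
        from dataclasses import replace
        p = replace(small_scene_params, target_rbr_ratio=0.3, seed=99)
        a, b = render_scene(p), render_scene(p)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.rot_mask, b.rot_mask)

    @pytest.mark.parametrize("target", [round(0.1 * i, 1) for i in range(10)])
    def test_target_band_across_range(self, target, small_scene_params):
        from dataclasses import replace
        scene = render_scene(replace(small_scene_params,
                                     target_rbr_ratio=target, seed=7))
        assert abs(scene.rbr_ratio - target) <= 0.02

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SceneParams(target_rbr_ratio=1.5)
        with pytest.raises(ValueError):
            SceneParams(occlusion_fraction=0.9)
        with pytest.raises(ValueError):
            SceneParams(stump_radius_range=(0.4, 0.1))

    def test_multi_stump_scene(self, small_scene_params):
        from dataclasses import replace
        scene = render_scene(replace(small_scene_params, n_stumps=2,
                                     stump_radius_range=(0.1, 0.18), seed=5))
        assert len(scene.annotations) == 2
        a, b = scene.annotations
        assert not np.any(a.stump_mask & b.stump_mask)


class TestSceneInvariants:
    """Structural ground-truth invariants over a batch of random scenes."""

    def test_invariants_over_batch(self, scene_batch):
        assert len(scene_batch) >= 100
        for scene in scene_batch:
            for ann in scene.annotations:
                # rot is a subset of stump
                assert not np.any(ann.rot_mask & ~ann.stump_mask)
                # bbox is the tight bounding rectangle
                assert ann.bbox == BoundingBox.from_mask(ann.stump_mask)
                # stored ratio is the exact pixel-count ratio
                assert ann.rbr_ratio == rbr_ratio(ann.rot_mask, ann.stump_mask)
                # stored class follows from the ratio
                assert class_from_ratio(ann.rbr_ratio) is ann.rot_class

    def test_class_counts_exact(self, scene_batch):
        counts = [sum(1 for s in scene_batch if s.rot_class is c) for c in RotClass]
        assert counts == [60, 24, 36]


class TestDatasetGeneration:
    def test_default_mix_proportions(self):
        assert default_class_mix(1000) == (502, 197, 301)
        mix = default_class_mix(100)
        assert sum(mix) == 100
        assert mix == (50, 20, 30)

    def test_roundtrip_and_determinism(self, tmp_path, small_scene_params):
        idx1 = generate_dataset((3, 2, 2), tmp_path / "a", small_scene_params, seed=7)
        idx2 = generate_dataset((3, 2, 2), tmp_path / "b", small_scene_params, seed=7)
        assert idx1.read_bytes() == idx2.read_bytes()
        scenes = load_dataset(idx1)
        assert len(scenes) == 7
        classes = [s.rot_class for s in scenes]
        assert classes.count(RotClass.NO_ROT) == 3
        assert classes.count(RotClass.ROT_LT_50) == 2
        assert classes.count(RotClass.ROT_GE_50) == 2
        # masks and ratios survive the PNG roundtrip exactly
        for s in scenes:
            assert s.rbr_ratio == pytest.approx(
                rbr_ratio(s.rot_mask, s.stump_mask), abs=1e-6)
        index = json.loads(idx1.read_text())
        assert {im["file_name"] for im in index["images"]} == {
            f"images/scene_{i:05d}.png" for i in range(7)}
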