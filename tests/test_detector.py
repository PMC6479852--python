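"""Detector units: frame resize, NMS, config validation, persistence."""

import numpy as np
import pytest

from stumprot.detector import (
    Detection,
    DetectorConfig,
    DetectorModel,
    FULL_SCALE_SCHEDULE,
    detect,
    load_model,
    nms,
    resize_for_detection,
    save_model,
    train_detector,
)
from stumprot.segquality import BoundingBox
from stumprot.simdata import SceneParams, generate_scenes


class TestResize:
    def test_full_resolution_frame(self):
        img = np.zeros((3456, 5184, 3), dtype=np.uint8)
        out, (sx, sy) = resize_for_detection(img)
        assert out.shape == (300, 400, 3)
        assert (sx, sy) == (5184 / 400, 3456 / 300) == (12.96, 11.52)

    def test_native_frame_unchanged(self):
        img = np.arange(300 * 400 * 3, dtype=np.uint8).reshape(300, 400, 3)
        out, scales = resize_for_detection(img)
        assert out is img and scales == (1.0, 1.0)

    def test_box_maps_back_to_full_frame(self):
        box = BoundingBox(0, 0, 400, 300)
        mapped = box.scaled(12.96, 11.52)
        assert (mapped.x_max, mapped.y_max) == (5184, 3456)

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            resize_for_detection(np.empty((0, 0, 3)))


class TestConfig:
    def test_thresholds_validated(self):
        with pytest.raises(ValueError):
            DetectorConfig(score_threshold=1.5)
        with pytest.raises(ValueError):
            DetectorConfig(patch_size=400)

    def test_full_scale_profile_schedule(self):
        cfg = DetectorConfig.full_scale()
        assert cfg.mini_batch == 1
        assert cfg.solver == "sgdm"
        assert cfg.train_schedule == FULL_SCALE_SCHEDULE
        assert [e for _lr, e in cfg.train_schedule] == [20, 20, 20, 10]
        assert [lr for lr, _e in cfg.train_schedule] == [1e-5, 1e-5, 1e-6, 1e-6]


class TestNMS:
    def test_disjoint_boxes_all_kept(self):
        dets = [Detection(BoundingBox(0, 0, 20, 20), 0.9),
                Detection(BoundingBox(100, 100, 130, 130), 0.8)]
        assert nms(dets, 0.3) == dets

    def test_duplicate_suppressed(self):
        dets = [Detection(BoundingBox(0, 0, 20, 20), 0.9),
                Detection(BoundingBox(1, 1, 21, 21), 0.8)]
        assert nms(dets, 0.3) == dets[:1]

    def test_idempotent(self, rng):
        dets = sorted(
            (Detection(BoundingBox(int(x), int(y), int(x) + 15, int(y) + 15),
                       float(s))
             for (x, y), s in zip(rng.integers(0, 60, size=(20, 2)),
                                  rng.random(20))),
            key=lambda d: -d.score)
        once = nms(dets, 0.3)
        assert nms(once, 0.3) == once


@pytest.fixture(scope="module")
def tiny_model():
    """A quickly trained detector on small frames for contract tests."""
    params = SceneParams(image_height=120, image_width=160,
                         stump_radius_range=(0.18, 0.38))
    scenes = generate_scenes((4, 2, 2), params, seed=31)
    config = DetectorConfig(input_size=(120, 160), proposal_min_size=24,
                            proposal_max_size=100, min_detection_size=18,
                            train_schedule=((0.03, 6), (0.006, 3)),
                            pos_per_scene=6, neg_per_scene=10,
                            hard_negative_rounds=0)
    return train_detector(scenes, config, seed=5), params


class TestDetectContract:
    def test_untrained_model_rejected(self):
        with pytest.raises(RuntimeError):
            detect(DetectorModel(DetectorConfig()), np.zeros((50, 50, 3), np.uint8))

    def test_output_sorted_and_in_bounds(self, tiny_model):
        model, params = tiny_model
        scene = generate_scenes((1, 0, 0), params, seed=77)[0]
        dets = detect(model, scene.image)
        th, tw = model.config.input_size
        scores = [d.score for d in dets]
        assert scores == sorted(scores, reverse=True)
        for d in dets:
            assert 0 <= d.bbox.x_min < d.bbox.x_max <= tw
            assert 0 <= d.bbox.y_min < d.bbox.y_max <= th
            assert model.config.score_threshold <= d.score <= 1.0

    def test_detection_deterministic(self, tiny_model):
        model, params = tiny_model
        scene = generate_scenes((0, 1, 0), params, seed=78)[0]
        assert detect(model, scene.image) == detect(model, scene.image)

    def test_save_load_roundtrip(self, tiny_model, tmp_path):
        model, params = tiny_model
        save_model(model, tmp_path / "det.npz")
        back = load_model(tmp_path / "det.npz")
        assert back.config == model.config
        scene = generate_scenes((1, 0, 0), params, seed=79)[0]
        assert detect(back, scene.image) == detect(model, scene.image)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_detector([], DetectorConfig())

    def test_save_untrained_rejected(self, tmp_path):
        with pytest.raises(RuntimeError):
            save_model(DetectorModel(DetectorConfig()), tmp_path / "x.npz")

    def test_training_deterministic_under_seed(self):
        params = SceneParams(image_height=96, image_width=128,
                             stump_radius_range=(0.2, 0.4))
        scenes = generate_scenes((2, 1, 1), params, seed=55)
        cfg = DetectorConfig(input_size=(96, 128), proposal_min_size=20,
                             proposal_max_size=90, min_detection_size=15,
                             train_schedule=((0.03, 3),),
                             hard_negative_rounds=0)
        m1 = train_detector(scenes, cfg, seed=9)
        m2 = train_detector(scenes, cfg, seed=9)
        for k, v in m1.net.state_arrays().items():
            assert np.array_equal(v, m2.net.state_arrays()[k])
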