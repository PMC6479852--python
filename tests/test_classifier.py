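"""Class balancing and the three classification routes on tiny tasks."""

import numpy as np
import pytest

from stumprot import classifier as clf
from stumprot.classifier import (
    ClassifierSpec,
    LabeledCrop,
    balance_classes,
    binary_label,
)
from stumprot.features import pretrain_desk_backbone
from stumprot.simdata import RotClass, SceneParams, generate_scenes


def _crops_from_scenes(scenes):
    out = []
    for i, s in enumerate(scenes):
        b = s.bbox
        out.append(LabeledCrop(image=s.image[b.y_min:b.y_max, b.x_min:b.x_max],
                               rot_class=s.rot_class, source_id=i))
    return out


@pytest.fixture(scope="module")
def crop_pool():
    params = SceneParams(image_height=128, image_width=128,
                         stump_radius_range=(0.2, 0.42))
    return _crops_from_scenes(generate_scenes((12, 12, 12), params, seed=77))


@pytest.fixture(scope="module")
def shared_backbone():
    return pretrain_desk_backbone(seed=3, n_scenes=24, epochs=3)


class TestBalanceClasses:
    def test_exact_counts(self, crop_pool):
        out = balance_classes(crop_pool, per_class=5, seed=0)
        assert len(out) == 15
        for cls in RotClass:
            assert sum(1 for c in out if c.rot_class is cls) == 5

    def test_balanced_input_at_minimum_is_identity_up_to_order(self, crop_pool):
        out = balance_classes(crop_pool, per_class=12, seed=0)
        assert sorted(c.source_id for c in out) == \
            sorted(c.source_id for c in crop_pool)

    def test_seed_determinism(self, crop_pool):
        a = balance_classes(crop_pool, per_class=4, seed=9)
        b = balance_classes(crop_pool, per_class=4, seed=9)
        assert [c.source_id for c in a] == [c.source_id for c in b]

    def test_no_replacement(self, crop_pool):
        out = balance_classes(crop_pool, per_class=10, seed=1)
        ids = [c.source_id for c in out]
        assert len(ids) == len(set(ids))

    def test_small_class_rejected(self, crop_pool):
        with pytest.raises(ValueError):
            balance_classes(crop_pool, per_class=13)

    def test_reference_protocol_counts(self):
        """Balancing (400, 160, 240) at 160 leaves 160 per class, 480 total."""
        rng = np.random.default_rng(0)
        pool = []
        tiny = rng.integers(0, 255, size=(4, 4, 3)).astype(np.uint8)
        for cls, n in zip(RotClass, (400, 160, 240)):
            pool += [LabeledCrop(image=tiny, rot_class=cls, source_id=i)
                     for i in range(n)]
        out = balance_classes(pool, per_class=160, seed=0)
        assert len(out) == 480


class TestSpecValidation:
    def test_bad_approach_rejected(self):
        with pytest.raises(ValueError):
            ClassifierSpec(approach="XX")

    def test_bad_n_classes_rejected(self):
        with pytest.raises(ValueError):
            ClassifierSpec(n_classes=4)

    def test_binary_label_collapse(self):
        assert binary_label(RotClass.NO_ROT) == "NO_ROT"
        assert binary_label(RotClass.ROT_LT_50) == "ROT"
        assert binary_label(RotClass.ROT_GE_50) == "ROT"

    def test_full_scale_finetune_profile(self):
        ft = clf.FinetuneSpec.full_scale()
        assert (ft.batch_size, ft.initial_lr, ft.max_epochs) == (16, 1e-4, 300)


class TestRoutes:
    def test_vf_head_width_matches_n_classes(self, crop_pool, shared_backbone):
        spec = ClassifierSpec(approach="VF", n_classes=3,
                              finetune=clf.FinetuneSpec(max_epochs=2))
        model = clf.train(spec, crop_pool, seed=0, backbone=shared_backbone)
        assert model.net.layers[-1].w.shape[1] == 3
        spec2 = ClassifierSpec(approach="VF", n_classes=2,
                               finetune=clf.FinetuneSpec(max_epochs=2))
        model2 = clf.train(spec2, crop_pool, seed=0, backbone=shared_backbone)
        assert model2.net.layers[-1].w.shape[1] == 2
        assert model2.class_order == ("NO_ROT", "ROT")

    def test_bs_feature_length_is_k(self, crop_pool):
        spec = ClassifierSpec(approach="BS", bof_k=20)
        model = clf.train(spec, crop_pool, seed=0)
        assert model.vocab.k == 20
        assert model.svm.coef_.shape[1] == 20

    def test_vs_predicts_consistently(self, crop_pool, shared_backbone):
        spec = ClassifierSpec(approach="VS", n_classes=2)
        model = clf.train(spec, crop_pool, seed=0, backbone=shared_backbone)
        crop = crop_pool[0].image
        assert clf.predict(model, crop) == clf.predict(model, crop)
        assert clf.predict(model, crop) in model.class_order

    def test_vf_fits_its_training_set(self, crop_pool, shared_backbone):
        """Fine-tuning on an easily separated set reaches high train accuracy."""
        spec = ClassifierSpec(approach="VF", n_classes=2,
                              finetune=clf.FinetuneSpec(max_epochs=12))
        model = clf.train(spec, crop_pool, seed=0, backbone=shared_backbone)
        preds = clf.predict_batch(model, [c.image for c in crop_pool])
        truth = [binary_label(c.rot_class) for c in crop_pool]
        acc = np.mean([p == t for p, t in zip(preds, truth)])
        assert acc >= 0.9

    def test_three_class_training_needs_all_grades(self, crop_pool):
        only_two = [c for c in crop_pool if c.rot_class is not RotClass.ROT_GE_50]
        with pytest.raises(ValueError):
            clf.train(ClassifierSpec(approach="BS", n_classes=3), only_two)

    def test_save_load_roundtrip(self, tmp_path, crop_pool, shared_backbone):
        spec = ClassifierSpec(approach="VS", n_classes=3)
        model = clf.train(spec, crop_pool, seed=0, backbone=shared_backbone)
        clf.save_classifier(model, tmp_path / "m.pkl")
        back = clf.load_classifier(tmp_path / "m.pkl")
        crops = [c.image for c in crop_pool[:6]]
        assert clf.predict_batch(back, crops) == clf.predict_batch(model, crops)
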