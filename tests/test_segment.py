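import numpy as np
import pytest

import retoct.segment.augmentation as augmentation
from retoct import phantom, surfaces
from retoct.config import PhantomConfig, SegModelConfig
from retoct.segment import train as seg
from retoct.types import LabelVolume


def _make_volume(seed, curv=25.0, noise=float("inf"), n_bscans=16,
                 vessels=0, meta_day=0):
    cfg = PhantomConfig(
        volume_shape=(n_bscans, 48, 128), fov_mm=(n_bscans * 0.01, 0.48, 0.64),
        ilm_offset_um=60.0, onh_radius_um=0.0, speckle_shape=noise,
        vessel_density=vessels,
        curvature_coeffs=((0.0, 0.0, curv), (0.0,), (curv,)),
    )
    geom = phantom.make_geometry(cfg)
    volume, labels = phantom.render_volume(geom, cfg, np.random.default_rng(seed))
    volume.meta = {"subject": seed, "eye": "control", "day": meta_day}
    return volume, labels


SESSION_CFG = SegModelConfig(
    epochs_frozen=15, epochs_finetune=40, epochs_pseudo=6,
    lr_finetune=0.015, batch_size=4, augment=False, seed=0,
)


@pytest.fixture(scope="session")
def training_data():
    return {
        "train": _make_volume(1),
        "val": _make_volume(2, curv=15.0),
        "test": _make_volume(3, curv=35.0),
        "unlabeled": [_make_volume(10 + i, curv=10.0 + 6 * i, n_bscans=8)[0]
                      for i in range(5)],
    }


@pytest.fixture(scope="session")
def frozen_model(training_data):
    model = seg.init_model(SESSION_CFG, (128, 48))
    snapshot = {k: v.copy() for k, v in model.params.items()}
    trained = seg.train_frozen_stage(
        model, [training_data["train"]], [training_data["val"]])
    return model, snapshot, trained


@pytest.fixture(scope="session")
def finetuned_model(frozen_model, training_data):
    _, _, frozen = frozen_model
    return seg.train_finetune_stage(
        frozen, [training_data["train"]], [training_data["val"]])


@pytest.fixture(scope="session")
def pseudo_round(finetuned_model, training_data):
    expanded, model = seg.pseudo_label_round(
        finetuned_model,
        training_data["unlabeled"],
        [training_data["train"], training_data["val"]],
        labeled_val=[training_data["val"]],
    )
    return expanded, model


class TestAugmentation:
    def test_identity_params_reproduce_input(self, rng):
        img = rng.uniform(0, 1, size=(64, 48)).astype(np.float32)
        lab = rng.integers(0, 12, size=(64, 48)).astype(np.int16)
        ident = augmentation.AffineParams(0.0, 0.0, 0.0, 0.0, False)
        out_img, out_lab = augmentation.apply_affine(img, lab, ident)
        assert np.array_equal(out_img, img)
        assert np.array_equal(out_lab, lab)

    def test_draw_ranges(self, rng):
        draws = [augmentation.draw_params(rng) for _ in range(2000)]
        tz = np.array([d.translate_z for d in draws])
        tx = np.array([d.translate_x for d in draws])
        ang = np.array([d.angle_deg for d in draws])
        crop = np.array([d.crop_frac for d in draws])
        assert np.abs(tz).max() <= 20.0 and np.abs(tx).max() <= 20.0
        assert np.abs(ang).max() <= 30.0
        assert crop.min() >= 0.0 and crop.max() <= 0.25
        # ranges are actually exercised
        assert np.abs(tz).max() > 18.0 and np.abs(ang).max() > 27.0

    def test_lateral_flip_frequency(self):
        rng = np.random.default_rng(99)
        flips = [augmentation.draw_params(rng).flip_lateral for _ in range(10_000)]
        assert np.mean(flips) == pytest.approx(0.5, abs=0.02)

    def test_labels_stay_integral_and_in_range(self, rng):
        img = rng.uniform(0, 1, size=(64, 48)).astype(np.float32)
        lab = rng.integers(0, 12, size=(64, 48)).astype(np.int16)
        out_img, out_lab = augmentation.augment(img, lab, rng)
        assert np.issubdtype(out_lab.dtype, np.integer)
        assert set(np.unique(out_lab)) <= set(range(12))

    def test_flip_is_lateral_only(self):
        img = np.arange(12.0, dtype=np.float32).reshape(4, 3)
        params = augmentation.AffineParams(0.0, 0.0, 0.0, 0.0, True)
        out, _ = augmentation.apply_affine(img, None, params)
        assert np.array_equal(out, img[:, ::-1])


class TestFrozenStage:
    def test_non_head_tensors_bit_identical(self, frozen_model):
        _, snapshot, trained = frozen_model
        for name, value in trained.params.items():
            if name in trained.head_names:
                continue
            assert np.array_equal(value, snapshot[name]), name

    def test_head_changed(self, frozen_model):
        _, snapshot, trained = frozen_model
        assert any(not np.array_equal(trained.params[n], snapshot[n])
                   for n in trained.head_names)

    def test_val_loss_not_worse_than_init(self, frozen_model):
        _, _, trained = frozen_model
        hist = [h for h in trained.history if h["stage"] == "frozen"]
        init_loss = hist[0]["val_loss"]
        best = min(h["val_loss"] for h in hist)
        assert best <= init_loss

    def test_beats_shuffled_baseline(self, frozen_model, training_data):
        _, _, trained = frozen_model
        test_vol, test_lab = training_data["test"]
        pred = seg.predict_volume(trained, test_vol)
        score = seg.mean_retinal_dice(pred, test_lab)
        shuffled = test_lab.copy()
        flat = shuffled.classes.reshape(-1).copy()
        np.random.default_rng(0).shuffle(flat)
        shuffled.classes = flat.reshape(shuffled.classes.shape)
        baseline = seg.mean_retinal_dice(shuffled, test_lab)
        assert score > baseline

    def test_shared_volume_rejected(self, training_data):
        model = seg.init_model(SESSION_CFG, (128, 48))
        pair = training_data["train"]
        with pytest.raises(ValueError, match="share"):
            seg.train_frozen_stage(model, [pair], [pair])


class TestFinetuneStage:
    def test_previously_frozen_tensor_changes(self, frozen_model, finetuned_model):
        _, _, frozen = frozen_model
        changed = any(
            not np.array_equal(finetuned_model.params[n], frozen.params[n])
            for n in finetuned_model.all_names - finetuned_model.head_names
        )
        assert changed

    def test_dice_not_worse_than_frozen(self, frozen_model, finetuned_model,
                                        training_data):
        _, _, frozen = frozen_model
        test_vol, test_lab = training_data["test"]
        d_frozen = seg.mean_retinal_dice(seg.predict_volume(frozen, test_vol), test_lab)
        d_ft = seg.mean_retinal_dice(
            seg.predict_volume(finetuned_model, test_vol), test_lab)
        assert d_ft >= d_frozen - 0.005

    def test_augmentation_active_during_finetune(self, training_data):
        base = SESSION_CFG.model_copy(update={"epochs_finetune": 2})
        losses = {}
        for flag in (False, True):
            cfg = base.model_copy(update={"augment": flag})
            model = seg.init_model(cfg, (128, 48))
            trained = seg.train_finetune_stage(
                model, [training_data["train"]], [training_data["val"]], config=cfg)
            losses[flag] = [h["train_loss"] for h in trained.history
                            if h["stage"] == "finetune" and h["epoch"] >= 0]
        # augmentation perturbs the training batches, so the trajectories differ
        assert losses[True] != losses[False]

    def test_deterministic_under_fixed_seed(self, training_data):
        cfg = SESSION_CFG.model_copy(update={"epochs_finetune": 2})
        runs = []
        for _ in range(2):
            model = seg.init_model(cfg, (128, 48))
            trained = seg.train_finetune_stage(
                model, [training_data["train"]], [training_data["val"]], config=cfg)
            runs.append([h["val_loss"] for h in trained.history])
        assert runs[0] == runs[1]


class TestPseudoLabelRound:
    def test_expanded_set_has_seven_volumes(self, pseudo_round):
        expanded, _ = pseudo_round
        assert len(expanded) == 7

    def test_dice_not_worse_than_before(self, finetuned_model, pseudo_round,
                                        training_data):
        _, model = pseudo_round
        test_vol, test_lab = training_data["test"]
        before = seg.mean_retinal_dice(
            seg.predict_volume(finetuned_model, test_vol), test_lab)
        after = seg.mean_retinal_dice(seg.predict_volume(model, test_vol), test_lab)
        assert after >= before - 0.005

    def test_pseudo_labels_pass_ordering_after_enforcement(self, pseudo_round):
        expanded, _ = pseudo_round
        _, pseudo_labels = expanded[-1]  # a pseudo-labeled volume
        stack = surfaces.labels_to_surfaces(pseudo_labels, strict=False)
        assert (np.diff(stack.heights, axis=0) >= -1e-9).all()

    def test_empty_unlabeled_set_is_noop_with_warning(self, finetuned_model,
                                                      training_data):
        labeled = [training_data["train"]]
        with pytest.warns(UserWarning):
            expanded, model = seg.pseudo_label_round(finetuned_model, [], labeled)
        assert expanded == labeled
        assert model is finetuned_model


class TestPredictVolume:
    def test_prediction_deterministic(self, finetuned_model, training_data):
        vol, _ = training_data["test"]
        a = seg.predict_volume(finetuned_model, vol)
        b = seg.predict_volume(finetuned_model, vol)
        assert np.array_equal(a.classes, b.classes)

    def test_shape_mismatch_rejected(self, finetuned_model):
        bad, _ = _make_volume(77, n_bscans=4)
        bad.intensity = bad.intensity[:, :32, :]
        with pytest.raises(ValueError, match="geometry"):
            seg.predict_volume(finetuned_model, bad)

    def test_vessel_shadow_volume_ordered_after_enforcement(self, pseudo_round):
        _, model = pseudo_round
        vol, _ = _make_volume(55, vessels=4, n_bscans=8)
        pred = seg.predict_volume(model, vol)
        stack = surfaces.labels_to_surfaces(pred, strict=False)
        # outer-boundary ordering violations after enforcement: none
        assert (np.diff(stack.heights[6:], axis=0) >= -1e-9).all()


class TestTransferProtocol:
    def test_frozen_stage_from_source_pretrained_checkpoint(self, training_data):
        """Source-domain pretraining stands in for the external pretrained
        model; the frozen head-only stage then adapts it to the target domain
        while every feature tensor stays bit-identical."""
        src_cfg = PhantomConfig(
            volume_shape=(12, 48, 128), fov_mm=(0.12, 0.48, 0.64),
            ilm_offset_um=60.0, onh_radius_um=0.0, speckle_shape=float("inf"),
            vessel_density=0, curvature_coeffs=((0.0, 0.0, 20.0), (0.0,), (20.0,)),
            layer_reflectivity=(6., 80., 55., 60., 30., 70., 20., 90., 45.,
                                100., 75., 40.),
            layer_thicknesses_um=(22., 10., 40., 28., 10., 70., 8., 24., 16., 8.),
        )
        geom = phantom.make_geometry(src_cfg)
        src_vol, src_lab = phantom.render_volume(
            geom, src_cfg, np.random.default_rng(40))
        src_vol.meta = {"subject": 40, "eye": "control", "day": 0}
        src2_vol, src2_lab = phantom.render_volume(
            geom, src_cfg, np.random.default_rng(41))
        src2_vol.meta = {"subject": 41, "eye": "control", "day": 0}

        cfg = SESSION_CFG.model_copy(update={"epochs_finetune": 15})
        model = seg.init_model(cfg, (128, 48))
        pretrained = seg.train_finetune_stage(
            model, [(src_vol, src_lab)], [(src2_vol, src2_lab)], config=cfg)

        snapshot = {k: v.copy() for k, v in pretrained.params.items()}
        adapted = seg.train_frozen_stage(
            pretrained, [training_data["train"]], [training_data["val"]])
        for name in adapted.all_names - adapted.head_names:
            assert np.array_equal(adapted.params[name], snapshot[name])
        # the adapted head does better than chance on the target domain
        test_vol, test_lab = training_data["test"]
        pred = seg.predict_volume(adapted, test_vol)
        score = seg.mean_retinal_dice(pred, test_lab)
        shuffled = test_lab.copy()
        flat = shuffled.classes.reshape(-1).copy()
        np.random.default_rng(0).shuffle(flat)
        shuffled.classes = flat.reshape(shuffled.classes.shape)
        assert score > seg.mean_retinal_dice(shuffled, test_lab)


class TestDice:
    def _lab(self, arr):
        return LabelVolume(classes=np.asarray(arr, dtype=np.int16).reshape(1, 1, -1),
                           spacing_um=(1, 1, 1))

    def test_identical_gives_ones(self):
        a = self._lab([0, 1, 2, 3])
        scores = seg.dice(a, a, classes=(0, 1, 2, 3))
        assert all(v == 1.0 for v in scores.values())

    def test_disjoint_gives_zero(self):
        scores = seg.dice(self._lab([1, 1, 0, 0]), self._lab([0, 0, 1, 1]),
                          classes=(1,))
        assert scores[1] == 0.0

    def test_half_overlap_gives_half(self):
        scores = seg.dice(self._lab([1, 1, 0, 0]), self._lab([0, 1, 1, 0]),
                          classes=(1,))
        assert scores[1] == 0.5

    def test_empty_vs_empty_is_one(self):
        scores = seg.dice(self._lab([0, 0]), self._lab([0, 0]), classes=(5,))
        assert scores[5] == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            seg.dice(self._lab([0, 1]), self._lab([0, 1, 2]))


class TestModelInit:
    def test_shape_must_be_divisible_by_four(self):
        with pytest.raises(ValueError):
            seg.init_model(SESSION_CFG, (126, 48))

    def test_cascade_adds_second_stage(self):
        cfg = SESSION_CFG.model_copy(update={"cascade": True})
        model = seg.init_model(cfg, (64, 48))
        assert any(k.startswith("c2.") for k in model.params)
        assert model.head_names == {"c2.head.W", "c2.head.b"}

    def test_cascade_forward_and_gradients(self):
        cfg = SESSION_CFG.model_copy(update={"cascade": True})
        vol, lab = _make_volume(8, n_bscans=4)
        model = seg.init_model(cfg, (128, 48))
        feats = seg.bscan_features(vol)
        labs = lab.classes.transpose(0, 2, 1).astype(np.int64)
        loss, grads = seg._loss_and_grads(model, feats, labs)
        assert np.isfinite(loss)
        # both stages receive non-zero gradients
        assert np.abs(grads["enc1a.W"]).max() > 0
        assert np.abs(grads["c2.enc1a.W"]).max() > 0
        assert set(grads) == set(model.params)
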