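"""Training orchestration: LR schedule, preprocessing, cropping, short seeded
training runs, freezing and checkpoint round-trips."""

import numpy as np
import pytest
from dataclasses import replace

from dtseg.networks import NetworkSpec
from dtseg.nn import Tensor
from dtseg.synthetic import PhantomSpec, make_dataset
from dtseg.training import (
    Checkpoint,
    TrainSpec,
    evaluate_pipeline,
    lr_schedule,
    prepare_cases,
    preprocess,
    random_crop,
    train_stage1,
    train_stage2,
)
from dtseg.volumes import IntensityVolume

TINY_NET = NetworkSpec(channel_widths=(2, 4, 8), norm_groups=2)
TINY_TRAIN = TrainSpec(crop_size=(12, 12, 8), lr0=2e-3, max_epochs=3)
TINY_PHANTOM = PhantomSpec(shape=(16, 16, 12), edge_blur_sigma=1.0, noise_sd=0.2)


@pytest.fixture(scope="module")
def tiny_cases():
    return prepare_cases(make_dataset(3, TINY_PHANTOM, seed=5), "A")


class TestLrSchedule:
    def test_polynomial_closed_form_over_whole_schedule(self):
        spec = TrainSpec(lr0=1e-4, max_epochs=110)
        for e in range(111):
            assert lr_schedule(e, spec) == pytest.approx(
                1e-4 * (1 - e / 110) ** 0.9, rel=1e-15
            )
        assert lr_schedule(0, spec) == 1e-4
        assert lr_schedule(110, spec) == 0.0
        assert lr_schedule(55, spec) == pytest.approx(1e-4 * 0.5**0.9)

    def test_strictly_decreasing(self):
        spec = TrainSpec(lr0=1e-4, max_epochs=110)
        values = [lr_schedule(e, spec) for e in range(111)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_out_of_range_epoch_raises(self):
        with pytest.raises(ValueError):
            lr_schedule(111, TrainSpec(max_epochs=110))


class TestPreprocess:
    def test_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        vol = IntensityVolume(rng.normal(3.0, 2.0, (8, 8, 8)))
        out = preprocess(vol).data
        assert out.mean() == pytest.approx(0.0, abs=1e-6)
        assert out.std() == pytest.approx(1.0, abs=1e-6)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(6, 6, 6))
        a = preprocess(IntensityVolume(x)).data
        b = preprocess(IntensityVolume(2.5 * x + 7.0)).data
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_constant_volume_warns_and_zeroes(self):
        with pytest.warns(UserWarning):
            out = preprocess(IntensityVolume(np.full((4, 4, 4), 3.0)))
        assert (out.data == 0).all()


class TestRandomCrop:
    def test_identity_when_crop_equals_volume(self):
        rng = np.random.default_rng(0)
        img = rng.random((8, 8, 8))
        lbl = (img > 0.5).astype(np.uint8)
        ci, cl, cd = random_crop(img, lbl, img, (8, 8, 8), rng)
        np.testing.assert_array_equal(ci, img)
        np.testing.assert_array_equal(cl, lbl)

    def test_same_rng_state_same_crop(self):
        img = np.random.default_rng(3).random((12, 12, 12))
        a = random_crop(img, img, None, (6, 6, 6), np.random.default_rng(9))
        b = random_crop(img, img, None, (6, 6, 6), np.random.default_rng(9))
        np.testing.assert_array_equal(a[0], b[0])

    def test_identical_windows_via_coordinate_grid(self):
        # crop a coordinate grid: all three outputs must show the same window
        grid = np.arange(10 * 10 * 10, dtype=float).reshape(10, 10, 10)
        ci, cl, cd = random_crop(grid, grid, grid, (4, 4, 4), np.random.default_rng(2))
        np.testing.assert_array_equal(ci, cl)
        np.testing.assert_array_equal(ci, cd)

    def test_pads_small_volumes_with_background(self):
        img = np.ones((4, 4, 4))
        ci, cl, _ = random_crop(img, img, None, (8, 8, 8), np.random.default_rng(0))
        assert ci.shape == (8, 8, 8)
        assert ci.sum() == 64  # original content preserved, zero padding


class TestStageOne:
    def test_loss_decreases_over_training(self, tiny_cases):
        spec1 = replace(TINY_NET, in_channels=1, with_distance_decoder=True)
        tspec = replace(TINY_TRAIN, max_epochs=5, seed=0)
        ckpt = train_stage1(tiny_cases, tspec, spec1)
        first = ckpt.history[0]["dice_loss"] + ckpt.history[0]["distance_loss"]
        last = ckpt.history[-1]["dice_loss"] + ckpt.history[-1]["distance_loss"]
        assert last < first

    def test_missing_maps_rejected(self):
        cases = prepare_cases(make_dataset(2, TINY_PHANTOM, seed=1), "none")
        spec1 = replace(TINY_NET, in_channels=1, with_distance_decoder=True)
        with pytest.raises(ValueError, match="missing"):
            train_stage1(cases, replace(TINY_TRAIN, max_epochs=1), spec1)

    def test_plain_unet_ablation_without_maps(self):
        cases = prepare_cases(make_dataset(2, TINY_PHANTOM, seed=2), "none")
        spec1 = replace(TINY_NET, in_channels=1, with_distance_decoder=False)
        tspec = replace(TINY_TRAIN, max_epochs=1, map_method="none")
        ckpt = train_stage1(cases, tspec, spec1)
        assert ckpt.history[0]["distance_loss"] is None

    def test_checkpoint_roundtrip_bit_identical(self, tiny_cases, tmp_path):
        spec1 = replace(TINY_NET, in_channels=1, with_distance_decoder=True)
        ckpt = train_stage1(tiny_cases, replace(TINY_TRAIN, max_epochs=1), spec1)
        path = tmp_path / "stage1.npz"
        ckpt.save(path)
        loaded = Checkpoint.load(path)
        x = Tensor(np.random.default_rng(0).normal(size=(1, 1, 8, 8, 8)))
        np.testing.assert_array_equal(
            ckpt.build()(x).segmentation.data, loaded.build()(x).segmentation.data
        )

    def test_reproducible_under_fixed_seed(self, tiny_cases):
        spec1 = replace(TINY_NET, in_channels=1, with_distance_decoder=True)
        tspec = replace(TINY_TRAIN, max_epochs=2, seed=11)
        a = train_stage1(tiny_cases, tspec, spec1)
        b = train_stage1(tiny_cases, tspec, spec1)
        for k in a.state:
            np.testing.assert_array_equal(a.state[k], b.state[k])


@pytest.fixture(scope="module")
def stage1_ckpt(tiny_cases):
    spec1 = replace(TINY_NET, in_channels=1, with_distance_decoder=True)
    return train_stage1(tiny_cases, replace(TINY_TRAIN, max_epochs=2), spec1)


class TestStageTwo:
    def test_stage1_weights_frozen(self, tiny_cases, stage1_ckpt):
        before = {k: v.copy() for k, v in stage1_ckpt.state.items()}
        spec2 = replace(TINY_NET, in_channels=2, with_distance_decoder=False)
        train_stage2(
            tiny_cases, stage1_ckpt, replace(TINY_TRAIN, max_epochs=1), spec2
        )
        for k in before:
            np.testing.assert_array_equal(before[k], stage1_ckpt.state[k])

    def test_bridge_channel_mismatch_rejected(self, tiny_cases, stage1_ckpt):
        spec2 = replace(TINY_NET, in_channels=3, with_distance_decoder=False)
        with pytest.raises(ValueError, match="channels"):
            train_stage2(
                tiny_cases, stage1_ckpt, replace(TINY_TRAIN, max_epochs=1), spec2
            )

    def test_distdice_requires_distance_prediction(self):
        cases = prepare_cases(make_dataset(2, TINY_PHANTOM, seed=3), "none")
        spec1 = replace(TINY_NET, in_channels=1, with_distance_decoder=False)
        tspec = replace(TINY_TRAIN, max_epochs=1, map_method="none",
                        stage2_loss="distdice")
        ck1 = train_stage1(cases, tspec, spec1)
        spec2 = replace(TINY_NET, in_channels=1, with_distance_decoder=False)
        with pytest.raises(ValueError, match="distance"):
            train_stage2(cases, ck1, tspec, spec2)

    def test_two_stage_evaluation_runs(self, tiny_cases, stage1_ckpt):
        spec2 = replace(TINY_NET, in_channels=2, with_distance_decoder=False)
        ck2 = train_stage2(
            tiny_cases, stage1_ckpt, replace(TINY_TRAIN, max_epochs=1), spec2
        )
        report = evaluate_pipeline(tiny_cases, stage1_ckpt, ck2)
        assert len(report.per_case) + len(report.excluded) == len(tiny_cases)


class TestTrainSpecValidation:
    def test_defaults_are_full_scale(self):
        spec = TrainSpec()
        assert spec.crop_size == (232, 232, 32)
        assert spec.lr0 == 1e-4
        assert spec.max_epochs == 110

    def test_crop_divisibility_check(self):
        with pytest.raises(ValueError, match="divisible"):
            TrainSpec(crop_size=(15, 16, 8)).check_against(NetworkSpec())

    def test_rejects_unknown_losses(self):
        with pytest.raises(ValueError):
            TrainSpec(stage1_distance_loss="huber")
        with pytest.raises(ValueError):
            TrainSpec(stage2_loss="boundary")
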