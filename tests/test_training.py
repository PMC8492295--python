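"""Training-loop mechanics: cropping, stepping, determinism, checkpoints."""

import dataclasses

import numpy as np
import pytest

from cgdenoise.gradients import InvalidStateError
from cgdenoise.networks import DiscriminatorConfig, GeneratorConfig, RDBConfig
from cgdenoise.synthetic import NoiseSpec, PairedSample, make_dataset
from cgdenoise.training import (
    TrainConfig,
    config_from_dict,
    config_to_dict,
    denoise,
    ensure_enhanced,
    extract_patch,
    fit,
    init_state,
    load_checkpoint,
    save_checkpoint,
    train_step,
)


def tiny_config(**kwargs):
    defaults = dict(
        epochs=2,
        patch_size=24,
        seed=0,
        generator=GeneratorConfig(
            n_rdbs=2, base_channels=8, rdb=RDBConfig(2, 4, 8)
        ),
        discriminator=DiscriminatorConfig(n_conv_stages=2, base_channels=4),
    )
    defaults.update(kwargs)
    return TrainConfig(**defaults)


@pytest.fixture
def dataset():
    data = make_dataset(3, 32, 32, [NoiseSpec("gaussian", sigma=0.15)], seed=0)
    for s in data:
        ensure_enhanced(s)
    return data


class TestExtractPatch:
    def test_degenerate_full_size_crop(self, dataset):
        s = dataset[0]
        crop = extract_patch(s, 32, np.random.default_rng(0))
        np.testing.assert_array_equal(crop.clean, s.clean)
        np.testing.assert_array_equal(crop.enhanced, s.enhanced)

    def test_alignment_against_index_oracle(self, dataset):
        s = dataset[0]
        crop = extract_patch(s, 20, np.random.default_rng(5))
        probe = np.random.default_rng(5)
        i, j = int(probe.integers(0, 13)), int(probe.integers(0, 13))
        np.testing.assert_array_equal(crop.clean, s.clean[i : i + 20, j : j + 20])
        np.testing.assert_array_equal(crop.noisy, s.noisy[i : i + 20, j : j + 20])
        np.testing.assert_array_equal(crop.enhanced, s.enhanced[i : i + 20, j : j + 20])

    def test_deterministic_offsets(self, dataset):
        a = extract_patch(dataset[0], 16, np.random.default_rng(9))
        b = extract_patch(dataset[0], 16, np.random.default_rng(9))
        np.testing.assert_array_equal(a.clean, b.clean)

    def test_oversized_patch_rejected(self, dataset):
        with pytest.raises(ValueError):
            extract_patch(dataset[0], 40, np.random.default_rng(0))


class TestTrainStep:
    def test_zero_learning_rate_freezes_parameters(self, dataset):
        config = tiny_config(learning_rate=0.0, clip_bound=10.0)  # loose clamp: no-op
        state = init_state(config)
        before_g = state.generator.state_dict()
        before_d = state.discriminator.state_dict()
        batch = [extract_patch(dataset[0], config.patch_size, state.rng)]
        train_step(state, batch, config)
        for k, v in state.generator.state_dict().items():
            np.testing.assert_array_equal(v, before_g[k])
        for k, v in state.discriminator.state_dict().items():
            np.testing.assert_array_equal(v, before_d[k])

    def test_report_identity_holds_exactly(self, dataset):
        config = tiny_config()
        state = init_state(config)
        batch = [extract_patch(dataset[0], config.patch_size, state.rng)]
        _, report = train_step(state, batch, config)
        assert report.total_g == report.wgan_g + config.lambda1 * report.recon
        assert report.recon >= 0.0

    def test_missing_enhancement_rejected(self):
        data = make_dataset(1, 32, 32, [NoiseSpec("gaussian", sigma=0.1)], seed=1)
        config = tiny_config()
        state = init_state(config)
        batch = [extract_patch(data[0], config.patch_size, state.rng)]
        with pytest.raises(InvalidStateError):
            train_step(state, batch, config)

    def test_wrong_batch_size_rejected(self, dataset):
        config = tiny_config()
        state = init_state(config)
        with pytest.raises(ValueError):
            train_step(state, [], config)

    @pytest.mark.parametrize("mode", ["l1", "wgan"])
    def test_loss_mode_variants_step(self, dataset, mode):
        config = tiny_config(loss_mode=mode, epochs=1)
        state = fit(dataset, config)
        assert state.step == len(dataset)
        if mode == "l1":
            assert all(r.wgan_g == 0.0 and r.wgan_d == 0.0 for r in state.history)

    def test_gradient_penalty_mode_steps(self, dataset):
        config = tiny_config(lipschitz_mode="gradient_penalty", epochs=1)
        state = fit(dataset, config)
        assert state.step == len(dataset)


class TestFit:
    def test_step_counting(self):
        data = make_dataset(1, 32, 32, [NoiseSpec("gaussian", sigma=0.1)], seed=2)
        state = fit(data, tiny_config(epochs=1, patch_size=32))
        assert state.step == 1 and state.epoch == 1

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            fit([], tiny_config())

    def test_full_determinism(self, dataset):
        config = tiny_config()
        h1 = [r.total_g for r in fit(list(dataset), config).history]
        h2 = [r.total_g for r in fit(list(dataset), config).history]
        assert h1 == h2

    def test_epoch_log_written(self, dataset, tmp_path):
        log = tmp_path / "losses.jsonl"
        fit(dataset, tiny_config(epochs=2), log_path=log)
        lines = log.read_text().strip().splitlines()
        assert len(lines) == 2
        import json

        rec = json.loads(lines[-1])
        assert set(rec) >= {"epoch", "step", "recon", "wgan_g", "wgan_d", "total_g"}


class TestCheckpoint:
    def test_resume_continues_identical_trajectory(self, dataset, tmp_path):
        config = tiny_config(epochs=4)
        straight = fit(list(dataset), config)

        half = fit(list(dataset), dataclasses.replace(config, epochs=2))
        path = tmp_path / "ck.npz"
        save_checkpoint(half, path)
        resumed = load_checkpoint(path)
        resumed = fit(list(dataset), config, state=resumed)
        assert [r.total_g for r in resumed.history] == [r.total_g for r in straight.history]
        assert resumed.step == straight.step

    def test_config_round_trip(self):
        config = tiny_config(lambda1=0.25, loss_mode="l1")
        back = config_from_dict(config_to_dict(config))
        assert back == config


class TestDenoise:
    def test_shape_range_and_determinism(self, dataset):
        state = init_state(tiny_config())
        out1 = denoise(state, dataset[0].noisy)
        out2 = denoise(state, dataset[0].noisy)
        assert out1.shape == dataset[0].noisy.shape
        assert out1.min() >= 0.0 and out1.max() <= 1.0
        np.testing.assert_array_equal(out1, out2)

    def test_undersized_image_rejected(self, dataset):
        state = init_state(tiny_config())
        with pytest.raises(ValueError):
            denoise(state, dataset[0].noisy[:8, :8])

    def test_patch_trained_full_image_inference(self, dataset):
        """Train on 24x24 crops, infer at 32x32: fully convolutional, no shape errors."""
        state = fit(dataset, tiny_config(epochs=1))
        out = denoise(state, dataset[0].noisy)
        assert out.shape == (32, 32)
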