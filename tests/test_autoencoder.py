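"""Padding, architecture shape contracts, training and encoding."""

import numpy as np
import pytest

from bqfmri.autoencoder import (Autoencoder3D, AutoencoderConfig, build_autoencoder,
                                crop_from_cube, desk_scale_config, encode_flatten,
                                encode_matrix, pad_to_cube, train_autoencoder)


def tiny_config(**overrides):
    """16^3 cube, latent (2, 2, 2, 4): cheap enough for per-test training."""
    kwargs = dict(input_shape=(12, 12, 12), padded_shape=(16, 16, 16),
                  latent_shape=(2, 2, 2, 4), n_conv_layers=3, n_transpose_layers=3,
                  channel_schedule=(2, 4, 4), learning_rate=1e-3, epochs=3,
                  batch_size=8, seed=0)
    kwargs.update(overrides)
    return AutoencoderConfig(**kwargs)


class TestPadToCube:
    def test_reference_shapes_pad_to_64_cube(self, rng):
        data = rng.random((53, 63, 46))
        padded = pad_to_cube(data, (64, 64, 64))
        assert padded.shape == (64, 64, 64)
        assert (padded == 0).sum() >= 64**3 - 53 * 63 * 46
        assert padded.sum() == pytest.approx(data.sum())

    def test_equal_shape_is_identity(self, rng):
        data = rng.random((8, 8, 8))
        assert np.array_equal(pad_to_cube(data, (8, 8, 8)), data)

    def test_crop_inverts_pad_bit_exactly(self, rng):
        data = rng.random((5, 7, 3))
        assert np.array_equal(crop_from_cube(pad_to_cube(data, (8, 8, 8)),
                                             (5, 7, 3)), data)

    def test_padded_smaller_than_input_rejected(self, rng):
        with pytest.raises(ValueError, match="axis y"):
            pad_to_cube(rng.random((4, 9, 4)), (8, 8, 8))


class TestArchitectureContracts:
    def test_reference_config_latent_and_flatten(self):
        cfg = AutoencoderConfig()
        assert cfg.latent_shape == (8, 8, 8, 128)
        assert cfg.flatten_length == 65_536
        desc = build_autoencoder(cfg).describe()
        assert desc["n_conv_layers"] == 9
        assert desc["n_transpose_layers"] == 3
        assert desc["stride_layers"] == [3, 6, 9]
        assert desc["output_shape"] == [64, 64, 64, 1]

    def test_scaled_config_flatten_length(self):
        cfg = AutoencoderConfig(input_shape=(32, 32, 32), padded_shape=(32, 32, 32),
                                latent_shape=(4, 4, 4, 8),
                                channel_schedule=(2, 2, 4, 4, 4, 8, 8, 8, 8))
        assert cfg.flatten_length == 512

    @pytest.mark.parametrize("cfg_kwargs", [
        dict(input_shape=(12, 12, 12), padded_shape=(16, 16, 16),
             latent_shape=(2, 2, 2, 4), n_conv_layers=3, n_transpose_layers=3,
             channel_schedule=(2, 4, 4)),
        dict(input_shape=(6, 8, 5), padded_shape=(8, 8, 8),
             latent_shape=(2, 2, 2, 3), n_conv_layers=4, n_transpose_layers=2,
             channel_schedule=(2, 2, 3, 3)),
    ])
    def test_encoder_decoder_shapes_for_valid_configs(self, cfg_kwargs, rng):
        cfg = AutoencoderConfig(epochs=1, **cfg_kwargs)
        model = build_autoencoder(cfg)
        x = rng.random((2, *cfg.padded_shape, 1)).astype(np.float32)
        latent = model.encoder.forward(x)
        assert latent.shape == (2, *cfg.latent_shape)
        recon = model.decoder.forward(latent)
        assert recon.shape == (2, *cfg.padded_shape, 1)

    def test_incompatible_latent_names_failing_axis(self):
        with pytest.raises(ValueError, match="axis x"):
            tiny_config(latent_shape=(3, 2, 2, 4))

    def test_padded_below_input_names_failing_axis(self):
        with pytest.raises(ValueError, match="axis z"):
            tiny_config(input_shape=(12, 12, 20))

    def test_channel_schedule_must_end_at_latent_channels(self):
        with pytest.raises(ValueError, match="latent channels"):
            tiny_config(channel_schedule=(2, 4, 8))

    def test_desk_scale_preset_matches_reference_depth(self):
        cfg = desk_scale_config()
        assert cfg.n_conv_layers == 9 and cfg.n_transpose_layers == 3
        assert cfg.flatten_length == 512


@pytest.fixture(scope="module")
def trained():
    rng = np.random.default_rng(42)
    maps = [rng.random((12, 12, 12)) for _ in range(20)]
    cfg = tiny_config(epochs=5)
    model, history = train_autoencoder(maps, cfg, seed=0)
    return maps, cfg, model, history


class TestTraining:
    def test_loss_decreases_over_training(self, trained):
        _, cfg, _, history = trained
        assert len(history) == cfg.epochs
        assert history[-1] < history[0]

    def test_training_is_deterministic(self, trained):
        maps, cfg, _, history = trained
        _, history2 = train_autoencoder(maps, cfg, seed=0)
        assert history == history2

    def test_constant_zero_maps_reconstruct_trivially(self):
        maps = [np.zeros((12, 12, 12)) for _ in range(4)]
        _, history = train_autoencoder(maps, tiny_config(epochs=2), seed=0)
        assert history[-1] == pytest.approx(0.0, abs=1e-8)

    def test_fewer_than_two_maps_rejected(self):
        with pytest.raises(ValueError, match="2 training maps"):
            train_autoencoder([np.zeros((12, 12, 12))], tiny_config(), seed=0)

    def test_encode_flatten_length_and_determinism(self, trained, rng):
        maps, cfg, model, _ = trained
        vec = encode_flatten(maps[0], model)
        assert vec.length == cfg.flatten_length == 32
        vec2 = encode_flatten(maps[0], model)
        assert np.array_equal(vec.values, vec2.values)

    def test_encode_flatten_shape_mismatch_rejected(self, trained, rng):
        _, _, model, _ = trained
        with pytest.raises(ValueError, match="shape"):
            encode_flatten(rng.random((9, 9, 9)), model)

    def test_encode_matrix_matches_per_map_encoding(self, trained):
        maps, cfg, model, _ = trained
        mat = encode_matrix([pad_to_cube(m, cfg.padded_shape) for m in maps[:5]],
                            model, batch_size=2)
        row0 = encode_flatten(maps[0], model).values
        assert mat.shape == (5, cfg.flatten_length)
        assert np.allclose(mat[0], row0, rtol=1e-6, atol=1e-8)

    def test_save_load_roundtrip_preserves_latents(self, trained, tmp_path):
        maps, _, model, _ = trained
        path = tmp_path / "model.npz"
        model.save(path)
        reloaded = Autoencoder3D.load(path)
        assert np.array_equal(encode_flatten(maps[1], model).values,
                              encode_flatten(maps[1], reloaded).values)
        assert reloaded.loss_history == model.loss_history
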