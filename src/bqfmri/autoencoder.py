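"""3D convolutional autoencoder: pad feature maps to a cube, compress, flatten.

The reference architecture pads 53x63x46 feature maps to 64^3, runs nine
3x3x3 convolution layers (ReLU; three of them stride 2, halving the grid
each time) down to a latent block of (8, 8, 8, 128), and reconstructs the
cube with three stride-2 transpose convolutions.  The flattened latent
block (length 65,536 by default) is the classifier input.  Training uses
Adam with mean-squared-error reconstruction loss.

A scaled-down configuration (smaller grid, narrower channels, fewer
epochs) exercises the identical code path at desk scale.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import FeatureMap3D
from .nn import Adam, Conv3D, ConvTranspose3D, ReLU, Sequential, mse_loss

logger = logging.getLogger(__name__)

REFERENCE_CHANNELS = (16, 16, 32, 32, 64, 64, 128, 128, 128)


def _default_decoder_channels(latent_c: int, n_layers: int) -> tuple[int, ...]:
    chans = [max(1, latent_c // 4 ** (i + 1)) for i in range(n_layers - 1)]
    return tuple(chans) + (1,)


@dataclass
class AutoencoderConfig:
    """Architecture and training settings.

    Defaults are the reference configuration: input 53x63x46 zero-padded to
    64^3, latent (8, 8, 8, 128) -> flatten 65,536, nine conv + three
    transpose layers, Adam lr 1e-4, MSE, 100 epochs.
    """

    input_shape: tuple[int, int, int] = (53, 63, 46)
    padded_shape: tuple[int, int, int] = (64, 64, 64)
    latent_shape: tuple[int, int, int, int] = (8, 8, 8, 128)
    n_conv_layers: int = 9
    n_transpose_layers: int = 3
    learning_rate: float = 1e-4
    epochs: int = 100
    batch_size: int = 8
    seed: int = 0
    channel_schedule: tuple[int, ...] = REFERENCE_CHANNELS
    decoder_channels: tuple[int, ...] | None = None
    stride_placement: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        self.input_shape = tuple(self.input_shape)
        self.padded_shape = tuple(self.padded_shape)
        self.latent_shape = tuple(self.latent_shape)
        self.channel_schedule = tuple(self.channel_schedule)
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        axes = "xyz"
        for ax, (p, i) in enumerate(zip(self.padded_shape, self.input_shape)):
            if p < i:
                raise ValueError(
                    f"padded_shape < input_shape on axis {axes[ax]}: {p} < {i}")
        n_halvings = self.n_transpose_layers
        for ax, (p, l) in enumerate(zip(self.padded_shape, self.latent_shape[:3])):
            if l * 2**n_halvings != p:
                raise ValueError(
                    f"latent axis {axes[ax]}: {l} * 2^{n_halvings} != padded {p}; "
                    "latent spatial dims must divide padded dims by a power of 2")
        if len(self.channel_schedule) != self.n_conv_layers:
            raise ValueError(
                f"channel_schedule length {len(self.channel_schedule)} != "
                f"n_conv_layers {self.n_conv_layers}")
        if self.channel_schedule[-1] != self.latent_shape[3]:
            raise ValueError(
                f"final encoder channels {self.channel_schedule[-1]} != "
                f"latent channels {self.latent_shape[3]}")
        if self.n_conv_layers < n_halvings:
            raise ValueError("need at least one conv layer per spatial halving")
        if self.decoder_channels is None:
            self.decoder_channels = _default_decoder_channels(
                self.latent_shape[3], self.n_transpose_layers)
        self.decoder_channels = tuple(self.decoder_channels)
        if len(self.decoder_channels) != self.n_transpose_layers:
            raise ValueError("decoder_channels length must equal n_transpose_layers")
        if self.decoder_channels[-1] != 1:
            raise ValueError("decoder must end with 1 output channel")
        if self.stride_placement is not None:
            self.stride_placement = tuple(self.stride_placement)
            ok = (len(self.stride_placement) == self.n_transpose_layers
                  and len(set(self.stride_placement)) == len(self.stride_placement)
                  and all(1 <= s <= self.n_conv_layers for s in self.stride_placement))
            if not ok:
                raise ValueError(
                    f"stride_placement {self.stride_placement} must be "
                    f"{self.n_transpose_layers} distinct 1-based layer indices "
                    f"within 1..{self.n_conv_layers}")

    @property
    def stride_layers(self) -> tuple[int, ...]:
        """1-based indices of the stride-2 encoder layers (default e.g. 3, 6, 9)."""
        if self.stride_placement is not None:
            return tuple(sorted(self.stride_placement))
        n, h = self.n_conv_layers, self.n_transpose_layers
        return tuple(round((i + 1) * n / h) for i in range(h))

    @property
    def flatten_length(self) -> int:
        return int(np.prod(self.latent_shape))

    def to_dict(self) -> dict:
        return {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.__dict__.items()}


def desk_scale_config(grid_shape: tuple[int, int, int] = (24, 24, 24),
                      seed: int = 0, epochs: int = 6) -> AutoencoderConfig:
    """Scaled-down configuration for desk-scale cohorts.

    Same depth as the reference architecture (nine conv + three transpose
    layers) with a 32^3 padded grid, narrow channels and early spatial
    downsampling (strides at layers 1, 3, 5), which keeps the per-fit cost
    of fold-wise retraining in the seconds range.  Latent (4, 4, 4, 8),
    flattened length 512.
    """
    return AutoencoderConfig(
        input_shape=tuple(grid_shape), padded_shape=(32, 32, 32),
        latent_shape=(4, 4, 4, 8),
        channel_schedule=(4, 8, 8, 8, 8, 8, 8, 8, 8),
        stride_placement=(1, 3, 5),
        learning_rate=1e-3, epochs=epochs, batch_size=12, seed=seed)


@dataclass
class LatentFeatureVector:
    """Flattened encoder output for one feature map (spatial-major, channel-minor)."""

    values: np.ndarray
    source_map_id: str = ""

    @property
    def length(self) -> int:
        return int(self.values.size)


def pad_to_cube(fmap: FeatureMap3D | np.ndarray,
                padded_shape: tuple[int, int, int] = (64, 64, 64)) -> np.ndarray:
    """Zero-pad a 3D map into a centered block of ``padded_shape``."""
    data = fmap.data if isinstance(fmap, FeatureMap3D) else np.asarray(fmap)
    axes = "xyz"
    pads = []
    for ax, (n, p) in enumerate(zip(data.shape, padded_shape)):
        if p < n:
            raise ValueError(f"padded_shape < map shape on axis {axes[ax]}: {p} < {n}")
        lo = (p - n) // 2
        pads.append((lo, p - n - lo))
    return np.pad(data, pads)


def crop_from_cube(padded: np.ndarray, input_shape: tuple[int, int, int]) -> np.ndarray:
    """Inverse of :func:`pad_to_cube`: recover the centered original block."""
    slices = []
    for n, p in zip(input_shape, padded.shape):
        lo = (p - n) // 2
        slices.append(slice(lo, lo + n))
    return padded[tuple(slices)]


class Autoencoder3D:
    """Encoder/decoder pair built from an :class:`AutoencoderConfig`."""

    def __init__(self, config: AutoencoderConfig) -> None:
        self.config = config
        rng = np.random.default_rng(config.seed)
        stride_at = set(config.stride_layers)
        enc: list = []
        c_in = 1
        for layer_idx, c_out in enumerate(config.channel_schedule, start=1):
            enc.append(Conv3D(c_in, c_out, stride=2 if layer_idx in stride_at else 1,
                              rng=rng))
            enc.append(ReLU())
            c_in = c_out
        dec: list = []
        for c_out in config.decoder_channels:
            dec.append(ConvTranspose3D(c_in, c_out, rng=rng))
            dec.append(ReLU())
            c_in = c_out
        self.encoder = Sequential(enc)
        self.decoder = Sequential(dec)
        self.loss_history: list[float] = []
        self.scale_mode = "per_map_max_abs"

    # -- description ---------------------------------------------------
    def describe(self) -> dict:
        cfg = self.config
        return {
            "n_conv_layers": cfg.n_conv_layers,
            "n_transpose_layers": cfg.n_transpose_layers,
            "stride_layers": list(cfg.stride_layers),
            "channel_schedule": list(cfg.channel_schedule),
            "decoder_channels": list(cfg.decoder_channels),
            "padded_shape": list(cfg.padded_shape),
            "latent_shape": list(cfg.latent_shape),
            "flatten_length": cfg.flatten_length,
            "output_shape": list(cfg.padded_shape) + [1],
            "input_scaling": self.scale_mode,
        }

    # -- numerics ------------------------------------------------------
    @staticmethod
    def _scale(batch: np.ndarray) -> np.ndarray:
        """Per-map division by max |value| (MSE stability); zero maps untouched."""
        flat = np.abs(batch.reshape(batch.shape[0], -1)).max(axis=1)
        flat[flat == 0] = 1.0
        return batch / flat[:, None, None, None, None]

    def _as_batch(self, maps) -> np.ndarray:
        arrs = []
        for m in maps:
            data = m.data if isinstance(m, FeatureMap3D) else np.asarray(m)
            if tuple(data.shape) != self.config.padded_shape:
                data = pad_to_cube(data, self.config.padded_shape)
            arrs.append(data)
        batch = np.stack(arrs)[..., None].astype(np.float32)
        return self._scale(batch)

    def reconstruct(self, maps) -> np.ndarray:
        x = self._as_batch(maps)
        return self.decoder.forward(self.encoder.forward(x))

    def encode(self, maps) -> np.ndarray:
        """Latent blocks for a list of maps: (n, *latent_shape)."""
        x = self._as_batch(maps)
        return np.asarray(self.encoder.forward(x), dtype=np.float64)

    def fit(self, maps, seed: int | None = None) -> list[float]:
        cfg = self.config
        if len(maps) < 2:
            raise ValueError("need at least 2 training maps")
        x = self._as_batch(maps)
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
        opt = Adam(self.encoder.layers + self.decoder.layers, lr=cfg.learning_rate)
        self.loss_history = []
        for epoch in range(cfg.epochs):
            order = rng.permutation(len(x))
            losses = []
            for start in range(0, len(x), cfg.batch_size):
                xb = x[order[start:start + cfg.batch_size]]
                recon = self.decoder.forward(self.encoder.forward(xb))
                loss, grad = mse_loss(recon, xb)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite reconstruction loss at epoch {epoch}, "
                        f"batch starting {start}: {loss}; consider a lower "
                        f"learning rate (current {cfg.learning_rate})")
                self.encoder.backward(self.decoder.backward(grad))
                opt.step()
                losses.append(loss)
            self.loss_history.append(float(np.mean(losses)))
        return self.loss_history

    # -- persistence ---------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Serialize weights + config + seed metadata into one .npz file."""
        arrays = {}
        for prefix, seq in (("enc", self.encoder), ("dec", self.decoder)):
            for i, layer in enumerate(seq.layers):
                for name, val in layer.params.items():
                    arrays[f"{prefix}.{i}.{name}"] = val
        arrays["__config__"] = np.frombuffer(
            json.dumps(self.config.to_dict()).encode(), dtype=np.uint8)
        arrays["__loss_history__"] = np.asarray(self.loss_history, dtype=np.float64)
        np.savez(str(path), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "Autoencoder3D":
        with np.load(str(path)) as npz:
            cfg = AutoencoderConfig(**json.loads(npz["__config__"].tobytes().decode()))
            model = cls(cfg)
            for prefix, seq in (("enc", model.encoder), ("dec", model.decoder)):
                for i, layer in enumerate(seq.layers):
                    for name in layer.params:
                        layer.params[name] = npz[f"{prefix}.{i}.{name}"]
            model.loss_history = list(npz["__loss_history__"])
        return model


def build_autoencoder(config: AutoencoderConfig) -> Autoencoder3D:
    return Autoencoder3D(config)


def train_autoencoder(maps, config: AutoencoderConfig,
                      seed: int | None = None) -> tuple[Autoencoder3D, list[float]]:
    """Train on a list of (padded) feature maps; returns (model, loss history)."""
    model = Autoencoder3D(config)
    history = model.fit(maps, seed=seed)
    return model, history


def encode_flatten(fmap, model: Autoencoder3D,
                   source_map_id: str = "") -> LatentFeatureVector:
    """Flattened latent code for one map (C-order: spatial-major, channel-minor)."""
    data = fmap.data if isinstance(fmap, FeatureMap3D) else np.asarray(fmap)
    if tuple(data.shape) == tuple(model.config.input_shape):
        data = pad_to_cube(data, model.config.padded_shape)
    if tuple(data.shape) != tuple(model.config.padded_shape):
        raise ValueError(f"map shape {data.shape} does not match padded shape "
                         f"{model.config.padded_shape}")
    latent = model.encode([data])[0]
    return LatentFeatureVector(values=latent.ravel(order="C"),
                               source_map_id=source_map_id)


def encode_matrix(maps, model: Autoencoder3D, batch_size: int = 8) -> np.ndarray:
    """Latent matrix (n_maps, flatten_length) for a list of maps."""
    rows = []
    for start in range(0, len(maps), batch_size):
        latent = model.encode(maps[start:start + batch_size])
        rows.append(latent.reshape(latent.shape[0], -1))
    return np.vstack(rows)
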