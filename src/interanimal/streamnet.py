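"""StreamNet: shallow multi-stream CNN configs, shapes, untrained features.

The StreamNet family are AlexNet-front-end networks, at most four
convolutional layers deep on the longest path (1 shallow + 2 intermediate
+ 1 deep), with the intermediate block replicated across N parallel
streams (N in {1, 2, 6}). Spatial geometry at a 64 x 64 input: shallow
conv (64, 11, 4, 2) + max pool (3, stride 2) -> 7 x 7; intermediate
[(192, 5, 1, 2) + pool, (384, 3, 1, 1)] -> 3 x 3; deep (256, 3, 1, 1)
from the intermediate (or (256, 3, 2, 0) directly from the shallow skip
path) -> 3 x 3. Each stream's two deep paths are summed and streams are
concatenated along channels; the readout adaptively average-pools to
6 x 6 and flattens.

This module is declarative-first: configs compute their own output shapes
exactly (floor arithmetic), and a seeded, untrained numpy forward pass
instantiates them for feature extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .predictivity import ModelFeatureSet

__all__ = [
    "ConvSpec",
    "StreamNetConfig",
    "build_streamnet_config",
    "compute_feature_shapes",
    "extract_untrained_features",
]

POOL_KERNEL, POOL_STRIDE = 3, 2


@dataclass(frozen=True)
class ConvSpec:
    """(number of filters, filter size, stride, padding) + optional pool."""

    n_filters: int
    kernel: int
    stride: int
    padding: int
    followed_by_pool: bool = False

    def __post_init__(self) -> None:
        if self.kernel < 1 or self.stride < 1 or self.n_filters < 1:
            raise ValueError("n_filters, kernel and stride must be >= 1")
        if self.padding < 0:
            raise ValueError("padding must be >= 0")

    def out_size(self, in_size: int) -> int:
        size = (in_size + 2 * self.padding - self.kernel) // self.stride + 1
        if self.followed_by_pool:
            size = (size - POOL_KERNEL) // POOL_STRIDE + 1
        return size


@dataclass(frozen=True)
class StreamNetConfig:
    """Declarative StreamNet description."""

    n_streams: int
    shallow: ConvSpec
    intermediate: tuple[ConvSpec, ...]
    deep_from_intermediate: ConvSpec
    deep_from_shallow: ConvSpec
    readout_pool: int = 6

    @property
    def longest_conv_path(self) -> int:
        # shallow + intermediate block + deep, excluding the readout
        return 1 + len(self.intermediate) + 1

    @property
    def deep_concat_channels(self) -> int:
        return self.n_streams * self.deep_from_intermediate.n_filters

    @property
    def intermediate_concat_channels(self) -> int:
        return self.n_streams * self.intermediate[-1].n_filters


def build_streamnet_config(n_streams: int,
                           allow_extension: bool = False) -> StreamNetConfig:
    """The published single- / dual- / six-stream variant.

    ``allow_extension`` permits other positive stream counts with the same
    per-stream parameters.
    """
    if n_streams not in (1, 2, 6) and not allow_extension:
        raise ValueError("n_streams must be 1, 2 or 6 "
                         "(pass allow_extension=True to override)")
    if n_streams < 1:
        raise ValueError("n_streams must be >= 1")
    return StreamNetConfig(
        n_streams=n_streams,
        shallow=ConvSpec(64, 11, 4, 2, followed_by_pool=True),
        intermediate=(ConvSpec(192, 5, 1, 2, followed_by_pool=True),
                      ConvSpec(384, 3, 1, 1)),
        deep_from_intermediate=ConvSpec(256, 3, 1, 1),
        deep_from_shallow=ConvSpec(256, 3, 2, 0),
    )


def compute_feature_shapes(config: StreamNetConfig,
                           input_side: int = 64) -> dict[str, tuple[int, int]]:
    """Per-module (spatial size, channel count); errors name the layer.

    Conv output is ``floor((W + 2P - K) / S) + 1``; the pool that follows
    a flagged conv is ``floor((W - 3) / 2) + 1``.
    """
    if input_side < 1:
        raise ValueError("input_side must be positive")
    shapes: dict[str, tuple[int, int]] = {"input": (input_side, 1)}

    size = config.shallow.out_size(input_side)
    if size < 1:
        raise ValueError(f"shallow conv collapses a {input_side}px input")
    shapes["shallow"] = (size, config.shallow.n_filters)

    inter = size
    for i, spec in enumerate(config.intermediate):
        inter = spec.out_size(inter)
        if inter < 1:
            raise ValueError(f"intermediate conv {i} collapses the input")
    shapes["intermediate"] = (inter, config.intermediate_concat_channels)

    deep_a = config.deep_from_intermediate.out_size(inter)
    deep_b = config.deep_from_shallow.out_size(size)
    if deep_a < 1:
        raise ValueError("deep conv (from intermediate) collapses the input")
    if deep_b < 1:
        raise ValueError("deep conv (from shallow skip) collapses the input")
    if deep_a != deep_b:
        raise ValueError(
            f"deep paths disagree: {deep_a} (intermediate) vs {deep_b} (skip)")
    shapes["deep"] = (deep_a, config.deep_concat_channels)
    shapes["readout"] = (config.readout_pool, config.deep_concat_channels)
    return shapes


# ---------------------------------------------------------------------------
# Untrained numpy forward pass


def _conv2d(x: np.ndarray, w: np.ndarray, stride: int, padding: int
            ) -> np.ndarray:
    """x: (N, C, H, W); w: (F, C, k, k) -> (N, F, Ho, Wo)."""
    k = w.shape[-1]
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    windows = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]  # (N, C, Ho, Wo, k, k)
    return np.tensordot(windows, w, axes=[(1, 4, 5), (1, 2, 3)]
                        ).transpose(0, 3, 1, 2)


def _maxpool(x: np.ndarray, kernel: int = POOL_KERNEL,
             stride: int = POOL_STRIDE) -> np.ndarray:
    windows = np.lib.stride_tricks.sliding_window_view(
        x, (kernel, kernel), axis=(2, 3))[:, :, ::stride, ::stride]
    return windows.max(axis=(4, 5))


def _adaptive_avg_pool(x: np.ndarray, out: int) -> np.ndarray:
    """Overlapping-window adaptive average pooling to (out, out)."""
    n, c, h, w = x.shape
    result = np.empty((n, c, out, out))
    for i in range(out):
        h0, h1 = (i * h) // out, -(-((i + 1) * h) // out)
        for j in range(out):
            w0, w1 = (j * w) // out, -(-((j + 1) * w) // out)
            result[:, :, i, j] = x[:, :, h0:h1, w0:w1].mean(axis=(2, 3))
    return result


def _init_weights(spec: ConvSpec, in_channels: int,
                  rng: np.random.Generator) -> np.ndarray:
    fan_in = in_channels * spec.kernel ** 2
    return rng.normal(scale=1.0 / np.sqrt(fan_in),
                      size=(spec.n_filters, in_channels,
                            spec.kernel, spec.kernel))


def _apply(spec: ConvSpec, x: np.ndarray, w: np.ndarray) -> np.ndarray:
    out = np.maximum(_conv2d(x, w, spec.stride, spec.padding), 0.0)
    if spec.followed_by_pool:
        out = _maxpool(out)
    return out


def extract_untrained_features(
    config: StreamNetConfig,
    images: np.ndarray,
    seed: int = 0,
    stimulus_ids: list[str] | None = None,
) -> ModelFeatureSet:
    """Per-module activations of a randomly initialised StreamNet.

    ``images`` is ``(N, H, W)`` or ``(N, H, W, C)``; weights are centred
    Gaussian with fan-in scaling, drawn from deterministic per-layer
    substreams of ``seed``, so features are bit-identical across calls.
    Returns layers ``shallow``, ``intermediate``, ``deep`` (streams
    concatenated along channels) and ``readout`` (adaptive 6 x 6 average
    pool), each flattened per stimulus.
    """
    x = np.asarray(images, dtype=float)
    if x.ndim == 3:
        x = x[:, None]  # grayscale channel
    elif x.ndim == 4:
        x = x.transpose(0, 3, 1, 2)
    else:
        raise ValueError("images must be (N, H, W) or (N, H, W, C)")
    if x.shape[-1] != x.shape[-2]:
        raise ValueError("images must be square")
    compute_feature_shapes(config, input_side=x.shape[-1])  # shape validation

    master = np.random.SeedSequence(seed)
    n_layer_draws = 1 + config.n_streams * (len(config.intermediate) + 2)
    streams = master.spawn(n_layer_draws)
    draw = iter(streams)

    shallow_w = _init_weights(config.shallow, x.shape[1],
                              np.random.default_rng(next(draw)))
    shallow = _apply(config.shallow, x, shallow_w)

    inter_outs, deep_outs = [], []
    for _ in range(config.n_streams):
        h = shallow
        in_ch = config.shallow.n_filters
        for spec in config.intermediate:
            w = _init_weights(spec, in_ch, np.random.default_rng(next(draw)))
            h = _apply(spec, h, w)
            in_ch = spec.n_filters
        inter_outs.append(h)
        w_deep = _init_weights(config.deep_from_intermediate, in_ch,
                               np.random.default_rng(next(draw)))
        w_skip = _init_weights(config.deep_from_shallow,
                               config.shallow.n_filters,
                               np.random.default_rng(next(draw)))
        deep = (_apply(config.deep_from_intermediate, h, w_deep)
                + _apply(config.deep_from_shallow, shallow, w_skip))
        deep_outs.append(deep)

    intermediate = np.concatenate(inter_outs, axis=1)
    deep = np.concatenate(deep_outs, axis=1)
    readout = _adaptive_avg_pool(deep, config.readout_pool)

    n = x.shape[0]
    layers = {
        "shallow": shallow.reshape(n, -1),
        "intermediate": intermediate.reshape(n, -1),
        "deep": deep.reshape(n, -1),
        "readout": readout.reshape(n, -1),
    }
    return ModelFeatureSet(layers=layers,
                           stimulus_ids=stimulus_ids or [],
                           provenance="untrained")
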