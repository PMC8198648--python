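"""Attention-gated residual trunk with spatial pyramid pooling.

The feature extractor is a truncated ResNet-style trunk (bottleneck blocks,
identity shortcuts H(x) = F(x) + x) whose final stage emits an ``N x M x C``
map (C = 1024 in the full configuration); channel- and spatial-attention gates
recalibrate the map, and spatial pyramid pooling collapses it to a fixed
``21 x C`` descriptor regardless of the input image size.  Because sawn boards
are rectangular with arbitrary aspect ratios, nothing here ever crops, pads or
squares the input.

Public feature maps are ``(H, W, C)`` arrays; internally computation runs
channel-first through the autodiff engine in :mod:`grainkit.network.autodiff`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .autodiff import Tensor, concat, conv2d, maxpool2d
from .pooling import DEFAULT_LEVELS, PyramidDescriptor, pyramid_bins, spp_pool

CHECKPOINT_FORMAT = "grainkit-backbone-v1"


class UndersizeError(ValueError):
    """Input image smaller than the trunk + pyramid can support."""


@dataclass(frozen=True)
class BackboneConfig:
    """Architecture of the trunk.

    The default mirrors the first three stages of a ResNet101 layout, stopping
    at the 1024-channel stage so that the pre-pyramid map is N x M x 1024; the
    2048-channel fourth stage is intentionally absent.  ``tiny()`` provides the
    scaled-down configuration used throughout the test suite.
    """

    stage_block_counts: tuple[int, ...] = (3, 4, 23)
    stage_channels: tuple[int, ...] = (256, 512, 1024)
    stem_channels: int = 64
    attention_placement: str = "per_stage_end"  # or "per_block"
    use_attention: bool = True
    channel_reduction: int = 1
    spatial_kernel: int = 7
    pyramid_levels: tuple[int, ...] = DEFAULT_LEVELS
    pool_statistic: str = "max"

    def __post_init__(self):
        if len(self.stage_block_counts) != len(self.stage_channels):
            raise ValueError("stage_block_counts and stage_channels must have equal length")
        if self.spatial_kernel % 2 != 1:
            raise ValueError(f"spatial attention kernel must be odd, got {self.spatial_kernel}")
        levels = tuple(self.pyramid_levels)
        if list(levels) != sorted(levels, reverse=True) or levels[-1] != 1:
            raise ValueError("pyramid levels must be strictly decreasing and end at 1")
        if self.attention_placement not in ("per_stage_end", "per_block"):
            raise ValueError(f"unknown attention placement {self.attention_placement!r}")

    @classmethod
    def tiny(cls, **overrides) -> "BackboneConfig":
        """Small trunk (3 stages of 1 block) used as the test vehicle."""
        kw = dict(stage_block_counts=(1, 1, 1), stage_channels=(8, 16, 32), stem_channels=8)
        kw.update(overrides)
        return cls(**kw)

    @property
    def out_channels(self) -> int:
        return self.stage_channels[-1]

    @property
    def total_stride(self) -> int:
        # stem conv (2) + stem pool (2); every stage after the first halves again
        return 4 * 2 ** (len(self.stage_block_counts) - 1)

    @property
    def min_input_size(self) -> int:
        """Smallest admissible image side: the final map must support the
        largest pyramid grid."""
        return self.total_stride * max(self.pyramid_levels)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "BackboneConfig":
        d = dict(d)
        for key in ("stage_block_counts", "stage_channels", "pyramid_levels"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# --------------------------------------------------------------------------
# parameter initialisation
# --------------------------------------------------------------------------

def _he(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in = int(np.prod(shape[1:]))
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


def _attention_param_specs(prefix: str, channels: int, config: BackboneConfig):
    r = config.channel_reduction
    k = config.spatial_kernel
    if r == 1:
        yield f"{prefix}.ca.w", (channels, channels, 1, 1)
        yield f"{prefix}.ca.b", (channels,)
    else:
        mid = max(channels // r, 1)
        yield f"{prefix}.ca.w1", (mid, channels, 1, 1)
        yield f"{prefix}.ca.b1", (mid,)
        yield f"{prefix}.ca.w2", (channels, mid, 1, 1)
        yield f"{prefix}.ca.b2", (channels,)
    yield f"{prefix}.sa.w", (1, 2, k, k)
    yield f"{prefix}.sa.b", (1,)


def _param_specs(config: BackboneConfig):
    yield "stem.w", (config.stem_channels, 3, 7, 7)
    yield "stem.b", (config.stem_channels,)
    in_ch = config.stem_channels
    for s, (n_blocks_, out_ch) in enumerate(zip(config.stage_block_counts, config.stage_channels)):
        mid = max(out_ch // 4, 1)
        for b in range(n_blocks_):
            p = f"stage{s}.block{b}"
            block_in = in_ch if b == 0 else out_ch
            stride = 2 if (s > 0 and b == 0) else 1
            yield f"{p}.conv1.w", (mid, block_in, 1, 1)
            yield f"{p}.conv1.b", (mid,)
            yield f"{p}.conv2.w", (mid, mid, 3, 3)
            yield f"{p}.conv2.b", (mid,)
            yield f"{p}.conv3.w", (out_ch, mid, 1, 1)
            yield f"{p}.conv3.b", (out_ch,)
            if block_in != out_ch or stride != 1:
                yield f"{p}.proj.w", (out_ch, block_in, 1, 1)
                yield f"{p}.proj.b", (out_ch,)
            if config.use_attention and config.attention_placement == "per_block":
                yield from _attention_param_specs(p, out_ch, config)
        if config.use_attention and config.attention_placement == "per_stage_end":
            yield from _attention_param_specs(f"stage{s}", out_ch, config)
        in_ch = out_ch


def init_params(config: BackboneConfig, seed: int) -> dict[str, np.ndarray]:
    """He-initialised conv weights, zero biases; pure function of the seed."""
    rng = np.random.default_rng(seed)
    params: dict[str, np.ndarray] = {}
    for name, shape in _param_specs(config):
        params[name] = np.zeros(shape) if name.endswith(".b") else _he(rng, shape)
    return params


# --------------------------------------------------------------------------
# attention gates and residual blocks (tensor path)
# --------------------------------------------------------------------------

def _channel_gate_t(t: Tensor, p: dict[str, Tensor], prefix: str, config: BackboneConfig) -> Tensor:
    c = t.shape[0]
    avg = t.mean(axis=(1, 2)).reshape(c, 1, 1)
    mx = t.max(axis=(1, 2)).reshape(c, 1, 1)

    def shared(v: Tensor) -> Tensor:
        if config.channel_reduction == 1:
            return conv2d(v, p[f"{prefix}.ca.w"], p[f"{prefix}.ca.b"])
        h = conv2d(v, p[f"{prefix}.ca.w1"], p[f"{prefix}.ca.b1"]).relu()
        return conv2d(h, p[f"{prefix}.ca.w2"], p[f"{prefix}.ca.b2"])

    return (shared(avg) + shared(mx)).sigmoid()  # (C, 1, 1), broadcastable


def _spatial_gate_t(t: Tensor, p: dict[str, Tensor], prefix: str, config: BackboneConfig) -> Tensor:
    mean_map = t.mean(axis=0, keepdims=True)
    max_map = t.max(axis=0, keepdims=True)
    stacked = concat([mean_map, max_map], axis=0)  # (2, H, W)
    k = config.spatial_kernel
    mask = conv2d(stacked, p[f"{prefix}.sa.w"], p[f"{prefix}.sa.b"], pad=k // 2)
    return mask.sigmoid()  # (1, H, W), broadcastable


def _apply_attention_t(t: Tensor, p, prefix: str, config: BackboneConfig) -> Tensor:
    t = t * _channel_gate_t(t, p, prefix, config)
    t = t * _spatial_gate_t(t, p, prefix, config)
    return t


def _bottleneck_t(x: Tensor, p, prefix: str, stride: int, has_proj: bool) -> Tensor:
    h = conv2d(x, p[f"{prefix}.conv1.w"], p[f"{prefix}.conv1.b"]).relu()
    h = conv2d(h, p[f"{prefix}.conv2.w"], p[f"{prefix}.conv2.b"], stride=stride, pad=1).relu()
    h = conv2d(h, p[f"{prefix}.conv3.w"], p[f"{prefix}.conv3.b"])
    if has_proj:
        shortcut = conv2d(x, p[f"{prefix}.proj.w"], p[f"{prefix}.proj.b"], stride=stride)
    else:
        shortcut = x
    return (h + shortcut).relu()


def forward_features_t(image_chw: Tensor, config: BackboneConfig, p: dict[str, Tensor]) -> Tensor:
    """Trunk forward pass: (3, H, W) tensor -> (C, N, M) feature map tensor."""
    t = conv2d(image_chw, p["stem.w"], p["stem.b"], stride=2, pad=3).relu()
    t = maxpool2d(t, kernel=3, stride=2, pad=1)
    for s, n_blocks_ in enumerate(config.stage_block_counts):
        for b in range(n_blocks_):
            prefix = f"stage{s}.block{b}"
            stride = 2 if (s > 0 and b == 0) else 1
            has_proj = f"{prefix}.proj.w" in p
            t = _bottleneck_t(t, p, prefix, stride, has_proj)
            if config.use_attention and config.attention_placement == "per_block":
                t = _apply_attention_t(t, p, prefix, config)
        if config.use_attention and config.attention_placement == "per_stage_end":
            t = _apply_attention_t(t, p, f"stage{s}", config)
    return t


def spp_pool_t(t: Tensor, levels=DEFAULT_LEVELS) -> Tensor:
    """Tensor SPP over a (C, N, M) map -> (n_blocks, C) tensor, max statistic."""
    _, h, w = t.shape
    if h < max(levels) or w < max(levels):
        raise UndersizeError(
            f"feature map {h}x{w} cannot support a {max(levels)}x{max(levels)} pyramid grid"
        )
    rows = []
    for n in levels:
        for r0, r1 in pyramid_bins(h, n):
            for c0, c1 in pyramid_bins(w, n):
                rows.append(t[:, r0:r1, c0:c1].max(axis=(1, 2)).reshape(1, -1))
    return concat(rows, axis=0)


# --------------------------------------------------------------------------
# public (H, W, C) operations
# --------------------------------------------------------------------------

def _hwc_to_chw_t(f: np.ndarray) -> Tensor:
    f = np.asarray(f, dtype=np.float64)
    if f.ndim != 3:
        raise ValueError(f"expected (H, W, C) array, got shape {f.shape}")
    return Tensor(f.transpose(2, 0, 1))


def channel_attention(feature_map: np.ndarray, weights: dict[str, np.ndarray]) -> np.ndarray:
    """Gate an (H, W, C) map per channel.

    Spatial average- and max-pooled channel vectors pass through the SAME 1x1
    convolution (``weights["w"]`` of shape (C, C, 1, 1) or (C, C), with bias
    ``weights["b"]``); the two responses are summed and sigmoid-squashed into a
    per-channel gate in (0, 1) that multiplies the input.
    """
    t = _hwc_to_chw_t(feature_map)
    c = t.shape[0]
    w = np.asarray(weights["w"], dtype=np.float64).reshape(c, c, 1, 1)
    b = np.asarray(weights.get("b", np.zeros(c)), dtype=np.float64)
    if w.shape[0] != c:
        raise ValueError(f"weight/channel mismatch: {w.shape[0]} vs {c} channels")
    p = {"x.ca.w": Tensor(w), "x.ca.b": Tensor(b)}
    cfg = BackboneConfig.tiny()
    out = t * _channel_gate_t(t, p, "x", cfg)
    return out.data.transpose(1, 2, 0)


def channel_gate(feature_map: np.ndarray, weights: dict[str, np.ndarray]) -> np.ndarray:
    """The (C,) gate vector the channel-attention op multiplies by."""
    t = _hwc_to_chw_t(feature_map)
    c = t.shape[0]
    w = np.asarray(weights["w"], dtype=np.float64).reshape(c, c, 1, 1)
    b = np.asarray(weights.get("b", np.zeros(c)), dtype=np.float64)
    p = {"x.ca.w": Tensor(w), "x.ca.b": Tensor(b)}
    return _channel_gate_t(t, p, "x", BackboneConfig.tiny()).data.reshape(-1)


def spatial_attention(
    feature_map: np.ndarray, weights: dict[str, np.ndarray], kernel: int | None = None
) -> np.ndarray:
    """Gate an (H, W, C) map per position.

    Channel-wise mean and max maps are stacked (2 channels), convolved with a
    single odd-sized kernel (``weights["w"]`` of shape (1, 2, k, k), bias
    ``weights["b"]``) under same-padding, and sigmoid-squashed into an
    (H, W) mask in (0, 1) that multiplies every channel.
    """
    t = _hwc_to_chw_t(feature_map)
    w = np.asarray(weights["w"], dtype=np.float64)
    k = w.shape[-1] if kernel is None else kernel
    if k % 2 != 1:
        raise ValueError(f"spatial attention kernel must be odd, got {k}")
    b = np.asarray(weights.get("b", np.zeros(1)), dtype=np.float64)
    cfg = BackboneConfig.tiny(spatial_kernel=k)
    p = {"x.sa.w": Tensor(w.reshape(1, 2, k, k)), "x.sa.b": Tensor(b)}
    out = t * _spatial_gate_t(t, p, "x", cfg)
    return out.data.transpose(1, 2, 0)


def spatial_gate(feature_map: np.ndarray, weights: dict[str, np.ndarray]) -> np.ndarray:
    """The (H, W) mask the spatial-attention op multiplies by."""
    t = _hwc_to_chw_t(feature_map)
    w = np.asarray(weights["w"], dtype=np.float64)
    k = w.shape[-1]
    cfg = BackboneConfig.tiny(spatial_kernel=k)
    p = {"x.sa.w": Tensor(w.reshape(1, 2, k, k)), "x.sa.b": Tensor(np.asarray(weights.get("b", np.zeros(1))))}
    return _spatial_gate_t(t, p, "x", cfg).data[0]


def residual_block(x: np.ndarray, branch, shortcut=None) -> np.ndarray:
    """Identity-shortcut residual mapping H(x) = F(x) + x.

    ``branch`` is any callable producing an array of x's shape (or of the
    projection shortcut's output shape when ``shortcut`` is given).
    """
    x = np.asarray(x, dtype=np.float64)
    fx = np.asarray(branch(x), dtype=np.float64)
    sx = x if shortcut is None else np.asarray(shortcut(x), dtype=np.float64)
    if fx.shape != sx.shape:
        raise ValueError(
            f"branch output shape {fx.shape} incompatible with shortcut shape {sx.shape}; "
            "configure a projection shortcut"
        )
    return fx + sx


def _prepare_image(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {img.shape}")
    return img.astype(np.float64) / 255.0 - 0.5


def forward_extract(
    image: np.ndarray, config: BackboneConfig, params: dict[str, np.ndarray]
) -> PyramidDescriptor:
    """Run an RGB image of arbitrary rectangular size through the trunk and
    pyramid-pool the final map into a fixed (21, C) descriptor.

    Raises :class:`UndersizeError` before touching any weights if either image
    side is below ``config.min_input_size``.
    """
    img = _prepare_image(image)
    h, w = img.shape[:2]
    m = config.min_input_size
    if h < m or w < m:
        raise UndersizeError(
            f"image {h}x{w} is too small: the trunk stride ({config.total_stride}) and the "
            f"largest pyramid grid ({max(config.pyramid_levels)}x{max(config.pyramid_levels)}) "
            f"require both sides >= {m} px"
        )
    p = {k: Tensor(v) for k, v in params.items()}
    fmap = forward_features_t(Tensor(img.transpose(2, 0, 1)), config, p)
    return spp_pool(
        fmap.data.transpose(1, 2, 0), config.pyramid_levels, config.pool_statistic
    )


# --------------------------------------------------------------------------
# checkpoints
# --------------------------------------------------------------------------

def save_checkpoint(path, params: dict[str, np.ndarray], config: BackboneConfig, extra: dict | None = None) -> None:
    meta = {"format": CHECKPOINT_FORMAT, "config": config.to_dict(), "extra": extra or {}}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **params)


def load_checkpoint(path) -> tuple[dict[str, np.ndarray], BackboneConfig, dict]:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        if meta.get("format") != CHECKPOINT_FORMAT:
            raise ValueError(f"unrecognised checkpoint format {meta.get('format')!r}")
        params = {k: z[k] for k in z.files if k != "__meta__"}
    return params, BackboneConfig.from_dict(meta["config"]), meta.get("extra", {})


def params_checksum(params: dict[str, np.ndarray]) -> str:
    """Order-independent byte-level digest of a parameter set."""
    import hashlib

    h = hashlib.sha256()
    for name in sorted(params):
        h.update(name.encode())
        h.update(np.ascontiguousarray(params[name]).tobytes())
    return h.hexdigest()
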