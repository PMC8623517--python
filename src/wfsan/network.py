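"""The wavelet-frequency-separation attention network (WFSAN).

The network predicts the high-resolution stationary-wavelet
coefficients from the low-resolution ones through two separated paths:

* an **approximate path** for the A sub-band (1 channel, ReLU
  activations — approximate Haar coefficients of a non-negative image
  are non-negative), built as conv 3×3 → ghost extension block →
  conv 1×1 → ghost extension block → conv 3×3 → sub-pixel head;
* a **detail path** for the stacked H, V, D sub-bands (3 channels, Tanh
  activations — detail coefficients are signed and sparse), built as
  conv 3×3 → (attention) ghost extension block → conv 1×1 → sub-pixel
  head.

Both block kinds emit 2×`primary_filters` channels: half from a dense
convolution (the primary features F), half from a cheap depthwise
linear map φ(F); the attention variant additionally gates φ(F) with a
spatial attention map in [0, 1] derived from channel-wise average and
max pooling.  The "G+S" combination (plain ghost in the approximate
path, spatial-attention ghost in the detail path) is the default; "G+G"
is the ablation alternative.

Sub-pixel heads produce scale²·{1, 3} channels with a linear 3×3
convolution and rearrange them to space, so an H×W input yields
sH×sW coefficient predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from PIL import Image

from . import nn
from .nn import (
    Adam,  # noqa: F401  (re-exported for convenience)
    Conv2d,
    DepthwiseConv2d,
    HardSigmoid,
    Layer,
    Param,
    PixelShuffle,
    ReLU,
    Tanh,
)
from .swt import WaveletBands, iswt2_level1, merge_bands, split_bands, swt2_level1

__all__ = [
    "BlockSpec",
    "NetworkConfig",
    "SpatialAttention",
    "GhostExtensionBlock",
    "AttentionGhostExtensionBlock",
    "WFSAN",
    "bicubic_upscale",
    "residual_base_from_image",
    "reconstruct_bands",
    "super_resolve",
]

GHOST = "ghost"
ATTENTION_GHOST = "attention_ghost"

_ACTS = {"relu": ReLU, "tanh": Tanh}


@dataclass
class BlockSpec:
    """Architectural description of one ghost-style block."""

    kind: str = GHOST
    primary_filters: int = 32
    primary_kernel: int = 3
    cheap_kernel: int = 3
    attention_kernel: int = 3
    activation: str = "relu"
    attention_bias: bool = False

    def __post_init__(self) -> None:
        if self.kind not in (GHOST, ATTENTION_GHOST):
            raise ValueError(f"unknown block kind {self.kind!r}")
        for k in (self.primary_kernel, self.cheap_kernel, self.attention_kernel):
            if k % 2 != 1:
                raise ValueError("all kernel sizes must be odd")
        if self.primary_filters < 1:
            raise ValueError("primary_filters must be >= 1")
        if self.activation not in _ACTS:
            raise ValueError(f"unknown activation {self.activation!r}")

    @property
    def out_channels(self) -> int:
        return 2 * self.primary_filters


@dataclass
class NetworkConfig:
    """Full architecture description of a WFSAN instance."""

    scale: int = 2
    base_filters: int = 32
    approx_block_kind: str = GHOST
    detail_block_kind: str = ATTENTION_GHOST
    approx_activation: str = "relu"
    detail_activation: str = "tanh"
    normalization: float = 255.0
    primary_kernel: int = 3
    cheap_kernel: int = 3
    attention_kernel: int = 3
    residual: bool = True

    def __post_init__(self) -> None:
        if self.scale not in (2, 3, 4):
            raise ValueError(f"scale must be one of 2, 3, 4; got {self.scale}")
        combo = (self.approx_block_kind, self.detail_block_kind)
        if combo not in ((GHOST, GHOST), (GHOST, ATTENTION_GHOST)):
            raise ValueError(
                "block combination must be G+G or G+S "
                f"(approx=ghost, detail=ghost|attention_ghost); got {combo}"
            )
        if self.base_filters < 1:
            raise ValueError("base_filters must be >= 1")
        if self.normalization <= 0:
            raise ValueError("normalization divisor must be positive")

    def block_spec(self, kind: str, activation: str) -> BlockSpec:
        return BlockSpec(
            kind=kind,
            primary_filters=self.base_filters,
            primary_kernel=self.primary_kernel,
            cheap_kernel=self.cheap_kernel,
            attention_kernel=self.attention_kernel,
            activation=activation,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**d)


class SpatialAttention(Layer):
    """Spatial attention map from channel-wise pooled features.

    Channel-wise average and max pooling give two H×W maps; they are
    concatenated and merged by one convolution to a single channel,
    then squashed with the hard sigmoid clamp((x+3)/6, 0, 1).  Output
    values are therefore always in [0, 1].  The merge convolution is
    bias-free by default (2k² parameters exactly).
    """

    def __init__(
        self,
        kernel: int = 3,
        *,
        bias: bool = False,
        rng: np.random.Generator | None = None,
        name: str = "attention",
    ) -> None:
        self.merge = Conv2d(2, 1, kernel, bias=bias, init="glorot", rng=rng, name=f"{name}.merge")
        self.gate = HardSigmoid()
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return self.merge.params()

    def forward(self, feats: np.ndarray) -> np.ndarray:
        if feats.ndim != 4 or feats.shape[1] < 1:
            raise ValueError("expected a (B, C, H, W) feature tensor")
        m_avg = feats.mean(axis=1, keepdims=True)
        m_max = feats.max(axis=1, keepdims=True)
        pooled = np.concatenate([m_avg, m_max], axis=1).astype(nn.DTYPE)
        amap = self.gate.forward(self.merge.forward(pooled))
        self._cache = (feats, m_max)
        return amap

    def backward(self, dmap: np.ndarray) -> np.ndarray:
        feats, m_max = self._cache
        dpooled = self.merge.backward(self.gate.backward(dmap))
        c = feats.shape[1]
        dfeats = np.broadcast_to(dpooled[:, :1] / c, feats.shape).astype(nn.DTYPE).copy()
        # max-pool routes gradient to the (first) arg-max channel
        idx = feats.argmax(axis=1)[:, None]
        np.put_along_axis(
            dfeats, idx, np.take_along_axis(dfeats, idx, axis=1) + dpooled[:, 1:2], axis=1
        )
        return dfeats


class GhostExtensionBlock(Layer):
    """Ghost extension block: concat(F, φ(F)).

    F is a dense convolution of the input followed by the block
    activation; φ is a bias-free depthwise (per-channel) linear map.
    Output width is exactly 2×primary_filters.
    """

    kind = GHOST

    def __init__(
        self,
        in_ch: int,
        spec: BlockSpec,
        *,
        rng: np.random.Generator | None = None,
        name: str = "ghost",
    ) -> None:
        init = "he" if spec.activation == "relu" else "glorot"
        self.spec = spec
        self.in_ch = in_ch
        self.primary = Conv2d(
            in_ch, spec.primary_filters, spec.primary_kernel,
            bias=True, init=init, rng=rng, name=f"{name}.primary",
        )
        self.cheap = DepthwiseConv2d(
            spec.primary_filters, spec.cheap_kernel,
            bias=False, init=init, rng=rng, name=f"{name}.cheap",
        )
        self.act = _ACTS[spec.activation]()

    @property
    def out_channels(self) -> int:
        return self.spec.out_channels

    def params(self) -> list[Param]:
        return self.primary.params() + self.cheap.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        f = self.act.forward(self.primary.forward(x))
        g = self.cheap.forward(f)
        return np.concatenate([f, g], axis=1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        c = self.spec.primary_filters
        df = dout[:, :c] + self.cheap.backward(dout[:, c:])
        return self.primary.backward(self.act.backward(df))


class AttentionGhostExtensionBlock(GhostExtensionBlock):
    """Ghost extension block whose cheap half is gated by spatial attention:
    concat(F, φ(F) ⊗ σ(f(M_avg, M_max)))."""

    kind = ATTENTION_GHOST

    def __init__(
        self,
        in_ch: int,
        spec: BlockSpec,
        *,
        rng: np.random.Generator | None = None,
        name: str = "attghost",
    ) -> None:
        super().__init__(in_ch, spec, rng=rng, name=name)
        self.attention = SpatialAttention(
            spec.attention_kernel, bias=spec.attention_bias, rng=rng, name=f"{name}.attention"
        )

    def params(self) -> list[Param]:
        return super().params() + self.attention.params()

    def forward(self, x: np.ndarray, attention_override: np.ndarray | None = None) -> np.ndarray:
        f = self.act.forward(self.primary.forward(x))
        g = self.cheap.forward(f)
        if attention_override is None:
            amap = self.attention.forward(g)
        else:
            amap = attention_override
        self._fwd = (g, amap, attention_override is not None)
        return np.concatenate([f, g * amap], axis=1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        c = self.spec.primary_filters
        g, amap, overridden = self._fwd
        dgated = dout[:, c:]
        dg = dgated * amap
        if not overridden:
            dmap = (dgated * g).sum(axis=1, keepdims=True)
            dg = dg + self.attention.backward(dmap)
        df = dout[:, :c] + self.cheap.backward(dg.astype(nn.DTYPE))
        return self.primary.backward(self.act.backward(df))


_BLOCKS = {GHOST: GhostExtensionBlock, ATTENTION_GHOST: AttentionGhostExtensionBlock}


class _Path(Layer):
    """Ordered, named layer chain with a sub-pixel tail."""

    def __init__(self, named_layers: list[tuple[str, Layer]]) -> None:
        self.named_layers = named_layers

    def params(self) -> list[Param]:
        out: list[Param] = []
        for _, layer in self.named_layers:
            out.extend(layer.params())
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        for _, layer in self.named_layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for _, layer in reversed(self.named_layers):
            dout = layer.backward(dout)
        return dout


class WFSAN:
    """The two-path coefficient-prediction network.

    Parameters
    ----------
    config : NetworkConfig
        Architecture description (scale, block kinds, filter widths).
    seed : int
        Seed for weight initialization (He-uniform on the ReLU path,
        Glorot-uniform on the Tanh path; biases zero).
    """

    def __init__(self, config: NetworkConfig, seed: int = 0) -> None:
        self.config = config
        rng = np.random.default_rng(seed)
        bf = config.base_filters
        s = config.scale
        k = config.primary_kernel

        a_spec = config.block_spec(config.approx_block_kind, config.approx_activation)
        d_spec = config.block_spec(config.detail_block_kind, config.detail_activation)
        a_blk = _BLOCKS[a_spec.kind]
        d_blk = _BLOCKS[d_spec.kind]

        self.approx_path = _Path([
            ("approx.conv_in", Conv2d(1, bf, k, init="he", rng=rng, name="approx.conv_in")),
            ("approx.act_in", ReLU()),
            ("approx.block1", a_blk(bf, a_spec, rng=rng, name="approx.block1")),
            ("approx.conv_mid", Conv2d(2 * bf, bf, 1, init="he", rng=rng, name="approx.conv_mid")),
            ("approx.act_mid", ReLU()),
            ("approx.block2", a_blk(bf, a_spec, rng=rng, name="approx.block2")),
            ("approx.conv_tail", Conv2d(2 * bf, bf, k, init="he", rng=rng, name="approx.conv_tail")),
            ("approx.act_tail", ReLU()),
            ("approx.head", Conv2d(bf, s * s * 1, k, init="he", rng=rng, name="approx.head")),
            ("approx.shuffle", PixelShuffle(s)),
        ])
        self.detail_path = _Path([
            ("detail.conv_in", Conv2d(3, bf, k, init="glorot", rng=rng, name="detail.conv_in")),
            ("detail.act_in", Tanh()),
            ("detail.block1", d_blk(bf, d_spec, rng=rng, name="detail.block1")),
            ("detail.conv_mid", Conv2d(2 * bf, bf, 1, init="glorot", rng=rng, name="detail.conv_mid")),
            ("detail.act_mid", Tanh()),
            ("detail.head", Conv2d(bf, s * s * 3, k, init="glorot", rng=rng, name="detail.head")),
            ("detail.shuffle", PixelShuffle(s)),
        ])
        if config.residual:
            # start exactly at the bicubic anchor: zero sub-pixel heads
            for path in (self.approx_path, self.detail_path):
                head = dict(path.named_layers)[
                    "approx.head" if path is self.approx_path else "detail.head"
                ]
                head.W.value[...] = 0.0
                head.b.value[...] = 0.0

    # -- parameter access ------------------------------------------------
    def params(self) -> list[Param]:
        return self.approx_path.params() + self.detail_path.params()

    def named_params(self) -> list[tuple[str, Param]]:
        return [(p.name, p) for p in self.params()]

    def named_layers(self) -> list[tuple[str, Layer]]:
        return self.approx_path.named_layers + self.detail_path.named_layers

    def n_params(self) -> int:
        return sum(p.size for p in self.params())

    # -- forward / backward ----------------------------------------------
    def forward(
        self,
        lca: np.ndarray,
        lcd: np.ndarray,
        residual_base: tuple[np.ndarray, np.ndarray] | None = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Predict HR coefficients from LR sub-band tensors.

        ``lca`` is (B, 1, H, W), ``lcd`` is (B, 3, H, W); returns
        (B, 1, sH, sW) and (B, 3, sH, sW).  In the residual variant
        (the default) the network output is added to the bicubic anchor
        sub-bands, which the caller supplies via ``residual_base`` —
        see :func:`residual_base_from_image`.
        """
        lca = np.asarray(lca, dtype=nn.DTYPE)
        lcd = np.asarray(lcd, dtype=nn.DTYPE)
        if lca.ndim != 4 or lcd.ndim != 4:
            raise ValueError("expected batched (B, C, H, W) tensors")
        if lca.shape[1] != 1:
            raise ValueError(f"approximate input must have 1 channel, got {lca.shape[1]}")
        if lcd.shape[1] != 3:
            raise ValueError(f"detail input must have 3 channels, got {lcd.shape[1]}")
        if lca.shape[2:] != lcd.shape[2:]:
            raise ValueError("approximate and detail inputs must share spatial shape")
        fa = self.approx_path.forward(lca)
        fd = self.detail_path.forward(lcd)
        if self.config.residual:
            if residual_base is None:
                raise ValueError(
                    "residual model needs the bicubic anchor sub-bands; "
                    "compute them with residual_base_from_image()"
                )
            fa = fa + residual_base[0]
            fd = fd + residual_base[1]
        return fa, fd

    def backward(self, dfa: np.ndarray, dfd: np.ndarray) -> None:
        # residual shift is additive in the outputs: gradients pass through
        self.approx_path.backward(np.asarray(dfa, dtype=nn.DTYPE))
        self.detail_path.backward(np.asarray(dfd, dtype=nn.DTYPE))

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    # -- weights as state -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.value.copy() for name, p in self.named_params()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_params():
            if name not in state:
                raise KeyError(f"missing weight {name!r} in state dict")
            if state[name].shape != p.value.shape:
                raise ValueError(f"shape mismatch for {name!r}")
            p.value[...] = state[name]


def bicubic_upscale(image: np.ndarray, scale: int) -> np.ndarray:
    """Bicubic ×scale upscaling of an 8-bit grayscale image (PIL backend)."""
    img = Image.fromarray(np.asarray(image, dtype=np.uint8), mode="L")
    h, w = image.shape
    return np.asarray(img.resize((w * scale, h * scale), Image.BICUBIC), dtype=np.float64)


def residual_base_from_image(
    image: np.ndarray, scale: int, normalization: float = 255.0
) -> tuple[np.ndarray, np.ndarray]:
    """Residual anchor: sub-bands of the bicubic-upscaled LR image.

    With the network heads at zero, reconstructing from this anchor
    reproduces plain bicubic upscaling exactly; training therefore
    starts at the bicubic baseline and learns only corrections.
    Returns ``(A, details)`` with shapes (1, sH, sW) and (3, sH, sW) on
    the normalized scale.
    """
    up = bicubic_upscale(image, scale) / normalization
    return split_bands(swt2_level1(up))


def reconstruct_bands(fa: np.ndarray, fd: np.ndarray, normalization: float = 255.0) -> np.ndarray:
    """Merge predicted coefficient tensors and invert the wavelet transform.

    ``fa`` is (1, H, W) (or (H, W)), ``fd`` is (3, H, W), both on the
    normalized scale; returns the image on the original pixel scale
    (un-clipped floats).
    """
    fa = np.asarray(fa, dtype=np.float64)
    if fa.ndim == 2:
        fa = fa[None]
    bands = merge_bands(fa, np.asarray(fd, dtype=np.float64))
    return iswt2_level1(bands) * normalization


def super_resolve(image: np.ndarray, model: WFSAN, scale: int | None = None) -> np.ndarray:
    """Upscale a grayscale 8-bit image with a (trained) WFSAN model.

    The image is normalized, decomposed into its four Haar sub-bands,
    the two network paths predict the HR coefficients, and the inverse
    transform reconstructs the image, which is clipped to [0, 255] and
    returned as uint8 of shape (scale·H, scale·W).
    """
    image = np.asarray(image)
    if image.ndim == 3:
        raise ValueError(
            "multi-channel input: convert to single-channel grayscale first "
            "(only one channel of information is used)"
        )
    if scale is not None and scale != model.config.scale:
        raise ValueError(
            f"requested scale {scale} but model was built for ×{model.config.scale}"
        )
    norm = model.config.normalization
    x = image.astype(np.float64) / norm
    approx, details = split_bands(swt2_level1(x))
    rbase = None
    if model.config.residual:
        ba, bd = residual_base_from_image(image, model.config.scale, norm)
        rbase = (ba[None].astype(nn.DTYPE), bd[None].astype(nn.DTYPE))
    fa, fd = model.forward(approx[None], details[None], residual_base=rbase)
    out = reconstruct_bands(fa[0], fd[0], norm)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)
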