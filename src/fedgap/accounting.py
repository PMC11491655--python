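"""Analytic cost model of a frozen vision-transformer encoder.

The encoder never runs here: its parameter count, forward FLOPs and quantized
storage size are closed-form functions of the architecture, which is all the
distributed-training cost ledger needs. FLOP counting conventions differ
between tools, so the convention is an explicit value (:class:`FlopConvention`)
rather than an implicit choice.

Also provides an affine per-tensor quantize-dequantize used to emulate 8-bit
encoder outputs on feature vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ViTSpec",
    "FlopConvention",
    "VIT_L16",
    "DEFAULT_VIT_CONVENTION",
    "DEFAULT_HEAD_CONVENTION",
    "vit_param_count",
    "vit_forward_flops",
    "quantized_size_bytes",
    "quantize_dequantize",
]


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class ViTSpec:
    """Architecture hyperparameters of a ViT encoder (accounting only)."""

    image_size: int = 224
    patch_size: int = 16
    in_channels: int = 3
    embed_dim: int = 1024
    depth: int = 24
    num_heads: int = 16
    mlp_ratio: int = 4
    has_cls_token: bool = True
    learned_pos_embed: bool = True

    def __post_init__(self) -> None:
        if self.image_size % self.patch_size != 0:
            raise ParameterError(
                f"image_size {self.image_size} not divisible by patch_size {self.patch_size}"
            )
        if self.embed_dim % self.num_heads != 0:
            raise ParameterError(
                f"embed_dim {self.embed_dim} not divisible by num_heads {self.num_heads}"
            )
        if self.depth < 0:
            raise ParameterError("depth must be >= 0")

    @property
    def patch_tokens(self) -> int:
        return (self.image_size // self.patch_size) ** 2

    @property
    def tokens(self) -> int:
        return self.patch_tokens + (1 if self.has_cls_token else 0)


#: ViT-Large/16 on 224x224 RGB — the architecture behind the 1024-d embeddings.
VIT_L16 = ViTSpec()


@dataclass(frozen=True)
class FlopConvention:
    """Explicit FLOP-counting convention.

    The default counts 2 FLOPs per multiply-accumulate over the patch-embedding
    convolution and every linear layer, and excludes bias additions, the
    attention score/value matrix products, and norms/activations.
    """

    flops_per_mac: int = 2
    count_bias_adds: bool = False
    count_attention_matmuls: bool = False
    count_norms_activations: bool = False

    def __post_init__(self) -> None:
        if self.flops_per_mac not in (1, 2):
            raise ParameterError("flops_per_mac must be 1 or 2")


DEFAULT_VIT_CONVENTION = FlopConvention()
#: Head accounting additionally counts bias additions (a 1024-d linear head
#: then costs 2*1024 + 1 = 2049 FLOPs per inference).
DEFAULT_HEAD_CONVENTION = FlopConvention(count_bias_adds=True)


def _block_params(spec: ViTSpec) -> int:
    d, r = spec.embed_dim, spec.mlp_ratio
    layernorms = 2 * (2 * d)
    qkv = d * 3 * d + 3 * d
    proj = d * d + d
    mlp = d * r * d + r * d + r * d * d + d
    return layernorms + qkv + proj + mlp


def vit_param_count(spec: ViTSpec) -> int:
    """Exact parameter count of the encoder (patch embed, cls token, learned
    positional embeddings, ``depth`` transformer blocks, final layer-norm)."""
    d = spec.embed_dim
    total = spec.patch_size**2 * spec.in_channels * d + d  # patch-embed conv + bias
    if spec.has_cls_token:
        total += d
    if spec.learned_pos_embed:
        total += spec.tokens * d
    total += spec.depth * _block_params(spec)
    total += 2 * d  # final layer-norm
    return int(total)


def vit_forward_flops(spec: ViTSpec, conv: FlopConvention = DEFAULT_VIT_CONVENTION) -> int:
    """Forward-pass FLOPs for one image under the given convention."""
    d, r, t = spec.embed_dim, spec.mlp_ratio, spec.tokens
    macs = spec.patch_tokens * spec.patch_size**2 * spec.in_channels * d
    macs += spec.depth * t * (3 * d * d + d * d + 2 * r * d * d)
    if conv.count_attention_matmuls:
        macs += spec.depth * 2 * t * t * d
    flops = conv.flops_per_mac * macs
    if conv.count_bias_adds:
        per_token_bias = 3 * d + d + r * d + d  # qkv, proj, two mlp layers
        flops += spec.patch_tokens * d  # patch-embed bias
        flops += spec.depth * t * per_token_bias
    if conv.count_norms_activations:
        # layer-norm ~ 5 FLOPs/element (mean, var, normalize, scale, shift);
        # GELU ~ 8 FLOPs/element on the MLP hidden activations.
        flops += spec.depth * t * (2 * 5 * d + 8 * r * d) + 5 * t * d
    return int(flops)


def quantized_size_bytes(param_count: int, bits: int) -> int:
    """Storage size of ``param_count`` parameters at ``bits`` per parameter."""
    if bits not in (8, 16, 32):
        raise ParameterError(f"unsupported bit width {bits} (use 8, 16 or 32)")
    if param_count < 0:
        raise ParameterError("param_count must be >= 0")
    return -(-param_count * bits // 8)  # ceil division


def quantize_dequantize(v: np.ndarray, bits: int = 8) -> np.ndarray:
    """Per-tensor affine quantize-dequantize.

    For a 2-D input each *row* is quantized independently (one tensor per
    feature vector). scale = (max-min)/(2^bits - 1), zero_point =
    round(-min/scale); reconstruction error is bounded by scale/2.
    """
    if not 2 <= bits <= 16:
        raise ParameterError(f"bits must be in [2, 16], got {bits}")
    v = np.asarray(v, dtype=float)
    if v.size == 0:
        raise ValueError("cannot quantize an empty vector")
    if not np.isfinite(v).all():
        raise ValueError("input contains NaN or inf")
    single = v.ndim == 1
    arr = v[None, :] if single else v
    lo = arr.min(axis=1, keepdims=True)
    hi = arr.max(axis=1, keepdims=True)
    levels = 2**bits - 1
    scale = (hi - lo) / levels
    scale = np.where(scale == 0, 1.0, scale)
    zp = np.round(-lo / scale)
    q = np.clip(np.round(arr / scale + zp), 0, levels)
    out = (q - zp) * scale
    # constant rows pass through untouched
    const = (hi == lo)
    out = np.where(const, arr, out)
    return out[0] if single else out
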