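"""Hierarchical shifted-window transformer classifier.

The backbone splits the input image into non-overlapping 4×4-pixel patches,
projects each patch to an embedding, and processes the token grid in stages.
Each stage applies pairs of transformer blocks — the first restricting
multi-head self-attention to regular M×M windows (W-MSA), the second to
windows shifted by (⌊M/2⌋, ⌊M/2⌋) (SW-MSA) via the cyclic-shift + mask
strategy — then merges 2×2 token neighbourhoods, halving resolution and
doubling channels.  A block pair computes

    ẑ^l     = W-MSA(LN(z^{l-1})) + z^{l-1}
    z^l     = MLP(LN(ẑ^l)) + ẑ^l
    ẑ^{l+1} = SW-MSA(LN(z^l)) + z^l
    z^{l+1} = MLP(LN(ẑ^{l+1})) + ẑ^{l+1}

with a learned relative-position bias added to the attention logits inside
every window.  The classification head is LayerNorm → global average pool
over tokens → linear.

The default configuration is the standard tiny variant of this architecture
(embed dim 96, depths 2-2-6-2, heads 3-6-12-24, window 7, MLP ratio 4): with
a 4-class head it has 27.5 M trainable parameters and an analytic cost of
4.5 G multiply-accumulates for one 224×224 forward pass, which
:func:`count_parameters` and :func:`model_mac_count` reproduce exactly.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .nn import LayerNorm, Linear, Module, Parameter, Tensor, xavier_uniform
from .windowing import MASK_NEG, build_attention_mask, default_shift

__all__ = [
    "SwinConfig", "SwinClassifier", "ModelSummary",
    "complexity_msa", "complexity_wmsa",
    "count_parameters", "model_mac_count", "summarize",
    "save_checkpoint", "load_checkpoint", "CHECKPOINT_FORMAT",
]

CHECKPOINT_FORMAT = "swinpoly-checkpoint-v1"


@dataclass(frozen=True)
class SwinConfig:
    """Architecture hyperparameters.

    Defaults are the tiny configuration: 224×224 input, 4×4 patches,
    embedding dim 96 doubling per stage, depths (2,2,6,2) with heads
    (3,6,12,24), window size 7, MLP expansion 4.
    """

    input_size: int = 224
    patch_size: int = 4
    embed_dim: int = 96
    depths: tuple[int, ...] = (2, 2, 6, 2)
    num_heads: tuple[int, ...] = (3, 6, 12, 24)
    window_size: int = 7
    mlp_ratio: float = 4.0
    num_classes: int = 4
    in_channels: int = 3

    def __post_init__(self):
        if self.input_size % self.patch_size:
            raise ValueError(
                f"input size {self.input_size} not divisible by patch size "
                f"{self.patch_size}")
        if len(self.depths) != len(self.num_heads):
            raise ValueError("depths and num_heads must have equal length")
        for d in self.depths:
            if d % 2:
                raise ValueError(
                    f"stage depths must be even (W-MSA/SW-MSA pairs), got {d}")
        for i, (res, dim, heads) in enumerate(
                zip(self.stage_resolutions(), self.stage_dims(), self.num_heads)):
            if dim % heads:
                raise ValueError(
                    f"stage {i}: head count {heads} does not divide dim {dim}")
            m = min(self.window_size, res)
            if res % m:
                raise ValueError(
                    f"stage {i}: resolution {res} not divisible by window {m}")

    def n_stages(self) -> int:
        return len(self.depths)

    def stage_dims(self) -> tuple[int, ...]:
        return tuple(self.embed_dim * 2 ** i for i in range(self.n_stages()))

    def stage_resolutions(self) -> tuple[int, ...]:
        r0 = self.input_size // self.patch_size
        return tuple(r0 // 2 ** i for i in range(self.n_stages()))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["depths"] = list(self.depths)
        d["num_heads"] = list(self.num_heads)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SwinConfig":
        d = dict(d)
        d["depths"] = tuple(d["depths"])
        d["num_heads"] = tuple(d["num_heads"])
        return cls(**d)


@dataclass
class ModelSummary:
    parameter_count: int
    mac_count: int

    def to_dict(self) -> dict:
        return {
            "parameter_count": self.parameter_count,
            "parameters_millions": round(self.parameter_count / 1e6, 1),
            "mac_count": self.mac_count,
            "macs_giga": round(self.mac_count / 1e9, 1),
        }


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class PatchEmbed(Module):
    """Flatten non-overlapping patch_size² pixel patches and project to C dims."""

    def __init__(self, cfg: SwinConfig, rng: np.random.Generator):
        super().__init__()
        p, cin = cfg.patch_size, cfg.in_channels
        self.patch_size = p
        self.proj = Linear(p * p * cin, cfg.embed_dim, rng)
        self.norm = LayerNorm(cfg.embed_dim)

    def __call__(self, x: Tensor) -> Tensor:
        b, hh, ww, cin = x.shape
        p = self.patch_size
        if hh % p or ww % p:
            raise ValueError(f"image side {hh}x{ww} not divisible by patch {p}")
        h, w = hh // p, ww // p
        x = (x.reshape(b, h, p, w, p, cin)
             .transpose(0, 1, 3, 2, 4, 5)
             .reshape(b, h, w, p * p * cin))
        return self.norm(self.proj(x))


def _relative_position_index(m: int) -> np.ndarray:
    """(M², M²) lookup into the (2M−1)² relative-position-bias table."""
    coords = np.stack(np.meshgrid(np.arange(m), np.arange(m), indexing="ij"))
    flat = coords.reshape(2, -1)
    rel = flat[:, :, None] - flat[:, None, :]  # (2, M², M²)
    rel = rel + (m - 1)
    return rel[0] * (2 * m - 1) + rel[1]


class WindowAttention(Module):
    """Multi-head self-attention inside one window, with relative position bias."""

    def __init__(self, dim: int, num_heads: int, window_size: int,
                 rng: np.random.Generator):
        super().__init__()
        if dim % num_heads:
            raise ValueError(f"heads {num_heads} must divide dim {dim}")
        self.dim = dim
        self.num_heads = num_heads
        self.window_size = window_size
        self.head_dim = dim // num_heads
        self.scale = self.head_dim ** -0.5
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)
        n_rel = (2 * window_size - 1) ** 2
        self.relative_position_bias_table = Parameter(
            np.zeros((n_rel, num_heads), dtype=np.float32))
        self._rel_index = _relative_position_index(window_size)

    def __call__(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        bw, n, d = x.shape  # (batch·windows, M², dim)
        nh, hd = self.num_heads, self.head_dim
        qkv = (self.qkv(x).reshape(bw, n, 3, nh, hd)
               .transpose(2, 0, 3, 1, 4))  # (3, bw, heads, N, hd)
        q, k, v = qkv[0], qkv[1], qkv[2]
        attn = (q * self.scale) @ k.transpose(0, 1, 3, 2)
        bias = (self.relative_position_bias_table
                .take(self._rel_index.reshape(-1))
                .reshape(n, n, nh)
                .transpose(2, 0, 1)
                .reshape(1, nh, n, n))
        attn = attn + bias
        if mask is not None:
            nw = mask.shape[0]
            attn = (attn.reshape(bw // nw, nw, nh, n, n)
                    + Tensor(mask[None, :, None].astype(np.float32)))
            attn = attn.reshape(bw, nh, n, n)
        attn = attn.softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(bw, n, d)
        return self.proj(out)


class Mlp(Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class SwinBlock(Module):
    """One transformer unit: (S)W-MSA with pre-norm residual, then MLP."""

    def __init__(self, dim: int, resolution: int, num_heads: int,
                 window_size: int, shifted: bool, mlp_ratio: float,
                 rng: np.random.Generator):
        super().__init__()
        self.resolution = resolution
        # degenerate case: a single window covers the map, shifting is a no-op
        self.window_size = min(window_size, resolution)
        self.shift = (default_shift(self.window_size)
                      if shifted and resolution > self.window_size else (0, 0))
        self.norm1 = LayerNorm(dim)
        self.attn = WindowAttention(dim, num_heads, self.window_size, rng)
        self.norm2 = LayerNorm(dim)
        self.mlp = Mlp(dim, int(dim * mlp_ratio), rng)
        self.attn_mask = (build_attention_mask(resolution, resolution,
                                               self.window_size, self.shift)
                          if self.shift != (0, 0) else None)

    def __call__(self, x: Tensor, capture: dict | None = None,
                 name: str = "") -> Tensor:
        b, h, w, d = x.shape
        m = self.window_size
        shortcut = x
        y = self.norm1(x)
        if capture is not None:
            capture[name + ".norm1"] = y.data
        if self.shift != (0, 0):
            y = y.roll((-self.shift[0], -self.shift[1]), axis=(1, 2))
        nh, nw = h // m, w // m
        y = (y.reshape(b, nh, m, nw, m, d)
             .transpose(0, 1, 3, 2, 4, 5)
             .reshape(b * nh * nw, m * m, d))
        y = self.attn(y, self.attn_mask)
        y = (y.reshape(b, nh, nw, m, m, d)
             .transpose(0, 1, 3, 2, 4, 5)
             .reshape(b, h, w, d))
        if self.shift != (0, 0):
            y = y.roll(self.shift, axis=(1, 2))
        x = shortcut + y
        y = self.norm2(x)
        if capture is not None:
            capture[name + ".norm2"] = y.data
        return x + self.mlp(y)


class PatchMerging(Module):
    """Concatenate 2×2 token neighbourhoods (4C), normalize, project to 2C."""

    def __init__(self, dim: int, rng: np.random.Generator):
        super().__init__()
        self.norm = LayerNorm(4 * dim)
        self.reduction = Linear(4 * dim, 2 * dim, rng, bias=False)

    def __call__(self, x: Tensor) -> Tensor:
        from .nn import concatenate
        b, h, w, d = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"patch merging requires even dims, got {h}x{w}")
        parts = [x[:, 0::2, 0::2, :], x[:, 1::2, 0::2, :],
                 x[:, 0::2, 1::2, :], x[:, 1::2, 1::2, :]]
        y = concatenate(parts, axis=-1)
        return self.reduction(self.norm(y))


class SwinClassifier(Module):
    """The full backbone + classification head."""

    def __init__(self, cfg: SwinConfig, rng: np.random.Generator | int = 0):
        super().__init__()
        if isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(int(rng))
        self.cfg = cfg
        self.patch_embed = PatchEmbed(cfg, rng)
        dims = cfg.stage_dims()
        resolutions = cfg.stage_resolutions()
        self._block_names: list[str] = []
        for s, (dim, res, depth, heads) in enumerate(
                zip(dims, resolutions, cfg.depths, cfg.num_heads)):
            for b in range(depth):
                name = f"stage{s}.block{b}"
                blk = SwinBlock(dim, res, heads, cfg.window_size,
                                shifted=(b % 2 == 1), mlp_ratio=cfg.mlp_ratio,
                                rng=rng)
                setattr(self, f"stage{s}_block{b}", blk)
                self._block_names.append(name)
            if s < cfg.n_stages() - 1:
                setattr(self, f"merge{s}", PatchMerging(dim, rng))
        self.norm = LayerNorm(dims[-1])
        self.head = Linear(dims[-1], cfg.num_classes, rng)

    # -- forward -------------------------------------------------------------
    def __call__(self, images: np.ndarray | Tensor,
                 capture: dict | None = None) -> Tensor:
        """Forward a batch of (B, H, W, in_channels) images to class logits.

        When `capture` is a dict, named intermediate activations
        ("stage{i}.block{j}.norm1|norm2") are stored into it as arrays.
        """
        x = images if isinstance(images, Tensor) else Tensor(
            np.asarray(images, dtype=np.float32))
        if x.ndim != 4:
            raise ValueError(f"expected (B, H, W, C) images, got shape {x.shape}")
        x = self.patch_embed(x)
        cfg = self.cfg
        for s in range(cfg.n_stages()):
            for b in range(cfg.depths[s]):
                blk = getattr(self, f"stage{s}_block{b}")
                x = blk(x, capture=capture, name=f"stage{s}.block{b}")
            if s < cfg.n_stages() - 1:
                x = getattr(self, f"merge{s}")(x)
        x = self.norm(x)
        b, h, w, d = x.shape
        x = x.reshape(b, h * w, d).mean(axis=1)
        return self.head(x)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Softmax class probabilities, batched; pure inference (no tape)."""
        logits = self(images)
        z = logits.data - logits.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)

    def activation_layer_names(self) -> list[str]:
        return [f"{n}.{which}" for n in self._block_names
                for which in ("norm1", "norm2")]


# ---------------------------------------------------------------------------
# analytic accounting
# ---------------------------------------------------------------------------

def complexity_msa(h: int, w: int, c: int) -> int:
    """MACs of global multi-head self-attention on an h×w token grid:
    4hwC² + 2(hw)²C."""
    return 4 * h * w * c * c + 2 * (h * w) ** 2 * c


def complexity_wmsa(h: int, w: int, c: int, m: int) -> int:
    """MACs of windowed multi-head self-attention: 4hwC² + 2M²hwC."""
    return 4 * h * w * c * c + 2 * m * m * h * w * c


def count_parameters(model_or_cfg: SwinClassifier | SwinConfig) -> int:
    """Exact trainable-parameter count (by summing actual tensor sizes)."""
    model = (model_or_cfg if isinstance(model_or_cfg, SwinClassifier)
             else SwinClassifier(model_or_cfg, rng=0))
    return model.num_parameters()


def model_mac_count(cfg: SwinConfig) -> int:
    """Total multiply-accumulates of one forward pass.

    Counts one MAC per multiply-add in every linear projection and attention
    product: patch embedding, per-block attention (the 4hwC² + 2M²hwC
    windowed-attention term), MLPs (2·ratio·hwC²), patch-merging reductions,
    and the classification head.  Normalizations, softmax and activation
    functions are not counted, matching the convention under which the
    default configuration costs 4.5 G.
    """
    total = 0
    r0 = cfg.input_size // cfg.patch_size
    total += r0 * r0 * cfg.embed_dim * (cfg.patch_size ** 2 * cfg.in_channels)
    dims = cfg.stage_dims()
    for s, (dim, res, depth) in enumerate(
            zip(dims, cfg.stage_resolutions(), cfg.depths)):
        m = min(cfg.window_size, res)
        hw = res * res
        attn = complexity_wmsa(res, res, dim, m)
        mlp = int(2 * cfg.mlp_ratio * hw * dim * dim)
        total += depth * (attn + mlp)
        if s < cfg.n_stages() - 1:
            total += (res // 2) ** 2 * (4 * dim) * (2 * dim)
    total += dims[-1] * cfg.num_classes
    return total


def summarize(cfg: SwinConfig) -> ModelSummary:
    return ModelSummary(parameter_count=count_parameters(cfg),
                        mac_count=model_mac_count(cfg))


# ---------------------------------------------------------------------------
# checkpoint I/O
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: SwinClassifier,
                    class_names: list[str] | None = None) -> None:
    """Serialize weights + config + class names into one .npz archive."""
    meta = {
        "format": CHECKPOINT_FORMAT,
        "config": model.cfg.to_dict(),
        "classes": list(class_names) if class_names else None,
    }
    state = {k.replace(".", "/"): v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> tuple[SwinClassifier, list[str] | None]:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        if meta.get("format") != CHECKPOINT_FORMAT:
            raise ValueError(f"unrecognized checkpoint format: {meta.get('format')!r}")
        state = {k.replace("/", "."): archive[k]
                 for k in archive.files if k != "__meta__"}
    cfg = SwinConfig.from_dict(meta["config"])
    model = SwinClassifier(cfg, rng=0)
    model.load_state_dict(state)
    return model, meta["classes"]
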