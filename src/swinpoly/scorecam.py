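"""Gradient-free visual explanation via channel-wise confidence scores.

For a trained classifier f and an input X, each channel A_k of an internal
activation (by default the second normalization layer of the last
transformer block, a 7×7 token map at the default geometry) is upsampled
bilinearly to the input size, min-max normalized into [0, 1],

    H_k = s(Up(A_k)),        s(A) = (A − min A) / (max A − min A),

and used as a mask on the input.  Its contribution toward class c is the
increase of confidence over an all-zero baseline image X_b,

    C(A_k) = f_c(X ∘ H_k) − f_c(X_b),

where f_c is the softmax output for class c.  The saliency map is the
ReLU-rectified combination of the upsampled channels weighted by the
softmax of their scores:

    V = ReLU( Σ_k α_k · Up(A_k) ),      α = softmax_k C(A_k).

Masked forwards run in batches for throughput; the result is identical to
the sequential per-channel loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

from .model import SwinClassifier

__all__ = ["ActivationStack", "SaliencyMap", "DEFAULT_LAYER",
           "extract_activations", "normalize_map", "upsample_bilinear",
           "channel_scores", "scorecam_map", "overlay_heatmap"]

#: "last" resolves to the second norm layer of the final transformer block.
DEFAULT_LAYER = "last"

#: masked forwards per model call
BATCH_CHUNK = 32


@dataclass
class ActivationStack:
    """K spatial channel maps (K, h, w) extracted at `layer`."""

    maps: np.ndarray
    layer: str

    @property
    def n_channels(self) -> int:
        return self.maps.shape[0]


@dataclass
class SaliencyMap:
    """Non-negative confidence-score map at input resolution, plus the
    per-channel weights and the class it explains."""

    values: np.ndarray
    class_index: int
    channel_weights: np.ndarray


def _resolve_layer(model: SwinClassifier, layer: str) -> str:
    names = model.activation_layer_names()
    if layer == DEFAULT_LAYER:
        return names[-1]  # last block's norm2
    if layer not in names:
        raise ValueError(
            f"unknown activation layer {layer!r}; valid layers: "
            f"{names + [DEFAULT_LAYER]}")
    return layer


def extract_activations(model: SwinClassifier, image: np.ndarray,
                        layer: str = DEFAULT_LAYER) -> ActivationStack:
    """Token activations at `layer`, reshaped to (K, h, w) spatial maps."""
    name = _resolve_layer(model, layer)
    image = np.asarray(image, dtype=np.float32)
    capture: dict = {}
    model(image[None], capture=capture)
    act = capture[name][0]  # (h, w, K)
    return ActivationStack(maps=np.ascontiguousarray(act.transpose(2, 0, 1)),
                           layer=name)


def normalize_map(a: np.ndarray) -> np.ndarray:
    """Min-max normalize into [0, 1]; a constant map maps to all zeros
    (a featureless channel should contribute no mask)."""
    a = np.asarray(a, dtype=np.float32)
    lo, hi = a.min(), a.max()
    if hi == lo:
        return np.zeros_like(a)
    return (a - lo) / (hi - lo)


def upsample_bilinear(a: np.ndarray, size: int) -> np.ndarray:
    """Bilinear upsampling of a 2-D map to size×size."""
    return np.asarray(Image.fromarray(np.asarray(a, dtype=np.float32), mode="F")
                      .resize((size, size), Image.BILINEAR))


def channel_scores(model: SwinClassifier, image: np.ndarray,
                   stack: ActivationStack, class_index: int,
                   baseline: np.ndarray | None = None,
                   chunk: int = BATCH_CHUNK) -> np.ndarray:
    """Increase-of-confidence C(A_k) = f_c(X∘H_k) − f_c(X_b) per channel.

    The baseline X_b defaults to the all-zero image.  Masked inputs are
    forwarded in chunks; chunk=1 reproduces the sequential loop exactly.
    """
    image = np.asarray(image, dtype=np.float32)
    size = image.shape[0]
    if baseline is None:
        baseline = np.zeros_like(image)
    masks = np.stack([normalize_map(upsample_bilinear(a, size))
                      for a in stack.maps])  # (K, H, W)
    masked = image[None] * masks[..., None]
    f_baseline = model.predict_proba(baseline[None])[0, class_index]
    scores = np.empty(stack.n_channels, dtype=np.float64)
    for start in range(0, stack.n_channels, max(1, chunk)):
        probs = model.predict_proba(masked[start:start + max(1, chunk)])
        scores[start:start + max(1, chunk)] = probs[:, class_index]
    return scores - f_baseline


def scorecam_map(model: SwinClassifier, image: np.ndarray,
                 class_index: int | None = None,
                 layer: str = DEFAULT_LAYER,
                 chunk: int = BATCH_CHUNK,
                 stack: ActivationStack | None = None) -> SaliencyMap:
    """The full confidence-score saliency map at input resolution.

    When `class_index` is None the predicted (argmax) class is explained.
    A precomputed :class:`ActivationStack` may be passed to reuse (or
    substitute) extracted activations.
    """
    image = np.asarray(image, dtype=np.float32)
    if class_index is None:
        class_index = int(np.argmax(model.predict_proba(image[None])[0]))
    if stack is None:
        stack = extract_activations(model, image, layer)
    scores = channel_scores(model, image, stack, class_index, chunk=chunk)
    z = scores - scores.max()
    alpha = np.exp(z) / np.exp(z).sum()
    size = image.shape[0]
    up = np.stack([upsample_bilinear(a, size) for a in stack.maps])
    v = np.maximum((alpha[:, None, None] * up).sum(axis=0), 0.0)
    return SaliencyMap(values=v.astype(np.float32), class_index=class_index,
                       channel_weights=alpha)


def overlay_heatmap(image: np.ndarray, saliency: np.ndarray,
                    alpha: float = 0.5, colormap: str = "jet") -> np.ndarray:
    """Alpha-blend the colormapped saliency onto the grayscale input.

    `saliency` must be normalized to [0, 1] and share the image's spatial
    shape.  Returns a uint8 RGB array; deterministic for fixed inputs.
    """
    import matplotlib
    image = np.asarray(image, dtype=np.float32)
    if image.ndim == 3:
        image = image[..., 0]
    saliency = np.asarray(saliency, dtype=np.float32)
    if saliency.shape != image.shape:
        raise ValueError(
            f"saliency shape {saliency.shape} does not match image "
            f"{image.shape}")
    cmap = matplotlib.colormaps[colormap]
    heat = cmap(np.clip(saliency, 0.0, 1.0))[..., :3]
    gray = np.repeat(image[..., None], 3, axis=2)
    blend = (1.0 - alpha) * gray + alpha * heat
    return (np.clip(blend, 0.0, 1.0) * 255).round().astype(np.uint8)
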