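"""Signed per-pixel attributions of the activation map w.r.t. the head score.

Both methods operate on the intermediate activation map A (C_act, h, w)
through the task head only; the U-Net below is fixed. Positive attribution
supports the protected class (score 1), negative the anthropogenic class
(score 0). No ReLU rectification is applied: the task is a single-target
regression, so negative evidence is as meaningful as positive.

Grad-CAM: channel weights are the spatial means of the score gradient,
``alpha_k = mean_p dYhat/dA_k(p)``; the attribution is ``sum_k alpha_k A_k(p)``.

Occlusion: square windows slide over the activation map; all channels in a
window are set to the tanh-neutral value 0, and the score drop
``delta = yhat(original) - yhat(occluded)`` is averaged per pixel over every
window covering it. Edge windows are clipped at the boundary, so every
pixel is covered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AttributionMap",
    "OcclusionConfig",
    "gradcam_from_activation",
    "occlusion_from_activation",
    "gradcam_attribution",
    "occlusion_attribution",
]


@dataclass
class AttributionMap:
    """(h, w) signed attribution grid with a validity mask and a method tag."""

    values: np.ndarray
    valid_mask: np.ndarray
    method: str = ""

    def __post_init__(self):
        if self.values.shape != self.valid_mask.shape:
            raise ValueError("values and valid_mask shapes differ")
        if not np.all(np.isfinite(self.values[self.valid_mask])):
            raise ValueError("non-finite attribution inside the valid region")

    @property
    def masked_fraction(self) -> float:
        return float(1.0 - self.valid_mask.mean())


@dataclass
class OcclusionConfig:
    l_patch: int = 8
    l_stride: int = 4
    fill: float = 0.0

    def __post_init__(self):
        if not 1 <= self.l_stride <= self.l_patch:
            raise ValueError(
                f"need 1 <= l_stride <= l_patch, got stride {self.l_stride}, "
                f"patch {self.l_patch}"
            )


def _head_gradient(head, a: np.ndarray) -> np.ndarray:
    """d yhat / d A for a batch of activation maps (n, C, h, w)."""
    for p in head.parameters():
        p.zero_grad()
    yhat = head.forward(a, train=False)
    ga = head.backward(np.ones_like(yhat))
    for p in head.parameters():
        p.zero_grad()
    return ga


def gradcam_from_activation(head, a: np.ndarray) -> np.ndarray:
    """Signed Grad-CAM attribution (h, w) of one activation map (C, h, w)."""
    ga = _head_gradient(head, a[None])[0]
    alpha = ga.mean(axis=(1, 2))  # global-average-pooled gradients per channel
    return np.tensordot(alpha, a, axes=(0, 0))


def occlusion_windows(h: int, w: int, config: OcclusionConfig):
    """Enumerate (r0, r1, c0, c1) windows, clipped at the map boundary."""
    l, s = config.l_patch, config.l_stride
    if l > h or l > w:
        raise ValueError(f"patch size {l} exceeds map size ({h}, {w})")
    return [
        (r0, min(r0 + l, h), c0, min(c0 + l, w))
        for r0 in range(0, h, s)
        for c0 in range(0, w, s)
    ]


def occlusion_from_activation(head, a: np.ndarray,
                              config: OcclusionConfig | None = None,
                              batch_size: int = 64) -> np.ndarray:
    """Sliding-window occlusion attribution (h, w) of one map (C, h, w)."""
    config = config or OcclusionConfig()
    c, h, w = a.shape
    windows = occlusion_windows(h, w, config)
    y0 = float(head.forward(a[None], train=False)[0])
    deltas = np.empty(len(windows), dtype=float)
    for start in range(0, len(windows), batch_size):
        chunk = windows[start:start + batch_size]
        batch = np.repeat(a[None], len(chunk), axis=0)
        for j, (r0, r1, c0, c1) in enumerate(chunk):
            batch[j, :, r0:r1, c0:c1] = config.fill
        deltas[start:start + len(chunk)] = y0 - head.forward(batch, train=False)
    acc = np.zeros((h, w), dtype=float)
    cover = np.zeros((h, w), dtype=float)
    for (r0, r1, c0, c1), d in zip(windows, deltas):
        acc[r0:r1, c0:c1] += d
        cover[r0:r1, c0:c1] += 1.0
    return acc / cover


def gradcam_attribution(network, pixels: np.ndarray) -> AttributionMap:
    """Grad-CAM attribution of a normalized (h, w, C_in) sample at the
    training tile size (the head is required)."""
    a = network.forward_activation(
        np.ascontiguousarray(pixels.transpose(2, 0, 1))[None]
    )[0]
    values = gradcam_from_activation(network.head, a)
    return AttributionMap(values, np.ones_like(values, dtype=bool), "gradcam")


def occlusion_attribution(network, pixels: np.ndarray,
                          config: OcclusionConfig | None = None) -> AttributionMap:
    """Occlusion attribution of a normalized (h, w, C_in) sample."""
    a = network.forward_activation(
        np.ascontiguousarray(pixels.transpose(2, 0, 1))[None]
    )[0]
    values = occlusion_from_activation(network.head, a, config)
    return AttributionMap(values, np.ones_like(values, dtype=bool), "occlusion")
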