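"""Harmonized attribution maps for arbitrary-size scenes.

At mapping time the task head is never evaluated: the fully convolutional
image-to-image network predicts the scene's activation map, and each
pixel's activation vector is looked up in the harmonization table. Pixels
whose cubes are density-masked (or unseen in training) are marked invalid.

Scenes of any height/width are handled by reflective padding to the next
multiple of 16 (the encoder's total downsampling factor) with post-hoc
cropping; large scenes can be processed in overlapping blocks whose margin
exceeds the network's receptive-field radius, which makes the blocked pass
agree with the whole-scene pass away from block seams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

from .activation_space import HarmonizationTable, _flat_index, _CLAMP_EPS
from .attribution import AttributionMap
from .nn.network import DOWNSAMPLE_FACTOR, Network
from .pipeline import normalize_tile

__all__ = [
    "SceneResult",
    "predict_activation_blocked",
    "predict_scene_attribution",
    "write_scene_result",
    "read_scene_result",
    "render_scene_result",
    "summarize_attributions",
]

RECEPTIVE_MARGIN = 64  # px; safely exceeds the U-Net receptive-field radius


@dataclass
class SceneResult:
    attribution: AttributionMap
    masked_fraction: float
    provenance: dict = field(default_factory=dict)


def _pad_to_multiple(x: np.ndarray, multiple: int) -> tuple[np.ndarray, tuple[int, int]]:
    h, w = x.shape[1], x.shape[2]
    ph = (-h) % multiple
    pw = (-w) % multiple
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, ph), (0, pw)), mode="reflect")
    return x, (h, w)


def predict_activation_blocked(network: Network, x: np.ndarray,
                               block_size: int = 256,
                               margin: int = RECEPTIVE_MARGIN) -> np.ndarray:
    """Activation map of (C_in, h, w) input, stitched from overlapping
    blocks; h and w must be divisible by 16."""
    c, h, w = x.shape
    if block_size % DOWNSAMPLE_FACTOR or margin % DOWNSAMPLE_FACTOR:
        raise ValueError("block_size and margin must be divisible by 16")
    out = np.empty((network.unet_spec.c_act, h, w), dtype=np.float32)
    for r0 in range(0, h, block_size):
        for c0 in range(0, w, block_size):
            r1 = min(r0 + block_size, h)
            c1 = min(c0 + block_size, w)
            er0, ec0 = max(0, r0 - margin), max(0, c0 - margin)
            er1, ec1 = min(h, r1 + margin), min(w, c1 + margin)
            block = x[:, er0:er1, ec0:ec1]
            padded, (bh, bw) = _pad_to_multiple(block, DOWNSAMPLE_FACTOR)
            a = network.forward_activation(padded[None])[0][:, :bh, :bw]
            out[:, r0:r1, c0:c1] = a[:, r0 - er0:r1 - er0, c0 - ec0:c1 - ec0]
    return out


def predict_scene_attribution(network: Network, table: HarmonizationTable,
                              scene: np.ndarray, normalized: bool = False,
                              block_size: int | None = None,
                              edge_margin: int = 0,
                              provenance: dict | None = None) -> SceneResult:
    """Map a (h, w, C_in) scene of any size to a harmonized attribution map.

    ``normalized=False`` treats the scene as integer reflectances in
    [0, 10000]; pass True for grids already scaled to [0, 1].
    """
    scene = np.asarray(scene)
    if scene.ndim != 3 or scene.shape[2] != network.unet_spec.c_in:
        raise ValueError(
            f"scene must be (h, w, {network.unet_spec.c_in}), got {scene.shape}"
        )
    if table.c_act != network.unet_spec.c_act:
        raise ValueError(
            f"table was built for C_act={table.c_act}, network has "
            f"C_act={network.unet_spec.c_act}"
        )
    pixels = scene.astype(np.float32) if normalized else normalize_tile(scene).astype(np.float32)
    x = np.ascontiguousarray(pixels.transpose(2, 0, 1))
    xp, (h, w) = _pad_to_multiple(x, DOWNSAMPLE_FACTOR)
    if block_size is None:
        a = network.forward_activation(xp[None])[0]
    else:
        a = predict_activation_blocked(network, xp, block_size)
    a = a[:, :h, :w]
    vec = np.clip(a.reshape(a.shape[0], -1).T.astype(float),
                  -1.0 + _CLAMP_EPS, 1.0 - _CLAMP_EPS)
    flat = _flat_index(vec, table.l_h, int(round(2.0 / table.l_h)))
    vals, valid = table.lookup(flat)
    values = vals.reshape(h, w)
    mask = valid.reshape(h, w)
    if edge_margin > 0:
        m = edge_margin
        border = np.zeros((h, w), dtype=bool)
        border[m:h - m, m:w - m] = True
        mask = mask & border
        values = np.where(mask, values, np.nan)
    return SceneResult(
        attribution=AttributionMap(values, mask, method=table.method),
        masked_fraction=float(1.0 - mask.mean()),
        provenance={**(provenance or {}),
                    "l_h": table.l_h,
                    "threshold_factor": table.threshold_factor},
    )


def write_scene_result(result: SceneResult, path) -> None:
    """Two-band float TIFF: attribution (NaN no-data at masked pixels) and
    validity mask; provenance in the description tag."""
    att = result.attribution
    stack = np.stack([
        np.where(att.valid_mask, att.values, np.nan).astype(np.float32),
        att.valid_mask.astype(np.float32),
    ])
    tifffile.imwrite(
        str(path), stack, photometric="minisblack",
        description=json.dumps({"method": att.method,
                                "masked_fraction": result.masked_fraction,
                                "provenance": result.provenance}),
    )


def read_scene_result(path) -> SceneResult:
    with tifffile.TiffFile(str(path)) as tf:
        stack = tf.asarray()
        desc = tf.pages[0].description or "{}"
    meta = json.loads(desc)
    mask = stack[1].astype(bool)
    return SceneResult(
        attribution=AttributionMap(stack[0].astype(float), mask,
                                   method=meta.get("method", "")),
        masked_fraction=float(meta.get("masked_fraction", 1.0 - mask.mean())),
        provenance=meta.get("provenance", {}),
    )


def render_scene_result(result: SceneResult, path, vmax: float | None = None) -> None:
    """PNG rendering: purple-green diverging scale, masked pixels gray."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    att = result.attribution
    valid = att.valid_mask
    if vmax is None:
        vmax = float(np.nanmax(np.abs(att.values[valid]))) if valid.any() else 1.0
        vmax = vmax or 1.0
    cmap = plt.get_cmap("PRGn").copy()
    cmap.set_bad(color="0.6")
    data = np.ma.masked_where(~valid, att.values)
    fig, ax = plt.subplots(figsize=(6, 6))
    im = ax.imshow(data, cmap=cmap, vmin=-vmax, vmax=vmax)
    ax.set_axis_off()
    fig.colorbar(im, ax=ax, shrink=0.8, label="harmonized attribution")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def _stats(values: np.ndarray, bins: int) -> dict:
    if values.size == 0:
        return {"empty": True, "n_valid": 0}
    counts, edges = np.histogram(values, bins=bins)
    return {
        "empty": False,
        "n_valid": int(values.size),
        "mean": float(values.mean()),
        "std": float(values.std()),
        "frac_positive": float(np.mean(values > 0)),
        "frac_negative": float(np.mean(values < 0)),
        "histogram": {"counts": counts.tolist(), "edges": edges.tolist()},
    }


def summarize_attributions(results, grouping_mask: np.ndarray | None = None,
                           bins: int = 32) -> dict:
    """Distribution summary over valid pixels of one or more scene results.

    With a ``grouping_mask`` (integer raster aligned with a single scene),
    per-group statistics are reported as well.
    """
    if isinstance(results, SceneResult):
        results = [results]
    all_vals = [r.attribution.values[r.attribution.valid_mask] for r in results]
    summary = {
        "overall": _stats(np.concatenate(all_vals) if all_vals else np.empty(0), bins),
        "per_scene": [_stats(v, bins) for v in all_vals],
    }
    if grouping_mask is not None:
        if len(results) != 1:
            raise ValueError("grouping_mask applies to a single scene result")
        att = results[0].attribution
        if grouping_mask.shape != att.values.shape:
            raise ValueError("grouping_mask shape mismatch")
        groups = {}
        for g in np.unique(grouping_mask):
            sel = (grouping_mask == g) & att.valid_mask
            groups[int(g)] = _stats(att.values[sel], bins)
        summary["per_group"] = groups
    return summary
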