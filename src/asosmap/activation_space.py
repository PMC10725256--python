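"""Activation space, hypercube harmonization, density masking, and ASOS.

Every pixel of every training activation map is a point in the open cube
(-1, 1)^C_act (tanh range). The space is tiled into (2/l_h)^C_act half-open
hypercubes of side l_h. Harmonization replaces per-image attributions with
a per-cube statistic computed in two stages: first the mean attribution of
the cube's pixels within each image, then the unweighted mean of those
per-image means — so an image contributing thousands of pixels to a cube
counts no more than an image contributing one.

ASOS (activation space occlusion sensitivity) defines the occluded set not
as a spatial patch but as all pixels of an image whose activations fall in
one hypercube: only similar features are switched off together. The score
drop ``delta = yhat(original) - yhat(occluded)`` is averaged, unweighted,
over the images that touch the cube.

Density masking withholds predictions for cubes whose training occupancy
falls below a factor (default 0.5) of the average occupancy over occupied
cubes; such activations are too rare in training for the statistic to be
trusted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "ActivationSpace",
    "HarmonizationTable",
    "cube_index",
    "cube_count",
    "build_space",
    "harmonize_attributions",
    "compute_density_mask",
    "asos_sensitivities",
    "save_table",
    "load_table",
    "export_scatter_csv",
]

_MAX_DENSE_CUBES = 20_000_000  # dense-array guard for high C_act / tiny l_h
_CLAMP_EPS = 1e-6


def _cubes_per_dim(l_h: float) -> int:
    n = 2.0 / l_h
    if abs(n - round(n)) > 1e-9:
        nearest = 2.0 / round(n) if round(n) >= 1 else 2.0
        raise ValueError(
            f"2/l_h must be an integer; l_h={l_h} gives {n:.6g} bins per axis "
            f"(nearest valid l_h: {nearest:.6g})"
        )
    return int(round(n))


def cube_count(l_h: float, c_act: int) -> int:
    """Number of addressable hypercubes, (2/l_h)**C_act."""
    return _cubes_per_dim(l_h) ** c_act


def cube_index(v: np.ndarray, l_h: float) -> np.ndarray:
    """Component-wise half-open bin index floor((v + 1) / l_h).

    ``v`` has shape (..., C_act) with every component strictly inside
    (-1, 1); returns integer indices of the same leading shape.
    """
    v = np.asarray(v, dtype=float)
    if np.any(v <= -1.0) or np.any(v >= 1.0):
        raise ValueError("activation components must lie strictly inside (-1, 1)")
    n = _cubes_per_dim(l_h)
    idx = np.floor((v + 1.0) / l_h).astype(np.int64)
    return np.clip(idx, 0, n - 1)


def _flat_index(v: np.ndarray, l_h: float, n: int) -> np.ndarray:
    """Raveled cube index for (..., C_act) activation vectors."""
    idx = cube_index(v, l_h)
    flat = idx[..., 0]
    for d in range(1, idx.shape[-1]):
        flat = flat * n + idx[..., d]
    return flat


@dataclass
class ActivationSpace:
    """Streaming per-cube occupancy over the training activation maps."""

    l_h: float
    c_act: int
    density: np.ndarray = field(repr=False, default=None)
    image_indices: list = field(default_factory=list, repr=False)
    image_shapes: list = field(default_factory=list)
    n_images: int = 0
    n_clamped: int = 0

    def __post_init__(self):
        self.n_per_dim = _cubes_per_dim(self.l_h)
        n_cubes = self.n_per_dim ** self.c_act
        if n_cubes > _MAX_DENSE_CUBES:
            raise ValueError(
                f"{n_cubes} hypercubes exceed the dense-table limit; "
                "increase l_h or reduce C_act"
            )
        if self.density is None:
            self.density = np.zeros(n_cubes, dtype=np.int64)

    @property
    def n_cubes(self) -> int:
        return self.n_per_dim ** self.c_act

    def add_map(self, activation_map: np.ndarray, keep_indices: bool = True) -> np.ndarray:
        """Accumulate one (C_act, h, w) activation map; returns its flat
        cube indices (h*w,). Numerically out-of-range activations are
        clamped into the open interval and counted."""
        c, h, w = activation_map.shape
        if c != self.c_act:
            raise ValueError(f"expected {self.c_act} channels, got {c}")
        vec = activation_map.reshape(c, -1).T.astype(float)
        out = np.abs(vec) >= 1.0
        if out.any():
            self.n_clamped += int(out.sum())
            vec = np.clip(vec, -1.0 + _CLAMP_EPS, 1.0 - _CLAMP_EPS)
        flat = _flat_index(vec, self.l_h, self.n_per_dim)
        self.density += np.bincount(flat, minlength=self.n_cubes)
        if keep_indices:
            self.image_indices.append(flat.astype(np.int32))
            self.image_shapes.append((h, w))
        self.n_images += 1
        return flat

    @property
    def occupied(self) -> np.ndarray:
        return self.density > 0

    def total_density(self) -> int:
        return int(self.density.sum())


@dataclass
class HarmonizationTable:
    """Per-hypercube harmonized attribution, occupancy, and mask metadata."""

    l_h: float
    c_act: int
    values: np.ndarray          # flat, NaN where no image touches the cube
    density: np.ndarray         # flat int64 occupancy counts
    n_images_per_cube: np.ndarray
    threshold_factor: float = 0.5
    method: str = ""
    provenance: dict = field(default_factory=dict)

    @property
    def occupied(self) -> np.ndarray:
        return self.density > 0

    @property
    def kept(self) -> np.ndarray:
        return compute_density_mask(self, self.threshold_factor)

    def lookup(self, flat_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(values, valid) for raveled cube indices; masked cubes -> NaN."""
        kept = self.kept
        valid = kept[flat_idx]
        vals = np.where(valid, self.values[flat_idx], np.nan)
        return vals, valid


def build_space(network, samples, l_h: float = 0.1, keep_indices: bool = True,
                batch_size: int = 16) -> ActivationSpace:
    """Predict activation maps for normalized (h, w, C_in) samples and
    accumulate the occupancy of the activation space."""
    space = ActivationSpace(l_h=l_h, c_act=network.unet_spec.c_act)
    samples = list(samples)
    for start in range(0, len(samples), batch_size):
        chunk = np.stack([
            np.ascontiguousarray(np.asarray(s).transpose(2, 0, 1))
            for s in samples[start:start + batch_size]
        ])
        maps = network.forward_activation(chunk)
        for m in maps:
            space.add_map(m, keep_indices=keep_indices)
    return space


def harmonize_attributions(space: ActivationSpace, attribution_maps,
                           method: str = "", threshold_factor: float = 0.5,
                           provenance: dict | None = None) -> HarmonizationTable:
    """Two-stage mean: per-image cube means first, then the unweighted mean
    of those means over all images touching the cube."""
    if not space.image_indices:
        raise ValueError("space was built without per-image indices")
    attribution_maps = list(attribution_maps)
    if len(attribution_maps) != len(space.image_indices):
        raise ValueError(
            f"{len(attribution_maps)} attribution maps for "
            f"{len(space.image_indices)} activation maps"
        )
    n_cubes = space.n_cubes
    sum_means = np.zeros(n_cubes, dtype=float)
    n_images = np.zeros(n_cubes, dtype=np.int64)
    for flat, attr, shape in zip(space.image_indices, attribution_maps,
                                 space.image_shapes):
        attr = np.asarray(attr, dtype=float)
        if attr.shape != shape:
            raise ValueError(
                f"attribution shape {attr.shape} misaligned with activation "
                f"map shape {shape}"
            )
        counts = np.bincount(flat, minlength=n_cubes)
        sums = np.bincount(flat, weights=attr.ravel(), minlength=n_cubes)
        touched = counts > 0
        sum_means[touched] += sums[touched] / counts[touched]
        n_images[touched] += 1
    values = np.full(n_cubes, np.nan)
    seen = n_images > 0
    values[seen] = sum_means[seen] / n_images[seen]
    return HarmonizationTable(
        l_h=space.l_h, c_act=space.c_act, values=values,
        density=space.density.copy(), n_images_per_cube=n_images,
        threshold_factor=threshold_factor, method=method,
        provenance=provenance or {},
    )


def compute_density_mask(table: HarmonizationTable, threshold_factor: float = 0.5
                         ) -> np.ndarray:
    """Boolean keep-mask over all cubes. Average density is taken over
    occupied cubes only; cubes below ``threshold_factor * average`` (and all
    unoccupied cubes) are masked."""
    occupied = table.occupied
    if not occupied.any():
        raise ValueError("table has no occupied cubes")
    average = table.density.sum() / occupied.sum()
    return occupied & (table.density >= threshold_factor * average)


def asos_sensitivities(network, samples, space: ActivationSpace,
                       threshold_factor: float = 0.5,
                       provenance: dict | None = None) -> HarmonizationTable:
    """Occlude one hypercube at a time: for each image, all pixels whose
    activations fall in the cube are zeroed (all channels) and the score
    drop is recorded; the table value is the unweighted mean drop over the
    images touching the cube."""
    if not space.image_indices:
        raise ValueError("space was built without per-image indices")
    samples = list(samples)
    if len(samples) != len(space.image_indices):
        raise ValueError("sample count does not match the space")
    n_cubes = space.n_cubes
    sum_delta = np.zeros(n_cubes, dtype=float)
    n_images = np.zeros(n_cubes, dtype=np.int64)
    for pixels, flat, shape in zip(samples, space.image_indices,
                                   space.image_shapes):
        x = np.ascontiguousarray(np.asarray(pixels).transpose(2, 0, 1))[None]
        a = network.forward_activation(x)[0]
        h, w = shape
        y0 = float(network.forward_score(a[None])[0])
        cubes_here = np.unique(flat)
        order = np.argsort(flat, kind="stable")
        bounds = np.searchsorted(flat[order], cubes_here)
        bounds = np.append(bounds, len(flat))
        deltas = np.empty(len(cubes_here))
        batch = 32
        for start in range(0, len(cubes_here), batch):
            sel = range(start, min(start + batch, len(cubes_here)))
            occ = np.repeat(a[None], len(sel), axis=0)
            for j, ci in enumerate(sel):
                pix = order[bounds[ci]:bounds[ci + 1]]
                occ[j].reshape(space.c_act, -1)[:, pix] = 0.0
            deltas[list(sel)] = y0 - network.forward_score(occ)
        sum_delta[cubes_here] += deltas
        n_images[cubes_here] += 1
    values = np.full(n_cubes, np.nan)
    seen = n_images > 0
    values[seen] = sum_delta[seen] / n_images[seen]
    return HarmonizationTable(
        l_h=space.l_h, c_act=space.c_act, values=values,
        density=space.density.copy(), n_images_per_cube=n_images,
        threshold_factor=threshold_factor, method="asos",
        provenance=provenance or {},
    )


def save_table(table: HarmonizationTable, path) -> None:
    """Compressed hierarchical archive + embedded JSON sidecar attributes."""
    with h5py.File(path, "w") as f:
        occ = np.flatnonzero(~np.isnan(table.values))
        f.create_dataset("cube_flat_index", data=occ, compression="gzip")
        f.create_dataset("values", data=table.values[occ], compression="gzip")
        f.create_dataset("density", data=table.density, compression="gzip")
        f.create_dataset("n_images_per_cube", data=table.n_images_per_cube[occ],
                         compression="gzip")
        f.attrs["l_h"] = table.l_h
        f.attrs["c_act"] = table.c_act
        f.attrs["threshold_factor"] = table.threshold_factor
        f.attrs["method"] = table.method
        f.attrs["provenance"] = json.dumps(table.provenance)


def load_table(path) -> HarmonizationTable:
    with h5py.File(path, "r") as f:
        l_h = float(f.attrs["l_h"])
        c_act = int(f.attrs["c_act"])
        n_cubes = cube_count(l_h, c_act)
        values = np.full(n_cubes, np.nan)
        n_images = np.zeros(n_cubes, dtype=np.int64)
        occ = f["cube_flat_index"][:]
        values[occ] = f["values"][:]
        n_images[occ] = f["n_images_per_cube"][:]
        return HarmonizationTable(
            l_h=l_h, c_act=c_act, values=values, density=f["density"][:],
            n_images_per_cube=n_images,
            threshold_factor=float(f.attrs["threshold_factor"]),
            method=str(f.attrs["method"]),
            provenance=json.loads(str(f.attrs["provenance"])),
        )


def export_scatter_csv(activation_maps, attribution_maps, path,
                       rate: float = 1e-4, seed: int = 0) -> int:
    """Sampled (activation vector, attribution) scatter export for plotting.

    Streams (C_act, h, w) activation maps and aligned (h, w) attribution
    maps, keeping each pixel with probability ``rate``; returns the number
    of rows written."""
    rng = np.random.default_rng(seed)
    n_written = 0
    with open(path, "w") as f:
        header_done = False
        for a, attr in zip(activation_maps, attribution_maps):
            c = a.shape[0]
            if not header_done:
                f.write(",".join(f"act_{k}" for k in range(c)) + ",attribution\n")
                header_done = True
            vec = a.reshape(c, -1).T
            attr = np.asarray(attr).ravel()
            keep = rng.random(len(vec)) < rate
            for row, val in zip(vec[keep], attr[keep]):
                f.write(",".join(f"{x:.6f}" for x in row) + f",{val:.6g}\n")
            n_written += int(keep.sum())
    return n_written
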