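"""Synthetic multispectral landscape tiles with class-specific textures.

Emulates the statistical structure of a Sentinel-2-style protected /
anthropogenic tile dataset so the whole pipeline can be exercised without
any downloads:

* anthropogenic tiles (label 0): piecewise-constant field polygons with
  sharp boundaries, thin linear roads, and compact bright settlement blobs;
* protected tiles (label 1): spatially correlated smooth random fields with
  low-frequency wetland/bare patches.

Both classes share the same per-band global means (enforced exactly before
quantization), so the classes are separable only by spatial texture, never
by a per-pixel brightness threshold. Values are integer reflectances in
[0, 10000] over 10 bands by default.

Tile coordinates are planar kilometres arranged in well-separated clusters,
mirroring the spatial clustering that drives the blocked data split.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree
from skimage.draw import line as draw_line

__all__ = [
    "SceneConfig",
    "MultispectralTile",
    "generate_tile",
    "generate_catalog",
    "write_tile",
    "read_tile",
    "load_catalog_tiles",
]

# Default per-band reflectance means, loosely shaped like boreal summer
# spectra over the 10 exported bands (visible low, NIR/red-edge high).
_DEFAULT_BAND_MEANS = np.array(
    [600.0, 900.0, 800.0, 1200.0, 2200.0, 2600.0, 2800.0, 2900.0, 2000.0, 1100.0]
)
_DEFAULT_BAND_SCALES = np.array(
    [150.0, 200.0, 220.0, 260.0, 450.0, 500.0, 520.0, 530.0, 420.0, 300.0]
)


@dataclass
class SceneConfig:
    """Parameters of the synthetic tile generator."""

    tile_size: int = 256
    n_bands: int = 10
    value_range: tuple[int, int] = (0, 10000)
    band_means: np.ndarray | None = None
    band_scales: np.ndarray | None = None
    # anthropogenic texture
    field_size: float = 28.0        # px, typical polygon diameter
    road_density: float = 1.2       # expected roads per 256 px tile edge
    settlement_density: float = 2.0  # expected settlement blobs per 256 px tile
    pixel_noise: float = 0.35       # per-pixel noise, units of band scale
    # protected texture
    correlation_length: float = 10.0  # px, Gaussian smoothing sigma
    patch_density: float = 1.5        # expected wetland/bare patches per tile
    smooth_noise: float = 1.0         # amplitude of the correlated field
    seed: int = 0

    def __post_init__(self):
        if self.tile_size < 32 or self.tile_size % 16:
            raise ValueError(
                f"tile_size must be >= 32 and divisible by 16, got {self.tile_size}"
            )
        if self.n_bands < 1:
            raise ValueError("n_bands must be >= 1")
        lo, hi = self.value_range
        if not lo < hi:
            raise ValueError(f"value_range bounds must be ordered, got {self.value_range}")

    def means_scales(self) -> tuple[np.ndarray, np.ndarray]:
        if self.band_means is not None:
            means = np.asarray(self.band_means, dtype=float)
        else:
            means = np.resize(_DEFAULT_BAND_MEANS, self.n_bands)
        if self.band_scales is not None:
            scales = np.asarray(self.band_scales, dtype=float)
        else:
            scales = np.resize(_DEFAULT_BAND_SCALES, self.n_bands)
        if means.shape != (self.n_bands,) or scales.shape != (self.n_bands,):
            raise ValueError("band_means/band_scales must have length n_bands")
        return means, scales


@dataclass
class MultispectralTile:
    """An (h, w, C_in) integer reflectance grid with image-level metadata."""

    pixels: np.ndarray
    label: int
    coords: tuple[float, float] = (0.0, 0.0)  # planar x, y in km
    id: str = ""

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 (anthropogenic) or 1 (protected), got {self.label}")


def _correlated_fields(rng, n_latent, size, sigma):
    """Unit-variance smooth Gaussian random fields, (n_latent, size, size)."""
    fields = np.empty((n_latent, size, size))
    for i in range(n_latent):
        f = gaussian_filter(rng.standard_normal((size, size)), sigma, mode="reflect")
        fields[i] = f / (f.std() + 1e-12)
    return fields


def _anthropogenic_texture(rng, cfg: SceneConfig) -> np.ndarray:
    """Dimensionless multi-band texture (C, h, w) in band-scale units."""
    size, nb = cfg.tile_size, cfg.n_bands
    area_factor = (size / 256.0) ** 2

    # Voronoi field polygons with per-field correlated offsets
    n_seeds = max(4, int((size / cfg.field_size) ** 2))
    seeds = rng.uniform(0, size, size=(n_seeds, 2))
    yy, xx = np.mgrid[0:size, 0:size]
    _, owner = cKDTree(seeds).query(np.column_stack([yy.ravel(), xx.ravel()]))
    owner = owner.reshape(size, size)
    shared = rng.normal(0, 1.0, n_seeds)          # cross-band field brightness
    loadings = rng.normal(1.0, 0.25, nb)
    tex = shared[owner][None, :, :] * loadings[:, None, None]
    tex += rng.normal(0, 0.3, (nb, n_seeds))[:, owner]  # band-specific detail

    # linear roads: thin, locally bright in all bands
    n_roads = rng.poisson(cfg.road_density * size / 256.0 * 2)
    for _ in range(n_roads):
        if rng.random() < 0.5:
            r0, r1 = rng.integers(0, size, 2)
            c0, c1 = 0, size - 1
        else:
            c0, c1 = rng.integers(0, size, 2)
            r0, r1 = 0, size - 1
        rr, cc = draw_line(int(r0), int(c0), int(r1), int(c1))
        tex[:, rr, cc] += 2.5
    # compact bright settlement blobs
    n_set = rng.poisson(cfg.settlement_density * area_factor)
    for _ in range(n_set):
        h = int(rng.integers(3, 9))
        w = int(rng.integers(3, 9))
        r = int(rng.integers(0, max(1, size - h)))
        c = int(rng.integers(0, max(1, size - w)))
        tex[:, r:r + h, c:c + w] += rng.uniform(2.0, 4.0)

    tex += rng.normal(0, cfg.pixel_noise, (nb, size, size))
    return tex


def _protected_texture(rng, cfg: SceneConfig) -> np.ndarray:
    size, nb = cfg.tile_size, cfg.n_bands
    latents = _correlated_fields(rng, 3, size, cfg.correlation_length)
    loadings = rng.normal(0, 1.0, (nb, 3))
    loadings[:, 0] = 1.0  # dominant shared component keeps bands correlated
    tex = cfg.smooth_noise * np.tensordot(loadings, latents, axes=(1, 0))

    # low-frequency wetland / bare patches: threshold an extra-smooth field
    n_patches = rng.poisson(cfg.patch_density * (size / 256.0) ** 2)
    if n_patches > 0:
        patch_field = _correlated_fields(rng, 1, size, 2.5 * cfg.correlation_length)[0]
        q = np.quantile(patch_field, min(0.95, 1.0 - 0.08 * n_patches))
        mask = patch_field > q
        shift = rng.normal(0, 1.5, nb)
        tex += mask[None, :, :] * shift[:, None, None]

    tex += rng.normal(0, 0.05, (nb, size, size))  # faint sensor noise
    return tex


def generate_tile(config: SceneConfig, label: int, seed: int | None = None,
                  coords: tuple[float, float] = (0.0, 0.0),
                  tile_id: str = "") -> MultispectralTile:
    """Generate one labeled synthetic tile; identical (config, seed) inputs
    produce bit-identical tiles."""
    if label not in (0, 1):
        raise ValueError(f"label must be 0 (anthropogenic) or 1 (protected), got {label}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    means, scales = config.means_scales()
    if label == 0:
        tex = _anthropogenic_texture(rng, config)
    else:
        tex = _protected_texture(rng, config)
    pixels = means[:, None, None] + scales[:, None, None] * tex
    # equalize per-band global means exactly so classes differ only in texture
    pixels += (means - pixels.mean(axis=(1, 2)))[:, None, None]
    lo, hi = config.value_range
    pixels = np.clip(np.rint(pixels), lo, hi).astype(np.int32)
    return MultispectralTile(
        pixels=pixels.transpose(1, 2, 0), label=label, coords=coords, id=tile_id
    )


def generate_catalog(config: SceneConfig, n_per_class: int,
                     cluster_spec: tuple[int, float, float] = (4, 2.0, 50.0),
                     seed: int = 0, out_dir: str | Path | None = None,
                     ) -> tuple[pd.DataFrame, list[MultispectralTile]]:
    """Generate a balanced, cluster-structured tile catalog.

    ``cluster_spec`` is (n_clusters, spread_km, inter_cluster_distance_km).
    Clusters are single-class, laid out on a grid ``separation`` km apart.
    Returns (catalog dataframe, tiles); tiles are also written to ``out_dir``
    as multiband TIFFs when it is given.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    n_clusters, spread, separation = cluster_spec
    if separation <= 10.0:
        warnings.warn(
            f"inter-cluster distance {separation} km is not larger than the "
            "10 km split threshold; the split clustering will merge clusters",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    side = int(np.ceil(np.sqrt(n_clusters)))
    centers = [(separation * (i % side), separation * (i // side))
               for i in range(n_clusters)]
    cluster_class = [i % 2 for i in range(n_clusters)]  # alternate classes

    records, tiles = [], []
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    counters = {0: 0, 1: 0}
    per_class_clusters = {
        lab: [i for i in range(n_clusters) if cluster_class[i] == lab] or [0]
        for lab in (0, 1)
    }
    for lab in (0, 1):
        for j in range(n_per_class):
            cl = per_class_clusters[lab][j % len(per_class_clusters[lab])]
            cx, cy = centers[cl]
            x = cx + rng.normal(0, spread)
            y = cy + rng.normal(0, spread)
            tile_id = f"{'anthropogenic' if lab == 0 else 'protected'}_{counters[lab]:05d}"
            counters[lab] += 1
            tile_seed = int(rng.integers(0, 2 ** 31 - 1))
            tile = generate_tile(config, lab, seed=tile_seed, coords=(x, y),
                                 tile_id=tile_id)
            path = ""
            if out_dir is not None:
                path = str(out_dir / f"{tile_id}.tif")
                write_tile(tile, path)
            records.append({
                "id": tile_id, "path": path, "label": lab,
                "category": "anthropogenic" if lab == 0 else "protected",
                "x_km": x, "y_km": y, "split": "",
            })
            tiles.append(tile)
    catalog = pd.DataFrame.from_records(records)
    if catalog["id"].duplicated().any():
        raise ValueError("catalog ids must be unique")
    if out_dir is not None:
        catalog.to_csv(out_dir / "catalog.csv", index=False)
    return catalog, tiles


def write_tile(tile: MultispectralTile, path: str | Path) -> None:
    """Write a multiband integer TIFF; metadata (label, coords, id) goes into
    the image description tag. Round-trips losslessly."""
    pixels = tile.pixels
    if pixels.ndim != 3:
        raise ValueError("tile pixels must be (h, w, C)")
    meta = {"label": int(tile.label), "coords": list(tile.coords), "id": tile.id,
            "grid": "local metric, km"}
    tifffile.imwrite(
        str(path),
        pixels.transpose(2, 0, 1).astype(np.int32),
        photometric="minisblack",
        description=json.dumps(meta),
    )


def read_tile(path: str | Path, expect_bands: int | None = None) -> MultispectralTile:
    with tifffile.TiffFile(str(path)) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].description or "{}"
    if arr.ndim == 2:
        arr = arr[None]
    if expect_bands is not None and arr.shape[0] != expect_bands:
        raise ValueError(
            f"band-count mismatch: file {path} has {arr.shape[0]} bands, "
            f"expected {expect_bands}"
        )
    try:
        meta = json.loads(desc)
    except json.JSONDecodeError:
        meta = {}
    return MultispectralTile(
        pixels=arr.transpose(1, 2, 0),
        label=int(meta.get("label", 0)),
        coords=tuple(meta.get("coords", (0.0, 0.0))),
        id=str(meta.get("id", "")),
    )


def load_catalog_tiles(catalog: pd.DataFrame, expect_bands: int | None = None
                       ) -> list[MultispectralTile]:
    """Read all tiles referenced by a catalog dataframe."""
    return [read_tile(row.path, expect_bands=expect_bands)
            for row in catalog.itertuples()]
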