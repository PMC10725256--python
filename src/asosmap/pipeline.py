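"""Data pipeline: normalization, augmentation, CutMix regression labeling,
and spatially blocked train/val/test splitting.

CutMix here is not an augmentation trick but the labeling device that turns
binary image labels into continuous regression targets: a full-height or
full-width stripe from a donor tile replaces one edge of a base tile, and
the target becomes the pixel-area-weighted mixture of the two labels,
``y = (1 - f') * y_base + f' * y_donor`` with ``f'`` the realized stripe
area fraction. Equal-label pairs are fixed points (y stays 0 or 1).

The split is blocked by spatial clusters so nearby tiles never straddle
train/val/test: tiles closer than a distance threshold chain into one
cluster (DBSCAN with min_samples=1, i.e. single-linkage semantics),
oversized clusters are re-partitioned with k-means, and whole clusters are
assigned to splits per category, greedily, to approach the 80/10/10
fractions; very small clusters always go to train.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN, KMeans

from .synthetic import MultispectralTile

__all__ = [
    "RegressionSample",
    "normalize_tile",
    "rotate_augment",
    "cutmix_pair",
    "make_regression_dataset",
    "subsample_records",
    "cluster_coordinates",
    "assign_splits",
    "split_catalog",
]

REFLECTANCE_MAX = 10_000.0
SPLIT_NAMES = ("train", "val", "test")


@dataclass
class RegressionSample:
    """A normalized (h, w, C_in) tile with a continuous target in [0, 1]."""

    pixels: np.ndarray
    y: float
    base_id: str = ""
    donor_id: str | None = None
    stripe_fraction: float = 0.0
    edge: str | None = None

    def __post_init__(self):
        if not 0.0 <= self.y <= 1.0:
            raise ValueError(f"target must be in [0, 1], got {self.y}")
        if not 0.0 <= self.stripe_fraction <= 0.5:
            raise ValueError(
                f"stripe fraction must be in [0, 0.5], got {self.stripe_fraction}"
            )


def normalize_tile(tile: MultispectralTile | np.ndarray) -> np.ndarray:
    """Integer reflectances -> float grid in [0, 1] (divide by 10,000, clip).

    Float grids already inside [0, 1] are passed through unchanged, so the
    operation is idempotent.
    """
    pixels = tile.pixels if isinstance(tile, MultispectralTile) else np.asarray(tile)
    if not np.all(np.isfinite(pixels)):
        raise ValueError("tile contains non-finite values")
    if np.issubdtype(pixels.dtype, np.floating) and pixels.size \
            and pixels.min() >= 0.0 and pixels.max() <= 1.0:
        return pixels.astype(float, copy=False)
    return np.clip(pixels / REFLECTANCE_MAX, 0.0, 1.0)


def rotate_augment(sample: RegressionSample, rng: np.random.Generator
                   ) -> RegressionSample:
    """Rotate by 0/90/180/270 degrees, chosen uniformly; target unchanged."""
    if sample.pixels.shape[0] != sample.pixels.shape[1]:
        raise ValueError("rotation augmentation requires square tiles")
    k = int(rng.integers(0, 4))
    return RegressionSample(
        pixels=np.rot90(sample.pixels, k, axes=(0, 1)), y=sample.y,
        base_id=sample.base_id, donor_id=sample.donor_id,
        stripe_fraction=sample.stripe_fraction, edge=sample.edge,
    )


def cutmix_pair(base: RegressionSample, donor: RegressionSample, f: float,
                edge: str) -> RegressionSample:
    """Paste a stripe of the donor's ``edge`` onto the base's same edge.

    The stripe spans the full height (left/right edges) or full width
    (top/bottom) and is ``round(f * extent)`` columns/rows wide. The target
    uses the realized pixel-area fraction, so label and pixel content agree
    exactly even after rounding.
    """
    if base.pixels.shape != donor.pixels.shape:
        raise ValueError(
            f"base and donor shapes differ: {base.pixels.shape} vs {donor.pixels.shape}"
        )
    if not 0.0 <= f <= 0.5:
        raise ValueError(f"stripe fraction must be between 0 and 0.5, got {f}")
    if edge not in ("left", "right", "top", "bottom"):
        raise ValueError(f"edge must be left/right/top/bottom, got {edge!r}")
    h, w = base.pixels.shape[:2]
    extent = w if edge in ("left", "right") else h
    width = int(np.rint(f * extent))
    pixels = base.pixels.copy()
    if width > 0:
        if edge == "left":
            pixels[:, :width] = donor.pixels[:, :width]
        elif edge == "right":
            pixels[:, -width:] = donor.pixels[:, -width:]
        elif edge == "top":
            pixels[:width, :] = donor.pixels[:width, :]
        else:
            pixels[-width:, :] = donor.pixels[-width:, :]
    f_real = width / extent
    y = (1.0 - f_real) * base.y + f_real * donor.y
    return RegressionSample(
        pixels=pixels, y=float(y), base_id=base.base_id, donor_id=donor.base_id,
        stripe_fraction=float(f_real), edge=edge,
    )


def make_regression_dataset(catalog: pd.DataFrame,
                            tiles: dict[str, MultispectralTile],
                            split: str = "train", seed: int = 0,
                            mode: str = "regression") -> list[RegressionSample]:
    """Build the sample set for one split.

    Regression mode materializes one CutMixed variant per record, with the
    donor drawn uniformly from the same split (no cross-split leakage),
    ``f ~ U(0, 0.5]`` and a uniform edge. Classification mode returns the
    raw labeled samples.
    """
    if mode not in ("regression", "classification"):
        raise ValueError(f"mode must be regression or classification, got {mode!r}")
    records = catalog[catalog["split"] == split] if "split" in catalog else catalog
    if len(records) == 0:
        raise ValueError(f"split {split!r} is empty")
    base_samples = {
        row.id: RegressionSample(
            pixels=normalize_tile(tiles[row.id]), y=float(row.label), base_id=row.id
        )
        for row in records.itertuples()
    }
    ids = list(base_samples)
    if mode == "classification":
        return [base_samples[i] for i in ids]
    rng = np.random.default_rng(seed)
    out = []
    for tile_id in ids:
        donor_id = ids[int(rng.integers(0, len(ids)))]
        f = float(rng.uniform(0.0, 0.5))
        if f == 0.0:
            f = 0.5
        edge = ("left", "right", "top", "bottom")[int(rng.integers(0, 4))]
        out.append(cutmix_pair(base_samples[tile_id], base_samples[donor_id], f, edge))
    return out


def subsample_records(catalog: pd.DataFrame, fraction: float, seed: int = 0
                      ) -> pd.DataFrame:
    """Random subset of floor(fraction * N) records (training-size ablation)."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    n = int(fraction * len(catalog))
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(catalog), size=n, replace=False)
    return catalog.iloc[np.sort(idx)].reset_index(drop=True)


def cluster_coordinates(coords: np.ndarray, threshold_km: float = 10.0,
                        max_cluster_size: int = 500, seed: int = 0) -> np.ndarray:
    """Chain tiles closer than ``threshold_km`` into clusters; re-partition
    oversized clusters with k-means (k = ceil(size / 250))."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2 or len(coords) == 0:
        raise ValueError("coords must be a non-empty (n, 2) array of planar km")
    if len(coords) == 1:
        return np.zeros(1, dtype=int)
    labels = DBSCAN(eps=threshold_km, min_samples=1).fit_predict(coords)
    next_label = labels.max() + 1
    for cl in np.unique(labels):
        members = np.flatnonzero(labels == cl)
        if len(members) > max_cluster_size:
            k = int(np.ceil(len(members) / (max_cluster_size / 2)))
            sub = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(
                coords[members]
            )
            labels[members] = next_label + sub
            next_label += k
    # relabel to consecutive integers
    _, labels = np.unique(labels, return_inverse=True)
    return labels


def assign_splits(cluster_ids: np.ndarray, categories: np.ndarray,
                  fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
                  small_cluster_size: int = 6, seed: int = 0) -> pd.DataFrame:
    """Assign whole clusters to train/val/test, separately per category.

    Clusters smaller than ``small_cluster_size`` go to train. The remaining
    clusters are assigned largest-first to the split with the largest
    remaining deficit relative to the target fractions, so realized
    fractions track the targets without ever splitting a cluster.
    """
    cluster_ids = np.asarray(cluster_ids)
    categories = np.asarray(categories)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    split = np.empty(len(cluster_ids), dtype=object)
    for cat in np.unique(categories):
        in_cat = np.flatnonzero(categories == cat)
        clusters, counts = np.unique(cluster_ids[in_cat], return_counts=True)
        total = counts.sum()
        small = counts < small_cluster_size
        assigned_counts = dict.fromkeys(SPLIT_NAMES, 0)
        cluster_split: dict[int, str] = {}
        for cl, cnt in zip(clusters[small], counts[small]):
            cluster_split[cl] = "train"
            assigned_counts["train"] += cnt
        big = np.flatnonzero(~small)
        if len(big) == 1 and not small.any():
            warnings.warn(
                f"category {cat!r} forms a single cluster; all samples "
                "assigned to train", stacklevel=2,
            )
        order = big[np.lexsort((rng.random(len(big)), -counts[big]))]
        for i in order:
            deficits = {
                s: fractions[j] * total - assigned_counts[s]
                for j, s in enumerate(SPLIT_NAMES)
            }
            target = max(SPLIT_NAMES, key=lambda s: deficits[s])
            cluster_split[clusters[i]] = target
            assigned_counts[target] += counts[i]
        for idx in in_cat:
            split[idx] = cluster_split[cluster_ids[idx]]
    return pd.DataFrame({"cluster": cluster_ids, "split": split})


def split_catalog(catalog: pd.DataFrame, threshold_km: float = 10.0,
                  fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
                  max_cluster_size: int = 500, small_cluster_size: int = 6,
                  seed: int = 0) -> pd.DataFrame:
    """Cluster catalog coordinates and add ``cluster``/``split`` columns."""
    coords = catalog[["x_km", "y_km"]].to_numpy(dtype=float)
    cluster_ids = cluster_coordinates(coords, threshold_km, max_cluster_size, seed)
    assignment = assign_splits(
        cluster_ids, catalog["category"].to_numpy(), fractions,
        small_cluster_size, seed,
    )
    out = catalog.copy()
    out["cluster"] = assignment["cluster"].to_numpy()
    out["split"] = assignment["split"].to_numpy()
    return out
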