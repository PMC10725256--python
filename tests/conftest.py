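import numpy as np
import pytest

from asosmap import (
    HarmonizedAttributionMapper,
    SceneConfig,
    UNetScoreRegressor,
    generate_catalog,
    make_regression_dataset,
    split_catalog,
)
from asosmap.nn import HeadSpec, Network, UNetSpec


@pytest.fixture(scope="session")
def tiny_network():
    """Small random-weight network for structural/contract tests."""
    return Network(
        unet_spec=UNetSpec(c_in=3, c_act=2, base_channels=4),
        head_spec=HeadSpec(),
        train_tile_size=64,
        seed=42,
    )


@pytest.fixture(scope="session")
def synthetic_catalog():
    """Small split catalog with in-memory tiles (10 clusters per class)."""
    cfg = SceneConfig(tile_size=64)
    catalog, tiles = generate_catalog(
        cfg, n_per_class=40, cluster_spec=(20, 2.0, 50.0), seed=0
    )
    catalog = split_catalog(catalog, seed=0)
    return catalog, {t.id: t for t in tiles}


@pytest.fixture(scope="session")
def trained_pipeline():
    """End-to-end fixture: synthetic data, trained model, harmonized tables.

    Scaled-down study conditions, fixed once: ~176 CutMixed training tiles
    of 64x64x10, an 8-channel-base U-Net trained for 100 epochs at batch 16
    (keeping the optimizer-iteration count in the thousands, the same
    correction the full-scale protocol applies to small data subsets), and
    harmonization over four CutMix materializations (~700 activation maps)
    with hypercube side 0.2 — the per-cube sample sizes a 700-map set
    supports. Shared session-wide because training dominates the suite's
    runtime.
    """
    cfg = SceneConfig(tile_size=64)
    catalog, tiles = generate_catalog(
        cfg, n_per_class=110, cluster_spec=(20, 2.0, 50.0), seed=0
    )
    catalog = split_catalog(catalog, seed=0)
    tiles_d = {t.id: t for t in tiles}
    train_s = make_regression_dataset(catalog, tiles_d, "train", seed=0)
    val_s = make_regression_dataset(catalog, tiles_d, "val", seed=1)
    x = np.stack([s.pixels for s in train_s])
    y = np.array([s.y for s in train_s])
    x_val = np.stack([s.pixels for s in val_s])
    y_val = np.array([s.y for s in val_s])
    est = UNetScoreRegressor(
        c_in=10, c_act=3, base_channels=8, tile_size=64,
        epochs=100, batch_size=16, seed=0,
    )
    est.fit(x, y, x_val, y_val)
    harmonize_pix = []
    for rep in range(4):
        harmonize_pix += [
            s.pixels
            for s in make_regression_dataset(catalog, tiles_d, "train", seed=rep)
        ]
    gradcam = HarmonizedAttributionMapper(
        model=est, method="gradcam", l_h=0.2).fit(harmonize_pix)
    asos = HarmonizedAttributionMapper(
        model=est, method="asos", l_h=0.2).fit(harmonize_pix)
    return {
        "catalog": catalog,
        "tiles": tiles_d,
        "estimator": est,
        "train_samples": train_s,
        "gradcam": gradcam,
        "asos": asos,
    }
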