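"""scikit-learn-style estimators wrapping the network and the harmonizer.

``UNetScoreRegressor`` is a fit/predict regressor over (n, h, w, C_in)
image stacks with continuous targets in [0, 1]. ``HarmonizedAttributionMapper``
is a fit/transform meta-estimator: fitting builds the activation space and
harmonization table from training images; transforming maps scenes (of any
size) to harmonized, density-masked attribution grids. Both follow the
sklearn parameter conventions (constructor params, trailing-underscore
fitted attributes, get_params/set_params) and compose with sklearn tools
that accept non-tabular X.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .activation_space import (
    asos_sensitivities,
    build_space,
    harmonize_attributions,
)
from .attribution import (
    OcclusionConfig,
    gradcam_from_activation,
    occlusion_from_activation,
)
from .mapping import SceneResult, predict_scene_attribution
from .nn import (
    HeadSpec,
    Network,
    TrainConfig,
    UNetSpec,
    evaluate_nrmse,
    train_model,
)

__all__ = ["UNetScoreRegressor", "HarmonizedAttributionMapper"]


def _to_nchw(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float32)
    if x.ndim != 4:
        raise ValueError(f"X must be (n, h, w, C), got shape {x.shape}")
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


class UNetScoreRegressor(RegressorMixin, BaseEstimator):
    """Two-part CNN scored regressor: U-Net activation map + shallow head.

    Parameters
    ----------
    c_in, c_act : int
        Input channels and activation-map channels.
    base_channels : int
        First-convolution width; doubles per encoding step.
    tile_size : int
        Training tile size; fixes the head's flatten size. Must be
        divisible by 16 and large enough for three stride-3 convolutions
        (>= 64 in practice).
    epochs, batch_size, max_lr, weight_decay, momentum : training knobs
        SGD with the 1cycle learning-rate policy.
    mode : {"regression", "classification"}
        MSE against continuous targets, or binary cross-entropy.
    rotate_augment : bool
        Random 0/90/180/270-degree rotations during training.
    seed : int
        Seeds weight init, batching, and augmentation.
    """

    def __init__(self, c_in: int = 10, c_act: int = 3, base_channels: int = 32,
                 tile_size: int = 64, epochs: int = 5, batch_size: int = 32,
                 max_lr: float = 1e-2, weight_decay: float = 1e-4,
                 momentum: float = 0.9, mode: str = "regression",
                 rotate_augment: bool = True, seed: int = 0):
        self.c_in = c_in
        self.c_act = c_act
        self.base_channels = base_channels
        self.tile_size = tile_size
        self.epochs = epochs
        self.batch_size = batch_size
        self.max_lr = max_lr
        self.weight_decay = weight_decay
        self.momentum = momentum
        self.mode = mode
        self.rotate_augment = rotate_augment
        self.seed = seed

    def fit(self, X, y, X_val=None, y_val=None):
        """Fit on (n, h, w, C_in) normalized images and targets in [0, 1]."""
        xb = _to_nchw(X)
        y = np.asarray(y, dtype=np.float32)
        self.network_ = Network(
            unet_spec=UNetSpec(c_in=self.c_in, c_act=self.c_act,
                               base_channels=self.base_channels),
            head_spec=HeadSpec(),
            train_tile_size=self.tile_size, seed=self.seed,
        )
        config = TrainConfig(
            batch_size=self.batch_size, epochs=self.epochs, max_lr=self.max_lr,
            weight_decay=self.weight_decay, momentum=self.momentum,
            mode=self.mode, seed=self.seed,
        )
        self.history_ = train_model(
            self.network_, xb, y,
            _to_nchw(X_val) if X_val is not None else None,
            np.asarray(y_val, dtype=np.float32) if y_val is not None else None,
            config, rotate_augment=self.rotate_augment,
        )
        self.n_features_in_ = xb.shape[1] * xb.shape[2] * xb.shape[3]
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "network_")
        xb = _to_nchw(X)
        out = np.empty(len(xb), dtype=float)
        for i in range(0, len(xb), self.batch_size):
            out[i:i + self.batch_size] = self.network_.forward(xb[i:i + self.batch_size])
        return out

    def activation_maps(self, X) -> np.ndarray:
        """Full-resolution (n, h, w, C_act) activation maps."""
        check_is_fitted(self, "network_")
        xb = _to_nchw(X)
        out = []
        for i in range(0, len(xb), self.batch_size):
            out.append(self.network_.forward_activation(xb[i:i + self.batch_size]))
        return np.concatenate(out).transpose(0, 2, 3, 1)

    def nrmse(self, X, y) -> float:
        """Root-mean-square error over the unit target range."""
        return evaluate_nrmse(self.predict(X), np.asarray(y, dtype=float))


class HarmonizedAttributionMapper(TransformerMixin, BaseEstimator):
    """Harmonizes per-image attributions over the activation space and maps
    scenes through the resulting hypercube table.

    Parameters
    ----------
    model : UNetScoreRegressor or Network
        A fitted regressor (or a bare trained network).
    method : {"gradcam", "occlusion", "asos"}
        Attribution method harmonized over the training set.
    l_h : float
        Hypercube side length; 2/l_h must be an integer.
    density_factor : float
        Density-mask threshold as a fraction of the average occupied-cube
        density.
    occlusion : OcclusionConfig, optional
        Patch/stride configuration for method="occlusion".
    """

    def __init__(self, model=None, method: str = "gradcam", l_h: float = 0.1,
                 density_factor: float = 0.5,
                 occlusion: OcclusionConfig | None = None):
        self.model = model
        self.method = method
        self.l_h = l_h
        self.density_factor = density_factor
        self.occlusion = occlusion

    def _network(self) -> Network:
        if isinstance(self.model, Network):
            return self.model
        if hasattr(self.model, "network_"):
            return self.model.network_
        raise ValueError("model must be a trained Network or fitted UNetScoreRegressor")

    def fit(self, X, y=None):
        """Build the activation space and harmonization table from
        (n, h, w, C_in) normalized training images (typically CutMixed)."""
        if self.method not in ("gradcam", "occlusion", "asos"):
            raise ValueError(f"unknown attribution method {self.method!r}")
        network = self._network()
        samples = [np.asarray(x, dtype=np.float32) for x in X]
        space = build_space(network, samples, l_h=self.l_h)
        if self.method == "asos":
            table = asos_sensitivities(
                network, samples, space, threshold_factor=self.density_factor)
        else:
            attribution_maps = []
            for pixels in samples:
                a = network.forward_activation(
                    np.ascontiguousarray(pixels.transpose(2, 0, 1))[None])[0]
                if self.method == "gradcam":
                    attribution_maps.append(gradcam_from_activation(network.head, a))
                else:
                    attribution_maps.append(occlusion_from_activation(
                        network.head, a, self.occlusion))
            table = harmonize_attributions(
                space, attribution_maps, method=self.method,
                threshold_factor=self.density_factor)
        self.space_ = space
        self.table_ = table
        return self

    def map_scene(self, scene: np.ndarray, normalized: bool = True,
                  block_size: int | None = None,
                  edge_margin: int = 0) -> SceneResult:
        """Harmonized attribution of one (h, w, C_in) scene of any size."""
        check_is_fitted(self, "table_")
        return predict_scene_attribution(
            self._network(), self.table_, scene, normalized=normalized,
            block_size=block_size, edge_margin=edge_margin,
        )

    def transform(self, X) -> list[SceneResult]:
        """Map each scene in X (iterable of (h, w, C_in) normalized grids)."""
        check_is_fitted(self, "table_")
        return [self.map_scene(np.asarray(scene)) for scene in X]
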