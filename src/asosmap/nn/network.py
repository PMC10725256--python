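"""Two-part network: image-to-image U-Net and a shallow task head.

The U-Net maps a multispectral image (N, C_in, h, w) to a full-resolution,
tanh-bounded activation map (N, C_act, h, w): four encoding steps (one
convolution each, batch-normalized, leaky-ReLU, 2x2 max-pooled), a
bottleneck convolution, and four decoding steps (bilinear upsampling,
skip concatenation, one convolution), followed by a 1x1 projection to
C_act channels activated with tanh (no batch norm on the output).

The head compresses the activation map to one sigmoid score in (0, 1):
three stride-3, kernel-5 convolutions that double the channel count each
time, a flatten, and two fully connected layers (384 and 1 units).
The head's flatten size is fixed by the training tile size; the U-Net is
fully convolutional and accepts any spatial size divisible by 16.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .layers import (
    BatchNorm2d,
    BilinearUpsample2x,
    Conv2d,
    Flatten,
    LeakyReLU,
    Linear,
    MaxPool2d,
    Module,
    Param,
    Sequential,
    Sigmoid,
    Tanh,
)

logger = logging.getLogger(__name__)

DOWNSAMPLE_FACTOR = 16  # 2**depth; admissible inputs have h, w divisible by this


@dataclass
class UNetSpec:
    c_in: int = 10
    c_act: int = 3
    depth: int = 4
    base_channels: int = 32
    leaky_slope: float = 0.01

    def encoder_channels(self) -> list[int]:
        return [self.base_channels * 2 ** i for i in range(self.depth)]


@dataclass
class HeadSpec:
    n_conv: int = 3
    kernel: int = 5
    stride: int = 3
    fc_units: int = 384
    leaky_slope: float = 0.01


@dataclass
class TrainConfig:
    batch_size: int = 32
    epochs: int = 5
    max_lr: float = 1e-2
    weight_decay: float = 1e-4
    momentum: float = 0.9
    mode: str = "regression"  # or "classification"
    seed: int = 0
    extra: dict = field(default_factory=dict)


class ConvBlock(Module):
    """conv(3x3, pad 1) -> batch norm -> leaky ReLU."""

    def __init__(self, c_in: int, c_out: int, slope: float, rng, dtype):
        self.conv = Conv2d(c_in, c_out, k=3, stride=1, pad=1, rng=rng, dtype=dtype)
        self.bn = BatchNorm2d(c_out, dtype=dtype)
        self.act = LeakyReLU(slope)

    def parameters(self):
        return self.conv.parameters() + self.bn.parameters()

    def forward(self, x, train=False):
        return self.act(self.bn(self.conv(x, train), train), train)

    def backward(self, gy):
        return self.conv.backward(self.bn.backward(self.act.backward(gy)))


class UNet(Module):
    def __init__(self, spec: UNetSpec, rng: np.random.Generator, dtype=np.float32):
        self.spec = spec
        enc_ch = spec.encoder_channels()
        bott_ch = enc_ch[-1] * 2
        s = spec.leaky_slope

        self.enc: list[ConvBlock] = []
        c = spec.c_in
        for c_out in enc_ch:
            self.enc.append(ConvBlock(c, c_out, s, rng, dtype))
            c = c_out
        self.pools = [MaxPool2d() for _ in enc_ch]
        self.bottleneck = ConvBlock(c, bott_ch, s, rng, dtype)

        self.ups: list[BilinearUpsample2x] = []
        self.dec: list[ConvBlock] = []
        c = bott_ch
        for skip_c in reversed(enc_ch):
            self.ups.append(BilinearUpsample2x())
            self.dec.append(ConvBlock(c + skip_c, skip_c, s, rng, dtype))
            c = skip_c
        self.project = Conv2d(c, spec.c_act, k=1, stride=1, pad=0, rng=rng, dtype=dtype)
        self.tanh = Tanh()

    def parameters(self) -> list[Param]:
        params: list[Param] = []
        for block in self.enc + [self.bottleneck] + self.dec:
            params += block.parameters()
        params += self.project.parameters()
        return params

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h, w = x.shape[2], x.shape[3]
        if h % DOWNSAMPLE_FACTOR or w % DOWNSAMPLE_FACTOR:
            raise ValueError(
                f"input spatial size ({h}, {w}) must be divisible by "
                f"{DOWNSAMPLE_FACTOR} (2**depth); pad the input first"
            )
        skips = []
        for block, pool in zip(self.enc, self.pools):
            x = block(x, train)
            skips.append(x)
            x = pool(x, train)
        x = self.bottleneck(x, train)
        self._skip_channels = [s.shape[1] for s in skips]
        for up, block, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up(x, train)
            x = np.concatenate([x, skip], axis=1)
            x = block(x, train)
        return self.tanh(self.project(x, train), train)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = self.project.backward(self.tanh.backward(gy))
        skip_grads = []
        for up, block, skip_c in zip(
            reversed(self.ups), reversed(self.dec), self._skip_channels
        ):
            g = block.backward(g)
            up_c = g.shape[1] - skip_c
            skip_grads.append(g[:, up_c:])
            g = up.backward(g[:, :up_c])
        g = self.bottleneck.backward(g)
        for block, pool, gskip in zip(
            reversed(self.enc), reversed(self.pools), reversed(skip_grads)
        ):
            g = block.backward(pool.backward(g) + gskip)
        return g


class Head(Module):
    """Shallow scorer on the activation map; fixed to the training tile size."""

    def __init__(self, spec: HeadSpec, c_act: int, tile_size: int,
                 rng: np.random.Generator, dtype=np.float32):
        self.spec = spec
        self.tile_size = tile_size
        layers: list[Module] = []
        c, size = c_act, tile_size
        for _ in range(spec.n_conv):
            layers += [Conv2d(c, 2 * c, spec.kernel, spec.stride, pad=0,
                              rng=rng, dtype=dtype),
                       LeakyReLU(spec.leaky_slope)]
            c *= 2
            size = (size - spec.kernel) // spec.stride + 1
            if size < 1:
                raise ValueError(
                    f"tile size {tile_size} too small for {spec.n_conv} "
                    f"stride-{spec.stride} convolutions"
                )
        self.flat_size = c * size * size
        layers += [Flatten(), Linear(self.flat_size, spec.fc_units, rng, dtype),
                   LeakyReLU(spec.leaky_slope), Linear(spec.fc_units, 1, rng, dtype),
                   Sigmoid()]
        self.net = Sequential(*layers)

    def parameters(self):
        return self.net.parameters()

    def forward(self, a: np.ndarray, train: bool = False) -> np.ndarray:
        if a.shape[2] != self.tile_size or a.shape[3] != self.tile_size:
            raise ValueError(
                f"head is fixed to {self.tile_size}x{self.tile_size} activation "
                f"maps, got {a.shape[2]}x{a.shape[3]}"
            )
        return self.net(a, train)[:, 0]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return self.net.backward(gy[:, None])


class Network(Module):
    """U-Net and head composed; the activation map is the intermediate layer."""

    def __init__(self, unet_spec: UNetSpec | None = None,
                 head_spec: HeadSpec | None = None,
                 train_tile_size: int = 256, seed: int = 0, dtype=np.float32):
        unet_spec = unet_spec or UNetSpec()
        head_spec = head_spec or HeadSpec()
        if train_tile_size % DOWNSAMPLE_FACTOR:
            raise ValueError(
                f"train_tile_size must be divisible by {DOWNSAMPLE_FACTOR}, "
                f"got {train_tile_size}"
            )
        rng = np.random.default_rng(seed)
        self.unet_spec = unet_spec
        self.head_spec = head_spec
        self.train_tile_size = train_tile_size
        self.unet = UNet(unet_spec, rng, dtype)
        self.head = Head(head_spec, unet_spec.c_act, train_tile_size, rng, dtype)
        n_unet = sum(p.data.size for p in self.unet.parameters())
        n_head = sum(p.data.size for p in self.head.parameters())
        logger.info("built network: %.2fM U-Net params, %.2fM head params",
                    n_unet / 1e6, n_head / 1e6)

    def parameters(self) -> list[Param]:
        return self.unet.parameters() + self.head.parameters()

    def n_parameters(self) -> tuple[int, int]:
        return (sum(p.data.size for p in self.unet.parameters()),
                sum(p.data.size for p in self.head.parameters()))

    def forward_activation(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """(N, C_in, h, w) -> activation maps (N, C_act, h, w)."""
        if x.shape[1] != self.unet_spec.c_in:
            raise ValueError(
                f"expected {self.unet_spec.c_in} input channels, got {x.shape[1]}"
            )
        return self.unet(x, train)

    def forward_score(self, a: np.ndarray, train: bool = False) -> np.ndarray:
        """Activation maps (N, C_act, t, t) -> scores in (0, 1)."""
        return self.head(a, train)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward_score(self.forward_activation(x, train), train)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return self.unet.backward(self.head.backward(gy))
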