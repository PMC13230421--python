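"""Generator and discriminator architectures.

Both generators share one architecture (encoder -> residual bottleneck ->
transposed-convolution decoder, tanh output in [-1, 1]); both discriminators
share one patch-wise convolutional classifier that emits a grid of realism
scores, one per receptive-field patch.  Layer recipe follows the canonical
cycle-consistent translation convention the method extends: a 7x7
reflect-padded stem, two stride-2 downsampling convs, residual blocks at the
bottleneck width, two stride-2 transposed convs, and a 7x7 output conv;
instance normalisation throughout; discriminator built from 4x4 stride-2
convs with leaky ReLU (receptive field 70x70 at the default depth).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (
    Conv2d,
    ConvTranspose2d,
    InstanceNorm2d,
    LeakyReLU,
    ReLU,
    ResidualBlock,
    Sequential,
    Tanh,
)

__all__ = [
    "GeneratorConfig",
    "DiscriminatorConfig",
    "Generator",
    "Discriminator",
    "build_generator",
    "build_discriminator",
]

DOWNSAMPLE_FACTOR = 4  # two stride-2 encoder stages


@dataclass(frozen=True)
class GeneratorConfig:
    in_channels: int = 2          # 2 when the brain mask is concatenated
    base_width: int = 64
    n_residual_blocks: int = 9
    image_size: int = 256

    def __post_init__(self):
        if self.in_channels not in (1, 2):
            raise ValueError("in_channels must be 1 or 2")
        if self.n_residual_blocks < 1:
            raise ValueError("n_residual_blocks must be >= 1")
        if self.base_width < 1:
            raise ValueError("base_width must be >= 1")


@dataclass(frozen=True)
class DiscriminatorConfig:
    in_channels: int = 1
    base_width: int = 64
    n_layers: int = 3
    use_norm: bool = True  # instance norm couples patches spatially; turn
    # off for a strictly local patch classifier

    def __post_init__(self):
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.base_width < 1:
            raise ValueError("base_width must be >= 1")


class Generator:
    def __init__(self, cfg: GeneratorConfig, rng: np.random.Generator):
        w = cfg.base_width
        layers = [
            Conv2d(cfg.in_channels, w, 7, padding=3, pad_mode="reflect", rng=rng),
            InstanceNorm2d(), ReLU(),
            Conv2d(w, 2 * w, 3, stride=2, padding=1, rng=rng),
            InstanceNorm2d(), ReLU(),
            Conv2d(2 * w, 4 * w, 3, stride=2, padding=1, rng=rng),
            InstanceNorm2d(), ReLU(),
        ]
        layers += [ResidualBlock(4 * w, rng=rng) for _ in range(cfg.n_residual_blocks)]
        layers += [
            ConvTranspose2d(4 * w, 2 * w, 3, stride=2, padding=1,
                            output_padding=1, rng=rng),
            InstanceNorm2d(), ReLU(),
            ConvTranspose2d(2 * w, w, 3, stride=2, padding=1,
                            output_padding=1, rng=rng),
            InstanceNorm2d(), ReLU(),
            Conv2d(w, 1, 7, padding=3, pad_mode="reflect", rng=rng),
            Tanh(),
        ]
        self.cfg = cfg
        self.net = Sequential(layers)

    def _check(self, x):
        if x.ndim != 4 or x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"generator expects (N,{self.cfg.in_channels},H,W), got {x.shape}"
            )
        if x.shape[2] % DOWNSAMPLE_FACTOR or x.shape[3] % DOWNSAMPLE_FACTOR:
            raise ValueError(
                f"spatial size {x.shape[2:]} not divisible by the total "
                f"downsampling factor {DOWNSAMPLE_FACTOR}"
            )

    def forward(self, x: np.ndarray):
        self._check(x)
        return self.net.forward(x)

    def backward(self, cache, dy):
        return self.net.backward(cache, dy)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[0]

    def zero_grad(self):
        self.net.zero_grad()

    def named_layers(self, prefix=""):
        return self.net.named_layers(prefix)

    def state_items(self, prefix=""):
        return self.net.state_items(prefix)


class Discriminator:
    def __init__(self, cfg: DiscriminatorConfig, rng: np.random.Generator):
        w = cfg.base_width
        norm = (lambda: [InstanceNorm2d()]) if cfg.use_norm else (lambda: [])
        layers = [Conv2d(cfg.in_channels, w, 4, stride=2, padding=1, rng=rng),
                  LeakyReLU(0.2)]
        mult = 1
        for _ in range(1, cfg.n_layers):
            prev, mult = mult, min(mult * 2, 8)
            layers += [Conv2d(w * prev, w * mult, 4, stride=2, padding=1, rng=rng),
                       *norm(), LeakyReLU(0.2)]
        prev, mult = mult, min(mult * 2, 8)
        layers += [Conv2d(w * prev, w * mult, 4, stride=1, padding=1, rng=rng),
                   *norm(), LeakyReLU(0.2),
                   Conv2d(w * mult, 1, 4, stride=1, padding=1, rng=rng)]
        self.cfg = cfg
        self.net = Sequential(layers)

    def forward(self, x: np.ndarray):
        if x.ndim != 4 or x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"discriminator expects (N,{self.cfg.in_channels},H,W), got {x.shape}"
            )
        return self.net.forward(x)

    def backward(self, cache, dy):
        return self.net.backward(cache, dy)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[0]

    def zero_grad(self):
        self.net.zero_grad()

    def named_layers(self, prefix=""):
        return self.net.named_layers(prefix)

    def state_items(self, prefix=""):
        return self.net.state_items(prefix)


def build_generator(cfg: GeneratorConfig,
                    rng: np.random.Generator | int | None = None) -> Generator:
    """Seeded Gaussian (sd 0.02) initialised generator."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return Generator(cfg, rng)


def build_discriminator(cfg: DiscriminatorConfig,
                        rng: np.random.Generator | int | None = None) -> Discriminator:
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return Discriminator(cfg, rng)
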