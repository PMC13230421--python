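"""Frozen feature extractor phi used by every fidelity-constrained loss.

Two backends share one interface:

``fixed_random``
    Three seeded stride-2 convolutional blocks with leaky-ReLU activations.
    Weights are a pure function of the seed and are never updated; this makes
    every fidelity loss testable and trainable with no downloads while
    exercising exactly the same code path as a pretrained backbone.

``pretrained_radiology``
    Loads an externally supplied radiology-pretrained weight file (``.npz``
    mapping parameter names to arrays, same architecture).  It is an error to
    request this backend without a weight path — there is no silent fallback.

Gradients flow through phi to its *input* (the generators need them) but phi's
parameters are frozen: layer ``trainable`` flags are off, so no parameter
gradient is ever accumulated, and the weight fingerprint is constant.
"""

from __future__ import annotations

import hashlib

import numpy as np

from .nn import Conv2d, LeakyReLU, Sequential

__all__ = ["FeatureExtractor", "build_extractor", "MIN_INPUT_SIZE"]

#: three stride-2 blocks halve the grid three times; inputs must be >= 8 px.
MIN_INPUT_SIZE = 8

_BACKENDS = ("fixed_random", "pretrained_radiology")


class FeatureExtractor:
    """Immutable feature mapping phi.  Use :func:`build_extractor`."""

    def __init__(self, backend: str, layer_tag: str, net: Sequential | None,
                 in_channels: int):
        self.backend = backend
        self.layer_tag = layer_tag
        self._net = net
        self.in_channels = in_channels
        self.weights_fingerprint = self._fingerprint()

    def _fingerprint(self) -> str:
        h = hashlib.sha256()
        if self._net is not None:
            for name, p in sorted(self._net.state_items()):
                h.update(name.encode())
                h.update(np.ascontiguousarray(p).tobytes())
        return h.hexdigest()

    # ------------------------------------------------------------------
    def extract(self, image: np.ndarray) -> np.ndarray:
        """phi(image) for a single image (C,H,W) or batch (N,C,H,W)."""
        out, _ = self.forward(image)
        return out

    def forward(self, image: np.ndarray):
        """Feature map plus the cache needed for input-gradient backprop."""
        x, squeeze = self._as_batch(image)
        if self.layer_tag == "input":
            out, cache = x, None
        else:
            if min(x.shape[2], x.shape[3]) < MIN_INPUT_SIZE:
                raise ValueError(
                    f"input spatial size {x.shape[2:]} below minimum {MIN_INPUT_SIZE}"
                )
            x = self._match_channels(x)
            out, cache = self._net.forward(x)
        return (out[0] if squeeze else out), (cache, squeeze, image.shape)

    def backward_input(self, cache, dfeat: np.ndarray) -> np.ndarray:
        """Gradient of a feature-space loss w.r.t. the extractor input."""
        inner, squeeze, in_shape = cache
        if squeeze:
            dfeat = dfeat[None]
        if self.layer_tag == "input":
            dx = dfeat
        else:
            dx = self._net.backward(inner, dfeat)
            orig_c = 1 if len(in_shape) == 2 else in_shape[-3]
            if dx.shape[1] != orig_c:
                dx = dx.sum(axis=1, keepdims=True)  # replicated channels share grad
        return dx[0] if squeeze else dx

    # ------------------------------------------------------------------
    def _as_batch(self, image):
        image = np.asarray(image)
        if image.dtype != np.float64:
            image = image.astype(np.float32, copy=False)
        if image.ndim == 2:
            return image[None, None], True
        if image.ndim == 3:
            return image[None], True
        if image.ndim == 4:
            return image, False
        raise ValueError("image must be 2-D, (C,H,W) or (N,C,H,W)")

    def _match_channels(self, x):
        if x.shape[1] == self.in_channels:
            return x
        if x.shape[1] == 1:
            return np.repeat(x, self.in_channels, axis=1)
        raise ValueError(
            f"cannot map {x.shape[1]}-channel input onto a backend expecting "
            f"{self.in_channels} channels"
        )


def _build_net(rng: np.random.Generator, in_channels: int, widths=(8, 16, 16)):
    layers = []
    cin = in_channels
    for w in widths:
        conv = Conv2d(cin, w, 3, stride=2, padding=1, rng=rng, init_sd=0.2)
        conv.trainable = False  # frozen: parameter grads are never accumulated
        layers += [conv, LeakyReLU(0.2)]
        cin = w
    return Sequential(layers)


def build_extractor(backend: str = "fixed_random", layer_tag: str = "conv3",
                    seed: int | None = None, in_channels: int = 1,
                    weights_path=None) -> FeatureExtractor:
    """Construct a frozen feature extractor.

    ``layer_tag='input'`` yields the identity mapping (test convenience);
    any other tag taps the output of the final convolutional stage.
    """
    if backend not in _BACKENDS:
        raise ValueError(f"unknown backend {backend!r}; expected one of {_BACKENDS}")
    if layer_tag == "input":
        return FeatureExtractor(backend, "input", None, in_channels)
    if backend == "fixed_random":
        if seed is None:
            raise ValueError("fixed_random backend requires a seed")
        rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed),
                                                           spawn_key=(71,)))
        net = _build_net(rng, in_channels)
        return FeatureExtractor(backend, layer_tag, net, in_channels)
    # pretrained_radiology
    if weights_path is None:
        raise FileNotFoundError(
            "pretrained_radiology backend requires an explicit weights_path; "
            "no weights are bundled. Use backend='fixed_random' for a "
            "deterministic desk-scale extractor."
        )
    net = _build_net(np.random.default_rng(0), in_channels)
    with np.load(weights_path) as data:
        state = dict(data.items())
    for name, layer in net.named_layers():
        for k in layer.params:
            key = f"{name}{k}"
            if key not in state:
                raise ValueError(f"weight file missing parameter {key}")
            if state[key].shape != layer.params[k].shape:
                raise ValueError(f"shape mismatch for parameter {key}")
            layer.params[k] = state[key].astype(float)
    return FeatureExtractor(backend, layer_tag, net, in_channels)
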