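"""Adam optimiser over the parameters of one or more layer trees."""

from __future__ import annotations

import numpy as np

from .layers import Layer


class Adam:
    """Adam with the beta settings conventional for adversarial training
    (beta1 = 0.5 damps momentum against oscillating gradients)."""

    def __init__(self, modules: list[Layer], lr=2e-4, beta1=0.5, beta2=0.999,
                 eps=1e-8):
        self.modules = list(modules)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._slots: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for name, _ in self._named_params():
            pass  # slots created lazily on first step so load order is free

    def _named_params(self):
        for i, mod in enumerate(self.modules):
            for name, layer in mod.named_layers(f"m{i}."):
                if not layer.trainable:
                    continue
                for k in layer.params:
                    yield f"{name}{k}", (layer, k)

    def zero_grad(self):
        for mod in self.modules:
            mod.zero_grad()

    def step(self, lr: float | None = None):
        lr = self.lr if lr is None else lr
        self.t += 1
        b1, b2 = self.b1, self.b2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for name, (layer, k) in self._named_params():
            g = layer.grads[k]
            if name not in self._slots:
                self._slots[name] = (np.zeros_like(g), np.zeros_like(g))
            m, v = self._slots[name]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            layer.params[k] -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    # -- checkpoint support ----------------------------------------------
    def state_dict(self) -> dict:
        out = {"t": self.t}
        for name, (m, v) in self._slots.items():
            out[f"m::{name}"] = m
            out[f"v::{name}"] = v
        return out

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self._slots = {}
        for key, arr in state.items():
            if key == "t":
                continue
            kind, name = key.split("::", 1)
            m, v = self._slots.get(name, (None, None))
            if kind == "m":
                self._slots[name] = (np.array(arr), v)
            else:
                self._slots[name] = (self._slots.get(name, (None, None))[0], np.array(arr))
        for name, (m, v) in self._slots.items():
            if m is None or v is None:
                raise ValueError(f"incomplete optimiser state for {name}")
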