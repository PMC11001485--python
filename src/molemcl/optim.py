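"""Adam optimiser over a flat name->array parameter registry."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam"]


class Adam:
    """Standard Adam (no weight decay, no schedule); updates in place."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.beta1**self.t
        bc2 = 1.0 - self.beta2**self.t
        for name, p in params.items():
            g = grads.get(name)
            if g is None:
                continue
            if name not in self.m:
                self.m[name] = np.zeros_like(p)
                self.v[name] = np.zeros_like(p)
            m = self.m[name]
            v = self.v[name]
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def state_dict(self) -> dict:
        return {
            "t": self.t,
            "m": {k: v.copy() for k, v in self.m.items()},
            "v": {k: v.copy() for k, v in self.v.items()},
            "hyper": {"lr": self.lr, "beta1": self.beta1, "beta2": self.beta2, "eps": self.eps},
        }

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.m = {k: np.asarray(v) for k, v in state["m"].items()}
        self.v = {k: np.asarray(v) for k, v in state["v"].items()}
        h = state["hyper"]
        self.lr, self.beta1, self.beta2, self.eps = h["lr"], h["beta1"], h["beta2"], h["eps"]
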