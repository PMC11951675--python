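"""Adam with an exponentially decayed learning rate.

The default schedule — initial rate 0.01 multiplied by 0.95 every 500 steps —
is the one used throughout model training here (gating network and,
optionally, GP hyperparameters).
"""

from __future__ import annotations

import numpy as np

__all__ = ["AdamOptimizer"]


class AdamOptimizer:
    """Minimal Adam over a list of parameter arrays.

    ``step(grads)`` returns the update to *subtract* from each parameter.
    """

    def __init__(
        self,
        shapes: list[tuple],
        lr: float = 0.01,
        decay: float = 0.95,
        decay_every: int = 500,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.lr0 = lr
        self.decay = decay
        self.decay_every = decay_every
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]

    @property
    def lr(self) -> float:
        return self.lr0 * self.decay ** (self.t // self.decay_every)

    def step(self, grads: list[np.ndarray]) -> list[np.ndarray]:
        self.t += 1
        lr = self.lr0 * self.decay ** ((self.t - 1) // self.decay_every)
        out = []
        for i, g in enumerate(grads):
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / (1 - self.beta1**self.t)
            vhat = self.v[i] / (1 - self.beta2**self.t)
            out.append(lr * mhat / (np.sqrt(vhat) + self.eps))
        return out

    def reset_moments(self) -> None:
        self.m = [np.zeros_like(a) for a in self.m]
        self.v = [np.zeros_like(a) for a in self.v]
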