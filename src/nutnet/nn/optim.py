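"""AdamW with decoupled weight decay and a cosine-annealing schedule."""

from __future__ import annotations

import numpy as np


class AdamW:
    def __init__(self, model, lr=1e-4, betas=(0.5, 0.999), weight_decay=0.0,
                 eps=1e-8):
        self.model = model
        self.base_lr = lr
        self.lr = lr
        self.b1, self.b2 = betas
        self.wd = weight_decay
        self.eps = eps
        self.t = 0
        self._m = {}
        self._v = {}
        for i, (layer, name, arr, _) in enumerate(model.parameters()):
            self._m[i] = np.zeros_like(arr)
            self._v[i] = np.zeros_like(arr)

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for i, (layer, name, arr, decay) in enumerate(self.model.parameters()):
            g = layer.grads[name]
            m = self._m[i]
            v = self._v[i]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            update = (m / bias1) / (np.sqrt(v / bias2) + self.eps)
            if decay and self.wd:
                update = update + self.wd * arr
            arr -= self.lr * update

    def zero_grad(self):
        self.model.zero_grad()


class CosineAnnealing:
    """lr(t) = lr_min + (lr0 - lr_min) * (1 + cos(pi * t / T)) / 2."""

    def __init__(self, optimizer: AdamW, total_steps: int, lr_min: float = 0.0):
        self.opt = optimizer
        self.total = max(1, total_steps)
        self.lr_min = lr_min
        self.step_i = 0

    def step(self):
        self.step_i = min(self.step_i + 1, self.total)
        frac = self.step_i / self.total
        self.opt.lr = (self.lr_min + (self.opt.base_lr - self.lr_min)
                       * 0.5 * (1.0 + np.cos(np.pi * frac)))
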