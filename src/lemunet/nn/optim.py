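"""AdamW on parameter pytrees (decoupled weight decay)."""

from __future__ import annotations

import numpy as np

from .core import tree_map


class AdamW:
    """Decoupled-weight-decay Adam.

    Defaults follow the common convention (betas 0.9/0.999, eps 1e-8,
    weight decay 0.01); the learning rate is the caller's business.
    """

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.01):
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.t = 0
        self.m = tree_map(np.zeros_like, params)
        self.v = tree_map(np.zeros_like, params)

    def step(self, params, grads):
        self.t += 1
        b1, b2, t = self.b1, self.b2, self.t
        c1 = 1.0 - b1**t
        c2 = 1.0 - b2**t

        def upd(p, g, m, v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            step = self.lr * ((m / c1) / (np.sqrt(v / c2) + self.eps) + self.wd * p)
            return (p - step).astype(p.dtype)

        return _zip_apply(upd, params, grads, self.m, self.v)


def _zip_apply(f, *trees):
    head = trees[0]
    if isinstance(head, dict):
        return {k: _zip_apply(f, *(t[k] for t in trees)) for k in head}
    if isinstance(head, (list, tuple)):
        return type(head)(_zip_apply(f, *parts) for parts in zip(*trees))
    return f(*trees)
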