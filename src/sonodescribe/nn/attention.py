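"""Soft-attention context pooling over the feature space.

Each spatial cell's feature vector f_i is scored by a single tanh perceptron,
the scores are normalized with a softmax into attention weights a_i (>= 0,
summing to 1), and the context is the weighted average c = sum_i a_i f_i.
The printed form of the normalization in the source architecture exponentiates
a *sum* of scores in the denominator, which cannot normalize; the softmax
reading, which the accompanying description requires ("add up to a total of
1"), is implemented here.
"""

from __future__ import annotations

import numpy as np


def soft_attention_forward(F: np.ndarray, V: np.ndarray):
    """Batched attention. F: (N, g2, d); V: (d,). Returns (a, c, cache)."""
    t = np.tanh(F @ V)                     # (N, g2) scores in [-1, 1]
    t_shift = t - t.max(axis=1, keepdims=True)
    e = np.exp(t_shift)
    a = e / e.sum(axis=1, keepdims=True)   # (N, g2)
    c = np.einsum("ng,ngd->nd", a, F)      # (N, d)
    return a, c, (F, V, t, a)


def soft_attention_backward(dc: np.ndarray, da: np.ndarray | None, cache):
    """Gradients of (a, c) w.r.t. F and V.

    ``dc`` is the gradient flowing into the context; ``da`` (optional) a
    direct gradient on the attention weights.  Returns (dF, dV).
    """
    F, V, t, a = cache
    da_total = np.einsum("nd,ngd->ng", dc, F)
    if da is not None:
        da_total = da_total + da
    dF = np.einsum("ng,nd->ngd", a, dc)
    # softmax backward
    dt = a * (da_total - (da_total * a).sum(axis=1, keepdims=True))
    # tanh backward
    dz = dt * (1.0 - t * t)
    dV = np.einsum("ng,ngd->d", dz, F)
    dF += dz[:, :, None] * V[None, None, :]
    return dF.astype(F.dtype), dV.astype(V.dtype)
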