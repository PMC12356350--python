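"""Minimal dense-network primitives: an MLP with hand-written backprop and
an Adam optimizer.  Everything is plain numpy float64; parameters are lists
of (W, b) arrays so the whole state serializes with ``np.savez``.
"""

from __future__ import annotations

import numpy as np


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class MLP:
    """Fully connected net, tanh hidden activations, linear output layer.

    ``sizes`` is the full layer-width sequence, e.g. ``[d, 256, 128, out]``.
    """

    def __init__(self, sizes, rng: np.random.Generator, skip: bool = False):
        self.sizes = list(sizes)
        self.weights = [glorot(rng, a, b) for a, b in zip(sizes[:-1], sizes[1:])]
        self.biases = [np.zeros(b) for b in sizes[1:]]
        # optional input->output linear shortcut, e.g. for PCA initialization
        self.skip = np.zeros((sizes[0], sizes[-1])) if skip else None

    @property
    def params(self):
        p = self.weights + self.biases
        return p + [self.skip] if self.skip is not None else p

    def set_params(self, arrays) -> None:
        k = len(self.weights)
        self.weights = [np.asarray(a, dtype=float) for a in arrays[:k]]
        if self.skip is not None:
            self.biases = [np.asarray(a, dtype=float) for a in arrays[k:-1]]
            self.skip = np.asarray(arrays[-1], dtype=float)
        else:
            self.biases = [np.asarray(a, dtype=float) for a in arrays[k:]]

    def copy_params(self):
        return [p.copy() for p in self.params]

    def forward(self, x: np.ndarray):
        """Return (output, cache); x is (batch, d)."""
        acts = [x]
        a = x
        last = len(self.weights) - 1
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            s = a @ W + b
            if i == last:
                a = s + (x @ self.skip if self.skip is not None else 0.0)
            else:
                a = np.tanh(s)
            acts.append(a)
        return a, acts

    def backward(self, acts, grad_out: np.ndarray):
        """Backprop ``grad_out`` (dL/d output) through the cached forward.

        Returns (grad_input, grads) with grads ordered like ``params``.
        """
        gW = [None] * len(self.weights)
        gb = [None] * len(self.biases)
        g = grad_out
        for i in range(len(self.weights) - 1, -1, -1):
            if i != len(self.weights) - 1:
                g = g * (1.0 - acts[i + 1] ** 2)  # tanh'
            gW[i] = acts[i].T @ g
            gb[i] = g.sum(axis=0)
            g = g @ self.weights[i].T
        if self.skip is not None:
            g_skip = acts[0].T @ grad_out
            g = g + grad_out @ self.skip.T
            return g, gW + gb + [g_skip]
        return g, gW + gb


class Adam:
    """Adam over a flat list of parameter arrays (updated in place)."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
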