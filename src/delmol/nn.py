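"""Minimal numpy neural-network primitives with explicit gradients.

The generative models in this package are small (tens of thousands of
parameters, short token sequences), so forward and backward passes are
written out by hand and verified against finite differences in the test
suite.  Only what the sequence VAE needs is provided: dense layers, a tanh
recurrence, softmax cross-entropy, logistic loss, and Adam.
"""

from __future__ import annotations

import numpy as np

__all__ = ["init_params", "Adam", "softmax", "clip_gradients"]


def _glorot(rng: np.random.Generator, n_out: int, n_in: int) -> np.ndarray:
    scale = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-scale, scale, size=(n_out, n_in))


def init_params(rng: np.random.Generator, shapes: dict[str, tuple[int, ...]]
                ) -> dict[str, np.ndarray]:
    """Glorot-uniform matrices, zero vectors/scalars."""
    params = {}
    for name, shape in shapes.items():
        if len(shape) == 2:
            params[name] = _glorot(rng, *shape)
        else:
            params[name] = np.zeros(shape)
    return params


def zeros_like_params(params: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    return {k: np.zeros_like(v) for k, v in params.items()}


def softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max()
    e = np.exp(shifted)
    return e / e.sum()


def clip_gradients(grads: dict[str, np.ndarray], max_norm: float = 5.0) -> None:
    total = np.sqrt(sum(float((g ** 2).sum()) for g in grads.values()))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for g in grads.values():
            g *= scale


class Adam:
    """Adam optimizer over a named parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.m = zeros_like_params(params)
        self.v = zeros_like_params(params)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = self.m[k] / (1 - b1 ** self.t)
            v_hat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= lr * m_hat / (np.sqrt(v_hat) + self.eps)
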