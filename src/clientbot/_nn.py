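"""Minimal LSTM machinery in numpy: forward/backward passes, Adagrad with
global-norm gradient clipping, and softmax output layers.

Everything is float64 and batch-free (one sequence at a time); the models
this package trains are desk-scale, where clarity and exact reproducibility
beat throughput.
"""

from __future__ import annotations

import numpy as np

__all__ = ["LSTMLayer", "SoftmaxOutput", "Adagrad", "clip_gradients", "softmax"]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class LSTMLayer:
    """Single LSTM layer with an input embedding.

    Gate layout in the combined weight matrix is [input, forget, cell, output].
    """

    def __init__(self, vocab_size: int, embed_dim: int, hidden: int, rng: np.random.Generator):
        self.vocab_size = vocab_size
        self.embed_dim = embed_dim
        self.hidden = hidden
        scale_e = 1.0 / np.sqrt(embed_dim)
        scale_w = 1.0 / np.sqrt(embed_dim + hidden)
        self.params = {
            "E": rng.uniform(-scale_e, scale_e, size=(vocab_size, embed_dim)),
            "W": rng.uniform(-scale_w, scale_w, size=(embed_dim + hidden, 4 * hidden)),
            "b": np.zeros(4 * hidden),
        }
        # forget-gate bias of 1 eases gradient flow early in training
        self.params["b"][hidden : 2 * hidden] = 1.0

    def zero_state(self) -> tuple[np.ndarray, np.ndarray]:
        return np.zeros(self.hidden), np.zeros(self.hidden)

    def step(self, token: int, state: tuple[np.ndarray, np.ndarray]):
        """One timestep. Returns (new_state, cache-for-backward)."""
        h_prev, c_prev = state
        H = self.hidden
        x = self.params["E"][token]
        xh = np.concatenate([x, h_prev])
        z = xh @ self.params["W"] + self.params["b"]
        i = _sigmoid(z[:H])
        f = _sigmoid(z[H : 2 * H])
        g = np.tanh(z[2 * H : 3 * H])
        o = _sigmoid(z[3 * H :])
        c = f * c_prev + i * g
        tanh_c = np.tanh(c)
        h = o * tanh_c
        cache = (token, xh, i, f, g, o, c_prev, tanh_c)
        return (h, c), cache

    def zero_grads(self) -> dict[str, np.ndarray]:
        return {k: np.zeros_like(v) for k, v in self.params.items()}

    def backward_step(self, dh, dc_next, cache, grads):
        """Backprop one timestep; returns (dh_prev, dc_prev)."""
        token, xh, i, f, g, o, c_prev, tanh_c = cache
        H = self.hidden
        dc = dc_next + dh * o * (1.0 - tanh_c**2)
        do = dh * tanh_c
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dz = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)]
        )
        grads["W"] += np.outer(xh, dz)
        grads["b"] += dz
        dxh = self.params["W"] @ dz
        grads["E"][token] += dxh[: self.embed_dim]
        dh_prev = dxh[self.embed_dim :]
        dc_prev = dc * f
        return dh_prev, dc_prev


class SoftmaxOutput:
    """Linear projection to vocabulary logits.

    Initialized to zero so an untrained model emits the uniform distribution.
    """

    def __init__(self, hidden: int, vocab_size: int):
        self.params = {"Wo": np.zeros((hidden, vocab_size)), "bo": np.zeros(vocab_size)}

    def logits(self, h: np.ndarray) -> np.ndarray:
        return h @ self.params["Wo"] + self.params["bo"]

    def probs(self, h: np.ndarray) -> np.ndarray:
        return softmax(self.logits(h))

    def zero_grads(self) -> dict[str, np.ndarray]:
        return {k: np.zeros_like(v) for k, v in self.params.items()}

    def loss_and_grad(self, h: np.ndarray, target: int, grads):
        """Cross-entropy in nats at one position; returns (loss, dh)."""
        p = self.probs(h)
        loss = -np.log(max(p[target], 1e-300))
        dlogits = p.copy()
        dlogits[target] -= 1.0
        grads["Wo"] += np.outer(h, dlogits)
        grads["bo"] += dlogits
        return loss, self.params["Wo"] @ dlogits


def clip_gradients(grad_groups: list[dict[str, np.ndarray]], max_norm: float) -> float:
    """Scale all gradients jointly so the global L2 norm is <= max_norm.

    Returns the post-clip global norm.
    """
    sq = sum(float((g**2).sum()) for grads in grad_groups for g in grads.values())
    norm = np.sqrt(sq)
    if norm > max_norm and norm > 0:
        scale = max_norm / norm
        for grads in grad_groups:
            for g in grads.values():
                g *= scale
        return max_norm
    return norm


class Adagrad:
    """Adaptive gradient descent: per-parameter learning rates from the
    accumulated squared gradient history."""

    def __init__(self, param_groups: list[dict[str, np.ndarray]], lr: float, eps: float = 1e-8):
        self.param_groups = param_groups
        self.lr = lr
        self.eps = eps
        self.accum = [{k: np.zeros_like(v) for k, v in params.items()} for params in param_groups]

    def update(self, grad_groups: list[dict[str, np.ndarray]]) -> None:
        for params, grads, accum in zip(self.param_groups, grad_groups, self.accum):
            for k in params:
                accum[k] += grads[k] ** 2
                params[k] -= self.lr * grads[k] / (np.sqrt(accum[k]) + self.eps)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
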