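"""NumPy feed-forward softmax network: forward pass, backprop, Adam.

The model is a fully connected net with relu or softplus hidden layers and a
softmax output; the training objective is mean cross-entropy plus an L2
weight penalty lambda * sum(W**2) over all weight matrices (biases are not
penalised).  Gradients are computed analytically by backpropagation; a
numerical-gradient check is part of the test suite.
"""

from __future__ import annotations

import numpy as np

Params = list[tuple[np.ndarray, np.ndarray]]  # (W, b) per layer


def init_params(layer_sizes: list[int], rng: np.random.Generator) -> Params:
    """He-style initialisation for each (fan_in, fan_out) weight matrix."""
    params: Params = []
    for fan_in, fan_out in zip(layer_sizes[:-1], layer_sizes[1:]):
        scale = np.sqrt(2.0 / fan_in)
        params.append((rng.normal(0.0, scale, size=(fan_in, fan_out)),
                       np.zeros(fan_out)))
    return params


def _activate(z: np.ndarray, activation: str) -> np.ndarray:
    if activation == "relu":
        return np.maximum(z, 0.0)
    if activation == "softplus":
        # stable log(1 + e^z)
        return np.logaddexp(0.0, z)
    raise ValueError(f"unknown activation {activation!r}")


def _activate_grad(z: np.ndarray, activation: str) -> np.ndarray:
    if activation == "relu":
        return (z > 0).astype(z.dtype)
    if activation == "softplus":
        return 1.0 / (1.0 + np.exp(-z))
    raise ValueError(f"unknown activation {activation!r}")


def softmax(scores: np.ndarray) -> np.ndarray:
    shifted = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def forward(
    params: Params,
    X: np.ndarray,
    activation: str = "relu",
    dropout_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, list]:
    """Return class probabilities and the per-layer cache for backprop.

    Dropout (inverted scaling) is applied to hidden activations only when an
    rng is supplied, i.e. during training.
    """
    cache = []
    a = X
    n_layers = len(params)
    for i, (W, b) in enumerate(params):
        z = a @ W + b
        if i < n_layers - 1:
            h = _activate(z, activation)
            mask = None
            if dropout_rate > 0.0 and rng is not None:
                mask = (rng.random(h.shape) >= dropout_rate) / (1.0 - dropout_rate)
                h = h * mask
            cache.append((a, z, mask))
            a = h
        else:
            cache.append((a, z, None))
    probs = softmax(cache[-1][1])
    return probs, cache


def loss_and_grads(
    params: Params,
    X: np.ndarray,
    Y_onehot: np.ndarray,
    lambda_l2: float = 0.0,
    activation: str = "relu",
    dropout_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[float, Params]:
    """Mean cross-entropy + lambda * sum(W^2), with analytic gradients."""
    n = X.shape[0]
    probs, cache = forward(params, X, activation, dropout_rate, rng)
    eps = 1e-12
    data_loss = -np.sum(Y_onehot * np.log(probs + eps)) / n
    penalty = lambda_l2 * sum(float(np.sum(W**2)) for W, _ in params)
    loss = data_loss + penalty

    grads: Params = [None] * len(params)  # type: ignore[list-item]
    delta = (probs - Y_onehot) / n  # d loss / d output scores
    for i in range(len(params) - 1, -1, -1):
        a_in, _z, _mask = cache[i]
        W, _b = params[i]
        grads[i] = (a_in.T @ delta + 2.0 * lambda_l2 * W, delta.sum(axis=0))
        if i > 0:
            delta = delta @ W.T  # gradient w.r.t. layer i's (dropped) input
            prev_mask = cache[i - 1][2]
            if prev_mask is not None:
                delta = delta * prev_mask
            delta = delta * _activate_grad(cache[i - 1][1], activation)
    return loss, grads


class Adam:
    """Adaptive-moment estimation with the standard bias correction."""

    def __init__(self, params: Params, learning_rate: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = learning_rate, beta1, beta2, eps
        self.t = 0
        self.m = [(np.zeros_like(W), np.zeros_like(b)) for W, b in params]
        self.v = [(np.zeros_like(W), np.zeros_like(b)) for W, b in params]

    def step(self, params: Params, grads: Params) -> Params:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        out: Params = []
        for i, ((W, b), (gW, gb)) in enumerate(zip(params, grads)):
            mW = b1 * self.m[i][0] + (1 - b1) * gW
            mb = b1 * self.m[i][1] + (1 - b1) * gb
            vW = b2 * self.v[i][0] + (1 - b2) * gW**2
            vb = b2 * self.v[i][1] + (1 - b2) * gb**2
            self.m[i], self.v[i] = (mW, mb), (vW, vb)
            mW_hat, mb_hat = mW / (1 - b1**self.t), mb / (1 - b1**self.t)
            vW_hat, vb_hat = vW / (1 - b2**self.t), vb / (1 - b2**self.t)
            out.append((W - self.lr * mW_hat / (np.sqrt(vW_hat) + self.eps),
                        b - self.lr * mb_hat / (np.sqrt(vb_hat) + self.eps)))
        return out
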