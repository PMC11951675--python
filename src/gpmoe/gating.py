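"""Softmax gating network: a small feedforward ReLU network mapping a
sample's (CLR-transformed) microbial profile to a probability vector over
experts.

Architecture (default): input d -> dense 128 (ReLU) -> dense 64 (ReLU) ->
dropout -> dense L -> softmax.  The final layer is affine (no ReLU) so logits
can be negative.  Dropout is applied only in training mode, after the last
hidden activation; evaluation-mode forward passes are deterministic pure
functions.

Forward and backward passes are explicit numpy; gradients are validated
against finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GatingParams", "init_gating", "gating_forward", "gating_backward"]


@dataclass
class GatingParams:
    """Weights/biases of the gating network.  ``weights[j]`` has shape
    (d_j, d_{j-1}); the last layer maps to L experts."""

    weights: list = field(default_factory=list)
    biases: list = field(default_factory=list)
    hidden_sizes: tuple = (128, 64)
    dropout_rate: float = 0.2

    @property
    def input_dim(self) -> int:
        return self.weights[0].shape[1]

    @property
    def n_experts(self) -> int:
        return self.weights[-1].shape[0]

    def flatten(self) -> list[np.ndarray]:
        return list(self.weights) + list(self.biases)

    def copy(self) -> "GatingParams":
        return GatingParams(
            [w.copy() for w in self.weights],
            [b.copy() for b in self.biases],
            self.hidden_sizes,
            self.dropout_rate,
        )


def init_gating(
    d: int,
    L: int,
    hidden: tuple = (128, 64),
    dropout_rate: float = 0.2,
    seed: int = 0,
) -> GatingParams:
    """Seeded initialization: symmetric uniform weights scaled by fan-in
    (U[-1/sqrt(fan_in), 1/sqrt(fan_in)]), zero biases.  ``hidden=()`` gives a
    single affine layer d -> L."""
    if d < 1 or L < 1:
        raise ValueError("need d >= 1 and L >= 1")
    if not 0.0 <= dropout_rate < 1.0:
        raise ValueError("dropout_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    sizes = [d, *hidden, L]
    weights, biases = [], []
    for j in range(1, len(sizes)):
        fan_in = sizes[j - 1]
        bound = 1.0 / np.sqrt(fan_in)
        weights.append(rng.uniform(-bound, bound, size=(sizes[j], fan_in)))
        biases.append(np.zeros(sizes[j]))
    return GatingParams(weights, biases, tuple(hidden), dropout_rate)


def _softmax(h: np.ndarray) -> np.ndarray:
    h = h - h.max(axis=1, keepdims=True)
    e = np.exp(h)
    return e / e.sum(axis=1, keepdims=True)


def _forward_cached(
    params: GatingParams,
    X: np.ndarray,
    training: bool,
    rng: np.random.Generator | None,
) -> tuple[np.ndarray, dict]:
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != params.input_dim:
        raise ValueError(
            f"X has {X.shape[1]} columns, gating expects {params.input_dim}"
        )
    n_layers = len(params.weights)
    acts = [X]
    mask = None
    a = X
    for j in range(n_layers - 1):
        z = a @ params.weights[j].T + params.biases[j]
        a = np.maximum(z, 0.0)
        if training and params.dropout_rate > 0 and j == n_layers - 2:
            if rng is None:
                rng = np.random.default_rng()
            mask = (rng.random(a.shape) >= params.dropout_rate) / (
                1.0 - params.dropout_rate
            )
            a = a * mask
        acts.append(a)
    logits = a @ params.weights[-1].T + params.biases[-1]
    if not np.all(np.isfinite(logits)):
        raise FloatingPointError("non-finite gating activations")
    W = _softmax(logits)
    return W, {"acts": acts, "mask": mask, "logits": logits}


def gating_forward(
    params: GatingParams,
    X: np.ndarray,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-sample expert weights w_l(x) = softmax(h(x))_l, shape (p, L).
    Rows sum to 1.  Dropout is active only with ``training=True`` (pass a
    seeded ``rng`` for reproducibility)."""
    W, _ = _forward_cached(params, X, training, rng)
    return W


def gating_backward(
    params: GatingParams, cache: dict, dlogits: np.ndarray
) -> list[np.ndarray]:
    """Backpropagate a gradient w.r.t. the output logits h through the
    network.  Returns gradients ordered as ``params.flatten()``:
    all weight matrices, then all bias vectors."""
    acts, mask = cache["acts"], cache["mask"]
    n_layers = len(params.weights)
    gW = [None] * n_layers
    gb = [None] * n_layers
    delta = dlogits
    gW[-1] = delta.T @ acts[-1]
    gb[-1] = delta.sum(axis=0)
    for j in range(n_layers - 2, -1, -1):
        delta = delta @ params.weights[j + 1]
        if mask is not None and j == n_layers - 2:
            delta = delta * mask
        delta = delta * (acts[j + 1] > 0)  # ReLU gate (post-dropout sign is safe: mask >= 0)
        gW[j] = delta.T @ acts[j]
        gb[j] = delta.sum(axis=0)
    return gW + gb


def mixture_nll_and_grads(
    params: GatingParams,
    X: np.ndarray,
    log_component_lik: np.ndarray,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[float, list[np.ndarray]]:
    """Mixture negative log-likelihood of the gated expert mixture and its
    gradients w.r.t. the gating parameters.

    ``log_component_lik[i, l]`` is the log density of sample i's targets
    under expert l (summed over output columns); experts are held fixed.
    The loss is  -sum_i log sum_l w_l(x_i) exp(ll_il), averaged over samples.
    """
    W, cache = _forward_cached(params, X, training, rng)
    h = cache["logits"]
    n = h.shape[0]
    # -logsumexp(h + ll) + logsumexp(h), summed over samples
    a = h + log_component_lik
    amax = a.max(axis=1, keepdims=True)
    lse_num = amax[:, 0] + np.log(np.exp(a - amax).sum(axis=1))
    hmax = h.max(axis=1, keepdims=True)
    lse_den = hmax[:, 0] + np.log(np.exp(h - hmax).sum(axis=1))
    loss = float(np.sum(lse_den - lse_num)) / n
    resp = np.exp(a - lse_num[:, None])  # responsibilities
    dlogits = (W - resp) / n
    grads = gating_backward(params, cache, dlogits)
    return loss, grads
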