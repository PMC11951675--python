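"""Single-expert Gaussian-process regression with an SE-ARD kernel.

Each expert is an exact zero-mean GP regressor

    y(x) = f(x) + eps,   f ~ GP(0, k),   eps ~ N(0, sigma_s^2),

with the squared-exponential automatic-relevance-determination kernel

    k(x, x') = sigma^2 * exp(-1/2 * sum_i (x_i - x'_i)^2 / l_i^2).

Hyperparameters (signal variance sigma^2, per-dimension length scales l_i,
noise variance sigma_s^2) are fitted by minimizing the negative log marginal
likelihood (NLML) in log-parameter space with analytic gradients.  Small
length scales mark inputs the regression function varies quickly along (high
relevance); large length scales effectively switch a dimension off.

Multiple output columns share one kernel and one noise variance: the training
objective is the NLML summed over outputs, so a single expert yields a single
ARD relevance vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize

from ._optim import AdamOptimizer

logger = logging.getLogger(__name__)

__all__ = [
    "ARDKernelParams",
    "GPExpertModel",
    "ard_kernel",
    "kernel_matrix",
    "nlml",
    "fit_gp_expert",
    "posterior_predict",
    "save_expert",
    "load_expert",
]

LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class ARDKernelParams:
    """SE-ARD kernel hyperparameters: signal variance and per-dimension
    length scales, all strictly positive."""

    variance: float
    lengthscales: np.ndarray

    def __post_init__(self) -> None:
        self.lengthscales = np.atleast_1d(np.asarray(self.lengthscales, dtype=float))
        if self.variance <= 0 or np.any(self.lengthscales <= 0):
            raise ValueError("kernel variance and length scales must be > 0")

    @property
    def d(self) -> int:
        return self.lengthscales.size


def ard_kernel(x: np.ndarray, x2: np.ndarray, params: ARDKernelParams) -> float:
    """Evaluate the SE-ARD kernel between two d-vectors."""
    x = np.asarray(x, float).ravel()
    x2 = np.asarray(x2, float).ravel()
    if x.size != params.d or x2.size != params.d:
        raise ValueError(
            f"input dimension ({x.size}, {x2.size}) does not match kernel d={params.d}"
        )
    r2 = np.sum(((x - x2) / params.lengthscales) ** 2)
    return float(params.variance * np.exp(-0.5 * r2))


def kernel_matrix(
    X: np.ndarray,
    X2: np.ndarray | None,
    params: ARDKernelParams,
    jitter: float = 0.0,
) -> np.ndarray:
    """Cross-covariance matrix K(X, X2); with ``X2=None`` the symmetric
    K(X, X) is returned with ``jitter`` added to the diagonal."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != params.d:
        raise ValueError(f"X has {X.shape[1]} columns, kernel expects {params.d}")
    Xs = X / params.lengthscales
    if X2 is None:
        sq = _sq_dists(Xs, Xs)
        K = params.variance * np.exp(-0.5 * sq)
        K[np.diag_indices_from(K)] = params.variance + jitter
    else:
        X2 = np.atleast_2d(np.asarray(X2, float))
        if X2.shape[1] != params.d:
            raise ValueError(f"X2 has {X2.shape[1]} columns, kernel expects {params.d}")
        K = params.variance * np.exp(-0.5 * _sq_dists(Xs, X2 / params.lengthscales))
    if not np.all(np.isfinite(K)):
        raise FloatingPointError("non-finite kernel matrix entries")
    return K


def _sq_dists(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    sq = (
        (A**2).sum(axis=1)[:, None]
        + (B**2).sum(axis=1)[None, :]
        - 2.0 * A @ B.T
    )
    return np.maximum(sq, 0.0)


@dataclass
class GPExpertModel:
    """A trained GP expert: kernel + noise hyperparameters, the training
    block, and a cached Cholesky factor of K(X,X) + sigma_s^2 I."""

    kernel: ARDKernelParams
    noise_variance: float
    train_inputs: np.ndarray
    train_targets: np.ndarray
    label: str = ""
    jitter: float = 0.0
    chol_factor: np.ndarray | None = field(default=None, repr=False)
    _alpha: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.train_inputs = np.atleast_2d(np.asarray(self.train_inputs, float))
        self.train_targets = np.asarray(self.train_targets, float)
        if self.train_targets.ndim == 1:
            self.train_targets = self.train_targets[:, None]
        if self.noise_variance <= 0:
            raise ValueError("noise variance must be > 0")
        if self.train_inputs.shape[0] != self.train_targets.shape[0]:
            raise ValueError("X and Y row counts differ")
        if self.chol_factor is None:
            self._factorize()

    @property
    def n_train(self) -> int:
        return self.train_inputs.shape[0]

    @property
    def n_outputs(self) -> int:
        return self.train_targets.shape[1]

    def _factorize(self) -> None:
        K = kernel_matrix(self.train_inputs, None, self.kernel)
        L, jitter = _chol_with_jitter(
            K + self.noise_variance * np.eye(self.n_train), self.kernel.variance
        )
        self.chol_factor = L
        self.jitter = jitter
        self._alpha = cho_solve((L, True), self.train_targets)


def _chol_with_jitter(A: np.ndarray, scale: float) -> tuple[np.ndarray, float]:
    """Cholesky of A (+ escalating jitter): start at 1e-6*scale, escalate
    tenfold up to 1e-2*scale before giving up."""
    jitter = 0.0
    eye = np.eye(A.shape[0])
    for level in [0.0, 1e-6, 1e-5, 1e-4, 1e-3, 1e-2]:
        jitter = level * scale
        try:
            return cholesky(A + jitter * eye, lower=True), jitter
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError(
        "covariance factorization failed even at jitter 1e-2 * signal variance"
    )


def nlml(model: GPExpertModel, target_column: int | None = None) -> float:
    """Negative log marginal likelihood

        1/2 y^T [K + sigma_s^2 I]^{-1} y + 1/2 log|K + sigma_s^2 I|
        + (n/2) log 2 pi,

    for one output column, or summed over all columns when
    ``target_column=None``."""
    L = model.chol_factor
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    Y = model.train_targets
    if target_column is not None:
        Y = Y[:, [target_column]]
    alpha = cho_solve((L, True), Y)
    quad = 0.5 * float(np.sum(Y * alpha))
    n, m = Y.shape[0], Y.shape[1]
    val = quad + 0.5 * m * logdet + 0.5 * m * n * LOG_2PI
    if not np.isfinite(val):
        raise FloatingPointError("non-finite NLML")
    return val


def _nlml_value_grad(
    theta: np.ndarray, X: np.ndarray, Y: np.ndarray, D_stack: np.ndarray
) -> tuple[float, np.ndarray]:
    """Summed-over-outputs NLML and its gradient w.r.t.
    theta = (log sigma^2, log l_1..l_d, log sigma_s^2)."""
    n, d = X.shape
    m = Y.shape[1]
    sig2 = np.exp(theta[0])
    ls = np.exp(theta[1 : 1 + d])
    noise = np.exp(theta[-1])
    params = ARDKernelParams(sig2, ls)
    K = kernel_matrix(X, None, params)
    A = K + noise * np.eye(n)
    try:
        L, jitter = _chol_with_jitter(A, sig2)
    except np.linalg.LinAlgError:
        return np.inf, np.zeros_like(theta)
    alpha = cho_solve((L, True), Y)  # (n, m)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    val = (
        0.5 * float(np.sum(Y * alpha))
        + 0.5 * m * logdet
        + 0.5 * m * n * LOG_2PI
    )
    # dNLML/dA = 1/2 (m A^{-1} - alpha alpha^T) =: 1/2 M
    A_inv = cho_solve((L, True), np.eye(n))
    M = m * A_inv - alpha @ alpha.T
    grad = np.empty_like(theta)
    grad[0] = 0.5 * float(np.sum(M * K))  # dA/dlog sig2 = K
    # dA/dlog l_i = K * D_i / l_i^2
    MK = M * K
    grad[1 : 1 + d] = 0.5 * np.einsum("ab,iab->i", MK, D_stack) / ls**2
    grad[-1] = 0.5 * noise * float(np.trace(M))  # dA/dlog noise = noise*I
    return val, grad


def _median_lengthscale_init(X: np.ndarray) -> np.ndarray:
    """Per-dimension median absolute pairwise difference, scaled by sqrt(d).

    The sqrt(d) factor keeps the *summed* scaled squared distance O(1) at the
    start, so the initial kernel has non-trivial off-diagonal structure; a
    per-dimension-only median in even moderate d initializes on a plateau
    where the kernel is effectively diagonal and NLML gradients vanish.
    Degenerate (near-constant) dimensions fall back to 1.
    """
    n, d = X.shape
    out = np.empty(d)
    iu = np.triu_indices(n, k=1)
    for i in range(d):
        diffs = np.abs(X[:, i][:, None] - X[:, i][None, :])[iu]
        med = np.median(diffs)
        out[i] = med if med > 1e-8 else 1.0
    return out * np.sqrt(d)


def fit_gp_expert(
    X: np.ndarray,
    Y: np.ndarray,
    init: ARDKernelParams | None = None,
    noise_init: float = 0.1,
    label: str = "",
    optimizer: str = "lbfgs",
    max_iter: int = 500,
    lr: float = 0.01,
    lr_decay: float = 0.95,
    lr_decay_every: int = 500,
    max_train: int = 2000,
    seed: int = 0,
) -> GPExpertModel:
    """Fit a GP expert by type-II maximum likelihood (NLML minimization) in
    log-parameter space.

    ``optimizer`` is ``"lbfgs"`` (default) or ``"adam"`` (exponentially
    decayed learning rate, matching the gating schedule).  ``max_iter=0``
    returns the initialization unchanged.  Blocks larger than ``max_train``
    are fitted on a seeded random subset (see docs/methods.md); set
    ``max_train=None`` to disable.
    """
    X = np.atleast_2d(np.asarray(X, float))
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, d = X.shape
    if n < 2:
        raise ValueError("a GP expert needs at least 2 training samples")
    if np.any(np.all(Y == 0.0, axis=0)):
        raise ValueError("constant-zero target column; drop it before fitting")
    if max_train is not None and n > max_train:
        keep = np.random.default_rng(seed).choice(n, size=max_train, replace=False)
        keep.sort()
        logger.warning(
            "block of %d samples exceeds max_train=%d; fitting on a seeded "
            "subset (subset-of-data approximation)",
            n,
            max_train,
        )
        X, Y = X[keep], Y[keep]
        n = max_train

    if init is None:
        init = ARDKernelParams(1.0, _median_lengthscale_init(X))
    if init.d != d:
        raise ValueError("init lengthscale dimension does not match X")
    theta0 = np.concatenate(
        [[np.log(init.variance)], np.log(init.lengthscales), [np.log(noise_init)]]
    )
    if max_iter == 0:
        return GPExpertModel(init, noise_init, X, Y, label=label)

    D_stack = (X[:, None, :] - X[None, :, :]) ** 2  # (n, n, d) -> transpose below
    D_stack = np.ascontiguousarray(np.moveaxis(D_stack, 2, 0))  # (d, n, n)
    f0, _ = _nlml_value_grad(theta0, X, Y, D_stack)

    bounds = [(-10.0, 10.0)] * theta0.size
    if optimizer == "lbfgs":
        res = minimize(
            _nlml_value_grad,
            theta0,
            args=(X, Y, D_stack),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_iter, "ftol": 1e-9},
        )
        theta, f_final = res.x, res.fun
        if not res.success:
            logger.warning(
                "NLML optimization stopped without convergence (%s); "
                "returning best iterate",
                res.message,
            )
    elif optimizer == "adam":
        adam = AdamOptimizer(
            [theta0.shape], lr=lr, decay=lr_decay, decay_every=lr_decay_every
        )
        theta = theta0.copy()
        best_theta, best_f = theta0.copy(), f0
        for _ in range(max_iter):
            f, g = _nlml_value_grad(theta, X, Y, D_stack)
            if f < best_f:
                best_f, best_theta = f, theta.copy()
            (step,) = adam.step([g])
            theta = np.clip(theta - step, -10.0, 10.0)
        f_final, _ = _nlml_value_grad(theta, X, Y, D_stack)
        if f_final > best_f:
            theta, f_final = best_theta, best_f
    else:
        raise ValueError(f"unknown optimizer {optimizer!r}")

    if f_final > f0:  # never return something worse than the init
        theta, f_final = theta0, f0
    sig2 = float(np.exp(theta[0]))
    ls = np.exp(theta[1 : 1 + d])
    noise = float(np.exp(theta[-1]))
    return GPExpertModel(ARDKernelParams(sig2, ls), noise, X, Y, label=label)


def posterior_predict(
    model: GPExpertModel, Xstar: np.ndarray, include_noise: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """GP posterior predictive at test points.

    mean = K(X*,X) [K + sigma_s^2 I]^{-1} Y           (per output column)
    var  = k(x*,x*) - K(x*,X) [K + sigma_s^2 I]^{-1} K(X,x*)

    The latent variance is shared across output columns (one kernel) and
    broadcast to shape (p, m).  ``include_noise=True`` adds the observation
    noise sigma_s^2, giving the predictive variance for new observations.
    """
    Xstar = np.atleast_2d(np.asarray(Xstar, float))
    if Xstar.shape[1] != model.kernel.d:
        raise ValueError(
            f"Xstar has {Xstar.shape[1]} columns, model expects {model.kernel.d}"
        )
    Ks = kernel_matrix(Xstar, model.train_inputs, model.kernel)  # (p, n)
    mean = Ks @ model._alpha  # (p, m)
    v = solve_triangular(model.chol_factor, Ks.T, lower=True)  # (n, p)
    var = model.kernel.variance - np.einsum("ij,ij->j", v, v)  # (p,)
    var = np.maximum(var, 0.0)
    if include_noise:
        var = var + model.noise_variance
    var = np.broadcast_to(var[:, None], mean.shape).copy()
    return mean, var


# ---------------------------------------------------------------------------
# serialization

_SCHEMA_VERSION = 1


def save_expert(model: GPExpertModel, path: str | Path) -> None:
    """Serialize an expert to an .npz archive (versioned schema)."""
    np.savez(
        path,
        schema_version=_SCHEMA_VERSION,
        variance=model.kernel.variance,
        lengthscales=model.kernel.lengthscales,
        noise_variance=model.noise_variance,
        train_inputs=model.train_inputs,
        train_targets=model.train_targets,
        label=np.array(model.label),
    )


def load_expert(path: str | Path) -> GPExpertModel:
    with np.load(path, allow_pickle=False) as z:
        if int(z["schema_version"]) != _SCHEMA_VERSION:
            raise ValueError("unsupported expert archive schema version")
        return GPExpertModel(
            ARDKernelParams(float(z["variance"]), z["lengthscales"]),
            float(z["noise_variance"]),
            z["train_inputs"],
            z["train_targets"],
            label=str(z["label"]),
        )
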