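"""Mixture of GP experts with a learned softmax gate.

Training is two-phase by default:

* **Phase 1** — samples are partitioned into blocks (by phenotype label,
  randomly, or phenotype-halved "double experts") and one GP expert is fitted
  per block by NLML minimization.
* **Phase 2** — with experts frozen, the gating network is trained on *all*
  training samples by minimizing the mixture negative log-likelihood
  -sum_i log sum_l w_l(x_i) N(y_i | f_l(x_i), s_l^2(x_i)), with Adam
  (initial learning rate 0.01, decayed by 0.95 every 500 steps).
* **Phase 3 (optional)** — alternating refinement rounds: training samples
  are reassigned to their highest-responsibility expert, experts are refitted
  on the new blocks, and the gate is retrained.

Prediction moment-matches the gated mixture:

    mu(x)      = sum_l w_l(x) f_l(x)
    sigma^2(x) = sum_l w_l(x) [ s_l^2(x) + (f_l(x) - mu(x))^2 ]

so the predictive variance carries both each expert's own uncertainty and the
between-expert disagreement.  Expert predictive variances include observation
noise, so mu +/- 2 sigma is a 95% credible band for new observations.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_io import PairedDataset
from .gating import GatingParams, gating_forward, init_gating, mixture_nll_and_grads
from .gp_expert import (
    ARDKernelParams,
    GPExpertModel,
    fit_gp_expert,
    posterior_predict,
)
from ._optim import AdamOptimizer

logger = logging.getLogger(__name__)

__all__ = [
    "ExpertAllocation",
    "MixturePrediction",
    "MoEConfig",
    "MoEModel",
    "allocate_experts",
    "train_dmovgpe",
    "predict_mixture",
    "mixture_moments",
    "credible_interval",
    "save_model",
    "load_model",
]

LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class ExpertAllocation:
    """Disjoint partition of training-sample indices into expert blocks."""

    strategy: str
    partition: dict[int, np.ndarray]
    expert_labels: list[str]

    @property
    def n_experts(self) -> int:
        return len(self.expert_labels)

    def validate(self, n: int) -> None:
        all_idx = np.concatenate([self.partition[l] for l in range(self.n_experts)])
        if len(all_idx) != n or len(np.unique(all_idx)) != n:
            raise ValueError("partition blocks must be disjoint and cover all samples")


def allocate_experts(
    labels: np.ndarray,
    strategy: str = "phenotype",
    seed: int = 0,
    min_block: int = 5,
) -> ExpertAllocation:
    """Partition training samples into expert blocks.

    * ``phenotype``: one expert per distinct label (sorted order).
    * ``random``: same number of experts, seeded shuffle into
      equal-as-possible blocks, labels ignored.
    * ``double``: each label block split in half (sizes differ by <= 1),
      doubling the expert count.

    Blocks smaller than ``min_block`` trigger a warning (small phenotype
    groups give weakly trained experts), not a failure.
    """
    labels = np.asarray(labels)
    distinct = sorted(np.unique(labels).tolist())
    n = labels.size
    partition: dict[int, np.ndarray] = {}
    expert_labels: list[str] = []
    if strategy == "phenotype":
        for lab in distinct:
            partition[len(expert_labels)] = np.flatnonzero(labels == lab)
            expert_labels.append(str(lab))
    elif strategy == "random":
        L = len(distinct)
        perm = np.random.default_rng(seed).permutation(n)
        for l, block in enumerate(np.array_split(perm, L)):
            partition[l] = np.sort(block)
            expert_labels.append(f"random_{l}")
    elif strategy == "double":
        rng = np.random.default_rng(seed)
        for lab in distinct:
            idx = np.flatnonzero(labels == lab)
            idx = rng.permutation(idx)
            half = (idx.size + 1) // 2
            for part, sub in enumerate((idx[:half], idx[half:])):
                partition[len(expert_labels)] = np.sort(sub)
                expert_labels.append(f"{lab}_{part + 1}")
    else:
        raise ValueError(f"unknown allocation strategy {strategy!r}")
    for l, block in partition.items():
        if block.size == 0:
            raise ValueError(f"expert block {expert_labels[l]!r} is empty")
        if block.size < min_block:
            warnings.warn(
                f"expert block {expert_labels[l]!r} has only {block.size} "
                f"samples (< {min_block}); its GP expert may be weakly trained",
                stacklevel=2,
            )
    alloc = ExpertAllocation(strategy, partition, expert_labels)
    alloc.validate(n)
    return alloc


@dataclass
class MixturePrediction:
    """Moment-matched mixture prediction: means, total variances, and the
    per-sample expert weights that produced them."""

    mean: np.ndarray
    variance: np.ndarray
    expert_weights: np.ndarray
    per_expert_means: np.ndarray | None = None


@dataclass
class MoEConfig:
    """Training configuration.  Defaults follow the reference protocol:
    128/64 hidden gating units with dropout, Adam at 0.01 decayed by 0.95
    every 500 steps, 2000 gating steps with early stopping."""

    hidden_sizes: tuple = (128, 64)
    dropout_rate: float = 0.2
    gating_steps: int = 2000
    lr: float = 0.01
    lr_decay: float = 0.95
    lr_decay_every: int = 500
    batch_size: int | None = None  # None: full batch for n<=512, else 64
    patience: int = 200
    gp_optimizer: str = "lbfgs"
    gp_max_iter: int = 500
    gp_noise_init: float = 0.1
    gp_max_train: int = 2000
    joint_finetune_rounds: int = 0
    seed: int = 0


@dataclass
class MoEModel:
    experts: list[GPExpertModel]
    gating: GatingParams
    allocation: ExpertAllocation
    config: MoEConfig = field(default_factory=MoEConfig)
    feature_names: list[str] | None = None
    target_names: list[str] | None = None

    @property
    def n_experts(self) -> int:
        return len(self.experts)


def _expert_log_lik(
    experts: list[GPExpertModel], X: np.ndarray, Y: np.ndarray
) -> np.ndarray:
    """log N(y_i | f_l(x_i), s_l^2(x_i)) summed over output columns -> (n, L)."""
    n, L = X.shape[0], len(experts)
    ll = np.empty((n, L))
    for l, ex in enumerate(experts):
        mean, var = posterior_predict(ex, X, include_noise=True)
        var = np.maximum(var, 1e-12)
        ll[:, l] = -0.5 * np.sum(
            (Y - mean) ** 2 / var + np.log(var) + LOG_2PI, axis=1
        )
    return ll


def _train_gating(
    gating: GatingParams,
    X: np.ndarray,
    log_lik: np.ndarray,
    cfg: MoEConfig,
    seed: int,
) -> GatingParams:
    n = X.shape[0]
    if cfg.gating_steps <= 0 or gating.n_experts == 1:
        return gating
    batch = cfg.batch_size or (n if n <= 512 else 64)
    batch = min(batch, n)
    rng = np.random.default_rng(seed)
    params = gating.copy()
    adam = AdamOptimizer(
        [a.shape for a in params.flatten()],
        lr=cfg.lr,
        decay=cfg.lr_decay,
        decay_every=cfg.lr_decay_every,
    )
    best_loss, best_params, since_best = np.inf, params.copy(), 0
    lr_halvings = 0
    step = 0
    while step < cfg.gating_steps:
        idx = np.arange(n) if batch == n else rng.choice(n, size=batch, replace=False)
        loss, grads = mixture_nll_and_grads(
            params, X[idx], log_lik[idx], training=True, rng=rng
        )
        if not np.isfinite(loss):
            lr_halvings += 1
            if lr_halvings > 3:
                raise FloatingPointError("gating loss diverged (NaN) after 3 restarts")
            adam.lr0 *= 0.5
            adam.reset_moments()
            params = best_params.copy()
            logger.warning("non-finite gating loss; halving learning rate and retrying")
            continue
        for p, upd in zip(params.flatten(), adam.step(grads)):
            p -= upd
        step += 1
        # early stopping on the training loss (stochastic under dropout)
        if loss < best_loss - 1e-9:
            best_loss, best_params, since_best = loss, params.copy(), 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                logger.info("gating early-stopped at step %d", step)
                break
    return best_params


def train_dmovgpe(
    dataset: PairedDataset,
    allocation: ExpertAllocation,
    config: MoEConfig | None = None,
) -> MoEModel:
    """Train the full mixture on a preprocessed (CLR-transformed) dataset.

    Inputs are the microbial table, targets the metabolite table.  Experts
    are fitted on their allocated blocks; the gate is then trained on all
    samples with experts frozen.  All randomness flows from ``config.seed``.
    """
    cfg = config or MoEConfig()
    X, Y = dataset.microbial, dataset.metabolite
    allocation.validate(X.shape[0])
    experts = []
    for l in range(allocation.n_experts):
        block = allocation.partition[l]
        experts.append(
            fit_gp_expert(
                X[block],
                Y[block],
                label=allocation.expert_labels[l],
                optimizer=cfg.gp_optimizer,
                max_iter=cfg.gp_max_iter,
                noise_init=cfg.gp_noise_init,
                lr=cfg.lr,
                lr_decay=cfg.lr_decay,
                lr_decay_every=cfg.lr_decay_every,
                max_train=cfg.gp_max_train,
                seed=cfg.seed + l,
            )
        )
    gating = init_gating(
        X.shape[1],
        allocation.n_experts,
        hidden=cfg.hidden_sizes,
        dropout_rate=cfg.dropout_rate,
        seed=cfg.seed,
    )
    log_lik = _expert_log_lik(experts, X, Y)
    gating = _train_gating(gating, X, log_lik, cfg, seed=cfg.seed + 1000)

    model = MoEModel(
        experts,
        gating,
        allocation,
        cfg,
        feature_names=list(dataset.microbial_names),
        target_names=list(dataset.metabolite_names),
    )
    for round_ in range(cfg.joint_finetune_rounds):
        model = _finetune_round(model, X, Y, cfg, round_)
    return model


def _finetune_round(
    model: MoEModel, X: np.ndarray, Y: np.ndarray, cfg: MoEConfig, round_: int
) -> MoEModel:
    """One coordinate-ascent refinement round: hard-reassign samples to their
    max-responsibility expert, refit experts, retrain gating."""
    log_lik = _expert_log_lik(model.experts, X, Y)
    logw = np.log(
        np.maximum(gating_forward(model.gating, X, training=False), 1e-300)
    )
    assign = np.argmax(logw + log_lik, axis=1)
    partition = {}
    for l in range(model.n_experts):
        block = np.flatnonzero(assign == l)
        # keep an expert alive on its old block if it loses every sample
        partition[l] = block if block.size >= 2 else model.allocation.partition[l]
    alloc = ExpertAllocation(
        f"{model.allocation.strategy}+finetune",
        partition,
        model.allocation.expert_labels,
    )
    experts = [
        fit_gp_expert(
            X[partition[l]],
            Y[partition[l]],
            init=model.experts[l].kernel,
            noise_init=model.experts[l].noise_variance,
            label=model.allocation.expert_labels[l],
            optimizer=cfg.gp_optimizer,
            max_iter=cfg.gp_max_iter,
            max_train=cfg.gp_max_train,
            seed=cfg.seed + 2000 + l,
        )
        for l in range(model.n_experts)
    ]
    log_lik = _expert_log_lik(experts, X, Y)
    gating = _train_gating(
        model.gating, X, log_lik, cfg, seed=cfg.seed + 3000 + round_
    )
    return MoEModel(
        experts, gating, alloc, cfg, model.feature_names, model.target_names
    )


def mixture_moments(
    weights: np.ndarray, means: np.ndarray, variances: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Moment-match a finite Gaussian mixture.

    weights (p, L); means, variances (L, p, m).  Returns mixture mean and
    variance of shape (p, m):

        mu      = sum_l w_l m_l
        sigma^2 = sum_l w_l (v_l + (m_l - mu)^2)
    """
    w = weights.T[:, :, None]  # (L, p, 1)
    mu = np.sum(w * means, axis=0)
    var = np.sum(w * (variances + (means - mu[None]) ** 2), axis=0)
    return mu, var


def predict_mixture(
    model: MoEModel, Xstar: np.ndarray, keep_expert_means: bool = False
) -> MixturePrediction:
    """Moment-matched mixture prediction at test points (evaluation-mode
    gating, no dropout)."""
    Xstar = np.atleast_2d(np.asarray(Xstar, float))
    L = model.n_experts
    means = []
    variances = []
    for ex in model.experts:
        m, v = posterior_predict(ex, Xstar, include_noise=True)
        means.append(m)
        variances.append(v)
    means = np.stack(means)  # (L, p, m)
    variances = np.stack(variances)
    weights = gating_forward(model.gating, Xstar, training=False)
    mu, var = mixture_moments(weights, means, variances)
    return MixturePrediction(
        mu, var, weights, per_expert_means=means if keep_expert_means else None
    )


def credible_interval(
    pred: MixturePrediction, k_sigma: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """mu +/- k_sigma * sigma bounds (k_sigma=2: the 95% credible band)."""
    half = k_sigma * np.sqrt(np.maximum(pred.variance, 0.0))
    return pred.mean - half, pred.mean + half


# ---------------------------------------------------------------------------
# model archive

_SCHEMA_VERSION = 1


def save_model(model: MoEModel, path: str | Path) -> None:
    """Write the model to a directory archive: a JSON manifest plus one .npz
    of arrays.  Loadable for prediction without refitting."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "schema_version": _SCHEMA_VERSION,
        "n_experts": model.n_experts,
        "expert_labels": model.allocation.expert_labels,
        "strategy": model.allocation.strategy,
        "hidden_sizes": list(model.gating.hidden_sizes),
        "dropout_rate": model.gating.dropout_rate,
        "feature_names": model.feature_names,
        "target_names": model.target_names,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(model.config).items()
        },
    }
    (path / "model.json").write_text(json.dumps(manifest, indent=2))
    arrays = {}
    for l, ex in enumerate(model.experts):
        arrays[f"expert{l}_variance"] = np.array(ex.kernel.variance)
        arrays[f"expert{l}_lengthscales"] = ex.kernel.lengthscales
        arrays[f"expert{l}_noise"] = np.array(ex.noise_variance)
        arrays[f"expert{l}_X"] = ex.train_inputs
        arrays[f"expert{l}_Y"] = ex.train_targets
        arrays[f"expert{l}_block"] = model.allocation.partition[l]
    for j, (w, b) in enumerate(zip(model.gating.weights, model.gating.biases)):
        arrays[f"gating_W{j}"] = w
        arrays[f"gating_b{j}"] = b
    np.savez(path / "arrays.npz", **arrays)


def load_model(path: str | Path) -> MoEModel:
    path = Path(path)
    manifest = json.loads((path / "model.json").read_text())
    if manifest["schema_version"] != _SCHEMA_VERSION:
        raise ValueError("unsupported model archive schema version")
    z = np.load(path / "arrays.npz", allow_pickle=False)
    experts = []
    partition = {}
    for l in range(manifest["n_experts"]):
        experts.append(
            GPExpertModel(
                ARDKernelParams(
                    float(z[f"expert{l}_variance"]), z[f"expert{l}_lengthscales"]
                ),
                float(z[f"expert{l}_noise"]),
                z[f"expert{l}_X"],
                z[f"expert{l}_Y"],
                label=manifest["expert_labels"][l],
            )
        )
        partition[l] = z[f"expert{l}_block"]
    n_layers = len(manifest["hidden_sizes"]) + 1
    gating = GatingParams(
        [z[f"gating_W{j}"] for j in range(n_layers)],
        [z[f"gating_b{j}"] for j in range(n_layers)],
        tuple(manifest["hidden_sizes"]),
        manifest["dropout_rate"],
    )
    alloc = ExpertAllocation(
        manifest["strategy"], partition, manifest["expert_labels"]
    )
    cfg_kwargs = manifest["config"]
    cfg_kwargs["hidden_sizes"] = tuple(cfg_kwargs["hidden_sizes"])
    cfg = MoEConfig(**cfg_kwargs)
    return MoEModel(
        experts,
        gating,
        alloc,
        cfg,
        manifest["feature_names"],
        manifest["target_names"],
    )
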