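"""Evaluation metrics and the stratified cross-validation harness.

The headline metric is Spearman's rank correlation coefficient (SCC) between
predicted and observed metabolite abundances, computed two ways:

* **per sample** — across the m metabolites of one sample; the mean over
  samples is the aggregate accuracy figure;
* **per metabolite** — across the n samples of one metabolite; used for the
  top-k means, and for the count of metabolites with SCC > 0.5, reported on a
  log10(count + 1) scale so zero counts stay finite.

Cross-validation is stratified five-fold by phenotype label, with
preprocessing statistics (feature filter, zero-replacement values) fitted on
each training fold only.  Fold results are reported as mean +/- sd.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .data_io import PairedDataset, Preprocessor
from .moe import MoEConfig, allocate_experts, predict_mixture, train_dmovgpe

logger = logging.getLogger(__name__)

__all__ = [
    "spearman",
    "per_sample_scc",
    "per_metabolite_scc",
    "EvalReport",
    "evaluate_predictions",
    "crossvalidate",
]


def spearman(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks (average
    ranks for ties).  Returns NaN for constant inputs (undefined)."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.size != b.size or a.size < 2:
        raise ValueError("spearman needs two equal-length vectors of length >= 2")
    if np.all(a == a[0]) or np.all(b == b[0]):
        warnings.warn("constant vector: Spearman correlation undefined", stacklevel=2)
        return float("nan")
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    return float(ra @ rb / math.sqrt((ra @ ra) * (rb @ rb)))


def _rowwise_scc(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Vectorized Spearman between corresponding rows of A and B; NaN rows
    where either side is constant."""
    ra = stats.rankdata(A, axis=1)
    rb = stats.rankdata(B, axis=1)
    ra = ra - ra.mean(axis=1, keepdims=True)
    rb = rb - rb.mean(axis=1, keepdims=True)
    na = np.sqrt((ra * ra).sum(axis=1))
    nb = np.sqrt((rb * rb).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (ra * rb).sum(axis=1) / (na * nb)
    out[(na == 0) | (nb == 0)] = np.nan
    return out


def per_sample_scc(Y_true: np.ndarray, Y_pred: np.ndarray) -> np.ndarray:
    """SCC of each sample's predicted vs observed metabolite profile."""
    Y_true, Y_pred = np.asarray(Y_true, float), np.asarray(Y_pred, float)
    if Y_true.shape != Y_pred.shape:
        raise ValueError("shape mismatch between truth and prediction")
    return _rowwise_scc(Y_true, Y_pred)


def per_metabolite_scc(Y_true: np.ndarray, Y_pred: np.ndarray) -> np.ndarray:
    """SCC of each metabolite across samples."""
    Y_true, Y_pred = np.asarray(Y_true, float), np.asarray(Y_pred, float)
    if Y_true.shape != Y_pred.shape:
        raise ValueError("shape mismatch between truth and prediction")
    return _rowwise_scc(Y_true.T, Y_pred.T)


@dataclass
class EvalReport:
    """Metric bundle for one evaluation (optionally aggregated over folds)."""

    per_sample: np.ndarray
    per_metabolite: np.ndarray
    mean_scc_samples: float
    mean_scc_top10: float
    mean_scc_top50: float
    n_scc_gt_threshold: int
    log10_count: float
    threshold: float = 0.5
    n_undefined: int = 0
    fold_means: list[float] = field(default_factory=list)
    summary_mean: float = float("nan")
    summary_sd: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "mean_scc_samples": self.mean_scc_samples,
            "mean_scc_top10": self.mean_scc_top10,
            "mean_scc_top50": self.mean_scc_top50,
            "n_scc_gt_threshold": self.n_scc_gt_threshold,
            "log10_count": self.log10_count,
            "threshold": self.threshold,
            "n_undefined": self.n_undefined,
            "fold_means": list(self.fold_means),
            "summary_mean": self.summary_mean,
            "summary_sd": self.summary_sd,
        }


def _top_k_mean(per_met: np.ndarray, k: int) -> float:
    vals = per_met[~np.isnan(per_met)]
    if vals.size == 0:
        return float("nan")
    if k > vals.size:
        warnings.warn(
            f"top-{k} requested but only {vals.size} metabolites with defined "
            "SCC; truncating",
            stacklevel=2,
        )
        k = vals.size
    return float(np.sort(vals)[::-1][:k].mean())


def evaluate_predictions(
    Y_true: np.ndarray, Y_pred: np.ndarray, threshold: float = 0.5
) -> EvalReport:
    """Compute the full metric suite for one prediction matrix."""
    ps = per_sample_scc(Y_true, Y_pred)
    pm = per_metabolite_scc(Y_true, Y_pred)
    n_undef = int(np.isnan(ps).sum() + np.isnan(pm).sum())
    if n_undef:
        logger.warning(
            "%d undefined SCC value(s) (constant vectors) excluded from means",
            n_undef,
        )
    count = int(np.nansum(pm > threshold))
    return EvalReport(
        per_sample=ps,
        per_metabolite=pm,
        mean_scc_samples=float(np.nanmean(ps)),
        mean_scc_top10=_top_k_mean(pm, 10),
        mean_scc_top50=_top_k_mean(pm, 50),
        n_scc_gt_threshold=count,
        log10_count=float(np.log10(count + 1)),
        threshold=threshold,
        n_undefined=n_undef,
    )


def crossvalidate(
    dataset: PairedDataset,
    config: MoEConfig | None = None,
    strategy: str = "phenotype",
    k: int = 5,
    seed: int = 0,
    max_zero_fraction: float = 0.5,
    epsilon: float | None = None,
    clr_tables: str = "both",
    threshold: float = 0.5,
) -> EvalReport:
    """Stratified k-fold cross-validation of the mixture model on a *raw*
    paired dataset.

    Each fold: fit preprocessing on the training split, transform both
    splits, allocate experts, train, predict the held-out split.  Every
    sample is tested exactly once; pooled predictions feed the metric suite
    and per-fold mean per-sample SCCs give the mean +/- sd summary.
    """
    cfg = config or MoEConfig(seed=seed)
    labels = dataset.labels
    min_class = min(np.bincount(np.unique(labels, return_inverse=True)[1]))
    if min_class < k:
        warnings.warn(
            f"smallest label group has {min_class} samples; reducing folds "
            f"from {k} to {min_class}",
            stacklevel=2,
        )
        k = max(2, min_class)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    n = dataset.n_samples
    m_orig = dataset.n_metabolites
    fold_means = []
    per_sample_all = np.full(n, np.nan)
    # per-metabolite SCC per fold, mapped to original feature indices
    # (folds may filter different sparse features)
    per_met_folds = np.full((k, m_orig), np.nan)
    for fold, (tr, te) in enumerate(skf.split(np.zeros(n), labels)):
        train = dataset.subset_samples(tr)
        test = dataset.subset_samples(te)
        prep = Preprocessor(
            max_zero_fraction=max_zero_fraction, epsilon=epsilon, which=clr_tables
        )
        train_t = prep.fit_transform(train)
        test_t = prep.transform(test)
        alloc = allocate_experts(train_t.labels, strategy, seed=seed + fold)
        fold_cfg = MoEConfig(**{**vars(cfg), "seed": cfg.seed + fold})
        model = train_dmovgpe(train_t, alloc, fold_cfg)
        pred = predict_mixture(model, test_t.microbial)
        per_sample_all[te] = per_sample_scc(test_t.metabolite, pred.mean)
        per_met_folds[fold, prep.keep_metabolite] = per_metabolite_scc(
            test_t.metabolite, pred.mean
        )
        fold_means.append(float(np.nanmean(per_sample_all[te])))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        per_met = np.nanmean(per_met_folds, axis=0)
    n_undef = int(np.isnan(per_sample_all).sum() + np.isnan(per_met).sum())
    count = int(np.nansum(per_met > threshold))
    report = EvalReport(
        per_sample=per_sample_all,
        per_metabolite=per_met,
        mean_scc_samples=float(np.nanmean(per_sample_all)),
        mean_scc_top10=_top_k_mean(per_met, 10),
        mean_scc_top50=_top_k_mean(per_met, 50),
        n_scc_gt_threshold=count,
        log10_count=float(np.log10(count + 1)),
        threshold=threshold,
        n_undefined=n_undef,
        fold_means=fold_means,
        summary_mean=float(np.mean(fold_means)),
        summary_sd=float(np.std(fold_means, ddof=1)) if len(fold_means) > 1 else 0.0,
    )
    return report
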