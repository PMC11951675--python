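"""ARD-based interpretability.

A fitted SE-ARD kernel carries one length scale per microbial feature; the
regression function varies fastest along dimensions with *small* length
scales, so the inverse length scale 1/l_i is a relevance score.  Because each
expert is fitted on one phenotype block, per-expert rankings are
phenotype-specific, while a single pooled GP yields a population-wide
ranking.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .gp_expert import GPExpertModel
from .moe import MoEModel

__all__ = [
    "FeatureRelevance",
    "relevance_from_expert",
    "top_features",
    "relevance_table",
    "plot_relevance",
]


@dataclass
class FeatureRelevance:
    """Per-expert feature relevance: inverse length scales and the induced
    descending rank order (ties broken by feature name, lexicographically)."""

    expert_label: str
    feature_names: list[str]
    inverse_lengthscales: np.ndarray
    rank_order: np.ndarray

    @property
    def d(self) -> int:
        return len(self.feature_names)


def relevance_from_expert(
    model: GPExpertModel, feature_names: list[str] | None = None
) -> FeatureRelevance:
    """Relevance scores 1/l_i of a fitted expert (the model is not mutated)."""
    ls = model.kernel.lengthscales
    if feature_names is None:
        feature_names = [f"feature_{i}" for i in range(ls.size)]
    if len(feature_names) != ls.size:
        raise ValueError("feature_names length does not match kernel dimension")
    inv = 1.0 / ls
    order = sorted(range(ls.size), key=lambda i: (-inv[i], feature_names[i]))
    return FeatureRelevance(
        model.label, list(feature_names), inv, np.asarray(order, dtype=int)
    )


def top_features(
    relevance: FeatureRelevance, k: int = 10
) -> list[tuple[str, float]]:
    """The ``k`` most relevant features as (name, inverse length scale)
    pairs, most relevant first."""
    if not 1 <= k <= relevance.d:
        raise ValueError(f"k must be in [1, {relevance.d}], got {k}")
    return [
        (relevance.feature_names[i], float(relevance.inverse_lengthscales[i]))
        for i in relevance.rank_order[:k]
    ]


def relevance_table(model: MoEModel, k: int | None = None) -> pd.DataFrame:
    """Long-format ranking across all experts of a mixture model with
    columns (expert, rank, feature, inverse_lengthscale)."""
    rows = []
    for ex in model.experts:
        rel = relevance_from_expert(ex, model.feature_names)
        kk = k if k is not None else rel.d
        for rank, (name, val) in enumerate(top_features(rel, min(kk, rel.d)), 1):
            rows.append(
                {
                    "expert": ex.label,
                    "rank": rank,
                    "feature": name,
                    "inverse_lengthscale": val,
                }
            )
    return pd.DataFrame(rows)


def plot_relevance(
    relevance: FeatureRelevance, k: int = 10, path: str | Path | None = None
):
    """Horizontal-bar plot of the top-k inverse length scales (raw values,
    no cross-expert normalization).  Requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pairs = top_features(relevance, k)
    names = [p[0] for p in pairs][::-1]
    vals = [p[1] for p in pairs][::-1]
    fig, ax = plt.subplots(figsize=(6, 0.4 * k + 1))
    ax.barh(names, vals, color="#4c72b0")
    ax.set_xlabel("inverse length scale (1/l)")
    ax.set_title(f"Top-{k} features — expert {relevance.expert_label!r}")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
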