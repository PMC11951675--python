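"""Paired microbiome-metabolome tables: I/O and compositional preprocessing.

Abundance tables are sample-by-feature matrices (samples in rows, features in
columns, first column holds sample IDs). Preprocessing follows the standard
compositional pipeline for such data:

1. drop features with more than ``max_zero_fraction`` of their values equal to
   zero (default: strictly more than 50%);
2. replace remaining zeros with a small positive value (default: half the
   smallest positive value of that feature, the multiplicative-replacement
   convention);
3. centred log-ratio (CLR) transform each row,
   ``clr(x)_j = log(x_j / gmean(x))``, so every row sums to zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RAW = "raw"
CLR = "clr"

__all__ = [
    "PairedDataset",
    "read_paired_tables",
    "filter_sparse_features",
    "replace_zeros",
    "clr_transform",
    "preprocess",
    "Preprocessor",
    "write_paired_tables",
]


@dataclass
class PairedDataset:
    """Aligned microbial and metabolite abundance matrices with labels.

    Both matrices share the row order of ``sample_ids``.  ``*_transformed``
    flags record whether a table still holds raw non-negative abundances
    (``"raw"``) or CLR-transformed real values (``"clr"``).
    """

    sample_ids: list[str]
    microbial: np.ndarray
    metabolite: np.ndarray
    microbial_names: list[str]
    metabolite_names: list[str]
    labels: np.ndarray
    microbial_transformed: str = RAW
    metabolite_transformed: str = RAW

    def __post_init__(self) -> None:
        self.microbial = np.asarray(self.microbial, dtype=float)
        self.metabolite = np.asarray(self.metabolite, dtype=float)
        self.labels = np.asarray(self.labels)
        self.validate()

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_microbes(self) -> int:
        return self.microbial.shape[1]

    @property
    def n_metabolites(self) -> int:
        return self.metabolite.shape[1]

    def validate(self) -> None:
        n = self.n_samples
        if self.microbial.shape != (n, len(self.microbial_names)):
            raise ValueError(
                f"microbial matrix shape {self.microbial.shape} inconsistent "
                f"with {n} samples x {len(self.microbial_names)} features"
            )
        if self.metabolite.shape != (n, len(self.metabolite_names)):
            raise ValueError(
                f"metabolite matrix shape {self.metabolite.shape} inconsistent "
                f"with {n} samples x {len(self.metabolite_names)} features"
            )
        if self.labels.shape != (n,):
            raise ValueError("labels must have one entry per sample")
        for name, mat, flag in (
            ("microbial", self.microbial, self.microbial_transformed),
            ("metabolite", self.metabolite, self.metabolite_transformed),
        ):
            if not np.all(np.isfinite(mat)):
                raise ValueError(f"{name} table contains non-finite values")
            if flag == RAW and mat.size and mat.min() < 0:
                raise ValueError(f"raw {name} abundances must be non-negative")

    def copy(self, **changes) -> "PairedDataset":
        base = dict(
            sample_ids=list(self.sample_ids),
            microbial=self.microbial.copy(),
            metabolite=self.metabolite.copy(),
            microbial_names=list(self.microbial_names),
            metabolite_names=list(self.metabolite_names),
            labels=self.labels.copy(),
            microbial_transformed=self.microbial_transformed,
            metabolite_transformed=self.metabolite_transformed,
        )
        base.update(changes)
        return PairedDataset(**base)

    def subset_samples(self, idx: Sequence[int]) -> "PairedDataset":
        idx = np.asarray(idx, dtype=int)
        return self.copy(
            sample_ids=[self.sample_ids[i] for i in idx],
            microbial=self.microbial[idx],
            metabolite=self.metabolite[idx],
            labels=self.labels[idx],
        )


def _read_table(path: Path, transpose: bool = False) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if transpose:
        df = df.T
    df.index = df.index.astype(str)
    return df


def _to_numeric(df: pd.DataFrame, table_name: str) -> np.ndarray:
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = ~np.isfinite(values)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-numeric abundance in {table_name} table at "
            f"sample '{df.index[i]}', feature '{df.columns[j]}'"
        )
    return values


def read_paired_tables(
    microbial_path: str | Path,
    metabolite_path: str | Path,
    metadata_path: str | Path,
    label_column: str,
    transpose: bool = False,
    transformed: str = RAW,
) -> PairedDataset:
    """Read microbial, metabolite and metadata tables and align them on the
    intersection of sample IDs (order follows the microbial table).

    TSV is assumed unless the file name ends in ``.csv``.  Samples missing
    from any table are dropped with a warning; an empty intersection is fatal.
    ``transformed="clr"`` marks tables that were already CLR-transformed
    (e.g. written by a previous preprocessing run).
    """
    mic = _read_table(Path(microbial_path), transpose)
    met = _read_table(Path(metabolite_path), transpose)
    meta = _read_table(Path(metadata_path))
    if label_column not in meta.columns:
        raise ValueError(
            f"label column '{label_column}' not found in metadata "
            f"(available: {list(meta.columns)})"
        )
    labels = meta[label_column].dropna()
    shared = [s for s in mic.index if s in met.index and s in labels.index]
    if not shared:
        raise ValueError("no overlapping samples between the three tables")
    n_dropped = len(set(mic.index) | set(met.index)) - len(shared)
    if n_dropped:
        logger.warning(
            "dropped %d sample(s) absent from at least one table or "
            "missing a label; %d retained",
            n_dropped,
            len(shared),
        )
    mic = mic.loc[shared]
    met = met.loc[shared]
    return PairedDataset(
        sample_ids=list(shared),
        microbial=_to_numeric(mic, "microbial"),
        metabolite=_to_numeric(met, "metabolite"),
        microbial_names=list(mic.columns.astype(str)),
        metabolite_names=list(met.columns.astype(str)),
        labels=labels.loc[shared].astype(str).to_numpy(),
        microbial_transformed=transformed,
        metabolite_transformed=transformed,
    )


def _zero_fraction(mat: np.ndarray) -> np.ndarray:
    return (mat == 0).mean(axis=0)


def filter_sparse_features(
    dataset: PairedDataset, max_zero_fraction: float = 0.5
) -> PairedDataset:
    """Drop features (in both tables) whose zero-fraction strictly exceeds
    ``max_zero_fraction``.  A feature with *exactly* the threshold fraction of
    zeros is retained."""
    if dataset.microbial_transformed != RAW or dataset.metabolite_transformed != RAW:
        raise ValueError("sparse-feature filtering requires raw tables")
    keep_mic = _zero_fraction(dataset.microbial) <= max_zero_fraction
    keep_met = _zero_fraction(dataset.metabolite) <= max_zero_fraction
    if not keep_mic.any() or not keep_met.any():
        raise ValueError(
            f"sparse-feature filter at {max_zero_fraction} removed every "
            f"feature (microbial kept {int(keep_mic.sum())}/{keep_mic.size}, "
            f"metabolite kept {int(keep_met.sum())}/{keep_met.size})"
        )
    return dataset.copy(
        microbial=dataset.microbial[:, keep_mic],
        metabolite=dataset.metabolite[:, keep_met],
        microbial_names=[n for n, k in zip(dataset.microbial_names, keep_mic) if k],
        metabolite_names=[n for n, k in zip(dataset.metabolite_names, keep_met) if k],
    )


def _replace_zeros_matrix(
    mat: np.ndarray, epsilon: float | None, table_name: str
) -> np.ndarray:
    out = mat.copy()
    for j in range(mat.shape[1]):
        col = out[:, j]
        zeros = col == 0
        if not zeros.any():
            continue
        if zeros.all():
            raise ValueError(
                f"{table_name} feature index {j} is entirely zero; "
                "run filter_sparse_features first"
            )
        eps = epsilon if epsilon is not None else 0.5 * col[col > 0].min()
        col[zeros] = eps
    return out


def replace_zeros(
    dataset: PairedDataset, epsilon: float | None = None
) -> PairedDataset:
    """Substitute zero abundances with a small positive value.

    ``epsilon=None`` (default) uses half the smallest positive value of each
    feature; a float gives a fixed replacement.  Nonzero entries are never
    touched.
    """
    if dataset.microbial_transformed != RAW or dataset.metabolite_transformed != RAW:
        raise ValueError("zero replacement requires raw tables")
    return dataset.copy(
        microbial=_replace_zeros_matrix(dataset.microbial, epsilon, "microbial"),
        metabolite=_replace_zeros_matrix(dataset.metabolite, epsilon, "metabolite"),
    )


def clr_matrix(mat: np.ndarray, log_base: str = "e") -> np.ndarray:
    """CLR-transform rows of a strictly positive matrix:
    ``log(x_j) - mean_j log(x_j)``, i.e. log ratio to the row geometric mean."""
    if mat.size and mat.min() <= 0:
        raise ValueError(
            "CLR requires strictly positive entries; apply replace_zeros first"
        )
    logs = np.log(mat)
    if log_base == "10":
        logs = logs / math.log(10.0)
    elif log_base != "e":
        raise ValueError(f"unsupported log base {log_base!r}")
    return logs - logs.mean(axis=1, keepdims=True)


def clr_transform(
    dataset: PairedDataset, which: str = "both", log_base: str = "e"
) -> PairedDataset:
    """Apply the CLR transform to the microbial table, the metabolite table,
    or both (default).  Transformed rows sum to zero."""
    if which not in ("microbial", "metabolite", "both"):
        raise ValueError("which must be 'microbial', 'metabolite' or 'both'")
    changes: dict = {}
    if which in ("microbial", "both"):
        changes["microbial"] = clr_matrix(dataset.microbial, log_base)
        changes["microbial_transformed"] = CLR
    if which in ("metabolite", "both"):
        changes["metabolite"] = clr_matrix(dataset.metabolite, log_base)
        changes["metabolite_transformed"] = CLR
    return dataset.copy(**changes)


def preprocess(
    dataset: PairedDataset,
    max_zero_fraction: float = 0.5,
    epsilon: float | None = None,
    which: str = "both",
    log_base: str = "e",
) -> tuple[PairedDataset, dict]:
    """filter -> replace zeros -> CLR, returning the transformed dataset and a
    provenance record of the choices made."""
    ds = filter_sparse_features(dataset, max_zero_fraction)
    ds = replace_zeros(ds, epsilon)
    ds = clr_transform(ds, which=which, log_base=log_base)
    provenance = {
        "max_zero_fraction": max_zero_fraction,
        "epsilon_rule": "fixed" if epsilon is not None else "half-min-positive",
        "epsilon": epsilon,
        "clr_tables": which,
        "log_base": log_base,
        "n_samples": ds.n_samples,
        "n_microbes": ds.n_microbes,
        "n_metabolites": ds.n_metabolites,
    }
    return ds, provenance


@dataclass
class Preprocessor:
    """Leakage-safe preprocessing for cross-validation: feature selection and
    per-feature zero-replacement values are fitted on training samples only,
    then applied unchanged to held-out samples.  (The CLR itself is per-row
    and carries no cross-sample statistics.)"""

    max_zero_fraction: float = 0.5
    epsilon: float | None = None
    which: str = "both"
    log_base: str = "e"
    keep_microbial: np.ndarray | None = field(default=None, repr=False)
    keep_metabolite: np.ndarray | None = field(default=None, repr=False)
    eps_microbial: np.ndarray | None = field(default=None, repr=False)
    eps_metabolite: np.ndarray | None = field(default=None, repr=False)

    def fit(self, train: PairedDataset) -> "Preprocessor":
        self.keep_microbial = _zero_fraction(train.microbial) <= self.max_zero_fraction
        self.keep_metabolite = (
            _zero_fraction(train.metabolite) <= self.max_zero_fraction
        )
        if not self.keep_microbial.any() or not self.keep_metabolite.any():
            raise ValueError("sparse-feature filter removed every feature")
        self.eps_microbial = self._fit_eps(train.microbial[:, self.keep_microbial])
        self.eps_metabolite = self._fit_eps(train.metabolite[:, self.keep_metabolite])
        return self

    def _fit_eps(self, mat: np.ndarray) -> np.ndarray:
        if self.epsilon is not None:
            return np.full(mat.shape[1], self.epsilon)
        eps = np.empty(mat.shape[1])
        for j in range(mat.shape[1]):
            pos = mat[:, j][mat[:, j] > 0]
            if pos.size == 0:
                raise ValueError(f"feature index {j} entirely zero in training fold")
            eps[j] = 0.5 * pos.min()
        return eps

    def transform(self, dataset: PairedDataset) -> PairedDataset:
        if self.keep_microbial is None:
            raise RuntimeError("Preprocessor.fit must be called first")
        mic = dataset.microbial[:, self.keep_microbial].copy()
        met = dataset.metabolite[:, self.keep_metabolite].copy()
        mic = np.where(mic == 0, self.eps_microbial, mic)
        met = np.where(met == 0, self.eps_metabolite, met)
        ds = dataset.copy(
            microbial=mic,
            metabolite=met,
            microbial_names=[
                n for n, k in zip(dataset.microbial_names, self.keep_microbial) if k
            ],
            metabolite_names=[
                n for n, k in zip(dataset.metabolite_names, self.keep_metabolite) if k
            ],
        )
        return clr_transform(ds, which=self.which, log_base=self.log_base)

    def fit_transform(self, train: PairedDataset) -> PairedDataset:
        return self.fit(train).transform(train)


def write_paired_tables(
    dataset: PairedDataset,
    microbial_path: str | Path,
    metabolite_path: str | Path,
    metadata_path: str | Path,
    label_column: str = "label",
    provenance: dict | None = None,
    provenance_path: str | Path | None = None,
) -> None:
    """Write the three tables in the dialect ``read_paired_tables`` accepts,
    plus an optional key=value provenance sidecar."""
    for path, mat, names in (
        (microbial_path, dataset.microbial, dataset.microbial_names),
        (metabolite_path, dataset.metabolite, dataset.metabolite_names),
    ):
        sep = "," if str(path).endswith(".csv") else "\t"
        pd.DataFrame(mat, index=dataset.sample_ids, columns=names).to_csv(
            path, sep=sep, index_label="sample_id"
        )
    sep = "," if str(metadata_path).endswith(".csv") else "\t"
    pd.DataFrame(
        {label_column: dataset.labels}, index=dataset.sample_ids
    ).to_csv(metadata_path, sep=sep, index_label="sample_id")
    if provenance is not None and provenance_path is not None:
        lines = [f"{k}={v}" for k, v in provenance.items()]
        Path(provenance_path).write_text("\n".join(lines) + "\n")
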