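"""Synthetic paired microbiome-metabolome datasets with known ground truth.

The generator emulates the structure of curated paired gut studies:

* **taxa**: per-group log-abundance profiles (group mean ~ N(0,1) per
  dimension, unit within-group spread), exponentiated, zero-inflated with an
  independent Bernoulli mask, and closed to relative abundances — giving
  non-negative, zero-inflated compositional tables;
* **metabolites**: a sparse subset of taxa (the per-group causal set) drives
  each group's metabolite profile through a smooth map — linear, sinusoidal,
  or a function drawn from an SE-ARD GP (the exactly well-specified case for
  calibration and parameter-recovery tests) — applied to the CLR of the taxa
  table, standardized to unit signal scale, plus Gaussian noise.  The stored
  metabolite table is exp(signal + noise), a positive abundance table;
* **phenotypes**: >= 2 groups may use disjoint causal sets and opposing
  maps, creating the heterogeneous structure mixture models exploit.

``generate`` returns both the raw on-disk-style dataset and a ground-truth
record (causal sets, map parameters, the latent CLR design and noiseless
signal) so tests can score recovery exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_io import PairedDataset, clr_matrix, write_paired_tables
from .gp_expert import ARDKernelParams, kernel_matrix

__all__ = ["SyntheticSpec", "generate", "make_fixture", "FIXTURES"]


@dataclass
class SyntheticSpec:
    """Generator configuration.  ``causal_sets[g]`` lists the taxa driving
    group g's metabolites; ``mapping[g]`` is ``linear``, ``sin`` or
    ``gp-sample``.  ``map_sign[g]`` flips a group's map (opposing maps)."""

    n_per_group: tuple = (50, 50)
    d: int = 30
    m: int = 20
    groups: tuple = ("groupA", "groupB")
    causal_sets: list = field(default_factory=list)  # default: first s taxa, shared
    s: int = 3
    mapping: tuple | str = "linear"
    map_sign: tuple | None = None
    noise_sd: float = 0.3
    zero_inflation: float = 0.2
    gp_lengthscale: float = 1.5
    shared_causal_mu: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        g = len(self.groups)
        if len(self.n_per_group) != g:
            raise ValueError("n_per_group and groups must have equal length")
        if isinstance(self.mapping, str):
            self.mapping = tuple([self.mapping] * g)
        if self.map_sign is None:
            self.map_sign = tuple([1.0] * g)
        if not self.causal_sets:
            self.causal_sets = [list(range(self.s)) for _ in range(g)]
        for cs in self.causal_sets:
            if len(cs) > self.d or max(cs, default=-1) >= self.d:
                raise ValueError("causal set indices exceed taxa count d")
        if not 0.0 <= self.zero_inflation < 1.0:
            raise ValueError("zero_inflation must be in [0, 1)")


def _apply_mapping(
    C: np.ndarray, kind: str, sign: float, m: int, ls: float, rng: np.random.Generator
) -> tuple[np.ndarray, dict]:
    """Map the causal CLR block C (n, s) to m latent metabolite columns."""
    s = C.shape[1]
    if kind == "linear":
        W = rng.normal(size=(s, m))
        Y = C @ W
        params = {"W": W}
    elif kind == "sin":
        W = rng.normal(size=(s, m))
        freq = rng.uniform(0.8, 1.6, size=(1, s))
        phase = rng.uniform(0, 2 * np.pi, size=(1, s))
        Y = np.sin(freq * C + phase) @ W
        params = {"W": W, "freq": freq, "phase": phase}
    elif kind == "gp-sample":
        kern = ARDKernelParams(1.0, np.full(s, ls))
        K = kernel_matrix(C, None, kern, jitter=1e-8)
        L = np.linalg.cholesky(K)
        Y = L @ rng.normal(size=(C.shape[0], m))
        params = {"lengthscale": ls}
    else:
        raise ValueError(f"unknown mapping {kind!r}")
    return sign * Y, params


def generate(spec: SyntheticSpec) -> tuple[PairedDataset, dict]:
    """Generate a raw paired dataset plus its ground truth, reproducibly
    from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n_total = sum(spec.n_per_group)
    logab = np.empty((n_total, spec.d))
    labels = np.empty(n_total, dtype=object)
    row = 0
    group_slices = []
    causal_union = sorted({j for cs in spec.causal_sets for j in cs})
    base_mu = rng.normal(0.0, 1.0, size=spec.d)
    for g, (lab, ng) in enumerate(zip(spec.groups, spec.n_per_group)):
        mu = rng.normal(0.0, 1.0, size=spec.d)
        if spec.shared_causal_mu:
            # causal taxa identically distributed across groups: group
            # identity lives only in the non-causal dimensions, so opposing
            # maps genuinely conflict for a pooled model
            mu[causal_union] = base_mu[causal_union]
        logab[row : row + ng] = mu + rng.normal(size=(ng, spec.d))
        labels[row : row + ng] = lab
        group_slices.append(slice(row, row + ng))
        row += ng

    abundance = np.exp(logab)
    if spec.zero_inflation > 0:
        mask = rng.random(abundance.shape) < spec.zero_inflation
        # never zero out an entire row
        for i in range(n_total):
            if mask[i].all():
                mask[i, np.argmax(abundance[i])] = False
        abundance = np.where(mask, 0.0, abundance)
    abundance = abundance / abundance.sum(axis=1, keepdims=True)  # closure

    # CLR design used by the causal maps (half-min-positive zero replacement)
    pos = abundance.copy()
    for j in range(spec.d):
        col = pos[:, j]
        if (col == 0).any():
            nz = col[col > 0]
            col[col == 0] = 0.5 * nz.min() if nz.size else 1e-6
    X_clr = clr_matrix(pos)

    Y_signal = np.empty((n_total, spec.m))
    map_params = []
    for g, sl in enumerate(group_slices):
        C = X_clr[sl][:, spec.causal_sets[g]]
        Yg, params = _apply_mapping(
            C,
            spec.mapping[g],
            spec.map_sign[g],
            spec.m,
            spec.gp_lengthscale,
            rng,
        )
        sd = Yg.std(axis=0, ddof=0)
        sd[sd < 1e-12] = 1.0
        if spec.mapping[g] != "gp-sample":  # GP draws already have unit prior scale
            Yg = Yg / sd
        Y_signal[sl] = Yg
        map_params.append(params)

    Y_obs = Y_signal + rng.normal(0.0, spec.noise_sd, size=Y_signal.shape)
    metabolite = np.exp(Y_obs)

    dataset = PairedDataset(
        sample_ids=[f"s{i:04d}" for i in range(n_total)],
        microbial=abundance,
        metabolite=metabolite,
        microbial_names=[f"taxon_{j:03d}" for j in range(spec.d)],
        metabolite_names=[f"met_{j:03d}" for j in range(spec.m)],
        labels=np.asarray(labels, dtype=str),
    )
    ground_truth = {
        "spec": spec,
        "causal_sets": spec.causal_sets,
        "map_params": map_params,
        "X_clr": X_clr,
        "Y_signal": Y_signal,
        "Y_obs": Y_obs,
        "noise_sd": spec.noise_sd,
        "group_slices": group_slices,
    }
    return dataset, ground_truth


FIXTURES: dict[str, SyntheticSpec] = {
    # smoke-test scale; zero inflation high enough that some features hit the
    # sparsity filter
    "tiny": SyntheticSpec(
        n_per_group=(10, 10),
        d=8,
        m=4,
        groups=("ctrl", "case"),
        s=2,
        mapping="linear",
        noise_sd=0.3,
        zero_inflation=0.35,
        seed=0,
    ),
    # ARD relevance recovery: 3 causal taxa among 30, single group, smooth
    # GP-drawn map so the SE-ARD expert is well-specified
    "ard": SyntheticSpec(
        n_per_group=(150,),
        d=30,
        m=10,
        groups=("healthy",),
        s=3,
        mapping="gp-sample",
        noise_sd=0.2,
        zero_inflation=0.1,
        gp_lengthscale=1.5,
        seed=0,
    ),
    # two phenotype groups with disjoint causal sets and opposing linear
    # maps: the heterogeneous case expert allocation should exploit
    "heterogeneous": SyntheticSpec(
        n_per_group=(60, 60),
        d=20,
        m=10,
        groups=("ctrl", "case"),
        causal_sets=[[0, 1, 2], [3, 4, 5]],
        s=3,
        mapping="linear",
        map_sign=(1.0, -1.0),
        noise_sd=0.3,
        zero_inflation=0.1,
        shared_causal_mu=True,
        seed=0,
    ),
    # well-specified GP draw over all taxa, no zeros: interval calibration
    "calibration": SyntheticSpec(
        n_per_group=(200,),
        d=5,
        m=4,
        groups=("healthy",),
        s=5,
        mapping="gp-sample",
        noise_sd=0.3,
        zero_inflation=0.0,
        gp_lengthscale=1.5,
        seed=0,
    ),
}


def make_fixture(
    name: str, out_dir: str | Path, seed: int | None = None
) -> tuple[PairedDataset, dict]:
    """Write a named preset as the three TSVs ``data_io`` reads
    (microbial.tsv, metabolite.tsv, metadata.tsv) and return the in-memory
    dataset and ground truth."""
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; choose from {sorted(FIXTURES)}")
    spec = FIXTURES[name]
    if seed is not None:
        spec = SyntheticSpec(**{**vars(spec), "seed": seed})
    dataset, gt = generate(spec)
    if name == "heterogeneous":
        check_group_signal(gt)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_paired_tables(
        dataset,
        out / "microbial.tsv",
        out / "metabolite.tsv",
        out / "metadata.tsv",
        label_column="label",
    )
    return dataset, gt


def check_group_signal(ground_truth: dict) -> None:
    """Generator sanity check for heterogeneous fixtures: within each group,
    a least-squares fit on the group's *own* causal CLR features must explain
    more signal variance than a fit on the other group's causal features."""
    gt = ground_truth
    slices = gt["group_slices"]
    sets = gt["causal_sets"]
    if len(slices) < 2:
        return
    for g, sl in enumerate(slices):
        Y = gt["Y_signal"][sl]
        r2 = []
        for cs in sets:
            C = gt["X_clr"][sl][:, cs]
            C1 = np.column_stack([C, np.ones(C.shape[0])])
            resid = Y - C1 @ np.linalg.lstsq(C1, Y, rcond=None)[0]
            r2.append(1.0 - resid.var() / Y.var())
        own = r2[g]
        best_other = max(v for i, v in enumerate(r2) if i != g)
        if own <= best_other:
            raise RuntimeError(
                f"generator sanity check failed: group {g} own-causal R^2 "
                f"{own:.3f} <= wrong-group R^2 {best_other:.3f}"
            )
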