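# Methods

## Problem setting

Given paired sample-by-feature tables — microbial taxa relative abundances
`X` (n×d) and metabolite abundances `Y` (n×m) — plus a per-sample phenotype
label, the package learns a predictive map from microbial profile to
metabolite profile with calibrated uncertainty. Cohorts that mix phenotypes
often mix taxa→metabolite relationships; the model addresses this with one
GP expert per phenotype and an input-dependent gate.

## Preprocessing

Both tables pass through the same compositional pipeline, in this fixed
order:

1. **Sparsity filter.** Features with *strictly more* than 50% zero values
   are removed (a feature with exactly half zeros is retained). The filter
   runs on raw tables, before zero replacement — afterwards the
   zero-fraction would be undefined.
2. **Zero replacement.** Remaining zeros become half the feature's smallest
   positive value (multiplicative-replacement convention; scale-aware). A
   fixed ε is available via `epsilon=`.
3. **CLR.** Each row x becomes `log(x_j) − mean_j log(x_j)`, i.e. the log
   ratio to the row's geometric mean; rows sum to zero and the transform is
   invariant to per-sample scaling (sequencing depth). Natural log is the
   default (the compositional-analysis convention); log10 is available for
   cross-checking. Both tables are transformed by default; `which="microbial"`
   restricts to the taxa table.

For cross-validation, `Preprocessor` fits the feature filter and
zero-replacement values on the training fold only and applies them unchanged
to the held-out fold; CLR itself is per-row and carries no cross-sample
statistics.

## GP experts

Each expert is an exact zero-mean GP regressor `y = f(x) + ε`,
`ε ~ N(0, σ_s²)`, with the SE-ARD kernel
`k(x,x') = σ² exp(−½ Σ_i (x_i−x'_i)²/l_i²)`.

* **Multi-output handling.** Output columns are modelled as independent GPs
  sharing one kernel and one noise variance per expert; hyperparameters are
  fitted on the NLML summed over columns. This yields exactly one ARD
  relevance vector per expert, which is the interpretability object the
  package reports. Cross-output covariance modelling is out of scope.
* **Fitting.** Type-II maximum likelihood in log-parameter space with
  analytic gradients. L-BFGS-B (bounds ±10 in log space, ftol 1e-9, up to
  500 iterations) is the default; Adam with the same exponential schedule as
  the gate is available. The fit never returns a worse iterate than its
  initialization.
* **Initialization.** σ² = 1, σ_s² = 0.1, and l_i = (per-dimension median
  absolute pairwise difference) × √d. The √d factor matters: without it the
  summed scaled distance across even a few dozen dimensions makes the
  initial kernel effectively diagonal, the NLML surface is flat there, and
  gradient optimizers stall immediately.
* **Numerics.** Cholesky factorization with escalating diagonal jitter
  (1e-6·σ² up to 1e-2·σ², ×10 steps) before failing. Predictive variance is
  clipped at zero; `include_noise=True` adds σ_s² (used everywhere a
  prediction is compared to observations).
* **Large blocks.** Blocks above `max_train` (default 2000) are fitted on a
  seeded random subset (subset-of-data approximation) with a warning. At the
  cohort sizes this package targets (tens to hundreds of samples per
  phenotype) the exact path always runs.

## Expert allocation

* `phenotype` (default): one expert per distinct label.
* `random`: same number of experts, seeded label-agnostic split — the
  ablation control.
* `double`: each label block halved (sizes differ ≤1), doubling the expert
  count.

Blocks smaller than 5 samples trigger a warning, not a failure: tiny
phenotype groups give weakly trained experts, which is a property of the
data, not an error.

## Gating network and training

The gate is a feedforward ReLU network, d → 128 → 64 → L with dropout (rate
0.2) after the second hidden activation — immediately before the output
layer — and a softmax output. Weights use seeded fan-in-scaled symmetric
uniform initialization; biases start at zero. Forward/backward passes are
explicit numpy and are verified against finite differences.

Training is two-phase: experts first (NLML on their blocks), then the gate
on **all** training samples by minimizing the mixture negative
log-likelihood `−Σ_i log Σ_l w_l(x_i) N(y_i | f_l(x_i), s_l²(x_i))` with
experts frozen, where the component densities use the experts' predictive
(noise-inclusive) means and variances at the training inputs. Optimizer:
hand-written Adam, learning rate 0.01 decayed ×0.95 every 500 steps; 2000
steps with early stopping (patience 200); full batch for n ≤ 512, else
minibatches of 64; non-finite loss halves the learning rate and restarts the
step, at most 3 times. Because each expert's in-sample predictive variance
is small on its own block, the responsibilities that drive the gate are
sharply informative about block membership, and the gate effectively learns
a phenotype classifier from the CLR profile.

An optional refinement (`joint_finetune_rounds > 0`) alternates hard
reassignment of training samples to their maximum-responsibility expert,
expert refits, and gate retraining — a deterministic coordinate-ascent
version of end-to-end training. Default is off: the two-phase fit is the
reference path.

## Prediction and uncertainty

Mixture moments are matched exactly:
`μ = Σ w_l f_l`, `σ² = Σ w_l (σ_l² + (f_l − μ)²)`. The second term makes the
predictive band widen wherever experts disagree, which is where
heterogeneous cohorts are hardest. `μ ± 2σ` is reported as the 95% credible
band; on well-specified simulated data its empirical coverage is checked to
lie in [0.90, 0.99].

## Evaluation

Spearman rank correlation (mid-ranks for ties, undefined-for-constant
vectors returned as NaN and excluded from means with a warning), computed
per sample and per metabolite. Summaries: mean per-sample SCC, mean SCC of
the top-10 and top-50 metabolites (by per-metabolite SCC; k is truncated
with a warning when m < k), and the count of metabolites with SCC > 0.5
reported as log10(count+1) so zero counts stay finite. Cross-validation is
stratified by label (default five folds, reduced with a warning when the
smallest label group is smaller than k); results are reported as mean ± sd
over folds. "Top-10" is interpreted as the 10 best-predicted metabolites;
the per-sample aggregate is always reported alongside.

## Synthetic data

The generator emulates curated paired gut-study structure: per-group
Gaussian log-abundances (group mean ~ N(0,1) per taxon), exponentiated,
Bernoulli zero-inflated, and closed to relative abundances; metabolites are
a group-specific smooth map (linear, sinusoidal, or a draw from an SE-ARD
GP) of the CLR of a sparse causal taxa subset, plus Gaussian noise, stored
as exp(·) so the table is a positive abundance table. With
`shared_causal_mu=True` the causal taxa are identically distributed across
groups, so opposing group maps genuinely conflict for any pooled model while
non-causal taxa still carry group identity for the gate — the cleanest
construction of gateable heterogeneity.

Presets: `tiny` (n=20, d=8, m=4; zero inflation 0.35 so the sparsity filter
is exercised), `ard` (n=150, d=30, 3 causal taxa, GP-drawn map — the
well-specified relevance-recovery case), `heterogeneous` (2×60 samples,
disjoint causal sets, opposing linear maps, shared causal distribution),
`calibration` (n=200, d=5, GP-drawn map, no zeros). For calibration the
coverage check scores the generator's latent observation scale directly
(CLR-ing the stored metabolite table would couple columns through the row
mean and break well-specification); the on-disk fixture files remain valid
abundance tables.

What the simulations do **not** emulate: phylogenetic correlation among
taxa, sequencing-depth artifacts, batch effects, non-Gaussian metabolite
noise. Passing tests therefore demonstrate correctness of the algebra and
the intended qualitative behaviours (relevance recovery, benefit of
phenotype allocation, calibration under well-specification), not field
performance on real cohorts.

## Problem sizes and determinism

Simulation studies use 10–20 seeds at n ≤ 200, d ≤ 30, m ≤ 20 — sizes at
which the exact GP path is fast and results are stable. All randomness flows
from explicit seeds: generator, allocation shuffles, gate initialization,
dropout masks and minibatch draws; repeated runs with the same seed
reproduce metrics bit-for-bit.

## Known limitations

* Independent outputs per expert: correlated metabolite residuals are not
  modelled.
* The gate is trained on in-sample expert likelihoods; with very small
  blocks the own-block variance advantage can overstate separability.
* Subset-of-data (not inducing-point) approximation for very large blocks.
* SE-ARD only; no Matérn or phenotype-adaptive kernels.
* The number of experts is fixed by the allocation strategy, not learned.
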