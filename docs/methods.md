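# Methods

This note documents the models, the synthetic data, the numerical choices
and the known limits of `latentfed`. Nothing here asserts an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The protocol being simulated

k sites hold disjoint feature-column subsets of one row-aligned cohort; the
binary target stays with the central orchestrator. Each site trains an
autoencoder on its slice, transmits the code-layer activations once, a
relay aligns rows across sites (sorted intersection of row IDs; rows
missing at any site are dropped and counted — the original single-table
setting never exercises this), and the central server trains a classifier
on the column-wise concatenation of the codes. Utility is judged by
comparing that model with a centralized raw-feature model on one shared
held-out split.

## Site autoencoder

* **Architecture.** Input width n = (#continuous) + Σ embedding widths.
  Encoder n → 64 → 128 (ReLU after every layer; the transmitted code is the
  post-activation output of the middle layer), decoder 128 → 64 → per-column
  heads: one linear unit per continuous column, one softmax over the level
  set per categorical column. The code layer must satisfy m ≥ n
  (overcompleteness); configurations violating it are rejected.
* **Loss.** Mean over rows of squared error on standardized continuous
  columns plus cross-entropy per categorical column. This per-column-head
  decomposition is this package's design: it keeps the loss interpretable
  for mixed types and makes the transmitted representation all-continuous.
* **Training.** SGD, initial learning rate 0.01, multiplied by 0.99 once
  per epoch (lr(t) = 0.01·0.99^t; a per-batch decay would collapse the rate
  within a single epoch at these dataset sizes), weight decay 0.1 applied
  as coupled L2 to dense weight matrices only (not biases, not embedding
  tables) — its role is to keep the overcomplete network away from the
  identity map. Defaults: 50 epochs, batch 64, both configurable.
* **Embeddings.** Width per categorical column: min(50, ⌈cardinality/2⌉),
  registered as `"default"` and swappable. Missing categorical cells map to
  a dedicated extra level (index = cardinality), used both as embedding
  input and reconstruction target; missing continuous cells are imputed
  with the training-rows median before standardization.
* **Initialization.** Uniform fan-in U(±1/√n_in) for dense layers,
  U(±0.05) for embeddings. The benchmark seeds site i with `seed + i`, so
  sites differ while runs reproduce bit-for-bit.

## Central classifier

Two ReLU hidden layers (200, 100), a single sigmoid output, Adam at 1e-3,
20 epochs, batch 64, decision threshold 0.5 with ties counted positive
(documented because accuracy on coarse scores depends on the convention).
Raw tabular inputs go through the same embedding rule as the autoencoder;
latent/matrix inputs are standardized and bypass embeddings. The exact
architecture is deliberately unremarkable: every benchmark arm uses the
same configuration, so comparisons are within-package and only the input
representation varies. AUROC is computed by midranks (equal to the
pairwise P(pos > neg) + ½P(tie) form; verified against a brute-force
all-pairs oracle in the tests).

## Benchmark protocol

One stratified 80/20 split (seeded, exact, identical rows for every arm)
is made before any site sees data; a stated split protocol is required for
the before/after comparison not to confound split noise. Autoencoders are
fit on training rows only — test rows are merely encoded, anything else
would leak. The report stores full-precision metrics; relative differences
100·(after − before)/before are rounded to 2 decimals. The code-dimension
sweep rescales the autoencoder to [m/2, m, m/2] per candidate m and skips
(with a warning) any m below the widest site input.

## Synthetic data

Continuous features are Gaussians with a per-column between-class mean
shift δ (class y mean ±δ/2, common sd = noise scale); categorical levels
are drawn from class-conditional multinomials tilted by a per-column skew
γ (p(l|y) ∝ exp((y−½)γu_l) with level scores u_l spread over [−1,1]).
Labels are balanced by construction (counts differ by ≤ 1). This family
was chosen because the continuous part has the closed-form Bayes accuracy
Φ(√(Σδ²)/2σ), giving acceptance tests an analytic ceiling.
`signal_allocation` rescales δ/γ so each site carries a chosen share of
Σ(δ²+γ²), enabling deliberately weak sites.

Preset shapes mirror the three study tables: `adult_like` 23,374 rows,
6 continuous + 8 categorical (cardinalities 9, 16, 7, 15, 6, 5, 2, 42),
sites of 5/5/4 columns; `schwannoma_like` 50 rows, 1 categorical + 14
continuous, sites 7/3/5; `eicu_like` 15,762 rows, 24 continuous + 8
categorical with 20% missing continuous cells, sites 3/4/9/3/3/4/6.
Preset effect sizes (δ ≈ 0.1–0.9, γ ≈ 0.2–0.7) were chosen once to give a
realistically separable clinical-style problem (central accuracy in the
high 0.7s–0.8s); they are conditions, not tuning knobs. What the generator
does **not** emulate: real marginal distributions, inter-feature
correlation structure, informative missingness, label noise. Passing tests
therefore demonstrate protocol correctness and utility retention under
clean, independent-feature signal — not performance on real clinical data.

## Privacy quantification

The perturbation claim is quantified by three transparent proxies defined
by this package (no formal guarantee is implied): the maximum absolute
Pearson correlation between any latent column and any standardized
original column (identity-encoding flag at |r| > 0.999); held-out R² of a
ridge regression (α = 1, reported, since attack strength depends on it)
from latent to each original continuous column — the best linear
reconstruction attacker; and a two-sample Kolmogorov–Smirnov statistic
between each original column and its best-correlated latent column.
Whether an untrained encoder is more or less invertible than a trained one
is direction-unknown, so it is reported, never asserted.

## Numerical choices and degenerate inputs

Standardization guards zero-variance columns (σ < 1e-12 → 1). Softmax and
log are clipped at 1e-12; the sigmoid/BCE use the stable softplus form.
Non-finite training loss raises an error naming the epoch. Constant
partitions train to a near-zero loss floor and emit zero-variance codes.
Undersampling draws majority rows uniformly without replacement and
preserves relative row order; the row filter reads "more than k nonnull"
as a strict inequality. All randomness flows through
`numpy.random.default_rng(seed)`; identical seeds give bit-identical
datasets, models and scores.

## Problem sizes

Unit and property tests run on fixtures of 40–2,000 rows with reduced
epochs; the utility-retention acceptance test uses the census-shaped
fixture at 4,000 rows across 3 seeds with full default training; the
acceptance script additionally runs the complete benchmark at the native
23,374-row preset size and the aggregation-dimension checks at full row
counts (one-epoch autoencoders, since only shapes are measured there).
These sizes are the package's own choices balancing statistical stability
against a desk-scale run.

## Known limitations

No cross-validation (single split per seed); no hyperparameter search or
calibration; binary targets only; the relay assumes harmonized row IDs (no
private set intersection); no differential-privacy accounting or nonlinear
model-inversion attacks; the sweep's "wider code helps" trend is assessed
only as a nonnegative rank correlation because all admissible widths are
already overcomplete.
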