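# Methods

This note defines the model and losses exactly as implemented, lists the
default parameters, describes what the synthetic generator does and does
not emulate, and records the numerical conventions the implementation
commits to.

## 1. Input representation

For drug *A* with descriptor set *S_A^t* of feature type *t* (binary
vectors over e.g. substructures, targets, enzymes, pathways), the
Jaccard similarity to drug *B* is

    J(A, B) = |S_A ∩ S_B| / (|S_A| + |S_B| − |S_A ∩ S_B|)

computed exactly on the binary descriptor matrices (`features.py`
vectorises it as an integer inner product, so the values are bit-exact
against set arithmetic). The **similarity profile** of a drug is the
concatenation, over the `T` feature types, of its Jaccard similarity
against *all* `n` drugs in the corpus, giving input width
`fea_dim = T·n`. Conventions:

- `J = 0` when both descriptor sets are empty (the 0/0 case); a
  `EmptyDescriptorWarning` is emitted because an all-zero descriptor row
  usually indicates a data problem.
- Profiles are computed against the full drug corpus, including drugs
  whose *pairs* are held out by a split. Only interaction labels are
  hidden from training; descriptor-level information about test drugs is
  considered available, matching how the cross-validation tasks are
  defined. `build_similarity_profiles(..., include_self=False)` zeroes
  the self-similarity column if that convention is preferred.

## 2. Network

One drug encoder is shared by both drugs of a pair:

1. The profile is reshaped into `n_tokens` tokens (one per feature-type
   block) and passed through multi-head self-attention with a residual
   connection; flattened, this is the first latent **DA1** (width
   `fea_dim`).
2. A two-layer GELU encoder produces **DA2** (width `h1`) and **DA3**
   (width `h2`); a mirrored two-layer decoder reconstructs the profile
   for the MSE term.

For a pair (A, B) the default **multi-scale fusion** concatenates
latents of complementary depth and projects each with a GELU linear
layer of output width `f`:

    FD1 = g(W1 [DA1; DB3]),  FD2 = g(W2 [DA2; DB2]),  FD3 = g(W3 [DA3; DB1])

Two ablations are built in: `single_scale` fuses equal depths
(`[DA_k; DB_k]`), and `none` skips fusion and uses only `[DA3; DB3]`.

**Latent reduction**: the five width-`h2` vectors (DA3, DB3, FD1, FD2,
FD3) are treated as tokens for a second attention block (again with a
residual), then flattened and passed through `n_reduce_layers` halving
blocks, each `Linear → GELU → Dropout → BatchNorm`. The result is the
**comprehensive feature vector (CFV)** of width `5·h2 / 2^L`. The
classifier is `Linear(c→c) → GELU → Dropout → BatchNorm → Linear(c→K)`.

The network runs on a small numpy reverse-mode autodiff core
(`_autograd.py`: float64 everywhere, Glorot initialisation, inverted
dropout, batch-norm running statistics, GELU via the tanh
approximation). Every primitive's gradient is tested against central
finite differences.

## 3. Losses

The training objective is the unweighted sum `L = l_MSE + l_con + l_cla`.

- **l_MSE** — sum of squared reconstruction errors divided by `fea_dim`,
  averaged over the batch and over the two drugs of the pair.
- **l_con** — supervised contrastive loss on the CFVs. With
  `sim(i,j) = cos(CFV_i, CFV_j) / τ`:

      l_i = −(1/(N_yi − 1)) Σ_{j≠i, y_j=y_i} log[ exp(sim(i,j)) / Σ_{k≠i} exp(sim(i,k)) ]

  and the batch loss is `Σ_i l_i / N` where `N` is the batch size.
  Anchors whose class appears only once in the batch contribute exactly
  zero (but still appear in the denominator `N`); a batch with no
  positive pair yields zero. Zero CFVs raise an error (cosine
  undefined) rather than being silently clipped.
- **l_cla** — scheduled: epochs `< switch_epoch` use label-smoothed
  cross-entropy with target `(1−ε)·onehot + ε/K` (uniform mass over all
  `K` classes, *including* the true class); epochs `≥ switch_epoch` use
  focal loss `−(1−p_t)^γ log p_t` with no smoothing and no class
  weights. The switch is by epoch, not by optimiser step. `γ = 0`
  recovers plain cross-entropy exactly.

## 4. Training, splits, metrics

The optimiser is RAdam (with the variance-rectification term; plain
Adam-with-warmup is not offered). `symmetrize_pairs=True` trains on both
orders of each pair and averages the two orders at prediction time,
making predictions order-invariant; otherwise the model is order
sensitive because multi-scale fusion is asymmetric.

Cross-validation (always 5 folds, seeded and reproducible):

- **Task 1** splits *records*, stratified per class: classes with ≥ 5
  records are dealt evenly, the remainder placed greedily on the least
  loaded fold so fold sizes differ by at most 1.
- **Tasks 2/3** split *drugs* into 5 folds; task 2 tests pairs with
  exactly one held-out drug, task 3 pairs with both held out. In both
  tasks the training set contains no pair touching a held-out drug.
  (Pairs with exactly one held-out drug are unused in task 3, and pairs
  with two held-out drugs unused in task 2.)

Metrics: accuracy; macro precision/recall/F1 averaged over classes
present in the test labels (absent predicted classes score 0, not NaN);
micro AUPR and AUC computed one-vs-rest on the flattened one-hot
matrix; plus a per-class `(class, support, f1, aupr)` table.

## 5. Default parameters

Full-size defaults (`TrainConfig` / `NetworkConfig`):

| Parameter | Default | Notes |
| --- | --- | --- |
| learning rate | 2e-5 | RAdam |
| batch size | 512 | |
| epochs | 120 | |
| switch epoch | 40 | smoothed CE before, focal after |
| label smoothing ε | 0.3 | CE phase only |
| focal γ | 2.0 | |
| temperature τ | 0.05 | contrastive loss |
| dropout | 0.3 | |
| attention heads | 4 | largest value ≤ 4 dividing the token width |
| h2 (deep latent) | ≈ fea_dim/4 | rounded to satisfy divisibility |
| h1 | 2·h2 | |
| f (fusion width) | = h2 | required: reduction tokens share one width |
| reduction layers L | 2 | CFV width = 5·h2/4 |

`toy_train_config()` (learning rate 2e-3, batch 32, 30 epochs, switch at
epoch 10) is a deliberate package choice for small synthetic runs: with
only tens of optimiser steps per epoch, a freshly initialised network
cannot move at 2e-5, so the toy schedule scales the step size and
shortens both phases proportionally. It is used by the end-to-end tests
and the acceptance script.

Constraint `f == h2`: the latent-reduction attention treats the five
constituents of its input as equal-width tokens, which forces the fusion
output width to equal `h2`. Configurations violating it (or any
divisibility constraint) raise `InvalidConfigError` at construction.

## 6. Synthetic benchmark generator

`synthetic_data.generate` plants recoverable structure:

- Each feature type has `A` archetype templates (random binary vectors
  with density `bit_density`, at least one bit each). Every drug is
  assigned an archetype (each archetype gets at least one drug) and
  copies its templates with independent bit flips at rate `bit_noise`.
- Each unordered archetype pair (including same-archetype pairs) is
  assigned to one interaction class. Classes receive archetype pairs,
  and then drug pairs, in proportion to power-law shares
  `w_c ∝ (c+1)^(−imbalance_exponent)` (largest-remainder rounding,
  at least one archetype pair per class), so class sizes are monotone
  non-increasing up to availability clipping.
- A fraction `pair_coverage` of all drug pairs is labelled;
  `label_noise` flips each label uniformly to another class.
- Ground truth (archetype assignments, templates, clean labels) is
  returned, enabling an oracle nearest-archetype classifier whose
  accuracy bounds what any model can achieve at a given noise level.

`paper_shaped_preset("dataset1" | "dataset2", scale)` reproduces the
drug/class/feature-type counts and the pair coverage of two common
benchmark geometries (572 drugs, 74 528 pairs, 65 classes, 4 feature
types; 1258 drugs, 323 539 pairs, 100 classes, 3 feature types) at any
scale; `rare_class_preset()` is a 20-class configuration with a heavy
power-law tail for studying rare-class behaviour.

**Scope.** The generator shows that the pipeline recovers planted
structure of the intended kind — similarity-profile inputs, class
determined by latent drug groupings, heavy class imbalance, label noise —
and enables controlled comparisons (with/without the contrastive term,
focal vs cross-entropy on rare classes). Passing these tests does *not*
demonstrate performance on real pharmacological data: real descriptor
correlations, class semantics and noise structure are richer than the
archetype model, and no claim about real-data accuracy is made anywhere
in this package.

## 7. Numerical conventions

- All computation is float64 numpy; results are bit-reproducible for a
  given seed on a given platform (BLAS reductions may differ across
  platforms at the 1e-15 level).
- Softmax and log-softmax subtract the row maximum (treated as a
  constant in the backward pass) before exponentiation.
- The contrastive denominator excludes `k = i` via a −1e30 additive mask
  rather than slicing, keeping the computation a single batched matrix
  product.
- Batch norm uses running statistics (momentum 0.1) in evaluation mode;
  `predict` always runs in evaluation mode and is deterministic.
- One seed drives everything downstream: parameter initialisation,
  dropout, batch shuffling and the synthetic generator all derive
  independent child generators from `numpy.random.SeedSequence`.

## 8. Limitations

- No GPU path and no minibatch parallelism: the numpy core is intended
  for datasets up to a few thousand drugs, not for large-scale training.
- Only the RAdam optimiser and the three cross-validation tasks
  described above are implemented.
- The class of a pair is predicted from descriptor similarity alone;
  mechanistic or dosage information is out of scope.
- Label smoothing applies only in the cross-entropy phase; combining
  smoothing with focal loss is not supported.
- Synthetic results bound internal consistency, not real-world accuracy
  (see §6).
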