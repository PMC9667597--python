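# ddiscl — multi-type drug–drug interaction prediction with supervised contrastive learning

`ddiscl` predicts the *type* of interaction between a pair of drugs (a
multi-class problem with dozens of event types) from binary drug
descriptors such as substructures, targets, enzymes and pathways. It
implements a three-part training objective on top of an
attention/autoencoder pair network:

1. **Reconstruction (MSE)** — each drug's feature vector is encoded and
   decoded; the reconstruction error regularises the encoder.
2. **Supervised contrastive loss** — pair embeddings (the *comprehensive
   feature vectors*, CFVs) of pairs with the same interaction type are
   pulled together and different types pushed apart, using
   temperature-scaled cosine similarity.
3. **Scheduled classification loss** — label-smoothed cross-entropy for
   the early epochs, then focal loss, which down-weights easy examples
   and helps the many rare interaction types.

The three terms are summed without weights.

## The model in brief

Each drug is represented by a **Jaccard similarity profile**: for every
feature type, the Jaccard similarity of its descriptor set against every
drug in the corpus, concatenated over feature types (so with `n` drugs
and `T` feature types the input width is `T·n`). A drug encoder treats
the `T` blocks as tokens for multi-head self-attention (with a residual
connection), then compresses through a two-layer GELU autoencoder. For
a pair (A, B), latents from the two drugs are fused at three scales
(shallow-with-deep, middle-with-middle, deep-with-shallow), the five
resulting latents are mixed by a second attention block, reduced by a
halving pyramid into the CFV, and classified by a two-layer head.

Evaluation follows three cross-validation regimes:

- **Task 1** — random stratified split over *pairs* (both drugs may be
  seen in training).
- **Task 2** — split over *drugs*; test pairs contain exactly one
  held-out drug.
- **Task 3** — test pairs contain two held-out drugs.

Reported metrics: accuracy, macro precision/recall/F1, micro AUPR and
AUC, plus a per-class table.

Because real descriptor databases cannot be redistributed here, the
package ships a **synthetic benchmark generator** that plants
recoverable structure: drugs are noisy copies of a small set of
archetypes, and the interaction type of a pair is a function of the two
archetypes, with a power-law class imbalance and optional label noise.
Presets reproduce the geometry of two common benchmark datasets
(572 drugs / 65 types / 4 feature types, and 1258 / 100 / 3) at any
scale.

## Worked example

```python
import numpy as np

from ddiscl import (
    SynthConfig, generate, build_similarity_profiles,
    split_task1, toy_train_config, default_network_config,
    train, predict, compute_metrics,
)

# 1. a small synthetic benchmark with planted pharmacological structure
cfg = SynthConfig(n_drugs=40, n_feature_types=4, n_classes=5,
                  n_archetypes=6, pair_coverage=0.6, label_noise=0.1, seed=0)
descriptors, dataset, truth = generate(cfg)
print(f"{descriptors.n_drugs} drugs, {len(dataset)} labelled pairs, "
      f"{dataset.n_classes} interaction types")

# 2. Jaccard similarity profiles (one block per feature type)
profiles = build_similarity_profiles(descriptors)
print(f"profile matrix: {profiles.matrix.shape}  (fea_dim = {profiles.fea_dim})")

# 3. stratified 5-fold split over pairs (task 1) and a short training run
fold = split_task1(dataset, seed=0).folds[0]
train_recs = [dataset.records[i] for i in fold.train_idx]
test_recs = [dataset.records[i] for i in fold.test_idx]

tcfg = toy_train_config(seed=0)
ncfg = default_network_config(profiles.fea_dim, dataset.n_classes,
                              n_feature_types=4, seed=0, symmetrize_pairs=True)
model, history = train(profiles, train_recs, tcfg, net_cfg=ncfg)
print(f"epoch 0: {history.rows[0].total:.3f} total "
      f"({history.rows[0].active_cla_loss}); "
      f"epoch {tcfg.epochs - 1}: {history.rows[-1].total:.3f} total "
      f"({history.rows[-1].active_cla_loss})")

# 4. evaluate on the held-out fold
y = np.array([lab for _, _, lab in test_recs])
probs = predict(model, profiles, [(a, b) for a, b, _ in test_recs])
rep = compute_metrics(y, probs)
print(f"ACC {rep.acc:.3f}  macro-F1 {rep.f1:.3f}  "
      f"AUPR {rep.aupr:.3f}  AUC {rep.auc:.3f}")
```

Output (python 3, numpy only — fully deterministic for a given seed):

```text
40 drugs, 468 labelled pairs, 5 interaction types
profile matrix: (40, 160)  (fea_dim = 160)
epoch 0: 9.344 total (cross_entropy); epoch 29: 6.275 total (focal)
ACC 0.872  macro-F1 0.823  AUPR 0.869  AUC 0.932
```

With 10 % of the labels deliberately corrupted, an accuracy near 0.87
is close to the best achievable on this toy problem.

## Command line

```bash
# synthetic data shaped like a 57-drug / 7-type benchmark slice
ddiscl generate --preset dataset1 --scale 0.05 --seed 0 --out data/

# one cross-validation fold (YAML config optional; see docs/methods.md)
ddiscl train --descriptors data/ --ddis data/ddis.csv \
             --task 1 --fold 0 --seed 0 --out runs/

# all five folds with aggregated metrics
ddiscl evaluate --descriptors data/ --ddis data/ddis.csv --task 1 --out runs/

# probabilities for new pairs
ddiscl predict --model runs/model_task1_fold0.npz --descriptors data/ \
               --pairs pairs.csv --out preds.csv
```

Exit codes: `2` for input validation errors (malformed CSVs, unknown
drugs, conflicting labels), `3` for training divergence.

## Testing

```bash
python -m pytest -q tests/
```

The suite validates every gradient against finite differences, the
vectorised losses against literal per-sample oracles, the Jaccard
primitive against Python set arithmetic, split hygiene for all three
tasks, and several end-to-end properties on synthetic data (signal
recovery, the geometric effect of the contrastive term, the rare-class
benefit of the focal phase). The end-to-end tests in
`tests/test_acceptance.py` train real models and take a few minutes.

## Package layout

| Module | Contents |
| --- | --- |
| `ddiscl.features` | Jaccard similarity and per-drug profiles |
| `ddiscl.network` | drug encoder, multi-scale fusion, latent reduction, classifier |
| `ddiscl.losses` | MSE, supervised contrastive, smoothed CE / focal + schedule |
| `ddiscl.splits_eval` | task 1/2/3 cross-validation, metric report |
| `ddiscl.training` | training loop (RAdam), prediction, checkpoints |
| `ddiscl.synthetic_data` | planted-structure generator and presets |
| `ddiscl.io` / `ddiscl.cli` | CSV/JSON/YAML readers and the `ddiscl` command |
| `ddiscl._autograd` | minimal numpy reverse-mode autodiff core |

See `docs/methods.md` for the precise mathematical definitions, default
hyper-parameters, and the scope and limitations of the synthetic
benchmarks.
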