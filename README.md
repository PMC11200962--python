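# gatedtab

Gated tabular Transformer for adverse-event risk prediction from
structured clinical records.

## The problem

Predicting major adverse cardiovascular events (MACE) and related
complications (ischemic, bleeding, infectious, febrile events,
revascularization) from a patient's structured electronic health record is
an imbalanced binary classification problem: the event class is a small
minority (~13% of records), the feature table mixes categorical findings,
continuous measurements and dates across clinical domains (demographics,
medical history, laboratory tests, follow-up, echocardiography,
angiography), and the informative structure is partly *interactions*
between variables rather than main effects.

`gatedtab` implements a TabTransformer-style model whose attention and
feed-forward branches are modulated by learned sigmoid gates, plus
everything needed around it: leakage-safe preprocessing, unsupervised
embedding pre-training, a reproducible training loop, an
imbalanced-classification evaluation suite, and a synthetic EHR cohort
generator for end-to-end verification when real hospital data cannot be
shared.

## The model

Each categorical column owns an embedding table `E ∈ R^(N×D)` (N
categories plus one reserved unknown slot); a record's codes are looked up
and summed with a per-column identifier embedding, giving one token per
column. The token sequence passes through post-norm Transformer blocks
with two gating mechanisms:

* **gated self-attention** — with multi-head attention output
  `A = Attention(Q, K, V) = softmax(QKᵀ/√d_k) V`, the gate
  `G = σ(X W_g + b_g)` (computed from the block input `X` by default, or
  from `A` itself) modulates the branch elementwise: `A′ = G ⊙ A`;
* **gated feed-forward** — inside the position-wise FFN,
  `F = ReLU(X₁ F₁ + b₁)` is modulated by `G_F = σ(X₁ F_g + b_gF)` as
  `F′ = F ⊙ G_F` before the output projection.

Gate coefficients live strictly in (0, 1), so the network can learn to
damp uninformative channels — the mechanism aimed at the minority-class
problem. With `gate_enabled=False` both gates are bypassed entirely,
recovering the plain TabTransformer block; this is the ablation axis used
throughout the evaluation. Continuous features bypass attention and join
the flattened contextual embeddings in an MLP head that emits one logit
per adverse event. Training minimises binary cross-entropy with Adam,
early-stops on validation loss and is bit-reproducible given a seed.

The model, the training loop and the autoencoder used for embedding
pre-training run on a small reverse-mode autodiff engine over numpy
(`gatedtab.autodiff`), checked against finite differences in the test
suite; there is no deep-learning framework dependency.

## Worked example

```python
from gatedtab import (BlockConfig, CohortSpec, GatedTabTransformer,
                      PreprocessConfig, Preprocessor, TrainConfig,
                      evaluate_events, generate_cohort, planted_signal_check,
                      split_dataset, train)

spec = CohortSpec(
    n_records=4000,
    group_sizes=dict(basic=2, history=4, lab=4, followup=2, echo=2, angio=2),
    events=["mace"],
)
cohort = generate_cohort(spec, seed=7)
print(f"cohort: {cohort.n_records} records, "
      f"{len(cohort.schema.feature_columns)} variables, "
      f"prevalence {cohort.frame['mace'].mean():.3f}, "
      f"oracle AUC {planted_signal_check(cohort):.3f}")

dataset = Preprocessor(cohort.schema, PreprocessConfig()).fit_transform(cohort.frame)
train_set, val_set, test_set = split_dataset(dataset, (0.8, 0.1, 0.1), seed=7)

model = GatedTabTransformer.from_dataset(
    dataset, config=BlockConfig(n_blocks=2, n_heads=4, embed_dim=32), seed=7,
    n_events=1)
report = train(model, train_set, val_set,
               TrainConfig(learning_rate=1e-3, batch_size=32, max_epochs=50,
                           patience=50, seed=7, class_weight="balanced"),
               event="mace")
print(f"trained {report.n_epochs} epochs, best epoch {report.best_epoch}, "
      f"best val AUC {max(report.val_auc):.3f}")

metrics = evaluate_events({"mace": model}, test_set)
block = metrics.events["mace"]
print(f"test: AUC {block.auc:.3f}, AP {block.ap:.3f}, F1 {block.f1:.3f}, "
      f"precision {block.precision:.3f}, recall {block.recall:.3f}")
cm = block.confusion
print(f"confusion at 0.5: TP {cm.tp}, FP {cm.fp}, FN {cm.fn}, TN {cm.tn}")
```

This prints:

```
cohort: 4000 records, 16 variables, prevalence 0.127, oracle AUC 0.929
trained 50 epochs, best epoch 19, best val AUC 0.888
test: AUC 0.848, AP 0.476, F1 0.443, precision 0.327, recall 0.686
confusion at 0.5: TP 35, FP 72, FN 16, TN 277
```

Reading the numbers: the generator planted a signal whose Bayes-optimal
score separates cases from controls at AUC 0.929 — no model can reliably
beat that. The gated model reaches test AUC 0.848 from 3200 training
records. With balanced class weighting the default 0.5 threshold recovers
69% of true events (recall) at 33% precision; the threshold is a clinical
choice and the full ROC/PR curves are exported alongside the report.

The same pipeline is available from a shell:

```bash
gatedtab simulate   --seed 7 --out sim/
gatedtab preprocess --data sim/raw.csv --schema sim/schema.json --out enc/
gatedtab pretrain   --data enc/ --epochs 50 --out emb/embeddings.npz
gatedtab train      --data enc/ --embeddings emb/embeddings.npz --out fit/
gatedtab evaluate   --data enc/ --checkpoint fit/checkpoint.npz --out eval/
gatedtab predict    --data enc/ --checkpoint fit/checkpoint.npz --out pred.csv
```

Every subcommand writes a JSON manifest (input hashes, config hash, seed),
and rerunning any step with identical inputs reproduces its artifacts
byte for byte.

## Layout

| module | contents |
| --- | --- |
| `gatedtab.schema` | `FeatureSchema`: column roles, clinical groups, vocabularies |
| `gatedtab.preprocess` | fit-on-train/transform-anywhere encoding to `EncodedDataset` |
| `gatedtab.embedding` | column embeddings, autoencoder pre-training |
| `gatedtab.model` | gated Transformer blocks and the `GatedTabTransformer` |
| `gatedtab.training` | stratified splits, Adam/BCE loop, early stopping |
| `gatedtab.evaluation` | confusion, P/R/F1, ROC/AUC, PR/AP per event |
| `gatedtab.synthetic` | schema-shaped synthetic cohorts with planted signal |
| `gatedtab.benchmark` | the reduced gated-vs-ungated learnability protocol |
| `gatedtab.autodiff` | the numpy reverse-mode autodiff engine |
| `gatedtab.cli` | `gatedtab` command-line pipeline |

See `docs/methods.md` for the modelling assumptions, parameter defaults
and known limitations.
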