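# Methods

This note records the modelling assumptions, parameter defaults and
numerical choices behind `gatedtab`, and what the synthetic verification
does and does not establish.

## Model

The backbone is a TabTransformer: only categorical columns enter the
attention stack, one token per column. A record's token is the sum of its
category embedding (a per-column table with one row per category plus one
reserved unknown row) and a learned per-column identifier embedding.
Continuous features skip attention entirely and join the flattened
contextual embeddings at the classification head. This split rests on the
assumption that the interactions worth modelling with attention live among
the discrete clinical findings, while continuous measurements contribute
mainly through the head; it keeps the sequence length equal to the number
of categorical columns and the cost quadratic in that number only.

Each block is post-norm: `X₁ = LN(X + Dropout(A′))`,
`X₂ = LN(X₁ + Dropout(FFN′(X₁)))`. Multi-head scaled dot-product attention
uses learned Q/K/V projections with biases and an output projection. The
two gates are:

* attention gate `G = σ(src·W_g + b_g)`, `A′ = G ⊙ A`, where `src` is the
  block input (default, `gate_input_source="layer_input"`) or the
  attention output (`"attention_output"`). Both readings appear in the
  literature on gated attention; the formal definition computes the gate
  from the layer input, so that is the default, and the switch makes the
  alternative testable. One gate per block acts on the merged multi-head
  output; `per_head_gate=True` gates each head separately before merging.
* FFN gate `G_F = σ(X₁·F_g + b_gF)` applied to the first-layer ReLU
  activation `F = ReLU(X₁·F₁ + b₁)`, i.e. `F′ = F ⊙ G_F`, followed by an
  output projection `F′·F₂ + b₂` back to the model dimension. The FFN is
  the usual two-layer design (hidden width `ffn_mult·D`, default 4·D); the
  gate modulates the post-nonlinearity signal.

With `gate_enabled=False` both gate multiplications are skipped entirely
(not fixed at 0.5), so the ungated configuration is exactly a plain
TabTransformer block — the ablation axis for every gating comparison.

The head flattens the contextual embeddings, concatenates the continuous
features and applies a two-hidden-layer ReLU MLP (widths 4·D and D) to one
logit per adverse event. Probabilities are `σ(logit)`. Multiple adverse
events are handled by default as separate single-event models sharing the
same code path; a multi-head variant is a one-argument change
(`n_events > 1`).

### Initialisation

Linear weights are Xavier-uniform; biases zero; embeddings N(0, 1/√D);
LayerNorm at scale 1, shift 0. Gate parameters are the exception: gate
weight matrices start at **zero** and gate biases at **+4**, so a freshly
initialised gated block multiplies its branches by a constant σ(4) ≈ 0.982
— functionally the ungated block — and learns data-dependent modulation
from there. This is the highway-network/ReZero convention of starting at
(near-)identity; with neutral gate initialisation (gates at 0.5) the gated
model systematically trailed its ungated counterpart on identical data,
an optimisation artifact rather than a property of gating.
`BlockConfig.gate_bias_init` exposes the bias.

### Default hyperparameters

| parameter | default | notes |
| --- | --- | --- |
| embedding dimension D | 128 | full-scale configuration |
| attention blocks | 6 | |
| attention heads | 8 | D divisible by heads enforced |
| dropout / attention / add-norm dropout | 0.1 each | train mode only |
| learning rate | 5e-6 | Adam |
| batch size | 256 | |
| max epochs | 200 | |
| early-stopping patience | 20 | on validation loss, best weights restored |
| split fractions | 0.70 / 0.15 / 0.15 | stratified on the outcome |
| gradient clip (global L2) | 1.0 | `clip_norm=None` disables |

The loss is binary cross-entropy on logits (numerically stable form);
optional inverse-prevalence class weights (`class_weight="balanced"`)
rescale per-record losses. The optimiser updates every parameter,
including the gate weights. "Converged" is operationalised as early
stopping: training stops when validation loss has not improved for
`patience` epochs and the best-epoch weights are restored. All randomness
(init, shuffling, dropout) flows from explicit integer seeds; identical
seed, config and data give bit-identical reports and checkpoints.

## Preprocessing

Fitted statistics come from the training split only and are frozen in a
JSON-serialisable state; transforming validation/test/deployment rows
reuses them unchanged.

* Continuous: outlier screen → impute → z-score → min-max. The outlier
  rule (z-score with k=3 by default, or IQR with m=1.5) uses training-split
  statistics; flagged cells are set missing and imputed (masking rather
  than row deletion, because deleting rows is not actionable when scoring
  a new patient; row deletion remains available as a standalone strategy).
  Imputation is the training mean (or median). Standardisation subtracts
  the mean and divides by the population (ddof=0) standard deviation, then
  min-max rescales the z-scores to [0, 1] using the training extremes —
  the two stated normalisations applied in sequence; on the training split
  the output is exactly [0, 1], other splits may exceed it slightly and
  are deliberately not clipped. A constant column maps to 0.5 everywhere
  and is flagged degenerate.
* Categorical: mode imputation (ties broken by vocabulary order), then
  integer codes against the schema vocabulary with one reserved unknown
  code for categories unseen at fit time (absorbed and counted, never an
  error).
* Datetime: expanded to year, month, day, day-of-week (Monday = 0) and a
  holiday flag against a user-supplied date list (no national calendar is
  bundled); the derived columns then follow the continuous path.
  Unparseable dates become missing and are imputed.
* Sliding-window aggregates (trailing, window includes the current point,
  shrinking at the series start; default window 3) are provided as a
  standalone operation for longitudinal inputs; the synthetic cohorts are
  cross-sectional, so the default pipeline does not apply them.
* Model-based imputation is an extension point, not implemented.

## Embedding pre-training

The autoencoder reconstructs the concatenated one-hot indicator vectors of
all categorical columns: `h = f(W_e x + b_e)`, `x̂ = g(W_d h + b_d)` with
f = ReLU and g = identity by default, minimising the mean over samples of
the squared reconstruction norm. Because inputs are indicators, the
encoder image of indicator `e_j` is the learned representation of category
j, and becomes its embedding row — the reading under which "use the
encoder weights to initialise the embedding matrix" is shape-consistent.
Pre-training is same-data and unsupervised; with `epochs=0` the seeded
random initialisation is returned unchanged. Training is full-batch Adam
(default lr 0.01), which is exact-deterministic and sufficient at the
scale of a category vocabulary.

## Evaluation conventions

* Positive call iff probability ≥ threshold (closed at the threshold).
* Precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic mean;
  zero denominators yield 0 with a warning so batch evaluation never
  aborts.
* ROC/AUC by the trapezoidal rule over all distinct thresholds, which
  equals the Mann-Whitney rank statistic with ties credited ½ — the test
  suite asserts this equivalence exactly against a brute-force pairwise
  oracle.
* Average precision is the step-wise sum Σ(R_k − R_{k−1})·P_k, no
  interpolation.
* Curves, AUC and AP are computed via scikit-learn, whose conventions
  match the definitions above; the oracles in the tests are independent
  reimplementations.

## Synthetic cohorts

The generator emulates the *shape* of a hospital EHR table: six clinical
groups (default 8/31/30/25/20/20 = 134 variables), mixed roles per group
(history and angiography mostly categorical, labs and ECHO mostly
continuous, basic information mixed with one admission date), categorical
cardinalities cycling 2–10 with Dirichlet-categorical marginals,
continuous columns alternating Normal and LogNormal, missing cells
completely at random (default 5%), and sporadic ×10 gross outliers
(default 1% of continuous cells).

Outcomes follow a logistic model on standardised feature values
(per-level random effects for categorical columns), with a configurable
share of linear-predictor variance carried by pairwise products
(`interaction_share`, default 0.25) — interactions are the regime in which
attention over feature tokens has something to exploit beyond a linear
model. The linear predictor is rescaled to a target standard deviation
(`signal_sd`, default 3.0) and the intercept is solved numerically so the
marginal prevalence matches the requested rate (default 0.13, the minority
share implied by published test-split marginals). On the default strong
signal the Bayes-oracle score — the true linear predictor, exposed for
every cohort — reaches AUC ≈ 0.92–0.94. A note on calibration: under a
logistic link a Gaussian score with sd 2 yields an oracle AUC of only
~0.88 at 13% prevalence (the binormal closed form Φ(d/√2) does not apply
to logistic generation), so "strong signal" is defined here as sd 3,
which puts the oracle above 0.9.

What the generator does **not** emulate: realistic clinical marginal
distributions, inter-feature correlation structure (beyond the planted
interactions), informative missingness, temporal admission sequences, or
follow-up dynamics. Passing tests on these cohorts therefore demonstrate
that the pipeline, model and training behave correctly and can recover a
planted interaction signal at realistic prevalence — not that any
particular clinical performance level would be attained on real records.

## The reduced benchmark

Full-scale training (134 columns, 6 blocks, D=128, 200 epochs) is far too
heavy for routine verification, so the gating comparison runs a fixed
reduced protocol chosen as this package's verification scale: 4000-record
cohorts with 16 columns (2/4/4/2/2/2 per group), prevalence 0.13, strong
default signal; 80/10/10 stratified splits; a 2-block, D=32, 4-head model;
Adam at lr 1e-3, batch 32, at most 50 epochs; three seeds per comparison,
compared on mean test AUC. Under this protocol the gated model reaches
mean test AUC ≈ 0.85–0.88 (a HistGradientBoosting reference sits in the
same range, and the Bayes oracle at ≈ 0.93), with the gated and ungated
variants within ±0.01 of each other. A null-signal control (signal_sd = 0)
trains the same model and checks its test AUC is statistically
indistinguishable from 0.5.

## Numerical choices

Float64 throughout; LayerNorm ε = 1e-5; numerically stable sigmoid and
BCE-on-logits; softmax with max-subtraction; population (ddof=0) standard
deviations; largest-remainder rounding for stratified split allocation;
checkpoints as named-array `.npz` archives plus JSON manifests (bit-stable
reload is asserted in the tests); SHA-256 over sorted parameter arrays as
the checkpoint checksum.

## Known limitations

* Follow-up variables are generated and encoded like any other group, but
  in deployment they may be unavailable at admission time; which variables
  are legitimately known at prediction time is a schema-level decision the
  package does not enforce.
* Only the TabTransformer backbone ships; the gate layers are written
  against generic block inputs but no other backbone is provided.
* No attribution/importance score is derived from the gates; the raw gate
  and attention tensors are exported (`collect_gates=True`) for
  inspection, nothing more.
* Whether gating is best applied per head or per block is genuinely open;
  both are implemented, per-block is the default.
* CPU-only by construction; the autodiff engine favours clarity and
  determinism over speed and is sized for desk-scale experiments.
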