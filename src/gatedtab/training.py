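"""Minibatch training loop with validation-based early stopping.

The loop optimises every model parameter — including the gate weights —
with Adam on a binary cross-entropy objective, shuffling minibatches each
epoch from a seeded generator, evaluating on a held-out validation split
after every epoch, and restoring the weights of the best validation epoch
when patience runs out.  Given the same seed, configuration and data the
loop is bit-reproducible: the returned report and parameter checksum are
identical across runs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from pydantic import BaseModel, model_validator
from sklearn.metrics import roc_auc_score

from .autodiff import Adam, bce_with_logits
from .model import GatedTabTransformer
from .preprocess import EncodedDataset

__all__ = ["TrainConfig", "TrainReport", "TrainingDiverged",
           "stratified_indices", "split_dataset", "train", "predict_risk"]


class TrainingDiverged(RuntimeError):
    """Loss became non-finite; carries diagnostic context."""


class TrainConfig(BaseModel):
    """Optimisation hyperparameters."""

    model_config = {"extra": "forbid"}

    learning_rate: float = 5e-6
    batch_size: int = 256
    max_epochs: int = 200
    patience: int = 20
    seed: int = 0
    class_weight: str = "none"          # "none" | "balanced"
    split: tuple[float, float, float] = (0.7, 0.15, 0.15)
    threshold: float = 0.5
    #: global gradient-norm clip; None disables clipping
    clip_norm: float | None = 1.0

    @model_validator(mode="after")
    def _check(self) -> "TrainConfig":
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {self.split}")
        if self.class_weight not in ("none", "balanced"):
            raise ValueError(f"unknown class_weight {self.class_weight!r}")
        return self


@dataclass
class TrainReport:
    """Per-epoch bookkeeping for one training run."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_auc: list[float] = field(default_factory=list)
    best_epoch: int = -1
    checksum: str = ""

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)

    def to_jsonl(self, path: str | Path) -> None:
        lines = [json.dumps({"epoch": e, "train_loss": tl, "val_loss": vl,
                             "val_auc": va})
                 for e, (tl, vl, va) in enumerate(
                     zip(self.train_loss, self.val_loss, self.val_auc))]
        lines.append(json.dumps({"best_epoch": self.best_epoch,
                                 "checksum": self.checksum}))
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _largest_remainder(n: int, fractions: tuple[float, ...]) -> list[int]:
    """Integer allocation of n items proportional to fractions, summing to n."""
    exact = [n * f for f in fractions]
    base = [int(np.floor(e)) for e in exact]
    short = n - sum(base)
    remainders = sorted(range(len(fractions)),
                        key=lambda i: exact[i] - base[i], reverse=True)
    for i in remainders[:short]:
        base[i] += 1
    return base


def stratified_indices(y: np.ndarray,
                       fractions: tuple[float, float, float],
                       seed: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, exhaustive, class-stratified row indices for three splits.

    Within each outcome class, rows are shuffled with the given seed and
    allocated by largest-remainder rounding, so each split's prevalence
    stays within rounding distance of the full data.  A non-empty split
    that would receive zero minority-class rows is an error (evaluation
    metrics would be undefined there).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    parts: list[list[np.ndarray]] = [[], [], []]
    classes = np.unique(y)
    for cls in classes:
        idx = rng.permutation(np.nonzero(y == cls)[0])
        counts = _largest_remainder(len(idx), fractions)
        start = 0
        for s, c in enumerate(counts):
            parts[s].append(idx[start:start + c])
            start += c
    minority = min(classes, key=lambda c: (y == c).sum())
    out = []
    for s, chunks in enumerate(parts):
        idx = np.sort(np.concatenate(chunks)) if chunks else np.array([], dtype=int)
        if fractions[s] > 0 and len(idx) > 0 and len(classes) > 1:
            if (y[idx] == minority).sum() == 0:
                raise ValueError(
                    f"split {s} received zero minority-class rows; "
                    "use a larger split or more data")
        out.append(idx)
    return tuple(out)  # type: ignore[return-value]


def split_dataset(dataset: EncodedDataset,
                  fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
                  seed: int = 0, event: str | None = None
                  ) -> tuple[EncodedDataset, EncodedDataset, EncodedDataset]:
    """Stratified train/validation/test split of an encoded dataset."""
    event = event or dataset.event_names[0]
    idx_tr, idx_va, idx_te = stratified_indices(
        dataset.event_labels(event), fractions, seed)
    return (dataset.subset(idx_tr), dataset.subset(idx_va),
            dataset.subset(idx_te))


def _clip_gradients(model: GatedTabTransformer, max_norm: float) -> None:
    """Rescale all gradients so their global L2 norm is at most max_norm."""
    total = 0.0
    grads = [p.grad for p in model.parameters().values() if p.grad is not None]
    for g in grads:
        total += float((g * g).sum())
    norm = np.sqrt(total)
    if norm > max_norm:
        scale = max_norm / norm
        for g in grads:
            g *= scale


def _eval_loss(model: GatedTabTransformer, codes: np.ndarray,
               cont: np.ndarray, y: np.ndarray,
               weights: np.ndarray | None) -> float:
    """BCE on a whole split in eval mode; weights indexed by class label."""
    logits, _ = model.forward(codes, cont, train=False)
    w = weights[y.astype(int)][:, None] if weights is not None else None
    return bce_with_logits(logits, y[:, None], w).item()


def train(model: GatedTabTransformer, train_set: EncodedDataset,
          val_set: EncodedDataset, config: TrainConfig,
          event: str | None = None) -> TrainReport:
    """Optimise the model on one adverse-event outcome.

    Early stopping monitors validation loss with the configured patience
    and restores the best-epoch weights before returning; with an empty
    validation split the loop simply runs to ``max_epochs``.
    """
    event = event or train_set.event_names[0]
    y_train = train_set.event_labels(event).astype(np.float64)
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.learning_rate)

    class_w = None
    if config.class_weight == "balanced":
        n = len(y_train)
        n_pos = max(y_train.sum(), 1.0)
        n_neg = max(n - y_train.sum(), 1.0)
        class_w = np.array([n / (2.0 * n_neg), n / (2.0 * n_pos)])

    has_val = val_set.n_rows > 0
    if has_val:
        y_val = val_set.event_labels(event).astype(np.float64)

    report = TrainReport()
    best = (np.inf, None)
    for epoch in range(config.max_epochs):
        perm = rng.permutation(train_set.n_rows)
        losses, sizes = [], []
        for start in range(0, len(perm), config.batch_size):
            batch = perm[start:start + config.batch_size]
            if batch.size == 0:
                warnings.warn("skipping empty minibatch")
                continue
            yb = y_train[batch]
            w = class_w[yb.astype(int)][:, None] if class_w is not None else None
            logits, _ = model.forward(train_set.cat_codes[batch],
                                      train_set.cont_values[batch],
                                      train=True, rng=rng)
            loss = bce_with_logits(logits, yb[:, None], w)
            if not np.isfinite(loss.item()):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}, batch {start // config.batch_size}: "
                    f"loss={loss.item()}, lr={config.learning_rate}")
            opt.zero_grad()
            loss.backward()
            if config.clip_norm is not None:
                _clip_gradients(model, config.clip_norm)
            opt.step()
            losses.append(loss.item())
            sizes.append(len(batch))
        report.train_loss.append(float(np.average(losses, weights=sizes)))

        if has_val:
            val_loss = _eval_loss(model, val_set.cat_codes,
                                  val_set.cont_values, y_val, class_w)
            probs = model.predict_proba(val_set.cat_codes, val_set.cont_values)
            col = 0 if model.n_events == 1 else _event_index(val_set, event)
            auc = (float(roc_auc_score(y_val, probs[:, col]))
                   if len(np.unique(y_val)) > 1 else float("nan"))
            report.val_loss.append(val_loss)
            report.val_auc.append(auc)
            if val_loss < best[0]:
                best = (val_loss, model.state_arrays())
                report.best_epoch = epoch
            elif epoch - report.best_epoch >= config.patience:
                break
        else:
            report.val_loss.append(float("nan"))
            report.val_auc.append(float("nan"))
            report.best_epoch = epoch

    if best[1] is not None:
        model.load_state(best[1])
    report.checksum = model.checksum()
    return report


def _event_index(dataset: EncodedDataset, event: str) -> int:
    try:
        return dataset.event_names.index(event)
    except ValueError:
        return 0


def predict_risk(model: GatedTabTransformer, dataset: EncodedDataset,
                 threshold: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Event probabilities and binary calls (positive iff prob >= threshold)."""
    probs = model.predict_proba(dataset.cat_codes, dataset.cont_values)
    return probs, (probs >= threshold).astype(np.int64)
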