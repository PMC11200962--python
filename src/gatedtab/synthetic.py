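"""Synthetic EHR-style cohort generator.

The real clinical cohorts this package targets are hospital-private, so
every other module is exercised against synthetic cohorts that reproduce
the *shape* of such data: six clinical variable groups totalling 134
mixed-type columns by default, rare binary adverse-event outcomes
(prevalence 0.13), missing cells, and occasional gross outliers.

Outcomes are drawn from a logistic model with optional pairwise
feature interactions:

    P(y = 1 | x) = sigmoid(alpha + sum_i beta_i v_i + sum_(i,j) gamma_ij v_i v_j)

where ``v_i`` is the standardised value of a continuous column or a
per-level effect for a categorical column.  The intercept ``alpha`` is
solved numerically so the marginal prevalence matches the requested rate,
and the linear predictor is rescaled to a chosen standard deviation so the
difficulty of the learning problem is controlled explicitly.  The
generating coefficients are recorded so tests can compare any trained
model against the Bayes-oracle score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.optimize import brentq
from sklearn.metrics import roc_auc_score

from .schema import (DEFAULT_EVENTS, DEFAULT_GROUP_SIZES, GROUPS, ColumnSpec,
                     FeatureSchema, Group)

__all__ = ["CohortSpec", "SyntheticCohort", "make_schema", "generate_cohort",
           "planted_signal_check"]

_DATE_START = np.datetime64("2014-01-01")
_DATE_END = np.datetime64("2019-12-31")

#: Fraction of columns per group that are categorical (rest continuous).
#: History and angiography are mostly discrete findings; labs and ECHO are
#: mostly measurements; basic information and follow-up are mixed.
_CAT_FRACTION: dict[Group, float] = {
    "basic": 0.5,
    "history": 0.8,
    "lab": 0.2,
    "followup": 0.5,
    "echo": 0.2,
    "angio": 0.8,
}


class CohortSpec(BaseModel):
    """Generating conditions for one synthetic cohort."""

    model_config = {"extra": "forbid"}

    n_records: int = 8000
    group_sizes: dict[str, int] = Field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    events: list[str] = Field(default_factory=lambda: list(DEFAULT_EVENTS))
    prevalence: float = 0.13
    #: number of features carrying main effects
    n_main_effects: int = 8
    #: number of pairwise interactions among the main-effect features
    n_interactions: int = 4
    #: standard deviation of the standardised linear predictor; 0 = null signal
    signal_sd: float = 3.0
    #: share of linear-predictor variance carried by the interaction terms
    interaction_share: float = 0.25
    missing_rate: float = 0.05
    outlier_rate: float = 0.01
    outlier_factor: float = 10.0
    min_cardinality: int = 2
    max_cardinality: int = 10

    @model_validator(mode="after")
    def _check(self) -> "CohortSpec":
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        if any(s <= 0 for s in self.group_sizes.values()):
            raise ValueError("group sizes must be positive")
        unknown = set(self.group_sizes) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown groups: {sorted(unknown)}")
        if not 0.0 <= self.interaction_share <= 1.0:
            raise ValueError("interaction_share must lie in [0, 1]")
        return self


@dataclass
class SyntheticCohort:
    """A generated raw table plus its ground truth."""

    frame: pd.DataFrame            # raw features + outcome columns + row_id
    schema: FeatureSchema
    scores: pd.DataFrame           # true linear predictor per event (n x events)
    coefficients: dict             # per-event generating coefficients
    spec: CohortSpec
    seed: int

    @property
    def n_records(self) -> int:
        return len(self.frame)

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.frame.to_csv(d / "raw.csv", index=False)
        self.schema.to_json(d / "schema.json")
        truth = {
            "seed": self.seed,
            "spec": self.spec.model_dump(),
            "coefficients": self.coefficients,
            "scores": {c: self.scores[c].tolist() for c in self.scores.columns},
        }
        (d / "truth.json").write_text(json.dumps(truth) + "\n", encoding="utf-8")


def make_schema(spec: CohortSpec) -> FeatureSchema:
    """Deterministic schema for a cohort spec.

    Columns are named ``<group>_<k>``.  Within each group, categorical and
    continuous roles are assigned round-robin at the group's categorical
    fraction; the first basic-information column is the admission date.
    Categorical cardinalities cycle through the configured range.
    """
    columns: list[ColumnSpec] = []
    card_cycle = spec.min_cardinality
    for group in GROUPS:
        size = spec.group_sizes.get(group, 0)
        frac = _CAT_FRACTION[group]
        acc = 0.0
        for k in range(size):
            name = f"{group}_{k}"
            if group == "basic" and k == 0:
                columns.append(ColumnSpec(name=name, role="datetime",
                                          group=group))
                continue
            acc += frac
            if acc >= 1.0 - 1e-9:
                acc -= 1.0
                vocab = [f"lv{i}" for i in range(card_cycle)]
                card_cycle += 1
                if card_cycle > spec.max_cardinality:
                    card_cycle = spec.min_cardinality
                columns.append(ColumnSpec(name=name, role="categorical",
                                          group=group, vocabulary=vocab))
            else:
                columns.append(ColumnSpec(name=name, role="continuous",
                                          group=group))
    for event in spec.events:
        columns.append(ColumnSpec(name=event, role="outcome", group="basic"))
    return FeatureSchema(columns=columns)


def _standardise(x: np.ndarray) -> np.ndarray:
    if x.size == 0:
        return x
    sd = x.std(ddof=0)
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def _solve_intercept(score: np.ndarray, prevalence: float) -> float:
    """Find alpha with mean(sigmoid(alpha + score)) = prevalence."""

    def gap(alpha: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(alpha + score))))) - prevalence

    return float(brentq(gap, -40.0, 40.0, xtol=1e-12))


def generate_cohort(spec: CohortSpec, seed: int = 0) -> SyntheticCohort:
    """Draw one reproducible cohort from the generating model."""
    rng = np.random.default_rng(seed)
    schema = make_schema(spec)
    n = spec.n_records
    feature_cols = schema.feature_columns

    raw: dict[str, np.ndarray] = {}
    signal_values: dict[str, np.ndarray] = {}
    cat_level_effects: dict[str, list[float]] = {}
    cont_count = 0
    for col in feature_cols:
        if col.role == "datetime":
            span = int((_DATE_END - _DATE_START) / np.timedelta64(1, "D"))
            offsets = rng.integers(0, span + 1, size=n)
            dates = _DATE_START + offsets.astype("timedelta64[D]")
            raw[col.name] = np.datetime_as_string(dates, unit="D")
        elif col.role == "continuous":
            # alternate clinically plausible marginals: Normal and LogNormal
            if cont_count % 2 == 0:
                mu = rng.uniform(-1.0, 1.0)
                sigma = rng.uniform(0.5, 2.0)
                x = rng.normal(mu, sigma, size=n)
            else:
                x = rng.lognormal(mean=0.0, sigma=0.5, size=n)
            cont_count += 1
            raw[col.name] = x
            signal_values[col.name] = _standardise(x)
        else:
            k = len(col.vocabulary)
            weights = rng.dirichlet(np.ones(k))
            codes = rng.choice(k, size=n, p=weights)
            raw[col.name] = np.array(col.vocabulary, dtype=object)[codes]
            effects = rng.normal(size=k)
            cat_level_effects[col.name] = effects.tolist()
            signal_values[col.name] = _standardise(effects[codes])

    # -- outcome model per event --------------------------------------
    eligible = [c.name for c in feature_cols if c.role != "datetime"]
    coefficients: dict[str, dict] = {}
    scores = {}
    frame = pd.DataFrame(raw, columns=[c.name for c in feature_cols])
    for event in spec.events:
        n_main = min(spec.n_main_effects, len(eligible))
        chosen = list(rng.choice(eligible, size=n_main, replace=False))
        betas = rng.normal(size=n_main)
        pair_idx: list[tuple[int, int]] = []
        if n_main >= 2 and spec.n_interactions > 0:
            all_pairs = [(i, j) for i in range(n_main) for j in range(i + 1, n_main)]
            take = min(spec.n_interactions, len(all_pairs))
            sel = rng.choice(len(all_pairs), size=take, replace=False)
            pair_idx = [all_pairs[s] for s in sel]
        gammas = rng.normal(size=len(pair_idx))

        if n == 0 or spec.signal_sd == 0.0:
            score = np.zeros(n)
        else:
            v = np.column_stack([signal_values[c] for c in chosen])
            s_main = _standardise(v @ betas)
            if pair_idx:
                s_int = _standardise(sum(
                    g * v[:, i] * v[:, j]
                    for g, (i, j) in zip(gammas, pair_idx)))
                w = spec.interaction_share
                score = np.sqrt(1.0 - w) * s_main + np.sqrt(w) * s_int
            else:
                score = s_main
            score = _standardise(score) * spec.signal_sd
        alpha = (_solve_intercept(score, spec.prevalence) if n > 0
                 else float(np.log(spec.prevalence / (1 - spec.prevalence))))
        prob = 1.0 / (1.0 + np.exp(-(alpha + score)))
        frame[event] = rng.binomial(1, prob) if n > 0 else np.array([], dtype=int)
        scores[event] = score
        coefficients[event] = {
            "alpha": alpha,
            "main_features": chosen,
            "betas": betas.tolist(),
            "interactions": [[chosen[i], chosen[j]] for i, j in pair_idx],
            "gammas": gammas.tolist(),
            "cat_level_effects": {c: cat_level_effects[c]
                                  for c in chosen if c in cat_level_effects},
        }

    # -- corruption: outliers then MCAR missingness --------------------
    cont_names = [c.name for c in feature_cols if c.role == "continuous"]
    if spec.outlier_rate > 0 and n > 0:
        for name in cont_names:
            hit = rng.random(n) < spec.outlier_rate
            frame.loc[hit, name] = frame.loc[hit, name] * spec.outlier_factor
    if spec.missing_rate > 0 and n > 0:
        for col in feature_cols:
            hit = rng.random(n) < spec.missing_rate
            if hit.any():
                frame.loc[hit, col.name] = (np.nan if col.role == "continuous"
                                            else None)

    frame.insert(0, "row_id", [f"r{i:06d}" for i in range(n)])
    return SyntheticCohort(frame=frame, schema=schema,
                           scores=pd.DataFrame(scores, dtype=float),
                           coefficients=coefficients, spec=spec, seed=seed)


def planted_signal_check(cohort: SyntheticCohort, event: str | None = None) -> float:
    """AUC of the true linear predictor — the Bayes-oracle reference.

    No trained model can beat this score except by sampling noise, so it
    upper-bounds what any fitted classifier should reach on the cohort.
    """
    event = event or cohort.spec.events[0]
    y = cohort.frame[event].to_numpy()
    s = cohort.scores[event].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError(f"event {event!r} has a single class")
    return float(roc_auc_score(y, s))
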