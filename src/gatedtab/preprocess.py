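"""Leakage-safe preprocessing of a mixed-type clinical feature table.

The pipeline turns a raw table (categorical, continuous and datetime
columns plus binary outcome columns) into an :class:`EncodedDataset` of
integer category codes and rescaled continuous values:

* continuous columns are outlier-screened, imputed, z-scored and then
  min-max rescaled to ``[0, 1]``;
* categorical columns are imputed with the training-split mode and
  integer-coded against the schema vocabulary, with one reserved code for
  categories unseen at fit time;
* datetime columns are expanded into calendar features (year, month, day,
  day of week with Monday = 0, and a holiday flag) which then follow the
  continuous path.

All statistics are fitted once on the training split and frozen in a
:class:`PreprocessState`; transforming any other split reuses them
unchanged, so no information can leak from validation or test rows into
the encoding.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel

from .schema import FeatureSchema

__all__ = [
    "PreprocessConfig",
    "NumericState",
    "PreprocessState",
    "EncodedDataset",
    "Preprocessor",
    "fit_transform_numeric",
    "transform_numeric",
    "encode_categorical",
    "decode_categorical",
    "extract_time_features",
    "window_aggregate",
    "impute_missing",
    "flag_outliers",
]

#: Derived calendar features appended for every datetime column.
TIME_FEATURES = ("year", "month", "day", "day_of_week", "is_holiday")


class DegenerateColumnWarning(UserWarning):
    """A continuous column with zero variance on the fitting split."""


class PreprocessConfig(BaseModel):
    """Tunable preprocessing behaviour (all fitted on the training split)."""

    model_config = {"extra": "forbid"}

    numeric_impute: Literal["mean", "median"] = "mean"
    outlier_rule: Literal["zscore", "iqr", "none"] = "zscore"
    outlier_k: float = 3.0          # z-score threshold
    iqr_m: float = 1.5              # IQR multiplier
    drop_threshold: float = 0.05    # max missing fraction for drop strategies
    holidays: list[str] = []        # ISO dates treated as holidays


# ---------------------------------------------------------------------------
# standalone column operations
# ---------------------------------------------------------------------------

@dataclass
class NumericState:
    """Frozen statistics for one continuous column."""

    mean: float
    sd: float                # population (ddof=0) standard deviation
    post_z_min: float
    post_z_max: float
    impute_value: float
    degenerate: bool = False
    # outlier-rule statistics, computed on raw observed training values
    raw_mean: float = 0.0
    raw_sd: float = 0.0
    q1: float = 0.0
    q3: float = 0.0


def _as_float(col) -> np.ndarray:
    return pd.to_numeric(pd.Series(col), errors="coerce").to_numpy(dtype=np.float64)


def fit_transform_numeric(col: Sequence[float]) -> tuple[np.ndarray, NumericState]:
    """Z-score then min-max rescale a continuous column to ``[0, 1]``.

    Both steps use statistics of the supplied (fitting) values, so the
    output of the fit split always lands in ``[0, 1]``.  A constant column
    maps to all ``0.5`` and raises :class:`DegenerateColumnWarning`.
    Missing values must already be imputed.
    """
    x = _as_float(col)
    if x.size == 0:
        raise ValueError("cannot fit an empty column")
    if np.isnan(x).all():
        raise ValueError("cannot fit an all-missing column")
    if np.isnan(x).any():
        raise ValueError("impute missing values before scaling")
    mean = float(x.mean())
    sd = float(x.std(ddof=0))
    if sd > 0.0:
        z = (x - mean) / sd
        lo, hi = float(z.min()), float(z.max())
    # a column constant up to float rounding has sd == 0 or a collapsed
    # post-z range; both are degenerate
    if sd == 0.0 or hi == lo:
        warnings.warn("constant continuous column", DegenerateColumnWarning,
                      stacklevel=2)
        state = NumericState(mean=mean, sd=sd, post_z_min=0.0, post_z_max=0.0,
                             impute_value=mean, degenerate=True)
        return np.full_like(x, 0.5), state
    state = NumericState(mean=mean, sd=sd, post_z_min=lo, post_z_max=hi,
                         impute_value=mean)
    return (z - lo) / (hi - lo), state


def transform_numeric(col: Sequence[float], state: NumericState) -> np.ndarray:
    """Apply frozen scaling statistics to new values (no refit, no clip)."""
    x = _as_float(col)
    if state.degenerate or state.post_z_max == state.post_z_min:
        return np.full_like(x, 0.5)
    z = (x - state.mean) / state.sd
    return (z - state.post_z_min) / (state.post_z_max - state.post_z_min)


def encode_categorical(col: Sequence, vocab: Sequence[str]
                       ) -> tuple[np.ndarray, np.ndarray, int]:
    """Integer-code a categorical column against an ordered vocabulary.

    Returns ``(codes, indicator, n_unknown)``.  In-vocabulary values get
    their vocabulary position and a one-hot indicator row; values unseen
    at fit time get the reserved code ``len(vocab)`` and an all-zero row.
    """
    mapping = {v: i for i, v in enumerate(vocab)}
    unknown = len(vocab)
    values = pd.Series(col).astype(object)
    codes = np.array([mapping.get(v, unknown) for v in values], dtype=np.int64)
    indicator = np.zeros((len(codes), len(vocab)), dtype=np.int64)
    known = codes < unknown
    indicator[np.nonzero(known)[0], codes[known]] = 1
    return codes, indicator, int((~known).sum())


def decode_categorical(codes: Sequence[int], vocab: Sequence[str]) -> list[str | None]:
    """Inverse of :func:`encode_categorical`; the unknown code maps to None."""
    return [vocab[c] if 0 <= c < len(vocab) else None for c in codes]


def extract_time_features(timestamps: Sequence, holidays: Sequence[str] = ()
                          ) -> pd.DataFrame:
    """Expand dates into calendar features.

    ``day_of_week`` is coded 0 = Monday … 6 = Sunday; ``is_holiday`` flags
    membership in the supplied holiday date list.  Unparseable entries
    yield missing values (handled downstream by imputation).
    """
    ts = pd.to_datetime(pd.Series(timestamps), errors="coerce", format="ISO8601")
    holiday_set = {pd.Timestamp(h).normalize() for h in holidays}
    normalized = ts.dt.normalize()
    return pd.DataFrame({
        "year": ts.dt.year,
        "month": ts.dt.month,
        "day": ts.dt.day,
        "day_of_week": ts.dt.dayofweek,
        "is_holiday": normalized.isin(holiday_set).astype(float).where(ts.notna()),
    })


def window_aggregate(series: Sequence[float], window: int,
                     stats: Sequence[str] = ("mean",)) -> pd.DataFrame:
    """Trailing sliding-window aggregates over a time-ordered series.

    The window includes the current point and shrinks at the start of the
    series, so every output row is defined.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    allowed = {"mean", "min", "max", "count"}
    bad = set(stats) - allowed
    if bad:
        raise ValueError(f"unsupported statistics: {sorted(bad)}")
    s = pd.Series(np.asarray(series, dtype=np.float64))
    roll = s.rolling(window, min_periods=1)
    return pd.DataFrame({stat: getattr(roll, stat)() for stat in stats})


def impute_missing(col: Sequence, strategy: str, *,
                   vocab: Sequence[str] | None = None,
                   value=None, drop_threshold: float = 0.05):
    """Fill (or drop) missing values in one column.

    ``mean`` / ``median`` apply to continuous columns only; ``mode`` works
    for any role, breaking ties by vocabulary order when a vocabulary is
    given.  ``drop_rows`` / ``drop_column`` are only permitted while the
    missing fraction is below ``drop_threshold``.  When ``value`` is
    supplied it is used verbatim (the frozen training-split statistic).
    """
    s = pd.Series(col)
    missing = s.isna()
    if strategy in ("mean", "median"):
        numeric = pd.to_numeric(s, errors="coerce")
        if numeric.isna().all() and not s.isna().all():
            raise ValueError(f"{strategy} imputation requires a continuous column")
        if value is None:
            value = getattr(numeric, strategy)()
        return numeric.fillna(value).to_numpy(), value
    if strategy == "mode":
        if value is None:
            counts = s.dropna().value_counts()
            if counts.empty:
                raise ValueError("cannot take the mode of an all-missing column")
            top = counts.max()
            candidates = set(counts[counts == top].index)
            order = list(vocab) if vocab else sorted(candidates, key=str)
            value = next(v for v in order if v in candidates)
        return s.fillna(value).to_numpy(), value
    if strategy in ("drop_rows", "drop_column"):
        frac = float(missing.mean())
        if frac >= drop_threshold:
            raise ValueError(
                f"{strategy} refused: missing fraction {frac:.3f} "
                f">= threshold {drop_threshold}")
        if strategy == "drop_rows":
            return s[~missing].to_numpy(), None
        return np.array([]), None
    raise ValueError(f"unknown imputation strategy {strategy!r}")


def flag_outliers(col: Sequence[float], rule: str = "zscore", *,
                  k: float = 3.0, m: float = 1.5,
                  state: NumericState | None = None) -> np.ndarray:
    """Boolean mask of extreme values in a continuous column.

    ``zscore`` flags ``|x - mean| > k * sd`` (population sd); ``iqr``
    flags values beyond ``m`` interquartile ranges outside the quartiles.
    Statistics come from ``state`` when given (transform of a non-fit
    split), else from the observed values.  Missing values are never
    flagged; a constant column flags nothing.
    """
    x = _as_float(col)
    obs = x[~np.isnan(x)]
    mask = np.zeros(x.shape, dtype=bool)
    if obs.size == 0:
        return mask
    if rule == "none":
        return mask
    if rule == "zscore":
        mean = state.raw_mean if state is not None else float(obs.mean())
        sd = state.raw_sd if state is not None else float(obs.std(ddof=0))
        if sd == 0.0:
            return mask
        with np.errstate(invalid="ignore"):
            mask = np.abs(x - mean) > k * sd
    elif rule == "iqr":
        q1 = state.q1 if state is not None else float(np.percentile(obs, 25))
        q3 = state.q3 if state is not None else float(np.percentile(obs, 75))
        iqr = q3 - q1
        with np.errstate(invalid="ignore"):
            mask = (x < q1 - m * iqr) | (x > q3 + m * iqr)
    else:
        raise ValueError(f"unknown outlier rule {rule!r}")
    mask &= ~np.isnan(x)
    return mask


# ---------------------------------------------------------------------------
# dataset container
# ---------------------------------------------------------------------------

@dataclass
class EncodedDataset:
    """Row-aligned encoded feature matrices plus outcome labels."""

    cat_codes: np.ndarray        # (n, n_categorical) int64
    cont_values: np.ndarray      # (n, n_continuous) float64
    outcomes: np.ndarray         # (n, n_events) int64
    row_ids: list[str]
    cat_names: list[str]
    cont_names: list[str]
    event_names: list[str]
    cat_cardinalities: list[int]  # vocabulary size incl. unknown slot

    @property
    def n_rows(self) -> int:
        return self.cat_codes.shape[0]

    def subset(self, idx: np.ndarray) -> "EncodedDataset":
        return EncodedDataset(
            cat_codes=self.cat_codes[idx],
            cont_values=self.cont_values[idx],
            outcomes=self.outcomes[idx],
            row_ids=[self.row_ids[i] for i in np.atleast_1d(idx)],
            cat_names=self.cat_names,
            cont_names=self.cont_names,
            event_names=self.event_names,
            cat_cardinalities=self.cat_cardinalities,
        )

    def event_labels(self, event: str) -> np.ndarray:
        return self.outcomes[:, self.event_names.index(event)]

    # -- persistence (CSV pair + outcomes) -----------------------------
    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.cat_codes, columns=self.cat_names,
                     index=pd.Index(self.row_ids, name="row_id")).to_csv(
            d / "cat_codes.csv")
        pd.DataFrame(self.cont_values, columns=self.cont_names,
                     index=pd.Index(self.row_ids, name="row_id")).to_csv(
            d / "cont_values.csv")
        pd.DataFrame(self.outcomes, columns=self.event_names,
                     index=pd.Index(self.row_ids, name="row_id")).to_csv(
            d / "outcomes.csv")
        meta = {"cat_cardinalities": self.cat_cardinalities}
        (d / "dataset.json").write_text(json.dumps(meta, indent=2) + "\n",
                                        encoding="utf-8")

    @classmethod
    def load(cls, directory: str | Path) -> "EncodedDataset":
        d = Path(directory)
        cat = pd.read_csv(d / "cat_codes.csv", index_col="row_id")
        cont = pd.read_csv(d / "cont_values.csv", index_col="row_id")
        out = pd.read_csv(d / "outcomes.csv", index_col="row_id")
        meta = json.loads((d / "dataset.json").read_text(encoding="utf-8"))
        return cls(
            cat_codes=cat.to_numpy(dtype=np.int64),
            cont_values=cont.to_numpy(dtype=np.float64),
            outcomes=out.to_numpy(dtype=np.int64),
            row_ids=[str(i) for i in cat.index],
            cat_names=list(cat.columns),
            cont_names=list(cont.columns),
            event_names=list(out.columns),
            cat_cardinalities=list(meta["cat_cardinalities"]),
        )


# ---------------------------------------------------------------------------
# fitted pipeline
# ---------------------------------------------------------------------------

@dataclass
class PreprocessState:
    """Everything fitted on the training split, serialisable to JSON."""

    numeric: dict[str, NumericState] = field(default_factory=dict)
    categorical_impute: dict[str, str] = field(default_factory=dict)
    cat_names: list[str] = field(default_factory=list)
    cont_names: list[str] = field(default_factory=list)
    event_names: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "numeric": {k: vars(v) for k, v in self.numeric.items()},
            "categorical_impute": self.categorical_impute,
            "cat_names": self.cat_names,
            "cont_names": self.cont_names,
            "event_names": self.event_names,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessState":
        return cls(
            numeric={k: NumericState(**v) for k, v in d["numeric"].items()},
            categorical_impute=dict(d["categorical_impute"]),
            cat_names=list(d["cat_names"]),
            cont_names=list(d["cont_names"]),
            event_names=list(d["event_names"]),
        )

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


class Preprocessor:
    """Fit-on-train / transform-anywhere encoder for a schema'd table."""

    def __init__(self, schema: FeatureSchema,
                 config: PreprocessConfig | None = None):
        self.schema = schema
        self.config = config or PreprocessConfig()
        self.state: PreprocessState | None = None
        self.log: list[str] = []

    # -- helpers -------------------------------------------------------
    def _expand(self, df: pd.DataFrame) -> pd.DataFrame:
        """Replace datetime columns by their derived calendar features."""
        df = df.copy()
        for col in self.schema.datetime_cols:
            feats = extract_time_features(df[col.name], self.config.holidays)
            for feat_name in TIME_FEATURES:
                df[f"{col.name}_{feat_name}"] = feats[feat_name].to_numpy()
            df = df.drop(columns=[col.name])
        return df

    def _cont_names(self) -> list[str]:
        names = [c.name for c in self.schema.continuous]
        for c in self.schema.datetime_cols:
            names.extend(f"{c.name}_{f}" for f in TIME_FEATURES)
        return names

    # -- fit / transform ----------------------------------------------
    def fit(self, df: pd.DataFrame) -> "Preprocessor":
        cfg = self.config
        table = self._expand(df)
        state = PreprocessState(
            cat_names=[c.name for c in self.schema.categorical],
            cont_names=self._cont_names(),
            event_names=[c.name for c in self.schema.outcomes],
        )
        n_imputed = n_flagged = 0
        for name in state.cont_names:
            x = _as_float(table[name])
            obs = x[~np.isnan(x)]
            if obs.size == 0:
                raise ValueError(f"column {name!r} is entirely missing")
            raw_mean = float(obs.mean())
            raw_sd = float(obs.std(ddof=0))
            q1 = float(np.percentile(obs, 25))
            q3 = float(np.percentile(obs, 75))
            probe = NumericState(0, 0, 0, 0, 0, raw_mean=raw_mean,
                                 raw_sd=raw_sd, q1=q1, q3=q3)
            mask = flag_outliers(x, cfg.outlier_rule, k=cfg.outlier_k,
                                 m=cfg.iqr_m, state=probe)
            n_flagged += int(mask.sum())
            x = x.copy()
            x[mask] = np.nan
            n_imputed += int(np.isnan(x).sum())
            filled, impute_value = impute_missing(
                x, cfg.numeric_impute, drop_threshold=cfg.drop_threshold)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", DegenerateColumnWarning)
                _, num_state = fit_transform_numeric(filled)
            if num_state.degenerate:
                self.log.append(f"degenerate continuous column: {name}")
            num_state.impute_value = float(impute_value)
            num_state.raw_mean, num_state.raw_sd = raw_mean, raw_sd
            num_state.q1, num_state.q3 = q1, q3
            state.numeric[name] = num_state
        for col in self.schema.categorical:
            _, mode_value = impute_missing(table[col.name], "mode",
                                           vocab=col.vocabulary)
            state.categorical_impute[col.name] = str(mode_value)
        self.state = state
        self.log.append(f"fit: {len(table)} rows, {n_flagged} outlier cells "
                        f"masked, {n_imputed} cells imputed")
        return self

    def transform(self, df: pd.DataFrame) -> EncodedDataset:
        if self.state is None:
            raise RuntimeError("Preprocessor.transform called before fit")
        cfg = self.config
        state = self.state
        table = self._expand(df)
        n = len(table)

        cont = np.empty((n, len(state.cont_names)), dtype=np.float64)
        n_flagged = n_imputed = 0
        for j, name in enumerate(state.cont_names):
            ns = state.numeric[name]
            x = _as_float(table[name])
            mask = flag_outliers(x, cfg.outlier_rule, k=cfg.outlier_k,
                                 m=cfg.iqr_m, state=ns)
            n_flagged += int(mask.sum())
            x = x.copy()
            x[mask] = np.nan
            n_imputed += int(np.isnan(x).sum())
            x[np.isnan(x)] = ns.impute_value
            cont[:, j] = transform_numeric(x, ns)

        cards: list[int] = []
        codes = np.empty((n, len(state.cat_names)), dtype=np.int64)
        n_unknown_total = 0
        for j, name in enumerate(state.cat_names):
            col_spec = self.schema[name]
            filled, _ = impute_missing(table[name], "mode",
                                       value=state.categorical_impute[name])
            col_codes, _, n_unknown = encode_categorical(filled, col_spec.vocabulary)
            n_unknown_total += n_unknown
            codes[:, j] = col_codes
            cards.append(col_spec.cardinality)

        outcomes = np.empty((n, len(state.event_names)), dtype=np.int64)
        for j, name in enumerate(state.event_names):
            outcomes[:, j] = pd.to_numeric(table[name]).to_numpy(dtype=np.int64)

        if "row_id" in table.columns:
            row_ids = [str(r) for r in table["row_id"]]
        else:
            row_ids = [str(i) for i in table.index]
        self.log.append(f"transform: {n} rows, {n_flagged} outlier cells, "
                        f"{n_imputed} imputed, {n_unknown_total} unknown categories")
        return EncodedDataset(
            cat_codes=codes, cont_values=cont, outcomes=outcomes,
            row_ids=row_ids, cat_names=list(state.cat_names),
            cont_names=list(state.cont_names),
            event_names=list(state.event_names), cat_cardinalities=cards)

    def fit_transform(self, df: pd.DataFrame) -> EncodedDataset:
        return self.fit(df).transform(df)

    # -- persistence ---------------------------------------------------
    def save_state(self, path: str | Path) -> None:
        if self.state is None:
            raise RuntimeError("nothing fitted yet")
        Path(path).write_text(
            json.dumps(self.state.to_dict(), indent=2) + "\n", encoding="utf-8")

    def load_state(self, path: str | Path) -> "Preprocessor":
        self.state = PreprocessState.from_dict(
            json.loads(Path(path).read_text(encoding="utf-8")))
        return self

    def write_log(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.log) + "\n", encoding="utf-8")
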