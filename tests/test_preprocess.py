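"""Unit and property tests for the preprocessing pipeline."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gatedtab.preprocess import (DegenerateColumnWarning, PreprocessConfig,
                                 Preprocessor, decode_categorical,
                                 encode_categorical, extract_time_features,
                                 fit_transform_numeric, flag_outliers,
                                 impute_missing, transform_numeric,
                                 window_aggregate)


# -- numeric scaling ----------------------------------------------------

def test_numeric_scaling_is_zscore_then_minmax():
    scaled, state = fit_transform_numeric([1.0, 2.0, 3.0])
    # z-scoring is a monotone affine map, so min-max lands on 0 / 0.5 / 1
    assert np.allclose(scaled, [0.0, 0.5, 1.0])
    assert state.mean == 2.0 and np.isclose(state.sd, np.sqrt(2 / 3))


def test_constant_column_maps_to_half_with_warning():
    with pytest.warns(DegenerateColumnWarning):
        scaled, state = fit_transform_numeric([5.0, 5.0, 5.0])
    assert np.all(scaled == 0.5) and state.degenerate


def test_value_at_mean_lands_inside_unit_interval():
    scaled, state = fit_transform_numeric([10.0, 20.0, 30.0, 40.0])
    at_mean = transform_numeric([25.0], state)[0]
    expected = (0.0 - state.post_z_min) / (state.post_z_max - state.post_z_min)
    assert np.isclose(at_mean, expected) and 0.0 < at_mean < 1.0


@pytest.mark.parametrize("bad", [[], [np.nan, np.nan]])
def test_empty_or_all_missing_column_is_an_error(bad):
    with pytest.raises(ValueError):
        fit_transform_numeric(bad)


@given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=50))
@settings(max_examples=50, deadline=None)
def test_fit_split_always_lands_in_unit_interval(values):
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateColumnWarning)
        scaled, _ = fit_transform_numeric(values)
    assert scaled.min() >= -1e-12 and scaled.max() <= 1 + 1e-12


# -- categorical encoding ----------------------------------------------

def test_in_vocabulary_value_gets_position_and_onehot():
    codes, ind, n_unknown = encode_categorical(["A"], ["A", "B"])
    assert codes[0] == 0 and ind.tolist() == [[1, 0]] and n_unknown == 0


def test_unseen_category_gets_reserved_code_and_zero_row():
    codes, ind, n_unknown = encode_categorical(["C"], ["A", "B"])
    assert codes[0] == 2 and ind.tolist() == [[0, 0]] and n_unknown == 1


def test_indicator_rows_sum_to_one_for_known_values():
    codes, ind, _ = encode_categorical(["B", "A", "B"], ["A", "B"])
    assert (ind.sum(axis=1) == 1).all()


@given(st.lists(st.sampled_from(["A", "B", "C", "D"]), min_size=1, max_size=30))
@settings(max_examples=50, deadline=None)
def test_decode_round_trips_known_categories(values):
    vocab = ["A", "B", "C", "D"]
    codes, _, _ = encode_categorical(values, vocab)
    assert decode_categorical(codes, vocab) == values


# -- time features ------------------------------------------------------

def test_calendar_features_match_known_dates():
    feats = extract_time_features(["2019-12-31", "2016-02-29"])
    assert feats.loc[0, ["year", "month", "day"]].tolist() == [2019, 12, 31]
    assert feats.loc[0, "day_of_week"] == 1       # a Tuesday
    assert feats.loc[1, "day"] == 29              # leap year parses


def test_holiday_flag_is_membership():
    feats = extract_time_features(["2019-01-01", "2019-01-02"],
                                  holidays=["2019-01-01"])
    assert feats["is_holiday"].tolist() == [1.0, 0.0]


def test_unparseable_date_becomes_missing():
    feats = extract_time_features(["not-a-date"])
    assert feats.isna().all(axis=None)


# -- sliding windows ----------------------------------------------------

def test_window_one_mean_is_identity():
    out = window_aggregate([3.0, 1.0, 4.0], 1, ["mean"])
    assert out["mean"].tolist() == [3.0, 1.0, 4.0]


def test_trailing_window_shrinks_at_series_start():
    out = window_aggregate([1, 2, 3, 4], 2, ["mean", "count"])
    assert out["mean"].tolist() == [1.0, 1.5, 2.5, 3.5]
    assert out["count"].tolist() == [1.0, 2.0, 2.0, 2.0]


def test_constant_series_gives_constant_aggregates():
    out = window_aggregate([7.0] * 5, 3, ["mean", "min", "max"])
    for stat in ("mean", "min", "max"):
        assert (out[stat] == 7.0).all()


def test_nonpositive_window_is_an_error():
    with pytest.raises(ValueError):
        window_aggregate([1.0], 0)


# -- imputation ---------------------------------------------------------

def test_mean_imputation_uses_observed_mean():
    filled, value = impute_missing([1.0, np.nan, 3.0], "mean")
    assert filled.tolist() == [1.0, 2.0, 3.0] and value == 2.0


def test_mode_imputation_breaks_ties_by_vocabulary_order():
    filled, value = impute_missing(["A", "A", "B", None], "mode",
                                   vocab=["A", "B"])
    assert value == "A" and list(filled) == ["A", "A", "B", "A"]
    # exact tie: vocabulary order decides
    _, tied = impute_missing(["B", "A", None], "mode", vocab=["A", "B"])
    assert tied == "A"


def test_no_missing_values_is_a_noop():
    filled, _ = impute_missing([1.0, 2.0], "mean")
    assert filled.tolist() == [1.0, 2.0]


def test_mean_on_categorical_column_is_an_error():
    with pytest.raises(ValueError):
        impute_missing(["A", "B", None], "mean")


def test_drop_strategies_respect_missing_threshold():
    filled, _ = impute_missing([1.0, np.nan, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0,
                                9.0, 10.0, 11.0, 12.0, 13.0, 14.0, 15.0,
                                16.0, 17.0, 18.0, 19.0, 20.0, 21.0],
                               "drop_rows", drop_threshold=0.10)
    assert len(filled) == 20
    with pytest.raises(ValueError):
        impute_missing([1.0, np.nan], "drop_rows", drop_threshold=0.10)


# -- outliers -----------------------------------------------------------

def test_zscore_rule_flags_only_the_extreme_point():
    mask = flag_outliers([0, 0, 0, 0, 100], "zscore", k=1.5)
    assert mask.tolist() == [False, False, False, False, True]


def test_constant_column_flags_nothing():
    assert not flag_outliers([5, 5, 5], "zscore", k=3).any()


def test_iqr_rule_flags_the_extreme_point():
    mask = flag_outliers([1, 2, 3, 4, 100], "iqr", m=1.5)
    assert mask.tolist() == [False, False, False, False, True]


# -- fitted pipeline properties -----------------------------------------

def test_fitting_state_is_frozen_when_transforming_other_splits(tiny_cohort):
    df = tiny_cohort.frame
    pre = Preprocessor(tiny_cohort.schema, PreprocessConfig())
    pre.fit(df.iloc[:400])
    before = pre.state.content_hash()
    pre.transform(df.iloc[400:])
    assert pre.state.content_hash() == before


def test_transform_of_fit_split_lands_in_unit_interval(tiny_cohort):
    pre = Preprocessor(tiny_cohort.schema, PreprocessConfig())
    ds = pre.fit_transform(tiny_cohort.frame)
    assert ds.cont_values.min() >= -1e-12
    assert ds.cont_values.max() <= 1 + 1e-12


def test_encoded_dataset_has_no_missing_and_codes_in_range(tiny_dataset):
    assert np.isfinite(tiny_dataset.cont_values).all()
    for j, card in enumerate(tiny_dataset.cat_cardinalities):
        col = tiny_dataset.cat_codes[:, j]
        assert col.min() >= 0 and col.max() < card


def test_pipeline_is_byte_deterministic(tiny_cohort, tmp_path):
    outputs = []
    for run in ("a", "b"):
        pre = Preprocessor(tiny_cohort.schema, PreprocessConfig())
        ds = pre.fit_transform(tiny_cohort.frame)
        d = tmp_path / run
        ds.save(d)
        outputs.append(b"".join(
            (d / f).read_bytes()
            for f in ("cat_codes.csv", "cont_values.csv", "outcomes.csv")))
    assert outputs[0] == outputs[1]


def test_state_json_round_trip(tiny_cohort, tmp_path):
    pre = Preprocessor(tiny_cohort.schema, PreprocessConfig())
    ds1 = pre.fit_transform(tiny_cohort.frame)
    pre.save_state(tmp_path / "state.json")
    pre2 = Preprocessor(tiny_cohort.schema, PreprocessConfig())
    pre2.load_state(tmp_path / "state.json")
    ds2 = pre2.transform(tiny_cohort.frame)
    assert np.array_equal(ds1.cat_codes, ds2.cat_codes)
    assert np.allclose(ds1.cont_values, ds2.cont_values)
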