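import numpy as np
import pandas as pd
import pytest

from neurofuse import EHRTransformer, apply_ehr_transform, fit_ehr_transform
from neurofuse.ehr import to_unit_interval
from neurofuse.io import RawEHRTable


def make_table(columns, schema, index=None):
    df = pd.DataFrame(columns, index=index)
    missing = df.isna()
    return RawEHRTable(values=df, schema=schema, missing=missing)


def test_missing_fraction_boundary_is_strict():
    """A feature missing in 8/10 training rows (80%) is dropped; one missing
    in exactly 7/10 (70%) survives — the rule is a strict inequality."""
    idx = [f"P{i}" for i in range(10)]
    vals80 = [np.nan] * 8 + [1.0, 2.0]
    vals70 = [np.nan] * 7 + [1.0, 2.0, 3.0]
    table = make_table(
        {"mostly_gone": vals80, "borderline": vals70},
        {"mostly_gone": "quantitative", "borderline": "quantitative"},
        index=idx,
    )
    state = fit_ehr_transform(table, idx)
    assert "mostly_gone" not in state.kept
    assert "borderline" in state.kept


def test_quantitative_affine_map_and_clipping():
    idx = ["P0", "P1", "P2", "P3"]
    table = make_table(
        {"score": [0.0, 5.0, 10.0, 50.0]}, {"score": "quantitative"}, index=idx
    )
    state = fit_ehr_transform(table, ["P0", "P1", "P2"])  # train range [0, 10]
    out = apply_ehr_transform(table, state)
    assert out.values["score"].loc[["P0", "P1", "P2"]].tolist() == [1.0, 1.5, 2.0]
    assert out.values["score"].loc["P3"] == 2.0  # out-of-range test value clipped


def test_binary_maps_to_one_two():
    idx = ["P0", "P1", "P2"]
    table = make_table({"flag": [0.0, 1.0, 0.0]}, {"flag": "binary"}, index=idx)
    out = apply_ehr_transform(table, fit_ehr_transform(table, idx))
    assert out.values["flag"].tolist() == [1.0, 2.0, 1.0]


def test_categorical_one_hot_levels():
    """A 3-level categorical expands to 3 columns in {1,2} with exactly one
    2 per row (verified against a literal one-hot construction)."""
    idx = ["P0", "P1", "P2", "P3"]
    raw = ["a", "b", "c", "a"]
    table = make_table({"diet": raw}, {"diet": "categorical"}, index=idx)
    out = apply_ehr_transform(table, fit_ehr_transform(table, idx))
    cols = [c for c in out.feature_names if c.startswith("diet=")]
    assert cols == ["diet=a", "diet=b", "diet=c"]
    block = out.values[cols].to_numpy()
    expected = np.ones((4, 3))
    for i, lv in enumerate(raw):  # independent one-hot oracle
        expected[i, ["a", "b", "c"].index(lv)] = 2.0
    assert np.array_equal(block, expected)
    assert (block == 2).sum(axis=1).tolist() == [1, 1, 1, 1]


def test_unseen_categorical_level_warns_not_errors():
    table = make_table(
        {"diet": ["a", "b", "a", "z"]}, {"diet": "categorical"},
        index=["P0", "P1", "P2", "P3"],
    )
    state = fit_ehr_transform(table, ["P0", "P1", "P2"])
    with pytest.warns(UserWarning, match="unseen"):
        out = apply_ehr_transform(table, state)
    assert out.values.loc["P3"].tolist() == [1.0, 1.0]  # all-reference row


def test_constant_feature_degenerate_but_retained():
    idx = ["P0", "P1", "P2"]
    table = make_table({"c": [4.0, 4.0, 4.0]}, {"c": "quantitative"}, index=idx)
    state = fit_ehr_transform(table, idx)
    assert "c" in state.kept and "c" in state.degenerate
    out = apply_ehr_transform(table, state)
    assert out.values["c"].tolist() == [1.5, 1.5, 1.5]


def test_missing_imputed_with_train_median():
    idx = ["P0", "P1", "P2", "P3"]
    table = make_table(
        {"x": [0.0, 10.0, 20.0, np.nan]}, {"x": "quantitative"}, index=idx
    )
    state = fit_ehr_transform(table, ["P0", "P1", "P2"])  # median 10
    out = apply_ehr_transform(table, state)
    assert out.values["x"].loc["P3"] == 1.5


def test_no_leakage_from_non_training_rows():
    idx = [f"P{i}" for i in range(6)]
    train = idx[:4]
    base = {"x": [1.0, 2.0, 3.0, 4.0, 100.0, np.nan]}
    altered = {"x": [1.0, 2.0, 3.0, 4.0, -999.0, 55.0]}
    s1 = fit_ehr_transform(make_table(base, {"x": "quantitative"}, idx), train)
    s2 = fit_ehr_transform(make_table(altered, {"x": "quantitative"}, idx), train)
    assert s1.minmax == s2.minmax and s1.medians == s2.medians


def test_transform_is_deterministic(small_cohort):
    t = EHRTransformer().fit(small_cohort.ehr, train_rows=small_cohort.patient_ids[:50])
    a = t.transform(small_cohort.ehr).values
    b = t.transform(small_cohort.ehr).values
    assert a.equals(b)
    arr = a.to_numpy()
    assert arr.min() >= 1.0 and arr.max() <= 2.0
    assert not np.isnan(arr).any()


def test_all_features_dropped_errors():
    idx = [f"P{i}" for i in range(10)]
    table = make_table({"x": [np.nan] * 9 + [1.0]}, {"x": "quantitative"}, idx)
    with pytest.raises(ValueError, match="threshold"):
        fit_ehr_transform(table, idx)


def test_unit_interval_rescale_roundtrip():
    x = np.array([[1.0, 1.5, 2.0]])
    u = to_unit_interval(x)
    assert u.tolist() == [[0.0, 0.5, 1.0]]


def test_state_json_roundtrip(small_cohort):
    from neurofuse.ehr import EHRTransformState

    state = fit_ehr_transform(small_cohort.ehr, small_cohort.patient_ids[:40])
    back = EHRTransformState.from_json(state.to_json())
    assert back.kept == state.kept
    assert back.minmax == state.minmax
    out1 = apply_ehr_transform(small_cohort.ehr, state).values
    out2 = apply_ehr_transform(small_cohort.ehr, back).values
    assert out1.equals(out2)
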