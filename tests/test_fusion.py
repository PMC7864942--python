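import numpy as np
import pandas as pd
import pytest

from neurofuse import (
    ClassifierSpec,
    concat_intermediate,
    decision_level_vote,
    feature_level_fuse,
    fit_decision_layer,
)
from neurofuse.fusion import (
    DEEP_FUSION_TREES,
    SNP_IMAGING_TREES,
    collapse_labels,
    make_decision_layer,
    task_for,
)


def codes_and_mask(n=6, seed=0):
    rng = np.random.default_rng(seed)
    codes = {
        "ehr": rng.random((n, 50)),
        "snp": rng.random((n, 50)),
        "imaging": rng.random((n, 100)),
    }
    mask = pd.DataFrame(
        {"ehr": [True] * n, "snp": [True] * n, "imaging": [True] * n},
        index=[f"P{i}" for i in range(n)],
    )
    return codes, mask


def test_concat_widths_and_block_order():
    codes, mask = codes_and_mask()
    fused, prov = concat_intermediate(codes, mask)
    assert fused.shape == (6, 200)
    assert prov[0].startswith("ehr:") and prov[50].startswith("snp:")
    assert prov[100].startswith("imaging:") and len(prov) == 200


def test_missing_imaging_block_is_zero():
    codes, mask = codes_and_mask()
    mask.loc["P2", "imaging"] = False
    fused, _ = concat_intermediate(codes, mask)
    assert np.all(fused[2, 100:200] == 0.0)
    assert np.any(fused[2, :100] != 0.0)


def test_single_modality_degenerate_concat():
    codes, mask = codes_and_mask()
    fused, _ = concat_intermediate({"ehr": codes["ehr"]}, mask[["ehr"]])
    assert np.array_equal(fused, codes["ehr"])


def test_all_modalities_missing_errors():
    codes, mask = codes_and_mask()
    mask.loc["P0", :] = False
    with pytest.raises(ValueError, match="no available modality"):
        concat_intermediate(codes, mask)


def test_rezeroing_masked_block_is_idempotent():
    """Predictions are unchanged when a missing modality's block is zeroed
    again: the zero-mask is the canonical representation."""
    codes, mask = codes_and_mask(n=30, seed=1)
    mask.loc[mask.index[:10], "snp"] = False
    fused, _ = concat_intermediate(codes, mask)
    y = np.random.default_rng(2).integers(0, 2, 30)
    clf = fit_decision_layer(fused, y, ClassifierSpec("random_forest"), seed=0)
    refused, _ = concat_intermediate(
        {"ehr": fused[:, :50], "snp": fused[:, 50:100], "imaging": fused[:, 100:]},
        mask,
    )
    assert np.array_equal(clf.predict(fused), clf.predict(refused))


def test_decision_layer_kinds_fit_separable_points():
    X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
    y = np.array([0, 0, 1, 1])
    for kind in ("knn", "svm_ovo", "random_forest", "decision_tree"):
        params = {"k": 1} if kind == "knn" else {}
        clf = fit_decision_layer(X, y, ClassifierSpec(kind, params), seed=0)
        assert (clf.predict(X) == y).all(), kind
        assert clf.predict_proba(X).shape == (4, 2)


def test_decision_layer_defaults_and_validation():
    assert DEEP_FUSION_TREES == 31
    assert SNP_IMAGING_TREES == 20
    rf = make_decision_layer(ClassifierSpec("random_forest"))
    assert rf.n_estimators == 31
    svm = make_decision_layer(ClassifierSpec("svm_ovo"))
    assert svm.decision_function_shape == "ovo"
    with pytest.raises(ValueError, match="unknown classifier"):
        ClassifierSpec("boosting")
    with pytest.raises(ValueError, match="not valid"):
        ClassifierSpec("knn", {"n_trees": 5})
    with pytest.raises(ValueError, match="two classes"):
        fit_decision_layer(np.ones((3, 2)), np.zeros(3), ClassifierSpec("knn", {"k": 1}))


def test_feature_level_fuse_provenance_roundtrip():
    ehr = pd.DataFrame({"mmse": [1.0, 2.0], "age": [1.5, 1.2]}, index=["P0", "P1"])
    snp = pd.DataFrame({"10:108777098": [1, 3]}, index=["P0", "P1"])
    mask = pd.DataFrame({"ehr": [True, True], "snp": [True, False]},
                        index=["P0", "P1"])
    fused, prov = feature_level_fuse({"ehr": ehr, "snp": snp}, mask)
    assert fused.shape == (2, 3)
    assert prov == ["ehr:mmse", "ehr:age", "snp:10:108777098"]
    assert fused[1, 2] == 0.0  # masked SNP block


def test_majority_vote_and_tie_rules():
    preds = {
        "ehr": ["AD", "CN", "MCI"],
        "snp": ["AD", "MCI", "AD"],
        "imaging": ["CN", "MCI", "CN"],
    }
    out = decision_level_vote(preds)
    assert out[0] == "AD"   # 2-1 majority
    assert out[1] == "MCI"  # 2-1 majority
    # row 2 is a 3-way tie -> fixed class order CN < MCI < AD
    assert out[2] == "CN"

    probs = {
        "ehr": {"AD": np.array([0.0, 0.0, 0.9]), "CN": np.array([0.0, 0.0, 0.05])},
        "snp": {"AD": np.array([0.0, 0.0, 0.8]), "CN": np.array([0.0, 0.0, 0.1])},
        "imaging": {"AD": np.array([0.0, 0.0, 0.1]), "CN": np.array([0.0, 0.0, 0.6])},
    }
    out2 = decision_level_vote(preds, probabilities=probs)
    assert out2[2] == "AD"  # tie broken by highest mean class-probability

    with pytest.raises(ValueError, match=">= 2"):
        decision_level_vote({"ehr": ["AD"]})


def test_task_table_and_label_collapse():
    assert task_for(["ehr", "snp", "imaging"]) == "three_class"
    assert task_for(["snp"]) == "cn_vs_mciad"
    assert task_for(["imaging"]) == "cn_vs_ad"
    with pytest.raises(ValueError, match="no task"):
        task_for([])

    labels = np.array(["CN", "MCI", "AD"], dtype=object)
    collapsed, keep = collapse_labels(labels, "cn_vs_mciad")
    assert collapsed.tolist() == ["CN", "MCI/AD", "MCI/AD"] and keep.all()
    collapsed, keep = collapse_labels(labels, "cn_vs_ad")
    assert keep.tolist() == [True, False, True]
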