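import json

import numpy as np
import pandas as pd
import pytest

from tmsdkit.features import FEATURE_NAMES
from tmsdkit.mleval import (
    MODEL_SPECS,
    ImportanceRanking,
    LabeledDataset,
    assemble_dataset,
    cross_validated_metrics,
    external_test,
    feature_importance,
    make_classifier,
    pearson_correlations,
    train_and_evaluate,
)


def make_frames(n=6):
    rng = np.random.default_rng(0)
    feats = pd.DataFrame(rng.normal(size=(n, 16)), columns=list(FEATURE_NAMES))
    feats.insert(0, "sample_id", [f"s{i}" for i in range(n)])
    rates = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "k": 10 ** rng.uniform(4, 6, n),
            "rate_class": (np.arange(n) % 3),
        }
    )
    return feats, rates


def separable_dataset(n_per_class=30, spread=0.05, seed=0):
    """Three well-separated Gaussian blobs along X2/X5/X11."""
    rng = np.random.default_rng(seed)
    rows = []
    centers = {0: (16, 55, 1), 1: (10, 40, 6), 2: (4, 25, 12)}
    for cls, (c2, c5, c11) in centers.items():
        for i in range(n_per_class):
            vals = dict.fromkeys(FEATURE_NAMES, 0.0)
            vals["X2"] = c2 + rng.normal(0, spread)
            vals["X5"] = c5 + rng.normal(0, spread)
            vals["X11"] = c11 + rng.normal(0, spread)
            rows.append({"sample_id": f"c{cls}_{i}", **vals,
                         "rate_class": cls, "k": 10 ** (6 - cls)})
    return LabeledDataset(frame=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# dataset assembly


def test_disjoint_ids_rejected():
    feats, rates = make_frames(4)
    rates["sample_id"] = ["x0", "x1", "x2", "x3"]
    with pytest.raises(ValueError, match="unmatched"):
        assemble_dataset(feats, rates)


def test_duplicate_ids_rejected():
    feats, rates = make_frames(4)
    feats.loc[1, "sample_id"] = "s0"
    with pytest.raises(ValueError, match="duplicate"):
        assemble_dataset(feats, rates)


def test_join_matches_and_is_order_invariant():
    feats, rates = make_frames(5)
    ds = assemble_dataset(feats, rates)
    assert len(ds) == 5
    shuffled = assemble_dataset(
        feats.sample(frac=1, random_state=3), rates.sample(frac=1, random_state=4)
    )
    pd.testing.assert_frame_equal(ds.frame, shuffled.frame)


def test_missing_feature_column_rejected():
    feats, rates = make_frames(4)
    with pytest.raises(ValueError, match="missing columns"):
        LabeledDataset(frame=feats.drop(columns=["X7"]).assign(rate_class=0, k=1e5))


# ---------------------------------------------------------------------------
# importance


def test_planted_x5_signal_is_top_ranked(small_dataset):
    frame = small_dataset.frame.copy()
    x5 = frame["X5"].to_numpy()
    frame["rate_class"] = 2 - np.digitize(x5, np.quantile(x5, [1 / 3, 2 / 3]))
    ds = LabeledDataset(frame=frame)
    tops = [feature_importance(ds, n_trees=300, seed=s).top_feature for s in range(5)]
    assert tops.count("X5") >= 4


def test_constant_feature_has_negligible_importance(small_dataset):
    frame = small_dataset.frame.copy()
    frame["X16"] = 1.0
    ranking = feature_importance(LabeledDataset(frame=frame), n_trees=200, seed=0)
    assert ranking.as_dict()["X16"] < 0.01


def test_single_class_dataset_rejected(small_dataset):
    frame = small_dataset.frame.copy()
    frame["rate_class"] = 1
    with pytest.raises(ValueError, match="2 classes"):
        feature_importance(LabeledDataset(frame=frame))


def test_importance_ranking_invariants(small_dataset):
    ranking = feature_importance(small_dataset, n_trees=200, seed=1)
    weights = np.array([w for _, w in ranking.ranking])
    assert weights.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(np.diff(weights) <= 1e-12)


def test_invalid_importance_weights_rejected():
    with pytest.raises(ValueError):
        ImportanceRanking(ranking=(("X1", 0.7), ("X2", 0.7)))


# ---------------------------------------------------------------------------
# correlations


def test_correlation_diagonal_and_planted_signal(small_dataset):
    corr = pearson_correlations(small_dataset)
    assert np.allclose(np.diag(corr.loc[list(FEATURE_NAMES), list(FEATURE_NAMES)]), 1.0)
    # the planted rate model makes log10 k track X2/X5 up and X11 down
    assert corr.loc["log10_k", "X2"] > 0.3
    assert corr.loc["log10_k", "X5"] > 0.3
    assert corr.loc["log10_k", "X11"] < -0.3


def test_zero_variance_column_reported_missing(small_dataset):
    frame = small_dataset.frame.copy()
    frame["X16"] = 2.5
    corr = pearson_correlations(LabeledDataset(frame=frame))
    assert corr.loc["X16", "X5"] != corr.loc["X16", "X5"]  # NaN


def test_correlations_need_three_rows(small_dataset):
    tiny = LabeledDataset(frame=small_dataset.frame.iloc[:2])
    with pytest.raises(ValueError):
        pearson_correlations(tiny)


# ---------------------------------------------------------------------------
# training and evaluation


@pytest.mark.parametrize("spec", MODEL_SPECS)
def test_separable_classes_are_perfectly_learned(spec):
    ds = separable_dataset()
    rep = train_and_evaluate(ds, spec, seed=0)
    assert rep.validation_accuracy == 1.0
    assert rep.micro_auc == 1.0 and rep.macro_auc == 1.0
    assert all(v == 1.0 for v in rep.per_class_auc.values())
    assert np.array(rep.confusion).sum() == 18  # 20% of 90


def test_unknown_model_spec_rejected():
    with pytest.raises(ValueError, match="unknown model spec"):
        make_classifier("perceptron")


def test_evaluation_is_reproducible(small_dataset):
    a = train_and_evaluate(small_dataset, "svm", seed=5).to_dict()
    b = train_and_evaluate(small_dataset, "svm", seed=5).to_dict()
    assert json.dumps(a, sort_keys=True) == json.dumps(b, sort_keys=True)


def test_report_values_are_probabilities(small_dataset):
    for spec in MODEL_SPECS:
        rep = train_and_evaluate(small_dataset, spec, seed=2)
        vals = [rep.train_accuracy, rep.validation_accuracy, rep.micro_auc,
                rep.macro_auc, *rep.per_class_auc.values()]
        assert all(0.0 <= v <= 1.0 for v in vals)
        assert sum(sum(row) for row in rep.confusion) == len(small_dataset) - round(
            0.8 * len(small_dataset)
        )


def test_constant_feature_does_not_change_tree_accuracy():
    ds = separable_dataset(spread=2.0, seed=3)
    X, y = ds.X, ds.y
    tree_full = make_classifier("decision_tree", 0).fit(X, y)
    kept = [i for i, n in enumerate(FEATURE_NAMES) if n in ("X2", "X5", "X11")]
    tree_small = make_classifier("decision_tree", 0).fit(X[:, kept], y)
    assert np.array_equal(tree_full.predict(X), tree_small.predict(X[:, kept]))


def test_cross_validated_metrics_on_separable_data():
    ds = separable_dataset()
    m = cross_validated_metrics(ds, "logistic_regression", cv_folds=3, seed=0)
    assert m["accuracy"] == 1.0 and m["macro_auc"] == 1.0


# ---------------------------------------------------------------------------
# external test set


def test_external_test_on_training_copy_matches_training_accuracy():
    ds = separable_dataset()
    preds, accs = external_test(ds, ds, seed=0)
    assert all(a == 1.0 for a in accs.values())
    assert len(preds) == len(ds)


def test_external_test_from_training_distribution(study300):
    ds = study300["dataset"]
    train = LabeledDataset(frame=ds.frame.iloc[:-16].reset_index(drop=True))
    test = LabeledDataset(frame=ds.frame.iloc[-16:].reset_index(drop=True))
    _, accs = external_test(train, test, seed=0)
    assert accs["svm"] >= 0.8


def test_length_mismatch_flagged_out_of_domain():
    ds = separable_dataset()
    train_frame = ds.frame.assign(invader_len=22)
    test_frame = ds.frame.iloc[:4].assign(invader_len=[22, 22, 20, 23])
    preds, _ = external_test(
        LabeledDataset(frame=train_frame), LabeledDataset(frame=test_frame)
    )
    assert list(preds["out_of_domain"]) == [False, False, True, True]


def test_schema_mismatch_rejected():
    ds = separable_dataset()
    frame = ds.frame.copy()
    cols = list(frame.columns)
    cols[3], cols[4] = cols[4], cols[3]
    with pytest.raises(ValueError, match="schema"):
        external_test(ds, LabeledDataset(frame=frame[cols]))
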