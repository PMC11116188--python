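"""Fine-tree training, prediction, metric suite, experiment plumbing."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mmcyto import (
    SimulationParams,
    default_classes,
    evaluate,
    generate_run,
    predict,
    run_comparison_experiment,
    train_fine_tree,
)
from mmcyto.classify import (
    model_from_json,
    model_to_json,
    n_internal_splits,
)


def _table(X, y):
    df = pd.DataFrame(X, columns=[f"PI_{i}kHz" for i in range(X.shape[1])])
    df["label"] = y
    df["run_id"] = "r"
    return df


def _clusters(rng, n_per=30, spread=0.05):
    """Four well-separated clusters in two features."""
    centers = np.array([[0, 0], [5, 0], [0, 5], [5, 5]], dtype=float)
    X, y = [], []
    for k, c in enumerate(centers):
        X.append(c + rng.normal(0, spread, size=(n_per, 2)))
        y += [k + 1] * n_per
    return np.vstack(X), np.array(y)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def test_separable_clusters_reach_perfect_cv(rng):
    X, y = _clusters(rng)
    model, cv_acc = train_fine_tree(_table(X, y), seed=0)
    assert cv_acc == 1.0
    assert set(model.classes) == {1, 2, 3, 4}


def test_shuffled_labels_give_chance_cv(rng):
    """Random labels on 4 balanced classes cross-validate near 25 %."""
    accs = []
    for seed in range(10):
        r = np.random.default_rng(seed)
        X = r.normal(size=(400, 2))
        y = np.repeat([1, 2, 3, 4], 100)
        r.shuffle(y)
        _, cv_acc = train_fine_tree(_table(X, y), seed=seed)
        accs.append(cv_acc)
    assert np.mean(accs) == pytest.approx(0.25, abs=0.05)


def test_training_is_deterministic(rng):
    X, y = _clusters(rng, spread=1.5)
    m1, cv1 = train_fine_tree(_table(X, y), seed=7)
    m2, cv2 = train_fine_tree(_table(X, y), seed=7)
    assert cv1 == cv2
    assert m1.training_fingerprint == m2.training_fingerprint
    t = _table(X, y)
    assert np.array_equal(predict(m1, t)[0], predict(m2, t)[0])


def test_training_rejects_small_classes(rng):
    X, y = _clusters(rng, n_per=3)
    with pytest.raises(ValueError):
        train_fine_tree(_table(X, y), cv_folds=5)
    with pytest.raises(ValueError):
        train_fine_tree(_table(X[:30], y[:30]))  # single class


def test_tree_respects_max_splits(rng):
    X = rng.normal(size=(600, 3))
    y = rng.integers(1, 5, size=600)
    model, _ = train_fine_tree(_table(X, y), max_splits=100, min_parent_size=2)
    assert n_internal_splits(model) <= 100


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def test_pure_leaves_reproduce_training_labels(rng):
    X, y = _clusters(rng)
    model, _ = train_fine_tree(_table(X, y), min_parent_size=2)
    t = _table(X, y)
    labels, proba = predict(model, t)
    assert np.array_equal(labels, y)
    assert np.allclose(proba.max(axis=1), 1.0)
    assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-12)


def test_single_split_tree_routes_by_threshold():
    """Two volume clusters either side of 10: the split lands between them."""
    X = np.array([[5.0]] * 20 + [[15.0]] * 20)
    y = np.array([1] * 20 + [2] * 20)
    model, _ = train_fine_tree(_table(X, y), cv_folds=5, seed=0)
    assert n_internal_splits(model) == 1
    test = _table(np.array([[5.0], [15.0]]), np.array([1, 2]))
    labels, _ = predict(model, test)
    assert labels.tolist() == [1, 2]


def test_predict_rejects_mismatched_columns(rng):
    X, y = _clusters(rng)
    model, _ = train_fine_tree(_table(X, y))
    bad = _table(X[:, :1], y)
    with pytest.raises(ValueError):
        predict(model, bad)


# ---------------------------------------------------------------------------
# metric suite
# ---------------------------------------------------------------------------

def test_binary_confusion_hand_values():
    """TP=8, FN=2, TN=9, FP=1 → TPR .8, TNR .9, FPR .1, FNR .2, ACC .85."""
    truth = [1] * 10 + [2] * 10
    pred = [1] * 8 + [2] * 2 + [2] * 9 + [1] * 1
    rep = evaluate(np.array(pred), np.array(truth), (1, 2))
    m = rep.per_class[1]
    assert m["tpr"] == pytest.approx(0.8)
    assert m["tnr"] == pytest.approx(0.9)
    assert m["fpr"] == pytest.approx(0.1)
    assert m["fnr"] == pytest.approx(0.2)
    assert m["acc"] == pytest.approx(0.85)
    assert rep.acc == pytest.approx(0.85)


def test_perfect_predictions():
    y = np.repeat([1, 2, 3, 4], 5)
    rep = evaluate(y, y)
    assert rep.acc == 1.0
    assert np.array_equal(rep.confusion.counts, np.diag([5, 5, 5, 5]))
    assert all(rep.per_class[c]["tpr"] == 1.0 for c in (1, 2, 3, 4))


def test_metrics_match_counting_oracle(rng):
    truth = rng.integers(1, 5, 200)
    pred = rng.integers(1, 5, 200)
    rep = evaluate(pred, truth, (1, 2, 3, 4))
    for c in (1, 2, 3, 4):
        tp = sum(1 for t, p in zip(truth, pred) if t == c and p == c)
        fn = sum(1 for t, p in zip(truth, pred) if t == c and p != c)
        fp = sum(1 for t, p in zip(truth, pred) if t != c and p == c)
        tn = sum(1 for t, p in zip(truth, pred) if t != c and p != c)
        m = rep.per_class[c]
        assert m["tpr"] == pytest.approx(tp / (tp + fn))
        assert m["tnr"] == pytest.approx(tn / (tn + fp))
        assert m["fpr"] == pytest.approx(fp / (tn + fp))
        assert m["fnr"] == pytest.approx(fn / (tp + fn))
        assert m["acc"] == pytest.approx((tp + tn) / 200)
    assert rep.confusion.total == 200


@settings(max_examples=80, deadline=None, derandomize=True)
@given(st.lists(st.integers(1, 4), min_size=2, max_size=60),
       st.lists(st.integers(1, 4), min_size=2, max_size=60))
def test_metric_identities_hold(truth, pred):
    n = min(len(truth), len(pred))
    rep = evaluate(np.array(pred[:n]), np.array(truth[:n]), (1, 2, 3, 4))
    assert rep.confusion.total == n
    for c in (1, 2, 3, 4):
        m = rep.per_class[c]
        if not np.isnan(m["tpr"]):
            assert m["tpr"] + m["fnr"] == pytest.approx(1.0, abs=1e-12)
        if not np.isnan(m["tnr"]):
            assert m["tnr"] + m["fpr"] == pytest.approx(1.0, abs=1e-12)


def test_evaluate_rejects_bad_input():
    with pytest.raises(ValueError):
        evaluate(np.array([1, 2]), np.array([1]))
    with pytest.raises(ValueError):
        evaluate(np.array([]), np.array([]))


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def test_json_model_roundtrip(rng):
    X, y = _clusters(rng, spread=1.0)
    model, _ = train_fine_tree(_table(X, y), seed=3)
    applier, names, classes = model_from_json(model_to_json(model))
    proba_a = applier.predict_proba(X)
    proba_b = model.estimator.predict_proba(X)
    assert np.allclose(proba_a, proba_b)
    assert names == model.feature_names
    assert classes == model.classes


# ---------------------------------------------------------------------------
# experiment plumbing
# ---------------------------------------------------------------------------

def test_experiment_rejects_overlapping_run_ids(config, unbiased_classes, clean_params):
    run = generate_run(config, unbiased_classes,
                       clean_params.replace(n_events_per_class=0), run_id="same")
    with pytest.raises(ValueError):
        run_comparison_experiment([run], [run])


def test_zero_noise_experiment_is_perfect(config, unbiased_classes):
    """With optics and electronics noise-free all modes classify perfectly."""
    def params(n, seed):
        return SimulationParams(
            n_events_per_class=n, seed=seed,
            aggregate_probability=0.0, sizing_jitter_um=0.0,
            pi_event_noise_sd=0.0, pi_channel_noise_sd=0.0,
            gain_drift_sd=0.0, baseline_drift_amp=0.0,
        )
    train = generate_run(config, unbiased_classes, params(8, 31), run_id="tr")
    test = generate_run(config, unbiased_classes, params(4, 32), run_id="te")
    report = run_comparison_experiment([train], [test], seed=0, min_parent_size=2)
    for key, block in report["modes"].items():
        assert block["test"]["acc"] == 1.0, key
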