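"""Fine-tree classification and the evaluation metric suite.

The classifier is a single CART decision tree with Gini impurity capped at
100 internal splits (the "fine tree" preset), trained on fused feature
tables, validated with stratified 5-fold cross-validation, and assessed on
independent test runs via confusion matrices and the standard one-vs-rest
metric set: ACC = (TP+TN)/(TN+TP+FN+FP), TPR = TP/(TP+FN),
TNR = TN/(TN+FP), FPR = FP/(TN+FP), FNR = FN/(TP+FN).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .config import AcquisitionConfig, SimulationParams, default_classes
from .electrical import detect_peaks, normalize_trace
from .fusion import (
    build_feature_table,
    feature_columns,
    label_events,
    match_events,
)
from .optical import extract_optical_events
from .synthetic import SyntheticRun, generate_run

__all__ = [
    "TreeModel",
    "ConfusionMatrix",
    "EvalReport",
    "train_fine_tree",
    "predict",
    "evaluate",
    "n_internal_splits",
    "model_to_json",
    "model_from_json",
    "process_run",
    "run_comparison_experiment",
]


@dataclass
class TreeModel:
    """A fitted fine tree plus the bookkeeping needed to reapply it."""

    estimator: DecisionTreeClassifier
    feature_names: list[str]
    classes: list[int]
    max_splits: int
    seed: int
    training_fingerprint: str


@dataclass(frozen=True)
class ConfusionMatrix:
    """K×K counts, rows = true class, cols = predicted class."""

    counts: np.ndarray
    class_order: tuple[int, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_order)
        if c.shape != (k, k) or np.any(c < 0):
            raise ValueError("counts must be a K×K non-negative matrix")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class EvalReport:
    """Confusion matrix plus the per-class one-vs-rest metric suite."""

    confusion: ConfusionMatrix
    acc: float                       # overall multiclass accuracy, trace/total
    per_class: dict[int, dict[str, float]]  # tpr, tnr, fpr, fnr, acc (one-vs-rest)
    cv_acc: float | None = None
    mode: str = ""
    frequency_set: str = ""

    def to_dict(self) -> dict:
        return {
            "class_order": list(self.confusion.class_order),
            "confusion": self.confusion.counts.tolist(),
            "acc": self.acc,
            "per_class": {str(k): v for k, v in sorted(self.per_class.items())},
            "cv_acc": self.cv_acc,
            "mode": self.mode,
            "frequency_set": self.frequency_set,
        }


def _fingerprint(X: np.ndarray, y: np.ndarray, cols: list[str]) -> str:
    h = hashlib.sha256()
    h.update(",".join(cols).encode())
    h.update(np.ascontiguousarray(X, dtype=np.float64).tobytes())
    h.update(np.ascontiguousarray(y, dtype=np.int64).tobytes())
    return h.hexdigest()[:16]


def _table_xy(table: pd.DataFrame, require_labels: bool = True):
    cols = feature_columns(table)
    if not cols:
        raise ValueError("table has no feature columns")
    X = table[cols].to_numpy(dtype=np.float64)
    if require_labels:
        if table["label"].isna().any():
            raise ValueError("table has unlabelled rows")
        y = table["label"].to_numpy(dtype=np.int64)
    else:
        y = None
    return X, y, cols


def train_fine_tree(
    table: pd.DataFrame,
    max_splits: int = 100,
    cv_folds: int = 5,
    seed: int = 0,
    *,
    min_parent_size: int = 20,
) -> tuple[TreeModel, float]:
    """Fit a Gini CART tree with at most ``max_splits`` internal splits.

    ``cv_acc`` is the mean accuracy over ``cv_folds`` stratified folds
    (each fold trains on the remainder and validates on the held-out
    part); the returned model is refit on the full table.  Deterministic
    given the seed.
    """
    X, y, cols = _table_xy(table)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes to train")
    if np.any(counts < cv_folds):
        small = classes[counts < cv_folds]
        raise ValueError(f"classes {small.tolist()} have fewer than {cv_folds} members")

    def make_clf():
        # internal splits = leaves - 1, so cap leaves at max_splits + 1.
        # min_samples_split mirrors the fine-tree preset's minimum parent
        # size, scaled to the few-hundred-event tables used here; without
        # it the tree grows near-single-sample noise leaves that do not
        # survive a device change.
        return DecisionTreeClassifier(
            criterion="gini", max_leaf_nodes=max_splits + 1,
            min_samples_split=min_parent_size, random_state=seed,
        )

    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    accs = []
    for tr, va in skf.split(X, y):
        clf = make_clf().fit(X[tr], y[tr])
        accs.append(float((clf.predict(X[va]) == y[va]).mean()))
    cv_acc = float(np.mean(accs))

    clf = make_clf().fit(X, y)
    model = TreeModel(
        estimator=clf,
        feature_names=cols,
        classes=[int(c) for c in classes],
        max_splits=max_splits,
        seed=seed,
        training_fingerprint=_fingerprint(X, y, cols),
    )
    return model, cv_acc


def n_internal_splits(model: TreeModel) -> int:
    """Number of internal decision nodes of the fitted tree."""
    t = model.estimator.tree_
    return int(np.sum(t.children_left != -1))


def predict(model: TreeModel, table: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-row class prediction and leaf-frequency class probabilities.

    Ties in leaf class frequencies resolve toward the lower class id
    (class order is ascending).
    """
    cols = feature_columns(table)
    if cols != model.feature_names:
        raise ValueError(
            f"feature columns {cols} do not match training columns {model.feature_names}"
        )
    X = table[cols].to_numpy(dtype=np.float64)
    proba = model.estimator.predict_proba(X)
    labels = np.array([model.classes[i] for i in np.argmax(proba, axis=1)])
    return labels, pd.DataFrame(proba, columns=model.classes, index=table.index)


def evaluate(
    predictions: np.ndarray,
    truth: np.ndarray,
    classes: tuple[int, ...] | None = None,
) -> EvalReport:
    """Confusion matrix and the exact metric suite from the counts.

    Per-class metrics are one-vs-rest: the class is positive, every other
    class pooled negative.  By construction TPR+FNR = 1 and TNR+FPR = 1
    whenever the denominators are non-zero (an absent denominator yields
    NaN rather than a silent 0).
    """
    pred = np.asarray(predictions).ravel()
    true = np.asarray(truth).ravel()
    if pred.size != true.size:
        raise ValueError("predictions and truth must have equal length")
    if pred.size == 0:
        raise ValueError("empty input")
    if classes is None:
        classes = tuple(sorted(np.unique(np.concatenate([true, pred])).tolist()))
    k = len(classes)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((k, k), dtype=np.int64)
    for t, p in zip(true, pred):
        counts[index[int(t)], index[int(p)]] += 1
    cm = ConfusionMatrix(counts=counts, class_order=tuple(int(c) for c in classes))
    total = cm.total
    per_class: dict[int, dict[str, float]] = {}
    for c in classes:
        i = index[c]
        tp = int(counts[i, i])
        fn = int(counts[i, :].sum() - tp)
        fp = int(counts[:, i].sum() - tp)
        tn = total - tp - fn - fp

        def ratio(a: int, b: int) -> float:
            return a / b if b > 0 else float("nan")

        per_class[int(c)] = {
            "tp": float(tp), "tn": float(tn), "fp": float(fp), "fn": float(fn),
            "tpr": ratio(tp, tp + fn),
            "tnr": ratio(tn, tn + fp),
            "fpr": ratio(fp, tn + fp),
            "fnr": ratio(fn, tp + fn),
            "acc": ratio(tp + tn, total),
        }
    acc = float(np.trace(counts) / total)
    return EvalReport(confusion=cm, acc=acc, per_class=per_class)


# ---------------------------------------------------------------------------
# JSON model serialization (no opaque binaries)
# ---------------------------------------------------------------------------

def model_to_json(model: TreeModel) -> str:
    """Serialize the tree structure to JSON (nodes, thresholds, leaf counts)."""
    t = model.estimator.tree_
    nodes = []
    for i in range(t.node_count):
        nodes.append({
            "id": i,
            "left": int(t.children_left[i]),
            "right": int(t.children_right[i]),
            "feature": int(t.feature[i]),
            "threshold": float(t.threshold[i]),
            "value": t.value[i][0].tolist(),
        })
    return json.dumps({
        "feature_names": model.feature_names,
        "classes": model.classes,
        "max_splits": model.max_splits,
        "seed": model.seed,
        "training_fingerprint": model.training_fingerprint,
        "nodes": nodes,
    }, indent=2, sort_keys=True)


@dataclass
class _JsonTree:
    """Pure-python applier for a JSON-serialized tree."""

    spec: dict

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        nodes = {n["id"]: n for n in self.spec["nodes"]}
        out = np.empty((X.shape[0], len(self.spec["classes"])))
        for r, x in enumerate(np.asarray(X, dtype=np.float64)):
            i = 0
            while nodes[i]["left"] != -1:
                n = nodes[i]
                i = n["left"] if x[n["feature"]] <= n["threshold"] else n["right"]
            v = np.asarray(nodes[i]["value"], dtype=np.float64)
            out[r] = v / v.sum()
        return out


def model_from_json(text: str) -> tuple[_JsonTree, list[str], list[int]]:
    """Load a JSON model; returns (applier, feature_names, classes)."""
    spec = json.loads(text)
    return _JsonTree(spec), list(spec["feature_names"]), [int(c) for c in spec["classes"]]


# ---------------------------------------------------------------------------
# end-to-end modality-comparison experiment
# ---------------------------------------------------------------------------

def process_run(
    run: SyntheticRun,
    *,
    tolerance_s: float = 0.05,
    prominence_k: float = 5.0,
):
    """Full per-run pipeline: frames → optical events, trace → electrical
    events, time matching, and ground-truth labelling.

    Returns the list of labelled fused events (rows for feature tables).
    """
    optical_events = extract_optical_events(
        run.frames, run.config, frame_times_s=run.frame_times_s,
    )
    optical_events = [e for e in optical_events if e.component_diameters_um]
    norm = normalize_trace(run.trace)
    electrical_events = detect_peaks(
        norm, prominence_k=prominence_k,
        expected_width_s=run.params.pulse_fwhm_s,
    )
    result = match_events(optical_events, electrical_events, tolerance_s)
    label_events(result.matches, run.truth, tolerance_s)
    matches = [m for m in result.matches if m.label is not None]
    for m in matches:
        m.run_id = run.run_id
    return matches


_MODE_KEYS = (
    ("electrical", "single"),
    ("electrical", "all"),
    ("optical", "none"),
    ("multimodal", "single"),
    ("multimodal", "all"),
)


def run_comparison_experiment(
    train_runs: list[SyntheticRun],
    test_runs: list[SyntheticRun],
    *,
    seed: int = 0,
    representative_frequency_hz: float = 500e3,
    tolerance_s: float = 0.05,
    max_splits: int = 100,
    cv_folds: int = 5,
    min_parent_size: int = 20,
) -> dict:
    """Train/test every mode × frequency-set combination.

    Test runs must come from different simulated devices (different
    run ids, their own gain drift) than the training runs.  For each of
    electrical/optical/multimodal with the representative single carrier
    and with all carriers, a fine tree is trained on the pooled training
    events, cross-validated, and evaluated on the pooled test events.
    """
    train_ids = {r.run_id for r in train_runs}
    test_ids = {r.run_id for r in test_runs}
    if train_ids & test_ids:
        raise ValueError(f"train and test share run_ids: {sorted(train_ids & test_ids)}")

    train_events = []
    for r in train_runs:
        train_events.extend(process_run(r, tolerance_s=tolerance_s))
    test_events = []
    for r in test_runs:
        test_events.extend(process_run(r, tolerance_s=tolerance_s))
    if not train_events or not test_events:
        raise ValueError("no labelled events in train or test runs")

    all_freqs = sorted(train_events[0].electrical.peak_intensity)
    fsets = {"single": [representative_frequency_hz], "all": all_freqs, "none": None}

    report: dict = {
        "seed": seed,
        "train_run_ids": sorted(train_ids),
        "test_run_ids": sorted(test_ids),
        "n_train_events": len(train_events),
        "n_test_events": len(test_events),
        "representative_frequency_hz": representative_frequency_hz,
        "modes": {},
    }
    for mode, fkey in _MODE_KEYS:
        freqs = fsets[fkey]
        tr = build_feature_table(train_events, mode, freqs)
        te = build_feature_table(test_events, mode, freqs)
        model, cv_acc = train_fine_tree(tr, max_splits=max_splits,
                                        cv_folds=cv_folds, seed=seed,
                                        min_parent_size=min_parent_size)
        classes = tuple(model.classes)
        rep_tr = evaluate(predict(model, tr)[0],
                          tr["label"].to_numpy(dtype=np.int64), classes)
        rep_te = evaluate(predict(model, te)[0],
                          te["label"].to_numpy(dtype=np.int64), classes)
        key = mode if fkey == "none" else f"{mode}_{fkey}"
        rep_tr.mode = rep_te.mode = mode
        rep_tr.frequency_set = rep_te.frequency_set = fkey
        report["modes"][key] = {
            "cv_acc": cv_acc,
            "n_splits": n_internal_splits(model),
            "train": rep_tr.to_dict(),
            "test": rep_te.to_dict(),
        }

    # per-modality averages over the two frequency configurations — the
    # form in which the headline test accuracies are usually quoted
    m = report["modes"]
    report["summary"] = {
        "test_acc_electrical": 0.5 * (m["electrical_single"]["test"]["acc"]
                                      + m["electrical_all"]["test"]["acc"]),
        "test_acc_optical": m["optical"]["test"]["acc"],
        "test_acc_multimodal": 0.5 * (m["multimodal_single"]["test"]["acc"]
                                      + m["multimodal_all"]["test"]["acc"]),
    }
    return report


def experiment_from_config(cfg: dict) -> dict:
    """End-to-end experiment from a plain manifest dictionary.

    Recognised keys (all optional except ``seed``): ``seed``,
    ``n_train_per_class`` (default 35 per training run),
    ``n_test_per_class`` (default 35, so the single default test run is
    ≈ one third of the three pooled training runs), ``n_train_runs``
    (default 3, emulating separate acquisition series on different
    devices) / ``n_test_runs`` (default 1),
    ``representative_frequency_hz`` (default 500 kHz), plus any
    :class:`SimulationParams` field overrides under ``params``.  Every
    random draw derives from ``seed``, so two invocations with the same
    manifest produce identical reports.
    """
    seed = int(cfg.get("seed", 0))
    n_train = int(cfg.get("n_train_per_class", 35))
    n_test = int(cfg.get("n_test_per_class", 35))
    n_train_runs = int(cfg.get("n_train_runs", 3))
    n_test_runs = int(cfg.get("n_test_runs", 1))
    rep_f = float(cfg.get("representative_frequency_hz", 500e3))
    overrides = dict(cfg.get("params", {}))
    config = AcquisitionConfig.from_dict(cfg["config"]) if "config" in cfg \
        else AcquisitionConfig()
    classes = default_classes()

    ss = np.random.SeedSequence(seed)
    child = ss.generate_state(n_train_runs + n_test_runs) % (2 ** 31)
    train_runs = []
    for i in range(n_train_runs):
        params = SimulationParams(**{**overrides,
                                     "n_events_per_class": n_train,
                                     "seed": int(child[i])})
        train_runs.append(generate_run(config, classes, params, run_id=f"train-{i:03d}"))
    test_runs = []
    for i in range(n_test_runs):
        params = SimulationParams(**{**overrides,
                                     "n_events_per_class": n_test,
                                     "seed": int(child[n_train_runs + i])})
        test_runs.append(generate_run(config, classes, params, run_id=f"test-{i:03d}"))
    report = run_comparison_experiment(
        train_runs, test_runs, seed=seed, representative_frequency_hz=rep_f,
    )
    report["manifest"] = {
        "seed": seed, "n_train_per_class": n_train, "n_test_per_class": n_test,
        "n_train_runs": n_train_runs, "n_test_runs": n_test_runs,
        "representative_frequency_hz": rep_f, "params": overrides,
    }
    return report
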