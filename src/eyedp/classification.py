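"""Classification protocols: practical utility and re-identification attacks.

Two tasks probe a (clean or privatized) cohort:

* ``class_prediction`` — predict the recording's class (document type,
  privacy-sensitivity level, ...) in a leave-one-person-out cross-validation;
  measures how useful the released data remain.
* ``person_identification`` — an attack: train on the first half of every
  recording's time series and predict the participant from the second half;
  accuracy near chance means the release hides personal identifiers.

Each retained time step is one example whose features are the per-window
feature vector. Signals are decimated (one sample kept per non-overlapping
window) before classification; training data are normalized to zero mean and
unit variance and the same parameters are applied to the test data. Four
classifiers are evaluated: k-NN (k = 11), an RBF-kernel SVM (C = 1, automatic
kernel scale), a decision tree, and a 10-tree random forest. Predictions may
be aggregated by majority vote per (participant, recording), with ties broken
uniformly at random under the protocol seed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from ._rng import substream
from .data import FeatureCohort, PrivateRelease

__all__ = [
    "CLASSIFIER_NAMES",
    "ClassificationProtocol",
    "AccuracyTable",
    "subsample",
    "normalize_fit_apply",
    "majority_vote",
    "run_protocol",
]

CLASSIFIER_NAMES = ("knn", "svm_rbf", "decision_tree", "random_forest")


def subsample(signal, window: int) -> np.ndarray:
    """Keep the first sample of each non-overlapping window of ``window`` steps."""
    if window < 1:
        raise ValueError("window must be >= 1")
    arr = np.asarray(signal)
    if arr.shape[0] < 1:
        raise ValueError("signal must be non-empty")
    return arr[::window]


def normalize_fit_apply(train: np.ndarray, test: np.ndarray):
    """Zero-mean/unit-variance normalization fit on train, applied to both.

    Constant training columns map to zero (scale treated as 1). Returns
    ``(train_normed, test_normed, (mean, scale))``. Applying the returned
    parameters a second time is *not* idempotent — the second application
    shifts already-centered data again.
    """
    train = np.asarray(train, dtype=float)
    test = np.asarray(test, dtype=float)
    if train.ndim != 2 or train.shape[0] < 1:
        raise ValueError("train matrix must be non-empty and 2-D")
    mean = train.mean(axis=0)
    scale = train.std(axis=0)
    scale = np.where(scale == 0.0, 1.0, scale)
    return (train - mean) / scale, (test - mean) / scale, (mean, scale)


def majority_vote(predictions, rng: np.random.Generator):
    """Most frequent label; ties broken uniformly at random with ``rng``."""
    preds = list(predictions)
    if not preds:
        raise ValueError("empty prediction group")
    counts = Counter(preds)
    top = max(counts.values())
    tied = sorted(label for label, c in counts.items() if c == top)
    if len(tied) == 1:
        return tied[0]
    return tied[rng.integers(len(tied))]


@dataclass(frozen=True)
class ClassificationProtocol:
    """Configuration of one classification run.

    ``window`` is the decimation factor; the defaults used in evaluation are
    10 for class prediction and 5 for person identification at a 0.5 s step
    (double both at a 1 s step).
    """

    task: str = "class_prediction"
    window: int = 10
    majority_voting: bool = True
    classifiers: tuple = CLASSIFIER_NAMES
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in {"class_prediction", "person_identification"}:
            raise ValueError(f"unknown task {self.task!r}")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        unknown = set(self.classifiers) - set(CLASSIFIER_NAMES)
        if unknown:
            raise ValueError(f"unknown classifiers: {sorted(unknown)}")


@dataclass(frozen=True)
class AccuracyTable:
    """Accuracy per (mechanism, epsilon, classifier) plus the chance level."""

    rows: dict
    chance_level: float
    task: str
    n_decisions: int

    def accuracy(self, classifier: str, mechanism: str = None,
                 epsilon: float = None) -> float:
        for (mech, eps, clf), acc in self.rows.items():
            if clf == classifier and (mechanism is None or mech == mechanism) \
                    and (epsilon is None or eps == epsilon):
                return acc
        raise KeyError(classifier)

    def to_frame(self) -> pd.DataFrame:
        recs = [{"mechanism": m, "epsilon": e, "classifier": c, "accuracy": a}
                for (m, e, c), a in self.rows.items()]
        return pd.DataFrame(recs)


def _build_classifier(name: str, protocol: ClassificationProtocol):
    params = protocol.hyperparameters.get(name, {})
    if name == "knn":
        return KNeighborsClassifier(**{"n_neighbors": 11, **params})
    if name == "svm_rbf":
        return SVC(**{"kernel": "rbf", "C": 1.0, "gamma": "scale", **params})
    if name == "decision_tree":
        return DecisionTreeClassifier(
            **{"random_state": protocol.seed, **params})
    if name == "random_forest":
        return RandomForestClassifier(
            **{"n_estimators": 10, "random_state": protocol.seed, **params})
    raise ValueError(f"unknown classifier {name!r}")


def _recording_examples(cohort: FeatureCohort, protocol: ClassificationProtocol):
    """Per recording: (group key, label, subsampled time-by-feature matrix)."""
    out = []
    for participant, recording, class_label in cohort.recordings:
        mat = cohort.recording_matrix(participant, recording)
        label = participant if protocol.task == "person_identification" else class_label
        out.append(((participant, recording), label, mat))
    return out


def _splits(recordings, protocol: ClassificationProtocol):
    """Yield (train_X, train_y, test entries) per evaluation split.

    Leave-one-person-out for class prediction; a single first-half/second-half
    split per recording for person identification (the adversary's best case:
    prior knowledge of each participant's earlier behavior).
    """
    w = protocol.window
    if protocol.task == "class_prediction":
        participants = sorted({g[0] for g, _, _ in recordings})
        if len({lbl for _, lbl, _ in recordings}) < 2:
            raise ValueError("class prediction needs >= 2 classes")
        for held_out in participants:
            train_X, train_y, test = [], [], []
            for group, label, mat in recordings:
                sub = subsample(mat, w)
                if group[0] == held_out:
                    test.append((group, label, sub))
                else:
                    train_X.append(sub)
                    train_y.extend([label] * sub.shape[0])
            yield np.vstack(train_X), np.asarray(train_y), test
    else:
        if len({g[0] for g, _, _ in recordings}) < 2:
            raise ValueError("person identification needs >= 2 participants")
        train_X, train_y, test = [], [], []
        for group, label, mat in recordings:
            half = mat.shape[0] // 2
            train_sub = subsample(mat[:half], w)
            test_sub = subsample(mat[half:], w)
            train_X.append(train_sub)
            train_y.extend([label] * train_sub.shape[0])
            test.append((group, label, test_sub))
        yield np.vstack(train_X), np.asarray(train_y), test


def run_protocol(data, protocol: ClassificationProtocol) -> AccuracyTable:
    """Run the configured task on a cohort or a private release.

    Returns per-classifier accuracies (majority-voted per recording when
    ``protocol.majority_voting``), keyed by the release's mechanism and
    epsilon (``("clean", inf)`` for an unprivatized cohort). Results are
    exactly reproducible under a fixed protocol seed.
    """
    if isinstance(data, PrivateRelease):
        cohort = data.cohort
        mech_key, eps_key = data.mechanism, data.epsilon
    else:
        cohort = data
        mech_key, eps_key = "clean", float("inf")
    recordings = _recording_examples(cohort, protocol)
    labels = sorted({lbl for _, lbl, _ in recordings})
    chance = 1.0 / len(labels)

    per_clf_correct = {c: 0 for c in protocol.classifiers}
    n_decisions = 0
    for train_X, train_y, test in _splits(recordings, protocol):
        test_X = np.vstack([mat for _, _, mat in test])
        train_n, test_n, _ = normalize_fit_apply(train_X, test_X)
        groups, truths, slices = [], [], []
        start = 0
        for group, label, mat in test:
            groups.append(group)
            truths.append(label)
            slices.append(slice(start, start + mat.shape[0]))
            start += mat.shape[0]
        for clf_name in protocol.classifiers:
            clf = _build_classifier(clf_name, protocol)
            clf.fit(train_n, train_y)
            preds = clf.predict(test_n)
            if protocol.majority_voting:
                for group, truth, sl in zip(groups, truths, slices):
                    rng = substream(protocol.seed, "vote", clf_name, *group)
                    if majority_vote(preds[sl], rng) == truth:
                        per_clf_correct[clf_name] += 1
            else:
                per_clf_correct[clf_name] += int((preds == np.asarray(truths).repeat(
                    [sl.stop - sl.start for sl in slices])).sum())
        n_decisions += len(groups) if protocol.majority_voting else test_n.shape[0]
    rows = {(mech_key, eps_key, c): per_clf_correct[c] / n_decisions
            for c in protocol.classifiers}
    return AccuracyTable(rows=rows, chance_level=chance, task=protocol.task,
                         n_decisions=n_decisions)
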