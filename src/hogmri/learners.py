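"""The fixed bank of base classifiers and hold-out evaluation metrics.

The bank holds 13 learners: a linear-kernel SVM, nine RBF-kernel SVMs
with sigma = 1..9 (kernel K(u, v) = exp(-|u - v|^2 / (2 sigma^2))),
Gaussian naive Bayes, a CART decision tree, and k-nearest neighbours
(k = 5).  SVMs and KNN see features standardised with training-fold
statistics, since unscaled columns would otherwise dominate distances;
solver internals are delegated to scikit-learn.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import DegenerateInputError


@dataclass(frozen=True)
class LearnerSpec:
    """Name and hyperparameters of one base learner."""

    name: str
    hyperparams: tuple = ()  # tuple of (key, value) pairs, hashable

    def params(self) -> dict:
        return dict(self.hyperparams)


def make_learner_bank() -> list[LearnerSpec]:
    """The default 13-member learner bank, in fixed order.

    SVM-linear, SVM-RBF-1 ... SVM-RBF-9, NaiveBayes, DecisionTree, KNN.
    """
    bank = [LearnerSpec("SVM-linear", (("C", 1.0),))]
    for sigma in range(1, 10):
        bank.append(LearnerSpec(f"SVM-RBF-{sigma}", (("C", 1.0), ("sigma", float(sigma)))))
    bank.append(LearnerSpec("NaiveBayes"))
    bank.append(LearnerSpec("DecisionTree"))
    bank.append(LearnerSpec("KNN", (("n_neighbors", 5),)))
    return bank


def build_estimator(spec: LearnerSpec, seed: int = 0):
    """Instantiate the scikit-learn estimator for a spec.

    SVMs and KNN are wrapped in a pipeline with a StandardScaler so the
    scaling statistics always come from the data the estimator is fit
    on (the training fold).
    """
    p = spec.params()
    if spec.name == "SVM-linear":
        est = SVC(kernel="linear", C=p.get("C", 1.0))
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    if spec.name.startswith("SVM-RBF"):
        sigma = p["sigma"]
        est = SVC(kernel="rbf", C=p.get("C", 1.0), gamma=1.0 / (2.0 * sigma ** 2))
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    if spec.name == "NaiveBayes":
        return GaussianNB()
    if spec.name == "DecisionTree":
        return DecisionTreeClassifier(random_state=seed)
    if spec.name == "KNN":
        return Pipeline([("scale", StandardScaler()),
                         ("clf", KNeighborsClassifier(n_neighbors=p.get("n_neighbors", 5)))])
    raise ValueError(f"unknown learner {spec.name!r}")


def fit_predict(spec: LearnerSpec, X_train, y_train, X_test, seed: int = 0) -> np.ndarray:
    """Fit the learner on the training data and predict labels for the test rows."""
    y_train = np.asarray(y_train)
    if np.unique(y_train).size < 2:
        raise DegenerateInputError("training data contains a single class")
    est = build_estimator(spec, seed)
    est.fit(np.asarray(X_train, dtype=float), y_train)
    return est.predict(np.asarray(X_test, dtype=float))


@dataclass
class EvalReport:
    """Confusion counts and the derived percentage metrics."""

    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def accuracy(self) -> float:
        """(TP + TN) / total, as a percentage."""
        return 100.0 * (self.tp + self.tn) / self.total

    @property
    def sensitivity(self) -> float:
        """TP / (TP + FN), as a percentage."""
        pos = self.tp + self.fn
        return 100.0 * self.tp / pos if pos else float("nan")

    @property
    def specificity(self) -> float:
        """TN / (TN + FP), as a percentage."""
        neg = self.tn + self.fp
        return 100.0 * self.tn / neg if neg else float("nan")

    def rounded(self) -> tuple[float, float, float]:
        """(accuracy, sensitivity, specificity) to one decimal place."""
        return (round(self.accuracy, 1), round(self.sensitivity, 1),
                round(self.specificity, 1))

    def to_dict(self) -> dict:
        acc, sens, spec = self.rounded()
        return {"accuracy": acc, "sensitivity": sens, "specificity": spec,
                "tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp}

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    def to_tsv_row(self) -> str:
        acc, sens, spec = self.rounded()
        return f"{acc}\t{sens}\t{spec}"


def evaluate(pred, truth, positive_class=0) -> EvalReport:
    """Confusion counts and accuracy/sensitivity/specificity.

    ``positive_class`` is the label counted as "positive" for
    sensitivity (default 0, the healthy-control code): the convention
    under which the published confusion arithmetic is self-consistent.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"prediction shape {pred.shape} != truth shape {truth.shape}")
    pos = truth == positive_class
    tp = int(np.sum(pos & (pred == positive_class)))
    fn = int(np.sum(pos & (pred != positive_class)))
    tn = int(np.sum(~pos & (pred != positive_class)))
    fp = int(np.sum(~pos & (pred == positive_class)))
    return EvalReport(tp, fn, tn, fp)
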