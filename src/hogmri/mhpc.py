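"""Joint learner and feature-set selection by incremental cross-validation.

The MHPC procedure picks a base classifier L* and feature subset FS*
from a bank of learners and an mRMR feature ranking:

1. rank all features by mRMR on the full training set;
2. for k = 1, 2, 3, ... evaluate every learner on the top-k features by
   5-fold cross-validation (one seeded, stratified partition shared by
   every (learner, k) pair), recording the mean (Eacc) and range
   (Racc = max - min) of the five fold accuracies;
3. stop when no learner has improved its best mean for ``patience``
   consecutive feature additions (the published stop rule — "no
   accuracy increase in all of the learners" — is a plateau criterion,
   since the CV curves are non-monotone), or when k reaches ``k_max``;
4. per learner keep the k with the largest mean; keep the five learners
   with the largest best-means; the winner is the one with the
   *smallest range* among those five (the top means are typically very
   close, so the tie-break favours fold-stability);
5. refit the winner on the whole training set restricted to FS*.

A strict mode re-ranks features inside each training fold, avoiding the
selection leakage of ranking on the full training set; it is off by
default to match the published procedure (the hold-out evaluation is
clean either way).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .errors import DegenerateInputError, SchemaError
from .learners import EvalReport, LearnerSpec, build_estimator, evaluate, make_learner_bank
from .mrmr import DiscretizedMatrix, discretize, mrmr_select


@dataclass
class LabeledDataset:
    """Subjects x features matrix with binary labels."""

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str] | None = None
    subject_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise SchemaError("X must be 2-D (subjects x features)")
        if self.y.shape != (self.X.shape[0],):
            raise SchemaError(f"labels shape {self.y.shape} != {self.X.shape[0]} subjects")
        if np.unique(self.y).size != 2:
            raise SchemaError("labels must contain exactly two classes")
        if self.feature_names is None:
            self.feature_names = [f"f{j}" for j in range(self.X.shape[1])]
        if self.subject_ids is None:
            self.subject_ids = [f"s{i}" for i in range(self.X.shape[0])]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    def subset(self, rows) -> "LabeledDataset":
        rows = np.asarray(rows)
        return LabeledDataset(self.X[rows], self.y[rows],
                              self.feature_names,
                              [self.subject_ids[i] for i in rows])


@dataclass
class CVRecord:
    """Cross-validation result for one (learner, feature set) pair."""

    learner: LearnerSpec
    fs: list[int]
    fold_accuracies: list[float]

    @property
    def fs_size(self) -> int:
        return len(self.fs)

    @property
    def mean(self) -> float:
        """Eacc: mean accuracy over the folds, in percent."""
        return float(np.mean(self.fold_accuracies))

    @property
    def range(self) -> float:
        """Racc: max - min fold accuracy, in percent."""
        return float(np.max(self.fold_accuracies) - np.min(self.fold_accuracies))


@dataclass
class MHPCConfig:
    """Knobs of the selection procedure.

    ``patience``: feature additions without any learner improving its
    best CV mean before stopping (default 20).  ``k_max``: hard cap on
    the feature-set size (default 1000; the selected subsets stay well
    under this in practice).  ``n_folds``: CV folds (5).  ``top_n``:
    learners retained for the range tie-break (5).  ``strict_per_fold``:
    re-rank features inside each training fold instead of once on the
    full training set.
    """

    patience: int = 20
    k_max: int = 1000
    n_folds: int = 5
    top_n: int = 5
    seed: int = 0
    strict_per_fold: bool = False
    mrmr_variant: str = "MID"


@dataclass
class SelectionResult:
    """Outcome of the selection: winner, top-5 table, full audit log."""

    best_learner: LearnerSpec
    best_feature_set: list[int]
    top5: list[CVRecord]
    final_classifier: object
    audit_log: list[CVRecord]
    ranking: list[int]

    def audit_tsv(self) -> str:
        """Audit log as TSV: learner, k, fold1..fold5, mean, range."""
        lines = ["learner\tk\t" +
                 "\t".join(f"fold{i + 1}" for i in range(len(self.audit_log[0].fold_accuracies))) +
                 "\tmean\trange"]
        for r in self.audit_log:
            folds = "\t".join(f"{a:.4f}" for a in r.fold_accuracies)
            lines.append(f"{r.learner.name}\t{r.fs_size}\t{folds}\t{r.mean:.4f}\t{r.range:.4f}")
        return "\n".join(lines) + "\n"

    def to_manifest(self) -> dict:
        return {
            "best_learner": self.best_learner.name,
            "hyperparams": self.best_learner.params(),
            "feature_set": [int(i) for i in self.best_feature_set],
            "top5": [
                {"learner": r.learner.name, "fs_size": r.fs_size,
                 "mean": round(r.mean, 4), "range": round(r.range, 4)}
                for r in self.top5
            ],
        }


def make_folds(y, n_folds: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """One seeded, class-stratified fold partition reused for every evaluation."""
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(y)), y)]


def cross_validate(spec: LearnerSpec, D: LabeledDataset, fs,
                   folds=None, seed: int = 0, n_folds: int = 5) -> CVRecord:
    """Fold accuracies of a learner on D restricted to the features ``fs``.

    The fold partition is fixed per seed, so repeated calls — and calls
    for different (learner, feature set) pairs — see identical folds.
    """
    fs = [int(i) for i in fs]
    if len(fs) < 1:
        raise ValueError("feature set must be non-empty")
    if D.n < 10:
        raise DegenerateInputError(f"need at least 10 subjects for 5-fold CV, got {D.n}")
    if folds is None:
        folds = make_folds(D.y, n_folds, seed)
    Xfs = D.X[:, fs]
    accs = []
    for tr, te in folds:
        if np.unique(D.y[tr]).size < 2:
            raise DegenerateInputError("a training fold contains a single class")
        est = build_estimator(spec, seed)
        est.fit(Xfs[tr], D.y[tr])
        accs.append(100.0 * float(np.mean(est.predict(Xfs[te]) == D.y[te])))
    return CVRecord(spec, fs, accs)


def _fold_rankings(D: LabeledDataset, folds, k_max: int, variant: str) -> list[list[int]]:
    """Per-training-fold mRMR rankings for the strict (leakage-free) mode."""
    out = []
    for tr, _ in folds:
        disc = discretize(D.X[tr])
        out.append(mrmr_select(disc, D.y[tr], min(k_max, D.d), variant).order)
    return out


def _cv_topk_strict(spec, D, k, folds, rankings, seed) -> CVRecord:
    accs = []
    for (tr, te), order in zip(folds, rankings):
        fs = order[:k]
        est = build_estimator(spec, seed)
        est.fit(D.X[tr][:, fs], D.y[tr])
        accs.append(100.0 * float(np.mean(est.predict(D.X[te][:, fs]) == D.y[te])))
    # the nominal fs (full-data top-k) is recorded for the audit log
    return CVRecord(spec, list(range(k)), accs)


def mhpc_select(D_train: LabeledDataset, bank: list[LearnerSpec] | None = None,
                config: MHPCConfig | None = None) -> SelectionResult:
    """Select the best (learner, feature set) pair by incremental 5-fold CV.

    Deterministic given (data, bank, config).  Ties among top-5
    membership break to the smaller feature-set size then bank order;
    equal smallest ranges among the top 5 break to bank order.
    """
    bank = make_learner_bank() if bank is None else list(bank)
    config = MHPCConfig() if config is None else config
    if D_train.d < 1:
        raise DegenerateInputError("training data has no features")

    folds = make_folds(D_train.y, config.n_folds, config.seed)
    k_max = min(config.k_max, D_train.d)

    disc = discretize(D_train.X)
    ranking = mrmr_select(disc, D_train.y, k_max, config.mrmr_variant).order
    strict_rankings = (_fold_rankings(D_train, folds, k_max, config.mrmr_variant)
                       if config.strict_per_fold else None)

    audit: list[CVRecord] = []
    best_by_learner: dict[str, CVRecord] = {}
    bank_pos = {spec.name: i for i, spec in enumerate(bank)}
    since_improvement = 0
    for k in range(1, k_max + 1):
        fs = ranking[:k]
        improved = False
        for spec in bank:
            if config.strict_per_fold:
                rec = _cv_topk_strict(spec, D_train, k, folds, strict_rankings, config.seed)
                rec = CVRecord(spec, fs, rec.fold_accuracies)
            else:
                rec = cross_validate(spec, D_train, fs, folds=folds, seed=config.seed)
            audit.append(rec)
            prev = best_by_learner.get(spec.name)
            if prev is None or rec.mean > prev.mean:
                best_by_learner[spec.name] = rec
                improved = True
        since_improvement = 0 if improved else since_improvement + 1
        if since_improvement >= config.patience:
            break
    else:
        if since_improvement < config.patience and k_max < D_train.d:
            warnings.warn(
                f"CV accuracy had not plateaued when k reached the cap ({k_max}); "
                "selecting among the visited feature-set sizes", stacklevel=2)

    # rank learners by their best CV mean; keep the top 5 (or all if fewer)
    bests = sorted(best_by_learner.values(),
                   key=lambda r: (-r.mean, r.fs_size, bank_pos[r.learner.name]))
    top = bests[:config.top_n]
    winner = min(top, key=lambda r: (r.range, bank_pos[r.learner.name]))

    final = build_estimator(winner.learner, config.seed)
    final.fit(D_train.X[:, winner.fs], D_train.y)
    return SelectionResult(winner.learner, winner.fs, top, final, audit, ranking)


def evaluate_holdout(result: SelectionResult, D_test: LabeledDataset,
                     positive_class=0) -> EvalReport:
    """Run the final classifier on hold-out subjects and score it."""
    if D_test.d <= max(result.best_feature_set):
        raise SchemaError(
            f"hold-out feature space ({D_test.d} columns) does not cover the "
            f"selected feature indices (max {max(result.best_feature_set)})")
    pred = result.final_classifier.predict(D_test.X[:, result.best_feature_set])
    return evaluate(pred, D_test.y, positive_class)
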