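"""MLP classification protocol.

The protocol mirrors common clinical-classifier practice on repeated
per-subject measurements: subjects (never individual pulses) are randomly
split 2:1 into a training pool and a held-out test set; within the
training pool, three repeated random 80/20 subject-level splits provide
cross-validation folds; a final model fitted on the whole training pool is
evaluated once on the held-out subjects.  The classifier is a multilayer
perceptron with a 40-node input layer, three hidden layers of 20
rectified-linear nodes and a single sigmoidal output unit (score >= 0.5 is
called AD).  Metrics are the pulse-level confusion matrix, accuracy,
sensitivity, specificity and the rank-statistic AUC; a subject-level mode
averages each subject's scores before thresholding.

``PulseClassificationModel`` wraps the protocol in a model/results pair:
construct it from a feature table, call :meth:`fit`, and read the fold,
averaged and hold-out reports off the returned results object.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPClassifier

from .features import FEATURE_COLUMNS, ZScoreNormalizer

__all__ = [
    "SplitPlan",
    "MLPConfig",
    "TrainedClassifier",
    "EvaluationReport",
    "make_split",
    "train_mlp",
    "predict",
    "evaluate",
    "run_protocol",
    "PulseClassificationModel",
    "ProtocolResults",
]

POSITIVE = "AD"


@dataclass(frozen=True)
class SplitPlan:
    """Subject-level 2:1 train/test split plus three 80/20 folds."""

    train_subjects: tuple
    test_subjects: tuple
    folds: tuple  # of (fit_subjects, validation_subjects)
    seed: int

    def __post_init__(self):
        train, test = set(self.train_subjects), set(self.test_subjects)
        if train & test:
            raise ValueError("train and test subjects overlap")
        for fit, val in self.folds:
            fit, val = set(fit), set(val)
            if fit & val:
                raise ValueError("fold fit and validation subjects overlap")
            if not (fit | val) <= train:
                raise ValueError("fold subjects must come from the training set")


@dataclass(frozen=True)
class MLPConfig:
    """Network and training settings (40 -> 20 -> 20 -> 20 -> 1)."""

    hidden_layer_sizes: tuple = (20, 20, 20)
    activation: str = "relu"
    solver: str = "adam"
    learning_rate: float = 1e-3
    alpha: float = 3.0  # L2 penalty; repeated rows per subject overfit fast without it
    max_epochs: int = 200
    early_stopping_patience: int = 20
    seed: int = 0

    def __post_init__(self):
        if tuple(self.hidden_layer_sizes) != (20, 20, 20):
            raise ValueError("the protocol uses exactly 3 hidden layers of 20 nodes")


@dataclass
class TrainedClassifier:
    """Fitted MLP plus its training history and normalization reference."""

    estimator: MLPClassifier
    config: MLPConfig
    normalizer: ZScoreNormalizer
    history: pd.DataFrame  # epoch, fit_accuracy, validation_accuracy
    n_features: int = len(FEATURE_COLUMNS)


@dataclass(frozen=True)
class EvaluationReport:
    """Confusion matrix and derived metrics for one evaluation run.

    Accuracy/sensitivity/specificity are recomputed from the stored counts
    on access, so the metric identities hold by construction.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    auc: float
    level: str = "pulse"  # or "subject"

    @property
    def n(self):
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self):
        return (self.tp + self.tn) / self.n * 100.0

    @property
    def sensitivity(self):
        d = self.tp + self.fn
        return self.tp / d * 100.0 if d else float("nan")

    @property
    def specificity(self):
        d = self.tn + self.fp
        return self.tn / d * 100.0 if d else float("nan")

    def as_dict(self):
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "level": self.level,
        }


def _allocate_two_thirds(counts):
    """Largest-remainder allocation of 2/3 of each class to training."""
    quotas = {c: 2 * n / 3 for c, n in counts.items()}
    floors = {c: int(np.floor(q)) for c, q in quotas.items()}
    total_target = int(np.floor(2 * sum(counts.values()) / 3))
    remainders = sorted(counts, key=lambda c: quotas[c] - floors[c], reverse=True)
    short = total_target - sum(floors.values())
    for c in remainders[:short]:
        floors[c] += 1
    return floors


def make_split(subjects, labels, seed, k=3, val_fraction=0.2) -> SplitPlan:
    """Stratified subject-level 2:1 split plus ``k`` repeated 80/20 folds.

    Each fold is an independent seeded stratified draw of ``val_fraction``
    of the training subjects (repeated random splits, not a partition).
    """
    subjects = list(subjects)
    labels = list(labels)
    by_class = {}
    for s, l in zip(subjects, labels):
        by_class.setdefault(l, []).append(s)
    for c, members in by_class.items():
        if len(members) < 6:
            raise ValueError(f"class {c!r} has {len(members)} subjects; need >= 6")
    rng = np.random.default_rng(seed)
    n_train = _allocate_two_thirds({c: len(m) for c, m in by_class.items()})
    train, test = [], []
    for c in sorted(by_class):
        members = sorted(by_class[c])
        perm = rng.permutation(len(members))
        train += [members[i] for i in perm[: n_train[c]]]
        test += [members[i] for i in perm[n_train[c] :]]
    if not test:
        raise ValueError("no subjects left for the test set")

    train_by_class = {}
    for s in train:
        train_by_class.setdefault(labels[subjects.index(s)], []).append(s)
    folds = []
    for _ in range(k):
        fit, val = [], []
        for c in sorted(train_by_class):
            members = sorted(train_by_class[c])
            n_val = max(1, int(round(val_fraction * len(members))))
            perm = rng.permutation(len(members))
            val += [members[i] for i in perm[:n_val]]
            fit += [members[i] for i in perm[n_val:]]
        folds.append((tuple(sorted(fit)), tuple(sorted(val))))
    return SplitPlan(
        train_subjects=tuple(sorted(train)),
        test_subjects=tuple(sorted(test)),
        folds=tuple(folds),
        seed=seed,
    )


def _as_xy(df):
    X = df[FEATURE_COLUMNS].to_numpy(dtype=float)
    y = (df["label"].to_numpy() == POSITIVE).astype(int)
    return X, y


def train_mlp(fit_df, config: MLPConfig, normalizer: ZScoreNormalizer, val_df=None) -> TrainedClassifier:
    """Train the MLP epoch by epoch with early stopping.

    ``fit_df``/``val_df`` are already-normalized feature rows.  Training
    stops when the monitored accuracy (validation if provided, else fit)
    has not improved for ``early_stopping_patience`` epochs; the best
    weights are restored.  Deterministic for a given config seed.
    """
    X, y = _as_xy(fit_df)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contain a single class")
    Xv, yv = _as_xy(val_df) if val_df is not None and len(val_df) else (None, None)
    clf = MLPClassifier(
        hidden_layer_sizes=tuple(config.hidden_layer_sizes),
        activation=config.activation,
        solver=config.solver,
        learning_rate_init=config.learning_rate,
        alpha=config.alpha,
        random_state=config.seed,
    )
    rng = np.random.default_rng(config.seed)
    best = (-np.inf, None, None, 0)
    rows = []
    since_best = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(y))
        clf.partial_fit(X[order], y[order], classes=[0, 1])
        fit_acc = float(np.mean(clf.predict(X) == y))
        val_acc = float(np.mean(clf.predict(Xv) == yv)) if Xv is not None else float("nan")
        rows.append({"epoch": epoch, "fit_accuracy": fit_acc, "validation_accuracy": val_acc})
        monitored = val_acc if Xv is not None else fit_acc
        if monitored > best[0]:
            best = (monitored, copy.deepcopy(clf.coefs_), copy.deepcopy(clf.intercepts_), epoch)
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.early_stopping_patience:
                break
    if best[1] is not None:
        clf.coefs_, clf.intercepts_ = best[1], best[2]
    return TrainedClassifier(
        estimator=clf,
        config=config,
        normalizer=normalizer,
        history=pd.DataFrame(rows),
    )


def predict(classifier: TrainedClassifier, df: pd.DataFrame):
    """Scores in [0, 1] and labels (score >= 0.5 -> AD) for normalized rows."""
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"expected {classifier.n_features} features; missing {missing}")
    X = df[FEATURE_COLUMNS].to_numpy(dtype=float)
    scores = classifier.estimator.predict_proba(X)[:, 1]
    return scores, (scores >= 0.5).astype(int)


def _rank_auc(scores, y):
    """Mann-Whitney AUC; ties counted half."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n0 == 0:
        return float("nan")
    order = np.argsort(scores, kind="mergesort")
    ranks = np.empty(len(scores))
    sorted_scores = scores[order]
    i = 0
    r = 1.0
    while i < len(scores):
        j = i
        while j + 1 < len(scores) and sorted_scores[j + 1] == sorted_scores[i]:
            j += 1
        ranks[order[i : j + 1]] = (r + (r + j - i)) / 2.0
        r += j - i + 1
        i = j + 1
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def evaluate(scores, y_true, level="pulse", subject_ids=None) -> EvaluationReport:
    """Confusion matrix, accuracy/sensitivity/specificity and AUC.

    ``level='subject'`` first averages each subject's scores, then
    thresholds the subject means.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y_true, dtype=int)
    if level == "subject":
        if subject_ids is None:
            raise ValueError("subject-level evaluation needs subject_ids")
        df = pd.DataFrame({"s": subject_ids, "score": scores, "y": y})
        agg = df.groupby("s").agg(score=("score", "mean"), y=("y", "first"))
        scores, y = agg["score"].to_numpy(), agg["y"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("evaluation needs both classes present")
    pred = (scores >= 0.5).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    return EvaluationReport(tp=tp, fp=fp, tn=tn, fn=fn, auc=_rank_auc(scores, y), level=level)


def _subset(df, subjects):
    return df[df["subject_id"].isin(subjects)]


def run_protocol(features: pd.DataFrame, plan: SplitPlan, config: MLPConfig, level="pulse"):
    """Cross-validated training plus hold-out evaluation.

    For each fold: z-score normalization and the MLP are fitted on the
    fold's fit subjects and evaluated on its validation subjects.  The
    final model is fitted on all training subjects (with an internal 80/20
    subject split for early-stopping monitoring) and evaluated once on the
    held-out subjects.  Returns a :class:`ProtocolResults`.
    """
    fold_reports, fold_classifiers = [], []
    for f, (fit_subj, val_subj) in enumerate(plan.folds):
        norm = ZScoreNormalizer().fit(_subset(features, fit_subj))
        fit_df = norm.transform(_subset(features, fit_subj))
        val_df = norm.transform(_subset(features, val_subj))
        clf = train_mlp(
            fit_df,
            MLPConfig(**{**config.__dict__, "seed": config.seed + 1 + f}),
            norm,
            val_df=val_df,
        )
        scores, _ = predict(clf, val_df)
        _, yv = _as_xy(val_df)
        fold_reports.append(evaluate(scores, yv, level=level, subject_ids=val_df["subject_id"]))
        fold_classifiers.append(clf)

    # final model: all training subjects; internal split only monitors early stopping
    rng = np.random.default_rng(config.seed + 104729)
    labels_by_subject = features.drop_duplicates("subject_id").set_index("subject_id")["label"]
    monitor = []
    for c in sorted(labels_by_subject[list(plan.train_subjects)].unique()):
        members = sorted(s for s in plan.train_subjects if labels_by_subject[s] == c)
        n_val = max(1, int(round(0.2 * len(members))))
        perm = rng.permutation(len(members))
        monitor += [members[i] for i in perm[:n_val]]
    fit_subj = tuple(s for s in plan.train_subjects if s not in set(monitor))
    norm = ZScoreNormalizer().fit(_subset(features, plan.train_subjects))
    clf = train_mlp(
        norm.transform(_subset(features, fit_subj)),
        MLPConfig(**{**config.__dict__, "seed": config.seed + 17}),
        norm,
        val_df=norm.transform(_subset(features, monitor)),
    )
    test_df = norm.transform(_subset(features, plan.test_subjects))
    scores, _ = predict(clf, test_df)
    _, yt = _as_xy(test_df)
    holdout = evaluate(scores, yt, level=level, subject_ids=test_df["subject_id"])
    return ProtocolResults(
        plan=plan,
        config=config,
        fold_reports=fold_reports,
        holdout_report=holdout,
        fold_classifiers=fold_classifiers,
        final_classifier=clf,
        level=level,
    )


@dataclass
class ProtocolResults:
    """Results of the full classification protocol."""

    plan: SplitPlan
    config: MLPConfig
    fold_reports: list
    holdout_report: EvaluationReport
    fold_classifiers: list = field(default_factory=list)
    final_classifier: TrainedClassifier | None = None
    level: str = "pulse"

    @property
    def average_report(self):
        """Fold-averaged metrics (means of the per-fold values)."""
        keys = ["accuracy", "sensitivity", "specificity", "auc"]
        return {k: float(np.mean([getattr(r, k) for r in self.fold_reports])) for k in keys}

    def as_dict(self):
        return {
            "seed": self.plan.seed,
            "level": self.level,
            "folds": [r.as_dict() for r in self.fold_reports],
            "average": self.average_report,
            "holdout": self.holdout_report.as_dict(),
        }

    def summary(self) -> str:
        lines = [
            f"MLP classification protocol ({self.level}-level metrics, seed {self.plan.seed})",
            f"  train subjects: {len(self.plan.train_subjects)}   "
            f"test subjects: {len(self.plan.test_subjects)}",
            f"{'':14s}{'Acc (%)':>9s}{'Sens (%)':>10s}{'Spec (%)':>10s}{'AUC':>7s}",
        ]
        def row(name, r):
            return (
                f"  {name:<12s}{r['accuracy']:>9.2f}{r['sensitivity']:>10.2f}"
                f"{r['specificity']:>10.2f}{r['auc']:>7.2f}"
            )
        for i, r in enumerate(self.fold_reports, 1):
            lines.append(row(f"fold {i}", r.as_dict()))
        lines.append(row("average", self.average_report))
        lines.append(row("hold-out", self.holdout_report.as_dict()))
        h = self.holdout_report
        lines.append(f"  hold-out confusion: TP={h.tp} FP={h.fp} TN={h.tn} FN={h.fn}")
        return "\n".join(lines)

    def plot_history(self, ax=None):
        """Training/validation accuracy curves of the final model."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        h = self.final_classifier.history
        ax.plot(h["epoch"], h["fit_accuracy"], label="training")
        ax.plot(h["epoch"], h["validation_accuracy"], label="validation")
        ax.set_xlabel("epoch")
        ax.set_ylabel("accuracy")
        ax.legend()
        return ax


class PulseClassificationModel:
    """Model object over a feature table: split, train, evaluate.

    Parameters
    ----------
    features : DataFrame with the 40 canonical feature columns plus
        ``subject_id`` and ``label``.
    """

    def __init__(self, features: pd.DataFrame):
        missing = [c for c in FEATURE_COLUMNS + ["subject_id", "label"] if c not in features]
        if missing:
            raise ValueError(f"feature table is missing columns: {missing}")
        self.features = features.reset_index(drop=True)

    @classmethod
    def from_dataframe(cls, features):
        return cls(features)

    def fit(self, seed=0, config: MLPConfig | None = None, level="pulse") -> ProtocolResults:
        config = config or MLPConfig(seed=seed)
        subjects = self.features.drop_duplicates("subject_id")
        plan = make_split(subjects["subject_id"], subjects["label"], seed=seed)
        return run_protocol(self.features, plan, config, level=level)
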