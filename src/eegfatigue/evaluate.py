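"""Leave-one-subject-out (LOSO) evaluation, metrics and reports.

"Leave-one-out" here means leave-one-SUBJECT-out: each fold holds out every
epoch of one subject and trains on everyone else, the protocol that probes
generalization to unseen drivers.  All fold-local transforms — correlation
pruning, per-feature z-scoring — are fitted on the fold's training rows
only and applied unchanged to the held-out subject, so no information leaks
across the subject boundary.

The module is organized around two objects in the fit/results idiom:
:class:`LosoEvaluation` is configured with a feature table and a classifier
kind; its :meth:`~LosoEvaluation.fit` runs the full cross-validation and
returns a :class:`LosoResults` carrying per-subject confusion matrices,
metric summaries (mean +/- SD across subjects), pooled ROC/AUC, and a
``summary()`` table.

The positive class is fatigue throughout; the decision threshold for
confusion matrices is fixed at 0.5, with ROC/AUC reported separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics as skmetrics
from sklearn.preprocessing import StandardScaler

from .data import CHANNELS, FeatureTable
from .entropy import EntropyConfig, build_feature_table
from .models import _substream_seeds, make_classifier
from .preprocess import PreprocessConfig, preprocess_pipeline
from .selection import correlation_prune

DEFAULT_CHANNEL_SETS = (("FP1",), ("FP2",), CHANNELS)


@dataclass
class ConfusionMatrix:
    """Binary confusion counts; positive = fatigue."""

    tn: int = 0
    fp: int = 0
    fn: int = 0
    tp: int = 0

    def __post_init__(self) -> None:
        if min(self.tn, self.fp, self.fn, self.tp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.tn + other.tn, self.fp + other.fp,
                               self.fn + other.fn, self.tp + other.tp)

    @classmethod
    def from_predictions(cls, labels: np.ndarray,
                         predicted: np.ndarray) -> "ConfusionMatrix":
        labels = np.asarray(labels, dtype=int)
        predicted = np.asarray(predicted, dtype=int)
        return cls(tn=int(np.sum((labels == 0) & (predicted == 0))),
                   fp=int(np.sum((labels == 0) & (predicted == 1))),
                   fn=int(np.sum((labels == 1) & (predicted == 0))),
                   tp=int(np.sum((labels == 1) & (predicted == 1))))


def compute_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """ACC, SN (=recall), SP, precision, F1 from confusion counts.

    Ratios with a zero denominator are *absent* from the result rather
    than reported as 0.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    out: dict[str, float] = {"ACC": (cm.tp + cm.tn) / cm.total}
    if cm.tp + cm.fn > 0:
        out["SN"] = out["recall"] = cm.tp / (cm.tp + cm.fn)
    if cm.tn + cm.fp > 0:
        out["SP"] = cm.tn / (cm.tn + cm.fp)
    if cm.tp + cm.fp > 0:
        out["precision"] = cm.tp / (cm.tp + cm.fp)
    if "precision" in out and "recall" in out and \
            (out["precision"] + out["recall"]) > 0:
        out["F1"] = (2 * out["precision"] * out["recall"]
                     / (out["precision"] + out["recall"]))
    return out


def roc_curve(labels: np.ndarray, scores: np.ndarray,
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """ROC points by threshold sweep and trapezoidal AUC.

    The trapezoidal AUC over the empirical ROC equals the normalized
    Mann-Whitney U statistic P(score+ > score-) + 0.5 P(tie).
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes")
    fpr, tpr, thresholds = skmetrics.roc_curve(labels, scores)
    return fpr, tpr, thresholds, float(skmetrics.auc(fpr, tpr))


def loso_split(table: FeatureTable):
    """Yield (subject_id, train_index, test_index) per subject.

    Test indices are all of that subject's rows; training indices are
    everyone else's.  A subject carrying only one class is kept with a
    warning (its fold metrics are partially undefined).
    """
    subjects = table.subjects
    unique = pd.unique(subjects)
    if len(unique) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    y = table.y
    for subject in unique:
        test = np.flatnonzero(subjects == subject)
        train = np.flatnonzero(subjects != subject)
        if len(np.unique(y[test])) < 2:
            warnings.warn(f"subject {subject!r} has a single class; fold "
                          "metrics will be partially undefined", stacklevel=2)
        yield subject, train, test


def summarize(per_subject_metrics: list[dict[str, float]]) -> pd.DataFrame:
    """Mean and sample SD (ddof=1) of each metric across subjects.

    A metric missing for some subject is excluded from that metric's n.
    """
    if len(per_subject_metrics) < 2:
        raise ValueError("need at least 2 subjects to summarize")
    names: list[str] = []
    for m in per_subject_metrics:
        names += [k for k in m if k not in names]
    rows = []
    for name in names:
        vals = np.array([m[name] for m in per_subject_metrics if name in m])
        rows.append({"metric": name, "mean": vals.mean(),
                     "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
                     "n": len(vals)})
    return pd.DataFrame(rows).set_index("metric")


@dataclass
class LosoResults:
    """Outcome of one LOSO run: per-subject and pooled diagnostics."""

    classifier: str
    per_subject: dict = field(default_factory=dict)
    pooled: ConfusionMatrix = field(default_factory=ConfusionMatrix)
    labels: np.ndarray = None
    scores: np.ndarray = None
    fold_details: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        return summarize([d["metrics"] for d in self.per_subject.values()])

    @property
    def mean_accuracy(self) -> float:
        return float(self.summary().loc["ACC", "mean"])

    @property
    def pooled_metrics(self) -> dict[str, float]:
        return compute_metrics(self.pooled)

    def roc(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
        return roc_curve(self.labels, self.scores)

    @property
    def auc(self) -> float:
        return self.roc()[3]

    def summary_text(self) -> str:
        lines = [f"LOSO results ({self.classifier}), "
                 f"{len(self.per_subject)} subjects, "
                 f"{self.pooled.total} epochs"]
        summ = self.summary()
        for metric, row in summ.iterrows():
            lines.append(f"  {metric:<10s} {row['mean']:.3f} +/- "
                         f"{row['sd']:.3f}  (n={int(row['n'])})")
        lines.append(f"  AUC (pooled) {self.auc:.3f}")
        cm = self.pooled
        lines.append(f"  pooled confusion  tn={cm.tn} fp={cm.fp} "
                     f"fn={cm.fn} tp={cm.tp}")
        return "\n".join(lines)

    def plot_roc(self, ax=None):
        import matplotlib.pyplot as plt
        fpr, tpr, _, auc_val = self.roc()
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(fpr, tpr, label=f"{self.classifier} (AUC={auc_val:.3f})")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend()
        return ax


class LosoEvaluation:
    """Configured LOSO cross-validation over a feature table.

    Parameters
    ----------
    table : FeatureTable
        Epoch-level features with subject ids and binary labels.
    classifier : str
        'stack' (learned meta-combiner), 'mean' (probability averaging),
        or a single base learner 'lr' / 'elm' / 'lgbm'.
    prune_threshold : float
        Pearson |r| threshold for train-fold feature pruning.
    """

    def __init__(self, table: FeatureTable, classifier: str = "stack",
                 prune_threshold: float = 0.98, n_inner_folds: int = 5,
                 decision_threshold: float = 0.5):
        self.table = table
        self.classifier = classifier
        self.prune_threshold = prune_threshold
        self.n_inner_folds = n_inner_folds
        self.decision_threshold = decision_threshold

    def fit(self, seed: int = 0) -> LosoResults:
        table = self.table
        y = table.y
        res = LosoResults(classifier=self.classifier)
        all_scores = np.full(len(table), np.nan)
        n_folds = len(pd.unique(table.subjects))
        fold_seeds = _substream_seeds(seed, n_folds)

        for fold, (subject, train, test) in enumerate(loso_split(table)):
            train_table = table.select_rows(
                np.isin(np.arange(len(table)), train))
            pruned_train, report = correlation_prune(train_table,
                                                     self.prune_threshold)
            kept = report.kept
            scaler = StandardScaler().fit(pruned_train.X)
            X_train = scaler.transform(pruned_train.X)
            X_test = scaler.transform(
                table.df.iloc[test][kept].to_numpy(dtype=float))

            kwargs = ({"n_inner_folds": self.n_inner_folds}
                      if self.classifier in ("stack", "mean") else {})
            model = make_classifier(self.classifier, seed=fold_seeds[fold],
                                    **kwargs)
            model.fit(X_train, y[train])
            scores = model.predict_proba(X_test)[:, 1]
            predicted = (scores >= self.decision_threshold).astype(int)

            cm = ConfusionMatrix.from_predictions(y[test], predicted)
            res.per_subject[subject] = {
                "confusion": cm,
                "metrics": compute_metrics(cm),
                "scores": scores,
                "labels": y[test],
            }
            res.pooled = res.pooled + cm
            res.fold_details[subject] = {
                "kept": kept,
                "prune_report": report,
                "scaler_mean": scaler.mean_.copy(),
                "scaler_scale": scaler.scale_.copy(),
            }
            all_scores[test] = scores

        res.labels = y
        res.scores = all_scores
        return res


def select_feature_set(table: FeatureTable, feature_set: str) -> FeatureTable:
    """Restrict to 'entropy' or 'rbp' feature columns."""
    if feature_set == "rbp":
        names = [n for n in table.feature_names if n.startswith("RBP_")]
    elif feature_set == "entropy":
        names = [n for n in table.feature_names if not n.startswith("RBP_")]
    else:
        raise ValueError("feature_set must be 'entropy' or 'rbp'")
    if not names:
        raise ValueError(f"table contains no {feature_set} features")
    return table.select_features(names)


def run_pipeline(recordings, seed: int = 0, classifier: str = "stack",
                 preprocess_config: PreprocessConfig | None = None,
                 entropy_config: EntropyConfig | None = None,
                 channel_sets=DEFAULT_CHANNEL_SETS, feature_set: str = "entropy",
                 include_rbp: bool = False, prune_threshold: float = 0.98,
                 n_inner_folds: int = 5,
                 ) -> tuple[FeatureTable, dict[tuple, LosoResults]]:
    """End-to-end run: preprocess -> features -> per-channel-set LOSO.

    Returns the full feature table (cached once, shared by all channel
    sets) and a mapping from channel-set tuple to :class:`LosoResults`.
    """
    epochs = []
    total_rejected = 0
    for rec in recordings:
        kept, rejected = preprocess_pipeline(rec, preprocess_config)
        epochs.extend(kept)
        total_rejected += rejected
    table = build_feature_table(epochs, entropy_config,
                                include_rbp=include_rbp or feature_set == "rbp")
    results: dict[tuple, LosoResults] = {}
    for chset in channel_sets:
        sub = select_feature_set(table, feature_set).channel_subset(
            tuple(chset))
        results[tuple(chset)] = LosoEvaluation(
            sub, classifier=classifier, prune_threshold=prune_threshold,
            n_inner_folds=n_inner_folds).fit(seed)
    return table, results
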