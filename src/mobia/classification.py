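"""Supervised facies classification of segmented objects.

Three classifier families are compared on the per-object feature table:
multinomial logistic regression (LR), a random forest (RF) and a fully
connected deep neural network (DNN, two hidden ReLU layers with a softmax
output).  Features are z-scored with statistics from the training split;
the standardiser travels with the model.

Accuracy is reported with both micro- and macro-averaged precision and
recall plus overall accuracy and average (mean one-vs-rest binary)
accuracy.  For single-label multiclass data micro precision, micro recall
and overall accuracy coincide by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .classes import DEFAULT_SCHEME, ClassScheme
from .features import FEATURE_COLUMNS
from .grid import ConfigurationError, DataError

__all__ = [
    "LabelledSet",
    "Classifier",
    "ClassificationResult",
    "MetricsBundle",
    "make_training_set",
    "split_train_test",
    "train",
    "predict",
    "evaluate",
]

MODEL_KINDS = ("LR", "RF", "DNN")


@dataclass
class LabelledSet:
    """Feature matrix with class labels for a set of segments."""

    segment_ids: np.ndarray
    features: pd.DataFrame  # rows aligned with segment_ids
    labels: np.ndarray  # class codes
    scheme: ClassScheme = DEFAULT_SCHEME

    def __post_init__(self):
        if self.scheme.excluded in set(self.labels):
            raise DataError("excluded class must not appear in a labelled set")
        if not np.isfinite(self.features.to_numpy(dtype=float)).all():
            raise DataError("features must be finite")

    @property
    def class_counts(self) -> dict[str, int]:
        vals, cnt = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), cnt.tolist()))

    def subset(self, idx: np.ndarray) -> "LabelledSet":
        return LabelledSet(
            self.segment_ids[idx],
            self.features.iloc[idx].reset_index(drop=True),
            self.labels[idx],
            self.scheme,
        )


@dataclass
class Classifier:
    kind: str
    model: object
    scaler: StandardScaler
    feature_names: list
    scheme: ClassScheme
    seed: int


@dataclass
class ClassificationResult:
    """Predicted class and class probabilities per segment."""

    labels: pd.Series  # class code per segment id
    proba: pd.DataFrame  # one column per scheme class, rows sum to 1


@dataclass
class MetricsBundle:
    overall_accuracy: float
    average_accuracy: float
    micro_precision: float
    macro_precision: float
    micro_recall: float
    macro_recall: float
    undefined_precision_classes: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "overall_accuracy": self.overall_accuracy,
            "average_accuracy": self.average_accuracy,
            "micro_precision": self.micro_precision,
            "macro_precision": self.macro_precision,
            "micro_recall": self.micro_recall,
            "macro_recall": self.macro_recall,
        }


# ---------------------------------------------------------------------------
# sampling and splitting
# ---------------------------------------------------------------------------


def _feature_matrix(table: pd.DataFrame, feature_names=None) -> pd.DataFrame:
    names = list(feature_names) if feature_names is not None else FEATURE_COLUMNS
    missing = [c for c in names if c not in table.columns]
    if missing:
        raise ConfigurationError(f"feature table lacks columns: {missing}")
    return table[names].astype(float)


def make_training_set(
    table: pd.DataFrame,
    labels: pd.Series,
    per_class: int = 150,
    seed: int = 0,
    scheme: ClassScheme = DEFAULT_SCHEME,
) -> LabelledSet:
    """Seeded balanced sampling of ``per_class`` objects per mapped class.

    Classes with fewer labelled objects are sampled with replacement and a
    warning; the excluded (OTHER) class is dropped entirely.
    """
    labels = labels.reindex(table.index)
    rng = np.random.default_rng(seed)
    sel_ids: list[np.ndarray] = []
    for code in scheme.codes:
        pool = np.asarray(table.index[labels == code])
        if pool.size == 0:
            raise ConfigurationError(f"class {code} has no labelled objects")
        if pool.size >= per_class:
            pick = rng.choice(pool, size=per_class, replace=False)
        else:
            warnings.warn(
                f"class {code}: only {pool.size} labelled objects; sampling "
                f"{per_class} with replacement",
                stacklevel=2,
            )
            pick = rng.choice(pool, size=per_class, replace=True)
        sel_ids.append(np.sort(pick))
    ids = np.concatenate(sel_ids)
    feats = _feature_matrix(table.loc[ids])
    y = np.asarray(labels.loc[ids])
    return LabelledSet(ids, feats.reset_index(drop=True), y, scheme)


def split_train_test(
    lset: LabelledSet, train_fraction: float = 0.15, seed: int = 0
) -> tuple[LabelledSet, LabelledSet]:
    """Stratified-by-class random split into exact train/test partition."""
    if not 0.0 < train_fraction < 1.0:
        raise ConfigurationError("train_fraction must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for code in np.unique(lset.labels):
        idx = np.flatnonzero(lset.labels == code)
        if idx.size < 2:
            raise ConfigurationError(
                f"class {code} has {idx.size} members; cannot stratify"
            )
        n_train = int(round(train_fraction * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        perm = rng.permutation(idx)
        train_idx.extend(perm[:n_train].tolist())
        test_idx.extend(perm[n_train:].tolist())
    return lset.subset(np.sort(train_idx)), lset.subset(np.sort(test_idx))


# ---------------------------------------------------------------------------
# training and prediction
# ---------------------------------------------------------------------------


def _make_estimator(kind: str, hyper: dict, seed: int):
    hyper = dict(hyper or {})
    if kind == "LR":
        return LogisticRegression(
            penalty="l2",
            C=hyper.pop("C", 1.0),
            max_iter=hyper.pop("max_iter", 2000),
            **hyper,
        )
    if kind == "RF":
        return RandomForestClassifier(
            n_estimators=hyper.pop("n_estimators", 100),
            max_features=hyper.pop("max_features", "sqrt"),
            random_state=seed,
            **hyper,
        )
    if kind == "DNN":
        return MLPClassifier(
            hidden_layer_sizes=hyper.pop("hidden_layer_sizes", (64, 64)),
            activation="relu",
            solver="adam",
            batch_size=hyper.pop("batch_size", 32),
            max_iter=hyper.pop("max_iter", 200),
            random_state=seed,
            **hyper,
        )
    raise ConfigurationError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")


def train(
    model_kind: str, train_set: LabelledSet, hyper: dict | None = None, seed: int = 0
) -> Classifier:
    """Fit one classifier on a labelled set (features z-scored internally)."""
    if train_set.labels.size == 0:
        raise ConfigurationError("training set is empty")
    X = train_set.features.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise DataError("non-finite features in training set")
    scaler = StandardScaler().fit(X)
    est = _make_estimator(model_kind, hyper or {}, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter on tiny toy sets
        est.fit(scaler.transform(X), train_set.labels)
    return Classifier(
        kind=model_kind,
        model=est,
        scaler=scaler,
        feature_names=list(train_set.features.columns),
        scheme=train_set.scheme,
        seed=seed,
    )


def predict(clf: Classifier, table: pd.DataFrame) -> ClassificationResult:
    """Per-object class probabilities and argmax class (scheme-order ties)."""
    X = _feature_matrix(table, clf.feature_names).to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise DataError("non-finite features in prediction table")
    p = clf.model.predict_proba(clf.scaler.transform(X))
    proba = pd.DataFrame(0.0, index=table.index, columns=list(clf.scheme.codes))
    for j, code in enumerate(clf.model.classes_):
        proba[code] = p[:, j]
    arg = proba.to_numpy().argmax(axis=1)  # first max = scheme order tie-break
    labels = pd.Series(
        [clf.scheme.codes[a] for a in arg], index=table.index, name="class"
    )
    return ClassificationResult(labels=labels, proba=proba)


# ---------------------------------------------------------------------------
# accuracy assessment
# ---------------------------------------------------------------------------


def evaluate(
    predicted, truth, scheme: ClassScheme = DEFAULT_SCHEME
) -> tuple[pd.DataFrame, MetricsBundle]:
    """Confusion matrix (rows true, columns predicted) and metric bundle."""
    y_pred = np.asarray(predicted)
    y_true = np.asarray(truth)
    if y_pred.shape != y_true.shape:
        raise DataError("prediction and truth vectors differ in length")
    codes = list(scheme.codes)
    index = {c: i for i, c in enumerate(codes)}
    bad = [v for v in np.unique(np.concatenate([y_true, y_pred])) if v not in index]
    if bad:
        raise DataError(f"labels outside the class scheme: {bad}")
    k = len(codes)
    cm = np.zeros((k, k), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        cm[index[t], index[p]] += 1
    total = cm.sum()
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    tn = total - tp - fp - fn

    overall = tp.sum() / total
    undefined = [codes[i] for i in range(k) if tp[i] + fp[i] == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        rec = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
    macro_p = prec.mean()
    macro_r = rec.mean()
    micro_p = tp.sum() / (tp.sum() + fp.sum())
    micro_r = tp.sum() / (tp.sum() + fn.sum())
    avg_acc = ((tp + tn) / total).mean()

    bundle = MetricsBundle(
        overall_accuracy=float(overall),
        average_accuracy=float(avg_acc),
        micro_precision=float(micro_p),
        macro_precision=float(macro_p),
        micro_recall=float(micro_r),
        macro_recall=float(macro_r),
        undefined_precision_classes=undefined,
    )
    cm_df = pd.DataFrame(cm, index=codes, columns=codes)
    cm_df.index.name = "true"
    cm_df.columns.name = "predicted"
    return cm_df, bundle
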