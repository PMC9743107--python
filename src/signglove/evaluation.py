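"""Leave-one-subject-out evaluation and multiclass metrics.

One fold per signer: the fold's test set is exactly that signer's
recordings, training uses everyone else, and the per-channel min-max
normalizer is fitted on the training signers only.  Test predictions from
all folds are pooled into a single confusion matrix by default (per-fold
metrics are also reported; a fold-averaged aggregation mode is available).

Metrics are the usual one-vs-rest counts per class i:

    precision_i = TP_i / (TP_i + FP_i)
    recall_i    = TP_i / (TP_i + FN_i)
    F1_i        = 2 precision_i recall_i / (precision_i + recall_i)

macro averages are unweighted means over classes, and accuracy is
micro-averaged precision, sum(TP) / total — which equals macro recall
exactly when class counts are balanced.  Zero-denominator classes score 0
with a warning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion_matrix

from . import models as _models
from .imu_preprocess import apply_normalizer, clean_recording, fit_normalizer
from .spatial_projection import make_projection_images

__all__ = [
    "EvaluationReport",
    "f1_from_precision_recall",
    "loocv_split",
    "confusion_from_labels",
    "per_class_metrics",
    "macro_metrics",
    "accuracy",
    "prepare_static_inputs",
    "prepare_dynamic_inputs",
    "run_loocv",
    "evaluate_parallel_model",
    "fit_baselines",
]


# -- metrics ----------------------------------------------------------------

def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def confusion_from_labels(y_true, y_pred, n_classes: int) -> np.ndarray:
    """K x K count matrix, rows true class, columns predicted."""
    return _sk_confusion_matrix(y_true, y_pred, labels=np.arange(n_classes))


def per_class_metrics(cm: np.ndarray) -> dict[str, np.ndarray]:
    """Per-class precision, recall and F1 from a confusion matrix."""
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2.0 * precision * recall / denom, 0.0)
    if np.any((tp + fp == 0) | (tp + fn == 0)):
        warnings.warn(
            "class(es) with zero denominator; metric set to 0", stacklevel=2
        )
    return {"precision": precision, "recall": recall, "f1": f1}


def macro_metrics(per_class: dict[str, np.ndarray]) -> dict[str, float]:
    """Unweighted arithmetic means of the per-class metrics."""
    if len(per_class["precision"]) == 0:
        raise ValueError("no classes")
    return {name: float(np.mean(vals)) for name, vals in per_class.items()}


def accuracy(cm: np.ndarray) -> float:
    """Micro-averaged precision: sum of diagonal counts over the total."""
    cm = np.asarray(cm)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm) / total)


@dataclass
class EvaluationReport:
    """Pooled confusion matrix, metrics, and the per-fold breakdown."""

    class_names: list[str]
    confusion: np.ndarray
    per_class: dict[str, np.ndarray]
    macro: dict[str, float]
    accuracy: float
    per_fold: list[dict] = field(default_factory=list)
    aggregation: str = "pooled"

    def to_dict(self) -> dict:
        return {
            "class_names": list(self.class_names),
            "confusion": np.asarray(self.confusion).tolist(),
            "per_class": {k: v.tolist() for k, v in self.per_class.items()},
            "macro": self.macro,
            "accuracy": self.accuracy,
            "per_fold": self.per_fold,
            "aggregation": self.aggregation,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "EvaluationReport":
        return cls(
            class_names=list(d["class_names"]),
            confusion=np.asarray(d["confusion"]),
            per_class={k: np.asarray(v) for k, v in d["per_class"].items()},
            macro=dict(d["macro"]),
            accuracy=float(d["accuracy"]),
            per_fold=list(d.get("per_fold", [])),
            aggregation=d.get("aggregation", "pooled"),
        )


def _report_from_counts(class_names, cm, per_fold, aggregation="pooled"):
    pcm = per_class_metrics(cm)
    if aggregation == "pooled":
        macro = macro_metrics(pcm)
        acc = accuracy(cm)
    elif aggregation == "fold_averaged":
        macro = {
            k: float(np.mean([f["macro"][k] for f in per_fold]))
            for k in ("precision", "recall", "f1")
        }
        acc = float(np.mean([f["accuracy"] for f in per_fold]))
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    return EvaluationReport(
        class_names=list(class_names),
        confusion=cm,
        per_class=pcm,
        macro=macro,
        accuracy=acc,
        per_fold=per_fold,
        aggregation=aggregation,
    )


# -- protocol ---------------------------------------------------------------

def loocv_split(recordings):
    """One fold per subject: (held-out subject, train recs, test recs)."""
    recordings = list(recordings)
    subjects = sorted({r.subject_id for r in recordings})
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    folds = []
    for subject in subjects:
        test = [r for r in recordings if r.subject_id == subject]
        train = [r for r in recordings if r.subject_id != subject]
        folds.append((subject, train, test))
    return folds


def run_loocv(
    recordings,
    fit_predict,
    class_names=None,
    aggregation: str = "pooled",
) -> EvaluationReport:
    """Run the protocol with any classifier.

    ``fit_predict(train_recs, test_recs, fold_index)`` returns predicted
    label names for the test recordings.  Test predictions are pooled across
    folds into one confusion matrix; per-fold metrics ride along.  Training
    failures propagate annotated with the fold's held-out subject.
    """
    recordings = list(recordings)
    kinds = {r.kind for r in recordings}
    if len(kinds) > 1:
        raise ValueError(
            "mixed static/dynamic recordings; evaluate each pipeline separately"
        )
    if class_names is None:
        class_names = sorted({r.gesture_label for r in recordings})
    label_to_idx = {c: i for i, c in enumerate(class_names)}
    k = len(class_names)
    pooled = np.zeros((k, k), dtype=int)
    per_fold = []
    for fold_index, (subject, train, test) in enumerate(loocv_split(recordings)):
        try:
            predicted = fit_predict(train, test, fold_index)
        except Exception as exc:  # annotate with fold identity
            raise RuntimeError(
                f"fold {fold_index} (held-out subject {subject}) failed"
            ) from exc
        y_true = [label_to_idx[r.gesture_label] for r in test]
        y_pred = [label_to_idx[p] for p in predicted]
        cm = confusion_from_labels(y_true, y_pred, k)
        pooled += cm
        fold_metrics = per_class_metrics(cm)
        per_fold.append(
            {
                "subject": subject,
                "n_test": len(test),
                "accuracy": accuracy(cm),
                "macro": macro_metrics(fold_metrics),
            }
        )
    return _report_from_counts(class_names, pooled, per_fold, aggregation)


# -- input preparation for the parallel-path models -------------------------

STATIC_CHANNELS = "earth"  # earth-frame linear acceleration joins the 5 flex


def _channel_stack(recs, normalizer, accel_attr: str):
    """(B, 1, n) arrays: 5 flex channels + 3 acceleration channels."""
    out = []
    normed = [apply_normalizer(normalizer, r) for r in recs]
    for c in range(5):
        out.append(np.stack([r.flex[:, c][None, :] for r in normed]))
    for c in range(3):
        out.append(
            np.stack([getattr(r, accel_attr)[:, c][None, :] for r in normed])
        )
    return out


def prepare_static_inputs(recs, normalizer, accel_attr: str = "accel_earth"):
    """8 per-channel input arrays for the static model (5 flex + 3 accel)."""
    return _channel_stack(recs, normalizer, accel_attr)


def prepare_dynamic_inputs(recs, normalizer, image_size: int = 224, stroke: int = 7):
    """3 projection-image arrays + 5 normalized flex arrays.

    Images are built from the cleaned earth-frame acceleration (their own
    per-axis path normalization makes min-max scaling redundant there); flex
    series use the fitted channel normalizer.
    """
    images = [
        make_projection_images(r, size=image_size, stroke=stroke).as_array()
        for r in recs
    ]
    stack = np.stack(images)  # (B, 3, S, S)
    image_inputs = [stack[:, i][:, None, :, :] for i in range(3)]
    normed = [apply_normalizer(normalizer, r) for r in recs]
    flex_inputs = [
        np.stack([r.flex[:, c][None, :] for r in normed]) for c in range(5)
    ]
    return image_inputs + flex_inputs


def evaluate_parallel_model(
    recordings,
    mode: str,
    cfg: _models.TrainConfig | None = None,
    spec1d: _models.Conv1DBlockSpec | None = None,
    spec2d: _models.Backbone2DSpec | None = None,
    image_size: int = 224,
    clean: bool = True,
    aggregation: str = "pooled",
) -> EvaluationReport:
    """LOOCV of the proposed parallel-path model (static or dynamic pipeline).

    Per fold: clean all recordings, fit the normalizer on the training
    signers, hold out a stratified validation split for early stopping,
    train, and predict the held-out signer.
    """
    if mode not in ("static", "dynamic"):
        raise ValueError("mode must be 'static' or 'dynamic'")
    cfg = cfg or _models.TrainConfig()
    recordings = list(recordings)
    if any(r.kind != mode for r in recordings):
        raise ValueError(f"all recordings must be {mode} for the {mode} pipeline")
    if clean:
        recordings = [
            clean_recording(r, ac_noise=bool(r.meta.get("ac_noise")))
            for r in recordings
        ]
    class_names = sorted({r.gesture_label for r in recordings})
    label_to_idx = {c: i for i, c in enumerate(class_names)}

    def prepare(recs, normalizer):
        if mode == "static":
            return prepare_static_inputs(recs, normalizer)
        return prepare_dynamic_inputs(recs, normalizer, image_size=image_size)

    def fit_predict(train, test, fold_index):
        rng = np.random.default_rng(cfg.seed + 1000 * fold_index)
        normalizer = fit_normalizer(train)
        labels = np.array([label_to_idx[r.gesture_label] for r in train])
        tr_idx, val_idx = _stratified_split(labels, cfg.val_fraction, rng)
        inputs = prepare(train, normalizer)
        if mode == "static":
            model = _models.build_static_model(
                rng, n_channels=8, n_classes=len(class_names), spec=spec1d
            )
        else:
            model = _models.build_dynamic_model(
                rng,
                n_classes=len(class_names),
                spec1d=spec1d,
                spec2d=spec2d,
                image_size=image_size,
            )
        fold_cfg = _models.TrainConfig(
            **{**cfg.__dict__, "seed": cfg.seed + 1000 * fold_index}
        )
        _models.train(
            model,
            [x[tr_idx] for x in inputs],
            labels[tr_idx],
            [x[val_idx] for x in inputs],
            labels[val_idx],
            fold_cfg,
        )
        pred_idx, _ = _models.predict(model, prepare(test, normalizer))
        return [class_names[i] for i in pred_idx]

    return run_loocv(recordings, fit_predict, class_names, aggregation)


def _stratified_split(labels: np.ndarray, val_fraction: float, rng):
    """Seeded stratified holdout: ~val_fraction of each class, at least 1."""
    tr, val = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        n_val = max(1, int(round(val_fraction * idx.size)))
        val.extend(idx[:n_val])
        tr.extend(idx[n_val:])
    return np.sort(tr), np.sort(val)


# -- baselines --------------------------------------------------------------

def fit_baselines(
    recordings,
    seed: int = 0,
    cnn_cfg: _models.TrainConfig | None = None,
    clean: bool = True,
) -> dict[str, EvaluationReport]:
    """Classical and single-path deep baselines under the same protocol.

    Logistic regression and random forest see flattened normalized channels;
    the 1D CNN baseline sees the stacked 18-channel series through a single
    ConvNet block (no parallel paths).
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.linear_model import LogisticRegression

    recordings = list(recordings)
    if clean:
        recordings = [
            clean_recording(r, ac_noise=bool(r.meta.get("ac_noise")))
            for r in recordings
        ]
    class_names = sorted({r.gesture_label for r in recordings})
    label_to_idx = {c: i for i, c in enumerate(class_names)}

    def flat_features(recs, normalizer):
        return np.stack(
            [apply_normalizer(normalizer, r).to_matrix().ravel() for r in recs]
        )

    def sklearn_fit_predict(make_clf):
        def fit_predict(train, test, fold_index):
            normalizer = fit_normalizer(train)
            clf = make_clf()
            clf.fit(
                flat_features(train, normalizer),
                [label_to_idx[r.gesture_label] for r in train],
            )
            pred = clf.predict(flat_features(test, normalizer))
            return [class_names[i] for i in pred]

        return fit_predict

    def cnn_fit_predict(train, test, fold_index):
        cfg = cnn_cfg or _models.TrainConfig(
            learning_rate=1e-3, max_epochs=30, patience=6, batch_size=16
        )
        rng = np.random.default_rng(seed + 1000 * fold_index)
        normalizer = fit_normalizer(train)

        def stacked(recs):
            return [
                np.stack(
                    [apply_normalizer(normalizer, r).to_matrix().T for r in recs]
                )
            ]

        labels = np.array([label_to_idx[r.gesture_label] for r in train])
        tr_idx, val_idx = _stratified_split(labels, cfg.val_fraction, rng)
        spec = _models.Conv1DBlockSpec()
        block = _models.conv1d_block(spec, rng, c_in=18, input_length=150)
        head = _models._head(rng, spec.embedding_dim, len(class_names))
        model = _models.ParallelPathModel(
            [block], head, [(18, 150)], len(class_names)
        )
        inputs = stacked(train)
        _models.train(
            model,
            [x[tr_idx] for x in inputs],
            labels[tr_idx],
            [x[val_idx] for x in inputs],
            labels[val_idx],
            _models.TrainConfig(**{**cfg.__dict__, "seed": seed + 1000 * fold_index}),
        )
        pred_idx, _ = _models.predict(model, stacked(test))
        return [class_names[i] for i in pred_idx]

    reports = {}
    reports["logistic_regression"] = run_loocv(
        recordings,
        sklearn_fit_predict(
            lambda: LogisticRegression(max_iter=2000, random_state=seed)
        ),
        class_names,
    )
    reports["random_forest"] = run_loocv(
        recordings,
        sklearn_fit_predict(
            lambda: RandomForestClassifier(n_estimators=200, random_state=seed)
        ),
        class_names,
    )
    reports["cnn_1d"] = run_loocv(recordings, cnn_fit_predict, class_names)
    return reports
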