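"""Patient-grouped, label-stratified cross-validation and its metrics.

Folds are stratified by label with patients grouped so that no patient
appears in both the training and validation set of any fold — spectra of
one surgical specimen are correlated, and splitting them across folds
would leak patient identity into the validation score.  Stratification
operates at patient granularity on each patient's majority target label
(a patient contributes spectra from several targets).

Reported metrics:

* one-vs-rest ROC AUC per class and their unweighted (macro) average,
  with tied scores given half credit;
* the multiclass confusion matrix (argmax of the score vector), as raw
  counts and row-normalized proportions;
* per-class binary confusion matrices at a 0.5 score threshold with
  recall, sensitivity, specificity, accuracy and precision.  Recall and
  sensitivity are synonymous for the positive class and are reported as
  two (equal) entries.

Two multiclass setups exist: 4-class (BCC structures only: EPI-H, EPI-T,
DER-H, LOB-T) and 5-class (adding TUM-T, with EPI-H merged across BCC and
SCC lesions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .models import TrainedModel, TrainingConfig, train
from .preprocess import ProcessedDataset
from .spectra import CLASS_ORDER_4, CLASS_ORDER_5

__all__ = [
    "FoldAssignment",
    "EvaluationReport",
    "CrossValidationResult",
    "make_grouped_stratified_folds",
    "ovr_auc",
    "confusion_matrix_multiclass",
    "binary_confusion_and_metrics",
    "cross_validate",
]


@dataclass
class FoldAssignment:
    """Patient-level fold assignment broadcast to spectra."""

    k: int
    spectrum_fold: np.ndarray  # (n_spectra,)
    patient_fold: dict[str, int]

    def __post_init__(self) -> None:
        folds = set(self.patient_fold.values())
        if not folds <= set(range(self.k)):
            raise ValueError("fold indices out of range")


def make_grouped_stratified_folds(
    patient_ids, labels, k: int = 5, seed: int = 0
) -> FoldAssignment:
    """Assign patients (and hence their spectra) to ``k`` folds.

    Each patient is represented by its majority label (ties broken by
    label sort order) and patients are split with stratified k-fold, so
    every spectrum of a patient shares the patient's fold and each fold's
    label mix approximates the global one as closely as patient
    granularity allows.
    """
    patient_ids = np.asarray(patient_ids)
    labels = np.asarray(labels)
    if patient_ids.shape != labels.shape:
        raise ValueError("patient_ids and labels must align")
    patients = pd.unique(patient_ids)
    if patients.size < k:
        raise ValueError(f"need at least {k} patients, got {patients.size}")

    majority = {}
    for pid in patients:
        counts = pd.Series(labels[patient_ids == pid]).value_counts()
        top = counts[counts == counts.max()].index
        majority[pid] = sorted(top)[0]
    strat = np.array([majority[p] for p in patients])

    with warnings.catch_warnings():
        # rare patient-level labels can fall below k members; stratification
        # is best-effort by construction
        warnings.simplefilter("ignore", UserWarning)
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        patient_fold: dict[str, int] = {}
        for fold, (_, val_idx) in enumerate(skf.split(np.zeros(patients.size), strat)):
            for i in val_idx:
                patient_fold[patients[i]] = fold

    spectrum_fold = np.array([patient_fold[p] for p in patient_ids])
    return FoldAssignment(k=k, spectrum_fold=spectrum_fold, patient_fold=patient_fold)


def ovr_auc(
    scores: np.ndarray, labels, class_order
) -> tuple[dict, float]:
    """One-vs-rest ROC AUC per class plus the macro (unweighted) average.

    Each class's AUC is the probability that a random positive outscores a
    random negative, ties counting half.  A class with no positives or no
    negatives gets ``nan`` and is excluded from the macro with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    per_class: dict = {}
    valid = []
    for j, cls in enumerate(class_order):
        pos = labels == cls
        if pos.all() or not pos.any():
            warnings.warn(f"class {cls!r} degenerate; AUC undefined", RuntimeWarning)
            per_class[cls] = float("nan")
            continue
        auc = float(roc_auc_score(pos.astype(int), scores[:, j]))
        per_class[cls] = auc
        valid.append(auc)
    macro = float(np.mean(valid)) if valid else float("nan")
    return per_class, macro


def confusion_matrix_multiclass(
    scores: np.ndarray, labels, class_order
) -> tuple[np.ndarray, np.ndarray]:
    """Counts and row-normalized proportions; predicted class = argmax score,
    rows indexed by ground truth in ``class_order``."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = list(class_order)
    pred = np.argmax(scores, axis=1)
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for i, cls in enumerate(classes):
        rows = pred[labels == cls]
        for j in range(len(classes)):
            counts[i, j] = int(np.sum(rows == j))
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        props = np.where(row_sums > 0, counts / row_sums, 0.0)
    return counts, props


def binary_confusion_and_metrics(
    scores: np.ndarray, labels, threshold: float = 0.5
) -> dict:
    """2x2 confusion matrix and metric set for one class-vs-rest task.

    ``labels`` are booleans (or 0/1) marking the positive class; a sample
    is predicted positive when its score exceeds ``threshold``.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    pred = scores > threshold
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    fn = int(np.sum(~pred & y))
    tn = int(np.sum(~pred & ~y))

    def _ratio(num: int, den: int) -> float:
        return num / den if den else float("nan")

    sens = _ratio(tp, tp + fn)
    metrics = {
        "recall": sens,  # synonym of sensitivity for the positive class
        "sensitivity": sens,
        "specificity": _ratio(tn, tn + fp),
        "accuracy": _ratio(tp + tn, tp + fp + fn + tn),
        "precision": _ratio(tp, tp + fp),
    }
    matrix = np.array([[tp, fn], [fp, tn]], dtype=int)
    return {"matrix": matrix, "tp": tp, "fp": fp, "fn": fn, "tn": tn, **metrics}


@dataclass
class EvaluationReport:
    """Aggregated out-of-fold evaluation of one model/setup."""

    class_order: tuple[str, ...]
    auc_per_class: dict
    macro_auc: float
    confusion_counts: np.ndarray
    confusion_props: np.ndarray
    binary_metrics: dict  # class -> metric dict (threshold 0.5)
    n_spectra: int
    n_excluded: int = 0

    def summary(self) -> str:
        lines = [
            f"classes: {', '.join(self.class_order)}",
            f"spectra evaluated: {self.n_spectra} (excluded: {self.n_excluded})",
            f"macro one-vs-rest AUC: {self.macro_auc:.4f}",
            "",
            "per-class metrics (one-vs-rest, threshold 0.5):",
            f"{'class':>8} {'AUC':>7} {'recall':>7} {'sens':>7} {'spec':>7} "
            f"{'acc':>7} {'prec':>7}",
        ]
        for cls in self.class_order:
            m = self.binary_metrics[cls]
            lines.append(
                f"{cls:>8} {self.auc_per_class[cls]:>7.4f} {m['recall']:>7.4f} "
                f"{m['sensitivity']:>7.4f} {m['specificity']:>7.4f} "
                f"{m['accuracy']:>7.4f} {m['precision']:>7.4f}"
            )
        lines.append("")
        lines.append("confusion matrix (rows = truth, count (row proportion)):")
        header = " ".join(f"{c:>16}" for c in self.class_order)
        lines.append(f"{'':>8} {header}")
        for i, cls in enumerate(self.class_order):
            cells = " ".join(
                f"{self.confusion_counts[i, j]:>6d} ({self.confusion_props[i, j]:>6.1%})"
                for j in range(len(self.class_order))
            )
            lines.append(f"{cls:>8} {cells}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "class_order": list(self.class_order),
            "auc_per_class": {k: float(v) for k, v in self.auc_per_class.items()},
            "macro_auc": float(self.macro_auc),
            "confusion_counts": self.confusion_counts.tolist(),
            "confusion_props": self.confusion_props.tolist(),
            "binary_metrics": {
                cls: {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                      for k, v in m.items()}
                for cls, m in self.binary_metrics.items()
            },
            "n_spectra": self.n_spectra,
            "n_excluded": self.n_excluded,
        }


@dataclass
class CrossValidationResult:
    report: EvaluationReport
    oof_scores: np.ndarray  # (n_spectra, n_classes), out-of-fold
    labels: np.ndarray
    folds: FoldAssignment
    class_order: tuple[str, ...]
    manifest: pd.DataFrame
    models: list[TrainedModel] = field(default_factory=list)
    indices: np.ndarray | None = None  # rows of the input kept for this setup


def _report_from_scores(
    scores: np.ndarray, labels: np.ndarray, class_order, n_excluded: int
) -> EvaluationReport:
    auc_per_class, macro = ovr_auc(scores, labels, class_order)
    counts, props = confusion_matrix_multiclass(scores, labels, class_order)
    binary = {
        cls: binary_confusion_and_metrics(scores[:, j], labels == cls)
        for j, cls in enumerate(class_order)
    }
    return EvaluationReport(
        class_order=tuple(class_order),
        auc_per_class=auc_per_class,
        macro_auc=macro,
        confusion_counts=counts,
        confusion_props=props,
        binary_metrics=binary,
        n_spectra=len(labels),
        n_excluded=n_excluded,
    )


def cross_validate(
    processed: ProcessedDataset,
    model_kind: str = "cnn",
    classes: int = 5,
    config: TrainingConfig | None = None,
    k: int = 5,
    seed: int = 0,
    keep_models: bool = True,
) -> CrossValidationResult:
    """Patient-grouped stratified k-fold evaluation of one model kind.

    Every spectrum is scored exactly once, by the fold model that never
    saw its patient; the report aggregates the out-of-fold scores.  For
    ``classes=4`` the dataset is restricted to BCC-lesion spectra (SCC
    spectra are excluded and counted in ``report.n_excluded``).
    """
    if classes not in (4, 5):
        raise ValueError("classes must be 4 or 5")
    config = config or TrainingConfig(seed=seed)
    class_order = CLASS_ORDER_4 if classes == 4 else CLASS_ORDER_5
    manifest = processed.manifest.reset_index(drop=True)
    keep = manifest["target"].isin(class_order).to_numpy()
    if classes == 4:
        keep &= (manifest["lesion"] == "BCC").to_numpy()
    n_excluded = int((~keep).sum())
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        raise ValueError("no spectra match the requested class setup")
    X = processed.features[idx]
    sub = manifest.iloc[idx].reset_index(drop=True)
    y = sub["target"].to_numpy()
    missing = set(class_order) - set(y)
    if missing:
        raise ValueError(f"dataset lacks classes {sorted(missing)}")

    folds = make_grouped_stratified_folds(sub["patient_id"].to_numpy(), y, k=k, seed=seed)
    oof = np.full((idx.size, len(class_order)), np.nan)
    models: list[TrainedModel] = []
    order_arr = np.array(class_order)
    for fold in range(k):
        val = folds.spectrum_fold == fold
        tr = ~val
        tr_patients = set(sub.loc[tr, "patient_id"])
        val_patients = set(sub.loc[val, "patient_id"])
        assert not (tr_patients & val_patients), "patient leakage across folds"
        model = train(model_kind, X[tr], y[tr], config)
        scores = model.predict_scores(X[val])
        # align score columns to the canonical class order
        col = {cls: j for j, cls in enumerate(model.classes)}
        aligned = np.zeros((scores.shape[0], len(class_order)))
        for j, cls in enumerate(class_order):
            if cls in col:
                aligned[:, j] = scores[:, col[cls]]
        oof[val] = aligned
        if keep_models:
            models.append(model)
    assert not np.isnan(oof).any(), "out-of-fold coverage incomplete"

    report = _report_from_scores(oof, y, class_order, n_excluded)
    return CrossValidationResult(
        report=report,
        oof_scores=oof,
        labels=y,
        folds=folds,
        class_order=tuple(class_order),
        manifest=sub,
        models=models,
        indices=idx,
    )
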