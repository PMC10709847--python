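"""Hierarchical top-k^2 prediction and evaluation metrics.

Routing: the k highest-probability groups are taken from the first layer;
each selected singleton group contributes its single type directly, while
each selected multi-type group contributes the top-min(k, group size)
types from its second-layer model.  The candidate set is the union, so at
the default k = 2 its size is between 2 and 4.  The top-1 prediction
routes through the argmax group only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support, roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

from .classifier import HierarchicalModel, ForestConfig, LayerModel, train_layer

logger = logging.getLogger("methtree")


@dataclass
class PredictionResult:
    """Ranked per-layer probabilities and the candidate diagnosis set."""

    sample_id: str
    layer1_probs: list[tuple[str, float]]
    layer2_probs: dict[str, list[tuple[str, float]]]
    candidate_set: list[str]
    top1_type: str


def _ranked(probs: pd.Series) -> list[tuple[str, float]]:
    # stable ranking: descending probability, ties by class label
    order = sorted(probs.index, key=lambda c: (-probs[c], c))
    return [(c, float(probs[c])) for c in order]


def predict_batch(model: HierarchicalModel, matrix: pd.DataFrame, k: int = 2) -> list[PredictionResult]:
    """Top-k^2 routing for every sample column of ``matrix``."""
    if k < 1:
        raise ValueError("k must be >= 1")
    probs1 = model.layer1.predict_proba(matrix)
    # second-layer probabilities computed once per group actually selected
    selected_groups: set[str] = set()
    ranked1 = {sid: _ranked(probs1.loc[sid]) for sid in probs1.index}
    for sid in probs1.index:
        for grp, _ in ranked1[sid][:k]:
            if len(model.assignment.classes_in_group(grp)) > 1:
                selected_groups.add(grp)
    probs2: dict[str, pd.DataFrame] = {}
    for grp in sorted(selected_groups):
        if grp not in model.layer2:
            raise ValueError(f"selected multi-type group {grp} has no layer-2 model")
        probs2[grp] = model.layer2[grp].predict_proba(matrix)

    results = []
    for sid in probs1.index:
        top_groups = ranked1[sid][:k]
        layer2_ranked: dict[str, list[tuple[str, float]]] = {}
        candidates: list[str] = []
        top1_type = None
        for rank, (grp, _) in enumerate(top_groups):
            members = model.assignment.classes_in_group(grp)
            if len(members) == 1:
                picks = [(members[0], 1.0)]
            else:
                ranked2 = _ranked(probs2[grp].loc[sid])
                layer2_ranked[grp] = ranked2
                picks = ranked2[: min(k, len(members))]
            for cls, _ in picks:
                if cls not in candidates:
                    candidates.append(cls)
            if rank == 0:
                top1_type = picks[0][0]
        results.append(PredictionResult(
            sample_id=str(sid),
            layer1_probs=ranked1[sid],
            layer2_probs=layer2_ranked,
            candidate_set=candidates,
            top1_type=top1_type,
        ))
    return results


def predict_topk2(model: HierarchicalModel, sample: pd.Series, k: int = 2,
                  sample_id: str = "sample") -> PredictionResult:
    """Top-k^2 routing for a single sample (a probe-indexed Series)."""
    matrix = sample.to_frame(name=sample_id)
    return predict_batch(model, matrix, k=k)[0]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def _check_aligned(predictions: Sequence[PredictionResult], truths: Sequence[str]):
    if len(predictions) != len(truths):
        raise ValueError(
            f"{len(predictions)} predictions vs {len(truths)} truth labels")


def topk2_accuracy(predictions: Sequence[PredictionResult],
                   truths: Sequence[str]) -> float:
    """Fraction of samples whose true label is in the candidate set."""
    _check_aligned(predictions, truths)
    hits = sum(t in p.candidate_set for p, t in zip(predictions, truths))
    return hits / len(predictions)


def top1_accuracy(predictions: Sequence[PredictionResult],
                  truths: Sequence[str]) -> float:
    _check_aligned(predictions, truths)
    hits = sum(t == p.top1_type for p, t in zip(predictions, truths))
    return hits / len(predictions)


@dataclass
class EvaluationReport:
    """Per-class and overall metrics of a prediction batch."""

    accuracy: float
    topk2: float
    per_class: pd.DataFrame          # precision, recall, support per class
    confusion: pd.DataFrame          # rows = truth, columns = predicted
    cv_scores: list[float] = field(default_factory=list)
    auc_per_class: dict[str, float] = field(default_factory=dict)
    auc_macro: float | None = None


def classification_report(predictions: Sequence[PredictionResult],
                          truths: Sequence[str]) -> EvaluationReport:
    """Precision/recall/confusion computed on the top-1 routed predictions."""
    _check_aligned(predictions, truths)
    y_true = list(truths)
    y_pred = [p.top1_type for p in predictions]
    labels = sorted(set(y_true) | set(y_pred))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prec, rec, _, support = precision_recall_fscore_support(
            y_true, y_pred, labels=labels, zero_division=0)
    per_class = pd.DataFrame(
        {"precision": prec, "recall": rec, "support": support}, index=labels)
    conf = pd.DataFrame(confusion_matrix(y_true, y_pred, labels=labels),
                        index=labels, columns=labels)
    return EvaluationReport(
        accuracy=top1_accuracy(predictions, truths),
        topk2=topk2_accuracy(predictions, truths),
        per_class=per_class,
        confusion=conf,
    )


def kfold_cv(matrix: pd.DataFrame, labels: pd.Series, panel: Sequence[str],
             config: ForestConfig, k_folds: int = 5,
             seed: int = 0) -> list[float]:
    """Stratified k-fold cross-validated accuracy of one layer.

    Classes smaller than ``k_folds`` force a fallback to unstratified
    folds (with a warning) so every sample still appears in exactly one
    validation fold.
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    labels = labels.reindex(matrix.columns)
    y = labels.to_numpy()
    counts = labels.value_counts()
    if counts.min() < k_folds:
        logger.warning(
            "class %s has %d < %d samples; falling back to unstratified folds",
            counts.idxmin(), int(counts.min()), k_folds)
        splitter = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(np.arange(len(y)))
    else:
        splitter = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(np.arange(len(y)), y)

    scores = []
    cols = np.array(matrix.columns)
    for train_idx, val_idx in split_iter:
        if len(np.unique(y[train_idx])) < 2:
            raise ValueError("a fold's training part has a single class")
        model = train_layer(matrix[cols[train_idx]],
                            labels.iloc[train_idx], panel, config)
        probs = model.predict_proba(matrix[cols[val_idx]])
        pred = probs.idxmax(axis=1).to_numpy()
        scores.append(float((pred == y[val_idx]).mean()))
    return scores


def ovr_auc(layer_model: LayerModel, matrix: pd.DataFrame,
            truths: Sequence[str]) -> tuple[dict[str, float], float]:
    """One-vs-rest AUC per class from ranked probabilities, plus the macro
    average.  Classes absent from the test set are excluded with a warning."""
    probs = layer_model.predict_proba(matrix)
    y = np.asarray(list(truths))
    if len(y) != probs.shape[0]:
        raise ValueError("truth labels misaligned with matrix samples")
    per_class: dict[str, float] = {}
    for cls in layer_model.classes:
        mask = (y == cls)
        if mask.all() or not mask.any():
            logger.warning("class %s absent (or universal) in test set; AUC skipped", cls)
            continue
        per_class[cls] = float(roc_auc_score(mask.astype(int), probs[cls].to_numpy()))
    if not per_class:
        raise ValueError("no class with both positives and negatives in test set")
    macro = float(np.mean(list(per_class.values())))
    return per_class, macro


def write_predictions(predictions: Sequence[PredictionResult], path) -> None:
    """TSV with candidate columns, top-1 call and layer-1 probabilities."""
    import json as _json

    max_c = max((len(p.candidate_set) for p in predictions), default=0)
    rows = []
    for p in predictions:
        row = {"sample_id": p.sample_id}
        for i in range(max_c):
            row[f"candidate_{i + 1}"] = (
                p.candidate_set[i] if i < len(p.candidate_set) else "")
        row["top1"] = p.top1_type
        row["layer1_probs"] = _json.dumps(
            {g: round(v, 6) for g, v in p.layer1_probs})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
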