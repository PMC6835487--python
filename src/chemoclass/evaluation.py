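"""Classifier evaluation for heavily imbalanced class ratios.

Performance of each per-class classifier is summarized by the area under
the precision-recall curve (AUC-PR) and by the sensitivity at the operating
point where 5% of background (negative) spectra are accepted, i.e. at 95%
specificity.  The latter is reported as ``tpr_fnr``.  Evaluation uses
compound-grouped k-fold cross-validation so near-identical replicate
spectra of one structure never straddle the train/test boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .classification import (ABUNDANCE_THRESHOLD, BIN_WIDTH, score_many,
                             train, vectorize)
from .ontology import MIN_FOREGROUND, Ontology, ReferenceSpectrum

logger = logging.getLogger("chemoclass")


@dataclass(frozen=True)
class EvaluationResult:
    class_id: str
    auc_pr: float
    tpr_fnr: float
    n_pos: int
    n_neg: int
    curve: tuple[tuple[float, float], ...]  # (recall, precision) points


def pr_curve(scores: Sequence[float], labels: Sequence[bool]
             ) -> list[tuple[float, float]]:
    """Precision-recall points swept over all distinct score thresholds.

    Thresholds descend; at each, predictions with score >= threshold are
    positive.  Tied scores enter the confusion matrix as one block.
    Returns (recall, precision) with recall non-decreasing.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and the same length")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0:
        raise ValueError("PR curve undefined without positive instances")
    if n_neg == 0:
        raise ValueError("PR curve degenerate without negative instances")

    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    l_sorted = labels[order]
    # block boundaries: last index of each tied-score run
    boundaries = np.nonzero(np.diff(s_sorted) != 0)[0]
    ends = np.append(boundaries, s_sorted.size - 1)

    tp_cum = np.cumsum(l_sorted)
    pred_cum = np.arange(1, s_sorted.size + 1)
    points = []
    for e in ends:
        tp = int(tp_cum[e])
        pred = int(pred_cum[e])
        points.append((tp / n_pos, tp / pred))
    return points


def auc_pr(curve: Sequence[tuple[float, float]]) -> float:
    """Area under a PR curve by right-continuous step integration.

    Equals ``sum over threshold steps of (R_i - R_{i-1}) * P_i`` (average
    precision); recall starts at 0.
    """
    area = 0.0
    prev_r = 0.0
    for r, p in curve:
        if r < prev_r - 1e-12:
            raise ValueError("curve recall must be non-decreasing")
        area += (r - prev_r) * p
        prev_r = r
    return float(area)


def tpr_at_rate(scores: Sequence[float], labels: Sequence[bool],
                rate: float = 0.05) -> float:
    """Sensitivity at the operating point accepting <= ``rate`` negatives.

    The smallest (most permissive) score threshold is chosen such that the
    fraction of negatives scoring >= threshold does not exceed ``rate``;
    the returned value is TP at that threshold divided by the number of
    positives.  Tied scores cross the threshold together.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0:
        raise ValueError("undefined without positive instances")
    if n_neg == 0:
        raise ValueError("undefined without negative instances")

    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    l_sorted = labels[order]
    boundaries = np.nonzero(np.diff(s_sorted) != 0)[0]
    ends = np.append(boundaries, s_sorted.size - 1)
    tp_cum = np.cumsum(l_sorted)
    fp_cum = np.cumsum(~l_sorted)

    best_tp = 0
    for e in ends:
        if fp_cum[e] / n_neg <= rate:
            best_tp = int(tp_cum[e])
        else:
            break
    return best_tp / n_pos


def _compound_folds(library: Sequence[ReferenceSpectrum], k: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Fold index per spectrum; all spectra of one compound share a fold."""
    compounds = sorted({r.compound_id for r in library})
    perm = rng.permutation(len(compounds))
    fold_of_compound = {compounds[j]: int(perm[j] % k) for j in range(len(compounds))}
    return np.array([fold_of_compound[r.compound_id] for r in library])


def cross_validate(library: Sequence[ReferenceSpectrum], ontology: Ontology,
                   class_ids: Sequence[str] | None = None, k: int = 5,
                   seed: int = 0, w: float = BIN_WIDTH,
                   threshold: float = ABUNDANCE_THRESHOLD,
                   rate: float = 0.05) -> list[EvaluationResult]:
    """Compound-grouped k-fold cross-validation of every per-class model.

    For each class, models are trained on k-1 folds and held-out spectra
    scored; out-of-fold scores are pooled over folds and summarized by
    AUC-PR and sensitivity at 5% background acceptance.  Classes whose
    foreground is smaller than ``max(k, MIN_FOREGROUND)`` (or empty
    background) are reported with both metrics 0, the convention for
    "could not assign enough spectra".
    """
    if k < 2:
        raise ValueError("k-fold cross-validation needs k >= 2")
    rng = np.random.default_rng(seed)
    folds = _compound_folds(library, k, rng)
    if class_ids is None:
        class_ids = ontology.ids

    from .ontology import build_split

    results = []
    for cid in class_ids:
        labels_all = np.array([cid in r.class_lineage for r in library])
        n_pos_total = int(labels_all.sum())
        n_neg_total = labels_all.size - n_pos_total
        if n_pos_total < max(k, MIN_FOREGROUND) or n_neg_total == 0:
            results.append(EvaluationResult(cid, 0.0, 0.0, n_pos_total,
                                            n_neg_total, ()))
            continue

        pooled_scores: list[np.ndarray] = []
        pooled_labels: list[np.ndarray] = []
        degenerate = False
        for fold in range(k):
            test_idx = np.nonzero(folds == fold)[0]
            train_idx = np.nonzero(folds != fold)[0]
            if test_idx.size == 0:
                continue
            train_lib = [library[i] for i in train_idx]
            split = build_split(train_lib, cid, ontology)
            if not split.trainable:
                degenerate = True
                break
            model = train(split, w=w, threshold=threshold)
            vecs = [vectorize(library[i].spectrum, w, threshold) for i in test_idx]
            pooled_scores.append(score_many(model, vecs))
            pooled_labels.append(labels_all[test_idx])
        if degenerate:
            results.append(EvaluationResult(cid, 0.0, 0.0, n_pos_total,
                                            n_neg_total, ()))
            continue

        scores = np.concatenate(pooled_scores)
        labels = np.concatenate(pooled_labels)
        curve = pr_curve(scores, labels)
        results.append(EvaluationResult(
            class_id=cid,
            auc_pr=auc_pr(curve),
            tpr_fnr=tpr_at_rate(scores, labels, rate=rate),
            n_pos=n_pos_total,
            n_neg=n_neg_total,
            curve=tuple(curve),
        ))
    return results


def evaluation_frame(results: Sequence[EvaluationResult],
                     ontology: Ontology | None = None) -> pd.DataFrame:
    """Per-class metric table (class name, id, AUC-PR, TPR-FNR, sizes)."""
    rows = []
    for r in results:
        rows.append({
            "class_name": ontology.name(r.class_id) if ontology else r.class_id,
            "chemont_id": r.class_id,
            "auc_pr": r.auc_pr,
            "tpr_fnr": r.tpr_fnr,
            "n_pos": r.n_pos,
            "n_neg": r.n_neg,
        })
    return pd.DataFrame(rows)
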