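"""Classification metrics and the cross-/external-validation protocols.

Internal validation is patient-grouped five-fold cross-validation repeated
with different seeds: all slides of a patient share a fold, folds are dealt
round-robin after a seeded patient shuffle so patient counts differ by at
most one.  External validation trains on a full discovery cohort (threshold
selected on the discovery slide scores) and evaluates once per repeat seed
on a disjoint test cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .io import CohortTable
from .model import ModelConfig, OMTModel, predict_slide, select_threshold, train


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.tn + self.fp + self.fn < 1:
            raise ValueError("confusion counts are all zero")


@dataclass(frozen=True)
class CVPlan:
    n_folds: int = 5
    n_repeats: int = 3
    seeds: tuple[int, ...] = (0, 1, 2)

    def __post_init__(self) -> None:
        if len(self.seeds) != self.n_repeats:
            raise ValueError("need one seed per repeat")


def metrics(counts: ConfusionCounts) -> dict:
    """F1, recall (sensitivity), fall-out (FPR) and precision from counts.

    Degenerate denominators yield 0 together with ``degenerate=True`` rather
    than NaN.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    degenerate = (tp + fn == 0) or (fp + tn == 0) or (tp + fp == 0)
    recall = tp / (tp + fn) if tp + fn else 0.0
    fallout = fp / (fp + tn) if fp + tn else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {
        "f1": f1,
        "recall": recall,
        "fallout": fallout,
        "precision": precision,
        "degenerate": degenerate,
    }


def confusion(
    scores: Sequence[float], labels: Sequence[int], threshold: float
) -> ConfusionCounts:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = (scores >= threshold).astype(int)
    return ConfusionCounts(
        tp=int(((pred == 1) & (labels == 1)).sum()),
        tn=int(((pred == 0) & (labels == 0)).sum()),
        fp=int(((pred == 1) & (labels == 0)).sum()),
        fn=int(((pred == 0) & (labels == 1)).sum()),
    )


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve (= normalised Mann-Whitney U, ties half)."""
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("AUROC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def grouped_kfold(
    cohort: CohortTable, n_folds: int = 5, seed: int = 0
) -> np.ndarray:
    """Fold index per slide; all slides of a patient share a fold.

    Patients are shuffled with the repeat seed and dealt round-robin, so
    fold patient counts differ by at most one.
    """
    patients = list(dict.fromkeys(cohort.patient_ids))  # stable unique order
    if len(patients) < n_folds:
        raise ValueError(f"{len(patients)} patients < {n_folds} folds")
    rng = np.random.default_rng(seed)
    shuffled = [patients[i] for i in rng.permutation(len(patients))]
    fold_of_patient = {p: i % n_folds for i, p in enumerate(shuffled)}
    return np.array([fold_of_patient[p] for p in cohort.patient_ids], dtype=int)


def _fit_and_score(
    train_feats: list[np.ndarray],
    train_labels: np.ndarray,
    test_feats: list[np.ndarray],
    test_ids: list[str],
    config: ModelConfig,
) -> tuple[OMTModel, np.ndarray, float]:
    """Train, pick tau on training-slide scores, score test slides."""
    model = train(train_feats, train_labels, config)
    train_scores = np.array(
        [predict_slide(model, f).omt_score for f in train_feats]
    )
    tau = select_threshold(train_scores, train_labels)
    model.threshold = tau
    test_scores = np.array(
        [predict_slide(model, f, sid).omt_score for f, sid in zip(test_feats, test_ids)]
    )
    return model, test_scores, tau


def _summarise(per_fold: list[dict]) -> dict:
    keys = ["f1", "recall", "fallout", "precision", "auroc"]
    return {
        k: {
            "mean": float(np.nanmean([m[k] for m in per_fold])),
            "sd": float(np.nanstd([m[k] for m in per_fold])),
        }
        for k in keys
    }


def run_internal_cv(
    slide_features: dict[str, np.ndarray],
    cohort: CohortTable,
    config: ModelConfig,
    plan: CVPlan = CVPlan(),
) -> dict:
    """Patient-grouped repeated k-fold CV of the IDaRS MLP.

    Returns per-slide held-out scores (one row per slide x repeat), per-fold
    metrics, their mean (sd) summary across folds x repeats, and the pooled
    confusion counts.
    """
    labels = cohort.labels()
    ids = cohort.slide_ids
    rows, fold_metrics = [], []
    pooled = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}

    for repeat, seed in enumerate(plan.seeds):
        folds = grouped_kfold(cohort, plan.n_folds, seed)
        for fold in range(plan.n_folds):
            test_mask = folds == fold
            tr_ids = [i for i, m in zip(ids, test_mask) if not m]
            te_ids = [i for i, m in zip(ids, test_mask) if m]
            cfg = ModelConfig(**{**config.__dict__, "seed": config.seed + 1000 * repeat + fold})
            _, te_scores, tau = _fit_and_score(
                [slide_features[i] for i in tr_ids],
                labels[~test_mask],
                [slide_features[i] for i in te_ids],
                te_ids,
                cfg,
            )
            te_labels = labels[test_mask]
            counts = confusion(te_scores, te_labels, tau)
            m = metrics(counts)
            m["auroc"] = (
                auroc(te_scores, te_labels)
                if len(set(te_labels.tolist())) == 2
                else np.nan
            )
            fold_metrics.append(m)
            for k in pooled:
                pooled[k] += getattr(counts, k)
            rows += [
                {
                    "slide_id": sid,
                    "repeat": repeat,
                    "fold": fold,
                    "omt_score": sc,
                    "label": int(lb),
                    "prediction": int(sc >= tau),
                }
                for sid, sc, lb in zip(te_ids, te_scores, te_labels)
            ]

    return {
        "slide_scores": pd.DataFrame(rows),
        "fold_metrics": fold_metrics,
        "summary": _summarise(fold_metrics),
        "pooled_counts": ConfusionCounts(**pooled),
    }


def run_external_validation(
    train_features: dict[str, np.ndarray],
    train_cohort: CohortTable,
    test_features: dict[str, np.ndarray],
    test_cohort: CohortTable,
    config: ModelConfig,
    n_repeats: int = 3,
) -> dict:
    """Train on the discovery cohort, evaluate on a disjoint test cohort."""
    overlap = set(train_cohort.slide_ids) & set(test_cohort.slide_ids)
    if overlap:
        raise ValueError(f"cohorts overlap: {sorted(overlap)}")
    tr_ids, te_ids = train_cohort.slide_ids, test_cohort.slide_ids
    tr_labels, te_labels = train_cohort.labels(), test_cohort.labels()

    repeat_metrics, rows = [], []
    for repeat in range(n_repeats):
        cfg = ModelConfig(**{**config.__dict__, "seed": config.seed + repeat})
        _, te_scores, tau = _fit_and_score(
            [train_features[i] for i in tr_ids],
            tr_labels,
            [test_features[i] for i in te_ids],
            te_ids,
            cfg,
        )
        m = metrics(confusion(te_scores, te_labels, tau))
        m["auroc"] = auroc(te_scores, te_labels)
        repeat_metrics.append(m)
        rows += [
            {
                "slide_id": sid,
                "repeat": repeat,
                "fold": -1,
                "omt_score": sc,
                "label": int(lb),
                "prediction": int(sc >= tau),
            }
            for sid, sc, lb in zip(te_ids, te_scores, te_labels)
        ]
    return {
        "slide_scores": pd.DataFrame(rows),
        "repeat_metrics": repeat_metrics,
        "summary": _summarise(repeat_metrics),
    }
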