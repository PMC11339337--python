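"""Replicate-aware leave-one-out cross-validation and accuracy reporting.

Each sample is predicted once by a model trained on all samples whose
replicate group differs from the test sample's group, so technical and
biological replicates of the test sample never leak into training. The gene
filter and feature standardization are likewise refit on each training fold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import RunConfig
from .matrix import ExpressionMatrix, filter_genes
from .model import PredictionResult, fit_composite, predict

logger = logging.getLogger(__name__)


@dataclass
class FoldRecord:
    """Provenance of one cross-validation fold, kept for leakage audits."""

    sample_id: str
    group_id: str
    train_samples: Tuple[str, ...]
    train_groups: frozenset
    gene_set: Tuple[str, ...]


@dataclass
class EvaluationReport:
    """Aggregated cross-validation results against ground-truth labels."""

    results: List[PredictionResult]
    truths: Dict[str, str]
    confusion_matrix: pd.DataFrame
    overall_accuracy: float
    per_class_accuracy: Dict[str, float]
    tier_table: Dict[float, Dict[str, float]]
    folds: List[FoldRecord] = field(default_factory=list)
    skipped: List[Tuple[str, str]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "overall_accuracy": self.overall_accuracy,
            "per_class_accuracy": self.per_class_accuracy,
            "tier_table": {str(t): row for t, row in self.tier_table.items()},
            "confusion_matrix": {
                truth: {pred: int(n) for pred, n in row.items()}
                for truth, row in self.confusion_matrix.iterrows()
            },
            "n_samples": len(self.results),
            "skipped": [list(s) for s in self.skipped],
            "predictions": [r.to_dict() | {"truth": self.truths[r.sample_id]} for r in self.results],
        }


def confusion(
    results: Sequence[PredictionResult],
    truths: Dict[str, str],
    classes: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Truth (rows) × predicted (columns) count matrix."""
    if not results:
        raise ValueError("confusion matrix of empty results")
    if classes is None:
        classes = sorted(set(truths.values()) | {r.called_class for r in results})
    mat = pd.DataFrame(0, index=list(classes), columns=list(classes), dtype=int)
    for r in results:
        mat.loc[truths[r.sample_id], r.called_class] += 1
    return mat


def tier_report(
    results: Sequence[PredictionResult],
    truths: Dict[str, str],
    thresholds: Sequence[float] = (0.5, 0.6, 0.8),
) -> Dict[float, Dict[str, float]]:
    """Per probability threshold t (strict >): fraction of samples called above
    t, and accuracy among them (None when nothing clears the bar)."""
    if not results:
        raise ValueError("tier report of empty results")
    table: Dict[float, Dict[str, float]] = {}
    n = len(results)
    for t in thresholds:
        above = [r for r in results if r.probability > t]
        correct = sum(1 for r in above if r.called_class == truths[r.sample_id])
        table[float(t)] = {
            "coverage": len(above) / n,
            "accuracy": (correct / len(above)) if above else None,
        }
    return table


def _report(
    results: List[PredictionResult],
    truths: Dict[str, str],
    classes: Sequence[str],
    thresholds: Sequence[float],
    folds: List[FoldRecord],
    skipped: List[Tuple[str, str]],
) -> EvaluationReport:
    conf = confusion(results, truths, classes=classes)
    n = len(results)
    overall = float(np.trace(conf.to_numpy())) / n
    per_class = {}
    for c in classes:
        row = conf.loc[c]
        total = int(row.sum())
        per_class[c] = (int(row[c]) / total) if total else float("nan")
    return EvaluationReport(
        results=results,
        truths=truths,
        confusion_matrix=conf,
        overall_accuracy=overall,
        per_class_accuracy=per_class,
        tier_table=tier_report(results, truths, thresholds),
        folds=folds,
        skipped=skipped,
    )


def grouped_loocv(
    m: ExpressionMatrix,
    config: Optional[RunConfig] = None,
    grouped: bool = True,
) -> EvaluationReport:
    """Leave-one-out cross-validation with replicate-group exclusion.

    For each sample, training uses every sample from a different replicate
    group (``grouped=False`` degrades to naive per-sample LOOCV, for leakage
    experiments). The gene filter is fitted per fold by default
    (``config.filter_scope='train_only'``); ``'cohort'`` reproduces a
    fit-once-on-everything protocol.

    A fold whose training set would leave some class with fewer than two
    samples is skipped with a warning and reported in ``skipped``.
    """
    config = config or RunConfig()
    classes = m.classes
    if len(classes) < 2:
        raise ValueError(f"cross-validation requires >= 2 classes, got {classes}")

    cohort_genes: Optional[List[str]] = None
    if config.filter_scope == "cohort":
        cohort_genes = filter_genes(m, config.max_zero_fraction).genes

    groups = m.groups
    results: List[PredictionResult] = []
    truths: Dict[str, str] = {}
    folds: List[FoldRecord] = []
    skipped: List[Tuple[str, str]] = []

    for sample_id in m.samples:
        test_group = groups.loc[sample_id]
        if grouped:
            train_ids = [s for s in m.samples if groups.loc[s] != test_group]
        else:
            train_ids = [s for s in m.samples if s != sample_id]
        train_labels = m.labels.loc[train_ids]
        counts = train_labels.value_counts()
        lacking = [c for c in classes if counts.get(c, 0) < 2]
        if lacking:
            msg = f"after removing group {test_group!r}, classes {lacking} have < 2 samples"
            warnings.warn(f"skipping fold for {sample_id}: {msg}", stacklevel=2)
            skipped.append((sample_id, msg))
            continue

        train = m.subset_samples(train_ids)
        if config.filter_scope == "cohort":
            train = train.subset_genes(cohort_genes)
        else:
            train = filter_genes(train, config.max_zero_fraction)

        model = fit_composite(train, config=config)
        profile = m.values.loc[sample_id]
        result = predict(model, profile, sample_id=sample_id)

        train_groups = frozenset(groups.loc[train_ids])
        if grouped and test_group in train_groups:
            raise AssertionError(f"leakage: group {test_group!r} present in training fold")
        folds.append(
            FoldRecord(
                sample_id=sample_id,
                group_id=test_group,
                train_samples=tuple(train_ids),
                train_groups=train_groups,
                gene_set=tuple(train.genes),
            )
        )
        results.append(result)
        truths[sample_id] = m.labels.loc[sample_id]

    if not results:
        raise ValueError("every fold was skipped; cohort too small for grouped LOOCV")
    return _report(results, truths, classes, config.thresholds, folds, skipped)
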