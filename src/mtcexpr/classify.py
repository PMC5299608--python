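"""Gene-signature classifier of RET mutation type.

The signature-building procedure: inside leave-one-out cross-validation, each
training fold reselects the genes satisfying a Welch t-test p-value below
``p_threshold`` and a fold change of at least ``fc_threshold`` in either
direction (FC >= c or FC <= 1/c on the linear scale); a linear-kernel SVM is
trained on those genes, standardised with training-fold statistics, and the
held-out sample is predicted.  Predictions aggregate into a confusion matrix
with the first-listed contrast label as the positive class.  The final
reported signature is selected once on all samples with the same criteria.

If a fold's criteria select nothing there is no signature to train on, and
the fold predicts the training-fold majority class: the degenerate
classifier.  This keeps the procedure honestly calibrated — on data with no
differential expression LOOCV accuracy equals the majority-class rate
instead of the near-chance performance an SVM fitted to spuriously selected
noise genes would give.  ``select_features`` called directly instead falls
back to the ``fallback_k`` smallest-p genes (logged), which is also how the
reported all-sample signature behaves.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .diffexpr import DifferentialExpression

logger = logging.getLogger(__name__)


@dataclass
class SelectionCriteria:
    p_threshold: float = 0.001
    fc_threshold: float = 4.0
    fallback_k: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0, 1)")
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must be > 1")

    def passes(self, p: float, fc: float) -> bool:
        """Does a (p, fold-change) pair satisfy both criteria?"""
        return p < self.p_threshold and (
            fc >= self.fc_threshold or fc <= 1.0 / self.fc_threshold
        )


@dataclass
class ConfusionMatrix:
    """2x2 counts with 'positive' = first-listed contrast class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def confusion_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, PPV, NPV under the standard
    definitions; ratios with a zero denominator are NaN (not available)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return {
        "accuracy": _ratio(cm.tp + cm.tn, cm.total),
        "sensitivity": _ratio(cm.tp, cm.tp + cm.fn),
        "specificity": _ratio(cm.tn, cm.tn + cm.fp),
        "ppv": _ratio(cm.tp, cm.tp + cm.fp),
        "npv": _ratio(cm.tn, cm.tn + cm.fn),
    }


def select_features(
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    contrast: tuple[str, str],
    criteria: SelectionCriteria | None = None,
    group_col: str | None = None,
    fallback: bool = True,
) -> list[str]:
    """Probes passing the univariate selection criteria, smallest p first.

    With ``fallback=True`` (the default) the ``fallback_k`` smallest-p
    probes are returned when nothing passes; with ``fallback=False`` the
    empty list is returned instead.
    """
    criteria = criteria or SelectionCriteria()
    de = DifferentialExpression(matrix, annotation, contrast, group_col).fit()
    tab = de.table
    hits = tab[
        (tab["p_value"] < criteria.p_threshold)
        & (
            (tab["fold_change"] >= criteria.fc_threshold)
            | (tab["fold_change"] <= 1.0 / criteria.fc_threshold)
        )
    ]
    if hits.empty and fallback:
        logger.info(
            "selection criteria matched no probe; falling back to top %d by p",
            criteria.fallback_k,
        )
        return list(tab.index[: criteria.fallback_k])
    return list(hits.index)


class SignatureClassifier:
    """LOOCV linear-SVM classifier with fold-internal gene selection.

    Parameters
    ----------
    matrix, annotation : filtered log2 expression and sample labels
    contrast : (positive label, negative label)
    criteria : univariate selection thresholds (default p < 0.001, 4-fold)
    C : SVM regularisation (default 1, the libsvm default)
    """

    def __init__(
        self,
        matrix: pd.DataFrame,
        annotation: pd.DataFrame,
        contrast: tuple[str, str],
        criteria: SelectionCriteria | None = None,
        C: float = 1.0,
        group_col: str | None = None,
    ):
        self.criteria = criteria or SelectionCriteria()
        self.C = C
        # reuse the DE model's contrast/label validation
        de = DifferentialExpression(matrix, annotation, contrast, group_col)
        self.group_col = de.group_col
        self.contrast = de.contrast
        labels = de.annotation[self.group_col]
        keep = labels.isin(self.contrast)
        self.matrix = matrix.loc[:, keep.to_numpy()]
        self.annotation = de.annotation.loc[keep]
        counts = self.annotation[self.group_col].value_counts()
        if counts.min() < 3:
            raise ValueError(
                f"each class needs >= 3 samples for LOOCV, got {dict(counts)}"
            )

    def _fit_fold(self, train_cols: np.ndarray):
        """Gene set and trained (svm, scaler) for one training fold.

        Returns (genes, svm, scaler); svm/scaler are None when the criteria
        selected no gene, in which case the fold predicts the training
        majority class.
        """
        train_matrix = self.matrix.iloc[:, train_cols]
        train_ann = self.annotation.iloc[train_cols]
        present = set(train_ann[self.group_col])
        if not set(self.contrast) <= present:
            raise ValueError("a class is absent from a training fold")
        genes = select_features(
            train_matrix, train_ann, self.contrast, self.criteria,
            self.group_col, fallback=False,
        )
        y = (train_ann[self.group_col] == self.contrast[0]).to_numpy(dtype=int)
        if not genes:
            logger.info("no gene passed selection in a fold; "
                        "predicting training majority class")
            return genes, None, None
        X = train_matrix.loc[genes].to_numpy(dtype=float).T
        scaler = StandardScaler().fit(X)
        svm = SVC(kernel="linear", C=self.C).fit(scaler.transform(X), y)
        return genes, svm, scaler

    def fit(self) -> "ClassifierResults":
        n = self.matrix.shape[1]
        labels = self.annotation[self.group_col]
        y_true = (labels == self.contrast[0]).to_numpy(dtype=int)
        y_pred = np.empty(n, dtype=int)
        per_fold_genes: list[list[str]] = []
        for i in range(n):
            train = np.array([j for j in range(n) if j != i])
            genes, svm, scaler = self._fit_fold(train)
            per_fold_genes.append(genes)
            if svm is None:
                y_train = y_true[train]
                y_pred[i] = int(y_train.mean() >= 0.5)
            else:
                x = self.matrix.iloc[:, i].loc[genes].to_numpy(dtype=float)[None, :]
                y_pred[i] = int(svm.predict(scaler.transform(x))[0])
        cm = ConfusionMatrix(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        )
        predictions = pd.DataFrame(
            {
                "true": np.where(y_true == 1, self.contrast[0], self.contrast[1]),
                "predicted": np.where(y_pred == 1, self.contrast[0], self.contrast[1]),
            },
            index=self.annotation.index,
        )
        signature = self._final_signature()
        return ClassifierResults(
            model=self,
            confusion=cm,
            metrics=confusion_metrics(cm),
            per_fold_genes=per_fold_genes,
            final_signature=signature,
            predictions=predictions,
        )

    def _final_signature(self) -> pd.DataFrame:
        """All-sample signature with its per-gene statistics (p, FDR, means,
        fold change)."""
        genes = select_features(
            self.matrix, self.annotation, self.contrast, self.criteria, self.group_col
        )
        de = DifferentialExpression(
            self.matrix, self.annotation, self.contrast, self.group_col
        ).fit()
        cols = ["p_value", "fdr", "mean_group1", "mean_group2", "fold_change"]
        return de.table.loc[genes, cols]


@dataclass
class ClassifierResults:
    model: SignatureClassifier
    confusion: ConfusionMatrix
    metrics: dict[str, float]
    per_fold_genes: list[list[str]]
    final_signature: pd.DataFrame
    predictions: pd.DataFrame

    def summary(self) -> str:
        pos, neg = self.model.contrast
        cm = self.confusion
        lines = [
            f"LOOCV linear-SVM classifier: {pos} (positive) vs {neg}",
            f"selection: p < {self.model.criteria.p_threshold:g}, "
            f">= {self.model.criteria.fc_threshold:g}-fold change; C = {self.model.C:g}",
            "",
            f"confusion matrix: {cm.tp}/{cm.tp + cm.fn} {pos} and "
            f"{cm.tn}/{cm.tn + cm.fp} {neg} correctly classified",
            "",
        ]
        for name, value in self.metrics.items():
            lines.append(f"  {name:12s} {100 * value:6.1f}%")
        lines.append("")
        lines.append("final signature (all samples):")
        lines.append(
            self.final_signature.to_string(float_format=lambda v: f"{v:.4g}")
        )
        return "\n".join(lines)
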