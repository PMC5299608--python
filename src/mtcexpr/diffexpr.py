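"""Per-probe differential expression between two sample groups.

The test is the two-sided Welch t-test on log2 intensities, with
Welch-Satterthwaite degrees of freedom; multiple testing is controlled by
the Benjamini-Hochberg step-up FDR.  Group means and fold changes are
reported on the linear intensity scale (2**x averaged within each group),
with the first-listed contrast label in the numerator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def welch_t_matrix(a: np.ndarray, b: np.ndarray):
    """Row-wise Welch t-test for two (probes x samples) blocks.

    Returns (t, df, p) arrays.  Rows where both groups have zero variance
    and equal means get t = 0, p = 1 (no evidence either way).
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("each group needs >= 2 values")
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    sa, sb = va / na, vb / nb
    se2 = sa + sb
    diff = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2**2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
    degenerate = se2 == 0
    if degenerate.any():
        warnings.warn(
            "zero variance in both groups for some probes; "
            "t set to 0 (equal means) or inf",
            stacklevel=2,
        )
        with np.errstate(invalid="ignore"):
            t = np.where(degenerate & (diff == 0), 0.0, t)
            t = np.where(degenerate & (diff != 0), np.sign(diff) * np.inf, t)
        df = np.where(degenerate, na + nb - 2, df)
    p = np.where(np.isinf(t), 0.0, 2.0 * stats.t.sf(np.abs(t), df))
    p = np.where(degenerate & (t == 0), 1.0, p)
    return t, df, p


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch t-test for one probe: (t, Welch-Satterthwaite df, two-sided p)."""
    t, df, p = welch_t_matrix(np.asarray(a)[None, :], np.asarray(b)[None, :])
    return float(t[0]), float(df[0]), float(p[0])


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change(mean1: float, mean2: float) -> float:
    """Linear fold change mean1/mean2 of linear-scale group means."""
    if mean1 <= 0 or mean2 <= 0:
        raise ValueError("group means must be positive on the linear scale")
    return mean1 / mean2


class DifferentialExpression:
    """Welch/BH differential-expression model for one two-group contrast.

    Parameters
    ----------
    matrix : probes x samples log2 expression (already filtered)
    annotation : per-sample labels indexed by sample id
    contrast : (label1, label2); label1 is the fold-change numerator
    group_col : annotation column holding the labels; inferred from the
        contrast labels when omitted
    """

    def __init__(
        self,
        matrix: pd.DataFrame,
        annotation: pd.DataFrame,
        contrast: tuple[str, str],
        group_col: str | None = None,
    ):
        self.matrix = matrix
        self.annotation = annotation.loc[matrix.columns]
        self.contrast = tuple(contrast)
        self.group_col = group_col or self._infer_group_col()
        labels = self.annotation[self.group_col]
        for lab in self.contrast:
            n = int((labels == lab).sum())
            if n < 2:
                raise ValueError(
                    f"contrast label {lab!r} has {n} sample(s) in column "
                    f"{self.group_col!r}; available labels: "
                    f"{sorted(labels.unique())}"
                )

    def _infer_group_col(self) -> str:
        for col in ("mutation_class", "origin"):
            if col in self.annotation.columns and set(self.contrast) <= set(
                self.annotation[col]
            ):
                return col
        raise ValueError(
            f"could not find contrast labels {self.contrast} in annotation "
            f"columns {list(self.annotation.columns)}"
        )

    def fit(self, fdr_threshold: float = 0.05) -> "DEResults":
        labels = self.annotation[self.group_col]
        m1 = (labels == self.contrast[0]).to_numpy()
        m2 = (labels == self.contrast[1]).to_numpy()
        X = self.matrix.to_numpy(dtype=float)
        a, b = X[:, m1], X[:, m2]
        t, df, p = welch_t_matrix(a, b)
        lin_a = np.exp2(a).mean(axis=1)
        lin_b = np.exp2(b).mean(axis=1)
        table = pd.DataFrame(
            {
                "mean_group1": lin_a,
                "mean_group2": lin_b,
                "fold_change": lin_a / lin_b,
                "t_stat": t,
                "df": df,
                "p_value": p,
                "fdr": bh_fdr(np.clip(p, np.nextafter(0, 1), 1.0)),
            },
            index=self.matrix.index,
        ).sort_values("p_value", kind="stable")
        return DEResults(self, table, fdr_threshold)


@dataclass
class DEResults:
    """Differential-expression table sorted by p-value."""

    model: DifferentialExpression
    table: pd.DataFrame
    fdr_threshold: float = 0.05

    def significant(self, threshold: float | None = None) -> pd.DataFrame:
        threshold = self.fdr_threshold if threshold is None else threshold
        return self.table[self.table["fdr"] < threshold]

    def summary(self, top: int = 10) -> str:
        lab1, lab2 = self.model.contrast
        sig = self.significant()
        head = [
            f"Differential expression: {lab1} vs {lab2} "
            f"({self.table.shape[0]} probes, Welch t / BH FDR)",
            f"probes with FDR < {self.fdr_threshold:g}: {sig.shape[0]}",
            "",
            self.table.head(top).to_string(
                float_format=lambda v: f"{v:.4g}",
                header=[
                    f"mean {lab1}", f"mean {lab2}", "FC", "t", "df", "p", "FDR"
                ],
            ),
        ]
        return "\n".join(head)
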