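"""RT-qPCR validation stage.

Quantifies target genes from Cq values via per-amplicon standard curves,
normalises by a geNorm reference-gene factor, and compares groups with the
Mann-Whitney U test under Bonferroni correction.

The geNorm stability measure for reference gene j is

    M_j = mean over other references k of  SD_samples( log2(q_j / q_k) )

(sample standard deviation, ddof=1).  A gene perfectly proportional to every
other reference across samples has M = 0.  The per-sample normalisation
factor is the geometric mean of the reference-gene quantities; it is defined
only up to a global scale, which cancels in group-ratio statistics.

Amplification efficiency E comes from the standard-curve slope of Cq on
log10(input quantity): E = 10^(-1/slope) - 1, so perfect doubling gives
slope = -1/log10(2) = -3.3219 and E = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class QPCRDataset:
    """Cq measurements plus standard curves and the reference-gene set.

    records: long table (sample_id, gene, replicate, cq)
    standard_curves: long table (gene, dilution_step, quantity, replicate, cq)
    reference_genes: genes used for normalisation (>= 2 required by geNorm)
    annotation: per-sample labels indexed by sample_id
    """

    records: pd.DataFrame
    standard_curves: pd.DataFrame
    reference_genes: list[str]
    annotation: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.reference_genes) < 2:
            raise ValueError("geNorm needs at least 2 reference genes")
        genes = set(self.records["gene"])
        missing = set(self.reference_genes) - genes
        if missing:
            raise ValueError(f"reference gene(s) without Cq records: {sorted(missing)}")
        # every sample must have Cq for every reference gene
        have = self.records.groupby("sample_id")["gene"].agg(set)
        for sample, g in have.items():
            if not set(self.reference_genes) <= g:
                raise ValueError(f"sample {sample!r} lacks reference-gene Cq values")

    @property
    def target_genes(self) -> list[str]:
        return sorted(set(self.records["gene"]) - set(self.reference_genes))


@dataclass
class StandardCurveFit:
    gene: str
    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        """Amplification efficiency E = 10^(-1/slope) - 1."""
        return 10.0 ** (-1.0 / self.slope) - 1.0


@dataclass
class GeNormResult:
    stability: pd.Series          # per-gene M, ascending = more stable
    ranking: list[str]            # genes from most to least stable
    normalization_factor: pd.Series  # per-sample geometric mean of references


def fit_standard_curve(quantities, cq, gene: str = "") -> StandardCurveFit:
    """OLS fit of Cq against log10(input quantity) for one amplicon."""
    q = np.asarray(quantities, dtype=float)
    y = np.asarray(cq, dtype=float)
    if (q <= 0).any():
        raise ValueError("standard-curve quantities must be positive")
    if len(np.unique(q)) < 3:
        raise ValueError("need >= 3 distinct concentrations for a standard curve")
    res = stats.linregress(np.log10(q), y)
    return StandardCurveFit(
        gene=gene,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
    )


def relative_quantity(cq, curve: StandardCurveFit):
    """Invert a fitted standard curve: quantity = 10^((Cq - intercept)/slope)."""
    if curve.slope == 0:
        raise ValueError("standard curve has zero slope")
    return 10.0 ** ((np.asarray(cq, dtype=float) - curve.intercept) / curve.slope)


def genorm_stability(ref_quantities: pd.DataFrame) -> GeNormResult:
    """geNorm gene-stability M and per-sample normalisation factor.

    ``ref_quantities`` is a samples x reference-genes grid of positive
    relative quantities.
    """
    q = ref_quantities.astype(float)
    if q.shape[1] < 2:
        raise ValueError("geNorm needs at least 2 reference genes")
    if q.shape[0] < 3:
        raise ValueError("geNorm needs at least 3 samples")
    if (q.values <= 0).any() or not np.isfinite(q.values).all():
        raise ValueError("reference quantities must be positive and finite")
    log_q = np.log2(q.values)
    genes = list(q.columns)
    m = {}
    for j, gene in enumerate(genes):
        sds = [
            np.std(log_q[:, j] - log_q[:, k], ddof=1)
            for k in range(len(genes))
            if k != j
        ]
        m[gene] = float(np.mean(sds))
    stability = pd.Series(m, name="M")
    nf = pd.Series(stats.gmean(q.values, axis=1), index=q.index, name="NF")
    return GeNormResult(
        stability=stability,
        ranking=list(stability.sort_values().index),
        normalization_factor=nf,
    )


def genorm_stepwise_ranking(ref_quantities: pd.DataFrame) -> list[str]:
    """Iterative geNorm ranking: repeatedly drop the least stable gene.

    Returns genes ordered least stable first; the final two (untestable
    against each other) close the list.  Optional — the validation stage
    itself uses a fixed a-priori reference set.
    """
    remaining = ref_quantities.copy()
    dropped: list[str] = []
    while remaining.shape[1] > 2:
        res = genorm_stability(remaining)
        worst = res.ranking[-1]
        dropped.append(worst)
        remaining = remaining.drop(columns=[worst])
    return dropped + list(remaining.columns)


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (statistic for the first group, p-value).

    Uses the exact null distribution when there are no ties and at most 20
    observations in total; otherwise the normal approximation with tie
    correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if np.ptp(pooled) == 0:
        warnings.warn("all values tied; Mann-Whitney p set to 1", stacklevel=2)
        return float(len(a) * len(b) / 2.0), 1.0
    method = "exact" if (not has_ties and len(pooled) <= 20) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bonferroni(p: float, n_tests: int) -> float:
    if not 0 < p <= 1:
        raise ValueError(f"p-value out of (0, 1]: {p}")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return min(1.0, p * n_tests)


def validate_genes(
    target_quantities: pd.DataFrame,
    nf: pd.Series,
    annotation: pd.DataFrame,
    contrast: tuple[str, str],
    group_col: str = "mutation_class",
    n_tests: int | None = None,
) -> pd.DataFrame:
    """Per-gene group comparison of normalised quantities.

    Each gene's quantities are divided by the per-sample normalisation
    factor, then the two contrast groups are compared with a two-sided
    Mann-Whitney U test; p-values are Bonferroni-adjusted with family size
    ``n_tests`` (default: the number of genes tested).  Fold change is the
    ratio of group means of normalised quantities (first contrast label in
    the numerator).
    """
    label1, label2 = contrast
    norm = target_quantities.div(nf.reindex(target_quantities.index), axis=0)
    groups = annotation.loc[norm.index, group_col]
    idx1, idx2 = groups == label1, groups == label2
    if idx1.sum() < 3 or idx2.sum() < 3:
        raise ValueError("each contrast group needs >= 3 samples")
    if n_tests is None:
        n_tests = norm.shape[1]
    rows = []
    for gene in norm.columns:
        x1 = norm.loc[idx1.values, gene].to_numpy()
        x2 = norm.loc[idx2.values, gene].to_numpy()
        u, p = mann_whitney(x1, x2)
        rows.append(
            {
                "gene": gene,
                "fold_change": float(np.mean(x1) / np.mean(x2)),
                "U": u,
                "p_value": p,
                "bonferroni_p": bonferroni(p, n_tests),
            }
        )
    return pd.DataFrame(rows).set_index("gene").sort_values("p_value")


class QPCRValidation:
    """Validation model for one qPCR dataset and one two-group contrast.

    ``fit()`` runs the full stage: replicate Cq values are averaged per
    sample/gene, each amplicon is quantified through its own standard curve,
    reference genes go through geNorm, and each target gene is tested between
    the contrast groups.
    """

    def __init__(
        self,
        dataset: QPCRDataset,
        contrast: tuple[str, str],
        group_col: str = "mutation_class",
        n_tests: int | None = None,
    ):
        self.dataset = dataset
        self.contrast = contrast
        self.group_col = group_col
        self.n_tests = n_tests

    def fit(self) -> "QPCRResults":
        ds = self.dataset
        curves: dict[str, StandardCurveFit] = {}
        for gene, grp in ds.standard_curves.groupby("gene"):
            curves[gene] = fit_standard_curve(grp["quantity"], grp["cq"], gene=gene)
        mean_cq = (
            ds.records.groupby(["sample_id", "gene"])["cq"].mean().unstack("gene")
        )
        quantities = mean_cq.copy()
        for gene in mean_cq.columns:
            if gene not in curves:
                raise ValueError(f"no standard curve for gene {gene!r}")
            quantities[gene] = relative_quantity(mean_cq[gene], curves[gene])
        genorm = genorm_stability(quantities[ds.reference_genes])
        table = validate_genes(
            quantities[ds.target_genes],
            genorm.normalization_factor,
            ds.annotation,
            self.contrast,
            group_col=self.group_col,
            n_tests=self.n_tests,
        )
        return QPCRResults(self, curves, quantities, genorm, table)


@dataclass
class QPCRResults:
    model: QPCRValidation
    standard_curves: dict[str, StandardCurveFit]
    quantities: pd.DataFrame  # samples x genes, un-normalised
    genorm: GeNormResult
    table: pd.DataFrame       # per-gene FC, U, p, bonferroni_p
    significant_level: float = field(default=0.05)

    def significant(self, alpha: float | None = None) -> pd.DataFrame:
        alpha = self.significant_level if alpha is None else alpha
        return self.table[self.table["bonferroni_p"] < alpha]

    def summary(self) -> str:
        lab1, lab2 = self.model.contrast
        lines = [
            f"qPCR validation: {lab1} vs {lab2} "
            f"({self.table.shape[0]} genes, Bonferroni family size "
            f"{self.model.n_tests or self.table.shape[0]})",
            "",
            "Amplification efficiencies:",
        ]
        for gene, c in sorted(self.standard_curves.items()):
            lines.append(
                f"  {gene:10s} slope {c.slope:8.4f}  E {100 * c.efficiency:6.1f}%"
                f"  R^2 {c.r_squared:.4f}"
            )
        lines.append("")
        lines.append("Reference-gene stability (geNorm M):")
        for gene, m in self.genorm.stability.sort_values().items():
            lines.append(f"  {gene:10s} M = {m:.4f}")
        lines.append("")
        lines.append(self.table.to_string(float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)
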