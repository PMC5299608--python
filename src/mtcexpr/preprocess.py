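"""Probe filtering applied before any downstream analysis.

Two filters, in the order they are meant to run:

1. control probe sets, recognised by identifier prefix (Affymetrix control
   sets start with "AFFX");
2. low-variability probe sets: a probe is kept only if at least
   ``min_fraction`` of samples deviate from the probe's median by at least
   ``fold_threshold`` on the linear scale in either direction, evaluated as
   |log2(x) - log2(median)| >= log2(fold_threshold).  With the defaults
   (15%, 1.5-fold) a probe in a 60-sample cohort needs 9 deviating samples.

The boundary is inclusive on both comparisons: exactly 1.5-fold counts as
deviating, and exactly 15% of samples counts as variable enough.  The
fraction is compared as count/n_samples >= min_fraction to avoid float
artefacts at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class EmptyFilterResult(ValueError):
    """A filter removed every probe."""


@dataclass
class FilterParams:
    min_fraction: float = 0.15
    fold_threshold: float = 1.5
    control_prefixes: tuple[str, ...] = ("AFFX",)

    def __post_init__(self) -> None:
        if not 0 < self.min_fraction < 1:
            raise ValueError("min_fraction must be in (0, 1)")
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must be > 1")


def remove_control_probes(matrix: pd.DataFrame, params: FilterParams) -> pd.DataFrame:
    """Drop probes whose id starts with any declared control prefix."""
    if matrix.empty:
        raise ValueError("empty expression matrix")
    if not params.control_prefixes:
        return matrix
    is_control = matrix.index.str.startswith(tuple(params.control_prefixes))
    out = matrix.loc[~is_control]
    if out.empty:
        raise EmptyFilterResult("control-probe filter removed every probe")
    return out


def variability_report(matrix: pd.DataFrame, params: FilterParams) -> pd.DataFrame:
    """Per-probe deviating-sample counts and the retain decision.

    Returns a DataFrame indexed by probe id with columns ``n_deviating``
    (samples at >= fold_threshold from the probe median, either direction)
    and ``retained``.
    """
    if matrix.shape[1] < 2:
        raise ValueError("variability filter needs >= 2 samples")
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        bad = matrix.index[~np.isfinite(values).all(axis=1)][0]
        raise ValueError(f"non-finite expression value in probe {bad!r}")
    # median of log2 values = log2 of the linear median (log is monotone)
    med = np.median(values, axis=1, keepdims=True)
    deviating = np.abs(values - med) >= np.log2(params.fold_threshold)
    counts = deviating.sum(axis=1)
    retained = counts / matrix.shape[1] >= params.min_fraction
    return pd.DataFrame(
        {"n_deviating": counts, "retained": retained}, index=matrix.index
    )


def variability_filter(matrix: pd.DataFrame, params: FilterParams) -> pd.DataFrame:
    """Keep probes with enough samples far from the probe median."""
    report = variability_report(matrix, params)
    out = matrix.loc[report["retained"]]
    if out.empty:
        raise EmptyFilterResult("variability filter removed every probe")
    return out


def filter_probes(
    matrix: pd.DataFrame, params: FilterParams | None = None
) -> pd.DataFrame:
    """Full pre-processing: control-probe removal then variability filter."""
    params = params or FilterParams()
    return variability_filter(remove_control_probes(matrix, params), params)
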