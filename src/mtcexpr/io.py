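"""Reading and writing of the plain-text tables the pipeline consumes.

Expression matrices are tab-separated text with probe-set identifiers as the
first column and one column per sample of log2 intensities (the layout an
RMA summarisation step writes out).  Sample annotations and qPCR data are
long-format TSV.  All readers validate identifiers and values and raise
:class:`ParseError` with enough context to locate the offending line.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

ORIGINS = ("hereditary", "sporadic")
MUTATION_CLASSES = ("MEN2A-like", "MEN2B-like", "RET-negative", "unknown", "other")


class ParseError(ValueError):
    """A file did not conform to the expected tabular layout."""


def _check_unique(values, kind: str, path) -> None:
    dup = pd.Index(values)[pd.Index(values).duplicated()]
    if len(dup):
        raise ParseError(f"{path}: duplicate {kind} id(s): {sorted(set(dup))}")


def read_expression_tsv(path) -> pd.DataFrame:
    """Read a probes x samples log2 expression matrix from TSV.

    Returns a DataFrame indexed by probe id with sample ids as columns.
    Raises :class:`ParseError` on duplicate probe/sample ids, ragged rows or
    non-numeric cells.
    """
    # pandas silently mangles duplicate header fields; check them literally
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    _check_unique(header[1:], "sample", path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ParseError(f"{path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no sample columns found")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    _check_unique(df.index, "probe", path)
    _check_unique(df.columns, "sample", path)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric expression value: {exc}") from exc
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)][0]
        raise ParseError(f"{path}: missing value in probe {bad!r}")
    df.index.name = "probe_id"
    df.columns.name = None
    return df


def write_expression_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="probe_id")


def read_annotation_tsv(path) -> pd.DataFrame:
    """Read a per-sample annotation table (sample_id, origin, mutation_class,
    family_id) into a DataFrame indexed by sample id."""
    ann = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "origin", "mutation_class"}
    missing = required - set(ann.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    _check_unique(ann["sample_id"], "sample", path)
    bad_origin = set(ann["origin"]) - set(ORIGINS)
    if bad_origin:
        raise ParseError(f"{path}: unknown origin value(s) {sorted(bad_origin)}")
    bad_class = set(ann["mutation_class"]) - set(MUTATION_CLASSES)
    if bad_class:
        raise ParseError(f"{path}: unknown mutation class(es) {sorted(bad_class)}")
    if "family_id" not in ann.columns:
        ann["family_id"] = pd.NA
    return ann.set_index("sample_id")


def write_annotation_tsv(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index_label="sample_id")


def check_annotation(matrix: pd.DataFrame, annotation: pd.DataFrame) -> None:
    """Every sample in the matrix must be annotated exactly once."""
    missing = set(matrix.columns) - set(annotation.index)
    if missing:
        raise ValueError(f"samples without annotation: {sorted(missing)}")


def read_qpcr_tsv(path) -> pd.DataFrame:
    """Read long-format qPCR records (sample_id, gene, replicate, cq)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "gene": str})
    required = {"sample_id", "gene", "replicate", "cq"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    if df["cq"].isna().any() or not np.isfinite(df["cq"]).all():
        raise ParseError(f"{path}: non-finite Cq value")
    return df


def read_standard_curve_tsv(path) -> pd.DataFrame:
    """Read a standard-curve dilution table (gene, dilution_step, quantity,
    replicate, cq)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    required = {"gene", "dilution_step", "quantity", "replicate", "cq"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    if (df["quantity"] <= 0).any():
        raise ParseError(f"{path}: non-positive input quantity")
    return df
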