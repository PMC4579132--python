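"""Readers and writers for the on-disk TSV formats.

Expression tables are stored genes-in-rows (first column gene IDs, header
row of sample IDs) — the community convention — and transposed to the
internal samples-in-rows orientation on load.  Labels are a two-column
TSV of sample ID and class name; samples absent from the file, or given
the sentinel ``UNLABELED``, are unlabeled.  Missing expression values are
the token ``NA`` (case-insensitive) or an empty field.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data import UNLABELED, DomainError, ExpressionMatrix, PartialLabelSet

__all__ = [
    "read_expression",
    "write_expression",
    "read_labels",
    "write_labels",
    "write_predictions",
]

_NA_TOKENS = ["NA", "na", "Na", "nA", "NaN", "nan", ""]
_UNLABELED_SENTINEL = "UNLABELED"
_FLOAT_FMT = "%.10g"


class FormatError(ValueError):
    """Malformed on-disk table."""


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Load a genes-in-rows TSV and transpose to samples × genes.

    The cell at (gene g, sample s) on disk becomes internal value (s, g).
    NA cells become missing entries (NaN) for the imputation path;
    negative values are rejected.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        raise FormatError("duplicate sample ids in expression header")
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            index_col=0,
            na_values=_NA_TOKENS,
            keep_default_na=False,
        )
    except pd.errors.ParserError as exc:
        raise FormatError(f"malformed expression table {path}: {exc}") from None
    sample_ids = [str(c) for c in df.columns]
    if len(set(sample_ids)) != len(sample_ids):
        raise FormatError("duplicate sample ids in expression header")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"non-numeric cell in expression table: {exc}") from None
    has_missing = bool(np.isnan(values).any())
    with np.errstate(invalid="ignore"):
        if (values < 0).any():
            raise DomainError("negative expression value on disk")
    return ExpressionMatrix(
        values=values.T,
        sample_ids=sample_ids,
        gene_ids=[str(g) for g in df.index],
        allow_missing=has_missing,
    )


def write_expression(data: ExpressionMatrix, path: str | Path) -> None:
    """Write genes-in-rows TSV at 10 significant digits; NaN becomes NA."""
    df = pd.DataFrame(
        data.values.T, index=data.gene_ids, columns=data.sample_ids
    )
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, na_rep="NA")


def read_labels(path: str | Path, sample_ids: Sequence[str]) -> PartialLabelSet:
    """Load a two-column sample_id/class TSV against a known sample list.

    Class order is first appearance in the file.  Listed sample IDs must
    exist; a sample listed twice with different classes is a conflict.
    An empty file yields a fully unlabeled set (unsupervised mode).
    """
    path = Path(path)
    order = {s: i for i, s in enumerate(sample_ids)}
    classes: list[str] = []
    assignment = np.full(len(sample_ids), UNLABELED, dtype=int)
    seen: dict[str, str] = {}
    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields")
        sid, cls = parts[0].strip(), parts[1].strip()
        if sid == "sample_id":  # optional header
            continue
        if sid not in order:
            raise KeyError(f"{path}:{lineno}: unknown sample id {sid!r}")
        if sid in seen and seen[sid] != cls:
            raise FormatError(
                f"{path}:{lineno}: sample {sid!r} listed with conflicting classes"
            )
        seen[sid] = cls
        if cls == _UNLABELED_SENTINEL:
            continue
        if cls not in classes:
            classes.append(cls)
        assignment[order[sid]] = classes.index(cls)
    return PartialLabelSet(classes=classes, assignment=assignment)


def write_labels(
    labels: PartialLabelSet, sample_ids: Sequence[str], path: str | Path
) -> None:
    """Write the two-column labels TSV; unlabeled samples are omitted."""
    lines = ["sample_id\tclass"]
    for sid, a in zip(sample_ids, labels.assignment):
        if a != UNLABELED:
            lines.append(f"{sid}\t{labels.classes[a]}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_predictions(
    sample_ids: Sequence[str],
    pred_names: Sequence[str],
    coefficients: np.ndarray,
    classes: Sequence[str],
    path: str | Path,
) -> None:
    """Predictions TSV: sample id, predicted class, coefficient row."""
    header = ["sample_id", "predicted_class"] + [f"coef_{c}" for c in classes]
    lines = ["\t".join(header)]
    for sid, name, row in zip(sample_ids, pred_names, coefficients):
        cells = [sid, str(name)] + [_FLOAT_FMT % v for v in row]
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")
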