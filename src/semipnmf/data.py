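"""Core in-memory containers: expression matrices and partial label sets.

Samples are rows and genes are columns throughout the library (the V in
``V ≈ [Q; H_U] W``).  On-disk expression tables use the community
genes-in-rows convention; the transpose is owned entirely by
:mod:`semipnmf.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

UNLABELED: int = -1
"""Sentinel assignment index for samples without a class label."""


class DimensionError(ValueError):
    """Shapes or identifier lengths are inconsistent."""


class DomainError(ValueError):
    """Values violate the non-negativity / finiteness domain."""


@dataclass
class ExpressionMatrix:
    """A non-negative expression matrix with sample and gene identifiers.

    Parameters
    ----------
    values:
        Array of shape ``(n_samples, n_genes)``.  Entries must be finite
        and non-negative; NaN is permitted only when ``allow_missing`` is
        set (the imputation path).
    sample_ids, gene_ids:
        Ordered identifiers matching the two axes.
    """

    values: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]
    allow_missing: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DimensionError("expression values must be a 2-D matrix")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        n, m = self.values.shape
        if len(self.sample_ids) != n:
            raise DimensionError(
                f"{len(self.sample_ids)} sample ids for {n} matrix rows"
            )
        if len(self.gene_ids) != m:
            raise DimensionError(f"{len(self.gene_ids)} gene ids for {m} matrix columns")
        if len(set(self.sample_ids)) != n:
            raise DimensionError("sample ids must be unique")
        finite = np.isfinite(self.values)
        if self.allow_missing:
            bad = ~finite & ~np.isnan(self.values)
            if bad.any():
                raise DomainError("expression values must be finite or NaN")
        elif not finite.all():
            raise DomainError("expression values must be finite")
        observed = self.values[finite]
        if (observed < 0).any():
            raise DomainError("expression values must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())


@dataclass
class PartialLabelSet:
    """Per-sample class assignments over an ordered class list.

    ``assignment[i]`` is a class index in ``[0, r)`` or :data:`UNLABELED`.
    The labeled block induces the binary indicator matrix ``Q`` with one 1
    per labeled row.
    """

    classes: list[str]
    assignment: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.classes = [str(c) for c in self.classes]
        self.assignment = np.asarray(self.assignment, dtype=int)
        r = len(self.classes)
        labeled = self.assignment != UNLABELED
        if labeled.any():
            idx = self.assignment[labeled]
            if idx.min() < 0 or idx.max() >= r:
                raise DomainError("assigned class index out of range")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def labeled_mask(self) -> np.ndarray:
        return self.assignment != UNLABELED

    @property
    def n_labeled(self) -> int:
        return int(self.labeled_mask.sum())

    @property
    def n_unlabeled(self) -> int:
        return int((~self.labeled_mask).sum())

    def indicator(self) -> np.ndarray:
        """The d × r one-hot matrix Q over the labeled samples, in sample order."""
        idx = self.assignment[self.labeled_mask]
        q = np.zeros((idx.size, self.n_classes))
        q[np.arange(idx.size), idx] = 1.0
        return q

    @classmethod
    def from_names(
        cls,
        names: Sequence[str | None],
        classes: Sequence[str] | None = None,
    ) -> "PartialLabelSet":
        """Build from per-sample class names; ``None`` marks unlabeled.

        Class order defaults to first appearance among the labeled names.
        """
        if classes is None:
            seen: list[str] = []
            for nm in names:
                if nm is not None and nm not in seen:
                    seen.append(nm)
            classes = seen
        lookup = {c: i for i, c in enumerate(classes)}
        assignment = np.array(
            [UNLABELED if nm is None else lookup[nm] for nm in names], dtype=int
        )
        return cls(classes=list(classes), assignment=assignment)
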