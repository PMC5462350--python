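"""Jaccard similarity and distance on binary vectors and images.

For two binary patterns the Jaccard coefficient is

    J = M11 / (M11 + M01 + M10)

where ``M11`` counts positions where both patterns are 1, ``M01`` positions
where the first is 0 and the second is 1, and ``M10`` the reverse.  The
Jaccard distance is ``1 - J``.  Positions where both patterns are 0 are
ignored, which makes the measure well suited to sparse binary edge maps
where the vast majority of pixels are background.

All counting is exact integer arithmetic; the single division happens at
the end, so small worked examples such as 2/7 reproduce bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .exceptions import DegeneratePairError, InvalidInputError

__all__ = [
    "JaccardCounts",
    "ClassAverageTable",
    "jaccard_counts",
    "jaccard_coefficient",
    "jaccard_distance",
    "pairwise_coefficients",
    "pairwise_distances",
    "average_class_coefficient",
]


@dataclass(frozen=True)
class JaccardCounts:
    """The (M11, M01, M10) triple underlying the coefficient and distance."""

    m11: int
    m01: int
    m10: int

    @property
    def union(self) -> int:
        return self.m11 + self.m01 + self.m10


@dataclass(frozen=True)
class ClassAverageTable:
    """Per-class average Jaccard coefficient of a probe against a training set.

    Attributes
    ----------
    averages : mapping of class label to mean coefficient in [0, 1]
    counts : mapping of class label to the number of training samples
    """

    averages: Mapping[object, float]
    counts: Mapping[object, int] = field(default_factory=dict)

    @property
    def classes(self) -> list:
        return list(self.averages.keys())


def _as_binary_vector(a, name: str = "input") -> np.ndarray:
    """Coerce a binary image (any 2-D grid) or vector to a flat uint8 vector."""
    arr = np.asarray(a)
    if hasattr(a, "pixels"):  # BinaryOrientationImage
        arr = np.asarray(a.pixels)
    if arr.ndim == 2:
        arr = arr.ravel()  # row-major, matching preprocessing.vectorize
    if arr.ndim != 1 or arr.size == 0:
        raise InvalidInputError(f"{name} must be a non-empty 1-D or 2-D binary array")
    if not np.isin(arr, (0, 1)).all():
        raise InvalidInputError(f"{name} must contain only 0s and 1s")
    return arr.astype(np.uint8, copy=False)


def jaccard_counts(a, b) -> JaccardCounts:
    """Exact M11/M01/M10 counts for two equal-length binary vectors."""
    va = _as_binary_vector(a, "a")
    vb = _as_binary_vector(b, "b")
    if va.shape != vb.shape:
        raise InvalidInputError(
            f"length mismatch: {va.size} vs {vb.size}; Jaccard counts need aligned vectors"
        )
    m11 = int(np.count_nonzero(va & vb))
    m01 = int(np.count_nonzero((1 - va) & vb))
    m10 = int(np.count_nonzero(va & (1 - vb)))
    return JaccardCounts(m11=m11, m01=m01, m10=m10)


def jaccard_coefficient(a, b, *, permissive: bool = False) -> float:
    """Jaccard similarity M11 / (M11 + M01 + M10) in [0, 1].

    Two all-zero vectors have an empty union.  By default that raises
    :class:`DegeneratePairError`; with ``permissive=True`` the pair is treated
    as identical (coefficient 1.0).
    """
    c = jaccard_counts(a, b)
    if c.union == 0:
        if permissive:
            return 1.0
        raise DegeneratePairError(
            "both vectors are all-zero (empty union); an all-zero orientation "
            "image usually indicates failed preprocessing"
        )
    return c.m11 / c.union


def jaccard_distance(a, b, *, permissive: bool = False) -> float:
    """Jaccard dissimilarity, exactly ``1 - jaccard_coefficient(a, b)``."""
    return 1.0 - jaccard_coefficient(a, b, permissive=permissive)


def _stack_binary(X, name: str = "X") -> np.ndarray:
    if isinstance(X, np.ndarray) and X.ndim == 2:
        M = X
    else:
        M = np.stack([_as_binary_vector(x, name) for x in X])
    if not np.isin(M, (0, 1)).all():
        raise InvalidInputError(f"{name} must contain only 0s and 1s")
    return M.astype(np.uint8, copy=False)


def pairwise_coefficients(y, X, *, permissive: bool = False) -> np.ndarray:
    """Vectorized Jaccard coefficient of ``y`` against each row of ``X``."""
    vy = _as_binary_vector(y, "y")
    M = _stack_binary(X)
    if M.shape[1] != vy.size:
        raise InvalidInputError(f"length mismatch: y has {vy.size}, rows have {M.shape[1]}")
    m11 = M @ vy.astype(np.int64)
    union = vy.sum(dtype=np.int64) + M.sum(axis=1, dtype=np.int64) - m11
    if (union == 0).any() and not permissive:
        raise DegeneratePairError("encountered an all-zero pair (empty union)")
    with np.errstate(invalid="ignore"):
        out = np.where(union > 0, m11 / np.maximum(union, 1), 1.0)
    return out.astype(float)


def pairwise_distances(y, X, *, permissive: bool = False) -> np.ndarray:
    """Vectorized Jaccard distance of ``y`` against each row of ``X``."""
    return 1.0 - pairwise_coefficients(y, X, permissive=permissive)


def average_class_coefficient(
    y,
    X,
    labels: Sequence,
    *,
    permissive: bool = False,
) -> ClassAverageTable:
    """Per-class arithmetic mean of Jaccard coefficients of ``y`` vs a training set.

    Parameters
    ----------
    y : binary probe vector (or 2-D binary image)
    X : sequence of binary training vectors, or an (n, D) binary matrix
    labels : length-n class label per training vector; every class must be
        non-empty (guaranteed by construction here) and every vector must
        match ``y`` in length.
    """
    labels = np.asarray(labels, dtype=object)
    if labels.size == 0:
        raise InvalidInputError("labels must be non-empty")
    coeffs = pairwise_coefficients(y, X, permissive=permissive)
    if coeffs.size != labels.size:
        raise InvalidInputError(
            f"{coeffs.size} training vectors but {labels.size} labels"
        )
    averages: dict = {}
    counts: dict = {}
    for lab in dict.fromkeys(labels.tolist()):  # preserves first-seen order
        sel = labels == lab
        counts[lab] = int(sel.sum())
        averages[lab] = float(coeffs[sel].mean())
    return ClassAverageTable(averages=averages, counts=counts)
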