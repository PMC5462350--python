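"""Coarse recognition stage: shortlist candidate classes by average Jaccard coefficient.

Classes whose training samples are, on average, most similar to the test
sample (largest mean Jaccard coefficient) are kept; the remaining classes are
excluded from all downstream sparse-representation work.  Excluding roughly
half of the classes both speeds up the fine stage and removes dissimilar
atoms that would otherwise only add noise to the representation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import InvalidInputError
from .jaccard import ClassAverageTable

__all__ = ["CandidateShortlist", "select_candidates", "default_S"]


@dataclass(frozen=True)
class CandidateShortlist:
    """The S candidate classes surviving coarse filtering.

    ``selected_classes`` is ordered by descending average coefficient with
    ties broken by lexicographically smaller class label, so the shortlist is
    deterministic across runs and platforms.
    """

    selected_classes: tuple
    scores: tuple
    excluded_classes: tuple

    @property
    def S(self) -> int:
        return len(self.selected_classes)

    def __contains__(self, label) -> bool:
        return label in self.selected_classes


def select_candidates(table: ClassAverageTable, S: int) -> CandidateShortlist:
    """Keep the ``S`` classes with the largest average Jaccard coefficient.

    Ties at the cut are resolved by stable sort on (-score, str(label)).
    """
    classes = list(table.averages.keys())
    C = len(classes)
    if not (1 <= int(S) <= C):
        raise InvalidInputError(f"S must satisfy 1 <= S <= C={C}, got {S}")
    S = int(S)
    order = sorted(classes, key=lambda lab: (-table.averages[lab], str(lab)))
    selected = tuple(order[:S])
    return CandidateShortlist(
        selected_classes=selected,
        scores=tuple(float(table.averages[lab]) for lab in selected),
        excluded_classes=tuple(order[S:]),
    )


def default_S(C: int) -> int:
    """Default shortlist size: half the number of training classes, floored.

    With 200 classes this keeps 100 candidates, i.e. half of the training
    set is excluded before the sparse solve.
    """
    if C < 2:
        raise InvalidInputError(f"need at least 2 classes, got C={C}")
    return int(C) // 2
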