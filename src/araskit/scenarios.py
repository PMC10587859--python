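"""Sensitivity-analysis weight vectors: equal weighting and dominance scenarios.

A dominance scenario gives one criterion ``k`` times the weight of each of
the others while keeping the total at one: the dominant criterion gets
``k / (n - 1 + k)`` and every other criterion ``1 / (n - 1 + k)``.
``k = 1`` collapses to equal weighting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .entropy import WeightProvenance, WeightVector
from .errors import DomainError

__all__ = ["DominanceScenario", "equal_weights", "dominance_weights", "scenario_label"]


def equal_weights(n_criteria: int, criterion_names: tuple[str, ...] | None = None) -> WeightVector:
    """Uniform weights ``1/n`` over ``n_criteria`` criteria."""
    if n_criteria < 1:
        raise DomainError(f"need at least one criterion, got {n_criteria}")
    w = np.full(n_criteria, 1.0 / n_criteria)
    return WeightVector(w, WeightProvenance.EQUAL, criterion_names)


def dominance_weights(
    n_criteria: int,
    dominant_index: int,
    k: float,
    criterion_names: tuple[str, ...] | None = None,
) -> WeightVector:
    """Weights where criterion ``dominant_index`` (0-based) is ``k``-fold dominant.

    The ratio dominant/other equals ``k`` exactly and the vector sums to one.
    """
    if n_criteria < 2:
        raise DomainError("dominance needs at least two criteria")
    if not 0 <= dominant_index < n_criteria:
        raise DomainError(
            f"dominant_index {dominant_index} out of range for {n_criteria} criteria"
        )
    if k < 1:
        raise DomainError(f"dominance factor k must be >= 1, got {k}")
    denom = n_criteria - 1 + k
    w = np.full(n_criteria, 1.0 / denom)
    w[dominant_index] = k / denom
    return WeightVector(w, WeightProvenance.DOMINANCE, criterion_names)


def scenario_label(k: float) -> str:
    """Conventional labels: k=3 -> "S1", k=2 -> "S2", otherwise "k=<k>"."""
    if k == 3:
        return "S1"
    if k == 2:
        return "S2"
    if k == 1:
        return "S0"
    return f"k={k:g}"


@dataclass(frozen=True)
class DominanceScenario:
    """One sensitivity scenario: a dominant criterion and its factor ``k``."""

    dominant_criterion: int | str
    k: float
    label: str | None = None

    def resolve_index(self, criterion_names: tuple[str, ...]) -> int:
        if isinstance(self.dominant_criterion, int):
            return self.dominant_criterion
        try:
            return criterion_names.index(self.dominant_criterion)
        except ValueError:
            raise DomainError(
                f"unknown dominant criterion {self.dominant_criterion!r}"
            ) from None

    def weights(self, criterion_names: tuple[str, ...]) -> WeightVector:
        idx = self.resolve_index(criterion_names)
        return dominance_weights(len(criterion_names), idx, self.k, criterion_names)

    @property
    def display_label(self) -> str:
        return self.label if self.label is not None else scenario_label(self.k)
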