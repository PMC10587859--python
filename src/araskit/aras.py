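"""Additive ratio assessment (ARAS) ranking.

An ideal "optimal alternative" row is prepended to the decision matrix
(column maximum for benefit criteria, minimum for cost criteria).  Benefit
columns are normalised to shares directly; cost columns via reciprocals.
The optimal row participates in the normalisation denominators.  Weighted
row sums give the optimality function ``S_i``; each alternative's utility
degree is ``K_i = S_i / S_opt`` relative to the optimal row, so
``K`` lies in ``(0, 1]``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .conversion import CriterionSpec, DecisionMatrix
from .entropy import WeightVector
from .errors import DomainError, StructuralError

__all__ = [
    "ExtendedMatrix",
    "ArasResult",
    "optimal_row",
    "extend_matrix",
    "normalize_extended",
    "apply_weights",
    "optimality_and_utility",
    "run_aras",
]


def optimal_row(matrix: DecisionMatrix) -> np.ndarray:
    """Ideal scores per criterion: column max (benefit) or min (cost)."""
    return np.where(matrix.cost_mask, matrix.x.min(axis=0), matrix.x.max(axis=0))


@dataclass(frozen=True)
class ExtendedMatrix:
    """Decision matrix with the optimal row prepended at index 0."""

    alternative_names: tuple[str, ...]
    criterion_specs: tuple[CriterionSpec, ...]
    rows: np.ndarray  # shape (m + 1, n); row 0 is the optimal alternative

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows, dtype=float)
        object.__setattr__(self, "rows", rows)
        if rows.shape != (len(self.alternative_names) + 1, len(self.criterion_specs)):
            raise StructuralError("extended matrix shape mismatch")
        cost = np.array([s.is_cost for s in self.criterion_specs], dtype=bool)
        body = rows[1:]
        ok = np.where(cost, rows[0] <= body.min(axis=0), rows[0] >= body.max(axis=0))
        if not np.all(ok):
            raise DomainError("optimal row is not extreme in every criterion")

    @property
    def cost_mask(self) -> np.ndarray:
        return np.array([s.is_cost for s in self.criterion_specs], dtype=bool)


def extend_matrix(matrix: DecisionMatrix) -> ExtendedMatrix:
    rows = np.vstack([optimal_row(matrix), matrix.x])
    return ExtendedMatrix(matrix.alternative_names, matrix.criterion_specs, rows)


def normalize_extended(ext: ExtendedMatrix) -> np.ndarray:
    """Column-normalise the extended matrix to shares summing to one.

    Benefit columns: ``X / sum(X)`` over rows 0..m.  Cost columns are first
    inverted (``1/X``) and the reciprocals normalised, so smaller raw scores
    earn larger shares.
    """
    rows = ext.rows
    cost = ext.cost_mask
    if np.any(rows[:, cost] <= 0):
        raise DomainError("cost criteria require strictly positive scores (reciprocal)")
    if np.any(rows[:, ~cost] < 0):
        raise DomainError("benefit criteria require non-negative scores")
    work = rows.astype(float).copy()
    if cost.any():
        work[:, cost] = 1.0 / rows[:, cost]
    sums = work.sum(axis=0)
    if np.any(sums <= 0):
        raise DomainError("a benefit column sums to zero; shares undefined")
    return work / sums


def apply_weights(normalized: np.ndarray, w: WeightVector) -> np.ndarray:
    """Scale each normalised column by its criterion weight."""
    if normalized.shape[1] != len(w):
        raise StructuralError(
            f"weight vector has {len(w)} entries for {normalized.shape[1]} criteria"
        )
    return normalized * w.w


@dataclass(frozen=True)
class ArasResult:
    """Full output of one ARAS run."""

    alternative_names: tuple[str, ...]
    weights: WeightVector
    extended: np.ndarray
    normalized: np.ndarray
    weighted: np.ndarray
    S: np.ndarray  # optimality values per alternative
    S_opt: float  # optimality value of the ideal row
    K: np.ndarray  # utility degrees per alternative

    @property
    def ranking_indices(self) -> tuple[int, ...]:
        # stable descending sort: ties keep input order
        return tuple(int(i) for i in np.argsort(-self.K, kind="stable"))

    @property
    def ranking(self) -> tuple[str, ...]:
        return tuple(self.alternative_names[i] for i in self.ranking_indices)

    @property
    def best(self) -> str:
        return self.ranking[0]

    def rank_of(self, alternative: str) -> int:
        """1-based rank position of an alternative."""
        return self.ranking.index(alternative) + 1

    def utility_of(self, alternative: str) -> float:
        return float(self.K[self.alternative_names.index(alternative)])

    def to_frame(self) -> pd.DataFrame:
        ranks = {name: r + 1 for r, name in enumerate(self.ranking)}
        return pd.DataFrame(
            {
                "S": self.S,
                "K": self.K,
                "rank": [ranks[a] for a in self.alternative_names],
            },
            index=list(self.alternative_names),
        ).rename_axis("alternative")

    def to_dict(self) -> dict:
        return {
            "S_opt": self.S_opt,
            "weights": [float(v) for v in self.weights.w],
            "alternatives": [
                {
                    "name": a,
                    "S": float(self.S[i]),
                    "K": float(self.K[i]),
                    "rank": self.rank_of(a),
                }
                for i, a in enumerate(self.alternative_names)
            ],
            "ranking": list(self.ranking),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2), encoding="utf-8")


def optimality_and_utility(
    weighted: np.ndarray,
    alternative_names: tuple[str, ...],
    weights: WeightVector,
    extended: np.ndarray | None = None,
    normalized: np.ndarray | None = None,
) -> ArasResult:
    """Row-sum the weighted grid and express utilities relative to row 0."""
    S_all = weighted.sum(axis=1)
    S_opt = float(S_all[0])
    if S_opt <= 0:
        raise DomainError("optimal-row optimality value must be positive")
    S = S_all[1:]
    K = S / S_opt
    return ArasResult(
        alternative_names=tuple(alternative_names),
        weights=weights,
        extended=extended if extended is not None else weighted,
        normalized=normalized if normalized is not None else weighted,
        weighted=weighted,
        S=S,
        S_opt=S_opt,
        K=K,
    )


def run_aras(matrix: DecisionMatrix, w: WeightVector) -> ArasResult:
    """Rank a decision matrix under a weight vector with ARAS."""
    ext = extend_matrix(matrix)
    normalized = normalize_extended(ext)
    weighted = apply_weights(normalized, w)
    return optimality_and_utility(
        weighted, matrix.alternative_names, w, extended=ext.rows, normalized=normalized
    )
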