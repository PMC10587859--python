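"""Objective criterion weighting from column dispersion (Shannon entropy).

The weight of a criterion is proportional to how much it discriminates
among the alternatives: constant columns carry maximal entropy (e = 1)
and zero weight; spread-out columns carry more.

Pipeline: reflect cost-direction columns onto the benefit orientation
(``x' = scale_max + scale_min - x``), form per-column shares, take the
Shannon entropy normalised by ``ln m``, convert to dispersion ``|1 - e|``
and normalise the dispersions to sum to one.

The cost-column reflection is applied by default and can be disabled with
``reverse_score=False`` for ablation; without it, cost criteria would be
weighted as if large scores were desirable.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .conversion import DecisionMatrix
from .errors import DegenerateMatrixError, DomainError, StructuralError

__all__ = [
    "WeightProvenance",
    "WeightVector",
    "EntropyDiagnostics",
    "reverse_score_cost_criteria",
    "column_shares",
    "entropy_per_criterion",
    "dispersion",
    "entropy_weights",
]

_SUM_TOL = 1e-12


class WeightProvenance(enum.Enum):
    ENTROPY = "entropy"
    EQUAL = "equal"
    DOMINANCE = "dominance"
    MANUAL = "manual"


@dataclass(frozen=True)
class WeightVector:
    """Per-criterion weights summing to one."""

    w: np.ndarray
    provenance: WeightProvenance = WeightProvenance.MANUAL
    criterion_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        object.__setattr__(self, "w", w)
        if w.ndim != 1 or w.size < 1:
            raise StructuralError("weight vector must be a non-empty 1-D array")
        if np.any(w < 0) or np.any(w > 1):
            raise DomainError(f"weights must lie in [0, 1], got {w}")
        if abs(w.sum() - 1.0) > _SUM_TOL * max(1, w.size):
            raise DomainError(f"weights must sum to 1, got {w.sum()!r}")
        if self.criterion_names is not None:
            names = tuple(self.criterion_names)
            object.__setattr__(self, "criterion_names", names)
            if len(names) != w.size:
                raise StructuralError("criterion_names length does not match weights")
        w.setflags(write=False)

    def __len__(self) -> int:
        return self.w.size

    def as_series(self) -> pd.Series:
        idx = self.criterion_names or [f"C{j + 1}" for j in range(len(self))]
        return pd.Series(self.w, index=list(idx), name="w")


@dataclass(frozen=True)
class EntropyDiagnostics:
    """Entropy ``e`` and dispersion ``d`` per criterion, with the row count
    ``m`` that entered the ``1/ln m`` normaliser."""

    e: np.ndarray
    d: np.ndarray
    m: int

    def to_frame(self, criterion_names: Sequence[str] | None = None) -> pd.DataFrame:
        cols = list(criterion_names) if criterion_names else [
            f"C{j + 1}" for j in range(self.e.size)
        ]
        return pd.DataFrame([self.e, self.d], index=["e_j", "d_j"], columns=cols)


def reverse_score_cost_criteria(matrix: DecisionMatrix) -> DecisionMatrix:
    """Reflect cost-criterion columns onto the benefit orientation.

    For each cost criterion ``x' = scale_max + scale_min - x``, so the
    scale endpoints swap and spacing is preserved.  Benefit columns pass
    through.  The result is flagged and cannot be reflected again.
    """
    if matrix.reverse_scored:
        raise DomainError("matrix is already reverse-scored; refusing to apply twice")
    x = matrix.x.copy()
    for j, spec in enumerate(matrix.criterion_specs):
        if spec.is_cost:
            x[:, j] = spec.scale_max + spec.scale_min - x[:, j]
    return matrix.with_values(x, reverse_scored=True)


def _values(matrix: DecisionMatrix | np.ndarray) -> np.ndarray:
    return matrix.x if isinstance(matrix, DecisionMatrix) else np.asarray(matrix, dtype=float)


def column_shares(matrix: DecisionMatrix | np.ndarray) -> np.ndarray:
    """Normalise each column to shares ``p_ij = x_ij / sum_i x_ij``."""
    x = _values(matrix)
    if np.any(x <= 0):
        raise DomainError("column shares require strictly positive scores")
    return x / x.sum(axis=0, keepdims=True)


def entropy_per_criterion(p: np.ndarray, m: int) -> np.ndarray:
    """Shannon entropy of each share column, normalised by ``ln m``.

    Uses the ``0 * ln 0 = 0`` convention for zero shares.
    """
    if m < 2:
        raise DomainError(f"entropy normaliser needs m >= 2 alternatives, got {m}")
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    return -plogp.sum(axis=0) / np.log(m)


def dispersion(e: np.ndarray) -> np.ndarray:
    """Dispersion ``d_j = |1 - e_j|``."""
    return np.abs(1.0 - np.asarray(e, dtype=float))


def entropy_weights(
    matrix: DecisionMatrix, *, reverse_score: bool = True
) -> tuple[WeightVector, EntropyDiagnostics]:
    """Compute entropy-based criterion weights for a decision matrix.

    Parameters
    ----------
    matrix
        Direction-annotated decision matrix with strictly positive scores.
    reverse_score
        Reflect cost columns before computing shares (default).  Disable
        only for ablation studies.

    Raises
    ------
    DegenerateMatrixError
        If every column is constant (total dispersion is zero); use equal
        weights instead.
    """
    m = matrix.n_alternatives
    work = matrix
    if reverse_score and not matrix.reverse_scored:
        work = reverse_score_cost_criteria(matrix)
    p = column_shares(work)
    e = entropy_per_criterion(p, m)
    d = dispersion(e)
    total = d.sum()
    if total <= _SUM_TOL:
        raise DegenerateMatrixError(
            "all criterion columns are constant; entropy weighting is undefined "
            "- use equal weights instead"
        )
    w = d / total
    return (
        WeightVector(w, WeightProvenance.ENTROPY, matrix.criterion_names),
        EntropyDiagnostics(e=e, d=d, m=m),
    )


def weight_report(
    weights: WeightVector, diagnostics: EntropyDiagnostics | None = None
) -> pd.DataFrame:
    """Tabulate e_j / d_j / w_j rows by criterion (diagnostics optional)."""
    rows = {}
    if diagnostics is not None:
        rows["e_j"] = diagnostics.e
        rows["d_j"] = diagnostics.d
    rows["w_j"] = weights.w
    cols = list(weights.criterion_names or [f"C{j + 1}" for j in range(len(weights))])
    return pd.DataFrame(rows, index=cols).T.rename_axis("parameter")


def export_weights(
    weights: WeightVector,
    diagnostics: EntropyDiagnostics | None,
    path: str | Path,
    fmt: str = "csv",
) -> None:
    frame = weight_report(weights, diagnostics)
    path = Path(path)
    if fmt == "csv":
        frame.to_csv(path)
    elif fmt == "json":
        payload = {
            "provenance": weights.provenance.value,
            "criteria": list(frame.columns),
            **{row: [float(v) for v in frame.loc[row]] for row in frame.index},
        }
        path.write_text(json.dumps(payload, indent=2), encoding="utf-8")
    elif fmt == "md":
        path.write_text(frame.to_markdown(), encoding="utf-8")
    else:
        raise ValueError(f"unknown format {fmt!r}")
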