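"""Qualitative-to-numeric conversion and the core decision-matrix types.

A decision problem is a grid of alternatives (rows) scored on criteria
(columns).  Qualitative grids (:class:`RawAssessmentTable`) carry ordinal
labels such as ``"good"`` or ``"lengthy"``; each criterion references a
:class:`ConversionRule` mapping its vocabulary onto descending consecutive
integers ending at 1.  :func:`convert_table` turns the labels into a
:class:`DecisionMatrix` of integer scores.

Criteria are direction-annotated: *benefit* criteria are maximised,
*cost* criteria minimised.  Scale bounds come from the conversion rule's
value range, not the observed column range.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, ConversionError, StructuralError

__all__ = [
    "Direction",
    "ConversionRule",
    "CriterionSpec",
    "RawAssessmentTable",
    "DecisionMatrix",
    "builtin_rules",
    "get_rule",
    "convert_table",
    "read_criteria_config",
    "write_criteria_config",
    "read_matrix_csv",
    "read_table_csv",
]


class Direction(enum.Enum):
    """Optimisation direction of a criterion."""

    MAX = "max"  # benefit: larger is better
    MIN = "min"  # cost: smaller is better

    @classmethod
    def parse(cls, value: "Direction | str") -> "Direction":
        if isinstance(value, Direction):
            return value
        v = str(value).strip().lower()
        aliases = {"max": cls.MAX, "benefit": cls.MAX, "min": cls.MIN, "cost": cls.MIN}
        if v not in aliases:
            raise ConfigError(f"unknown criterion direction {value!r} (use max/min)")
        return aliases[v]


def _canon(label: str) -> str:
    return str(label).strip().lower()


@dataclass(frozen=True)
class ConversionRule:
    """An ordinal vocabulary mapped to descending consecutive integers.

    ``ordered_labels`` runs from best/largest to worst/smallest; the
    assigned values are ``len(labels) .. 1``.
    """

    rule_id: int
    ordered_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        canon = [_canon(l) for l in self.ordered_labels]
        if len(set(canon)) != len(canon):
            raise ConfigError(f"rule {self.rule_id}: duplicate labels {self.ordered_labels}")
        if not canon:
            raise ConfigError(f"rule {self.rule_id}: empty vocabulary")

    @property
    def values(self) -> tuple[int, ...]:
        n = len(self.ordered_labels)
        return tuple(range(n, 0, -1))

    @property
    def scale_min(self) -> int:
        return 1

    @property
    def scale_max(self) -> int:
        return len(self.ordered_labels)

    @property
    def mapping(self) -> dict[str, int]:
        return {_canon(l): v for l, v in zip(self.ordered_labels, self.values)}

    def lookup(self, label: str) -> int:
        """Resolve a label (case-insensitive, whitespace-trimmed) to its score."""
        try:
            return self.mapping[_canon(label)]
        except KeyError:
            raise ConversionError(
                f"label {label!r} is not in rule {self.rule_id}'s vocabulary "
                f"{list(self.ordered_labels)}"
            ) from None


#: The five bundled ordinal vocabularies.
_BUILTIN = (
    ConversionRule(1, ("excellent", "very good", "good", "fair", "poor")),
    ConversionRule(2, ("lengthy", "moderate", "minimal")),
    ConversionRule(3, ("high", "medium", "low", "none")),
    ConversionRule(4, ("substantial", "moderate", "minimal", "none")),
    ConversionRule(5, ("easiest", "easy", "moderate", "difficult")),
)


def builtin_rules() -> tuple[ConversionRule, ...]:
    """Return the five built-in conversion rules (ids 1-5)."""
    return _BUILTIN


def get_rule(rule_id: int) -> ConversionRule:
    for rule in _BUILTIN:
        if rule.rule_id == rule_id:
            return rule
    raise ConfigError(f"no built-in conversion rule with id {rule_id}")


@dataclass(frozen=True)
class CriterionSpec:
    """Name, direction and scale of one criterion.

    ``rule_id`` is ``None`` for numeric (pre-scored) criteria; then
    ``scale_min``/``scale_max`` must be given explicitly.
    """

    name: str
    direction: Direction
    rule_id: int | None = None
    scale_min: int = 1
    scale_max: int = 5

    def __post_init__(self) -> None:
        object.__setattr__(self, "direction", Direction.parse(self.direction))
        if self.rule_id is not None:
            rule = get_rule(self.rule_id)
            object.__setattr__(self, "scale_min", rule.scale_min)
            object.__setattr__(self, "scale_max", rule.scale_max)
        if self.scale_min < 1 or self.scale_max <= self.scale_min:
            raise ConfigError(
                f"criterion {self.name!r}: need 1 <= scale_min < scale_max, "
                f"got [{self.scale_min}, {self.scale_max}]"
            )

    @property
    def is_cost(self) -> bool:
        return self.direction is Direction.MIN

    @property
    def rule(self) -> ConversionRule | None:
        return get_rule(self.rule_id) if self.rule_id is not None else None


def _check_rectangular(rows: Sequence[Sequence], n_cols: int, what: str) -> None:
    for i, row in enumerate(rows):
        if len(row) != n_cols:
            raise StructuralError(
                f"{what}: row {i} has {len(row)} cells, expected {n_cols}"
            )


@dataclass(frozen=True)
class RawAssessmentTable:
    """Alternatives x criteria grid of qualitative labels."""

    alternative_names: tuple[str, ...]
    criterion_specs: tuple[CriterionSpec, ...]
    labels: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "alternative_names", tuple(self.alternative_names))
        object.__setattr__(self, "criterion_specs", tuple(self.criterion_specs))
        object.__setattr__(self, "labels", tuple(tuple(r) for r in self.labels))
        if len(self.labels) != len(self.alternative_names):
            raise StructuralError("label grid has wrong number of rows")
        _check_rectangular(self.labels, len(self.criterion_specs), "assessment table")
        for i, row in enumerate(self.labels):
            for j, lab in enumerate(row):
                spec = self.criterion_specs[j]
                if spec.rule is None:
                    raise ConfigError(
                        f"criterion {spec.name!r} is numeric; qualitative labels "
                        f"require a conversion rule"
                    )
                spec.rule.lookup(lab)  # raises ConversionError if unknown

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.alternative_names), len(self.criterion_specs)

    def label(self, alternative: str, criterion: str) -> str:
        i = self.alternative_names.index(alternative)
        j = [s.name for s in self.criterion_specs].index(criterion)
        return self.labels[i][j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.labels),
            index=list(self.alternative_names),
            columns=[s.name for s in self.criterion_specs],
        ).rename_axis("alternative")

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)


@dataclass(frozen=True)
class DecisionMatrix:
    """Numeric alternatives x criteria decision matrix.

    Every score must be finite and lie within its criterion's scale bounds.
    ``reverse_scored`` marks matrices whose cost columns have already been
    reflected (see :func:`araskit.entropy.reverse_score_cost_criteria`); it
    guards against applying the reflection twice.
    """

    alternative_names: tuple[str, ...]
    criterion_specs: tuple[CriterionSpec, ...]
    x: np.ndarray
    reverse_scored: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "alternative_names", tuple(self.alternative_names))
        object.__setattr__(self, "criterion_specs", tuple(self.criterion_specs))
        x = np.asarray(self.x, dtype=float)
        object.__setattr__(self, "x", x)
        if x.ndim != 2:
            raise StructuralError(f"decision matrix must be 2-D, got shape {x.shape}")
        m, n = x.shape
        if m != len(self.alternative_names) or n != len(self.criterion_specs):
            raise StructuralError(
                f"matrix shape {x.shape} does not match {len(self.alternative_names)} "
                f"alternatives x {len(self.criterion_specs)} criteria"
            )
        if m < 1 or n < 1:
            raise StructuralError("need at least one alternative and one criterion")
        if not np.all(np.isfinite(x)):
            raise StructuralError("decision matrix contains non-finite scores")
        lo = np.array([s.scale_min for s in self.criterion_specs], dtype=float)
        hi = np.array([s.scale_max for s in self.criterion_specs], dtype=float)
        if np.any(x < lo) or np.any(x > hi):
            bad = np.argwhere((x < lo) | (x > hi))[0]
            i, j = int(bad[0]), int(bad[1])
            spec = self.criterion_specs[j]
            raise StructuralError(
                f"score {x[i, j]} for {self.alternative_names[i]!r} / {spec.name!r} "
                f"outside scale [{spec.scale_min}, {spec.scale_max}]"
            )
        x.setflags(write=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.x.shape

    @property
    def n_alternatives(self) -> int:
        return self.x.shape[0]

    @property
    def n_criteria(self) -> int:
        return self.x.shape[1]

    @property
    def criterion_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.criterion_specs)

    @property
    def cost_mask(self) -> np.ndarray:
        return np.array([s.is_cost for s in self.criterion_specs], dtype=bool)

    def with_values(self, x: np.ndarray, *, reverse_scored: bool | None = None) -> "DecisionMatrix":
        return replace(
            self,
            x=np.array(x, dtype=float),
            reverse_scored=self.reverse_scored if reverse_scored is None else reverse_scored,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.x,
            index=list(self.alternative_names),
            columns=list(self.criterion_names),
        ).rename_axis("alternative")

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)


def convert_table(raw: RawAssessmentTable) -> DecisionMatrix:
    """Convert a qualitative table to its numeric decision matrix.

    Each cell is looked up in its criterion's conversion rule
    (case-insensitive, surrounding whitespace ignored); alternative and
    criterion order are preserved.
    """
    m, n = raw.shape
    x = np.empty((m, n), dtype=float)
    for j, spec in enumerate(raw.criterion_specs):
        rule = spec.rule
        for i in range(m):
            try:
                x[i, j] = rule.lookup(raw.labels[i][j])
            except ConversionError as exc:
                raise ConversionError(
                    f"alternative {raw.alternative_names[i]!r}, criterion "
                    f"{spec.name!r}: {exc}"
                ) from None
    return DecisionMatrix(raw.alternative_names, raw.criterion_specs, x)


# ---------------------------------------------------------------------------
# configuration and CSV I/O


def _spec_from_dict(d: dict) -> CriterionSpec:
    try:
        name = d["name"]
        direction = Direction.parse(d["direction"])
    except KeyError as exc:
        raise ConfigError(f"criterion config missing key {exc}") from None
    rule = d.get("rule", "numeric")
    if rule in (None, "numeric"):
        scale = d.get("scale")
        if scale is None:
            raise ConfigError(f"numeric criterion {name!r} needs 'scale: [min, max]'")
        lo, hi = (int(v) for v in scale)
        return CriterionSpec(name, direction, rule_id=None, scale_min=lo, scale_max=hi)
    return CriterionSpec(name, direction, rule_id=int(rule))


def read_criteria_config(path: str | Path) -> tuple[CriterionSpec, ...]:
    """Load criterion specs from a YAML or JSON list.

    Each entry is ``{name, direction: max|min, rule: 1-5|numeric,
    scale: [min, max]}``; ``scale`` is required only for numeric criteria.
    """
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    if isinstance(data, dict) and "criteria" in data:
        data = data["criteria"]
    if not isinstance(data, list) or not data:
        raise ConfigError(f"{path}: expected a non-empty list of criterion entries")
    return tuple(_spec_from_dict(d) for d in data)


def write_criteria_config(specs: Iterable[CriterionSpec], path: str | Path) -> None:
    entries = []
    for s in specs:
        entry: dict = {"name": s.name, "direction": s.direction.value}
        if s.rule_id is not None:
            entry["rule"] = s.rule_id
        else:
            entry["rule"] = "numeric"
            entry["scale"] = [s.scale_min, s.scale_max]
        entries.append(entry)
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(entries, indent=2), encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(entries, sort_keys=False), encoding="utf-8")


def _read_grid_csv(path: str | Path, *, as_text: bool = False) -> pd.DataFrame:
    # keep_default_na off in text mode: "None" is a legitimate ordinal label
    df = pd.read_csv(
        path, index_col=0, keep_default_na=not as_text,
        dtype=str if as_text else None,
    )
    if df.shape[1] < 1 or df.shape[0] < 1:
        raise StructuralError(f"{path}: empty table")
    if df.isna().any().any():
        raise StructuralError(f"{path}: missing cells are not supported")
    return df


def read_matrix_csv(path: str | Path, specs: Sequence[CriterionSpec]) -> DecisionMatrix:
    """Read a numeric decision matrix: first column alternative names, header criteria."""
    df = _read_grid_csv(path)
    names = [str(c).strip() for c in df.columns]
    if names != [s.name for s in specs]:
        raise ConfigError(
            f"{path}: CSV criteria {names} do not match config "
            f"{[s.name for s in specs]}"
        )
    return DecisionMatrix(
        tuple(str(a) for a in df.index), tuple(specs), df.to_numpy(dtype=float)
    )


def read_table_csv(path: str | Path, specs: Sequence[CriterionSpec]) -> RawAssessmentTable:
    """Read a qualitative assessment table (same layout as :func:`read_matrix_csv`)."""
    df = _read_grid_csv(path, as_text=True)
    names = [str(c).strip() for c in df.columns]
    if names != [s.name for s in specs]:
        raise ConfigError(
            f"{path}: CSV criteria {names} do not match config "
            f"{[s.name for s in specs]}"
        )
    labels = tuple(tuple(str(v) for v in row) for row in df.itertuples(index=False))
    return RawAssessmentTable(tuple(str(a) for a in df.index), tuple(specs), labels)
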