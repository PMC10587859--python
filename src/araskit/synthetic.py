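"""Random decision problems for property testing.

Generates qualitative tables or numeric matrices with the structure the
analysis assumes: bounded ordinal scales, mixed benefit/cost directions,
optional constant (degenerate) columns.  A single integer seed drives one
reproducible generator instance; there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .conversion import (
    CriterionSpec,
    DecisionMatrix,
    Direction,
    RawAssessmentTable,
    builtin_rules,
)
from .errors import ConfigError

__all__ = ["GeneratorConfig", "generate", "random_criteria"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Specification of one random decision problem.

    ``label_mode`` selects the output type: ``"qualitative"`` yields a
    :class:`RawAssessmentTable` whose cells are drawn from each rule's
    vocabulary, ``"numeric"`` a :class:`DecisionMatrix` with uniform
    integer scores within each criterion's scale.  ``degenerate_columns``
    lists criterion indices forced constant at a sampled level.
    ``label_skew`` optionally biases the draw towards the top label
    (0 = uniform, 1 = almost surely the first label) to create
    near-degenerate columns.
    """

    n_alternatives: int
    criterion_specs: tuple[CriterionSpec, ...]
    label_mode: str = "numeric"
    degenerate_columns: tuple[int, ...] = field(default_factory=tuple)
    label_skew: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_alternatives < 2:
            raise ConfigError(
                f"need at least 2 alternatives, got {self.n_alternatives}"
            )
        if self.label_mode not in ("qualitative", "numeric"):
            raise ConfigError(f"unknown label_mode {self.label_mode!r}")
        if not self.criterion_specs:
            raise ConfigError("need at least one criterion")
        if not 0.0 <= self.label_skew < 1.0:
            raise ConfigError("label_skew must be in [0, 1)")
        for j in self.degenerate_columns:
            if not 0 <= j < len(self.criterion_specs):
                raise ConfigError(f"degenerate column index {j} out of range")
        if self.label_mode == "qualitative":
            for s in self.criterion_specs:
                if s.rule_id is None:
                    raise ConfigError(
                        f"qualitative mode needs a conversion rule for {s.name!r}"
                    )


def random_criteria(
    n_criteria: int,
    rng: np.random.Generator,
    *,
    with_rules: bool = True,
) -> tuple[CriterionSpec, ...]:
    """Draw criterion specs with random rules/scales and directions."""
    rules = builtin_rules()
    specs = []
    for j in range(n_criteria):
        direction = Direction.MAX if rng.random() < 0.5 else Direction.MIN
        if with_rules:
            rule = rules[rng.integers(len(rules))]
            specs.append(CriterionSpec(f"C{j + 1}", direction, rule_id=rule.rule_id))
        else:
            lo = int(rng.integers(1, 3))
            hi = lo + int(rng.integers(2, 6))
            specs.append(
                CriterionSpec(f"C{j + 1}", direction, rule_id=None, scale_min=lo, scale_max=hi)
            )
    return tuple(specs)


def _label_probs(n_labels: int, skew: float) -> np.ndarray:
    if skew == 0.0:
        return np.full(n_labels, 1.0 / n_labels)
    # geometric decay away from the first label; skew -> 1 concentrates mass
    p = (1.0 - skew) ** np.arange(n_labels)
    return p / p.sum()


def generate(config: GeneratorConfig) -> RawAssessmentTable | DecisionMatrix:
    """Generate a random decision problem; deterministic under the seed."""
    rng = np.random.default_rng(config.seed)
    m = config.n_alternatives
    specs = config.criterion_specs
    degenerate = set(config.degenerate_columns)

    if config.label_mode == "qualitative":
        columns: list[list[str]] = []
        for j, spec in enumerate(specs):
            vocab = spec.rule.ordered_labels
            probs = _label_probs(len(vocab), config.label_skew)
            if j in degenerate:
                level = rng.choice(len(vocab), p=probs)
                col = [vocab[level]] * m
            else:
                draws = rng.choice(len(vocab), size=m, p=probs)
                col = [vocab[d] for d in draws]
            columns.append(col)
        names = tuple(f"Alt{i + 1}" for i in range(m))
        labels = tuple(tuple(columns[j][i] for j in range(len(specs))) for i in range(m))
        return RawAssessmentTable(names, specs, labels)

    x = np.empty((m, len(specs)), dtype=float)
    for j, spec in enumerate(specs):
        levels = np.arange(spec.scale_min, spec.scale_max + 1)
        probs = _label_probs(len(levels), config.label_skew)[::-1]
        if j in degenerate:
            x[:, j] = rng.choice(levels, p=probs)
        else:
            x[:, j] = rng.choice(levels, size=m, p=probs)
    names = tuple(f"Alt{i + 1}" for i in range(m))
    return DecisionMatrix(names, specs, x)
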