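"""Scenario grids and ranking comparison for sensitivity analysis.

Runs ARAS once per (criterion, dominance factor) cell plus the entropy and
equal-weight baselines, compares rankings, and assembles wide/long summary
tables and a best-option report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import kendalltau

from .aras import ArasResult, run_aras
from .conversion import DecisionMatrix
from .entropy import entropy_weights
from .errors import StructuralError
from .scenarios import dominance_weights, equal_weights, scenario_label

__all__ = [
    "ScenarioGrid",
    "RankComparison",
    "run_scenario_grid",
    "compare_rankings",
    "best_option_report",
]


@dataclass(frozen=True)
class RankComparison:
    """Agreement between two rankings of the same alternatives."""

    identical: bool
    kendall_tau: float
    first_divergence: int | None  # earliest differing rank position (1-based)


def compare_rankings(a: ArasResult, b: ArasResult) -> RankComparison:
    """Compare two ARAS rankings: identity flag, Kendall tau, first divergence."""
    if set(a.alternative_names) != set(b.alternative_names):
        raise StructuralError("rankings cover different alternative sets")
    ranks_a = [a.rank_of(name) for name in a.alternative_names]
    ranks_b = [b.rank_of(name) for name in a.alternative_names]
    if len(ranks_a) < 2:
        tau = 1.0
    else:
        tau = float(kendalltau(ranks_a, ranks_b).statistic)
    first = None
    for pos, (x, y) in enumerate(zip(a.ranking, b.ranking), start=1):
        if x != y:
            first = pos
            break
    return RankComparison(identical=first is None, kendall_tau=tau, first_divergence=first)


@dataclass(frozen=True)
class ScenarioGrid:
    """All dominance-scenario ARAS runs plus the baselines.

    ``cells`` is keyed by ``(criterion_name, scenario_label)``.
    """

    matrix: DecisionMatrix
    cells: Mapping[tuple[str, str], ArasResult]
    baselines: Mapping[str, ArasResult]
    k_by_label: Mapping[str, float] = field(default_factory=dict)

    @property
    def scenario_labels(self) -> tuple[str, ...]:
        seen: list[str] = []
        for _, label in self.cells:
            if label not in seen:
                seen.append(label)
        return tuple(seen)

    def cell(self, criterion: str, label: str) -> ArasResult:
        return self.cells[(criterion, label)]

    def to_long_frame(self) -> pd.DataFrame:
        """Long format: one row per (criterion, scenario, rank, alternative, K)."""
        records = []
        for (crit, label), res in self.cells.items():
            for pos, name in enumerate(res.ranking, start=1):
                records.append(
                    {
                        "criterion": crit,
                        "scenario": label,
                        "rank": pos,
                        "alternative": name,
                        "K": res.utility_of(name),
                    }
                )
        return pd.DataFrame.from_records(records)

    def to_wide_frame(self, digits: int = 2) -> pd.DataFrame:
        """Wide table: rank positions as rows, (criterion, scenario) columns."""
        short = {name: f"A{i + 1}" for i, name in enumerate(self.matrix.alternative_names)}
        cols = {}
        for (crit, label), res in self.cells.items():
            cols[(crit, label)] = [
                f"{short[name]} ({res.utility_of(name):.{digits}f})"
                for name in res.ranking
            ]
        frame = pd.DataFrame(cols)
        frame.index = pd.Index(range(1, len(frame) + 1), name="rank")
        frame.columns = pd.MultiIndex.from_tuples(frame.columns, names=["criterion", "scenario"])
        return frame


def run_scenario_grid(
    matrix: DecisionMatrix,
    k_values: Sequence[float] = (3, 2),
    *,
    include_entropy: bool = True,
) -> ScenarioGrid:
    """Run ARAS for every criterion x dominance factor, plus baselines.

    ``k = 3`` is labelled "S1" and ``k = 2`` "S2"; other factors get
    ``"k=<value>"`` labels.  The equal-weight baseline is always computed;
    the entropy baseline can be skipped (e.g. for degenerate matrices).
    """
    names = matrix.criterion_names
    n = matrix.n_criteria
    baselines: dict[str, ArasResult] = {
        "equal": run_aras(matrix, equal_weights(n, names))
    }
    if include_entropy:
        w_ent, _ = entropy_weights(matrix)
        baselines["entropy"] = run_aras(matrix, w_ent)
    cells: dict[tuple[str, str], ArasResult] = {}
    k_by_label: dict[str, float] = {}
    for k in k_values:
        label = scenario_label(k)
        k_by_label[label] = float(k)
        for j, crit in enumerate(names):
            cells[(crit, label)] = run_aras(matrix, dominance_weights(n, j, k, names))
    return ScenarioGrid(matrix=matrix, cells=cells, baselines=baselines, k_by_label=k_by_label)


def best_option_report(grid: ScenarioGrid, digits: int = 2) -> dict:
    """Summarise the winner (top-ranked alternative and its K) per scenario cell.

    Machine-readable; render with :func:`format_best_option_report` for humans.
    """
    report: dict = {"baselines": {}, "scenarios": []}
    for name, res in grid.baselines.items():
        report["baselines"][name] = {
            "winner": res.best,
            "K": round(float(res.K.max()), digits),
        }
    for (crit, label), res in grid.cells.items():
        report["scenarios"].append(
            {
                "criterion": crit,
                "scenario": label,
                "winner": res.best,
                "K": round(float(res.K.max()), digits),
            }
        )
    return report


def format_best_option_report(report: dict) -> str:
    lines = ["Best option per weighting", "=" * 26]
    for name, entry in report["baselines"].items():
        lines.append(f"baseline [{name}]: {entry['winner']} (K = {entry['K']})")
    for entry in report["scenarios"]:
        lines.append(
            f"{entry['scenario']} dominant {entry['criterion']!r}: "
            f"{entry['winner']} (K = {entry['K']})"
        )
    return "\n".join(lines)


def export_grid(grid: ScenarioGrid, out_dir: str | Path, fmt: str = "csv", digits: int = 2) -> list[Path]:
    """Write the long CSV/JSON grid and the wide Markdown table; return paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    long = grid.to_long_frame()
    if fmt == "json":
        p = out_dir / "scenario_grid.json"
        p.write_text(long.to_json(orient="records", indent=2), encoding="utf-8")
    else:
        p = out_dir / "scenario_grid.csv"
        long.to_csv(p, index=False)
    written.append(p)
    p_md = out_dir / "scenario_grid.md"
    p_md.write_text(grid.to_wide_frame(digits=digits).to_markdown(), encoding="utf-8")
    written.append(p_md)
    p_best = out_dir / "best_options.json"
    p_best.write_text(json.dumps(best_option_report(grid, digits), indent=2), encoding="utf-8")
    written.append(p_best)
    return written
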