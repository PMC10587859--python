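import numpy as np
import pytest

from araskit.aras import run_aras
from araskit.errors import StructuralError
from araskit.rounding import round_half_away
from araskit.scenarios import dominance_weights, equal_weights
from araskit.sensitivity import (
    ScenarioGrid,
    best_option_report,
    compare_rankings,
    format_best_option_report,
    run_scenario_grid,
)

from reference_values import SCENARIO_CELLS_2DP, SCENARIO_EXCLUSIONS


@pytest.fixture(scope="module")
def case_grid(case_matrix):
    return run_scenario_grid(case_matrix, (3, 2))


class TestScenarioGrid:
    def test_grid_covers_all_cells(self, case_grid, case_matrix):
        assert case_grid.scenario_labels == ("S1", "S2")
        assert len(case_grid.cells) == 16
        for crit in case_matrix.criterion_names:
            for label in ("S1", "S2"):
                assert (crit, label) in case_grid.cells

    def test_every_cell_ranking_is_permutation(self, case_grid, case_matrix):
        for res in case_grid.cells.values():
            assert sorted(res.ranking) == sorted(case_matrix.alternative_names)

    def test_published_cells_reproduce(self, case_grid, case_matrix):
        names = case_matrix.alternative_names
        checked = 0
        for (label, crit_idx), cells in SCENARIO_CELLS_2DP.items():
            res = case_grid.cell(case_matrix.criterion_names[crit_idx - 1], label)
            for opt, printed in cells.items():
                if (label, crit_idx, opt) in SCENARIO_EXCLUSIONS:
                    continue
                got = round_half_away(res.utility_of(names[opt - 1]), 2)
                assert got == pytest.approx(printed, abs=1e-9), (label, crit_idx, opt)
                checked += 1
        assert checked == 16 * 7 - len(SCENARIO_EXCLUSIONS)

    def test_excluded_cells_really_disagree(self, case_grid, case_matrix):
        # the exclusion list must stay honest: each entry differs from the
        # print by more than 0.005 under exact recomputation
        names = case_matrix.alternative_names
        for label, crit_idx, opt in SCENARIO_EXCLUSIONS:
            res = case_grid.cell(case_matrix.criterion_names[crit_idx - 1], label)
            printed = SCENARIO_CELLS_2DP[(label, crit_idx)][opt]
            assert abs(res.utility_of(names[opt - 1]) - printed) > 0.005

    def test_published_orderings_reproduce(self, case_grid, case_matrix):
        # the within-column ordering of every published cell is reproduced
        names = case_matrix.alternative_names
        for (label, crit_idx), cells in SCENARIO_CELLS_2DP.items():
            res = case_grid.cell(case_matrix.criterion_names[crit_idx - 1], label)
            expected = tuple(names[opt - 1] for opt in cells)
            assert res.ranking == expected, (label, crit_idx)

    def test_named_headline_cells(self, case_grid, case_matrix):
        c1 = case_matrix.criterion_names[0]
        c3 = case_matrix.criterion_names[2]
        a7 = case_matrix.alternative_names[6]
        a2 = case_matrix.alternative_names[1]
        assert round_half_away(case_grid.cell(c1, "S1").utility_of(a7), 2) == 0.80
        assert round_half_away(case_grid.cell(c1, "S2").utility_of(a7), 2) == 0.78
        assert round_half_away(case_grid.cell(c3, "S1").utility_of(a2), 2) == 0.69
        assert case_grid.cell(c3, "S1").best == a2

    def test_k_one_reproduces_equal_ranking(self, case_matrix):
        grid = run_scenario_grid(case_matrix, (1,))
        equal = grid.baselines["equal"]
        for res in grid.cells.values():
            assert res.ranking == equal.ranking
            np.testing.assert_allclose(res.K, equal.K, atol=1e-12)

    def test_long_frame(self, case_grid):
        frame = case_grid.to_long_frame()
        assert set(frame.columns) == {"criterion", "scenario", "rank", "alternative", "K"}
        assert len(frame) == 16 * 7

    def test_wide_frame(self, case_grid):
        wide = case_grid.to_wide_frame(digits=2)
        assert wide.shape == (7, 16)
        assert wide.iloc[0, 0].startswith("A7 (0.80)")


class TestCompareRankings:
    def test_entropy_vs_equal_identical(self, case_matrix, case_grid):
        cmp = compare_rankings(case_grid.baselines["entropy"], case_grid.baselines["equal"])
        assert cmp.identical
        assert cmp.kendall_tau == pytest.approx(1.0)
        assert cmp.first_divergence is None

    def test_self_comparison(self, case_grid):
        res = case_grid.baselines["entropy"]
        cmp = compare_rankings(res, res)
        assert cmp.identical and cmp.kendall_tau == pytest.approx(1.0)

    def test_reversal(self, case_matrix):
        # flipping every criterion direction reverses preferences enough to
        # check the tau = -1 path via a constructed reverse ranking
        from araskit.aras import ArasResult
        from araskit.entropy import WeightVector

        res = run_aras(case_matrix, equal_weights(8, case_matrix.criterion_names))
        reversed_res = ArasResult(
            alternative_names=res.alternative_names,
            weights=res.weights,
            extended=res.extended,
            normalized=res.normalized,
            weighted=res.weighted,
            S=res.S,
            S_opt=res.S_opt,
            K=-res.K,  # descending sort of -K reverses the order
        )
        cmp = compare_rankings(res, reversed_res)
        assert cmp.kendall_tau == pytest.approx(-1.0)
        assert not cmp.identical
        assert cmp.first_divergence == 1

    def test_mismatched_alternatives(self, case_grid):
        from araskit.conversion import CriterionSpec, DecisionMatrix, Direction

        specs = (CriterionSpec("x", Direction.MAX, rule_id=None, scale_min=1, scale_max=5),)
        other = run_aras(
            DecisionMatrix(("p", "q"), specs, np.array([[1.0], [2.0]])),
            equal_weights(1, ("x",)),
        )
        with pytest.raises(StructuralError):
            compare_rankings(case_grid.baselines["equal"], other)


class TestBestOptionReport:
    def test_baseline_winner(self, case_grid):
        report = best_option_report(case_grid)
        assert (
            report["baselines"]["entropy"]["winner"]
            == "Implant-supported fixed provisional restoration"
        )
        assert report["baselines"]["entropy"]["K"] == 0.78

    def test_treatment_time_s1_winner(self, case_grid, case_matrix):
        report = best_option_report(case_grid)
        entry = next(
            e
            for e in report["scenarios"]
            if e["criterion"] == "Treatment time" and e["scenario"] == "S1"
        )
        assert entry["winner"] == "Vacuum-formed appliances"
        assert entry["K"] == 0.69

    def test_empty_grid(self, case_matrix):
        grid = ScenarioGrid(matrix=case_matrix, cells={}, baselines={})
        report = best_option_report(grid)
        assert report == {"baselines": {}, "scenarios": []}

    def test_human_readable_format(self, case_grid):
        text = format_best_option_report(best_option_report(case_grid))
        assert "baseline [entropy]" in text
        assert "S1 dominant 'Treatment time'" in text


class TestWinnerPiecewiseConstant:
    def test_winner_changes_finitely_in_k(self, case_matrix):
        # winner as a function of k is piecewise constant with few switches
        ks = np.linspace(1, 6, 51)
        winners = []
        for k in ks:
            w = dominance_weights(8, 2, float(k), case_matrix.criterion_names)
            winners.append(run_aras(case_matrix, w).best)
        switches = sum(a != b for a, b in zip(winners, winners[1:]))
        assert switches <= 3
        assert winners[0] == "Implant-supported fixed provisional restoration"
        assert winners[-1] == "Vacuum-formed appliances"
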