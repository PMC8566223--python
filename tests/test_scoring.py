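"""Normalisation, scorecard ranking, global scores and validation scoring."""

import math

import numpy as np
import pandas as pd
import pytest

from glycobench.performance_tests import TestResult, run_all_tests
from glycobench.reference_sets import SiteGlycoformTable
from glycobench.scoring import (
    build_scorecard,
    global_perf,
    glycoprotein_validation,
    heatmap_table,
    normalize_scores,
    pearson_r2,
)

from conftest import make_psm, make_report


def _results(raws, test_id="N4"):
    return [TestResult(test_id, f"t{i}", raw) for i, raw in enumerate(raws)]


class TestNormalization:
    def test_divide_by_max(self):
        frame = normalize_scores(_results([2.0, 4.0, 8.0]))
        assert list(frame["normalized"]) == [0.25, 0.5, 1.0]

    def test_all_equal_normalise_to_one(self):
        frame = normalize_scores(_results([3.0, 3.0, 3.0]))
        assert list(frame["normalized"]) == [1.0, 1.0, 1.0]

    def test_min_max(self):
        frame = normalize_scores(_results([2.0, 4.0, 8.0]), method="min_max")
        assert list(frame["normalized"]) == pytest.approx([0.0, 1 / 3, 1.0])

    def test_all_zero_warns(self):
        with pytest.warns(UserWarning, match="normalised to 0"):
            frame = normalize_scores(_results([0.0, 0.0]))
        assert list(frame["normalized"]) == [0.0, 0.0]

    def test_inapplicable_stay_unnormalised(self):
        results = _results([2.0, 4.0]) + [TestResult("N4", "t9", 99.0, applicable=False)]
        frame = normalize_scores(results)
        assert math.isnan(frame.loc[frame["team_id"] == "t9", "normalized"].iloc[0])
        # the inapplicable 99 did not enter the max
        assert frame.loc[frame["team_id"] == "t1", "normalized"].iloc[0] == 1.0


class TestScorecard:
    def _card(self):
        results = []
        for i, (n2, n4) in enumerate([(0.9, 100.0), (0.7, 50.0), (0.3, 25.0)]):
            results.append(TestResult("N2", f"t{i}", n2))
            results.append(TestResult("N4", f"t{i}", n4))
        groups = {"t0": "developer", "t1": "developer", "t2": "user"}
        return build_scorecard(results, groups)

    def test_ranks_within_groups(self):
        card = self._card()
        assert card.summary.loc["t0", "rank_n"] == 1
        assert card.summary.loc["t1", "rank_n"] == 2
        assert card.summary.loc["t2", "rank_n"] == 1  # only user

    def test_overall_is_mean_of_normalized(self):
        card = self._card()
        assert card.overall("t1", "N") == pytest.approx((0.7 / 0.9 + 0.5) / 2)

    def test_overall_invariant_to_added_inapplicable_test(self):
        results = [TestResult("N2", "t0", 0.8), TestResult("N2", "t1", 0.4)]
        base = build_scorecard(results, {"t0": "user", "t1": "user"})
        extended = build_scorecard(
            results + [TestResult("N6", "t0", 0.0, applicable=False),
                       TestResult("N6", "t1", 0.0, applicable=False)],
            {"t0": "user", "t1": "user"},
        )
        assert base.summary["overall_n"].equals(extended.summary["overall_n"])

    def test_ties_share_better_rank(self):
        results = [TestResult("N2", t, v) for t, v in
                   [("a", 0.5), ("b", 0.5), ("c", 0.2)]]
        card = build_scorecard(results, {t: "user" for t in "abc"})
        assert list(card.summary.loc[["a", "b", "c"], "rank_n"]) == [1.0, 1.0, 3.0]

    def test_high_band_is_top_third(self, small_cohort, bundle):
        results, _ = run_all_tests(small_cohort.reports, bundle)
        groups = {r.team_id: r.group for r in small_cohort.reports}
        card = build_scorecard(results, groups)
        for group, members in card.summary.groupby("group").groups.items():
            block = card.summary.loc[members]
            expected = math.ceil(block["overall_n"].notna().sum() / 3)
            assert int(block["high_band_n"].sum()) >= expected  # >= because of ties
            assert block.loc[block["rank_n"] == 1, "high_band_n"].all()

    def test_rank_one_has_maximal_overall(self, small_cohort, bundle):
        results, _ = run_all_tests(small_cohort.reports, bundle)
        groups = {r.team_id: r.group for r in small_cohort.reports}
        summary = build_scorecard(results, groups).summary
        for _, block in summary.groupby("group"):
            top = block.loc[block["rank_n"] == 1, "overall_n"]
            assert np.allclose(top, block["overall_n"].max())
            # ranks form a permutation up to ties
            assert sorted(block["rank_n"].astype(int)) == sorted(
                block["overall_n"].rank(method="min", ascending=False).astype(int)
            )

    def test_heatmap_layout(self, small_cohort, bundle):
        results, _ = run_all_tests(small_cohort.reports, bundle)
        groups = {r.team_id: r.group for r in small_cohort.reports}
        card = build_scorecard(results, groups)
        table = heatmap_table(card, "N")
        assert set(table.columns) == {"N1", "N2", "N3", "N4", "N5", "N6"}
        assert len(table) == len(small_cohort.reports)


class TestPearsonR2:
    def test_affine_relation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r2(x, 2 * x + 1) == pytest.approx(1.0)

    def test_anticorrelation_squares_to_one(self):
        assert pearson_r2([1, 2, 3], [6, 5, 4]) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # x=(1,2,3,4), y=(1,3,2,4): covariance 1.0, variances 1.25 -> r=0.8
        assert pearson_r2([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.64, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            pearson_r2([1, 1, 1], [1, 2, 3])


class TestGlobalPerf:
    def test_all_unit_components(self):
        results = []
        for test_id in ("N1", "N3"):
            results.append(TestResult(test_id, "t0", 1.0, sensitivity=1.0, specificity=1.0))
        for test_id in ("N2", "N4", "N5", "N6"):
            results.append(TestResult(test_id, "t0", 1.0))
        frame = global_perf(normalize_scores(results))
        assert frame.loc["t0", "n_sensitivity"] == 1.0
        assert frame.loc["t0", "n_specificity"] == 1.0

    def test_coverage_heavy_strategy_trades_specificity(self):
        # team A maximises the coverage-side tests, team B the accuracy side
        results = []
        for team, sens, spec in [("A", 1.0, 0.5), ("B", 0.5, 1.0)]:
            results += [
                TestResult("N1", team, sens * spec, sensitivity=sens, specificity=spec),
                TestResult("N3", team, (sens + spec) / 2, sensitivity=sens, specificity=spec),
                TestResult("N2", team, spec),
                TestResult("N6", team, spec),
                TestResult("N4", team, 100 * sens),
                TestResult("N5", team, sens),
            ]
        frame = global_perf(normalize_scores(results))
        assert frame.loc["A", "n_sensitivity"] > frame.loc["A", "n_specificity"]
        assert frame.loc["B", "n_specificity"] > frame.loc["B", "n_sensitivity"]

    def test_missing_component_counted(self):
        results = [TestResult("O1", "t0", 0.8), TestResult("O5", "t0", 1.0)]
        frame = global_perf(normalize_scores(results))
        assert frame.loc["t0", "o_specificity_n_components"] == 2
        assert frame.loc["t0", "o_sensitivity_n_components"] == 0


class TestGlycoproteinValidation:
    def _site_table(self):
        frame = pd.DataFrame({
            "protein": ["P01009"] * 2,
            "site": ["Asn70"] * 2,
            "peptide": ["YLGNATAIFFLPDEGK"] * 2,
            "composition": ["Hex5HexNAc4Fuc0NeuAc2", "Hex5HexNAc4Fuc0NeuAc1"],
            "actual_fraction": [0.7, 0.3],
            "expected": [1, 1],
        })
        return SiteGlycoformTable(frame=frame)

    def _site_report(self, team_id, counts):
        psms = []
        for comp, n in counts.items():
            psms += [make_psm(team_id=team_id, spectrum_id=f"{comp}-{i}",
                              peptide="YLGNATAIFFLPDEGK", protein="P01009",
                              composition=comp) for i in range(n)]
        return make_report(team_id=team_id, psms=psms)

    def test_dot_product_and_cross_team_normalisation(self):
        # team approx reports (0.6, 0.4) -> 0.6*0.7 + 0.4*0.3 = 0.54;
        # team exact reports the actual split -> 0.7^2 + 0.3^2 = 0.58 (the max)
        reports = [
            self._site_report("approx", {"Hex5HexNAc4NeuAc2": 6, "Hex5HexNAc4NeuAc1": 4}),
            self._site_report("exact", {"Hex5HexNAc4NeuAc2": 7, "Hex5HexNAc4NeuAc1": 3}),
        ]
        frame = glycoprotein_validation(reports, self._site_table())
        assert frame.loc["exact", "specificity"] == pytest.approx(1.0)
        assert frame.loc["approx", "specificity"] == pytest.approx(0.54 / 0.58)
        assert frame.loc["exact", "sensitivity"] == 1.0  # both expected glycoforms seen
        assert frame.loc["exact", "combined"] == pytest.approx(1.0)

    def test_team_missing_all_proteins_scores_zero(self):
        reports = [
            self._site_report("present", {"Hex5HexNAc4NeuAc2": 5}),
            make_report(team_id="absent",
                        psms=[make_psm(team_id="absent", protein="Q00000",
                                       peptide="LVNEVTEFAK")]),
        ]
        frame = glycoprotein_validation(reports, self._site_table())
        assert frame.loc["absent", "combined"] == 0.0
        assert frame.loc["absent", "n_proteins_reported"] == 0

    def test_validation_tracks_overall_score_on_cohort(self, small_cohort, bundle):
        results, _ = run_all_tests(small_cohort.reports, bundle)
        groups = {r.team_id: r.group for r in small_cohort.reports}
        card = build_scorecard(results, groups)
        validation = glycoprotein_validation(small_cohort.reports, bundle.site_glycoforms)
        overall = card.summary.loc[validation.index, "overall_n"]
        assert pearson_r2(validation["combined"], overall) > 0.3
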