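"""Confusion accounting, sensitivity, delay averaging, harm, concordance."""

import random

import pytest

import clinalg as ca
from clinalg.cohort import NO_DIAGNOSIS, Case, ObservedManagement
from clinalg.engine import TraversalResult, TraversalStatus
from clinalg.evaluation import (
    concordance,
    harm,
    mean_delay,
    reconstruct_case_stream,
    score_case,
    sensitivity,
    tabulate,
)
from clinalg.reporting import load_delay_table

from conftest import make_minimal, make_patient

COVERED = frozenset({"A", "B", "C"})


def fit_result(dx, pid="p"):
    return TraversalResult(pid, "alg", TraversalStatus.FIT, dx, (), 0.0, 0)


def nofit_result(pid="p"):
    return TraversalResult(pid, "alg", TraversalStatus.NO_FIT_MISSING_FINDING, None, (), 0.0, 0)


class TestScoreCase:
    def test_correct_prediction(self):
        assert score_case("A", fit_result("A"), COVERED) == [("A", "tp")]

    def test_wrong_prediction_counts_both_ways(self):
        """A wrong diagnosis is a miss for the true condition and a
        commission error for the predicted one."""
        assert sorted(score_case("A", fit_result("B"), COVERED)) == [("A", "fn"), ("B", "fp")]

    def test_no_fit_is_fn_only(self):
        assert score_case("A", nofit_result(), COVERED) == [("A", "fn")]

    def test_fit_without_diagnosis_is_fn_only(self):
        assert score_case("A", fit_result(None), COVERED) == [("A", "fn")]

    def test_sentinel_cases(self):
        assert score_case(NO_DIAGNOSIS, fit_result("B"), COVERED) == [("B", "fp")]
        assert score_case(NO_DIAGNOSIS, nofit_result(), COVERED) == []

    def test_uncovered_prediction_rejected(self):
        with pytest.raises(ValueError, match="covered"):
            score_case("A", fit_result("Z"), COVERED)


class TestTabulate:
    def test_single_correct_case(self):
        cells = tabulate([Case("p", "A")], [fit_result("A")], {"A"})
        assert (cells["A"].tp, cells["A"].fp, cells["A"].fn, cells["A"].tn) == (1, 0, 0, 0)
        assert cells["A"].fit == 1

    def test_replay_of_packaged_counts_reproduces_them(self, count_tables):
        """A case stream consistent with the published count table, replayed
        through the per-case accounting rule, reproduces every cell."""
        for alg_id, cells in count_tables.items():
            cases, results = reconstruct_case_stream(cells, alg_id)
            replayed = tabulate(cases, results, set(cells))
            for dx, cell in cells.items():
                got = replayed[dx]
                assert (got.tp, got.fp, got.fn, got.tn, got.fit, got.n_cases) == (
                    cell.tp, cell.fp, cell.fn, cell.tn, cell.fit, cell.n_cases
                ), (alg_id, dx)

    def test_table2_row_tb_smear_positive(self, count_tables):
        cell = count_tables["chuk"]["tb_smear_positive"]
        assert (cell.fp, cell.tp, cell.fn, cell.tn) == (1, 42, 1, 140)

    @pytest.mark.parametrize("seed", range(50))
    def test_conservation_on_random_streams(self, seed):
        """Every diagnosis row of a tabulated random 50-case stream sums to
        the case total, and TP+FN totals the in-scope cases."""
        rng = random.Random(seed)
        dxs = ["A", "B", "C"]
        cases, results = [], []
        for i in range(50):
            true = rng.choice(dxs + [NO_DIAGNOSIS])
            cases.append(Case(f"p{i}", true))
            roll = rng.random()
            if roll < 0.2:
                results.append(nofit_result(f"p{i}"))
            elif roll < 0.3:
                results.append(fit_result(None, f"p{i}"))
            else:
                results.append(fit_result(rng.choice(dxs), f"p{i}"))
        cells = tabulate(cases, results, set(dxs))
        n_in_scope = sum(c.true_diagnosis != NO_DIAGNOSIS for c in cases)
        for cell in cells.values():
            assert cell.tp + cell.fp + cell.fn + cell.tn == 50
        assert sum(c.tp + c.fn for c in cells.values()) == n_in_scope
        # oracle equivalence: direct per-case counter replay
        brute = {dx: {"tp": 0, "fp": 0, "fn": 0} for dx in dxs}
        for case, result in zip(cases, results):
            for dx, counter in score_case(case.true_diagnosis, result, set(dxs)):
                brute[dx][counter] += 1
        for dx in dxs:
            assert (cells[dx].tp, cells[dx].fp, cells[dx].fn) == (
                brute[dx]["tp"], brute[dx]["fp"], brute[dx]["fn"]
            )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="cases"):
            tabulate([Case("p", "A")], [], {"A"})


class TestSensitivity:
    def test_restricted_from_published_totals(self, count_tables):
        assert sensitivity(count_tables["chuk"]) == pytest.approx(100 * 176 / 184)
        assert round(sensitivity(count_tables["chuk"]), 1) == 95.7

    def test_all_correct_is_100(self):
        cells = {"A": ca.ConfusionCell("A", tp=5)}
        assert sensitivity(cells) == 100.0

    def test_inclusive_denominator(self, count_tables):
        value = sensitivity(count_tables["who"], "inclusive", n_enrolled=201)
        assert round(value, 1) == 64.2

    def test_zero_denominator_raises(self):
        with pytest.raises(ZeroDivisionError):
            sensitivity({"A": ca.ConfusionCell("A")})


class TestMeanDelay:
    def test_weighted_chuk_matches_published_average(self, count_tables):
        delays = load_delay_table(ca.fixture_path("table3_delays.csv"))["chuk_days"]
        counts = {dx: c.n_cases for dx, c in count_tables["chuk"].items()}
        assert round(mean_delay(delays, counts, weighted=True), 2) == 1.86

    def test_constant_delays(self):
        delays = {"A": 2.0, "B": 2.0}
        counts = {"A": 3, "B": 9}
        assert mean_delay(delays, counts, weighted=True) == 2.0
        assert mean_delay(delays, counts, weighted=False) == 2.0

    def test_weighting_arithmetic(self):
        delays = {"A": 1.0, "B": 3.0}
        counts = {"A": 3, "B": 1}
        assert mean_delay(delays, counts, weighted=True) == pytest.approx(1.5)
        assert mean_delay(delays, counts, weighted=False) == pytest.approx(2.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mean_delay({}, {})


class TestHarm:
    def test_published_splits(self, count_tables, harm_weights):
        msf = harm(count_tables["msf"], harm_weights)
        assert (msf.commission, msf.omission, msf.total) == (64, 176, 240)
        who = harm(count_tables["who"], harm_weights)
        assert who.total == 487.5
        chuk = harm(count_tables["chuk"], harm_weights)
        assert (chuk.commission, chuk.omission) == (27, 63)

    def test_no_errors_no_harm(self):
        cells = {"A": ca.ConfusionCell("A", tp=10, tn=5)}
        weights = ca.HarmWeights({"A": (8.0, 4.0)})
        assert harm(cells, weights) == ca.HarmScore(0.0, 0.0)

    def test_harm_strictly_increasing_in_errors(self, harm_weights):
        base = {"pcp": ca.ConfusionCell("pcp", fp=1, fn=1)}
        more_fp = {"pcp": ca.ConfusionCell("pcp", fp=2, fn=1)}
        more_fn = {"pcp": ca.ConfusionCell("pcp", fp=1, fn=2)}
        h0 = harm(base, harm_weights).total
        assert harm(more_fp, harm_weights).total > h0
        assert harm(more_fn, harm_weights).total > h0

    def test_missing_weight_for_erroneous_diagnosis(self):
        cells = {"A": ca.ConfusionCell("A", fn=1)}
        with pytest.raises(KeyError, match="A"):
            harm(cells, ca.HarmWeights({"B": (8, 4)}))


class TestConcordance:
    def setup_method(self):
        self.alg = make_minimal()

    def result(self, tests=("chest_xray", "sputum_smear"), dx="tb"):
        return TraversalResult("p", "alg", TraversalStatus.FIT, dx, (), 0.0, 0)

    def test_identical_management(self, chuk):
        profiles = ca.calibrate_profiles(chuk)
        findings = {f: v for f, (v, _p) in profiles["tb_smear_positive"].items()}
        result = ca.traverse(chuk, make_patient(findings=findings))
        observed = ObservedManagement(
            tests=ca.tests_along_path(chuk, result), treatment="tb_smear_positive"
        )
        assert concordance(result, observed, chuk) == 10

    def test_same_tests_different_order_is_similar(self, chuk):
        profiles = ca.calibrate_profiles(chuk)
        findings = {f: v for f, (v, _p) in profiles["tb_smear_positive"].items()}
        result = ca.traverse(chuk, make_patient(findings=findings))
        reordered = tuple(reversed(ca.tests_along_path(chuk, result)))
        observed = ObservedManagement(tests=reordered, treatment="tb_smear_positive")
        assert concordance(result, observed, chuk) == 8

    def test_different_treatment_scores_zero(self, chuk):
        profiles = ca.calibrate_profiles(chuk)
        findings = {f: v for f, (v, _p) in profiles["tb_smear_positive"].items()}
        result = ca.traverse(chuk, make_patient(findings=findings))
        observed = ObservedManagement(
            tests=ca.tests_along_path(chuk, result), treatment="pcp"
        )
        assert concordance(result, observed, chuk) == 0


class TestEvaluateAlgorithm:
    def test_empty_cohort_no_crash(self, chuk):
        report = ca.evaluate_algorithm(chuk, [])
        assert report.n_cases == 0
        assert report.fit_count == 0

    def test_study_shaped_cohort_report(self, chuk, harm_weights, study_cohort):
        """On the packaged noise-free archetype cohort only the dual
        diagnosis can be missed: 183/184 correct, every case fits."""
        report = ca.evaluate_algorithm(
            chuk, study_cohort, weights=harm_weights, n_enrolled=len(study_cohort)
        )
        assert report.n_cases == 184
        assert report.fit_count == 184
        assert report.sensitivity_restricted == pytest.approx(100 * 183 / 184)
        total_fn = sum(c.fn for c in report.cells.values())
        assert total_fn == 1
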