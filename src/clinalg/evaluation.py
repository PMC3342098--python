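"""Confusion accounting, sensitivity, delay summaries and harm scoring.

The accounting rule for a routed case is asymmetric by design: a flowchart
that reaches the wrong diagnosis produces *both* a false negative for the
true condition (it was missed) and a false positive for the condition it
wrongly assigned (a commission error).  A case that fails to fit the
flowchart, or fits but ends at a non-diagnostic action, produces a false
negative only — there is no wrong diagnosis to charge.  This is what makes
the per-diagnosis TP+FN sums add up to the full case count even when some
cases never fit.

Harm is scored by weighting each error with a per-diagnosis intuitive harm
weight on a 0-10 scale: omission weights multiply false negatives,
commission weights multiply false positives, and the totals are summed over
diagnoses.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

from .cohort import SENTINELS, Case, HarmWeights, ObservedManagement, PatientRecord
from .engine import TraversalResult, TraversalStatus, tests_along_path, traverse_cohort
from .flowchart import ClinicalAlgorithm

__all__ = [
    "ConfusionCell",
    "HarmScore",
    "EvaluationReport",
    "score_case",
    "tabulate",
    "sensitivity",
    "mean_delay",
    "harm",
    "concordance",
    "evaluate_algorithm",
    "report_from_counts",
    "load_counts",
    "write_counts",
    "reconstruct_case_stream",
]


@dataclass
class ConfusionCell:
    """Per-diagnosis error counts — one row of a per-algorithm accuracy table.

    ``fit`` counts the cases of this diagnosis that found a pathway through
    the flowchart (whether or not the pathway ended at the right diagnosis);
    ``n_cases`` is the number of cases whose true diagnosis this is.
    """

    diagnosis: str
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0
    fit: int = 0
    n_cases: int = 0


@dataclass(frozen=True)
class HarmScore:
    commission: float
    omission: float

    @property
    def total(self) -> float:
        return self.commission + self.omission


def score_case(
    true_diagnosis: str,
    result: TraversalResult,
    covered: frozenset | set,
) -> list[tuple[str, str]]:
    """Counter increments for one routed case.

    Returns ``(diagnosis, counter)`` pairs with counter in ``{"tp", "fp",
    "fn"}``.  A sentinel true diagnosis contributes a false positive only
    when a diagnosis was wrongly reached, nothing otherwise.
    """
    predicted = result.terminal_diagnosis if result.status is TraversalStatus.FIT else None
    if predicted is not None and predicted not in covered:
        raise ValueError(
            f"predicted diagnosis {predicted!r} is not in the covered set of "
            f"algorithm {result.algorithm_id!r}"
        )
    if true_diagnosis in SENTINELS:
        return [(predicted, "fp")] if predicted is not None else []
    if predicted == true_diagnosis:
        return [(true_diagnosis, "tp")]
    if predicted is not None:
        return [(true_diagnosis, "fn"), (predicted, "fp")]
    return [(true_diagnosis, "fn")]


def tabulate(
    cases: list[Case],
    results: list[TraversalResult],
    covered: frozenset | set,
) -> dict[str, ConfusionCell]:
    """Aggregate per-case increments into per-diagnosis confusion cells.

    True negatives are completed by conservation: for every diagnosis,
    ``tn = N - tp - fp - fn`` with N the number of cases scored.
    """
    if len(cases) != len(results):
        raise ValueError(f"{len(cases)} cases but {len(results)} results")
    cells = {dx: ConfusionCell(diagnosis=dx) for dx in sorted(covered)}
    for case, result in zip(cases, results):
        for dx, counter in score_case(case.true_diagnosis, result, covered):
            setattr(cells[dx], counter, getattr(cells[dx], counter) + 1)
        if case.true_diagnosis in cells:
            cells[case.true_diagnosis].n_cases += 1
            if result.status is TraversalStatus.FIT:
                cells[case.true_diagnosis].fit += 1
    n = len(cases)
    for cell in cells.values():
        cell.tn = n - cell.tp - cell.fp - cell.fn
    return cells


def sensitivity(
    cells: dict[str, ConfusionCell],
    denominator_mode: str = "restricted",
    n_enrolled: int | None = None,
) -> float:
    """Overall sensitivity in percent.

    ``restricted`` divides total true positives by in-scope cases (TP+FN);
    ``inclusive`` divides by the number of enrolled patients, counting the
    undiagnosed and rare-diagnosis patients in the denominator.
    """
    tp = sum(c.tp for c in cells.values())
    if denominator_mode == "restricted":
        denom = tp + sum(c.fn for c in cells.values())
    elif denominator_mode == "inclusive":
        if n_enrolled is None:
            raise ValueError("inclusive sensitivity requires n_enrolled")
        denom = n_enrolled
    else:
        raise ValueError(f"unknown denominator_mode {denominator_mode!r}")
    if denom == 0:
        raise ZeroDivisionError("sensitivity denominator is zero")
    return 100.0 * tp / denom


def mean_delay(
    per_diagnosis_delays: dict[str, float],
    case_counts: dict[str, int],
    weighted: bool = True,
) -> float:
    """Average per-diagnosis delay-to-management in days.

    The case-weighted mean weights each diagnosis by its case count; the
    unweighted mean averages over diagnoses regardless of frequency.
    """
    if not per_diagnosis_delays:
        raise ValueError("no delays given")
    if set(per_diagnosis_delays) != set(case_counts):
        raise ValueError("delay and case-count tables cover different diagnoses")
    if not weighted:
        return sum(per_diagnosis_delays.values()) / len(per_diagnosis_delays)
    total_cases = sum(case_counts.values())
    if total_cases == 0:
        raise ValueError("zero total cases")
    return sum(per_diagnosis_delays[d] * case_counts[d] for d in per_diagnosis_delays) / total_cases


def harm(cells: dict[str, ConfusionCell], weights: HarmWeights) -> HarmScore:
    """Harm-weighted error score: commission = Σ fp·w_commission, omission =
    Σ fn·w_omission, summed over diagnoses."""
    commission = omission = 0.0
    for dx, cell in cells.items():
        if cell.fp == 0 and cell.fn == 0:
            continue
        if dx not in weights.diagnoses:
            raise KeyError(f"no harm weights for diagnosis {dx!r} (fp={cell.fp}, fn={cell.fn})")
        commission += cell.fp * weights.commission(dx)
        omission += cell.fn * weights.omission(dx)
    return HarmScore(commission=commission, omission=omission)


def concordance(
    result: TraversalResult,
    observed: ObservedManagement,
    alg: ClinicalAlgorithm,
) -> int:
    """Score agreement between the flowchart's virtual management and the
    observed ward management on the 10/8/0 scale.

    identical (10): same ordered test sequence and same terminal decision;
    similar (8): same tests in a different order, same terminal decision;
    different (0): anything else, in particular a different terminal
    decision.  The observed treatment label is compared against the
    traversal's terminal diagnosis.
    """
    virtual_tests = tests_along_path(alg, result)
    decision = result.terminal_diagnosis
    if decision is None or observed.treatment != decision:
        return 0
    if tuple(observed.tests) == virtual_tests:
        return 10
    if sorted(observed.tests) == sorted(virtual_tests):
        return 8
    return 0


# ---------------------------------------------------------------------------
# whole-algorithm reports


@dataclass
class EvaluationReport:
    """Everything one flowchart scores on one cohort (or count table)."""

    algorithm_id: str
    cells: dict[str, ConfusionCell]
    n_cases: int
    sensitivity_restricted: float
    sensitivity_inclusive: float | None
    fit_count: int
    fit_rate: float
    mean_delay_weighted: float | None
    mean_delay_unweighted: float | None
    harm_score: HarmScore | None = None
    excluded_cases: int = 0

    @property
    def harm_commission(self):
        return None if self.harm_score is None else self.harm_score.commission

    @property
    def harm_omission(self):
        return None if self.harm_score is None else self.harm_score.omission

    @property
    def harm_total(self):
        return None if self.harm_score is None else self.harm_score.total


def _report(
    algorithm_id: str,
    cells: dict[str, ConfusionCell],
    n_cases: int,
    weights: HarmWeights | None,
    delays: dict[str, float] | None,
    n_enrolled: int | None,
    excluded: int,
) -> EvaluationReport:
    fit_count = sum(c.fit for c in cells.values())
    counts = {dx: c.n_cases for dx, c in cells.items()}
    mdw = mdu = None
    if delays is not None:
        active = {dx: d for dx, d in delays.items() if counts.get(dx, 0) > 0}
        if active:
            mdw = mean_delay(active, {dx: counts[dx] for dx in active}, weighted=True)
            mdu = mean_delay(active, {dx: counts[dx] for dx in active}, weighted=False)
    in_scope = sum(c.tp + c.fn for c in cells.values())
    return EvaluationReport(
        algorithm_id=algorithm_id,
        cells=cells,
        n_cases=n_cases,
        sensitivity_restricted=(
            sensitivity(cells, "restricted") if in_scope else float("nan")
        ),
        sensitivity_inclusive=(
            sensitivity(cells, "inclusive", n_enrolled) if n_enrolled else None
        ),
        fit_count=fit_count,
        fit_rate=100.0 * fit_count / n_cases if n_cases else 0.0,
        mean_delay_weighted=mdw,
        mean_delay_unweighted=mdu,
        harm_score=harm(cells, weights) if weights is not None else None,
        excluded_cases=excluded,
    )


def evaluate_algorithm(
    alg: ClinicalAlgorithm,
    cohort: list[PatientRecord],
    weights: HarmWeights | None = None,
    n_enrolled: int | None = None,
    max_loop_iterations: int = 3,
) -> EvaluationReport:
    """Route a cohort through a flowchart and score it end to end.

    Cases outside the flowchart's diagnosis spectrum and sentinel cases are
    excluded from the restricted confusion table (their count is reported);
    per-diagnosis delays come from the traversals themselves.
    """
    from .cohort import expand_cases, filter_in_scope

    cases = expand_cases(cohort)
    covered = alg.diagnoses_covered
    in_scope, excluded = filter_in_scope(cases, covered)
    results = traverse_cohort(alg, in_scope, cohort, max_loop_iterations=max_loop_iterations)
    cells = tabulate(in_scope, results, covered)
    delays: dict[str, list[float]] = {}
    for case, result in zip(in_scope, results):
        delays.setdefault(case.true_diagnosis, []).append(result.delay_days)
    per_dx_delay = {dx: sum(v) / len(v) for dx, v in delays.items()}
    return _report(
        alg.algorithm_id, cells, len(in_scope), weights, per_dx_delay, n_enrolled, len(excluded)
    )


def report_from_counts(
    algorithm_id: str,
    cells: dict[str, ConfusionCell],
    weights: HarmWeights | None = None,
    delays: dict[str, float] | None = None,
    n_enrolled: int | None = None,
) -> EvaluationReport:
    """Score a pre-tabulated accuracy table directly (the replication path:
    no traversal, the counts are the input)."""
    n_cases = sum(c.n_cases for c in cells.values())
    return _report(algorithm_id, cells, n_cases, weights, delays, n_enrolled, 0)


# ---------------------------------------------------------------------------
# count-table I/O and case-stream reconstruction

_COUNT_COLUMNS = ("algorithm", "diagnosis", "n_cases", "fp", "tp", "fn", "tn", "fit")


def load_counts(path) -> dict[str, dict[str, ConfusionCell]]:
    """Read a per-algorithm × per-diagnosis count CSV
    (``algorithm,diagnosis,n_cases,fp,tp,fn,tn,fit``)."""
    tables: dict[str, dict[str, ConfusionCell]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            cell = ConfusionCell(
                diagnosis=row["diagnosis"],
                tp=int(row["tp"]),
                fp=int(row["fp"]),
                fn=int(row["fn"]),
                tn=int(row["tn"]),
                fit=int(row["fit"]),
                n_cases=int(row["n_cases"]),
            )
            tables.setdefault(row["algorithm"], {})[cell.diagnosis] = cell
    return tables


def write_counts(tables: dict[str, dict[str, ConfusionCell]], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COUNT_COLUMNS)
        for alg_id in sorted(tables):
            for dx in sorted(tables[alg_id]):
                c = tables[alg_id][dx]
                writer.writerow([alg_id, dx, c.n_cases, c.fp, c.tp, c.fn, c.tn, c.fit])


def reconstruct_case_stream(
    cells: dict[str, ConfusionCell],
    algorithm_id: str = "reconstructed",
) -> tuple[list[Case], list[TraversalResult]]:
    """Build a synthetic case/result stream consistent with a confusion
    table, for replaying the accounting rule case by case.

    For each diagnosis d the fn_d missed cases are split into: cases that
    fit and received some other diagnosis (these absorb the table's false
    positives, matched greedily to a different diagnosis), cases that fit
    but ended without a diagnosis, and cases that never fit — so that both
    the fit column and the fp column are reproduced exactly.  Raises if the
    table admits no such stream.
    """
    slack = {dx: c.fit - c.tp for dx, c in cells.items()}  # fn cases that fit
    if any(v < 0 for v in slack.values()):
        raise ValueError("fit < tp for some diagnosis: inconsistent table")
    if any(cells[dx].fn < slack[dx] for dx in cells):
        raise ValueError("fit - tp exceeds fn for some diagnosis: inconsistent table")

    # match each false positive of diagnosis e to a missed case of some d != e
    wrong_pairs: dict[str, list[str]] = {dx: [] for dx in cells}  # true dx -> predicted list
    fp_instances = [dx for dx in sorted(cells) for _ in range(cells[dx].fp)]
    remaining = dict(slack)
    for e in fp_instances:
        candidates = [d for d in sorted(cells) if d != e and remaining[d] > 0]
        if not candidates:
            raise ValueError(f"cannot attribute a false positive for {e!r} to any missed case")
        d = max(candidates, key=lambda d: (remaining[d], d))
        wrong_pairs[d].append(e)
        remaining[d] -= 1

    def _result(pid, status, diagnosis=None):
        return TraversalResult(
            patient_id=pid,
            algorithm_id=algorithm_id,
            status=status,
            terminal_diagnosis=diagnosis,
            path=(),
            delay_days=0.0,
            loop_iterations=0,
        )

    cases: list[Case] = []
    results: list[TraversalResult] = []
    i = 0
    for dx in sorted(cells):
        c = cells[dx]
        fit_no_dx = slack[dx] - len(wrong_pairs[dx])
        no_fit = c.fn - slack[dx]
        outcomes = (
            [("tp", dx)] * c.tp
            + [("wrong", p) for p in wrong_pairs[dx]]
            + [("fit_no_dx", None)] * fit_no_dx
            + [("no_fit", None)] * no_fit
        )
        for kind, pred in outcomes:
            i += 1
            pid = f"case{i:04d}"
            cases.append(Case(patient_id=pid, true_diagnosis=dx))
            if kind == "no_fit":
                results.append(_result(pid, TraversalStatus.NO_FIT_MISSING_FINDING))
            else:
                results.append(_result(pid, TraversalStatus.FIT, pred if kind != "tp" else dx))
    return cases, results
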