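"""Clinical Algorithm Nosology: structural complexity and pairwise similarity.

Two complementary instruments for comparing flowcharts independently of any
accuracy claim:

* CASA (Clinical Algorithm Structural Analysis) scores design complexity
  from structure alone: ``2·n1Dx + 1·n2D0 + Σ(Lp)i`` where n1Dx counts
  diagnostic boxes, n2D0 every other box, and each loop contributes a loop
  parameter Lp.  The source methodology does not fix how Lp is valued, so
  the rule is pluggable: ``unit`` charges 1 per backward edge, ``enclosed``
  charges the number of boxes the loop spans.

* CAPA (Clinical Algorithm Patient Abstraction) compares how two flowcharts
  would manage the same patients: each case's pathway is abstracted to its
  ordered test sequence plus terminal decision and the pair is scored
  identical (10), similar (8, same tests in a different order with the same
  decision) or different (0).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Callable

from .cohort import Case, PatientRecord
from .engine import TraversalStatus, tests_along_path, traverse_cohort
from .flowchart import Census, ClinicalAlgorithm, FlowEdge, census

__all__ = ["CasaResult", "CapaResult", "casa_score", "capa_compare", "LOOP_RULES"]


def _unit_loop(alg: ClinicalAlgorithm, edge: FlowEdge) -> float:
    return 1.0


def _enclosed_loop(alg: ClinicalAlgorithm, edge: FlowEdge) -> float:
    """Number of boxes the loop spans: nodes between the loop target and the
    loop source (inclusive) in the entry-rooted depth-first ordering."""
    index = {nid: i for i, nid in enumerate(alg.dfs_order)}
    return float(index[edge.source] - index[edge.target] + 1)


LOOP_RULES: dict[str, Callable[[ClinicalAlgorithm, FlowEdge], float]] = {
    "unit": _unit_loop,
    "enclosed": _enclosed_loop,
}


@dataclass(frozen=True)
class CasaResult:
    algorithm_id: str
    n1_dx: int
    n2_d0: int
    loop_params: tuple[float, ...]
    score: float

    @property
    def box_census(self) -> Census:
        return Census(self.n1_dx, self.n2_d0, ())


def casa_score(alg: ClinicalAlgorithm, loop_param_rule="unit") -> CasaResult:
    """CASA structural complexity: ``2·n1Dx + n2D0 + Σ Lp``.

    *loop_param_rule* is a key of :data:`LOOP_RULES` or a callable
    ``(algorithm, backward_edge) -> Lp``.
    """
    rule = LOOP_RULES[loop_param_rule] if isinstance(loop_param_rule, str) else loop_param_rule
    c = census(alg)
    loop_params = tuple(rule(alg, e) for e in c.backward_edges)
    score = 2 * c.n_diagnostic + c.n_other + sum(loop_params)
    return CasaResult(
        algorithm_id=alg.algorithm_id,
        n1_dx=c.n_diagnostic,
        n2_d0=c.n_other,
        loop_params=loop_params,
        score=score,
    )


@dataclass(frozen=True)
class CapaResult:
    algorithm_pair: tuple[str, str]
    per_case_scores: tuple[int, ...]
    n_excluded: int  # cases that failed to fit at least one of the pair

    @property
    def distribution(self) -> dict[int, float]:
        """Proportion of scored cases in each category (10/8/0)."""
        n = len(self.per_case_scores)
        counts = Counter(self.per_case_scores)
        return {s: counts.get(s, 0) / n for s in (10, 8, 0)} if n else {10: 0.0, 8: 0.0, 0: 0.0}

    @property
    def aggregate(self) -> int:
        """Modal category score over scored cases (ties go to the higher
        score); 0 when no case could be scored."""
        if not self.per_case_scores:
            return 0
        counts = Counter(self.per_case_scores)
        return max((10, 8, 0), key=lambda s: (counts.get(s, 0), s))


def _abstract(alg, result):
    return tests_along_path(alg, result), result.terminal_diagnosis


def _score_pair(abstraction_a, abstraction_b) -> int:
    tests_a, decision_a = abstraction_a
    tests_b, decision_b = abstraction_b
    if decision_a != decision_b:
        return 0
    if tests_a == tests_b:
        return 10
    if sorted(tests_a) == sorted(tests_b):
        return 8
    return 0


def capa_compare(
    alg_a: ClinicalAlgorithm,
    alg_b: ClinicalAlgorithm,
    cases: list[Case],
    cohort: list[PatientRecord],
    max_loop_iterations: int = 3,
) -> CapaResult:
    """Patient-level similarity of two flowcharts over a shared case set.

    A case that fails to fit either flowchart cannot be abstracted and is
    excluded from the distribution (its count is reported).  The comparison
    is symmetric: swapping the two flowcharts permutes nothing but the pair
    label.
    """
    results_a = traverse_cohort(alg_a, cases, cohort, max_loop_iterations)
    results_b = traverse_cohort(alg_b, cases, cohort, max_loop_iterations)
    scores = []
    excluded = 0
    for ra, rb in zip(results_a, results_b):
        if ra.status is not TraversalStatus.FIT or rb.status is not TraversalStatus.FIT:
            excluded += 1
            continue
        scores.append(_score_pair(_abstract(alg_a, ra), _abstract(alg_b, rb)))
    return CapaResult(
        algorithm_pair=(alg_a.algorithm_id, alg_b.algorithm_id),
        per_case_scores=tuple(scores),
        n_excluded=excluded,
    )
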