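"""Virtual application of a flowchart to a patient.

`traverse` simulates the step-by-step management a clinician following the
flowchart would deliver: start at the entry clinical state, answer each
dichotomous question from the patient's recorded findings, and walk until a
terminal action box is reached ("fit") or the walk stalls.  Stalls are
statuses, never exceptions: a decision that needs an unrecorded finding, a
loop traversed more often than the configured bound, or a dead end.

Delay accounting is theoretical-serial: every box consumes its turnaround
(``delay_days``) when entered, and a box re-entered through a loop consumes
it again — i.e. all investigations are assumed to run one after another,
which is the pessimistic reading clinicians in practice beat by running
tests in parallel.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .cohort import Case, PatientRecord
from .flowchart import ClinicalAlgorithm, NodeKind

__all__ = ["TraversalStatus", "TraversalResult", "traverse", "traverse_cohort", "path_delay", "tests_along_path"]


class TraversalStatus(str, enum.Enum):
    FIT = "FIT"
    NO_FIT_MISSING_FINDING = "NO_FIT_MISSING_FINDING"
    NO_FIT_LOOP_LIMIT = "NO_FIT_LOOP_LIMIT"
    NO_FIT_DEAD_END = "NO_FIT_DEAD_END"


@dataclass(frozen=True)
class TraversalResult:
    """The pathway one patient takes through one flowchart."""

    patient_id: str
    algorithm_id: str
    status: TraversalStatus
    terminal_diagnosis: str | None
    path: tuple[str, ...]
    delay_days: float
    loop_iterations: int

    @property
    def fit(self) -> bool:
        return self.status is TraversalStatus.FIT


def traverse(
    alg: ClinicalAlgorithm,
    patient: PatientRecord,
    max_loop_iterations: int = 3,
) -> TraversalResult:
    """Route *patient* through *alg*; always terminates, fully deterministic.

    At each decision box the predicate is evaluated against the patient's
    findings: true follows the yes-edge, false the no-edge, and unknown
    stops the walk with ``NO_FIT_MISSING_FINDING`` (the flowchart gives no
    guidance without the answer).  Each traversal of a backward edge counts
    one loop iteration; exceeding *max_loop_iterations* stops with
    ``NO_FIT_LOOP_LIMIT``.
    """
    path: list[str] = []
    delay = 0.0
    loops = 0
    status = TraversalStatus.FIT
    diagnosis = None
    current = alg.entry_node
    max_steps = len(alg.nodes) * (max_loop_iterations + 1) + 1  # hard safety cap

    while True:
        node = alg.nodes[current]
        path.append(current)
        delay += node.delay_days
        if len(path) > max_steps:  # unreachable for validated flowcharts
            status = TraversalStatus.NO_FIT_LOOP_LIMIT
            break

        if node.kind is NodeKind.DECISION:
            answer = node.predicate.evaluate(patient.findings)
            if answer is None:
                status = TraversalStatus.NO_FIT_MISSING_FINDING
                break
            edge = alg.outgoing(current, "yes" if answer else "no")
        else:
            edge = alg.outgoing(current, "next")
            if edge is None:  # terminal box
                if node.kind is NodeKind.DIAGNOSTIC_ACTION:
                    diagnosis = node.diagnosis
                elif node.kind is not NodeKind.OTHER_ACTION:
                    status = TraversalStatus.NO_FIT_DEAD_END
                break

        if edge is None:  # decision without the needed branch (invalid input)
            status = TraversalStatus.NO_FIT_DEAD_END
            break
        if edge.backward:
            if loops >= max_loop_iterations:
                status = TraversalStatus.NO_FIT_LOOP_LIMIT
                break
            loops += 1
        current = edge.target

    return TraversalResult(
        patient_id=patient.patient_id,
        algorithm_id=alg.algorithm_id,
        status=status,
        terminal_diagnosis=diagnosis,
        path=tuple(path),
        delay_days=delay,
        loop_iterations=loops,
    )


def traverse_cohort(
    alg: ClinicalAlgorithm,
    cases: list[Case],
    cohort: list[PatientRecord],
    max_loop_iterations: int = 3,
) -> list[TraversalResult]:
    """One :class:`TraversalResult` per case, order preserved.

    Cases are routed independently (no cross-case state); a dual-diagnosis
    patient is simply routed once per case with identical findings.
    """
    by_id = {p.patient_id: p for p in cohort}
    results = []
    for case in cases:
        try:
            patient = by_id[case.patient_id]
        except KeyError:
            raise KeyError(f"case references unknown patient_id {case.patient_id!r}") from None
        results.append(traverse(alg, patient, max_loop_iterations=max_loop_iterations))
    return results


def path_delay(alg: ClinicalAlgorithm, result: TraversalResult) -> float:
    """Serial delay of a pathway: sum of node turnarounds along the path,
    counting re-entered nodes once per entry.  Defined for non-fit paths
    too (delay accrued until the stall)."""
    try:
        return sum(alg.nodes[nid].delay_days for nid in result.path)
    except KeyError as exc:
        raise KeyError(f"path references unknown node {exc}") from None


def tests_along_path(alg: ClinicalAlgorithm, result: TraversalResult) -> tuple[str, ...]:
    """Ordered test identifiers encountered along a pathway (the 'patient
    abstraction' used by CAPA and by clinician-concordance scoring)."""
    return tuple(
        alg.nodes[nid].test_id for nid in result.path if alg.nodes[nid].test_id is not None
    )
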