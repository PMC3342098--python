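"""Shared fixtures and generators for the test suite."""

from __future__ import annotations

import random

import pytest

import clinalg as ca
from clinalg.flowchart import ClinicalAlgorithm, FlowEdge, FlowNode, NodeKind, Predicate


@pytest.fixture(scope="session")
def chuk() -> ClinicalAlgorithm:
    return ca.load_algorithm(ca.fixture_path("chuk_synthetic.yaml"))


@pytest.fixture(scope="session")
def msf() -> ClinicalAlgorithm:
    return ca.load_algorithm(ca.fixture_path("msf_synthetic.yaml"))


@pytest.fixture(scope="session")
def who() -> ClinicalAlgorithm:
    return ca.load_algorithm(ca.fixture_path("who_synthetic.yaml"))


@pytest.fixture(scope="session")
def harm_weights() -> ca.HarmWeights:
    return ca.load_harm_weights(ca.fixture_path("table4_harm.csv"))


@pytest.fixture(scope="session")
def count_tables():
    return ca.load_counts(ca.fixture_path("table2_counts.csv"))


@pytest.fixture(scope="session")
def study_cohort():
    return ca.load_cohort(ca.fixture_path("table1_cohort_synthetic.csv"))


# ---------------------------------------------------------------------------
# toy flowcharts


def make_minimal(delay: float = 0.0) -> ClinicalAlgorithm:
    """Smallest legal flowchart: clinical state -> one diagnostic box."""
    return ClinicalAlgorithm(
        algorithm_id="minimal",
        name="minimal",
        entry_node="entry",
        nodes={
            "entry": FlowNode("entry", NodeKind.CLINICAL_STATE),
            "dx": FlowNode(
                "dx", NodeKind.DIAGNOSTIC_ACTION, diagnosis="tb", delay_days=delay
            ),
        },
        edges=[FlowEdge("entry", "dx", "next")],
    )


def make_toy3() -> ClinicalAlgorithm:
    """Three boolean decisions; terminal diagnosis is a pure function of
    findings a, b, c (truth table enumerable by hand)."""
    n = {
        "entry": FlowNode("entry", NodeKind.CLINICAL_STATE),
        "dA": FlowNode("dA", NodeKind.DECISION, predicate=Predicate("a", "present")),
        "dB": FlowNode("dB", NodeKind.DECISION, predicate=Predicate("b", "present")),
        "dC": FlowNode("dC", NodeKind.DECISION, predicate=Predicate("c", "present")),
        "dx1": FlowNode("dx1", NodeKind.DIAGNOSTIC_ACTION, diagnosis="dx1"),
        "dx2": FlowNode("dx2", NodeKind.DIAGNOSTIC_ACTION, diagnosis="dx2"),
        "dx3": FlowNode("dx3", NodeKind.DIAGNOSTIC_ACTION, diagnosis="dx3"),
        "dx4": FlowNode("dx4", NodeKind.DIAGNOSTIC_ACTION, diagnosis="dx4"),
    }
    e = [
        FlowEdge("entry", "dA", "next"),
        FlowEdge("dA", "dB", "yes"),
        FlowEdge("dA", "dC", "no"),
        FlowEdge("dB", "dx1", "yes"),
        FlowEdge("dB", "dx2", "no"),
        FlowEdge("dC", "dx3", "yes"),
        FlowEdge("dC", "dx4", "no"),
    ]
    return ClinicalAlgorithm("toy3", "toy3", "entry", n, e)


def make_patient(pid="p", findings=None, dx=("tb",), age=30) -> ca.PatientRecord:
    return ca.PatientRecord(
        patient_id=pid, age=age, sex="male", findings=findings or {}, true_diagnoses=dx
    )


# ---------------------------------------------------------------------------
# random flowchart generator (for round-trip, census and CASA properties)


def random_flowchart(seed: int, max_depth: int = 4, p_loop: float = 0.15) -> ClinicalAlgorithm:
    """A random valid flowchart: a binary decision tree with random
    predicates, random delays, a mix of terminal kinds, and occasional
    backward edges from other_action boxes to an ancestor."""
    rng = random.Random(seed)
    nodes: dict[str, FlowNode] = {"entry": FlowNode("entry", NodeKind.CLINICAL_STATE)}
    edges: list[FlowEdge] = []
    counter = {"n": 0}

    def fresh(prefix):
        counter["n"] += 1
        return f"{prefix}{counter['n']}"

    def random_predicate():
        f = f"f{rng.randint(1, 6)}"
        op = rng.choice(["present", "absent", "equals", "at_least", "at_most", "in_set"])
        if op in ("present", "absent"):
            return Predicate(f, op)
        if op == "in_set":
            return Predicate(f, op, tuple(sorted(rng.sample(["u", "v", "w", "x"], 2))))
        if op == "equals":
            return Predicate(f, op, rng.choice(["u", "v", "w"]))
        return Predicate(f, op, rng.randint(0, 5))

    def build(parent: str, branch: str, depth: int, ancestors: list[str]):
        if depth > 0 and rng.random() < 0.7:
            nid = fresh("d")
            nodes[nid] = FlowNode(
                nid, NodeKind.DECISION, predicate=random_predicate(),
                delay_days=rng.choice([0, 0, 1, 2]),
            )
            edges.append(FlowEdge(parent, nid, branch))
            build(nid, "yes", depth - 1, ancestors + [nid])
            build(nid, "no", depth - 1, ancestors + [nid])
        elif rng.random() < p_loop and ancestors:
            # a re-test box that sends the clinician back to an earlier point
            nid = fresh("loop")
            nodes[nid] = FlowNode(
                nid, NodeKind.OTHER_ACTION, test_id="retest", delay_days=1
            )
            edges.append(FlowEdge(parent, nid, branch))
            edges.append(FlowEdge(nid, rng.choice(ancestors), "next", backward=True))
        elif rng.random() < 0.8:
            nid = fresh("dx")
            nodes[nid] = FlowNode(
                nid, NodeKind.DIAGNOSTIC_ACTION, diagnosis=f"dx_{nid}",
                delay_days=rng.choice([0, 1]),
            )
            edges.append(FlowEdge(parent, nid, branch))
        else:
            nid = fresh("act")
            nodes[nid] = FlowNode(nid, NodeKind.OTHER_ACTION, test_id="refer")
            edges.append(FlowEdge(parent, nid, branch))

    build("entry", "next", max_depth, ["entry"])
    return ClinicalAlgorithm(f"rand{seed}", f"rand{seed}", "entry", nodes, edges)


def random_patient(seed: int) -> ca.PatientRecord:
    """Random findings over the vocabulary random_flowchart draws from,
    including missing values."""
    rng = random.Random(seed ^ 0x5EED)
    findings = {}
    for i in range(1, 7):
        roll = rng.random()
        if roll < 0.2:
            continue  # unknown
        if roll < 0.5:
            findings[f"f{i}"] = rng.choice([True, False])
        elif roll < 0.8:
            findings[f"f{i}"] = rng.choice(["u", "v", "w", "x"])
        else:
            findings[f"f{i}"] = rng.randint(0, 5)
    return make_patient(pid=f"rp{seed}", findings=findings)
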