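"""Flowchart model: parsing, validation, serialization, census."""

import pytest

import clinalg as ca
from clinalg.flowchart import (
    FlowchartError,
    FlowEdge,
    FlowNode,
    NodeKind,
    Predicate,
    census,
    parse_algorithm,
    serialize_algorithm,
)

from conftest import make_minimal, random_flowchart

MINIMAL_DOC = """
algorithm_id: mini
entry: start
nodes:
  - {id: start, kind: clinical_state}
  - {id: tb, kind: diagnostic_action, diagnosis: TB}
edges:
  - {from: start, to: tb, branch: next}
"""


class TestParse:
    def test_minimal_document(self):
        alg = parse_algorithm(MINIMAL_DOC)
        assert len(alg.nodes) == 2
        assert len(alg.edges) == 1
        assert alg.diagnoses_covered == {"TB"}

    def test_decision_with_single_branch_names_the_node(self):
        doc = """
algorithm_id: bad
entry: start
nodes:
  - {id: start, kind: clinical_state}
  - {id: q, kind: decision, predicate: {finding: x, op: present}}
  - {id: tb, kind: diagnostic_action, diagnosis: TB}
edges:
  - {from: start, to: q, branch: next}
  - {from: q, to: tb, branch: yes}
"""
        with pytest.raises(FlowchartError, match="'q'"):
            parse_algorithm(doc)

    @pytest.mark.parametrize(
        "mutation, match",
        [
            ({"entry": "nowhere"}, "entry"),
            ({"nodes": [{"id": "start", "kind": "clinical_state"}]}, "missing top-level|unknown node"),
        ],
    )
    def test_schema_violations(self, mutation, match):
        import yaml

        doc = yaml.safe_load(MINIMAL_DOC)
        doc.update(mutation)
        with pytest.raises(FlowchartError):
            parse_algorithm(doc)

    def test_unreachable_node_rejected(self):
        import yaml

        d = yaml.safe_load(MINIMAL_DOC)
        d["nodes"].append({"id": "island", "kind": "other_action"})
        with pytest.raises(FlowchartError, match="island"):
            parse_algorithm(d)

    def test_dangling_edge_rejected(self):
        import yaml

        d = yaml.safe_load(MINIMAL_DOC)
        d["edges"].append({"from": "tb", "to": "ghost", "branch": "next"})
        with pytest.raises(FlowchartError, match="ghost"):
            parse_algorithm(d)

    def test_terminal_must_be_action(self):
        doc = """
algorithm_id: bad
entry: start
nodes:
  - {id: start, kind: clinical_state}
edges: []
"""
        with pytest.raises(FlowchartError, match="terminal"):
            parse_algorithm(doc)


class TestPredicate:
    def test_reference_value_rules(self):
        with pytest.raises(FlowchartError):
            Predicate("x", "present", True)
        with pytest.raises(FlowchartError):
            Predicate("x", "at_least")
        with pytest.raises(FlowchartError):
            Predicate("x", "looks_like", 1)

    @pytest.mark.parametrize(
        "pred, findings, expected",
        [
            (Predicate("x", "present"), {"x": True}, True),
            (Predicate("x", "present"), {"x": False}, False),
            (Predicate("x", "present"), {}, None),
            (Predicate("x", "absent"), {"x": False}, True),
            (Predicate("x", "equals", "v"), {"x": "v"}, True),
            (Predicate("x", "equals", "v"), {"x": "w"}, False),
            (Predicate("x", "at_least", 3), {"x": 3}, True),
            (Predicate("x", "at_least", 3), {"x": 2.5}, False),
            (Predicate("x", "at_most", 3), {"x": 4}, False),
            (Predicate("x", "in_set", ("u", "v")), {"x": "u"}, True),
            (Predicate("x", "in_set", ("u", "v")), {"x": "w"}, False),
            (Predicate("x", "at_least", 3), {"x": ca.UNKNOWN}, None),
        ],
    )
    def test_three_valued_evaluation(self, pred, findings, expected):
        assert pred.evaluate(findings) is expected


class TestSerialize:
    def test_minimal_roundtrip_shape(self):
        alg = make_minimal()
        text = serialize_algorithm(alg)
        reparsed = parse_algorithm(text)
        assert len(reparsed.nodes) == 2 and len(reparsed.edges) == 1

    def test_serialization_deterministic(self, chuk):
        assert serialize_algorithm(chuk) == serialize_algorithm(chuk)

    @pytest.mark.parametrize("fixture_name", ["chuk", "msf", "who"])
    def test_fixture_roundtrip_identity(self, fixture_name, request):
        alg = request.getfixturevalue(fixture_name)
        reparsed = parse_algorithm(serialize_algorithm(alg))
        assert alg.structurally_equal(reparsed)

    @pytest.mark.parametrize("seed", range(50))
    def test_random_roundtrip_identity(self, seed):
        """serialize -> parse preserves nodes, edges, kinds, predicates and
        delays exactly, for arbitrary valid flowcharts."""
        alg = random_flowchart(seed)
        reparsed = parse_algorithm(serialize_algorithm(alg))
        assert alg.structurally_equal(reparsed)
        assert reparsed.nodes == alg.nodes


class TestCensus:
    def test_minimal_counts(self):
        c = census(make_minimal())
        assert (c.n_diagnostic, c.n_other, list(c.backward_edges)) == (1, 1, [])

    def test_loop_edge_listed(self):
        doc = """
algorithm_id: loopy
entry: start
nodes:
  - {id: start, kind: clinical_state}
  - {id: q, kind: decision, predicate: {finding: x, op: present}}
  - {id: retry, kind: other_action}
  - {id: tb, kind: diagnostic_action, diagnosis: TB}
edges:
  - {from: start, to: q, branch: next}
  - {from: q, to: tb, branch: yes}
  - {from: q, to: retry, branch: no}
  - {from: retry, to: q, branch: next}
"""
        alg = parse_algorithm(doc)
        c = census(alg)
        assert c.n_diagnostic == 1 and c.n_other == 3
        assert [(e.source, e.target) for e in c.backward_edges] == [("retry", "q")]

    @pytest.mark.parametrize("seed", range(100))
    def test_census_matches_bruteforce(self, seed):
        """Census totals equal an independent enumeration of the node and
        edge sets for random flowcharts."""
        alg = random_flowchart(seed)
        c = census(alg)
        n_dx_brute = sum(
            1 for n in list(alg.nodes.values()) if n.kind == NodeKind.DIAGNOSTIC_ACTION
        )
        assert c.n_diagnostic == n_dx_brute
        assert c.n_diagnostic + c.n_other == len(alg.nodes)
        assert set(c.backward_edges) == {e for e in alg.edges if e.backward}

    def test_backward_detection_topological(self):
        """An un-flagged edge pointing to an earlier box is detected as a
        loop; detection depends on topology, not labels."""
        doc = """
algorithm_id: l2
entry: s0
nodes:
  - {id: s0, kind: clinical_state}
  - {id: a0, kind: other_action}
  - {id: q0, kind: decision, predicate: {finding: x, op: present}}
  - {id: t0, kind: diagnostic_action, diagnosis: TB}
  - {id: b0, kind: other_action}
edges:
  - {from: s0, to: a0, branch: next}
  - {from: a0, to: q0, branch: next}
  - {from: q0, to: t0, branch: yes}
  - {from: q0, to: b0, branch: no}
  - {from: b0, to: a0, branch: next}
"""
        alg = parse_algorithm(doc)
        (loop,) = census(alg).backward_edges
        assert (loop.source, loop.target) == ("b0", "a0")
        # relabel every node: the same edge (by topology) is still the loop
        relabeled = doc
        for old, new in [("s0", "n_e"), ("a0", "n_a"), ("q0", "n_q"),
                         ("t0", "n_t"), ("b0", "n_b")]:
            relabeled = relabeled.replace(old, new)
        (loop2,) = census(parse_algorithm(relabeled)).backward_edges
        assert (loop2.source, loop2.target) == ("n_b", "n_a")


class TestNodeInvariants:
    def test_decision_needs_predicate(self):
        with pytest.raises(FlowchartError):
            FlowNode("d", NodeKind.DECISION)

    def test_only_diagnostic_carries_diagnosis(self):
        with pytest.raises(FlowchartError):
            FlowNode("a", NodeKind.OTHER_ACTION, diagnosis="TB")
        with pytest.raises(FlowchartError):
            FlowNode("a", NodeKind.DIAGNOSTIC_ACTION)

    def test_negative_delay_rejected(self):
        with pytest.raises(FlowchartError):
            FlowNode("a", NodeKind.OTHER_ACTION, delay_days=-1)

    def test_diagnoses_covered_matches_labels(self, chuk, msf, who):
        for alg in (chuk, msf, who):
            labels = {
                n.diagnosis
                for n in alg.nodes.values()
                if n.kind == NodeKind.DIAGNOSTIC_ACTION
            }
            assert alg.diagnoses_covered == labels


def test_test_catalog_load(tmp_path):
    p = tmp_path / "cat.csv"
    p.write_text("test_id,turnaround_days\nchest_xray,1\nsputum_smear,2\n")
    assert ca.load_test_catalog(p) == {"chest_xray": 1.0, "sputum_smear": 2.0}
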