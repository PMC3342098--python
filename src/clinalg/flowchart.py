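"""Clinical algorithm flowcharts: model, validation, (de)serialization, census.

A clinical algorithm is a serial, dichotomous flowchart: boxes (nodes) are
clinical states, yes/no decision points, diagnostic actions (boxes that
assign a diagnosis, usually with a treatment) or other actions (tests,
referrals).  Transitions are edges labelled ``yes``/``no`` out of decision
boxes and ``next`` otherwise.  Loops — edges that send the clinician back to
an earlier box, e.g. "repeat the X-ray after an antibiotic trial" — are
explicit backward edges.

The document format is a small YAML/JSON tree::

    algorithm_id: toy
    name: Toy flowchart
    entry: start
    nodes:
      - {id: start, kind: clinical_state, label: "cough > 3 weeks"}
      - {id: q1, kind: decision, predicate: {finding: smear_result, op: equals, value: positive}}
      - {id: tb, kind: diagnostic_action, diagnosis: tb_smear_positive}
      - {id: other, kind: other_action, label: refer}
    edges:
      - {from: start, to: q1, branch: next}
      - {from: q1, to: tb, branch: yes}
      - {from: q1, to: other, branch: no}
"""

from __future__ import annotations

import enum
import numbers
from dataclasses import dataclass, field, replace

import networkx as nx
import yaml

__all__ = [
    "NodeKind",
    "Predicate",
    "FlowNode",
    "FlowEdge",
    "ClinicalAlgorithm",
    "FlowchartError",
    "UNKNOWN",
    "parse_algorithm",
    "load_algorithm",
    "serialize_algorithm",
    "census",
    "Census",
    "load_test_catalog",
]


class FlowchartError(ValueError):
    """A flowchart document or algorithm violates a structural invariant."""


class _Unknown:
    """Singleton for an unknown/missing finding value."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):  # pragma: no cover - cosmetic
        return "UNKNOWN"

    def __bool__(self):
        raise TypeError("UNKNOWN has no truth value; handle it explicitly")


#: Sentinel for a finding whose value was not recorded or was obscured.
UNKNOWN = _Unknown()


class NodeKind(str, enum.Enum):
    """The four box kinds of a serial dichotomous flowchart.

    ``DIAGNOSTIC_ACTION`` boxes are the only ones that carry a diagnosis
    label; they are the ``n1Dx`` boxes of the CASA complexity score, every
    other kind counts toward ``n2D0``.
    """

    CLINICAL_STATE = "clinical_state"
    DECISION = "decision"
    DIAGNOSTIC_ACTION = "diagnostic_action"
    OTHER_ACTION = "other_action"


_COMPARATORS = ("present", "absent", "equals", "at_least", "at_most", "in_set")
_NO_VALUE = ("present", "absent")


@dataclass(frozen=True)
class Predicate:
    """A dichotomous criterion on one finding.

    Evaluation against a findings map is three-valued: ``True``, ``False``,
    or ``None`` when the finding is missing or :data:`UNKNOWN` — the engine
    turns ``None`` into a no-fit, never into a default branch.
    """

    finding: str
    op: str
    value: object = None

    def __post_init__(self):
        if self.op not in _COMPARATORS:
            raise FlowchartError(f"unknown comparator {self.op!r}")
        if self.op in _NO_VALUE and self.value is not None:
            raise FlowchartError(f"comparator {self.op!r} takes no reference value")
        if self.op not in _NO_VALUE and self.value is None:
            raise FlowchartError(f"comparator {self.op!r} requires a reference value")
        if self.op == "in_set" and not isinstance(self.value, (frozenset, tuple)):
            object.__setattr__(self, "value", tuple(self.value))

    def evaluate(self, findings: dict) -> bool | None:
        v = findings.get(self.finding, UNKNOWN)
        if v is UNKNOWN:
            return None
        if self.op == "present":
            return bool(v)
        if self.op == "absent":
            return not bool(v)
        if self.op == "equals":
            return v == self.value
        if self.op == "in_set":
            return v in self.value
        if not isinstance(v, numbers.Real):
            return None  # a non-numeric value cannot answer a threshold question
        if self.op == "at_least":
            return v >= self.value
        return v <= self.value  # at_most


@dataclass(frozen=True)
class FlowNode:
    """One flowchart box."""

    node_id: str
    kind: NodeKind
    label: str = ""
    predicate: Predicate | None = None
    diagnosis: str | None = None
    test_id: str | None = None
    delay_days: float = 0.0

    def __post_init__(self):
        if self.kind is NodeKind.DECISION and self.predicate is None:
            raise FlowchartError(f"decision node {self.node_id!r} has no predicate")
        if self.kind is not NodeKind.DECISION and self.predicate is not None:
            raise FlowchartError(f"non-decision node {self.node_id!r} has a predicate")
        if self.diagnosis is not None and self.kind is not NodeKind.DIAGNOSTIC_ACTION:
            raise FlowchartError(
                f"node {self.node_id!r}: only diagnostic_action boxes carry a diagnosis"
            )
        if self.kind is NodeKind.DIAGNOSTIC_ACTION and self.diagnosis is None:
            raise FlowchartError(f"diagnostic_action node {self.node_id!r} lacks a diagnosis")
        if self.delay_days < 0:
            raise FlowchartError(f"node {self.node_id!r}: delay_days must be >= 0")


_BRANCHES = ("yes", "no", "next")


@dataclass(frozen=True)
class FlowEdge:
    """A transition between boxes; ``backward`` marks loop edges."""

    source: str
    target: str
    branch: str
    backward: bool = False

    def __post_init__(self):
        if self.branch not in _BRANCHES:
            raise FlowchartError(
                f"edge {self.source!r}->{self.target!r}: branch must be one of {_BRANCHES}"
            )


@dataclass
class ClinicalAlgorithm:
    """A validated serial dichotomous flowchart.

    Construction validates every structural invariant: the entry box is a
    clinical state, every decision box has exactly one yes- and one no-edge,
    every box is reachable from the entry, and every terminal box is an
    action.  Backward (loop) edges are detected from the entry-rooted
    depth-first ordering; an explicit ``backward`` flag in the document
    overrides detection (figures mark loops graphically and encodings may
    assert them).
    """

    algorithm_id: str
    name: str
    entry_node: str
    nodes: dict[str, FlowNode]
    edges: list[FlowEdge]
    _dfs_order: list[str] = field(init=False, repr=False, default_factory=list)

    def __post_init__(self):
        self._validate()

    # -- validation -------------------------------------------------------

    def _validate(self) -> None:
        if self.entry_node not in self.nodes:
            raise FlowchartError(f"entry node {self.entry_node!r} does not exist")
        if self.nodes[self.entry_node].kind is not NodeKind.CLINICAL_STATE:
            raise FlowchartError(f"entry node {self.entry_node!r} must be a clinical_state box")
        for e in self.edges:
            for end in (e.source, e.target):
                if end not in self.nodes:
                    raise FlowchartError(f"edge {e.source!r}->{e.target!r}: unknown node {end!r}")

        out: dict[str, dict[str, list[FlowEdge]]] = {nid: {} for nid in self.nodes}
        for e in self.edges:
            out[e.source].setdefault(e.branch, []).append(e)

        for nid, node in self.nodes.items():
            branches = {b: len(es) for b, es in out[nid].items()}
            if node.kind is NodeKind.DECISION:
                if branches.get("yes", 0) != 1 or branches.get("no", 0) != 1 or "next" in branches:
                    raise FlowchartError(
                        f"decision node {nid!r} must have exactly one yes-edge and one "
                        f"no-edge (found {branches or 'none'})"
                    )
            else:
                if "yes" in branches or "no" in branches:
                    raise FlowchartError(f"non-decision node {nid!r} has a yes/no branch")
                if branches.get("next", 0) > 1:
                    raise FlowchartError(f"node {nid!r} has multiple next-edges")

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((e.source, e.target) for e in self.edges)
        reachable = set(nx.descendants(g, self.entry_node)) | {self.entry_node}
        unreachable = sorted(set(self.nodes) - reachable)
        if unreachable:
            raise FlowchartError(f"nodes unreachable from entry: {unreachable}")

        for nid in self.nodes:
            if not out[nid] and self.nodes[nid].kind in (
                NodeKind.CLINICAL_STATE,
                NodeKind.DECISION,
            ):
                raise FlowchartError(
                    f"terminal node {nid!r} must be a diagnostic_action or other_action box"
                )

        self._dfs_order = self._compute_dfs_order()
        index = {nid: i for i, nid in enumerate(self._dfs_order)}
        # Loop-edge resolution: an explicit backward=True flag is kept; an
        # un-flagged edge whose target does not come later in the DFS order
        # is promoted to backward (topological detection).
        self.edges = [
            replace(e, backward=True)
            if (not e.backward and index[e.target] <= index[e.source])
            else e
            for e in self.edges
        ]

    def _compute_dfs_order(self) -> list[str]:
        """Entry-rooted depth-first ordering; yes before no before next,
        remaining ties broken by target node_id."""
        rank = {"yes": 0, "no": 1, "next": 2}
        succ: dict[str, list[str]] = {nid: [] for nid in self.nodes}
        for e in sorted(self.edges, key=lambda e: (rank[e.branch], e.target)):
            succ[e.source].append(e.target)
        order, seen = [], set()
        stack = [self.entry_node]
        while stack:
            nid = stack.pop()
            if nid in seen:
                continue
            seen.add(nid)
            order.append(nid)
            stack.extend(reversed(succ[nid]))
        return order

    # -- introspection ----------------------------------------------------

    @property
    def dfs_order(self) -> list[str]:
        return list(self._dfs_order)

    @property
    def diagnoses_covered(self) -> frozenset[str]:
        return frozenset(
            n.diagnosis for n in self.nodes.values() if n.kind is NodeKind.DIAGNOSTIC_ACTION
        )

    def outgoing(self, node_id: str, branch: str) -> FlowEdge | None:
        for e in self.edges:
            if e.source == node_id and e.branch == branch:
                return e
        return None

    def terminal_nodes(self) -> list[str]:
        sources = {e.source for e in self.edges}
        return [nid for nid in self._dfs_order if nid not in sources]

    def structurally_equal(self, other: "ClinicalAlgorithm") -> bool:
        return (
            self.algorithm_id == other.algorithm_id
            and self.entry_node == other.entry_node
            and self.nodes == other.nodes
            and sorted(self.edges, key=_edge_key) == sorted(other.edges, key=_edge_key)
        )


def _edge_key(e: FlowEdge):
    return (e.source, e.branch, e.target)


# ---------------------------------------------------------------------------
# parsing / serialization


def _parse_predicate(doc: dict, node_id: str) -> Predicate:
    try:
        value = doc.get("value")
        if isinstance(value, list):
            value = tuple(value)
        return Predicate(finding=doc["finding"], op=doc["op"], value=value)
    except KeyError as exc:
        raise FlowchartError(f"node {node_id!r}: predicate missing key {exc}") from None


def parse_algorithm(document: str | dict) -> ClinicalAlgorithm:
    """Parse a flowchart document (YAML text or an equivalent mapping).

    Raises :class:`FlowchartError` naming the offending node or edge on any
    schema or invariant violation.
    """
    doc = yaml.safe_load(document) if isinstance(document, str) else document
    if not isinstance(doc, dict):
        raise FlowchartError("flowchart document must be a mapping")
    for key in ("algorithm_id", "entry", "nodes", "edges"):
        if key not in doc:
            raise FlowchartError(f"flowchart document missing top-level key {key!r}")

    nodes: dict[str, FlowNode] = {}
    for nd in doc["nodes"]:
        nid = nd.get("id")
        if not nid:
            raise FlowchartError(f"node entry without id: {nd!r}")
        if nid in nodes:
            raise FlowchartError(f"duplicate node id {nid!r}")
        try:
            kind = NodeKind(nd.get("kind", ""))
        except ValueError:
            raise FlowchartError(f"node {nid!r}: unknown kind {nd.get('kind')!r}") from None
        pred = _parse_predicate(nd["predicate"], nid) if "predicate" in nd else None
        nodes[nid] = FlowNode(
            node_id=nid,
            kind=kind,
            label=nd.get("label", ""),
            predicate=pred,
            diagnosis=nd.get("diagnosis"),
            test_id=nd.get("test"),
            delay_days=float(nd.get("delay_days", 0.0)),
        )

    def _branch(raw) -> str:
        # YAML 1.1 reads bare yes/no as booleans; accept either spelling
        if raw is True:
            return "yes"
        if raw is False:
            return "no"
        return str(raw)

    edges = [
        FlowEdge(
            source=ed["from"],
            target=ed["to"],
            branch=_branch(ed.get("branch", "next")),
            backward=bool(ed.get("backward", False)),
        )
        for ed in doc["edges"]
    ]
    return ClinicalAlgorithm(
        algorithm_id=doc["algorithm_id"],
        name=doc.get("name", doc["algorithm_id"]),
        entry_node=doc["entry"],
        nodes=nodes,
        edges=edges,
    )


def load_algorithm(path) -> ClinicalAlgorithm:
    """Read and parse a flowchart document from *path*."""
    with open(path, encoding="utf-8") as fh:
        return parse_algorithm(fh.read())


def serialize_algorithm(alg: ClinicalAlgorithm) -> str:
    """Serialize to YAML with deterministic node order (entry-rooted DFS,
    ties by node_id); two serializations of the same algorithm are
    byte-identical."""
    nodes_out = []
    for nid in alg.dfs_order:
        n = alg.nodes[nid]
        nd: dict = {"id": n.node_id, "kind": n.kind.value}
        if n.label:
            nd["label"] = n.label
        if n.predicate is not None:
            pd = {"finding": n.predicate.finding, "op": n.predicate.op}
            if n.predicate.value is not None:
                v = n.predicate.value
                pd["value"] = list(v) if isinstance(v, tuple) else v
            nd["predicate"] = pd
        if n.diagnosis is not None:
            nd["diagnosis"] = n.diagnosis
        if n.test_id is not None:
            nd["test"] = n.test_id
        if n.delay_days:
            nd["delay_days"] = n.delay_days
        nodes_out.append(nd)

    index = {nid: i for i, nid in enumerate(alg.dfs_order)}
    rank = {"yes": 0, "no": 1, "next": 2}
    edges_out = []
    for e in sorted(alg.edges, key=lambda e: (index[e.source], rank[e.branch], e.target)):
        ed: dict = {"from": e.source, "to": e.target, "branch": e.branch}
        if e.backward:
            ed["backward"] = True
        edges_out.append(ed)

    doc = {
        "algorithm_id": alg.algorithm_id,
        "name": alg.name,
        "entry": alg.entry_node,
        "nodes": nodes_out,
        "edges": edges_out,
    }
    return yaml.safe_dump(doc, sort_keys=False, default_flow_style=None)


# ---------------------------------------------------------------------------
# census


@dataclass(frozen=True)
class Census:
    """Box and loop counts underlying the CASA complexity score."""

    n_diagnostic: int
    n_other: int
    backward_edges: tuple[FlowEdge, ...]


def census(alg: ClinicalAlgorithm) -> Census:
    """Count diagnostic boxes (n1Dx), all other boxes (n2D0) and loop edges."""
    n_dx = sum(1 for n in alg.nodes.values() if n.kind is NodeKind.DIAGNOSTIC_ACTION)
    back = tuple(e for e in alg.edges if e.backward)
    return Census(n_diagnostic=n_dx, n_other=len(alg.nodes) - n_dx, backward_edges=back)


def load_test_catalog(path) -> dict[str, float]:
    """Read a ``test_id,turnaround_days`` CSV into a dict."""
    import csv

    catalog: dict[str, float] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            catalog[row["test_id"]] = float(row["turnaround_days"])
    return catalog
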