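"""Translate a workflow plus job into an executable task DAG.

The graph mirrors the workflow's dataflow: one node per step, plus two
synthetic endpoints — ``JobDispatcher`` (serializes job inputs and provisions
the run) and ``JobCleanup`` (delivers declared outputs to the output folder).
A step-to-step edge (A, B) exists iff some input of B sources an output of A;
parallel data edges between one pair collapse into a single scheduling edge.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx

from .documents import StepSpec, WorkflowDocument, validate_connectivity
from .errors import ConnectivityError, CycleDetected, errors_only
from .jobs import JobDescriptor

DISPATCHER_ID = "JobDispatcher"
CLEANUP_ID = "JobCleanup"


@dataclass
class TaskNode:
    task_id: str
    kind: str                       # "dispatcher" | "step" | "cleanup"
    step_ref: Optional[StepSpec] = field(default=None, compare=False)
    upstream_ids: set[str] = field(default_factory=set)
    downstream_ids: set[str] = field(default_factory=set)


@dataclass
class DagGraph:
    run_uid: str
    nodes: dict[str, TaskNode]
    edges: set[tuple[str, str]]

    @property
    def step_ids(self) -> list[str]:
        return [t.task_id for t in self.nodes.values() if t.kind == "step"]

    def step_edges(self) -> set[tuple[str, str]]:
        return {(a, b) for (a, b) in self.edges
                if self.nodes[a].kind == "step" and self.nodes[b].kind == "step"}

    def parents(self, task_id: str) -> set[str]:
        return self.nodes[task_id].upstream_ids

    def children(self, task_id: str) -> set[str]:
        return self.nodes[task_id].downstream_ids

    def descendants(self, task_id: str) -> set[str]:
        g = self.to_networkx()
        return set(nx.descendants(g, task_id))

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def digest(self) -> str:
        payload = json.dumps({
            "nodes": sorted(self.nodes),
            "edges": sorted(self.edges),
        }, sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()


def step_dependencies(doc: WorkflowDocument) -> set[tuple[str, str]]:
    """Dataflow edges between steps: (A, B) iff an input of B sources an
    output of A.  Derived solely from each step's ``in`` source references."""
    step_ids = {s.id for s in doc.steps}
    edges: set[tuple[str, str]] = set()
    for step in doc.steps:
        for src in step.sources():
            if "/" in src:
                producer = src.split("/", 1)[0]
                if producer in step_ids and producer != step.id:
                    edges.add((producer, step.id))
    return edges


def _find_cycle(edges: Iterable[tuple[str, str]]) -> Optional[list[str]]:
    g = nx.DiGraph(list(edges))
    try:
        cyc = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        return None
    return [a for a, _ in cyc]


def build_dag(doc: WorkflowDocument, job: JobDescriptor) -> DagGraph:
    """Build the executable DAG for one run.

    Dispatcher edges go to every step that consumes only workflow inputs or
    constants (including isolated steps); cleanup edges come from every step
    feeding a workflow output and from every sink step, so no work is
    orphaned.  Raises :class:`CycleDetected` when the dataflow has a cycle
    and :class:`ConnectivityError` when the wiring is unsound.
    """
    diags = errors_only(validate_connectivity(doc))
    if diags:
        raise ConnectivityError("; ".join(d.message for d in diags))

    dep_edges = step_dependencies(doc)
    cycle = _find_cycle(dep_edges)
    if cycle is not None:
        raise CycleDetected(cycle)

    nodes: dict[str, TaskNode] = {
        DISPATCHER_ID: TaskNode(DISPATCHER_ID, "dispatcher"),
        CLEANUP_ID: TaskNode(CLEANUP_ID, "cleanup"),
    }
    for step in doc.steps:
        nodes[step.id] = TaskNode(step.id, "step", step_ref=step)

    edges: set[tuple[str, str]] = set(dep_edges)

    has_step_parent = {b for _, b in dep_edges}
    has_step_child = {a for a, _ in dep_edges}
    output_producers = {
        (out.output_source or "").split("/", 1)[0]
        for out in doc.outputs if "/" in (out.output_source or "")
    }

    for step in doc.steps:
        if step.id not in has_step_parent:
            edges.add((DISPATCHER_ID, step.id))
        if step.id not in has_step_child or step.id in output_producers:
            edges.add((step.id, CLEANUP_ID))

    if not doc.steps:
        edges.add((DISPATCHER_ID, CLEANUP_ID))

    for a, b in edges:
        nodes[a].downstream_ids.add(b)
        nodes[b].upstream_ids.add(a)

    return DagGraph(run_uid=job.uid, nodes=nodes, edges=edges)


def topological_layers(dag: DagGraph) -> list[list[str]]:
    """Kahn layers: layer 0 is the dispatcher; each node sits one layer past
    its deepest parent.  Layers are sorted lists for reproducible display."""
    g = dag.to_networkx()
    if not nx.is_directed_acyclic_graph(g):
        raise CycleDetected(_find_cycle(dag.edges) or [])
    depth: dict[str, int] = {}
    for node in nx.topological_sort(g):
        preds = list(g.predecessors(node))
        depth[node] = 0 if not preds else 1 + max(depth[p] for p in preds)
    layers: list[list[str]] = [[] for _ in range(max(depth.values()) + 1)]
    for node, d in depth.items():
        layers[d].append(node)
    return [sorted(layer) for layer in layers]


def export_dot(dag: DagGraph) -> str:
    """Deterministic Graphviz DOT rendering (statements sorted)."""
    shape = {"dispatcher": "invhouse", "cleanup": "house", "step": "box"}
    lines = [f'digraph "{dag.run_uid}" {{']
    for tid in sorted(dag.nodes):
        lines.append(f'  "{tid}" [shape={shape[dag.nodes[tid].kind]}];')
    for a, b in sorted(dag.edges):
        lines.append(f'  "{a}" -> "{b}";')
    lines.append("}")
    return "\n".join(lines) + "\n"


def from_json(text: str) -> DagGraph:
    """Rebuild a DagGraph (without step bodies) from its JSON dump."""
    data = json.loads(text)
    nodes = {n["task_id"]: TaskNode(n["task_id"], n["kind"])
             for n in data["nodes"]}
    edges = {(a, b) for a, b in data["edges"]}
    for a, b in edges:
        nodes[a].downstream_ids.add(b)
        nodes[b].upstream_ids.add(a)
    return DagGraph(run_uid=data["run_uid"], nodes=nodes, edges=edges)


def to_json(dag: DagGraph) -> str:
    """JSON dump of nodes and edges for the CLI graph view."""
    return json.dumps({
        "run_uid": dag.run_uid,
        "nodes": [{"task_id": t.task_id, "kind": t.kind} for t in
                  sorted(dag.nodes.values(), key=lambda t: t.task_id)],
        "edges": sorted(dag.edges),
    }, indent=2)
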