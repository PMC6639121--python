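"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately dumb: a quadratic dependency scanner, a
permutation-based linear-extension enumerator and a set-walk reachability,
so the engine's graph code is always checked against something that cannot
share its bugs.
"""

from __future__ import annotations

import itertools
from pathlib import Path

import pytest

from cwlflow import EngineConfig, load_document, parse_job_file
from cwlflow.documents import WorkflowDocument
from cwlflow.jobs import JobDescriptor
from cwlflow.scheduler import Engine


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_step_edges(doc: WorkflowDocument) -> set[tuple[str, str]]:
    """Quadratic scan: for every ordered step pair (A, B), (A, B) is an edge
    iff some input of B sources an output of A."""
    edges = set()
    for a, b in itertools.permutations(doc.steps, 2):
        for binding in b.in_bindings.values():
            src = binding.get("source", "")
            if "/" in src and src.split("/", 1)[0] == a.id:
                edges.add((a.id, b.id))
    return edges


def linear_extensions(nodes: set[str], edges: set[tuple[str, str]]) -> set[tuple[str, ...]]:
    """All total orders consistent with the edges (enumeration; small n only)."""
    out = set()
    for perm in itertools.permutations(sorted(nodes)):
        index = {n: i for i, n in enumerate(perm)}
        if all(index[a] < index[b] for a, b in edges):
            out.add(perm)
    return out


def brute_force_descendants(edges: set[tuple[str, str]], start: str) -> set[str]:
    """Reachable-from set by repeated frontier expansion."""
    reach: set[str] = set()
    frontier = {start}
    while frontier:
        nxt = {b for a, b in edges if a in frontier and b not in reach}
        reach |= nxt
        frontier = nxt
    return reach


def brute_force_layers(nodes: set[str], edges: set[tuple[str, str]]) -> dict[str, int]:
    """Longest path from any source, per node, by path enumeration."""
    parents = {n: {a for a, b in edges if b == n} for n in nodes}

    def depth(n: str) -> int:
        if not parents[n]:
            return 0
        return 1 + max(depth(p) for p in parents[n])

    return {n: depth(n) for n in nodes}


def task_start_order(store, uid: str) -> list[str]:
    """Task ids in the order they entered the running state."""
    return [tr["task_id"] for tr in store.transitions(uid)
            if tr["new"] == "running" and tr["task_id"] is not None]


# ---------------------------------------------------------------------------
# engine / fixture plumbing
# ---------------------------------------------------------------------------

@pytest.fixture
def make_engine(tmp_path):
    """Factory for engines sharing one store inside the test's tmp dir."""
    engines = []

    def factory(worker_count: int = 1, **kw) -> Engine:
        cfg = EngineConfig(
            jobs_folder=tmp_path / "jobs",
            temp_folder=tmp_path / "temp",
            output_default=tmp_path / "out",
            store_path=tmp_path / "state.db",
            worker_count=worker_count,
            **kw,
        )
        eng = Engine(cfg)
        engines.append(eng)
        return eng

    yield factory
    for eng in engines:
        eng.close()


def load_fixture_job(manifest, uid: str | None = None,
                     output_folder: Path | None = None):
    """Parse a generated fixture's job file, optionally re-keyed so one
    fixture tree can back several runs.  Invalid fixtures (no job file)
    get a bare descriptor."""
    if manifest.job_file is None:
        return JobDescriptor(uid=uid or f"{manifest.name}-job",
                             workflow_path=manifest.path,
                             output_folder=output_folder or manifest.path.parent)
    job = parse_job_file(manifest.job_file)
    if uid is not None:
        job.uid = uid
    if output_folder is not None:
        job.output_folder = Path(output_folder)
    return job


def run_fixture(engine: Engine, manifest, uid: str | None = None,
                output_folder: Path | None = None, **exec_kw):
    job = load_fixture_job(manifest, uid=uid, output_folder=output_folder)
    engine.register_job(job)
    return engine.execute_run(job.uid, **exec_kw), job


def workflow_of(manifest) -> WorkflowDocument:
    return load_document(manifest.path).body
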