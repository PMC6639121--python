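"""Synthetic workflows, tools, jobs and data for testing the engine.

Three generators, no downloads and no bioinformatics tools required:

* :func:`make_chipseq_like` — a 5-step pipeline with the topology of a
  basic ChIP-Seq analysis (align → sort → index / peak-call → coverage),
  where each step is a tiny deterministic text transform standing in for
  the real aligner/sorter/peak-caller.  Input reads are seeded pseudo-reads
  (uniform 4-letter strings, length 36, 1000 of them).
* :func:`make_topology_suite` — small graphs stressing DAG construction:
  single step, linear chain, diamond, fan-out/fan-in, isolated step, and
  two invalid shapes (cycle, dangling source).
* :func:`make_binding_suite` — 12 CommandLineTool cases covering the
  command-line binding rules, each with frozen expected argv derived from
  the CWL v1.0 binding algorithm.

Every generator is a pure function of (outdir, seed): the same call emits
byte-identical trees.
"""

from __future__ import annotations

import json
import random
import sys
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass(frozen=True)
class FixtureManifest:
    """What a generated fixture is supposed to look like once loaded."""

    name: str
    path: Path = field(compare=False)
    step_ids: tuple[str, ...] = ()
    intended_edges: frozenset[tuple[str, str]] = frozenset()
    expected_output_ids: frozenset[str] = frozenset()
    seed: int = 0
    job_file: Path | None = field(compare=False, default=None)
    valid: bool = True


def _dump_yaml(path: Path, data: dict) -> None:
    path.write_text(yaml.safe_dump(data, sort_keys=True, default_flow_style=False))


# ---------------------------------------------------------------------------
# stub step scripts (pure text transforms; POSIX-portable via the running
# Python interpreter)
# ---------------------------------------------------------------------------

_STUBS = {
    "stub_align.py": """\
import hashlib, sys
reads = [l.strip() for l in open(sys.argv[1]) if l.strip()]
with open("aligned.sam", "w") as out:
    for r in reads:
        h = int(hashlib.sha1(r.encode()).hexdigest(), 16)
        out.write("chr%d\\t%d\\t%s\\n" % (h % 5 + 1, (h // 5) % 10000, r))
""",
    "stub_sort.py": """\
import sys
rows = []
for line in open(sys.argv[1]):
    c, p, r = line.rstrip("\\n").split("\\t")
    rows.append((c, int(p), r))
rows.sort()
with open("sorted.sam", "w") as out:
    for c, p, r in rows:
        out.write("%s\\t%d\\t%s\\n" % (c, p, r))
""",
    "stub_index.py": """\
import sys
counts = {}
for line in open(sys.argv[1]):
    c = line.split("\\t", 1)[0]
    counts[c] = counts.get(c, 0) + 1
with open("index.txt", "w") as out:
    for c in sorted(counts):
        out.write("%s\\t%d\\n" % (c, counts[c]))
""",
    "stub_peaks.py": """\
import sys
buckets = {}
for line in open(sys.argv[1]):
    c, p, _ = line.split("\\t")
    b = int(p) // 500
    buckets[(c, b)] = buckets.get((c, b), 0) + 1
with open("peaks.txt", "w") as out:
    for (c, b), n in sorted(buckets.items()):
        if n >= 3:
            out.write("%s\\t%d\\t%d\\t%d\\n" % (c, b * 500, b * 500 + 500, n))
""",
    "stub_coverage.py": """\
import sys
reads = {}
for line in open(sys.argv[1]):
    c = line.split("\\t", 1)[0]
    reads[c] = reads.get(c, 0) + 1
peaks = {}
for line in open(sys.argv[2]):
    c = line.split("\\t", 1)[0]
    peaks[c] = peaks.get(c, 0) + 1
with open("coverage.txt", "w") as out:
    for c in sorted(reads):
        out.write("%s\\t%d\\t%d\\n" % (c, reads[c], peaks.get(c, 0)))
""",
    "stub_combine.py": """\
import sys
label = sys.argv[1]
with open("out.txt", "w") as out:
    for path in sys.argv[2:]:
        out.write(open(path).read())
    out.write("[%s]\\n" % label)
""",
    "stub_fail.py": """\
import sys
sys.exit(1)
""",
}


def _write_stubs(bindir: Path, names=None) -> None:
    bindir.mkdir(parents=True, exist_ok=True)
    for name, body in _STUBS.items():
        if names is None or name in names:
            (bindir / name).write_text(body)


def _stub_command(bindir: Path, script: str) -> list[str]:
    return [sys.executable, str(bindir / script)]


def _file_tool(bindir: Path, script: str, inputs: list[str], out_id: str,
               out_glob: str, extra_args: list[str] | None = None) -> dict:
    """A CommandLineTool whose File inputs bind positionally after the stub."""
    return {
        "cwlVersion": "v1.0",
        "class": "CommandLineTool",
        "baseCommand": _stub_command(bindir, script) + (extra_args or []),
        "inputs": [
            {"id": iid, "type": "File", "inputBinding": {"position": i + 1}}
            for i, iid in enumerate(inputs)
        ],
        "outputs": [
            {"id": out_id, "type": "File", "outputBinding": {"glob": out_glob}}
        ],
    }


# ---------------------------------------------------------------------------
# ChIP-Seq-shaped pipeline
# ---------------------------------------------------------------------------

READ_LENGTH = 36
READ_COUNT = 1000


def pseudo_reads(seed: int, count: int = READ_COUNT,
                 length: int = READ_LENGTH) -> list[str]:
    rng = random.Random(seed)
    return ["".join(rng.choice("ACGT") for _ in range(length))
            for _ in range(count)]


def make_chipseq_like(outdir: str | Path, seed: int) -> FixtureManifest:
    """Emit the 5-step demonstration pipeline with stub commands.

    Wiring: align→sort, sort→index, sort→peaks, sort→coverage and
    peaks→coverage; the workflow delivers the index report, the peak list
    and the coverage table.
    """
    outdir = Path(outdir)
    tools = outdir / "tools"
    data = outdir / "data"
    bindir = outdir / "bin"
    for d in (tools, data):
        d.mkdir(parents=True, exist_ok=True)
    _write_stubs(bindir, {"stub_align.py", "stub_sort.py", "stub_index.py",
                          "stub_peaks.py", "stub_coverage.py"})

    reads_file = data / "reads.txt"
    reads_file.write_text("\n".join(pseudo_reads(seed)) + "\n")

    _dump_yaml(tools / "align.cwl",
               _file_tool(bindir, "stub_align.py", ["reads"], "sam", "aligned.sam"))
    _dump_yaml(tools / "sort.cwl",
               _file_tool(bindir, "stub_sort.py", ["sam"], "sorted", "sorted.sam"))
    _dump_yaml(tools / "index.cwl",
               _file_tool(bindir, "stub_index.py", ["sorted"], "index", "index.txt"))
    _dump_yaml(tools / "peaks.cwl",
               _file_tool(bindir, "stub_peaks.py", ["sorted"], "peaks", "peaks.txt"))
    _dump_yaml(tools / "coverage.cwl",
               _file_tool(bindir, "stub_coverage.py", ["sorted", "peaks"],
                          "coverage", "coverage.txt"))

    workflow = {
        "cwlVersion": "v1.0",
        "class": "Workflow",
        "id": "chipseq_like",
        "inputs": [{"id": "reads", "type": "File"}],
        "outputs": [
            {"id": "index_report", "type": "File",
             "outputSource": "index/index"},
            {"id": "peak_list", "type": "File",
             "outputSource": "peaks/peaks"},
            {"id": "coverage_table", "type": "File",
             "outputSource": "coverage/coverage"},
        ],
        "steps": [
            {"id": "align", "run": "tools/align.cwl",
             "in": {"reads": "reads"}, "out": ["sam"]},
            {"id": "sort", "run": "tools/sort.cwl",
             "in": {"sam": "align/sam"}, "out": ["sorted"]},
            {"id": "index", "run": "tools/index.cwl",
             "in": {"sorted": "sort/sorted"}, "out": ["index"]},
            {"id": "peaks", "run": "tools/peaks.cwl",
             "in": {"sorted": "sort/sorted"}, "out": ["peaks"]},
            {"id": "coverage", "run": "tools/coverage.cwl",
             "in": {"sorted": "sort/sorted", "peaks": "peaks/peaks"},
             "out": ["coverage"]},
        ],
    }
    wf_path = outdir / "chipseq_like.cwl"
    _dump_yaml(wf_path, workflow)

    job_path = outdir / "chipseq_job.yml"
    _dump_yaml(job_path, {
        "workflow": str(wf_path),
        "output_folder": str(outdir / "output"),
        "uid": f"chipseq-{seed}",
        "reads": {"class": "File", "path": str(reads_file)},
    })

    return FixtureManifest(
        name="chipseq_like",
        path=wf_path,
        step_ids=("align", "sort", "index", "peaks", "coverage"),
        intended_edges=frozenset({
            ("align", "sort"), ("sort", "index"), ("sort", "peaks"),
            ("sort", "coverage"), ("peaks", "coverage"),
        }),
        expected_output_ids=frozenset({"index_report", "peak_list",
                                       "coverage_table"}),
        seed=seed,
        job_file=job_path,
    )


# ---------------------------------------------------------------------------
# topology-stress suite
# ---------------------------------------------------------------------------

def _combine_tool(bindir: Path, label: str, n_inputs: int) -> dict:
    return {
        "cwlVersion": "v1.0",
        "class": "CommandLineTool",
        "baseCommand": _stub_command(bindir, "stub_combine.py") + [label],
        "inputs": [
            {"id": f"in{i}", "type": "File", "inputBinding": {"position": i + 1}}
            for i in range(1, n_inputs + 1)
        ],
        "outputs": [
            {"id": "out", "type": "File", "outputBinding": {"glob": "out.txt"}}
        ],
    }


_TOPOLOGIES: dict[str, dict] = {
    # name -> {steps: {id: [source refs]}, outputs: {wf_out: source}, valid}
    "single": {
        "steps": {"A": ["seed_file"]},
        "outputs": {"result": "A/out"},
        "valid": True,
    },
    "linear3": {
        "steps": {"A": ["seed_file"], "B": ["A/out"], "C": ["B/out"]},
        "outputs": {"result": "C/out"},
        "valid": True,
    },
    "diamond": {
        "steps": {"A": ["seed_file"], "B": ["A/out"], "C": ["A/out"],
                  "D": ["B/out", "C/out"]},
        "outputs": {"result": "D/out"},
        "valid": True,
    },
    "fan": {
        "steps": {"S": ["seed_file"], "F1": ["S/out"], "F2": ["S/out"],
                  "F3": ["S/out"], "J": ["F1/out", "F2/out", "F3/out"]},
        "outputs": {"result": "J/out"},
        "valid": True,
    },
    "isolated": {
        "steps": {"A": ["seed_file"], "Z": ["seed_file"]},
        "outputs": {"result": "A/out"},
        "valid": True,
    },
    "cyclic_invalid": {
        "steps": {"A": ["B/out"], "B": ["A/out"]},
        "outputs": {"result": "B/out"},
        "valid": False,
    },
    "dangling_invalid": {
        "steps": {"A": ["ghost/out"]},
        "outputs": {"result": "A/out"},
        "valid": False,
    },
}


def _intended_edges(steps: dict[str, list[str]]) -> frozenset[tuple[str, str]]:
    edges = set()
    for sid, sources in steps.items():
        for src in sources:
            if "/" in src and src.split("/", 1)[0] in steps:
                edges.add((src.split("/", 1)[0], sid))
    return frozenset(edges)


def make_topology_suite(outdir: str | Path) -> list[FixtureManifest]:
    """Emit the seven topology fixtures (five valid, two invalid)."""
    outdir = Path(outdir)
    bindir = outdir / "bin"
    _write_stubs(bindir, {"stub_combine.py", "stub_fail.py"})
    seed_file = outdir / "seed.txt"
    outdir.mkdir(parents=True, exist_ok=True)
    seed_file.write_text("alpha\nbeta\ngamma\n")

    manifests = []
    for name, topo in _TOPOLOGIES.items():
        fdir = outdir / name
        tools = fdir / "tools"
        tools.mkdir(parents=True, exist_ok=True)
        steps_def = []
        for sid, sources in topo["steps"].items():
            tool_path = tools / f"{sid}.cwl"
            _dump_yaml(tool_path, _combine_tool(bindir, sid, len(sources)))
            steps_def.append({
                "id": sid,
                "run": f"tools/{sid}.cwl",
                "in": {f"in{i + 1}": src for i, src in enumerate(sources)},
                "out": ["out"],
            })
        workflow = {
            "cwlVersion": "v1.0",
            "class": "Workflow",
            "id": name,
            "inputs": [{"id": "seed_file", "type": "File"}],
            "outputs": [
                {"id": oid, "type": "File", "outputSource": src}
                for oid, src in topo["outputs"].items()
            ],
            "steps": steps_def,
        }
        wf_path = fdir / f"{name}.cwl"
        _dump_yaml(wf_path, workflow)

        job_path = None
        if topo["valid"]:
            job_path = fdir / "job.yml"
            _dump_yaml(job_path, {
                "workflow": str(wf_path),
                "output_folder": str(fdir / "output"),
                "uid": f"{name}-job",
                "seed_file": {"class": "File", "path": str(seed_file)},
            })
        manifests.append(FixtureManifest(
            name=name,
            path=wf_path,
            step_ids=tuple(topo["steps"]),
            intended_edges=_intended_edges(topo["steps"]),
            expected_output_ids=frozenset(topo["outputs"]),
            job_file=job_path,
            valid=topo["valid"],
        ))
    return manifests


def make_failing_variant(outdir: str | Path, fail_step: str = "B") -> FixtureManifest:
    """A diamond whose ``fail_step`` exits 1 — for failure-path tests.

    The failing tool keeps the original step's input arity so the workflow
    wiring stays valid; regenerating the suite restores the healthy tool.
    """
    outdir = Path(outdir)
    manifests = make_topology_suite(outdir)
    diamond = next(m for m in manifests if m.name == "diamond")
    bindir = outdir / "bin"
    arity = len(_TOPOLOGIES["diamond"]["steps"][fail_step])
    fail_tool = {
        "cwlVersion": "v1.0",
        "class": "CommandLineTool",
        "baseCommand": _stub_command(bindir, "stub_fail.py"),
        "inputs": [{"id": f"in{i}", "type": "File",
                    "inputBinding": {"position": i}}
                   for i in range(1, arity + 1)],
        "outputs": [{"id": "out", "type": "File",
                     "outputBinding": {"glob": "out.txt"}}],
    }
    _dump_yaml(outdir / "diamond" / "tools" / f"{fail_step}.cwl", fail_tool)
    return diamond


# ---------------------------------------------------------------------------
# command-line binding conformance suite
# ---------------------------------------------------------------------------

def _binding_cases() -> list[dict]:
    """The 12 frozen conformance cases.

    Expected argv values follow the CWL v1.0 binding rules: tokens sorted
    by (position, tie-break key), prefix/separate handling, itemSeparator
    joining, boolean flags, null omission, and File path substitution
    (File tokens are recorded as basenames; the staged path always ends in
    the basename).
    """
    return [
        {
            "name": "pos-order",
            "tool": {"baseCommand": ["tool"], "inputs": [
                {"id": "a", "type": "string", "inputBinding": {"position": 3}},
                {"id": "b", "type": "string", "inputBinding": {"position": 1}},
                {"id": "c", "type": "string", "inputBinding": {"position": 2}},
            ], "outputs": []},
            "values": {"a": "A", "b": "B", "c": "C"},
            "expected_argv": ["tool", "B", "C", "A"],
        },
        {
            "name": "tie-lex",
            "tool": {"baseCommand": ["tool"], "inputs": [
                {"id": "zeta", "type": "string", "inputBinding": {"position": 1}},
                {"id": "alpha", "type": "string", "inputBinding": {"position": 1}},
            ], "outputs": []},
            "values": {"zeta": "Z", "alpha": "A"},
            "expected_argv": ["tool", "A", "Z"],
        },
        {
            "name": "prefix-separate",
            "tool": {"baseCommand": ["tool"], "inputs": [
                {"id": "threads", "type": "int",
                 "inputBinding": {"position": 1, "prefix": "-t"}},
            ], "outputs": []},
            "values": {"threads": 4},
            "expected_argv": ["tool", "-t", "4"],
        },
        {
            "name": "prefix-joined",
            "tool": {"baseCommand": ["tool"], "inputs": [
                {"id": "level", "type": "string",
                 "inputBinding": {"position": 1, "prefix": "--level=",
                                  "separate": False}},
            ], "outputs": []},
            "values": {"level": "high"},
            "expected_argv": ["tool", "--level=high"],
        },
        {
            "name": "array-itemsep",
            "tool": {"baseCommand": ["tool"], "inputs": [
                {"id": "items", "type": "string[]",
                 "inputBinding": {"position": 1, "prefix": "-i",
                                  "itemSeparator": ","}},
            ], "outputs": []},
            "values": {"items": ["a", "b", "c"]},
            "expected_argv": ["tool", "-i", "a,b,c"],
        },
        {
            "name": "array-plain",
            "tool": {"baseCommand": ["tool"], "inputs": [
                {"id": "files", "type": "string[]",
                 "inputBinding": {"position": 1, "prefix": "-f"}},
            ], "outputs": []},
            "values": {"files": ["x", "y"]},
            "expected_argv": ["tool", "-f", "x", "y"],
        },
        {
            "name": "bool-true",
            "tool": {"baseCommand": ["tool"], "inputs": [
                {"id": "verbose", "type": "boolean",
                 "inputBinding": {"position": 1, "prefix": "--verbose"}},
            ], "outputs": []},
            "values": {"verbose": True},
            "expected_argv": ["tool", "--verbose"],
        },
        {
            "name": "bool-false",
            "tool": {"baseCommand": ["tool"], "inputs": [
                {"id": "verbose", "type": "boolean",
                 "inputBinding": {"position": 1, "prefix": "--verbose"}},
            ], "outputs": []},
            "values": {"verbose": False},
            "expected_argv": ["tool"],
        },
        {
            "name": "optional-null",
            "tool": {"baseCommand": ["tool"], "inputs": [
                {"id": "opt", "type": "string?",
                 "inputBinding": {"position": 1, "prefix": "-o"}},
                {"id": "req", "type": "string",
                 "inputBinding": {"position": 2}},
            ], "outputs": []},
            "values": {"req": "go"},
            "expected_argv": ["tool", "go"],
        },
        {
            "name": "stdio-redirect",
            "tool": {"baseCommand": ["cat"],
                     "stdin": "$(inputs.src.path)",
                     "stdout": "captured.txt",
                     "inputs": [{"id": "src", "type": "File"}],
                     "outputs": [{"id": "echoed", "type": "stdout"}]},
            "values": {"src": {"class": "File", "path": "__DATA__/src.txt"}},
            "expected_argv": ["cat"],
            "files": {"src.txt": "hello stdin\n"},
            "expect_stdout": "captured.txt",
        },
        {
            "name": "valuefrom-interp",
            "tool": {"baseCommand": ["tool"], "inputs": [
                {"id": "sample", "type": "string",
                 "inputBinding": {"position": 1,
                                  "valueFrom": "out_$(inputs.sample).bam"}},
            ], "outputs": []},
            "values": {"sample": "s1"},
            "expected_argv": ["tool", "out_s1.bam"],
        },
        {
            "name": "file-path",
            "tool": {"baseCommand": ["tool"], "inputs": [
                {"id": "data", "type": "File",
                 "inputBinding": {"position": 1}},
            ], "outputs": []},
            "values": {"data": {"class": "File", "path": "__DATA__/input_data.txt"}},
            "expected_argv": ["tool", "input_data.txt"],
            "files": {"input_data.txt": "payload\n"},
        },
    ]


def make_binding_suite(outdir: str | Path) -> list[dict]:
    """Emit the 12 binding cases: per case a tool document, a values file,
    any referenced data files, and the frozen expected argv as JSON.

    Returns the case records with ``__DATA__`` placeholders resolved to
    real paths.  File tokens in ``expected_argv`` are basenames; compare
    against a bound argv with staged paths reduced to basenames.
    """
    outdir = Path(outdir)
    records = []
    for case in _binding_cases():
        cdir = outdir / case["name"]
        ddir = cdir / "data"
        ddir.mkdir(parents=True, exist_ok=True)
        for fname, content in case.get("files", {}).items():
            (ddir / fname).write_text(content)

        values = json.loads(
            json.dumps(case["values"]).replace("__DATA__", str(ddir)))
        tool_doc = {"cwlVersion": "v1.0", "class": "CommandLineTool",
                    **case["tool"]}
        (cdir / "tool.cwl").write_text(json.dumps(tool_doc, indent=2,
                                                  sort_keys=True))
        (cdir / "values.json").write_text(json.dumps(values, indent=2,
                                                     sort_keys=True))
        (cdir / "expected_argv.json").write_text(
            json.dumps(case["expected_argv"], indent=2))
        records.append({
            "name": case["name"],
            "dir": cdir,
            "tool_path": cdir / "tool.cwl",
            "values": values,
            "expected_argv": case["expected_argv"],
            "expect_stdout": case.get("expect_stdout"),
        })
    return records


def normalize_argv(argv: list[str], workdir: str | Path) -> list[str]:
    """Reduce staged file tokens to basenames for comparison with the
    frozen expectations (staging rewrites File paths under ``workdir``)."""
    wd = str(workdir)
    return [Path(tok).name if tok.startswith(wd) else tok for tok in argv]
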