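"""Parameter references, command-line binding conformance, staging,
process execution, container command construction and output collection."""

import json
import os
from pathlib import Path

import pytest

from cwlflow import (
    bind_command_line,
    build_container_argv,
    collect_outputs,
    eval_param_ref,
    execute_step,
    load_document,
    run_process,
    stage_step,
)
from cwlflow.errors import (
    AmbiguousOutput,
    MissingOutput,
    MissingRequiredInput,
    SpawnError,
    StagingError,
    TypeMismatch,
    UnknownReference,
    UnsupportedExpression,
)
from cwlflow.fixtures import make_binding_suite, normalize_argv
from cwlflow.runner import CommandPlan, make_artifact, sha1_of


# ---------------------------------------------------------------------------
# parameter references
# ---------------------------------------------------------------------------

CTX = {
    "inputs": {
        "threads": 4,
        "sample": "s1",
        "reads": {"class": "File", "path": "/data/a.fq", "basename": "a.fq"},
    },
    "runtime": {"outdir": "/work", "cores": 2},
}


@pytest.mark.parametrize("expr, expected", [
    ("$(inputs.threads)", 4),                       # lone ref keeps native type
    ("$(inputs.sample)", "s1"),
    ("$(inputs.reads.path)", "/data/a.fq"),
    ("$(inputs.reads.basename)", "a.fq"),
    ("$(runtime.outdir)", "/work"),
    ("$(runtime.cores)", 2),
    ("out_$(inputs.sample).bam", "out_s1.bam"),     # interpolation
    ("-p$(inputs.threads)x$(runtime.cores)", "-p4x2"),
    ("no references here", "no references here"),
])
def test_param_ref_evaluation(expr, expected):
    assert eval_param_ref(expr, CTX) == expected


def test_javascript_rejected():
    with pytest.raises(UnsupportedExpression):
        eval_param_ref("${ return 1 }", CTX)


def test_unknown_reference_named():
    with pytest.raises(UnknownReference, match="inputs.ghost"):
        eval_param_ref("$(inputs.ghost)", CTX)


# ---------------------------------------------------------------------------
# binding conformance: the 12-case frozen suite
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def binding_cases(tmp_path_factory):
    return make_binding_suite(tmp_path_factory.mktemp("bind"))


def test_suite_has_twelve_cases(binding_cases):
    assert len(binding_cases) == 12


def test_binding_conformance(binding_cases, tmp_path):
    """Constructed argv equals the frozen expectation token-for-token for
    every case (File tokens compared as basenames after staging)."""
    for case in binding_cases:
        workdir = tmp_path / case["name"]
        workdir.mkdir()
        tool = load_document(case["tool_path"]).body
        staged = stage_step(case["values"], workdir)
        plan = bind_command_line(tool, staged, workdir, task_id=case["name"])
        got = normalize_argv(plan.argv, workdir)
        assert got == case["expected_argv"], case["name"]
        expected_file = json.loads(
            (case["dir"] / "expected_argv.json").read_text())
        assert got == expected_file
        if case["expect_stdout"]:
            assert plan.stdout_path == workdir / case["expect_stdout"]
            assert plan.stdin_path is not None


def test_missing_required_input_raises(binding_cases, tmp_path):
    case = next(c for c in binding_cases if c["name"] == "pos-order")
    tool = load_document(case["tool_path"]).body
    with pytest.raises(MissingRequiredInput, match="'a'"):
        bind_command_line(tool, {"b": "B", "c": "C"}, tmp_path)


def test_type_mismatch_raises(binding_cases, tmp_path):
    case = next(c for c in binding_cases if c["name"] == "prefix-separate")
    tool = load_document(case["tool_path"]).body
    with pytest.raises(TypeMismatch):
        bind_command_line(tool, {"threads": "four"}, tmp_path)


def test_default_fills_absent_input(tmp_path):
    from cwlflow import loads_document
    tool = loads_document(
        '{cwlVersion: v1.0, class: CommandLineTool, baseCommand: [tool],'
        ' inputs: [{id: k, type: int, default: 9,'
        ' inputBinding: {position: 1, prefix: -k}}], outputs: []}').body
    plan = bind_command_line(tool, {}, tmp_path)
    assert plan.argv == ["tool", "-k", "9"]


# ---------------------------------------------------------------------------
# staging
# ---------------------------------------------------------------------------

def test_staging_links_preserve_content(tmp_path):
    src = tmp_path / "payload.txt"
    src.write_text("the payload\n")
    workdir = tmp_path / "wd"
    workdir.mkdir()
    staged = stage_step({"f": {"class": "File", "path": str(src)}, "n": 3},
                        workdir)
    staged_path = Path(staged["f"]["path"])
    assert staged_path.parent == workdir / "inputs"
    assert sha1_of(staged_path) == sha1_of(src)
    assert staged["n"] == 3                      # scalars pass through


def test_staging_collision_gets_suffix(tmp_path):
    a = tmp_path / "d1" / "same.txt"
    b = tmp_path / "d2" / "same.txt"
    for p, text in ((a, "one\n"), (b, "two\n")):
        p.parent.mkdir()
        p.write_text(text)
    workdir = tmp_path / "wd"
    workdir.mkdir()
    staged = stage_step({"x": {"class": "File", "path": str(a)},
                         "y": {"class": "File", "path": str(b)}}, workdir)
    assert staged["x"]["path"] != staged["y"]["path"]
    assert Path(staged["y"]["path"]).read_text() == "two\n"


def test_staging_missing_source_raises(tmp_path):
    workdir = tmp_path / "wd"
    workdir.mkdir()
    with pytest.raises(StagingError):
        stage_step({"f": {"class": "File", "path": str(tmp_path / "gone")}},
                   workdir)


# ---------------------------------------------------------------------------
# process execution
# ---------------------------------------------------------------------------

def test_exit_codes_returned_not_raised(tmp_path):
    assert run_process(CommandPlan(argv=["true"], workdir=tmp_path)) == 0
    assert run_process(CommandPlan(argv=["false"], workdir=tmp_path)) == 1


def test_spawn_error_distinct_from_nonzero_exit(tmp_path):
    with pytest.raises(SpawnError):
        run_process(CommandPlan(argv=["definitely-not-a-real-binary-xyz"],
                                workdir=tmp_path))


def test_stdout_capture_and_env(tmp_path):
    plan = CommandPlan(argv=["sh", "-c", "echo value=$CWLFLOW_T"],
                       workdir=tmp_path, stdout_path=tmp_path / "cap.txt",
                       env={"CWLFLOW_T": "42"})
    assert run_process(plan) == 0
    assert (tmp_path / "cap.txt").read_text() == "value=42\n"


# ---------------------------------------------------------------------------
# container command construction (never executed)
# ---------------------------------------------------------------------------

def test_docker_wrapping_order(tmp_path):
    plan = CommandPlan(argv=["echo", "hi"], workdir=tmp_path)
    argv = build_container_argv(plan, {"dockerPull": "alpine:3"}, "docker")
    assert argv[:2] == ["docker", "run"]
    for needle in (f"{tmp_path}:{tmp_path}", "alpine:3", "echo", "hi"):
        assert needle in argv
    assert argv.index("alpine:3") < argv.index("echo") < argv.index("hi")


def test_singularity_wrapping(tmp_path):
    plan = CommandPlan(argv=["echo", "hi"], workdir=tmp_path)
    argv = build_container_argv(plan, {"dockerPull": "docker://alpine"},
                                "singularity")
    assert argv[0] == "singularity" and "exec" in argv
    assert "docker://alpine" in argv


def test_empty_image_rejected_at_load_time():
    from cwlflow import loads_document
    from cwlflow.errors import UnsupportedFeature
    with pytest.raises(UnsupportedFeature, match="image"):
        loads_document(
            '{cwlVersion: v1.0, class: CommandLineTool, baseCommand: [t],'
            ' inputs: [], outputs: [],'
            ' requirements: [{class: DockerRequirement}]}')


# ---------------------------------------------------------------------------
# output collection
# ---------------------------------------------------------------------------

def _glob_tool(type_, glob="*.txt"):
    from cwlflow import loads_document
    return loads_document(json.dumps({
        "cwlVersion": "v1.0", "class": "CommandLineTool",
        "baseCommand": ["t"], "inputs": [],
        "outputs": [{"id": "o", "type": type_,
                     "outputBinding": {"glob": glob}}]})).body


def test_array_glob_lexicographic(tmp_path):
    (tmp_path / "b.txt").write_text("b")
    (tmp_path / "a.txt").write_text("a")
    tool = _glob_tool("File[]")
    out = collect_outputs(tool, tmp_path, CommandPlan(argv=["t"], workdir=tmp_path))
    assert [a.basename for a in out["o"]] == ["a.txt", "b.txt"]


def test_single_file_glob_cardinality(tmp_path):
    tool = _glob_tool("File")
    plan = CommandPlan(argv=["t"], workdir=tmp_path)
    with pytest.raises(MissingOutput, match="'o'"):
        collect_outputs(tool, tmp_path, plan)
    (tmp_path / "one.txt").write_text("1")
    out = collect_outputs(tool, tmp_path, plan)
    assert out["o"].basename == "one.txt"
    assert out["o"].checksum == sha1_of(tmp_path / "one.txt")
    (tmp_path / "two.txt").write_text("2")
    with pytest.raises(AmbiguousOutput):
        collect_outputs(tool, tmp_path, plan)


def test_optional_output_zero_matches_is_none(tmp_path):
    tool = _glob_tool("File?")
    out = collect_outputs(tool, tmp_path, CommandPlan(argv=["t"], workdir=tmp_path))
    assert out["o"] is None


def test_execute_step_end_to_end_stdout(tmp_path):
    """A full stage→bind→run→collect pass on a stdout-capturing tool."""
    from cwlflow import loads_document
    src = tmp_path / "in.txt"
    src.write_text("line\n")
    tool = loads_document(json.dumps({
        "cwlVersion": "v1.0", "class": "CommandLineTool",
        "baseCommand": ["cat"],
        "stdin": "$(inputs.src.path)",
        "inputs": [{"id": "src", "type": "File"}],
        "outputs": [{"id": "echoed", "type": "stdout"}]})).body
    wd = tmp_path / "wd"
    result = execute_step(tool, {"src": {"class": "File", "path": str(src)}},
                          wd, task_id="cat1")
    assert result.exit_code == 0
    art = result.outputs["echoed"]
    assert art.basename == "cat1.stdout"
    assert art.checksum == sha1_of(src)          # checksum conservation


def test_step_is_hermetic(tmp_path):
    """A step creates files only inside its working directory."""
    from cwlflow import loads_document
    before = {p for p in tmp_path.rglob("*")}
    tool = loads_document(json.dumps({
        "cwlVersion": "v1.0", "class": "CommandLineTool",
        "baseCommand": ["sh", "-c", "echo made > made.txt"],
        "inputs": [], "outputs": [
            {"id": "o", "type": "File", "outputBinding": {"glob": "made.txt"}}]
    })).body
    wd = tmp_path / "wd"
    result = execute_step(tool, {}, wd, task_id="herm")
    assert result.exit_code == 0
    created = {p for p in tmp_path.rglob("*")} - before
    assert all(wd in p.parents or p == wd for p in created)
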