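"""Document loading, subset enforcement, connectivity and round-trip."""

import json

import pytest

from cwlflow import load_document, loads_document, to_canonical_json, validate_connectivity
from cwlflow.documents import CwlType, ToolDocument, parse_type, types_compatible
from cwlflow.errors import (
    ParseError,
    UnresolvedReference,
    UnsupportedFeature,
    VersionError,
)
from cwlflow.fixtures import make_chipseq_like, make_topology_suite

from conftest import workflow_of

MINIMAL_TOOL = """\
{cwlVersion: v1.0, class: CommandLineTool, baseCommand: [echo],
 inputs: [], outputs: []}
"""


def test_minimal_tool_parses():
    doc = loads_document(MINIMAL_TOOL)
    assert doc.class_kind == "CommandLineTool"
    tool = doc.body
    assert tool.base_command == ["echo"]
    assert tool.inputs == [] and tool.outputs == []


def test_wrong_version_rejected():
    with pytest.raises(VersionError):
        loads_document(MINIMAL_TOOL.replace("v1.0", "v1.1"))


@pytest.mark.parametrize("mutation, exc", [
    # unknown top-level key: nothing is silently dropped
    ("{cwlVersion: v1.0, class: CommandLineTool, baseCommand: [echo],"
     " inputs: [], outputs: [], successCodes: [0]}", UnsupportedFeature),
    # JavaScript expressions are out of subset
    ("{cwlVersion: v1.0, class: CommandLineTool, baseCommand: [echo],"
     " arguments: ['${ return 1 }'], inputs: [], outputs: []}", UnsupportedFeature),
    # record types out of subset
    ("{cwlVersion: v1.0, class: CommandLineTool, baseCommand: [echo],"
     " inputs: [{id: r, type: {type: record, fields: []}}], outputs: []}",
     UnsupportedFeature),
    # only the two-member null union is allowed
    ("{cwlVersion: v1.0, class: CommandLineTool, baseCommand: [echo],"
     " inputs: [{id: u, type: [string, int]}], outputs: []}", UnsupportedFeature),
    # unknown requirement kinds fail closed
    ("{cwlVersion: v1.0, class: CommandLineTool, baseCommand: [echo],"
     " inputs: [], outputs: [],"
     " requirements: [{class: InlineJavascriptRequirement}]}", UnsupportedFeature),
    # empty command line is invalid
    ("{cwlVersion: v1.0, class: CommandLineTool, inputs: [], outputs: []}",
     ParseError),
    # duplicate input ids
    ("{cwlVersion: v1.0, class: CommandLineTool, baseCommand: [echo],"
     " inputs: [{id: x, type: string}, {id: x, type: int}], outputs: []}",
     ParseError),
])
def test_subset_violations_rejected(mutation, exc):
    with pytest.raises(exc):
        loads_document(mutation)


def test_scatter_step_rejected(tmp_path):
    manifests = make_topology_suite(tmp_path)
    single = next(m for m in manifests if m.name == "single")
    text = single.path.read_text().replace("in:", "scatter: in1\n  in:")
    bad = tmp_path / "single" / "scattered.cwl"
    bad.write_text(text)
    with pytest.raises(UnsupportedFeature, match="scatter"):
        load_document(bad)


def test_missing_run_file_is_unresolved(tmp_path):
    wf = tmp_path / "wf.cwl"
    wf.write_text(json.dumps({
        "cwlVersion": "v1.0", "class": "Workflow",
        "inputs": [{"id": "x", "type": "File"}],
        "outputs": [{"id": "o", "type": "File", "outputSource": "s/out"}],
        "steps": [{"id": "s", "run": "nope.cwl", "in": {"in1": "x"},
                   "out": ["out"]}],
    }))
    with pytest.raises(UnresolvedReference, match="nope.cwl"):
        load_document(wf)


def test_reserved_step_id_rejected(tmp_path):
    manifests = make_topology_suite(tmp_path)
    single = next(m for m in manifests if m.name == "single")
    text = single.path.read_text().replace("id: A", "id: JobDispatcher")
    bad = tmp_path / "single" / "reserved.cwl"
    bad.write_text(text)
    with pytest.raises(ParseError, match="reserved"):
        load_document(bad)


def test_chipseq_fixture_steps_match_manifest(tmp_path):
    manifest = make_chipseq_like(tmp_path, seed=7)
    wf = workflow_of(manifest)
    assert tuple(s.id for s in wf.steps) == manifest.step_ids
    assert all(s.run.class_kind == "CommandLineTool" for s in wf.steps)


@pytest.mark.parametrize("raw, expect", [
    ("File", CwlType("File")),
    ("string?", CwlType("string", optional=True)),
    ("int[]", CwlType("int", is_array=True)),
    (["null", "File"], CwlType("File", optional=True)),
    ({"type": "array", "items": "string"}, CwlType("string", is_array=True)),
])
def test_type_grammar(raw, expect):
    assert parse_type(raw, where="t") == expect


def test_type_compatibility_rules():
    assert types_compatible(CwlType("File"), CwlType("File"))
    assert types_compatible(CwlType("File"), CwlType("File", optional=True))
    assert not types_compatible(CwlType("File"), CwlType("int"))
    assert not types_compatible(CwlType("File"), CwlType("File", is_array=True))


def test_connectivity_clean_on_valid_fixtures(tmp_path):
    for m in make_topology_suite(tmp_path):
        if m.name == "dangling_invalid":
            continue
        assert validate_connectivity(workflow_of(m)) == []


def test_connectivity_names_dangling_source(tmp_path):
    manifests = make_topology_suite(tmp_path)
    dangling = next(m for m in manifests if m.name == "dangling_invalid")
    diags = validate_connectivity(workflow_of(dangling))
    assert len(diags) == 1
    assert "ghost/out" in diags[0].reference


def test_connectivity_flags_type_mismatch(tmp_path):
    wf_path = tmp_path / "wf.cwl"
    wf_path.write_text(json.dumps({
        "cwlVersion": "v1.0", "class": "Workflow",
        "inputs": [{"id": "n", "type": "int"}],
        "outputs": [],
        "steps": [{"id": "s", "run": {
            "class": "CommandLineTool", "baseCommand": ["echo"],
            "inputs": [{"id": "f", "type": "File",
                        "inputBinding": {"position": 1}}],
            "outputs": []}, "in": {"f": "n"}, "out": []}],
    }))
    diags = validate_connectivity(load_document(wf_path).body)
    assert len(diags) == 1 and "mismatch" in diags[0].message


def test_canonical_roundtrip_is_fixpoint(tmp_path):
    """Serializing and reloading yields the same canonical form, for both
    the tool and the workflow document classes."""
    manifest = make_chipseq_like(tmp_path, seed=3)
    for path in [manifest.path, tmp_path / "tools" / "align.cwl"]:
        doc = load_document(path)
        canon = to_canonical_json(doc)
        reread = tmp_path / f"canon_{path.stem}.json"
        reread.write_text(canon)
        assert to_canonical_json(load_document(reread)) == canon


def test_load_independent_of_key_order(tmp_path):
    a = tmp_path / "a.cwl"
    b = tmp_path / "b.cwl"
    a.write_text('{"cwlVersion": "v1.0", "class": "CommandLineTool",'
                 ' "baseCommand": ["echo"], "inputs": [], "outputs": []}')
    b.write_text('{"outputs": [], "inputs": [], "baseCommand": ["echo"],'
                 ' "class": "CommandLineTool", "cwlVersion": "v1.0"}')
    assert load_document(a).body == load_document(b).body
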