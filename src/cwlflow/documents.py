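"""Loading and validation of CWL v1.0 documents (supported subset).

Two document classes are handled: ``CommandLineTool`` and ``Workflow``.
YAML and JSON are both accepted (JSON parse is attempted first; the file
extension is advisory only).  The parser is fail-closed: every key it does
not consume raises :class:`~cwlflow.errors.UnsupportedFeature`, so no part
of a document is ever silently ignored.

Out of subset (rejected at load time): JavaScript expressions, ``scatter``,
nested workflows as step run-targets, schema-salad record/enum types,
``$import``/``$include``, secondaryFiles and multi-member type unions other
than ``["null", T]``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Union

import yaml

from .errors import (
    Diagnostic,
    ParseError,
    UnresolvedReference,
    UnsupportedFeature,
    VersionError,
)

SUPPORTED_VERSION = "v1.0"

#: task ids reserved for the synthetic DAG endpoints; a workflow step may
#: not use them (step ids become task ids verbatim).
RESERVED_TASK_IDS = frozenset({"JobDispatcher", "JobCleanup"})

SCALAR_TYPES = frozenset({"string", "int", "long", "float", "double", "boolean"})
BASE_TYPES = SCALAR_TYPES | {"File"}

SUPPORTED_REQUIREMENTS = frozenset(
    {"DockerRequirement", "ResourceRequirement", "EnvVarRequirement"}
)


# ---------------------------------------------------------------------------
# type model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CwlType:
    """A type in the supported subset: scalar or File, optionally an array,
    optionally nullable (the two-member union ``["null", T]``)."""

    base: str                # one of BASE_TYPES, or "stdout" for outputs
    is_array: bool = False
    optional: bool = False

    def __str__(self) -> str:
        s = self.base + ("[]" if self.is_array else "")
        return s + ("?" if self.optional else "")

    def to_cwl(self) -> Any:
        inner: Any = self.base
        if self.is_array:
            inner = {"type": "array", "items": self.base}
        if self.optional:
            return ["null", inner]
        return inner


def parse_type(raw: Any, *, where: str, output: bool = False) -> CwlType:
    """Parse a CWL type expression in the supported subset."""
    optional = False
    if isinstance(raw, list):
        if len(raw) == 2 and "null" in raw:
            optional = True
            raw = raw[0] if raw[1] == "null" else raw[1]
        else:
            raise UnsupportedFeature(
                f"{where}: only the two-member union ['null', T] is supported, got {raw!r}"
            )
    is_array = False
    if isinstance(raw, str):
        if raw.endswith("?"):
            optional = True
            raw = raw[:-1]
        if raw.endswith("[]"):
            is_array = True
            raw = raw[:-2]
        base = raw
    elif isinstance(raw, dict):
        if raw.get("type") != "array":
            raise UnsupportedFeature(
                f"{where}: compound type {raw.get('type')!r} is not supported"
            )
        items = raw.get("items")
        if not isinstance(items, str) or items not in BASE_TYPES:
            raise UnsupportedFeature(f"{where}: array items must be a scalar or File, got {items!r}")
        is_array = True
        base = items
        extra = set(raw) - {"type", "items"}
        if extra:
            raise UnsupportedFeature(f"{where}: unsupported array-type keys {sorted(extra)}")
    else:
        raise UnsupportedFeature(f"{where}: cannot interpret type {raw!r}")

    if base == "stdout":
        if not output or is_array or optional:
            raise UnsupportedFeature(f"{where}: 'stdout' is only valid as a plain output type")
        return CwlType("stdout")
    if base not in BASE_TYPES:
        raise UnsupportedFeature(f"{where}: type {base!r} is outside the supported subset")
    return CwlType(base, is_array=is_array, optional=optional)


def types_compatible(src: CwlType, dst: CwlType) -> bool:
    """Dataflow compatibility: File↔File, same scalar, X↔optional-X."""
    if src.base == "stdout":
        src = CwlType("File", src.is_array, src.optional)
    return src.base == dst.base and src.is_array == dst.is_array


# ---------------------------------------------------------------------------
# binding and parameter model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CommandBindingSpec:
    position: int = 0
    prefix: Optional[str] = None
    separate: bool = True
    item_separator: Optional[str] = None
    value_from: Optional[str] = None

    def to_cwl(self) -> dict:
        d: dict[str, Any] = {"position": self.position}
        if self.prefix is not None:
            d["prefix"] = self.prefix
        if not self.separate:
            d["separate"] = False
        if self.item_separator is not None:
            d["itemSeparator"] = self.item_separator
        if self.value_from is not None:
            d["valueFrom"] = self.value_from
        return d


@dataclass(frozen=True)
class OutputBindingSpec:
    glob_pattern: str = ""
    capture: str = "files"   # "files" | "stdout"


@dataclass(frozen=True)
class IOParameter:
    id: str
    cwl_type: CwlType
    default_value: Any = None
    has_default: bool = False
    input_binding: Optional[CommandBindingSpec] = None
    output_binding: Optional[OutputBindingSpec] = None
    output_source: Optional[str] = None   # workflow outputs only
    doc: Optional[str] = None

    @property
    def required(self) -> bool:
        return not self.cwl_type.optional and not self.has_default


@dataclass(frozen=True)
class Requirement:
    kind: str
    payload: dict


# ---------------------------------------------------------------------------
# documents
# ---------------------------------------------------------------------------

@dataclass
class ToolDocument:
    base_command: list[str]
    arguments: list[CommandBindingSpec]
    inputs: list[IOParameter]
    outputs: list[IOParameter]
    stdin_ref: Optional[str] = None
    stdout_name: Optional[str] = None
    stderr_name: Optional[str] = None
    requirements: list[Requirement] = field(default_factory=list)

    def input(self, pid: str) -> IOParameter:
        return _by_id(self.inputs, pid)

    def output(self, pid: str) -> IOParameter:
        return _by_id(self.outputs, pid)

    def requirement(self, kind: str) -> Optional[Requirement]:
        for r in self.requirements:
            if r.kind == kind:
                return r
        return None


@dataclass
class StepSpec:
    id: str
    run: "CWLDocument"
    run_ref: str = field(compare=False, default="")
    # step-input-id -> {"source": ref} and/or {"default": value}
    in_bindings: dict[str, dict] = field(default_factory=dict)
    out_ids: list[str] = field(default_factory=list)

    def sources(self) -> list[str]:
        return [b["source"] for b in self.in_bindings.values() if "source" in b]


@dataclass
class WorkflowDocument:
    inputs: list[IOParameter]
    outputs: list[IOParameter]
    steps: list[StepSpec]

    def input(self, pid: str) -> IOParameter:
        return _by_id(self.inputs, pid)

    def step(self, sid: str) -> StepSpec:
        for s in self.steps:
            if s.id == sid:
                return s
        raise KeyError(sid)


@dataclass
class CWLDocument:
    class_kind: str          # "CommandLineTool" | "Workflow"
    cwl_version: str
    id: str
    body: Union[ToolDocument, WorkflowDocument]
    source_path: Optional[Path] = field(compare=False, default=None)


def _by_id(params: list[IOParameter], pid: str) -> IOParameter:
    for p in params:
        if p.id == pid:
            return p
    raise KeyError(pid)


# ---------------------------------------------------------------------------
# raw parsing helpers
# ---------------------------------------------------------------------------

def _parse_text(text: str, origin: str) -> dict:
    """JSON first, then YAML; the result must be a mapping."""
    try:
        data = json.loads(text)
    except (json.JSONDecodeError, ValueError):
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ParseError(f"{origin}: not valid JSON or YAML: {exc}") from exc
    if not isinstance(data, dict):
        raise ParseError(f"{origin}: document is not a mapping")
    return data


def _check_keys(mapping: dict, allowed: set[str], where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise UnsupportedFeature(
            f"{where}: unsupported key(s) {sorted(unknown)} (fail-closed subset)"
        )


def _reject_js(text: str, where: str) -> None:
    if isinstance(text, str) and "${" in text:
        raise UnsupportedFeature(f"{where}: JavaScript expressions (${{...}}) are not supported")


def _listify_params(raw: Any, where: str) -> list[dict]:
    """Normalize CWL's map/list parameter forms into a list of dicts with 'id'."""
    out: list[dict] = []
    if raw is None:
        return out
    if isinstance(raw, dict):
        for pid, body in raw.items():
            if isinstance(body, (str, list)):
                body = {"type": body}
            elif not isinstance(body, dict):
                raise ParseError(f"{where}: parameter {pid!r} body must be a type or mapping")
            entry = dict(body)
            entry["id"] = pid
            out.append(entry)
    elif isinstance(raw, list):
        for body in raw:
            if not isinstance(body, dict) or "id" not in body:
                raise ParseError(f"{where}: list-form parameters need an 'id'")
            out.append(dict(body))
    else:
        raise ParseError(f"{where}: inputs/outputs must be a mapping or list")
    ids = [e["id"] for e in out]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ParseError(f"{where}: duplicate parameter id(s) {sorted(dupes)}")
    return out


def _parse_binding(raw: dict, where: str) -> CommandBindingSpec:
    _check_keys(raw, {"position", "prefix", "separate", "itemSeparator", "valueFrom"}, where)
    vf = raw.get("valueFrom")
    if vf is not None:
        _reject_js(vf, where)
    pos = raw.get("position", 0)
    if not isinstance(pos, int):
        raise ParseError(f"{where}: position must be an integer")
    return CommandBindingSpec(
        position=pos,
        prefix=raw.get("prefix"),
        separate=bool(raw.get("separate", True)),
        item_separator=raw.get("itemSeparator"),
        value_from=vf,
    )


def _parse_requirements(raw: Any, where: str) -> list[Requirement]:
    if raw is None:
        return []
    entries: list[tuple[str, dict]] = []
    if isinstance(raw, list):
        for item in raw:
            if not isinstance(item, dict) or "class" not in item:
                raise ParseError(f"{where}: each requirement needs a 'class'")
            body = {k: v for k, v in item.items() if k != "class"}
            entries.append((item["class"], body))
    elif isinstance(raw, dict):
        entries = [(k, dict(v) if isinstance(v, dict) else {}) for k, v in raw.items()]
    else:
        raise ParseError(f"{where}: requirements must be a list or mapping")
    reqs = []
    for kind, payload in entries:
        if kind not in SUPPORTED_REQUIREMENTS:
            raise UnsupportedFeature(f"{where}: requirement {kind!r} is not supported")
        if kind == "DockerRequirement":
            image = payload.get("dockerPull") or payload.get("dockerImageId")
            if not image:
                raise UnsupportedFeature(
                    f"{where}: DockerRequirement without an image identifier"
                )
        reqs.append(Requirement(kind=kind, payload=payload))
    return reqs


# ---------------------------------------------------------------------------
# CommandLineTool
# ---------------------------------------------------------------------------

_TOOL_KEYS = {
    "cwlVersion", "class", "id", "label", "doc",
    "baseCommand", "arguments", "inputs", "outputs",
    "stdin", "stdout", "stderr", "requirements",
}

_PARAM_IN_KEYS = {"id", "type", "default", "inputBinding", "doc", "label"}
_PARAM_OUT_KEYS = {"id", "type", "outputBinding", "doc", "label"}


def _parse_tool(data: dict, origin: str) -> ToolDocument:
    _check_keys(data, _TOOL_KEYS, origin)

    base = data.get("baseCommand", [])
    if isinstance(base, str):
        base = [base]
    if not isinstance(base, list) or not all(isinstance(t, str) for t in base):
        raise ParseError(f"{origin}: baseCommand must be a string or list of strings")

    arguments: list[CommandBindingSpec] = []
    for i, arg in enumerate(data.get("arguments") or []):
        where = f"{origin} arguments[{i}]"
        if isinstance(arg, str):
            _reject_js(arg, where)
            arguments.append(CommandBindingSpec(value_from=arg))
        elif isinstance(arg, dict):
            arguments.append(_parse_binding(arg, where))
        else:
            raise ParseError(f"{where}: argument must be a string or binding mapping")

    if not base and not arguments:
        raise ParseError(f"{origin}: baseCommand and arguments are both empty")

    inputs: list[IOParameter] = []
    for entry in _listify_params(data.get("inputs"), f"{origin} inputs"):
        where = f"{origin} input {entry['id']!r}"
        _check_keys(entry, _PARAM_IN_KEYS, where)
        binding = None
        if "inputBinding" in entry:
            binding = _parse_binding(entry["inputBinding"] or {}, where)
        inputs.append(IOParameter(
            id=entry["id"],
            cwl_type=parse_type(entry.get("type"), where=where),
            default_value=entry.get("default"),
            has_default="default" in entry,
            input_binding=binding,
            doc=entry.get("doc"),
        ))

    outputs: list[IOParameter] = []
    stdout_declared = False
    for entry in _listify_params(data.get("outputs"), f"{origin} outputs"):
        where = f"{origin} output {entry['id']!r}"
        _check_keys(entry, _PARAM_OUT_KEYS, where)
        ctype = parse_type(entry.get("type"), where=where, output=True)
        if ctype.base == "stdout":
            stdout_declared = True
            ob = OutputBindingSpec(capture="stdout")
            ctype = CwlType("File")
        else:
            raw_ob = entry.get("outputBinding")
            if ctype.base != "File":
                raise UnsupportedFeature(
                    f"{where}: only File, File[] and stdout outputs are in the subset"
                )
            if not isinstance(raw_ob, dict) or "glob" not in raw_ob:
                raise ParseError(f"{where}: File output requires outputBinding.glob")
            _check_keys(raw_ob, {"glob"}, where)
            _reject_js(raw_ob["glob"], where)
            ob = OutputBindingSpec(glob_pattern=raw_ob["glob"], capture="files")
        outputs.append(IOParameter(id=entry["id"], cwl_type=ctype, output_binding=ob,
                                   doc=entry.get("doc")))

    stdin_ref = data.get("stdin")
    if stdin_ref is not None:
        _reject_js(stdin_ref, f"{origin} stdin")
    stdout_name = data.get("stdout")
    if stdout_name is not None:
        _reject_js(stdout_name, f"{origin} stdout")
    if stdout_declared and stdout_name is None:
        stdout_name = None  # generated per-task at bind time ("<task_id>.stdout")

    return ToolDocument(
        base_command=list(base),
        arguments=arguments,
        inputs=inputs,
        outputs=outputs,
        stdin_ref=stdin_ref,
        stdout_name=stdout_name,
        stderr_name=data.get("stderr"),
        requirements=_parse_requirements(data.get("requirements"), origin),
    )


# ---------------------------------------------------------------------------
# Workflow
# ---------------------------------------------------------------------------

_WF_KEYS = {"cwlVersion", "class", "id", "label", "doc", "inputs", "outputs",
            "steps", "requirements"}
_WF_OUT_KEYS = {"id", "type", "outputSource", "doc", "label"}
_STEP_KEYS = {"id", "run", "in", "out", "label", "doc"}
_UNSUPPORTED_STEP_KEYS = {"scatter", "scatterMethod", "when", "requirements", "hints"}


def _normalize_steps(raw: Any, where: str) -> list[dict]:
    out: list[dict] = []
    if isinstance(raw, dict):
        for sid, body in raw.items():
            if not isinstance(body, dict):
                raise ParseError(f"{where}: step {sid!r} body must be a mapping")
            entry = dict(body)
            entry["id"] = sid
            out.append(entry)
    elif isinstance(raw, list):
        for body in raw:
            if not isinstance(body, dict) or "id" not in body:
                raise ParseError(f"{where}: list-form steps need an 'id'")
            out.append(dict(body))
    else:
        raise ParseError(f"{where}: steps must be a mapping or list")
    return out


def _parse_step_inputs(raw: Any, where: str) -> dict[str, dict]:
    bindings: dict[str, dict] = {}
    if raw is None:
        return bindings
    if isinstance(raw, dict):
        items = list(raw.items())
    elif isinstance(raw, list):
        items = []
        for body in raw:
            if not isinstance(body, dict) or "id" not in body:
                raise ParseError(f"{where}: list-form step inputs need an 'id'")
            items.append((body["id"], {k: v for k, v in body.items() if k != "id"}))
    else:
        raise ParseError(f"{where}: step 'in' must be a mapping or list")

    for iid, body in items:
        spec: dict[str, Any] = {}
        if isinstance(body, str):
            spec["source"] = body
        elif isinstance(body, dict):
            _check_keys(body, {"source", "default"}, f"{where} input {iid!r}")
            if "source" in body:
                src = body["source"]
                if isinstance(src, list):
                    raise UnsupportedFeature(
                        f"{where} input {iid!r}: multi-source (MultipleInputFeature) not supported"
                    )
                spec["source"] = src
            if "default" in body:
                spec["default"] = body["default"]
        else:
            # a bare scalar is a constant default
            spec["default"] = body
        if not spec:
            raise ParseError(f"{where} input {iid!r}: needs a source or default")
        bindings[iid] = spec
    return bindings


def _parse_workflow(data: dict, origin: str, base_dir: Path, depth: int) -> WorkflowDocument:
    _check_keys(data, _WF_KEYS, origin)
    _parse_requirements(data.get("requirements"), origin)  # validate-only at wf level

    inputs: list[IOParameter] = []
    for entry in _listify_params(data.get("inputs"), f"{origin} inputs"):
        where = f"{origin} input {entry['id']!r}"
        _check_keys(entry, _PARAM_IN_KEYS - {"inputBinding"}, where)
        inputs.append(IOParameter(
            id=entry["id"],
            cwl_type=parse_type(entry.get("type"), where=where),
            default_value=entry.get("default"),
            has_default="default" in entry,
            doc=entry.get("doc"),
        ))

    outputs: list[IOParameter] = []
    for entry in _listify_params(data.get("outputs"), f"{origin} outputs"):
        where = f"{origin} output {entry['id']!r}"
        _check_keys(entry, _WF_OUT_KEYS, where)
        src = entry.get("outputSource")
        if not isinstance(src, str):
            raise ParseError(f"{where}: outputSource is required")
        outputs.append(IOParameter(
            id=entry["id"],
            cwl_type=parse_type(entry.get("type"), where=where),
            output_source=src,
            doc=entry.get("doc"),
        ))

    steps: list[StepSpec] = []
    seen: set[str] = set()
    for entry in _normalize_steps(data.get("steps"), f"{origin} steps"):
        sid = entry["id"]
        where = f"{origin} step {sid!r}"
        bad = set(entry) & _UNSUPPORTED_STEP_KEYS
        if bad:
            raise UnsupportedFeature(f"{where}: unsupported step key(s) {sorted(bad)}")
        _check_keys(entry, _STEP_KEYS, where)
        if sid in seen:
            raise ParseError(f"{origin}: duplicate step id {sid!r}")
        if sid in RESERVED_TASK_IDS:
            raise ParseError(f"{where}: step id collides with a reserved task id")
        seen.add(sid)

        run_raw = entry.get("run")
        if isinstance(run_raw, str):
            run_path = Path(run_raw)
            if not run_path.is_absolute():
                run_path = (base_dir / run_path).resolve()
            if not run_path.exists():
                raise UnresolvedReference(f"{where}: run file {run_raw!r} not found")
            run_doc = load_document(run_path, _depth=depth + 1)
            run_ref = run_raw
        elif isinstance(run_raw, dict):
            run_doc = _load_mapping(run_raw, origin=f"{where} inline run",
                                    base_dir=base_dir, depth=depth + 1)
            run_ref = ""
        else:
            raise ParseError(f"{where}: 'run' must be a path or inline tool")
        if run_doc.class_kind != "CommandLineTool":
            raise UnsupportedFeature(
                f"{where}: nested workflows as step run-targets are not supported"
            )

        out_raw = entry.get("out") or []
        out_ids: list[str] = []
        for o in out_raw:
            if isinstance(o, str):
                out_ids.append(o)
            elif isinstance(o, dict) and "id" in o:
                out_ids.append(o["id"])
            else:
                raise ParseError(f"{where}: 'out' entries must be ids")
        tool = run_doc.body
        assert isinstance(tool, ToolDocument)
        declared = {p.id for p in tool.outputs}
        missing = [o for o in out_ids if o not in declared]
        if missing:
            raise UnresolvedReference(
                f"{where}: out id(s) {missing} not declared by the referenced tool"
            )

        steps.append(StepSpec(
            id=sid,
            run=run_doc,
            run_ref=run_ref,
            in_bindings=_parse_step_inputs(entry.get("in"), where),
            out_ids=out_ids,
        ))

    return WorkflowDocument(inputs=inputs, outputs=outputs, steps=steps)


# ---------------------------------------------------------------------------
# entry points
# ---------------------------------------------------------------------------

def _load_mapping(data: dict, origin: str, base_dir: Path, depth: int,
                  source_path: Optional[Path] = None) -> CWLDocument:
    version = data.get("cwlVersion", SUPPORTED_VERSION if depth > 0 else None)
    if version is None:
        raise ParseError(f"{origin}: missing cwlVersion")
    if version != SUPPORTED_VERSION:
        raise VersionError(f"{origin}: cwlVersion {version!r} is not supported (need v1.0)")

    kind = data.get("class")
    doc_id = data.get("id") or (source_path.stem if source_path else origin)

    if kind == "CommandLineTool":
        body: Union[ToolDocument, WorkflowDocument] = _parse_tool(data, origin)
    elif kind == "Workflow":
        if depth > 0:
            raise UnsupportedFeature(
                f"{origin}: nested workflows (class: Workflow inside a step) are not supported"
            )
        body = _parse_workflow(data, origin, base_dir, depth)
    else:
        raise UnsupportedFeature(f"{origin}: document class {kind!r} is not supported")

    return CWLDocument(class_kind=kind, cwl_version=version, id=str(doc_id),
                       body=body, source_path=source_path)


def load_document(path: Union[str, Path], _depth: int = 0) -> CWLDocument:
    """Load, resolve and validate one CWL document from ``path``.

    ``run:`` file references inside workflow steps are loaded recursively,
    relative to the referring document's directory.
    """
    path = Path(path).resolve()
    if not path.exists():
        raise UnresolvedReference(f"document {path} does not exist")
    data = _parse_text(path.read_text(), str(path))
    return _load_mapping(data, origin=path.name, base_dir=path.parent,
                         depth=_depth, source_path=path)


def loads_document(text: str, origin: str = "<string>",
                   base_dir: Union[str, Path] = ".") -> CWLDocument:
    """Load a document from a string (run refs resolve against ``base_dir``)."""
    return _load_mapping(_parse_text(text, origin), origin=origin,
                         base_dir=Path(base_dir), depth=0)


# ---------------------------------------------------------------------------
# connectivity validation
# ---------------------------------------------------------------------------

def _resolve_source(ref: str, wf: WorkflowDocument) -> Optional[CwlType]:
    """Resolve 'input_id' or 'step/out_id' to a type; None if dangling."""
    if "/" in ref:
        sid, oid = ref.split("/", 1)
        for s in wf.steps:
            if s.id == sid:
                tool = s.run.body
                assert isinstance(tool, ToolDocument)
                if oid in s.out_ids:
                    try:
                        return tool.output(oid).cwl_type
                    except KeyError:
                        return None
                return None
        return None
    try:
        return wf.input(ref).cwl_type
    except KeyError:
        return None


def validate_connectivity(doc: WorkflowDocument) -> list[Diagnostic]:
    """Check that every step input source and workflow outputSource resolves
    and that connected types are dataflow-compatible.  Returns diagnostics;
    an empty list means the wiring is sound."""
    diags: list[Diagnostic] = []

    for step in doc.steps:
        tool = step.run.body
        assert isinstance(tool, ToolDocument)
        declared_inputs = {p.id for p in tool.inputs}
        for iid, binding in step.in_bindings.items():
            if iid not in declared_inputs:
                diags.append(Diagnostic(
                    "error",
                    f"step {step.id!r} wires unknown tool input {iid!r}",
                    reference=f"{step.id}/{iid}",
                ))
                continue
            src = binding.get("source")
            if src is None:
                continue
            src_type = _resolve_source(src, doc)
            if src_type is None:
                diags.append(Diagnostic(
                    "error",
                    f"step {step.id!r} input {iid!r} references dangling source {src!r}",
                    reference=src,
                ))
                continue
            dst_type = tool.input(iid).cwl_type
            if not types_compatible(src_type, dst_type):
                diags.append(Diagnostic(
                    "error",
                    f"type mismatch on {step.id}/{iid}: source {src!r} is "
                    f"{src_type}, input expects {dst_type}",
                    reference=src,
                ))
        # required tool inputs must be wired or defaulted
        for p in tool.inputs:
            if p.required and p.id not in step.in_bindings:
                diags.append(Diagnostic(
                    "error",
                    f"step {step.id!r} leaves required tool input {p.id!r} unwired",
                    reference=f"{step.id}/{p.id}",
                ))

    for out in doc.outputs:
        src = out.output_source or ""
        src_type = _resolve_source(src, doc)
        if src_type is None:
            diags.append(Diagnostic(
                "error",
                f"workflow output {out.id!r} references dangling source {src!r}",
                reference=src,
            ))
        elif not types_compatible(src_type, out.cwl_type):
            diags.append(Diagnostic(
                "error",
                f"type mismatch on workflow output {out.id!r}: source {src!r} is "
                f"{src_type}, output declares {out.cwl_type}",
                reference=src,
            ))
    return diags


# ---------------------------------------------------------------------------
# canonical serialization (debugging / round-trip)
# ---------------------------------------------------------------------------

def _param_in_to_cwl(p: IOParameter) -> dict:
    d: dict[str, Any] = {"id": p.id, "type": p.cwl_type.to_cwl()}
    if p.has_default:
        d["default"] = p.default_value
    if p.input_binding is not None:
        d["inputBinding"] = p.input_binding.to_cwl()
    if p.doc is not None:
        d["doc"] = p.doc
    return d


def _tool_to_cwl(tool: ToolDocument, doc_id: str) -> dict:
    outs = []
    for p in sorted(tool.outputs, key=lambda q: q.id):
        ob = p.output_binding
        if ob is not None and ob.capture == "stdout":
            o: dict[str, Any] = {"id": p.id, "type": "stdout"}
        else:
            o = {"id": p.id, "type": p.cwl_type.to_cwl(),
                 "outputBinding": {"glob": ob.glob_pattern if ob else ""}}
        if p.doc is not None:
            o["doc"] = p.doc
        outs.append(o)
    d: dict[str, Any] = {
        "cwlVersion": SUPPORTED_VERSION,
        "class": "CommandLineTool",
        "id": doc_id,
        "baseCommand": list(tool.base_command),
        "inputs": [_param_in_to_cwl(p) for p in sorted(tool.inputs, key=lambda q: q.id)],
        "outputs": outs,
    }
    if tool.arguments:
        d["arguments"] = [a.to_cwl() for a in tool.arguments]
    if tool.stdin_ref is not None:
        d["stdin"] = tool.stdin_ref
    if tool.stdout_name is not None:
        d["stdout"] = tool.stdout_name
    if tool.stderr_name is not None:
        d["stderr"] = tool.stderr_name
    if tool.requirements:
        d["requirements"] = [{"class": r.kind, **r.payload} for r in tool.requirements]
    return d


def to_canonical_json(doc: CWLDocument) -> str:
    """Serialize back to canonical CWL JSON.  Reloading the result yields a
    structurally equal document (ids sorted, defaults normalized)."""
    if isinstance(doc.body, ToolDocument):
        data = _tool_to_cwl(doc.body, doc.id)
    else:
        wf = doc.body
        outs = []
        for p in sorted(wf.outputs, key=lambda q: q.id):
            outs.append({"id": p.id, "type": p.cwl_type.to_cwl(),
                         "outputSource": p.output_source})
        steps = []
        for s in wf.steps:
            ins = []
            for iid in sorted(s.in_bindings):
                entry: dict[str, Any] = {"id": iid}
                entry.update(s.in_bindings[iid])
                ins.append(entry)
            steps.append({
                "id": s.id,
                "run": _tool_to_cwl(s.run.body, s.run.id),  # inlined canonically
                "in": ins,
                "out": sorted(s.out_ids),
            })
        data = {
            "cwlVersion": SUPPORTED_VERSION,
            "class": "Workflow",
            "id": doc.id,
            "inputs": [_param_in_to_cwl(p) for p in sorted(wf.inputs, key=lambda q: q.id)],
            "outputs": outs,
            "steps": steps,
        }
    return json.dumps(data, indent=2, sort_keys=True)
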