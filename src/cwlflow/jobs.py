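"""Job-file intake: parsing, validation, and jobs-folder scanning.

A job is one run request, encoded as a JSON or YAML mapping with three
mandatory fields — ``workflow`` (path to the CWL descriptor), ``output_folder``
(where results are delivered) and ``uid`` (the unique run identifier) — plus
workflow-specific input values.  File inputs use the CWL File form
``{class: File, path: ...}``.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from .documents import CwlType, ToolDocument, WorkflowDocument
from .errors import Diagnostic, MissingMandatoryField, ParseError

MANDATORY_FIELDS = ("workflow", "output_folder", "uid")


@dataclass
class JobDescriptor:
    """One run request extracted from a job file."""

    uid: str
    workflow_path: Path
    output_folder: Path
    inputs: dict[str, Any] = field(default_factory=dict)
    submitted_at: float = field(default=0.0, compare=False)
    source_file: Optional[Path] = field(default=None, compare=False)
    warnings: list[Diagnostic] = field(default_factory=list, compare=False)


def _parse_mapping(text: str, origin: str) -> dict:
    try:
        data = json.loads(text)
    except (json.JSONDecodeError, ValueError):
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ParseError(f"{origin}: not valid JSON or YAML: {exc}") from exc
    if not isinstance(data, dict):
        raise ParseError(f"{origin}: job file is not a mapping")
    return data


def parse_job_file(path: str | Path) -> JobDescriptor:
    """Parse one job file.  Mandatory fields are extracted; every remaining
    top-level key becomes a workflow input value.

    Relative ``workflow``/``output_folder`` paths are resolved against the
    job file's directory and flagged with a warning (the canonical form is
    absolute paths).
    """
    path = Path(path).resolve()
    data = _parse_mapping(path.read_text(), str(path))

    for fname in MANDATORY_FIELDS:
        if fname not in data or data[fname] in (None, ""):
            raise MissingMandatoryField(fname)

    warnings: list[Diagnostic] = []

    def _resolve(raw: str, what: str) -> Path:
        p = Path(str(raw))
        if not p.is_absolute():
            warnings.append(Diagnostic(
                "warning",
                f"{what} {raw!r} is relative; resolved against the job file directory",
                reference=str(raw),
            ))
            p = path.parent / p
        return p.resolve() if p.exists() else Path(str(p))

    inputs = {k: v for k, v in data.items() if k not in MANDATORY_FIELDS}
    return JobDescriptor(
        uid=str(data["uid"]),
        workflow_path=_resolve(data["workflow"], "workflow path"),
        output_folder=_resolve(data["output_folder"], "output folder"),
        inputs=inputs,
        submitted_at=time.time(),
        source_file=path,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# validation against the workflow
# ---------------------------------------------------------------------------

def _value_matches(value: Any, ctype: CwlType) -> bool:
    if value is None:
        return ctype.optional
    if ctype.is_array:
        if not isinstance(value, list):
            return False
        return all(_value_matches(v, CwlType(ctype.base)) for v in value)
    if ctype.base == "File":
        return isinstance(value, dict) and value.get("class") == "File" and "path" in value
    if ctype.base == "boolean":
        return isinstance(value, bool)
    if ctype.base in ("int", "long"):
        return isinstance(value, int) and not isinstance(value, bool)
    if ctype.base in ("float", "double"):
        return isinstance(value, (int, float)) and not isinstance(value, bool)
    if ctype.base == "string":
        return isinstance(value, str)
    return False


def validate_job(job: JobDescriptor, doc: WorkflowDocument | ToolDocument) -> list[Diagnostic]:
    """Check a job's inputs against the workflow contract.

    Errors: a required input missing or of the wrong type; a File input
    whose path does not exist.  Extra keys matching no workflow input are
    warnings only, keeping jobs forward-compatible with workflow edits.
    """
    diags: list[Diagnostic] = list(job.warnings)
    declared = {p.id: p for p in doc.inputs}

    for pid, param in declared.items():
        if pid not in job.inputs:
            if param.required:
                diags.append(Diagnostic(
                    "error", f"required workflow input {pid!r} is missing from the job",
                    reference=pid,
                ))
            continue
        value = job.inputs[pid]
        if not _value_matches(value, param.cwl_type):
            diags.append(Diagnostic(
                "error",
                f"job input {pid!r} has incompatible value {value!r} "
                f"for declared type {param.cwl_type}",
                reference=pid,
            ))
            continue
        for fv in _file_values(value):
            p = Path(fv["path"])
            if not p.is_absolute() and job.source_file is not None:
                p = job.source_file.parent / p
            if not p.exists():
                diags.append(Diagnostic(
                    "error", f"File input {pid!r}: path {fv['path']!r} does not exist",
                    reference=pid,
                ))

    for key in job.inputs:
        if key not in declared:
            diags.append(Diagnostic(
                "warning", f"job key {key!r} matches no workflow input (ignored)",
                reference=key,
            ))
    return diags


def _file_values(value: Any) -> list[dict]:
    if isinstance(value, dict) and value.get("class") == "File":
        return [value]
    if isinstance(value, list):
        out = []
        for v in value:
            out.extend(_file_values(v))
        return out
    return []


# ---------------------------------------------------------------------------
# jobs-folder scanning
# ---------------------------------------------------------------------------

JOB_SUFFIXES = {".json", ".yml", ".yaml", ".job"}


def content_hash(path: Path) -> str:
    return hashlib.sha1(path.read_bytes()).hexdigest()


def scan_jobs_folder(folder: str | Path, store) -> list[JobDescriptor]:
    """Return descriptors for job files not yet registered in ``store``.

    Previously seen uids are skipped silently.  Malformed files are recorded
    in the store as rejected runs, keyed by content hash so each bad content
    is reported exactly once; editing the file makes it eligible again.
    Job files are never mutated or removed.
    """
    folder = Path(folder)
    fresh: list[JobDescriptor] = []
    for path in sorted(folder.iterdir()):
        if not path.is_file() or path.suffix.lower() not in JOB_SUFFIXES:
            continue
        chash = content_hash(path)
        if store.is_rejected(chash):
            continue
        try:
            job = parse_job_file(path)
        except Exception as exc:  # noqa: BLE001 - every failure becomes a record
            store.record_rejection(str(path), chash, [
                Diagnostic("error", str(exc)),
            ])
            continue
        if store.has_uid(job.uid):
            continue
        fresh.append(job)
    return fresh
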