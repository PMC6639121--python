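"""Single-step execution: parameter references, command-line binding,
input staging, process launch and typed output collection.

The binding algorithm follows the CWL v1.0 rules for the supported subset:
``argv`` is ``baseCommand`` followed by bound tokens sorted by
``(position, tie-break key)`` where the tie-break key is the input
parameter's id (lexicographic) or, for ``arguments``, the argument's
zero-padded index.  Prefix handling honours ``separate``; arrays with
``itemSeparator`` collapse to one joined token; booleans contribute their
prefix only when true; null or absent optional inputs contribute nothing.
"""

from __future__ import annotations

import hashlib
import os
import re
import shutil
import subprocess
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional

from .documents import CommandBindingSpec, CwlType, IOParameter, ToolDocument
from .errors import (
    AmbiguousOutput,
    MissingOutput,
    MissingRequiredInput,
    SpawnError,
    StagingError,
    TypeMismatch,
    UnknownReference,
    UnsupportedExpression,
)
from .jobs import _value_matches


# ---------------------------------------------------------------------------
# artifacts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FileArtifact:
    """A produced or consumed file with provenance and integrity metadata."""

    path: str
    basename: str
    size_bytes: int
    checksum: str                       # "sha1$<hex>"
    produced_by: tuple[str, str, str] = ("", "", "")   # (run_uid, task_id, output_id)

    def as_cwl(self) -> dict:
        return {"class": "File", "path": self.path, "basename": self.basename,
                "size": self.size_bytes, "checksum": self.checksum}


def sha1_of(path: str | Path) -> str:
    h = hashlib.sha1()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return "sha1$" + h.hexdigest()


def make_artifact(path: str | Path, produced_by: tuple[str, str, str] = ("", "", "")) -> FileArtifact:
    p = Path(path)
    return FileArtifact(
        path=str(p),
        basename=p.name,
        size_bytes=p.stat().st_size,
        checksum=sha1_of(p),
        produced_by=produced_by,
    )


# ---------------------------------------------------------------------------
# parameter references
# ---------------------------------------------------------------------------

_REF_RE = re.compile(
    r"\$\((inputs\.[A-Za-z_][A-Za-z0-9_]*(?:\.(?:path|basename))?"
    r"|runtime\.(?:outdir|cores)"
    r"|self(?:\.(?:path|basename))?)\)"
)


def _lookup_ref(body: str, context: Mapping[str, Any]) -> Any:
    parts = body.split(".")
    ns = parts[0]
    if ns == "inputs":
        inputs = context.get("inputs", {})
        if parts[1] not in inputs:
            raise UnknownReference(f"unknown input reference $({body})")
        value = inputs[parts[1]]
        attr = parts[2] if len(parts) > 2 else None
    elif ns == "runtime":
        runtime = context.get("runtime", {})
        if parts[1] not in runtime:
            raise UnknownReference(f"unknown runtime reference $({body})")
        return runtime[parts[1]]
    elif ns == "self":
        if "self" not in context:
            raise UnknownReference("$(self) used outside a valueFrom context")
        value = context["self"]
        attr = parts[1] if len(parts) > 1 else None
    else:  # pragma: no cover - regex prevents this
        raise UnknownReference(f"unknown namespace in $({body})")

    if attr is None:
        return value
    fdict = value.as_cwl() if isinstance(value, FileArtifact) else value
    if not isinstance(fdict, dict) or fdict.get("class") != "File":
        raise UnknownReference(f"$({body}): .{attr} only applies to File values")
    if attr == "path":
        return fdict["path"]
    return fdict.get("basename") or Path(fdict["path"]).name


def eval_param_ref(expr: Any, context: Mapping[str, Any]) -> Any:
    """Evaluate restricted ``$(...)`` parameter references in ``expr``.

    A lone reference returns the referenced value with its native type;
    references embedded in longer text are string-interpolated; text with
    no references passes through unchanged.  Anything starting ``${`` is a
    JavaScript expression and is rejected.
    """
    if not isinstance(expr, str):
        return expr
    if "${" in expr:
        raise UnsupportedExpression(
            f"JavaScript expressions are not supported: {expr!r}"
        )
    m = _REF_RE.fullmatch(expr)
    if m:
        return _lookup_ref(m.group(1), context)

    def repl(match: re.Match) -> str:
        return _stringify(_lookup_ref(match.group(1), context))

    return _REF_RE.sub(repl, expr)


def _stringify(value: Any) -> str:
    if isinstance(value, FileArtifact):
        return value.path
    if isinstance(value, dict) and value.get("class") == "File":
        return str(value["path"])
    if isinstance(value, bool):
        return "true" if value else "false"
    return str(value)


# ---------------------------------------------------------------------------
# command-line binding
# ---------------------------------------------------------------------------

@dataclass
class CommandPlan:
    argv: list[str]
    workdir: Path
    stdin_path: Optional[Path] = None
    stdout_path: Optional[Path] = None
    stderr_path: Optional[Path] = None
    env: dict[str, str] = field(default_factory=dict)
    container_argv: Optional[list[str]] = None


def _value_tokens(value: Any, binding: CommandBindingSpec) -> list[str]:
    """Tokens contributed by one bound value (CWL v1.0 rules, subset)."""
    prefix = binding.prefix
    if value is None:
        return []
    if isinstance(value, bool):
        if value:
            return [prefix] if prefix else []
        return []
    if isinstance(value, list):
        if not value:
            return []
        items = [_stringify(v) for v in value]
        if binding.item_separator is not None:
            joined = binding.item_separator.join(items)
            return _with_prefix(joined, prefix, binding.separate)
        if prefix is None:
            return items
        if binding.separate:
            return [prefix, *items]
        return [prefix + items[0], *items[1:]]
    return _with_prefix(_stringify(value), prefix, binding.separate)


def _with_prefix(token: str, prefix: Optional[str], separate: bool) -> list[str]:
    if prefix is None:
        return [token]
    return [prefix, token] if separate else [prefix + token]


def bind_command_line(
    tool: ToolDocument,
    values: Mapping[str, Any],
    workdir: str | Path,
    task_id: str = "step",
    runtime: Optional[dict] = None,
) -> CommandPlan:
    """Construct the full command plan for one tool invocation.

    ``values`` maps input ids to concrete (already staged) values; tool
    defaults fill the gaps.  Raises :class:`MissingRequiredInput` or
    :class:`TypeMismatch` before any process is started.
    """
    workdir = Path(workdir)
    runtime = {"outdir": str(workdir), "cores": os.cpu_count() or 1, **(runtime or {})}

    effective: dict[str, Any] = {}
    for param in tool.inputs:
        if param.id in values and values[param.id] is not None:
            value = values[param.id]
        elif param.has_default:
            value = param.default_value
        elif param.cwl_type.optional:
            value = None
        else:
            raise MissingRequiredInput(f"input {param.id!r} has no value and no default")
        if value is not None and not _value_matches(value, param.cwl_type):
            raise TypeMismatch(
                f"input {param.id!r}: value {value!r} does not match type {param.cwl_type}"
            )
        effective[param.id] = value

    context = {"inputs": effective, "runtime": runtime}

    bound: list[tuple[tuple[int, str], list[str]]] = []
    for i, arg in enumerate(tool.arguments):
        value = eval_param_ref(arg.value_from, context) if arg.value_from is not None else None
        tokens = _value_tokens(value, arg) if arg.value_from is not None else []
        bound.append(((arg.position, f"{i:06d}"), tokens))
    for param in tool.inputs:
        binding = param.input_binding
        if binding is None:
            continue
        value = effective[param.id]
        if binding.value_from is not None and value is not None:
            value = eval_param_ref(binding.value_from, {**context, "self": value})
        if isinstance(value, (dict, FileArtifact)):
            value = _stringify(value)
        bound.append(((binding.position, param.id), _value_tokens(value, binding)))

    argv = list(tool.base_command)
    for _, tokens in sorted(bound, key=lambda kv: kv[0]):
        argv.extend(tokens)
    if not argv:
        raise MissingRequiredInput("binding produced an empty command line")

    stdin_path = None
    if tool.stdin_ref is not None:
        stdin_path = Path(_stringify(eval_param_ref(tool.stdin_ref, context)))

    stdout_path = None
    wants_stdout = any(
        p.output_binding is not None and p.output_binding.capture == "stdout"
        for p in tool.outputs
    )
    if tool.stdout_name is not None or wants_stdout:
        name = tool.stdout_name if tool.stdout_name is not None else f"{task_id}.stdout"
        stdout_path = workdir / _stringify(eval_param_ref(name, context))

    stderr_path = None
    if tool.stderr_name is not None:
        stderr_path = workdir / _stringify(eval_param_ref(tool.stderr_name, context))

    env: dict[str, str] = {}
    env_req = tool.requirement("EnvVarRequirement")
    if env_req is not None:
        env_def = env_req.payload.get("envDef", {})
        pairs = env_def.items() if isinstance(env_def, dict) else (
            (e["envName"], e["envValue"]) for e in env_def)
        for name, raw in pairs:
            env[name] = _stringify(eval_param_ref(raw, context))

    plan = CommandPlan(argv=argv, workdir=workdir, stdin_path=stdin_path,
                       stdout_path=stdout_path, stderr_path=stderr_path, env=env)

    docker = tool.requirement("DockerRequirement")
    if docker is not None:
        plan.container_argv = build_container_argv(plan, docker.payload, "docker")
    return plan


# ---------------------------------------------------------------------------
# staging
# ---------------------------------------------------------------------------

def stage_step(job_values: Mapping[str, Any], workdir: str | Path) -> dict[str, Any]:
    """Make input files readable from the step's working directory.

    Files are symlinked by basename into an ``inputs/`` subdirectory of
    ``workdir`` (copy fallback when linking fails); name collisions get a
    numeric suffix.  Keeping staged inputs out of the workdir root means a
    process writing a file named like one of its inputs cannot clobber the
    upstream artifact through the link, and output globs never match
    staged inputs.  The returned mapping has File paths rewritten to the
    staged locations; scalars pass through untouched.
    """
    workdir = Path(workdir) / "inputs"
    workdir.mkdir(parents=True, exist_ok=True)
    staged_names: set[str] = set()

    def stage_value(value: Any) -> Any:
        if isinstance(value, FileArtifact):
            return stage_value(value.as_cwl())
        if isinstance(value, dict) and value.get("class") == "File":
            src = Path(value["path"])
            if not src.exists():
                raise StagingError(f"input file {src} vanished before staging")
            name = src.name
            stem, dot, ext = name.partition(".")
            n = 1
            while name in staged_names:
                name = f"{stem}_{n}{dot}{ext}" if dot else f"{stem}_{n}"
                n += 1
            staged_names.add(name)
            dest = workdir / name
            try:
                if dest.exists() or dest.is_symlink():
                    dest.unlink()
                dest.symlink_to(src.resolve())
            except OSError:
                try:
                    shutil.copy2(src, dest)
                except OSError as exc:
                    raise StagingError(f"cannot stage {src} -> {dest}: {exc}") from exc
            return {**value, "path": str(dest), "basename": name}
        if isinstance(value, list):
            return [stage_value(v) for v in value]
        return value

    return {k: stage_value(v) for k, v in job_values.items()}


# ---------------------------------------------------------------------------
# process execution
# ---------------------------------------------------------------------------

def run_process(plan: CommandPlan, log_path: str | Path | None = None) -> int:
    """Run the planned process; return its exit code.

    stdout/stderr go to the plan's paths when set, otherwise to
    ``log_path``.  A missing executable raises :class:`SpawnError` —
    distinct from a nonzero exit, which is returned, not raised.
    """
    out_target = plan.stdout_path or log_path
    err_target = plan.stderr_path or log_path
    stdin_fh = open(plan.stdin_path, "rb") if plan.stdin_path else subprocess.DEVNULL
    opened: list[Any] = []
    try:
        if out_target is not None:
            out_fh = open(out_target, "ab")
            opened.append(out_fh)
        else:
            out_fh = subprocess.DEVNULL
        if err_target is not None and err_target == out_target:
            err_fh = out_fh
        elif err_target is not None:
            err_fh = open(err_target, "ab")
            opened.append(err_fh)
        else:
            err_fh = subprocess.DEVNULL
        try:
            proc = subprocess.run(
                plan.argv,
                cwd=plan.workdir,
                env={**os.environ, **plan.env},
                stdin=stdin_fh,
                stdout=out_fh,
                stderr=err_fh,
                check=False,
            )
        except FileNotFoundError as exc:
            raise SpawnError(f"executable not found: {plan.argv[0]!r}") from exc
        return proc.returncode
    finally:
        for fh in opened:
            fh.close()
        if stdin_fh is not subprocess.DEVNULL:
            stdin_fh.close()


def build_container_argv(plan: CommandPlan, payload: Mapping[str, Any],
                         engine: str) -> list[str]:
    """Construct (never execute) the container-wrapped invocation."""
    image = payload.get("dockerPull") or payload.get("dockerImageId")
    if not image:
        raise ValueError("DockerRequirement payload lacks an image identifier")
    wd = str(plan.workdir)
    if engine == "docker":
        return ["docker", "run", "--rm", "-v", f"{wd}:{wd}", "-w", wd,
                str(image), *plan.argv]
    if engine == "singularity":
        return ["singularity", "exec", "--bind", f"{wd}:{wd}", "--pwd", wd,
                str(image), *plan.argv]
    raise ValueError(f"unknown container engine {engine!r}")


# ---------------------------------------------------------------------------
# output collection
# ---------------------------------------------------------------------------

def collect_outputs(
    tool: ToolDocument,
    workdir: str | Path,
    plan: CommandPlan,
    inputs: Optional[Mapping[str, Any]] = None,
    produced_by: tuple[str, str] = ("", ""),
) -> dict[str, Any]:
    """Collect declared outputs after a successful (exit 0) run.

    stdout-captured outputs resolve to the plan's stdout file; glob patterns
    (after parameter-reference evaluation) match relative to ``workdir``
    with lexicographic basename order.  A non-optional File output with no
    match raises :class:`MissingOutput`; multiple matches on a single-File
    output raise :class:`AmbiguousOutput`.
    """
    workdir = Path(workdir)
    context = {"inputs": dict(inputs or {}), "runtime": {"outdir": str(workdir)}}
    run_uid, task_id = produced_by
    results: dict[str, Any] = {}

    for param in tool.outputs:
        ob = param.output_binding
        if ob is None:  # pragma: no cover - parser guarantees a binding
            continue
        tag = (run_uid, task_id, param.id)
        if ob.capture == "stdout":
            if plan.stdout_path is None or not Path(plan.stdout_path).exists():
                raise MissingOutput(f"output {param.id!r}: no stdout was captured")
            results[param.id] = make_artifact(plan.stdout_path, tag)
            continue
        pattern = _stringify(eval_param_ref(ob.glob_pattern, context))
        if Path(pattern).is_absolute():
            raise MissingOutput(
                f"output {param.id!r}: glob {pattern!r} must be workdir-relative"
            )
        matches = sorted((p for p in workdir.glob(pattern) if p.is_file()),
                         key=lambda p: p.name)
        if param.cwl_type.is_array:
            results[param.id] = [make_artifact(m, tag) for m in matches]
        elif len(matches) == 1:
            results[param.id] = make_artifact(matches[0], tag)
        elif not matches:
            if param.cwl_type.optional:
                results[param.id] = None
            else:
                raise MissingOutput(
                    f"output {param.id!r}: glob {pattern!r} matched nothing in {workdir}"
                )
        else:
            raise AmbiguousOutput(
                f"output {param.id!r}: glob {pattern!r} matched "
                f"{len(matches)} files but the type is a single File"
            )
    return results


@dataclass
class StepResult:
    task_id: str
    exit_code: int
    outputs: dict[str, Any] = field(default_factory=dict)
    started_at: float = 0.0
    ended_at: float = 0.0
    log_path: Optional[str] = None


def execute_step(
    tool: ToolDocument,
    values: Mapping[str, Any],
    workdir: str | Path,
    task_id: str,
    run_uid: str = "",
    log_path: str | Path | None = None,
) -> StepResult:
    """Stage, bind, run and collect one step end to end."""
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    staged = stage_step(values, workdir)
    plan = bind_command_line(tool, staged, workdir, task_id=task_id)
    started = time.time()
    code = run_process(plan, log_path=log_path)
    ended = time.time()
    outputs: dict[str, Any] = {}
    if code == 0:
        outputs = collect_outputs(tool, workdir, plan, inputs=staged,
                                  produced_by=(run_uid, task_id))
    return StepResult(task_id=task_id, exit_code=code, outputs=outputs,
                      started_at=started, ended_at=ended,
                      log_path=str(log_path) if log_path else None)
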