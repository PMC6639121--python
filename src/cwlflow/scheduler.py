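"""The execution engine: dependency-gated dispatch of DAG tasks to a worker
pool, with persisted state enabling pause/resume, step restart and crash
recovery.

Every run starts with the synthetic ``JobDispatcher`` task (validates the
job and persists the resolved input mapping so no later task reads the job
file) and ends with ``JobCleanup`` (atomically delivers the workflow's
declared outputs to the job's output folder and writes a manifest).  Step
work itself runs as OS subprocesses; up to ``worker_count`` of them run
concurrently, fed from the ready set in deterministic (queue, task id)
order.  All state lives in the :class:`~cwlflow.store.RunStore`; the engine
can be killed and re-invoked at any point and will continue from the store.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
import time
from concurrent.futures import FIRST_COMPLETED, ThreadPoolExecutor, wait
from pathlib import Path
from typing import Any, Callable, Optional

from . import dag as dag_mod
from .config import EngineConfig
from .dag import CLEANUP_ID, DISPATCHER_ID, DagGraph, build_dag
from .documents import CWLDocument, WorkflowDocument, load_document, to_canonical_json, validate_connectivity
from .errors import (
    DeliveryError,
    Diagnostic,
    DigestMismatch,
    UnknownTask,
    ValidationError,
    errors_only,
)
from .jobs import JobDescriptor, validate_job
from .runner import FileArtifact, execute_step, make_artifact
from .store import (
    FAILED,
    PAUSED_HOLD,
    PENDING,
    QUEUED,
    R_FAILED,
    R_PAUSED,
    R_REGISTERED,
    R_RUNNING,
    R_SUCCESS,
    RUNNING,
    SUCCESS,
    TERMINAL_TASK,
    UPSTREAM_FAILED,
    RunState,
    RunStore,
)

log = logging.getLogger("cwlflow")


def run_digest(doc: CWLDocument, dag: DagGraph) -> str:
    """Content hash binding a run to its workflow file and graph shape;
    a changed workflow file invalidates resume.  Step tool files are not
    hashed: repairing a failed tool and restarting its step is the point
    of step restart."""
    h = hashlib.sha1()
    if doc.source_path is not None and doc.source_path.exists():
        h.update(doc.source_path.read_bytes())
    else:  # inline / string-loaded documents fall back to canonical form
        h.update(to_canonical_json(doc).encode())
    h.update(dag.digest().encode())
    return h.hexdigest()


def ready_tasks(run: RunState, dag: DagGraph) -> set[str]:
    """Exactly the pending tasks all of whose DAG parents are success."""
    ready = set()
    for tid, tstate in run.tasks.items():
        if tstate.status != PENDING:
            continue
        if all(run.tasks[p].status == SUCCESS for p in dag.parents(tid)):
            ready.add(tid)
    return ready


class Engine:
    """One engine instance over a config and its run-state store."""

    def __init__(self, config: EngineConfig):
        self.config = config
        config.ensure_folders()
        self.store = RunStore(config.store_path)

    def close(self) -> None:
        self.store.close()

    # ------------------------------------------------------------------
    # registration
    # ------------------------------------------------------------------

    def register_job(self, job: JobDescriptor) -> DagGraph:
        """Validate a job end-to-end and persist the new run (status
        ``registered``).  Raises :class:`ValidationError` on bad wiring or
        inputs and :class:`DuplicateUid` on a uid collision."""
        doc = load_document(job.workflow_path)
        wf = self._as_workflow(doc)
        diags = errors_only(validate_connectivity(wf)) + errors_only(
            validate_job(job, wf))
        if diags:
            raise ValidationError("; ".join(d.message for d in diags))
        dag = build_dag(wf, job)
        self.store.register_run(
            uid=job.uid,
            workflow_path=str(job.workflow_path),
            output_folder=str(job.output_folder),
            job={"uid": job.uid, "workflow": str(job.workflow_path),
                 "output_folder": str(job.output_folder), "inputs": job.inputs},
            dag_json=dag_mod.to_json(dag),
            dag_digest=run_digest(doc, dag),
            task_ids={t.task_id: t.kind for t in dag.nodes.values()},
        )
        log.info("run %s registered (%d tasks)", job.uid, len(dag.nodes))
        return dag

    @staticmethod
    def _as_workflow(doc: CWLDocument) -> WorkflowDocument:
        if isinstance(doc.body, WorkflowDocument):
            return doc.body
        # single-tool runs are wrapped as a one-step workflow elsewhere;
        # here a tool document is a usage error
        raise ValidationError("job workflow must be a CWL Workflow document")

    def _load_run(self, uid: str) -> tuple[RunState, CWLDocument, WorkflowDocument, DagGraph]:
        run = self.store.get_run(uid)
        doc = load_document(run.workflow_path)
        wf = self._as_workflow(doc)
        job = JobDescriptor(uid=uid, workflow_path=Path(run.workflow_path),
                            output_folder=Path(run.output_folder),
                            inputs=run.job.get("inputs", {}))
        dag = build_dag(wf, job)
        if run_digest(doc, dag) != run.dag_digest:
            raise DigestMismatch(
                f"workflow file for run {uid!r} changed since registration")
        return run, doc, wf, dag

    # ------------------------------------------------------------------
    # task bodies
    # ------------------------------------------------------------------

    def dispatch_job(self, uid: str, wf: WorkflowDocument) -> dict:
        """JobDispatcher body: validate inputs once more, resolve every File
        path to absolute form, apply workflow-input defaults, and persist
        the mapping — later tasks read only the store, never the job file.
        Idempotent: an already-dispatched run is returned unchanged."""
        existing = self.store.get_dispatch(uid)
        if existing is not None:
            return existing
        run = self.store.get_run(uid)
        job = JobDescriptor(uid=uid, workflow_path=Path(run.workflow_path),
                            output_folder=Path(run.output_folder),
                            inputs=run.job.get("inputs", {}))
        diags = errors_only(validate_job(job, wf))
        if diags:
            raise ValidationError("; ".join(d.message for d in diags))

        def absolutize(value: Any) -> Any:
            if isinstance(value, dict) and value.get("class") == "File":
                p = Path(value["path"]).resolve()
                return {**value, "path": str(p), "basename": p.name}
            if isinstance(value, list):
                return [absolutize(v) for v in value]
            return value

        mapping = {}
        for param in wf.inputs:
            if param.id in job.inputs:
                mapping[param.id] = absolutize(job.inputs[param.id])
            elif param.has_default:
                mapping[param.id] = absolutize(param.default_value)
        self.store.set_dispatch(uid, mapping)
        return mapping

    def _step_values(self, uid: str, step, run: RunState) -> dict[str, Any]:
        """Resolve a step's input values from the dispatched mapping and
        upstream task outputs."""
        dispatch = self.store.get_dispatch(uid) or {}
        values: dict[str, Any] = {}
        for iid, binding in step.in_bindings.items():
            if "source" in binding:
                src = binding["source"]
                if "/" in src:
                    sid, oid = src.split("/", 1)
                    outs = run.tasks[sid].outputs or {}
                    values[iid] = outs.get(oid)
                else:
                    values[iid] = dispatch.get(src)
                if values[iid] is None and "default" in binding:
                    values[iid] = binding["default"]
            elif "default" in binding:
                values[iid] = binding["default"]
        return values

    def _task_workdir(self, uid: str, task_id: str) -> Path:
        return self.config.temp_folder / uid / task_id

    def _run_step_task(self, uid: str, task_id: str, run: RunState,
                       dag: DagGraph) -> tuple[int, dict]:
        step = dag.nodes[task_id].step_ref
        assert step is not None
        workdir = self._task_workdir(uid, task_id)
        if workdir.exists():
            shutil.rmtree(workdir)       # fresh directory per attempt
        workdir.mkdir(parents=True)
        values = self._step_values(uid, step, run)
        log_path = workdir / f"{task_id}.log"
        result = execute_step(step.run.body, values, workdir, task_id=task_id,
                              run_uid=uid, log_path=log_path)
        outputs = {
            oid: _serialize_output(val)
            for oid, val in result.outputs.items()
            if oid in step.out_ids
        }
        return result.exit_code, outputs

    def cleanup_job(self, uid: str, wf: WorkflowDocument,
                    run: RunState) -> dict:
        """JobCleanup body: move the workflow-declared outputs (and only
        those) atomically into the job's output folder, write a manifest
        next to them, and drop the run's temp tree unless ``keep_temp``."""
        out_folder = Path(run.output_folder)
        try:
            out_folder.mkdir(parents=True, exist_ok=True)
        except OSError as exc:
            raise DeliveryError(f"cannot create output folder {out_folder}: {exc}")

        dispatch = self.store.get_dispatch(uid) or {}
        manifest: dict[str, Any] = {"run_uid": uid, "outputs": {}}
        wf_by_step: dict[str, list[tuple[str, Any]]] = {}
        for out in wf.outputs:
            src = out.output_source or ""
            if "/" in src:
                sid, oid = src.split("/", 1)
                value = (run.tasks[sid].outputs or {}).get(oid)
            else:
                value = dispatch.get(src)
            wf_by_step.setdefault(out.id, []).append((src, value))

        delivered: dict[str, list[dict]] = {}
        try:
            for out_id, pairs in wf_by_step.items():
                entries = []
                for _, value in pairs:
                    for fdict in _iter_files(value):
                        src_path = Path(fdict["path"])
                        dest = out_folder / src_path.name
                        tmp = out_folder / f".{src_path.name}.partial"
                        shutil.copy2(src_path, tmp)
                        tmp.replace(dest)
                        art = make_artifact(dest, (uid, CLEANUP_ID, out_id))
                        entries.append({"basename": art.basename,
                                        "size": art.size_bytes,
                                        "checksum": art.checksum,
                                        "path": art.path})
                delivered[out_id] = entries
        except OSError as exc:
            raise DeliveryError(f"delivery into {out_folder} failed: {exc}")

        manifest["outputs"] = delivered
        tmp_manifest = out_folder / ".manifest.json.partial"
        tmp_manifest.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        tmp_manifest.replace(out_folder / "manifest.json")

        if not self.config.keep_temp:
            run_temp = self.config.temp_folder / uid
            if run_temp.exists():
                shutil.rmtree(run_temp, ignore_errors=True)
        return manifest

    # ------------------------------------------------------------------
    # the scheduling loop
    # ------------------------------------------------------------------

    def execute_run(
        self,
        uid: str,
        worker_count: Optional[int] = None,
        on_task_complete: Optional[Callable[[str, str], None]] = None,
        stop_after_n_tasks: Optional[int] = None,
    ) -> RunState:
        """Drive the run to a terminal (or paused) state.

        ``on_task_complete(task_id, status)`` fires after each task settles
        (used by the CLI for progress and by fault-injection tests).
        ``stop_after_n_tasks`` aborts the loop after that many completions
        with state exactly as persisted — a controlled stand-in for killing
        the engine process mid-run; a later call continues from the store.
        """
        workers = worker_count or self.config.worker_count
        run, doc, wf, dag = self._load_run(uid)
        self.store.recover_stale(uid)
        if run.status in (R_REGISTERED, R_PAUSED):
            self.store.set_run_status(uid, R_RUNNING)

        completed = 0
        inflight: dict[Any, str] = {}

        def queue_key(tid: str) -> tuple[str, str]:
            q = self.config.task_queue_assignment.get(tid, "default")
            return (q, tid)

        with ThreadPoolExecutor(max_workers=workers) as pool:
            while True:
                run = self.store.get_run(uid)
                paused = run.status == R_PAUSED
                if not paused:
                    ready = sorted(ready_tasks(run, dag) - set(inflight.values()),
                                   key=queue_key)
                    for tid in ready[: max(0, workers - len(inflight))]:
                        self.store.transition_task(uid, tid, QUEUED)
                        log.info("%s/%s pending -> queued", uid, tid)
                        fut = pool.submit(self._worker, uid, tid, wf, dag)
                        inflight[fut] = tid
                if not inflight:
                    break
                done, _ = wait(inflight, return_when=FIRST_COMPLETED)
                for fut in done:
                    tid = inflight.pop(fut)
                    status = fut.result()
                    completed += 1
                    self._after_task(uid, tid, status, dag)
                    if on_task_complete is not None:
                        on_task_complete(tid, status)
                if stop_after_n_tasks is not None and completed >= stop_after_n_tasks:
                    # drain current in-flight work, then stop mid-run
                    for fut, tid in list(inflight.items()):
                        status = fut.result()
                        self._after_task(uid, tid, status, dag)
                    inflight.clear()
                    return self.store.get_run(uid)

        return self._finalize(uid)

    def _worker(self, uid: str, task_id: str, wf: WorkflowDocument,
                dag: DagGraph) -> str:
        """Run one task body in a pool worker; returns the final status."""
        self.store.transition_task(uid, task_id, RUNNING)
        log.info("%s/%s queued -> running", uid, task_id)
        kind = dag.nodes[task_id].kind
        try:
            if kind == "dispatcher":
                self.dispatch_job(uid, wf)
                exit_code, outputs = 0, {}
            elif kind == "cleanup":
                run = self.store.get_run(uid)
                manifest = self.cleanup_job(uid, wf, run)
                exit_code, outputs = 0, {"manifest": manifest}
            else:
                run = self.store.get_run(uid)
                exit_code, outputs = self._run_step_task(uid, task_id, run, dag)
        except Exception as exc:  # noqa: BLE001 - any failure is a task failure
            log.error("%s/%s failed: %s", uid, task_id, exc)
            self.store.transition_task(uid, task_id, FAILED, exit_code=None)
            return FAILED
        status = SUCCESS if exit_code == 0 else FAILED
        self.store.transition_task(uid, task_id, status, exit_code=exit_code,
                                   outputs=outputs)
        log.info("%s/%s running -> %s", uid, task_id, status)
        return status

    def _after_task(self, uid: str, task_id: str, status: str,
                    dag: DagGraph) -> None:
        if status != FAILED:
            return
        run = self.store.get_run(uid)
        attempts = run.tasks[task_id].attempt
        if attempts <= self.config.retry_limit:
            # back to pending: the ready loop re-queues it on the next tick
            self.store.transition_task(uid, task_id, PENDING)
            log.info("%s/%s retrying (attempt %d)", uid, task_id, attempts + 1)
            return
        for desc in sorted(dag.descendants(task_id)):
            if run.tasks[desc].status == PENDING:
                self.store.transition_task(uid, desc, UPSTREAM_FAILED)
                log.info("%s/%s pending -> upstream_failed", uid, desc)

    def _finalize(self, uid: str) -> RunState:
        run = self.store.get_run(uid)
        if run.status == R_PAUSED:
            return run
        statuses = {t.status for t in run.tasks.values()}
        if statuses == {SUCCESS}:
            self.store.set_run_status(uid, R_SUCCESS)
        elif statuses & {FAILED, UPSTREAM_FAILED} and statuses <= TERMINAL_TASK:
            self.store.set_run_status(uid, R_FAILED)
        return self.store.get_run(uid)

    # ------------------------------------------------------------------
    # lifecycle controls
    # ------------------------------------------------------------------

    def pause_run(self, uid: str) -> RunState:
        """Hold all pending tasks; running tasks finish.  The executing
        loop observes the paused status and stops queueing."""
        run = self.store.get_run(uid)
        if run.status != R_RUNNING:
            return run
        self.store.set_run_status(uid, R_PAUSED)
        for tid, t in sorted(run.tasks.items()):
            if t.status == PENDING:
                self.store.transition_task(uid, tid, PAUSED_HOLD)
        return self.store.get_run(uid)

    def resume_run(self, uid: str) -> RunState:
        """Release holds after a pause; completed work is never redone.
        A no-op on runs that are not paused.  Raises
        :class:`DigestMismatch` when the workflow file changed."""
        run = self.store.get_run(uid)
        if run.status != R_PAUSED:
            return run
        self._load_run(uid)            # digest check
        for tid, t in sorted(run.tasks.items()):
            if t.status == PAUSED_HOLD:
                self.store.transition_task(uid, tid, PENDING)
        self.store.set_run_status(uid, R_RUNNING)
        return self.store.get_run(uid)

    def restart_step(self, uid: str, task_id: str, cascade: bool = False) -> RunState:
        """Reset one task to pending (``cascade`` also resets its transitive
        descendants); upstream successes and their persisted outputs are
        reused verbatim.  Tasks that never ran (upstream_failed) are always
        released back to pending so the run can complete."""
        run = self.store.get_run(uid)
        if task_id not in run.tasks:
            raise UnknownTask(f"no task {task_id!r} in run {uid!r}")
        _, _, _, dag = self._load_run(uid)
        targets = {task_id}
        for desc in dag.descendants(task_id):
            st = run.tasks[desc].status
            if st == UPSTREAM_FAILED or (cascade and st in TERMINAL_TASK):
                targets.add(desc)
        for tid in sorted(targets):
            if run.tasks[tid].status != PENDING:
                self.store.transition_task(uid, tid, PENDING)
                log.info("%s/%s reset to pending (restart)", uid, tid)
        self.store.set_run_status(uid, R_RUNNING)
        return self.store.get_run(uid)

    def run_history(self) -> list[dict]:
        return self.store.run_history()


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _serialize_output(value: Any) -> Any:
    if isinstance(value, FileArtifact):
        return value.as_cwl()
    if isinstance(value, list):
        return [_serialize_output(v) for v in value]
    return value


def _iter_files(value: Any):
    if isinstance(value, dict) and value.get("class") == "File":
        yield value
    elif isinstance(value, list):
        for v in value:
            yield from _iter_files(v)
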