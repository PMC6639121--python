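"""Scheduler semantics: gating, parallel equivalence, failure propagation,
pause/resume, step restart, crash recovery and delivery."""

import json
from pathlib import Path

import pytest

from cwlflow import build_dag, load_document, ready_tasks
from cwlflow.dag import CLEANUP_ID, DISPATCHER_ID
from cwlflow.errors import DigestMismatch, UnknownTask, ValidationError
from cwlflow.fixtures import (
    make_chipseq_like,
    make_failing_variant,
    make_topology_suite,
)
from cwlflow.runner import sha1_of
from cwlflow.store import (
    R_FAILED,
    R_SUCCESS,
    SUCCESS,
    UPSTREAM_FAILED,
)

from conftest import (
    brute_force_descendants,
    linear_extensions,
    load_fixture_job,
    run_fixture,
    task_start_order,
    workflow_of,
)


@pytest.fixture
def topo(tmp_path):
    return {m.name: m for m in make_topology_suite(tmp_path / "fx")}


def _delivered_checksums(folder: Path) -> dict[str, str]:
    return {p.name: sha1_of(p) for p in sorted(folder.iterdir())
            if p.name != "manifest.json"}


# ---------------------------------------------------------------------------
# gating
# ---------------------------------------------------------------------------

def test_ready_tasks_gate_on_parent_success(topo, make_engine):
    m = topo["diamond"]
    eng = make_engine()
    job = load_fixture_job(m)
    dag = eng.register_job(job)
    run = eng.store.get_run(job.uid)
    # before the dispatcher completes no step is ready
    assert ready_tasks(run, dag) == {DISPATCHER_ID}
    # simulate dispatcher and A succeeding -> exactly {B, C} become ready
    for tid in (DISPATCHER_ID, "A"):
        for st in ("queued", "running", "success"):
            eng.store.transition_task(job.uid, tid, st)
    run = eng.store.get_run(job.uid)
    assert ready_tasks(run, dag) == {"B", "C"}


def test_all_success_means_nothing_ready(topo, make_engine):
    eng = make_engine()
    state, job = run_fixture(eng, topo["diamond"])
    dag = build_dag(workflow_of(topo["diamond"]), job)
    assert ready_tasks(state, dag) == set()


# ---------------------------------------------------------------------------
# end-to-end execution
# ---------------------------------------------------------------------------

def test_linear_fixture_runs_to_success(topo, make_engine):
    eng = make_engine()
    state, job = run_fixture(eng, topo["linear3"])
    assert state.status == R_SUCCESS
    # conservation: a successful run has steps + 2 success tasks
    assert sum(t.status == SUCCESS for t in state.tasks.values()) == 3 + 2
    out = Path(job.output_folder)
    assert (out / "manifest.json").exists()
    # the final text carries every step's stamp in order
    assert (out / "out.txt").read_text().endswith("[A]\n[B]\n[C]\n")


def test_trace_is_linear_extension_of_dag(topo, make_engine):
    m = topo["diamond"]
    eng = make_engine()
    state, job = run_fixture(eng, m)
    assert state.status == R_SUCCESS
    dag = build_dag(workflow_of(m), job)
    order = task_start_order(eng.store, job.uid)
    assert tuple(order) in linear_extensions(set(dag.nodes), dag.edges)


def test_worker_counts_give_identical_outputs(tmp_path, make_engine):
    """worker_count 1 vs 3 deliver byte-identical artifacts."""
    m = make_chipseq_like(tmp_path / "chip", seed=7)
    sums = {}
    for workers in (1, 3):
        eng = make_engine(worker_count=workers)
        out = tmp_path / f"out{workers}"
        state, job = run_fixture(eng, m, uid=f"chip-w{workers}",
                                 output_folder=out)
        assert state.status == R_SUCCESS
        sums[workers] = _delivered_checksums(out)
    assert sums[1] == sums[3]
    assert set(sums[1]) == {"index.txt", "peaks.txt", "coverage.txt"}


def test_queue_names_act_as_priorities(topo, make_engine):
    """With one worker, a task assigned to a lexicographically earlier
    queue runs before its default-queue siblings."""
    m = topo["fan"]
    eng = make_engine(worker_count=1,
                      queue_names={"default", "aaa-priority"},
                      task_queue_assignment={"F2": "aaa-priority"})
    state, job = run_fixture(eng, m)
    assert state.status == R_SUCCESS
    order = task_start_order(eng.store, job.uid)
    fan_steps = [t for t in order if t in ("F1", "F2", "F3")]
    assert fan_steps[0] == "F2"


def test_safety_no_task_starts_before_parents_succeed(tmp_path, make_engine):
    m = make_chipseq_like(tmp_path / "chip", seed=11)
    eng = make_engine(worker_count=3)
    state, job = run_fixture(eng, m)
    dag = build_dag(workflow_of(m), job)
    trs = eng.store.transitions(job.uid)
    started = {t["task_id"]: t["ts"] for t in trs if t["new"] == "running"}
    succeeded = {t["task_id"]: t["ts"] for t in trs if t["new"] == "success"}
    for a, b in dag.edges:
        assert succeeded[a] <= started[b]


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def test_dispatch_persists_absolute_paths_and_is_idempotent(topo, make_engine):
    m = topo["single"]
    eng = make_engine()
    job = load_fixture_job(m)
    eng.register_job(job)
    wf = workflow_of(m)
    mapping = eng.dispatch_job(job.uid, wf)
    assert Path(mapping["seed_file"]["path"]).is_absolute()
    again = eng.dispatch_job(job.uid, wf)
    assert again == mapping


def test_vanished_file_fails_run_before_steps(topo, make_engine, tmp_path):
    m = topo["single"]
    eng = make_engine()
    job = load_fixture_job(m)
    eng.register_job(job)
    seed = Path(job.inputs["seed_file"]["path"])
    seed.unlink()                                  # vanishes after registration
    state = eng.execute_run(job.uid)
    assert state.status == R_FAILED
    assert state.tasks[DISPATCHER_ID].status == "failed"
    assert state.tasks["A"].status == UPSTREAM_FAILED
    assert not Path(job.output_folder).exists()


def test_duplicate_uid_rejected_at_register(topo, make_engine):
    eng = make_engine()
    run_fixture(eng, topo["single"])
    from cwlflow.errors import DuplicateUid
    with pytest.raises(DuplicateUid):
        eng.register_job(load_fixture_job(topo["single"]))


# ---------------------------------------------------------------------------
# failure propagation, retries, delivery on failure
# ---------------------------------------------------------------------------

def test_failed_step_poisons_descendants_and_blocks_delivery(tmp_path, make_engine):
    m = make_failing_variant(tmp_path / "fx", fail_step="B")
    eng = make_engine()
    state, job = run_fixture(eng, m)
    assert state.status == R_FAILED
    assert state.tasks["B"].status == "failed"
    assert state.tasks["D"].status == UPSTREAM_FAILED
    assert state.tasks[CLEANUP_ID].status == UPSTREAM_FAILED
    assert state.tasks["C"].status == SUCCESS       # independent branch ran
    # nothing delivered on failure
    out = Path(job.output_folder)
    assert not out.exists() or list(out.iterdir()) == []
    # forensics: temp retained because cleanup never ran
    assert (eng.config.temp_folder / job.uid).exists()


def test_retry_limit_gives_extra_attempts(tmp_path, make_engine):
    m = make_failing_variant(tmp_path / "fx", fail_step="B")
    eng = make_engine(retry_limit=2)
    state, job = run_fixture(eng, m)
    assert state.status == R_FAILED
    assert state.tasks["B"].attempt == 3            # 1 + 2 retries


# ---------------------------------------------------------------------------
# pause / resume
# ---------------------------------------------------------------------------

def test_pause_resume_reexecutes_nothing(topo, make_engine):
    m = topo["diamond"]
    eng = make_engine()
    job = load_fixture_job(m)
    eng.register_job(job)

    paused_after_a = []

    def pause_after_a(task_id, status):
        if task_id == "A":
            eng.pause_run(job.uid)
            paused_after_a.append(task_id)

    state = eng.execute_run(job.uid, on_task_complete=pause_after_a)
    assert paused_after_a and state.status == "paused"
    done_before = {tid for tid, t in state.tasks.items() if t.status == SUCCESS}
    assert "A" in done_before and "D" not in done_before

    eng.resume_run(job.uid)
    state = eng.execute_run(job.uid)
    assert state.status == R_SUCCESS
    assert all(t.attempt == 1 for t in state.tasks.values())


def test_resume_of_unpaused_run_is_noop(topo, make_engine):
    eng = make_engine()
    state, job = run_fixture(eng, topo["single"])
    assert eng.resume_run(job.uid).status == R_SUCCESS


def test_workflow_edit_between_pause_and_resume_detected(topo, make_engine):
    m = topo["diamond"]
    eng = make_engine()
    job = load_fixture_job(m)
    eng.register_job(job)
    eng.execute_run(job.uid,
                    on_task_complete=lambda t, s: eng.pause_run(job.uid))
    # edit the workflow file: digest must mismatch on resume
    m.path.write_text(m.path.read_text().replace("id: diamond", "id: edited"))
    with pytest.raises(DigestMismatch):
        eng.resume_run(job.uid)


# ---------------------------------------------------------------------------
# step restart
# ---------------------------------------------------------------------------

def _run_failed_diamond(tmp_path, make_engine, fail_step="D"):
    m = make_failing_variant(tmp_path / "fx", fail_step=fail_step)
    eng = make_engine()
    state, job = run_fixture(eng, m)
    assert state.status == R_FAILED
    return m, eng, job


def _repair_diamond(tmp_path):
    # regenerating the suite rewrites every tool with its healthy version
    make_topology_suite(tmp_path / "fx")


def test_restart_single_failed_step(tmp_path, make_engine):
    m, eng, job = _run_failed_diamond(tmp_path, make_engine, fail_step="D")
    _repair_diamond(tmp_path)
    eng.restart_step(job.uid, "D", cascade=False)
    state = eng.execute_run(job.uid)
    assert state.status == R_SUCCESS
    for tid in ("A", "B", "C"):
        assert state.tasks[tid].attempt == 1        # untouched upstream
    assert state.tasks["D"].attempt == 2


def test_restart_cascade_resets_exact_descendant_set(tmp_path, make_engine):
    m, eng, job = _run_failed_diamond(tmp_path, make_engine, fail_step="D")
    _repair_diamond(tmp_path)
    dag = build_dag(workflow_of(m), job)

    eng.restart_step(job.uid, "B", cascade=True)
    state = eng.store.get_run(job.uid)
    reset = {tid for tid, t in state.tasks.items() if t.status == "pending"}
    oracle = {"B"} | brute_force_descendants(dag.edges, "B")
    assert reset == oracle
    assert "C" not in reset and "A" not in reset

    state = eng.execute_run(job.uid)
    assert state.status == R_SUCCESS
    assert state.tasks["B"].attempt == 2
    assert state.tasks["D"].attempt == 2
    assert state.tasks["C"].attempt == 1


def test_restart_unknown_task(topo, make_engine):
    eng = make_engine()
    _, job = run_fixture(eng, topo["single"])
    with pytest.raises(UnknownTask):
        eng.restart_step(job.uid, "nope")


# ---------------------------------------------------------------------------
# crash recovery
# ---------------------------------------------------------------------------

def test_interrupted_run_resumes_to_identical_outputs(tmp_path, make_engine):
    """Stopping the engine mid-run and re-invoking produces outputs
    byte-identical to an uninterrupted run of the same fixture."""
    m = make_chipseq_like(tmp_path / "chip", seed=5)

    eng = make_engine()
    out_ref = tmp_path / "ref_out"
    state, _ = run_fixture(eng, m, uid="ref", output_folder=out_ref)
    assert state.status == R_SUCCESS

    out_crash = tmp_path / "crash_out"
    job = load_fixture_job(m, uid="crashy", output_folder=out_crash)
    eng.register_job(job)
    partial = eng.execute_run(job.uid, stop_after_n_tasks=3)
    assert partial.status == "running"              # mid-flight snapshot
    done = sum(t.status == SUCCESS for t in partial.tasks.values())
    assert 0 < done < len(partial.tasks)

    # a second engine over the same store picks the run up from disk
    eng2 = make_engine()
    state = eng2.execute_run(job.uid)
    assert state.status == R_SUCCESS
    assert all(t.attempt == 1 for t in state.tasks.values())
    assert _delivered_checksums(out_crash) == _delivered_checksums(out_ref)


# ---------------------------------------------------------------------------
# delivery contract
# ---------------------------------------------------------------------------

def test_delivery_exact_outputs_and_temp_removal(tmp_path, make_engine):
    m = make_chipseq_like(tmp_path / "chip", seed=9)
    eng = make_engine()
    state, job = run_fixture(eng, m)
    assert state.status == R_SUCCESS
    out = Path(job.output_folder)
    assert sorted(p.name for p in out.iterdir()) == [
        "coverage.txt", "index.txt", "manifest.json", "peaks.txt"]
    manifest = json.loads((out / "manifest.json").read_text())
    assert set(manifest["outputs"]) == set(m.expected_output_ids)
    for entries in manifest["outputs"].values():
        for e in entries:
            assert sha1_of(out / e["basename"]) == e["checksum"]
    assert not (eng.config.temp_folder / job.uid).exists()


def test_keep_temp_retains_workdirs(tmp_path, make_engine):
    m = make_chipseq_like(tmp_path / "chip", seed=9)
    eng = make_engine(keep_temp=True)
    state, job = run_fixture(eng, m)
    assert state.status == R_SUCCESS
    assert (eng.config.temp_folder / job.uid / "align").exists()
    out = Path(job.output_folder)
    assert (out / "manifest.json").exists()


def test_unwritable_output_folder_fails_run_keeps_temp(topo, make_engine, tmp_path):
    # output folder path runs through a regular file -> cannot be created
    m = topo["single"]
    eng = make_engine()
    blocker = tmp_path / "blocker.txt"
    blocker.write_text("in the way")
    job = load_fixture_job(m, output_folder=blocker / "sub")
    eng.register_job(job)
    state = eng.execute_run(job.uid)
    assert state.status == R_FAILED
    assert state.tasks[CLEANUP_ID].status == "failed"
    # artifacts retained in temp for forensics
    assert (eng.config.temp_folder / job.uid / "A" / "out.txt").exists()


def test_run_history_lists_runs_newest_first(topo, make_engine):
    eng = make_engine()
    run_fixture(eng, topo["single"])
    run_fixture(eng, topo["linear3"])
    hist = eng.run_history()
    assert [h["uid"] for h in hist] == ["linear3-job", "single-job"]
    for h in hist:
        assert h["status"] == R_SUCCESS
        for t in h["tasks"].values():
            assert t["duration"] is not None and t["duration"] >= 0
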