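"""Embedded, crash-consistent run-state store.

One SQLite file holds everything needed to resume an interrupted engine:
runs, per-task states, the dispatched input mapping, a transition log and
rejected-job records.  Every state transition is one transaction, so the
store is always a consistent snapshot — the source of truth on restart.
"""

from __future__ import annotations

import json
import sqlite3
import threading
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

from .errors import Diagnostic, DuplicateUid, UnknownRun

# task statuses
PENDING = "pending"
QUEUED = "queued"
RUNNING = "running"
SUCCESS = "success"
FAILED = "failed"
UPSTREAM_FAILED = "upstream_failed"
PAUSED_HOLD = "paused-hold"

TERMINAL_TASK = {SUCCESS, FAILED, UPSTREAM_FAILED}

#: legal task transitions (old -> allowed new)
_TASK_TRANSITIONS: dict[str, set[str]] = {
    PENDING: {QUEUED, UPSTREAM_FAILED, PAUSED_HOLD},
    QUEUED: {RUNNING, PAUSED_HOLD},
    RUNNING: {SUCCESS, FAILED},
    FAILED: {QUEUED, PENDING},        # retry / restart
    SUCCESS: {PENDING},               # explicit restart only
    UPSTREAM_FAILED: {PENDING},
    PAUSED_HOLD: {PENDING},
}

# run statuses
R_REGISTERED = "registered"
R_RUNNING = "running"
R_PAUSED = "paused"
R_SUCCESS = "success"
R_FAILED = "failed"
R_REJECTED = "rejected"


_SCHEMA = """
CREATE TABLE IF NOT EXISTS runs (
    uid TEXT PRIMARY KEY,
    workflow_path TEXT NOT NULL,
    output_folder TEXT NOT NULL,
    job_json TEXT NOT NULL,
    dag_json TEXT NOT NULL,
    dag_digest TEXT NOT NULL,
    status TEXT NOT NULL,
    created_at REAL NOT NULL,
    finished_at REAL,
    dispatch_json TEXT
);
CREATE TABLE IF NOT EXISTS tasks (
    run_uid TEXT NOT NULL,
    task_id TEXT NOT NULL,
    kind TEXT NOT NULL,
    status TEXT NOT NULL,
    attempt INTEGER NOT NULL DEFAULT 0,
    exit_code INTEGER,
    started_at REAL,
    ended_at REAL,
    outputs_json TEXT,
    PRIMARY KEY (run_uid, task_id)
);
CREATE TABLE IF NOT EXISTS transitions (
    seq INTEGER PRIMARY KEY AUTOINCREMENT,
    ts REAL NOT NULL,
    run_uid TEXT NOT NULL,
    task_id TEXT,
    old_status TEXT,
    new_status TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS rejections (
    content_hash TEXT PRIMARY KEY,
    path TEXT NOT NULL,
    ts REAL NOT NULL,
    diagnostics_json TEXT NOT NULL
);
"""


@dataclass
class TaskState:
    task_id: str
    kind: str
    status: str = PENDING
    attempt: int = 0
    exit_code: Optional[int] = None
    started_at: Optional[float] = None
    ended_at: Optional[float] = None
    outputs: Optional[dict] = None


@dataclass
class RunState:
    run_uid: str
    workflow_path: str
    output_folder: str
    job: dict
    dag_digest: str
    status: str
    created_at: float
    finished_at: Optional[float] = None
    tasks: dict[str, TaskState] = field(default_factory=dict)


class RunStore:
    """Transactional access to the run-state file.  Safe for use from the
    engine's worker threads (one connection, serialized writes)."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self._lock = threading.RLock()
        self._conn = sqlite3.connect(self.path, check_same_thread=False,
                                     isolation_level=None)
        self._conn.execute("PRAGMA journal_mode=WAL")
        self._conn.executescript(_SCHEMA)  # executescript manages its own txn

    def close(self) -> None:
        self._conn.close()

    # -- transaction helper ------------------------------------------------

    def _txn(self):
        store = self

        class _Txn:
            def __enter__(self):
                store._lock.acquire()
                store._conn.execute("BEGIN IMMEDIATE")
                return store._conn

            def __exit__(self, exc_type, exc, tb):
                try:
                    if exc_type is None:
                        store._conn.execute("COMMIT")
                    else:
                        store._conn.execute("ROLLBACK")
                finally:
                    store._lock.release()
                return False

        return _Txn()

    # -- registration ------------------------------------------------------

    def has_uid(self, uid: str) -> bool:
        with self._lock:
            cur = self._conn.execute("SELECT 1 FROM runs WHERE uid=?", (uid,))
            return cur.fetchone() is not None

    def register_run(self, uid: str, workflow_path: str, output_folder: str,
                     job: dict, dag_json: str, dag_digest: str,
                     task_ids: dict[str, str]) -> None:
        """Insert a new run with all tasks pending.  ``task_ids`` maps
        task_id -> kind.  A duplicate uid raises :class:`DuplicateUid`."""
        now = time.time()
        with self._txn() as conn:
            cur = conn.execute("SELECT 1 FROM runs WHERE uid=?", (uid,))
            if cur.fetchone() is not None:
                raise DuplicateUid(f"uid {uid!r} is already registered")
            conn.execute(
                "INSERT INTO runs (uid, workflow_path, output_folder, job_json,"
                " dag_json, dag_digest, status, created_at) VALUES (?,?,?,?,?,?,?,?)",
                (uid, workflow_path, output_folder, json.dumps(job),
                 dag_json, dag_digest, R_REGISTERED, now),
            )
            for tid, kind in task_ids.items():
                conn.execute(
                    "INSERT INTO tasks (run_uid, task_id, kind, status, attempt)"
                    " VALUES (?,?,?,?,0)",
                    (uid, tid, kind, PENDING),
                )
            conn.execute(
                "INSERT INTO transitions (ts, run_uid, task_id, old_status, new_status)"
                " VALUES (?,?,NULL,NULL,?)",
                (now, uid, R_REGISTERED),
            )

    def record_rejection(self, path: str, chash: str,
                         diagnostics: list[Diagnostic]) -> None:
        with self._txn() as conn:
            conn.execute(
                "INSERT OR IGNORE INTO rejections (content_hash, path, ts,"
                " diagnostics_json) VALUES (?,?,?,?)",
                (chash, path, time.time(), json.dumps(
                    [{"severity": d.severity, "message": d.message,
                      "reference": d.reference} for d in diagnostics])),
            )

    def is_rejected(self, chash: str) -> bool:
        with self._lock:
            cur = self._conn.execute(
                "SELECT 1 FROM rejections WHERE content_hash=?", (chash,))
            return cur.fetchone() is not None

    def rejections(self) -> list[dict]:
        with self._lock:
            cur = self._conn.execute(
                "SELECT path, ts, diagnostics_json FROM rejections ORDER BY ts")
            return [{"path": p, "ts": ts, "diagnostics": json.loads(dj)}
                    for p, ts, dj in cur.fetchall()]

    # -- run access --------------------------------------------------------

    def get_run(self, uid: str) -> RunState:
        with self._lock:
            cur = self._conn.execute(
                "SELECT uid, workflow_path, output_folder, job_json, dag_digest,"
                " status, created_at, finished_at FROM runs WHERE uid=?", (uid,))
            row = cur.fetchone()
            if row is None:
                raise UnknownRun(f"no run with uid {uid!r}")
            run = RunState(
                run_uid=row[0], workflow_path=row[1], output_folder=row[2],
                job=json.loads(row[3]), dag_digest=row[4], status=row[5],
                created_at=row[6], finished_at=row[7],
            )
            cur = self._conn.execute(
                "SELECT task_id, kind, status, attempt, exit_code, started_at,"
                " ended_at, outputs_json FROM tasks WHERE run_uid=?", (uid,))
            for t in cur.fetchall():
                run.tasks[t[0]] = TaskState(
                    task_id=t[0], kind=t[1], status=t[2], attempt=t[3],
                    exit_code=t[4], started_at=t[5], ended_at=t[6],
                    outputs=json.loads(t[7]) if t[7] else None,
                )
            return run

    def get_dag_json(self, uid: str) -> str:
        with self._lock:
            cur = self._conn.execute("SELECT dag_json FROM runs WHERE uid=?", (uid,))
            row = cur.fetchone()
            if row is None:
                raise UnknownRun(f"no run with uid {uid!r}")
            return row[0]

    def set_run_status(self, uid: str, status: str) -> None:
        with self._txn() as conn:
            cur = conn.execute("SELECT status FROM runs WHERE uid=?", (uid,))
            row = cur.fetchone()
            if row is None:
                raise UnknownRun(f"no run with uid {uid!r}")
            old = row[0]
            finished = time.time() if status in (R_SUCCESS, R_FAILED) else None
            conn.execute(
                "UPDATE runs SET status=?, finished_at=COALESCE(?, finished_at)"
                " WHERE uid=?",
                (status, finished, uid))
            conn.execute(
                "INSERT INTO transitions (ts, run_uid, task_id, old_status,"
                " new_status) VALUES (?,?,NULL,?,?)",
                (time.time(), uid, old, status))

    def set_dispatch(self, uid: str, mapping: dict) -> None:
        with self._txn() as conn:
            conn.execute("UPDATE runs SET dispatch_json=? WHERE uid=?",
                         (json.dumps(mapping), uid))

    def get_dispatch(self, uid: str) -> Optional[dict]:
        with self._lock:
            cur = self._conn.execute(
                "SELECT dispatch_json FROM runs WHERE uid=?", (uid,))
            row = cur.fetchone()
            if row is None or row[0] is None:
                return None
            return json.loads(row[0])

    # -- task transitions --------------------------------------------------

    def transition_task(self, uid: str, task_id: str, new_status: str,
                        exit_code: Optional[int] = None,
                        outputs: Optional[dict] = None) -> None:
        """Apply one legal task transition atomically.

        The attempt counter increments exactly on queued -> running;
        start/end timestamps are stamped on running entry/exit."""
        now = time.time()
        with self._txn() as conn:
            cur = conn.execute(
                "SELECT status, attempt FROM tasks WHERE run_uid=? AND task_id=?",
                (uid, task_id))
            row = cur.fetchone()
            if row is None:
                raise UnknownRun(f"no task {task_id!r} in run {uid!r}")
            old, attempt = row
            if new_status not in _TASK_TRANSITIONS.get(old, set()):
                raise ValueError(
                    f"illegal task transition {old} -> {new_status} "
                    f"({uid}/{task_id})")
            sets = ["status=?"]
            args: list[Any] = [new_status]
            if old == QUEUED and new_status == RUNNING:
                sets += ["attempt=?", "started_at=?", "ended_at=NULL"]
                args += [attempt + 1, now]
            if new_status in (SUCCESS, FAILED):
                sets += ["ended_at=?", "exit_code=?"]
                args += [now, exit_code]
                if outputs is not None:
                    sets.append("outputs_json=?")
                    args.append(json.dumps(outputs))
            if new_status == PENDING:   # restart: clear previous result
                sets += ["exit_code=NULL", "outputs_json=NULL",
                         "started_at=NULL", "ended_at=NULL"]
            args += [uid, task_id]
            conn.execute(
                f"UPDATE tasks SET {', '.join(sets)} WHERE run_uid=? AND task_id=?",
                args)
            conn.execute(
                "INSERT INTO transitions (ts, run_uid, task_id, old_status,"
                " new_status) VALUES (?,?,?,?,?)",
                (now, uid, task_id, old, new_status))

    def recover_stale(self, uid: str) -> list[str]:
        """Reset tasks left queued/running by a dead engine back to pending.

        Crash recovery only: bypasses the legal-transition table because a
        stale ``running`` row has no live process behind it.  Each reset is
        logged as a ``recovered`` transition."""
        recovered = []
        now = time.time()
        with self._txn() as conn:
            cur = conn.execute(
                "SELECT task_id, status FROM tasks WHERE run_uid=? AND status IN (?,?)",
                (uid, QUEUED, RUNNING))
            for tid, old in cur.fetchall():
                conn.execute(
                    "UPDATE tasks SET status=?, started_at=NULL, ended_at=NULL"
                    " WHERE run_uid=? AND task_id=?", (PENDING, uid, tid))
                conn.execute(
                    "INSERT INTO transitions (ts, run_uid, task_id, old_status,"
                    " new_status) VALUES (?,?,?,?,?)",
                    (now, uid, tid, old, "recovered:" + PENDING))
                recovered.append(tid)
        return recovered

    def transitions(self, uid: str) -> list[dict]:
        with self._lock:
            cur = self._conn.execute(
                "SELECT ts, task_id, old_status, new_status FROM transitions"
                " WHERE run_uid=? ORDER BY seq", (uid,))
            return [{"ts": r[0], "task_id": r[1], "old": r[2], "new": r[3]}
                    for r in cur.fetchall()]

    # -- history -----------------------------------------------------------

    def run_uids(self) -> list[str]:
        with self._lock:
            cur = self._conn.execute(
                "SELECT uid FROM runs ORDER BY created_at DESC, uid")
            return [r[0] for r in cur.fetchall()]

    def run_history(self) -> list[dict]:
        """Per-run summaries, newest first, with per-task durations."""
        out = []
        for uid in self.run_uids():
            run = self.get_run(uid)
            out.append({
                "uid": uid,
                "workflow": run.workflow_path,
                "status": run.status,
                "created_at": run.created_at,
                "finished_at": run.finished_at,
                "tasks": {
                    tid: {
                        "status": t.status,
                        "attempt": t.attempt,
                        "duration": (t.ended_at - t.started_at)
                        if t.started_at is not None and t.ended_at is not None
                        else None,
                        "started_at": t.started_at,
                        "ended_at": t.ended_at,
                    }
                    for tid, t in sorted(run.tasks.items())
                },
            })
        return out
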