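"""Pause, resume and step restart on a live run.

Pauses the diamond run after step A, resumes it, then demonstrates a
cascade restart of B: exactly B and its descendants re-execute while the
sibling branch C keeps its first attempt.
"""

import tempfile
from pathlib import Path

from cwlflow import EngineConfig, parse_job_file
from cwlflow.fixtures import make_topology_suite
from cwlflow.scheduler import Engine

root = Path(tempfile.mkdtemp(prefix="cwlflow-lc-"))
diamond = next(m for m in make_topology_suite(root / "fx")
               if m.name == "diamond")

engine = Engine(EngineConfig(
    jobs_folder=root / "jobs", temp_folder=root / "temp",
    output_default=root / "out", store_path=root / "state.db",
    keep_temp=True))

job = parse_job_file(diamond.job_file)
engine.register_job(job)

state = engine.execute_run(
    job.uid,
    on_task_complete=lambda task, status: (
        task == "A" and engine.pause_run(job.uid)))
print(f"after pause: run={state.status}")
for tid, t in sorted(state.tasks.items()):
    print(f"  {tid:<14} {t.status}")

engine.resume_run(job.uid)
state = engine.execute_run(job.uid)
print(f"after resume: run={state.status} "
      f"(attempts all 1: {all(t.attempt == 1 for t in state.tasks.values())})")

engine.restart_step(job.uid, "B", cascade=True)
state = engine.execute_run(job.uid)
print("after cascade restart of B:")
for tid in ("A", "B", "C", "D"):
    print(f"  {tid}: attempt {state.tasks[tid].attempt}")
# B and D show attempt 2 (re-executed); A and C keep attempt 1 — completed
# work upstream and on the untouched branch is reused, never redone.
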