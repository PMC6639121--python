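# cwlflow

A lightweight, self-contained execution engine for pipelines written in a
subset of the Common Workflow Language v1.0. Bioinformatics analyses —
ChIP-Seq, RNA-Seq and the like — are increasingly published as CWL
documents so they can be rerun anywhere; `cwlflow` runs such pipelines by
translating each workflow's *dataflow* into a directed acyclic task graph
and driving that graph with a persistent, Airflow-style scheduler. It is
aimed at bioinformaticians and infrastructure developers who want CWL
execution with real pipeline-manager ergonomics (run history, pause/resume,
per-step restart) without standing up a full workflow platform.

## The model

A CWL `Workflow` composes `CommandLineTool` steps wired by dataflow: a step
input may *source* another step's output (`stepA/out`). From one workflow
plus one job (a JSON/YAML request with mandatory `workflow`,
`output_folder` and `uid` fields), the engine builds a task DAG:

* one node per workflow step, with an edge (A, B) **iff** some input of B
  sources an output of A — the dataflow is the dependency structure;
* a synthetic **JobDispatcher** root that validates the job and persists
  the resolved input mapping, and a **JobCleanup** sink that atomically
  delivers the workflow's declared outputs to the job's output folder.

Execution is dependency-gated: a task becomes *ready* exactly when all its
parents have succeeded; up to `worker_count` ready tasks run concurrently
as OS processes, in deterministic (queue, task id) order. Every state
transition (`pending → queued → running → success/failed`, plus
`upstream_failed` poisoning and `paused-hold`) is one transaction in an
embedded SQLite store, so a killed engine resumes from exactly where it
stopped. Each step's command line is constructed by the CWL v1.0 binding
algorithm (position sort with lexicographic ties, prefixes,
`itemSeparator`, boolean flags, restricted `$(...)` parameter references);
inputs are staged into an isolated per-task working directory and outputs
collected by glob or stdout capture as sha1-checksummed artifacts.

Out of subset (rejected at load time, never silently ignored): JavaScript
expressions, `scatter`, nested workflows, schema-salad record/enum types,
secondaryFiles. Docker/Singularity invocations are constructed but not
executed unless a container engine is configured.

## Worked example

```sh
python examples/run_pipeline.py
```

builds a 5-step demonstration pipeline shaped like a basic ChIP-Seq
analysis — align → sort → {index, peak-call} → coverage — over 1000 seeded
pseudo-reads, with each tool a tiny deterministic text transform, then runs
it with two workers:

```
workflow: /tmp/cwlflow-demo-qolrnru3/fixture/chipseq_like.cwl
steps:    align, sort, index, peaks, coverage
run chipseq-7: success
  coverage_table   coverage.txt       60 B  sha1$1c17d8503850053a6327809bfb381741a0d8b08e
  index_report     index.txt          45 B  sha1$d11c820a8fbb58e389cdfc527e8777c8c022a7d6
  peak_list        peaks.txt        1730 B  sha1$c895f4a0c37f24d1a09ae82af5bd758fbcc3218f
```

Each line is one delivered workflow output with its size and checksum; the
checksums are identical for any worker count because the steps are
deterministic and the scheduler only ever runs a task after its dataflow
parents succeed. The other examples show DAG inspection
(`inspect_dag.py`), the binding algorithm (`bind_command.py`) and
pause/resume/restart (`lifecycle.py`).

The same engine is scriptable from a shell:

```sh
cwlflow --workdir /data/engine run job.yml        # one-shot run
cwlflow --workdir /data/engine watch              # jobs-folder service
cwlflow --workdir /data/engine status <uid> --graph | dot -Tpng > dag.png
cwlflow --workdir /data/engine restart <uid> <step> --cascade
```

Exit codes: 0 success, 1 run failure, 2 validation/usage error.

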