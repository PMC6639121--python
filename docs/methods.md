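# Methods

## What the engine computes

`cwlflow` executes pipelines written in a defined subset of CWL v1.0. The
unit of work is a **run**: one workflow document plus one job file. The job
file is a JSON or YAML mapping whose three mandatory fields are `workflow`
(path to the CWL descriptor), `output_folder` (where results are delivered)
and `uid` (the unique run identifier keying all persisted state); every
other top-level key is a workflow input value, with File values in the CWL
form `{class: File, path: ...}`.

The run is compiled to a task DAG before anything executes. Step-to-step
edges are derived purely from dataflow: (A, B) is an edge iff some input of
B sources an output of A (`A/out_id`). Parallel data edges between one step
pair collapse into a single scheduling edge, since scheduling cares about
precedence, not multiplicity. Two synthetic tasks complete the graph:
`JobDispatcher` (no upstream) re-validates the job, resolves every File
path to absolute form and persists the mapping, so no later task ever reads
the job file; `JobCleanup` (no downstream) copies the workflow-declared
outputs — and only those — into the output folder via write-to-temp-name
plus atomic rename, writes a `manifest.json` (output id, basename, size,
sha1), and removes the run's temp tree. The dispatcher feeds every step
with no step parents; cleanup collects every sink step and every step that
feeds a workflow output, so no work is orphaned. Isolated steps (connected
to nothing) are wired dispatcher→step→cleanup rather than rejected: CWL
permits side-effect-only diagnostic steps.

## Scheduling and state

Per-task state follows a fixed machine — `pending → queued → running →
{success, failed}`, with `pending → upstream_failed` when an ancestor
exhausts its retries, `paused-hold` as a reversible hold, and `failed →
pending` for retry/restart. A task is **ready** exactly when all its DAG
parents are `success`. The loop queues ready tasks in deterministic order
(queue name, then task id lexicographically — queue names act as priority
classes), runs up to `worker_count` concurrently, and reacts to
completions. Step work is an OS subprocess per task; the pool that feeds
those subprocesses is a thread pool inside the engine process, which on one
machine gives the same concurrency contract as a pool of independent
worker processes consuming a shared queue while keeping the store simple.

Every transition is a single SQLite transaction (WAL journal), so the store
is always a consistent snapshot and is the sole source of truth: killing
the engine at any point and re-invoking `execute_run` continues the run,
first resetting any stale `queued`/`running` rows (tasks with no live
process) back to `pending` via a logged recovery transition. The attempt
counter increments exactly on `queued → running`, which is what makes
"pause/resume re-executes nothing" and "restart re-runs exactly the chosen
set" directly assertable.

Pause marks the run paused and holds all pending tasks; running tasks
finish. Resume releases holds after checking the run digest — a sha1 over
the workflow file bytes plus the graph's node/edge set. Deliberately, step
*tool* files are not part of the digest: repairing a broken tool and
restarting its step is the main use of restart, while editing the workflow
file itself invalidates resume. Restart resets the target task to pending
(attempt history preserved in the transition log); with `cascade` it also
resets all transitive descendants, and tasks that never ran
(`upstream_failed`) are always released so the run can complete. Upstream
successes and their persisted outputs are reused verbatim — which is also
why a failed run keeps its temp tree (cleanup never ran), making
restart-after-repair possible without re-executing healthy branches.

## Command-line binding and step execution

Binding follows the CWL v1.0 algorithm for the supported subset: `argv` is
`baseCommand` followed by bound tokens sorted by `(position, tie-break
key)`; the tie-break key is the input parameter id (lexicographic) or, for
`arguments`, the argument's zero-padded list index. `separate: true` emits
prefix and value as two tokens, `false` concatenates; arrays with
`itemSeparator` join into one token, arrays without emit the prefix once
followed by the items; boolean true contributes its prefix only, false and
null contribute nothing. Parameter references are the restricted `$(...)`
grammar over `inputs.<id>[.path|.basename]`, `runtime.outdir`,
`runtime.cores` and `self` (in `valueFrom`); anything beginning `${` is a
JavaScript expression and is rejected — as is every document key the parser
does not consume, so no CWL feature is ever silently dropped.

Each step attempt gets a fresh working directory under
`temp/<uid>/<task_id>`. Input files are symlinked by basename into an
`inputs/` subdirectory of that workdir (copy fallback when linking fails;
collisions get numeric suffixes). Staging into a subdirectory rather than
the workdir root means a tool that writes a file named like one of its
inputs cannot truncate the upstream artifact through the link, and output
globs never match staged inputs. Outputs are collected only as File,
File[] or stdout captures: glob patterns (after reference evaluation)
match relative to the workdir, sorted lexicographically by basename for
determinism; zero matches on a non-optional single-File output is an
error, as is more than one. Success is exit code 0 only.

Container execution is construct-only by default: when a tool carries a
`DockerRequirement` the full `docker run`/`singularity exec` invocation is
built and recorded, but the plain argv is what executes unless
`container_mode` is configured. The container claim is an integration
property of the host, not an algorithm, and construct-only keeps the suite
runnable on machines without an engine.

## The fixture generators

All tests run on generated inputs; nothing is downloaded and no
bioinformatics tools are invoked.

* **ChIP-Seq-shaped pipeline** (`make_chipseq_like`): five steps with the
  topology align → sort → {index, peak-call} → {coverage}, where coverage
  also consumes the peak list. Each tool is a small Python text transform:
  "alignment" hashes each read to a (chromosome, position) pair, "sort"
  orders the records, "index" counts per chromosome, "peak-call" reports
  500-unit buckets holding ≥ 3 reads, "coverage" tabulates reads and peaks
  per chromosome. The input is 1000 seeded uniform 4-letter reads of
  length 36 — small enough for sub-second steps, structured enough that
  the sort and peak stubs do visible work. The generator is a pure
  function of (outdir, seed); the job file carries the three mandatory
  fields plus the reads File.
* **Topology suite** (`make_topology_suite`): single-step, linear-3,
  diamond, fan-out/fan-in, isolated-step, plus two invalid shapes (a
  2-cycle and a dangling source). Each manifest records the intended edge
  set, so every fixture is self-checking: building its DAG must reproduce
  the manifest exactly.
* **Binding suite** (`make_binding_suite`): 12 CommandLineTool cases
  covering positions, position ties, prefixes with `separate` true/false,
  arrays with/without `itemSeparator`, booleans, optional-null omission,
  stdin/stdout redirection, `valueFrom` interpolation and File path
  substitution. The expected argv for each case is derived from the CWL
  v1.0 binding rules and frozen as JSON next to the tool document; File
  tokens are recorded as basenames since the staged absolute path varies
  with the working directory. Re-deriving the expectations with an
  external reference CWL executor, where one is installed, is a
  one-command exercise: run each `tool.cwl` with its `values.json` and
  diff the printed command line — the engine itself never depends on one.

What the stubs do **not** emulate: real tool runtimes and memory
footprints, container pulls, large files, multi-gigabyte staging costs,
non-deterministic tools, or any biological meaning in the outputs. Green
tests therefore certify the orchestration semantics (graph construction,
binding, gating, persistence, delivery), not the performance or scientific
validity of any particular pipeline.

## Numerical and design choices

* Ties everywhere break lexicographically (binding positions, ready-task
  order, glob matches, DOT statements) so traces and artifacts are
  reproducible and diffable.
* `retry_limit` defaults to 0: a failed step fails the run. Retries are
  per-engine configuration.
* Duplicate `uid`s are rejected at registration; a rejected or malformed
  job file is recorded once per content hash and re-considered only when
  its content changes. Job files are never mutated or deleted.
* Relative `workflow`/`output_folder` paths in a job are accepted,
  resolved against the job file's directory, and flagged with a warning;
  unknown job keys warn rather than fail so jobs stay forward-compatible
  with workflow edits.
* Optionality is only the two-member union `["null", T]`; all other unions
  are rejected to keep type checking decidable without schema-salad.
* Nested workflows as step run-targets are rejected rather than flattened
  or executed as sub-runs; inline tools are supported.
* The problem sizes used by the test suite and the acceptance script —
  ≤ 6-step graphs for exhaustive linear-extension enumeration, 1000
  pseudo-reads, worker counts 1 and 3 — are chosen so every check is an
  exact, exhaustive comparison rather than a sample.

## Known limitations

The engine is single-machine: the multi-node broker/worker architecture it
is modeled on is reduced to one shared store and an in-process pool, and
queue names are honored as priorities rather than separate brokers. No web
GUI or REST API — observability is the CLI (`status`, `logs`, `history`,
DOT export). The CWL subset excludes JavaScript expressions, `scatter`,
subworkflows, secondaryFiles and `InitialWorkDirRequirement`; documents
using them are rejected loudly at load time. Crash recovery assumes the
filesystem survived the crash; a lost temp volume fails the affected runs
rather than recomputing silently.
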