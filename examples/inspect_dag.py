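"""Translate a workflow into its task DAG and inspect it.

Builds the diamond fixture, shows the Kahn layers (tasks that may run
concurrently share a layer) and prints the Graphviz DOT rendering.
"""

import tempfile
from pathlib import Path

from cwlflow import build_dag, export_dot, load_document, parse_job_file, topological_layers
from cwlflow.fixtures import make_topology_suite

root = Path(tempfile.mkdtemp(prefix="cwlflow-dag-"))
diamond = next(m for m in make_topology_suite(root) if m.name == "diamond")

wf = load_document(diamond.path).body
job = parse_job_file(diamond.job_file)
dag = build_dag(wf, job)

print(f"nodes: {len(dag.nodes)} (steps + dispatcher + cleanup)")
print(f"step-step edges: {sorted(dag.step_edges())}")
for depth, layer in enumerate(topological_layers(dag)):
    print(f"layer {depth}: {layer}")
# B and C share a layer: with >=2 workers they execute concurrently.

print()
print(export_dot(dag))
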