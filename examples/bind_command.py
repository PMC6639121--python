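"""Show the command-line binding algorithm on one tool document.

A tool with positions, a prefixed int, an itemSeparator array and a
boolean flag is bound against concrete values; the printed argv is
exactly what the engine would execute.
"""

import tempfile
from pathlib import Path

from cwlflow import bind_command_line, loads_document

TOOL = """
cwlVersion: v1.0
class: CommandLineTool
baseCommand: [aligner]
inputs:
  - {id: threads, type: int, inputBinding: {position: 1, prefix: -t}}
  - {id: fast, type: boolean, inputBinding: {position: 2, prefix: --fast}}
  - id: chroms
    type: string[]
    inputBinding: {position: 3, prefix: -c, itemSeparator: ","}
  - {id: sample, type: string,
     inputBinding: {position: 4, valueFrom: "out_$(inputs.sample).sam"}}
outputs: []
"""

tool = loads_document(TOOL).body
workdir = Path(tempfile.mkdtemp(prefix="cwlflow-bind-"))
plan = bind_command_line(
    tool, {"threads": 4, "fast": True, "chroms": ["chr1", "chr2"],
           "sample": "s1"}, workdir)
print(plan.argv)
# ['aligner', '-t', '4', '--fast', '-c', 'chr1,chr2', 'out_s1.sam']
# -t/4 are separate tokens (separate defaults to true), the boolean
# contributes its flag only, the array collapses to one comma-joined
# token, and the valueFrom reference interpolates the input value.
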