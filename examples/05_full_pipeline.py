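"""Run the complete pipeline and read its consolidated report.

Equivalent to ``ceo run-all --seed 7 --outdir ceo_demo``: simulate,
verify the planted guides, quantify enrichment, census the repeats,
and aggregate methylation, with a manifest of every output file.
"""

import dataclasses
import tempfile
from pathlib import Path

from ceoseq import RunConfig, run_all

outdir = Path(tempfile.mkdtemp(prefix="ceo_demo_"))
config = dataclasses.replace(RunConfig(), seed=7, outdir=str(outdir))
run_all(config)

print((outdir / "report.txt").read_text())
print("files written:")
for path in sorted(outdir.iterdir()):
    print(f"  {path.name}")
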