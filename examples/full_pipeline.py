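"""End-to-end pipeline run on the bundled synthetic fixture.

Writes a complete input bundle (six training studies, one testing study,
an interaction network with a planted dense module and hub, a GMT and an
IHC cohort), runs every stage and prints the manifest summary.
"""

import json
import tempfile
from pathlib import Path

from metanet import PipelineConfig, run_pipeline
from metanet.synthetic import write_pipeline_fixture

workdir = Path(tempfile.mkdtemp(prefix="metanet_demo_"))
cfg_path = write_pipeline_fixture(workdir / "inputs", seed=0)
manifest = run_pipeline(PipelineConfig.from_file(cfg_path), workdir / "results")

print(f"inputs:  {workdir / 'inputs'}")
print(f"results: {workdir / 'results'}")
print("stages completed:", [s["name"] for s in manifest["stages"]])

degs = json.loads((workdir / "results" / "degs.json").read_text())
print("\ncombined DEGs:", degs["combined"])
hubs = json.loads((workdir / "results" / "hubs.json").read_text())
for h in hubs:
    print(f"module {h['module']}: hubs {h['hubs']} "
          f"(distance quartile cutoff {h['quartile_cutoff']:.2f})")
# Rerunning with the same config reproduces every output byte-for-byte;
# the manifest records SHA-256 hashes of all inputs and stage outputs.
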