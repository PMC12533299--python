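"""One-call orchestration: simulate -> preprocess -> screen -> enrich ->
cluster -> risk, with provenance and a reproducible artifact bundle.

The same workflow is available from the shell as `ctcmet run`.
"""

import json
import tempfile
from pathlib import Path

from ctcmet import run_pipeline

outdir = Path(tempfile.mkdtemp(prefix="ctcmet_"))
artifacts = run_pipeline({"seed": 1}, outdir)

print("artifacts:")
for name, path in artifacts.items():
    print(f"  {name:18s} {path.name}")

report = json.loads(artifacts["risk_report"].read_text())
print("\nrisk summary:")
for r in report:
    print(f"  {r['endpoint']}: subgroup={r['subgroup']} cutoff={r['cutoff']} "
          f"AUC={r['auc']:.3f}")
clus = json.loads(artifacts["clustering_report"].read_text())
print(f"\nselected k = {clus['selected_k']}, "
      f"subgroup sizes = {clus['subgroup_sizes']}")
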