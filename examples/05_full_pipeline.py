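"""One-call orchestration: simulate a dataset, run every stage, inspect
the report bundle.

Equivalent to `dosagescan simulate ... && dosagescan run-all ...` from a
shell.
"""

import json
import tempfile
from pathlib import Path

from dosagescan.pipeline import RunConfig, run_pipeline
from dosagescan.synthetic_data import SimConfig, generate_dataset

work = Path(tempfile.mkdtemp())
data = generate_dataset(SimConfig(seed=11), work / "data")
p = data["paths"]

summary = run_pipeline(RunConfig(
    snp_states=p["snp_states"], snp_log2=p["snp_log2"],
    cytobands=p["cytobands"], genes=p["genes"], expression=p["expression"],
    out_dir=str(work / "run"), seed=11, cluster_monte_carlo=1000,
))

print("outputs:", sorted(f.name for f in (work / "run").iterdir()))
print(json.dumps({k: summary[k] for k in ("cna", "mrr", "de")}, indent=1))
print("dosage-vs-expression (average row):")
print(json.dumps(summary["dosage_expression"]["average"], indent=1))
# "cn_pct" vs "nocn_pct" is the headline contrast: how much more often
# genes inside copy-number-altered regions change expression than genes
# outside them.
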