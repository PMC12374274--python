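"""Full pipeline run with planted hotspots, then the run summary.

Runs simulate -> preprocess -> heritability -> calibrate -> scan -> QC
-> hotspots through the pipeline orchestrator and prints the summary a
user would inspect first.
"""

import json
from pathlib import Path
import tempfile

from meqtlmap import PipelineConfig, run_pipeline, summarize_run

cfg = PipelineConfig(
    n_individuals=250, n_variants=1500, n_cpgs=250,
    frac_cis_cpgs=0.25, n_hotspots=1, hotspot_n_targets=40,
    hotspot_effect_mean=8.0, n_misassemblies=1,
    n_perm=5, cpg_fraction=0.2, seed=17, run_enrichment=False,
)
out = Path(tempfile.mkdtemp()) / "run"
run_pipeline(cfg, out)
report = summarize_run(out)

print(json.dumps({k: v for k, v in report.items() if k != "hotspots"}, indent=1))
for h in report["hotspots"]:
    print(f"hotspot {h['hotspot']}: lead {h['lead_variant']} "
          f"({h['n_trans_cpgs']} trans-CpGs, {h['n_independent']} independent, "
          f"{h['pct_opposite']:.0f}% opposite-direction)")
# The summary mirrors the headline structure of a real analysis: the
# share of CpGs with cis/trans signals, mean heritability, the derived
# thresholds, the mean distance to the top cis SNP, and one row per
# detected trans hotspot.
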