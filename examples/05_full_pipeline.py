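"""Run the entire analysis pipeline end to end on a synthetic cohort.

Simulates the default three-study cohort, builds the composite, fits all
twelve outcome models for each predictor (mixed models for the pooled
sleep-disturbance analysis, Huber regressions for the Study-2 diary and
GSQS analyses), compares extreme sleeper groups, and writes every output
table plus a reproducibility manifest.
"""

import tempfile
from pathlib import Path

from sleepcog import CohortConfig
from sleepcog.pipeline import RunConfig, render_table, run_pipeline

out_dir = Path(tempfile.mkdtemp(prefix="sleepcog_demo_"))
results = run_pipeline(
    RunConfig(out_dir=out_dir, synthetic=CohortConfig(), bootstrap_B=200, seed=4)
)

print("Sleep disturbance (pooled mixed models, N = 235):")
print(render_table(results["associations"]["sleep_disturbance"]))
print("\nSleep diary (Study-2 Huber regressions, N = 103): first rows")
print(render_table(results["associations"]["diary"].head(3)))

eg = results["extreme_groups"]
row = eg[eg["outcome"] == "counting_span"].iloc[0]
print(
    f"\nGood vs poor sleepers on counting span: difference "
    f"{row['difference']:.2f} (d = {row['cohens_d']:.2f}, "
    f"p = {row['p_welch']:.2f}, BF01 = {row['bf01']:.2f})"
)
print(f"\nAll outputs written to {out_dir}:")
for path in sorted(out_dir.iterdir()):
    print(f"  {path.name}")
print("\nWith the default null generator every table should show small"
      " betas, CIs spanning zero and BF01 mostly in the substantial-"
      "evidence-for-H0 band (3-10+).")
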