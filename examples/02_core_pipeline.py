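"""Full pipeline on a synthetic biopsy-core cohort.

Generates a small benign/malignant phantom cohort (benign cores carry
fewer, larger calcifications; malignant more numerous, smaller ones),
segments each core with the local-adaptive method, measures every object
and prints the per-subject summary table plus the group comparisons.
"""

import json
from pathlib import Path

import pandas as pd

import calcimorph as cm
from calcimorph.pipeline import PipelineConfig, run_pipeline, validate_tables

spec = cm.CohortSpec(
    n_benign=3,
    n_malignant=3,
    count_mean={"benign": 6, "malignant": 12},
    voxel_size=0.07,       # coarser than the 35 um reference, for speed
    core_length_mm=12.0,
    max_volume_mm3=0.02,
    seed=7,
)
cfg = PipelineConfig(
    cohort=spec, voxel_size_mm=spec.voxel_size, seed=7,
    output_dir="scratch/example_run",
)
out = run_pipeline(cfg)

subjects = pd.read_csv(out / "subjects.csv")
print("per-subject summary (means over measurable objects):")
print(subjects[["subject", "group", "obj_n", "obj_n_measurable",
                "obj_v_mm3", "st_th_mm", "smi"]].to_string(index=False))

comparisons = json.loads(Path(out / "comparisons.json").read_text())
print("\ngroup comparisons (normality-gated, alpha = 0.05):")
for row in comparisons["group_comparisons"]:
    print(f"  {row['parameter']:<10} {row['test']:<13} p = {row['p']:.3f}"
          f"{'  *' if row['significant'] else ''}")

print("\nconsistency checks:")
print(validate_tables(out).to_string(index=False))
print(f"\nall tables in {out}/ — identical config + seed reproduces them "
      "byte for byte.")
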