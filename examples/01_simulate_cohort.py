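"""Simulate the synthetic cohort and TMT abundance data.

Generates the default two-diagnosis x two-race cohort, allocates samples to
multiplexed batches, and simulates the log2 abundance matrix with planted
co-expression modules, batch shifts, and block-wise missingness.
"""

import numpy as np

from csfnet import (BatchDesign, CohortSpec, ModulePlantSpec, generate_cohort,
                    generate_tmt)

cohort = generate_cohort(CohortSpec())
print(f"cohort: {len(cohort)} samples")
print(cohort.groupby(["diagnosis", "race"])
      .agg(n=("age", "size"), age=("age", "mean"), moca=("moca", "mean"),
           ttau=("ttau", "mean"))
      .round(1))

matrix, truth = generate_tmt(cohort, ModulePlantSpec(), BatchDesign(), seed=0)
print(f"\nabundance matrix: {matrix.data.shape[0]} proteins x "
      f"{matrix.data.shape[1]} columns "
      f"({len(matrix.sample_columns)} sample channels, "
      f"{len(matrix.gis_columns)} GIS, the rest biomarker pools)")
print("planted module sizes:")
print(truth.module_membership.value_counts().drop("M0").sort_index())
print(f"background proteins: {(truth.module_membership == 'M0').sum()}")
print(f"missing fraction: "
      f"{float(np.mean(matrix.data.isna().to_numpy())):.3f}")

# batches are balanced for diagnosis/race by the snake allocator
batch_of = matrix.batches[matrix.sample_columns]
sample_of = matrix.sample_of_column
dx_by_batch = {}
for col, b in batch_of.items():
    dx_by_batch.setdefault(b, []).append(
        cohort.loc[sample_of[col], "diagnosis"])
ad_frac = {b: np.mean([d == "AD" for d in v]) for b, v in dx_by_batch.items()}
print(f"\nAD fraction per batch: min {min(ad_frac.values()):.2f}, "
      f"max {max(ad_frac.values()):.2f}")
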