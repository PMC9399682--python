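"""Balance an imbalanced binary task with SMOTE (k = 10).

The development cohort's first peel task (AD vs everyone else) is
205 vs 780; SMOTE equalizes the counts by interpolating each synthetic
sample between a minority point and one of its 10 nearest minority
neighbours, so no synthetic subject leaves the minority convex hull.
"""

import numpy as np
import pandas as pd

from adcascade import SmoteConfig, balance_binary_task

rng = np.random.default_rng(0)
n_ad, n_rest = 205, 780
task = pd.DataFrame({
    "cdr": np.concatenate([rng.normal(4.3, 1.5, n_ad), rng.normal(1.0, 0.9, n_rest)]),
    "faq": np.concatenate([rng.normal(12.9, 6.5, n_ad), rng.normal(1.7, 3.0, n_rest)]),
    "label": ["AD"] * n_ad + ["rest"] * n_rest,
})

balanced = balance_binary_task(task, SmoteConfig(k=10, seed=1))
counts = balanced["label"].value_counts()
n_synth = int(balanced["synthetic"].sum())

print(f"before: AD={n_ad}, rest={n_rest}")
print(f"after : AD={counts['AD']}, rest={counts['rest']} ({n_synth} synthetic AD rows)")

synth = balanced[balanced["synthetic"]]
real = task[task["label"] == "AD"]
print("\nsynthetic rows stay inside the minority range:")
for col in ("cdr", "faq"):
    print(f"  {col}: synthetic [{synth[col].min():.2f}, {synth[col].max():.2f}] "
          f"within real [{real[col].min():.2f}, {real[col].max():.2f}]")
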