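"""Synthetic minority oversampling (SMOTE) for the binary cascade tasks.

New minority samples are random linear interpolations x_i + u (x_nn - x_i)
between a minority point and one of its k nearest minority neighbours
(u ~ Uniform[0,1], Euclidean metric).  Majority points never participate,
so every synthetic sample lies inside the convex hull of the minority
class.  The default k = 10 follows the study setting; the pipeline calls
this on z-scored features so the Euclidean metric is scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

__all__ = ["SmoteConfig", "smote_oversample", "balance_binary_task"]


@dataclass
class SmoteConfig:
    k: int = 10
    seed: int = 0
    target: str = "majority"  # equalize minority count to the majority count

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.target != "majority":
            raise ValueError("the only supported balancing target is 'majority'")


def smote_oversample(
    X_min: np.ndarray, X_maj: np.ndarray, config: SmoteConfig
) -> np.ndarray:
    """Synthetic minority rows equalizing the two class counts.

    Returns an array of ``len(X_maj) - len(X_min)`` synthetic samples
    (empty if already balanced).  Deterministic given ``config.seed``.
    """
    X_min = np.asarray(X_min, dtype=float)
    X_maj = np.asarray(X_maj, dtype=float)
    n_min, n_maj = len(X_min), len(X_maj)
    if n_min <= config.k:
        raise ValueError(
            f"minority class has {n_min} samples but k={config.k}; "
            "lower k below the minority class size"
        )
    if not (np.isfinite(X_min).all() and np.isfinite(X_maj).all()):
        raise ValueError("features must be finite")
    n_new = n_maj - n_min
    if n_new <= 0:
        return np.empty((0, X_min.shape[1]))
    # neighbours among minority points only; drop each point's self-match
    nn = NearestNeighbors(n_neighbors=config.k + 1).fit(X_min)
    neigh = nn.kneighbors(X_min, return_distance=False)[:, 1:]
    rng = np.random.default_rng(config.seed)
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(0, config.k, size=n_new)
    u = rng.random(size=n_new)[:, None]
    anchors = X_min[base]
    partners = X_min[neigh[base, pick]]
    return anchors + u * (partners - anchors)


def balance_binary_task(
    task_data: pd.DataFrame,
    config: SmoteConfig,
    *,
    label_col: str = "label",
    categorical_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Equalize the two class counts of a binary training table.

    Original rows are preserved verbatim; synthetic rows are appended and
    flagged in a boolean ``synthetic`` column.  Categorical 0/1 columns are
    interpolated then rounded back to the nearest observed category.
    """
    classes = task_data[label_col].unique()
    if len(classes) != 2:
        raise ValueError(
            f"binary task requires exactly two classes, found {sorted(map(str, classes))}"
        )
    counts = task_data[label_col].value_counts()
    minority, majority = counts.index[-1], counts.index[0]
    feat_cols = [c for c in task_data.columns if c not in (label_col, "subject_id", "synthetic")]
    out = task_data.copy()
    out["synthetic"] = False
    if counts[minority] == counts[majority]:
        return out

    X_min = task_data.loc[task_data[label_col] == minority, feat_cols].to_numpy(dtype=float)
    X_maj = task_data.loc[task_data[label_col] == majority, feat_cols].to_numpy(dtype=float)
    synth = smote_oversample(X_min, X_maj, config)
    synth_df = pd.DataFrame(synth, columns=feat_cols)
    for col in categorical_columns or []:
        if col in synth_df.columns:
            levels = np.unique(task_data[col].dropna().to_numpy(dtype=float))
            vals = synth_df[col].to_numpy(dtype=float)
            synth_df[col] = levels[np.abs(vals[:, None] - levels[None, :]).argmin(axis=1)]
    synth_df[label_col] = minority
    synth_df["synthetic"] = True
    if "subject_id" in task_data.columns:
        synth_df["subject_id"] = [f"synthetic_{i:05d}" for i in range(len(synth_df))]
    return pd.concat([out, synth_df], ignore_index=True)[list(out.columns)]
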