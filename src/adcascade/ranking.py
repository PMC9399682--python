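"""Feature ranking from a fitted weight matrix.

A fitted d x T weight matrix is collapsed to one signed weight per
feature (mean across visits), converted to a dimensionless importance
|ln|w||, and ranked: rank 1 is the largest |ln|w||.

Note the direction of this scale: for surviving weights of magnitude
below 1 (as all selected cortical weights are), |ln|w|| is *decreasing*
in |w|, so rank 1 is the smallest-magnitude surviving weight.  The
package follows that published convention literally rather than
rationalizing it.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FeatureEntry",
    "FeatureReport",
    "select_features",
    "aggregate_weight",
    "importance",
    "rank_features",
    "build_report",
    "load_reference_features",
]


@dataclass
class FeatureEntry:
    feature_id: str
    w: float
    importance: float
    rank: int


@dataclass
class FeatureReport:
    """Ranked selected features; entries sorted by rank (1 = top)."""

    entries: list[FeatureEntry]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": [e.feature_id for e in self.entries],
                "w": [e.w for e in self.entries],
                "abs_ln_abs_w": [round(e.importance, 3) for e in self.entries],
                "rank": [e.rank for e in self.entries],
            }
        )

    def __len__(self) -> int:
        return len(self.entries)


def select_features(
    W_hat: np.ndarray, feature_ids: list[str] | None = None, epsilon: float = 1e-8
):
    """Features whose weight-row Euclidean norm exceeds ``epsilon``.

    Order follows the input row order.  Returns ids if given, else row
    indices.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    W_hat = np.atleast_2d(np.asarray(W_hat, dtype=float))
    idx = np.flatnonzero(np.linalg.norm(W_hat, axis=1) > epsilon)
    if feature_ids is None:
        return idx.tolist()
    return [feature_ids[i] for i in idx]


def aggregate_weight(W_row: np.ndarray) -> float:
    """Collapse a feature's per-visit weights to one signed value (mean)."""
    return float(np.mean(np.asarray(W_row, dtype=float)))


def importance(w: float) -> float:
    """|ln|w|| — the dimensionless importance of an aggregated weight.

    Undefined at w = 0 (such features must have been filtered out first).
    """
    if w == 0:
        raise ValueError("importance is undefined for w = 0; filter zero-weight features first")
    return abs(math.log(abs(w)))


def rank_features(entries: list[tuple[str, float]]) -> FeatureReport:
    """Rank (feature_id, w) pairs by importance, descending.

    Rank 1 is the largest |ln|w||; ties break lexicographically on
    feature_id.  Input order is irrelevant.
    """
    scored = [(fid, float(w), importance(w)) for fid, w in entries]
    scored.sort(key=lambda t: (-t[2], t[0]))
    return FeatureReport(
        entries=[
            FeatureEntry(feature_id=fid, w=w, importance=imp, rank=i + 1)
            for i, (fid, w, imp) in enumerate(scored)
        ]
    )


def build_report(
    W_hat: np.ndarray, feature_ids: list[str], epsilon: float = 1e-8
) -> FeatureReport:
    """Select, aggregate, and rank in one step."""
    W_hat = np.atleast_2d(np.asarray(W_hat, dtype=float))
    idx = select_features(W_hat, epsilon=epsilon)
    pairs = [(feature_ids[i], aggregate_weight(W_hat[i])) for i in idx]
    return rank_features(pairs)


def load_reference_features() -> pd.DataFrame:
    """The packaged 40-feature reference table (published ADNI selection).

    Columns: feature_id, atlas_index, short_name, hemisphere, property,
    w (signed aggregated weight), abs_ln_abs_w, rank.
    """
    ref = importlib.resources.files("adcascade.data") / "selected_features_reference.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)
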