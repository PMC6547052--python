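"""Weight-map summarization: region ranking and cross-fold aggregation.

Per-voxel kernel weights (or selection indicators) from many
cross-validation models are summarized at the level of atlas regions —
regions ranked by the mean absolute weight of their voxels, with the count
of selected voxels — and at the level of single features (selection
frequency and mean weight across models).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import FSModel

__all__ = [
    "AtlasLabels",
    "RegionRanking",
    "region_rank",
    "selection_frequency",
    "average_weights",
]


@dataclass
class AtlasLabels:
    """Integer region label per voxel column (0 = unlabeled) plus a name map."""

    labels: np.ndarray
    region_names: dict[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        present = set(np.unique(self.labels).tolist()) - {0}
        if any(r <= 0 for r in present):
            raise ValueError("region ids must be positive (0 = unlabeled)")
        missing = present - set(self.region_names)
        if missing:
            raise ValueError(f"region ids without a name: {sorted(missing)}")


@dataclass
class RegionRanking:
    """Regions sorted descending by mean |weight| (ties by region id)."""

    table: pd.DataFrame  # columns: region_id, region, mean_abs_weight, n_selected

    def top(self, n: int = 10) -> pd.DataFrame:
        return self.table.head(n)


def region_rank(weights: np.ndarray, atlas: AtlasLabels) -> RegionRanking:
    """Rank atlas regions by the average absolute weight of their voxels.

    A region's selected-voxel count is the number of its columns with a
    nonzero weight.  Unlabeled columns (id 0) and regions without columns
    are excluded.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.shape != atlas.labels.shape:
        raise ValueError(
            f"weights length {weights.shape} does not match atlas "
            f"{atlas.labels.shape}"
        )
    rows = []
    for rid in sorted(set(np.unique(atlas.labels).tolist()) - {0}):
        in_region = atlas.labels == rid
        w = weights[in_region]
        rows.append(
            {
                "region_id": rid,
                "region": atlas.region_names[rid],
                "mean_abs_weight": float(np.mean(np.abs(w))),
                "n_selected": int(np.count_nonzero(w)),
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(
            ["mean_abs_weight", "region_id"], ascending=[False, True]
        ).reset_index(drop=True)
    return RegionRanking(table=df)


def _selected_columns(model: FSModel, m: int) -> np.ndarray:
    if model.n_features_in != m:
        raise ValueError("models were trained on different feature spaces")
    return model.selected_columns


def selection_frequency(models: list[FSModel], m: int) -> np.ndarray:
    """Fraction of models in which each of the m features is selected."""
    if not models:
        raise ValueError("empty model list")
    counts = np.zeros(m)
    for mdl in models:
        counts[_selected_columns(mdl, m)] += 1
    return counts / len(models)


def average_weights(models: list[FSModel], m: int) -> np.ndarray:
    """Per-feature mean kernel weight η across models (zero where unselected)."""
    if not models:
        raise ValueError("empty model list")
    total = np.zeros(m)
    for mdl in models:
        total[_selected_columns(mdl, m)] += mdl.column_weights
    return total / len(models)
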