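"""Responsivity and repetition-suppression magnitude within preferred ROIs.

Responsivity to a block type is the median β across the voxels of the
category's own ("preferred") CS ROI; RS magnitude is the median of the
*voxelwise* difference β_different − β_same, which in general differs from
the difference of the two medians.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glm import BetaMap
from .roi import ROIDefinition, roi_voxel_rows

__all__ = ["MeasureRecord", "responsivity", "rs_magnitude", "records_to_frame"]


@dataclass(frozen=True)
class MeasureRecord:
    """One long-format dependent-measure observation."""

    participant_id: str
    group: str
    hemisphere: str
    measure: str
    value: float
    age: float = float("nan")
    category: str | None = None
    condition: str | None = None
    model_kind: str | None = None

    def __post_init__(self) -> None:
        if self.measure == "responsivity" and self.condition is None:
            raise ValueError("responsivity records need a condition")
        if self.measure == "model_fit" and self.model_kind is None:
            raise ValueError("model_fit records need a model kind")


def records_to_frame(records: list[MeasureRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "group": r.group,
                "hemisphere": r.hemisphere,
                "age": r.age,
                "measure": r.measure,
                "category": r.category if r.category is not None else pd.NA,
                "condition": r.condition if r.condition is not None else pd.NA,
                "model_kind": r.model_kind if r.model_kind is not None else pd.NA,
                "value": r.value,
            }
            for r in records
        ]
    )


def _roi_betas(adapt_betas: BetaMap, roi: ROIDefinition, label: str) -> np.ndarray:
    rows = roi_voxel_rows(adapt_betas, roi)
    return adapt_betas.beta(label)[rows]


def responsivity(
    adapt_betas: BetaMap,
    roi: ROIDefinition,
    category: str,
    condition: str,
    participant_id: str = "",
    group: str = "",
    hemisphere: str = "",
    age: float = float("nan"),
) -> MeasureRecord:
    """Median β for one block type within the preferred CS ROI."""
    if roi.category != category:
        raise ValueError(
            f"ROI is for {roi.category!r}, not the preferred ROI of {category!r}"
        )
    label = f"{category}_{condition}"
    if label not in adapt_betas.conditions:
        raise ValueError(f"block type {label!r} absent from BetaMap")
    value = float("nan") if roi.empty else float(np.median(_roi_betas(adapt_betas, roi, label)))
    return MeasureRecord(
        participant_id=participant_id,
        group=group,
        hemisphere=hemisphere or roi.hemisphere,
        measure="responsivity",
        value=value,
        age=age,
        category=category,
        condition=condition,
    )


def rs_magnitude(
    adapt_betas: BetaMap,
    roi: ROIDefinition,
    category: str,
    participant_id: str = "",
    group: str = "",
    hemisphere: str = "",
    age: float = float("nan"),
) -> MeasureRecord:
    """Median voxelwise β_different − β_same within the preferred CS ROI.

    Positive values indicate repetition suppression.
    """
    if roi.category != category:
        raise ValueError(
            f"ROI is for {roi.category!r}, not the preferred ROI of {category!r}"
        )
    for cond in ("different", "same"):
        if f"{category}_{cond}" not in adapt_betas.conditions:
            raise ValueError(f"block type {category}_{cond} absent from BetaMap")
    if roi.empty:
        value = float("nan")
    else:
        diff = _roi_betas(adapt_betas, roi, f"{category}_different")
        same = _roi_betas(adapt_betas, roi, f"{category}_same")
        value = float(np.median(diff - same))
    return MeasureRecord(
        participant_id=participant_id,
        group=group,
        hemisphere=hemisphere or roi.hemisphere,
        measure="rs_magnitude",
        value=value,
        age=age,
        category=category,
    )
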