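"""Per-ROI immunoreactivity quantification, normalization and grouping.

Immunoreactivity (IR) per ROI is the *integrated density*: the sum of
background-subtracted intensities over the ROI's pixels — a cumulative
measure that scales with both local concentration and punctum size.  Raw
integrated densities are normalized by the channel mean over the included
ROIs, and each ROI is assigned to one of three stratification groups by its
normalized IR: ``high`` (> 2x mean), ``low`` (< 0.5x mean), ``mid``
otherwise (boundary values fall in ``mid`` — the thresholds are strict
inequalities).  The "whole population" view used in downstream statistics
is all included ROIs, not a fourth disjoint group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import ChannelImage
from .segment import RoiSet

__all__ = [
    "IrTable",
    "integrated_density",
    "normalize_ir",
    "assign_groups",
    "build_ir_table",
]

HIGH_FACTOR = 2.0
LOW_FACTOR = 0.5


def integrated_density(image: ChannelImage, rois: RoiSet) -> np.ndarray:
    """Sum of background-subtracted intensities over each ROI's pixels.

    Every ROI must lie fully inside the image's valid region — edge ROIs
    are removed earlier in the pipeline, so overlap with invalid pixels
    indicates an ordering bug and raises.
    """
    if rois.label_image.shape != image.pixels.shape:
        raise ValueError("ROI label image and channel image shapes differ")
    if rois.n_rois == 0:
        return np.empty(0)
    invalid_labels = np.unique(rois.label_image[~image.valid_mask])
    if len(invalid_labels[invalid_labels > 0]):
        raise ValueError(
            "ROIs overlap invalid pixels; run edge-ROI removal before quantification"
        )
    return np.asarray(
        ndimage.sum_labels(image.pixels, rois.label_image, np.arange(1, rois.n_rois + 1))
    )


def normalize_ir(values: np.ndarray) -> np.ndarray:
    """Divide per-ROI values by their mean; the result has mean exactly 1."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("cannot normalize an empty value set")
    mean = values.mean()
    if mean <= 0:
        raise ValueError("mean integrated density must be positive")
    return values / mean


def assign_groups(normalized: np.ndarray) -> np.ndarray:
    """Label each ROI ``high`` (> 2), ``low`` (< 0.5) or ``mid``.

    Inequalities are strict, so values exactly at a threshold are ``mid``.
    Labels are scale-free by construction: they depend only on normalized
    values, which are invariant to rescaling the raw densities.
    """
    normalized = np.asarray(normalized, dtype=np.float64)
    out = np.full(normalized.shape, "mid", dtype=object)
    out[normalized > HIGH_FACTOR] = "high"
    out[normalized < LOW_FACTOR] = "low"
    return out.astype(str)


@dataclass
class IrTable:
    """Per-ROI integrated densities, normalized IR and group labels."""

    table: pd.DataFrame
    group_channel: str

    @property
    def groups(self) -> np.ndarray:
        return self.table["group"].to_numpy()

    def normalized(self, channel: str) -> np.ndarray:
        return self.table[f"{channel}_normalized_ir"].to_numpy()


def build_ir_table(
    rois: RoiSet,
    channels: dict[str, ChannelImage],
    group_channel: str | None = None,
) -> IrTable:
    """Quantify every channel over the ROI set and group by one channel.

    ``group_channel`` (default: the first channel) is the marker under
    test; any further channel serves the two-channel linearity control.
    """
    if not channels:
        raise ValueError("at least one channel is required")
    names = list(channels)
    group_channel = group_channel or names[0]
    if group_channel not in channels:
        raise KeyError(f"group_channel {group_channel!r} not among channels {names}")
    centroids = rois.centroids
    data: dict[str, np.ndarray] = {
        "roi_id": np.arange(1, rois.n_rois + 1),
        "area_px": rois.areas_px,
        "centroid_row": centroids[:, 0] if rois.n_rois else np.empty(0),
        "centroid_col": centroids[:, 1] if rois.n_rois else np.empty(0),
    }
    for name in names:
        raw = integrated_density(channels[name], rois)
        data[f"{name}_integrated_density"] = raw
        data[f"{name}_normalized_ir"] = normalize_ir(raw) if rois.n_rois else raw
    table = pd.DataFrame(data)
    table["group"] = (
        assign_groups(data[f"{group_channel}_normalized_ir"]) if rois.n_rois else np.empty(0, str)
    )
    return IrTable(table=table, group_channel=group_channel)
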