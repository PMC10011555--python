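"""Fiber and soma classification on the enhanced volumes.

Fiber voxels are segmented on the vesselness map with Li's minimum
cross-entropy threshold; the optional cell-body channel is binarized
with Yen's maximum-correlation criterion and subtracted, suppressing
lipofuscin-bright somata that survive the tubular enhancement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_li, threshold_yen

from .frangi3d import VesselnessResult


@dataclass
class MaskSet:
    """Fiber mask, optional soma mask and their combination
    (fiber AND NOT soma)."""

    fiber_mask: np.ndarray
    soma_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (self.soma_mask is not None
                and self.soma_mask.shape != self.fiber_mask.shape):
            raise ValueError("fiber and soma masks must be congruent")

    @property
    def combined(self) -> np.ndarray:
        if self.soma_mask is None:
            return self.fiber_mask
        return self.fiber_mask & ~self.soma_mask


@dataclass
class OrientationField:
    """Per-voxel axial unit vectors retained on the combined mask."""

    vectors: np.ndarray   # (..., 3), zero where mask is false
    mask: np.ndarray


def li_fiber_mask(v_map: np.ndarray) -> np.ndarray:
    """Binarize a vesselness (or enhanced intensity) map with Li's
    iterative minimum cross-entropy threshold, applied to the float
    values directly. A constant map yields an empty mask and a warning."""
    v_map = np.asarray(v_map)
    if v_map.min() == v_map.max():
        warnings.warn("constant map: no threshold exists, returning an "
                      "empty fiber mask", stacklevel=2)
        return np.zeros(v_map.shape, dtype=bool)
    return v_map > threshold_li(v_map)


def yen_soma_mask(soma_channel: np.ndarray | None) -> np.ndarray | None:
    """Binarize the cell-body channel with Yen's maximum-correlation
    threshold; ``None`` (channel absent) skips soma rejection, and a
    constant channel yields an empty mask."""
    if soma_channel is None:
        return None
    soma_channel = np.asarray(soma_channel)
    if soma_channel.min() == soma_channel.max():
        return np.zeros(soma_channel.shape, dtype=bool)
    return soma_channel > threshold_yen(soma_channel)


def apply_masks(orient: VesselnessResult, masks: MaskSet) -> OrientationField:
    """Retain orientation vectors only on the combined mask; voxels
    outside it (or without a defined orientation) are zeroed."""
    if masks.fiber_mask.shape != orient.vesselness.shape:
        raise ValueError("mask shape does not match the vesselness result")
    combined = masks.combined & (orient.scale_index >= 0)
    vectors = np.where(combined[..., None], orient.orientation, 0.0)
    return OrientationField(vectors.astype(np.float32), combined)
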