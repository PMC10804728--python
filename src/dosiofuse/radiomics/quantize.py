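"""Isotropic resampling and gray-level discretization.

Feature extraction operates on a 1 mm isotropic lattice (standardizing voxel
size across scanners and preserving the rotational structure of the texture
matrices) with in-ROI intensities discretized to a fixed number of gray
levels (fixed-bin-number rule, default 64).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..dicom_io import resample_to_reference
from ..grids import ROIMask, VolumeGrid

__all__ = ["QuantizedROI", "resample_isotropic", "discretize_fbn"]


@dataclass(frozen=True)
class QuantizedROI:
    """Discretized ROI: integer levels 1..n_levels inside the mask, 0 outside."""

    levels: np.ndarray  # int array, 0 = outside mask
    n_levels: int
    vmin: float
    vmax: float

    @property
    def mask(self) -> np.ndarray:
        return self.levels > 0

    def __post_init__(self) -> None:
        inside = self.levels[self.levels > 0]
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if inside.size and (inside.min() < 1 or inside.max() > self.n_levels):
            raise ValueError("in-mask levels must lie in [1, n_levels]")


def resample_isotropic(
    volume: VolumeGrid, mask: ROIMask, spacing: float = 1.0
) -> tuple[VolumeGrid, ROIMask]:
    """Resample volume (trilinear) and mask (nearest) to an isotropic lattice."""
    if mask.n_voxels == 0:
        raise ValueError("mask is empty")
    if np.allclose(volume.spacing, (spacing,) * 3):
        return volume, mask
    old = np.asarray(volume.spacing)  # (dx, dy, dz)
    shape_xyz = np.asarray(volume.shape)[::-1]
    new_shape_xyz = np.maximum(np.round(shape_xyz * old / spacing).astype(int), 1)
    reference = VolumeGrid(
        data=np.zeros(tuple(new_shape_xyz[::-1])),
        spacing=(spacing,) * 3,
        origin=volume.origin,
        orientation=volume.orientation,
        modality_tag="FUSED",
    )
    vol_rs = resample_to_reference(volume, reference, interpolation="trilinear")
    mask_vol = VolumeGrid(
        data=mask.data.astype(float), spacing=mask.spacing, origin=mask.origin,
        orientation=mask.orientation, modality_tag="FUSED",
    )
    mask_rs_data = resample_to_reference(mask_vol, reference, interpolation="nearest").data > 0.5
    if not mask_rs_data.any():
        raise ValueError("mask vanished after resampling; ROI smaller than target spacing")
    mask_rs = ROIMask(
        data=mask_rs_data, spacing=reference.spacing, origin=reference.origin,
        orientation=reference.orientation,
    )
    return vol_rs, mask_rs


def discretize_fbn(volume: VolumeGrid, mask: ROIMask, n_levels: int = 64) -> QuantizedROI:
    """Fixed-bin-number discretization over the ROI's own intensity range.

    ``level = min(Ng, floor(Ng * (x - min) / (max - min)) + 1)``; a constant
    ROI maps to all level 1."""
    if mask.n_voxels == 0:
        raise ValueError("mask is empty")
    m = mask.data
    vals = volume.data[m]
    vmin, vmax = float(vals.min()), float(vals.max())
    levels = np.zeros(volume.shape, dtype=np.int32)
    if vmax - vmin < 1e-12:
        levels[m] = 1
    else:
        scaled = np.floor(n_levels * (volume.data[m] - vmin) / (vmax - vmin)).astype(np.int32) + 1
        levels[m] = np.minimum(scaled, n_levels)
    return QuantizedROI(levels=levels, n_levels=n_levels, vmin=vmin, vmax=vmax)
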