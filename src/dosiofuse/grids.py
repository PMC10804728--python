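"""Core volumetric containers.

A :class:`VolumeGrid` is a 3D scalar field (CT in HU, planned dose in Gy, or
unitless fused intensities) on a regular lattice described by voxel spacing,
an origin and direction cosines in the DICOM patient (LPS) coordinate frame.
Array axes are ordered ``(z, y, x)`` — slice, row, column — matching the
DICOM slice stacking convention; voxel indices are 0-based and refer to voxel
centers.

A :class:`ROIMask` is a boolean field on the same lattice marking a region of
interest (typically the gross tumor volume, GTV).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["VolumeGrid", "ROIMask", "ContourSet", "save_sidecar", "load_sidecar"]


def _identity_orientation() -> np.ndarray:
    return np.eye(3)


@dataclass(frozen=True)
class VolumeGrid:
    """A 3D scalar field with geometry.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Voxel values, axes ordered slice/row/column.
    spacing : tuple of float
        ``(dx, dy, dz)`` voxel spacing in mm, all positive.
    origin : tuple of float
        Patient-space (LPS) coordinates of the center of voxel (0, 0, 0), mm.
    orientation : ndarray, shape (3, 3)
        Direction cosines; columns are the patient-space directions of the
        x (column), y (row) and z (slice) index axes.
    modality_tag : str
        One of ``CT``, ``DOSE``, ``FUSED``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: np.ndarray = field(default_factory=_identity_orientation)
    modality_tag: str = "CT"

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        object.__setattr__(self, "orientation", np.asarray(self.orientation, dtype=float))
        if data.ndim != 3 or min(data.shape) < 1:
            raise ValueError(f"VolumeGrid data must be a non-empty 3D array, got shape {data.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be positive, got {self.spacing}")
        if self.orientation.shape != (3, 3):
            raise ValueError("orientation must be a 3x3 direction-cosine matrix")
        if self.modality_tag not in ("CT", "DOSE", "FUSED"):
            raise ValueError(f"unknown modality_tag {self.modality_tag!r}")
        if self.modality_tag == "CT" and not np.all(np.isfinite(data)):
            raise ValueError("CT volume contains non-finite values")
        if self.modality_tag == "DOSE" and data.size and np.nanmin(data) < 0:
            raise ValueError("DOSE volume contains negative values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mm^3."""
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def same_lattice(self, other: "VolumeGrid | ROIMask", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.orientation, other.orientation, atol=atol)
        )

    def index_to_patient(self, indices: np.ndarray) -> np.ndarray:
        """Map fractional voxel indices ``(k, j, i)`` to patient (LPS) mm."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        # column order of `orientation` is (x, y, z) axes; indices come (z,y,x)
        xyz_idx = idx[:, ::-1]
        scaled = xyz_idx * np.asarray(self.spacing)
        pts = scaled @ self.orientation.T + np.asarray(self.origin)
        return pts if np.asarray(indices).ndim > 1 else pts[0]

    def patient_to_index(self, points: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`index_to_patient`; returns fractional (k, j, i)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float)) - np.asarray(self.origin)
        inv = np.linalg.inv(self.orientation)
        xyz_idx = (pts @ inv.T) / np.asarray(self.spacing)
        kji = xyz_idx[:, ::-1]
        return kji if np.asarray(points).ndim > 1 else kji[0]

    def with_data(self, data: np.ndarray, modality_tag: str | None = None) -> "VolumeGrid":
        return replace(self, data=data, modality_tag=modality_tag or self.modality_tag)


@dataclass(frozen=True)
class ROIMask:
    """Boolean ROI mask on a reference lattice (same geometry fields as VolumeGrid)."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: np.ndarray = field(default_factory=_identity_orientation)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=bool)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        object.__setattr__(self, "orientation", np.asarray(self.orientation, dtype=float))
        if data.ndim != 3:
            raise ValueError("ROIMask data must be 3D")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def same_lattice(self, other, atol: float = 1e-6) -> bool:
        return VolumeGrid.same_lattice(self, other, atol=atol)  # type: ignore[arg-type]

    index_to_patient = VolumeGrid.index_to_patient
    patient_to_index = VolumeGrid.patient_to_index

    @classmethod
    def from_grid(cls, reference: VolumeGrid, data: np.ndarray) -> "ROIMask":
        return cls(data=data, spacing=reference.spacing, origin=reference.origin,
                   orientation=reference.orientation)


class ContourSet:
    """Named planar polygons in patient coordinates, grouped by ROI name.

    Each polygon is an (n, 3) array of vertices; all vertices of one polygon
    lie on one axial plane (shared z within tolerance).
    """

    def __init__(self, contours: dict[str, list[np.ndarray]] | None = None):
        self._contours: dict[str, list[np.ndarray]] = {}
        for name, polys in (contours or {}).items():
            for poly in polys:
                self.add(name, poly)

    def add(self, roi_name: str, polygon: np.ndarray) -> None:
        poly = np.asarray(polygon, dtype=float)
        if poly.ndim != 2 or poly.shape[1] != 3 or poly.shape[0] < 3:
            raise ValueError("polygon must be an (n>=3, 3) array of patient-space vertices")
        if np.ptp(poly[:, 2]) > 1e-3:
            raise ValueError("polygon vertices must share one axial plane")
        self._contours.setdefault(roi_name, []).append(poly)

    @property
    def roi_names(self) -> list[str]:
        return sorted(self._contours)

    def polygons(self, roi_name: str) -> list[np.ndarray]:
        if roi_name not in self._contours:
            raise KeyError(
                f"ROI {roi_name!r} not found; available ROIs: {self.roi_names}"
            )
        return self._contours[roi_name]

    def __len__(self) -> int:
        return sum(len(v) for v in self._contours.values())


def save_sidecar(path: str | Path, volume: VolumeGrid | ROIMask, name: str = "volume") -> None:
    """Write a volume or mask as a compressed .npz plus a JSON geometry sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path.with_suffix(".npz"), data=volume.data)
    meta = {
        "name": name,
        "kind": "mask" if isinstance(volume, ROIMask) else "volume",
        "spacing": list(volume.spacing),
        "origin": list(volume.origin),
        "orientation": np.asarray(volume.orientation).tolist(),
    }
    if isinstance(volume, VolumeGrid):
        meta["modality_tag"] = volume.modality_tag
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_sidecar(path: str | Path) -> VolumeGrid | ROIMask:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    data = np.load(path.with_suffix(".npz"))["data"]
    common = dict(
        data=data,
        spacing=tuple(meta["spacing"]),
        origin=tuple(meta["origin"]),
        orientation=np.asarray(meta["orientation"]),
    )
    if meta["kind"] == "mask":
        return ROIMask(**common)
    return VolumeGrid(modality_tag=meta.get("modality_tag", "CT"), **common)
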