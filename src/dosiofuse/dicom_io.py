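"""DICOM ingestion and lattice operations.

Reads a planning CT series, an RTDOSE grid and RTSTRUCT contours; places the
dose on the CT lattice using header geometry only (no image registration, per
the DICOM location tags); rasterizes GTV contours to a voxel mask; crops
volume and mask to the ROI bounding box.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pydicom
from matplotlib.path import Path as MplPath
from scipy import ndimage

from .grids import ContourSet, ROIMask, VolumeGrid

__all__ = [
    "read_ct_series",
    "read_rtdose",
    "read_rtstruct",
    "resample_to_reference",
    "rasterize_contours",
    "crop_to_roi",
]


def _orientation_from_iop(iop, normal=None) -> np.ndarray:
    row = np.asarray(iop[:3], dtype=float)   # direction of increasing column (x index)
    col = np.asarray(iop[3:], dtype=float)   # direction of increasing row (y index)
    if normal is None:
        normal = np.cross(row, col)
    # columns of the matrix are the patient directions of (x, y, z) index axes
    return np.stack([row, col, np.asarray(normal, float)], axis=1)


def read_ct_series(directory_path: str | Path) -> VolumeGrid:
    """Read one axial CT series from a directory into a HU volume.

    Slices are sorted by their position along the slice normal; rescale
    slope/intercept are applied so voxel values are Hounsfield units.

    Raises
    ------
    ValueError
        If the directory mixes series UIDs, or slice positions are missing /
        duplicated (the error reports the gap location).
    """
    directory_path = Path(directory_path)
    files = sorted(p for p in directory_path.iterdir() if p.is_file())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if getattr(ds, "Modality", None) == "CT":
            slices.append(ds)
    if not slices:
        raise ValueError(f"no CT slices found in {directory_path}")
    uids = {ds.SeriesInstanceUID for ds in slices}
    if len(uids) > 1:
        raise ValueError(f"directory mixes {len(uids)} CT series UIDs: {sorted(uids)}")

    iop = slices[0].ImageOrientationPatient
    normal = np.cross(np.asarray(iop[:3], float), np.asarray(iop[3:], float))
    slices.sort(key=lambda ds: float(np.dot(normal, np.asarray(ds.ImagePositionPatient, float))))

    positions = np.array(
        [np.dot(normal, np.asarray(ds.ImagePositionPatient, float)) for ds in slices]
    )
    gaps = np.diff(positions)
    if len(gaps):
        if np.any(gaps < 1e-6):
            raise ValueError("duplicate slice positions in CT series")
        median_gap = float(np.median(gaps))
        bad = np.nonzero(np.abs(gaps - median_gap) > 0.5 * median_gap)[0]
        if bad.size:
            missing_at = positions[bad[0]] + median_gap
            raise ValueError(
                f"missing CT slice: expected a slice near position {missing_at:.2f} mm "
                f"(gap of {gaps[bad[0]]:.2f} mm vs. median {median_gap:.2f} mm)"
            )
        dz = median_gap
    else:
        dz = float(getattr(slices[0], "SliceThickness", 1.0))

    arrays = []
    for ds in slices:
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arrays.append(arr * slope + intercept)
    data = np.stack(arrays, axis=0)
    if min(data.shape) < 2:
        raise ValueError(f"CT series is degenerate: shape {data.shape}")
    dy, dx = (float(v) for v in slices[0].PixelSpacing)
    origin = tuple(float(v) for v in slices[0].ImagePositionPatient)
    return VolumeGrid(
        data=data,
        spacing=(dx, dy, dz),
        origin=origin,
        orientation=_orientation_from_iop(iop, normal),
        modality_tag="CT",
    )


def read_rtdose(file_path: str | Path) -> VolumeGrid:
    """Read an RTDOSE file into a Gy volume (grid scaling applied)."""
    ds = pydicom.dcmread(str(file_path))
    if getattr(ds, "DoseGridScaling", None) in (None, ""):
        raise ValueError("RTDOSE is missing DoseGridScaling")
    scaling = float(ds.DoseGridScaling)
    data = ds.pixel_array.astype(float) * scaling
    if data.ndim == 2:
        data = data[None]
    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector], dtype=float)
    if len(offsets) >= 2:
        steps = np.diff(offsets)
        if np.ptp(steps) > 1e-3 * max(abs(steps).max(), 1.0):
            raise ValueError(f"non-uniform GridFrameOffsetVector steps: {steps}")
        dz = float(abs(steps[0]))
        sign = float(np.sign(steps[0]))
    else:
        dz, sign = 1.0, 1.0
    dy, dx = (float(v) for v in ds.PixelSpacing)
    iop = ds.ImageOrientationPatient
    normal = sign * np.cross(np.asarray(iop[:3], float), np.asarray(iop[3:], float))
    origin = tuple(float(v) for v in ds.ImagePositionPatient)
    return VolumeGrid(
        data=data,
        spacing=(dx, dy, dz),
        origin=origin,
        orientation=_orientation_from_iop(iop, normal),
        modality_tag="DOSE",
    )


def read_rtstruct(file_path: str | Path) -> ContourSet:
    """Read RTSTRUCT contours into a :class:`ContourSet` (patient coordinates)."""
    ds = pydicom.dcmread(str(file_path))
    names = {
        int(item.ROINumber): str(item.ROIName)
        for item in ds.StructureSetROISequence
    }
    contours = ContourSet()
    for roi in getattr(ds, "ROIContourSequence", []):
        name = names.get(int(roi.ReferencedROINumber), str(roi.ReferencedROINumber))
        for contour in getattr(roi, "ContourSequence", []):
            pts = np.asarray([float(v) for v in contour.ContourData]).reshape(-1, 3)
            contours.add(name, pts)
    return contours


def resample_to_reference(
    moving: VolumeGrid,
    reference: VolumeGrid,
    interpolation: str = "trilinear",
) -> VolumeGrid:
    """Resample ``moving`` onto the lattice of ``reference`` via header geometry.

    Voxels of the reference lattice outside the moving grid's support are
    filled with 0 (physically, for dose: no dose recorded there).
    """
    if interpolation not in ("trilinear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    if abs(np.linalg.det(np.asarray(moving.orientation))) < 1e-9:
        raise ValueError("degenerate orientation matrix on moving grid")
    order = 1 if interpolation == "trilinear" else 0

    nz, ny, nx = reference.shape
    kk, jj, ii = np.meshgrid(
        np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
    )
    idx = np.stack([kk.ravel(), jj.ravel(), ii.ravel()], axis=1).astype(float)
    pts = reference.index_to_patient(idx)
    mov_idx = moving.patient_to_index(pts)  # fractional (k, j, i)
    coords = mov_idx.T.reshape(3, nz, ny, nx)
    out = ndimage.map_coordinates(
        moving.data, coords, order=order, mode="constant", cval=0.0, prefilter=False
    )
    return VolumeGrid(
        data=out,
        spacing=reference.spacing,
        origin=reference.origin,
        orientation=reference.orientation,
        modality_tag=moving.modality_tag,
    )


def rasterize_contours(
    contours: ContourSet, roi_name: str, reference: VolumeGrid
) -> ROIMask:
    """Rasterize planar contours of one ROI onto the reference lattice.

    A voxel is true iff its center lies inside the polygon on its slice
    (even-odd rule); multiple polygons on one slice are unioned.
    """
    try:
        polys = contours.polygons(roi_name)
    except KeyError as exc:
        raise ValueError(str(exc)) from exc
    if not polys:
        raise ValueError(f"ROI {roi_name!r} has no contours")

    nz, ny, nx = reference.shape
    mask = np.zeros(reference.shape, dtype=bool)
    dz = reference.spacing[2]
    jj, ii = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    for poly in polys:
        # map all vertices into index space; slice index from the shared plane
        kji = reference.patient_to_index(poly)
        k_f = float(np.mean(kji[:, 0]))
        k = int(round(k_f))
        if not (0 <= k < nz) or abs(k_f - k) > 0.5 + 1e-9:
            # plane does not land on a reference slice within half a thickness
            raise ValueError(
                f"contour plane at fractional slice {k_f:.3f} does not map onto a "
                f"reference slice within half a slice thickness ({dz / 2:.2f} mm)"
            )
        verts_xy = kji[:, ::-1][:, :2]  # (i, j) in index units
        path = MplPath(verts_xy)
        lo = np.maximum(np.floor(verts_xy.min(axis=0)).astype(int), 0)
        hi = np.minimum(np.ceil(verts_xy.max(axis=0)).astype(int) + 1, [nx, ny])
        sub_i = ii[lo[1]:hi[1], lo[0]:hi[0]]
        sub_j = jj[lo[1]:hi[1], lo[0]:hi[0]]
        pts = np.stack([sub_i.ravel(), sub_j.ravel()], axis=1).astype(float)
        inside = path.contains_points(pts, radius=1e-9)
        mask[k, lo[1]:hi[1], lo[0]:hi[0]] |= inside.reshape(sub_i.shape)
    return ROIMask.from_grid(reference, mask)


def crop_to_roi(
    volume: VolumeGrid, mask: ROIMask, margin_voxels: int = 0
) -> tuple[VolumeGrid, ROIMask]:
    """Crop volume and mask to the mask's bounding box plus a voxel margin.

    The crop is clipped to the volume bounds and the origin updated so voxel
    patient coordinates are preserved.
    """
    if not volume.same_lattice(mask):
        raise ValueError("volume and mask must share one lattice")
    if mask.n_voxels == 0:
        raise ValueError("cannot crop to an empty mask")
    nz, ny, nx = volume.shape
    idx = np.nonzero(mask.data)
    lo = [max(int(a.min()) - margin_voxels, 0) for a in idx]
    hi = [min(int(a.max()) + margin_voxels + 1, n) for a, n in zip(idx, (nz, ny, nx))]
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    new_origin = tuple(volume.index_to_patient(np.asarray(lo, dtype=float)))
    cropped_vol = VolumeGrid(
        data=volume.data[sl],
        spacing=volume.spacing,
        origin=new_origin,
        orientation=volume.orientation,
        modality_tag=volume.modality_tag,
    )
    cropped_mask = ROIMask(
        data=mask.data[sl],
        spacing=mask.spacing,
        origin=new_origin,
        orientation=mask.orientation,
    )
    return cropped_vol, cropped_mask
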