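"""Synthetic phantoms and survival cohorts.

Two generators make every downstream stage testable without clinical data:

* :func:`make_phantom_pair` builds a co-registered CT-like volume (soft-tissue
  background around 0-80 HU with a textured spherical "tumor"), a dose-like
  volume (smooth peak around a 70 Gy prescription centered on the tumor) and
  the spherical GTV mask.
* :func:`simulate_cohort` draws multi-center survival cohorts from a
  Cox-Weibull model with known coefficients, per-center feature-distribution
  shifts (mimicking inter-center heterogeneity) and independent uniform
  censoring calibrated to a requested rate.

All randomness derives from a single seed fanned out to per-component child
seeds through ``numpy.random.SeedSequence`` spawn keys.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import ROIMask, VolumeGrid

__all__ = ["SyntheticCohort", "make_phantom_pair", "simulate_cohort", "write_dicom_fixture"]

PRESCRIPTION_GY = 70.0  # typical prescribed total dose for head-and-neck RT


@dataclass
class SyntheticCohort:
    """A multi-center survival cohort with known feature-hazard structure.

    Attributes
    ----------
    features : DataFrame, shape (n, p)
        Covariates (standard normal, optionally center-shifted).
    time, event : ndarray
        Observed follow-up in days and event indicator (1=dead, 0=censored).
    center : ndarray of str
        Center label per patient.
    linear_predictor : ndarray
        Ground-truth beta . x per patient (exact).
    beta : ndarray
        True coefficient vector.
    baseline : tuple (shape k, scale lam) of the Weibull baseline.
    censor_rate : float
        Requested censoring fraction.
    """

    features: pd.DataFrame
    time: np.ndarray
    event: np.ndarray
    center: np.ndarray
    linear_predictor: np.ndarray
    beta: np.ndarray
    baseline: tuple[float, float]
    censor_rate: float
    seed: int | None = None
    informative: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.time)

    def to_frame(self) -> pd.DataFrame:
        df = self.features.copy()
        df["time"] = self.time
        df["event"] = self.event
        df["center"] = self.center
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SyntheticCohort":
        meta = ["time", "event", "center"]
        feats = df.drop(columns=meta)
        return cls(
            features=feats,
            time=df["time"].to_numpy(float),
            event=df["event"].to_numpy(int),
            center=df["center"].to_numpy(str),
            linear_predictor=np.full(len(df), np.nan),
            beta=np.full(feats.shape[1], np.nan),
            baseline=(np.nan, np.nan),
            censor_rate=np.nan,
        )


def _child_rng(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(key + 1)[key])


def make_phantom_pair(
    shape: tuple[int, int, int] = (32, 32, 32),
    tumor_radius_mm: float = 8.0,
    texture_mode: str = "speckle",
    seed: int = 0,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> tuple[VolumeGrid, VolumeGrid, ROIMask]:
    """Build a co-registered (CT, dose, GTV mask) triple.

    Parameters
    ----------
    shape : (nz, ny, nx), each >= 16.
    tumor_radius_mm : sphere radius; must fit inside the volume.
    texture_mode : {'uniform', 'speckle', 'gradient'}
        Tumor interior texture: one constant HU value, voxelwise speckle
        noise, or a linear intensity ramp.
    seed : deterministic outputs for equal seeds.
    """
    if min(shape) < 16:
        raise ValueError(f"shape must be >= (16,16,16), got {shape}")
    if texture_mode not in ("uniform", "speckle", "gradient"):
        raise ValueError(f"unknown texture_mode {texture_mode!r}")
    dx, dy, dz = spacing
    half_extent = min(
        shape[0] * dz, shape[1] * dy, shape[2] * dx
    ) / 2.0
    if tumor_radius_mm >= half_extent:
        raise ValueError(
            f"tumor radius {tumor_radius_mm} mm does not fit inside the "
            f"volume (half-extent {half_extent:.1f} mm)"
        )
    rng = _child_rng(seed, 0)
    nz, ny, nx = shape
    zz, yy, xx = np.meshgrid(
        (np.arange(nz) - (nz - 1) / 2) * dz,
        (np.arange(ny) - (ny - 1) / 2) * dy,
        (np.arange(nx) - (nx - 1) / 2) * dx,
        indexing="ij",
    )
    r = np.sqrt(xx**2 + yy**2 + zz**2)
    gtv = r <= tumor_radius_mm

    # soft-tissue background ~0-80 HU with mild smooth variation + noise
    background = 40.0 + 20.0 * np.sin(xx / 17.0) * np.cos(yy / 13.0) + rng.normal(0, 4, shape)
    ct = background
    if texture_mode == "uniform":
        ct = np.where(gtv, 60.0, ct)
    elif texture_mode == "speckle":
        speckle = 55.0 + rng.normal(0, 12, shape)
        ct = np.where(gtv, speckle, ct)
    else:  # gradient
        ramp = 30.0 + 50.0 * (xx - xx.min()) / max(np.ptp(xx), 1e-9)
        ct = np.where(gtv, ramp, ct)

    # smooth dose peak at prescription level, Gaussian fall-off beyond the GTV
    sigma = max(tumor_radius_mm * 1.5, 1.0)
    dose = PRESCRIPTION_GY * np.exp(-np.maximum(r - tumor_radius_mm, 0.0) ** 2 / (2 * sigma**2))

    origin = (0.0, 0.0, 0.0)
    ct_grid = VolumeGrid(ct, spacing=spacing, origin=origin, modality_tag="CT")
    dose_grid = VolumeGrid(dose, spacing=spacing, origin=origin, modality_tag="DOSE")
    mask = ROIMask.from_grid(ct_grid, gtv)
    return ct_grid, dose_grid, mask


def simulate_cohort(
    n_per_center: list[int],
    beta: np.ndarray,
    baseline: tuple[float, float] = (1.2, 1000.0),
    censor_rate: float = 0.3,
    seed: int = 0,
    center_shift_sd: float = 0.0,
    feature_names: list[str] | None = None,
    min_center_size: int = 2,
) -> SyntheticCohort:
    """Draw a multi-center cohort from a Cox-Weibull model.

    Event times follow ``T = lam * (-log U / exp(beta.x)) ** (1/k)`` with
    Weibull baseline ``(k, lam)``; censoring times are uniform on
    ``(0, c_max)`` with ``c_max`` calibrated so the expected censored
    fraction matches ``censor_rate``.

    Parameters
    ----------
    n_per_center : patients per center; centers are labelled C1..CK.
    beta : coefficient vector; its length fixes the feature count.
    baseline : Weibull shape k and scale lam (days), both > 0.
    censor_rate : fraction in [0, 1).
    center_shift_sd : SD of per-center feature-mean shifts (distribution
        shift only; the hazard model itself is shared across centers).
    """
    k, lam = baseline
    if k <= 0 or lam <= 0:
        raise ValueError(f"Weibull parameters must be positive, got k={k}, lam={lam}")
    if not (0 <= censor_rate < 1):
        raise ValueError(f"censor_rate must be in [0, 1), got {censor_rate}")
    if any(n < min_center_size for n in n_per_center):
        raise ValueError(f"every center must have >= {min_center_size} patients")
    beta = np.asarray(beta, dtype=float)
    p = beta.size
    n_total = int(sum(n_per_center))
    names = feature_names or [f"f{i:03d}" for i in range(p)]

    rng_x = _child_rng(seed, 0)
    rng_t = _child_rng(seed, 1)
    rng_c = _child_rng(seed, 2)

    centers = np.concatenate(
        [np.full(n, f"C{i + 1}") for i, n in enumerate(n_per_center)]
    )
    X = rng_x.standard_normal((n_total, p))
    if center_shift_sd > 0:
        shifts = rng_x.normal(0, center_shift_sd, size=(len(n_per_center), p))
        start = 0
        for i, n in enumerate(n_per_center):
            X[start:start + n] += shifts[i]
            start += n

    eta = X @ beta
    u = rng_t.uniform(size=n_total)
    t_event = lam * (-np.log(u) / np.exp(eta)) ** (1.0 / k)

    if censor_rate == 0:
        time, event = t_event, np.ones(n_total, dtype=int)
    else:
        c_max = _calibrate_censor_horizon(k, lam, eta, censor_rate)
        t_cens = rng_c.uniform(0, c_max, size=n_total)
        event = (t_event <= t_cens).astype(int)
        time = np.minimum(t_event, t_cens)
    time = np.maximum(time, 1e-8)

    return SyntheticCohort(
        features=pd.DataFrame(X, columns=names),
        time=time,
        event=event,
        center=centers,
        linear_predictor=eta,
        beta=beta,
        baseline=(float(k), float(lam)),
        censor_rate=float(censor_rate),
        seed=seed,
        informative=[names[i] for i in np.nonzero(beta)[0]],
    )


def _calibrate_censor_horizon(k: float, lam: float, eta: np.ndarray, rate: float) -> float:
    """Find c_max so that P(censored) = E_x P(T > C), C ~ U(0, c_max), equals `rate`.

    P(censored | x) = (1/c_max) * int_0^c_max S(t|x) dt, computed by quadrature
    and solved by bisection on c_max.
    """
    from scipy.integrate import quad
    from scipy.optimize import brentq

    haz_mult = np.exp(eta)
    # subsample for speed; calibration needs only the mixture expectation
    if haz_mult.size > 400:
        haz_mult = haz_mult[:: max(1, haz_mult.size // 400)]

    def censored_prob(c_max: float) -> float:
        def surv_mixture(t: float) -> float:
            return float(np.mean(np.exp(-haz_mult * (t / lam) ** k)))

        integral, _ = quad(surv_mixture, 0, c_max, limit=100)
        return integral / c_max

    lo, hi = 1e-6 * lam, 1e4 * lam
    # censored_prob decreases in c_max from ~1 to ~0
    return brentq(lambda c: censored_prob(c) - rate, lo, hi, xtol=1e-3 * lam)


def write_dicom_fixture(
    out_dir: str | Path,
    ct: VolumeGrid,
    dose: VolumeGrid | None = None,
    gtv_contours: list[np.ndarray] | None = None,
    roi_name: str = "GTV",
    rescale_intercept: float = -1024.0,
) -> dict[str, Path]:
    """Write a minimal CT series (one file per slice) plus optional RTDOSE and
    RTSTRUCT, for ingestion tests. Axis-aligned geometry only."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {"ct_dir": out_dir / "ct"}
    paths["ct_dir"].mkdir(exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    frame_uid = generate_uid()
    dx, dy, dz = ct.spacing
    ox, oy, oz = ct.origin

    def _base(modality: str, sop_class: str) -> FileDataset:
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = sop_class
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = sop_class
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = modality
        ds.PatientName = "Phantom^Synthetic"
        ds.PatientID = "PHANTOM"
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = frame_uid
        return ds

    ct_sop = "1.2.840.10008.5.1.4.1.1.2"
    stored = np.round(ct.data - rescale_intercept).astype(np.uint16)
    for k in range(ct.shape[0]):
        ds = _base("CT", ct_sop)
        ds.SeriesInstanceUID = series_uid
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [ox, oy, oz + k * dz]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [dy, dx]
        ds.SliceThickness = dz
        ds.Rows, ds.Columns = ct.shape[1], ct.shape[2]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = rescale_intercept
        ds.PixelData = stored[k].tobytes()
        path = paths["ct_dir"] / f"ct_{k:03d}.dcm"
        ds.save_as(str(path), enforce_file_format=True)

    if dose is not None:
        ds = _base("RTDOSE", "1.2.840.10008.5.1.4.1.1.481.2")
        ds.SeriesInstanceUID = generate_uid()
        scaling = max(float(dose.data.max()), 1e-6) / 60000.0
        ds.DoseGridScaling = scaling
        ds.DoseUnits = "GY"
        ds.DoseSummationType = "PLAN"
        ds.ImagePositionPatient = list(dose.origin)
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [dose.spacing[1], dose.spacing[0]]
        ds.GridFrameOffsetVector = [k * dose.spacing[2] for k in range(dose.shape[0])]
        ds.NumberOfFrames = dose.shape[0]
        ds.Rows, ds.Columns = dose.shape[1], dose.shape[2]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = np.round(dose.data / scaling).astype(np.uint16).tobytes()
        paths["dose"] = out_dir / "rtdose.dcm"
        ds.save_as(str(paths["dose"]), enforce_file_format=True)

    if gtv_contours is not None:
        from pydicom.dataset import Dataset

        ds = _base("RTSTRUCT", "1.2.840.10008.5.1.4.1.1.481.3")
        ds.SeriesInstanceUID = generate_uid()
        roi = Dataset()
        roi.ROINumber = 1
        roi.ROIName = roi_name
        roi.ReferencedFrameOfReferenceUID = frame_uid
        ds.StructureSetROISequence = [roi]
        roi_contour = Dataset()
        roi_contour.ReferencedROINumber = 1
        seq = []
        for poly in gtv_contours:
            c = Dataset()
            c.ContourGeometricType = "CLOSED_PLANAR"
            c.NumberOfContourPoints = len(poly)
            c.ContourData = [float(v) for v in np.asarray(poly).ravel()]
            seq.append(c)
        roi_contour.ContourSequence = seq
        ds.ROIContourSequence = [roi_contour]
        paths["struct"] = out_dir / "rtstruct.dcm"
        ds.save_as(str(paths["struct"]), enforce_file_format=True)

    return paths
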