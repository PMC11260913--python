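"""Volumetric CT input/output and CT-number ↔ density conversion.

A reconstructed CT volume assigns each voxel a CT number (CTN) derived from
the material's linear X-ray attenuation coefficient μ relative to water and
air,

    CTN_HU = 1000 · (μ − μw) / (μw − μa),

so water maps to 0 HU and air to −1000 HU.  Clinical scanners store these
values with a fixed positive offset so that air sits near 0 stored units and
water near the offset (default 1024).  For cheese densitometry the stored
value is converted to an apparent density in kg/m³ by subtracting that
offset,

    ρ = CTN_stored − offset,

which places the cheese protein/fat matrix at roughly 1100–1200 kg/m³ and
leaves background air near zero — the convention every downstream threshold
in this package assumes.  The offset is configurable; rescale slope and
intercept found in DICOM headers are recorded in the metadata but never
silently applied.

Two on-disk formats are supported: a DICOM series (one file per slice) and a
raster-plus-sidecar pair (``.npy`` array next to a ``.json`` holding shape,
spacing and scan metadata).  Both round-trip integer CT volumes losslessly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

__all__ = [
    "ScanMeta",
    "ScanVolume",
    "DensityVolume",
    "AttenuationCoefficients",
    "CalibrationError",
    "IngestError",
    "attenuation_to_ctn",
    "ctn_to_density",
    "density_to_ctn",
    "scan_to_density",
    "read_volume",
    "write_volume",
]

DEFAULT_CTN_OFFSET = 1024.0

_CT_IMAGE_STORAGE = "1.2.840.10008.5.1.4.1.1.2"


class CalibrationError(ValueError):
    """Raised when attenuation calibration constants are physically invalid."""


class IngestError(RuntimeError):
    """Raised when a volume on disk is incomplete or inconsistent.

    Attributes
    ----------
    missing : list of int
        Slice indices that were expected but not found (empty when the
        failure is not a gap).
    """

    def __init__(self, message: str, missing: list[int] | None = None):
        super().__init__(message)
        self.missing = list(missing or [])


@dataclass
class ScanMeta:
    """Identity of a scanned wheel: which cheese, which batch, how old."""

    cheese_id: str = "unknown"
    batch_id: str = "unknown"
    age_days: int = 0
    source: str = ""
    rescale_slope: float | None = None
    rescale_intercept: float | None = None

    def __post_init__(self):
        if self.age_days < 0:
            raise ValueError(f"age_days must be >= 0, got {self.age_days}")


@dataclass
class ScanVolume:
    """3D integer CT-number grid.

    ``ctn`` is indexed ``(slice, row, column)``; ``spacing`` is the matching
    physical step ``(dz, dy, dx)`` in mm, with ``dz`` the slice thickness
    used for 2D→3D volume extrapolation.  Voxel physical position is
    ``index × spacing`` (0-based).
    """

    ctn: np.ndarray
    spacing: tuple[float, float, float]
    meta: ScanMeta = field(default_factory=ScanMeta)

    def __post_init__(self):
        self.ctn = np.asarray(self.ctn)
        if self.ctn.ndim != 3 or min(self.ctn.shape) < 1:
            raise ValueError("ctn must be a 3D array with >=1 voxel per axis")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")

    @property
    def voxel_volume_mm3(self) -> float:
        dz, dy, dx = self.spacing
        return dx * dy * dz


@dataclass
class DensityVolume:
    """3D apparent-density grid in kg/m³, same shape/spacing as its source scan."""

    rho: np.ndarray
    spacing: tuple[float, float, float]
    meta: ScanMeta = field(default_factory=ScanMeta)

    def __post_init__(self):
        self.rho = np.asarray(self.rho, dtype=float)
        if self.rho.ndim != 3:
            raise ValueError("rho must be a 3D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")


@dataclass
class AttenuationCoefficients:
    """Linear attenuation coefficients (1/m) for a material, water and air."""

    mu: float
    mu_w: float
    mu_a: float

    def __post_init__(self):
        if self.mu < 0 or self.mu_a < 0 or self.mu_w <= 0:
            raise CalibrationError(
                "attenuation coefficients must be nonnegative (mu_w > 0)"
            )
        if self.mu_w <= self.mu_a:
            raise CalibrationError(
                f"water attenuation ({self.mu_w}) must exceed air ({self.mu_a})"
            )


def attenuation_to_ctn(coeffs: AttenuationCoefficients) -> float:
    """Hounsfield-scale CT number of a material: 1000·(μ − μw)/(μw − μa)."""
    if not isinstance(coeffs, AttenuationCoefficients):
        coeffs = AttenuationCoefficients(*coeffs)
    return 1000.0 * (coeffs.mu - coeffs.mu_w) / (coeffs.mu_w - coeffs.mu_a)


def ctn_to_density(ctn, offset: float = DEFAULT_CTN_OFFSET):
    """Convert stored CT numbers to apparent density (kg/m³): ρ = CTN − offset.

    Works elementwise on arrays.  Total function; the exact inverse is
    :func:`density_to_ctn`.
    """
    if offset <= 0:
        raise ValueError(f"offset must be > 0, got {offset}")
    return np.asarray(ctn, dtype=float) - offset if np.ndim(ctn) else float(ctn) - offset


def density_to_ctn(rho, offset: float = DEFAULT_CTN_OFFSET):
    """Inverse of :func:`ctn_to_density`: stored CTN = ρ + offset.

    Returns real values; rounding to integer happens only at serialization,
    so ``ctn_to_density(density_to_ctn(x)) == x`` exactly.
    """
    return np.asarray(rho, dtype=float) + offset if np.ndim(rho) else float(rho) + offset


def scan_to_density(scan: ScanVolume, offset: float = DEFAULT_CTN_OFFSET) -> DensityVolume:
    """Apply the configured CTN→density conversion to a whole scan."""
    return DensityVolume(
        rho=ctn_to_density(scan.ctn, offset=offset),
        spacing=scan.spacing,
        meta=scan.meta,
    )


# ---------------------------------------------------------------------------
# DICOM series
# ---------------------------------------------------------------------------

def _write_dicom_series(vol: ScanVolume, directory: Path) -> None:
    directory.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(vol.ctn)
    if arr.min() < 0 or arr.max() > 0xFFFF:
        raise ValueError(
            "DICOM series stores unsigned 16-bit pixels; "
            f"CTN range [{arr.min()}, {arr.max()}] does not fit"
        )
    arr = arr.astype(np.uint16)
    dz, dy, dx = vol.spacing
    series_uid = generate_uid()
    study_uid = generate_uid()
    frame_uid = generate_uid()
    meta_json = json.dumps(asdict(vol.meta))

    for i in range(arr.shape[0]):
        ds = Dataset()
        ds.file_meta = FileMetaDataset()
        ds.file_meta.MediaStorageSOPClassUID = _CT_IMAGE_STORAGE
        ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
        ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.SOPClassUID = _CT_IMAGE_STORAGE
        ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.PatientID = vol.meta.cheese_id
        ds.PatientName = vol.meta.cheese_id
        ds.StudyDescription = vol.meta.batch_id
        ds.ImageComments = meta_json
        ds.InstanceNumber = i + 1
        ds.ImagePositionPatient = [0.0, 0.0, round(i * dz, 6)]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.SliceThickness = dz
        ds.SliceLocation = round(i * dz, 6)
        ds.PixelSpacing = [dy, dx]
        ds.Rows, ds.Columns = arr.shape[1], arr.shape[2]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = 0.0
        ds.PixelData = arr[i].tobytes()
        ds.save_as(directory / f"slice_{i:04d}.dcm", enforce_file_format=True)


def _read_dicom_series(directory: Path) -> ScanVolume:
    files = sorted(directory.glob("*.dcm")) or sorted(
        p for p in directory.iterdir() if p.is_file()
    )
    if not files:
        raise IngestError(f"no DICOM slices found in {directory}")
    slices = []
    for f in files:
        try:
            slices.append(pydicom.dcmread(f))
        except Exception as exc:  # corrupt slice is an ingest failure
            raise IngestError(f"cannot read DICOM slice {f}: {exc}") from exc

    # sort by spatial position along the slice axis
    def zpos(ds):
        if "ImagePositionPatient" in ds:
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "SliceLocation", getattr(ds, "InstanceNumber", 0)))

    slices.sort(key=zpos)

    ref = slices[0]
    pixel_spacing = [float(v) for v in ref.PixelSpacing]
    for ds in slices[1:]:
        if [float(v) for v in ds.PixelSpacing] != pixel_spacing:
            raise IngestError("inconsistent in-plane pixel spacing across slices")

    # detect gaps from instance numbers and from z positions
    inst = sorted(int(ds.InstanceNumber) for ds in slices if "InstanceNumber" in ds)
    if inst and len(inst) == len(slices):
        expected = list(range(inst[0], inst[0] + len(inst)))
        if inst != expected:
            missing = sorted(set(range(inst[0], inst[-1] + 1)) - set(inst))
            raise IngestError(
                f"missing slice instance number(s) {missing}", missing=missing
            )
    zs = np.array([zpos(ds) for ds in slices], dtype=float)
    if len(zs) > 2:
        steps = np.diff(zs)
        med = float(np.median(steps))
        if med > 0 and np.any(steps > 1.5 * med):
            gap_after = [int(i) for i in np.nonzero(steps > 1.5 * med)[0]]
            raise IngestError(
                f"slice position gap after sorted index(es) {gap_after}",
                missing=[g + 1 for g in gap_after],
            )

    dz = float(np.median(np.diff(zs))) if len(zs) > 1 else float(
        getattr(ref, "SliceThickness", 1.0)
    )
    arr = np.stack([ds.pixel_array for ds in slices]).astype(np.int32)

    meta = ScanMeta(source=str(directory))
    if "ImageComments" in ref:
        try:
            meta = ScanMeta(**json.loads(ref.ImageComments))
        except (json.JSONDecodeError, TypeError):
            pass
    meta.source = str(directory)
    meta.rescale_slope = float(getattr(ref, "RescaleSlope", 1.0))
    meta.rescale_intercept = float(getattr(ref, "RescaleIntercept", 0.0))

    return ScanVolume(ctn=arr, spacing=(dz, pixel_spacing[0], pixel_spacing[1]), meta=meta)


# ---------------------------------------------------------------------------
# Raster + JSON sidecar
# ---------------------------------------------------------------------------

def _write_raster(vol: ScanVolume, path: Path) -> None:
    path = path.with_suffix(".npy")
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(vol.ctn)
    np.save(path, arr)
    sidecar = {
        "shape": list(arr.shape),
        "spacing_mm": list(vol.spacing),
        "dtype": str(arr.dtype),
        "meta": asdict(vol.meta),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def _read_raster(path: Path) -> ScanVolume:
    path = Path(path)
    if path.suffix == ".json":
        path = path.with_suffix(".npy")
    elif path.suffix != ".npy":
        path = path.with_suffix(".npy")
    sidecar_path = path.with_suffix(".json")
    if not path.exists():
        raise IngestError(f"raster array not found: {path}")
    if not sidecar_path.exists():
        raise IngestError(f"sidecar not found: {sidecar_path}")
    arr = np.load(path)
    sidecar = json.loads(sidecar_path.read_text())
    if list(arr.shape) != list(sidecar["shape"]):
        raise IngestError(
            f"sidecar shape {sidecar['shape']} disagrees with array {list(arr.shape)}"
        )
    meta = ScanMeta(**sidecar.get("meta", {}))
    meta.source = str(path)
    return ScanVolume(ctn=arr, spacing=tuple(sidecar["spacing_mm"]), meta=meta)


def _detect_format(path: Path) -> str:
    if path.is_dir():
        return "dicom-series"
    return "raster"


def read_volume(path, format: str | None = None) -> ScanVolume:
    """Read a CT volume from a DICOM series directory or a raster+sidecar pair.

    Slices are sorted by spatial position; spacing comes from file metadata;
    stored pixel values are exposed unmodified (rescale slope/intercept, when
    present, are recorded in ``meta`` but not applied).

    Raises
    ------
    IngestError
        If the path is missing, slices are missing (the error lists the
        gaps), or per-slice spacing is inconsistent.
    """
    path = Path(path)
    if not path.exists() and not (
        path.with_suffix(".npy").exists() or path.with_suffix(".json").exists()
    ):
        raise IngestError(f"path does not exist: {path}")
    fmt = format or _detect_format(path)
    if fmt == "dicom-series":
        return _read_dicom_series(path)
    if fmt in ("raster", "raster+sidecar"):
        return _read_raster(path)
    raise ValueError(f"unknown format {fmt!r}")


def write_volume(vol: ScanVolume, path, format: str = "dicom-series") -> None:
    """Write a volume so that :func:`read_volume` round-trips it losslessly."""
    path = Path(path)
    if format == "dicom-series":
        _write_dicom_series(vol, path)
    elif format in ("raster", "raster+sidecar"):
        _write_raster(vol, path)
    else:
        raise ValueError(f"unknown format {format!r}")
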