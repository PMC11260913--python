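"""Per-cavity and per-wheel morphometrics.

Each labeled cavity is measured three ways:

* **volume** — per-slice cavity area summed and multiplied by the slice
  thickness, converted to cm³.  On voxel data this is algebraically
  identical to ``voxel_count × voxel volume``; both are computed and the
  identity is asserted.
* **surface area** — the area of an isosurface mesh extracted by marching
  cubes at level 0 of the signed Euclidean distance field of the cavity.
  The distance-field isosurface sits half a voxel outside the voxel centers
  and suppresses the staircase overestimation that marching cubes on raw
  binary data exhibits; it is deterministic for a fixed input.
* **roundness** — 3D sphericity, the isoperimetric ratio

      Ψ = π^{1/3} · (6V)^{2/3} / A,

  equal to 1 for a perfect sphere and lower for flat or elongated shapes.
  Discrete estimation can push Ψ above 1 for cavities a few voxels across;
  such values are reported as-is.

Wheel-level summaries follow the standard report layout: eye count, mean and
10th/90th-percentile eye volume and roundness, total eye volume, wheel
volume (cheese matrix only, excluding cavities), Ratio = eye volume / wheel
volume, and Eye% = 100 · eye volume / (wheel volume + eye volume).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from .segmentation import LabelMap
from .volume_io import ScanMeta

__all__ = [
    "CavityRecord",
    "WheelSummary",
    "cavity_volume",
    "cavity_surface_area",
    "roundness",
    "build_catalog",
    "flag_cracks",
    "summarize_wheel",
    "percentile",
    "catalog_to_rows",
]

logger = logging.getLogger(__name__)

DEFAULT_CRACK_ROUNDNESS_CUTOFF = 0.4
DEFAULT_CRACK_VOLUME_CUTOFF_CM3 = 1.0


class UndefinedScoreError(ValueError):
    """Raised when a shape score is requested for a degenerate region."""


@dataclass
class CavityRecord:
    """Measurements of one labeled cavity."""

    label: int
    voxel_count: int
    slice_areas: list[tuple[int, float]]  # (slice index, area mm²)
    volume_cm3: float
    surface_area_mm2: float
    roundness: float
    centroid_mm: tuple[float, float, float]  # (z, y, x)
    bbox: tuple[tuple[int, int], ...]  # per-axis (start, stop) voxel ranges
    crack_flag: bool = False


@dataclass
class WheelSummary:
    """Per-wheel report metrics.

    Volume and roundness statistics are ``None`` (absent, not zero) when the
    wheel has no cavities, so empty wheels do not bias group statistics.
    """

    cheese_id: str
    age_days: int
    n_eyes: int
    mean_eye_volume_cm3: float | None
    eye_volume_p10_cm3: float | None
    eye_volume_p90_cm3: float | None
    total_eye_volume_cm3: float
    wheel_volume_cm3: float
    ratio: float
    eye_percent: float
    mean_roundness: float | None
    roundness_p10: float | None
    roundness_p90: float | None
    n_crack_flagged: int = 0
    batch_id: str = "unknown"

    def to_dict(self) -> dict:
        return {
            "cheese_id": self.cheese_id,
            "batch_id": self.batch_id,
            "age_days": self.age_days,
            "n_eyes": self.n_eyes,
            "mean_eye_volume_cm3": self.mean_eye_volume_cm3,
            "eye_volume_p10_cm3": self.eye_volume_p10_cm3,
            "eye_volume_p90_cm3": self.eye_volume_p90_cm3,
            "total_eye_volume_cm3": self.total_eye_volume_cm3,
            "wheel_volume_cm3": self.wheel_volume_cm3,
            "ratio": self.ratio,
            "eye_percent": self.eye_percent,
            "mean_roundness": self.mean_roundness,
            "roundness_p10": self.roundness_p10,
            "roundness_p90": self.roundness_p90,
            "n_crack_flagged": self.n_crack_flagged,
        }


def cavity_volume(slice_areas, dz: float) -> float:
    """Volume (cm³) from per-slice areas (mm²) and slice thickness dz (mm)."""
    if dz <= 0:
        raise ValueError(f"dz must be > 0, got {dz}")
    areas = np.asarray([a for _, a in slice_areas] if slice_areas and
                       isinstance(slice_areas[0], (tuple, list)) else slice_areas,
                       dtype=float)
    if np.any(areas < 0):
        raise ValueError("slice areas must be nonnegative")
    return float(areas.sum() * dz / 1000.0)


def cavity_surface_area(
    labels: np.ndarray, label: int, spacing: tuple[float, float, float]
) -> float:
    """Surface area (mm²) of one labeled region via an SDF isosurface mesh.

    The region is cropped to its bounding box (2-voxel pad), a signed
    Euclidean distance field (outside − inside, in mm) is computed, and the
    zero level set is meshed with marching cubes.
    """
    region = labels == label
    if not region.any():
        raise ValueError(f"label {label} not present")
    objs = ndimage.find_objects(region.astype(np.int8), max_label=1)
    region = np.pad(region[objs[0]], 2)
    dz, dy, dx = spacing
    sampling = (dz, dy, dx)
    outside = ndimage.distance_transform_edt(~region, sampling=sampling)
    inside = ndimage.distance_transform_edt(region, sampling=sampling)
    sdf = outside - inside
    verts, faces, _, _ = measure.marching_cubes(sdf, level=0.0, spacing=sampling)
    return float(measure.mesh_surface_area(verts, faces))


def roundness(volume_cm3: float, surface_area_mm2: float) -> float:
    """3D sphericity Ψ = π^{1/3}(6V)^{2/3}/A with V in mm³, A in mm²."""
    if surface_area_mm2 <= 0:
        raise UndefinedScoreError("surface area must be > 0 for a roundness score")
    if volume_cm3 <= 0:
        raise UndefinedScoreError("volume must be > 0 for a roundness score")
    v_mm3 = volume_cm3 * 1000.0
    return float(np.pi ** (1.0 / 3.0) * (6.0 * v_mm3) ** (2.0 / 3.0) / surface_area_mm2)


def build_catalog(labelmap: LabelMap) -> list[CavityRecord]:
    """Measure every cavity in a label map.

    The slice-area route and the voxel-count route to volume are both
    computed; they are identical on voxel data and this is asserted.
    """
    labels = labelmap.labels
    dz, dy, dx = labelmap.spacing
    pixel_area = dx * dy
    voxel_mm3 = dx * dy * dz
    records: list[CavityRecord] = []
    if labelmap.n_cavities == 0:
        return records

    objects = ndimage.find_objects(labels, max_label=labelmap.n_cavities)
    centroids = ndimage.center_of_mass(
        labels > 0, labels, index=range(1, labelmap.n_cavities + 1)
    )
    for k in range(1, labelmap.n_cavities + 1):
        sl = objects[k - 1]
        if sl is None:
            continue
        sub = labels[sl] == k
        voxel_count = int(sub.sum())
        z0 = sl[0].start
        per_slice = sub.sum(axis=(1, 2))
        slice_areas = [
            (int(z0 + i), float(c * pixel_area))
            for i, c in enumerate(per_slice)
            if c > 0
        ]
        vol_slices = cavity_volume(slice_areas, dz)
        vol_voxels = voxel_count * voxel_mm3 / 1000.0
        assert abs(vol_slices - vol_voxels) < 1e-9 * max(1.0, vol_voxels), (
            "slice-area and voxel-count volumes must coincide"
        )
        area = cavity_surface_area(labels[sl], k, labelmap.spacing)
        cz, cy, cx = centroids[k - 1]
        records.append(
            CavityRecord(
                label=k,
                voxel_count=voxel_count,
                slice_areas=slice_areas,
                volume_cm3=vol_voxels,
                surface_area_mm2=area,
                roundness=roundness(vol_voxels, area),
                centroid_mm=(float(cz * dz), float(cy * dy), float(cx * dx)),
                bbox=tuple((s.start, s.stop) for s in sl),
            )
        )
    return records


def flag_cracks(
    catalog: list[CavityRecord],
    roundness_cutoff: float = DEFAULT_CRACK_ROUNDNESS_CUTOFF,
    volume_cutoff_cm3: float = DEFAULT_CRACK_VOLUME_CUTOFF_CM3,
) -> list[CavityRecord]:
    """Flag large, low-roundness cavities as cracks/splits (in place).

    A cavity is flagged when roundness < ``roundness_cutoff`` **and** volume
    > ``volume_cutoff_cm3``: cracks are flat (low sphericity) and, unlike
    residual noise, substantial in volume.
    """
    for rec in catalog:
        rec.crack_flag = (
            rec.roundness < roundness_cutoff and rec.volume_cm3 > volume_cutoff_cm3
        )
    n = sum(r.crack_flag for r in catalog)
    if n:
        logger.info("flagged %d cavity(ies) as crack/split", n)
    return catalog


def percentile(values, q: float) -> float:
    """Percentile by linear interpolation between order statistics."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("percentile of empty input is undefined")
    if not 0 <= q <= 100:
        raise ValueError(f"q must be in [0, 100], got {q}")
    return float(np.percentile(values, q, method="linear"))


def summarize_wheel(
    catalog: list[CavityRecord],
    wheel_voxel_count: int,
    spacing: tuple[float, float, float],
    meta: ScanMeta | None = None,
    include_cracks: bool = True,
) -> WheelSummary:
    """Aggregate a cavity catalog into per-wheel report metrics.

    ``wheel_voxel_count`` counts cheese-matrix voxels only (the wheel minus
    its cavities).  With ``include_cracks=False``, crack-flagged cavities are
    excluded from the eye statistics (they remain flagged in the catalog).
    """
    meta = meta or ScanMeta()
    dz, dy, dx = spacing
    wheel_volume_cm3 = wheel_voxel_count * dx * dy * dz / 1000.0
    eyes = catalog if include_cracks else [r for r in catalog if not r.crack_flag]
    n_eyes = len(eyes)
    total = float(sum(r.volume_cm3 for r in eyes))
    if wheel_volume_cm3 <= 0:
        raise ValueError("wheel volume must be positive")
    ratio = total / wheel_volume_cm3
    eye_percent = 100.0 * ratio / (1.0 + ratio) if total else 0.0

    if n_eyes:
        vols = [r.volume_cm3 for r in eyes]
        rounds = [r.roundness for r in eyes]
        stats = dict(
            mean_eye_volume_cm3=float(np.mean(vols)),
            eye_volume_p10_cm3=percentile(vols, 10),
            eye_volume_p90_cm3=percentile(vols, 90),
            mean_roundness=float(np.mean(rounds)),
            roundness_p10=percentile(rounds, 10),
            roundness_p90=percentile(rounds, 90),
        )
    else:
        stats = dict(
            mean_eye_volume_cm3=None,
            eye_volume_p10_cm3=None,
            eye_volume_p90_cm3=None,
            mean_roundness=None,
            roundness_p10=None,
            roundness_p90=None,
        )

    return WheelSummary(
        cheese_id=meta.cheese_id,
        batch_id=meta.batch_id,
        age_days=meta.age_days,
        n_eyes=n_eyes,
        total_eye_volume_cm3=total,
        wheel_volume_cm3=wheel_volume_cm3,
        ratio=ratio,
        eye_percent=eye_percent,
        n_crack_flagged=sum(r.crack_flag for r in catalog),
        **stats,
    )


def catalog_to_rows(catalog: list[CavityRecord]) -> list[dict]:
    """Flatten a catalog for CSV export (units in the column names)."""
    return [
        {
            "label": r.label,
            "voxel_count": r.voxel_count,
            "volume_cm3": r.volume_cm3,
            "surface_area_mm2": r.surface_area_mm2,
            "roundness": r.roundness,
            "centroid_z_mm": r.centroid_mm[0],
            "centroid_y_mm": r.centroid_mm[1],
            "centroid_x_mm": r.centroid_mm[2],
            "n_slices": len(r.slice_areas),
            "crack_flag": r.crack_flag,
        }
        for r in catalog
    ]
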