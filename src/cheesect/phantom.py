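"""Synthetic cheese-wheel phantoms with analytic ground truth.

A phantom is a cylindrical wheel of uniform density (default 1150 kg/m³,
inside the 1100–1200 kg/m³ range typical of semi-hard cheese) surrounded by
air, optionally wrapped in a thin wax shell, and carrying two kinds of
gas-filled voids:

* **eyes** — spheres with radii drawn from a configurable distribution,
  placed uniformly in the wheel interior; they may be allowed to overlap,
  in which case touching spheres coalesce into one connected cavity exactly
  as neighbouring eyes do in a real wheel;
* **cracks** — thin oriented rectangular slabs, the flat splits that form
  when gas pressure exceeds what the matrix can stretch around.

The density field is rasterized by a voxel-center membership test (a voxel
belongs to a feature iff its center lies inside), forward-converted to
stored CT numbers, optionally degraded with additive white Gaussian noise in
density units, and quantized to integers.  Because membership is a center
test, every analytic ground-truth quantity (sphere volume 4/3·π·r³, slab
volume L·W·T, pairwise overlap) is exact up to discretization, which is what
makes the phantom usable as a segmentation oracle.

Ground truth records, per inserted feature, the shape class, placement,
analytic volume and expected roundness class, plus the expected connected-
component count after merging geometrically intersecting features.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .volume_io import ScanMeta, ScanVolume, density_to_ctn, DEFAULT_CTN_OFFSET

__all__ = [
    "EyeModel",
    "CrackModel",
    "WaxShell",
    "PhantomSpec",
    "SphereFeature",
    "CrackFeature",
    "GroundTruth",
    "PlacementError",
    "generate_phantom",
    "place_eyes",
    "insert_crack",
    "young_mature_cohorts",
]

AIR_DENSITY = 1.2  # kg/m³
DEFAULT_WHEEL_DENSITY = 1150.0
DEFAULT_WAX_DENSITY = 930.0


class PlacementError(RuntimeError):
    """Raised when requested features cannot be placed inside the wheel."""


@dataclass
class EyeModel:
    """Eye population: count and radius distribution.

    ``radius_dist`` is ``"uniform"`` (radii ~ U(radius_range)) or
    ``"lognormal"`` (ln r ~ N(lognormal_mu, lognormal_sigma), clipped to
    radius_range).
    """

    n_eyes: int = 0
    radius_dist: str = "uniform"
    radius_range: tuple[float, float] = (2.0, 6.0)
    lognormal_mu: float = 1.0
    lognormal_sigma: float = 0.4
    allow_overlap: bool = False
    min_separation_mm: float = 2.0  # extra gap enforced when overlap is off


@dataclass
class CrackModel:
    """Crack population: count and slab extents (length × width × thickness, mm)."""

    count: int = 0
    length_mm: float = 40.0
    width_mm: float = 30.0
    thickness_mm: float = 1.25


@dataclass
class WaxShell:
    thickness_mm: float = 0.0
    density: float = DEFAULT_WAX_DENSITY


@dataclass
class PhantomSpec:
    """Full generative description of one synthetic wheel."""

    wheel_radius_mm: float = 165.0
    wheel_height_mm: float = 120.0
    wheel_density: float = DEFAULT_WHEEL_DENSITY
    background_density: float = AIR_DENSITY
    spacing: tuple[float, float, float] = (1.25, 1.0, 1.0)  # (dz, dy, dx)
    eyes: EyeModel = field(default_factory=EyeModel)
    cracks: CrackModel = field(default_factory=CrackModel)
    wax: WaxShell = field(default_factory=WaxShell)
    noise_sigma: float = 0.0  # kg/m³, additive white Gaussian
    seed: int = 0
    margin_mm: float = 6.0  # air margin around the wheel
    shape: tuple[int, int, int] | None = None  # override computed grid shape
    cheese_id: str = "phantom"
    batch_id: str = "synthetic"
    age_days: int = 0
    ctn_offset: float = DEFAULT_CTN_OFFSET

    def __post_init__(self):
        if self.wheel_radius_mm <= 0 or self.wheel_height_mm <= 0:
            raise ValueError("wheel radius and height must be positive")
        if self.wheel_density < 0 or self.background_density < 0:
            raise ValueError("densities must be nonnegative")
        dz, dy, dx = self.spacing
        if self.margin_mm < 2 * max(dx, dy, dz):
            raise ValueError("air margin must be at least 2 voxels")

    def grid_shape(self) -> tuple[int, int, int]:
        if self.shape is not None:
            return tuple(int(s) for s in self.shape)
        dz, dy, dx = self.spacing
        nz = math.ceil((self.wheel_height_mm + 2 * self.margin_mm) / dz)
        ny = math.ceil((2 * self.wheel_radius_mm + 2 * self.margin_mm) / dy)
        nx = math.ceil((2 * self.wheel_radius_mm + 2 * self.margin_mm) / dx)
        return nz, ny, nx


@dataclass
class SphereFeature:
    center_mm: tuple[float, float, float]  # (z, y, x)
    radius_mm: float
    shape_class: str = "sphere"

    @property
    def volume_cm3(self) -> float:
        return 4.0 / 3.0 * math.pi * self.radius_mm**3 / 1000.0

    @property
    def roundness_class(self) -> str:
        return "≈1"


@dataclass
class CrackFeature:
    center_mm: tuple[float, float, float]
    axes: tuple[tuple[float, float, float], ...]  # orthonormal (u, v, w) rows
    extents_mm: tuple[float, float, float]  # (length, width, thickness)
    shape_class: str = "crack"

    @property
    def volume_cm3(self) -> float:
        l, w, t = self.extents_mm
        return l * w * t / 1000.0

    @property
    def roundness_class(self) -> str:
        return "<0.6"


@dataclass
class GroundTruth:
    """Analytic truth for every inserted feature plus the merge analysis."""

    features: list
    expected_component_count: int
    merged_groups: list[list[int]]  # feature indices per expected component
    wheel_radius_mm: float
    wheel_height_mm: float
    wheel_density: float
    spacing: tuple[float, float, float]
    seed: int

    @property
    def total_feature_volume_cm3(self) -> float:
        return sum(f.volume_cm3 for f in self.features)

    def analytic_wheel_volume_cm3(self) -> float:
        """Cylinder volume minus inserted voids (overlaps ignored)."""
        cyl = math.pi * self.wheel_radius_mm**2 * self.wheel_height_mm / 1000.0
        return cyl - self.total_feature_volume_cm3

    def to_json(self) -> str:
        payload = {
            "expected_component_count": self.expected_component_count,
            "merged_groups": self.merged_groups,
            "wheel_radius_mm": self.wheel_radius_mm,
            "wheel_height_mm": self.wheel_height_mm,
            "wheel_density": self.wheel_density,
            "spacing": list(self.spacing),
            "seed": self.seed,
            "features": [
                {**asdict(f), "volume_cm3": f.volume_cm3,
                 "roundness_class": f.roundness_class}
                for f in self.features
            ],
        }
        return json.dumps(payload, indent=2)


# ---------------------------------------------------------------------------
# Feature placement
# ---------------------------------------------------------------------------

def _sample_radius(eyes: EyeModel, rng: np.random.Generator) -> float:
    lo, hi = eyes.radius_range
    if eyes.radius_dist == "uniform":
        return float(rng.uniform(lo, hi))
    if eyes.radius_dist == "lognormal":
        return float(np.clip(rng.lognormal(eyes.lognormal_mu, eyes.lognormal_sigma), lo, hi))
    raise ValueError(f"unknown radius_dist {eyes.radius_dist!r}")


def place_eyes(spec: PhantomSpec, rng: np.random.Generator) -> list[SphereFeature]:
    """Sample eye spheres uniformly inside the wheel with full containment.

    Each center keeps a margin of (radius + 1 voxel) from the wheel surface,
    radially and axially.  When overlap is disallowed, rejection sampling
    enforces pairwise center distance > rᵢ + rⱼ + ``min_separation_mm``;
    after 10·n failed attempts for an eye a :class:`PlacementError` is
    raised suggesting fewer or smaller eyes.
    """
    eyes = spec.eyes
    if eyes.n_eyes == 0:
        return []
    dz, dy, dx = spec.spacing
    voxel = max(dx, dy, dz)
    nz, ny, nx = spec.grid_shape()
    cz, cy, cx = (nz - 1) * dz / 2, (ny - 1) * dy / 2, (nx - 1) * dx / 2
    half_h = spec.wheel_height_mm / 2

    placed: list[SphereFeature] = []
    max_attempts = 10 * max(1, eyes.n_eyes)
    for _ in range(eyes.n_eyes):
        r = _sample_radius(eyes, rng)
        if r >= spec.wheel_radius_mm:
            raise PlacementError(
                f"eye radius {r:.1f} mm does not fit in wheel radius "
                f"{spec.wheel_radius_mm:.1f} mm"
            )
        margin = r + voxel
        r_max = spec.wheel_radius_mm - margin
        z_half = half_h - margin
        if r_max <= 0 or z_half <= 0:
            raise PlacementError(
                f"eye radius {r:.1f} mm cannot be contained; "
                "reduce radii or enlarge the wheel"
            )
        for attempt in range(max_attempts):
            rad = r_max * math.sqrt(rng.uniform())
            theta = rng.uniform(0, 2 * math.pi)
            z = cz + rng.uniform(-z_half, z_half)
            y = cy + rad * math.sin(theta)
            x = cx + rad * math.cos(theta)
            if eyes.allow_overlap:
                break
            ok = all(
                math.dist((z, y, x), p.center_mm)
                > r + p.radius_mm + eyes.min_separation_mm
                for p in placed
            )
            if ok:
                break
        else:
            raise PlacementError(
                f"could not place eye {len(placed) + 1}/{eyes.n_eyes} after "
                f"{max_attempts} attempts; try fewer or smaller eyes"
            )
        placed.append(SphereFeature(center_mm=(z, y, x), radius_mm=r))
    return placed


def _random_orthonormal_triad(rng: np.random.Generator) -> np.ndarray:
    m = rng.normal(size=(3, 3))
    q, _ = np.linalg.qr(m)
    return q.T  # rows are orthonormal


def insert_crack(
    spec: PhantomSpec, rng: np.random.Generator, max_attempts: int = 200
) -> CrackFeature:
    """Place one thin slab void with random orientation inside the wheel.

    Orientation and center are rejection-sampled until all eight slab
    corners sit inside the wheel with a two-voxel margin (so a crack never
    opens to the rind); infeasible extents raise a validation error.
    """
    cr = spec.cracks
    if cr.thickness_mm <= 0:
        raise ValueError("crack thickness must be positive")
    half_diag = math.hypot(cr.length_mm, cr.width_mm) / 2
    voxel = max(spec.spacing)
    if half_diag >= spec.wheel_radius_mm - 2 * voxel:
        raise ValueError(
            "crack extents do not fit inside the wheel; reduce length/width"
        )
    nz, ny, nx = spec.grid_shape()
    dz, dy, dx = spec.spacing
    cz, cy, cx = (nz - 1) * dz / 2, (ny - 1) * dy / 2, (nx - 1) * dx / 2
    r_lim = spec.wheel_radius_mm - 2 * voxel
    z_lim = spec.wheel_height_mm / 2 - 2 * dz
    half = np.array([cr.length_mm, cr.width_mm, cr.thickness_mm]) / 2
    signs = np.array(list(itertools.product((-1, 1), repeat=3)), dtype=float)

    slack_r = max(spec.wheel_radius_mm - half_diag - 2 * voxel, 0.0)
    for _ in range(max_attempts):
        triad = _random_orthonormal_triad(rng)
        rad = slack_r * math.sqrt(rng.uniform())
        theta = rng.uniform(0, 2 * math.pi)
        jz = rng.uniform(-z_lim, z_lim) if z_lim > 0 else 0.0
        center = np.array(
            [cz + jz, cy + rad * math.sin(theta), cx + rad * math.cos(theta)]
        )
        corners = center + (signs * half) @ triad
        radial = np.hypot(corners[:, 1] - cy, corners[:, 2] - cx)
        if np.all(radial < r_lim) and np.all(np.abs(corners[:, 0] - cz) < z_lim):
            return CrackFeature(
                center_mm=tuple(float(v) for v in center),
                axes=tuple(tuple(float(v) for v in row) for row in triad),
                extents_mm=(cr.length_mm, cr.width_mm, cr.thickness_mm),
            )
    raise ValueError(
        f"crack extents {cr.length_mm}×{cr.width_mm} mm do not fit inside the "
        f"wheel at any sampled orientation ({max_attempts} attempts); "
        "reduce length/width"
    )


# ---------------------------------------------------------------------------
# Overlap analysis (expected component count)
# ---------------------------------------------------------------------------

def _sphere_sphere_intersect(a: SphereFeature, b: SphereFeature) -> bool:
    return math.dist(a.center_mm, b.center_mm) < a.radius_mm + b.radius_mm


def _sphere_crack_intersect(s: SphereFeature, c: CrackFeature) -> bool:
    axes = np.asarray(c.axes)
    half = np.asarray(c.extents_mm) / 2
    d = np.asarray(s.center_mm) - np.asarray(c.center_mm)
    local = axes @ d
    clamped = np.clip(local, -half, half)
    return float(np.linalg.norm(local - clamped)) < s.radius_mm


def _crack_crack_intersect(a: CrackFeature, b: CrackFeature) -> bool:
    """Oriented-box overlap by the separating axis theorem."""
    ra = np.asarray(a.extents_mm) / 2
    rb = np.asarray(b.extents_mm) / 2
    A = np.asarray(a.axes)
    B = np.asarray(b.axes)
    t = np.asarray(b.center_mm) - np.asarray(a.center_mm)
    axes = [A[i] for i in range(3)] + [B[i] for i in range(3)] + [
        np.cross(A[i], B[j]) for i in range(3) for j in range(3)
    ]
    for ax in axes:
        n = np.linalg.norm(ax)
        if n < 1e-12:
            continue
        ax = ax / n
        proj_a = float(np.abs(A @ ax) @ ra)
        proj_b = float(np.abs(B @ ax) @ rb)
        if abs(float(t @ ax)) > proj_a + proj_b:
            return False
    return True


def _features_intersect(a, b) -> bool:
    if isinstance(a, SphereFeature) and isinstance(b, SphereFeature):
        return _sphere_sphere_intersect(a, b)
    if isinstance(a, SphereFeature) and isinstance(b, CrackFeature):
        return _sphere_crack_intersect(a, b)
    if isinstance(a, CrackFeature) and isinstance(b, SphereFeature):
        return _sphere_crack_intersect(b, a)
    return _crack_crack_intersect(a, b)


def merge_analysis(features: list) -> list[list[int]]:
    """Union-find grouping of features that geometrically intersect."""
    parent = list(range(len(features)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(features)), 2):
        if _features_intersect(features[i], features[j]):
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[rj] = ri
    groups: dict[int, list[int]] = {}
    for i in range(len(features)):
        groups.setdefault(find(i), []).append(i)
    return sorted(groups.values())


# ---------------------------------------------------------------------------
# Rasterization + forward model
# ---------------------------------------------------------------------------

def _coords(shape, spacing):
    nz, ny, nx = shape
    dz, dy, dx = spacing
    z = np.arange(nz)[:, None, None] * dz
    y = np.arange(ny)[None, :, None] * dy
    x = np.arange(nx)[None, None, :] * dx
    return z, y, x


def _rasterize_sphere(rho, s: SphereFeature, spacing, value):
    dz, dy, dx = spacing
    cz, cy, cx = s.center_mm
    r = s.radius_mm
    z0 = max(int((cz - r) / dz) - 1, 0)
    z1 = min(int((cz + r) / dz) + 2, rho.shape[0])
    y0 = max(int((cy - r) / dy) - 1, 0)
    y1 = min(int((cy + r) / dy) + 2, rho.shape[1])
    x0 = max(int((cx - r) / dx) - 1, 0)
    x1 = min(int((cx + r) / dx) + 2, rho.shape[2])
    z = np.arange(z0, z1)[:, None, None] * dz
    y = np.arange(y0, y1)[None, :, None] * dy
    x = np.arange(x0, x1)[None, None, :] * dx
    inside = (z - cz) ** 2 + (y - cy) ** 2 + (x - cx) ** 2 <= r * r
    rho[z0:z1, y0:y1, x0:x1][inside] = value


def _rasterize_crack(rho, c: CrackFeature, spacing, value, wheel_mask):
    dz, dy, dx = spacing
    axes = np.asarray(c.axes)
    half = np.asarray(c.extents_mm) / 2
    center = np.asarray(c.center_mm)
    # bounding sphere of the slab limits the subgrid
    rad = float(np.linalg.norm(half))
    z0 = max(int((center[0] - rad) / dz) - 1, 0)
    z1 = min(int((center[0] + rad) / dz) + 2, rho.shape[0])
    y0 = max(int((center[1] - rad) / dy) - 1, 0)
    y1 = min(int((center[1] + rad) / dy) + 2, rho.shape[1])
    x0 = max(int((center[2] - rad) / dx) - 1, 0)
    x1 = min(int((center[2] + rad) / dx) + 2, rho.shape[2])
    z = np.arange(z0, z1)[:, None, None] * dz - center[0]
    y = np.arange(y0, y1)[None, :, None] * dy - center[1]
    x = np.arange(x0, x1)[None, None, :] * dx - center[2]
    inside = np.ones(z.shape[:1] + y.shape[1:2] + x.shape[2:], dtype=bool)
    for ax, h in zip(axes, half):
        proj = z * ax[0] + y * ax[1] + x * ax[2]
        inside &= np.abs(proj) <= h
    sub = rho[z0:z1, y0:y1, x0:x1]
    sub[inside & wheel_mask[z0:z1, y0:y1, x0:x1]] = value


def generate_phantom(spec: PhantomSpec) -> tuple[ScanVolume, GroundTruth]:
    """Rasterize a phantom and forward-model it to stored CT numbers.

    Deterministic for a fixed spec (the spec's seed drives both placement
    and noise).  A voxel takes the cavity density iff its center lies inside
    an inserted feature; the density field is then converted with the
    configured density→CTN offset, Gaussian noise (``noise_sigma`` in kg/m³)
    is added, and the result is rounded to integers.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.grid_shape()
    dz, dy, dx = spec.spacing
    nz, ny, nx = shape
    cz, cy, cx = (nz - 1) * dz / 2, (ny - 1) * dy / 2, (nx - 1) * dx / 2

    z, y, x = _coords(shape, spec.spacing)
    radial2 = (y - cy) ** 2 + (x - cx) ** 2
    in_cyl_z = np.abs(z - cz) <= spec.wheel_height_mm / 2
    wheel = (radial2 <= spec.wheel_radius_mm**2) & in_cyl_z

    rho = np.full(shape, spec.background_density, dtype=float)
    if spec.wax.thickness_mm > 0:
        rw = spec.wheel_radius_mm + spec.wax.thickness_mm
        in_wax_z = np.abs(z - cz) <= spec.wheel_height_mm / 2 + spec.wax.thickness_mm
        wax = (radial2 <= rw**2) & in_wax_z & ~wheel
        rho[wax] = spec.wax.density
    rho[wheel] = spec.wheel_density

    features: list = list(place_eyes(spec, rng))
    for _ in range(spec.cracks.count):
        features.append(insert_crack(spec, rng))

    for f in features:
        if isinstance(f, SphereFeature):
            _rasterize_sphere(rho, f, spec.spacing, spec.background_density)
        else:
            _rasterize_crack(rho, f, spec.spacing, spec.background_density, wheel)

    if spec.noise_sigma > 0:
        rho = rho + rng.normal(0.0, spec.noise_sigma, size=shape)

    ctn = np.rint(density_to_ctn(rho, offset=spec.ctn_offset)).astype(np.int32)
    np.clip(ctn, 0, 0xFFFF, out=ctn)

    groups = merge_analysis(features)
    truth = GroundTruth(
        features=features,
        expected_component_count=len(groups),
        merged_groups=groups,
        wheel_radius_mm=spec.wheel_radius_mm,
        wheel_height_mm=spec.wheel_height_mm,
        wheel_density=spec.wheel_density,
        spacing=spec.spacing,
        seed=spec.seed,
    )
    meta = ScanMeta(
        cheese_id=spec.cheese_id,
        batch_id=spec.batch_id,
        age_days=spec.age_days,
        source="phantom",
    )
    return ScanVolume(ctn=ctn, spacing=spec.spacing, meta=meta), truth


def young_mature_cohorts(
    n_per_group: int,
    young_params: dict,
    mature_params: dict,
    seed: int = 0,
    **shared,
) -> tuple[list[PhantomSpec], list[PhantomSpec]]:
    """Two phantom cohorts emulating young and mature ripening stages.

    ``young_params`` / ``mature_params`` update the :class:`EyeModel` of
    each cohort (e.g. ``{"n_eyes": 12, "radius_range": (2, 5)}``); extra
    keyword arguments are shared :class:`PhantomSpec` fields (wheel
    geometry, noise, ...).  Per-wheel seeds are derived from ``seed`` so a
    fixed seed reproduces both cohorts exactly.
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 wheels per group")
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=2 * n_per_group)

    def build(params: dict, idx: int, age: int, tag: str) -> PhantomSpec:
        eye_kwargs = dict(params)
        age_days = eye_kwargs.pop("age_days", age)
        return PhantomSpec(
            eyes=EyeModel(**eye_kwargs),
            seed=int(seeds[idx]),
            cheese_id=f"{tag}-{idx % n_per_group + 1:02d}",
            batch_id=tag,
            age_days=age_days,
            **shared,
        )

    young = [build(young_params, i, 44, "young") for i in range(n_per_group)]
    mature = [
        build(mature_params, n_per_group + i, 170, "mature")
        for i in range(n_per_group)
    ]
    return young, mature
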