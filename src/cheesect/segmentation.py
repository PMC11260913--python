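"""Density thresholding, wheel extraction and cavity labeling.

The decision boundary between cheese matrix and everything else is a single
manual density threshold (default 850 kg/m³, well below the 1100–1200 kg/m³
density of semi-hard cheese).  Voxels at or above the threshold form the
cheese phase (binary 1); everything below — external air, gas-filled eyes,
cracks — forms the 0 phase.  Cavities are then the below-threshold connected
components that lie inside the wheel and are not reachable from the volume
boundary (those are external air).

Connectivity defaults follow the usual complementary-phase convention for 3D
binary topology: 26-connectivity for the cheese (foreground) phase,
6-connectivity for the cavity/air phase, so that a one-voxel diagonal chain
of cheese cannot be crossed by a cavity and vice versa.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume_io import DensityVolume

__all__ = [
    "BinaryMask",
    "LabelMap",
    "NoWheelError",
    "threshold_volume",
    "extract_wheel",
    "label_cavities",
    "labeling_oracle",
    "connectivity_structure",
]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 850.0  # kg/m³
DEFAULT_MIN_VOLUME_CM3 = 0.01

_CONN_RANK = {6: 1, 18: 2, 26: 3}


class NoWheelError(RuntimeError):
    """Raised when no cheese-phase voxels exist to extract a wheel from."""


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3×3×3 binary structuring element for 6-, 18- or 26-connectivity."""
    try:
        rank = _CONN_RANK[int(connectivity)]
    except KeyError:
        raise ValueError(f"connectivity must be one of 6, 18, 26; got {connectivity}")
    return ndimage.generate_binary_structure(3, rank)


@dataclass
class BinaryMask:
    """Cheese/not-cheese decision: True = cheese matrix, False = cavity or air."""

    mask: np.ndarray
    spacing: tuple[float, float, float]
    threshold_used: float = DEFAULT_THRESHOLD

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def voxel_volume_mm3(self) -> float:
        dz, dy, dx = self.spacing
        return dx * dy * dz


@dataclass
class LabelMap:
    """Labeled cavities: 0 = cheese or external air, 1..K = cavities.

    Labels are contiguous and assigned in decreasing cavity-volume order.
    Bookkeeping voxel counts support the conservation identity
    ``cavity + cheese + external air + discarded specks = field of view``.
    """

    labels: np.ndarray
    n_cavities: int
    connectivity_used: int
    spacing: tuple[float, float, float]
    external_air_voxels: int = 0
    discarded_speck_voxels: int = 0
    discarded_speck_count: int = 0
    rind_open_merged: bool = False
    mode: str = "3d"
    voxel_counts: dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not self.voxel_counts and self.n_cavities:
            counts = np.bincount(self.labels.ravel(), minlength=self.n_cavities + 1)
            self.voxel_counts = {k: int(counts[k]) for k in range(1, self.n_cavities + 1)}


def threshold_volume(
    rho: DensityVolume, threshold: float = DEFAULT_THRESHOLD
) -> BinaryMask:
    """Classify voxels as cheese (ρ ≥ threshold, inclusive) or not.

    The boundary case is inclusive so the threshold value itself falls on the
    cheese side.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    return BinaryMask(
        mask=rho.rho >= threshold, spacing=rho.spacing, threshold_used=float(threshold)
    )


def extract_wheel(mask: BinaryMask, connectivity: int = 26) -> BinaryMask:
    """Keep only the largest connected cheese component (the wheel).

    Isolated above-threshold specks (debris, noise) are dropped.  A tie
    between equal-size components is broken deterministically in favour of
    the component containing the smallest linear voxel index, with a warning.
    """
    structure = connectivity_structure(connectivity)
    labels, n = ndimage.label(mask.mask, structure=structure)
    if n == 0:
        raise NoWheelError("mask contains no cheese-phase voxels")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    best = int(np.argmax(counts))  # first maximal label == smallest min linear index
    ties = np.nonzero(counts == counts[best])[0]
    if len(ties) > 1:
        logger.warning(
            "wheel extraction tie between %d equal-size components (%d voxels); "
            "keeping the one with the smallest linear index",
            len(ties),
            counts[best],
        )
    wheel = labels == best
    dropped = int(mask.mask.sum() - wheel.sum())
    if dropped:
        logger.info("extract_wheel dropped %d non-wheel cheese voxels", dropped)
    return BinaryMask(mask=wheel, spacing=mask.spacing, threshold_used=mask.threshold_used)


def _touches_boundary(labels: np.ndarray) -> np.ndarray:
    """Set of labels present on any face of the volume."""
    faces = [
        labels[0], labels[-1],
        labels[:, 0], labels[:, -1],
        labels[:, :, 0], labels[:, :, -1],
    ]
    return np.unique(np.concatenate([f.ravel() for f in faces]))


def label_cavities(
    mask: BinaryMask,
    wheel: BinaryMask,
    connectivity: int = 6,
    min_volume_cm3: float = DEFAULT_MIN_VOLUME_CM3,
    mode: str = "3d",
) -> LabelMap:
    """Identify cavities as connected below-threshold regions inside the wheel.

    External air is every below-threshold component reachable from the volume
    boundary; cavities are the remaining components that intersect the
    wheel's filled interior.  Cavities open to the rind are, by construction,
    connected to external air and therefore merge into it (flagged in the
    log).  Components smaller than ``min_volume_cm3`` are discarded as noise
    specks and accounted separately.

    ``mode='2d-stacked'`` labels the same cavity voxel set slice by slice
    with the matching 2D connectivity instead of in 3D; total cavity volume
    is identical, only the component count differs.
    """
    if mask.mask.shape != wheel.mask.shape:
        raise ValueError("mask and wheel shapes differ")
    below = ~mask.mask
    structure = connectivity_structure(connectivity)
    comp, n = ndimage.label(below, structure=structure)

    boundary_labels = set(_touches_boundary(comp).tolist()) - {0}
    wheel_filled = ndimage.binary_fill_holes(wheel.mask)
    if bool(np.all(np.isin(np.arange(1, 7), _wheel_faces_touched(wheel.mask)))):
        logger.warning(
            "wheel touches all six volume faces; field of view may clip the wheel"
        )

    counts = np.bincount(comp.ravel(), minlength=n + 1)
    inside = np.unique(comp[wheel_filled & below])
    inside = set(int(v) for v in inside if v != 0)

    voxel_mm3 = mask.voxel_volume_mm3
    min_voxels = min_volume_cm3 * 1000.0 / voxel_mm3

    cavity_ids, external_ids, speck_ids = [], [], []
    for lbl in range(1, n + 1):
        if lbl in boundary_labels:
            external_ids.append(lbl)
        elif lbl in inside:
            if counts[lbl] >= min_voxels:
                cavity_ids.append(lbl)
            else:
                speck_ids.append(lbl)
        else:
            # below-threshold pocket outside the wheel interior, not
            # boundary-connected: background from the wheel's perspective
            external_ids.append(lbl)

    rind_open = bool(boundary_labels & inside)
    if rind_open:
        logger.warning(
            "below-threshold region(s) inside the wheel connect to external air "
            "(rind-open defect); merged into background and not counted"
        )
    if speck_ids:
        logger.info(
            "discarded %d sub-threshold speck component(s) totalling %d voxels "
            "(min volume %.4g cm³)",
            len(speck_ids),
            int(sum(counts[s] for s in speck_ids)),
            min_volume_cm3,
        )

    # relabel in decreasing volume order (stable for equal sizes)
    cavity_ids.sort(key=lambda l: (-counts[l], l))
    mapping = np.zeros(n + 1, dtype=np.int32)
    for new, old in enumerate(cavity_ids, start=1):
        mapping[old] = new
    out = mapping[comp]

    if mode == "2d-stacked":
        out = _relabel_per_slice(out > 0, connectivity)
        k = int(out.max())
        cavity_ids = list(range(1, k + 1))
    elif mode != "3d":
        raise ValueError(f"mode must be '3d' or '2d-stacked', got {mode!r}")

    external_voxels = int(sum(counts[e] for e in external_ids))
    speck_voxels = int(sum(counts[s] for s in speck_ids))
    return LabelMap(
        labels=out,
        n_cavities=len(cavity_ids) if mode == "3d" else int(out.max()),
        connectivity_used=int(connectivity),
        spacing=mask.spacing,
        external_air_voxels=external_voxels,
        discarded_speck_voxels=speck_voxels,
        discarded_speck_count=len(speck_ids),
        rind_open_merged=rind_open,
        mode=mode,
    )


def _relabel_per_slice(cavity_mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Per-slice 2D labeling of an already-identified cavity voxel set."""
    structure2d = ndimage.generate_binary_structure(2, 1 if connectivity == 6 else 2)
    out = np.zeros(cavity_mask.shape, dtype=np.int32)
    next_label = 1
    for z in range(cavity_mask.shape[0]):
        lab, k = ndimage.label(cavity_mask[z], structure=structure2d)
        if k:
            sl = lab > 0
            out[z][sl] = lab[sl] + (next_label - 1)
            next_label += k
    return out


def _wheel_faces_touched(wheel: np.ndarray) -> np.ndarray:
    touched = []
    for axis in range(3):
        first = np.take(wheel, 0, axis=axis)
        last = np.take(wheel, -1, axis=axis)
        if first.any():
            touched.append(2 * axis + 1)
        if last.any():
            touched.append(2 * axis + 2)
    return np.asarray(touched)


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

_OFFSETS = {
    6: [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)],
}
_OFFSETS[18] = _OFFSETS[6] + [
    (a, b, c)
    for a in (-1, 0, 1)
    for b in (-1, 0, 1)
    for c in (-1, 0, 1)
    if abs(a) + abs(b) + abs(c) == 2
]
_OFFSETS[26] = [
    (a, b, c)
    for a in (-1, 0, 1)
    for b in (-1, 0, 1)
    for c in (-1, 0, 1)
    if (a, b, c) != (0, 0, 0)
]


def labeling_oracle(mask: BinaryMask, connectivity: int = 6) -> LabelMap:
    """Breadth-first flood-fill reference labeler for small volumes (≤ 32³).

    Independent of :func:`label_cavities` (no ``scipy.ndimage``): plain BFS
    over explicit neighbour offsets.  External air is found by flooding from
    every boundary below-threshold voxel; the remaining below-threshold
    components are cavities, labeled in decreasing size order.  No wheel or
    minimum-size handling — intended for partition-equivalence checks on
    random binary volumes.
    """
    shape = mask.mask.shape
    if np.prod(shape) > 32**3:
        raise ValueError("labeling_oracle refuses volumes larger than 32³ voxels")
    offsets = _OFFSETS[int(connectivity)]
    below = ~mask.mask
    visited = np.zeros(shape, dtype=bool)

    def flood(seed):
        q = deque([seed])
        visited[seed] = True
        comp = [seed]
        while q:
            z, y, x = q.popleft()
            for dz, dy, dx in offsets:
                nz, ny, nx = z + dz, y + dy, x + dx
                if 0 <= nz < shape[0] and 0 <= ny < shape[1] and 0 <= nx < shape[2]:
                    if below[nz, ny, nx] and not visited[nz, ny, nx]:
                        visited[nz, ny, nx] = True
                        q.append((nz, ny, nx))
                        comp.append((nz, ny, nx))
        return comp

    external_voxels = 0
    for seed in zip(*np.nonzero(below)):
        z, y, x = seed
        on_boundary = (
            z in (0, shape[0] - 1) or y in (0, shape[1] - 1) or x in (0, shape[2] - 1)
        )
        if on_boundary and not visited[seed]:
            external_voxels += len(flood(seed))

    components = []
    for seed in zip(*np.nonzero(below & ~visited)):
        if not visited[seed]:
            components.append(flood(seed))

    components.sort(key=len, reverse=True)
    labels = np.zeros(shape, dtype=np.int32)
    for k, comp in enumerate(components, start=1):
        for vox in comp:
            labels[vox] = k
    return LabelMap(
        labels=labels,
        n_cavities=len(components),
        connectivity_used=int(connectivity),
        spacing=mask.spacing,
        external_air_voxels=external_voxels,
    )
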