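"""End-to-end analysis of one scan: density → masks → cavities → summary."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

from scipy import ndimage

from . import morphometry, segmentation
from .morphometry import CavityRecord, WheelSummary
from .segmentation import BinaryMask, LabelMap
from .volume_io import DensityVolume, ScanVolume, scan_to_density

__all__ = ["PipelineConfig", "AnalysisResult", "analyze_scan"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters, serialized with every report.

    Defaults: 850 kg/m³ cheese threshold, stored-CTN offset 1024,
    26/6 complementary connectivity (cheese/cavity), 0.01 cm³ minimum cavity
    volume, full-3D labeling, 3D sphericity roundness, crack flagging at
    roundness < 0.4 and volume > 1 cm³ (flagged cavities stay in the eye
    summaries), α = 0.05.
    """

    threshold: float = 850.0
    ctn_offset: float = 1024.0
    wheel_connectivity: int = 26
    cavity_connectivity: int = 6
    min_volume_cm3: float = 0.01
    labeling_mode: str = "3d"
    roundness_definition: str = "sphericity3d"
    crack_roundness_cutoff: float = 0.4
    crack_volume_cutoff_cm3: float = 1.0
    include_cracks_in_summary: bool = True
    wax_erosion_mm: float = 0.0  # erode the wheel rind before volume counting
    alpha: float = 0.05
    out_dir: str = "cheesect_out"
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Load from a flat ``key = value`` text file; unknown keys rejected."""
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            default = getattr(cls, key)
            if isinstance(default, bool):
                kwargs[key] = value.lower() in ("1", "true", "yes", "on")
            elif isinstance(default, int):
                kwargs[key] = int(value)
            elif isinstance(default, float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


@dataclass
class AnalysisResult:
    """Everything produced for one wheel."""

    summary: WheelSummary
    catalog: list[CavityRecord]
    density: DensityVolume
    mask: BinaryMask
    wheel: BinaryMask
    labelmap: LabelMap
    config: PipelineConfig = field(default_factory=PipelineConfig)


def analyze_scan(scan: ScanVolume, config: PipelineConfig | None = None) -> AnalysisResult:
    """Run the full single-wheel pipeline on a CT scan."""
    config = config or PipelineConfig()
    density = scan_to_density(scan, offset=config.ctn_offset)
    mask = segmentation.threshold_volume(density, threshold=config.threshold)
    wheel = segmentation.extract_wheel(mask, connectivity=config.wheel_connectivity)
    labelmap = segmentation.label_cavities(
        mask,
        wheel,
        connectivity=config.cavity_connectivity,
        min_volume_cm3=config.min_volume_cm3,
        mode=config.labeling_mode,
    )
    catalog = morphometry.build_catalog(labelmap)
    morphometry.flag_cracks(
        catalog,
        roundness_cutoff=config.crack_roundness_cutoff,
        volume_cutoff_cm3=config.crack_volume_cutoff_cm3,
    )
    wheel_voxels = int(wheel.mask.sum())
    if config.wax_erosion_mm > 0:
        iters = max(1, round(config.wax_erosion_mm / min(scan.spacing)))
        eroded = ndimage.binary_erosion(wheel.mask, iterations=iters)
        logger.info(
            "wax erosion %.2f mm (%d iteration(s)) removed %d rind voxels "
            "from the wheel-volume count",
            config.wax_erosion_mm, iters, wheel_voxels - int(eroded.sum()),
        )
        wheel_voxels = int(eroded.sum())
    summary = morphometry.summarize_wheel(
        catalog,
        wheel_voxel_count=wheel_voxels,
        spacing=scan.spacing,
        meta=scan.meta,
        include_cracks=config.include_cracks_in_summary,
    )
    return AnalysisResult(
        summary=summary,
        catalog=catalog,
        density=density,
        mask=mask,
        wheel=wheel,
        labelmap=labelmap,
        config=config,
    )
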