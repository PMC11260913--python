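"""Figure and file outputs for analysis results.

All numeric outputs (CSV/JSON) are written independently of plotting; the
montage images are illustrations only.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__
from .group_stats import GroupComparison
from .morphometry import catalog_to_rows
from .pipeline import AnalysisResult

__all__ = [
    "write_analysis_outputs",
    "save_slice_montage",
    "save_quarter_sections",
    "write_comparison_outputs",
]


def write_analysis_outputs(result: AnalysisResult, out_dir, stem: str) -> dict:
    """Write cavity CSV, summary JSON and montage PNGs for one wheel.

    Returns the paths written.  JSON embeds the resolved config and package
    version for provenance; dict keys are emitted in a fixed order so
    re-running on identical input is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    csv_path = out_dir / f"{stem}_cavities.csv"
    pd.DataFrame(
        catalog_to_rows(result.catalog),
        columns=[
            "label", "voxel_count", "volume_cm3", "surface_area_mm2", "roundness",
            "centroid_z_mm", "centroid_y_mm", "centroid_x_mm", "n_slices", "crack_flag",
        ],
    ).to_csv(csv_path, index=False)
    paths["cavities_csv"] = csv_path

    summary_path = out_dir / f"{stem}_summary.json"
    payload = {
        "software": {"name": "cheesect", "version": __version__},
        "config": result.config.to_dict(),
        "summary": result.summary.to_dict(),
        "labeling": {
            "n_cavities": result.labelmap.n_cavities,
            "mode": result.labelmap.mode,
            "connectivity": result.labelmap.connectivity_used,
            "external_air_voxels": result.labelmap.external_air_voxels,
            "discarded_speck_count": result.labelmap.discarded_speck_count,
            "discarded_speck_voxels": result.labelmap.discarded_speck_voxels,
            "rind_open_merged": result.labelmap.rind_open_merged,
        },
    }
    summary_path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    paths["summary_json"] = summary_path

    montage_path = out_dir / f"{stem}_montage.png"
    save_slice_montage(result, montage_path)
    paths["montage_png"] = montage_path

    quarter_path = out_dir / f"{stem}_sections.png"
    save_quarter_sections(result, quarter_path)
    paths["sections_png"] = quarter_path
    return paths


def _outline(ax, labels2d):
    if labels2d.any():
        ax.contour(labels2d > 0, levels=[0.5], colors="red", linewidths=0.6)


def save_slice_montage(result: AnalysisResult, path, n_slices: int = 6) -> None:
    """Grid of axial density slices with cavity outlines."""
    rho = result.density.rho
    labels = result.labelmap.labels
    idx = np.linspace(0, rho.shape[0] - 1, n_slices).astype(int)
    ncols = 3
    nrows = int(np.ceil(n_slices / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(3.2 * ncols, 3.2 * nrows))
    for ax, z in zip(np.ravel(axes), idx):
        ax.imshow(rho[z], cmap="gray", vmin=0, vmax=1300)
        _outline(ax, labels[z])
        ax.set_title(f"slice {z}", fontsize=8)
        ax.axis("off")
    for ax in np.ravel(axes)[len(idx):]:
        ax.axis("off")
    fig.suptitle(f"{result.summary.cheese_id}: density with cavity outlines")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def save_quarter_sections(result: AnalysisResult, path) -> None:
    """Half-depth axial cut and mid-plane vertical cut, side by side."""
    rho = result.density.rho
    labels = result.labelmap.labels
    zc = rho.shape[0] // 2
    yc = rho.shape[1] // 2
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4.2))
    ax1.imshow(rho[zc], cmap="gray", vmin=0, vmax=1300)
    _outline(ax1, labels[zc])
    ax1.set_title("half-depth cut")
    ax2.imshow(rho[:, yc, :], cmap="gray", vmin=0, vmax=1300, aspect="auto")
    _outline(ax2, labels[:, yc, :])
    ax2.set_title("mid-plane cut")
    for ax in (ax1, ax2):
        ax.axis("off")
    fig.suptitle(f"{result.summary.cheese_id}: sections")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def write_comparison_outputs(
    comparisons: list[GroupComparison], out_dir, table_text: str, config_dict: dict
) -> dict:
    """Write the group-comparison report (JSON + CSV + text table)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "software": {"name": "cheesect", "version": __version__},
        "config": config_dict,
        "note": "no multiple-testing correction across metrics",
        "comparisons": [
            {
                "metric": c.metric,
                "groups": c.group_labels,
                "means": c.group_means,
                "sds": c.group_sds,
                "ns": c.group_ns,
                "F": c.anova.F,
                "df": [c.anova.df_between, c.anova.df_within],
                "p": c.anova.p,
                "letters": c.letters,
                "tukey": [
                    {
                        "pair": [p.group_a, p.group_b],
                        "difference": p.difference,
                        "p_adjusted": p.p_adjusted,
                        "significant": p.significant,
                    }
                    for p in c.tukey
                ],
            }
            for c in comparisons
        ],
    }
    json_path = out_dir / "comparison.json"
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True))

    rows = []
    for c in comparisons:
        for name, mean, sd, n in zip(
            c.group_labels, c.group_means, c.group_sds, c.group_ns
        ):
            rows.append(
                {
                    "metric": c.metric,
                    "group": name,
                    "n": n,
                    "mean": mean,
                    "sd": sd,
                    "letters": c.letters[name],
                    "F": c.anova.F,
                    "p": c.anova.p,
                }
            )
    csv_path = out_dir / "comparison.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False)

    table_path = out_dir / "comparison_table.txt"
    table_path.write_text(table_text + "\n")
    return {"json": json_path, "csv": csv_path, "table": table_path}
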