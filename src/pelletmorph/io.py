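"""File I/O: images, volume stacks, tables, reports.

Conventions fixed repo-wide: lengths in µm (total hyphal length reported in
m), concentrations in mL⁻¹ and g L⁻¹, time in h; voxel indices 0-based with
world coordinate = index × voxel_size + origin.  Volumes travel as
multi-page TIFF stacks with a JSON sidecar naming the voxel size; projection
images as 16-bit TIFF; tables as CSV.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .image2d import Image2D, PelletRegion2D
from .kinetics import GrowthSeries
from .tomo3d import PelletMetrics3D, PelletVolume, RadialProfile

__all__ = [
    "read_image",
    "write_image",
    "read_volume",
    "write_volume",
    "regions_to_dataframe",
    "metrics_to_dataframe",
    "read_metrics_csv",
    "write_metrics_csv",
    "radial_profiles_to_dataframe",
    "read_growth_series_csv",
    "write_json",
]


def read_image(path, pixel_size: float, sampled_volume: float = 1.0) -> Image2D:
    """Read a 2D TIFF/PNG population image."""
    arr = np.asarray(iio.imread(path)).astype(float)
    if arr.ndim == 3:  # collapse colour to luminance
        arr = arr.mean(axis=-1)
    return Image2D(arr, pixel_size, sampled_volume)


def write_image(path, img: Image2D) -> None:
    """Write an image as 16-bit TIFF; intensities are rescaled to 0–65535."""
    arr = img.pixels
    lo, hi = float(arr.min()), float(arr.max())
    scale = 65535.0 / (hi - lo) if hi > lo else 0.0
    out = ((arr - lo) * scale).astype(np.uint16)
    tifffile.imwrite(str(path), out)


def write_volume(path, vol: PelletVolume) -> None:
    """Write a binary volume as multi-page TIFF plus a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(str(path), vol.grid.astype(np.uint8) * 255)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps({"voxel_size_um": vol.voxel_size, "origin_um": vol.origin.tolist()})
    )


def read_volume(path, voxel_size: float | None = None) -> PelletVolume:
    """Read a multi-page TIFF stack; voxel size from arg or JSON sidecar."""
    path = Path(path)
    origin = np.zeros(3)
    if voxel_size is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise ValueError(
                f"voxel size unknown: pass voxel_size or provide sidecar {sidecar.name} "
                "with field 'voxel_size_um'"
            )
        meta = json.loads(sidecar.read_text())
        if "voxel_size_um" not in meta:
            raise ValueError(f"sidecar {sidecar.name} missing field 'voxel_size_um'")
        voxel_size = float(meta["voxel_size_um"])
        origin = np.asarray(meta.get("origin_um", [0, 0, 0]), dtype=float)
    grid = np.asarray(tifffile.imread(str(path))) > 0
    return PelletVolume(grid, voxel_size, origin)


def regions_to_dataframe(regions: list[PelletRegion2D]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "label": r.label,
                "area_um2": r.area,
                "diameter_um": r.area_equivalent_diameter,
                "centroid_x_um": r.centroid[0],
                "centroid_y_um": r.centroid[1],
                "is_dispersed": r.is_dispersed,
                "touches_border": r.touches_border,
            }
            for r in regions
        ]
    )


def metrics_to_dataframe(metrics: list[PelletMetrics3D]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(m) for m in metrics])


def write_metrics_csv(path, metrics: list[PelletMetrics3D]) -> None:
    metrics_to_dataframe(metrics).to_csv(path, index=False, float_format="%.10g")


def read_metrics_csv(path) -> list[PelletMetrics3D]:
    df = pd.read_csv(path)
    fields = {f.name for f in dataclasses.fields(PelletMetrics3D)}
    missing = fields - set(df.columns)
    if missing:
        raise ValueError(f"metrics table missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        kwargs = {k: row[k] for k in fields}
        for opt in ("avg_branch_length", "hyphal_diameter"):
            if pd.isna(kwargs[opt]):
                kwargs[opt] = None
        if pd.isna(kwargs["n_spore_clusters"]):
            kwargs["n_spore_clusters"] = None
        else:
            kwargs["n_spore_clusters"] = int(kwargs["n_spore_clusters"])
        if pd.isna(kwargs["pellet_id"]):
            kwargs["pellet_id"] = None
        for k in ("n_tips", "n_branch_points", "n_branch_segments"):
            kwargs[k] = int(kwargs[k])
        kwargs["envelope_degenerate"] = bool(kwargs["envelope_degenerate"])
        out.append(PelletMetrics3D(**kwargs))
    return out


def radial_profiles_to_dataframe(profiles: dict[str, RadialProfile]) -> pd.DataFrame:
    """Long-format table: pellet_id, shell_inner_r_um, solid_fraction."""
    rows = []
    for pid, prof in profiles.items():
        for r, f in zip(prof.shell_inner_radii, prof.solid_fraction_per_shell):
            rows.append(
                {"pellet_id": pid, "shell_inner_r_um": float(r), "solid_fraction": float(f)}
            )
    return pd.DataFrame(rows)


def read_growth_series_csv(path, replicate: str | None = None) -> GrowthSeries:
    """Read a kinetics CSV (time_h, cdw_g_per_L, glucose_g_per_L[, replicate]).

    Malformed rows are rejected with the offending row and column named.
    """
    df = pd.read_csv(path)
    required = ["time_h", "cdw_g_per_L", "glucose_g_per_L"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in required:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ValueError(f"{path}: non-numeric value in column '{col}', row {bad[0]}")
        if col != "time_h":
            neg = df.index[df[col] < 0]
            if len(neg):
                raise ValueError(f"{path}: negative value in column '{col}', row {neg[0]}")
    return GrowthSeries.from_dataframe(df, replicate)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")
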