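"""File formats: NIfTI-1 volumes with a JSON frame-timing sidecar, CSV
curves and tables, YAML configuration, and the run manifest.

NIfTI has no standard field for dynamic frame timing, so a 4-D image is
always written as a pair: ``image.nii.gz`` plus ``image.json`` holding
``frame_starts_s``, ``frame_durations_s`` and the axis-convention tag.
CSV numbers are written with 12 significant digits for reproducible diffs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .frames import FrameSchedule, SampledCurve
from .synth import AXIS_CONVENTION, DynamicImage

__all__ = [
    "CSV_FLOAT_FORMAT",
    "RunManifest",
    "read_dynamic_image",
    "write_dynamic_image",
    "read_curve_csv",
    "write_curve_csv",
    "write_volume",
    "read_volume",
    "write_results",
]

CSV_FLOAT_FORMAT = "%.12g"


def _affine(voxel_size_mm: float) -> np.ndarray:
    return np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])


def write_dynamic_image(
    img: DynamicImage, path_image: str | Path, path_timing: str | Path | None = None
) -> tuple[Path, Path]:
    """Write a dynamic image as NIfTI-1 plus its JSON timing sidecar."""
    path_image = Path(path_image)
    if path_timing is None:
        path_timing = path_image.with_suffix("").with_suffix(".json")
    path_timing = Path(path_timing)
    nib.save(nib.Nifti1Image(img.data, _affine(img.voxel_size_mm)), str(path_image))
    sidecar = {
        "frame_starts_s": img.schedule.starts_s.tolist(),
        "frame_durations_s": img.schedule.durations_s.tolist(),
        "axis_convention": img.axis_convention,
        "voxel_size_mm": img.voxel_size_mm,
    }
    path_timing.write_text(json.dumps(sidecar, indent=1))
    return path_image, path_timing


def read_dynamic_image(
    path_image: str | Path, path_timing: str | Path
) -> DynamicImage:
    """Read and validate a 4-D dynamic volume with its timing sidecar.

    Raises descriptive errors on frame-count mismatch, missing sidecar
    keys, or a non-contiguous / non-monotone schedule.
    """
    path_timing = Path(path_timing)
    if not path_timing.exists():
        raise FileNotFoundError(f"missing timing sidecar: {path_timing}")
    sidecar = json.loads(path_timing.read_text())
    for key in ("frame_starts_s", "frame_durations_s"):
        if key not in sidecar:
            raise ValueError(f"timing sidecar lacks required key {key!r}")
    schedule = FrameSchedule(
        np.asarray(sidecar["frame_starts_s"], dtype=float),
        np.asarray(sidecar["frame_durations_s"], dtype=float),
    )
    nii = nib.load(str(path_image))
    data = np.asarray(nii.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path_image}: expected a 4-D volume, got {data.ndim}-D")
    if data.shape[3] != schedule.n_frames:
        raise ValueError(
            f"{path_image}: {data.shape[3]} frames but sidecar lists "
            f"{schedule.n_frames}"
        )
    voxel = float(sidecar.get("voxel_size_mm", abs(nii.affine[0, 0])))
    return DynamicImage(
        data=data,
        schedule=schedule,
        voxel_size_mm=voxel,
        axis_convention=sidecar.get("axis_convention", AXIS_CONVENTION),
    )


def write_volume(
    data: np.ndarray, voxel_size_mm: float, path: str | Path
) -> Path:
    """Write a 3-D map or mask as NIfTI-1 (masks as 8-bit)."""
    path = Path(path)
    arr = np.asarray(data)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    nib.save(nib.Nifti1Image(arr, _affine(voxel_size_mm)), str(path))
    return path


def read_volume(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj)


def write_curve_csv(curve: SampledCurve, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"time_s": curve.times_s, "value_kBq_per_mL": curve.values}
    ).to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)
    return path


def read_curve_csv(path: str | Path) -> SampledCurve:
    df = pd.read_csv(path)
    for col in ("time_s", "value_kBq_per_mL"):
        if col not in df.columns:
            raise ValueError(f"{path}: curve CSV lacks column {col!r}")
    return SampledCurve(
        df["time_s"].to_numpy(float), df["value_kBq_per_mL"].to_numpy(float)
    )


@dataclass
class RunManifest:
    """Record of one pipeline run: config, seeds, outputs, version."""

    config: dict[str, Any] = field(default_factory=dict)
    seeds: dict[str, int] = field(default_factory=dict)
    conditions: list[str] = field(default_factory=list)
    stages: dict[str, str] = field(default_factory=dict)
    artifacts: list[str] = field(default_factory=list)
    tool_version: str = ""

    def add_artifact(self, path: str | Path) -> None:
        self.artifacts.append(str(path))

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "config": self.config,
            "seeds": self.seeds,
            "conditions": self.conditions,
            "stages": self.stages,
            "artifacts": self.artifacts,
            "tool_version": self.tool_version,
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        return path


def write_results(
    tables: dict[str, pd.DataFrame],
    maps: dict[str, tuple[np.ndarray, float]],
    manifest: RunManifest,
    out_dir: str | Path,
) -> list[Path]:
    """Write CSV tables, NIfTI maps and the manifest to a directory.

    ``maps`` values are ``(array, voxel_size_mm)`` pairs.  Every written
    file is listed in the manifest; rerunning with identical inputs
    reproduces identical CSV content (fixed 12-significant-digit format).
    Returns the written paths (manifest last).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, df in tables.items():
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False, float_format=CSV_FLOAT_FORMAT)
        written.append(p)
        manifest.add_artifact(p)
    for name, (arr, voxel) in maps.items():
        p = out_dir / f"{name}.nii.gz"
        write_volume(arr, voxel, p)
        written.append(p)
        manifest.add_artifact(p)
    mpath = out_dir / "manifest.json"
    manifest.add_artifact(mpath)
    manifest.write(mpath)
    written.append(mpath)
    return written


def load_yaml_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}
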