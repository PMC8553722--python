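"""Reading and writing volumes, masks and puncta tables.

Volumes go to one TIFF stack per channel plus a sidecar JSON recording
channel names and physical voxel sizes; label volumes to a single TIFF;
puncta tables to CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .localization import SegmentationLabels, VoxelGrid

__all__ = [
    "write_volume", "read_volume", "write_labels", "read_labels",
    "write_puncta", "read_puncta",
]

SIDECAR = "volume.json"


def write_volume(directory, grid: VoxelGrid, prefix: str = "") -> Path:
    """Write each channel as ``<prefix><channel>.tif`` plus a sidecar JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {"voxel_size_um_zyx": list(grid.voxel_size), "channels": {}}
    for name, arr in grid.channels.items():
        fname = f"{prefix}{name}.tif"
        tifffile.imwrite(directory / fname, arr.astype(np.float32))
        meta["channels"][name] = fname
    sidecar = directory / f"{prefix}{SIDECAR}"
    sidecar.write_text(json.dumps(meta, indent=2))
    return sidecar


def read_volume(sidecar) -> VoxelGrid:
    sidecar = Path(sidecar)
    meta = json.loads(sidecar.read_text())
    channels = {
        name: tifffile.imread(sidecar.parent / fname)
        for name, fname in meta["channels"].items()
    }
    return VoxelGrid(channels=channels, voxel_size=tuple(meta["voxel_size_um_zyx"]))


def write_labels(path, labels: SegmentationLabels) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, labels.labels.astype(np.int32))
    path.with_suffix(".json").write_text(
        json.dumps({"voxel_size_um_zyx": list(labels.voxel_size)})
    )
    return path


def read_labels(path) -> SegmentationLabels:
    path = Path(path)
    arr = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return SegmentationLabels(arr.astype(np.int32), tuple(meta["voxel_size_um_zyx"]))


def write_puncta(path, table: pd.DataFrame) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


def read_puncta(path) -> pd.DataFrame:
    return pd.read_csv(path)
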