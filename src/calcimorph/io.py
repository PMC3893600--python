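"""Volumetric image and table I/O.

Volumes are reconstructed micro-CT stacks: a 3D scalar grid in (z, y, x)
order (slice index = axis 0, x fastest-varying in files) with an isotropic
voxel size in mm.  Voxel ``i`` occupies the cube whose centre sits at
``(i + 0.5) * voxel_size`` mm; this convention is used everywhere meshes or
world coordinates are produced.  Only isotropic voxels are supported —
anisotropic input is an explicit error, never silently resampled.

The voxel size is supplied by the caller (CLI/config); vendor log formats
are proprietary and are not parsed.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "VoxelVolume",
    "BinaryMask",
    "CountTable",
    "read_volume",
    "write_volume",
    "read_count_table",
    "load_reference_counts",
    "load_reference_morphometry",
    "load_reference_size_classes",
]

READER_COLUMNS = [
    "expert1_r1",
    "expert1_r2",
    "expert2_r1",
    "expert2_r2",
    "expert3_r1",
    "expert3_r2",
]


@dataclass
class VoxelVolume:
    """A 3D grayscale grid with isotropic voxel size.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Intensity in detector units.
    voxel_size : float
        Isotropic voxel edge length in mm (> 0).
    name : str
        Free-text sample identifier.
    """

    data: np.ndarray
    voxel_size: float
    name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError(f"all dimensions must be >= 1, got {self.data.shape}")
        if not (self.voxel_size > 0):
            raise ValueError(f"voxel_size must be > 0 mm, got {self.voxel_size}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(
            np.isfinite(self.data)
        ):
            raise ValueError("volume intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class BinaryMask:
    """Boolean foreground mask with the voxel size of its source volume."""

    data: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")
        if not (self.voxel_size > 0):
            raise ValueError("voxel_size must be > 0 mm")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


_TIFF_EXTS = {".tif", ".tiff"}


def read_volume(path: str | Path, voxel_size_mm: float, name: str | None = None) -> VoxelVolume:
    """Read a slice-stack directory or a single multi-page TIFF.

    A directory is read as equally sized 2D slices stacked along axis 0 in
    lexicographic filename order.  Dtype is preserved.
    """
    if voxel_size_mm is None or not (voxel_size_mm > 0):
        raise ValueError("a positive voxel size in mm is required (configuration error)")
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _TIFF_EXTS)
        if not files:
            raise FileNotFoundError(f"no TIFF slices found in {path}")
        slices = [tifffile.imread(f) for f in files]
        shapes = {s.shape for s in slices}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent slice shapes in {path}: {sorted(shapes)}")
        data = np.stack(slices, axis=0)
    else:
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
    return VoxelVolume(data, voxel_size_mm, name=name or path.stem)


def write_volume(vol: VoxelVolume, path: str | Path, as_stack: bool = False) -> None:
    """Write a volume as a multi-page TIFF, or as a slice directory.

    Lossless round-trip for integer dtypes.
    """
    if 0 in vol.data.shape:
        raise ValueError("refusing to write an empty volume")
    path = Path(path)
    if as_stack:
        path.mkdir(parents=True, exist_ok=True)
        ndig = len(str(vol.data.shape[0] - 1))
        for k in range(vol.data.shape[0]):
            tifffile.imwrite(path / f"slice_{k:0{ndig}d}.tif", vol.data[k])
    else:
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, vol.data)


@dataclass
class CountTable:
    """Per-subject microcalcification counts: six expert readings + micro-CT.

    Three expert mammographers each counted twice (reading sessions three
    months apart); the seventh value is the automated object count from the
    3D analysis of the same biopsy cores.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.frame
        required = ["subject", "group", *READER_COLUMNS, "microct"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"count table missing columns: {missing}")
        counts = df[READER_COLUMNS + ["microct"]]
        if counts.isna().any().any():
            raise ValueError("count table has missing count values")
        arr = counts.to_numpy()
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integers")
        if (arr < 0).any():
            raise ValueError("counts must be nonnegative")
        bad = set(df["group"]) - {"benign", "malignant"}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        self.frame = df.reset_index(drop=True)

    def readings(self, subject: str) -> tuple[np.ndarray, int]:
        row = self.frame.loc[self.frame["subject"] == subject]
        if row.empty:
            raise KeyError(subject)
        return (
            row[READER_COLUMNS].to_numpy()[0].astype(int),
            int(row["microct"].iloc[0]),
        )

    def group(self, label: str) -> "CountTable":
        return CountTable(self.frame[self.frame["group"] == label].copy())

    def __len__(self) -> int:
        return len(self.frame)


def read_count_table(path: str | Path) -> CountTable:
    """Read and validate a reader-count CSV (header row, UTF-8)."""
    return CountTable(pd.read_csv(path))


def _data_path(fname: str):
    return importlib.resources.files("calcimorph.data").joinpath(fname)


def load_reference_counts() -> CountTable:
    """Expert and micro-CT counts for the 11-subject reference biopsy cohort."""
    with importlib.resources.as_file(_data_path("reference_counts.csv")) as p:
        return read_count_table(p)


def load_reference_morphometry() -> pd.DataFrame:
    """Per-subject mean morphometric parameters of the reference cohort.

    Columns: obj_v_mm3, obj_s_mm2, sv_per_mm, st_th_mm, smi, obj_n —
    each value is the average over all microcalcifications in that subject's
    biopsy cores.
    """
    with importlib.resources.as_file(_data_path("reference_subject_morphometry.csv")) as p:
        return pd.read_csv(p)


def load_reference_size_classes() -> pd.DataFrame:
    """Per-group object counts of the reference cohort by volume class.

    ``small_objects`` are > 2 voxels and <= 0.0042 mm^3, ``large_objects``
    > 0.0042 mm^3; ``total_objects`` includes sub-resolution (<= 2 voxel)
    objects; ``macro_excluded`` counts > 1 mm objects removed upstream.
    """
    with importlib.resources.as_file(_data_path("reference_size_classes.csv")) as p:
        return pd.read_csv(p)
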