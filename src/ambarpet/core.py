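"""Core volume data model and NIfTI-1 I/O.

A :class:`Volume` is a 3-D scalar grid with isotropic-or-not voxel spacing and
a ``space_tag`` asserting that two volumes live in the same analysis space.
The tag plays the role that spatial normalisation to a common stereotactic
space plays for real scans: volumes may only be combined arithmetically when
their grids, voxel sizes and space tags agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Volume",
    "AtlasParcellation",
    "read_volume",
    "write_volume",
    "read_parcellation",
    "write_parcellation",
]

#: voxel-size agreement tolerance (mm) when combining two volumes
VOXEL_SIZE_TOL_MM = 1e-3


@dataclass(frozen=True)
class Volume:
    """A 3-D scalar brain volume.

    Parameters
    ----------
    data:
        3-D float array. Stored internally in double precision; written to
        disk as float32.
    voxel_size_mm:
        Edge length of a voxel along each axis, in millimetres.
    space_tag:
        Identifier of the common analysis space (default ``"phantom"``).
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    space_tag: str = "phantom"

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=np.float64)
        if arr.ndim != 3:
            raise ValueError(f"expected 3D volume, got {arr.ndim}D")
        if not np.all(np.isfinite(arr)):
            raise ValueError("volume contains non-finite values")
        vs = tuple(float(v) for v in self.voxel_size_mm)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size_mm must be 3 positive scalars, got {self.voxel_size_mm}")
        object.__setattr__(self, "data", arr)
        object.__setattr__(self, "voxel_size_mm", vs)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def like(self, data: np.ndarray) -> "Volume":
        """New volume on this grid with different data."""
        return replace(self, data=np.asarray(data, dtype=np.float64))

    def assert_compatible(self, other: "Volume") -> None:
        """Raise unless the two volumes may be combined voxel-wise."""
        if self.shape != other.shape:
            raise ValueError(f"shape mismatch: {self.shape} vs {other.shape}")
        if any(
            abs(a - b) > VOXEL_SIZE_TOL_MM
            for a, b in zip(self.voxel_size_mm, other.voxel_size_mm)
        ):
            raise ValueError(
                f"voxel size mismatch: {self.voxel_size_mm} vs {other.voxel_size_mm}"
            )
        if self.space_tag != other.space_tag:
            raise ValueError(f"space tag mismatch: {self.space_tag!r} vs {other.space_tag!r}")


@dataclass(frozen=True)
class AtlasParcellation:
    """Integer label volume plus its region table.

    ``regions`` has columns ``region_id, name, lobe, cerebellum_flag`` and
    optionally ``ad_flag`` (regions carrying seeded disease decline in the
    phantom). Label 0 is background and never appears in the table.
    """

    labels: np.ndarray
    regions: pd.DataFrame
    voxel_size_mm: tuple[float, float, float]
    space_tag: str = "phantom"

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 3:
            raise ValueError("parcellation labels must be a 3D grid")
        if not np.issubdtype(lab.dtype, np.integer):
            lab = lab.astype(np.int32)
        object.__setattr__(self, "labels", lab)
        req = {"region_id", "name", "lobe", "cerebellum_flag"}
        missing = req - set(self.regions.columns)
        if missing:
            raise ValueError(f"region table missing columns: {sorted(missing)}")
        present = set(np.unique(lab)) - {0}
        table_ids = set(int(r) for r in self.regions["region_id"])
        if not present <= table_ids:
            raise ValueError(f"labels missing from region table: {sorted(present - table_ids)}")
        if not self.regions["cerebellum_flag"].astype(bool).any():
            raise ValueError("parcellation must flag at least one cerebellum region")
        object.__setattr__(
            self, "voxel_size_mm", tuple(float(v) for v in self.voxel_size_mm)
        )

    @property
    def region_ids(self) -> list[int]:
        return [int(r) for r in self.regions["region_id"]]

    def cerebellum_ids(self) -> list[int]:
        m = self.regions["cerebellum_flag"].astype(bool)
        return [int(r) for r in self.regions.loc[m, "region_id"]]

    def ad_ids(self) -> list[int]:
        if "ad_flag" not in self.regions.columns:
            return []
        m = self.regions["ad_flag"].astype(bool)
        return [int(r) for r in self.regions.loc[m, "region_id"]]

    def region_mask(self, region_ids: Iterable[int]) -> np.ndarray:
        return np.isin(self.labels, np.fromiter((int(i) for i in region_ids), dtype=np.int64))

    def assert_compatible(self, vol: Volume) -> None:
        if self.labels.shape != vol.shape:
            raise ValueError(
                f"atlas grid {self.labels.shape} does not match volume grid {vol.shape}"
            )
        if any(
            abs(a - b) > VOXEL_SIZE_TOL_MM
            for a, b in zip(self.voxel_size_mm, vol.voxel_size_mm)
        ):
            raise ValueError("atlas voxel size does not match volume voxel size")


def _affine(voxel_size_mm: tuple[float, float, float]) -> np.ndarray:
    aff = np.diag(list(voxel_size_mm) + [1.0])
    return aff


def write_volume(volume: Volume, path: str | Path) -> Path:
    """Write a volume as NIfTI-1, float32 on disk."""
    path = Path(path)
    img = nib.Nifti1Image(volume.data.astype(np.float32), _affine(volume.voxel_size_mm))
    img.header.set_xyzt_units("mm")
    img.header["descrip"] = volume.space_tag.encode()[:79]
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path, space_tag: str | None = None) -> Volume:
    """Read a 3-D NIfTI-1 scalar volume.

    Raises on a missing file, a non-3D image, or NaN voxels, naming the path.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim == 4 and data.shape[-1] == 1 else data
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume in {path}, got {data.ndim}D")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"volume {path} contains NaN or infinite voxels")
    zooms = img.header.get_zooms()[:3]
    tag = space_tag
    if tag is None:
        descrip = bytes(img.header["descrip"]).split(b"\x00")[0].decode(errors="ignore")
        tag = descrip or "phantom"
    return Volume(np.asarray(data, dtype=np.float64), tuple(float(z) for z in zooms), tag)


def write_parcellation(atlas: AtlasParcellation, nifti_path: str | Path, table_path: str | Path) -> None:
    """Persist an atlas as an integer NIfTI volume plus a region CSV."""
    img = nib.Nifti1Image(atlas.labels.astype(np.int16), _affine(atlas.voxel_size_mm))
    img.header["descrip"] = atlas.space_tag.encode()[:79]
    nib.save(img, str(nifti_path))
    atlas.regions.to_csv(table_path, index=False)


def read_parcellation(nifti_path: str | Path, table_path: str | Path) -> AtlasParcellation:
    nifti_path, table_path = Path(nifti_path), Path(table_path)
    for p in (nifti_path, table_path):
        if not p.exists():
            raise FileNotFoundError(f"parcellation file not found: {p}")
    img = nib.load(str(nifti_path))
    labels = np.asanyarray(img.dataobj).astype(np.int32)
    if labels.ndim != 3:
        raise ValueError(f"expected 3D parcellation in {nifti_path}, got {labels.ndim}D")
    regions = pd.read_csv(table_path)
    descrip = bytes(img.header["descrip"]).split(b"\x00")[0].decode(errors="ignore")
    return AtlasParcellation(
        labels,
        regions,
        tuple(float(z) for z in img.header.get_zooms()[:3]),
        descrip or "phantom",
    )
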