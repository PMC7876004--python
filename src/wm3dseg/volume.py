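"""Core volume containers and file I/O.

All volumes use (z, y, x) axis order with 0-based indexing.  Voxel centers
sit at integer index coordinates; world coordinates are ``index *
voxel_size_nm`` per axis.  Two containers cover the pipeline: a scalar
:class:`VolumeGrid` (image intensities or class probabilities) and an
integer :class:`LabelVolume` (0 = background, each positive value one
object instance).
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
import tifffile

__all__ = [
    "VolumeGrid",
    "LabelVolume",
    "read_volume",
    "write_volume",
    "read_tiff_stack",
    "write_tiff_stack",
]


def _as_voxel_size(voxel_size_nm) -> tuple[float, float, float]:
    vs = tuple(float(v) for v in np.atleast_1d(voxel_size_nm).ravel())
    if len(vs) == 1:
        vs = vs * 3
    if len(vs) != 3:
        raise ValueError(f"voxel_size_nm must have 1 or 3 entries, got {vs}")
    if any(v <= 0 for v in vs):
        raise ValueError(f"voxel sizes must be positive, got {vs}")
    return vs


@dataclass
class VolumeGrid:
    """3D scalar field with voxel-size metadata.

    Parameters
    ----------
    data :
        3D array indexed (z, y, x).
    voxel_size_nm :
        Physical voxel size (z, y, x) in nanometres; a scalar is broadcast
        to all three axes.
    is_probability :
        If True, values are validated to lie in [0, 1].
    """

    data: np.ndarray
    voxel_size_nm: tuple[float, float, float] = (50.0, 50.0, 50.0)
    is_probability: bool = False

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        self.voxel_size_nm = _as_voxel_size(self.voxel_size_nm)
        if self.is_probability:
            lo, hi = float(self.data.min()), float(self.data.max())
            if lo < -1e-9 or hi > 1 + 1e-9:
                raise ValueError(
                    f"probability volume outside [0, 1]: range [{lo}, {hi}]"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def dtype_tag(self) -> str:
        dt = self.data.dtype
        if dt == np.uint8:
            return "uint8"
        if dt == np.uint16:
            return "uint16"
        return "float"

    @property
    def voxel_volume_um3(self) -> float:
        z, y, x = self.voxel_size_nm
        return z * y * x * 1e-9

    def copy(self) -> "VolumeGrid":
        return VolumeGrid(self.data.copy(), self.voxel_size_nm, self.is_probability)


@dataclass
class LabelVolume:
    """3D non-negative integer field; 0 is background, each positive value
    labels one instance."""

    data: np.ndarray
    voxel_size_nm: tuple[float, float, float] = (50.0, 50.0, 50.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        if not np.issubdtype(self.data.dtype, np.integer):
            if np.any(self.data != np.round(self.data)):
                raise ValueError("label volume must be integer-valued")
            self.data = self.data.astype(np.int32)
        if self.data.size and self.data.min() < 0:
            raise ValueError("label volume must be non-negative")
        self.voxel_size_nm = _as_voxel_size(self.voxel_size_nm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def labels(self) -> np.ndarray:
        """Sorted positive labels present in the volume."""
        u = np.unique(self.data)
        return u[u > 0]

    @property
    def n_instances(self) -> int:
        return int(self.labels.size)

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.data.copy(), self.voxel_size_nm)


# ---------------------------------------------------------------------------
# HDF5 and TIFF I/O


def write_volume(path, vol, dataset: str = "volume") -> None:
    """Write a VolumeGrid or LabelVolume to an HDF5 dataset with
    ``voxel_size_nm`` and ``axis_order`` attributes."""
    with h5py.File(path, "a") as f:
        if dataset in f:
            del f[dataset]
        d = f.create_dataset(dataset, data=vol.data, compression="gzip")
        d.attrs["voxel_size_nm"] = np.asarray(vol.voxel_size_nm, dtype=float)
        d.attrs["axis_order"] = "zyx"
        d.attrs["kind"] = "labels" if isinstance(vol, LabelVolume) else "scalar"


def read_volume(path, dataset: str = "volume"):
    """Read a volume written by :func:`write_volume`; returns VolumeGrid or
    LabelVolume according to the stored kind."""
    with h5py.File(path, "r") as f:
        d = f[dataset]
        data = d[()]
        vs = tuple(d.attrs.get("voxel_size_nm", (50.0, 50.0, 50.0)))
        kind = d.attrs.get("kind", "scalar")
    if kind == "labels":
        return LabelVolume(data, vs)
    return VolumeGrid(data, vs)


def read_tiff_stack(path, voxel_size_nm=(50.0, 50.0, 50.0)) -> VolumeGrid:
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    return VolumeGrid(data, voxel_size_nm)


def write_tiff_stack(path, vol: VolumeGrid) -> None:
    tifffile.imwrite(path, vol.data, photometric="minisblack")
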