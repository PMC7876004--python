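"""Training-label engineering from a high-resolution segmentation.

A high-resolution, small field-of-view segmentation (myelin, myelinated
and unmyelinated axons, mitochondria, cells) is converted into the class
sets a semantic segmenter is trained on: a 4-class axon set {background,
myelin, myelinated axon, mitochondrion} and a 3-class nucleus set
{background, nucleus, nucleus membrane}, then down-sampled in-plane to the
resolution of the low-resolution acquisitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy import stats

from .volume import LabelVolume, VolumeGrid

__all__ = [
    "ClassLabelVolume",
    "AXON_CLASS_MAP",
    "NUCLEUS_CLASS_MAP",
    "relabel_for_axon_training",
    "make_nucleus_membrane_labels",
    "downsample_xy",
]

# canonical source classes of the high-resolution segmentation
AXON_CLASS_MAP = {
    "background": 0,
    "myelin": 1,
    "myelinated_axon": 2,
    "mitochondrion": 3,
    "unmyelinated_axon": 4,
    "cell": 5,
}

NUCLEUS_CLASS_MAP = {"background": 0, "nucleus": 1, "nucleus_membrane": 2}


@dataclass
class ClassLabelVolume:
    """Small-integer class volume with a name -> value table (background=0)."""

    data: np.ndarray
    class_map: dict[str, int]
    voxel_size_nm: tuple[float, float, float] = (50.0, 50.0, 50.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if "background" not in self.class_map or self.class_map["background"] != 0:
            raise ValueError("class_map must include background=0")
        present = set(np.unique(self.data).tolist())
        allowed = set(self.class_map.values())
        if not present <= allowed:
            raise ValueError(f"voxel values {present - allowed} missing from class_map")

    def mask(self, name: str) -> np.ndarray:
        return self.data == self.class_map[name]


def relabel_for_axon_training(source_labels: ClassLabelVolume) -> ClassLabelVolume:
    """Set unmyelinated axons and cells to background; keep myelin,
    myelinated axons and mitochondria."""
    cm = source_labels.class_map
    for needed in ("unmyelinated_axon", "cell", "myelin",
                   "myelinated_axon", "mitochondrion"):
        if needed not in cm:
            raise ValueError(
                "expected classes {unmyelinated_axon, cell, myelin, "
                f"myelinated_axon, mitochondrion}}; class_map has {sorted(cm)}"
            )
    out = source_labels.data.copy()
    out[(out == cm["unmyelinated_axon"]) | (out == cm["cell"])] = 0
    keep = {k: v for k, v in cm.items()
            if k in ("background", "myelin", "myelinated_axon", "mitochondrion")}
    return ClassLabelVolume(out, keep, source_labels.voxel_size_nm)


def make_nucleus_membrane_labels(nucleus_labels: LabelVolume,
                                 se_width: int = 11) -> ClassLabelVolume:
    """Create an artificial nucleus-membrane class by a slice-wise 2D
    morphological gradient.

    Per slice, with a flat ``se_width`` x ``se_width`` square element:
    membrane = dilation(mask) - erosion(mask); nucleus = eroded interior.
    The element is 2D because the source data are processed slice-wise.
    """
    if se_width < 3 or se_width % 2 == 0:
        raise ValueError(f"se_width must be odd and >= 3, got {se_width}")
    mask = nucleus_labels.data > 0
    se = np.ones((se_width, se_width), bool)
    out = np.zeros(mask.shape, np.int8)
    for z in range(mask.shape[0]):
        dil = ndi.binary_dilation(mask[z], structure=se)
        ero = ndi.binary_erosion(mask[z], structure=se)
        out[z][dil & ~ero] = NUCLEUS_CLASS_MAP["nucleus_membrane"]
        out[z][ero] = NUCLEUS_CLASS_MAP["nucleus"]
    return ClassLabelVolume(out, dict(NUCLEUS_CLASS_MAP),
                            nucleus_labels.voxel_size_nm)


def _block_mode(data: np.ndarray, factor: int) -> np.ndarray:
    """In-plane block majority vote; ties break toward the smaller value."""
    nz, ny, nx = data.shape
    oy, ox = ny // factor, nx // factor
    trimmed = data[:, :oy * factor, :ox * factor]
    blocks = trimmed.reshape(nz, oy, factor, ox, factor)
    blocks = blocks.transpose(0, 1, 3, 2, 4).reshape(nz, oy, ox, factor * factor)
    # scipy's mode returns the smallest value among ties
    return stats.mode(blocks, axis=-1, keepdims=False).mode


def downsample_xy(vol, factor: int):
    """Down-sample in the x-y plane by an integer factor: block mean for
    intensities, block majority vote for labels (ties toward the smaller
    class value); z is unchanged and in-plane voxel size scales by
    ``factor``."""
    if factor < 1:
        raise ValueError(f"factor must be >= 1, got {factor}")
    if factor == 1:
        return vol
    vz, vy, vx = vol.voxel_size_nm
    new_vs = (vz, vy * factor, vx * factor)
    if isinstance(vol, VolumeGrid):
        data = np.asarray(vol.data, float)
        nz, ny, nx = data.shape
        oy, ox = ny // factor, nx // factor
        trimmed = data[:, :oy * factor, :ox * factor]
        mean = trimmed.reshape(nz, oy, factor, ox, factor).mean(axis=(2, 4))
        return VolumeGrid(mean, new_vs)
    if isinstance(vol, ClassLabelVolume):
        return ClassLabelVolume(_block_mode(vol.data, factor),
                                dict(vol.class_map), new_vs)
    if isinstance(vol, LabelVolume):
        return LabelVolume(_block_mode(vol.data, factor), new_vs)
    raise TypeError(f"unsupported volume type {type(vol)}")
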