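"""Initial instance segmentation from class probability maps.

Probability maps for myelin, myelinated axons and mitochondria are
binarized at fixed thresholds; the dilated mitochondria mask is unified
with the axon mask to form the intra-axonal space (IAS); 26-connected
components of the IAS, morphologically closed and size-filtered, give the
initial — possibly under-segmented — axon instances.  The myelin mask
needs no further processing.  Mitochondria instances are assigned to final
axons after shape decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .evalmetrics import voi
from .volume import LabelVolume, VolumeGrid

__all__ = [
    "BinarizationThresholds",
    "IntraAxonalSpace",
    "binarize_maps",
    "make_intra_axonal_space",
    "initial_axon_instances",
    "segment_myelin",
    "mito_instances",
    "select_threshold_by_voi",
    "DEFAULT_MIN_AXON_VOXELS",
]

# volume of a circular cylinder, base radius 0.25 um and height 3 um,
# resolved at isotropic 50 nm voxels
DEFAULT_MIN_AXON_VOXELS = 4700

_STRUCT26 = np.ones((3, 3, 3), bool)
_CUBE3 = np.ones((3, 3, 3), bool)


@dataclass(frozen=True)
class BinarizationThresholds:
    """Class thresholds; a voxel is foreground iff probability is strictly
    greater than the threshold."""

    theta_myelin: float = 0.5
    theta_axon: float = 0.8
    theta_mito: float = 0.8

    def __post_init__(self):
        for name, v in self.__dict__.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class IntraAxonalSpace:
    """Binary intra-axonal-space mask and the thresholds that produced it."""

    mask: np.ndarray
    provenance: BinarizationThresholds | None = None


def _prob_data(m):
    return m.data if isinstance(m, VolumeGrid) else np.asarray(m)


def binarize_maps(maps: dict, thr: BinarizationThresholds):
    """Binarize the three class maps with strict ``>`` thresholds; returns
    (myelin, axon, mito) boolean grids."""
    out = []
    for name, theta in (("myelin", thr.theta_myelin),
                        ("axon", thr.theta_axon),
                        ("mito", thr.theta_mito)):
        pm = _prob_data(maps[name])
        if pm.min() < -1e-9 or pm.max() > 1 + 1e-9:
            raise ValueError(f"{name} map outside [0, 1]")
        out.append(pm > theta)
    return tuple(out)


def make_intra_axonal_space(axon_mask: np.ndarray,
                            mito_mask: np.ndarray) -> IntraAxonalSpace:
    """IAS = axon mask united with the mitochondria mask dilated by a flat
    3x3x3 cube (mitochondria sit inside axons but are a separate class)."""
    axon_mask = np.asarray(axon_mask, bool)
    mito_mask = np.asarray(mito_mask, bool)
    if axon_mask.shape != mito_mask.shape:
        raise ValueError(
            f"shape mismatch: {axon_mask.shape} vs {mito_mask.shape}")
    ias = axon_mask | ndi.binary_dilation(mito_mask, structure=_CUBE3)
    return IntraAxonalSpace(mask=ias)


def initial_axon_instances(ias: IntraAxonalSpace,
                           min_voxels: int = DEFAULT_MIN_AXON_VOXELS
                           ) -> LabelVolume:
    """26-connected components of the IAS, each closed with a 3x3x3 cube,
    size-filtered, and labeled 1..K in decreasing size order."""
    if min_voxels < 0:
        raise ValueError("min_voxels must be >= 0")
    comp, n = ndi.label(ias.mask, structure=_STRUCT26)
    kept = []
    for lab in range(1, n + 1):
        m = comp == lab
        m = ndi.binary_closing(m, structure=_CUBE3)
        size = int(m.sum())
        if size >= min_voxels:
            kept.append((size, lab, m))
    kept.sort(key=lambda t: (-t[0], t[1]))
    out = np.zeros(ias.mask.shape, np.int32)
    for new_lab, (_, _, m) in enumerate(kept, start=1):
        out[m & (out == 0)] = new_lab
    return LabelVolume(out)


def segment_myelin(myelin_mask: np.ndarray) -> np.ndarray:
    """The binarized myelin map is the final myelin segmentation."""
    return np.asarray(myelin_mask, bool)


def mito_instances(mito_mask: np.ndarray, final_axons: LabelVolume,
                   min_inside_fraction: float = 0.5):
    """26-connected mitochondria components kept iff at least
    ``min_inside_fraction`` of their voxels lie within one single axon
    instance; returns (LabelVolume, {mito label: axon label})."""
    comp, n = ndi.label(np.asarray(mito_mask, bool), structure=_STRUCT26)
    axons = final_axons.data
    out = np.zeros(comp.shape, np.int32)
    assignment = {}
    next_lab = 1
    for lab in range(1, n + 1):
        m = comp == lab
        overlay = axons[m]
        inside = overlay[overlay > 0]
        if inside.size == 0:
            continue
        vals, counts = np.unique(inside, return_counts=True)
        best = int(np.argmax(counts))
        if counts[best] / m.sum() >= min_inside_fraction:
            out[m] = next_lab
            assignment[next_lab] = int(vals[best])
            next_lab += 1
    return LabelVolume(out, final_axons.voxel_size_nm), assignment


def select_threshold_by_voi(prob_map, truth: LabelVolume, thresholds):
    """Pick the binarization threshold minimizing VOI split + merge of the
    induced 26-connected instance segmentation against the reference; ties
    break toward the smaller threshold."""
    thresholds = sorted(float(t) for t in np.atleast_1d(thresholds))
    if not thresholds:
        raise ValueError("threshold grid must be non-empty")
    pm = _prob_data(prob_map)
    best_t, best_v = None, np.inf
    for t in thresholds:
        comp, _ = ndi.label(pm > t, structure=_STRUCT26)
        s, m = voi(comp, truth.data)
        total = s + m
        if total < best_v - 1e-12:
            best_v, best_t = total, t
    return best_t
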