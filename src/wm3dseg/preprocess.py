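"""Stack alignment, contrast normalization, bit-depth conversion, tiling.

Serial block-face stacks drift slice-to-slice.  Alignment estimates the
translation between consecutive slices by phase correlation, accumulates
the shifts, and applies the cumulative shift minus its running average so
that slow trends — the genuine orientation of axons through the block —
are preserved while per-slice jitter is removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.registration import phase_cross_correlation

from .volume import VolumeGrid

__all__ = [
    "ShiftSeries",
    "drift_correct",
    "contrast_normalize",
    "to_uint8",
    "tile_volume",
    "reassemble_tiles",
]


@dataclass
class ShiftSeries:
    """Per-slice-pair shifts (voxels); entry i is the displacement of slice
    i+1 relative to slice i."""

    dx: np.ndarray
    dy: np.ndarray
    window: int

    def __post_init__(self):
        self.dx = np.asarray(self.dx, float)
        self.dy = np.asarray(self.dy, float)
        if self.dx.shape != self.dy.shape:
            raise ValueError("dx and dy must have equal length")


def _running_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centred running mean with shrinking (truncated) windows at the ends."""
    half = window // 2
    n = len(x)
    out = np.empty(n)
    csum = np.concatenate(([0.0], np.cumsum(x)))
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = (csum[hi] - csum[lo]) / (hi - lo)
    return out


def drift_correct(stack: VolumeGrid, window: int = 25):
    """Align a serial-section stack by FFT cross-correlation at voxel precision.

    Returns the aligned stack and the raw estimated per-pair shifts.  The
    applied correction per slice is the cumulative shift minus the running
    average (shrinking windows at the ends) of the cumulative series, so a
    linear trend survives while jitter is cancelled.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    data = np.asarray(stack.data)
    nz = data.shape[0]
    if nz < 2:
        raise ValueError("stack must have at least 2 slices")
    if data.shape[1] < 8 or data.shape[2] < 8:
        raise ValueError(f"slices too small to register: {data.shape[1:]}")

    dy = np.zeros(nz - 1)
    dx = np.zeros(nz - 1)
    for i in range(nz - 1):
        shift, _, _ = phase_cross_correlation(
            data[i].astype(float), data[i + 1].astype(float),
            normalization=None, upsample_factor=4,
        )
        dy[i], dx[i] = shift  # displacement of slice i+1 relative to slice i

    # cumulative position of each slice relative to slice 0
    cum_y = np.concatenate(([0.0], np.cumsum(dy)))
    cum_x = np.concatenate(([0.0], np.cumsum(dx)))
    corr_y = np.rint(cum_y - _running_average(cum_y, window)).astype(int)
    corr_x = np.rint(cum_x - _running_average(cum_x, window)).astype(int)

    out = np.empty_like(data)
    for i in range(nz):
        out[i] = np.roll(np.roll(data[i], corr_y[i], axis=0), corr_x[i], axis=1)
    return (
        VolumeGrid(out, stack.voxel_size_nm),
        ShiftSeries(dx=dx, dy=dy, window=window),
    )


def contrast_normalize(stack: VolumeGrid) -> VolumeGrid:
    """Affinely rescale each slice so its mean and standard deviation match
    the global mean and standard deviation of the whole stack (computed
    before normalization).  Constant slices are shifted to the global mean."""
    data = np.asarray(stack.data, float)
    if np.ptp(data) == 0:
        raise ValueError("stack is constant; contrast normalization undefined")
    g_mean = data.mean()
    g_std = data.std()
    out = np.empty_like(data)
    for i in range(data.shape[0]):
        sl = data[i]
        s_mean, s_std = sl.mean(), sl.std()
        if s_std == 0:
            out[i] = g_mean
        else:
            out[i] = (sl - s_mean) * (g_std / s_std) + g_mean
    return VolumeGrid(out, stack.voxel_size_nm)


def to_uint8(stack: VolumeGrid) -> VolumeGrid:
    """Linear min-max rescale to [0, 255] with round-half-up; constant
    volumes map to zero with a warning."""
    data = np.asarray(stack.data, float)
    lo, hi = data.min(), data.max()
    if hi == lo:
        warnings.warn("constant volume; to_uint8 output is all zeros")
        return VolumeGrid(np.zeros(data.shape, np.uint8), stack.voxel_size_nm)
    scaled = (data - lo) / (hi - lo) * 255.0
    out = np.floor(scaled + 0.5).clip(0, 255).astype(np.uint8)
    return VolumeGrid(out, stack.voxel_size_nm)


def tile_volume(vol: VolumeGrid, patch_shape):
    """Non-overlapping tiling; border patches may be smaller.  Returns a list
    of (patch VolumeGrid, (z0, y0, x0) origin offset) allowing bit-identical
    reassembly."""
    ps = tuple(int(p) for p in patch_shape)
    if any(p < 1 for p in ps):
        raise ValueError(f"patch_shape must be >= 1 per axis, got {ps}")
    data = vol.data
    tiles = []
    for z0 in range(0, data.shape[0], ps[0]):
        for y0 in range(0, data.shape[1], ps[1]):
            for x0 in range(0, data.shape[2], ps[2]):
                patch = data[z0:z0 + ps[0], y0:y0 + ps[1], x0:x0 + ps[2]]
                tiles.append((VolumeGrid(patch.copy(), vol.voxel_size_nm),
                              (z0, y0, x0)))
    return tiles


def reassemble_tiles(tiles, shape) -> VolumeGrid:
    """Inverse of :func:`tile_volume`."""
    first = tiles[0][0]
    out = np.zeros(shape, dtype=first.data.dtype)
    for patch, (z0, y0, x0) in tiles:
        pz, py, px = patch.data.shape
        out[z0:z0 + pz, y0:y0 + py, x0:x0 + px] = patch.data
    return VolumeGrid(out, first.voxel_size_nm)
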