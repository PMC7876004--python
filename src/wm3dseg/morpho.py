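"""Per-axon morphometry along the curve skeleton.

For every myelinated axon: cross-sections perpendicular to the skeleton at
fixed arc spacing (equivalent diameter ``2 sqrt(area/pi)`` and eccentricity
``sqrt(1 - (b/a)^2)`` of the second-moment fitted ellipse), tortuosity
(skeleton arc length over endpoint Euclidean distance), and the spatial
distribution of its mitochondria via two inter-mitochondrial distance
definitions: geodesic distance between consecutive projected centroids,
and shortest geodesic gap between consecutive projected extents.  Volume
densities summarize whole datasets: axon density = V_axons / (V_myelin +
V_axons); cell density = nucleus count per unit volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .csd import SubSkeleton, _plane_frame
from .volume import LabelVolume

__all__ = [
    "AxonRecord",
    "DensitySummary",
    "axon_cross_sections",
    "tortuosity",
    "inter_mito_distances_centroid",
    "inter_mito_distances_shortest",
    "densities",
    "summarize_axon",
    "skeleton_from_mask",
]


@dataclass
class AxonRecord:
    axon_id: int
    arc_length_um: float
    euclidean_length_um: float
    tortuosity: float
    median_diameter_um: float
    median_eccentricity: float
    cross_sections: pd.DataFrame | None = None
    mito_ids: list = field(default_factory=list)
    inter_mito_centroid_um: list = field(default_factory=list)
    inter_mito_shortest_um: list = field(default_factory=list)

    def as_row(self) -> dict:
        imc = self.inter_mito_centroid_um
        ims = self.inter_mito_shortest_um
        return dict(
            axon_id=self.axon_id,
            arc_length_um=self.arc_length_um,
            euclidean_length_um=self.euclidean_length_um,
            tortuosity=self.tortuosity,
            median_diameter_um=self.median_diameter_um,
            median_eccentricity=self.median_eccentricity,
            n_mitochondria=len(self.mito_ids),
            mean_inter_mito_centroid_um=(float(np.mean(imc)) if imc
                                         else math.nan),
            mean_inter_mito_shortest_um=(float(np.mean(ims)) if ims
                                         else math.nan),
        )


@dataclass
class DensitySummary:
    axon_density: float          # V_axons / (V_myelin + V_axons)
    cell_density_per_um3: float  # nucleus count / volume


def _section_region(mask, point, tangent, half_width, resolution=0.5):
    """In-plane 8-connected region of ``mask`` containing ``point``; returns
    (binary 2D image, pixel area) or None when empty."""
    t, u, v = _plane_frame(tangent)
    n = int(np.ceil(2 * half_width / resolution)) + 1
    g = np.linspace(-half_width, half_width, n)
    gu, gv = np.meshgrid(g, g, indexing="ij")
    coords = (np.asarray(point, float)[None, :]
              + gu.ravel()[:, None] * u[None, :]
              + gv.ravel()[:, None] * v[None, :])
    vals = ndi.map_coordinates(mask.astype(np.float32), coords.T, order=1,
                               mode="constant", cval=0.0)
    img = vals.reshape(n, n) >= 0.5
    if not img.any():
        return None
    lab, _ = ndi.label(img, structure=np.ones((3, 3), bool))
    c = n // 2
    centre_lab = lab[c, c]
    if centre_lab == 0:
        nz = np.argwhere(lab > 0)
        d = np.abs(nz - c).sum(axis=1)
        if d.min() > 2 / resolution:
            return None
        centre_lab = lab[tuple(nz[int(np.argmin(d))])]
    return lab == centre_lab


def _ellipse_from_region(region, resolution=0.5):
    """(area, eccentricity, major axis length) from in-plane second moments."""
    pts = np.argwhere(region).astype(float) * resolution
    area = len(pts) * resolution ** 2
    c = pts.mean(axis=0)
    rel = pts - c
    cov = rel.T @ rel / len(pts)
    evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    evals = np.maximum(evals, 1e-12)
    a = 4.0 * math.sqrt(evals[0])   # ellipse major axis length
    b = 4.0 * math.sqrt(evals[1])
    ecc = math.sqrt(max(0.0, 1.0 - (b / a) ** 2))
    return area, ecc, a


def axon_cross_sections(mask: np.ndarray, psi: SubSkeleton,
                        spacing_um: float = 0.2,
                        voxel_size_nm=(50.0, 50.0, 50.0)) -> pd.DataFrame:
    """Cross-sections at fixed arc spacing, excluding one local diameter at
    each skeleton end; equivalent diameter and second-moment eccentricity
    per sample.  Empty cross-sections are skipped."""
    vox_um = float(voxel_size_nm[0]) / 1000.0
    spacing_vox = spacing_um / vox_um
    L = psi.length
    r0 = float(psi.radius[0])
    r1 = float(psi.radius[-1])
    s_start, s_end = 2 * r0, L - 2 * r1
    rows = []
    if s_end <= s_start:
        return pd.DataFrame(columns=["arc_um", "diameter_um", "eccentricity"])
    for s in np.arange(s_start, s_end + 1e-9, spacing_vox):
        p = psi.at_arc(s)
        t = psi.tangent_at_arc(s)
        r_loc = float(np.interp(s, psi.arc, psi.radius))
        region = _section_region(mask, p, t, half_width=max(4 * r_loc, 6.0))
        if region is None:
            continue
        area_vox, ecc, _ = _ellipse_from_region(region)
        area_um2 = area_vox * vox_um ** 2
        rows.append(dict(arc_um=s * vox_um,
                         diameter_um=2.0 * math.sqrt(area_um2 / math.pi),
                         eccentricity=ecc))
    return pd.DataFrame(rows)


def tortuosity(psi_points: np.ndarray) -> float:
    """Arc length over endpoint Euclidean distance of a polyline."""
    pts = np.asarray(psi_points, float)
    if len(pts) < 2:
        raise ValueError("polyline needs >= 2 points")
    ed = float(np.linalg.norm(pts[-1] - pts[0]))
    if ed == 0:
        raise ValueError("coincident endpoints: tortuosity undefined")
    gd = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
    return gd / ed


def _project_to_arc(psi: SubSkeleton, points: np.ndarray) -> np.ndarray:
    """Arc position of the nearest skeleton sample for each 3D point."""
    tree = cKDTree(psi.points)
    _, idx = tree.query(np.atleast_2d(points), workers=1)
    return psi.arc[idx]


def inter_mito_distances_centroid(psi: SubSkeleton, mito: LabelVolume,
                                  mito_ids, vox_um: float = 0.05):
    """Geodesic distances between consecutive projected mitochondria
    centroids along the skeleton (um)."""
    if len(mito_ids) < 2:
        return []
    cents = np.array([np.argwhere(mito.data == m).mean(axis=0)
                      for m in mito_ids], float)
    s = np.sort(_project_to_arc(psi, cents))
    return (np.diff(s) * vox_um).tolist()


def inter_mito_distances_shortest(psi: SubSkeleton, mito: LabelVolume,
                                  mito_ids, vox_um: float = 0.05):
    """Shortest geodesic gaps between consecutive mitochondria: each
    mitochondrion projects to an arc interval; the gap is
    max(0, next interval start - previous interval end) (um)."""
    if len(mito_ids) < 2:
        return []
    intervals = []
    for m in mito_ids:
        vox = np.argwhere(mito.data == m).astype(float)
        s = _project_to_arc(psi, vox)
        intervals.append((float(s.min()), float(s.max())))
    intervals.sort()
    out = []
    for (_, prev_hi), (nxt_lo, _) in zip(intervals[:-1], intervals[1:]):
        out.append(max(0.0, nxt_lo - prev_hi) * vox_um)
    return out


def densities(axon_labels: LabelVolume, myelin_mask: np.ndarray,
              nuclei_labels: LabelVolume) -> DensitySummary:
    """Axon density = V_axons / (V_myelin + V_axons); cell density =
    nucleus count per um^3 of dataset volume."""
    v_ax = int(np.count_nonzero(axon_labels.data))
    v_my = int(np.count_nonzero(myelin_mask))
    if v_ax + v_my == 0:
        raise ValueError("no myelin or axon voxels; axon density undefined")
    vz, vy, vx = axon_labels.voxel_size_nm
    vol_um3 = axon_labels.data.size * (vz * vy * vx * 1e-9)
    n_nuc = nuclei_labels.n_instances if nuclei_labels is not None else 0
    return DensitySummary(axon_density=v_ax / (v_ax + v_my),
                          cell_density_per_um3=n_nuc / vol_um3)


def skeleton_from_mask(mask: np.ndarray) -> SubSkeleton:
    """Convenience: skeletonize a single-tube mask and return its (single)
    longest sub-skeleton."""
    from .csd import partition_skeleton, skeletonize

    sk = skeletonize(mask)
    subs = partition_skeleton(sk)
    return max(subs, key=lambda s: s.length)


def summarize_axon(axon_id: int, mask: np.ndarray, psi: SubSkeleton,
                   mito: LabelVolume | None = None, mito_ids=(),
                   spacing_um: float = 0.2,
                   voxel_size_nm=(50.0, 50.0, 50.0)) -> AxonRecord:
    """Full per-axon morphometry record."""
    vox_um = float(voxel_size_nm[0]) / 1000.0
    cs = axon_cross_sections(mask, psi, spacing_um, voxel_size_nm)
    tau = tortuosity(psi.points)
    gd = psi.length * vox_um
    ed = float(np.linalg.norm(psi.points[-1] - psi.points[0])) * vox_um
    mito_ids = list(mito_ids)
    imc = inter_mito_distances_centroid(psi, mito, mito_ids, vox_um) \
        if mito is not None and len(mito_ids) >= 2 else []
    ims = inter_mito_distances_shortest(psi, mito, mito_ids, vox_um) \
        if mito is not None and len(mito_ids) >= 2 else []
    return AxonRecord(
        axon_id=axon_id,
        arc_length_um=gd,
        euclidean_length_um=ed,
        tortuosity=tau,
        median_diameter_um=(float(cs["diameter_um"].median())
                            if len(cs) else math.nan),
        median_eccentricity=(float(cs["eccentricity"].median())
                             if len(cs) else math.nan),
        cross_sections=cs,
        mito_ids=mito_ids,
        inter_mito_centroid_um=imc,
        inter_mito_shortest_um=ims,
    )
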