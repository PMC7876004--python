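"""Synthetic white-matter phantoms with ground truth.

The generator reproduces, in simplified geometry, exactly the failure
modes the instance-segmentation stages must fix:

* tubular "axons" (generalized cylinders around smooth center curves) with
  myelin shells and mitochondria inclusions, where a configurable fraction
  of axon pairs is fused at a contact point — emulating the missing axonal
  membrane at node-of-Ranvier-like sites that merges neighbouring
  intra-axonal spaces into one connected component;
* ellipsoidal "nuclei" whose one-to-two-voxel membrane shell is partially
  deleted in contiguous patches, including touching pairs whose interiors
  connect through the shared gap — the under-segmentation case the
  deformable-model stage must split;
* textured stacks resliced with recorded per-slice drift.

Emulated probability maps are the ground-truth masks blurred by a Gaussian
and perturbed by clipped noise, with per-voxel class sums renormalized to
at most 1.  All randomness flows through one seeded generator; outputs are
bit-identical for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .preprocess import ShiftSeries
from .volume import LabelVolume, VolumeGrid

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "make_axon_phantom",
    "make_nucleus_phantom",
    "make_drift_stack",
]


@dataclass
class PhantomSpec:
    """Geometry and noise parameters of the synthetic volumes.

    Defaults mirror a 50 nm isotropic white-matter acquisition: axon radii
    0.2-0.3 um (4-6 voxels), myelin sheaths 0.15 um thick, nuclei of radius
    about 1 um, and mildly noisy class-probability maps.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_nm: tuple[float, float, float] = (50.0, 50.0, 50.0)
    n_axons: int = 2
    radius_range_um: tuple[float, float] = (0.2, 0.3)
    radius_wobble: float = 0.1
    myelin_thickness_um: float = 0.15
    merge_fraction: float = 0.0
    crossing_angle_deg: float | None = None
    n_nuclei: int = 2
    n_touching_pairs: int = 0
    nucleus_radius_um: tuple[float, float] = (0.7, 0.9)
    membrane_gap_fraction: float = 0.0
    n_mitochondria_per_axon: tuple[int, int] = (0, 2)
    axis_aligned: bool = False
    noise_sd: float = 0.05
    blur_sigma_vox: float = 0.6
    edge_slope: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.n_axons < 0 or self.n_nuclei < 0:
            raise ValueError("counts must be non-negative")
        for frac in (self.merge_fraction, self.membrane_gap_fraction):
            if not (0 <= frac < 1 or frac == 1):
                raise ValueError("fractions must lie in [0, 1]")
        if self.radius_range_um[0] <= 0 or self.nucleus_radius_um[0] <= 0:
            raise ValueError("radii must be positive")

    @property
    def voxel_um(self) -> float:
        vz, vy, vx = self.voxel_size_nm
        if not (vz == vy == vx):
            raise ValueError("phantom generation requires isotropic voxels")
        return vz / 1000.0


@dataclass
class PhantomTruth:
    """Ground truth accompanying a phantom volume.

    ``axon_labels`` is a disjoint labeling (overlap at fusion sites goes to
    the smaller label); ``axon_masks`` keeps the full per-axon masks so
    overlap-aware evaluation is possible.  Center curves are polylines in
    voxel coordinates (z, y, x); multiply by the voxel size for world
    coordinates.
    """

    axon_labels: LabelVolume | None = None
    axon_masks: list = field(default_factory=list)
    myelin_mask: np.ndarray | None = None
    mito_labels: LabelVolume | None = None
    mito_axon_ids: dict = field(default_factory=dict)
    nucleus_labels: LabelVolume | None = None
    center_curves: list = field(default_factory=list)
    merge_sites: list = field(default_factory=list)
    radius_profiles: list = field(default_factory=list)
    shifts: ShiftSeries | None = None
    seed: int = 0

    def validate(self) -> None:
        """Check the structural invariants of the truth."""
        if self.axon_labels is not None and self.myelin_mask is not None:
            if np.any((self.axon_labels.data > 0) & self.myelin_mask):
                raise AssertionError("axon labels overlap myelin")
        if self.mito_labels is not None and self.axon_masks:
            for lab in self.mito_labels.labels:
                m = self.mito_labels.data == lab
                inside = [i for i, am in enumerate(self.axon_masks)
                          if np.all(am[m])]
                if len(inside) != 1:
                    raise AssertionError(
                        f"mitochondrion {lab} lies inside {len(inside)} axons")
        for i, curve in enumerate(self.center_curves):
            if i < len(self.axon_masks):
                idx = np.rint(curve).astype(int)
                ok = np.all((idx >= 0) & (idx < np.array(self.axon_masks[i].shape)),
                            axis=1)
                pts = idx[ok]
                if pts.size and not np.all(
                        self.axon_masks[i][pts[:, 0], pts[:, 1], pts[:, 2]]):
                    raise AssertionError(f"center curve {i} exits its axon mask")


# ---------------------------------------------------------------------------
# helpers


def _unit(v):
    v = np.asarray(v, float)
    return v / np.linalg.norm(v)


def _smooth_curve(p0, direction, length, rng, wobble_amp=0.0, step=0.5):
    """Polyline through ``p0`` along ``direction`` with a low-frequency
    lateral perturbation of amplitude ``wobble_amp`` (voxels)."""
    direction = _unit(direction)
    # orthonormal frame
    a = np.array([1.0, 0.0, 0.0])
    if abs(direction @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    u = _unit(np.cross(direction, a))
    w = np.cross(direction, u)
    t = np.arange(-length / 2, length / 2 + step, step)
    phase1, phase2 = rng.uniform(0, 2 * np.pi, 2)
    lam = max(length, 1.0)
    off = (np.sin(2 * np.pi * t / lam + phase1)[:, None] * u
           + np.cos(2 * np.pi * t / lam + phase2)[:, None] * w) * wobble_amp
    return np.asarray(p0)[None, :] + t[:, None] * direction[None, :] + off


def _clip_curve(curve, shape, margin):
    ok = np.all((curve >= margin) & (curve <= np.array(shape) - 1 - margin), axis=1)
    if not ok.any():
        return curve[:0]
    i0, i1 = np.argmax(ok), len(ok) - np.argmax(ok[::-1])
    return curve[i0:i1]


def _tube_fields(curve, radius_profile, shape):
    """Distance to the curve and per-voxel nearest-sample index, restricted
    to a bounding box; returns (mask_fn) data for the tube."""
    rmax = float(np.max(radius_profile))
    lo = np.maximum(np.floor(curve.min(axis=0) - rmax - 4).astype(int), 0)
    hi = np.minimum(np.ceil(curve.max(axis=0) + rmax + 4).astype(int) + 1,
                    np.array(shape))
    grids = np.meshgrid(*[np.arange(lo[d], hi[d]) for d in range(3)],
                        indexing="ij")
    coords = np.stack([g.ravel() for g in grids], axis=1).astype(float)
    tree = cKDTree(curve)
    dist, idx = tree.query(coords, workers=1)
    box_shape = tuple(hi - lo)
    return (lo, box_shape,
            dist.reshape(box_shape), idx.reshape(box_shape))


def _place_in_volume(shape, lo, box, arr=None):
    full = np.zeros(shape, bool) if arr is None else arr
    return full, (slice(lo[0], lo[0] + box[0]),
                  slice(lo[1], lo[1] + box[1]),
                  slice(lo[2], lo[2] + box[2]))


def _emulate_probability_maps(masks: dict, spec: PhantomSpec, rng):
    """Blur ground-truth masks, add clipped noise, renormalize sums <= 1."""
    maps = {}
    for name, mask in masks.items():
        pm = ndi.gaussian_filter(mask.astype(float), spec.blur_sigma_vox)
        # semantic segmenters emit near-binary scores with sub-voxel
        # transitions; sharpen the blurred mask around its 0.5 contour
        pm = (pm - 0.5) * spec.edge_slope + 0.5
        if spec.noise_sd > 0:
            pm = pm + rng.normal(0, spec.noise_sd, pm.shape)
        maps[name] = np.clip(pm, 0.0, 1.0)
    total = np.sum([m for m in maps.values()], axis=0)
    scale = np.where(total > 1.0, 1.0 / np.maximum(total, 1e-12), 1.0)
    for name in maps:
        maps[name] = maps[name] * scale
    return {name: VolumeGrid(m, spec.voxel_size_nm, is_probability=True)
            for name, m in maps.items()}


# ---------------------------------------------------------------------------
# axon phantom


def _axon_geometry(spec: PhantomSpec, rng):
    """Choose center curves and radii; returns list of (curve, radius_profile)
    and the merge pair list."""
    shape = np.array(spec.shape, float)
    vox = spec.voxel_um
    rmin, rmax = (r / vox for r in spec.radius_range_um)
    diag = float(np.linalg.norm(shape))
    curves, radii = [], []
    n_merge = int(round(spec.merge_fraction * (spec.n_axons // 2)))
    merge_pairs = [(2 * i, 2 * i + 1) for i in range(n_merge)]
    merged_partners = {a for p in merge_pairs for a in p}

    center = shape / 2
    for i in range(spec.n_axons):
        r0 = rng.uniform(rmin, rmax)
        placed = False
        for _ in range(200):
            if i in merged_partners and i % 2 == 1:
                # partner tube: cross the previous tube where its centerline
                # actually passes nearest the volume center
                prev = curves[i - 1]
                k = int(np.argmin(np.linalg.norm(prev - center, axis=1)))
                anchor = prev[k]
                k2 = min(k + 5, len(prev) - 1)
                prev_dir = _unit(prev[k2] - prev[max(k - 5, 0)])
                if spec.crossing_angle_deg is not None:
                    ang = np.deg2rad(spec.crossing_angle_deg)
                else:
                    ang = rng.uniform(np.deg2rad(30), np.deg2rad(90))
                a = np.array([1.0, 0, 0])
                if abs(prev_dir @ a) > 0.9:
                    a = np.array([0.0, 1, 0])
                perp = _unit(np.cross(prev_dir, a))
                d = _unit(np.cos(ang) * prev_dir + np.sin(ang) * perp)
                # slight perpendicular offset keeps centerlines distinct while
                # the intra-axonal spaces genuinely overlap at the contact
                off_dir = _unit(np.cross(prev_dir, d))
                p0 = anchor + off_dir * 0.6 * min(r0, radii[i - 1][k])
                wob = 0.0
            else:
                if spec.axis_aligned:
                    # follow the volume's longest axis (white-matter tracts
                    # run along the block) with a small angular spread
                    d = np.zeros(3)
                    d[int(np.argmax(shape))] = 1.0
                    d = _unit(d + rng.normal(0, 0.08, 3))
                else:
                    d = _unit(rng.normal(size=3))
                p0 = center + rng.uniform(-0.2, 0.2, 3) * shape
                wob = spec.radius_wobble * r0 * 2
            curve = _smooth_curve(p0, d, diag, rng, wobble_amp=wob)
            curve = _clip_curve(curve, spec.shape, margin=1.0)
            if len(curve) < 10:
                continue
            prof = r0 * (1 + spec.radius_wobble
                         * np.sin(np.linspace(0, 3 * np.pi, len(curve))
                                  + rng.uniform(0, 2 * np.pi)))
            # non-merged tubes must stay clear of all previous tubes
            if i not in merged_partners or i % 2 == 0:
                sep_ok = True
                need = (prof.max() + rmax + 2 * spec.myelin_thickness_um / vox + 1)
                for j, cj in enumerate(curves):
                    if (i in merged_partners and j in merged_partners
                            and (j, i) in merge_pairs):
                        continue
                    dmin = cKDTree(cj).query(curve, workers=1)[0].min()
                    if dmin < need:
                        sep_ok = False
                        break
                if not sep_ok:
                    continue
            curves.append(curve)
            radii.append(prof)
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place axon {i}: separation constraint unsatisfiable "
                f"for shape={spec.shape}, radius_range_um={spec.radius_range_um}")
    return curves, radii, merge_pairs


def make_axon_phantom(spec: PhantomSpec):
    """Generate a tubular-axon phantom.

    Returns ``(volume, maps, truth)`` where ``maps`` is a dict of emulated
    probability maps for {"myelin", "axon", "mito"} and ``truth`` the
    :class:`PhantomTruth`.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    vox = spec.voxel_um
    thick_vox = spec.myelin_thickness_um / vox

    curves, radii, merge_pairs = _axon_geometry(spec, rng)

    axon_masks = []
    myelin = np.zeros(shape, bool)
    tube_dist = []
    for curve, prof in zip(curves, radii):
        lo, box, dist, idx = _tube_fields(curve, prof, shape)
        local_r = prof[idx]
        m_ax = np.zeros(shape, bool)
        _, sl = _place_in_volume(shape, lo, box)
        m_ax[sl] = dist <= local_r
        m_my = np.zeros(shape, bool)
        m_my[sl] = (dist > local_r) & (dist <= local_r + thick_vox)
        axon_masks.append(m_ax)
        myelin |= m_my
        tube_dist.append((lo, box, dist, idx))

    # fuse: erase myelin in a sphere around the closest approach of each pair
    merge_sites = []
    for (i, j) in merge_pairs:
        d, idx = cKDTree(curves[j]).query(curves[i], workers=1)
        k = int(np.argmin(d))
        site = 0.5 * (curves[i][k] + curves[j][idx[k]])
        merge_sites.append(site)
        rad = radii[i][k] + radii[j][idx[k]] + thick_vox
        zz, yy, xx = np.ogrid[:shape[0], :shape[1], :shape[2]]
        sphere = ((zz - site[0]) ** 2 + (yy - site[1]) ** 2
                  + (xx - site[2]) ** 2) <= rad ** 2
        myelin &= ~sphere

    ias_union = np.zeros(shape, bool)
    for m in axon_masks:
        ias_union |= m
    myelin &= ~ias_union

    # mitochondria: tangent-aligned ellipsoids strictly inside an axon
    mito = np.zeros(shape, np.int32)
    mito_axon_ids = {}
    next_mid = 1
    lo_n, hi_n = spec.n_mitochondria_per_axon
    for ai, (curve, prof) in enumerate(zip(curves, radii)):
        n_m = int(rng.integers(lo_n, hi_n + 1))
        if n_m == 0 or len(curve) < 40:
            continue
        positions = rng.choice(
            np.arange(15, len(curve) - 15), size=n_m, replace=False)
        for k in sorted(positions):
            c = curve[k]
            tang = _unit(curve[min(k + 5, len(curve) - 1)]
                         - curve[max(k - 5, 0)])
            a_len = min(2.5 * prof[k], 8.0)        # semi-axis along the tube
            b_len = 0.55 * prof[k]                 # cross-sectional semi-axis
            lo = np.maximum(np.floor(c - a_len - 1).astype(int), 0)
            hi = np.minimum(np.ceil(c + a_len + 2).astype(int), np.array(shape))
            grids = np.meshgrid(*[np.arange(lo[d], hi[d]) for d in range(3)],
                                indexing="ij")
            rel = np.stack([g - c[d] for d, g in enumerate(grids)], axis=-1)
            along = rel @ tang
            perp = np.linalg.norm(rel - along[..., None] * tang, axis=-1)
            ell = (along / a_len) ** 2 + (perp / b_len) ** 2 <= 1.0
            sub = tuple(slice(lo[d], hi[d]) for d in range(3))
            ell &= axon_masks[ai][sub]          # strictly inside this axon
            for other in range(len(axon_masks)):
                if other != ai:
                    ell &= ~axon_masks[other][sub]
            if ell.sum() < 4:
                continue
            region = mito[sub]
            region[ell & (region == 0)] = next_mid
            mito_axon_ids[next_mid] = ai + 1
            next_mid += 1

    # disjoint axon labeling: overlap goes to the smaller label
    axon_labels = np.zeros(shape, np.int32)
    for ai in reversed(range(len(axon_masks))):
        axon_labels[axon_masks[ai]] = ai + 1

    masks = {
        "myelin": myelin,
        "axon": ias_union & (mito == 0),
        "mito": mito > 0,
    }
    maps = _emulate_probability_maps(masks, spec, rng)

    # background intensity volume: myelin dark, axoplasm bright
    intensity = 0.55 * np.ones(shape)
    intensity[myelin] = 0.15
    intensity[ias_union] = 0.75
    intensity[mito > 0] = 0.35
    intensity = ndi.gaussian_filter(intensity, 0.8)
    intensity += rng.normal(0, spec.noise_sd, shape)
    vol = VolumeGrid(np.clip(intensity, 0, 1), spec.voxel_size_nm)

    truth = PhantomTruth(
        axon_labels=LabelVolume(axon_labels, spec.voxel_size_nm),
        axon_masks=axon_masks,
        myelin_mask=myelin,
        mito_labels=LabelVolume(mito, spec.voxel_size_nm),
        mito_axon_ids=mito_axon_ids,
        center_curves=curves,
        merge_sites=merge_sites,
        radius_profiles=radii,
        seed=spec.seed,
    )
    return vol, maps, truth


# ---------------------------------------------------------------------------
# nucleus phantom


def make_nucleus_phantom(spec: PhantomSpec):
    """Generate an ellipsoidal-nucleus phantom with membrane gaps.

    Returns ``(maps, truth)``; maps holds probability grids for
    {"nucleus", "membrane"}.  ``n_touching_pairs`` of the nuclei are placed
    as touching pairs whose interiors connect through a membrane-free
    contact, the canonical under-segmentation case.
    """
    rng = np.random.default_rng(spec.seed)
    shape = np.array(spec.shape)
    vox = spec.voxel_um
    rmin, rmax = (r / vox for r in spec.nucleus_radius_um)

    centers, rads = [], []
    n_paired = 2 * min(spec.n_touching_pairs, spec.n_nuclei // 2)
    i = 0
    attempts = 0
    while i < spec.n_nuclei:
        attempts += 1
        if attempts > 5000:
            raise RuntimeError(
                "could not place nuclei: packing constraint unsatisfiable "
                f"for shape={spec.shape}, nucleus_radius_um={spec.nucleus_radius_um}")
        r = rng.uniform(rmin, rmax)
        if i < n_paired and i % 2 == 1:
            # touching partner: slight interior overlap makes the pair merge;
            # the pair axis is biased in-plane so pairs fit thin volumes
            d = rng.normal(size=3)
            d[0] *= 0.25
            d = _unit(d)
            c = centers[-1] + d * (rads[-1] + r - 1.0)
        else:
            c = rng.uniform(rmax + 3, shape - rmax - 3)
        if np.any(c < r + 1) or np.any(c > shape - r - 2):
            continue
        ok = True
        for j, (cj, rj) in enumerate(zip(centers, rads)):
            if i < n_paired and i % 2 == 1 and j == i - 1:
                continue
            if np.linalg.norm(c - cj) < r + rj + 6:
                ok = False
                break
        if not ok:
            continue
        centers.append(c)
        rads.append(r)
        i += 1

    interiors = np.zeros(tuple(shape), np.int32)
    membrane = np.zeros(tuple(shape), bool)
    zz, yy, xx = np.ogrid[:shape[0], :shape[1], :shape[2]]
    for k, (c, r) in enumerate(zip(centers, rads)):
        dist = np.sqrt((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2)
        interiors[(dist <= r) & (interiors == 0)] = k + 1
        membrane |= (dist > r) & (dist <= r + 2.0)
    membrane &= interiors == 0  # membranes never intrude into interiors

    # touching pairs share a membrane-free contact window: the probability
    # maps then connect the two interiors into one component, the
    # under-segmentation case the deformable model must split
    for k in range(0, n_paired, 2):
        c0, c1 = centers[k], centers[k + 1]
        contact = c0 + (c1 - c0) * rads[k] / (rads[k] + rads[k + 1])
        hole = ((zz - contact[0]) ** 2 + (yy - contact[1]) ** 2
                + (xx - contact[2]) ** 2) <= 5.0 ** 2
        membrane &= ~hole

    # delete contiguous membrane patches until the requested fraction is gone
    if spec.membrane_gap_fraction > 0 and membrane.any():
        target = int(spec.membrane_gap_fraction * membrane.sum())
        removed = 0
        mem_idx = np.argwhere(membrane)
        while removed < target:
            seed_pt = mem_idx[rng.integers(len(mem_idx))]
            patch_r = rng.uniform(3, 6)
            ball = ((zz - seed_pt[0]) ** 2 + (yy - seed_pt[1]) ** 2
                    + (xx - seed_pt[2]) ** 2) <= patch_r ** 2
            hit = membrane & ball
            removed += int(hit.sum())
            membrane &= ~ball
            mem_idx = np.argwhere(membrane)
            if len(mem_idx) == 0:
                break

    masks = {"nucleus": interiors > 0, "membrane": membrane}
    maps = _emulate_probability_maps(masks, spec, rng)
    truth = PhantomTruth(
        nucleus_labels=LabelVolume(interiors, spec.voxel_size_nm),
        seed=spec.seed,
    )
    return maps, truth


# ---------------------------------------------------------------------------
# drifted stack


def make_drift_stack(spec: PhantomSpec, trend: str = "none",
                     jitter_amplitude: int = 0):
    """Generate a textured stack whose slices are displaced by a recorded
    per-slice position series = trend + i.i.d. uniform integer jitter.

    The returned :class:`ShiftSeries` holds the pairwise displacements
    (slice i+1 relative to slice i), matching what stack registration
    estimates.  The ground-truth per-slice positions are attached as
    ``positions_y`` / ``positions_x`` attributes for residual checks.
    """
    if jitter_amplitude < 0:
        raise ValueError("jitter_amplitude must be >= 0")
    if trend not in ("none", "linear"):
        raise ValueError(f"unknown trend {trend!r}")
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape

    if trend == "linear":
        base = 0.2 * np.arange(nz)
    else:
        base = np.zeros(nz)
    jit_y = rng.integers(-jitter_amplitude, jitter_amplitude + 1, nz)
    jit_x = rng.integers(-jitter_amplitude, jitter_amplitude + 1, nz)
    pos_y = np.rint(base).astype(int) + jit_y
    pos_x = np.rint(base).astype(int) + jit_x
    pos_y[0] = pos_x[0] = 0

    margin = int(np.abs(np.concatenate([pos_y, pos_x])).max()) + 1
    texture = rng.uniform(size=(nz, ny + 2 * margin, nx + 2 * margin))
    texture = ndi.gaussian_filter(texture, (3.0, 2.5, 2.5))
    texture = (texture - texture.min()) / np.ptp(texture)

    out = np.empty((nz, ny, nx))
    for i in range(nz):
        y0 = margin + pos_y[i]
        x0 = margin + pos_x[i]
        out[i] = texture[i, y0:y0 + ny, x0:x0 + nx]

    shifts = ShiftSeries(dx=np.diff(pos_x).astype(float),
                         dy=np.diff(pos_y).astype(float), window=25)
    shifts.positions_y = pos_y  # type: ignore[attr-defined]
    shifts.positions_x = pos_x  # type: ignore[attr-defined]
    # unshifted reference stack, for residual checks after registration
    shifts.reference = VolumeGrid(  # type: ignore[attr-defined]
        texture[:, margin:margin + ny, margin:margin + nx].copy(),
        spec.voxel_size_nm)
    return VolumeGrid(out, spec.voxel_size_nm), shifts
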