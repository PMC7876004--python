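"""End-to-end orchestration of the segmentation pipeline.

Stages run in order: binarization of class probability maps, intra-axonal
space and initial instances, cylindrical shape decomposition of every
initial instance, nucleus segmentation in the deformable-model framework,
mitochondria assignment, morphometry, and (when ground truth is supplied)
evaluation.  All randomness flows from one seed; per-object decomposition
is order-stable, so outputs are identical regardless of worker count.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import csd, evalmetrics, initseg, morpho, nuclei_gdm
from .volume import LabelVolume, VolumeGrid, write_volume

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    theta_myelin: float = 0.5
    theta_axon: float = 0.8
    theta_mito: float = 0.8
    theta_nucleus: float = 0.5
    theta_h: float = 0.85
    alpha_s: float = 10.0
    alpha_e: float = 1.5
    min_axon_voxels: int = initseg.DEFAULT_MIN_AXON_VOXELS
    min_nucleus_voxels: int = 1000
    gdm_depth_um: float = 0.3
    gdm_iterations: int = 300
    gdm_smooth_weight: float = 2.5
    mito_min_inside_fraction: float = 0.5
    morpho_spacing_um: float = 0.2
    voxel_size_nm: tuple = (50.0, 50.0, 50.0)
    workers: int = 1
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(asdict(self), f, sort_keys=True)


@dataclass
class PipelineResult:
    myelin_mask: np.ndarray | None = None
    axon_labels: LabelVolume | None = None
    axon_masks: list = field(default_factory=list)
    mito_labels: LabelVolume | None = None
    mito_assignment: dict = field(default_factory=dict)
    nucleus_labels: LabelVolume | None = None
    morphometry: pd.DataFrame | None = None
    scores: dict = field(default_factory=dict)


def _decompose_all(initial: LabelVolume, cfg: PipelineConfig):
    """Run CSD on every initial instance (order-stable across workers) and
    re-label the constituents into one volume."""
    masks = []
    for lab in initial.labels:          # ascending label order: deterministic
        m = initial.data == lab
        try:
            res = csd.decompose(m, alpha_s=cfg.alpha_s, alpha_e=cfg.alpha_e,
                                theta_h=cfg.theta_h)
            masks.extend(res.masks)
        except ValueError:
            masks.append(m)
    masks.sort(key=lambda m: (-int(m.sum())))
    out = np.zeros(initial.data.shape, np.int32)
    for i, m in enumerate(masks, start=1):
        out[m & (out == 0)] = i
    return LabelVolume(out, cfg.voxel_size_nm), masks


def run_pipeline(maps: dict, cfg: PipelineConfig | None = None,
                 nucleus_maps: dict | None = None,
                 truth=None, out_dir=None) -> PipelineResult:
    """Execute the full instance-segmentation pipeline on probability maps.

    ``maps`` holds {"myelin", "axon", "mito"}; ``nucleus_maps`` optionally
    {"nucleus", "membrane"}.  When ``truth`` (a PhantomTruth or LabelVolume)
    is given, evaluation scores are attached.  ``out_dir`` writes volumes,
    CSV tables, the resolved config and a JSON report.
    """
    cfg = cfg or PipelineConfig()
    result = PipelineResult()
    thr = initseg.BinarizationThresholds(cfg.theta_myelin, cfg.theta_axon,
                                         cfg.theta_mito)
    my, ax, mi = initseg.binarize_maps(maps, thr)
    result.myelin_mask = initseg.segment_myelin(my)
    ias = initseg.make_intra_axonal_space(ax, mi)
    initial = initseg.initial_axon_instances(ias, cfg.min_axon_voxels)
    axons, masks = _decompose_all(initial, cfg)
    result.axon_labels = axons
    result.axon_masks = masks
    result.mito_labels, result.mito_assignment = initseg.mito_instances(
        mi, axons, cfg.mito_min_inside_fraction)

    if nucleus_maps is not None:
        result.nucleus_labels = nuclei_gdm.segment_nuclei(
            nucleus_maps["nucleus"], nucleus_maps["membrane"],
            theta_nucleus=cfg.theta_nucleus, depth_um=cfg.gdm_depth_um,
            min_voxels=cfg.min_nucleus_voxels,
            iterations=cfg.gdm_iterations,
            smooth_weight=cfg.gdm_smooth_weight,
            voxel_size_nm=cfg.voxel_size_nm)

    # morphometry per axon
    rows = []
    mito_by_axon = {}
    for mid, aid in result.mito_assignment.items():
        mito_by_axon.setdefault(aid, []).append(mid)
    for lab in axons.labels:
        mask = axons.data == lab
        try:
            psi = morpho.skeleton_from_mask(mask)
            rec = morpho.summarize_axon(
                int(lab), mask, psi, result.mito_labels,
                mito_by_axon.get(int(lab), []),
                spacing_um=cfg.morpho_spacing_um,
                voxel_size_nm=cfg.voxel_size_nm)
            rows.append(rec.as_row())
        except ValueError:
            continue
    result.morphometry = pd.DataFrame(rows)

    if truth is not None:
        truth_labels = truth if isinstance(truth, LabelVolume) \
            else truth.axon_labels
        score = evalmetrics.score_segmentation(axons.data, truth_labels.data)
        result.scores = score.as_dict()
        if not isinstance(truth, LabelVolume) and truth.myelin_mask is not None:
            p, r, f1 = evalmetrics.precision_recall_f1(result.myelin_mask,
                                                       truth.myelin_mask)
            result.scores.update(myelin_precision=p, myelin_recall=r,
                                 myelin_f1=f1)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cfg.to_yaml(out / "config.yaml")
        write_volume(out / "axons.h5", axons)
        write_volume(out / "myelin.h5",
                     VolumeGrid(result.myelin_mask.astype(np.uint8),
                                cfg.voxel_size_nm))
        if result.mito_labels is not None:
            write_volume(out / "mitochondria.h5", result.mito_labels)
        if result.nucleus_labels is not None:
            write_volume(out / "nuclei.h5", result.nucleus_labels)
        result.morphometry.to_csv(out / "morphometry.csv", index=False,
                                  float_format="%.6f")
        if result.scores:
            with open(out / "scores.json", "w") as f:
                json.dump(result.scores, f, indent=2, sort_keys=True)
    return result
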