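"""False-positive elimination with a quadratic-kernel SVM.

Each candidate instance (axon or nucleus) is summarized by six shape
features computed at one-third linear scale — volume, surface area
(marching-cubes mesh area), equivalent diameter, extent, solidity and
principal-axis length — standardized to zero mean / unit variance, and
classified by a support vector machine with the quadratic kernel
``((x . y) / sigma^2 + 1)^2``.  Hyperparameters (C, sigma) are selected on
a log grid by 5-fold cross-validation.  Leave-one-group-out evaluation
scores the classifier per animal group.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import marching_cubes, mesh_surface_area, regionprops
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from .volume import LabelVolume

__all__ = [
    "FEATURE_NAMES",
    "FPClassifier",
    "component_features",
    "standardize",
    "train_fp_classifier",
    "apply_fp_filter",
    "logo_evaluate",
]

FEATURE_NAMES = [
    "volume",
    "surface_area",
    "equivalent_diameter",
    "extent",
    "solidity",
    "principal_axis_length",
]


@dataclass
class FPClassifier:
    C: float
    sigma: float
    feature_means: np.ndarray
    feature_sds: np.ndarray
    svc: SVC | None = None

    def decision(self, features: pd.DataFrame) -> np.ndarray:
        X = (features[FEATURE_NAMES].to_numpy() - self.feature_means) \
            / self.feature_sds
        return self.svc.predict(X).astype(bool)

    def to_json(self, path) -> None:
        payload = {
            "C": self.C, "sigma": self.sigma,
            "feature_means": self.feature_means.tolist(),
            "feature_sds": self.feature_sds.tolist(),
            "kernel": "((x.y)/sigma^2 + 1)^2",
        }
        with open(path, "w") as f:
            json.dump(payload, f, indent=2)


def _downscale_labels(labels: LabelVolume, factor: int) -> np.ndarray:
    """Isotropic linear downscaling of a label volume by majority vote."""
    data = labels.data
    f = factor
    nz, ny, nx = (s // f for s in data.shape)
    if min(nz, ny, nx) == 0:
        return data.copy()
    trimmed = data[:nz * f, :ny * f, :nx * f]
    blocks = trimmed.reshape(nz, f, ny, f, nx, f)
    blocks = blocks.transpose(0, 2, 4, 1, 3, 5).reshape(nz, ny, nx, f ** 3)
    from scipy import stats
    return stats.mode(blocks, axis=-1, keepdims=False).mode


def component_features(labels: LabelVolume, scale_factor: int = 3
                       ) -> pd.DataFrame:
    """Six shape features per labeled component, computed after isotropic
    downscaling by ``scale_factor``.  Components that vanish at the reduced
    scale are recorded with volume 0 and ``vanished=True``."""
    small = _downscale_labels(labels, scale_factor) if scale_factor > 1 \
        else labels.data
    rows = []
    present = {int(r.label): r for r in regionprops(small)}
    for lab in labels.labels:
        lab = int(lab)
        r = present.get(lab)
        if r is None or r.area == 0:
            rows.append(dict(label=lab, volume=0.0, surface_area=0.0,
                             equivalent_diameter=0.0, extent=0.0,
                             solidity=0.0, principal_axis_length=0.0,
                             vanished=True))
            continue
        vol = float(r.area)
        mask = small == lab
        padded = np.pad(mask, 1).astype(float)
        try:
            verts, faces, _, _ = marching_cubes(padded, level=0.5)
            surf = float(mesh_surface_area(verts, faces))
        except (ValueError, RuntimeError):
            surf = 6.0 * vol ** (2 / 3)
        eq_d = (6.0 * vol / np.pi) ** (1.0 / 3.0)
        try:
            solidity = float(r.solidity)
        except Exception:
            solidity = 1.0
        try:
            pal = float(r.axis_major_length)
        except Exception:
            pal = eq_d
        rows.append(dict(label=lab, volume=vol, surface_area=surf,
                         equivalent_diameter=eq_d, extent=float(r.extent),
                         solidity=solidity, principal_axis_length=pal,
                         vanished=False))
    return pd.DataFrame(rows)


def standardize(features: pd.DataFrame, fit_stats=None):
    """Z-score the feature columns.  Without ``fit_stats`` the statistics
    are estimated (>= 2 rows required) and returned; with stats they are
    reused.  Zero-variance features keep sd = 1 with a warning."""
    X = features[FEATURE_NAMES].to_numpy(float)
    if fit_stats is None:
        if len(X) < 2:
            raise ValueError("need >= 2 rows to fit standardization stats")
        means = X.mean(axis=0)
        sds = X.std(axis=0, ddof=0)
        if np.any(sds == 0):
            warnings.warn("zero-variance feature(s); sd set to 1")
            sds = np.where(sds == 0, 1.0, sds)
    else:
        means, sds = fit_stats
    out = features.copy()
    out[FEATURE_NAMES] = (X - means) / sds
    return out, (np.asarray(means), np.asarray(sds))


def _make_svc(C: float, sigma: float) -> SVC:
    # quadratic kernel ((x.y)/sigma^2 + 1)^2
    return SVC(kernel="poly", degree=2, gamma=1.0 / sigma ** 2, coef0=1.0,
               C=C, max_iter=20000)


def train_fp_classifier(features: pd.DataFrame, labels, folds: int = 5,
                        grid_size: int = 13, seed: int = 0) -> FPClassifier:
    """Fit the quadratic-kernel SVM; (C, sigma) searched on a log-uniform
    ``grid_size x grid_size`` grid over [1e-6, 1e6] minimizing k-fold
    cross-validated misclassification.  Deterministic for a fixed seed."""
    y = np.asarray(labels, bool)
    if y.all() or not y.any():
        raise ValueError("training data must contain both classes")
    std, stats = standardize(features)
    X = std[FEATURE_NAMES].to_numpy(float)
    grid = np.logspace(-6, 6, grid_size)
    n_splits = min(folds, int(np.bincount(y.astype(int)).min()))
    n_splits = max(n_splits, 2)
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    best = (None, None, -np.inf)
    for C in grid:
        for sigma in grid:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    score = cross_val_score(_make_svc(C, sigma), X, y,
                                            cv=cv).mean()
                except ValueError:
                    continue
            # ties prefer the smoother model: larger sigma, then smaller C
            better = (score > best[2] + 1e-12
                      or (abs(score - best[2]) <= 1e-12
                          and (best[1] is None or sigma > best[1]
                               or (sigma == best[1] and C < best[0]))))
            if better:
                best = (C, sigma, score)
    C, sigma, _ = best
    svc = _make_svc(C, sigma).fit(X, y)
    return FPClassifier(C=float(C), sigma=float(sigma),
                        feature_means=stats[0], feature_sds=stats[1], svc=svc)


def apply_fp_filter(model: FPClassifier, labels: LabelVolume,
                    features: pd.DataFrame) -> LabelVolume:
    """Remove components the classifier rejects; survivors keep their ids
    and voxels untouched."""
    keep = model.decision(features)
    keep_labels = set(int(l) for l, k in zip(features["label"], keep) if k)
    out = labels.data.copy()
    out[~np.isin(out, sorted(keep_labels))] = 0
    return LabelVolume(out, labels.voxel_size_nm)


def _prf(y_true, y_pred):
    tp = int(np.sum(y_true & y_pred))
    fp = int(np.sum(~y_true & y_pred))
    fn = int(np.sum(y_true & ~y_pred))
    p = tp / (tp + fp) if tp + fp else float("nan")
    r = tp / (tp + fn) if tp + fn else float("nan")
    if np.isnan(p) or np.isnan(r):
        f1 = float("nan")
    elif p + r == 0:
        f1 = 0.0
    else:
        f1 = 2 * p * r / (p + r)
    return p, r, f1


def logo_evaluate(features: pd.DataFrame, labels, group_ids,
                  seed: int = 0) -> pd.DataFrame:
    """Leave-one-group-out: for every group, train on all other groups and
    score precision/recall/F1 on the held-out group.  Groups containing a
    single class are scored with the metrics flagged as nan where
    undefined."""
    y = np.asarray(labels, bool)
    groups = np.asarray(group_ids)
    uniq = sorted(set(groups.tolist()))
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups for leave-one-group-out")
    rows = []
    for g in uniq:
        test = groups == g
        train = ~test
        if y[train].all() or not y[train].any():
            rows.append(dict(group=g, precision=float("nan"),
                             recall=float("nan"), f1=float("nan"),
                             n=int(test.sum())))
            continue
        model = train_fp_classifier(features[train].reset_index(drop=True),
                                    y[train], seed=seed)
        pred = model.decision(features[test].reset_index(drop=True))
        p, r, f1 = _prf(y[test], pred)
        rows.append(dict(group=g, precision=p, recall=r, f1=f1,
                         n=int(test.sum())))
    return pd.DataFrame(rows)
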