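"""Segmentation comparison metrics.

Voxel-wise precision/recall/F1 for semantic masks, and pair-counting /
information-theoretic metrics for instance labelings: variation of
information (VOI, split and merge conditional entropies), Wallace split
and merge indices, Rand index, and the adapted Rand error (ARE, one minus
the F-score of pair precision/recall with zero-labeled ground-truth voxels
excluded).

All pair-counting quantities are computed from the joint contingency table
of the two labelings, never by enumerating voxel pairs, so they scale to
full volumes.  The pair counts (a, b, c, d) refer to unordered voxel pairs:
same label in both / same in A only / same in B only / different in both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import sparse

__all__ = [
    "PairCounts",
    "SegScore",
    "precision_recall_f1",
    "pair_counts",
    "wallace_indices",
    "voi",
    "adapted_rand_error",
    "score_segmentation",
]


@dataclass(frozen=True)
class PairCounts:
    a: int
    b: int
    c: int
    d: int

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class SegScore:
    """Bundle of all comparison scores between a predicted labeling A and a
    reference labeling B."""

    voi_split: float
    voi_merge: float
    wallace_split: float
    wallace_merge: float
    rand_index: float
    adapted_rand_error: float

    @property
    def voi_sum(self) -> float:
        return self.voi_split + self.voi_merge

    def as_dict(self) -> dict:
        d = {k: float(v) for k, v in self.__dict__.items()}
        d["voi_sum"] = self.voi_sum
        return d


def precision_recall_f1(pred: np.ndarray, truth: np.ndarray):
    """Voxel-wise precision, recall and F1 between two binary masks.

    Undefined ratios (empty denominator) are returned as ``nan``.
    """
    A = np.asarray(pred, bool)
    B = np.asarray(truth, bool)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    inter = int(np.count_nonzero(A & B))
    na, nb = int(np.count_nonzero(A)), int(np.count_nonzero(B))
    p = inter / na if na else math.nan
    r = inter / nb if nb else math.nan
    if math.isnan(p) or math.isnan(r) or (p + r) == 0:
        f1 = math.nan if (math.isnan(p) or math.isnan(r)) else 0.0
    else:
        f1 = 2 * p * r / (p + r)
    return p, r, f1


def _contingency(A: np.ndarray, B: np.ndarray) -> sparse.csr_matrix:
    A = np.asarray(A).ravel()
    B = np.asarray(B).ravel()
    if A.shape != B.shape:
        raise ValueError("label volumes must have the same shape")
    ai, au = np.unique(A, return_inverse=True)
    bi, bu = np.unique(B, return_inverse=True)
    m = sparse.coo_matrix(
        (np.ones(A.size), (au, bu)), shape=(ai.size, bi.size)
    ).tocsr()
    m.row_labels = ai  # type: ignore[attr-defined]
    m.col_labels = bi  # type: ignore[attr-defined]
    return m


def _pair_counts_from_table(m: sparse.csr_matrix) -> PairCounts:
    n = m.sum()
    nij = np.asarray(m.todense(), float)
    ai = nij.sum(axis=1)  # cluster sizes in A
    bj = nij.sum(axis=0)  # cluster sizes in B
    sum_nij2 = float((nij * (nij - 1) / 2).sum())
    sum_ai2 = float((ai * (ai - 1) / 2).sum())
    sum_bj2 = float((bj * (bj - 1) / 2).sum())
    total = n * (n - 1) / 2
    a = sum_nij2
    b = sum_ai2 - sum_nij2
    c = sum_bj2 - sum_nij2
    d = total - a - b - c
    return PairCounts(int(round(a)), int(round(b)), int(round(c)), int(round(d)))


def pair_counts(A: np.ndarray, B: np.ndarray) -> PairCounts:
    """Unordered voxel-pair counts (a, b, c, d) between two labelings."""
    return _pair_counts_from_table(_contingency(A, B))


def wallace_indices(pc: PairCounts):
    """Wallace splitting index a/(a+b) and merging index a/(a+c); ``nan``
    when a denominator is zero."""
    split = pc.a / (pc.a + pc.b) if (pc.a + pc.b) else math.nan
    merge = pc.a / (pc.a + pc.c) if (pc.a + pc.c) else math.nan
    return split, merge


def voi(A: np.ndarray, B: np.ndarray, ignore_zero: bool = False, base: float = 2.0):
    """Variation-of-information split H(A|B) and merge H(B|A) in bits
    (``base=2``) or nats (``base=e``).

    With ``ignore_zero`` voxels labeled 0 in B are excluded from the joint
    distribution before computing the entropies.
    """
    A = np.asarray(A).ravel()
    B = np.asarray(B).ravel()
    if A.shape != B.shape:
        raise ValueError("label volumes must have the same shape")
    if ignore_zero:
        keep = B != 0
        A, B = A[keep], B[keep]
    if A.size == 0:
        return 0.0, 0.0
    m = _contingency(A, B)
    p = np.asarray(m.todense(), float) / m.sum()
    pa = p.sum(axis=1)
    pb = p.sum(axis=0)
    nz = p > 0
    logb = np.log(base)
    # H(A|B) = -sum p_ij log(p_ij / p_.j); H(B|A) symmetric
    pj = np.broadcast_to(pb, p.shape)
    pi = np.broadcast_to(pa[:, None], p.shape)
    h_a_given_b = -float(np.sum(p[nz] * np.log(p[nz] / pj[nz]))) / logb
    h_b_given_a = -float(np.sum(p[nz] * np.log(p[nz] / pi[nz]))) / logb
    return max(h_a_given_b, 0.0), max(h_b_given_a, 0.0)


def adapted_rand_error(A: np.ndarray, B: np.ndarray):
    """Adapted Rand error and plain Rand index.

    ARE = 1 - F, with F the harmonic mean of pair precision a/(a+b) and
    pair recall a/(a+c), computed after discarding voxels with label 0 in
    the reference B.  The Rand index (a+d)/total is reported over the same
    voxel subset.
    """
    A = np.asarray(A).ravel()
    B = np.asarray(B).ravel()
    if A.shape != B.shape:
        raise ValueError("label volumes must have the same shape")
    keep = B != 0
    A, B = A[keep], B[keep]
    if A.size < 2:
        return 0.0, 1.0
    pc = pair_counts(A, B)
    prec = pc.a / (pc.a + pc.b) if (pc.a + pc.b) else math.nan
    rec = pc.a / (pc.a + pc.c) if (pc.a + pc.c) else math.nan
    if math.isnan(prec) or math.isnan(rec) or (prec + rec) == 0:
        f = 0.0
    else:
        f = 2 * prec * rec / (prec + rec)
    rand = (pc.a + pc.d) / pc.total if pc.total else 1.0
    return 1.0 - f, rand


def score_segmentation(pred: np.ndarray, truth: np.ndarray,
                       ignore_zero_voi: bool = False) -> SegScore:
    """All instance-level scores between predicted and reference labelings."""
    vs, vm = voi(pred, truth, ignore_zero=ignore_zero_voi)
    pc = pair_counts(pred, truth)
    ws, wm = wallace_indices(pc)
    are, rand = adapted_rand_error(pred, truth)
    return SegScore(vs, vm, ws, wm, rand, are)
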