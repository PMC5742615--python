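"""Segmentation quality metrics.

Two complementary views:

* frame level — the normalized Hamming distance between per-frame class
  sequences, after optimally matching the arbitrary unsupervised labels
  to the ground-truth labels (one-to-one assignment on the confusion
  matrix, solved exactly);
* boundary level — precision / recall / F-measure of estimated segment
  boundaries, where an estimated boundary within ±tol frames of an
  unclaimed true boundary counts as a true positive, unmatched true
  boundaries as false negatives, and unmatched estimates as false
  positives.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import linear_sum_assignment

from .types import Segmentation

__all__ = [
    "EvalReport",
    "match_labels",
    "normalized_hamming",
    "boundary_prf",
    "f_measure",
    "evaluate",
    "evaluate_corpus",
]


@dataclass(frozen=True)
class EvalReport:
    """Bundle of segmentation metrics for one comparison."""

    hamming: float | None
    precision: float
    recall: float
    f_measure: float
    n_tp: int
    n_fp: int
    n_fn: int
    tolerance: int
    label_map: dict[int, int] | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["label_map"] is not None:
            d["label_map"] = {str(k): v for k, v in d["label_map"].items()}
        return d


def _as_labels(x) -> np.ndarray:
    if isinstance(x, Segmentation):
        return x.labels()
    return np.asarray(x, dtype=int)


def match_labels(est, truth) -> dict[int, int]:
    """Optimal one-to-one map from estimated class ids to truth class ids.

    Maximizes total frame agreement over all injective assignments
    (Hungarian algorithm on the negated confusion matrix). Estimated
    classes left without a partner are absent from the map and score as
    disagreement everywhere they occur.
    """
    est = _as_labels(est)
    truth = _as_labels(truth)
    if est.shape != truth.shape:
        raise ValueError(
            f"labelings must have equal length, got {est.size} vs {truth.size}"
        )
    est_ids = np.unique(est)
    true_ids = np.unique(truth)
    conf = np.zeros((est_ids.size, true_ids.size), dtype=int)
    for i, e in enumerate(est_ids):
        mask = est == e
        for j, tcl in enumerate(true_ids):
            conf[i, j] = int(np.sum(truth[mask] == tcl))
    rows, cols = linear_sum_assignment(-conf)
    return {int(est_ids[i]): int(true_ids[j]) for i, j in zip(rows, cols)}


def normalized_hamming(est, truth) -> float:
    """Fraction of frames misclassified after optimal label matching.

    0 means perfect agreement up to a relabeling of classes; 1 means
    total disagreement. Invariant under any permutation of the estimated
    label names.
    """
    est = _as_labels(est)
    truth = _as_labels(truth)
    mapping = match_labels(est, truth)
    mapped = np.array([mapping.get(int(e), -1) for e in est])
    return float(np.mean(mapped != truth))


def f_measure(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def _match_boundaries(est_b: list[int], true_b: list[int],
                      tol: int) -> tuple[int, int, int]:
    """One-to-one boundary matching; returns (n_tp, n_fp, n_fn).

    True boundaries are processed left to right; each claims the nearest
    unclaimed estimated boundary within ±tol, ties broken toward the
    earlier estimate.
    """
    est_sorted = sorted(est_b)
    claimed = [False] * len(est_sorted)
    n_tp = 0
    for b in sorted(true_b):
        best = None
        best_dist = tol + 1
        for i, e in enumerate(est_sorted):
            if claimed[i]:
                continue
            d = abs(e - b)
            if d < best_dist:  # strict: ties keep the earlier estimate
                best, best_dist = i, d
        if best is not None:
            claimed[best] = True
            n_tp += 1
    n_fp = len(est_b) - n_tp
    n_fn = len(true_b) - n_tp
    return n_tp, n_fp, n_fn


def boundary_prf(est_seg: Segmentation, true_seg: Segmentation,
                 tol: int) -> EvalReport:
    """Boundary precision / recall / F-measure at tolerance ±tol frames.

    Only interior boundaries count: the shared endpoints at frame 0 and
    frame T carry no information and are excluded.
    """
    if tol < 0:
        raise ValueError("tolerance must be >= 0")
    if est_seg.total_frames != true_seg.total_frames:
        raise ValueError(
            f"segmentations cover different spans: {est_seg.total_frames} "
            f"vs {true_seg.total_frames} frames"
        )
    n_tp, n_fp, n_fn = _match_boundaries(
        est_seg.boundaries(), true_seg.boundaries(), tol
    )
    p = n_tp / (n_tp + n_fp) if n_tp + n_fp else 0.0
    r = n_tp / (n_tp + n_fn) if n_tp + n_fn else 0.0
    return EvalReport(
        hamming=None,
        precision=p,
        recall=r,
        f_measure=f_measure(p, r),
        n_tp=n_tp,
        n_fp=n_fp,
        n_fn=n_fn,
        tolerance=tol,
    )


def evaluate(est_seg: Segmentation, true_seg: Segmentation,
             tol: int = 4) -> EvalReport:
    """Full report: normalized Hamming plus boundary P/R/F for one sequence."""
    rep = boundary_prf(est_seg, true_seg, tol)
    est_l, true_l = est_seg.labels(), true_seg.labels()
    return EvalReport(
        hamming=normalized_hamming(est_l, true_l),
        precision=rep.precision,
        recall=rep.recall,
        f_measure=rep.f_measure,
        n_tp=rep.n_tp,
        n_fp=rep.n_fp,
        n_fn=rep.n_fn,
        tolerance=tol,
        label_map=match_labels(est_l, true_l),
    )


def evaluate_corpus(est_segs: list[Segmentation], true_segs: list[Segmentation],
                    tol: int = 4) -> EvalReport:
    """Corpus-level report: labels matched globally, boundary counts pooled.

    Frame labels of all sequences are concatenated before matching, since
    class identities are shared across the corpus; boundary TP/FP/FN are
    summed per sequence and precision/recall computed from the pooled
    counts.
    """
    if len(est_segs) != len(true_segs):
        raise ValueError("corpus segmentation lists differ in length")
    est_l = np.concatenate([s.labels() for s in est_segs])
    true_l = np.concatenate([s.labels() for s in true_segs])
    n_tp = n_fp = n_fn = 0
    for e, t in zip(est_segs, true_segs):
        rep = boundary_prf(e, t, tol)
        n_tp += rep.n_tp
        n_fp += rep.n_fp
        n_fn += rep.n_fn
    p = n_tp / (n_tp + n_fp) if n_tp + n_fp else 0.0
    r = n_tp / (n_tp + n_fn) if n_tp + n_fn else 0.0
    return EvalReport(
        hamming=normalized_hamming(est_l, true_l),
        precision=p,
        recall=r,
        f_measure=f_measure(p, r),
        n_tp=n_tp,
        n_fp=n_fp,
        n_fn=n_fn,
        tolerance=tol,
        label_map=match_labels(est_l, true_l),
    )
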