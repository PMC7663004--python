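"""Confusion-matrix accuracy metrics for plant detection.

The unit of evaluation is the plant, not the pixel: detections are matched
one-to-one to expert-marked ground-truth centroids, and four measures are
computed from the resulting confusion counts —

    producer's accuracy  Pacc   = TP / GT
    user's accuracy      Uacc   = TP / (TP + FP)
    recall                      = TP / (TP + FN)
    average accuracy     Acc    = (Pacc + Uacc) / 2

Pacc is the fraction of real plants found; Uacc the fraction of detections
that are real plants. When every ground-truth plant is either detected or
missed (GT = TP + FN), Pacc and recall coincide.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .agave_counter import DetectionSet

__all__ = [
    "GroundTruth",
    "ConfusionCounts",
    "MetricsReport",
    "match_detections",
    "producer_accuracy",
    "user_accuracy",
    "recall_metric",
    "average_accuracy",
    "make_report",
    "pooled_summary",
    "SURVEY_REGION_COUNTS",
]


@dataclass
class GroundTruth:
    """Expert-marked plant centroids as (row, col) pairs."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        self.points = pts

    @property
    def n(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    gt: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.gt) < 0:
            raise ValueError("confusion counts must be nonnegative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            self.gt + other.gt,
        )


@dataclass(frozen=True)
class MetricsReport:
    """The four accuracy measures plus the counts they came from."""

    p_acc: float
    u_acc: float
    recall: float
    acc: float
    counts: ConfusionCounts

    def rounded(self, ndigits: int = 4) -> dict:
        """Metrics rounded for reporting; full precision kept internally."""
        return {
            "p_acc": round(self.p_acc, ndigits),
            "u_acc": round(self.u_acc, ndigits),
            "recall": round(self.recall, ndigits),
            "acc": round(self.acc, ndigits),
        }


#: Confusion counts (tp, fp, fn, gt) reported for the nine evaluated
#: regions of a three-field commercial blue-agave UAV survey; used as the
#: worked example of the metrics and for the pooled summary.
SURVEY_REGION_COUNTS: dict[str, ConfusionCounts] = {
    "field1_blue": ConfusionCounts(tp=198, fp=1, fn=25, gt=223),
    "field1_purple": ConfusionCounts(tp=336, fp=9, fn=33, gt=369),
    "field1_red": ConfusionCounts(tp=344, fp=11, fn=70, gt=414),
    "field2_blue": ConfusionCounts(tp=326, fp=25, fn=60, gt=386),
    "field2_purple": ConfusionCounts(tp=99, fp=13, fn=6, gt=105),
    "field2_red": ConfusionCounts(tp=177, fp=7, fn=8, gt=185),
    "field3_blue": ConfusionCounts(tp=101, fp=10, fn=2, gt=103),
    "field3_purple": ConfusionCounts(tp=192, fp=25, fn=7, gt=199),
    "field3_red": ConfusionCounts(tp=78, fp=15, fn=5, gt=83),
}


def _as_points(det: DetectionSet | np.ndarray) -> np.ndarray:
    if isinstance(det, DetectionSet):
        return det.detections[["row", "col"]].to_numpy(dtype=float)
    return np.asarray(det, dtype=float).reshape(-1, 2)


def match_detections(
    det: DetectionSet | np.ndarray,
    gt: GroundTruth | np.ndarray,
    radius_px: float = 17.0,
) -> ConfusionCounts:
    """Greedy one-to-one matching of detections to ground-truth points.

    Candidate pairs within ``radius_px`` are taken in order of increasing
    centroid distance, each point used at most once. Matched pairs are TP,
    unmatched detections FP, unmatched ground-truth points FN. The default
    radius of 17 px is about half a meter at 3 cm/px — half the typical
    along-row plant spacing, so a detection is credited only to the plant
    it actually sits on.
    """
    if radius_px <= 0:
        raise ValueError("radius_px must be positive")
    dpts = _as_points(det)
    gpts = gt.points if isinstance(gt, GroundTruth) else GroundTruth(gt).points
    nd, ng = len(dpts), len(gpts)
    if nd == 0 or ng == 0:
        return ConfusionCounts(tp=0, fp=nd, fn=ng, gt=ng)
    dist = np.linalg.norm(dpts[:, None, :] - gpts[None, :, :], axis=2)
    pairs = [
        (dist[i, j], i, j)
        for i in range(nd)
        for j in range(ng)
        if dist[i, j] <= radius_px
    ]
    pairs.sort()
    used_d: set[int] = set()
    used_g: set[int] = set()
    tp = 0
    for _, i, j in pairs:
        if i in used_d or j in used_g:
            continue
        used_d.add(i)
        used_g.add(j)
        tp += 1
    return ConfusionCounts(tp=tp, fp=nd - tp, fn=ng - tp, gt=ng)


def producer_accuracy(c: ConfusionCounts) -> float:
    """TP / GT — fraction of ground-truth plants detected."""
    if c.gt == 0:
        raise ValueError("no ground truth")
    return c.tp / c.gt


def user_accuracy(c: ConfusionCounts) -> float:
    """TP / (TP + FP) — fraction of detections that are real plants."""
    if c.tp + c.fp == 0:
        raise ValueError("no detections")
    return c.tp / (c.tp + c.fp)


def recall_metric(c: ConfusionCounts) -> float:
    """TP / (TP + FN)."""
    if c.tp + c.fn == 0:
        raise ValueError("no ground truth outcomes")
    return c.tp / (c.tp + c.fn)


def average_accuracy(c: ConfusionCounts) -> float:
    """(Pacc + Uacc) / 2 — balances missed plants against false alarms."""
    return (producer_accuracy(c) + user_accuracy(c)) / 2.0


def make_report(c: ConfusionCounts) -> MetricsReport:
    """All four metrics for one region."""
    return MetricsReport(
        p_acc=producer_accuracy(c),
        u_acc=user_accuracy(c),
        recall=recall_metric(c),
        acc=average_accuracy(c),
        counts=c,
    )


def pooled_summary(counts: list[ConfusionCounts]) -> MetricsReport:
    """Micro-pooled metrics: sum the counts over regions, then compute.

    Pooling the counts (rather than averaging per-region metrics) weights
    every plant equally across regions of different size.
    """
    if not counts:
        raise ValueError("pooled_summary needs at least one region")
    total = counts[0]
    for c in counts[1:]:
        total = total + c
    return make_report(total)


def optimal_match_count(
    det_points: np.ndarray, gt_points: np.ndarray, radius_px: float
) -> int:
    """Maximum number of one-to-one matches within the radius.

    Exhaustive search over assignments — exponential, intended only as a
    cross-check of the greedy matcher on small instances.
    """
    dpts = np.asarray(det_points, dtype=float).reshape(-1, 2)
    gpts = np.asarray(gt_points, dtype=float).reshape(-1, 2)
    nd, ng = len(dpts), len(gpts)
    if nd == 0 or ng == 0:
        return 0
    dist = np.linalg.norm(dpts[:, None, :] - gpts[None, :, :], axis=2)
    ok = dist <= radius_px
    best = 0
    k = min(nd, ng)
    for det_sub in itertools.combinations(range(nd), k):
        for perm in itertools.permutations(range(ng), k):
            m = sum(1 for i, j in zip(det_sub, perm) if ok[i, j])
            best = max(best, m)
    return best
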