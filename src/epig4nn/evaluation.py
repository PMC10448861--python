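"""Threshold-sweep metrics, peak-set overlap and region-stratified evaluation.

Under the severe class imbalance of in-cell G4 formation (a few percent
positives), the area under the precision–recall curve is the primary
metric; AUROC is reported alongside for class separability. PR areas use
step-wise summation (no linear interpolation), the standard for imbalanced
genomic classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from intervaltree import IntervalTree
from sklearn.metrics import (average_precision_score, precision_recall_curve,
                             roc_auc_score, roc_curve)

from .genomio import GenomicInterval
from .pqs import PQSMotif


@dataclass
class EvalResult:
    """ROC and PR curves with their areas and class counts."""

    roc_points: List[Tuple[float, float]]
    pr_points: List[Tuple[float, float]]
    auroc: float
    auprc: float
    n_pos: int
    n_neg: int


def _check_binary(labels: np.ndarray) -> Tuple[int, int]:
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos + n_neg != len(labels):
        raise ValueError("labels must be 0/1")
    return n_pos, n_neg


def roc_auc(
    scores: Sequence[float], labels: Sequence[int]
) -> Tuple[List[Tuple[float, float]], float]:
    """ROC curve (FPR, TPR) points and its area.

    The area equals the probability that a random positive outscores a
    random negative, with ties counting one half; both classes must be
    present.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=np.float64)
    n_pos, n_neg = _check_binary(y)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for ROC")
    fpr, tpr, _ = roc_curve(y, s)
    return list(zip(fpr.tolist(), tpr.tolist())), float(roc_auc_score(y, s))


def pr_auc(
    scores: Sequence[float], labels: Sequence[int]
) -> Tuple[List[Tuple[float, float]], float]:
    """Precision–recall curve (recall, precision) points and step-wise area.

    The area is the non-interpolated sum of precision times incremental
    recall over descending score thresholds; random scores give an area
    near the positive prevalence. At least one positive is required.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=np.float64)
    n_pos, n_neg = _check_binary(y)
    if n_pos == 0:
        raise ValueError("at least one positive is required for PR")
    precision, recall, _ = precision_recall_curve(y, s)
    points = list(zip(recall.tolist(), precision.tolist()))
    return points, float(average_precision_score(y, s))


def evaluate(scores: Sequence[float], labels: Sequence[int]) -> EvalResult:
    """Full evaluation bundle: both curves, both areas, class counts."""
    y = np.asarray(labels)
    n_pos, n_neg = _check_binary(y)
    roc_points, auroc = roc_auc(scores, labels)
    pr_points, auprc = pr_auc(scores, labels)
    return EvalResult(roc_points, pr_points, auroc, auprc, n_pos, n_neg)


def _build_trees(peaks: Sequence[GenomicInterval]) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)
    return trees


def overlap_fraction(
    peaks_a: Sequence[GenomicInterval], peaks_b: Sequence[GenomicInterval]
) -> float:
    """Fraction of ``peaks_a`` with at least 1 bp overlap with ``peaks_b``."""
    if not peaks_a:
        return 0.0
    trees = _build_trees(peaks_b)
    hits = sum(
        1
        for p in peaks_a
        if p.chrom in trees and trees[p.chrom].overlaps(p.start, p.end)
    )
    return hits / len(peaks_a)


@dataclass
class StratumResult:
    """Per-stratum evaluation with positive proportions.

    ``auroc``/``auprc`` are NaN when undefined (empty stratum or a single
    class); proportions are the fraction of experimental label-1 motifs and
    of motifs predicted positive at probability 0.5.
    """

    n: int
    n_pos: int
    experimental_positive_fraction: float
    predicted_positive_fraction: float
    auroc: float
    auprc: float
    pr_points: List[Tuple[float, float]]


def stratified_eval(
    scores: Sequence[float],
    labels: Sequence[int],
    motifs: Sequence[PQSMotif],
    regions: Mapping[str, Sequence[GenomicInterval]],
    threshold: float = 0.5,
) -> Dict[str, StratumResult]:
    """Evaluate per genomic stratum (e.g. promoter / enhancer / random).

    Motifs are assigned to the first stratum (in the mapping's order, so
    list promoters before enhancers) whose regions they overlap by >= 1 bp;
    motifs matching no stratum are dropped. Empty strata and single-class
    strata report NaN areas rather than raising.
    """
    if not (len(scores) == len(labels) == len(motifs)):
        raise ValueError("scores, labels and motifs must be parallel")
    trees = {name: _build_trees(regs) for name, regs in regions.items()}
    assigned: Dict[str, List[int]] = {name: [] for name in regions}
    for i, m in enumerate(motifs):
        iv = m.interval
        for name in regions:
            t = trees[name]
            if iv.chrom in t and t[iv.chrom].overlaps(iv.start, iv.end):
                assigned[name].append(i)
                break
    scores_arr = np.asarray(scores, dtype=np.float64)
    labels_arr = np.asarray(labels)
    out: Dict[str, StratumResult] = {}
    for name, idx in assigned.items():
        if not idx:
            out[name] = StratumResult(0, 0, 0.0, 0.0, math.nan, math.nan, [])
            continue
        s, y = scores_arr[idx], labels_arr[idx]
        n_pos = int(np.sum(y == 1))
        exp_frac = n_pos / len(y)
        pred_frac = float(np.mean(s > threshold))
        if n_pos == 0 or n_pos == len(y):
            out[name] = StratumResult(
                len(y), n_pos, exp_frac, pred_frac, math.nan, math.nan, []
            )
        else:
            pr_points, auprc = pr_auc(s, y)
            _, auroc = roc_auc(s, y)
            out[name] = StratumResult(
                len(y), n_pos, exp_frac, pred_frac, auroc, auprc, pr_points
            )
    return out
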