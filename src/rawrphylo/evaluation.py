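"""Benchmarking metrics for support estimates, trees and alignments.

Support-threshold confusion classes are defined over the non-trivial
bipartitions of the estimated (annotation) tree relative to a reference
tree: a bipartition with support >= threshold is a positive, and it is a
true positive iff the reference tree also displays it. Sweeping the
threshold over the observed support values yields a precision-recall
curve whose area (trapezoidal, over recall-ordered points) summarizes
type I/II error of the support estimates. Aggregate PR-AUC pools confusion
counts across datasets at each threshold before computing the curve.

Alignment/tree error statistics: normalized Robinson-Foulds distance (nRF),
sum-of-pairs alignment error (SP-FN/SP-FP), average normalized Hamming
distance (ANHD) and gappiness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import dendropy
import numpy as np

from .io_formats import GAP, Alignment
from .support import SupportMap, nontrivial_bipartitions, taxon_set

__all__ = [
    "ConfusionCounts",
    "PRCurve",
    "confusion_at_threshold",
    "pr_curve",
    "aggregate_pr_auc",
    "nrf_distance",
    "sp_errors",
    "anhd",
    "gappiness",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int
    threshold: float

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class PRCurve:
    """PR points as (recall, precision, threshold), recall-ordered, plus the
    trapezoidal area under the curve."""

    points: tuple[tuple[float, float, float], ...]
    auc: float


def _labelled_scores(
    est: dendropy.Tree, support: SupportMap, ref: dendropy.Tree
) -> list[tuple[float, bool]]:
    if taxon_set(est) != taxon_set(ref):
        raise ValueError("estimated and reference trees have different taxon sets")
    est_bips = nontrivial_bipartitions(est)
    if set(support.entries) != set(est_bips):
        raise ValueError(
            "support map domain does not match the estimated tree's "
            "non-trivial bipartitions"
        )
    ref_bips = nontrivial_bipartitions(ref)
    return [(support.entries[b], b in ref_bips) for b in est_bips]


def _confusion(scores: list[tuple[float, bool]], thr: float) -> ConfusionCounts:
    tp = sum(1 for s, pos in scores if s >= thr and pos)
    fp = sum(1 for s, pos in scores if s >= thr and not pos)
    fn = sum(1 for s, pos in scores if s < thr and pos)
    tn = sum(1 for s, pos in scores if s < thr and not pos)
    return ConfusionCounts(tp, fp, fn, tn, thr)


def confusion_at_threshold(
    est: dendropy.Tree, support: SupportMap, ref: dendropy.Tree, thr: float
) -> ConfusionCounts:
    """Classify each estimated bipartition by (support >= thr) x (present in
    the reference tree)."""
    return _confusion(_labelled_scores(est, support, ref), thr)


def _curve_from_scores(scores: list[tuple[float, bool]]) -> PRCurve:
    n_pos = sum(1 for _, pos in scores if pos)
    if n_pos == 0:
        raise ValueError(
            "no estimated bipartition is present in the reference tree; "
            "recall is undefined"
        )
    thresholds = sorted({s for s, _ in scores}, reverse=True)
    # sentinel above the maximum support: nothing is called positive
    points = [(0.0, 1.0, thresholds[0] + 1.0)]
    for thr in thresholds:
        c = _confusion(scores, thr)
        precision = c.tp / (c.tp + c.fp)  # tp+fp >= 1 at an observed score
        recall = c.tp / (c.tp + c.fn)
        points.append((recall, precision, thr))
    # points are in descending-threshold order, so recall is non-decreasing;
    # trapezoidal integration follows that order (ties in recall contribute
    # zero width), matching the standard library convention
    rec = np.array([p[0] for p in points])
    prec = np.array([p[1] for p in points])
    auc = float(np.trapezoid(prec, rec))
    return PRCurve(tuple(points), auc)


def pr_curve(est: dendropy.Tree, support: SupportMap, ref: dendropy.Tree) -> PRCurve:
    """Precision-recall curve for one annotated tree against a reference.

    Thresholds sweep the sorted unique support values plus a sentinel above
    the maximum (recall 0, precision 1 by convention); AUC is trapezoidal
    over recall-ordered points with no further interpolation.
    """
    return _curve_from_scores(_labelled_scores(est, support, ref))


def aggregate_pr_auc(
    cases: list[tuple[dendropy.Tree, SupportMap, dendropy.Tree]],
    mean_auc: bool = False,
) -> float:
    """PR-AUC across several (estimated tree, support, reference) cases.

    By default confusion counts are pooled across cases at each threshold
    before precision/recall are computed (an aggregate curve, not a mean of
    per-case AUCs); ``mean_auc=True`` averages per-case AUCs instead.
    """
    if not cases:
        raise ValueError("need at least one case")
    if mean_auc:
        return float(np.mean([pr_curve(*c).auc for c in cases]))
    pooled: list[tuple[float, bool]] = []
    for c in cases:
        pooled.extend(_labelled_scores(*c))
    return _curve_from_scores(pooled).auc


def nrf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> float:
    """Normalized Robinson-Foulds distance: the symmetric difference of the
    two non-trivial bipartition sets divided by their total size (equals
    ``2(n-3)`` for two binary trees). 0 iff identical topologies."""
    if taxon_set(t1) != taxon_set(t2):
        raise ValueError("trees have different taxon sets")
    b1 = nontrivial_bipartitions(t1)
    b2 = nontrivial_bipartitions(t2)
    denom = len(b1) + len(b2)
    if denom == 0:
        return 0.0
    return len(b1 ^ b2) / denom


def _homology_pairs(a: Alignment) -> set[tuple[int, int, int, int]]:
    """Residue-residue homology pairs implied by an alignment: tuples
    (taxon_i, residue_i, taxon_j, residue_j) with i < j, for every column
    where both rows carry a residue."""
    residx = []
    for _, row in a.records:
        arr = np.array(list(row)) != GAP
        residx.append(np.where(arr, np.cumsum(arr) - 1, -1))
    pairs: set[tuple[int, int, int, int]] = set()
    n = len(a)
    for i, j in combinations(range(n), 2):
        ri, rj = residx[i], residx[j]
        both = (ri >= 0) & (rj >= 0)
        for x, y in zip(ri[both], rj[both]):
            pairs.add((i, int(x), j, int(y)))
    return pairs


def sp_errors(true_aln: Alignment, est_aln: Alignment) -> tuple[float, float]:
    """Sum-of-pairs alignment error.

    SP-FN is the proportion of residue-pair homologies in the true
    alignment missing from the estimate; SP-FP the proportion of estimated
    homologies absent from the truth. Requires both alignments to describe
    the same underlying unaligned sequences.
    """
    if true_aln.labels != est_aln.labels:
        raise ValueError("alignments must have identical ordered taxon labels")
    for (lab, t_row), e_row in zip(true_aln.records, est_aln.rows):
        if t_row.replace(GAP, "") != e_row.replace(GAP, ""):
            raise ValueError(f"underlying sequence of taxon {lab!r} differs")
    t_pairs = _homology_pairs(true_aln)
    e_pairs = _homology_pairs(est_aln)
    if not t_pairs or not e_pairs:
        raise ValueError("an alignment implies no homology pairs")
    sp_fn = len(t_pairs - e_pairs) / len(t_pairs)
    sp_fp = len(e_pairs - t_pairs) / len(e_pairs)
    return sp_fn, sp_fp


def anhd(a: Alignment) -> float:
    """Average normalized Hamming distance over all unordered row pairs.

    Sites gapped in either row of a pair are excluded from both numerator
    and denominator; N counts as a mismatch. Pairs with no comparable sites
    are excluded from the average with a warning.
    """
    if len(a) < 2:
        raise ValueError("need at least two rows")
    mat = np.array([list(row) for row in a.rows])
    gaps = mat == GAP
    ns = mat == "N"
    vals = []
    for i, j in combinations(range(len(a)), 2):
        ok = ~gaps[i] & ~gaps[j]
        comp = int(ok.sum())
        if comp == 0:
            warnings.warn(f"rows {i} and {j} share no comparable sites; pair skipped")
            continue
        mism = (mat[i] != mat[j]) | ns[i] | ns[j]
        vals.append(float((mism & ok).sum()) / comp)
    if not vals:
        raise ValueError("no row pair has comparable sites")
    return float(np.mean(vals))


def gappiness(a: Alignment) -> float:
    """Proportion of the alignment matrix consisting of gap characters."""
    if len(a) == 0 or a.n_cols == 0:
        raise ValueError("empty alignment")
    total = len(a) * a.n_cols
    gaps = sum(row.count(GAP) for row in a.rows)
    return gaps / total
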