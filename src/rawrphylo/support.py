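"""Branch support estimation on an annotation tree.

Support for an internal edge is the fraction of re-estimated replicate
trees that display the edge's bipartition. Three pipelines share this
calculation and differ only in how replicates are produced:

* :func:`rawr_support` — reversal (or teleportation) random-walk replicates
  of the annotation MSA, unaligned, then re-aligned and re-estimated
  (two-phase ``g(f(X_i))``).
* :func:`bootstrap_support` — i.i.d. column resamples of the annotation
  MSA, re-estimated directly (no re-alignment: a bootstrap replicate has no
  neighbor structure, so re-aligning it is not meaningful).
* :func:`multilocus_support` — per-partition random-walk resampling in
  aligned mode, the all-four-nucleotides partition filter, supermatrix
  concatenation, then tree re-estimation per replicate.

Bipartitions are canonicalized as the frozenset of taxon labels on the side
NOT containing the lexicographically smallest taxon, which makes equality
well-defined under arbitrary rooting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy

from .io_formats import Alignment, PartitionScheme, SequenceSet
from .reestimation import AlignerBackend, TreeBackend, align, infer_tree
from .resampling import (
    Replicate,
    WalkParams,
    _trace_for_mode,
    extract_replicate,
    replicate_rngs,
    resample_many,
)

__all__ = [
    "Bipartition",
    "SupportMap",
    "taxon_set",
    "nontrivial_bipartitions",
    "displays",
    "compute_support",
    "attach_support",
    "rawr_support",
    "bootstrap_support",
    "filter_partitions",
    "multilocus_support",
]

#: A canonical bipartition: the side of the split not containing the
#: lexicographically smallest taxon label.
Bipartition = frozenset


@dataclass(frozen=True)
class SupportMap:
    """Support values for the non-trivial bipartitions of an annotation
    tree; every value is ``m / n_replicates`` for an integer ``m``."""

    entries: dict[Bipartition, float]
    n_replicates: int

    def __getitem__(self, b: Bipartition) -> float:
        return self.entries[b]

    def __len__(self) -> int:
        return len(self.entries)

    def items(self):
        return self.entries.items()


def taxon_set(t: dendropy.Tree) -> frozenset:
    return frozenset(leaf.taxon.label for leaf in t.leaf_node_iter())


def nontrivial_bipartitions(t: dendropy.Tree) -> frozenset:
    """Canonical non-trivial bipartitions of a tree (one per internal edge,
    both sides of size >= 2), invariant to rooting."""
    all_taxa = taxon_set(t)
    if len(all_taxa) < 4:
        return frozenset()
    anchor = min(all_taxa)
    below: dict[dendropy.Node, frozenset] = {}
    out = set()
    for node in t.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
        else:
            below[node] = frozenset().union(*(below[c] for c in node.child_nodes()))
        if node.parent_node is None:
            continue
        side = below[node]
        other = all_taxa - side
        if len(side) < 2 or len(other) < 2:
            continue
        out.add(side if anchor not in side else other)
    return frozenset(out)


def displays(t: dendropy.Tree, b: Bipartition) -> bool:
    """True iff ``b`` is a non-trivial bipartition of ``t``. The bipartition
    is given as a canonical side; its taxa must be a subset of the tree's
    taxon set with a non-trivial complement."""
    taxa = taxon_set(t)
    if not b or not (b < taxa):
        raise ValueError("bipartition side must be a proper subset of the tree's taxa")
    anchor = min(taxa)
    canon = b if anchor not in b else taxa - b
    return canon in nontrivial_bipartitions(t)


def compute_support(
    annotation: dendropy.Tree, reestimates: list[dendropy.Tree]
) -> SupportMap:
    """Fraction of re-estimated trees displaying each non-trivial
    bipartition of the annotation tree."""
    if not reestimates:
        raise ValueError("empty re-estimate list")
    taxa = taxon_set(annotation)
    for i, t in enumerate(reestimates):
        if taxon_set(t) != taxa:
            raise ValueError(f"re-estimate {i} has a different taxon set")
    bips = nontrivial_bipartitions(annotation)
    counts = {b: 0 for b in bips}
    for t in reestimates:
        present = nontrivial_bipartitions(t)
        for b in bips:
            if b in present:
                counts[b] += 1
    k = len(reestimates)
    return SupportMap({b: c / k for b, c in counts.items()}, k)


def attach_support(
    tree: dendropy.Tree, support: SupportMap, percent: bool = False
) -> dendropy.Tree:
    """Return a copy of ``tree`` with support written as internal-node
    labels (proportions to 3 decimals, or integer percentages)."""
    t = tree.clone(depth=1)
    taxa = taxon_set(t)
    anchor = min(taxa)
    below: dict[dendropy.Node, frozenset] = {}
    for node in t.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
            continue
        below[node] = frozenset().union(*(below[c] for c in node.child_nodes()))
        side = below[node]
        other = taxa - side
        if node.parent_node is None or len(side) < 2 or len(other) < 2:
            continue
        canon = side if anchor not in side else other
        if canon in support.entries:
            v = support.entries[canon]
            node.label = f"{round(v * 100):d}" if percent else f"{v:.3f}"
    return t


def _reestimate_trees(
    replicates: list[Replicate],
    f: AlignerBackend | None,
    g: TreeBackend,
    realign: bool,
    on_error: str = "abort",
) -> list[dendropy.Tree]:
    trees = []
    for idx, rep in enumerate(replicates):
        try:
            if realign:
                aln = align(rep.unaligned, f)
            else:
                aln = rep.resampled_alignment
            trees.append(infer_tree(aln, g))
        except Exception as exc:
            if on_error == "skip":
                warnings.warn(f"replicate {idx} failed and was skipped: {exc}")
                continue
            raise
    if not trees:
        raise RuntimeError("all replicates failed re-estimation")
    return trees


def rawr_support(
    seqs: SequenceSet,
    f: AlignerBackend,
    g: TreeBackend,
    params: WalkParams = WalkParams(),
    k: int = 100,
    on_error: str = "abort",
) -> tuple[dendropy.Tree, SupportMap]:
    """Random-walk resampling support (``params.mode`` selects the reversal
    walk or the teleportation variant).

    Estimates the annotation MSA ``A = f(seqs)`` and tree ``T = g(A)``,
    draws ``k`` unaligned walk replicates of ``A``, re-estimates
    ``T_i = g(f(X_i))``, and returns ``T`` (with supports attached) plus
    the support map. On replicate failure the default policy aborts;
    ``on_error='skip'`` drops the replicate and renormalizes by the number
    of successes.
    """
    if params.mode == "bootstrap":
        raise ValueError("use bootstrap_support for bootstrap resampling")
    a = align(seqs, f)
    annotation = infer_tree(a, g)
    reps = resample_many(a, params, k)
    trees = _reestimate_trees(reps, f, g, realign=True, on_error=on_error)
    support = compute_support(annotation, trees)
    return attach_support(annotation, support), support


def bootstrap_support(
    a: Alignment,
    g: TreeBackend,
    k: int = 100,
    seed: int | None = None,
    on_error: str = "abort",
) -> tuple[dendropy.Tree, SupportMap]:
    """Felsenstein bootstrap support: i.i.d. column resamples of ``a``,
    tree re-estimation on each aligned replicate (no re-alignment)."""
    annotation = infer_tree(a, g)
    params = WalkParams(mode="bootstrap", seed=seed)
    reps = resample_many(a, params, k)
    trees = _reestimate_trees(reps, None, g, realign=False, on_error=on_error)
    support = compute_support(annotation, trees)
    return attach_support(annotation, support), support


def filter_partitions(replicates: list[Alignment]) -> list[Alignment]:
    """Retain exactly the partitions whose resampled alignment contains at
    least one each of A, C, G and T (gaps and N do not count); avoids
    degenerate substitution-model fits on nucleotide-deficient partitions."""
    kept = []
    for aln in replicates:
        chars = set("".join(aln.rows))
        if {"A", "C", "G", "T"} <= chars:
            kept.append(aln)
    if not kept:
        raise ValueError("all partitions were filtered out (missing nucleotides)")
    return kept


def _concat(alignments: list[Alignment]) -> tuple[Alignment, PartitionScheme]:
    labels = alignments[0].labels
    rows = ["" for _ in labels]
    parts = []
    pos = 0
    for p_idx, aln in enumerate(alignments):
        if aln.labels != labels:
            raise ValueError("partitions must share an identical ordered taxon set")
        for i, row in enumerate(aln.rows):
            rows[i] += row
        parts.append((f"p{p_idx + 1}", pos, pos + aln.n_cols))
        pos += aln.n_cols
    return (
        Alignment(tuple(zip(labels, rows))),
        PartitionScheme(tuple(parts)),
    )


def multilocus_support(
    partitions: list[Alignment],
    g: TreeBackend,
    params: WalkParams = WalkParams(),
    k: int = 100,
    on_error: str = "abort",
) -> tuple[dendropy.Tree, SupportMap]:
    """Partitioned (multi-locus) random-walk support.

    The annotation tree is estimated on the full concatenation. For each
    replicate, every partition is independently resampled by a random walk
    in aligned mode (columns stay aligned; no unalign/re-align step, so
    re-estimation matches the bootstrap protocol), partitions missing any of
    the four nucleotides are dropped, and the survivors are concatenated
    into a supermatrix on which the tree is re-estimated.
    """
    if not partitions:
        raise ValueError("need at least one partition")
    if params.mode == "bootstrap":
        raise ValueError("multilocus_support resamples by random walk")
    full, _ = _concat(partitions)
    annotation = infer_tree(full, g)
    rngs = replicate_rngs(params.seed, k)
    trees = []
    for j, rng in enumerate(rngs):
        resampled = []
        for part in partitions:
            trace = _trace_for_mode(part.n_cols, params.gamma, params.mode, rng)
            resampled.append(extract_replicate(part, trace).resampled_alignment)
        try:
            survivors = filter_partitions(resampled)
            supermatrix, _ = _concat(survivors)
            trees.append(infer_tree(supermatrix, g))
        except Exception as exc:
            if on_error == "skip":
                warnings.warn(f"replicate {j} failed and was skipped: {exc}")
                continue
            raise
    if not trees:
        raise RuntimeError("all replicates failed re-estimation")
    support = compute_support(annotation, trees)
    return attach_support(annotation, support), support
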