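"""MSA and tree re-estimation backends.

The support pipeline composes two contracts: an aligner ``f`` mapping
unaligned sequences to an MSA, and a tree estimator ``g`` mapping an MSA to
an unrooted tree. Both are plain callables with a ``name`` attribute.

Two families of backends are provided:

* Built-in, dependency-free estimators suitable for desk-scale work: a
  progressive profile aligner (k-mer guide distances, average-linkage guide
  tree, profile-profile Needleman-Wunsch with linear gap costs) and a
  neighbor-joining tree estimator on Jukes-Cantor-corrected distances.
  These are deliberately simple distance-based methods; maximum-likelihood
  search is left to external tools.
* Subprocess adapters for external tools (MAFFT for alignment; a generic
  command-template tree adapter usable for RAxML and similar), which shell
  out with configurable command templates.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Protocol, runtime_checkable

import dendropy
import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .io_formats import GAP, Alignment, SequenceSet, parse_fasta, parse_newick, write_fasta

__all__ = [
    "AlignerBackend",
    "TreeBackend",
    "BuiltinAligner",
    "BuiltinNJTree",
    "MafftAligner",
    "CommandTreeBackend",
    "FixedTreeBackend",
    "BackendError",
    "align",
    "infer_tree",
    "builtin_align",
    "builtin_tree",
    "nj_tree",
    "jc_distance_matrix",
]


class BackendError(RuntimeError):
    """An estimation backend failed; carries its diagnostics."""


@runtime_checkable
class AlignerBackend(Protocol):
    name: str

    def __call__(self, seqs: SequenceSet) -> Alignment: ...


@runtime_checkable
class TreeBackend(Protocol):
    name: str

    def __call__(self, a: Alignment) -> dendropy.Tree: ...


def align(seqs: SequenceSet, backend: AlignerBackend) -> Alignment:
    """Run an aligner backend and validate its contract: same taxa, and
    unaligning the output reproduces every input sequence exactly."""
    out = backend(seqs)
    if out.labels != seqs.labels:
        raise BackendError(
            f"aligner {backend.name!r} changed the taxon set or order"
        )
    for (lab, seq), row in zip(seqs.records, out.rows):
        if row.replace(GAP, "") != seq:
            raise BackendError(
                f"aligner {backend.name!r} altered the sequence of taxon {lab!r}"
            )
    return out


def infer_tree(a: Alignment, backend: TreeBackend) -> dendropy.Tree:
    """Run a tree backend and validate that its leaf set equals the
    alignment's taxon set."""
    tree = backend(a)
    leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    if leaves != set(a.labels):
        raise BackendError(
            f"tree backend {backend.name!r} returned leaf set {sorted(leaves)} "
            f"!= taxon set {sorted(a.labels)}"
        )
    return tree


# ---------------------------------------------------------------------------
# Built-in progressive aligner
# ---------------------------------------------------------------------------

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, GAP: 5}
_CHAR = np.array(list("ACGTN-"), dtype="<U1")

# Column scoring: match +2, mismatch -1 between A/C/G/T; N and gaps
# contribute 0. New gaps cost -2 per column (linear).
_MATCH_SCORE = 2.0
_MISMATCH_SCORE = -1.0
_GAP_PENALTY = -2.0
_GUIDE_KMER = 3


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE[c] for c in seq], dtype=np.uint8)


def _kmer_profile(seq: str, k: int = _GUIDE_KMER) -> dict[str, int]:
    prof: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        prof[w] = prof.get(w, 0) + 1
    return prof


def _kmer_distance(p1: dict[str, int], p2: dict[str, int]) -> float:
    n1, n2 = sum(p1.values()), sum(p2.values())
    if n1 == 0 or n2 == 0:
        return 1.0
    shared = sum(min(c, p2.get(w, 0)) for w, c in p1.items())
    return 1.0 - shared / min(n1, n2)


def _profile_freqs(profile: np.ndarray) -> np.ndarray:
    """Per-column A/C/G/T frequencies of a (n_rows, n_cols) code matrix,
    normalized by the number of rows (gaps and N dilute the column)."""
    n_rows, n_cols = profile.shape
    freqs = np.zeros((n_cols, 4))
    for b in range(4):
        freqs[:, b] = (profile == b).sum(axis=0)
    return freqs / max(n_rows, 1)


def _nw_profiles(p1: np.ndarray, p2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Global profile-profile alignment with linear gap costs.

    Returns the two profiles with gap columns inserted so they have equal
    length. Deterministic tie-breaking: diagonal > up > left.
    """
    f1, f2 = _profile_freqs(p1), _profile_freqs(p2)
    m = np.full((4, 4), _MISMATCH_SCORE)
    np.fill_diagonal(m, _MATCH_SCORE)
    S = f1 @ m @ f2.T  # (L1, L2) expected column-pair score
    L1, L2 = S.shape
    g = _GAP_PENALTY
    H = np.empty((L1 + 1, L2 + 1))
    H[0, :] = g * np.arange(L2 + 1)
    H[:, 0] = g * np.arange(L1 + 1)
    offs = g * np.arange(L2 + 1)
    for i in range(1, L1 + 1):
        # best predecessor via diagonal or up, then a running max handles
        # arbitrarily long horizontal gap runs in one vectorized pass
        cand = np.maximum(H[i - 1, :-1] + S[i - 1, :], H[i - 1, 1:] + g)
        x = np.empty(L2 + 1)
        x[0] = H[i, 0]
        x[1:] = cand
        H[i, :] = np.maximum.accumulate(x - offs) + offs
    # traceback by local argmax of the three candidate moves
    i, j = L1, L2
    moves: list[int] = []  # 0=diag, 1=up, 2=left
    while i > 0 or j > 0:
        if i == 0:
            moves.append(2)
            j -= 1
            continue
        if j == 0:
            moves.append(1)
            i -= 1
            continue
        c_diag = H[i - 1, j - 1] + S[i - 1, j - 1]
        c_up = H[i - 1, j] + g
        c_left = H[i, j - 1] + g
        best = max(c_diag, c_up, c_left)
        if c_diag >= best - 1e-9:
            moves.append(0)
            i -= 1
            j -= 1
        elif c_up >= best - 1e-9:
            moves.append(1)
            i -= 1
        else:
            moves.append(2)
            j -= 1
    moves.reverse()
    L = len(moves)
    out1 = np.full((p1.shape[0], L), _CODE[GAP], dtype=np.uint8)
    out2 = np.full((p2.shape[0], L), _CODE[GAP], dtype=np.uint8)
    i = j = 0
    for col, mv in enumerate(moves):
        if mv in (0, 1):
            out1[:, col] = p1[:, i]
            i += 1
        if mv in (0, 2):
            out2[:, col] = p2[:, j]
            j += 1
    return out1, out2


def builtin_align(seqs: SequenceSet) -> Alignment:
    """Progressive alignment: k-mer guide distances, average-linkage guide
    tree, profile-profile merging with linear gap costs.

    Deterministic given input order. Empty input sequences become all-gap
    rows. A single sequence aligns to itself.
    """
    n = len(seqs)
    if n == 0 or all(len(s) == 0 for s in seqs.sequences):
        raise BackendError("builtin aligner requires at least one non-empty sequence")
    if n == 1:
        return Alignment(seqs.records)
    profiles: dict[int, np.ndarray] = {
        i: _encode(seq).reshape(1, -1) for i, seq in enumerate(seqs.sequences)
    }
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    kprofs = [_kmer_profile(s) for s in seqs.sequences]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = _kmer_distance(kprofs[i], kprofs[j])
    Z = linkage(squareform(dist, checks=False), method="average")
    next_id = n
    for a_id, b_id in Z[:, :2].astype(int):
        p1, p2 = profiles.pop(a_id), profiles.pop(b_id)
        if p1.shape[1] == 0 or p2.shape[1] == 0:
            # degenerate (empty-sequence) side: pad with all-gap rows
            L = max(p1.shape[1], p2.shape[1])
            p1 = np.hstack([p1, np.full((p1.shape[0], L - p1.shape[1]), _CODE[GAP], np.uint8)])
            p2 = np.hstack([p2, np.full((p2.shape[0], L - p2.shape[1]), _CODE[GAP], np.uint8)])
            merged = np.vstack([p1, p2])
        else:
            o1, o2 = _nw_profiles(p1, p2)
            merged = np.vstack([o1, o2])
        profiles[next_id] = merged
        members[next_id] = members.pop(a_id) + members.pop(b_id)
        next_id += 1
    final = profiles[next_id - 1]
    order = members[next_id - 1]
    rows: list[str] = [""] * n
    for r, orig in enumerate(order):
        rows[orig] = "".join(_CHAR[final[r]])
    return Alignment(tuple(zip(seqs.labels, rows)))


@dataclass(frozen=True)
class BuiltinAligner:
    name: str = "builtin"

    def __call__(self, seqs: SequenceSet) -> Alignment:
        return builtin_align(seqs)


# ---------------------------------------------------------------------------
# Built-in distance tree backend
# ---------------------------------------------------------------------------

#: Distance assigned when Jukes-Cantor correction is undefined (saturated
#: pairs, or pairs with no comparable sites).
MAX_DISTANCE = 5.0


def jc_distance_matrix(a: Alignment) -> tuple[np.ndarray, list[str]]:
    """Pairwise Jukes-Cantor distances over gap-excluded pairwise sites.

    Sites where either row has a gap are skipped; N counts as a mismatch.
    Saturated or incomparable pairs get :data:`MAX_DISTANCE`. Rows are
    ordered by taxon label for deterministic downstream tie-breaking.
    """
    order = sorted(range(len(a)), key=lambda i: a.labels[i])
    labels = [a.labels[i] for i in order]
    mat = np.array([_encode(a.rows[i]) for i in order])
    n = len(labels)
    d = np.zeros((n, n))
    gap = _CODE[GAP]
    for i in range(n):
        for j in range(i + 1, n):
            ok = (mat[i] != gap) & (mat[j] != gap)
            comp = int(ok.sum())
            if comp == 0:
                dij = MAX_DISTANCE
            else:
                ncode = _CODE["N"]
                mism = (mat[i] != mat[j]) | (mat[i] == ncode) | (mat[j] == ncode)
                p = float((mism & ok).sum()) / comp
                if p >= 0.749999:
                    dij = MAX_DISTANCE
                else:
                    dij = min(-0.75 * np.log(1.0 - 4.0 * p / 3.0), MAX_DISTANCE)
            d[i, j] = d[j, i] = dij
    return d, labels


def nj_tree(dist: np.ndarray, labels: list[str]) -> dendropy.Tree:
    """Neighbor joining on a distance matrix (delegates to scikit-bio),
    returned as an unrooted dendropy tree."""
    import io as _io

    import skbio
    from skbio.tree import nj as _skbio_nj

    if len(labels) < 3:
        raise BackendError("neighbor joining requires >= 3 taxa")
    dm = skbio.DistanceMatrix(dist, ids=labels)
    buf = _io.StringIO()
    _skbio_nj(dm).write(buf, format="newick")
    return parse_newick(buf.getvalue())


def builtin_tree(a: Alignment) -> dendropy.Tree:
    """Neighbor joining on Jukes-Cantor-corrected distances.

    Zero-length (all-gap) rows have no comparable sites with anyone; rather
    than invent a placement, the backend refuses them and suggests a
    minimum-length filter upstream.
    """
    if len(a) < 3:
        raise BackendError("builtin tree backend requires >= 3 taxa")
    for lab, row in a.records:
        if row.replace(GAP, "") == "":
            raise BackendError(
                f"taxon {lab!r} has an empty (all-gap) sequence; filter "
                "zero-length taxa before tree estimation"
            )
    d, labels = jc_distance_matrix(a)
    return nj_tree(d, labels)


@dataclass(frozen=True)
class BuiltinNJTree:
    name: str = "builtin"

    def __call__(self, a: Alignment) -> dendropy.Tree:
        return builtin_tree(a)


@dataclass(frozen=True)
class FixedTreeBackend:
    """Tree backend that returns a copy of a fixed tree regardless of input.

    Useful for identity checks: with a constant estimator every annotation
    bipartition is displayed by every replicate, so all supports are 1.
    """

    tree: dendropy.Tree
    name: str = "fixed"

    def __call__(self, a: Alignment) -> dendropy.Tree:
        return self.tree.clone(depth=1)


# ---------------------------------------------------------------------------
# External tool adapters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MafftAligner:
    """Subprocess adapter for MAFFT. ``args`` is the argument template; the
    input FASTA path is appended and the alignment read from stdout."""

    executable: str = "mafft"
    args: tuple[str, ...] = ("--auto", "--quiet")
    timeout: float | None = 600.0

    @property
    def name(self) -> str:
        return f"mafft({self.executable})"

    def available(self) -> bool:
        return shutil.which(self.executable) is not None

    def __call__(self, seqs: SequenceSet) -> Alignment:
        if not self.available():
            raise BackendError(f"executable {self.executable!r} not found on PATH")
        with tempfile.TemporaryDirectory() as tmp:
            inp = Path(tmp) / "in.fasta"
            inp.write_text(write_fasta(seqs))
            try:
                proc = subprocess.run(
                    [self.executable, *self.args, str(inp)],
                    capture_output=True,
                    text=True,
                    timeout=self.timeout,
                )
            except subprocess.TimeoutExpired as exc:
                raise BackendError(f"{self.name} timed out: {exc}") from exc
        if proc.returncode != 0:
            raise BackendError(
                f"{self.name} exited {proc.returncode}: {proc.stderr[-2000:]}"
            )
        out = parse_fasta(proc.stdout, aligned=True)
        # restore input record order (mafft preserves it, but be safe)
        by_label = dict(out.records)
        try:
            return Alignment(tuple((lab, by_label[lab]) for lab in seqs.labels))
        except KeyError as exc:
            raise BackendError(f"{self.name} dropped taxon {exc}") from exc


@dataclass(frozen=True)
class CommandTreeBackend:
    """Generic subprocess adapter for tree estimators such as RAxML.

    ``command_template`` is formatted with ``alignment`` (input FASTA path),
    ``workdir`` and ``prefix``; ``output_template`` names the Newick file the
    tool writes, formatted the same way. Example RAxML template::

        raxmlHPC -s {alignment} -w {workdir} -n {prefix} -m GTRGAMMA -p 12345

    with ``output_template='{workdir}/RAxML_bestTree.{prefix}'``.
    """

    command_template: str
    output_template: str
    name: str = "command"
    timeout: float | None = 3600.0

    def __call__(self, a: Alignment) -> dendropy.Tree:
        with tempfile.TemporaryDirectory() as tmp:
            inp = Path(tmp) / "in.fasta"
            inp.write_text(write_fasta(a))
            fmt = dict(alignment=str(inp), workdir=tmp, prefix="run")
            cmd = self.command_template.format(**fmt).split()
            try:
                proc = subprocess.run(
                    cmd, capture_output=True, text=True, timeout=self.timeout
                )
            except subprocess.TimeoutExpired as exc:
                raise BackendError(f"{self.name} timed out: {exc}") from exc
            if proc.returncode != 0:
                raise BackendError(
                    f"{self.name} exited {proc.returncode}: {proc.stderr[-2000:]}"
                )
            out_path = Path(self.output_template.format(**fmt))
            if not out_path.exists():
                raise BackendError(f"{self.name} produced no output at {out_path}")
            return parse_newick(out_path.read_text())


ALIGNER_FACTORIES: dict[str, Callable[[], AlignerBackend]] = {
    "builtin": BuiltinAligner,
    "mafft": MafftAligner,
}

TREE_FACTORIES: dict[str, Callable[[], TreeBackend]] = {
    "builtin": BuiltinNJTree,
}
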