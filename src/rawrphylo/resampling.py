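"""Replicate generation by random walks on alignment columns.

Three resampling modes over the columns of an input MSA:

``rawr``
    A reversal random walk. The walk starts at a uniformly random column
    facing a uniformly random direction, samples the current column at each
    step, reverses with certainty at the first/last column when facing
    outward and with probability ``gamma`` at interior columns, and stops
    once it has sampled as many columns as the alignment has (the
    sequence-length convergence criterion). Consecutive sampled columns are
    therefore always neighbors in the source alignment ("neighbor
    preservation"), which is what keeps local sequence homology meaningful
    in a replicate.

``teleport``
    As above, except that with probability ``gamma`` the walk jumps to a
    uniformly random column and direction instead of reversing. Neighbor
    preservation holds within the segments between jumps. At ``gamma=1``
    every column is an independent uniform draw, so this mode interpolates
    between the reversal walk and the bootstrap.

``bootstrap``
    Felsenstein's column bootstrap: n_cols i.i.d. uniform draws with
    replacement, no adjacency structure.

A replicate used for tree re-estimation is the column gather in walk order;
for the ``rawr``/``teleport`` single-locus protocol the gathered columns are
then unaligned (gaps dropped) so that alignment re-estimation is performed
from scratch on each replicate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import GAP, Alignment, SequenceSet

__all__ = [
    "GAMMA_DEFAULT",
    "GAMMA_GRID",
    "WalkParams",
    "WalkTrace",
    "Replicate",
    "rawr_walk",
    "teleport_walk",
    "bootstrap_columns",
    "extract_replicate",
    "unalign",
    "resample_many",
]

#: Reversal probability default and the grid explored in the study.
GAMMA_DEFAULT = 1e-1
GAMMA_GRID = (1e-3, 1e-2, 2e-2, 5e-2, 1e-1, 2e-1, 3e-1)

MODES = ("rawr", "teleport", "bootstrap")


@dataclass(frozen=True)
class WalkParams:
    """Parameters of a resampling walk.

    gamma : reversal probability (``rawr``) or teleport probability
        (``teleport``); ignored by ``bootstrap``.
    seed : RNG seed; replicate streams are derived from it deterministically.
    mode : one of ``rawr``, ``teleport``, ``bootstrap``.
    """

    gamma: float = GAMMA_DEFAULT
    seed: int | None = None
    mode: str = "rawr"

    def __post_init__(self) -> None:
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError(f"gamma must be in [0,1], got {self.gamma}")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")


@dataclass(frozen=True)
class WalkTrace:
    """Ordered column indices sampled by one walk.

    ``start`` and ``direction`` record the initial state (direction is +1
    for rightward, -1 for leftward; both are None for bootstrap traces).
    """

    column_indices: tuple[int, ...]
    mode: str
    start: int | None = None
    direction: int | None = None

    def __len__(self) -> int:
        return len(self.column_indices)

    @property
    def segments(self) -> tuple[tuple[int, ...], ...]:
        """Maximal runs of unit-step movement (between reversal/teleport
        events, or singletons for bootstrap traces)."""
        idx = self.column_indices
        if not idx:
            return ()
        segs: list[list[int]] = [[idx[0]]]
        run_step: int | None = None  # direction of the current run, once set
        for a, b in zip(idx, idx[1:]):
            step = b - a
            if step in (-1, 1) and run_step in (None, step):
                segs[-1].append(b)
                run_step = step
            else:
                segs.append([b])
                run_step = None
        return tuple(tuple(s) for s in segs)


@dataclass(frozen=True)
class Replicate:
    """One resampled replicate: the column gather (in walk order), its
    unaligned form, and the trace that produced it."""

    resampled_alignment: Alignment
    unaligned: SequenceSet
    trace: WalkTrace


def _check_ncols(n_cols: int) -> None:
    if n_cols < 1:
        raise ValueError(f"n_cols must be >= 1, got {n_cols}")


def _walk(
    n_cols: int,
    gamma: float,
    rng: np.random.Generator,
    teleport: bool,
    start: int | None = None,
    direction: int | None = None,
) -> WalkTrace:
    # Boundary rule: at column 0 or n_cols-1 the walk reverses iff it faces
    # outward, with certainty; the gamma draw applies at interior columns
    # only (a gamma reversal fired at a boundary column facing inward would
    # step outside the alignment).
    i = int(rng.integers(n_cols)) if start is None else int(start)
    d = (1 if rng.integers(2) == 0 else -1) if direction is None else int(direction)
    if not (0 <= i < n_cols):
        raise ValueError(f"start {i} out of range [0,{n_cols})")
    start_i, start_d = i, d
    out = np.empty(n_cols, dtype=np.intp)
    for step in range(n_cols):
        out[step] = i
        if teleport and rng.random() < gamma:
            i = int(rng.integers(n_cols))
            d = 1 if rng.integers(2) == 0 else -1
            continue
        at_left, at_right = i == 0, i == n_cols - 1
        if at_left or at_right:
            if (at_left and d == -1) or (at_right and d == 1):
                d = -d
        elif not teleport and rng.random() < gamma:
            d = -d
        i += d
    mode = "teleport" if teleport else "rawr"
    return WalkTrace(tuple(int(x) for x in out), mode, start_i, start_d)


def rawr_walk(n_cols: int, params: WalkParams) -> WalkTrace:
    """Run one reversal random walk over ``n_cols`` columns.

    The trace has length exactly ``n_cols`` and every consecutive pair of
    indices differs by exactly 1.
    """
    _check_ncols(n_cols)
    return _walk(n_cols, params.gamma, np.random.default_rng(params.seed), False)


def teleport_walk(n_cols: int, params: WalkParams) -> WalkTrace:
    """Run one teleportation walk (reversals replaced by uniform restarts)."""
    _check_ncols(n_cols)
    return _walk(n_cols, params.gamma, np.random.default_rng(params.seed), True)


def bootstrap_columns(n_cols: int, params: WalkParams) -> WalkTrace:
    """Sample ``n_cols`` columns i.i.d. uniformly with replacement."""
    _check_ncols(n_cols)
    rng = np.random.default_rng(params.seed)
    idx = rng.integers(n_cols, size=n_cols)
    return WalkTrace(tuple(int(x) for x in idx), "bootstrap")


def unalign(a: Alignment) -> SequenceSet:
    """Drop gap characters from every row, preserving residue order and
    labels. Sequence lengths may differ afterwards; all-gap rows yield
    empty sequences."""
    return SequenceSet(tuple((lab, row.replace(GAP, "")) for lab, row in a.records))


def extract_replicate(a: Alignment, trace: WalkTrace) -> Replicate:
    """Gather the traced columns of ``a`` in walk order and unalign them."""
    n = a.n_cols
    for i in trace.column_indices:
        if not (0 <= i < n):
            raise ValueError(f"trace index {i} out of range [0,{n})")
    mat = np.array([list(row) for row in a.rows], dtype="<U1")
    gathered = mat[:, list(trace.column_indices)]
    rows = tuple(
        (lab, "".join(gathered[r])) for r, lab in enumerate(a.labels)
    )
    resampled = Alignment(rows)
    return Replicate(resampled, unalign(resampled), trace)


def _trace_for_mode(n_cols: int, gamma: float, mode: str, rng: np.random.Generator) -> WalkTrace:
    if mode == "rawr":
        return _walk(n_cols, gamma, rng, False)
    if mode == "teleport":
        return _walk(n_cols, gamma, rng, True)
    idx = rng.integers(n_cols, size=n_cols)
    return WalkTrace(tuple(int(x) for x in idx), "bootstrap")


def replicate_rngs(seed: int | None, k: int) -> list[np.random.Generator]:
    """Independent per-replicate generators derived from one master seed via
    ``numpy.random.SeedSequence.spawn`` (the documented stream scheme)."""
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(k)]


def resample_many(a: Alignment, params: WalkParams, k: int) -> list[Replicate]:
    """Generate ``k`` independent replicates of ``a`` under ``params``.

    Fully reproducible: replicate ``i`` is drawn from the ``i``-th stream
    spawned from ``params.seed``, so the same seed yields identical lists.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    _check_ncols(a.n_cols)
    out = []
    for rng in replicate_rngs(params.seed, k):
        trace = _trace_for_mode(a.n_cols, params.gamma, params.mode, rng)
        out.append(extract_replicate(a, trace))
    return out
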