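"""Synthetic benchmark generator: random model trees plus GTR + indel
sequence evolution with exact homology tracking.

Model trees are grown by a random birth process (uniform random leaf
splitting), every branch length is drawn from Uniform(0,1), and all branch
lengths are rescaled so the maximum root-to-leaf path equals the requested
height. Sequences then evolve down the tree from a root sequence drawn
from the stationary base frequencies: substitutions follow the general
time-reversible (GTR) rate matrix, scaled to one expected substitution per
site per unit branch length, with optional Gamma rate variation across
sites; insertions and deletions arrive as Poisson point events along each
branch with geometrically distributed lengths. Every surviving residue
keeps a globally unique column identity, so the generator emits the true
alignment (with gap padding for lineage-specific indels) alongside the
unaligned sequences and the model tree.

Note: sites within a sequence do NOT evolve i.i.d. once indels act on
contiguous runs — which is exactly the violation of the bootstrap's i.i.d.
assumption the resampling method is designed for.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .io_formats import Alignment, SequenceSet
from .resampling import unalign

__all__ = [
    "GTRParams",
    "ModelCondition",
    "CONDITIONS_10_TAXON",
    "sample_model_tree",
    "evolve_sequences",
    "make_condition_fixtures",
]

_BASES = np.array(list("ACGT"), dtype="<U1")


@dataclass(frozen=True)
class GTRParams:
    """GTR substitution parameters plus a simple indel process.

    base_freqs : stationary frequencies (A, C, G, T), summing to 1.
    exchange_rates : symmetric exchangeabilities (AC, AG, AT, CG, CT, GT).
    gamma_shape : optional shape for Gamma-distributed per-site rates
        (mean 1); ``None`` disables rate variation.
    insertion_prob / deletion_prob : event rates per site per unit branch
        length.
    indel_mean_length : mean of the geometric indel length distribution.
    """

    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    exchange_rates: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    gamma_shape: float | None = None
    insertion_prob: float = 0.0
    deletion_prob: float = 0.0
    indel_mean_length: float = 2.0

    def __post_init__(self) -> None:
        freqs = np.asarray(self.base_freqs, dtype=float)
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError("base frequencies must sum to 1")
        if np.any(freqs < 0):
            raise ValueError("base frequencies must be nonnegative")
        if len(self.exchange_rates) != 6 or any(r <= 0 for r in self.exchange_rates):
            raise ValueError("need 6 positive exchange rates")
        if self.indel_mean_length < 1.0:
            raise ValueError("mean indel length must be >= 1")

    @classmethod
    def jukes_cantor(cls, indel_prob: float = 0.0, **kw) -> "GTRParams":
        """Neutral default: equal frequencies and exchangeabilities, with
        insertion and deletion rates both set to ``indel_prob``."""
        return cls(insertion_prob=indel_prob, deletion_prob=indel_prob, **kw)

    def rate_matrix(self) -> np.ndarray:
        """The scaled GTR rate matrix: rows sum to 0 and the expected
        substitution rate at stationarity is 1 per unit branch length."""
        pi = np.asarray(self.base_freqs, dtype=float)
        ac, ag, at, cg, ct, gt = self.exchange_rates
        s = np.array(
            [
                [0.0, ac, ag, at],
                [ac, 0.0, cg, ct],
                [ag, cg, 0.0, gt],
                [at, ct, gt, 0.0],
            ]
        )
        q = s * pi[np.newaxis, :]
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -float(np.dot(pi, np.diag(q)))
        if mu <= 0:
            raise ValueError("degenerate rate matrix")
        return q / mu


@dataclass(frozen=True)
class ModelCondition:
    """One benchmark condition: taxon count, tree height, indel event rate,
    root length and replicate count (mirroring the benchmark parameter
    triples such as 10 taxa / height 0.47 / indel 0.13)."""

    name: str
    n_taxa: int
    height: float
    indel_prob: float
    root_length: int = 1000
    n_replicates: int = 20

    def __post_init__(self) -> None:
        if self.n_taxa < 4:
            raise ValueError("need at least 4 taxa")
        if self.height <= 0:
            raise ValueError("height must be positive")
        if self.root_length < 1:
            raise ValueError("root length must be >= 1")


#: The published 10-taxon benchmark parameter triples, in increasing order
#: of evolutionary divergence.
CONDITIONS_10_TAXON = (
    ModelCondition("10.A", 10, 0.47, 0.13),
    ModelCondition("10.B", 10, 0.7, 0.1),
    ModelCondition("10.C", 10, 1.2, 0.06),
    ModelCondition("10.D", 10, 2.0, 0.031),
    ModelCondition("10.E", 10, 4.4, 0.013),
)


def sample_model_tree(n_taxa: int, height: float, seed=None) -> dendropy.Tree:
    """Random birth model tree of exact height.

    Topology grows by splitting a uniformly chosen leaf until ``n_taxa``
    leaves exist; every edge gets a Uniform(0,1) length; lengths are then
    rescaled so the maximum root-to-leaf distance equals ``height``.
    """
    if n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    if height <= 0:
        raise ValueError("height must be positive")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace([f"t{i + 1}" for i in range(n_taxa)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    leaves = [tree.seed_node.new_child(), tree.seed_node.new_child()]
    while len(leaves) < n_taxa:
        parent = leaves.pop(int(rng.integers(len(leaves))))
        leaves.append(parent.new_child())
        leaves.append(parent.new_child())
    for node, taxon in zip(leaves, taxa):
        node.taxon = taxon
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node:
            edge.length = float(rng.uniform(0.0, 1.0))
    depth = max(
        leaf.distance_from_root() for leaf in tree.leaf_node_iter()
    )
    scale = height / depth
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length * scale
    return tree


def _transition_matrices(q: np.ndarray):
    """Eigen-factorization of Q so per-branch (and per-rate) transition
    matrices are cheap: P(t) = U exp(L t) U^-1."""
    lam, u = np.linalg.eig(q)
    uinv = np.linalg.inv(u)

    def pmat(t: float) -> np.ndarray:
        p = (u * np.exp(lam * t)) @ uinv
        p = np.real(p)
        p = np.clip(p, 0.0, None)
        return p / p.sum(axis=1, keepdims=True)

    return pmat


def _evolve_branch(
    parent: tuple[list[int], np.ndarray, np.ndarray],
    blen: float,
    params: GTRParams,
    pmat,
    rng: np.random.Generator,
    master: list[int],
    id_counter: list[int],
) -> tuple[list[int], np.ndarray, np.ndarray]:
    ids, chars, rates = parent
    ids = list(ids)
    chars = chars.copy()
    rates = rates.copy()
    # substitutions: per-site transition under the site's rate multiplier
    if blen > 0 and len(chars) > 0:
        if params.gamma_shape is None:
            p = pmat(blen)
            new = np.empty_like(chars)
            u = rng.random(len(chars))
            cum = np.cumsum(p, axis=1)
            new = (u[:, None] < cum[chars]).argmax(axis=1)
            chars = new.astype(np.int8)
        else:
            for r in np.unique(rates):
                mask = rates == r
                p = pmat(blen * float(r))
                u = rng.random(int(mask.sum()))
                cum = np.cumsum(p, axis=1)
                chars[mask] = (u[:, None] < cum[chars[mask]]).argmax(axis=1)
    # deletions: Poisson number of events, geometric lengths
    geom_p = 1.0 / params.indel_mean_length
    n_del = rng.poisson(params.deletion_prob * blen * len(ids)) if ids else 0
    for _ in range(n_del):
        if not ids:
            break
        start = int(rng.integers(len(ids)))
        length = int(rng.geometric(geom_p))
        del ids[start : start + length]
        chars = np.delete(chars, slice(start, min(start + length, len(chars))))
        rates = np.delete(rates, slice(start, min(start + length, len(rates))))
    # insertions: new residues get fresh column identities, spliced into the
    # master column order next to their insertion point
    n_ins = rng.poisson(params.insertion_prob * blen * (len(ids) + 1))
    freqs = np.asarray(params.base_freqs)
    for _ in range(n_ins):
        pos = int(rng.integers(len(ids) + 1))
        length = int(rng.geometric(geom_p))
        new_ids = [id_counter[0] + i for i in range(length)]
        id_counter[0] += length
        new_chars = rng.choice(4, size=length, p=freqs).astype(np.int8)
        if params.gamma_shape is None:
            new_rates = np.ones(length)
        else:
            sh = params.gamma_shape
            new_rates = rng.gamma(sh, 1.0 / sh, size=length)
        if pos > 0:
            anchor = master.index(ids[pos - 1]) + 1
        elif ids:
            anchor = master.index(ids[0])
        else:
            anchor = len(master)
        master[anchor:anchor] = new_ids
        ids[pos:pos] = new_ids
        chars = np.concatenate([chars[:pos], new_chars, chars[pos:]]).astype(np.int8)
        rates = np.concatenate([rates[:pos], new_rates, rates[pos:]])
    return ids, chars, rates


def evolve_sequences(
    tree: dendropy.Tree,
    params: GTRParams,
    root_length: int = 1000,
    seed=None,
) -> tuple[Alignment, SequenceSet]:
    """Simulate sequence evolution down ``tree``.

    Returns the true alignment (columns in master homology order, gaps
    where a lineage lacks the residue) and the unaligned leaf sequences;
    ``unalign(true_aln)`` equals the emitted sequences by construction.
    """
    if root_length < 1:
        raise ValueError("root length must be >= 1")
    rng = np.random.default_rng(seed)
    q = params.rate_matrix()
    pmat = _transition_matrices(q)
    freqs = np.asarray(params.base_freqs)
    root_chars = rng.choice(4, size=root_length, p=freqs).astype(np.int8)
    if params.gamma_shape is None:
        root_rates = np.ones(root_length)
    else:
        sh = params.gamma_shape
        root_rates = rng.gamma(sh, 1.0 / sh, size=root_length)
    master = list(range(root_length))
    id_counter = [root_length]
    states = {tree.seed_node: (master.copy(), root_chars, root_rates)}
    leaf_states: dict[str, tuple[list[int], np.ndarray]] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            pass
        else:
            blen = node.edge.length or 0.0
            states[node] = _evolve_branch(
                states[node.parent_node], blen, params, pmat, rng, master, id_counter
            )
        if node.is_leaf():
            ids, chars, _ = states[node]
            leaf_states[node.taxon.label] = (ids, chars)
    # keep only columns surviving in at least one leaf, in master order
    alive = set()
    for ids, _ in leaf_states.values():
        alive.update(ids)
    columns = [cid for cid in master if cid in alive]
    col_index = {cid: k for k, cid in enumerate(columns)}
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    records = []
    for lab in labels:
        ids, chars = leaf_states[lab]
        row = np.full(len(columns), "-", dtype="<U1")
        for cid, ch in zip(ids, chars):
            row[col_index[cid]] = _BASES[ch]
        records.append((lab, "".join(row)))
    true_aln = Alignment(tuple(records))
    return true_aln, unalign(true_aln)


def make_condition_fixtures(
    cond: ModelCondition, seed=None, params: GTRParams | None = None
) -> tuple[list[tuple[dendropy.Tree, Alignment, SequenceSet]], dict]:
    """Draw ``cond.n_replicates`` independent (model tree, true alignment,
    unaligned sequences) fixtures plus a manifest of every parameter and
    per-replicate seed."""
    if params is None:
        params = GTRParams.jukes_cantor(indel_prob=cond.indel_prob)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(cond.n_replicates)
    fixtures = []
    rep_seeds = []
    for child in children:
        tree_seed, seq_seed = child.spawn(2)
        tree = sample_model_tree(cond.n_taxa, cond.height, tree_seed)
        true_aln, seqs = evolve_sequences(tree, params, cond.root_length, seq_seed)
        fixtures.append((tree, true_aln, seqs))
        rep_seeds.append(
            {
                "tree_entropy": str(tree_seed.entropy),
                "seq_entropy": str(seq_seed.entropy),
            }
        )
    manifest = {
        "condition": {
            "name": cond.name,
            "n_taxa": cond.n_taxa,
            "height": cond.height,
            "indel_prob": cond.indel_prob,
            "root_length": cond.root_length,
            "n_replicates": cond.n_replicates,
        },
        "gtr": {
            "base_freqs": list(params.base_freqs),
            "exchange_rates": list(params.exchange_rates),
            "gamma_shape": params.gamma_shape,
            "insertion_prob": params.insertion_prob,
            "deletion_prob": params.deletion_prob,
            "indel_mean_length": params.indel_mean_length,
        },
        "seed": None if seed is None else int(seed),
        "replicate_seeds": rep_seeds,
    }
    return fixtures, manifest
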