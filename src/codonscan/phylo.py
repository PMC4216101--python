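"""Distance-based phylogeny: Tamura 3-parameter distances, neighbor joining,
codon bootstrap, and outgroup rooting.

The estimator is deliberately deterministic: NJ ties are broken on the
lexicographically smallest pair of cluster labels (a cluster's label is its
alphabetically first leaf), negative NJ branch lengths are clamped to zero
with the deficit moved to the sibling edge, and bootstrap resampling is
seeded and draws whole codon columns so the reading frame is preserved.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .seq_io import CodingAlignment

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "SaturationError",
    "t3p_distance",
    "distance_matrix",
    "nj_build",
    "bootstrap_support",
    "root_with_outgroup",
]


class SaturationError(ValueError):
    """Raised when a distance formula's log argument is non-positive."""


_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def t3p_distance(seq_a: str, seq_b: str, gamma_shape: float | None = None) -> float:
    """Tamura 3-parameter distance between two aligned nucleotide sequences.

    Sites where either sequence is not a plain base are dropped pairwise.
    With P the transition proportion, Q the transversion proportion, θ the
    mean GC content of the pair and h = 2θ(1−θ):

        d = −h·ln(1 − P/h − Q) − ½(1−h)·ln(1 − 2Q)

    With ``gamma_shape`` a, each −ln(x) is replaced by the gamma-rates
    correction a·(x^(−1/a) − 1).
    """
    a, b = seq_a.upper(), seq_b.upper()
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    usable = transitions = transversions = gc = 0
    for x, y in zip(a, b):
        if x not in "ACGT" or y not in "ACGT":
            continue
        usable += 1
        gc += (x in "GC") + (y in "GC")
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            transitions += 1
        else:
            transversions += 1
    if usable == 0:
        raise ValueError("no pairwise-complete sites")
    P = transitions / usable
    Q = transversions / usable
    theta = gc / (2 * usable)
    h = 2.0 * theta * (1.0 - theta)
    x1 = 1.0 - (P / h if h > 0 else 0.0) - Q
    x2 = 1.0 - 2.0 * Q
    if x1 <= 0 or x2 <= 0:
        raise SaturationError(
            f"T3P distance saturated (P={P:.4f}, Q={Q:.4f}, theta={theta:.4f})"
        )
    if gamma_shape is None:
        def neglog(x: float) -> float:
            return -math.log(x)
    else:
        shape = float(gamma_shape)
        if shape <= 0:
            raise ValueError("gamma shape must be positive")
        def neglog(x: float) -> float:
            return shape * (x ** (-1.0 / shape) - 1.0)
    d = (h * neglog(x1) if h > 0 else 0.0) + 0.5 * (1.0 - h) * neglog(x2)
    return max(d, 0.0)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with zero diagonal."""

    taxa: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal not zero")
        if not np.isfinite(self.values).all():
            raise ValueError("distance matrix has non-finite entries")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.taxa.index(a), self.taxa.index(b)])

    def to_phylip(self) -> str:
        lines = [f" {len(self.taxa)}"]
        for i, t in enumerate(self.taxa):
            row = " ".join(f"{v:.6f}" for v in self.values[i])
            lines.append(f"{t}  {row}")
        return "\n".join(lines) + "\n"


def distance_matrix(
    aln: CodingAlignment, gamma_shape: float | None = None
) -> DistanceMatrix:
    """All-pairs T3P(+Γ) distance matrix of an alignment."""
    taxa = list(aln.taxa)
    n = len(taxa)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = t3p_distance(
                aln.sequences[taxa[i]], aln.sequences[taxa[j]], gamma_shape
            )
            values[i, j] = values[j, i] = d
    return DistanceMatrix(taxa=taxa, values=values)


@dataclass
class TreeNode:
    """A rooted tree node; NJ output is rooted at a trifurcating basal node."""

    name: str | None = None
    length: float = 0.0  # branch length to parent
    support: float | None = None  # bootstrap % on the edge to parent
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.leaves()]

    def postorder(self):
        for child in self.children:
            yield from child.postorder()
        yield self

    def copy(self) -> "TreeNode":
        node = TreeNode(name=self.name, length=self.length, support=self.support)
        node.children = [c.copy() for c in self.children]
        return node

    def to_newick(self, with_support: bool = True) -> str:
        def fmt(node: TreeNode, top: bool) -> str:
            if node.is_leaf():
                body = node.name or ""
            else:
                inner = ",".join(fmt(c, False) for c in node.children)
                label = ""
                if with_support and node.support is not None and not top:
                    label = f"{node.support:g}"
                body = f"({inner}){label}"
            if top:
                return body
            return f"{body}:{node.length:.6f}"

        return fmt(self, True) + ";"

    def bipartitions(self, with_support: bool = False, min_length: float = 0.0):
        """Internal-edge bipartitions as canonical frozensets of leaf labels.

        Each internal edge splits the leaf set in two; the side *not*
        containing the alphabetically first leaf is the canonical key, so
        bipartition sets compare across rootings.  Internal edges shorter
        than ``min_length`` are treated as unresolved and skipped.
        """
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        result = {} if with_support else set()

        def visit(node: TreeNode) -> frozenset:
            if node.is_leaf():
                return frozenset([node.name])
            below = frozenset().union(*(visit(c) for c in node.children))
            if (
                node is not self
                and len(below) > 1
                and len(all_leaves - below) > 1
                and node.length >= min_length
            ):
                key = below if anchor not in below else all_leaves - below
                if with_support:
                    result[key] = node
                else:
                    result.add(key)
            return below

        visit(self)
        return result


def from_newick(newick: str) -> TreeNode:
    """Parse a newick string (via dendropy) into a :class:`TreeNode`."""
    tree = dendropy.Tree.get(data=newick, schema="newick")

    def convert(dnode) -> TreeNode:
        node = TreeNode(
            name=dnode.taxon.label if dnode.taxon else None,
            length=dnode.edge.length or 0.0,
        )
        node.children = [convert(c) for c in dnode.child_nodes()]
        return node

    return convert(tree.seed_node)


def nj_build(dm: DistanceMatrix) -> TreeNode:
    """Neighbor joining (Saitou–Nei) with pinned, deterministic behavior.

    The pair minimizing the Q criterion is joined; exact ties are broken by
    the lexicographically smallest (cluster label, cluster label) pair, where
    a cluster's label is its alphabetically first leaf.  Negative branch
    lengths are clamped to zero and the deficit moved to the sibling edge.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError(f"neighbor joining needs >= 3 taxa, got {n}")
    nodes: dict[str, TreeNode] = {t: TreeNode(name=t) for t in dm.taxa}
    labels = {t: t for t in dm.taxa}  # cluster -> alphabetically first leaf
    d: dict[frozenset, float] = {}
    active = list(dm.taxa)
    for i in range(n):
        for j in range(i + 1, n):
            d[frozenset((dm.taxa[i], dm.taxa[j]))] = float(dm.values[i, j])

    def dist(a: str, b: str) -> float:
        return 0.0 if a == b else d[frozenset((a, b))]

    counter = 0
    while len(active) > 3:
        m = len(active)
        r = {a: sum(dist(a, b) for b in active) for a in active}
        best = None
        best_q = math.inf
        for ii in range(m):
            for jj in range(ii + 1, m):
                a, b = active[ii], active[jj]
                q = (m - 2) * dist(a, b) - r[a] - r[b]
                key = tuple(sorted((labels[a], labels[b])))
                if q < best_q - 1e-12 or (
                    abs(q - best_q) <= 1e-12
                    and best is not None
                    and key < tuple(sorted((labels[best[0]], labels[best[1]])))
                ):
                    best_q = q
                    best = (a, b)
        a, b = best
        if labels[b] < labels[a]:
            a, b = b, a
        dab = dist(a, b)
        la = 0.5 * dab + (r[a] - r[b]) / (2.0 * (m - 2))
        lb = dab - la
        if la < 0:
            lb += -la
            la = 0.0
        if lb < 0:
            la += -lb
            lb = 0.0
        parent_key = f"__internal{counter}"
        counter += 1
        parent = TreeNode()
        na, nb = nodes[a], nodes[b]
        na.length, nb.length = la, lb
        parent.children = [na, nb]
        nodes[parent_key] = parent
        labels[parent_key] = min(labels[a], labels[b])
        for c in active:
            if c in (a, b):
                continue
            d[frozenset((parent_key, c))] = 0.5 * (dist(a, c) + dist(b, c) - dab)
        active = [c for c in active if c not in (a, b)] + [parent_key]

    a, b, c = active
    la = 0.5 * (dist(a, b) + dist(a, c) - dist(b, c))
    lb = 0.5 * (dist(a, b) + dist(b, c) - dist(a, c))
    lc = 0.5 * (dist(a, c) + dist(b, c) - dist(a, b))
    root = TreeNode()
    for key, length in sorted(
        ((a, la), (b, lb), (c, lc)), key=lambda kl: labels[kl[0]]
    ):
        node = nodes[key]
        node.length = max(length, 0.0)
        root.children.append(node)
    return root


def root_with_outgroup(tree: TreeNode, outgroup: str) -> TreeNode:
    """Root on the midpoint of the outgroup's pendant edge."""
    tree = tree.copy()
    if outgroup not in tree.leaf_names():
        raise ValueError(f"outgroup taxon {outgroup!r} not in tree")
    if len(tree.children) == 2 and any(
        c.is_leaf() and c.name == outgroup for c in tree.children
    ):
        return tree  # already rooted on the outgroup's pendant edge

    parent_of: dict[int, TreeNode | None] = {id(tree): None}
    target = None
    for node in tree.postorder():
        for child in node.children:
            parent_of[id(child)] = node
        if node.is_leaf() and node.name == outgroup:
            target = node
    parent = parent_of[id(target)]

    half = target.length / 2.0
    # Invert the path from the outgroup's parent up to the old root.
    new_root = TreeNode()
    path = []
    node = parent
    while node is not None:
        path.append(node)
        node = parent_of[id(node)]
    orig_len = [n.length for n in path]
    orig_sup = [n.support for n in path]
    parent.children = [c for c in parent.children if c is not target]
    for upper, lower in zip(path[1:], path):
        upper.children = [c for c in upper.children if c is not lower]
    # Reattach from the top down: each former parent becomes a child,
    # inheriting the inverted edge's original length and support.
    for i, (upper, lower) in enumerate(zip(path[1:], path)):
        upper.length = orig_len[i]
        upper.support = orig_sup[i]
        lower.children.append(upper)
    old_root = path[-1]
    if len(old_root.children) == 1 and not old_root.is_leaf():
        # suppress the degree-2 node left at the old root position
        grandparent = path[-2] if len(path) >= 2 else None
        only = old_root.children[0]
        if grandparent is not None:
            only.length += old_root.length
            only.support = only.support or old_root.support
            grandparent.children = [
                only if c is old_root else c for c in grandparent.children
            ]
    target.length = half
    parent.length = half
    new_root.children = [target, parent]
    return new_root


def bootstrap_support(
    aln: CodingAlignment,
    n_reps: int = 1000,
    seed: int = 0,
    gamma_shape: float | None = None,
    builder=None,
) -> TreeNode:
    """NJ tree with bootstrap supports from codon-column resampling.

    Whole codon columns are drawn with replacement (frame preserved); support
    for each internal bipartition of the point-estimate tree is the percent
    of replicate trees containing it.  Replicates with saturated distances
    are dropped and logged; more than 10% dropped is an error.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    builder = builder or nj_build
    point = builder(distance_matrix(aln, gamma_shape))
    # zero-length internal edges (e.g. identical sequences) are unresolved
    # and carry no supportable bipartition
    partitions = point.bipartitions(with_support=True, min_length=1e-9)
    if not partitions:
        return point

    rng = np.random.default_rng(seed)
    counts = {key: 0 for key in partitions}
    n_codons = aln.n_codons
    dropped = 0
    for _ in range(n_reps):
        cols = rng.integers(0, n_codons, size=n_codons)
        resampled = {
            t: "".join(seq[3 * c : 3 * c + 3] for c in cols)
            for t, seq in aln.sequences.items()
        }
        try:
            rep_aln = CodingAlignment(
                taxa=list(aln.taxa),
                sequences=resampled,
                reference=aln.reference,
                code=aln.code,
            )
            rep_tree = builder(distance_matrix(rep_aln, gamma_shape))
        except (SaturationError, ValueError) as exc:
            dropped += 1
            logger.warning("bootstrap replicate dropped: %s", exc)
            continue
        rep_parts = rep_tree.bipartitions()
        for key in counts:
            if key in rep_parts:
                counts[key] += 1
    if dropped > 0.10 * n_reps:
        raise SaturationError(
            f"{dropped}/{n_reps} bootstrap replicates dropped (saturation)"
        )
    used = n_reps - dropped
    for key, node in partitions.items():
        node.support = 100.0 * counts[key] / used
    return point
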