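"""Kimura two-parameter distances, neighbor joining, and bootstrap support.

K2P separates transitions (A<->G, C<->T) from transversions:

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

with P and Q the observed transition and transversion proportions over the
counted sites. Sites containing gaps or ambiguous bases are dropped per pair
(pairwise deletion) or pre-dropped for all taxa (complete deletion).

Neighbor joining is the standard Saitou–Nei agglomeration on the
rate-corrected Q criterion, with deterministic lexicographic tie-breaking.
Negative branch-length estimates are clamped to zero with the deficit
transferred to the sibling edge, so printed trees stay additive in sum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SaturationError",
    "DistanceMatrix",
    "TreeNode",
    "k2p_distance",
    "k2p_matrix",
    "complete_deletion",
    "neighbor_joining",
    "bootstrap_support",
    "random_additive_matrix",
]

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}
_VALID = {"A", "C", "G", "T"}


class SaturationError(ValueError):
    """Raised when observed divergence exceeds the K2P domain."""


@dataclass(frozen=True)
class DistanceMatrix:
    taxa: tuple[str, ...]
    values: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape must match taxon count")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if not np.all(np.isfinite(v)):
            raise ValueError("distances must be finite")
        object.__setattr__(self, "values", v)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.taxa.index(pair[0])
        j = self.taxa.index(pair[1])
        return float(self.values[i, j])


@dataclass
class TreeNode:
    """Simple rooted representation of an (unrooted) tree: the root carries
    >= 3 children; every edge holds its length and optional support."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf():
            return [self.name]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def newick(self, include_support: bool = False) -> str:
        return self._newick(include_support) + ";"

    def _newick(self, include_support: bool) -> str:
        if self.is_leaf():
            return self.name
        inner = ",".join(
            f"{child._newick(include_support)}:{length:.6f}"
            for child, length in self.children
        )
        label = ""
        if include_support and self.support is not None:
            label = str(int(round(100 * self.support)))
        return f"({inner}){label}"

    def path_distances(self) -> dict[frozenset, float]:
        """Leaf-to-leaf path lengths, keyed by frozenset of the two names."""
        dists: dict[frozenset, float] = {}

        def walk(node: "TreeNode") -> list[tuple[str, float]]:
            if node.is_leaf():
                return [(node.name, 0.0)]
            below: list[tuple[str, float]] = []
            for child, length in node.children:
                sub = [(leaf, d + length) for leaf, d in walk(child)]
                for leaf1, d1 in sub:
                    for leaf2, d2 in below:
                        dists[frozenset((leaf1, leaf2))] = d1 + d2
                below.extend(sub)
            return below

        walk(self)
        return dists

    def bipartitions(self) -> set[frozenset[str]]:
        """Leaf sets of all internal edges (smaller side, but canonicalized
        by the caller against the full taxon set)."""
        parts: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> list[str]:
            if node.is_leaf():
                return [node.name]
            below: list[str] = []
            for child, _ in node.children:
                sub = walk(child)
                if not child.is_leaf() and child is not node:
                    parts.add(frozenset(sub))
                below.extend(sub)
            return below

        walk(self)
        return parts


def random_additive_matrix(
    rng: np.random.Generator, n_taxa: int
) -> tuple[tuple[str, ...], np.ndarray, set[frozenset[str]]]:
    """Random additive distance matrix from a random binary tree.

    Returns (taxa, matrix, true internal splits canonicalized to the side
    not containing the first taxon) — ground truth for testing
    distance-based reconstruction.
    """
    if n_taxa < 3:
        raise ValueError("need >= 3 taxa")
    taxa = tuple(f"t{i}" for i in range(n_taxa))
    dist = {(a, b): 0.0 for a in taxa for b in taxa}
    groups: list[list[str]] = [[t] for t in taxa]
    extra = {t: 0.0 for t in taxa}
    leafsets: list[frozenset[str]] = []
    while len(groups) > 1:
        i, j = sorted(rng.choice(len(groups), size=2, replace=False))
        li = float(rng.uniform(0.05, 0.5))
        lj = float(rng.uniform(0.05, 0.5))
        gi, gj = groups[i], groups[j]
        for a in gi:
            for b in gj:
                d = extra[a] + li + extra[b] + lj
                dist[(a, b)] = dist[(b, a)] = d
        for g in (gi, gj):
            if 2 <= len(g) <= n_taxa - 2:
                leafsets.append(frozenset(g))
        for a in gi:
            extra[a] += li
        for b in gj:
            extra[b] += lj
        groups = [g for k, g in enumerate(groups) if k not in (i, j)] + [gi + gj]
    mat = np.array([[dist[(a, b)] for b in taxa] for a in taxa])
    full = frozenset(taxa)
    anchor = min(taxa)
    splits = {s if anchor not in s else full - s for s in leafsets}
    return taxa, mat, splits


def _pq_counts(a: str, b: str) -> tuple[int, int, int]:
    """(sites, transitions, transversions) over pairwise-counted positions."""
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    n = ts = tv = 0
    for x, y in zip(a.upper(), b.upper()):
        if x not in _VALID or y not in _VALID:
            continue
        n += 1
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            ts += 1
        else:
            tv += 1
    return n, ts, tv


def k2p_distance(a: str, b: str) -> float:
    """Kimura two-parameter distance between two aligned DNA sequences.

    Sites where either sequence has a gap or ambiguous base are dropped
    (pairwise deletion); pre-filter columns with :func:`complete_deletion`
    for complete-deletion semantics. Raises SaturationError when the
    observed proportions leave the formula's domain, never returns NaN.
    """
    n, ts, tv = _pq_counts(a, b)
    if n == 0:
        raise ValueError("no counted sites between sequences")
    P = ts / n
    Q = tv / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"substitution saturation: P={P:.4f}, Q={Q:.4f} outside K2P domain"
        )
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def complete_deletion(seqs: dict[str, str]) -> dict[str, str]:
    """Drop every column in which ANY taxon has a gap or ambiguous base."""
    names = list(seqs)
    length = {len(s) for s in seqs.values()}
    if len(length) != 1:
        raise ValueError("aligned sequences must have equal length")
    keep = [
        i
        for i in range(length.pop())
        if all(seqs[n][i].upper() in _VALID for n in names)
    ]
    return {n: "".join(seqs[n][i] for i in keep) for n in names}


def k2p_matrix(seqs: dict[str, str], deletion: str = "pairwise") -> DistanceMatrix:
    if deletion not in ("pairwise", "complete"):
        raise ValueError("deletion must be 'pairwise' or 'complete'")
    if deletion == "complete":
        seqs = complete_deletion(seqs)
    taxa = tuple(seqs)
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = k2p_distance(seqs[taxa[i]], seqs[taxa[j]])
    return DistanceMatrix(taxa=taxa, values=d)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining.

    Join selection minimizes Q(i,j) = (r-2) d(i,j) - R_i - R_j; ties are
    broken by the lexicographically smallest taxon-name pair, so the result
    is invariant to input order. Branch lengths use the standard three-point
    formulas; negative estimates are clamped to zero with the deficit moved
    to the sibling edge.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in dm.taxa]
    # sort key per active node: smallest leaf name below it
    labels: list[str] = list(dm.taxa)
    D = dm.values.copy()
    active = list(range(n))

    while len(active) > 3:
        r = len(active)
        R = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ii, i in enumerate(active):
            for j in active[ii + 1 :]:
                q = (r - 2) * D[i, j] - R[i] - R[j]
                key = (q, *sorted((labels[i], labels[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = D[i, j]
        li = 0.5 * dij + (R[i] - R[j]) / (2.0 * (r - 2))
        lj = dij - li
        # clamp negatives, preserving the pair's summed length
        if li < 0.0:
            lj += li
            li = 0.0
        if lj < 0.0:
            li += lj
            lj = 0.0
        if li < 0.0:
            li = 0.0
        if lj < 0.0:
            lj = 0.0
        parent = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        # distances from the new node
        k_new = D.shape[0]
        D = np.pad(D, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            D[k_new, k] = D[k, k_new] = 0.5 * (D[i, k] + D[j, k] - dij)
        nodes.append(parent)
        labels.append(min(labels[i], labels[j]))
        active = [k for k in active if k not in (i, j)] + [k_new]

    i, j, k = active
    # three-point formulas for the final star
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    root = TreeNode(
        children=[
            (nodes[i], max(li, 0.0)),
            (nodes[j], max(lj, 0.0)),
            (nodes[k], max(lk, 0.0)),
        ]
    )
    return root


def _canonical_bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Internal bipartitions as the side not containing the first taxon."""
    all_leaves = frozenset(tree.leaves())
    anchor = min(all_leaves)
    out = set()
    for part in tree.bipartitions():
        side = part if anchor not in part else all_leaves - part
        if 2 <= len(side) <= len(all_leaves) - 2:
            out.add(side)
    return out


def bootstrap_support(
    seqs: dict[str, str],
    n_reps: int = 100,
    seed: int = 0,
    deletion: str = "pairwise",
) -> TreeNode:
    """NJ tree on the original alignment with bootstrap supports.

    Columns are resampled with replacement ``n_reps`` times; each replicate
    is run through K2P + NJ, and the support of each internal edge of the
    original tree is the fraction of replicates containing the same
    bipartition. Replicates whose resampled distances saturate are counted
    as not containing any bipartition. Deterministic for a fixed seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    length = {len(s) for s in seqs.values()}
    if len(length) != 1:
        raise ValueError("aligned sequences must have equal length")
    ncol = length.pop()
    if ncol < 2:
        raise ValueError("alignment must have >= 2 columns")
    if deletion == "complete":
        seqs = complete_deletion(seqs)
        ncol = len(next(iter(seqs.values())))
        deletion = "pairwise"  # columns already clean
    tree = neighbor_joining(k2p_matrix(seqs, deletion="pairwise"))
    target = _canonical_bipartitions(tree)
    hits = {part: 0 for part in target}
    rng = np.random.default_rng(seed)
    names = list(seqs)
    cols = [[seqs[n][i] for n in names] for i in range(ncol)]
    for _ in range(n_reps):
        idx = rng.integers(0, ncol, size=ncol)
        resampled = {
            n: "".join(cols[i][k] for i in idx) for k, n in enumerate(names)
        }
        try:
            rep_tree = neighbor_joining(k2p_matrix(resampled, deletion="pairwise"))
        except (SaturationError, ValueError):
            continue
        rep_parts = _canonical_bipartitions(rep_tree)
        for part in target:
            if part in rep_parts:
                hits[part] += 1

    def annotate(node: TreeNode) -> frozenset[str]:
        below: set[str] = set()
        for child, _ in node.children:
            sub = annotate(child)
            below |= sub
        if node.is_leaf():
            return frozenset([node.name])
        leafset = frozenset(below)
        all_leaves = frozenset(tree.leaves())
        anchor = min(all_leaves)
        side = leafset if anchor not in leafset else all_leaves - leafset
        if side in hits:
            node.support = hits[side] / n_reps
        return leafset

    annotate(tree)
    return tree
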