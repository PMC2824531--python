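import math

import numpy as np
import pytest

from psychrocomp.phylo import (
    DistanceMatrix,
    SaturationError,
    TreeNode,
    bootstrap_support,
    complete_deletion,
    k2p_distance,
    k2p_matrix,
    neighbor_joining,
)


def seq_with_pq(n, n_ts, n_tv):
    """Aligned pair with exactly n_ts transitions and n_tv transversions."""
    a = ["A"] * n
    b = ["A"] * n
    for i in range(n_ts):
        b[i] = "G"  # A->G transition
    for i in range(n_ts, n_ts + n_tv):
        b[i] = "C"  # A->C transversion
    return "".join(a), "".join(b)


class TestK2P:
    def test_identical_sequences_zero(self):
        assert k2p_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_direct_formula(self):
        # P = 0.1, Q = 0.05 -> d = -0.5 ln(0.75) - 0.25 ln(0.9)
        a, b = seq_with_pq(100, 10, 5)
        expected = -0.5 * math.log(0.75) - 0.25 * math.log(0.9)
        assert k2p_distance(a, b) == pytest.approx(expected, abs=1e-12)

    def test_saturation_error_not_nan(self):
        a, b = seq_with_pq(100, 50, 0)  # 1 - 2P = 0
        with pytest.raises(SaturationError):
            k2p_distance(a, b)

    def test_pairwise_deletion_drops_ambiguous_sites(self):
        assert k2p_distance("ACGTN", "ACGT-") == 0.0
        with pytest.raises(ValueError, match="no counted sites"):
            k2p_distance("NNN", "ACG")

    def test_symmetry_and_jensen_bound(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = 400
            a = "".join(rng.choice(list("ACGT"), n))
            b = list(a)
            for i in rng.choice(n, size=40, replace=False):
                b[i] = rng.choice([c for c in "ACGT" if c != b[i]])
            b = "".join(b)
            try:
                d1 = k2p_distance(a, b)
            except SaturationError:
                continue
            assert d1 == k2p_distance(b, a)
            pdist = sum(x != y for x, y in zip(a, b)) / n
            assert d1 >= pdist - 1e-12

    def test_complete_deletion(self):
        seqs = {"x": "ACGTN", "y": "ACG-A", "z": "ACGTA"}
        clean = complete_deletion(seqs)
        assert clean == {"x": "ACG", "y": "ACG", "z": "ACG"}


def random_additive_tree(rng, n_taxa):
    """Random binary tree; returns (taxa, path-distance matrix, splits)."""
    nodes = [(f"t{i}", None) for i in range(n_taxa)]
    # build random topology by sequential joining; track leaf sets + distances
    dist = {(f"t{i}", f"t{j}"): 0.0 for i in range(n_taxa) for j in range(n_taxa)}
    leafsets = []
    groups = [[f"t{i}"] for i in range(n_taxa)]
    extra = {f"t{i}": 0.0 for i in range(n_taxa)}  # distance from leaf to group root
    while len(groups) > 1:
        i, j = sorted(rng.choice(len(groups), size=2, replace=False))
        li = float(rng.uniform(0.05, 0.5))
        lj = float(rng.uniform(0.05, 0.5))
        gi, gj = groups[i], groups[j]
        for a in gi:
            for b in gj:
                d = extra[a] + li + extra[b] + lj
                dist[(a, b)] = dist[(b, a)] = d
        merged = gi + gj
        if 2 <= len(gi) <= n_taxa - 2:
            leafsets.append(frozenset(gi))
        if 2 <= len(gj) <= n_taxa - 2:
            leafsets.append(frozenset(gj))
        for a in gi:
            extra[a] += li
        for b in gj:
            extra[b] += lj
        groups = [g for k, g in enumerate(groups) if k not in (i, j)] + [merged]
    taxa = tuple(f"t{i}" for i in range(n_taxa))
    mat = np.array([[dist[(a, b)] for b in taxa] for a in taxa])
    # canonicalize splits to the side not containing the anchor taxon
    full = frozenset(taxa)
    anchor = min(taxa)
    splits = {
        s if anchor not in s else full - s
        for s in leafsets
        if 2 <= len(s) <= n_taxa - 2
    }
    return taxa, mat, splits


def tree_path_distances(tree: TreeNode):
    """Leaf-to-leaf path lengths by recursive accumulation."""
    dists = {}

    def walk(node):
        # returns list of (leaf, distance-to-node)
        if node.is_leaf():
            return [(node.name, 0.0)]
        below = []
        for child, length in node.children:
            sub = [(leaf, d + length) for leaf, d in walk(child)]
            for leaf1, d1 in sub:
                for leaf2, d2 in below:
                    dists[frozenset((leaf1, leaf2))] = d1 + d2
            below.extend(sub)
        return below

    walk(tree)
    return dists


def canonical_splits(tree: TreeNode):
    leaves = frozenset(tree.leaves())
    anchor = min(leaves)
    out = set()
    for part in tree.bipartitions():
        side = part if anchor not in part else leaves - part
        if 2 <= len(side) <= len(leaves) - 2:
            out.add(side)
    return out


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        taxa = ("a", "b", "c")
        d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = neighbor_joining(DistanceMatrix(taxa, d))
        lengths = {child.name: l for child, l in tree.children}
        assert lengths["a"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.6))
        assert lengths["b"] == pytest.approx(0.5 * (0.3 + 0.6 - 0.5))
        assert lengths["c"] == pytest.approx(0.5 * (0.5 + 0.6 - 0.3))

    def test_four_taxon_topology_against_enumeration(self):
        """On an additive 4-taxon matrix, NJ picks the unique topology whose
        implied path metric reproduces the input (brute force over all 3)."""
        rng = np.random.default_rng(17)
        for _ in range(20):
            taxa, mat, splits = random_additive_tree(rng, 4)
            dm = DistanceMatrix(taxa, mat)
            tree = neighbor_joining(dm)
            # brute-force oracle: the correct split satisfies the four-point
            # condition with the strictly smallest sum
            t = list(taxa)
            sums = {
                frozenset((t[0], t[1])): mat[0, 1] + mat[2, 3],
                frozenset((t[0], t[2])): mat[0, 2] + mat[1, 3],
                frozenset((t[0], t[3])): mat[0, 3] + mat[1, 2],
            }
            best_pair = min(sums, key=lambda k: sums[k])
            got = canonical_splits(tree)
            if len(got) == 1:
                side = next(iter(got))
                anchor_side = side if t[0] not in side else frozenset(taxa) - side
                expected_side = (
                    best_pair if t[0] not in best_pair else frozenset(taxa) - best_pair
                )
                assert anchor_side == expected_side

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 7, 8])
    def test_additive_matrices_recovered_exactly(self, n_taxa):
        """NJ on an additive matrix reproduces topology and path distances."""
        rng = np.random.default_rng(100 + n_taxa)
        for _ in range(10):
            taxa, mat, true_splits = random_additive_tree(rng, n_taxa)
            tree = neighbor_joining(DistanceMatrix(taxa, mat))
            got = tree_path_distances(tree)
            for i, a in enumerate(taxa):
                for b in taxa[i + 1 :]:
                    assert got[frozenset((a, b))] == pytest.approx(
                        mat[taxa.index(a), taxa.index(b)], abs=1e-9
                    )
            assert canonical_splits(tree) == set(true_splits)

    def test_order_invariance(self):
        rng = np.random.default_rng(23)
        taxa, mat, _ = random_additive_tree(rng, 6)
        tree1 = neighbor_joining(DistanceMatrix(taxa, mat))
        perm = list(rng.permutation(len(taxa)))
        taxa2 = tuple(taxa[i] for i in perm)
        mat2 = mat[np.ix_(perm, perm)]
        tree2 = neighbor_joining(DistanceMatrix(taxa2, mat2))
        assert canonical_splits(tree1) == canonical_splits(tree2)
        assert tree_path_distances(tree1) == pytest.approx(tree_path_distances(tree2))

    def test_against_skbio(self):
        """Independent oracle: scikit-bio's NJ finds the same topology."""
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        rng = np.random.default_rng(31)
        taxa, mat, _ = random_additive_tree(rng, 7)
        ours = canonical_splits(neighbor_joining(DistanceMatrix(taxa, mat)))
        sk_tree = sk_nj(SkDM(mat, ids=list(taxa)))
        anchor = min(taxa)
        theirs = set()
        for node in sk_tree.non_tips():
            side = frozenset(t.name for t in node.tips())
            side = side if anchor not in side else frozenset(taxa) - side
            if 2 <= len(side) <= len(taxa) - 2:
                theirs.add(side)
        assert ours == theirs

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(("a", "b"), np.zeros((2, 2))))


def clade_alignment(rng, n_per_clade=2, n_cols=600, within=0.02, between=0.25):
    """Two deeply separated clades of near-identical sequences."""
    anc = rng.choice(list("ACGT"), n_cols)
    other = anc.copy()
    idx = rng.choice(n_cols, size=int(between * n_cols), replace=False)
    for i in idx:
        other[i] = rng.choice([c for c in "ACGT" if c != other[i]])
    seqs = {}
    for k, base in (("a", anc), ("b", other)):
        for j in range(n_per_clade):
            s = base.copy()
            idx = rng.choice(n_cols, size=int(within * n_cols), replace=False)
            for i in idx:
                s[i] = rng.choice([c for c in "ACGT" if c != s[i]])
            seqs[f"{k}{j}"] = "".join(s)
    return seqs


class TestBootstrap:
    def test_deep_clade_high_support(self):
        rng = np.random.default_rng(8)
        seqs = clade_alignment(rng)
        tree = bootstrap_support(seqs, n_reps=100, seed=3)
        supports = [
            node.support
            for node, _ in _iter_internal(tree)
            if node.support is not None
        ]
        assert supports and min(supports) >= 0.95

    def test_determinism(self):
        rng = np.random.default_rng(8)
        seqs = clade_alignment(rng)
        t1 = bootstrap_support(seqs, n_reps=30, seed=9)
        t2 = bootstrap_support(seqs, n_reps=30, seed=9)
        assert t1.newick(include_support=True) == t2.newick(include_support=True)

    def test_short_alignment_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_support({"a": "A", "b": "A", "c": "A"}, n_reps=5, seed=0)

    def test_newick_output_parses(self):
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(8)
        seqs = clade_alignment(rng)
        tree = bootstrap_support(seqs, n_reps=20, seed=1)
        parsed = dendropy.Tree.get(data=tree.newick(include_support=True), schema="newick")
        assert {leaf.taxon.label for leaf in parsed.leaf_node_iter()} == set(seqs)


def _iter_internal(tree):
    stack = [(tree, None)]
    while stack:
        node, parent = stack.pop()
        if not node.is_leaf():
            yield node, parent
            for child, _ in node.children:
                stack.append((child, node))
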