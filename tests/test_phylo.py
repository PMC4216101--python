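"""T3P distances, neighbor joining, bootstrap and rooting."""

import math

import dendropy
import numpy as np
import pytest

from codonscan.seq_io import CodingAlignment
from codonscan.phylo import (
    DistanceMatrix,
    SaturationError,
    TreeNode,
    bootstrap_support,
    distance_matrix,
    from_newick,
    nj_build,
    root_with_outgroup,
    t3p_distance,
)
from codonscan.synthetic_data import SimulationSpec, simulate_alignment


def _pair_with(P: float, Q: float, theta: float, L: int = 1200):
    """Construct a sequence pair with exact transition/transversion
    proportions and exact mean GC content.

    Substituted sites each contribute one GC base across the pair (G/A for
    transitions, A/C for transversions), so the number of identical GC sites
    is chosen to make the pair's mean GC exactly theta.
    """
    n_ts = round(P * L)
    n_tv = round(Q * L)
    g = round((2 * theta * L - n_ts - n_tv) / 2)  # identical GC sites
    assert 0 <= g <= L - n_ts - n_tv
    a, b = [], []
    for _ in range(n_ts):
        a.append("G")
        b.append("A")
    for _ in range(n_tv):
        a.append("A")
        b.append("C")
    for _ in range(g):
        a.append("G")
        b.append("G")
    while len(a) < L:
        a.append("A")
        b.append("A")
    return "".join(a), "".join(b)


class TestT3PDistance:
    def test_identical_is_zero(self):
        assert t3p_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_closed_form(self):
        a, b = _pair_with(P=0.1, Q=0.05, theta=0.4)
        L = len(a)
        P = sum(
            (x, y) in {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
            for x, y in zip(a, b)
        ) / L
        Q = sum(
            x != y
            and (x, y)
            not in {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
            for x, y in zip(a, b)
        ) / L
        theta = sum(x in "GC" for x in a + b) / (2 * L)
        h = 2 * theta * (1 - theta)
        expected = -h * math.log(1 - P / h - Q) - 0.5 * (1 - h) * math.log(
            1 - 2 * Q
        )
        assert t3p_distance(a, b) == pytest.approx(expected, abs=1e-12)

    def test_reduces_to_k2p_at_half_gc(self):
        a, b = _pair_with(P=0.08, Q=0.04, theta=0.5)
        P, Q = 0.08, 0.04
        k2p = -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)
        assert t3p_distance(a, b) == pytest.approx(k2p, abs=1e-10)

    def test_symmetric(self):
        a, b = _pair_with(P=0.1, Q=0.05, theta=0.35)
        assert t3p_distance(a, b) == pytest.approx(t3p_distance(b, a))

    def test_gamma_large_shape_approaches_plain(self):
        a, b = _pair_with(P=0.1, Q=0.05, theta=0.4)
        assert t3p_distance(a, b, gamma_shape=1e6) == pytest.approx(
            t3p_distance(a, b), rel=1e-4
        )

    def test_gamma_inflates_distance(self):
        a, b = _pair_with(P=0.12, Q=0.06, theta=0.45)
        assert t3p_distance(a, b, gamma_shape=0.5) > t3p_distance(a, b)

    def test_saturation_error(self):
        a = "A" * 100
        b = "G" * 100
        with pytest.raises(SaturationError):
            t3p_distance(a, b)


def _additive_matrix_from_tree(newick: str) -> DistanceMatrix:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(t.label for t in tree.taxon_namespace)
    lookup = {t.label: t for t in tree.taxon_namespace}
    n = len(taxa)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(lookup[taxa[i]], lookup[taxa[j]])
            values[i, j] = values[j, i] = d
    return DistanceMatrix(taxa=taxa, values=values)


def _random_tree_newick(rng, n_taxa: int) -> str:
    """Random binary topology with positive branch lengths."""
    nodes = [f"t{i}" for i in range(n_taxa)]
    lengths = {name: round(rng.uniform(0.05, 0.5), 3) for name in nodes}
    items = [f"{n}:{lengths[n]}" for n in nodes]
    while len(items) > 2:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        merged = f"({items[i]},{items[j]}):{round(rng.uniform(0.05, 0.5), 3)}"
        items = [x for k, x in enumerate(items) if k not in (i, j)] + [merged]
    return f"({items[0]},{items[1]});"


class TestNJ:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(
            taxa=["a", "b", "c"],
            values=np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]]),
        )
        tree = nj_build(dm)
        lengths = {leaf.name: leaf.length for leaf in tree.leaves()}
        assert lengths["a"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.6))
        assert lengths["b"] == pytest.approx(0.5 * (0.3 + 0.6 - 0.5))
        assert lengths["c"] == pytest.approx(0.5 * (0.5 + 0.6 - 0.3))

    def test_too_few_taxa(self):
        dm = DistanceMatrix(taxa=["a", "b"], values=np.array([[0, 1], [1, 0]]))
        with pytest.raises(ValueError):
            nj_build(dm)

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 8])
    def test_recovers_additive_topology(self, n_taxa):
        rng = np.random.default_rng(n_taxa)
        for _ in range(5):
            newick = _random_tree_newick(rng, n_taxa)
            dm = _additive_matrix_from_tree(newick)
            tree = nj_build(dm)
            expected = from_newick(newick).bipartitions()
            assert tree.bipartitions() == expected

    def test_branch_lengths_on_additive_matrix(self):
        newick = "((a:0.1,b:0.2):0.05,(c:0.3,d:0.15):0.07);"
        dm = _additive_matrix_from_tree(newick)
        tree = nj_build(dm)
        got = {leaf.name: leaf.length for leaf in tree.leaves()}
        assert got["a"] == pytest.approx(0.1, abs=1e-9)
        assert got["d"] == pytest.approx(0.15, abs=1e-9)

    def test_matches_dendropy_nj_topology(self):
        rng = np.random.default_rng(99)
        newick = _random_tree_newick(rng, 7)
        dm = _additive_matrix_from_tree(newick)
        ours = nj_build(dm).bipartitions()
        pdm_csv = "," + ",".join(dm.taxa) + "\n" + "\n".join(
            dm.taxa[i] + "," + ",".join(str(v) for v in dm.values[i])
            for i in range(len(dm.taxa))
        )
        import io

        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            io.StringIO(pdm_csv), delimiter=","
        )
        dtree = pdm.nj_tree()
        theirs = from_newick(dtree.as_string(schema="newick")).bipartitions()
        assert ours == theirs

    def test_deterministic_under_exact_ties(self):
        # four equidistant taxa: every Q is tied; output must be stable
        v = np.full((4, 4), 0.5)
        np.fill_diagonal(v, 0.0)
        dm = DistanceMatrix(taxa=["d", "c", "b", "a"], values=v)
        t1 = nj_build(dm).to_newick()
        dm2 = DistanceMatrix(taxa=["a", "b", "c", "d"], values=v)
        t2 = nj_build(dm2).to_newick()
        assert t1 == t2

    def test_negative_branches_clamped(self):
        values = np.array(
            [
                [0.0, 0.1, 0.4, 0.5],
                [0.1, 0.0, 0.5, 0.4],
                [0.4, 0.5, 0.0, 0.1],
                [0.5, 0.4, 0.1, 0.0],
            ]
        )
        dm = DistanceMatrix(taxa=["a", "b", "c", "d"], values=values)
        tree = nj_build(dm)
        for node in tree.postorder():
            assert node.length >= 0.0


class TestRooting:
    def test_three_taxon_two_child_root(self):
        dm = DistanceMatrix(
            taxa=["a", "b", "c"],
            values=np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]]),
        )
        rooted = root_with_outgroup(nj_build(dm), "c")
        assert len(rooted.children) == 2
        assert sorted(rooted.leaf_names()) == ["a", "b", "c"]

    def test_idempotent_topology(self):
        dm = DistanceMatrix(
            taxa=["a", "b", "c", "d"],
            values=np.array(
                [
                    [0.0, 0.2, 0.6, 0.7],
                    [0.2, 0.0, 0.6, 0.7],
                    [0.6, 0.6, 0.0, 0.3],
                    [0.7, 0.7, 0.3, 0.0],
                ]
            ),
        )
        once = root_with_outgroup(nj_build(dm), "d")
        twice = root_with_outgroup(once, "d")
        assert once.bipartitions() == twice.bipartitions()
        assert sorted(twice.leaf_names()) == ["a", "b", "c", "d"]

    def test_unknown_taxon(self):
        dm = DistanceMatrix(
            taxa=["a", "b", "c"],
            values=np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]]),
        )
        with pytest.raises(ValueError):
            root_with_outgroup(nj_build(dm), "zz")

    def test_ingroup_monophyletic_on_fixture(self, receptor_fixture):
        aln = receptor_fixture.alignment
        tree = nj_build(distance_matrix(aln))
        rooted = root_with_outgroup(tree, "Outgroup")
        # the non-outgroup side of the root contains every other taxon
        sides = [set(c.leaf_names()) for c in rooted.children]
        assert {"Outgroup"} in sides
        big = max(sides, key=len)
        assert big == set(aln.taxa) - {"Outgroup"}
        # families should come out monophyletic at this simulation depth
        parts = rooted.bipartitions()
        anchor = min(aln.taxa)
        for fam in ("B", "C"):
            clade = frozenset(f"Gen{fam}{i}" for i in range(1, 7))
            key = clade if anchor not in clade else frozenset(aln.taxa) - clade
            assert key in parts


def _canonical(tree: TreeNode, clade: set) -> frozenset:
    leaves = frozenset(tree.leaf_names())
    anchor = min(leaves)
    clade = frozenset(clade)
    return clade if anchor not in clade else leaves - clade


class TestBootstrap:
    def test_identical_sequences_no_supported_splits(self):
        seq = "ATGAAACGT" * 5
        aln = CodingAlignment(
            taxa=["a", "b", "c", "d"],
            sequences={t: seq for t in "abcd"},
            reference="a",
        )
        tree = bootstrap_support(aln, n_reps=10, seed=0)
        assert all(
            node.support is None for node in tree.postorder() if not node.is_leaf()
        )

    def test_same_seed_reproducible(self, receptor_fixture):
        aln = receptor_fixture.alignment
        t1 = bootstrap_support(aln, n_reps=20, seed=5)
        t2 = bootstrap_support(aln, n_reps=20, seed=5)
        assert t1.to_newick() == t2.to_newick()

    def test_clear_clades_high_support(self):
        spec = SimulationSpec(
            tree="((a:0.05,b:0.05):0.5,(c:0.05,d:0.05):0.5);",
            n_codons=300,
            seed=13,
            default_omega=0.2,
        )
        aln, _ = simulate_alignment(spec)
        tree = bootstrap_support(aln, n_reps=100, seed=3)
        supports = {
            frozenset(k): v.support
            for k, v in tree.bipartitions(with_support=True).items()
        }
        key = _canonical(tree, {"a", "b"})
        assert supports[key] >= 95

    def test_support_invariant_to_taxon_order(self):
        spec = SimulationSpec(
            tree="((a:0.1,b:0.1):0.3,(c:0.1,d:0.1):0.3);",
            n_codons=150,
            seed=17,
            default_omega=0.3,
        )
        aln, _ = simulate_alignment(spec)
        perm = ["c", "a", "d", "b"]
        aln2 = CodingAlignment(
            taxa=perm,
            sequences={t: aln.sequences[t] for t in perm},
            reference="c",
        )
        def sup(tree):
            return {
                frozenset(k): v.support
                for k, v in tree.bipartitions(with_support=True).items()
            }
        assert sup(bootstrap_support(aln, n_reps=30, seed=9)) == sup(
            bootstrap_support(aln2, n_reps=30, seed=9)
        )
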