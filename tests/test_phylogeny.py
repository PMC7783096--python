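import itertools
import math

import numpy as np
import pandas as pd
import pytest

from genefam import phylogeny, simulate
from genefam.phylogeny import Alignment, DistanceMatrix


# --- independent additive-tree oracle --------------------------------------
# A random unrooted binary tree is grown by splitting random edges; its path
# distances and bipartitions are computed by graph traversal, with no code
# shared with the NJ implementation under test.


def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    taxa = [f"T{i:02d}" for i in range(n_taxa)]
    adj: dict[int, dict[int, float]] = {}
    next_id = [0]

    def new_node() -> int:
        next_id[0] += 1
        return next_id[0] - 1

    def connect(a, b, w):
        adj.setdefault(a, {})[b] = w
        adj.setdefault(b, {})[a] = w

    leaves = {}
    center = new_node()
    for i in range(3):
        leaf = new_node()
        leaves[taxa[i]] = leaf
        connect(center, leaf, rng.uniform(0.1, 1.0))
    for i in range(3, n_taxa):
        edges = [(a, b) for a in adj for b in adj[a] if a < b]
        a, b = edges[rng.integers(len(edges))]
        w = adj[a].pop(b)
        adj[b].pop(a)
        mid = new_node()
        split = rng.uniform(0.2, 0.8)
        connect(a, mid, w * split)
        connect(mid, b, w * (1 - split))
        leaf = new_node()
        leaves[taxa[i]] = leaf
        connect(mid, leaf, rng.uniform(0.1, 1.0))

    def path_length(src: int, dst: int) -> float:
        stack, seen = [(src, 0.0)], {src}
        while stack:
            node, acc = stack.pop()
            if node == dst:
                return acc
            for nxt, w in adj[node].items():
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append((nxt, acc + w))
        raise AssertionError("disconnected oracle tree")

    D = np.zeros((n_taxa, n_taxa))
    for i, j in itertools.combinations(range(n_taxa), 2):
        D[i, j] = D[j, i] = path_length(leaves[taxa[i]], leaves[taxa[j]])

    leaf_ids = set(leaves.values())
    name_of = {v: k for k, v in leaves.items()}
    ref = min(taxa)
    biparts = set()
    for a in adj:
        for b in adj[a]:
            if a < b and a not in leaf_ids and b not in leaf_ids:
                # leaves on b's side of edge (a, b)
                stack, seen = [b], {a, b}
                side = set()
                while stack:
                    node = stack.pop()
                    if node in leaf_ids:
                        side.add(name_of[node])
                    for nxt in adj[node]:
                        if nxt not in seen:
                            seen.add(nxt)
                            stack.append(nxt)
                if ref in side:
                    side = set(taxa) - side
                if 1 < len(side) < n_taxa - 1:
                    biparts.add(frozenset(side))
    return taxa, D, biparts


class TestPairwiseDistances:
    def test_identical_rows_zero(self):
        aln = Alignment(("a", "b", "c"), ("ACDE", "ACDE", "ACDE"))
        dm = phylogeny.pairwise_distances(aln)
        assert np.allclose(dm.d, 0.0)

    def test_hand_computed_poisson(self):
        aln = Alignment(("a", "b", "c"), ("AAAA", "AAAT", "AAAA"))
        dm = phylogeny.pairwise_distances(aln, "poisson")
        assert dm.d[0, 1] == pytest.approx(-math.log(0.75))
        dm_p = phylogeny.pairwise_distances(aln, "none")
        assert dm_p.d[0, 1] == pytest.approx(0.25)

    def test_gap_columns_excluded(self):
        aln = Alignment(("a", "b", "c"), ("A-AA", "ATAA", "AAAA"))
        dm = phylogeny.pairwise_distances(aln, "none")
        assert dm.d[0, 1] == 0.0

    def test_no_comparable_columns_names_pair(self):
        aln = Alignment(("a", "b", "c"), ("A--", "-T-", "AAA"))
        with pytest.raises(ValueError, match="'a' and 'b'"):
            phylogeny.pairwise_distances(aln)

    def test_unknown_correction_rejected(self):
        aln = Alignment(("a", "b", "c"), ("AA", "AA", "AA"))
        with pytest.raises(ValueError):
            phylogeny.pairwise_distances(aln, "gamma")


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        taxa = ("a", "b", "c")
        d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = phylogeny.neighbor_joining(DistanceMatrix(taxa, d))
        lengths = {child.name: l for child, l in tree.root.children}
        assert lengths["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_four_taxon_additive_recovery(self):
        rng = np.random.default_rng(0)
        taxa, D, biparts = random_additive_tree(4, rng)
        tree = phylogeny.neighbor_joining(DistanceMatrix(tuple(taxa), D))
        assert tree.bipartitions() == biparts
        path = tree.path_distances()
        assert np.allclose(path.loc[taxa, taxa].values, D, atol=1e-9)

    def test_five_taxon_additivity(self):
        rng = np.random.default_rng(1)
        taxa, D, _ = random_additive_tree(5, rng)
        tree = phylogeny.neighbor_joining(DistanceMatrix(tuple(taxa), D))
        assert np.allclose(tree.path_distances().loc[taxa, taxa].values, D, atol=1e-9)

    def test_exact_on_random_additive_matrices(self):
        # 50 random trees, 4-8 taxa: exact topology and branch lengths
        rng = np.random.default_rng(7)
        for rep in range(50):
            n = int(rng.integers(4, 9))
            taxa, D, biparts = random_additive_tree(n, rng)
            tree = phylogeny.neighbor_joining(DistanceMatrix(tuple(taxa), D))
            assert tree.bipartitions() == biparts, f"rep {rep}"
            assert np.allclose(
                tree.path_distances().loc[taxa, taxa].values, D, atol=1e-9
            ), f"rep {rep}"

    def test_non_symmetric_rejected(self):
        d = np.array([[0.0, 1.0, 2.0], [1.5, 0.0, 1.0], [2.0, 1.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            phylogeny.neighbor_joining(DistanceMatrix(("a", "b", "c"), d))

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            phylogeny.neighbor_joining(
                DistanceMatrix(("a", "b"), np.zeros((2, 2)))
            )

    def test_branch_lengths_non_negative(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = 6
            D = rng.uniform(0.1, 2.0, size=(n, n))
            D = (D + D.T) / 2
            np.fill_diagonal(D, 0.0)
            tree = phylogeny.neighbor_joining(
                DistanceMatrix(tuple(f"t{i}" for i in range(n)), D)
            )

            def walk(node):
                for child, length in node.children:
                    assert length >= 0
                    walk(child)

            walk(tree.root)


def two_block_alignment(n_per_block=4, n_cols=60, diff=0.4, seed=0):
    """Two internally identical blocks differing at a fraction of columns."""
    rng = np.random.default_rng(seed)
    base = rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n_cols)
    other = base.copy()
    k = int(diff * n_cols)
    pos = rng.choice(n_cols, size=k, replace=False)
    for p in pos:
        choices = [c for c in "ACDEFGHIKLMNPQRSTVWY" if c != base[p]]
        other[p] = rng.choice(choices)
    taxa, rows = [], []
    for i in range(n_per_block):
        taxa.append(f"A{i}")
        rows.append("".join(base))
    for i in range(n_per_block):
        taxa.append(f"B{i}")
        rows.append("".join(other))
    return Alignment(tuple(taxa), tuple(rows))


class TestBootstrap:
    def test_forced_split_gets_full_support(self):
        aln = two_block_alignment()
        tree = phylogeny.bootstrap_support(aln, n_reps=50, seed=1)
        split = frozenset(f"B{i}" for i in range(4))
        supported = {
            frozenset(
                set(n.leaves())
                if "A0" not in n.leaves()
                else set(aln.taxa) - set(n.leaves())
            ): n.support
            for n in tree.internal_nodes()
        }
        assert supported.get(split) == 100.0

    def test_single_replicate_support_binary(self):
        aln = two_block_alignment(n_per_block=3, seed=2)
        tree = phylogeny.bootstrap_support(aln, n_reps=1, seed=3)
        for node in tree.internal_nodes():
            assert node.support in (0.0, 100.0)

    def test_supports_bounded(self):
        aln = two_block_alignment(seed=4)
        tree = phylogeny.bootstrap_support(aln, n_reps=25, seed=5)
        for node in tree.internal_nodes():
            assert 0.0 <= node.support <= 100.0

    def test_deterministic_for_fixed_seed(self):
        aln = two_block_alignment(seed=6)
        t1 = phylogeny.bootstrap_support(aln, n_reps=20, seed=9)
        t2 = phylogeny.bootstrap_support(aln, n_reps=20, seed=9)
        assert t1.newick() == t2.newick()

    def test_zero_reps_rejected(self):
        with pytest.raises(ValueError):
            phylogeny.bootstrap_support(two_block_alignment(), 0, 1)


class TestExtractClades:
    def test_all_low_support_all_orphans(self):
        aln = two_block_alignment(seed=8)
        tree = phylogeny.bootstrap_support(aln, n_reps=10, seed=2)
        for node in tree.internal_nodes():
            node.support = 10.0
        partition = phylogeny.extract_clades(tree, min_support=70)
        assert partition.clades == ()
        assert set(partition.orphans) == set(aln.taxa)

    def test_partition_covers_taxa_disjointly(self):
        aln = two_block_alignment(seed=10)
        tree = phylogeny.bootstrap_support(aln, n_reps=30, seed=3)
        partition = phylogeny.extract_clades(tree, min_support=60)
        members = [m for c in partition.clades for m in c.members]
        assert len(members) == len(set(members))
        assert set(members) | set(partition.orphans) == set(aln.taxa)
        assert not (set(members) & set(partition.orphans))

    def test_min_size_one_promotes_orphans(self):
        aln = two_block_alignment(seed=11)
        tree = phylogeny.bootstrap_support(aln, n_reps=10, seed=4)
        for node in tree.internal_nodes():
            node.support = 0.0
        partition = phylogeny.extract_clades(tree, min_support=70, min_size=1)
        assert partition.orphans == ()
        assert {c.members for c in partition.clades} == {(t,) for t in aln.taxa}

    def test_min_size_zero_rejected(self):
        aln = two_block_alignment(seed=12)
        tree = phylogeny.bootstrap_support(aln, n_reps=5, seed=5)
        with pytest.raises(ValueError):
            phylogeny.extract_clades(tree, min_size=0)

    def test_three_clade_truth_recovery(self, models):
        # generator clades mutated from distinct (diverged) consensi
        spec = simulate.FamilySpec(
            architectures=(("MD", "PK"),) * 3,
            genes_per_clade=(4, 4, 4),
            substitution_rate=0.01,
            clade_divergence=0.15,
        )
        proteome = simulate.generate_proteome(spec, models, seed=21)
        rows = []
        for pid, grp in proteome.hits.groupby("protein", sort=False):
            seq = proteome.sequences[pid]
            rows.append(
                (pid, "".join(seq[r.start - 1 : r.end] for r in grp.itertuples()))
            )
        aln = Alignment(tuple(r[0] for r in rows), tuple(r[1] for r in rows))
        tree = phylogeny.bootstrap_support(aln, n_reps=100, seed=22)
        partition = phylogeny.extract_clades(tree, min_support=70, min_size=2)
        truth = {
            frozenset(proteome.proteins[proteome.proteins.clade == c].protein)
            for c in ("C1", "C2", "C3")
        }
        assert {frozenset(c.members) for c in partition.clades} == truth


class TestCladeExpansion:
    def test_identical_proportions(self):
        chi2, p = phylogeny.clade_expansion_test(10, 100, 10, 100)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_textbook_formula_oracle(self):
        # independent hand oracle: chi2 = sum (O - E)^2 / E over the 2x2 table
        table = np.array([[20.0, 126.0], [4.0, 83.0]])
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        oracle = ((table - expected) ** 2 / expected).sum()
        chi2, _ = phylogeny.clade_expansion_test(20, 146, 4, 87)
        assert chi2 == pytest.approx(oracle, rel=1e-12)

    def test_doubling_cells_doubles_statistic(self):
        chi2, _ = phylogeny.clade_expansion_test(20, 146, 4, 87)
        chi2_double, _ = phylogeny.clade_expansion_test(40, 292, 8, 174)
        assert chi2_double == pytest.approx(2 * chi2)

    def test_zero_expected_cell_advises_exact_test(self):
        with pytest.raises(ValueError, match="exact"):
            phylogeny.clade_expansion_test(0, 10, 0, 10)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            phylogeny.clade_expansion_test(11, 10, 1, 10)
        with pytest.raises(ValueError):
            phylogeny.clade_expansion_test(0, 0, 1, 10)


class TestNewick:
    def test_newick_parses_with_dendropy(self):
        import dendropy

        aln = two_block_alignment(seed=13)
        tree = phylogeny.bootstrap_support(aln, n_reps=10, seed=6)
        parsed = dendropy.Tree.get(data=tree.newick(), schema="newick")
        assert {leaf.taxon.label for leaf in parsed.leaf_node_iter()} == set(aln.taxa)
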