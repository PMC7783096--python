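"""Neighbor-joining trees with bootstrap support, clade extraction, expansion test."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class Alignment:
    """Equal-length gapped amino-acid rows keyed by taxon id."""

    taxa: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa and rows differ in length")
        if len(self.taxa) < 3:
            raise ValueError("alignment needs >= 3 taxa")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError("rows must all have the same length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def matrix(self) -> np.ndarray:
        return np.array([list(r) for r in self.rows], dtype="U1")

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        from Bio import SeqIO

        taxa, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            taxa.append(rec.id)
            rows.append(str(rec.seq))
        return cls(tuple(taxa), tuple(rows))


@dataclass(frozen=True)
class DistanceMatrix:
    taxa: tuple[str, ...]
    d: np.ndarray
    correction: str = "poisson"

    def __post_init__(self) -> None:
        if self.d.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("distance matrix shape mismatch")


class Node:
    """Tree node; leaves carry a name, internal nodes carry bootstrap support."""

    __slots__ = ("name", "children", "support", "tiebreak_id")

    def __init__(self, name: str | None = None):
        self.name = name
        self.children: list[tuple["Node", float]] = []
        self.support: float | None = None
        self.tiebreak_id: str = name or ""

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class SupportTree:
    """Unrooted tree held as a trifurcation at the root; supports in percent."""

    root: Node
    taxa: tuple[str, ...]

    def leaf_order(self) -> list[str]:
        return self.root.leaves()

    def internal_nodes(self) -> list[Node]:
        out = []

        def walk(node: Node) -> None:
            for child, _ in node.children:
                if not child.is_leaf:
                    out.append(child)
                    walk(child)

        walk(self.root)
        return out

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions, each as the side excluding the first taxon."""
        ref = min(self.taxa)
        full = set(self.taxa)
        out = set()
        for node in self.internal_nodes():
            side = set(node.leaves())
            if ref in side:
                side = full - side
            if 1 < len(side) < len(full) - 1:
                out.add(frozenset(side))
        return out

    def path_distances(self) -> pd.DataFrame:
        """Leaf-to-leaf patristic distances."""
        dist = pd.DataFrame(0.0, index=list(self.taxa), columns=list(self.taxa))

        def below(node: Node, acc: float) -> list[tuple[str, float]]:
            if node.is_leaf:
                return [(node.name, acc)]
            out = []
            for child, length in node.children:
                out.extend(below(child, acc + length))
            return out

        def walk(node: Node) -> None:
            groups = [below(child, length) for child, length in node.children]
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    for a, da in groups[i]:
                        for b, db in groups[j]:
                            dist.loc[a, b] = dist.loc[b, a] = da + db
            for child, _ in node.children:
                if not child.is_leaf:
                    walk(child)

        walk(self.root)
        return dist

    def newick(self) -> str:
        def fmt(node: Node, length: float | None) -> str:
            if node.is_leaf:
                body = node.name
            else:
                inner = ",".join(fmt(c, l) for c, l in node.children)
                label = "" if node.support is None else f"{node.support:g}"
                body = f"({inner}){label}"
            return body if length is None else f"{body}:{length:.6g}"

        inner = ",".join(fmt(c, l) for c, l in self.root.children)
        return f"({inner});"


@dataclass(frozen=True)
class Clade:
    clade_id: str
    members: tuple[str, ...]
    support: float | None


@dataclass(frozen=True)
class CladePartition:
    clades: tuple[Clade, ...]
    orphans: tuple[str, ...]


def pairwise_distances(aln: Alignment, correction: str = "poisson") -> DistanceMatrix:
    """Per-pair p-distance over gap-free columns; optional Poisson correction.

    Sites with a gap in either row are excluded for that pair.  A pair with
    zero comparable columns is an error.  For the Poisson correction
    d = -ln(1 - p), p is capped at 0.99.
    """
    if correction not in ("none", "poisson"):
        raise ValueError(f"unknown correction {correction!r}")
    mat = aln.matrix()
    gap = (mat == "-") | (mat == ".")
    n = len(aln.taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gap[i] | gap[j])
            m = int(ok.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable columns between {aln.taxa[i]!r} and {aln.taxa[j]!r}"
                )
            p = float((mat[i, ok] != mat[j, ok]).sum()) / m
            if correction == "poisson":
                d[i, j] = d[j, i] = -math.log(1.0 - min(p, 0.99))
            else:
                d[i, j] = d[j, i] = p
    return DistanceMatrix(aln.taxa, d, correction)


def neighbor_joining(dm: DistanceMatrix) -> SupportTree:
    """Saitou–Nei agglomeration with deterministic tie-breaking.

    Ties on the Q criterion are broken by the lexicographically smallest
    (id, id) pair, internal nodes inheriting the smallest leaf id beneath
    them.  Negative branch lengths are clamped to zero with the deficit moved
    to the sibling branch, preserving the joined pair's distance.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    if not np.allclose(dm.d, dm.d.T):
        raise ValueError("distance matrix must be symmetric")
    nodes = [Node(t) for t in dm.taxa]
    D = dm.d.astype(float).copy()

    while len(nodes) > 3:
        k = len(nodes)
        r = D.sum(axis=1)
        Q = (k - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        best = None
        for i, j in np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12)):
            if i >= j:
                continue
            key = tuple(sorted((nodes[i].tiebreak_id, nodes[j].tiebreak_id)))
            if best is None or key < best[0]:
                best = (key, int(i), int(j))
        _, i, j = best
        li = D[i, j] / 2 + (r[i] - r[j]) / (2 * (k - 2))
        lj = D[i, j] - li
        if li < 0:
            lj -= li
            li = 0.0
        elif lj < 0:
            li -= lj
            lj = 0.0
        parent = Node()
        parent.children = [(nodes[i], float(li)), (nodes[j], float(lj))]
        parent.tiebreak_id = min(nodes[i].tiebreak_id, nodes[j].tiebreak_id)
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [x for x in range(k) if x not in (i, j)]
        D2 = np.zeros((len(keep) + 1, len(keep) + 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dnew[keep]
        nodes = [nodes[x] for x in keep] + [parent]
        D = D2

    a = max(0.0, (D[0, 1] + D[0, 2] - D[1, 2]) / 2)
    b = max(0.0, (D[0, 1] + D[1, 2] - D[0, 2]) / 2)
    c = max(0.0, (D[0, 2] + D[1, 2] - D[0, 1]) / 2)
    root = Node()
    root.children = [(nodes[0], a), (nodes[1], b), (nodes[2], c)]
    root.tiebreak_id = min(nd.tiebreak_id for nd in nodes)
    return SupportTree(root=root, taxa=dm.taxa)


def bootstrap_support(
    aln: Alignment,
    n_reps: int,
    seed: int,
    correction: str = "poisson",
) -> SupportTree:
    """NJ tree from the full alignment with bipartition bootstrap percentages.

    Columns are resampled with replacement per replicate; support of each
    internal bipartition of the full-data tree is the percentage of replicate
    trees containing it.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tree = neighbor_joining(pairwise_distances(aln, correction))
    ref = min(aln.taxa)
    full = set(aln.taxa)

    def node_bipartition(node: Node) -> frozenset:
        side = set(node.leaves())
        if ref in side:
            side = full - side
        return frozenset(side)

    internal = tree.internal_nodes()
    targets = {id(nd): node_bipartition(nd) for nd in internal}
    counts = {id(nd): 0 for nd in internal}

    rng = np.random.default_rng(seed)
    mat = aln.matrix()
    ncol = aln.n_columns
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        rep_rows = tuple("".join(row) for row in mat[:, cols])
        rep_aln = Alignment(aln.taxa, rep_rows)
        rep_tree = neighbor_joining(pairwise_distances(rep_aln, correction))
        rep_biparts = rep_tree.bipartitions()
        for nd in internal:
            if targets[id(nd)] in rep_biparts:
                counts[id(nd)] += 1
    for nd in internal:
        nd.support = 100.0 * counts[id(nd)] / n_reps
    return tree


def extract_clades(
    tree: SupportTree,
    min_support: float = 70.0,
    min_size: int = 2,
    singletons_as_clades: bool = False,
) -> CladePartition:
    """Maximal supported subtrees become clades; the rest are orphans.

    A node qualifies when its support is at least *min_support* and it has at
    least *min_size* leaves; qualifying nodes closest to the root win, so
    clades never nest.  With ``min_size=1`` (or the explicit flag) orphans are
    promoted to singleton clades.  Clades are numbered by the position of
    their first leaf in the tree's leaf order.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    promote = singletons_as_clades or min_size == 1
    full = set(tree.taxa)
    order = {t: i for i, t in enumerate(tree.leaf_order())}

    # Work on bipartitions rather than rooted nodes: the NJ root may fall
    # inside a true clade, in which case the clade only exists as the
    # complement of a node's leaf set.  The clade candidate of a supported
    # split is its smaller side (ties: the side entered last in leaf order).
    candidates: dict[frozenset, float] = {}
    for node in tree.internal_nodes():
        if node.support is None or node.support < min_support:
            continue
        side = set(node.leaves())
        other = full - side
        if len(other) < len(side) or (
            len(other) == len(side)
            and min(order[t] for t in other) > min(order[t] for t in side)
        ):
            side = other
        key = frozenset(side)
        if len(key) >= max(min_size, 2):
            candidates[key] = max(candidates.get(key, 0.0), node.support)

    # bipartition sides form a laminar family: accept largest-first, skipping
    # anything nested inside an accepted clade, to get maximal non-nested sets
    clade_sets: list[tuple[tuple[str, ...], float | None]] = []
    accepted: list[frozenset] = []
    for key in sorted(candidates, key=lambda k: (-len(k), min(order[t] for t in k))):
        if any(key & a for a in accepted):
            continue
        accepted.append(key)
        members = tuple(sorted(key, key=order.__getitem__))
        clade_sets.append((members, candidates[key]))

    grouped = {m for members, _ in clade_sets for m in members}
    orphans = [t for t in tree.leaf_order() if t not in grouped]
    if promote:
        clade_sets.extend(((o,), None) for o in orphans)
        orphans = []
    order = {t: i for i, t in enumerate(tree.leaf_order())}
    clade_sets.sort(key=lambda cs: min(order[m] for m in cs[0]))
    clades = tuple(
        Clade(f"K{i + 1}", members, support)
        for i, (members, support) in enumerate(clade_sets)
    )
    return CladePartition(clades=clades, orphans=tuple(orphans))


def clade_expansion_test(
    count_a: int, total_a: int, count_b: int, total_b: int
) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on the 2x2 table
    [[count_a, total_a - count_a], [count_b, total_b - count_b]].
    """
    if not (0 <= count_a <= total_a and 0 <= count_b <= total_b):
        raise ValueError("counts must satisfy 0 <= count <= total")
    if total_a <= 0 or total_b <= 0:
        raise ValueError("totals must be positive")
    table = np.array(
        [[count_a, total_a - count_a], [count_b, total_b - count_b]], dtype=float
    )
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if (expected == 0).any():
        raise ValueError("expected cell is zero; use an exact test instead")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def clades_to_frame(partition: CladePartition) -> pd.DataFrame:
    rows = [
        {
            "clade": c.clade_id,
            "support": "" if c.support is None else f"{c.support:g}",
            "members": ";".join(c.members),
        }
        for c in partition.clades
    ]
    return pd.DataFrame(rows, columns=["clade", "support", "members"])
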