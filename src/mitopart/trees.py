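"""Unrooted phylogenetic trees: a light adjacency structure for inference.

Leaves are numbered ``0 .. n-1`` in the order of ``Tree.taxa``; internal node
ids are arbitrary integers >= n.  Branch lengths live on undirected edges keyed
by the sorted node pair.  The structure supports multifurcations (needed for
consensus trees); inference code keeps trees binary.

Bipartition utilities encode each split as an integer bitmask over the *sorted*
taxon labels, canonicalized to the side not containing the alphabetically first
taxon, so keys are comparable across trees that share a taxon set.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np


def _ekey(a: int, b: int) -> tuple[int, int]:
    return (a, b) if a < b else (b, a)


class TreeError(ValueError):
    pass


@dataclass
class Tree:
    """Unrooted tree over a fixed taxon set.

    Parameters
    ----------
    taxa
        Leaf labels; leaf ``i`` carries ``taxa[i]``.  Labels must be unique.
    adj
        Adjacency lists, ``node -> list of neighbor nodes``.
    lengths
        Branch lengths keyed by sorted node pair.
    """

    taxa: tuple[str, ...]
    adj: dict[int, list[int]] = field(default_factory=dict)
    lengths: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.taxa = tuple(self.taxa)
        if len(set(self.taxa)) != len(self.taxa):
            raise TreeError("duplicate taxon labels")

    # -- basic accessors -------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def nodes(self) -> list[int]:
        return list(self.adj)

    def leaves(self) -> list[int]:
        return [v for v in self.adj if v < self.n_taxa]

    def internal_nodes(self) -> list[int]:
        return [v for v in self.adj if v >= self.n_taxa]

    def edges(self) -> list[tuple[int, int]]:
        out = []
        for u, nbrs in self.adj.items():
            for v in nbrs:
                if u < v:
                    out.append((u, v))
        return out

    def internal_edges(self) -> list[tuple[int, int]]:
        n = self.n_taxa
        return [(u, v) for u, v in self.edges() if u >= n and v >= n]

    def degree(self, v: int) -> int:
        return len(self.adj[v])

    def is_binary(self) -> bool:
        return all(len(nbrs) == 3 for v, nbrs in self.adj.items() if v >= self.n_taxa)

    def branch_length(self, u: int, v: int) -> float:
        return self.lengths[_ekey(u, v)]

    def set_branch_length(self, u: int, v: int, value: float) -> None:
        self.lengths[_ekey(u, v)] = float(value)

    def total_length(self) -> float:
        return float(sum(self.lengths.values()))

    def copy(self) -> "Tree":
        return Tree(
            self.taxa,
            {v: list(nbrs) for v, nbrs in self.adj.items()},
            dict(self.lengths),
        )

    # -- traversal -------------------------------------------------------
    def postorder(self, root: int | None = None) -> list[tuple[int, int | None]]:
        """(node, parent) pairs, children before parents, rooted at *root*."""
        if root is None:
            internals = self.internal_nodes()
            root = min(internals) if internals else 0
        order: list[tuple[int, int | None]] = []
        stack: list[tuple[int, int | None]] = [(root, None)]
        while stack:
            node, parent = stack.pop()
            order.append((node, parent))
            for nbr in self.adj[node]:
                if nbr != parent:
                    stack.append((nbr, node))
        order.reverse()
        return order

    def children_map(self, root: int | None = None) -> tuple[int, dict[int, list[int]]]:
        if root is None:
            internals = self.internal_nodes()
            root = min(internals) if internals else 0
        children: dict[int, list[int]] = {v: [] for v in self.adj}
        for node, parent in self.postorder(root):
            if parent is not None:
                children[parent].append(node)
        return root, children

    # -- bipartitions ----------------------------------------------------
    def _leaf_rank(self) -> dict[int, int]:
        order = sorted(range(self.n_taxa), key=lambda i: self.taxa[i])
        return {leaf: rank for rank, leaf in enumerate(order)}

    def bipartitions(self, include_trivial: bool = False) -> set[int]:
        """Splits as bitmasks over sorted taxa (side without the first label)."""
        n = self.n_taxa
        rank = self._leaf_rank()
        full = (1 << n) - 1
        masks: dict[int, int] = {}
        root = min(self.internal_nodes()) if n > 2 else 0
        for node, parent in self.postorder(root):
            m = (1 << rank[node]) if node < n else 0
            for nbr in self.adj[node]:
                if nbr != parent:
                    m |= masks[nbr]
            masks[node] = m
        out: set[int] = set()
        for node, parent in self.postorder(root):
            if parent is None:
                continue
            m = masks[node]
            if m & 1:
                m = full & ~m
            k = bin(m).count("1")
            if include_trivial or (2 <= k <= n - 2):
                out.add(m)
        return out

    # -- newick ----------------------------------------------------------
    def to_newick(self, precision: int = 10) -> str:
        if self.n_taxa == 1:
            return f"{self.taxa[0]};"
        root = min(self.internal_nodes()) if self.n_taxa > 2 else 0

        def fmt(node: int, parent: int | None) -> str:
            kids = [v for v in self.adj[node] if v != parent]
            if not kids:
                label = self.taxa[node]
            else:
                label = "(" + ",".join(fmt(k, node) for k in kids) + ")"
            if parent is None:
                return label
            bl = self.lengths.get(_ekey(node, parent))
            return label if bl is None else f"{label}:{bl:.{precision}g}"

        return fmt(root, None) + ";"

    @classmethod
    def from_newick(cls, newick: str, taxa: Sequence[str] | None = None) -> "Tree":
        """Parse a newick string (via dendropy) into an unrooted Tree."""
        dt = dendropy.Tree.get(data=newick, schema="newick",
                               preserve_underscores=True)
        dt.deroot()
        leaf_labels = [lf.taxon.label for lf in dt.leaf_node_iter()]
        if taxa is None:
            taxa = leaf_labels
        index = {label: i for i, label in enumerate(taxa)}
        missing = set(leaf_labels) - set(index)
        if missing or len(leaf_labels) != len(taxa):
            raise TreeError(f"taxon mismatch between newick and taxa: {missing}")
        tree = cls(tuple(taxa), {i: [] for i in range(len(taxa))}, {})
        next_id = len(taxa)
        node_ids: dict[object, int] = {}
        for nd in dt.preorder_node_iter():
            if nd.is_leaf():
                node_ids[nd] = index[nd.taxon.label]
            else:
                node_ids[nd] = next_id
                tree.adj[next_id] = []
                next_id += 1
            if nd.parent_node is not None:
                u, v = node_ids[nd.parent_node], node_ids[nd]
                tree.adj[u].append(v)
                tree.adj[v].append(u)
                bl = nd.edge.length
                tree.lengths[_ekey(u, v)] = float(bl) if bl is not None else 0.0
        return tree


# ---------------------------------------------------------------------------
# topology keys and distances
# ---------------------------------------------------------------------------

def topology_key(tree: Tree) -> tuple:
    """Canonical hashable key for an unrooted topology (branch lengths ignored).

    Two trees over the same taxon set get equal keys iff their non-trivial
    bipartition sets coincide.
    """
    return (tuple(sorted(tree.taxa)), tuple(sorted(tree.bipartitions())))


def rf_distance(t1: Tree, t2: Tree) -> int:
    """Robinson–Foulds distance: |symmetric difference| of non-trivial splits."""
    if sorted(t1.taxa) != sorted(t2.taxa):
        raise TreeError("trees have different taxon sets")
    return len(t1.bipartitions() ^ t2.bipartitions())


# ---------------------------------------------------------------------------
# construction helpers
# ---------------------------------------------------------------------------

def star_tree(taxa: Sequence[str], branch_length: float = 0.1) -> Tree:
    n = len(taxa)
    hub = n
    adj = {i: [hub] for i in range(n)}
    adj[hub] = list(range(n))
    lengths = {_ekey(i, hub): branch_length for i in range(n)}
    return Tree(tuple(taxa), adj, lengths)


def random_topology(taxa: Sequence[str], rng: np.random.Generator,
                    branch_length_mean: float = 0.1) -> Tree:
    """Uniform random unrooted binary topology by random stepwise addition."""
    n = len(taxa)
    if n < 2:
        raise TreeError("need >= 2 taxa")
    tree = Tree(tuple(taxa), {i: [] for i in range(n)}, {})

    def bl() -> float:
        return float(rng.exponential(branch_length_mean))

    if n == 2:
        tree.adj[0] = [1]
        tree.adj[1] = [0]
        tree.lengths[_ekey(0, 1)] = bl()
        return tree
    hub = n
    tree.adj[hub] = [0, 1, 2]
    for i in range(3):
        tree.adj[i] = [hub]
        tree.lengths[_ekey(i, hub)] = bl()
    next_id = n + 1
    for leaf in range(3, n):
        edges = tree.edges()
        u, v = edges[rng.integers(len(edges))]
        mid = next_id
        next_id += 1
        old = tree.lengths.pop(_ekey(u, v))
        tree.adj[u][tree.adj[u].index(v)] = mid
        tree.adj[v][tree.adj[v].index(u)] = mid
        tree.adj[mid] = [u, v, leaf]
        tree.adj[leaf] = [mid]
        tree.lengths[_ekey(u, mid)] = old / 2
        tree.lengths[_ekey(v, mid)] = old / 2
        tree.lengths[_ekey(leaf, mid)] = bl()
    return tree


def all_topologies(taxa: Sequence[str], branch_length: float = 0.1,
                   max_taxa: int = 9) -> Iterable[Tree]:
    """Enumerate every unrooted binary topology ((2n-5)!! of them).

    Refuses above *max_taxa* leaves (combinatorial guard).
    """
    n = len(taxa)
    if n > max_taxa:
        raise TreeError(f"exhaustive enumeration refused for {n} > {max_taxa} taxa")
    if n < 3:
        yield random_topology(taxa, np.random.default_rng(0), branch_length)
        return

    def build(base: Tree, leaf: int, next_id: int) -> Iterable[Tree]:
        if leaf == n:
            yield base
            return
        for u, v in base.edges():
            t = base.copy()
            mid = next_id
            old = t.lengths.pop(_ekey(u, v))
            t.adj[u][t.adj[u].index(v)] = mid
            t.adj[v][t.adj[v].index(u)] = mid
            t.adj[mid] = [u, v, leaf]
            t.adj[leaf] = [mid]
            t.lengths[_ekey(u, mid)] = old / 2
            t.lengths[_ekey(v, mid)] = old / 2
            t.lengths[_ekey(leaf, mid)] = branch_length
            yield from build(t, leaf + 1, next_id + 1)

    hub = n
    seed_adj = {i: [hub] for i in range(3)}
    seed_adj[hub] = [0, 1, 2]
    seed = Tree(tuple(taxa), seed_adj,
                {_ekey(i, hub): branch_length for i in range(3)})
    yield from build(seed, 3, n + 1)


# ---------------------------------------------------------------------------
# NNI
# ---------------------------------------------------------------------------

def nni_neighbors(tree: Tree, edge: tuple[int, int] | None = None) -> list[Tree]:
    """The two nearest-neighbor-interchange rearrangements around an internal
    edge (all internal edges if *edge* is None)."""
    edges = [edge] if edge is not None else tree.internal_edges()
    out = []
    for u, v in edges:
        if u < tree.n_taxa or v < tree.n_taxa:
            raise TreeError("NNI requires an internal edge")
        a_nbrs = [x for x in tree.adj[u] if x != v]
        b_nbrs = [x for x in tree.adj[v] if x != u]
        a = a_nbrs[1]  # swap a fixed neighbor of u with each neighbor of v
        for b in b_nbrs:
            t = tree.copy()
            _swap_subtrees(t, u, a, v, b)
            out.append(t)
    return out


def _swap_subtrees(t: Tree, u: int, a: int, v: int, b: int) -> None:
    """Detach subtree a from u and b from v, reattach swapped (lengths follow)."""
    la = t.lengths.pop(_ekey(u, a))
    lb = t.lengths.pop(_ekey(v, b))
    t.adj[u][t.adj[u].index(a)] = b
    t.adj[v][t.adj[v].index(b)] = a
    t.adj[a][t.adj[a].index(u)] = v
    t.adj[b][t.adj[b].index(v)] = u
    t.lengths[_ekey(u, b)] = lb
    t.lengths[_ekey(v, a)] = la


def random_nni(tree: Tree, rng: np.random.Generator) -> Tree:
    """One NNI move: uniform internal edge, uniform choice of the two swaps."""
    edges = tree.internal_edges()
    if not edges:
        raise TreeError("no internal edge: NNI undefined for < 4 taxa")
    u, v = edges[rng.integers(len(edges))]
    a_nbrs = [x for x in tree.adj[u] if x != v]
    b_nbrs = [x for x in tree.adj[v] if x != u]
    a = a_nbrs[1]
    b = b_nbrs[int(rng.integers(2))]
    t = tree.copy()
    _swap_subtrees(t, u, a, v, b)
    return t


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def majority_rule_consensus(trees: Sequence[Tree], threshold: float = 0.5) -> Tree:
    """Majority-rule consensus (threshold > 0.5 guarantees compatibility).

    ``threshold=1.0`` gives the strict consensus (splits present in every tree).
    Returned tree is possibly multifurcating; each retained split's branch
    length is the mean length of that split's edge over the trees carrying it.
    """
    if not trees:
        raise TreeError("no trees given")
    taxa_sorted = sorted(trees[0].taxa)
    for t in trees[1:]:
        if sorted(t.taxa) != taxa_sorted:
            raise TreeError("consensus requires a shared taxon set")
    n = len(taxa_sorted)
    counts: dict[int, int] = {}
    for t in trees:
        for m in t.bipartitions():
            counts[m] = counts.get(m, 0) + 1
    ntrees = len(trees)
    cut = min(threshold, 1.0 - 1e-12)
    keep = [m for m, c in counts.items() if c / ntrees > cut]
    keep.sort(key=lambda m: (bin(m).count("1"), m))

    cons = star_tree(taxa_sorted, branch_length=1.0)
    rank = {lab: i for i, lab in enumerate(taxa_sorted)}
    next_id = n + 1
    for mask in keep:
        members = [i for i in range(n) if mask >> rank[cons.taxa[i]] & 1]
        # find the node all members currently hang off (their common parent)
        parents = {cons.adj[i][0] if i < n else None for i in members}
        # members may already be behind internal nodes: climb via mask containment
        node_mask: dict[int, int] = {}
        root, children = cons.children_map(n)
        for nd, par in cons.postorder(n):
            m = (1 << rank[cons.taxa[nd]]) if nd < n else 0
            for ch in children.get(nd, []):
                m |= node_mask[ch]
            node_mask[nd] = m
        # children of root-side nodes covered exactly by mask
        target_parent = None
        group: list[int] = []
        for nd in cons.adj:
            kids = children.get(nd, [])
            sub = [k for k in kids if node_mask[k] & mask == node_mask[k]]
            if sub and sum(bin(node_mask[k]).count("1") for k in sub) == bin(mask).count("1"):
                target_parent, group = nd, sub
                break
        if target_parent is None or len(group) < 2:
            continue  # incompatible with already-placed splits (threshold <= 0.5)
        new = next_id
        next_id += 1
        cons.adj[new] = []
        for ch in group:
            cons.adj[target_parent].remove(ch)
            cons.adj[ch][cons.adj[ch].index(target_parent)] = new
            cons.adj[new].append(ch)
            cons.lengths[_ekey(new, ch)] = cons.lengths.pop(_ekey(target_parent, ch))
        cons.adj[new].append(target_parent)
        cons.adj[target_parent].append(new)
        lens = [t.lengths[_find_split_edge(t, mask)] for t in trees
                if mask in t.bipartitions()]
        cons.lengths[_ekey(new, target_parent)] = float(np.mean(lens))
    return cons


def _find_split_edge(tree: Tree, mask: int) -> tuple[int, int]:
    n = tree.n_taxa
    rank = tree._leaf_rank()
    full = (1 << n) - 1
    root = min(tree.internal_nodes())
    masks: dict[int, int] = {}
    for node, parent in tree.postorder(root):
        m = (1 << rank[node]) if node < n else 0
        for nbr in tree.adj[node]:
            if nbr != parent:
                m |= masks[nbr]
        masks[node] = m
    for node, parent in tree.postorder(root):
        if parent is None:
            continue
        m = masks[node]
        if m & 1:
            m = full & ~m
        if m == mask:
            return _ekey(node, parent)
    raise TreeError("split not found in tree")
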