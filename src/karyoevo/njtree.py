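"""Neighbor-joining trees, outgroup rooting, and Newick serialization.

The neighbor-joining agglomeration (Q-criterion, Saitou–Nei branch-length
formulas) is implemented here directly so that tie-breaking and
negative-branch handling are fully deterministic: Q ties break to the
lexicographically smallest pair of subtree labels, and a negative branch
estimate is clamped to zero with the deficit moved to its sibling so the
joined pair's path length is preserved.  Non-metric dissimilarities are
accepted — the event-weighted karyotype distance does not guarantee the
triangle inequality.
"""

from __future__ import annotations

import logging
from typing import Optional

from .distance import CONTROL_LABEL, DistanceMatrix

logger = logging.getLogger(__name__)


class PhyloTree:
    """A tree with branch lengths over named leaves.

    Stored as an undirected adjacency map; ``root`` is set after outgroup
    rooting, otherwise ``anchor`` names the internal node used as the
    trifurcating base for serialization.
    """

    def __init__(self, adjacency: dict[int, dict[int, float]],
                 names: dict[int, str],
                 root: Optional[int] = None,
                 anchor: Optional[int] = None) -> None:
        self.adjacency = {u: dict(nb) for u, nb in adjacency.items()}
        self.names = dict(names)
        self.root = root
        self.anchor = anchor if anchor is not None else root
        for u, nb in self.adjacency.items():
            for v, w in nb.items():
                if abs(self.adjacency[v][u] - w) > 1e-12:
                    raise ValueError("asymmetric adjacency")

    # -- basic queries ---------------------------------------------------
    @property
    def is_rooted(self) -> bool:
        return self.root is not None

    def leaf_ids(self) -> list[int]:
        return sorted(u for u in self.adjacency
                      if len(self.adjacency[u]) == 1 and u in self.names)

    def leaf_labels(self) -> list[str]:
        return [self.names[u] for u in self.leaf_ids()]

    def _leaf_by_name(self, name: str) -> int:
        for u in self.leaf_ids():
            if self.names[u] == name:
                return u
        raise KeyError(f"no leaf named {name!r}")

    def path_length(self, a: str, b: str) -> float:
        """Sum of branch lengths on the unique path between two leaves."""
        start, goal = self._leaf_by_name(a), self._leaf_by_name(b)
        stack = [(start, None, 0.0)]
        while stack:
            node, prev, dist = stack.pop()
            if node == goal:
                return dist
            for nb, w in self.adjacency[node].items():
                if nb != prev:
                    stack.append((nb, node, dist + w))
        raise RuntimeError("disconnected tree")

    def root_to_leaf_lengths(self) -> dict[str, float]:
        if not self.is_rooted:
            raise ValueError("tree is not rooted")
        out: dict[str, float] = {}
        stack = [(self.root, None, 0.0)]
        while stack:
            node, prev, dist = stack.pop()
            nbs = [v for v in self.adjacency[node] if v != prev]
            if not nbs and node in self.names:
                out[self.names[node]] = dist
            for nb in nbs:
                stack.append((nb, node, dist + self.adjacency[node][nb]))
        return out

    def clade_leaves(self, node: int, parent: Optional[int]) -> list[int]:
        """Leaf ids below ``node`` when entered from ``parent``."""
        out, stack = [], [(node, parent)]
        while stack:
            u, prev = stack.pop()
            nbs = [v for v in self.adjacency[u] if v != prev]
            if not nbs:
                out.append(u)
            for v in nbs:
                stack.append((v, u))
        return out

    def splits(self) -> set[frozenset]:
        """Non-trivial leaf bipartitions, one per internal edge."""
        all_leaves = frozenset(self.leaf_labels())
        out: set[frozenset] = set()
        seen: set[tuple[int, int]] = set()
        for u in self.adjacency:
            for v in self.adjacency[u]:
                if (v, u) in seen:
                    continue
                seen.add((u, v))
                side = frozenset(self.names[x]
                                 for x in self.clade_leaves(v, u))
                other = all_leaves - side
                if len(side) >= 2 and len(other) >= 2:
                    out.add(frozenset({side, other}))
        return out

    # -- serialization ---------------------------------------------------
    def _newick_node(self, node: int, parent: Optional[int]) -> str:
        children = [v for v in self.adjacency[node] if v != parent]
        if not children:
            return self.names.get(node, f"n{node}")
        inner = ",".join(
            f"{self._newick_node(c, node)}:{self.adjacency[node][c]:.6f}"
            for c in children)
        label = self.names.get(node, "")
        return f"({inner}){label}"

    def to_newick(self) -> str:
        base = self.root if self.is_rooted else self.anchor
        if base is None:
            base = max(self.adjacency, key=lambda u: len(self.adjacency[u]))
        return self._newick_node(base, None) + ";"


def neighbor_joining(matrix: DistanceMatrix) -> PhyloTree:
    """Classic neighbor joining on a dissimilarity matrix (unrooted).

    Deterministic: Q-criterion ties break by the lexicographically
    smallest (min-leaf-label) pair; negative branch-length estimates are
    clamped to zero with the deficit shifted to the sibling branch.
    """
    labels = matrix.labels
    n0 = len(labels)
    if n0 < 3:
        raise ValueError("neighbor joining needs at least 3 labels")

    D: dict[int, dict[int, float]] = {
        i: {j: float(matrix.values[i, j]) for j in range(n0) if j != i}
        for i in range(n0)}
    names = dict(enumerate(labels))
    tie_key = dict(enumerate(labels))
    adjacency: dict[int, dict[int, float]] = {i: {} for i in range(n0)}
    active = list(range(n0))
    next_id = n0

    def connect(u: int, v: int, w: float) -> None:
        adjacency.setdefault(u, {})[v] = w
        adjacency.setdefault(v, {})[u] = w

    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i][j] for j in active if j != i) for i in active}
        best: Optional[tuple[float, tuple[str, str], int, int]] = None
        for a in range(m):
            for b in range(a + 1, m):
                i, j = active[a], active[b]
                q = (m - 2) * D[i][j] - r[i] - r[j]
                key = tuple(sorted((tie_key[i], tie_key[j])))
                cand = (q, key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        li = 0.5 * D[i][j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i][j] - li
        if li < 0:
            logger.debug("clamping negative branch %.4g at join (%s,%s)",
                         li, tie_key[i], tie_key[j])
            lj += li
            li = 0.0
        if lj < 0:
            logger.debug("clamping negative branch %.4g at join (%s,%s)",
                         lj, tie_key[i], tie_key[j])
            li += lj
            lj = 0.0
        u = next_id
        next_id += 1
        connect(u, i, li)
        connect(u, j, lj)
        tie_key[u] = min(tie_key[i], tie_key[j])
        D[u] = {}
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (D[i][k] + D[j][k] - D[i][j])
            D[u][k] = duk
            D[k][u] = duk
        active.remove(i)
        active.remove(j)
        active.append(u)

    a, b, c = sorted(active, key=lambda x: tie_key[x])
    v = next_id
    la = max(0.0, 0.5 * (D[a][b] + D[a][c] - D[b][c]))
    lb = max(0.0, 0.5 * (D[a][b] + D[b][c] - D[a][c]))
    lc = max(0.0, 0.5 * (D[a][c] + D[b][c] - D[a][b]))
    connect(v, a, la)
    connect(v, b, lb)
    connect(v, c, lc)
    return PhyloTree(adjacency, names, root=None, anchor=v)


def root_with_outgroup(tree: PhyloTree,
                       outgroup_label: str = CONTROL_LABEL) -> PhyloTree:
    """Root the tree on the outgroup's pendant edge.

    The root is placed at the outgroup end of the edge (root-to-outgroup
    length 0), so the path length from the root to any leaf equals the
    accumulated event weight away from the normal ancestor.
    """
    og = tree._leaf_by_name(outgroup_label)
    (inner, length), = tree.adjacency[og].items()
    adjacency = {u: dict(nb) for u, nb in tree.adjacency.items()}
    del adjacency[og][inner]
    del adjacency[inner][og]
    root = max(adjacency) + 1
    adjacency[root] = {og: 0.0, inner: length}
    adjacency[og][root] = 0.0
    adjacency[inner][root] = length
    return PhyloTree(adjacency, tree.names, root=root)


def write_newick(tree: PhyloTree, path) -> None:
    """Write the tree as Newick with 6-decimal branch lengths."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(tree.to_newick() + "\n")


def read_newick(source) -> PhyloTree:
    """Read a Newick tree (path or string) into a :class:`PhyloTree`."""
    import dendropy

    text = None
    try:
        with open(source, encoding="utf-8") as fh:
            text = fh.read()
    except (OSError, TypeError):
        text = str(source)
    dtree = dendropy.Tree.get(data=text, schema="newick",
                              preserve_underscores=True)
    adjacency: dict[int, dict[int, float]] = {}
    names: dict[int, str] = {}
    ids: dict = {}

    def nid(node) -> int:
        if node not in ids:
            ids[node] = len(ids)
        return ids[node]

    for edge in dtree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        u, v = nid(edge.tail_node), nid(edge.head_node)
        w = float(edge.length or 0.0)
        adjacency.setdefault(u, {})[v] = w
        adjacency.setdefault(v, {})[u] = w
    for node in dtree.leaf_node_iter():
        names[nid(node)] = node.taxon.label if node.taxon else ""
    seed = nid(dtree.seed_node)
    adjacency.setdefault(seed, {})
    rooted = len(dtree.seed_node.child_nodes()) == 2
    return PhyloTree(adjacency, names,
                     root=seed if rooted else None, anchor=seed)
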