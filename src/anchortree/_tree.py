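"""Light-weight rooted-tree machinery shared by the simulators and estimators.

Public modules exchange :class:`dendropy.Tree` objects; the hot loops
(multispecies-coalescent simulation, triplet scoring, NNI search) run on a
compact representation: leaves are integers ``0..n-1`` in the order of a taxon
label list, internal nodes are larger integers, and the topology is a
``children`` dict mapping each internal node to its pair of children.
"""

from __future__ import annotations

import itertools

import dendropy
import numpy as np

__all__ = [
    "from_dendropy",
    "to_dendropy",
    "mrca_depth_matrix",
    "star_rank_matrix",
    "random_topology",
    "nni_neighbors",
    "newick_of",
]


def from_dendropy(tree: dendropy.Tree, labels: list[str]) -> tuple[dict, int, dict]:
    """Convert a rooted dendropy tree into (children, root, blen).

    ``labels`` fixes the leaf integer assignment; every leaf of ``tree`` must
    carry a taxon whose label is in ``labels``.  ``blen[node]`` is the length
    of the edge above ``node`` (``None`` entries become 0.0).
    """
    index = {lab: i for i, lab in enumerate(labels)}
    children: dict[int, tuple[int, ...]] = {}
    blen: dict[int, float] = {}
    next_id = len(labels)
    ids: dict[object, int] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            lab = nd.taxon.label if nd.taxon is not None else nd.label
            if lab not in index:
                raise ValueError(f"leaf label {lab!r} not in taxon list")
            ids[nd] = index[lab]
        else:
            ids[nd] = next_id
            next_id += 1
            children[ids[nd]] = tuple(ids[ch] for ch in nd.child_nodes())
        blen[ids[nd]] = nd.edge.length if nd.edge.length is not None else 0.0
    return children, ids[tree.seed_node], blen


def to_dendropy(
    children: dict,
    root: int,
    labels: list[str],
    blen: dict | None = None,
    taxon_namespace: dendropy.TaxonNamespace | None = None,
) -> dendropy.Tree:
    tns = taxon_namespace or dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = True

    def build(node_id: int) -> dendropy.Node:
        nd = dendropy.Node()
        if node_id < len(labels):
            nd.taxon = tns.get_taxon(labels[node_id])
        else:
            for ch in children[node_id]:
                nd.add_child(build(ch))
        if blen is not None:
            nd.edge.length = blen.get(node_id)
        return nd

    tree.seed_node = build(root)
    return tree


def newick_of(children: dict, root: int, labels: list[str]) -> str:
    """Branch-length-free newick string (deterministic, children in stored order)."""

    def rec(v: int) -> str:
        if v < len(labels):
            return labels[v]
        return "(" + ",".join(rec(c) for c in children[v]) + ")"

    return rec(root) + ";"


def _leaf_lists(children: dict, root: int, n_leaves: int) -> dict[int, list[int]]:
    leaves: dict[int, list[int]] = {}

    def rec(v: int) -> list[int]:
        if v < n_leaves:
            leaves[v] = [v]
        else:
            acc: list[int] = []
            for ch in children[v]:
                acc.extend(rec(ch))
            leaves[v] = acc
        return leaves[v]

    rec(root)
    return leaves


def _fill_cross_pairs(M: np.ndarray, children: dict, node: int, leaves: dict, value: float) -> None:
    kids = children[node]
    for a, b in itertools.combinations(kids, 2):
        la, lb = leaves[a], leaves[b]
        M[np.ix_(la, lb)] = value
        M[np.ix_(lb, la)] = value


def mrca_depth_matrix(children: dict, root: int, n_leaves: int) -> np.ndarray:
    """M[i, j] = depth (edges below root) of the MRCA of leaves i and j.

    Only entries for leaves present in the tree are filled; absent pairs stay
    at -1.  Diagonal is left at -1 (never used).
    """
    M = np.full((n_leaves, n_leaves), -1.0)
    depth = {root: 0}
    stack = [root]
    order = []
    while stack:
        v = stack.pop()
        order.append(v)
        if v in children:
            for ch in children[v]:
                depth[ch] = depth[v] + 1
                stack.append(ch)
    leaves = _leaf_lists(children, root, n_leaves)
    for v in order:
        if v in children:
            _fill_cross_pairs(M, children, v, leaves, depth[v])
    return M


def star_rank_matrix(children: dict, root: int, n_leaves: int) -> np.ndarray:
    """M[i, j] = STAR rank of the MRCA of i and j; -1 where undefined.

    Rank convention: the root of a gene tree with ``k`` leaves has rank
    ``k - 1`` and every internal node has rank one less than its parent.
    Pairwise STAR distance is twice this rank.
    """
    present = sorted(_leaf_lists(children, root, n_leaves)[root])
    k = len(present)
    M = np.full((n_leaves, n_leaves), -1.0)
    rank = {root: float(k - 1)}
    stack = [root]
    order = []
    while stack:
        v = stack.pop()
        order.append(v)
        if v in children:
            for ch in children[v]:
                rank[ch] = rank[v] - 1.0
                stack.append(ch)
    leaves = _leaf_lists(children, root, n_leaves)
    for v in order:
        if v in children:
            _fill_cross_pairs(M, children, v, leaves, rank[v])
    return M


def random_topology(n_leaves: int, rng: np.random.Generator) -> tuple[dict, int]:
    """Uniform random coalescent-style rooted binary topology on 0..n-1."""
    nodes = list(range(n_leaves))
    next_id = n_leaves
    children: dict[int, tuple[int, int]] = {}
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        children[next_id] = (a, b)
        nodes = [x for x in nodes if x not in (a, b)] + [next_id]
        next_id += 1
    return children, nodes[0]


def nni_neighbors(children: dict, root: int):
    """Yield rooted NNI neighbours (new ``children`` dicts) of a binary tree.

    One edge (u, v) with v internal produces two rearrangements: swap the
    sibling of v with either child of v.
    """
    parent = {}
    for u, kids in children.items():
        for c in kids:
            parent[c] = u
    for v in children:
        if v == root:
            continue
        u = parent[v]
        sib = children[u][0] if children[u][1] == v else children[u][1]
        a, b = children[v]
        for keep, move in ((b, a), (a, b)):
            new = dict(children)
            new[v] = (sib, keep)
            new[u] = tuple(move if x == sib else x for x in children[u])
            yield new
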