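"""Tree construction and comparison utilities.

Provides the neighbor-joining engine shared by the distance-based gene-tree
estimator, STAR, and the tree-of-trees visualisation, plus rooted
Robinson-Foulds distances (as counts and as percent of the rooted maximum
``2(n - 2)``) and bootstrap-support summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = [
    "nj_tree",
    "root_with_outgroup",
    "clade_sets",
    "bipartition_sets",
    "RFResult",
    "rf_distance",
    "mean_bootstrap",
    "annotate_support",
]


def nj_tree(
    labels: list[str],
    distances: np.ndarray,
    taxon_namespace: dendropy.TaxonNamespace | None = None,
) -> dendropy.Tree:
    """Neighbor-joining (Saitou & Nei) on a full distance matrix.

    Returns an unrooted dendropy tree (``is_rooted = False``) with a
    trifurcating seed node and non-negative branch lengths.  Ties in the
    Q-criterion break on the lowest index pair, so the result is
    deterministic for a fixed input.
    """
    D = np.asarray(distances, dtype=float).copy()
    m = len(labels)
    if D.shape != (m, m):
        raise ValueError("distance matrix shape does not match labels")
    if m < 2:
        raise ValueError("need at least two taxa")
    if not np.allclose(D, D.T, equal_nan=True):
        raise ValueError("distance matrix must be symmetric")
    if np.isnan(D).any():
        raise ValueError("distance matrix contains undefined entries")

    tns = taxon_namespace or dendropy.TaxonNamespace(labels)
    nodes = []
    for lab in labels:
        nd = dendropy.Node()
        nd.taxon = tns.get_taxon(lab)
        nodes.append(nd)

    active = list(range(m))
    while len(active) > 2:
        k = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(np.argmin(Q), Q.shape)
        if i > j:
            i, j = j, i
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (k - 2)) if k > 2 else 0.5 * dij
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        na, nb = nodes[ai], nodes[aj]
        parent.add_child(na)
        parent.add_child(nb)
        na.edge.length = li
        nb.edge.length = lj
        # distance of the new node to every other active node
        new_row = 0.5 * (D[ai, active] + D[aj, active] - dij)
        D = np.vstack([D, np.zeros((1, D.shape[1]))])
        D = np.hstack([D, np.zeros((D.shape[0], 1))])
        new_idx = D.shape[0] - 1
        for pos, a in enumerate(active):
            D[new_idx, a] = D[a, new_idx] = max(new_row[pos], 0.0)
        nodes.append(parent)
        active = [a for a in active if a not in (ai, aj)] + [new_idx]

    tree = dendropy.Tree(taxon_namespace=tns)
    if len(active) == 2:
        a, b = active
        root = dendropy.Node()
        root.add_child(nodes[a])
        root.add_child(nodes[b])
        half = max(D[a, b], 0.0) / 2.0
        nodes[a].edge.length = half
        nodes[b].edge.length = half
        tree.seed_node = root
    else:
        tree.seed_node = nodes[active[0]]
    tree.is_rooted = False
    return tree


def root_with_outgroup(tree: dendropy.Tree, outgroup) -> dendropy.Tree:
    """Root (a possibly unrooted) tree on the edge leading to the outgroup.

    ``outgroup`` is a label or list of labels.  With several outgroup taxa the
    tree is rooted on the edge above their MRCA (the outgroup must be, or
    become, monophyletic after rooting at one of its members).
    """
    labels = [outgroup] if isinstance(outgroup, str) else list(outgroup)
    if not labels:
        raise ValueError("empty outgroup")
    taxa = [tree.taxon_namespace.get_taxon(lab) for lab in labels]
    if any(t is None for t in taxa):
        missing = [lab for lab, t in zip(labels, taxa) if t is None]
        raise ValueError(f"outgroup taxa not in tree: {missing}")
    if len(taxa) == 1:
        leaf = tree.find_node_with_taxon_label(labels[0])
        edge = leaf.edge
        length = edge.length or 0.0
        tree.reroot_at_edge(edge, length1=length / 2.0, length2=length / 2.0)
    else:
        # temporarily root at one outgroup member so the rest form a clade
        leaf = tree.find_node_with_taxon_label(labels[0])
        tree.reroot_at_edge(leaf.edge, length1=(leaf.edge.length or 0.0) / 2.0,
                            length2=(leaf.edge.length or 0.0) / 2.0)
        mrca = tree.mrca(taxa=taxa[1:]) if len(taxa) > 2 else \
            tree.find_node_with_taxon_label(labels[1])
        edge = mrca.edge
        length = edge.length or 0.0
        tree.reroot_at_edge(edge, length1=length / 2.0, length2=length / 2.0)
    tree.is_rooted = True
    tree.update_bipartitions(suppress_unifurcations=True)
    return tree


def _leaf_labels(nd) -> frozenset:
    return frozenset(lf.taxon.label for lf in nd.leaf_iter())


def clade_sets(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial clades (leaf-label sets) of a rooted tree.

    Excludes single leaves and the full taxon set, so a binary rooted tree on
    n leaves contributes n - 2 clades.
    """
    all_leaves = _leaf_labels(tree.seed_node)
    out = set()
    for nd in tree.preorder_internal_node_iter():
        cl = _leaf_labels(nd)
        if 1 < len(cl) < len(all_leaves):
            out.add(cl)
    return out


def bipartition_sets(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial bipartitions for unrooted comparison.

    Each bipartition is represented by the frozenset pair (smaller side first
    by a canonical order) wrapped in a frozenset, so orientation is ignored.
    """
    all_leaves = _leaf_labels(tree.seed_node)
    out = set()
    for nd in tree.preorder_internal_node_iter():
        cl = _leaf_labels(nd)
        if 1 < len(cl) < len(all_leaves) - 1:
            out.add(frozenset((cl, all_leaves - cl)))
    return out


@dataclass(frozen=True)
class RFResult:
    """Robinson-Foulds distance with its maximum and percentage."""

    rf: int
    max_rf: int
    n_taxa: int

    @property
    def percent(self) -> float:
        return 100.0 * self.rf / self.max_rf if self.max_rf else 0.0


def rf_distance(
    tree_a: dendropy.Tree,
    tree_b: dendropy.Tree,
    rooted: bool = True,
    prune_to_common: bool = False,
) -> RFResult:
    """Robinson-Foulds distance between two trees on the same leaf set.

    Rooted mode (default) takes the symmetric difference of clade sets with
    maximum ``2(n - 2)``; unrooted mode uses bipartitions with maximum
    ``2(n - 3)``.  With ``prune_to_common`` both trees are restricted to their
    shared taxa first.
    """
    la, lb = _leaf_labels(tree_a.seed_node), _leaf_labels(tree_b.seed_node)
    if la != lb:
        common = la & lb
        if len(common) < 3:
            raise ValueError("trees share fewer than 3 taxa")
        if not prune_to_common:
            raise ValueError(
                "trees have different leaf sets; pass prune_to_common=True")
        tree_a = tree_a.extract_tree(
            node_filter_fn=lambda nd: nd.taxon is None or nd.taxon.label in common)
        tree_b = tree_b.extract_tree(
            node_filter_fn=lambda nd: nd.taxon is None or nd.taxon.label in common)
        la = common
    n = len(la)
    if n < 3:
        raise ValueError("need at least 3 shared taxa")
    if rooted:
        ca, cb = clade_sets(tree_a), clade_sets(tree_b)
        max_rf = 2 * (n - 2)
    else:
        ca, cb = bipartition_sets(tree_a), bipartition_sets(tree_b)
        max_rf = 2 * (n - 3)
    return RFResult(rf=len(ca ^ cb), max_rf=max_rf, n_taxa=n)


def _node_support(nd) -> float | None:
    if getattr(nd, "support", None) is not None:
        return float(nd.support)
    if nd.label is not None:
        try:
            return float(nd.label)
        except ValueError:
            return None
    return None


def mean_bootstrap(tree: dendropy.Tree) -> float:
    """Arithmetic mean of internal-node support values, root excluded."""
    vals = []
    for nd in tree.preorder_internal_node_iter():
        if nd is tree.seed_node:
            continue
        s = _node_support(nd)
        if s is not None:
            vals.append(s)
    if not vals:
        raise ValueError("tree carries no internal-node support values")
    return float(np.mean(vals))


def annotate_support(tree: dendropy.Tree, replicate_trees) -> dendropy.Tree:
    """Label internal nodes with the % of replicate trees containing the clade."""
    reps = [clade_sets(t) for t in replicate_trees]
    if not reps:
        raise ValueError("no replicate trees")
    all_leaves = _leaf_labels(tree.seed_node)
    for nd in tree.preorder_internal_node_iter():
        cl = _leaf_labels(nd)
        if nd is tree.seed_node or not (1 < len(cl) < len(all_leaves)):
            continue
        freq = 100.0 * sum(cl in r for r in reps) / len(reps)
        nd.support = freq
        nd.label = f"{freq:g}"
    return tree
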