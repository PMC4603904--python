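"""Species-tree estimation from gene trees under the multispecies coalescent.

Two summary estimators in a Model/Results shape:

* :class:`STAR` — pairwise distances are twice the average rank of the
  gene-tree coalescence joining two taxa (root rank = number of taxa in that
  gene tree minus one, each internal node one less than its parent),
  averaged over the gene trees containing both taxa and resolved by
  neighbor joining.
* :class:`MPEST` — maximises a pseudo-likelihood over rooted triplets: a
  species-tree triple with internal branch ``t`` (coalescent units) predicts
  the matching rooted triplet with probability ``1 - (2/3)exp(-t)`` and each
  alternative with ``(1/3)exp(-t)``; per-triple branch lengths are profiled
  out with the closed-form MLE ``-ln(1.5 (1 - p1))`` inside an NNI hill
  climb with random restarts.

Both return a :class:`SpeciesTreeResult` carrying the tree, the fit
diagnostics and a ``summary()`` table.  The module also provides rooted
triplet tallies, the pseudo-likelihood of a fixed species tree, and the
MetaTree-style tree-of-trees built from pairwise Robinson-Foulds distances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import dendropy
import numpy as np

from ._tree import (from_dendropy, mrca_depth_matrix, nni_neighbors,
                    random_topology, star_rank_matrix, to_dendropy)
from .treeops import (RFResult, annotate_support, mean_bootstrap, nj_tree,
                      rf_distance, root_with_outgroup)

__all__ = [
    "TripletCounts",
    "triplet_counts",
    "mpest_triplet_mle",
    "mpest_score",
    "STAR",
    "MPEST",
    "SpeciesTreeResult",
    "metatree",
]

T_MIN = 1e-6
T_MAX = 10.0


def _taxa_of(gene_trees, taxa=None) -> list[str]:
    if taxa is not None:
        return list(taxa)
    labels = set()
    for t in gene_trees:
        labels.update(lf.taxon.label for lf in t.leaf_node_iter())
    return sorted(labels)


def _triple_arrays(n: int):
    triples = np.array(list(itertools.combinations(range(n), 3)),
                       dtype=np.int64)
    return triples


def _depth3(M: np.ndarray, triples: np.ndarray) -> np.ndarray:
    """(T, 3): depth of the pair MRCA excluding taxon in slot s."""
    i, j, k = triples[:, 0], triples[:, 1], triples[:, 2]
    return np.stack([M[j, k], M[i, k], M[i, j]], axis=1)


def _slots(M: np.ndarray, triples: np.ndarray) -> np.ndarray:
    """Resolved singleton slot (0/1/2) per triple, -1 if absent/unresolved."""
    d3 = _depth3(M, triples)
    present = (d3 >= 0).all(axis=1)
    order = np.argsort(d3, axis=1)
    top, second = order[:, 2], order[:, 1]
    strict = d3[np.arange(len(d3)), top] > d3[np.arange(len(d3)), second]
    out = np.where(present & strict, top, -1)
    return out.astype(np.int8)


@dataclass
class TripletCounts:
    """Rooted-triplet tallies over a set of gene trees.

    ``counts[t, s]`` is the number of gene trees resolving triple ``t``
    (taxa ``triples[t]``, indices into ``taxa``) with the taxon in slot
    ``s`` as the outsider.
    """

    taxa: list[str]
    triples: np.ndarray
    counts: np.ndarray

    @property
    def n_per_triple(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def for_triple(self, a: str, b: str, c: str) -> dict[str, int]:
        """Counts keyed by the outsider taxon of each rooted resolution."""
        idx = sorted(self.taxa.index(x) for x in (a, b, c))
        row = np.flatnonzero((self.triples == idx).all(axis=1))
        if len(row) != 1:
            raise KeyError(f"no such triple: {(a, b, c)}")
        r = int(row[0])
        return {self.taxa[self.triples[r, s]]: int(self.counts[r, s])
                for s in range(3)}


def triplet_slot_table(gene_trees, taxa: list[str]) -> np.ndarray:
    """(G, T) slot table; reusable for fast subset tallies."""
    n = len(taxa)
    triples = _triple_arrays(n)
    rows = []
    for gt in gene_trees:
        children, root, _ = from_dendropy(gt, taxa)
        M = mrca_depth_matrix(children, root, n)
        rows.append(_slots(M, triples))
    return np.vstack(rows) if rows else np.empty((0, len(triples)),
                                                 dtype=np.int8)


def _counts_from_slots(slot_table: np.ndarray, n_taxa: int,
                       idx=None) -> np.ndarray:
    sub = slot_table if idx is None else slot_table[np.asarray(idx)]
    T = sub.shape[1]
    counts = np.zeros((T, 3), dtype=np.int64)
    for s in range(3):
        counts[:, s] = (sub == s).sum(axis=0)
    return counts


def triplet_counts(gene_trees, taxa=None) -> TripletCounts:
    """Exhaustive rooted-triplet tally; unresolved triples are excluded
    from that triple's total, absent taxa leave their triples untouched."""
    taxa = _taxa_of(gene_trees, taxa)
    slot_table = triplet_slot_table(gene_trees, taxa)
    counts = _counts_from_slots(slot_table, len(taxa))
    return TripletCounts(taxa=taxa, triples=_triple_arrays(len(taxa)),
                         counts=counts)


def mpest_triplet_mle(n_matching: int, n_total: int,
                      t_max: float = T_MAX) -> float:
    """Closed-form MLE of a triple's internal branch length.

    Maximises the trinomial likelihood with matching probability
    ``1 - (2/3)exp(-t)``: ``t_hat = -ln(1.5 (1 - n1/N))``, clamped to
    ``[T_MIN, t_max]``.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    p1 = n_matching / n_total
    if p1 >= 1.0:
        return t_max
    t = -np.log(1.5 * (1.0 - p1))
    return float(np.clip(t, T_MIN, t_max))


def _pseudo_loglik(n1: np.ndarray, N: np.ndarray, t: np.ndarray) -> float:
    e = np.exp(-t)
    p1 = 1.0 - (2.0 / 3.0) * e
    palt = e / 3.0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = n1 * np.log(p1) + (N - n1) * np.log(palt)
    return float(np.where(N > 0, terms, 0.0).sum())


def _score_topology(children, root, n, triples, counts,
                    t_max: float = T_MAX) -> float:
    """Profile pseudo-log-likelihood of a rooted topology."""
    M = mrca_depth_matrix(children, root, n)
    d3 = _depth3(M, triples)
    slot = np.argmax(d3, axis=1)
    n1 = counts[np.arange(len(counts)), slot]
    N = counts.sum(axis=1)
    with np.errstate(divide="ignore"):
        t = -np.log(1.5 * np.clip(1.0 - n1 / np.maximum(N, 1), 1e-300, None))
    t = np.clip(t, T_MIN, t_max)
    return _pseudo_loglik(n1, N, t)


def mpest_score(species_tree: dendropy.Tree, counts: TripletCounts) -> float:
    """Pseudo-log-likelihood of a species tree with fixed branch lengths.

    The internal branch length of each triple is the coalescent-unit path
    length between the pair MRCA and the triple MRCA on the species tree.
    """
    taxa = counts.taxa
    children, root, blen = from_dendropy(species_tree, taxa)
    for v, b in blen.items():
        if v >= len(taxa) and v != root and b < 0:
            raise ValueError("negative internal branch length")
    n = len(taxa)
    # depth in coalescent units and in edge counts
    M_top = mrca_depth_matrix(children, root, n)
    depth_cu: dict[int, float] = {root: 0.0}
    stack = [root]
    while stack:
        v = stack.pop()
        if v in children:
            for c in children[v]:
                depth_cu[c] = depth_cu[v] + blen[c]
                stack.append(c)
    # map topological depth to cu depth via an MRCA-id matrix
    M_cu = _mrca_value_matrix(children, root, n, depth_cu)
    d3_top = _depth3(M_top, counts.triples)
    d3_cu = _depth3(M_cu, counts.triples)
    slot = np.argmax(d3_top, axis=1)
    rows = np.arange(len(counts.triples))
    deep = d3_cu[rows, slot]
    shallow = np.min(d3_cu, axis=1)
    t = np.maximum(deep - shallow, 0.0)
    n1 = counts.counts[rows, slot]
    N = counts.counts.sum(axis=1)
    return _pseudo_loglik(n1, N, t)


def _mrca_value_matrix(children, root, n, value: dict) -> np.ndarray:
    from ._tree import _fill_cross_pairs, _leaf_lists
    M = np.full((n, n), -1.0)
    leaves = _leaf_lists(children, root, n)
    stack = [root]
    while stack:
        v = stack.pop()
        if v in children:
            _fill_cross_pairs(M, children, v, leaves, value[v])
            stack.extend(children[v])
    return M


# ---------------------------------------------------------------------------
# results container

@dataclass
class SpeciesTreeResult:
    """Estimated species tree plus fit diagnostics."""

    tree: dendropy.Tree
    method: str
    taxa: list[str]
    n_gene_trees: int
    log_pseudolikelihood: float | None = None
    distance_matrix: np.ndarray | None = None
    unresolved: bool = False
    bootstrap_replicates: int = 0

    def rf_to(self, other, rooted: bool = True) -> RFResult:
        tree = other.tree if isinstance(other, SpeciesTreeResult) else other
        return rf_distance(self.tree, tree, rooted=rooted)

    @property
    def mean_bootstrap(self) -> float:
        return mean_bootstrap(self.tree)

    def newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()

    def write(self, path) -> None:
        self.tree.write(path=str(path), schema="newick")

    def summary(self) -> str:
        lines = [
            f"{self.method} species tree",
            f"  taxa:             {len(self.taxa)}",
            f"  gene trees:       {self.n_gene_trees}",
        ]
        if self.log_pseudolikelihood is not None:
            lines.append(
                f"  log pseudo-lik.:  {self.log_pseudolikelihood:.4f}")
        if self.bootstrap_replicates:
            lines.append(
                f"  mean bootstrap:   {self.mean_bootstrap:.1f}"
                f"  ({self.bootstrap_replicates} replicates)")
        if self.unresolved:
            lines.append("  WARNING: flat pseudo-likelihood surface; "
                         "topology not uniquely resolved")
        lines.append("  topology:         " +
                     self.tree.as_string(
                         schema="newick", suppress_edge_lengths=True,
                         suppress_rooting=True).strip())
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# STAR

def star_rank_matrices(gene_trees, taxa: list[str]) -> np.ndarray:
    """(G, n, n) stack of per-gene-tree rank matrices (-1 where absent)."""
    n = len(taxa)
    mats = np.empty((len(gene_trees), n, n))
    for g, gt in enumerate(gene_trees):
        children, root, _ = from_dendropy(gt, taxa)
        mats[g] = star_rank_matrix(children, root, n)
    return mats


def star_distance_from(mats: np.ndarray, idx=None) -> np.ndarray:
    sub = mats if idx is None else mats[np.asarray(idx)]
    present = sub >= 0
    count = present.sum(axis=0)
    np.fill_diagonal(count, 1)
    if (count == 0).any():
        raise ValueError(
            "a taxon pair is never together in any gene tree; "
            "STAR distance undefined")
    total = np.where(present, sub, 0.0).sum(axis=0)
    D = 2.0 * total / count
    np.fill_diagonal(D, 0.0)
    return D


class STAR:
    """Species tree from average gene-tree coalescence ranks.

    Parameters
    ----------
    gene_trees : list of rooted dendropy trees (taxa may be missing
        from individual trees, but every pair must co-occur somewhere).
    outgroup : label or list of labels used to root the NJ tree; with no
        outgroup the rank-distance tree is midpoint-rooted (rank distances
        are near-ultrametric, so the midpoint sits at the deepest split).
    """

    def __init__(self, gene_trees, outgroup=None, taxa=None):
        if not gene_trees:
            raise ValueError("need at least one gene tree")
        self.gene_trees = list(gene_trees)
        self.outgroup = outgroup
        self.taxa = _taxa_of(self.gene_trees, taxa)
        self._mats = None

    def distance_matrix(self) -> np.ndarray:
        if self._mats is None:
            self._mats = star_rank_matrices(self.gene_trees, self.taxa)
        return star_distance_from(self._mats)

    def fit(self, bootstrap_replicates: int = 0,
            seed: int = 0) -> SpeciesTreeResult:
        D = self.distance_matrix()
        tree = self._tree_from(D)
        result = SpeciesTreeResult(
            tree=tree, method="STAR", taxa=self.taxa,
            n_gene_trees=len(self.gene_trees), distance_matrix=D,
            bootstrap_replicates=bootstrap_replicates)
        if bootstrap_replicates > 0:
            rng = np.random.default_rng(seed)
            g = len(self.gene_trees)
            reps = []
            for _ in range(bootstrap_replicates):
                idx = rng.integers(0, g, size=g)
                reps.append(self._tree_from(star_distance_from(self._mats,
                                                               idx)))
            annotate_support(tree, reps)
        return result

    def _tree_from(self, D: np.ndarray) -> dendropy.Tree:
        tree = nj_tree(self.taxa, D)
        if self.outgroup is not None:
            return root_with_outgroup(tree, self.outgroup)
        tree.reroot_at_midpoint()
        tree.is_rooted = True
        return tree


# ---------------------------------------------------------------------------
# MP-EST

class MPEST:
    """Maximum pseudo-likelihood species tree from rooted triplets.

    NNI hill-climbing over rooted topologies with per-triple branch lengths
    profiled out in closed form; random restarts (plus the STAR topology as
    a warm start when available) guard against local optima.  Deterministic
    for a fixed seed.
    """

    def __init__(self, gene_trees=None, counts: TripletCounts | None = None,
                 outgroup=None, taxa=None):
        if counts is None:
            if not gene_trees:
                raise ValueError("provide gene trees or triplet counts")
            counts = triplet_counts(gene_trees, taxa=taxa)
        self.counts = counts
        self.gene_trees = list(gene_trees) if gene_trees else None
        self.outgroup = outgroup
        self.taxa = counts.taxa

    def fit(self, n_starts: int = 5, seed: int = 0,
            start_tree: dendropy.Tree | None = None,
            t_max: float = T_MAX) -> SpeciesTreeResult:
        n = len(self.taxa)
        triples, counts = self.counts.triples, self.counts.counts
        rng = np.random.default_rng(seed)
        starts = []
        if start_tree is not None:
            ch, root, _ = from_dendropy(start_tree, self.taxa)
            starts.append((ch, root))
        elif self.gene_trees:
            try:
                st = STAR(self.gene_trees, outgroup=self.outgroup,
                          taxa=self.taxa).fit()
                ch, root, _ = from_dendropy(st.tree, self.taxa)
                starts.append((ch, root))
            except ValueError:
                pass
        while len(starts) < max(n_starts, 1):
            starts.append(random_topology(n, rng))

        def clade_key(ch, root):
            from ._tree import _leaf_lists
            leaves = _leaf_lists(ch, root, n)
            return frozenset(frozenset(leaves[v]) for v in ch)

        best = None
        near_tie = False
        for ch, root in starts:
            ch, score = self._climb(ch, root, n, triples, counts, t_max)
            if best is None or score > best[1] + 1e-9:
                best = (ch, score, root)
                near_tie = False
            elif (abs(score - best[1]) <= 1e-9 and
                  clade_key(ch, root) != clade_key(best[0], best[2])):
                near_tie = True
        ch, score, root = best
        if self.counts.counts.sum() == 0:
            near_tie = True
        blen = self._branch_lengths(ch, root, n, triples, counts, t_max)
        tree = to_dendropy(ch, root, self.taxa, blen=blen)
        return SpeciesTreeResult(
            tree=tree, method="MP-EST", taxa=self.taxa,
            n_gene_trees=(len(self.gene_trees) if self.gene_trees
                          else int(self.counts.n_per_triple.max(initial=0))),
            log_pseudolikelihood=score, unresolved=near_tie)

    def _climb(self, ch, root, n, triples, counts, t_max):
        score = _score_topology(ch, root, n, triples, counts, t_max)
        while True:
            best_n, best_s = None, score
            for nb in nni_neighbors(ch, root):
                s = _score_topology(nb, root, n, triples, counts, t_max)
                if s > best_s + 1e-9:
                    best_n, best_s = nb, s
            if best_n is None:
                return ch, score
            ch, score = best_n, best_s

    def _branch_lengths(self, ch, root, n, triples, counts, t_max):
        parent = {}
        for u, kids in ch.items():
            for c in kids:
                parent[c] = u
        node_id = {v: float(v) for v in list(ch) + list(range(n))}
        M_id = _mrca_value_matrix(ch, root, n, node_id)
        M_top = mrca_depth_matrix(ch, root, n)
        d3 = _depth3(M_top, triples)
        slot = np.argmax(d3, axis=1)
        rows = np.arange(len(triples))
        i, j, k = triples[:, 0], triples[:, 1], triples[:, 2]
        pair_m = np.stack([M_id[j, k], M_id[i, k], M_id[i, j]], axis=1)
        deep_node = pair_m[rows, slot].astype(int)
        # MRCA of the whole triple = the min-depth pair MRCA
        shallow_node = pair_m[rows, np.argmin(d3, axis=1)].astype(int)
        n1 = counts[rows, slot]
        N = counts.sum(axis=1)
        acc: dict[int, list[float]] = {}
        for r in rows:
            v, u = int(deep_node[r]), int(shallow_node[r])
            if N[r] > 0 and parent.get(v) == u:
                acc.setdefault(v, []).append(
                    mpest_triplet_mle(int(n1[r]), int(N[r]), t_max))
        blen = {}
        for v in ch:
            if v == root:
                continue
            blen[v] = float(np.mean(acc[v])) if v in acc else T_MIN
        return blen


# ---------------------------------------------------------------------------
# tree-of-trees

def metatree(labelled_trees, rooted: bool = True) -> dendropy.Tree:
    """MetaTree-style tree-of-trees: NJ on pairwise RF distances.

    ``labelled_trees`` is a list of (label, tree); trees are pruned to the
    shared taxon set before comparison.  The returned Newick tree has the
    labels as leaves.
    """
    labelled_trees = list(labelled_trees)
    if len(labelled_trees) < 3:
        raise ValueError("tree-of-trees needs at least 3 trees")
    labels = [lab for lab, _ in labelled_trees]
    if len(set(labels)) != len(labels):
        raise ValueError("tree labels must be unique")
    m = len(labelled_trees)
    D = np.zeros((m, m))
    for a in range(m):
        for b in range(a + 1, m):
            res = rf_distance(labelled_trees[a][1], labelled_trees[b][1],
                              rooted=rooted, prune_to_common=True)
            D[a, b] = D[b, a] = res.rf
    return nj_tree(labels, D)
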