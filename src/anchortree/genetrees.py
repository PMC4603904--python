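"""Distance-based gene-tree estimation for desk-scale analyses.

A Jukes-Cantor-corrected distance matrix resolved by neighbor joining, with
optional nonparametric (site-resampling) bootstrap support.  Externally built
maximum-likelihood gene trees can be imported as Newick instead
(:func:`read_gene_trees`); this estimator exists so the whole pipeline runs
without external programs.
"""

from __future__ import annotations

import dendropy
import numpy as np

from .treeops import annotate_support, nj_tree, root_with_outgroup

__all__ = ["jc_distance_matrix", "estimate_gene_tree", "read_gene_trees",
           "write_gene_trees"]

_MAX_D = 5.0  # cap for saturated (p >= 3/4) distances


def jc_distance_matrix(names: list[str], seqs: list[str]) -> np.ndarray:
    """Jukes-Cantor distances over shared unambiguous sites."""
    arrs = [np.frombuffer(s.upper().encode(), dtype=np.uint8) for s in seqs]
    if len({len(a) for a in arrs}) > 1:
        raise ValueError("alignment rows have unequal lengths")
    acgt = [np.isin(a, np.frombuffer(b"ACGT", dtype=np.uint8)) for a in arrs]
    m = len(names)
    D = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            both = acgt[i] & acgt[j]
            n = int(both.sum())
            if n == 0:
                raise ValueError(
                    f"{names[i]} and {names[j]} share no comparable sites")
            p = float((arrs[i][both] != arrs[j][both]).mean())
            if p >= 0.75:
                d = _MAX_D
            else:
                d = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
            D[i, j] = D[j, i] = min(d, _MAX_D)
    return D


def estimate_gene_tree(alignment, outgroup=None,
                       bootstrap_replicates: int = 0,
                       seed: int = 0) -> dendropy.Tree:
    """NJ gene tree from an alignment (dict name -> sequence or row list).

    Rooted by ``outgroup`` when given.  With ``bootstrap_replicates`` > 0,
    alignment columns are resampled with replacement and internal nodes are
    labelled with clade support in percent.
    """
    if isinstance(alignment, dict):
        rows = sorted(alignment.items())
    else:
        rows = [(n, s) for n, s in alignment]
    if len(rows) < 3:
        raise ValueError("gene-tree estimation needs at least 3 sequences")
    names = [n for n, _ in rows]
    seqs = [s for _, s in rows]
    tree = nj_tree(names, jc_distance_matrix(names, seqs))
    if outgroup is not None:
        tree = root_with_outgroup(tree, outgroup)
    else:
        tree.is_rooted = True
    if bootstrap_replicates > 0:
        rng = np.random.default_rng(seed)
        ncol = len(seqs[0])
        reps = []
        for _ in range(bootstrap_replicates):
            cols = rng.integers(0, ncol, size=ncol)
            bseqs = ["".join(s[c] for c in cols) for s in seqs]
            bt = nj_tree(names, jc_distance_matrix(names, bseqs))
            if outgroup is not None:
                bt = root_with_outgroup(bt, outgroup)
            reps.append(bt)
        annotate_support(tree, reps)
    return tree


def read_gene_trees(path, taxon_namespace=None) -> list[dendropy.Tree]:
    """Read rooted Newick gene trees (one per line/statement)."""
    trees = dendropy.TreeList.get(path=str(path), schema="newick",
                                  taxon_namespace=taxon_namespace,
                                  rooting="default-rooted")
    return list(trees)


def write_gene_trees(trees, path) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.as_string(schema="newick", suppress_rooting=True))
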