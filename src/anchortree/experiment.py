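"""Locus-subsampling experiment: how many loci does a species-tree method need?

Random locus subsets of increasing size (default 3, 4, 5, 10, 25, 50, 100,
200; five replicates each, drawn independently so subsets may overlap) are
analysed with STAR and/or MP-EST; each replicate tree is scored by its
Robinson-Foulds distance (% of the rooted maximum 2(n-2)) to a reference
tree (by default the full-data STAR tree) and by its mean bootstrap support
from a multilocus (gene-tree resampling) bootstrap.  Per (method, size) the
report carries the replicate RF values, their mean, the coefficient of
variation, and the mean bootstrap; the plateau size is the smallest subset
size whose CV is minimal — the point where adding loci stops improving
consistency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .speciestree import (MPEST, STAR, SpeciesTreeResult, TripletCounts,
                          _counts_from_slots, _triple_arrays,
                          star_distance_from, star_rank_matrices,
                          triplet_slot_table)
from .treeops import annotate_support, mean_bootstrap, rf_distance

__all__ = [
    "SubsampleDesign",
    "ExperimentReport",
    "SubsamplingExperiment",
    "subsample_loci",
    "coefficient_of_variation",
]

DEFAULT_SIZES = (3, 4, 5, 10, 25, 50, 100, 200)


@dataclass
class SubsampleDesign:
    subset_sizes: tuple = DEFAULT_SIZES
    replicates: int = 5
    seed: int = 0
    reference_tree: dendropy.Tree | None = None
    methods: tuple = ("STAR", "MPEST")
    outgroup: str | list | None = None
    bootstrap_replicates: int = 50
    mpest_starts: int = 2
    rooted_rf: bool = True

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def subsample_loci(loci, size: int, seed: int, replicate: int = 0) -> list:
    """Uniform subset without replacement; deterministic per (seed, size,
    replicate).  Replicates are drawn independently and may overlap."""
    loci = list(loci)
    if size > len(loci):
        raise ValueError(f"subset size {size} exceeds {len(loci)} loci")
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed),
                               spawn_key=(int(size), int(replicate))))
    idx = rng.choice(len(loci), size=size, replace=False)
    return [loci[i] for i in sorted(idx)]


def coefficient_of_variation(values) -> float:
    """Sample SD (n-1 denominator) over the mean; NaN when the mean is zero
    but the spread is not (undefined)."""
    vals = np.asarray(list(values), dtype=float)
    if len(vals) < 2:
        raise ValueError("CV needs at least two values")
    sd = float(vals.std(ddof=1))
    mean = float(vals.mean())
    if mean == 0.0:
        return 0.0 if sd == 0.0 else float("nan")
    return sd / mean


@dataclass
class ExperimentReport:
    """Per-replicate table plus aggregates, the machine-readable analogue of
    an RF/bootstrap-versus-locus-number figure."""

    table: pd.DataFrame
    design: SubsampleDesign
    reference_tree: dendropy.Tree
    skipped: list = field(default_factory=list)

    def aggregate(self) -> pd.DataFrame:
        rows = []
        for (method, size), grp in self.table.groupby(["method", "size"]):
            cv = coefficient_of_variation(grp["rf_percent"]) \
                if len(grp) > 1 else 0.0
            rows.append({
                "method": method, "size": size,
                "mean_rf_percent": grp["rf_percent"].mean(),
                "cv_rf": 0.0 if np.isnan(cv) else cv,
                "cv_defined": not np.isnan(cv),
                "mean_bootstrap": grp["mean_bootstrap"].mean(),
            })
        return pd.DataFrame(rows).sort_values(["method", "size"],
                                              ignore_index=True)

    def plateau_size(self, method: str) -> int:
        agg = self.aggregate()
        sub = agg[agg["method"] == method]
        if sub.empty:
            raise KeyError(f"no results for method {method!r}")
        min_cv = sub["cv_rf"].min()
        return int(sub[sub["cv_rf"] <= min_cv + 1e-12]["size"].min())

    def summary(self) -> str:
        lines = ["locus-subsampling experiment",
                 f"  replicates per size: {self.design.replicates}"]
        agg = self.aggregate()
        lines.append("  method   size  mean RF%   CV(RF)  mean bootstrap")
        for _, r in agg.iterrows():
            lines.append(
                f"  {r['method']:<7} {int(r['size']):>5}  "
                f"{r['mean_rf_percent']:>7.2f}  {r['cv_rf']:>7.3f}  "
                f"{r['mean_bootstrap']:>8.1f}")
        for method in agg["method"].unique():
            lines.append(f"  plateau ({method}): "
                         f"{self.plateau_size(method)} loci")
        if self.skipped:
            lines.append(f"  skipped methods: {', '.join(self.skipped)}")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def plot(self, path=None):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        agg = self.aggregate()
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
        for method, grp in agg.groupby("method"):
            ax1.plot(grp["size"], grp["mean_rf_percent"], "o-", label=method)
            ax2.plot(grp["size"], grp["mean_bootstrap"], "o-", label=method)
        for ax, ylab in ((ax1, "mean RF % to reference"),
                         (ax2, "mean bootstrap")):
            ax.set_xscale("log")
            ax.set_xlabel("number of loci")
            ax.set_ylabel(ylab)
            ax.legend()
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig


class SubsamplingExperiment:
    """Run the subsampling design over a fixed set of gene trees.

    ``gene_trees`` is a list of rooted dendropy trees (one per locus).  The
    reference tree defaults to the STAR tree from all loci.  Species-tree
    node support is estimated by resampling gene trees with replacement and
    re-estimating with the rank-distance (STAR) engine, which makes the
    bootstrap affordable for both methods.
    """

    def __init__(self, gene_trees, design: SubsampleDesign | None = None,
                 taxa=None):
        self.design = design or SubsampleDesign()
        self.gene_trees = list(gene_trees)
        if not self.gene_trees:
            raise ValueError("no gene trees supplied")
        star = STAR(self.gene_trees, outgroup=self.design.outgroup, taxa=taxa)
        self.taxa = star.taxa
        self._star = star
        self._mats = star_rank_matrices(self.gene_trees, self.taxa)
        self._slot_table = None  # built lazily when MPEST is requested

    def _star_tree(self, idx=None) -> dendropy.Tree:
        D = star_distance_from(self._mats, idx)
        return self._star._tree_from(D)

    def _mpest_result(self, idx, seed) -> SpeciesTreeResult:
        if self._slot_table is None:
            self._slot_table = triplet_slot_table(self.gene_trees, self.taxa)
        counts = TripletCounts(
            taxa=self.taxa, triples=_triple_arrays(len(self.taxa)),
            counts=_counts_from_slots(self._slot_table, len(self.taxa), idx))
        model = MPEST(counts=counts, outgroup=self.design.outgroup)
        return model.fit(n_starts=self.design.mpest_starts, seed=seed,
                         start_tree=self._star_tree(idx))

    def run(self) -> ExperimentReport:
        design = self.design
        reference = design.reference_tree or self._star_tree()
        n_loci = len(self.gene_trees)
        methods, skipped = [], []
        for m in design.methods:
            (methods if m.upper().replace("-", "") in ("STAR", "MPEST")
             else skipped).append(m)
        rows = []
        for size in design.subset_sizes:
            if size > n_loci:
                raise ValueError(
                    f"subset size {size} exceeds {n_loci} available loci")
            for rep in range(design.replicates):
                idx = subsample_loci(range(n_loci), size, design.seed, rep)
                boot_trees = self._bootstrap_trees(idx, design, rep)
                for method in methods:
                    key = method.upper().replace("-", "")
                    if key == "STAR":
                        tree = self._star_tree(idx)
                    else:
                        seed = int(np.random.SeedSequence(
                            entropy=design.seed,
                            spawn_key=(size, rep, 7)).generate_state(1)[0]
                            % (2**31))
                        tree = self._mpest_result(idx, seed).tree
                    rf = rf_distance(tree, reference,
                                     rooted=design.rooted_rf)
                    mb = np.nan
                    if boot_trees:
                        annotate_support(tree, boot_trees)
                        mb = mean_bootstrap(tree)
                    rows.append({"method": method, "size": size,
                                 "replicate": rep,
                                 "rf_percent": rf.percent,
                                 "mean_bootstrap": mb})
        table = pd.DataFrame(rows)
        return ExperimentReport(table=table, design=design,
                                reference_tree=reference, skipped=skipped)

    def _bootstrap_trees(self, idx, design, rep):
        if design.bootstrap_replicates <= 0:
            return []
        rng = np.random.default_rng(np.random.SeedSequence(
            entropy=design.seed, spawn_key=(len(idx), rep, 13)))
        idx = np.asarray(idx)
        out = []
        for _ in range(design.bootstrap_replicates):
            res = idx[rng.integers(0, len(idx), size=len(idx))]
            out.append(self._star_tree(res))
        return out
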