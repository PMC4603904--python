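"""Synthetic anchored-enrichment datasets with known truth.

The generator emulates the statistical structure the downstream pipeline
assumes: a Yule species tree with branch lengths in coalescent units, gene
trees drawn from the multispecies coalescent (one haploid lineage per species
per locus), sequences evolved under Jukes-Cantor or HKY, and paired 150 bp
Illumina-style reads from 150-350 bp fragments with quality-annotated errors.
Locus lengths follow a truncated log-normal matched to a 424-2156 bp range
with mean 1374 bp; a configurable fraction of taxon-locus cells is deleted to
emulate missing data (default 1.5 %).  Optional paralogous locus copies
(diverged along an elongated root branch) and unrelated contaminant reads give
the orthology and cluster filters something real to reject.

Every operation is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from ._seq import BASES, revcomp
from ._tree import to_dendropy, from_dendropy
from .merge import ReadPair

__all__ = [
    "SubstitutionModel",
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_species_tree",
    "simulate_gene_trees",
    "simulate_sequences",
    "simulate_reads",
    "simulate_dataset",
]


@dataclass(frozen=True)
class SubstitutionModel:
    """Nucleotide substitution model for sequence simulation.

    ``rate`` converts the gene-tree branch lengths (coalescent units) into
    expected substitutions per site; with ``rate=1`` branch lengths are taken
    as substitutions per site directly.
    """

    name: str = "JC"
    kappa: float = 2.0
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    rate: float = 1.0

    def __post_init__(self):
        if self.name not in ("JC", "HKY"):
            raise ValueError("substitution model must be 'JC' or 'HKY'")
        if abs(sum(self.base_freqs) - 1.0) > 1e-9 or min(self.base_freqs) < 0:
            raise ValueError("base frequencies must be a probability vector")
        if self.rate < 0:
            raise ValueError("rate must be non-negative")

    def freqs(self) -> np.ndarray:
        if self.name == "JC":
            return np.full(4, 0.25)
        return np.asarray(self.base_freqs, dtype=float)

    def transition_matrix(self, d: float) -> np.ndarray:
        """P(child | parent) for a branch of ``d`` expected subs/site."""
        if d < 0:
            raise ValueError("negative branch length")
        if self.name == "JC":
            p = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
            P = np.full((4, 4), p / 3.0)
            np.fill_diagonal(P, 1.0 - p)
            return P
        pi = self.freqs()
        # HKY rate matrix: transitions (A<->G, C<->T) get kappa
        Q = np.zeros((4, 4))
        transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A,C,G,T order
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                Q[i, j] = pi[j] * (self.kappa if (i, j) in transitions else 1.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mean_rate = -np.dot(pi, np.diag(Q))
        Q /= mean_rate
        return linalg.expm(Q * d)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset generator."""

    n_species: int = 25
    n_loci: int = 377
    locus_length_range: tuple[int, int] = (424, 2156)
    mean_locus_length: float = 1374.0
    internal_branch_scale: float = 1.0
    substitution_model: SubstitutionModel = field(
        default_factory=lambda: SubstitutionModel(rate=0.02))
    read_length: int = 150
    fragment_size_range: tuple[int, int] = (150, 350)
    per_base_error_rate: float = 0.005
    coverage: float = 20.0
    missing_fraction: float = 0.015
    paralog_rate: float = 0.0
    contaminant_rate: float = 0.0
    paralog_divergence: float = 0.25
    reference_divergence: float = 0.05
    rate_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("per_base_error_rate", "missing_fraction",
                     "paralog_rate", "contaminant_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.locus_length_range
        if not lo <= self.mean_locus_length <= hi:
            raise ValueError("locus length range must bracket the mean")
        if self.read_length <= 0 or self.coverage <= 0:
            raise ValueError("read_length and coverage must be positive")
        if self.fragment_size_range[0] > self.fragment_size_range[1]:
            raise ValueError("fragment size range inverted")

    def species_labels(self) -> list[str]:
        width = len(str(self.n_species))
        return [f"sp{i + 1:0{width}d}" for i in range(self.n_species)]


# ---------------------------------------------------------------------------
# species tree (Yule) and gene trees (multispecies coalescent)

def simulate_species_tree(config: SimulationConfig,
                          seed: int | None = None) -> dendropy.Tree:
    """Pure-birth (Yule) species tree with coalescent-unit branch lengths.

    Lineages split at rate 1; all waiting times are multiplied by
    ``internal_branch_scale`` so the scale directly controls the expected
    depth of incomplete lineage sorting.  The returned tree is rooted,
    binary and ultrametric.
    """
    n = config.n_species
    if n < 3:
        raise ValueError("n_species must be at least 3")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    labels = config.species_labels()

    birth: dict[int, float] = {0: 0.0}
    split: dict[int, float] = {}
    children: dict[int, tuple[int, int]] = {}
    active = [0]
    next_tmp = 1
    t = 0.0
    while len(active) < n:
        k = len(active)
        t += rng.exponential(1.0 / k)
        v = active.pop(int(rng.integers(k)))
        split[v] = t
        a, b = next_tmp, next_tmp + 1
        next_tmp += 2
        children[v] = (a, b)
        birth[a] = birth[b] = t
        active.extend([a, b])
    t_final = t + rng.exponential(1.0 / n)

    # relabel: leaves 0..n-1 (creation order), internals n..2n-2
    leaf_ids = {tmp: i for i, tmp in enumerate(sorted(active))}
    internal_ids = {tmp: n + i for i, tmp in enumerate(sorted(children))}
    remap = {**leaf_ids, **internal_ids}
    ch = {remap[v]: tuple(remap[c] for c in kids) for v, kids in children.items()}
    scale = config.internal_branch_scale
    blen = {}
    for tmp, new in remap.items():
        death = split.get(tmp, t_final)
        blen[new] = (death - birth[tmp]) * scale
    root = remap[0]
    blen[root] = 0.0
    return to_dendropy(ch, root, labels, blen=blen)


def min_internal_branch(tree: dendropy.Tree) -> float:
    """Shortest internal (non-root, non-terminal) branch length."""
    vals = [nd.edge.length for nd in tree.preorder_internal_node_iter()
            if nd is not tree.seed_node and nd.edge.length is not None]
    if not vals:
        raise ValueError("tree has no internal branches")
    return float(min(vals))


def scale_to_min_internal(tree: dendropy.Tree,
                          min_length: float) -> dendropy.Tree:
    """Globally rescale branch lengths so the shortest internal branch
    equals ``min_length`` coalescent units (shape and ultrametricity are
    preserved; only the overall depth changes)."""
    cur = min_internal_branch(tree)
    if cur <= 0:
        raise ValueError("tree has a zero-length internal branch")
    factor = min_length / cur
    out = tree.clone(depth=1)
    for nd in out.preorder_node_iter():
        if nd.edge.length is not None:
            nd.edge.length *= factor
    return out


def _node_ages(children: dict, root: int, blen: dict, n_leaves: int) -> dict[int, float]:
    ages: dict[int, float] = {}

    def rec(v: int) -> float:
        if v < n_leaves:
            ages[v] = 0.0
        else:
            ages[v] = max(rec(c) + blen[c] for c in children[v])
        return ages[v]

    rec(root)
    return ages


def _msc_one_tree(children, root, blen, ages, n_leaves, rng):
    """One gene tree under the MSC with a single lineage sampled per species."""
    gchildren: dict[int, tuple[int, int]] = {}
    gheight: dict[int, float] = {i: 0.0 for i in range(n_leaves)}
    next_id = [n_leaves]

    def coalesce(lineages: list[int], t0: float, t1: float) -> list[int]:
        t = t0
        while len(lineages) > 1:
            k = len(lineages)
            t += rng.exponential(2.0 / (k * (k - 1)))
            if t > t1:
                break
            i, j = rng.choice(k, size=2, replace=False)
            a, b = lineages[int(i)], lineages[int(j)]
            new = next_id[0]
            next_id[0] += 1
            gchildren[new] = (a, b)
            gheight[new] = t
            lineages = [x for x in lineages if x not in (a, b)] + [new]
        return lineages

    def rec(v: int) -> list[int]:
        if v < n_leaves:
            lineages = [v]
        else:
            lineages = []
            for c in children[v]:
                lineages.extend(rec(c))
        if v == root:
            return coalesce(lineages, ages[v], np.inf)
        return coalesce(lineages, ages[v], ages[v] + blen[v])

    remaining = rec(root)
    assert len(remaining) == 1
    groot = remaining[0]
    gblen = {}
    parent = {}
    for u, kids in gchildren.items():
        for c in kids:
            parent[c] = u
    for v in gheight:
        gblen[v] = gheight[parent[v]] - gheight[v] if v in parent else 0.0
    return gchildren, groot, gblen


def simulate_gene_trees(species_tree: dendropy.Tree, n_loci: int,
                        seed: int = 0) -> list[dendropy.Tree]:
    """Gene trees under the multispecies coalescent within ``species_tree``.

    The species tree must be rooted with branch lengths in coalescent units;
    one haploid lineage enters per species, and lineages within a species-tree
    branch coalesce at the standard rate of 1 per pair per coalescent unit.
    """
    labels = sorted(t.label for t in species_tree.taxon_namespace)
    children, root, blen = from_dendropy(species_tree, labels)
    n = len(labels)
    ages = _node_ages(children, root, blen, n)
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace(labels)
    out = []
    for _ in range(n_loci):
        gch, groot, gblen = _msc_one_tree(children, root, blen, ages, n, rng)
        out.append(to_dendropy(gch, groot, labels, blen=gblen,
                               taxon_namespace=tns))
    return out


# ---------------------------------------------------------------------------
# sequences

def _mutate(seq_idx: np.ndarray, P: np.ndarray, rng) -> np.ndarray:
    cum = np.cumsum(P, axis=1)
    out = np.empty_like(seq_idx)
    u = rng.random(seq_idx.shape[0])
    for s in range(4):
        m = seq_idx == s
        if m.any():
            out[m] = np.searchsorted(cum[s], u[m], side="right")
    return np.minimum(out, 3)


def _evolve(children, root, blen_subs, length, model, rng, root_idx=None):
    """Evolve sequences down a tree; returns ({leaf: idx array}, root idx array)."""
    if root_idx is None:
        root_idx = rng.choice(4, size=length, p=model.freqs())
    states = {root: root_idx}
    leaves = {}
    stack = [root]
    while stack:
        v = stack.pop()
        if v in children:
            for c in children[v]:
                P = model.transition_matrix(blen_subs[c])
                states[c] = _mutate(states[v], P, rng)
                stack.append(c)
        else:
            leaves[v] = states[v]
    return leaves, root_idx


_BASE_ARR = np.frombuffer(BASES.encode(), dtype=np.uint8)


def _idx_to_str(idx: np.ndarray) -> str:
    return _BASE_ARR[idx].tobytes().decode("ascii")


def simulate_sequences(gene_tree: dendropy.Tree, length: int,
                       model: SubstitutionModel | None = None,
                       seed: int = 0) -> dict[str, str]:
    """Aligned sequences (one per tip) evolved along ``gene_tree``.

    Branch lengths are multiplied by ``model.rate`` to obtain expected
    substitutions per site.  No indels are introduced, so the returned
    sequences are positionally homologous.
    """
    if length <= 0:
        raise ValueError("sequence length must be positive")
    model = model or SubstitutionModel()
    labels = sorted(lf.taxon.label for lf in gene_tree.leaf_node_iter())
    children, root, blen = from_dendropy(gene_tree, labels)
    blen_subs = {v: b * model.rate for v, b in blen.items()}
    rng = np.random.default_rng(seed)
    leaves, _ = _evolve(children, root, blen_subs, length, model, rng)
    return {labels[i]: _idx_to_str(arr) for i, arr in sorted(leaves.items())}


# ---------------------------------------------------------------------------
# reads

_PHRED_OK = (30, 41)
_PHRED_ERR = (10, 21)


def _read_with_errors(seq: str, error_rate: float, rng) -> tuple[str, np.ndarray]:
    idx = np.array([BASES.index(c) for c in seq], dtype=np.int64)
    qual = rng.integers(*_PHRED_OK, size=len(seq))
    if error_rate > 0:
        err = rng.random(len(seq)) < error_rate
        if err.any():
            shift = rng.integers(1, 4, size=int(err.sum()))
            idx[err] = (idx[err] + shift) % 4
            qual[err] = rng.integers(*_PHRED_ERR, size=int(err.sum()))
    return _idx_to_str(idx), qual


def _expected_read_bases(config: SimulationConfig) -> float:
    lo, hi = config.fragment_size_range
    sizes = np.arange(lo, hi + 1)
    return float(np.minimum(2 * config.read_length, sizes).mean())


def simulate_reads(locus_sequences: dict[str, dict[str, str]],
                   config: SimulationConfig,
                   seed: int = 0) -> tuple[dict[str, list[ReadPair]], pd.DataFrame]:
    """Paired reads from fragments of the given per-locus, per-sample sequences.

    Returns a dict mapping sample to its read pairs, and a truth table with
    one row per pair recording source locus, fragment coordinates and copy
    label (locus ids containing ``"|paralog"`` or ``"contaminant"`` pass
    through, so injected copies stay traceable).
    """
    if not locus_sequences:
        raise ValueError("no sequences supplied")
    rng = np.random.default_rng(seed)
    rl = config.read_length
    lo, hi = config.fragment_size_range
    mean_bases = _expected_read_bases(config)
    reads: dict[str, list[ReadPair]] = {}
    rows = []
    counters: dict[str, int] = {}
    for locus in sorted(locus_sequences):
        for sample in sorted(locus_sequences[locus]):
            seq = locus_sequences[locus][sample]
            L = len(seq)
            n_frags = max(1, int(round(L * config.coverage / mean_bases)))
            for _ in range(n_frags):
                fl = int(rng.integers(lo, hi + 1))
                fl = min(fl, L)
                start = int(rng.integers(0, L - fl + 1))
                frag = seq[start:start + fl]
                r1 = frag[:rl]
                r2 = revcomp(frag)[:rl]
                s1, q1 = _read_with_errors(r1, config.per_base_error_rate, rng)
                s2, q2 = _read_with_errors(r2, config.per_base_error_rate, rng)
                k = counters.get(sample, 0)
                counters[sample] = k + 1
                rid = f"{sample}.{k}"
                reads.setdefault(sample, []).append(
                    ReadPair(id=rid, seq1=s1, qual1=q1, seq2=s2, qual2=q2))
                rows.append({"read_id": rid, "sample": sample, "locus": locus,
                             "frag_start": start, "frag_len": fl})
    truth = pd.DataFrame(rows, columns=["read_id", "sample", "locus",
                                        "frag_start", "frag_len"])
    return reads, truth


# ---------------------------------------------------------------------------
# full datasets

def _locus_length_sampler(config: SimulationConfig):
    lo, hi = config.locus_length_range
    if lo == hi:
        return lambda rng: lo
    sigma = 0.3

    def trunc_mean(mu):
        d = stats.lognorm(s=sigma, scale=np.exp(mu))
        a, b = d.cdf(lo), d.cdf(hi)
        xs = np.linspace(lo, hi, 4001)
        pdf = d.pdf(xs) / (b - a)
        return np.trapezoid(xs * pdf, xs)

    mu = optimize.brentq(lambda m: trunc_mean(m) - config.mean_locus_length,
                         np.log(lo), np.log(hi))
    scale = np.exp(mu)

    def draw(rng):
        while True:
            x = scale * np.exp(sigma * rng.standard_normal())
            if lo <= x <= hi:
                return int(round(x))

    return draw


@dataclass
class SimulatedDataset:
    """A complete synthetic dataset plus the truth tables for every stage."""

    config: SimulationConfig
    species_tree: dendropy.Tree
    gene_trees: list
    locus_ids: list[str]
    locus_lengths: dict[str, int]
    alignments: dict[str, dict[str, str]]
    paralog_alignments: dict[str, dict[str, str]]
    reference_seqs: dict[str, str]
    missing: set
    reads: dict[str, list]
    truth: pd.DataFrame

    @property
    def paralog_loci(self) -> list[str]:
        return sorted(self.paralog_alignments)

    def probe_references(self, probe_length: int = 400):
        """Probe-region references (central window of a diverged relative)."""
        from .assembly import ProbeReference
        refs = []
        for locus in self.locus_ids:
            seq = self.reference_seqs[locus]
            L = len(seq)
            p = min(probe_length, L)
            start = (L - p) // 2
            mask = np.zeros(L, dtype=bool)
            mask[start:start + p] = True
            refs.append(ProbeReference(locus_id=locus, sequence=seq,
                                       conserved_site_mask=mask))
        return refs

    def write_reads(self, directory):
        from .merge import write_fastq_pairs
        import pathlib
        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for sample, pairs in sorted(self.reads.items()):
            write_fastq_pairs(pairs, d / f"{sample}_R1.fastq",
                              d / f"{sample}_R2.fastq")

    def write_truth(self, path):
        self.truth.to_csv(path, sep="\t", index=False)

    def write_trees(self, directory):
        import pathlib
        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.species_tree.write(path=str(d / "species_tree.nwk"),
                                schema="newick")
        with open(d / "gene_trees.nwk", "w") as fh:
            for t in self.gene_trees:
                fh.write(t.as_string(schema="newick"))


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate species tree, gene trees, sequences and reads in one pass."""
    rng = np.random.default_rng(config.seed)
    species_tree = simulate_species_tree(config, seed=int(rng.integers(2**31)))
    gene_trees = simulate_gene_trees(species_tree, config.n_loci,
                                     seed=int(rng.integers(2**31)))
    labels = config.species_labels()
    draw_len = _locus_length_sampler(config)
    model = config.substitution_model
    width = len(str(config.n_loci))
    locus_ids = [f"L{i + 1:0{width}d}" for i in range(config.n_loci)]
    locus_lengths = {}
    alignments: dict[str, dict[str, str]] = {}
    paralogs: dict[str, dict[str, str]] = {}
    refs: dict[str, str] = {}
    missing: set = set()

    for locus, gtree in zip(locus_ids, gene_trees):
        L = draw_len(rng)
        locus_lengths[locus] = L
        mult = (np.exp(config.rate_sigma * rng.standard_normal())
                if config.rate_sigma > 0 else 1.0)
        children, root, blen = from_dendropy(gtree, labels)
        blen_subs = {v: b * model.rate * mult for v, b in blen.items()}
        leaves, root_idx = _evolve(children, root, blen_subs, L, model, rng)
        aln = {labels[i]: _idx_to_str(a) for i, a in sorted(leaves.items())}
        # reference: a diverged relative of the locus, playing the probe role
        P = model.transition_matrix(config.reference_divergence)
        refs[locus] = _idx_to_str(_mutate(root_idx, P, rng))
        if config.paralog_rate > 0 and rng.random() < config.paralog_rate:
            P = model.transition_matrix(config.paralog_divergence)
            para_root = _mutate(root_idx, P, rng)
            pleaves, _ = _evolve(children, root, blen_subs, L, model, rng,
                                 root_idx=para_root)
            paralogs[locus] = {labels[i]: _idx_to_str(a)
                               for i, a in sorted(pleaves.items())}
        if config.missing_fraction > 0:
            for sp in labels:
                if rng.random() < config.missing_fraction:
                    missing.add((sp, locus))
                    del aln[sp]
                    if locus in paralogs and sp in paralogs[locus]:
                        del paralogs[locus][sp]
        alignments[locus] = aln

    read_source: dict[str, dict[str, str]] = {
        locus: dict(aln) for locus, aln in alignments.items()}
    for locus, paln in paralogs.items():
        read_source[f"{locus}|paralog"] = paln
    if config.contaminant_rate > 0:
        n_contam = max(1, int(round(config.contaminant_rate * config.n_loci)))
        for c in range(n_contam):
            L = draw_len(rng)
            seq = _idx_to_str(rng.choice(4, size=L, p=model.freqs()))
            victims = rng.choice(labels, size=max(1, len(labels) // 3),
                                 replace=False)
            read_source[f"contaminant{c + 1}"] = {sp: seq for sp in victims}

    reads, truth = simulate_reads(read_source, config,
                                  seed=int(rng.integers(2**31)))
    return SimulatedDataset(
        config=config, species_tree=species_tree, gene_trees=gene_trees,
        locus_ids=locus_ids, locus_lengths=locus_lengths,
        alignments=alignments, paralog_alignments=paralogs,
        reference_seqs=refs, missing=missing, reads=reads, truth=truth)


def triplet_match_frequency(t: float, n_loci: int, seed: int = 0) -> float:
    """Monte-Carlo frequency of gene trees matching a 3-species tree.

    Builds a rooted 3-taxon species tree whose single internal branch has
    length ``t`` coalescent units, simulates ``n_loci`` gene trees and returns
    the fraction whose rooted triplet matches the species tree.  The MSC
    closed form for this quantity is ``1 - (2/3) exp(-t)``.
    """
    nwk = f"((A:1.0,B:1.0):{t},C:{1.0 + t});"
    sp = dendropy.Tree.get(data=nwk, schema="newick")
    sp.is_rooted = True
    gts = simulate_gene_trees(sp, n_loci, seed=seed)
    match = 0
    for gt in gts:
        children, root, _ = from_dendropy(gt, ["A", "B", "C"])
        # the cherry is the pair under the non-root internal node
        for kids in children.values():
            if all(k < 3 for k in kids):
                match += set(kids) == {0, 1}
    return match / n_loci
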