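# Methods

`anchortree` re-creates, at desk scale, the computational path from raw
anchored-hybrid-enrichment read pairs to a multispecies-coalescent (MSC)
species tree, together with the locus-subsampling experiment that asks how
many loci a summary species-tree method needs.  This note records the models,
the numerical choices, and what the synthetic data do and do not emulate.

## Synthetic data generator

The generator is first-class code, not a fixture: every downstream stage is
validated against its truth tables.

**Species tree.** A pure-birth (Yule) tree grown forward in time at rate 1
until the requested number of tips, with one extra Exp(1/n) stretch so the
final cherry has positive length.  All branch lengths are multiplied by
`internal_branch_scale` and interpreted in coalescent units, so the scale
directly tunes the depth of incomplete lineage sorting (ILS).
`scale_to_min_internal` rescales a tree globally so its shortest internal
branch hits a chosen value; the validation scenarios use minimum internal
branches of 1.25 coalescent units ("clean" recovery runs) and 0.5
("moderate ILS" trend runs).

**Gene trees.** Standard MSC with one haploid lineage per species per locus
(the study design this emulates sampled one individual per taxon): lineages
entering a species-tree branch coalesce at rate 1 per pair per coalescent
unit; unresolved lineages continue into the parent branch, and everything
coalesces above the root.  The implementation is ~50 lines and is checked
against the closed form for rooted-triplet concordance,
P(match) = 1 − (2/3)e^(−t), at t ∈ {0, 0.5, 2} with 10⁴ loci (3 binomial
standard errors).  Writing the simulator in-package (rather than driving
msprime or dendropy's simulators) keeps branch lengths in coalescent units
end to end and gives bit-reproducible seeding at every stage; the closed
form provides the independent oracle.

**Sequences.** Jukes-Cantor or HKY (κ, base frequencies) with the rate
matrix normalised to one expected substitution per site per unit branch
length; `SubstitutionModel.rate` converts coalescent units to
substitutions/site (default 0.02 in full-dataset simulations, giving a few
percent pairwise divergence, in line with anchored loci).  No indels: the
simulated sequences are positionally homologous, which is what lets
consensus accuracy be scored exactly.

**Locus lengths.** Truncated log-normal (σ = 0.3 on the log scale, location
solved numerically) so that the minimum/mean/maximum approximate
424/1374/2156 bp — the only facts available about the real length
distribution are its range and mean.

**Reads.** Fragments uniform on 150–350 bp (the sonication target range;
with 150 bp reads this puts ~75 % of fragments under 300 bp, so most pairs
overlap), PE150 reads from each end, per-base substitution errors at a
configurable rate with Phred 10–20 on error bases and 30–40 on correct
bases, so quality-aware mismatch reconciliation is actually exercised.
Coverage is the expected per-base read depth.

**Missing data, paralogs, contaminants.** Taxon–locus cells are deleted by
independent Bernoulli draws (default 1.5 %).  A paralogous locus copy is a
duplicate diverged along an elongated root branch (default 0.25
substitutions/site, far enough that the copies share essentially no 60-mers
but still map to the same probe at > 55 % identity — exactly the situation
the assembler's cluster separation and the orthology filter must handle).
Contaminants are reads from unrelated random sequences.  Per-locus rate
heterogeneity is exposed as a log-normal multiplier (`rate_sigma`) rather
than asserting any particular distribution of informativeness.

**Probe references.** Each locus gets a reference sequence diverged 0.05
substitutions/site from the locus root — a stand-in for the related-genome
probe source — with only a central window (default 400 bp) marked as the
conserved probe region, so flank recovery must go through the de-novo
extension path.

What the generator does *not* emulate: indels, base-composition bias,
adapter read-through, platform-specific error profiles, within-species
polymorphism.  Passing tests therefore demonstrate the pipeline's logic
under the MSC with substitution-only divergence, not robustness to
alignment error or population sampling.

## Read merging

For each candidate overlap m (from 5 bp, below which the tail probability
can never reach any sensible threshold) between read 1 and the
reverse-complemented mate, the merge criterion is the binomial upper tail
P(X ≥ k | n = m, p = 0.25) for k observed matches — the chance of that much
agreement between unrelated reads under an i.i.d. uniform null.  The
overlap minimising this probability is chosen (ties to the longest
overlap) and the pair merges only if it falls below 10⁻¹⁰.  Inside the
overlap, agreements get summed qualities capped at Phred 60; disagreements
take the higher-quality base with the quality difference, and an
equal-quality disagreement becomes N at quality 0 — the symmetric choice,
which makes merging exactly equivariant under swapping the mates.
Ambiguous bases count as mismatches.  Unmerged pairs are kept and used
downstream as two single reads.

## Assembly

**Mapping.** Spaced 20-mers sample every third base over a 58 bp window
(the same spacing convention the orthology distance uses).  A preliminary
hit needs ≥ 17 of 20 spaced positions to match an indexed reference
window.  This threshold is implemented exactly but cheaply: the 20
positions split into four blocks of five; a window with ≤ 3 mismatches must
match at least one block verbatim (pigeonhole), so block-keyed lookups plus
full verification find every qualifying seed, and a whole-k-mer exact
dictionary short-circuits the common error-free case.  Preliminary hits are
confirmed when more than 55 of the first 100 aligned bases match the
reference; for shorter overlaps the same proportion (> 55 %) is required,
since a fixed count is undefined there.  Both orientations are tried;
equally good confirmed hits at different loci make a read ambiguous and it
is dropped.

**Extension.** All 60-mers of mapped reads go into a hash table; an
unmapped read joins a locus when it shares an exact 60-mer, contributing
its own 60-mers immediately.  Passes repeat until one full pass recruits
nothing (a fixed point reached in ≤ n_reads passes).

**Cluster separation.** 60-mers found together in ≥ 2 reads are merged into
components (implemented through read pairs: any two 60-mers shared by the
same two reads co-occur in two reads by construction; candidate read pairs
are restricted to placements overlapping by at least a 60-mer length, which
cannot exclude a shared exact 60-mer).  Reads follow the component holding
most of their 60-mers; reads whose 60-mers all sit in singleton components
stand alone.  A single-copy locus at decent coverage yields one cluster;
a diverged paralog, a contaminant, or a coverage break yields more.

**Refinement.** Each read may shift by up to ±2 columns and receive at most
one gap, accepted only when the read's agreement with the other reads'
columns strictly increases — so total column agreement never decreases and
a perfectly agreeing cluster is a fixed point (a read that already matches
every overlapping base is never moved, which prevents drift onto
coincidental repeats at cluster edges).

**Consensus.** Per column with coverage n and e non-majority bases, the
polymorphism is "explainable as sequencing error" when
P(X ≥ e | X ~ Binomial(n, 0.1)) ≥ 0.05; then the majority base is called
(ties broken alphabetically before the test), otherwise the IUPAC code of
all observed bases (e.g. R for A+G).  Columns with coverage < 5 are
soft-masked to lowercase; clusters with < 10 reads are discarded as likely
low-level contamination.  When one locus yields several surviving clusters
for a sample, the default sends the largest to orthology and reports the
rest; an "all clusters" mode emits every consensus so orthology itself can
adjudicate (useful when paralogy is suspected).

## Orthology and masking

The pairwise distance between two consensuses is 1 minus their shared
fraction of 20-mers, pooling consecutive and every-third-base spaced
20-mers (the spacing tolerates higher divergence).  The shared fraction is
Jaccard-normalised by default ("percent observed in the two sequences
found in both" is ambiguous between union and per-sequence denominators;
min-normalisation is available).  Soft-masked content participates
uppercased; k-mers touching other ambiguity codes are skipped.

Clustering is an agglomerative neighbor-joining: the pair minimising the NJ
Q-criterion joins unless the join would put two sequences of the same
sample in one cluster — forbidden joins fall through to the next-best pair,
merged clusters carry size-weighted average distances, and joining stops
when every remaining pair is forbidden.  Clusters covering at least 50 % of
the species (inclusive, reading "at least" literally) survive.

Masking runs in three steps: (1) a site is good when its most common
character — gaps count as characters — occurs in more than half the
sequences (strict); (2) 20-base windows of each sequence (sliding over the
sequence's own bases, skipping gaps; sliding is the stricter reading of
"20 bp regions") containing fewer than 10 good sites are lowercased;
(3) columns with fewer than 4 unmasked bases are deleted.  Column deletion
can shift step-2 windows, so the three steps iterate to a fixed point;
this is what makes masking idempotent, and on realistic inputs the second
iteration is already a no-op.  Alignment itself (MAFFT in the original
workflow) is an external step; the package consumes aligned FASTA.

Alignment summaries: parsimony-informative sites require two states each in
two or more sequences (unambiguous bases only); uncorrected divergence is
the mismatch fraction over sites where both sequences carry unambiguous
bases; missingness counts gaps, N and ?.

## Species trees

**Gene trees.** A Jukes-Cantor-corrected NJ estimator (with
column-resampling bootstrap) stands in for external maximum-likelihood
programs so the pipeline runs self-contained; externally built Newick gene
trees can be imported instead.

**STAR.** In each gene tree the root takes rank (number of taxa in that
tree − 1) and every internal node one less than its parent; the distance
between two taxa is twice the rank of their MRCA, averaged over the gene
trees containing both (tolerating missing taxa; a pair never co-occurring
is an error).  NJ resolves the matrix; the tree is rooted on the outgroup
when one is configured, otherwise at the midpoint (rank distances are
near-ultrametric, so the midpoint falls at the deepest split).

**MP-EST.** For each species triple with internal branch t the MSC predicts
the matching rooted triplet with probability 1 − (2/3)e^(−t) and each
alternative with (1/3)e^(−t).  The pseudo-likelihood of a topology sums,
over triples, the multinomial log-likelihood of the observed triplet counts
with t profiled out by its closed-form MLE t̂ = −ln(1.5(1 − p̂₁)) clamped to
[10⁻⁶, 10] (the exact method co-estimates shared branch lengths; profiling
per triple is the desk-scale simplification and reproduces the closed-form
stationary point exactly on single triples).  Search is NNI hill-climbing
over rooted topologies from the STAR tree plus random restarts,
deterministic under a fixed seed; a flat surface (tied optima with
different topologies, or empty counts) is flagged as unresolved.  Final
internal branches take the mean t̂ of the triples whose internal path is
exactly that edge.

**Robinson-Foulds.** Rooted by default: the symmetric difference of
non-trivial clade sets, with maximum 2(n − 2) — the count of internal
branches of two rooted n-taxon trees — reported also as a percentage.
Unrooted (bipartition) comparison with maximum 2(n − 3) is available.
Mean bootstrap is the arithmetic mean of internal-node supports, root
excluded.  The MetaTree-style tree-of-trees applies NJ to the matrix of
pairwise RF distances between labelled trees pruned to their shared taxa.

## Subsampling experiment

Subsets of 3, 4, 5, 10, 25, 50, 100 and 200 loci (five independent
replicates each; replicates may overlap, as nothing stronger than
"different random sets" is implied) are analysed with STAR and MP-EST; each
replicate tree is scored by rooted RF% against a reference (default: the
full-data STAR tree) and by its mean bootstrap.  Species-tree support
comes from a multilocus bootstrap: loci are resampled with replacement and
species trees re-estimated — with the rank-distance (STAR) engine for both
methods' support values, because refitting the triplet search for every
replicate is prohibitive at desk scale while the resampling uncertainty it
measures is the same.  The coefficient of variation of the replicate RF
values (sample SD over mean; 0-with-flag when the mean is 0) is the
plateau diagnostic: the plateau size is the smallest subset size attaining
the minimal CV, ties to the smallest size.

Validation scenarios (sizes chosen to keep the whole suite in minutes on
one core): recovery uses 20 replicates of 10 species × 100 clean gene
trees; the trend run uses 15 species × 200 loci at minimum internal branch
0.5 with subsets up to 100 loci; the end-to-end pipeline run uses 10
species × 30 loci at coverage 20 with 1 % read error and 20 % paralogous
loci.

## Known limitations

* No indel realism anywhere; the one-gap-per-read refinement is exercised
  by fixtures, not by the generator.
* The MP-EST pseudo-likelihood profiles branch lengths per triple instead
  of sharing them across triples; topology search is NNI-only.
* Unmerged mates are mapped independently, not as linked pairs.
* The 17/20 preliminary rule is applied through the exact block index only
  when no perfect seed exists anywhere in the read (a pure optimisation on
  error-free data, but a read with both a perfect seed at one locus and a
  17/20 seed at another will not see the latter).
* CV-based plateau detection is a point summary; the full CV curve is in
  the report for the user to judge.
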