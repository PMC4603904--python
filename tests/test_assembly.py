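"""Assembly: spaced-seed index, 17/20 and 55/100 mapping rules, 60-mer
extension, cluster separation, alignment refinement and binomial consensus."""

import numpy as np
import pytest

import anchortree as at
from anchortree._seq import revcomp
from anchortree.assembly import (SPACED_PATTERN, SPACED_SPAN, AlignedRead,
                                 AssemblyCluster, AssemblyParams, SeqRead)


def _q(n, v=35):
    return np.full(n, v)


def _ref(seq, locus="L1", mask=None):
    return at.ProbeReference(locus_id=locus, sequence=seq,
                             conserved_site_mask=mask)


def _rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestSpacedIndex:
    def test_minimal_reference_admits_expected_kmers(self, rng):
        seq = _rand_seq(rng, SPACED_SPAN)  # exactly one window
        idx = at.build_spaced_index([_ref(seq)])
        assert len(idx) == 1
        assert idx.post_offset.tolist() == [0]

    def test_kmers_spanning_n_excluded(self, rng):
        seq = _rand_seq(rng, 100)
        seq = seq[:30] + "N" + seq[31:]
        idx = at.build_spaced_index([_ref(seq)])
        # brute force: an offset is excluded iff a pattern position hits the N
        expected = [o for o in range(100 - SPACED_SPAN + 1)
                    if 30 not in (o + SPACED_PATTERN)]
        assert idx.post_offset.tolist() == expected

    def test_shared_kmer_yields_postings_in_both_loci(self, rng):
        core = _rand_seq(rng, SPACED_SPAN)
        s1 = core + _rand_seq(rng, 40)
        s2 = _rand_seq(rng, 40) + core
        idx = at.build_spaced_index([_ref(s1, "A"), _ref(s2, "B")])
        key = "".join(core[p] for p in SPACED_PATTERN).encode()
        postings = idx.exact[key]
        loci = {idx.post_locus[i] for i in postings}
        assert loci == {0, 1}

    def test_duplicate_locus_rejected(self, rng):
        seq = _rand_seq(rng, 80)
        with pytest.raises(ValueError):
            at.build_spaced_index([_ref(seq, "A"), _ref(seq, "A")])

    def test_mask_restricts_indexable_offsets(self, rng):
        seq = _rand_seq(rng, 120)
        mask = np.zeros(120, dtype=bool)
        mask[10:90] = True
        idx = at.build_spaced_index([_ref(seq, mask=mask)])
        assert idx.post_offset.min() >= 10
        assert idx.post_offset.max() + SPACED_SPAN <= 90


class TestMapRead:
    def test_verbatim_copy_maps_at_offset(self, rng):
        ref = _rand_seq(rng, 500)
        idx = at.build_spaced_index([_ref(ref)])
        read = SeqRead("r", ref[137:287], _q(150))
        hit = at.map_read(read, idx)
        assert hit is not None
        assert (hit.locus_id, hit.pos, hit.orientation) == ("L1", 137, "+")

    def test_reverse_complement_maps(self, rng):
        ref = _rand_seq(rng, 500)
        idx = at.build_spaced_index([_ref(ref)])
        read = SeqRead("r", revcomp(ref[137:287]), _q(150))
        hit = at.map_read(read, idx)
        assert hit is not None and hit.orientation == "-"
        assert hit.pos == 137

    def test_scrambled_read_unmapped(self, rng):
        ref = _rand_seq(rng, 500)
        idx = at.build_spaced_index([_ref(ref)])
        frag = list(ref[100:250])
        positions = rng.permutation(150)[:75]
        for p in positions:
            frag[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[frag[p]]
        assert at.map_read(SeqRead("r", "".join(frag), _q(150)), idx) is None

    def test_sixteen_of_twenty_no_preliminary_hit(self, rng):
        # corrupting every 5th base puts exactly 4 mismatches in every
        # spaced window (pattern step 3 and period 5 are coprime), so each
        # seed matches 16/20: one short of the preliminary threshold
        ref = _rand_seq(rng, 300)
        idx = at.build_spaced_index([_ref(ref)])
        read = list(ref[50:200])
        comp = {"A": "C", "C": "G", "G": "T", "T": "A"}
        for i in range(0, 150, 5):
            read[i] = comp[read[i]]
        assert at.map_read(SeqRead("r", "".join(read), _q(150)), idx) is None

    def test_seventeen_of_twenty_still_seeds(self, rng):
        # three mismatches inside one spaced window still give a
        # preliminary hit; the rest of the read is clean so it confirms
        ref = _rand_seq(rng, 300)
        idx = at.build_spaced_index([_ref(ref)])
        read = list(ref[50:200])
        comp = {"A": "C", "C": "G", "G": "T", "T": "A"}
        # hit three pattern positions of every window's first half so no
        # window is error free, but each still has >= 17 matches
        for col in range(0, 150, 58):
            for p in (0, 3, 6):
                if col + p < 150:
                    read[col + p] = comp[read[col + p]]
        hit = at.map_read(SeqRead("r", "".join(read), _q(150)), idx)
        assert hit is not None and hit.pos == 50


class TestExtendAssembly:
    def test_flank_read_recruited_by_60mer(self, rng):
        locus = _rand_seq(rng, 600)
        mapped = [AlignedRead("m", locus[200:350], _q(150), "L1", 200)]
        flank = SeqRead("f", locus[141:260], _q(119))  # shares 60-mers
        new = at.extend_assembly(mapped, [flank])
        assert len(new) == 1 and new[0].pos == 141

    def test_59_matching_bases_not_recruited(self, rng):
        locus = _rand_seq(rng, 400)
        mapped = [AlignedRead("m", locus[100:250], _q(150), "L1", 100)]
        # read overlapping by 59 bases only
        tail = locus[191:250] + _rand_seq(rng, 80)
        new = at.extend_assembly(mapped, [SeqRead("f", tail, _q(139))])
        assert new == []

    def test_transitive_chain_recruited(self, rng):
        locus = _rand_seq(rng, 800)
        seed = AlignedRead("r1", locus[0:150], _q(150), "L1", 0)
        r2 = SeqRead("r2", locus[90:300], _q(210))
        r3 = SeqRead("r3", locus[240:450], _q(210))
        # r3 shares 60-mers with r2 only; needs the fixed-point iteration
        new = at.extend_assembly([seed], [r3, r2])
        assert {r.id for r in new} == {"r2", "r3"}
        assert {r.id: r.pos for r in new} == {"r2": 90, "r3": 240}


class TestClusterReads:
    def _reads_tiling(self, seq, start, stop, step, rl, prefix):
        return [AlignedRead(f"{prefix}{i}", seq[p:p + rl], _q(rl), "L1", p)
                for i, p in enumerate(range(start, stop - rl + 1, step))]

    def test_single_copy_locus_one_cluster(self, rng):
        locus = _rand_seq(rng, 700)
        reads = self._reads_tiling(locus, 0, 700, 30, 150, "r")
        clusters = at.cluster_reads(reads)
        assert len(clusters) == 1
        assert clusters[0].n_reads == len(reads)

    def test_diverged_paralog_forms_second_cluster(self, rng):
        locus = _rand_seq(rng, 600)
        paralog = "".join(
            c if rng.random() > 0.3 else
            {"A": "C", "C": "G", "G": "T", "T": "A"}[c] for c in locus)
        reads = (self._reads_tiling(locus, 0, 600, 40, 150, "o") +
                 self._reads_tiling(paralog, 0, 600, 40, 150, "p"))
        clusters = at.cluster_reads(reads)
        assert len(clusters) == 2
        for c in clusters:
            kinds = {r.id[0] for r in c.reads}
            assert len(kinds) == 1  # no cluster mixes the two copies

    def test_unlinked_reads_two_clusters(self, rng):
        locus = _rand_seq(rng, 600)
        r1 = AlignedRead("a", locus[0:150], _q(150), "L1", 0)
        r2 = AlignedRead("b", locus[400:550], _q(150), "L1", 400)
        assert len(at.cluster_reads([r1, r2])) == 2


class TestRefineAlignment:
    def test_perfect_cluster_unchanged(self, rng):
        locus = _rand_seq(rng, 400)
        reads = [AlignedRead(f"r{i}", locus[p:p + 150], _q(150), "L1", p)
                 for i, p in enumerate(range(0, 250, 50))]
        before = [(r.pos, r.gap) for r in reads]
        cluster = at.refine_alignment(
            AssemblyCluster("L1", "s", list(reads)))
        assert [(r.pos, r.gap) for r in cluster.reads] == before

    def test_offset_read_shifted_back(self, rng):
        locus = _rand_seq(rng, 400)
        reads = [AlignedRead(f"r{i}", locus[p:p + 150], _q(150), "L1", p)
                 for i, p in enumerate(range(0, 250, 50))]
        reads[2].pos += 1  # misplace one read
        cluster = at.refine_alignment(AssemblyCluster("L1", "s", reads))
        assert cluster.reads[2].pos == 100

    def test_deletion_gets_gap(self, rng):
        locus = _rand_seq(rng, 400)
        reads = [AlignedRead(f"r{i}", locus[p:p + 150], _q(150), "L1", p)
                 for i, p in enumerate(range(0, 200, 40))]
        # one read with a 1 bp deletion at its index 70
        delseq = locus[80:150] + locus[151:231]
        reads.append(AlignedRead("del", delseq, _q(150), "L1", 80))
        cluster = at.refine_alignment(AssemblyCluster("L1", "s", reads))
        bad = [r for r in cluster.reads if r.id == "del"][0]
        assert bad.gap == 70 and bad.pos == 80


class TestConsensus:
    def _column_cluster(self, bases_per_read):
        reads = [AlignedRead(f"r{i}", b, _q(1), "L1", 0)
                 for i, b in enumerate(bases_per_read)]
        return AssemblyCluster("L1", "s", reads)

    def test_minor_base_explained_as_error(self):
        c = self._column_cluster(["A"] * 9 + ["G"])
        # P(X>=1 | n=10, e=0.1) = 1 - 0.9^10 ~ 0.651 >= 0.05 -> majority
        assert at.call_consensus(c).sequence == "A"

    def test_balanced_polymorphism_gets_iupac(self):
        c = self._column_cluster(["A"] * 5 + ["G"] * 5)
        # P(X>=5 | n=10, e=0.1) ~ 1.63e-3 < 0.05 -> both bases observed
        assert at.call_consensus(c).sequence == "R"

    def test_low_coverage_soft_masked(self):
        c = self._column_cluster(["A"] * 4)
        assert at.call_consensus(c).sequence == "a"

    def test_error_free_cluster_reproduces_source(self, rng):
        locus = _rand_seq(rng, 500)
        reads = [AlignedRead(f"r{i}", locus[p:p + 100], _q(100), "L1", p)
                 for i, p in enumerate(range(0, 401, 10))]
        cons = at.call_consensus(AssemblyCluster("L1", "s", reads))
        assert cons.ref_start == 0
        covered = cons.sequence.upper()
        assert covered == locus[:len(covered)]
        # everything at coverage >= 5 stays uppercase
        for ch, cov in zip(cons.sequence, cons.coverage):
            assert ch.isupper() == (cov >= 5)

    def test_binomial_tail_matches_direct_summation(self):
        from math import comb
        from scipy import stats
        for n in (1, 4, 10, 37, 150):
            for e in range(0, n + 1):
                direct = sum(comb(n, k) * 0.1 ** k * 0.9 ** (n - k)
                             for k in range(e, n + 1))
                sf = float(stats.binom.sf(e - 1, n, 0.1))
                assert sf == pytest.approx(direct, rel=1e-10)


class TestFilterAndDriver:
    def test_cluster_size_boundary(self, rng):
        locus = _rand_seq(rng, 400)

        def cluster_of(n):
            reads = [AlignedRead(f"r{i}", locus[:150], _q(150), "L1", 0)
                     for i in range(n)]
            return AssemblyCluster("L1", "s", reads)

        params = AssemblyParams()
        assert at.filter_clusters([cluster_of(9)], params) == []
        kept = at.filter_clusters([cluster_of(10)], params)
        assert len(kept) == 1
        assert at.filter_clusters([], params) == []

    def test_assemble_sample_end_to_end(self, small_dataset):
        ds = small_dataset
        refs = ds.probe_references()
        sample = ds.config.species_labels()[0]
        summary = at.merge_pairs(ds.reads[sample])
        reads = at.reads_for_assembly(summary)
        consensuses, report = at.assemble_sample(reads, refs,
                                                 sample_id=sample)
        assert {c.locus_id for c in consensuses} == set(ds.locus_ids)
        for c in consensuses:
            true = ds.alignments[c.locus_id][c.sample_id]
            matches = total = 0
            for i, ch in enumerate(c.sequence):
                pos = c.ref_start + i
                if 0 <= pos < len(true) and ch.isupper() and ch in "ACGT":
                    total += 1
                    matches += ch == true[pos]
            assert total > 0.8 * len(true)
            assert matches / total >= 0.995
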