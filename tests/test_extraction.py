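"""k-mer selection and the three extraction filters."""

import numpy as np
import pysam
import pytest

import oracles
from kmergt.extraction import (
    KmerProfile,
    TrainingSample,
    build_index,
    candidates_from_clipped_reads,
    candidates_from_reference,
    cap_per_sv,
    deduplicate_across_svs,
    filter_by_training_genotype,
    filter_reference_occurrences,
    select_control_kmers,
)
from kmergt.kmers import canonical, count_reads, decode_kmer, encode_kmer
from kmergt.variants import Genotype, SVRecord, SVType


def canon_seq(seq):
    return decode_kmer(canonical(encode_kmer(seq), len(seq)), len(seq))


def by_role(profiles, role):
    return {decode_kmer(p.code, p.k) for p in profiles if p.role == role}


class TestCandidatesFromReference:
    def test_deletion_junction_and_inner_kmers(self, toy_ref):
        sv = SVRecord("d", "chr1", 4, 8, SVType.DEL)
        profiles = candidates_from_reference(toy_ref, sv, k=4)
        # windows of the spliced haplotype "AAAAGGGG" straddling position 4
        assert by_role(profiles, "junction_alt") == {
            canon_seq(s) for s in ("AAAG", "AAGG", "AGGG")
        }
        assert by_role(profiles, "inner_ref") == {canon_seq("CCCC")}

    def test_short_insertion_has_no_inner_kmers(self, toy_ref):
        sv = SVRecord("i", "chr1", 8, 8, SVType.INS, inserted_seq="TT")
        profiles = candidates_from_reference(toy_ref, sv, k=4)
        assert by_role(profiles, "inner_alt") == set()
        # every window of "...CCCCTTGGGG..." that overlaps either junction
        alt = toy_ref[4:8] + "TT" + toy_ref[8:12]
        expected = {
            canon_seq(alt[s : s + 4])
            for s in range(len(alt) - 3)
            if s < 6 and s + 4 > 4  # covers a junction at offset 4 or 6
        }
        assert by_role(profiles, "junction_alt") == expected

    def test_zero_length_deletion_yields_nothing(self, toy_ref):
        sv = SVRecord("d", "chr1", 8, 8, SVType.DEL)
        assert candidates_from_reference(toy_ref, sv, k=4) == set()

    def test_neighbors_are_adjacent_source_windows(self, rng):
        ref = "".join(rng.choice(list("ACGT"), size=400))
        sv = SVRecord("d", "chr1", 150, 250, SVType.DEL)
        k = 8
        inner = [p for p in candidates_from_reference(ref, sv, k=k)
                 if p.role == "inner_ref"]
        assert inner
        for p in inner:
            seq = decode_kmer(p.code, k)
            pos = ref.find(seq)
            if pos < 0:
                pos = ref.find(oracles.revcomp(seq))
            assert pos > 0
            adjacent = {
                canonical(encode_kmer(ref[pos - 1 : pos - 1 + k]), k),
                canonical(encode_kmer(ref[pos + 1 : pos + 1 + k]), k),
            }
            assert {p.left_neighbor, p.right_neighbor} == adjacent

    def test_flank_below_k_minus_1_rejected(self, toy_ref):
        sv = SVRecord("d", "chr1", 4, 8, SVType.DEL)
        with pytest.raises(ValueError):
            candidates_from_reference(toy_ref, sv, k=4, flank=2)


def _write_sam(path, ref_len, reads):
    header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": ref_len}]}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for name, seq, pos, cigar, flag in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = name
            a.query_sequence = seq
            a.reference_id = 0
            a.reference_start = pos
            a.cigarstring = cigar
            a.flag = flag
            a.mapping_quality = 60
            out.write(a)


class TestClippedReads:
    def test_trailing_softclip_kmers(self, tmp_path):
        # 8 bp read, bases 0-3 aligned at the breakpoint, bases 4-7 clipped:
        # windows starting at 1..4 each overlap a clipped base
        sam = tmp_path / "clip.sam"
        _write_sam(sam, 1000, [("r1", "ACGGTCCA", 496, "4M4S", 0)])
        sv = SVRecord("d", "chr1", 500, 700, SVType.DEL)
        profiles = candidates_from_clipped_reads(str(sam), sv, k=4)
        expected = {canon_seq("ACGGTCCA"[s : s + 4]) for s in range(1, 5)}
        assert {decode_kmer(p.code, 4) for p in profiles} == expected
        assert all(p.role == "junction_alt" for p in profiles)

    def test_no_clips_near_breakpoints_yields_empty(self, tmp_path):
        sam = tmp_path / "noclip.sam"
        _write_sam(sam, 1000, [("r1", "ACGGTCCA", 100, "8M", 0)])
        sv = SVRecord("d", "chr1", 500, 700, SVType.DEL)
        assert candidates_from_clipped_reads(str(sam), sv, k=4) == set()

    def test_reverse_strand_clip_gives_same_canonical_codes(self, tmp_path):
        seq = "ACGGTCCA"
        sam_f = tmp_path / "f.sam"
        sam_r = tmp_path / "r.sam"
        _write_sam(sam_f, 1000, [("r1", seq, 496, "4M4S", 0)])
        # BAM convention: the stored sequence is already reference-oriented
        _write_sam(sam_r, 1000, [("r1", seq, 496, "4M4S", 16)])
        sv = SVRecord("d", "chr1", 500, 700, SVType.DEL)
        codes_f = {p.code for p in candidates_from_clipped_reads(str(sam_f), sv, k=4)}
        codes_r = {p.code for p in candidates_from_clipped_reads(str(sam_r), sv, k=4)}
        assert codes_f == codes_r


def _random_ref(rng, n=10_000):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestReferenceOccurrenceFilter:
    def test_all_candidates_of_a_toy_sv_survive(self, rng):
        ref = _random_ref(rng)
        sv = SVRecord("d", "chr1", 4000, 4200, SVType.DEL)
        candidates = candidates_from_reference(ref, sv, k=16)
        kept = filter_reference_occurrences(candidates, {"chr1": ref}, [sv], 16)
        assert kept == candidates  # random 10 kb: no spurious repeats

    def test_alt_kmer_with_offsite_occurrence_removed(self, rng):
        ref = _random_ref(rng)
        sv = SVRecord("d", "chr1", 4000, 4200, SVType.DEL)
        k = 16
        candidates = candidates_from_reference(ref, sv, k=k)
        junction = next(p for p in candidates if p.role == "junction_alt")
        # plant a second copy of this k-mer 40 kb... far away in the reference
        planted = ref[:9000] + decode_kmer(junction.code, k) + ref[9000 + k :]
        kept = filter_reference_occurrences(candidates, {"chr1": planted}, [sv], k)
        assert junction not in kept

    def test_duplicated_inner_ref_kmer_removed(self, rng):
        ref = _random_ref(rng)
        sv = SVRecord("d", "chr1", 4000, 4200, SVType.DEL)
        k = 16
        candidates = candidates_from_reference(ref, sv, k=k)
        inner = next(p for p in candidates if p.role == "inner_ref")
        dup = ref[:500] + decode_kmer(inner.code, k) + ref[500 + k :]
        kept = filter_reference_occurrences(candidates, {"chr1": dup}, [sv], k)
        assert inner not in kept

    def test_idempotent(self, rng):
        ref = _random_ref(rng)
        sv = SVRecord("d", "chr1", 4000, 4200, SVType.DEL)
        once = filter_reference_occurrences(
            candidates_from_reference(ref, sv, k=16), {"chr1": ref}, [sv], 16
        )
        twice = filter_reference_occurrences(once, {"chr1": ref}, [sv], 16)
        assert once == twice


def _profile(seq, sv_id, role="junction_alt", copies=(0, 1, 2)):
    k = len(seq)
    return KmerProfile(
        code=canonical(encode_kmer(seq), k), k=k, sv_id=sv_id, role=role,
        left_neighbor=None, right_neighbor=None, copies=copies,
    )


class TestDeduplicateAcrossSVs:
    def test_shared_kmer_dropped_from_both(self):
        shared = _profile("ACGTTCCA", "a")
        shared_b = _profile("ACGTTCCA", "b")
        own = _profile("GGCTTCCA", "a")
        kept = deduplicate_across_svs({shared, shared_b, own})
        assert kept == {own}

    def test_disjoint_sets_unchanged(self):
        a, b = _profile("ACGTTCCA", "a"), _profile("GGCTTCCA", "b")
        assert deduplicate_across_svs({a, b}) == {a, b}

    def test_only_shared_codes_removed_among_three_svs(self):
        shared1 = _profile("ACGTTCCA", "a")
        shared2 = _profile("ACGTTCCA", "b")
        solo = _profile("GGCTTCCA", "c")
        assert deduplicate_across_svs({shared1, shared2, solo}) == {solo}


class TestTrainingGenotypeFilter:
    """Counts are engineered directly through synthetic reads.

    Each read is exactly one k-mer long, so every occurrence is accepted
    without checkable neighbors and counts equal read multiplicities.
    """

    K = 8

    def _setup(self, candidate_count):
        candidate = _profile("ACGTTCCA", "sv1", role="inner_alt", copies=(0, 1, 2))
        controls = [
            _profile(seq, "*", role="control", copies=(2, 2, 2))
            for seq in ("AACCGGTT", "AAACCGTT", "ACACGGTT", "AGACGGTT")
        ]
        reads = ["ACGTTCCA"] * candidate_count
        for p in controls:
            reads += [decode_kmer(p.code, self.K)] * 30
        return candidate, controls, reads

    def test_concordant_kmer_kept(self):
        candidate, controls, reads = self._setup(candidate_count=14)
        sample = TrainingSample(reads=reads, truth={"sv1": Genotype.HET})
        kept = filter_by_training_genotype([candidate], [sample], controls, self.K)
        assert kept == {candidate}
        assert sample.stats.mu == pytest.approx(30.0)

    def test_discordant_kmer_removed(self):
        # counted ~mu: a hidden paralog would predict 1/1, truth says 0/1
        candidate, controls, reads = self._setup(candidate_count=31)
        sample = TrainingSample(reads=reads, truth={"sv1": Genotype.HET})
        kept = filter_by_training_genotype([candidate], [sample], controls, self.K)
        assert kept == set()

    def test_unknown_truth_passes_vacuously(self):
        candidate, controls, reads = self._setup(candidate_count=31)
        sample = TrainingSample(reads=reads, truth={})
        kept = filter_by_training_genotype([candidate], [sample], controls, self.K)
        assert kept == {candidate}


class TestCapPerSV:
    def test_junction_kmers_preferred(self, rng):
        profiles = [
            _profile("".join(rng.choice(list("ACGT"), size=8)), "sv1",
                     role="inner_ref", copies=(2, 1, 0))
            for _ in range(80)
        ] + [
            _profile("".join(rng.choice(list("ACGT"), size=8)), "sv1",
                     role="junction_alt")
            for _ in range(10)
        ]
        capped = cap_per_sv(profiles, max_per_sv=16)
        assert len(capped) == 16
        assert sum(1 for p in capped if p.role == "junction_alt") == 10


def test_control_kmers_unique_and_outside_footprints(rng):
    ref = _random_ref(rng, 20_000)
    sv = SVRecord("d", "chr1", 5000, 5200, SVType.DEL)
    controls = select_control_kmers({"chr1": ref}, [sv], k=16, n=50, rng=rng)
    assert len(controls) == 50
    for p in controls:
        seq = decode_kmer(p.code, 16)
        assert oracles.substring_count(ref, seq) == 1
        pos = max(ref.find(seq), ref.find(oracles.revcomp(seq)))
        assert not (5000 - 15 <= pos <= 5200 + 15)
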