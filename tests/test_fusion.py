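"""Chimeric-pair counting, junction assembly/localization, RBM and fusion ORF."""

import numpy as np
import pytest

from resistkit.fusion import (
    FusionCall,
    FusionDetector,
    RBMProfile,
    InvalidParameterError,
    assemble_junction,
    compute_rbm,
    find_chimeric_pairs,
    fusion_orf,
    locate_junction,
    region_fold,
)
from resistkit.mapping import KmerReadMapper, MateAlignment, ReadPairAlignment
from resistkit.synth import (
    expected_chimeric_pairs,
    make_coding_transcript,
    make_transcript,
    simulate_read_pairs,
)


def _mate(tx, start, span=75, status="unique"):
    return MateAlignment(status=status, transcript=tx, start=start, span=span)


class TestChimericPairs:
    def test_single_concordant_pair_yields_empty_table(self):
        aln = [ReadPairAlignment("p", _mate("tx1", 10), _mate("tx1", 200))]
        table = find_chimeric_pairs(aln)
        assert table.counts == ()
        assert table.n_concordant == 1

    def test_discordant_pairs_counted_per_unordered_pair(self):
        aln = [
            ReadPairAlignment("a", _mate("tx1", 1), _mate("tx2", 1)),
            ReadPairAlignment("b", _mate("tx2", 5), _mate("tx1", 9)),
            ReadPairAlignment("c", _mate("tx1", 5), _mate("tx3", 9)),
            ReadPairAlignment("d", _mate("tx1", 5), MateAlignment(status="ambiguous")),
        ]
        table = find_chimeric_pairs(aln)
        assert table.counts[0] == (("tx1", "tx2"), 2)
        assert table.count("tx3", "tx1") == 1
        assert table.n_excluded == 1

    def test_wildtype_only_library_has_zero_chimeric_pairs(self, study):
        transcripts = {"tx5": study["tx5"], "tx3": study["tx3"]}
        pairs, _ = simulate_read_pairs(transcripts, {"tx5": 1.0, "tx3": 1.0},
                                       n_pairs=2000, seed=4)
        mapper = KmerReadMapper().fit(study["wt_set"])
        table = find_chimeric_pairs(mapper.map_pairs(pairs))
        assert table.count("tx5", "tx3") == 0

    def test_fusion_library_count_matches_truth_bookkeeping(self, study):
        pairs, truth = simulate_read_pairs(
            {"fusion": study["fusion"]}, {"fusion": 1.0}, n_pairs=2000, seed=8
        )
        mapper = KmerReadMapper().fit(study["wt_set"])
        table = find_chimeric_pairs(mapper.map_pairs(pairs))
        expected = expected_chimeric_pairs(truth, "fusion", study["j5"])
        assert table.count("tx5", "tx3") == expected


class TestAssembly:
    def test_tiling_reads_reassemble_the_region_exactly(self):
        region = make_transcript(300, seed=21)
        reads = [region[i : i + 75] for i in range(0, 226, 5)]
        result = assemble_junction(reads, k=31)
        assert not result.failed
        assert result.contigs[0] == region

    def test_two_identical_reads_assemble_to_the_read(self):
        read = make_transcript(75, seed=22)
        result = assemble_junction([read, read], k=31)
        assert result.contigs[0] == read

    def test_unlinked_regions_stay_separate_contigs(self):
        r1 = make_transcript(200, seed=23)
        r2 = make_transcript(200, seed=24)
        reads = [r1[i : i + 75] for i in range(0, 126, 5)]
        reads += [r2[i : i + 75] for i in range(0, 126, 5)]
        result = assemble_junction(reads, k=31)
        assert len(result.contigs) >= 2
        top2 = result.contigs[:2]
        assert not any(r1 in c and r2 in c for c in top2)
        assert any(c == r1 for c in top2) and any(c == r2 for c in top2)

    def test_short_fragments_flag_assembly_failure(self):
        read = make_transcript(35, seed=25)
        result = assemble_junction([read, read], k=31)
        assert result.failed

    def test_fewer_than_two_reads_rejected(self):
        with pytest.raises(InvalidParameterError):
            assemble_junction([make_transcript(75, seed=1)])


class TestLocateJunction:
    def test_study_architecture_coordinates(self, study):
        contig = study["fusion"][1906:2106]  # 100 bases each side of the junction
        call = locate_junction(contig, study["tx5"], study["tx3"])
        assert (call.j5, call.j3) == (2006, 1202)
        assert call.homology_interval == 0

    def test_fusion_sequence_identity(self, study):
        contig = study["fusion"][1906:2106]
        call = locate_junction(contig, study["tx5"], study["tx3"])
        rebuilt = study["tx5"][: call.j5] + study["tx3"][call.j3 - 1 :]
        assert rebuilt == study["fusion"]
        assert len(rebuilt) == call.j5 + (len(study["tx3"]) - call.j3 + 1)

    def test_contig_within_one_transcript_is_no_call(self, study):
        contig = study["tx5"][100:300]
        assert locate_junction(contig, study["tx5"], study["tx3"]) is None

    def test_too_short_contig_rejected(self, study):
        with pytest.raises(InvalidParameterError):
            locate_junction("ACGT" * 10, study["tx5"], study["tx3"], min_anchor=25)

    def test_matches_brute_force_split_oracle_on_random_junctions(self):
        rng = np.random.default_rng(31)
        for trial in range(10):
            tx5 = make_transcript(1000, seed=100 + trial)
            tx3 = make_transcript(1000, seed=200 + trial)
            j5 = int(rng.integers(200, 800))
            j3 = int(rng.integers(200, 800))
            fusion = tx5[:j5] + tx3[j3 - 1 :]
            contig = fusion[j5 - 100 : j5 + 100]
            call = locate_junction(contig, tx5, tx3, min_anchor=25)
            oracle = _oracle_best_split(contig, tx5, tx3, 25)
            assert call is not None
            assert (call.contig_split, call.match5 + call.match3) == oracle


def _oracle_best_split(contig, tx5, tx3, min_anchor):
    """Naive linear-scan evaluation of every split point."""
    best = None
    for s in range(min_anchor, len(contig) - min_anchor + 1):
        m5 = next((t for t in range(s, -1, -1) if contig[s - t : s] in tx5), 0)
        m3 = next((t for t in range(len(contig) - s, -1, -1) if contig[s : s + t] in tx3), 0)
        if m5 < min_anchor or m3 < min_anchor:
            continue
        if best is None or m5 + m3 > best[1]:
            best = (s, m5 + m3)
    return best


class TestRBM:
    def test_single_read_in_million_read_library_is_unit_rbm(self):
        aln = [ReadPairAlignment("p", _mate("tx", 101), MateAlignment(status="unmapped"))]
        profile = compute_rbm(aln, "tx", 1000, library_size=10**6)
        assert np.count_nonzero(profile.rbm) == 75
        assert profile.rbm[100:175] == pytest.approx(np.ones(75))
        assert profile.rbm[99] == 0.0

    def test_rbm_invariant_to_doubling_library(self):
        aln = [ReadPairAlignment("p", _mate("tx", 1), _mate("tx", 300))]
        p1 = compute_rbm(aln, "tx", 500, library_size=1000)
        p2 = compute_rbm(aln * 2, "tx", 500, library_size=2000)
        assert p2.rbm == pytest.approx(p1.rbm)

    def test_coverage_conservation_across_transcripts(self, study):
        transcripts = {"tx5": study["tx5"], "tx3": study["tx3"]}
        pairs, _ = simulate_read_pairs(transcripts, {"tx5": 1.0, "tx3": 1.0},
                                       n_pairs=500, seed=6)
        mapper = KmerReadMapper().fit(study["wt_set"])
        alignments = mapper.map_pairs(pairs)
        total_cov = sum(
            compute_rbm(alignments, tid, len(seq), 1000).coverage.sum()
            for tid, seq in transcripts.items()
        )
        aligned_bases = sum(
            m.span
            for a in alignments
            for m in (a.mate1, a.mate2)
            if m.status == "unique"
        )
        assert total_cov == aligned_bases

    def test_region_fold_of_identical_profiles_is_one(self):
        p = RBMProfile("tx", np.arange(100, dtype=float), 1000)
        assert region_fold(p, p, (1, 100)) == 1.0

    def test_region_fold_arithmetic_without_pseudocount(self):
        a = RBMProfile("tx", np.full(50, 20.0), 10**6)
        b = RBMProfile("tx", np.full(50, 1.0), 10**6)
        assert region_fold(a, b, (1, 50), pseudocount=0.0) == pytest.approx(20.0)

    def test_empty_region_rejected(self):
        p = compute_rbm([], "tx", 50, 1000)
        with pytest.raises(InvalidParameterError):
            region_fold(p, p, (30, 20))


class TestFusionORF:
    def test_study_junction_translates_to_reported_protein_ranges(self):
        # CDS offsets 228 and 62 make the 2006/1202 junction in-frame:
        # (2006-228+1)/3 = 593 retained 5' residues, 3' side resumes at 381
        seq3, cds3 = make_coding_transcript(766, utr5=61, utr3=585, seed=41)
        assert cds3 == 62 and len(seq3) == 2947
        call = FusionCall("tx5", 2006, "tx3", 1202, "", 0)
        orf = fusion_orf(call, cds_start5=228, cds_start3=62, seq3=seq3)
        assert orf.in_frame
        assert orf.five_prime_aa == (1, 593)
        assert orf.three_prime_aa == (381, 766)
        assert orf.protein_length == 593 + (766 - 381 + 1)

    def test_single_retained_codon(self):
        seq3, cds3 = make_coding_transcript(100, utr5=30, utr3=30, seed=42)
        call = FusionCall("tx5", 230, "tx3", cds3, "", 0)  # cds5=228: one codon
        orf = fusion_orf(call, cds_start5=228, cds_start3=cds3, seq3=seq3)
        assert orf.in_frame and orf.five_prime_aa == (1, 1)

    def test_one_base_shift_breaks_the_frame(self):
        seq3, cds3 = make_coding_transcript(100, utr5=30, utr3=30, seed=43)
        call = FusionCall("tx5", 2007, "tx3", 1202, "", 0)
        orf = fusion_orf(call, cds_start5=228, cds_start3=62, seq3=seq3)
        assert not orf.in_frame and orf.five_prime_aa is None

    def test_junction_in_utr_reported_not_fatal(self):
        seq3, cds3 = make_coding_transcript(100, utr5=30, utr3=30, seed=44)
        call = FusionCall("tx5", 100, "tx3", 62, "", 0)
        orf = fusion_orf(call, cds_start5=228, cds_start3=62, seq3=seq3)
        assert orf.junction_in_utr


class TestEndToEnd:
    def test_pipeline_recovers_simulated_junction_exactly(self, study):
        transcripts = {"tx5": study["tx5"], "tx3": study["tx3"],
                       "fusion": study["fusion"]}
        abundances = {"tx5": 1.0, "tx3": 1.0, "fusion": 2.0}
        pairs, _ = simulate_read_pairs(transcripts, abundances, n_pairs=6000, seed=17)
        report = FusionDetector().detect(pairs, study["wt_set"])
        assert report.status == "called"
        call = report.call
        assert (call.five_prime_tx, call.j5) == ("tx5", 2006)
        assert (call.three_prime_tx, call.j3) == ("tx3", 1202)
        assert call.supporting_pairs >= 20
        assert call.spanning_reads >= 20

    def test_wildtype_only_library_produces_no_call(self, study):
        transcripts = {"tx5": study["tx5"], "tx3": study["tx3"]}
        pairs, _ = simulate_read_pairs(transcripts, {"tx5": 1.0, "tx3": 1.0},
                                       n_pairs=3000, seed=18)
        report = FusionDetector().detect(pairs, study["wt_set"])
        assert report.status == "no_fusion"
        assert report.call is None
        assert report.chimeric.count("tx5", "tx3") == 0
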