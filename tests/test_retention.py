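"""Junction parsing, retention calling, transcript surgery, consequences."""

import numpy as np
import pytest
from Bio.Seq import Seq

from pignstab import retention as ret
from pignstab import simulate as sim
from pignstab.junctions import (
    JunctionRecord,
    read_junctions,
    write_junctions,
)


class TestJunctionIO:
    def test_sj_tab_convention(self, tmp_path):
        p = tmp_path / "sj.tab"
        p.write_text("chr1\t101\t160\t1\t1\t1\t7\t0\t30\n")
        (j,) = read_junctions(p, "sj_tab")
        assert (j.donor, j.acceptor) == (100, 161)
        assert j.strand == "+" and j.unique_reads == 7

    def test_bed12_blocks_match_sj_case(self, tmp_path):
        p = tmp_path / "j.bed"
        p.write_text(
            "chr1\t0\t200\tJ1\t7\t+\t0\t200\t0,0,0\t2\t100,40\t0,160\n"
        )
        (j,) = read_junctions(p, "bed12")
        assert (j.donor, j.acceptor) == (100, 161)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.tab"
        p.write_text("")
        assert read_junctions(p, "sj_tab") == []

    def test_malformed_line_reports_lineno(self, tmp_path):
        p = tmp_path / "bad.tab"
        p.write_text("chr1\t101\t160\t1\t1\t1\t7\t0\t30\nchr1\toops\n")
        with pytest.raises(ValueError, match=":2"):
            read_junctions(p, "sj_tab")

    def test_unknown_dialect(self, tmp_path):
        p = tmp_path / "x"
        p.write_text("")
        with pytest.raises(ValueError, match="dialect"):
            read_junctions(p, "starfleet")

    @pytest.mark.parametrize("dialect", ["sj_tab", "bed12"])
    def test_write_read_round_trip(self, tmp_path, dialect):
        records = [
            JunctionRecord("chrS", 60, 311, "+", 50),
            JunctionRecord("chrS", 98, 311, "+", 9),
            JunctionRecord("chrS", 400, 481, "+", 50),
        ]
        p = tmp_path / "out"
        write_junctions(records, p, dialect)
        back = read_junctions(p, dialect)
        assert [(j.donor, j.acceptor, j.unique_reads) for j in back] == [
            (j.donor, j.acceptor, j.unique_reads) for j in records
        ]

    def test_donor_must_precede_acceptor(self):
        with pytest.raises(ValueError, match="donor"):
            JunctionRecord("chr1", 200, 100, "+")


def _oracle_classify(donor, acceptor, exons, introns):
    """Independent longhand classification for a plus-strand gene."""
    ends = [e for _, e in exons]
    starts = [s for s, _ in exons]
    d_exon = ends.index(donor) if donor in ends else None
    a_exon = starts.index(acceptor) if acceptor in starts else None
    d_intron = next((i for i, (s, e) in enumerate(introns) if s <= donor <= e), None)
    a_intron = next((i for i, (s, e) in enumerate(introns) if s <= acceptor <= e), None)
    if d_exon is not None and a_exon is not None:
        if a_exon == d_exon + 1:
            return "annotated"
        if a_exon > d_exon + 1:
            return "exon_skip"
        return "other"
    if d_intron is not None and a_exon == d_intron + 1:
        return "partial_retention_5prime"
    if d_exon is not None and a_intron == d_exon:
        return "partial_retention_3prime"
    if d_intron is not None and d_intron == a_intron:
        return "intronic"
    return "other"


class TestClassifyJunction:
    def test_annotated_boundary_pair(self, toy_gene):
        model, _ = toy_gene
        (s1, e1), (s2, e2), _ = model.exons
        j = JunctionRecord(model.chrom, e1, s2, "+")
        assert ret.classify_junction(j, model) == "annotated"

    def test_retention_38nt_at_intron_start(self, toy_gene):
        model, _ = toy_gene
        (s1, e1), (s2, _), _ = model.exons
        j = JunctionRecord(model.chrom, e1 + 38, s2, "+", unique_reads=5)
        cls, event = ret.classify_junction_detail(j, model)
        assert cls == "partial_retention_5prime"
        assert event.fragment_length == 38
        assert event.fragment == (e1 + 1, e1 + 38)
        assert event.intron_index == 1

    def test_exon_skip(self, toy_gene):
        model, _ = toy_gene
        (_, e1), _, (s3, _) = model.exons
        j = JunctionRecord(model.chrom, e1, s3, "+")
        assert ret.classify_junction(j, model) == "exon_skip"

    def test_outside_span_is_other_with_warning(self, toy_gene):
        model, _ = toy_gene
        j = JunctionRecord(model.chrom, 2000, 3000, "+")
        with pytest.warns(UserWarning, match="outside gene span"):
            assert ret.classify_junction(j, model) == "other"

    def test_agrees_with_enumeration_oracle(self):
        spec = sim.ToyGeneSpec(
            exon_lengths=(30, 40, 50, 30), intron_lengths=(60, 70, 80), seed=5
        )
        model, _ = sim.gen_gene_model(spec)
        exons, introns = model.exons, model.introns
        boundary_points = [c for s, e in exons for c in (s, e)]
        offsets = range(-2, 3)
        candidates = sorted(
            {b + o for b in boundary_points for o in offsets}
        )
        span = model.span
        checked = 0
        for donor in candidates:
            for acceptor in candidates:
                if donor >= acceptor:
                    continue
                if donor < span[0] or acceptor > span[1]:
                    continue
                j = JunctionRecord(model.chrom, donor, acceptor, "+")
                expected = _oracle_classify(donor, acceptor, exons, introns)
                assert ret.classify_junction(j, model) == expected, (donor, acceptor)
                checked += 1
        assert checked > 100


class TestCallRetentions:
    def test_annotated_only_yields_nothing(self, toy_gene):
        model, _ = toy_gene
        juncs = sim.gen_junction_file(model, [], include_annotated=True)
        assert ret.call_retentions(juncs, model) == []

    def test_read_threshold_filters(self, toy_gene):
        model, _ = toy_gene
        ev = sim.make_retention_event(model, 1, 20, supporting_reads=1)
        juncs = sim.gen_junction_file(model, [ev])
        assert ret.call_retentions(juncs, model, min_reads=2) == []
        assert len(ret.call_retentions(juncs, model, min_reads=1)) == 1

    def test_duplicate_junctions_merge_reads(self, toy_gene):
        model, _ = toy_gene
        ev = sim.make_retention_event(model, 1, 20, supporting_reads=3)
        juncs = sim.gen_junction_file(model, [ev, ev], include_annotated=False)
        (called,) = ret.call_retentions(juncs, model, min_reads=2)
        assert called.supporting_reads == 6

    def test_length_window(self, toy_gene):
        model, _ = toy_gene
        evs = [
            sim.make_retention_event(model, 1, n, supporting_reads=5)
            for n in (5, 38, 142)
        ]
        juncs = sim.gen_junction_file(model, evs, include_annotated=False)
        called = ret.call_retentions(juncs, model, min_reads=2, min_len=11, max_len=142)
        assert [e.fragment_length for e in called] == [38, 142]

    @pytest.mark.parametrize("n", [11, 38, 142])
    @pytest.mark.parametrize("end", ["5prime", "3prime"])
    def test_round_trip_recovers_length(self, toy_gene, n, end):
        model, _ = toy_gene
        ev = sim.make_retention_event(model, 1, n, end, supporting_reads=9)
        juncs = sim.gen_junction_file(model, [ev])
        (called,) = ret.call_retentions(juncs, model, min_reads=1)
        assert called.fragment_length == n
        assert called.retained_end == end
        assert called.intron_index == 1


class TestAberrantTranscript:
    def test_five_prime_retention_string_surgery(self):
        spec = sim.ToyGeneSpec(exon_lengths=(30, 30), intron_lengths=(60,), seed=2)
        model, genome = sim.gen_gene_model(spec)
        assert model.span == (1, 120)
        assert model.introns == ((31, 90),)
        ev = sim.make_retention_event(model, 1, 4, "5prime")
        seq, coord_map, last_j = ret.aberrant_transcript(model, genome, ev)
        normal = genome[:30] + genome[30:34] + genome[90:]
        assert seq == normal
        assert len(seq) == 64
        assert seq[30:34] == genome[30:34]  # first 4 intronic bases
        assert last_j == 34
        assert coord_map[30] == 31 and coord_map[34] == 91

    def test_minus_strand_mirror_gives_identical_transcript(
        self, toy_gene, toy_gene_minus
    ):
        model_p, genome_p = toy_gene
        model_m, genome_m = toy_gene_minus
        ev_p = sim.make_retention_event(model_p, 1, 38, "5prime")
        ev_m = sim.make_retention_event(model_m, 1, 38, "5prime")
        seq_p, _, lj_p = ret.aberrant_transcript(model_p, genome_p, ev_p)
        seq_m, _, lj_m = ret.aberrant_transcript(model_m, genome_m, ev_m)
        assert seq_p == seq_m
        assert lj_p == lj_m

    def test_event_outside_intron_errors(self, toy_gene):
        model, genome = toy_gene
        bad = ret.RetentionEvent(1, "5prime", 10, (1, 10))
        with pytest.raises(ValueError, match="inside its intron"):
            ret.aberrant_transcript(model, genome, bad)


class TestPredictConsequence:
    def test_one_nt_insertion_matches_translation_oracle(self):
        # normal CDS ATG AAA TAA -> protein "MK"; insert T after codon 1
        transcript = "ATGTAAATAACCC"
        pred = ret.predict_consequence(
            transcript, cds_offset=0, last_junction_pos=10,
            inserted_nt=1, annotated_protein="MK",
        )
        oracle = str(Seq(transcript[:12]).translate())
        assert oracle.index("*") + 1 == 2
        assert pred.frameshift
        assert pred.ptc_codon_index == 2
        assert pred.truncated_protein_length == 1

    def test_in_frame_insertion_extends_by_one(self, toy_gene):
        model, genome = toy_gene
        ev = sim.make_retention_event(model, 1, 3, "5prime")
        pred = ret.consequence_for_event(model, genome, ev)
        normal_len = len(model.protein(genome))
        assert not pred.frameshift
        assert pred.ptc_codon_index is None
        assert pred.truncated_protein_length == normal_len + 1

    @pytest.mark.parametrize("n", [1, 2, 3, 6, 38, 141, 142])
    def test_frameshift_iff_length_not_multiple_of_three(self, toy_gene, n):
        model, genome = toy_gene
        ev = sim.make_retention_event(model, 1, n, "5prime")
        pred = ret.consequence_for_event(model, genome, ev)
        assert pred.frameshift == (n % 3 != 0)
        if n % 3 == 0:
            assert pred.truncated_protein_length == len(model.protein(genome)) + n // 3

    def test_nmd_rule_50nt(self):
        # PTC at codon 2 (transcript position 4); junction far downstream
        transcript = "ATGTAAATAA" + "C" * 100
        pred = ret.predict_consequence(
            transcript, 0, last_junction_pos=100, inserted_nt=1, annotated_protein="MK"
        )
        assert pred.nmd_sensitive
        near = ret.predict_consequence(
            transcript, 0, last_junction_pos=20, inserted_nt=1, annotated_protein="MK"
        )
        assert not near.nmd_sensitive

    def test_non_stop_flagged(self):
        with pytest.warns(UserWarning, match="non-stop"):
            pred = ret.predict_consequence(
                "ATGAAAAAAAAA", 0, 6, 1, annotated_protein="MK"
            )
        assert pred.non_stop
        assert pred.ptc_codon_index is None


class TestProteinMW:
    def test_glycine_residue_mass(self):
        assert ret.protein_mw("G") * 1000 == pytest.approx(75.07, abs=0.01)

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="empty"):
            ret.protein_mw("")

    def test_unknown_residue_named(self):
        with pytest.raises(ValueError, match="B"):
            ret.protein_mw("GAB")

    def test_mass_additivity(self):
        rng = np.random.default_rng(0)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(10):
            s1 = "".join(rng.choice(list(aas), size=rng.integers(1, 30)))
            s2 = "".join(rng.choice(list(aas), size=rng.integers(1, 30)))
            lhs = ret.protein_mw(s1 + s2) * 1000
            rhs = (ret.protein_mw(s1) + ret.protein_mw(s2)) * 1000 - ret.WATER_DA
            assert lhs == pytest.approx(rhs, abs=1e-6)
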