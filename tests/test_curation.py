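"""Placement, isoform/allele/paralog calls, keyword screening and
catalogue reconciliation."""

import numpy as np
import pytest

from amp_arsenal import synthetic_panel
from amp_arsenal.curation import (
    GeneRecord,
    TranscriptRecord,
    build_catalogue,
    classify_pair,
    keyword_screen,
    mrna_differences,
    place_transcript,
)
from amp_arsenal.sequence_io import ScaffoldSeq, revcomp
from amp_arsenal.synthetic_data import FamilySpec, make_family, make_isoforms


def _tr(tid, mrna, cds_span=(1, 3), family="defensin", placement=None):
    return TranscriptRecord(tid, mrna, cds_span, family=family, placement=placement)


def _rand_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestPlaceTranscript:
    def test_exact_substring_single_block_intron_free(self, rng):
        t_seq = _rand_dna(rng, 400)
        scf = ScaffoldSeq.from_seq("s1", _rand_dna(rng, 300) + t_seq + _rand_dna(rng, 300))
        pl = place_transcript(_tr("t", t_seq, (1, 300)), [scf])
        assert pl is not None and pl.coverage == 1.0
        assert len(pl.blocks) == 1 and not pl.introns

    def test_two_exon_transcript_across_gt_ag_intron(self, rng):
        # boundary bases fixed so exact-match blocks end exactly at the
        # splice sites (no accidental extension into the intron)
        e1 = _rand_dna(rng, 119) + "A"
        e2 = "C" + _rand_dna(rng, 149)
        intron = "GT" + _rand_dna(rng, 80) + "AG"
        scf = ScaffoldSeq.from_seq(
            "s1", _rand_dna(rng, 200) + e1 + intron + e2 + _rand_dna(rng, 200))
        pl = place_transcript(_tr("t", e1 + e2, (1, 200)), [scf])
        assert pl is not None and len(pl.blocks) == 2
        assert len(pl.introns) == 1 and pl.introns[0][2] is True  # canonical

    def test_reverse_strand_placement(self, rng):
        t_seq = _rand_dna(rng, 300)
        scf = ScaffoldSeq.from_seq(
            "s1", _rand_dna(rng, 100) + revcomp(t_seq) + _rand_dna(rng, 100))
        pl = place_transcript(_tr("t", t_seq, (1, 200)), [scf])
        assert pl is not None and pl.strand == "-" and pl.coverage == 1.0

    def test_exon_lost_in_assembly_gap_sets_gap_flag(self, rng):
        e1, e2 = _rand_dna(rng, 100), _rand_dna(rng, 200)
        # first exon replaced by an N-gap in the scaffold
        scf = ScaffoldSeq.from_seq(
            "s1", _rand_dna(rng, 150) + "N" * 100 + e2 + _rand_dna(rng, 150))
        pl = place_transcript(_tr("t", e1 + e2, (1, 250)), [scf], min_coverage=0.5)
        assert pl is not None
        assert pl.coverage < 0.9  # only the second exon anchors
        assert pl.gap_flags  # the flanking N-run is reported

    def test_unrelated_transcript_unplaced(self, rng):
        scf = ScaffoldSeq.from_seq("s1", _rand_dna(rng, 600))
        assert place_transcript(_tr("t", _rand_dna(rng, 300), (1, 200)), [scf]) is None

    def test_non_dna_rejected(self, rng):
        scf = ScaffoldSeq.from_seq("s1", _rand_dna(rng, 100))
        with pytest.raises(ValueError):
            place_transcript(_tr("t", "ACGU" * 30, (1, 10)), [scf])


class TestMrnaDifferences:
    def test_substitutions_counted_per_site(self):
        assert mrna_differences("ACGTACGT", "ACCTACCT") == 2

    def test_multibase_indel_counts_once(self):
        assert mrna_differences("AAATTTCCC", "AAACCC") == 1

    def test_mixed_case_from_study(self):
        # a 9-nt deletion plus one substitution: 2 total differences
        a = "ACGTACGTA" + "GGGCCCTTT" + "ACGTACGTA"
        b = "ACGTACGTA" + "ACGTACGTA"
        b = b[:12] + ("T" if b[12] != "T" else "G") + b[13:]
        assert mrna_differences(a, b) == 2


class TestClassifyPair:
    @pytest.fixture()
    def placed_pair(self, rng):
        genes, scaffolds = make_family(FamilySpec("defensin", 2, 0.02), seed=8)
        trs = []
        for g in genes:
            t = _tr(g.record.name, g.mrna, (len(g.utr5) + 1, len(g.utr5) + len(g.record.cds)))
            t.placement = place_transcript(t, scaffolds)
            trs.append(t)
        return trs

    def test_retained_utr_intron_isoforms(self):
        genes, scaffolds = make_family(
            FamilySpec("defensin", 1, 0.0, utr3_intron_len=453), seed=1)
        i1, i2 = make_isoforms(genes[0], intron_len=453)
        assert len(i2.mrna) - len(i1.mrna) == 453
        for t in (i1, i2):
            t.placement = place_transcript(t, scaffolds)
        assert t.placement is not None
        assert classify_pair(i1, i2) == "isoform"

    def test_unplaced_pair_with_two_differences_is_allele(self, rng):
        mrna = _rand_dna(rng, 240)
        # one 9-nt deletion in the 5' UTR plus one substitution
        other = mrna[9:]
        other = other[:100] + ("A" if other[100] != "A" else "C") + other[101:]
        t1, t2 = _tr("a", mrna), _tr("b", other)
        assert classify_pair(t1, t2) == "allele"

    def test_six_differences_is_paralog_even_unplaced(self):
        mrna = "ACGT" * 60
        other = list(mrna)
        for i in (10, 50, 90, 130, 170, 210):
            other[i] = "A" if other[i] != "A" else "C"
        assert classify_pair(_tr("a", mrna), _tr("b", "".join(other))) == "paralog"

    def test_distinct_loci_paralog_despite_identical_cds(self, rng):
        seq = _rand_dna(rng, 300)
        scf = ScaffoldSeq.from_seq(
            "s1", seq + _rand_dna(rng, 400) + seq + _rand_dna(rng, 100))
        t1, t2 = _tr("a", seq, (1, 200)), _tr("b", seq, (1, 200))
        from amp_arsenal.curation import Placement

        t1.placement = Placement("s1", "+", [(1, 300, 1, 300)], 1.0)
        t2.placement = Placement("s1", "+", [(1, 300, 701, 1000)], 1.0)
        assert classify_pair(t1, t2) == "paralog"

    def test_symmetric(self, placed_pair):
        t1, t2 = placed_pair
        assert classify_pair(t1, t2) == classify_pair(t2, t1)

    def test_different_families_rejected(self):
        with pytest.raises(ValueError):
            classify_pair(_tr("a", "ACGT" * 20, family="defensin"),
                          _tr("b", "ACGT" * 20, family="termicin"))


class TestKeywordScreen:
    def test_tenecin_matches_case_insensitively(self):
        assert keyword_screen({"x": "Tenecin-1"}) == ["x"]

    def test_giant_lens_excluded(self):
        prods = {"a": "Attacin-like protein", "b": "Giant-lens protein"}
        assert keyword_screen(prods) == ["a"]

    def test_empty_keyword_list_returns_nothing(self):
        assert keyword_screen({"a": "Tenecin-1"}, keywords=()) == []


class TestBuildCatalogue:
    def test_panel_reconciliation_counts(self):
        mrnas = synthetic_panel.panel_mrnas()
        transcripts = [TranscriptRecord(g, seq, span)
                       for g, (seq, span) in mrnas.items()]
        recs = build_catalogue(transcripts, synthetic_panel.panel_scaffolds().values())
        assert len(recs) == 39
        assert sum(1 for r in recs if r.scaffold == "Unplaced") == 5
        assert len({r.scaffold for r in recs if r.scaffold != "Unplaced"}) == 10

    def test_identical_cds_distinct_placements_stay_separate(self):
        genes, scaffolds = make_family(FamilySpec("termicin", 3, 0.0), seed=2)
        transcripts = []
        for i, g in enumerate(genes):
            # distinct UTRs so each transcript anchors best at its own locus
            span = (len(g.utr5) + 1, len(g.utr5) + len(g.record.cds))
            transcripts.append(TranscriptRecord(f"t{i}", g.mrna, span))
        recs = build_catalogue(transcripts, scaffolds)
        assert len(recs) == 3  # identical CDS, but three loci

    def test_lone_unplaced_transcript_yields_one_unplaced_record(self, rng):
        cds = synthetic_panel.panel_cds()["termicin_g1"]
        t = TranscriptRecord("t", _rand_dna(rng, 30) + cds + _rand_dna(rng, 30),
                             (31, 30 + len(cds)))
        scf = ScaffoldSeq.from_seq("s1", _rand_dna(rng, 500))
        recs = build_catalogue([t], [scf])
        assert len(recs) == 1 and recs[0].scaffold == "Unplaced"
        assert recs[0].family == "termicin"

    def test_tandem_copy_split_into_two_records(self, rng):
        genes, _ = make_family(FamilySpec("defensin", 1, 0.0), seed=3)
        g = genes[0]
        locus = g.mrna
        scf = ScaffoldSeq.from_seq(
            "s1", _rand_dna(rng, 200) + locus + _rand_dna(rng, 150)
            + locus + _rand_dna(rng, 200))
        span = (len(g.utr5) + 1, len(g.utr5) + len(g.record.cds))
        recs = build_catalogue([TranscriptRecord("t", g.mrna, span)], [scf])
        assert len(recs) == 2  # one annotated mRNA spanning two gene copies

    def test_deterministic_names_and_order(self):
        mrnas = synthetic_panel.panel_mrnas()
        def run():
            ts = [TranscriptRecord(g, seq, span) for g, (seq, span) in mrnas.items()]
            return [r.name for r in
                    build_catalogue(ts, synthetic_panel.panel_scaffolds().values())]
        names = run()
        assert names == run()
        assert names[0].startswith("defensin_g1")
        fams = [n.split("_g")[0] for n in names]
        order = ["defensin", "termicin", "drosomycin", "attacin-like", "blattellicin"]
        assert fams == sorted(fams, key=order.index)
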