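import math

import pandas as pd
import pytest

from denovotx.formats import Annotation, FeatureRecord
from denovotx.homology import MatchCriterion, SeqIndex
from denovotx.screen import (
    GenomicLocus,
    PipelineConfig,
    TranscriptRecord,
    annotation_screen,
    exon_distance,
    expression_filter,
    genic_context,
    load_transcripts,
    outgroup_transcript_screen,
    parse_trinity_id,
    place_on_genome,
    structural_filter,
)

from conftest import random_seq


class TestTrinityIds:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("TRINITY_DN7862_c0_g3_i2", ("TRINITY_DN7862_c0_g3", 2)),
            ("TRINITY_DN90_c0_g3", ("TRINITY_DN90_c0_g3", 1)),
            ("TRINITY_DN1_c12_g40_i17", ("TRINITY_DN1_c12_g40", 17)),
        ],
    )
    def test_parses_group_and_isoform(self, text, expected):
        assert parse_trinity_id(text) == expected

    def test_strict_mode_rejects_foreign_ids(self):
        with pytest.raises(ValueError, match="Trinity"):
            parse_trinity_id("foo_bar", strict=True)

    def test_lenient_mode_makes_singleton_group(self):
        assert parse_trinity_id("foo_bar") == ("foo_bar", 1)


def _ann(*features):
    return Annotation(list(features))


def _locus(start, end, chrom="chr1"):
    return GenomicLocus(chrom, start, end, "+", 1.0)


class TestExonDistance:
    def test_overlap_gives_zero(self):
        ann = _ann(FeatureRecord("chr1", 1000, 1400, "+", "exon", "g", "t"))
        assert exon_distance(_locus(1200, 1600), ann) == 0

    def test_gap_in_half_open_coordinates(self):
        ann = _ann(FeatureRecord("chr1", 500, 750, "+", "exon", "g", "t"))
        assert exon_distance(_locus(1000, 1500), ann) == 250

    def test_adjacency_gives_zero(self):
        ann = _ann(FeatureRecord("chr1", 500, 1000, "+", "exon", "g", "t"))
        assert exon_distance(_locus(1000, 1500), ann) == 0

    def test_empty_annotation_is_infinite(self):
        assert exon_distance(_locus(10, 20), _ann()) == math.inf

    def test_other_chromosome_exons_do_not_count(self):
        ann = _ann(FeatureRecord("chr2", 1000, 1200, "+", "exon", "g", "t"))
        assert exon_distance(_locus(1000, 1200, "chr1"), ann) == math.inf


class TestGenicContext:
    GENE = FeatureRecord("chr1", 1000, 5000, "+", "gene", "g")
    EX1 = FeatureRecord("chr1", 1000, 1500, "+", "exon", "g", "t")
    EX2 = FeatureRecord("chr1", 4500, 5000, "+", "exon", "g", "t")

    def test_inside_intron_is_intronic(self):
        ann = _ann(self.GENE, self.EX1, self.EX2)
        assert genic_context(_locus(2000, 2500), ann) == "intronic"

    def test_between_genes_is_intergenic(self):
        ann = _ann(self.GENE, self.EX1, self.EX2)
        assert genic_context(_locus(8000, 8500), ann) == "intergenic"

    def test_exon_overlap_is_genic(self):
        ann = _ann(self.GENE, self.EX1, self.EX2)
        assert genic_context(_locus(1400, 1900), ann) == "genic_overlap"

    def test_forty_percent_straddle_is_intergenic(self):
        # locus [4600, 5600) has 400/1000 inside the gene span — below the
        # 50% rule — but overlaps EX2, so use a gene without that exon
        gene = FeatureRecord("chr1", 1000, 5000, "+", "gene", "g")
        ex = FeatureRecord("chr1", 1000, 1500, "+", "exon", "g", "t")
        ann = _ann(gene, ex)
        assert genic_context(_locus(4600, 5600), ann) == "intergenic"
        # exactly 50% inside ([4600,5400) vs gene end 5000) hits the rule
        assert genic_context(_locus(4600, 5400), ann) == "intronic"


class TestStructuralFilter:
    CFG = PipelineConfig()

    def _run(self, length, distance_exon_end):
        # exon placed so that locus start - exon end == distance_exon_end
        locus_start = 10_000
        ann = _ann(
            FeatureRecord("chr1", 5000, locus_start - distance_exon_end, "+", "exon", "g", "t")
        )
        tr = TranscriptRecord("TRINITY_DN1_c0_g1_i1", "TRINITY_DN1_c0_g1", 1, "A" * length)
        return structural_filter(tr, _locus(locus_start, locus_start + length), ann, self.CFG)

    def test_boundary_length_and_distance_pass(self):
        assert self._run(302, 251) == (True, None)

    def test_length_exactly_300_fails_short(self):
        assert self._run(300, 251) == (False, "short")

    def test_distance_exactly_250_fails_near_exon(self):
        assert self._run(302, 250) == (False, "near_exon")

    def test_first_violated_rule_reported(self):
        # violates both length and distance: length is reported
        assert self._run(299, 10) == (False, "short")


class TestExpressionFilter:
    CFG = PipelineConfig()

    def _isoforms(self, *lengths):
        return [
            TranscriptRecord(f"TRINITY_DN5_c0_g1_i{m + 1}", "TRINITY_DN5_c0_g1", m + 1, "A" * n)
            for m, n in enumerate(lengths)
        ]

    def test_tpm_exactly_one_passes(self):
        isos = self._isoforms(400)
        tpm = pd.DataFrame({"lib1": [1.0]}, index=[isos[0].transcript_id])
        ok, _ = expression_filter("g", isos, {isos[0].transcript_id: True}, tpm, self.CFG)
        assert ok

    def test_max_tpm_below_one_fails(self):
        isos = self._isoforms(400)
        tpm = pd.DataFrame({"lib1": [0.99], "lib2": [0.5]}, index=[isos[0].transcript_id])
        ok, _ = expression_filter("g", isos, {isos[0].transcript_id: True}, tpm, self.CFG)
        assert not ok

    def test_group_passes_via_one_qualifying_isoform(self):
        # i1 passes everything; i2 is structurally short but is retained
        isos = self._isoforms(400, 250)
        tpm = pd.DataFrame(
            {"lib1": [1.4, 0.2]}, index=[t.transcript_id for t in isos]
        )
        ok, _ = expression_filter(
            "g", isos,
            {isos[0].transcript_id: True, isos[1].transcript_id: False},
            tpm, self.CFG,
        )
        assert ok

    def test_absent_isoform_rows_count_as_zero(self):
        isos = self._isoforms(400)
        tpm = pd.DataFrame({"lib1": [5.0]}, index=["other"])
        ok, max_tpm = expression_filter(
            "g", isos, {isos[0].transcript_id: True}, tpm, self.CFG
        )
        assert not ok and max_tpm[isos[0].transcript_id] == 0.0


class TestPlacement:
    def test_exact_copy_recovers_locus(self, rng):
        genome = random_seq(rng, 30_000)
        idx = SeqIndex([("chr1", genome)])
        tr = TranscriptRecord("TRINITY_DN2_c0_g1_i1", "TRINITY_DN2_c0_g1", 1,
                              genome[10_000:10_500])
        locus = place_on_genome(tr, idx, MatchCriterion())
        assert (locus.chrom, locus.start, locus.end) == ("chr1", 10_000, 10_500)
        assert locus.placement_identity == 1.0 and not locus.chimeric

    def test_two_exon_transcript_merges_across_genomic_gap(self, rng):
        genome = random_seq(rng, 30_000)
        idx = SeqIndex([("chr1", genome)])
        seq = genome[5000:5400] + genome[5700:6100]  # 300 bp genomic gap
        tr = TranscriptRecord("TRINITY_DN3_c0_g1_i1", "TRINITY_DN3_c0_g1", 1, seq)
        locus = place_on_genome(tr, idx, MatchCriterion())
        assert (locus.start, locus.end) == (5000, 6100)

    def test_random_sequence_is_unplaced(self, rng):
        genome = random_seq(rng, 30_000)
        idx = SeqIndex([("chr1", genome)])
        tr = TranscriptRecord("TRINITY_DN4_c0_g1_i1", "TRINITY_DN4_c0_g1", 1,
                              random_seq(rng, 500))
        assert place_on_genome(tr, idx, MatchCriterion()) is None


class TestScreens:
    def test_database_order_changes_evidence_not_membership(self, rng):
        cds = random_seq(rng, 800)
        te = random_seq(rng, 800)
        transcripts = load_transcripts(
            [
                ("TRINITY_DN10_c0_g1_i1", cds[100:500]),   # matches both dbs? no: cds only
                ("TRINITY_DN11_c0_g1_i1", te[100:500]),
                ("TRINITY_DN12_c0_g1_i1", random_seq(rng, 400)),
            ]
        )
        idx_cds = SeqIndex([("cds1", cds)])
        idx_te = SeqIndex([("te1", te)])
        order_a = {("focal", "CDS"): idx_cds, ("focal", "transposon"): idx_te}
        order_b = {("focal", "transposon"): idx_te, ("focal", "CDS"): idx_cds}
        surv_a, rem_a = annotation_screen(transcripts, order_a, MatchCriterion())
        surv_b, rem_b = annotation_screen(transcripts, order_b, MatchCriterion())
        assert [t.transcript_id for t in surv_a] == [t.transcript_id for t in surv_b]
        assert set(rem_a) == set(rem_b)

    def test_empty_annotation_database_set_rejected(self):
        with pytest.raises(ValueError, match="at least one database"):
            annotation_screen([], {}, MatchCriterion())

    def test_outgroup_screen_on_empty_transcript_list(self):
        surv, rem = outgroup_transcript_screen([], {}, MatchCriterion())
        assert surv == [] and rem == {}


class TestCascadeOnDefaultRun:
    def test_stage_counts_partition_the_input(self, pipeline_run):
        trace = pipeline_run.trace
        assert sum(trace.stage_counts().values()) == len(trace)
        assert len(trace) == len(pipeline_run.dataset.transcripts)

    def test_candidates_carry_loci_and_isoforms(self, pipeline_run):
        for cand in pipeline_run.candidates:
            assert cand.locus is not None
            assert cand.locus.placement_identity >= 0.80
            assert len(cand.isoforms) >= 1

    def test_rescued_short_isoform_is_retained_with_its_group(self, pipeline_run):
        ds = pipeline_run.dataset
        short_isos = [
            t for t, s in ds.transcripts
            if len(s) <= 300
            and ds.truth.set_index("transcript_id").loc[t, "class"] == "true_denovo"
        ]
        assert short_isos, "default plan should plant a rescued short isoform"
        retained = {
            iso.transcript_id for c in pipeline_run.candidates for iso in c.isoforms
        }
        for tid in short_isos:
            assert tid in retained
            assert "retained_via_group" in pipeline_run.trace.evidence(tid)
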