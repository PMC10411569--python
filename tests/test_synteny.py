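import pandas as pd
import pytest

from denovotx.formats import Annotation, FeatureRecord
from denovotx.screen import CandidateGene, GenomicLocus, TranscriptRecord
from denovotx.synteny import (
    SyntenyResult,
    SpeciesSynteny,
    build_query_region,
    flanking_genes,
    locate_orthologs,
    run_synteny,
    tier_candidates,
    validate_microsynteny,
)

from conftest import random_seq


def _locus(start, end, chrom="chr1"):
    return GenomicLocus(chrom, start, end, "+", 1.0)


def _gene(gid, start, end, chrom="chr1"):
    return FeatureRecord(chrom, start, end, "+", "gene", gid)


class TestFlankingGenes:
    def test_genes_either_side(self):
        ann = Annotation([_gene("A", 0, 10_000), _gene("B", 20_000, 30_000)])
        assert flanking_genes(_locus(12_000, 13_000), ann) == ("A", "B")

    def test_locus_before_first_gene(self):
        ann = Annotation([_gene("B", 20_000, 30_000)])
        assert flanking_genes(_locus(1000, 2000), ann) == (None, "B")

    def test_tie_breaks_to_lower_gene_id(self):
        # two genes ending at the same boundary upstream of the locus
        ann = Annotation([_gene("Z", 0, 10_000), _gene("A", 5000, 10_000)])
        up, down = flanking_genes(_locus(12_000, 13_000), ann)
        assert up == "A" and down is None


class TestQueryRegion:
    GENOME = {"chr1": "A" * 1_000_000}

    def test_flank_arithmetic(self):
        seq, span, clipped = build_query_region(self.GENOME, _locus(10_000, 10_500))
        assert span == (5000, 15_500) and len(seq) == 10_500 and not clipped

    def test_clipped_at_chromosome_start(self):
        _seq, span, clipped = build_query_region(self.GENOME, _locus(2000, 2500))
        assert span == (0, 7500) and clipped

    def test_zero_flank_is_locus_only(self):
        _seq, span, _ = build_query_region(self.GENOME, _locus(100, 200), flank=0)
        assert span == (100, 200)


class TestLocateOrthologs:
    TABLE = pd.DataFrame(
        {
            "focal_gene_id": ["gA", "gB"],
            "outgroup_species": ["sp1", "sp1"],
            "ortholog_gene_id": ["sp1_gA", "sp1_gB"],
            "chrom": ["scf1", "scf1"],
            "start": [100, 900],
            "end": [500, 1200],
        }
    )

    def test_present_gene_returns_locus(self):
        loci = locate_orthologs(["gA"], self.TABLE, "sp1")
        assert loci["gA"] == ("scf1", 100, 500)

    def test_absent_gene_marked_none(self):
        assert locate_orthologs(["gX"], self.TABLE, "sp1")["gX"] is None

    def test_unknown_species_rejected(self):
        with pytest.raises(ValueError, match="absent from the ortholog table"):
            locate_orthologs(["gA"], self.TABLE, "nope")

    def test_falls_back_to_outgroup_annotation(self):
        table = self.TABLE.drop(columns=["chrom", "start", "end"])
        ann = Annotation([_gene("sp1_gA", 4000, 4600, chrom="scfX")])
        loci = locate_orthologs(["gA"], table, "sp1", ann)
        assert loci["gA"] == ("scfX", 4000, 4600)


class TestValidateMicrosynteny:
    def _world(self, rng):
        """Focal chromosome: geneA, candidate, geneB embedded in random
        sequence; returns pieces for constructing outgroup variants."""
        up = random_seq(rng, 3000)
        geneA = random_seq(rng, 2000)
        inter1 = random_seq(rng, 1500)
        cand = random_seq(rng, 600)
        inter2 = random_seq(rng, 1500)
        geneB = random_seq(rng, 2000)
        down = random_seq(rng, 3000)
        chrom = up + geneA + inter1 + cand + inter2 + geneB + down
        a0 = len(up)
        b0 = a0 + len(geneA) + len(inter1) + len(cand) + len(inter2)
        cand_start = a0 + len(geneA) + len(inter1)
        return {
            "chrom": chrom,
            "geneA": (a0, a0 + 2000),
            "geneB": (b0, b0 + 2000),
            "cand": (cand_start, cand_start + 600),
            "parts": (up, geneA, inter1, cand, inter2, geneB, down),
        }

    def test_identical_outgroup_validates(self, rng):
        w = self._world(rng)
        region, _, _ = build_query_region({"c": w["chrom"]}, _locus(*w["cand"], chrom="c"))
        loci = {"gA": ("c", *w["geneA"]), "gB": ("c", *w["geneB"])}
        ok, reason, match = validate_microsynteny("cand", region, loci, {"c": w["chrom"]})
        assert ok and reason == "validated" and match.identity >= 0.99

    def test_split_flanks_fail(self, rng):
        w = self._world(rng)
        up, geneA, inter1, cand, inter2, geneB, down = w["parts"]
        scf1 = up + geneA + inter1
        scf2 = inter2 + geneB + down
        region, _, _ = build_query_region({"c": w["chrom"]}, _locus(*w["cand"], chrom="c"))
        loci = {
            "gA": ("scf1", len(up), len(up) + 2000),
            "gB": ("scf2", len(inter2), len(inter2) + 2000),
        }
        ok, reason, _ = validate_microsynteny(
            "cand", region, loci, {"scf1": scf1, "scf2": scf2}
        )
        assert not ok and reason == "split_flanks"

    def test_no_located_flank_orthologs_fail(self, rng):
        w = self._world(rng)
        region, _, _ = build_query_region({"c": w["chrom"]}, _locus(*w["cand"], chrom="c"))
        ok, reason, _ = validate_microsynteny(
            "cand", region, {"gA": None, "gB": None}, {"c": w["chrom"]}
        )
        assert not ok and reason == "no_flank_orthologs"

    def test_single_located_flank_suffices(self, rng):
        w = self._world(rng)
        region, _, _ = build_query_region({"c": w["chrom"]}, _locus(*w["cand"], chrom="c"))
        loci = {"gA": ("c", *w["geneA"]), "gB": None}
        ok, reason, _ = validate_microsynteny("cand", region, loci, {"c": w["chrom"]})
        assert ok

    def test_candidate_deleted_from_outgroup_still_validates(self, rng):
        # the check certifies region orthology, not transcript presence:
        # replace the candidate's own sequence with unrelated bases
        w = self._world(rng)
        up, geneA, inter1, cand, inter2, geneB, down = w["parts"]
        og = up + geneA + inter1 + random_seq(rng, 600) + inter2 + geneB + down
        region, _, _ = build_query_region({"c": w["chrom"]}, _locus(*w["cand"], chrom="c"))
        loci = {"gA": ("c", *w["geneA"]), "gB": ("c", *w["geneB"])}
        ok, reason, _ = validate_microsynteny("cand", region, loci, {"c": og})
        assert ok


class TestTiers:
    def _result(self, flags):
        res = SyntenyResult("c1")
        for i, v in enumerate(flags):
            res.per_species[f"sp{i}"] = SpeciesSynteny(
                f"sp{i}", "gA", "gB", {}, v, "x"
            )
        return res

    @pytest.mark.parametrize(
        "flags,tier",
        [((True, True), "both_outgroups"), ((True, False), "one_outgroup"),
         ((False, True), "one_outgroup"), ((False, False), "none")],
    )
    def test_tier_assignment(self, flags, tier):
        assert self._result(flags).tier == tier

    def test_tiers_partition_candidates(self, pipeline_run):
        tiers = tier_candidates(pipeline_run.synteny)
        assert set(tiers) == {c.candidate_id for c in pipeline_run.candidates}
        counts = pipeline_run.manifest.tier_counts
        assert sum(counts.values()) == len(pipeline_run.candidates)
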