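"""Microsynteny validation of candidate loci against outgroup genomes.

For each candidate locus the annotated genes immediately upstream and
downstream are located, their orthologs looked up in the ortholog table,
and the candidate region (locus plus 5 kb flanks) searched for homology
on the outgroup scaffold carrying those orthologs, within the interval
they span extended by 50 kb on each side.  Validation certifies that the
*region* is orthologous — a match to flank sequence alone suffices, since
the candidate itself may be diverged or absent in the outgroup.
Candidates are never removed here, only tiered (``both_outgroups`` /
``one_outgroup`` / ``none``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .formats import Annotation
from .homology import AlignmentMatch, MatchCriterion, Scoring, SeqIndex, has_match

__all__ = [
    "SyntenyResult",
    "flanking_genes",
    "build_query_region",
    "locate_orthologs",
    "validate_microsynteny",
    "tier_candidates",
    "run_synteny",
    "ORTHOLOG_WINDOW_PAD",
]

ORTHOLOG_WINDOW_PAD = 50_000

TIERS = ("both_outgroups", "one_outgroup", "none")


@dataclass
class SpeciesSynteny:
    species: str
    upstream_gene: str | None
    downstream_gene: str | None
    ortholog_loci: dict  # focal gene id -> (chrom, start, end) or None
    validated: bool
    reason: str
    region_match: AlignmentMatch | None = None


@dataclass
class SyntenyResult:
    candidate_id: str
    per_species: dict[str, SpeciesSynteny] = field(default_factory=dict)

    @property
    def tier(self) -> str:
        n = sum(1 for s in self.per_species.values() if s.validated)
        if n >= 2:
            return "both_outgroups"
        if n == 1:
            return "one_outgroup"
        return "none"


def flanking_genes(locus, annotation: Annotation) -> tuple[str | None, str | None]:
    """Nearest gene ending before the locus and nearest starting after it,
    same chromosome, either strand; boundary-distance ties break to the
    lower gene id."""
    up_best = None   # (distance, gene_id)
    down_best = None
    for gid, (chrom, gs, ge, _strand) in annotation.gene_spans.items():
        if chrom != locus.chrom:
            continue
        if ge <= locus.start:
            key = (locus.start - ge, gid)
            if up_best is None or key < up_best:
                up_best = key
        elif gs >= locus.end:
            key = (gs - locus.end, gid)
            if down_best is None or key < down_best:
                down_best = key
    return (up_best[1] if up_best else None, down_best[1] if down_best else None)


def build_query_region(
    focal_genome: dict[str, str], locus, flank: int = 5000
) -> tuple[str, tuple[int, int], bool]:
    """Focal sequence spanning the locus with ``flank`` bp each side,
    clipped at chromosome boundaries (clipping flagged)."""
    chrom_seq = focal_genome[locus.chrom]
    start = locus.start - flank
    end = locus.end + flank
    clipped = start < 0 or end > len(chrom_seq)
    start = max(0, start)
    end = min(len(chrom_seq), end)
    return chrom_seq[start:end], (start, end), clipped


def locate_orthologs(
    gene_ids,
    ortholog_table: pd.DataFrame,
    species: str,
    outgroup_annotation: Annotation | None = None,
) -> dict[str, tuple[str, int, int] | None]:
    """Outgroup loci of the given focal genes' orthologs.

    The table locus columns are used when present; otherwise the ortholog
    id is looked up in the outgroup annotation.  Missing entries map to
    None.
    """
    if species not in set(ortholog_table["outgroup_species"]):
        raise ValueError(f"species {species!r} absent from the ortholog table")
    sub = ortholog_table[ortholog_table["outgroup_species"] == species]
    by_gene = sub.set_index("focal_gene_id")
    out: dict[str, tuple[str, int, int] | None] = {}
    for gid in gene_ids:
        if gid is None or gid not in by_gene.index:
            out[gid] = None
            continue
        row = by_gene.loc[gid]
        if "chrom" in row.index and pd.notna(row.get("chrom")):
            out[gid] = (str(row["chrom"]), int(row["start"]), int(row["end"]))
        elif outgroup_annotation is not None:
            span = outgroup_annotation.gene_spans.get(str(row["ortholog_gene_id"]))
            out[gid] = (span[0], span[1], span[2]) if span else None
        else:
            out[gid] = None
    return out


def validate_microsynteny(
    candidate_id: str,
    query_region: str,
    ortholog_loci: dict[str, tuple[str, int, int] | None],
    outgroup_genome: dict[str, str],
    criterion: MatchCriterion = MatchCriterion(),
    scoring: Scoring = Scoring(),
    window_pad: int = ORTHOLOG_WINDOW_PAD,
    k: int = 11,
) -> tuple[bool, str, AlignmentMatch | None]:
    """Per-species microsynteny test.

    Validated iff (a) the located flank-ortholog loci lie on one outgroup
    scaffold (one located flank suffices to define it; zero is automatic
    failure), and (b) the query region has a qualifying homologous segment
    on that scaffold within the ortholog interval extended by
    ``window_pad`` each side.  Returns (validated, reason, match).
    """
    located = [v for v in ortholog_loci.values() if v is not None]
    if not located:
        return False, "no_flank_orthologs", None
    scaffolds = {v[0] for v in located}
    if len(scaffolds) > 1:
        return False, "split_flanks", None
    scaffold = located[0][0]
    if scaffold not in outgroup_genome:
        return False, f"scaffold_missing:{scaffold}", None
    lo = max(0, min(v[1] for v in located) - window_pad)
    hi = min(len(outgroup_genome[scaffold]), max(v[2] for v in located) + window_pad)
    window = outgroup_genome[scaffold][lo:hi]
    if len(window) < criterion.min_len:
        return False, "window_too_small", None
    idx = SeqIndex([(scaffold, window)], k=k)
    ok, best = has_match(query_region, idx, criterion, scoring, query_id=candidate_id)
    if not ok:
        return False, "no_region_homology", None
    shifted = AlignmentMatch(
        query_id=best.query_id,
        subject_id=best.subject_id,
        q_start=best.q_start,
        q_end=best.q_end,
        s_start=best.s_start + lo,
        s_end=best.s_end + lo,
        strand=best.strand,
        aligned_len=best.aligned_len,
        identity=best.identity,
        score=best.score,
    )
    return True, "validated", shifted


def tier_candidates(results: dict[str, SyntenyResult]) -> dict[str, str]:
    """Tier by number of outgroups validated; candidates are never removed."""
    return {cid: r.tier for cid, r in results.items()}


def run_synteny(
    candidates,
    annotation: Annotation,
    focal_genome: dict[str, str],
    ortholog_table: pd.DataFrame,
    outgroup_genomes: dict[str, dict[str, str]],
    criterion: MatchCriterion = MatchCriterion(),
    scoring: Scoring = Scoring(),
    flank: int = 5000,
    outgroup_annotations: dict[str, Annotation] | None = None,
    k: int = 11,
) -> dict[str, SyntenyResult]:
    """Validate every candidate against every outgroup genome."""
    results: dict[str, SyntenyResult] = {}
    for cand in candidates:
        res = SyntenyResult(candidate_id=cand.candidate_id)
        if cand.locus is None:
            results[cand.candidate_id] = res
            continue
        up, down = flanking_genes(cand.locus, annotation)
        region, _span, _clipped = build_query_region(focal_genome, cand.locus, flank)
        for species, genome in sorted(outgroup_genomes.items()):
            og_ann = (outgroup_annotations or {}).get(species)
            loci = locate_orthologs(
                [g for g in (up, down) if g is not None],
                ortholog_table,
                species,
                og_ann,
            )
            validated, reason, match = validate_microsynteny(
                cand.candidate_id, region, loci, genome, criterion, scoring, k=k
            )
            res.per_species[species] = SpeciesSynteny(
                species=species,
                upstream_gene=up,
                downstream_gene=down,
                ortholog_loci=loci,
                validated=validated,
                reason=reason,
                region_match=match,
            )
        results[cand.candidate_id] = res
    return results
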