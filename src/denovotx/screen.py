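"""The filter cascade that turns assembled transcripts into candidates.

Stages, applied in order, each transcript terminating at exactly one:

1. ``annotation_match``   — homology to any annotation-class database of
   any species (3'UTR, 5'UTR, intron, miRNA, miscRNA, ncRNA, pseudogene,
   transposon, tRNA, CDS);
2. ``outgroup_transcript_match`` — homology to any outgroup assembled
   transcript database;
3. ``unplaced``           — no qualifying placement on the focal genome;
4. ``short`` / ``near_exon`` / ``not_intergenic`` — structural filters
   (length > 300 bp, nearest-exon distance > 250 bp, intergenic context),
   reported as the first rule violated;
5. ``low_expression``     — gene-group expression below TPM >= 1 in every
   library;
6. ``candidate``          — survived everything.

The expression rule is applied at the gene-group (Trinity ``_g``) level:
a group passes if at least one isoform satisfies every criterion, and
then all isoforms that reached the structural stage are retained.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import pandas as pd

from .formats import Annotation
from .homology import (
    AlignmentMatch,
    MatchCriterion,
    Scoring,
    SeqIndex,
    has_match,
    search_matches,
)

__all__ = [
    "PipelineConfig",
    "TranscriptRecord",
    "GenomicLocus",
    "FilterTrace",
    "CandidateGene",
    "ScreenDatabases",
    "HomologySearcher",
    "parse_trinity_id",
    "load_transcripts",
    "annotation_screen",
    "outgroup_transcript_screen",
    "place_on_genome",
    "exon_distance",
    "genic_context",
    "structural_filter",
    "expression_filter",
    "run_screen",
]

STAGES = (
    "annotation_match",
    "outgroup_transcript_match",
    "unplaced",
    "short",
    "near_exon",
    "not_intergenic",
    "low_expression",
    "candidate",
)


@dataclass(frozen=True)
class PipelineConfig:
    """All cascade thresholds; no stage code carries literals."""

    match_criterion: MatchCriterion = MatchCriterion(0.80, 100)
    min_transcript_len: int = 300   # strict >
    min_exon_distance: int = 250    # strict >
    tpm_threshold: float = 1.0      # inclusive >=
    synteny_flank: int = 5000
    orf_min_len: int = 75
    merge_gap: int = 1000           # co-linear placement merge distance
    seed_k: int = 11
    scoring: Scoring = Scoring()

    def __post_init__(self):
        if min(self.min_transcript_len, self.min_exon_distance,
               self.synteny_flank, self.orf_min_len) <= 0 or self.tpm_threshold <= 0:
            raise ValueError("all thresholds must be positive")

    def as_dict(self) -> dict:
        return {
            "min_identity": self.match_criterion.min_identity,
            "min_match_len": self.match_criterion.min_len,
            "min_transcript_len": self.min_transcript_len,
            "min_exon_distance": self.min_exon_distance,
            "tpm_threshold": self.tpm_threshold,
            "synteny_flank": self.synteny_flank,
            "orf_min_len": self.orf_min_len,
            "merge_gap": self.merge_gap,
            "seed_k": self.seed_k,
        }


@dataclass(frozen=True)
class TranscriptRecord:
    transcript_id: str
    gene_group: str
    isoform: int
    sequence: str


@dataclass(frozen=True)
class GenomicLocus:
    chrom: str
    start: int
    end: int
    strand: str
    placement_identity: float
    chimeric: bool = False


@dataclass
class CandidateGene:
    candidate_id: str                   # the gene group
    isoforms: list[TranscriptRecord]
    locus: GenomicLocus | None
    evidence: dict = field(default_factory=dict)
    expression_summary: dict | None = None
    synteny_tier: str | None = None
    longest_orf_nt: int | None = None
    orfs: list = field(default_factory=list)


class FilterTrace:
    """Per-transcript terminal disposition: the cascade's audit trail."""

    def __init__(self):
        self._trace: dict[str, tuple[str, str]] = {}

    def set(self, transcript_id: str, stage: str, evidence: str = "") -> None:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        self._trace[transcript_id] = (stage, evidence)

    def stage(self, transcript_id: str) -> str:
        return self._trace[transcript_id][0]

    def evidence(self, transcript_id: str) -> str:
        return self._trace[transcript_id][1]

    def stage_counts(self) -> dict[str, int]:
        counts = {s: 0 for s in STAGES}
        for stage, _ in self._trace.values():
            counts[stage] += 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"transcript_id": t, "stage": s, "evidence": e}
            for t, (s, e) in sorted(self._trace.items())
        ]
        return pd.DataFrame(rows, columns=["transcript_id", "stage", "evidence"])

    def __len__(self) -> int:
        return len(self._trace)

    def __contains__(self, tid) -> bool:
        return tid in self._trace


_TRINITY_RE = re.compile(r"^(TRINITY_DN\d+_c\d+_g\d+)(?:_i(\d+))?$")


def parse_trinity_id(text: str, strict: bool = False) -> tuple[str, int]:
    """Split a Trinity-style ID into (gene group, isoform number).

    ``TRINITY_DN7862_c0_g3_i2`` -> (``TRINITY_DN7862_c0_g3``, 2); a
    missing ``_i`` suffix means isoform 1.  Unparseable IDs raise in
    strict mode, otherwise the ID becomes its own singleton group.
    """
    m = _TRINITY_RE.match(text)
    if m is None:
        if strict:
            raise ValueError(f"not a Trinity-style transcript id: {text!r}")
        return text, 1
    group, iso = m.group(1), m.group(2)
    return group, int(iso) if iso is not None else 1


def load_transcripts(records, strict: bool = False) -> list[TranscriptRecord]:
    out = []
    for name, seq in records:
        if not seq:
            raise ValueError(f"empty transcript sequence for {name!r}")
        group, iso = parse_trinity_id(name, strict=strict)
        out.append(TranscriptRecord(name, group, iso, seq))
    return out


@dataclass
class ScreenDatabases:
    """Indexed search targets for the cascade."""

    annotation_indexes: dict[tuple[str, str], SeqIndex]  # (species, class)
    outgroup_tx_indexes: dict[str, SeqIndex]             # species
    genome_index: SeqIndex

    @classmethod
    def build(
        cls,
        annotation_dbs: dict[tuple[str, str], list[tuple[str, str]]],
        outgroup_tx_dbs: dict[str, list[tuple[str, str]]],
        focal_genome: dict[str, str],
        k: int = 11,
    ) -> "ScreenDatabases":
        ann = {
            key: SeqIndex(records, k=k)
            for key, records in sorted(annotation_dbs.items())
            if records
        }
        ogt = {
            sp: SeqIndex(records, k=k)
            for sp, records in sorted(outgroup_tx_dbs.items())
            if records
        }
        gidx = SeqIndex(sorted(focal_genome.items()), k=k)
        return cls(ann, ogt, gidx)


class HomologySearcher:
    """Memoizing wrapper around :func:`search_matches`.

    Raw matches depend on scoring only, never on the acceptance criterion,
    so one search serves every criterion applied afterwards (e.g. across a
    threshold sweep).
    """

    def __init__(self, scoring: Scoring = Scoring()):
        self.scoring = scoring
        self._cache: dict[tuple[str, int], list[AlignmentMatch]] = {}

    def matches(self, query: str, index: SeqIndex, query_id: str) -> list[AlignmentMatch]:
        key = (query_id, id(index))
        if key not in self._cache:
            self._cache[key] = search_matches(
                query, index, self.scoring, query_id=query_id
            )
        return self._cache[key]


def annotation_screen(
    transcripts: list[TranscriptRecord],
    annotation_indexes: dict[tuple[str, str], SeqIndex],
    criterion: MatchCriterion,
    searcher: HomologySearcher | None = None,
) -> tuple[list[TranscriptRecord], dict[str, str]]:
    """Remove transcripts matching ANY class database of ANY species.

    Returns (survivors, removed evidence keyed by transcript id).
    """
    if not annotation_indexes:
        raise ValueError("annotation screen requires at least one database")
    searcher = searcher or HomologySearcher()
    survivors, removed = [], {}
    for tr in transcripts:
        hit = None
        for (species, cls), idx in annotation_indexes.items():
            ok, best = has_match(
                tr.sequence, idx, criterion, searcher.scoring,
                query_id=tr.transcript_id,
                matches=searcher.matches(tr.sequence, idx, tr.transcript_id),
            )
            if ok:
                hit = (species, cls, best)
                break
        if hit is None:
            survivors.append(tr)
        else:
            species, cls, best = hit
            removed[tr.transcript_id] = (
                f"species={species} class={cls} subject={best.subject_id} "
                f"identity={best.identity:.3f} len={best.aligned_len}"
            )
    return survivors, removed


def outgroup_transcript_screen(
    transcripts: list[TranscriptRecord],
    outgroup_tx_indexes: dict[str, SeqIndex],
    criterion: MatchCriterion,
    searcher: HomologySearcher | None = None,
) -> tuple[list[TranscriptRecord], dict[str, str]]:
    """Remove transcripts with homologs among outgroup assembled transcripts."""
    searcher = searcher or HomologySearcher()
    survivors, removed = [], {}
    for tr in transcripts:
        hit = None
        for species, idx in outgroup_tx_indexes.items():
            ok, best = has_match(
                tr.sequence, idx, criterion, searcher.scoring,
                query_id=tr.transcript_id,
                matches=searcher.matches(tr.sequence, idx, tr.transcript_id),
            )
            if ok:
                hit = (species, best)
                break
        if hit is None:
            survivors.append(tr)
        else:
            species, best = hit
            removed[tr.transcript_id] = (
                f"species={species} subject={best.subject_id} "
                f"identity={best.identity:.3f} len={best.aligned_len}"
            )
    return survivors, removed


def place_on_genome(
    transcript: TranscriptRecord,
    genome_index: SeqIndex,
    criterion: MatchCriterion,
    merge_gap: int = 1000,
    searcher: HomologySearcher | None = None,
) -> GenomicLocus | None:
    """Locate the transcript on the focal genome.

    The locus is the subject span of the highest-scoring qualifying match,
    merged with co-linear qualifying matches on the same chromosome and
    strand within ``merge_gap`` bp (multi-exon placement).  Chimeric
    placements (remaining qualifying matches elsewhere) keep the best
    segment and are flagged.  Returns None if nothing qualifies.
    """
    searcher = searcher or HomologySearcher()
    matches = searcher.matches(transcript.sequence, genome_index, transcript.transcript_id)
    qualifying = [
        m for m in matches if criterion.accepts(m.identity, m.aligned_len)
    ]
    if not qualifying:
        return None
    qualifying.sort(key=AlignmentMatch.sort_key)
    best = qualifying[0]
    cluster = [best]
    for m in qualifying[1:]:
        if m.subject_id != best.subject_id or m.strand != best.strand:
            continue
        lo = min(c.s_start for c in cluster)
        hi = max(c.s_end for c in cluster)
        gap = max(m.s_start - hi, lo - m.s_end)
        if gap <= merge_gap:
            cluster.append(m)
    chimeric = len(cluster) < len(qualifying)
    start = min(c.s_start for c in cluster)
    end = max(c.s_end for c in cluster)
    total_cols = sum(c.aligned_len for c in cluster)
    ident = sum(c.identity * c.aligned_len for c in cluster) / total_cols
    return GenomicLocus(
        chrom=best.subject_id,
        start=start,
        end=end,
        strand=best.strand,
        placement_identity=ident,
        chimeric=chimeric,
    )


def exon_distance(locus: GenomicLocus, annotation: Annotation) -> float:
    """bp between a placed locus and the nearest exon of any gene, either
    strand; 0 on overlap or adjacency, +inf with no exons on record."""
    tree = annotation.exon_tree(locus.chrom)
    if tree.overlap(locus.start, locus.end):
        return 0
    best = math.inf
    for iv in tree:  # exons on other chromosomes do not count
        if iv.begin >= locus.end:
            gap = iv.begin - locus.end
        elif iv.end <= locus.start:
            gap = locus.start - iv.end
        else:  # pragma: no cover - overlap handled above
            gap = 0
        best = min(best, gap)
    return best


def genic_context(locus: GenomicLocus, annotation: Annotation) -> str:
    """``genic_overlap`` on exon overlap; ``intronic`` if >=50% of the locus
    lies within a gene span without touching its exons; else ``intergenic``."""
    if annotation.exon_tree(locus.chrom).overlap(locus.start, locus.end):
        return "genic_overlap"
    span = locus.end - locus.start
    best_frac = 0.0
    for iv in annotation.gene_tree(locus.chrom).overlap(locus.start, locus.end):
        ov = min(locus.end, iv.end) - max(locus.start, iv.begin)
        best_frac = max(best_frac, ov / span)
    return "intronic" if best_frac >= 0.5 else "intergenic"


def structural_filter(
    transcript: TranscriptRecord,
    locus: GenomicLocus,
    annotation: Annotation,
    config: PipelineConfig,
) -> tuple[bool, str | None]:
    """Length, nearest-exon distance, and genomic-context rules, in order;
    the first violated rule is the reported reason."""
    if len(transcript.sequence) <= config.min_transcript_len:
        return False, "short"
    if exon_distance(locus, annotation) <= config.min_exon_distance:
        return False, "near_exon"
    if genic_context(locus, annotation) != "intergenic":
        return False, "not_intergenic"
    return True, None


def expression_filter(
    gene_group: str,
    isoforms: list[TranscriptRecord],
    structural_pass: dict[str, bool],
    tpm: pd.DataFrame,
    config: PipelineConfig,
) -> tuple[bool, dict[str, float]]:
    """Group-level rule: pass iff >=1 isoform passes the structural rules
    AND reaches TPM >= threshold in >=1 library.  Absent rows count as 0.

    Returns (passed, per-isoform max TPM).
    """
    max_tpm = {}
    for tr in isoforms:
        if tr.transcript_id in tpm.index:
            max_tpm[tr.transcript_id] = float(tpm.loc[tr.transcript_id].max())
        else:
            max_tpm[tr.transcript_id] = 0.0
    passed = any(
        structural_pass.get(tr.transcript_id, False)
        and max_tpm[tr.transcript_id] >= config.tpm_threshold
        for tr in isoforms
    )
    return passed, max_tpm


def run_screen(
    transcripts: list[TranscriptRecord],
    databases: ScreenDatabases,
    annotation: Annotation,
    tpm: pd.DataFrame,
    config: PipelineConfig,
    searcher: HomologySearcher | None = None,
) -> tuple[list[CandidateGene], FilterTrace]:
    """Run the full cascade; returns candidates plus the audit trail.

    The FilterTrace partitions the input: every transcript gets exactly
    one terminal stage and stage counts sum to the input count.
    """
    searcher = searcher or HomologySearcher(config.scoring)
    trace = FilterTrace()
    crit = config.match_criterion

    s1, removed1 = annotation_screen(
        transcripts, databases.annotation_indexes, crit, searcher
    )
    for tid, ev in removed1.items():
        trace.set(tid, "annotation_match", ev)

    s2, removed2 = outgroup_transcript_screen(
        s1, databases.outgroup_tx_indexes, crit, searcher
    )
    for tid, ev in removed2.items():
        trace.set(tid, "outgroup_transcript_match", ev)

    placed: dict[str, GenomicLocus] = {}
    s3: list[TranscriptRecord] = []
    for tr in s2:
        locus = place_on_genome(
            tr, databases.genome_index, crit, config.merge_gap, searcher
        )
        if locus is None:
            trace.set(tr.transcript_id, "unplaced", "no qualifying genome placement")
        else:
            placed[tr.transcript_id] = locus
            s3.append(tr)

    structural_pass: dict[str, bool] = {}
    structural_reason: dict[str, str] = {}
    for tr in s3:
        ok, reason = structural_filter(tr, placed[tr.transcript_id], annotation, config)
        structural_pass[tr.transcript_id] = ok
        if not ok:
            structural_reason[tr.transcript_id] = reason

    groups: dict[str, list[TranscriptRecord]] = {}
    for tr in s3:
        groups.setdefault(tr.gene_group, []).append(tr)

    candidates: list[CandidateGene] = []
    for group in sorted(groups):
        isoforms = sorted(groups[group], key=lambda t: t.isoform)
        passed, max_tpm = expression_filter(
            group, isoforms, structural_pass, tpm, config
        )
        if passed:
            # candidate locus: the placement of the longest passing isoform
            passing = [
                t for t in isoforms
                if structural_pass[t.transcript_id]
                and max_tpm[t.transcript_id] >= config.tpm_threshold
            ]
            anchor = max(passing, key=lambda t: len(t.sequence))
            for tr in isoforms:
                note = ""
                if not structural_pass[tr.transcript_id]:
                    note = (
                        f"retained_via_group (own violation: "
                        f"{structural_reason[tr.transcript_id]})"
                    )
                elif max_tpm[tr.transcript_id] < config.tpm_threshold:
                    note = "retained_via_group (own max TPM below threshold)"
                trace.set(tr.transcript_id, "candidate", note)
            candidates.append(
                CandidateGene(
                    candidate_id=group,
                    isoforms=isoforms,
                    locus=placed[anchor.transcript_id],
                    evidence={
                        "anchor_isoform": anchor.transcript_id,
                        "max_tpm": max_tpm,
                    },
                )
            )
        else:
            for tr in isoforms:
                if structural_pass[tr.transcript_id]:
                    trace.set(
                        tr.transcript_id,
                        "low_expression",
                        f"max TPM {max_tpm[tr.transcript_id]:.3f} < "
                        f"{config.tpm_threshold}",
                    )
                else:
                    trace.set(
                        tr.transcript_id,
                        structural_reason[tr.transcript_id],
                        "",
                    )
    assert len(trace) == len(transcripts), "trace does not partition the input"
    return candidates, trace
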