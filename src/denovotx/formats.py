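"""Readers and writers for the external formats the pipeline touches.

Conventions
-----------
All *internal* coordinates are 0-based half-open, on every type in this
package.  GTF (1-based closed) is converted on read and write; BED is
written natively.  Sequences are uppercased on read and restricted to the
nucleotide alphabet ``A C G T N``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from intervaltree import IntervalTree

__all__ = [
    "FormatError",
    "FeatureRecord",
    "Annotation",
    "FEATURE_CLASSES",
    "read_fasta",
    "write_fasta",
    "read_annotation",
    "parse_annotation_lines",
    "write_annotation",
    "read_ortholog_table",
    "write_ortholog_table",
    "read_expression_table",
    "write_expression_table",
    "write_candidate_outputs",
]

VALID_ALPHABET = frozenset("ACGTN")

#: Closed feature-class vocabulary.  The non-GTF-standard members name the
#: annotation-class sequence databases used by the homology screen.
FEATURE_CLASSES = frozenset(
    {
        "gene",
        "exon",
        "CDS",
        "intron",
        "3UTR",
        "5UTR",
        "miRNA",
        "miscRNA",
        "ncRNA",
        "pseudogene",
        "transposon",
        "tRNA",
        "intergenic",
    }
)


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into an ordered list of ``(name, sequence)``.

    Names are the token before the first whitespace; sequences are
    uppercased.  Empty files, duplicate names, empty records and characters
    outside ``A C G T N`` are format errors naming the offending record.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"empty sequence for FASTA record {name!r} in {path}")
        if name in seen:
            raise FormatError(f"duplicate FASTA record name {name!r} in {path}")
        bad = set(seq) - VALID_ALPHABET
        if bad:
            raise FormatError(
                f"illegal characters {sorted(bad)} in FASTA record {name!r} in {path}"
            )
        seen.add(name)
        records.append((name, seq))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    seqrecords = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecords)


# ---------------------------------------------------------------------------
# Annotation (GTF-style, 9 columns)
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class FeatureRecord:
    """One annotated feature, internal 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    strand: str
    feature_class: str
    gene_id: str
    transcript_id: str | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"invalid interval [{self.start},{self.end}) for {self.gene_id}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"invalid strand {self.strand!r} for {self.gene_id}")
        if self.feature_class not in FEATURE_CLASSES:
            raise FormatError(
                f"unknown feature class {self.feature_class!r} for {self.gene_id}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


class Annotation:
    """A set of features with per-chromosome interval indexes.

    Exon and gene-span interval trees back the nearest-exon and
    genomic-context queries of the screening cascade.  Intron features, if
    absent, are derived as gaps between consecutive exons of a transcript.
    """

    def __init__(self, features: Sequence[FeatureRecord]):
        self.features: list[FeatureRecord] = list(features)
        self._exon_trees: dict[str, IntervalTree] = {}
        self._gene_trees: dict[str, IntervalTree] = {}
        self._build()

    def _build(self) -> None:
        self.genes: dict[str, FeatureRecord] = {}
        self.transcripts: dict[str, list[FeatureRecord]] = {}
        for f in self.features:
            if f.feature_class == "gene":
                self.genes[f.gene_id] = f
            elif f.feature_class == "exon":
                self._exon_trees.setdefault(f.chrom, IntervalTree()).addi(
                    f.start, f.end, f
                )
                if f.transcript_id is not None:
                    self.transcripts.setdefault(f.transcript_id, []).append(f)
        for tid in self.transcripts:
            self.transcripts[tid].sort(key=lambda f: f.start)
        # gene spans: explicit gene records, else the union of their exons
        spans: dict[str, tuple[str, int, int, str]] = {}
        for gid, g in self.genes.items():
            spans[gid] = (g.chrom, g.start, g.end, g.strand)
        for f in self.features:
            if f.feature_class == "exon" and f.gene_id not in self.genes:
                c, s, e, st = spans.get(f.gene_id, (f.chrom, f.start, f.end, f.strand))
                spans[f.gene_id] = (c, min(s, f.start), max(e, f.end), st)
        self.gene_spans: dict[str, tuple[str, int, int, str]] = spans
        for gid, (c, s, e, st) in spans.items():
            self._gene_trees.setdefault(c, IntervalTree()).addi(s, e, gid)

    def exon_tree(self, chrom: str) -> IntervalTree:
        return self._exon_trees.get(chrom, IntervalTree())

    def gene_tree(self, chrom: str) -> IntervalTree:
        return self._gene_trees.get(chrom, IntervalTree())

    def exons(self) -> list[FeatureRecord]:
        return [f for f in self.features if f.feature_class == "exon"]

    def introns(self) -> list[FeatureRecord]:
        """Annotated introns, or gaps between consecutive exons if absent."""
        explicit = [f for f in self.features if f.feature_class == "intron"]
        if explicit:
            return explicit
        derived = []
        for tid, exons in self.transcripts.items():
            for a, b in zip(exons, exons[1:]):
                if b.start > a.end:
                    derived.append(
                        FeatureRecord(
                            a.chrom, a.end, b.start, a.strand, "intron", a.gene_id, tid
                        )
                    )
        return derived

    def transcript_sequence(self, transcript_id: str, genome: dict[str, str]) -> str:
        """Spliced exon sequence of a transcript (reverse-complemented on −)."""
        exons = self.transcripts[transcript_id]
        seq = "".join(genome[f.chrom][f.start : f.end] for f in exons)
        if exons[0].strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq

    def __len__(self) -> int:
        return len(self.features)


def parse_annotation_lines(lines: Iterable[str], source: str = "<memory>") -> Annotation:
    feats: list[FeatureRecord] = []
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise FormatError(
                f"{source}:{lineno}: expected 9 tab-separated columns, got {len(cols)}"
            )
        chrom, _src, fclass, start_s, end_s, _score, strand, _frame, attrs = cols
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError:
            raise FormatError(f"{source}:{lineno}: non-integer coordinates") from None
        if end1 < start1:
            raise FormatError(
                f"{source}:{lineno}: end ({end1}) < start ({start1})"
            )
        if start1 < 1:
            raise FormatError(f"{source}:{lineno}: 1-based start must be >= 1")
        if strand not in ("+", "-"):
            raise FormatError(f"{source}:{lineno}: unknown strand {strand!r}")
        if fclass not in FEATURE_CLASSES:
            raise FormatError(f"{source}:{lineno}: unknown feature class {fclass!r}")
        attr = _parse_attributes(attrs)
        gene_id = attr.get("gene_id")
        if not gene_id:
            raise FormatError(f"{source}:{lineno}: missing gene_id attribute")
        feats.append(
            FeatureRecord(
                chrom=chrom,
                start=start1 - 1,  # to 0-based half-open
                end=end1,
                strand=strand,
                feature_class=fclass,
                gene_id=gene_id,
                transcript_id=attr.get("transcript_id"),
            )
        )
    return Annotation(feats)


def _parse_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if " " in part:
            key, _, value = part.partition(" ")
            attrs[key] = value.strip().strip('"')
    return attrs


def read_annotation(path) -> Annotation:
    with open(path) as fh:
        return parse_annotation_lines(fh, source=str(path))


def feature_to_gtf_line(f: FeatureRecord, source: str = "denovotx") -> str:
    attrs = f'gene_id "{f.gene_id}";'
    if f.transcript_id is not None:
        attrs += f' transcript_id "{f.transcript_id}";'
    return "\t".join(
        [
            f.chrom,
            source,
            f.feature_class,
            str(f.start + 1),  # back to 1-based closed
            str(f.end),
            ".",
            f.strand,
            ".",
            attrs,
        ]
    )


def write_annotation(path, annotation: Annotation | Sequence[FeatureRecord]) -> None:
    feats = annotation.features if isinstance(annotation, Annotation) else annotation
    with open(path, "w") as fh:
        for f in feats:
            fh.write(feature_to_gtf_line(f) + "\n")


# ---------------------------------------------------------------------------
# Ortholog table
# ---------------------------------------------------------------------------

ORTHOLOG_COLUMNS = [
    "focal_gene_id",
    "outgroup_species",
    "ortholog_gene_id",
    "chrom",
    "start",
    "end",
]


def read_ortholog_table(path) -> pd.DataFrame:
    """TSV of (focal_gene_id, outgroup_species, ortholog_gene_id[, locus]).

    Ortholog loci, when present, are internal 0-based half-open.
    """
    df = pd.read_csv(path, sep="\t", dtype={"focal_gene_id": str})
    missing = [c for c in ORTHOLOG_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise FormatError(f"ortholog table {path} missing columns {missing}")
    dup = df.duplicated(subset=["focal_gene_id", "outgroup_species"])
    if dup.any():
        pairs = df.loc[dup, ["focal_gene_id", "outgroup_species"]].values.tolist()
        raise FormatError(f"duplicate (focal gene, species) pairs in {path}: {pairs}")
    return df


def write_ortholog_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------


def read_expression_table(path) -> pd.DataFrame:
    """TSV with a header row of library names and transcript IDs in column 1.

    Returns a non-negative numeric matrix (rows = transcripts, columns =
    libraries); blank cells become 0.  Negative or non-numeric cells are
    format errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-numeric cell in expression table {path}: {exc}") from None
    df = df.fillna(0)
    if (df.values < 0).any():
        rows = df.index[(df.values < 0).any(axis=1)].tolist()
        raise FormatError(f"negative values in expression table {path}, rows {rows}")
    return df


def write_expression_table(path, df: pd.DataFrame, float_format: str | None = None) -> None:
    df.to_csv(path, sep="\t", float_format=float_format)


# ---------------------------------------------------------------------------
# Candidate outputs
# ---------------------------------------------------------------------------

REPORT_COLUMNS = [
    "candidate_id",
    "n_isoforms",
    "locus",
    "n_libraries_expressed",
    "max_TPM",
    "synteny_tier",
    "longest_ORF_nt",
]


def write_candidate_outputs(candidates, paths: dict, reference_annotation=None) -> None:
    """Write the final candidate report set.

    ``paths`` maps any of ``bed``, ``fasta``, ``gtf``, ``report`` to file
    paths.  ``candidates`` is an iterable of finalized CandidateGene objects
    (see :mod:`denovotx.screen`).  The merged GTF contains the reference
    features (if given) plus one gene/transcript/exon group per candidate;
    candidate loci go to BED (0-based half-open, natively).
    """
    cands = sorted(candidates, key=lambda c: c.candidate_id)
    if "bed" in paths:
        with open(paths["bed"], "w") as fh:
            for c in cands:
                if c.locus is None:
                    continue
                strand = c.locus.strand or "+"
                fh.write(
                    f"{c.locus.chrom}\t{c.locus.start}\t{c.locus.end}\t"
                    f"{c.candidate_id}\t0\t{strand}\n"
                )
    if "fasta" in paths:
        recs = [(iso.transcript_id, iso.sequence) for c in cands for iso in c.isoforms]
        seqrecords = [SeqRecord(Seq(s), id=n, description="") for n, s in recs]
        with open(paths["fasta"], "w") as fh:
            SeqIO.FastaIO.FastaWriter(fh, wrap=70).write_file(seqrecords)
    if "gtf" in paths:
        with open(paths["gtf"], "w") as fh:
            if reference_annotation is not None:
                feats = (
                    reference_annotation.features
                    if isinstance(reference_annotation, Annotation)
                    else reference_annotation
                )
                for f in feats:
                    fh.write(feature_to_gtf_line(f, source="reference") + "\n")
            for c in cands:
                if c.locus is None:
                    continue
                strand = c.locus.strand or "+"
                gene = FeatureRecord(
                    c.locus.chrom, c.locus.start, c.locus.end, strand, "gene", c.candidate_id
                )
                fh.write(feature_to_gtf_line(gene, source="candidate") + "\n")
                for iso in c.isoforms:
                    for fclass in ("exon",):
                        feat = FeatureRecord(
                            c.locus.chrom,
                            c.locus.start,
                            c.locus.end,
                            strand,
                            fclass,
                            c.candidate_id,
                            iso.transcript_id,
                        )
                        fh.write(feature_to_gtf_line(feat, source="candidate") + "\n")
    if "report" in paths:
        rows = []
        for c in cands:
            locus = (
                f"{c.locus.chrom}:{c.locus.start}-{c.locus.end}" if c.locus else "NA"
            )
            summ = c.expression_summary or {}
            rows.append(
                {
                    "candidate_id": c.candidate_id,
                    "n_isoforms": len(c.isoforms),
                    "locus": locus,
                    "n_libraries_expressed": summ.get("n_libraries_expressed", "NA"),
                    "max_TPM": summ.get("max_TPM", "NA"),
                    "synteny_tier": c.synteny_tier or "NA",
                    "longest_ORF_nt": c.longest_orf_nt if c.longest_orf_nt else "NA",
                }
            )
        pd.DataFrame(rows, columns=REPORT_COLUMNS).to_csv(
            paths["report"], sep="\t", index=False
        )
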