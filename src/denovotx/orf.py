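"""Open-reading-frame discovery on candidate transcripts.

ORFs run ATG through stop codon (inclusive) in any of the six frames;
nested starts sharing a stop report only the longest.  Stopless runs at a
transcript end are reported as partial and excluded from the minimum
length pass by default.  The default minimum length is 75 nt; a 30 nt
preset is exposed for the permissive convention some coding-potential
tools report against.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

__all__ = ["OrfRecord", "find_orfs", "export_orf_peptides", "MIN_ORF_DEFAULT", "MIN_ORF_PERMISSIVE"]

MIN_ORF_DEFAULT = 75
MIN_ORF_PERMISSIVE = 30

STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class OrfRecord:
    """One ORF on a transcript; coordinates are 0-based half-open on the
    input (forward) transcript sequence, regardless of strand."""

    transcript_id: str
    strand: str
    frame: int
    start: int
    end: int
    length_nt: int
    peptide: str
    partial: bool = False

    def __post_init__(self):
        if self.length_nt % 3 != 0:
            raise ValueError("ORF length must be divisible by 3")


def find_orfs(
    sequence: str,
    min_len_nt: int = MIN_ORF_DEFAULT,
    transcript_id: str = "transcript",
    include_partial: bool = False,
) -> list[OrfRecord]:
    """All qualifying ORFs of a transcript, both strands, all three frames.

    Returned sorted by length descending; ties by (strand '+' first, lower
    start on the forward sequence).
    """
    if min_len_nt < 3:
        raise ValueError("min_len_nt must be >= 3")
    seq = sequence.upper()
    n = len(seq)
    out: list[OrfRecord] = []
    for strand in ("+", "-"):
        s = seq if strand == "+" else str(Seq(seq).reverse_complement())
        for frame in range(3):
            i = frame
            pending_start: int | None = None
            while i + 3 <= n:
                codon = s[i : i + 3]
                if pending_start is None and codon == "ATG":
                    pending_start = i
                if codon in STOPS and pending_start is not None:
                    out.extend(
                        _make(s, n, strand, frame, pending_start, i + 3, False,
                              transcript_id, min_len_nt)
                    )
                    pending_start = None
                i += 3
            if pending_start is not None and include_partial:
                end = pending_start + 3 * ((n - pending_start) // 3)
                out.extend(
                    _make(s, n, strand, frame, pending_start, end, True,
                          transcript_id, min_len_nt)
                )
    out.sort(key=lambda o: (-o.length_nt, o.strand != "+", o.start))
    return out


def _make(s, n, strand, frame, a, b, partial, tid, min_len):
    length = b - a
    if length < min_len:
        return []
    coding = s[a:b]
    pep = str(Seq(coding).translate())
    if not partial:
        pep = pep[:-1]  # drop the stop symbol
    if strand == "+":
        start, end = a, b
    else:
        start, end = n - b, n - a
    return [
        OrfRecord(
            transcript_id=tid,
            strand=strand,
            frame=frame,
            start=start,
            end=end,
            length_nt=length,
            peptide=pep,
            partial=partial,
        )
    ]


def export_orf_peptides(orfs_by_transcript: dict[str, list[OrfRecord]], path) -> None:
    """Write one peptide FASTA record per ORF, for downstream coding-potential
    or signal-peptide tools.  IDs are ``<transcript>|<strand><frame>|<start>-<end>``."""
    with open(path, "w") as fh:
        any_written = False
        for tid in sorted(orfs_by_transcript):
            for o in orfs_by_transcript[tid]:
                fh.write(f">{o.transcript_id}|{o.strand}{o.frame}|{o.start}-{o.end}\n")
                fh.write(o.peptide + "\n")
                any_written = True
        if not any_written:
            fh.write("; no ORFs passed the minimum length\n")
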