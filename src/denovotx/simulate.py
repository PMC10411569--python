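"""Synthetic genome/transcriptome datasets with full ground truth.

The generator builds a self-consistent world for the screening cascade: a
focal genome with annotated multi-exon genes; two outgroup genomes derived
from it by neutral substitutions and indels (with focal-to-outgroup
coordinate maps); an ortholog table; annotation-class sequence databases;
outgroup transcript databases; and a set of planted transcripts.  Planted
transcripts comprise true intergenic de novo gene groups plus one decoy
class per filter stage, each decoy violating exactly its designed
criterion, with per-library expression levels straddling the TPM
threshold.  Every transcript carries a ground-truth class label and the
filter stage at which it should terminate.

Intron databases are built with deliberately incomplete coverage (a few
"host" genes are omitted in every species): real annotation-class
databases never cover everything, which is exactly why the cascade also
applies a genomic-context filter, and the intronic decoy class exercises
that path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .formats import (
    Annotation,
    FeatureRecord,
    write_annotation,
    write_fasta,
    write_ortholog_table,
    write_expression_table,
)
from .homology import encode, _DECODE

__all__ = [
    "OutgroupSpec",
    "SimPlan",
    "SimulationError",
    "SyntheticDataset",
    "EXPECTED_STAGE",
    "simulate_dataset",
    "mutate_genome",
    "random_sequence",
    "simulate_counts",
]


class SimulationError(ValueError):
    """Raised when a plan cannot be realized (e.g. genome too small)."""


@dataclass(frozen=True)
class OutgroupSpec:
    """Divergence model of one outgroup species relative to the focal genome."""

    name: str
    sub_rate: float = 0.05
    indel_rate: float = 0.002

    def __post_init__(self):
        if not (0 <= self.sub_rate < 1 and 0 <= self.indel_rate < 1):
            raise SimulationError("divergence rates must be in [0, 1)")


#: designed terminal stage of each planted transcript class
EXPECTED_STAGE = {
    "true_denovo": "candidate",
    "annotated_copy": "annotation_match",
    "te_copy": "annotation_match",
    "outgroup_shared": "outgroup_transcript_match",
    "unplaced": "unplaced",
    "short": "short",
    "near_exon": "near_exon",
    "intronic": "not_intergenic",
    "low_expression": "low_expression",
}

DEFAULT_CLASS_COUNTS = {
    "true_denovo": 12,
    "annotated_copy": 5,
    "te_copy": 5,
    "intronic": 5,
    "near_exon": 5,
    "short": 5,
    "low_expression": 5,
    "outgroup_shared": 5,
    "unplaced": 5,
}


@dataclass
class SimPlan:
    """Study conditions of the default synthetic experiment.

    Sizes follow the scale the cascade is exercised at: a 2 x 500 kb focal
    genome carrying ~60 multi-exon genes, two outgroups at ~5% and ~10%
    nucleotide divergence (the range over which an 80%-identity screen
    must still find flank homology), 12 planted de novo gene groups, five
    decoys per filter stage, and six expression libraries whose per-class
    TPM targets straddle the TPM >= 1 threshold.
    """

    n_chroms: int = 2
    genome_length_per_chrom: int = 500_000
    n_genes: int = 60
    exons_per_gene: tuple[int, int] = (2, 4)
    exon_len: tuple[int, int] = (200, 600)
    intron_len: tuple[int, int] = (250, 500)
    outgroups: tuple[OutgroupSpec, ...] = (
        OutgroupSpec("outgroup_A", sub_rate=0.05, indel_rate=0.002),
        OutgroupSpec("outgroup_B", sub_rate=0.10, indel_rate=0.004),
    )
    synteny_break_fraction: float = 0.25
    class_counts: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_COUNTS))
    n_libraries: int = 6
    n_intron_hosts: int = 5
    ortholog_dropout: int = 2
    counts_scale: float = 400.0  # read counts per (TPM x kb)
    seed: int = 0

    def __post_init__(self):
        if any(v < 0 for v in self.class_counts.values()):
            raise SimulationError("class counts must be >= 0")
        if not (0 <= self.synteny_break_fraction <= 1):
            raise SimulationError("synteny_break_fraction must be in [0, 1]")
        unknown = set(self.class_counts) - set(EXPECTED_STAGE)
        if unknown:
            raise SimulationError(f"unknown transcript classes: {sorted(unknown)}")


@dataclass
class Outgroup:
    spec: OutgroupSpec
    genome: dict[str, str]          # scaffolds (post synteny-break splitting)
    annotation: Annotation
    coord_maps: dict[str, np.ndarray]  # focal chrom -> focal->pre-split coords
    scaffold_cuts: dict[str, list[int]]  # focal chrom -> cut positions (pre-split coords)

    def map_interval(self, chrom: str, start: int, end: int):
        """Map a focal interval to (scaffold, start, end) in this outgroup."""
        cm = self.coord_maps[chrom]
        a, b = int(cm[start]), int(cm[end])
        return _to_scaffold(chrom, a, b, self.scaffold_cuts.get(chrom, []))


def _to_scaffold(chrom: str, a: int, b: int, cuts: list[int]):
    idx = int(np.searchsorted(cuts, a, side="right"))
    base = cuts[idx - 1] if idx > 0 else 0
    name = f"{chrom}_s{idx}" if cuts else chrom
    return name, a - base, b - base


@dataclass
class SyntheticDataset:
    plan: SimPlan
    focal_genome: dict[str, str]
    annotation: Annotation
    outgroups: dict[str, Outgroup]
    ortholog_table: pd.DataFrame
    annotation_dbs: dict[tuple[str, str], list[tuple[str, str]]]
    outgroup_tx_dbs: dict[str, list[tuple[str, str]]]
    transcripts: list[tuple[str, str]]
    truth: pd.DataFrame
    counts: pd.DataFrame
    lengths: pd.Series
    libraries: list[str]
    tpm_targets: pd.DataFrame
    synteny_break_groups: list[str]  # gene_groups planted over broken loci

    @property
    def true_groups(self) -> set[str]:
        t = self.truth
        return set(t.loc[t["class"] == "true_denovo", "gene_group"])

    def write(self, outdir) -> None:
        """Write every pipeline input format to a directory."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(out / "focal_genome.fasta", sorted(self.focal_genome.items()))
        write_annotation(out / "annotation.gtf", self.annotation)
        write_fasta(out / "transcripts.fasta", self.transcripts)
        write_ortholog_table(out / "orthologs.tsv", self.ortholog_table)
        for sp, og in self.outgroups.items():
            write_fasta(out / f"outgroup_genome_{sp}.fasta", sorted(og.genome.items()))
            write_annotation(out / f"outgroup_annotation_{sp}.gtf", og.annotation)
            write_fasta(out / f"outgroup_transcripts_{sp}.fasta", self.outgroup_tx_dbs[sp])
        for (sp, cls), records in sorted(self.annotation_dbs.items()):
            if records:
                write_fasta(out / f"db_{sp}_{cls}.fasta", records)
        write_expression_table(out / "counts.tsv", self.counts, float_format="%d")
        self.lengths.rename("length").to_frame().rename_axis("transcript_id").to_csv(
            out / "lengths.tsv", sep="\t"
        )
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        meta = asdict(self.plan)
        meta["outgroups"] = [asdict(o) for o in self.plan.outgroups]
        pd.Series({k: str(v) for k, v in meta.items()}).to_csv(
            out / "plan.tsv", sep="\t", header=False
        )


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------


def random_sequence(rng: np.random.Generator, n: int) -> str:
    return _DECODE[rng.integers(0, 4, size=n).astype(np.uint8)].tobytes().decode()


def mutate_genome(
    sequence: str,
    sub_rate: float,
    indel_rate: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[str, np.ndarray]:
    """Neutral divergence: per-site substitutions and geometric indels.

    Substitutions are uniform over the three alternative bases; indels
    occur per site at ``indel_rate``, insertion or deletion with equal
    probability, length geometric with mean 2.  Returns the mutated
    sequence and a coordinate map ``m`` of length ``len(sequence)+1`` with
    ``m[i]`` the mutated-sequence coordinate of focal coordinate ``i``
    (deleted bases map to the deletion point).
    """
    if not (0 <= sub_rate < 1 and 0 <= indel_rate < 1):
        raise SimulationError("rates must be in [0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    enc = encode(sequence).astype(np.int64)
    n = len(enc)
    if sub_rate > 0:
        mask = (rng.random(n) < sub_rate) & (enc <= 3)
        shifts = rng.integers(1, 4, size=n)
        enc = np.where(mask, (enc + shifts) % 4, enc)
    cmap = np.empty(n + 1, dtype=np.int64)
    if indel_rate > 0:
        events = np.nonzero(rng.random(n) < indel_rate)[0]
    else:
        events = np.empty(0, dtype=np.int64)
    kinds = rng.random(len(events)) < 0.5  # True = insertion
    lens = rng.geometric(0.5, size=len(events)) if len(events) else np.empty(0, int)
    parts: list[np.ndarray] = []
    out = 0
    last = 0
    for p, is_ins, L in zip(events, kinds, lens):
        p = int(p)
        if p < last:
            continue  # swallowed by a previous deletion
        seg = enc[last:p]
        parts.append(seg)
        cmap[last:p] = np.arange(out, out + len(seg))
        out += len(seg)
        last = p
        if is_ins:
            parts.append(rng.integers(0, 4, size=int(L)))
            out += int(L)
        else:
            L_eff = min(int(L), n - p)
            cmap[p : p + L_eff] = out
            last = p + L_eff
    seg = enc[last:n]
    parts.append(seg)
    cmap[last:n] = np.arange(out, out + len(seg))
    out += len(seg)
    cmap[n] = out
    merged = np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)
    mutated = _DECODE[merged.astype(np.uint8)].tobytes().decode()
    return mutated, cmap


def simulate_counts(
    targets: pd.DataFrame, lengths: pd.Series, counts_scale: float = 400.0
) -> pd.DataFrame:
    """Integer count matrix whose TPMs reproduce the targets.

    Targets must sum to 1e6 per library (a background row absorbs the
    remainder when building a dataset); counts are
    ``round(target * length_kb * counts_scale)``, so after TPM
    normalization each value lands within rounding error of its target.
    """
    lens_kb = lengths.reindex(targets.index).astype(float) / 1000.0
    counts = (targets.mul(lens_kb, axis=0) * counts_scale).round().astype(np.int64)
    return counts


# ---------------------------------------------------------------------------
# world building
# ---------------------------------------------------------------------------


def _layout_genes(plan: SimPlan, rng: np.random.Generator):
    """Place genes sequentially along chromosomes; returns features and
    per-gene metadata."""
    chroms = [f"chr{i + 1}" for i in range(plan.n_chroms)]
    per_chrom = [plan.n_genes // plan.n_chroms] * plan.n_chroms
    for i in range(plan.n_genes % plan.n_chroms):
        per_chrom[i] += 1
    host_step = max(1, plan.n_genes // max(1, plan.n_intron_hosts))
    host_idx = {2 + i * host_step for i in range(plan.n_intron_hosts)}
    features: list[FeatureRecord] = []
    genes: list[dict] = []
    gi = 0
    for chrom, ngen in zip(chroms, per_chrom):
        cursor = int(rng.integers(4000, 9000))
        for _ in range(ngen):
            gid = f"gene{gi:03d}"
            is_host = gi in host_idx
            n_ex = int(rng.integers(plan.exons_per_gene[0], plan.exons_per_gene[1] + 1))
            if is_host:
                n_ex = max(2, n_ex)
            ex_lens = rng.integers(plan.exon_len[0], plan.exon_len[1] + 1, n_ex)
            in_lens = rng.integers(plan.intron_len[0], plan.intron_len[1] + 1, max(0, n_ex - 1))
            if is_host and n_ex >= 2:
                in_lens = in_lens.copy()
                in_lens[0] = 1300  # long intron hosting an intronic decoy
            strand = "+" if rng.random() < 0.5 else "-"
            start = cursor
            exons = []
            pos = start
            for k in range(n_ex):
                exons.append((pos, pos + int(ex_lens[k])))
                pos += int(ex_lens[k])
                if k < n_ex - 1:
                    pos += int(in_lens[k])
            end = pos
            if end > plan.genome_length_per_chrom - 4000:
                raise SimulationError(
                    f"plan infeasible: genes exceed {chrom} length "
                    f"({end} > {plan.genome_length_per_chrom - 4000})"
                )
            tid = f"{gid}.t1"
            features.append(FeatureRecord(chrom, start, end, strand, "gene", gid))
            for a, b in exons:
                features.append(FeatureRecord(chrom, a, b, strand, "exon", gid, tid))
            genes.append(
                {
                    "gene_id": gid,
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "strand": strand,
                    "transcript_id": tid,
                    "exons": exons,
                    "in_intron_db": not is_host,
                    "is_host": is_host,
                    "long_intron": (exons[0][1], exons[1][0]) if is_host else None,
                }
            )
            cursor = end + int(rng.integers(6000, 16000))
            gi += 1
    return chroms, features, genes


def _intergenic_gaps(genes: list[dict]) -> list[tuple[str, int, int, str, str]]:
    """Between-gene gaps as (chrom, gap_start, gap_end, left_gene, right_gene)."""
    gaps = []
    by_chrom: dict[str, list[dict]] = {}
    for g in genes:
        by_chrom.setdefault(g["chrom"], []).append(g)
    for chrom, gs in by_chrom.items():
        gs.sort(key=lambda g: g["start"])
        for a, b in zip(gs, gs[1:]):
            gaps.append((chrom, a["end"], b["start"], a["gene_id"], b["gene_id"]))
    return gaps


def _trinity_ids(rng: np.random.Generator, n_groups: int) -> list[str]:
    dns = rng.choice(np.arange(100, 99999), size=n_groups, replace=False)
    return [f"TRINITY_DN{int(d)}_c0_g1" for d in dns]


def plant_transcripts(
    focal_genome: dict[str, str],
    genes: list[dict],
    plan: SimPlan,
    rng: np.random.Generator,
    te_library: list[tuple[str, str]],
):
    """Plant true de novo gene groups and one decoy class per filter stage.

    Returns (transcripts, truth rows, planted locus info).  Genome-derived
    classes are exact copies of focal sequence placed in dedicated
    intergenic gaps (>250 bp from any exon unless the class is designed to
    violate that rule); each decoy violates exactly the criterion of its
    designed stage.
    """
    counts = plan.class_counts
    gaps = _intergenic_gaps(genes)
    hosts = [g for g in genes if g["is_host"]]
    need_gaps = (
        counts.get("true_denovo", 0)
        + counts.get("near_exon", 0)
        + counts.get("short", 0)
        + counts.get("low_expression", 0)
        + counts.get("outgroup_shared", 0)
    )
    if need_gaps > len(gaps):
        raise SimulationError(
            f"plan infeasible: {need_gaps} planted loci need distinct intergenic "
            f"gaps but only {len(gaps)} exist"
        )
    if counts.get("intronic", 0) > len(hosts):
        raise SimulationError("not enough long-intron host genes for intronic decoys")
    gap_order = rng.permutation(len(gaps))
    gap_iter = iter(gap_order)
    n_groups = sum(counts.values())
    group_ids = iter(_trinity_ids(rng, n_groups))

    transcripts: list[tuple[str, str]] = []
    truth_rows: list[dict] = []
    planted: list[dict] = []

    def extract(chrom, start, end):
        return focal_genome[chrom][start:end]

    def place_in_gap(length, near_exon=False):
        chrom, gs, ge, lg, rg = gaps[next(gap_iter)]
        if near_exon:
            d = int(rng.integers(20, 251))
            start = gs + d
        else:
            lo, hi = gs + 300, ge - 300 - length
            if hi <= lo:
                raise SimulationError("intergenic gap too small for planted locus")
            start = int(rng.integers(lo, hi))
        return chrom, start, start + length, lg, rg

    def emit(group, iso, cls, seq, chrom=None, start=None, end=None):
        tid = f"{group}_i{iso}"
        transcripts.append((tid, seq))
        truth_rows.append(
            {
                "transcript_id": tid,
                "gene_group": group,
                "class": cls,
                "expected_stage": EXPECTED_STAGE[cls],
                "chrom": chrom if chrom else "NA",
                "start": start if start is not None else -1,
                "end": end if end is not None else -1,
            }
        )

    # --- true de novo gene groups ----------------------------------------
    for j in range(counts.get("true_denovo", 0)):
        group = next(group_ids)
        length = int(rng.integers(400, 1201))
        chrom, start, end, lg, rg = place_in_gap(length)
        seq = extract(chrom, start, end)
        emit(group, 1, "true_denovo", seq, chrom, start, end)
        planted.append(
            {"gene_group": group, "class": "true_denovo", "chrom": chrom,
             "start": start, "end": end, "left_gene": lg, "right_gene": rg}
        )
        if j == 0:
            # a 250 bp isoform: fails the length filter alone but is retained
            # because another isoform of the group passes every criterion
            emit(group, 2, "true_denovo", seq[:250], chrom, start, start + 250)
        elif j in (1, 2, 3):
            sub_len = max(302, int(0.7 * length))
            emit(group, 2, "true_denovo", seq[:sub_len], chrom, start, start + sub_len)

    # --- decoys ------------------------------------------------------------
    for _ in range(counts.get("outgroup_shared", 0)):
        group = next(group_ids)
        length = int(rng.integers(400, 901))
        chrom, start, end, lg, rg = place_in_gap(length)
        emit(group, 1, "outgroup_shared", extract(chrom, start, end), chrom, start, end)
    for _ in range(counts.get("low_expression", 0)):
        group = next(group_ids)
        length = int(rng.integers(400, 801))
        chrom, start, end, lg, rg = place_in_gap(length)
        emit(group, 1, "low_expression", extract(chrom, start, end), chrom, start, end)
    for _ in range(counts.get("short", 0)):
        group = next(group_ids)
        length = int(rng.integers(150, 301))
        chrom, start, end, lg, rg = place_in_gap(length)
        emit(group, 1, "short", extract(chrom, start, end), chrom, start, end)
    for _ in range(counts.get("near_exon", 0)):
        group = next(group_ids)
        length = int(rng.integers(350, 801))
        chrom, start, end, lg, rg = place_in_gap(length, near_exon=True)
        emit(group, 1, "near_exon", extract(chrom, start, end), chrom, start, end)
    for k in range(counts.get("intronic", 0)):
        group = next(group_ids)
        host = hosts[k]
        ia, ib = host["long_intron"]
        length = int(rng.integers(302, min(651, ib - ia - 540)))
        start = ia + (ib - ia - length) // 2
        emit(group, 1, "intronic", extract(host["chrom"], start, start + length),
             host["chrom"], start, start + length)
    for _ in range(counts.get("annotated_copy", 0)):
        group = next(group_ids)
        g = genes[int(rng.integers(0, len(genes)))]
        ex = g["exons"][int(rng.integers(0, len(g["exons"])))]
        length = min(ex[1] - ex[0], int(rng.integers(180, 500)))
        start = ex[0] + int(rng.integers(0, ex[1] - ex[0] - length + 1))
        seq, _ = mutate_genome(extract(g["chrom"], start, start + length), 0.02, 0.0, rng=rng)
        emit(group, 1, "annotated_copy", seq)
    for _ in range(counts.get("te_copy", 0)):
        group = next(group_ids)
        te_name, te_seq = te_library[int(rng.integers(0, len(te_library)))]
        length = int(rng.integers(400, min(1001, len(te_seq))))
        start = int(rng.integers(0, len(te_seq) - length + 1))
        seq, _ = mutate_genome(te_seq[start : start + length], 0.03, 0.0, rng=rng)
        emit(group, 1, "te_copy", seq)
    for _ in range(counts.get("unplaced", 0)):
        group = next(group_ids)
        emit(group, 1, "unplaced", random_sequence(rng, int(rng.integers(400, 801))))

    truth = pd.DataFrame(truth_rows)
    return transcripts, truth, planted


def _expression_targets(
    transcripts, truth: pd.DataFrame, genes, libraries, rng
) -> pd.DataFrame:
    """Per-transcript per-library target TPMs; a background row tops each
    library up to 1e6 so computed TPMs land on their targets."""
    n_lib = len(libraries)
    rows: dict[str, np.ndarray] = {}
    cls = dict(zip(truth["transcript_id"], truth["class"]))
    iso_rank: dict[str, int] = {}
    for tid, _ in transcripts:
        iso_rank[tid] = int(tid.rsplit("_i", 1)[1])
    group_seen: set[str] = set()
    for tid, _seq in transcripts:
        v = np.zeros(n_lib)
        c = cls[tid]
        if c == "true_denovo":
            if iso_rank[tid] == 1:
                n_expr = int(rng.integers(1, 4))
                libs = rng.choice(n_lib, size=n_expr, replace=False)
                v[libs] = rng.uniform(1.05, 2.5, size=n_expr)
                others = [i for i in range(n_lib) if i not in set(libs.tolist())]
                low = rng.choice(others, size=min(3, len(others)), replace=False)
                v[low] = rng.uniform(0.1, 0.9, size=len(low))
            else:
                libs = rng.choice(n_lib, size=2, replace=False)
                v[libs] = rng.uniform(0.2, 0.6, size=2)
        elif c == "low_expression":
            libs = rng.choice(n_lib, size=3, replace=False)
            v[libs] = rng.uniform(0.3, 0.6, size=3)
        else:
            libs = rng.choice(n_lib, size=2, replace=False)
            v[libs] = rng.uniform(1.5, 3.0, size=2)
        rows[tid] = v
    for g in genes:
        rows[g["gene_id"]] = np.exp(
            rng.uniform(np.log(0.2), np.log(300.0), size=n_lib)
        )
    df = pd.DataFrame(rows, index=libraries).T
    background = 1e6 - df.sum(axis=0)
    if (background <= 0).any():
        raise SimulationError("target TPMs exceed 1e6 per library")
    df.loc["background_pool"] = background
    return df


def simulate_dataset(plan: SimPlan | None = None) -> SyntheticDataset:
    """Build the complete labeled dataset a pipeline run consumes.

    Deterministic given ``plan.seed``; the same plan and seed reproduce
    byte-identical outputs from :meth:`SyntheticDataset.write`.
    """
    plan = plan or SimPlan()
    rng = np.random.default_rng(plan.seed)
    chroms, features, genes = _layout_genes(plan, rng)
    focal_genome = {
        c: random_sequence(rng, plan.genome_length_per_chrom) for c in chroms
    }
    annotation = Annotation(features)

    te_library = [
        (f"TE_cons{i + 1}", random_sequence(rng, int(rng.integers(1200, 2001))))
        for i in range(3)
    ]

    transcripts, truth, planted = plant_transcripts(
        focal_genome, genes, plan, rng, te_library
    )

    # outgroup genomes, coordinate maps, annotations
    n_breaks = int(round(plan.synteny_break_fraction * len(
        [p for p in planted if p["class"] == "true_denovo"]
    )))
    true_planted = [p for p in planted if p["class"] == "true_denovo"]
    break_idx = rng.choice(len(true_planted), size=n_breaks, replace=False) if n_breaks else []
    break_loci = [true_planted[int(i)] for i in break_idx]
    break_groups = [p["gene_group"] for p in break_loci]

    outgroups: dict[str, Outgroup] = {}
    outgroup_tx_dbs: dict[str, list[tuple[str, str]]] = {}
    ortho_rows = []
    annotation_dbs: dict[tuple[str, str], list[tuple[str, str]]] = {}

    # focal annotation-class databases
    annotation_dbs[("focal", "CDS")] = [
        (f"focal_cds_{g['gene_id']}",
         annotation.transcript_sequence(g["transcript_id"], focal_genome))
        for g in genes
    ]
    annotation_dbs[("focal", "intron")] = [
        (f"focal_intron_{f.gene_id}_{f.start}", focal_genome[f.chrom][f.start:f.end])
        for f in annotation.introns()
        if next(g for g in genes if g["gene_id"] == f.gene_id)["in_intron_db"]
        and f.end - f.start >= 60
    ]
    annotation_dbs[("focal", "transposon")] = list(te_library)

    flank_genes = {p["left_gene"] for p in planted if "left_gene" in p} | {
        p["right_gene"] for p in planted if "right_gene" in p
    }
    dropout_pool = [g["gene_id"] for g in genes if g["gene_id"] not in flank_genes]

    for spec in plan.outgroups:
        sp = spec.name
        genome_pre: dict[str, str] = {}
        cmaps: dict[str, np.ndarray] = {}
        for c in chroms:
            mseq, cmap = mutate_genome(
                focal_genome[c], spec.sub_rate, spec.indel_rate, rng=rng
            )
            genome_pre[c] = mseq
            cmaps[c] = cmap
        # synteny breaks: cut the outgroup chromosome at the mapped midpoint
        # of each broken candidate locus, splitting its flanks across scaffolds
        cuts: dict[str, list[int]] = {c: [] for c in chroms}
        for p in break_loci:
            mid = (p["start"] + p["end"]) // 2
            cuts[p["chrom"]].append(int(cmaps[p["chrom"]][mid]))
        for c in cuts:
            cuts[c] = sorted(cuts[c])
        genome: dict[str, str] = {}
        for c in chroms:
            cc = cuts[c]
            if not cc:
                genome[c] = genome_pre[c]
            else:
                bounds = [0] + cc + [len(genome_pre[c])]
                for si, (a, b) in enumerate(zip(bounds, bounds[1:])):
                    genome[f"{c}_s{si}"] = genome_pre[c][a:b]
        # outgroup annotation + ortholog table
        dropped = set(
            rng.choice(dropout_pool, size=min(plan.ortholog_dropout, len(dropout_pool)),
                       replace=False).tolist()
        )
        og_feats = []
        tx_db = []
        for g in genes:
            ogid = f"{sp}_{g['gene_id']}"
            cm = cmaps[g["chrom"]]
            scf, a, b = _to_scaffold(
                g["chrom"], int(cm[g["start"]]), int(cm[g["end"]]), cuts[g["chrom"]]
            )
            scf_e, _, _ = _to_scaffold(
                g["chrom"], int(cm[g["end"]]) - 1, int(cm[g["end"]]), cuts[g["chrom"]]
            )
            assert scf == scf_e, "gene straddles a synteny-break cut"
            og_feats.append(FeatureRecord(scf, a, b, g["strand"], "gene", ogid))
            ex_parts = []
            for (xa, xb) in g["exons"]:
                sxa, sxb = int(cm[xa]), int(cm[xb])
                escf, ea, eb = _to_scaffold(g["chrom"], sxa, sxb, cuts[g["chrom"]])
                if eb > ea:
                    og_feats.append(
                        FeatureRecord(escf, ea, eb, g["strand"], "exon", ogid, f"{ogid}.t1")
                    )
                ex_parts.append(genome_pre[g["chrom"]][sxa:sxb])
            tx_seq = "".join(ex_parts)
            if g["strand"] == "-":
                tx_seq = str(Seq(tx_seq).reverse_complement())
            if len(tx_seq) >= 60:
                tx_db.append((f"{sp}_tx_{g['gene_id']}", tx_seq))
            if g["gene_id"] not in dropped:
                ortho_rows.append(
                    {
                        "focal_gene_id": g["gene_id"],
                        "outgroup_species": sp,
                        "ortholog_gene_id": ogid,
                        "chrom": scf,
                        "start": a,
                        "end": b,
                    }
                )
        og_ann = Annotation(og_feats)
        # outgroup annotation-class databases (same incomplete intron coverage)
        annotation_dbs[(sp, "CDS")] = [
            (f"{sp}_cds_{n.split('_tx_')[1]}", s) for n, s in tx_db
        ]
        annotation_dbs[(sp, "intron")] = [
            (f"{sp}_intron_{f.gene_id}_{f.start}",
             genome[f.chrom][f.start:f.end])
            for f in og_ann.introns()
            if next(
                g for g in genes if f.gene_id == f"{sp}_{g['gene_id']}"
            )["in_intron_db"] and f.end - f.start >= 60
        ]
        annotation_dbs[(sp, "transposon")] = list(te_library)
        # shared decoys: their diverged form is transcribed in the outgroup
        seq_by_id = dict(transcripts)
        shared_ids = truth.loc[truth["class"] == "outgroup_shared", "transcript_id"]
        for tid in shared_ids:
            mseq, _ = mutate_genome(seq_by_id[tid], 0.10, 0.005, rng=rng)
            tx_db.append((f"{sp}_shared_{tid}", mseq))
        outgroup_tx_dbs[sp] = tx_db
        outgroups[sp] = Outgroup(
            spec=spec, genome=genome, annotation=og_ann,
            coord_maps=cmaps, scaffold_cuts=cuts,
        )

    ortholog_table = pd.DataFrame(ortho_rows)
    libraries = [
        f"{geno}_{tissue}"
        for geno in ("RAL304", "RAL307")
        for tissue in ("spermatheca", "seminal_receptacle", "parovaria")
    ][: plan.n_libraries]
    targets = _expression_targets(transcripts, truth, genes, libraries, rng)
    lengths = pd.Series(
        {
            **{tid: len(seq) for tid, seq in transcripts},
            **{
                g["gene_id"]: sum(b - a for a, b in g["exons"]) for g in genes
            },
            "background_pool": 1000,
        }
    )
    counts = simulate_counts(targets, lengths, plan.counts_scale)

    return SyntheticDataset(
        plan=plan,
        focal_genome=focal_genome,
        annotation=annotation,
        outgroups=outgroups,
        ortholog_table=ortholog_table,
        annotation_dbs=annotation_dbs,
        outgroup_tx_dbs=outgroup_tx_dbs,
        transcripts=transcripts,
        truth=truth,
        counts=counts,
        lengths=lengths,
        libraries=libraries,
        tpm_targets=targets,
        synteny_break_groups=break_groups,
    )
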