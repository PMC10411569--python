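"""Orchestration: simulate/load -> screen -> expression -> synteny -> ORFs
-> report, as one reproducible run with a manifest.

A run is driven by a configuration mapping (or TOML file) that either
names a ``dataset_dir`` of pipeline inputs or carries a ``[simulate]``
table for a self-contained synthetic run.  All thresholds live in
:class:`denovotx.screen.PipelineConfig`; the manifest records the exact
configuration, stage counts and tier counts, and fully determines a
rerun.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import expression as expr
from . import orf as orfmod
from .formats import (
    Annotation,
    read_annotation,
    read_expression_table,
    read_fasta,
    read_ortholog_table,
    write_candidate_outputs,
)
from .homology import MatchCriterion, Scoring
from .screen import (
    CandidateGene,
    FilterTrace,
    HomologySearcher,
    PipelineConfig,
    ScreenDatabases,
    load_transcripts,
    run_screen,
)
from .simulate import SimPlan, OutgroupSpec, SyntheticDataset, simulate_dataset
from .synteny import run_synteny, tier_candidates

__all__ = [
    "RunManifest",
    "RunResult",
    "ConfigurationError",
    "load_config",
    "config_to_pipeline_config",
    "run_all",
    "compare_to_truth",
    "load_dataset_dir",
]


class ConfigurationError(ValueError):
    pass


@dataclass
class RunManifest:
    config: dict
    input_digests: dict
    stage_counts: dict
    candidate_count: int
    tier_counts: dict
    seed: int | None
    timestamp: str

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


@dataclass
class RunResult:
    candidates: list[CandidateGene]
    trace: FilterTrace
    tpm: pd.DataFrame
    expression_summaries: pd.DataFrame
    cohort_stats: dict
    synteny: dict
    manifest: RunManifest
    dataset: SyntheticDataset | None = None
    output_dir: Path | None = None


def load_config(path) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def config_to_pipeline_config(cfg: dict) -> PipelineConfig:
    th = cfg.get("thresholds", {})
    crit = MatchCriterion(
        float(th.get("min_identity", 0.80)), int(th.get("min_match_len", 100))
    )
    return PipelineConfig(
        match_criterion=crit,
        min_transcript_len=int(th.get("min_transcript_len", 300)),
        min_exon_distance=int(th.get("min_exon_distance", 250)),
        tpm_threshold=float(th.get("tpm_threshold", 1.0)),
        synteny_flank=int(th.get("synteny_flank", 5000)),
        orf_min_len=int(th.get("orf_min_len", 75)),
        seed_k=int(th.get("seed_k", 11)),
    )


@dataclass
class _Inputs:
    """Everything a screen+synteny run consumes, however it was obtained."""

    focal_genome: dict
    annotation: Annotation
    annotation_dbs: dict
    outgroup_tx_dbs: dict
    outgroup_genomes: dict
    outgroup_annotations: dict
    ortholog_table: pd.DataFrame
    transcripts: list
    counts: pd.DataFrame
    lengths: pd.Series
    truth: pd.DataFrame | None = None
    digests: dict = field(default_factory=dict)


def _inputs_from_dataset(ds: SyntheticDataset) -> _Inputs:
    return _Inputs(
        focal_genome=ds.focal_genome,
        annotation=ds.annotation,
        annotation_dbs=ds.annotation_dbs,
        outgroup_tx_dbs=ds.outgroup_tx_dbs,
        outgroup_genomes={sp: og.genome for sp, og in ds.outgroups.items()},
        outgroup_annotations={sp: og.annotation for sp, og in ds.outgroups.items()},
        ortholog_table=ds.ortholog_table,
        transcripts=ds.transcripts,
        counts=ds.counts,
        lengths=ds.lengths,
        truth=ds.truth,
        digests={"simulated_seed": ds.plan.seed},
    )


def load_dataset_dir(path) -> _Inputs:
    """Load a directory of pipeline inputs as written by
    :meth:`denovotx.simulate.SyntheticDataset.write` (or assembled by hand
    in the same layout)."""
    d = Path(path)
    if not d.is_dir():
        raise ConfigurationError(f"dataset directory not found: {d}")
    digests = {}

    def _req(name):
        p = d / name
        if not p.exists():
            raise ConfigurationError(f"missing required input {name} in {d}")
        digests[name] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
        return p

    focal = dict(read_fasta(_req("focal_genome.fasta")))
    annotation = read_annotation(_req("annotation.gtf"))
    transcripts = read_fasta(_req("transcripts.fasta"))
    ortho = read_ortholog_table(_req("orthologs.tsv"))
    counts = read_expression_table(_req("counts.tsv"))
    annotation_dbs = {}
    outgroup_tx_dbs = {}
    outgroup_genomes = {}
    outgroup_annotations = {}
    for p in sorted(d.glob("db_*.fasta")):
        _sp_cls = p.stem[len("db_"):]
        sp, _, cls = _sp_cls.rpartition("_")
        digests[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
        annotation_dbs[(sp, cls)] = read_fasta(p)
    for p in sorted(d.glob("outgroup_transcripts_*.fasta")):
        sp = p.stem[len("outgroup_transcripts_"):]
        digests[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
        outgroup_tx_dbs[sp] = read_fasta(p)
    for p in sorted(d.glob("outgroup_genome_*.fasta")):
        sp = p.stem[len("outgroup_genome_"):]
        digests[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
        outgroup_genomes[sp] = dict(read_fasta(p))
        ann_p = d / f"outgroup_annotation_{sp}.gtf"
        if ann_p.exists():
            outgroup_annotations[sp] = read_annotation(ann_p)
    if not outgroup_genomes:
        raise ConfigurationError(f"no outgroup_genome_*.fasta files in {d}")
    lengths_p = d / "lengths.tsv"
    if lengths_p.exists():
        lengths = pd.read_csv(lengths_p, sep="\t", index_col=0).iloc[:, 0]
    else:
        lengths = _derive_lengths(counts, transcripts, annotation, focal)
    truth = None
    truth_p = d / "truth.tsv"
    if truth_p.exists():
        truth = pd.read_csv(truth_p, sep="\t")
    # chromosome-name consistency check before any compute
    ann_chroms = {f.chrom for f in annotation.features}
    unknown = ann_chroms - set(focal)
    if unknown:
        raise ConfigurationError(
            f"annotation chromosomes absent from genome: {sorted(unknown)}"
        )
    return _Inputs(
        focal_genome=focal,
        annotation=annotation,
        annotation_dbs=annotation_dbs,
        outgroup_tx_dbs=outgroup_tx_dbs,
        outgroup_genomes=outgroup_genomes,
        outgroup_annotations=outgroup_annotations,
        ortholog_table=ortho,
        transcripts=transcripts,
        counts=counts,
        lengths=lengths,
        truth=truth,
        digests=digests,
    )


def _derive_lengths(counts, transcripts, annotation, genome) -> pd.Series:
    lens = {tid: len(seq) for tid, seq in transcripts}
    for tid, exons in annotation.transcripts.items():
        gid = exons[0].gene_id
        lens.setdefault(gid, sum(f.length for f in exons))
    out = {}
    for rid in counts.index:
        if rid in lens:
            out[rid] = lens[rid]
        else:
            out[rid] = 1000  # untyped rows (e.g. a background pool)
    return pd.Series(out)


def _plan_from_config(sim_cfg: dict, seed: int | None) -> SimPlan:
    kwargs = dict(sim_cfg)
    if seed is not None:
        kwargs["seed"] = seed
    if "outgroups" in kwargs:
        kwargs["outgroups"] = tuple(
            OutgroupSpec(**og) for og in kwargs["outgroups"]
        )
    try:
        return SimPlan(**kwargs)
    except TypeError as exc:
        raise ConfigurationError(f"bad [simulate] key: {exc}") from None


def run_all(
    config: dict | str | Path,
    output_dir=None,
    searcher: HomologySearcher | None = None,
    databases: ScreenDatabases | None = None,
) -> RunResult:
    """Run the full pipeline under one configuration.

    ``config`` is a mapping or a TOML path with optional tables
    ``simulate`` (SimPlan fields), ``thresholds`` (PipelineConfig fields),
    and keys ``dataset_dir``, ``output_dir``, ``seed``.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    pcfg = config_to_pipeline_config(config)
    seed = config.get("seed")
    dataset = None
    if "dataset_dir" in config:
        inputs = load_dataset_dir(config["dataset_dir"])
    elif "simulate" in config or seed is not None:
        dataset = simulate_dataset(_plan_from_config(config.get("simulate", {}), seed))
        inputs = _inputs_from_dataset(dataset)
        seed = dataset.plan.seed
    else:
        raise ConfigurationError(
            "config must provide either 'dataset_dir' or a [simulate] table/seed"
        )

    searcher = searcher or HomologySearcher(pcfg.scoring)
    if databases is None:
        databases = ScreenDatabases.build(
            inputs.annotation_dbs, inputs.outgroup_tx_dbs, inputs.focal_genome,
            k=pcfg.seed_k,
        )
    transcripts = load_transcripts(inputs.transcripts)
    tpm = expr.compute_tpm(inputs.counts, inputs.lengths)
    candidates, trace = run_screen(
        transcripts, databases, inputs.annotation, tpm, pcfg, searcher
    )

    cand_iso = {c.candidate_id: [t.transcript_id for t in c.isoforms] for c in candidates}
    summaries, cohort = expr.summarize_candidates(tpm, cand_iso, pcfg.tpm_threshold)
    for c in candidates:
        row = summaries[summaries["candidate_id"] == c.candidate_id]
        if len(row):
            c.expression_summary = {
                "n_libraries_expressed": int(row["n_libraries_expressed"].iloc[0]),
                "n_libraries_nonzero": int(row["n_libraries_nonzero"].iloc[0]),
                "max_TPM": round(float(row["max_TPM"].iloc[0]), 4),
                "mean_TPM_of_expressed": (
                    round(float(row["mean_TPM_of_expressed"].iloc[0]), 4)
                    if pd.notna(row["mean_TPM_of_expressed"].iloc[0])
                    else None
                ),
            }

    syn = run_synteny(
        candidates,
        inputs.annotation,
        inputs.focal_genome,
        inputs.ortholog_table,
        inputs.outgroup_genomes,
        pcfg.match_criterion,
        pcfg.scoring,
        flank=pcfg.synteny_flank,
        outgroup_annotations=inputs.outgroup_annotations,
        k=pcfg.seed_k,
    )
    tiers = tier_candidates(syn)
    for c in candidates:
        c.synteny_tier = tiers.get(c.candidate_id, "none")
        orfs = {}
        longest = 0
        for iso in c.isoforms:
            found = orfmod.find_orfs(iso.sequence, pcfg.orf_min_len, iso.transcript_id)
            orfs[iso.transcript_id] = found
            if found:
                longest = max(longest, found[0].length_nt)
        c.orfs = orfs
        c.longest_orf_nt = longest or None

    tier_counts = {t: 0 for t in ("both_outgroups", "one_outgroup", "none")}
    for c in candidates:
        tier_counts[c.synteny_tier] += 1

    manifest = RunManifest(
        config={
            "thresholds": pcfg.as_dict(),
            **{k: v for k, v in config.items() if k not in ("thresholds",)},
        },
        input_digests=inputs.digests,
        stage_counts=trace.stage_counts(),
        candidate_count=len(candidates),
        tier_counts=tier_counts,
        seed=seed,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )

    out = output_dir or config.get("output_dir")
    outpath = None
    if out is not None:
        outpath = Path(out)
        outpath.mkdir(parents=True, exist_ok=True)
        write_candidate_outputs(
            candidates,
            {
                "bed": outpath / "candidates.bed",
                "fasta": outpath / "candidates.fasta",
                "gtf": outpath / "merged.gtf",
                "report": outpath / "candidates.tsv",
            },
            reference_annotation=inputs.annotation,
        )
        trace.to_frame().to_csv(outpath / "filter_trace.tsv", sep="\t", index=False)
        summaries.to_csv(outpath / "expression_summary.tsv", sep="\t", index=False)
        _synteny_frame(syn).to_csv(outpath / "synteny.tsv", sep="\t", index=False)
        _orf_frame(candidates).to_csv(outpath / "orfs.tsv", sep="\t", index=False)
        orfmod.export_orf_peptides(
            {tid: o for c in candidates for tid, o in c.orfs.items()},
            outpath / "orf_peptides.fasta",
        )
        (outpath / "manifest.json").write_text(manifest.to_json() + "\n")

    return RunResult(
        candidates=candidates,
        trace=trace,
        tpm=tpm,
        expression_summaries=summaries,
        cohort_stats=cohort,
        synteny=syn,
        manifest=manifest,
        dataset=dataset,
        output_dir=outpath,
    )


def _synteny_frame(syn: dict) -> pd.DataFrame:
    rows = []
    for cid in sorted(syn):
        res = syn[cid]
        for sp in sorted(res.per_species):
            s = res.per_species[sp]
            m = s.region_match
            rows.append(
                {
                    "candidate_id": cid,
                    "species": sp,
                    "upstream_gene": s.upstream_gene or "NA",
                    "downstream_gene": s.downstream_gene or "NA",
                    "validated": s.validated,
                    "reason": s.reason,
                    "tier": res.tier,
                    "match_locus": f"{m.subject_id}:{m.s_start}-{m.s_end}" if m else "NA",
                    "match_identity": round(m.identity, 4) if m else "NA",
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "candidate_id", "species", "upstream_gene", "downstream_gene",
            "validated", "reason", "tier", "match_locus", "match_identity",
        ],
    )


def _orf_frame(candidates) -> pd.DataFrame:
    rows = []
    for c in sorted(candidates, key=lambda c: c.candidate_id):
        for tid in sorted(c.orfs):
            for o in c.orfs[tid]:
                rows.append(
                    {
                        "candidate_id": c.candidate_id,
                        "transcript_id": tid,
                        "strand": o.strand,
                        "frame": o.frame,
                        "start": o.start,
                        "end": o.end,
                        "length_nt": o.length_nt,
                        "peptide": o.peptide,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "candidate_id", "transcript_id", "strand", "frame",
            "start", "end", "length_nt", "peptide",
        ],
    )


def compare_to_truth(candidates, trace: FilterTrace, truth: pd.DataFrame) -> dict:
    """Precision/recall over gene groups plus the per-class stage confusion.

    ``truth`` is the simulator manifest (transcript_id, gene_group, class,
    expected_stage).  The confusion table counts transcripts by (designed
    stage, observed stage); off-diagonal zero means every decoy was removed
    exactly where designed.
    """
    predicted = {c.candidate_id for c in candidates}
    true_groups = set(truth.loc[truth["class"] == "true_denovo", "gene_group"])
    tp = len(predicted & true_groups)
    precision = tp / len(predicted) if predicted else float("nan")
    recall = tp / len(true_groups) if true_groups else float("nan")
    rows = []
    agree = 0
    for rec in truth.to_dict("records"):
        tid = rec["transcript_id"]
        observed = trace.stage(tid) if tid in trace else "missing"
        rows.append(
            {
                "transcript_id": tid,
                "class": rec["class"],
                "designed_stage": rec["expected_stage"],
                "observed_stage": observed,
                "agree": observed == rec["expected_stage"],
            }
        )
        agree += observed == rec["expected_stage"]
    confusion = (
        pd.DataFrame(rows)
        .groupby(["class", "designed_stage", "observed_stage"])
        .size()
        .reset_index(name="n")
    )
    return {
        "precision": precision,
        "recall": recall,
        "n_predicted": len(predicted),
        "n_true": len(true_groups),
        "stage_agreement": agree / len(truth) if len(truth) else float("nan"),
        "per_transcript": pd.DataFrame(rows),
        "confusion": confusion,
    }
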