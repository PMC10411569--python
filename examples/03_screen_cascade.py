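"""Run the full filter cascade and audit where every transcript stopped.

Stages, in order: homology to annotation-class databases of any species;
homology to outgroup assembled transcripts; genome placement; length
(>300 bp), nearest-exon distance (>250 bp) and intergenic-context rules;
and the TPM >= 1 in >= 1 library expression rule applied per gene group.
"""

from denovotx import PipelineConfig, ScreenDatabases, SimPlan, simulate_dataset
from denovotx.expression import compute_tpm
from denovotx.pipeline import compare_to_truth
from denovotx.screen import load_transcripts, run_screen

plan = SimPlan(
    genome_length_per_chrom=220_000,
    n_genes=20,
    class_counts={
        "true_denovo": 3, "annotated_copy": 2, "te_copy": 2, "intronic": 2,
        "near_exon": 2, "short": 2, "low_expression": 2, "outgroup_shared": 2,
        "unplaced": 2,
    },
    n_intron_hosts=2,
    n_libraries=4,
    seed=7,
)
ds = simulate_dataset(plan)
databases = ScreenDatabases.build(ds.annotation_dbs, ds.outgroup_tx_dbs, ds.focal_genome)
tpm = compute_tpm(ds.counts, ds.lengths)
candidates, trace = run_screen(
    load_transcripts(ds.transcripts), databases, ds.annotation, tpm, PipelineConfig()
)

print("terminal stage counts (they partition the input):")
for stage, n in trace.stage_counts().items():
    print(f"  {stage:26s} {n}")
print(f"  total = {sum(trace.stage_counts().values())} "
      f"(input transcripts: {len(ds.transcripts)})")

cmp = compare_to_truth(candidates, trace, ds.truth)
print(f"\ncandidate gene groups: {len(candidates)}")
print(f"precision {cmp['precision']:.2f}, recall {cmp['recall']:.2f}, "
      f"per-transcript stage agreement {cmp['stage_agreement']:.2f}")
print("\n1.0 across the board means each decoy was removed exactly at the "
      "stage built to catch it and all planted de novo groups survived.")
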