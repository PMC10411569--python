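"""Build a labeled synthetic dataset and look at its ground truth.

The simulator creates a focal genome with annotated multi-exon genes, two
diverged outgroup genomes, an ortholog table, and planted transcripts:
true intergenic de novo gene groups plus one decoy class per filter
stage, each decoy violating exactly the criterion its stage tests.
"""

from denovotx import SimPlan, simulate_dataset

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
    seed=42,
)
ds = simulate_dataset(plan)

print(f"focal genome: {len(ds.focal_genome)} chromosomes, "
      f"{sum(len(s) for s in ds.focal_genome.values()):,} bp")
print(f"annotated genes: {len(ds.annotation.gene_spans)}")
print(f"planted transcripts: {len(ds.transcripts)}")
print(f"outgroups: {sorted(ds.outgroups)}")
print("\nplanted classes and the stage each is designed to stop at:")
for cls, sub in ds.truth.groupby("class"):
    print(f"  {cls:16s} n={len(sub):2d} -> {sub['expected_stage'].iloc[0]}")
print("\nEvery transcript carries one truth label; the screen cascade is "
      "judged by whether it reproduces exactly this partition.")
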