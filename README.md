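# denovotx

Identification of candidate **de novo genes** — genes born from
ancestrally nongenic, intergenic DNA — from de novo assembled
transcripts, as practised in comparative transcriptomics of *Drosophila*
tissues.

A transcript assembled from RNA-seq of a focal species is a de novo gene
*candidate* when it (i) has no homolog among annotated gene features or
transposable elements in the focal species or its outgroups, (ii) has no
homolog among transcripts assembled from outgroup species, (iii) maps to
intergenic sequence of the focal genome, far from annotated exons, and
(iv) is reproducibly expressed.  Because absence of an outgroup homolog
could instead reflect a gap or error in an outgroup assembly, surviving
candidates are additionally checked for **microsynteny**: the genes
flanking the candidate locus are mapped through an ortholog table, and
the candidate region (locus ± 5 kb) must find homology near those
orthologs on a single outgroup scaffold.  Failures are down-tiered, not
discarded.

`denovotx` implements this entire decision procedure as a tested library
plus a thin CLI:

- **homology** — an in-repo seed-and-extend local nucleotide aligner
  (exact k-mer seeds, ungapped trigger, banded affine-gap extension with
  X-drop, trimming to the maximal-scoring segment) implementing the match
  rule used everywhere: *identity ≥ 80% over ≥ 100 alignment columns*,
  gaps counted, both strands.
- **screen** — the filter cascade with a conserved audit trail
  (`FilterTrace`): annotation-class databases → outgroup transcript
  databases → genome placement → length > 300 bp, nearest-exon distance
  > 250 bp, intergenic context → TPM ≥ 1 in ≥ 1 library, applied at the
  Trinity gene-group level (one qualifying isoform retains all isoforms).
- **expression** — TPM from counts (`TPM_t = (c_t/L_t) / Σ(c/L) × 10⁶`),
  isoform pooling, per-candidate summaries, and the per-library fraction
  of annotated genes expressed above the candidates' maximum.
- **synteny** — flanking-gene/ortholog microsynteny validation and
  tiering (`both_outgroups` / `one_outgroup` / `none`).
- **orf** — six-frame ORF discovery (ATG→stop, longest per stop) and
  peptide export for downstream coding-potential tools.
- **simulate** — a synthetic genome/transcriptome generator that plants
  true de novo gene groups *and one decoy class per filter stage*, each
  decoy violating exactly the criterion its stage tests, so the whole
  cascade can be validated against known truth.
- **pipeline** — one reproducible `run-all` with a manifest.

## Worked example

Simulate the default scaled-down study world and run everything:

```python
from denovotx import run_all, compare_to_truth

res = run_all({"seed": 1}, output_dir="out")
print(res.manifest.stage_counts)
cmp = compare_to_truth(res.candidates, res.trace, res.dataset.truth)
print(cmp["precision"], cmp["recall"])
```

prints

```
{'annotation_match': 10, 'outgroup_transcript_match': 5, 'unplaced': 5,
 'short': 5, 'near_exon': 5, 'not_intergenic': 5, 'low_expression': 5,
 'candidate': 16}
1.0 1.0
```

The stage counts partition the 56 input transcripts: ten decoys matched
annotation databases (gene copies and transposon copies), five matched
outgroup transcript sets (sequences planted as transcribed in the
outgroups), five failed genome placement, fifteen failed a structural
rule, five fell below TPM 1 — and 16 transcripts in exactly the 12
planted de novo gene groups survived (precision = recall = 1.0; four
groups carry a second isoform, including one 250 bp isoform retained
only because its sibling passes every rule).  Of the 12 candidates, 9
validate microsynteny in both simulated outgroups and 3 — planted over
deliberate synteny breaks — validate in neither and are kept as weaker,
`none`-tier candidates.

The same run from a shell, with the dataset written to disk first so the
truth manifest is available for the comparison:

```sh
denovotx simulate --seed 1 --out data
denovotx run-all --dataset-dir data --out out
denovotx compare-truth --run-dir out --truth data/truth.tsv
```

`examples/` contains one short narrative script per capability
(simulation, the match criterion, the cascade, expression summaries,
synteny validation, ORFs).

## Scope

The package replaces the *roles* of BLAST/HISAT2/StringTie at desk scale
and consumes counts rather than reads; transcript assembly, read
alignment, and external coding-potential scorers (CPC2/CPAT/SignalP) are
out of scope — ORF peptides are exported in a form those tools accept.
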