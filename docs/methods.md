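# Methods

## The decision procedure

A de novo gene candidate is an assembled transcript (Trinity-style ID,
grouped into gene groups `TRINITY_DN<k>_c<x>_g<j>` with isoforms
`_i<m>`) that survives a fixed cascade of filters.  Every input
transcript terminates at exactly one stage, recorded with evidence in a
`FilterTrace`; the stage counts always sum to the input count, which the
pipeline asserts.

1. **Annotation screen.**  The transcript is searched against
   annotation-class sequence databases (3′UTR, 5′UTR, intron, miRNA,
   miscRNA, ncRNA, pseudogene, transposon, tRNA, CDS) for every species
   available.  Any qualifying match anywhere removes it
   (`annotation_match`).
2. **Outgroup transcript screen.**  Likewise against transcript sets
   assembled from outgroup species (`outgroup_transcript_match`).  This
   is the operational definition of "no evidence of expression in the
   outgroups".
3. **Genome placement.**  The transcript must place on the focal genome
   by the same match rule; the locus is the subject span of the best
   qualifying alignment, merged with co-linear same-strand qualifying
   alignments within 1 kb (a stand-in for spliced alignment of
   multi-exon transcripts).  Chimeric placements keep the best segment
   and are flagged.  No placement → `unplaced`.
4. **Structural rules**, in order, first violation reported:
   length > 300 bp (strict), nearest-exon distance > 250 bp (strict,
   exons of any gene on either strand, measured from the placed locus in
   half-open coordinates), intergenic context (`short` / `near_exon` /
   `not_intergenic`).
5. **Expression rule**, applied per gene group: at least one isoform
   must itself pass the structural rules *and* reach TPM ≥ 1 (inclusive)
   in at least one library; a passing group retains all isoforms that
   reached this stage (`low_expression` otherwise).

Survivors are candidates.  Microsynteny validation then tiers them
(never removes): for each outgroup, the annotated genes immediately
up/downstream of the locus are mapped through the ortholog table;
validation requires the located orthologs to lie on one scaffold (one
located flank suffices; zero fails) and the candidate region — locus
± `synteny_flank` — to find a qualifying match on that scaffold within
the ortholog interval ± 50 kb.  A match to flank sequence alone is
deliberately sufficient: the check certifies *region* orthology, and de
novo birth predicts conserved flanks without a conserved transcript.
Tiers are `both_outgroups`, `one_outgroup`, `none`.

## The match rule and its aligner

Everything above shares one homology criterion: a local alignment with
**identity ≥ 0.80 over ≥ 100 alignment columns**, where gap columns
count toward both the denominator and the length (the convention of
standard local-alignment tools).  The aligner is a seed-and-extend
search owned by this package:

- exact k-mer seeds (k = 11 default, valid range 8–15; k-mers containing
  N are not indexed), found by binary search over sorted k-mer codes;
  subject records are concatenated with N-runs long enough that no
  alignment can bridge records;
- seeds grouped into diagonal buckets; a bucket with ≥ 3 hits extends
  directly, sparse buckets must first pass an ungapped two-way extension
  scoring ≥ 20 (a BLAST-like trigger that discards the ~99.99% of
  spurious single seeds cheaply);
- gapped extension: banded affine dynamic programming (match +1,
  mismatch −2, a length-L gap costs 4 + L), band half-width 10
  *recentered each row on the previous row's best cell* so multi-kb
  extensions can follow indel drift, X-drop 40, extension capped at
  20 000 columns;
- the stitched left + seed + right alignment is trimmed to its
  maximal-scoring contiguous segment (Kadane over per-column score
  deltas), from which identity, column count and coordinates derive;
- seeds falling inside an alignment already produced are skipped, so one
  homologous region yields one match; both strands are searched by
  reverse-complementing the query.

The reference point in tests is Biopython's `PairwiseAligner` in local
(Smith–Waterman) mode under identical scoring, applied to the same
criterion.  On 240 random pairs (unrelated and 0–30% diverged, ≤ 500
bp) the two agree in ≥ 99% of cases, and the rare disagreements sit
within 1 column or 0.5% identity of the threshold — the regime where a
heuristic and an exact aligner may legitimately rank alignments
differently.  One consequence worth knowing: under this scoring a
uniformly ~75%-identical window is only marginally positive, so *any*
optimal local aligner trims mismatch-led edges; naive expectations of
"25 substitutions in 100 bp → identity 0.75 over 100 columns" are off
by the trimmed edge, and tests freeze oracle-computed values instead.

A note on monotonicity: `has_match` is monotone in the criterion
(raising `min_identity` or `min_len` never turns a non-match into a
match), and the candidate count is monotone non-increasing in the
structural/expression thresholds.  The candidate count is *not* monotone
in the match criterion itself, because that criterion gates the removal
screens: stricter matching removes fewer transcripts upstream.  This is
a property of the cascade's semantics, not an implementation artifact,
and the test suite pins both true monotonicities.

## Expression model

TPM is computed from a counts matrix as `rate_t = count_t / length_kb`,
`TPM_t = rate_t / Σ rates × 10⁶` per library; effective length is the
transcript length, since the pipeline consumes counts rather than reads
(no fragment-length correction is meaningful at that interface).
Columns of a computed matrix sum to 10⁶ (asserted to 10⁻⁶ relative).
Isoform TPMs are summed to candidate level ("pooled"); replicate
aggregation then applies one of two deliberate conventions: `any_library`
(max ≥ 1, inclusive — the pipeline's own acceptance rule) or
`replicate_mean` (mean strictly > 1 — the rule for calls on external
replicate resources).  Both are exposed; they are not harmonized on
purpose.  Per-candidate summaries report libraries at TPM ≥ 1, nonzero
libraries, max TPM, and the mean of expressed observations; the cohort
statistic pools expressed observations across candidates.  A
contextual statistic — the per-library fraction of annotated genes
expressed above the candidates' maximum TPM — quantifies how lowly
expressed candidates are relative to the annotated transcriptome.

## The synthetic study conditions

The simulator exists so that every stage has labeled ground truth; its
defaults are the package's standing study conditions and are not tuned
per run:

- focal genome: 2 chromosomes × 500 kb of i.i.d. random sequence
  (uniform base composition; homopolymer runs long enough to matter to
  seeding are vanishingly improbable at these lengths);
- ~60 genes, 2–4 exons of 200–600 bp, introns 250–500 bp, placed
  sequentially with 6–16 kb intergenic gaps; five "host" genes carry a
  1300 bp intron;
- two outgroups derived by neutral per-site substitution (uniform over
  the three alternatives) and indels (rate per site, insertion/deletion
  equiprobable, geometric lengths with mean 2): 5%/0.2% and 10%/0.4% —
  the second sits at the divergence where an 80%-identity screen still
  must work — with exact focal→outgroup coordinate maps;
- an ortholog table mapping every focal gene to both outgroups (minus
  two random non-flank genes per species, exercising missing-ortholog
  handling);
- planted transcripts: 12 true de novo gene groups (intergenic copies,
  400–1200 bp, > 250 bp from any exon; four groups carry a second
  isoform, one of them 250 bp to exercise the isoform-rescue rule) and
  five decoys per stage: copies of exons and of transposon consensus
  (annotation screen), intergenic copies also injected at ~11%
  divergence into the outgroup transcript sets (outgroup screen),
  random non-genomic sequence (placement), 150–300 bp copies (length),
  copies 20–250 bp from a gene boundary (distance), copies centered in
  host-gene introns (context), and copies expressed at ~0.5 TPM
  (expression);
- intron databases deliberately omit the host genes, in every species:
  real annotation-class databases are never complete, which is exactly
  why a genomic-context filter exists alongside the database screen, and
  the intronic decoy class exercises that path;
- synteny breaks: 25% of true loci (3 of 12) have both outgroup
  chromosomes cut into separate scaffolds at the locus midpoint,
  splitting the flanking orthologs;
- expression: 6 libraries (2 genotypes × 3 female reproductive-tract
  tissues).  True groups get 1–3 libraries at 1.05–2.5 TPM plus ~3
  libraries at 0.1–0.9 TPM — low expression in few libraries, the
  regime de novo genes occupy; annotated genes draw log-uniform 0.2–300
  TPM; a background row absorbs the remainder so targets are realized
  exactly, and integer counts are `round(target × length_kb × 400)`,
  landing within ~2% (asserted < 10%) of target after normalization.

Everything derives from one seeded generator; identical plan + seed
reproduce byte-identical files, and the full pipeline on the defaults
recovers exactly the planted groups (precision = recall = 1), removing
each decoy at its designed stage.

What the simulation does **not** emulate — and hence what passing tests
do not show about real data: read-level noise and assembly artifacts
(chimeras, fragmentation), realistic base composition, repeats and
segmental duplication, transcribed-but-unannotated features beyond the
planted classes, selection on the diverging outgroups, and expression
estimation error upstream of the counts matrix.  Results on real
transcriptomes inherit all of those.

## ORFs

ORFs run ATG through stop codon inclusive, both strands (assemblies may
be antisense), all three frames; nested starts sharing a stop keep the
longest; stopless runs at a transcript end are flagged partial and
excluded from the minimum-length pass by default.  The default minimum
is 75 nt, with a permissive 30 nt preset also exposed, since both
conventions circulate among coding-potential tools; coordinates are
reported on the forward transcript, and exported peptides omit the stop.

## Numerical and design choices

- Internal coordinates are 0-based half-open everywhere; GTF converts at
  the boundary, BED is native.  Candidate strand comes from placement.
- Tie-breaks are total and documented: matches by (score, identity,
  subject id, subject start); ORFs by (length, '+' strand, start);
  flanking genes by (boundary distance, gene id).  Reruns are
  byte-identical.
- The intronic-context rule uses a ≥ 50% overlap threshold for loci
  straddling a gene boundary; partial straddles below it are intergenic.
- One located flank ortholog suffices to attempt synteny validation;
  manual rescue of failures (e.g. genome-browser inspection over larger
  regions) is out of scope — failures are tiered, not rescued.
- Whether a per-candidate "max TPM" should pool isoforms is ambiguous in
  the field's reporting; pooled values are used and the report says so.
- All thresholds live in `PipelineConfig` and are recorded verbatim in
  every run manifest; stage code contains no literals.

## Problem sizes

Default runs use the 1 Mb / ~60-gene / 56-transcript world above — the
scale at which a seeded k-mer index plus banded extension makes
exhaustive screening interactive (a full pipeline run is ~15 s on one
core) while still giving every filter ≥ 5 labeled exercises.  The
oracle-equivalence checks use 240 alignment pairs ≤ 500 bp and 100
random transcripts ≤ 3 kb for the six-frame enumeration.

## Known limitations

- The aligner is heuristic: a qualifying homology whose only seeds fall
  in low-identity context can be missed near the criterion boundary
  (bounded by the oracle-agreement tests); there are no E-values, no
  protein-level or translated search, and no low-complexity masking.
- The 1 kb co-linear merge is a placement heuristic, not a splice model;
  introns longer than 1 kb fragment a placement.
- Synteny validation depends on the ortholog table; misassigned
  orthologs produce spurious `split_flanks` failures (tiered, so
  recoverable downstream).
- TPM from counts cannot model positional or fragment-length bias.
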