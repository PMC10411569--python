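"""Six-frame ORF discovery on candidate transcripts.

ORFs run ATG through stop (inclusive), both strands, all three frames;
nested starts sharing a stop keep only the longest.  The default minimum
is 75 nt; peptides are exported without the stop symbol for downstream
coding-potential tools.
"""

import numpy as np

from denovotx import find_orfs

(orf,) = find_orfs("ATGAAATAA", min_len_nt=9)
print(f"minimal ORF: length {orf.length_nt} nt, peptide {orf.peptide!r} "
      f"(stop excluded)\n")

rng = np.random.default_rng(11)
transcript = "".join("ACGT"[i] for i in rng.integers(0, 4, 900))
orfs = find_orfs(transcript, min_len_nt=75, transcript_id="TRINITY_DN1_c0_g1_i1")
print(f"random 900 nt transcript: {len(orfs)} ORFs >= 75 nt "
      f"(longest first)")
for o in orfs[:5]:
    print(f"  strand {o.strand} frame {o.frame}  [{o.start:3d},{o.end:3d})  "
          f"{o.length_nt:3d} nt  {o.peptide[:20]}...")
print("\nIn random sequence, short ORFs arise by chance — the reason the "
      "minimum-length rule exists before any coding-potential scoring.")
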