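"""Unit and property tests of the seed-and-extend homology search.

The independent oracle throughout is Biopython's PairwiseAligner in local
(Smith-Waterman) mode under the same scoring scheme; the acceptance suite
runs the large-sample equivalence check.
"""

import numpy as np
import pytest
from Bio import Align

from denovotx.homology import (
    MatchCriterion,
    Scoring,
    SeqIndex,
    build_kmer_index,
    has_match,
    revcomp,
    search_matches,
    seed_extend,
)

from conftest import random_seq


def oracle_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 1
    a.mismatch_score = -2
    a.open_gap_score = -5
    a.extend_gap_score = -1
    return a


def oracle_best(query: str, subject: str):
    """(identity, columns) of the optimal local alignment over both strands,
    or None if nothing scores positively."""
    a = oracle_aligner()
    best = None
    for q in (query, revcomp(query)):
        if a.score(q, subject) <= 0:
            continue
        aln = a.align(q, subject)[0]
        c = aln.counts()
        cols = c.identities + c.mismatches + c.gaps
        if best is None or aln.score > best[0]:
            best = (aln.score, c.identities / cols, cols)
    return None if best is None else best[1:]


class TestKmerIndex:
    def test_positions_of_repeated_kmer(self):
        idx = build_kmer_index([("a", "ACGTACGTACGT")], k=8)
        assert idx.lookup("ACGTACGT") == [0, 4]

    def test_absent_kmer_empty(self):
        idx = build_kmer_index([("a", "ACGTACGTACGT")], k=8)
        assert idx.lookup("AAAAAAAA") == []

    def test_n_containing_kmers_not_indexed(self):
        idx = build_kmer_index([("a", "ACGTNCGTACGTT")], k=8)
        # every window covering the N is invalid
        assert idx.lookup("ACGTNCGT") == []

    def test_k_larger_than_shortest_sequence_rejected(self):
        with pytest.raises(ValueError, match="shortest"):
            build_kmer_index([("a", "ACGTAC")], k=11)


class TestSeedExtend:
    def test_identical_sequences_give_full_length_identity(self, rng):
        s = random_seq(rng, 150)
        m = seed_extend(s, s, (40, 40))
        assert m.identity == 1.0 and m.aligned_len == 150
        assert (m.q_start, m.q_end, m.s_start, m.s_end) == (0, 150, 0, 150)

    def test_quarter_substitutions_agree_with_sw_oracle(self, rng):
        # 25 substitutions in 100 bp: ~75% identity.  Under local scoring
        # the optimal alignment trims a mismatch-led edge, so the exact
        # expectation comes from the Smith-Waterman oracle on the pair.
        s = random_seq(rng, 100)
        q = list(s)
        for p in range(1, 100, 4):
            if 44 <= p < 58:
                continue  # intact island provides the exact seed
            q[p] = "ACGT"[("ACGT".index(q[p]) + 1) % 4]
        q = "".join(q)
        m = seed_extend(q, s, _first_common_seed(q, s))
        ident, cols = oracle_best(q, s)
        assert m.aligned_len == cols
        assert m.identity == pytest.approx(ident)
        assert 0.70 <= m.identity <= 0.85  # heavily diverged, nowhere near 1.0

    def test_gap_costs_match_oracle_on_deletion(self, rng):
        s = random_seq(rng, 260)
        q = s[:120] + s[127:250]  # 7 bp deletion
        m = seed_extend(q, s, _first_common_seed(q, s))
        ident, cols = oracle_best(q, s)
        assert m.aligned_len == cols
        assert m.identity == pytest.approx(ident)


def _first_common_seed(q, s, k=11):
    for i in range(len(q) - k + 1):
        j = s.find(q[i : i + k])
        if j >= 0:
            return (i, j)
    raise AssertionError("no common seed")


class TestHasMatch:
    def test_long_exact_substring_qualifies(self, rng):
        s = random_seq(rng, 600)
        idx = SeqIndex([("s", s)])
        ok, best = has_match(s[200:350], idx)
        assert ok and best.aligned_len >= 100 and best.identity >= 0.80

    def test_identity_below_threshold_fails(self, rng):
        # every 4th base of a 120 bp window substituted: ~75% identity in
        # every sub-window, so no trimming can reach the 80% threshold
        s = random_seq(rng, 400)
        q = list(s[100:220])
        for p in range(1, 120, 4):
            q[p] = "ACGT"[("ACGT".index(q[p]) + 1) % 4]
        q = "".join(q)
        ok, _ = has_match(q, SeqIndex([("s", s)]))
        ident, cols = oracle_best(q, s)
        assert ident < 0.80
        assert ok is False

    def test_short_perfect_match_fails_length_bound(self, rng):
        # a 99 bp exact island: 100% identity but < 100 columns
        island = random_seq(rng, 99)
        subject = random_seq(rng, 300) + island + random_seq(rng, 300)
        ok, _ = has_match(island, SeqIndex([("s", subject)]))
        assert ok is False
        ok2, best2 = has_match(
            island, SeqIndex([("s", subject)]), MatchCriterion(0.80, 99)
        )
        assert ok2 and best2.aligned_len == 99

    def test_reverse_complement_detection_symmetry(self, rng):
        s = random_seq(rng, 500)
        idx = SeqIndex([("s", s)])
        q = s[150:330]
        ok_f, m_f = has_match(q, idx)
        ok_r, m_r = has_match(revcomp(q), idx)
        assert ok_f and ok_r
        assert (m_f.s_start, m_f.s_end) == (m_r.s_start, m_r.s_end)
        assert {m_f.strand, m_r.strand} == {"+", "-"}

    def test_raising_thresholds_never_creates_a_match(self, rng):
        # monotonicity: stricter criteria can only lose matches
        for _ in range(25):
            s = random_seq(rng, 300)
            q_src = s[50 : 50 + int(rng.integers(80, 200))]
            q = list(q_src)
            for p in range(len(q)):
                if rng.random() < 0.15:
                    q[p] = "ACGT"[("ACGT".index(q[p]) + 1) % 4]
            q = "".join(q)
            idx = SeqIndex([("s", s)])
            matches = search_matches(q, idx)
            prev = True
            for ident, mlen in [(0.80, 100), (0.85, 120), (0.95, 160)]:
                ok, _ = has_match(q, idx, MatchCriterion(ident, mlen), matches=matches)
                assert prev or not ok  # False can never turn True
                prev = ok

    def test_tie_break_prefers_lower_subject_then_start(self, rng):
        q = random_seq(rng, 150)
        pad = random_seq(rng, 60)
        # identical copies in two subjects and twice within one subject
        idx = SeqIndex([("b", pad + q + pad + q), ("a", pad + q)])
        ok, best = has_match(q, idx)
        assert ok and best.subject_id == "a" and best.s_start == 60


class TestSearchMatches:
    def test_one_match_per_homologous_region(self, rng):
        s = random_seq(rng, 800)
        idx = SeqIndex([("s", s)])
        out = search_matches(s[100:400], idx)
        plus = [m for m in out if m.strand == "+"]
        assert len(plus) == 1
        assert (plus[0].s_start, plus[0].s_end) == (100, 400)

    def test_two_separate_copies_reported_separately(self, rng):
        q = random_seq(rng, 200)
        s = random_seq(rng, 300) + q + random_seq(rng, 2000) + q + random_seq(rng, 300)
        out = [m for m in search_matches(q, SeqIndex([("s", s)])) if m.strand == "+"]
        starts = sorted(m.s_start for m in out)
        assert starts == [300, 2500]
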