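"""In-repo local nucleotide homology search (seed-and-extend).

Implements the match criterion used throughout the screening cascade: a
match is a local alignment with identity >= 80% over at least 100
alignment columns (gap columns count).  The search is BLAST-like at desk
scale: exact k-mer seeds over an indexed subject set, an ungapped
extension trigger, then banded affine-gap extension with X-drop and
trimming to the maximal-scoring segment.  Both subject strands are
searched by reverse-complementing the query.

Scoring: match +1, mismatch -2, gap open -4, gap extend -1 (a length-L
gap costs 4 + L).  Identity is matches / alignment columns, gaps
included, the BLAST convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AlignmentMatch",
    "MatchCriterion",
    "Scoring",
    "SeqIndex",
    "build_kmer_index",
    "seed_extend",
    "search_matches",
    "has_match",
    "encode",
    "revcomp",
]

NEG = -1.0e18

_ENCODE = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate("ACGT"):
    _ENCODE[ord(b)] = i
    _ENCODE[ord(b.lower())] = i
_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

#: subject records are concatenated with this many N's between them; long
#: enough that neither mismatches nor a single gap can bridge two records
#: under the default X-drop.
_SEPARATOR = 64


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 (A=0 C=1 G=2 T=3, other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    arr = _COMPLEMENT[encode(seq)][::-1]
    return _DECODE[arr].tobytes().decode("ascii")


@dataclass(frozen=True)
class MatchCriterion:
    """Acceptance rule for a homology match: identity and alignment length."""

    min_identity: float = 0.80
    min_len: int = 100

    def __post_init__(self):
        if not (0 < self.min_identity <= 1):
            raise ValueError("min_identity must be in (0, 1]")
        if self.min_len < 1:
            raise ValueError("min_len must be positive")

    def accepts(self, identity: float, aligned_len: int) -> bool:
        return identity >= self.min_identity and aligned_len >= self.min_len


@dataclass(frozen=True)
class Scoring:
    """Alignment scoring and extension control parameters."""

    match: int = 1
    mismatch: int = -2
    gap_open: int = -4   # opening surcharge; first gap column scores open+extend
    gap_extend: int = -1
    band: int = 10       # half-width of the (adaptively recentered) band
    xdrop: int = 40
    ungapped_trigger: int = 20
    max_extension: int = 20000


@dataclass(frozen=True)
class AlignmentMatch:
    """A local alignment between a query and one subject record.

    Coordinates are 0-based half-open.  ``strand`` is the query strand
    relative to the subject; for '-' the query coordinates refer to the
    original (input) query orientation.  ``aligned_len`` counts alignment
    columns including gap columns; ``identity`` = matches / aligned_len.
    """

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    aligned_len: int
    identity: float
    score: int

    def sort_key(self):
        # highest score first; ties by higher identity, lower subject_id,
        # lower s_start
        return (-self.score, -self.identity, self.subject_id, self.s_start)


class SeqIndex:
    """Exact k-mer position index over a set of subject sequences.

    k-mers containing non-ACGT characters are not indexed.  Lookup is by
    sorted k-mer code + binary search; positions are global offsets into
    the concatenation of all records (separated by N runs) and are mapped
    back to per-record coordinates on demand.
    """

    def __init__(self, records: Sequence[tuple[str, str]], k: int = 11):
        if not (8 <= k <= 15):
            raise ValueError(f"k must be in [8, 15], got {k}")
        if not records:
            raise ValueError("cannot index an empty sequence set")
        shortest = min(len(s) for _, s in records)
        if k > shortest:
            raise ValueError(
                f"k={k} exceeds the shortest subject sequence ({shortest} bp)"
            )
        self.k = k
        self.names = [n for n, _ in records]
        self.lengths = np.array([len(s) for _, s in records], dtype=np.int64)
        sep = "N" * _SEPARATOR
        self.concat = encode(sep.join(s for _, s in records))
        # start offset of each record in the concatenation
        starts = np.zeros(len(records), dtype=np.int64)
        pos = 0
        for i, (_, s) in enumerate(records):
            starts[i] = pos
            pos += len(s) + _SEPARATOR
        self.offsets = starts
        codes, valid = _kmer_codes(self.concat, k)
        positions = np.nonzero(valid)[0]
        codes = codes[positions]
        order = np.argsort(codes, kind="stable")
        self._sorted_codes = codes[order]
        self._sorted_pos = positions[order]

    def lookup(self, kmer: str) -> list[int]:
        """Global positions of one exact k-mer (empty if absent or invalid)."""
        enc = encode(kmer)
        if len(enc) != self.k or (enc > 3).any():
            return []
        code = 0
        for b in enc:
            code = code * 4 + int(b)
        lo = np.searchsorted(self._sorted_codes, code, side="left")
        hi = np.searchsorted(self._sorted_codes, code, side="right")
        return sorted(int(p) for p in self._sorted_pos[lo:hi])

    def lookup_record(self, kmer: str) -> list[tuple[str, int]]:
        """Like :meth:`lookup` but as (record name, record-local position)."""
        out = []
        for gpos in self.lookup(kmer):
            ridx = self.record_index(gpos)
            out.append((self.names[ridx], gpos - int(self.offsets[ridx])))
        return out

    def record_index(self, gpos: int) -> int:
        return int(np.searchsorted(self.offsets, gpos, side="right") - 1)

    def _seed_hits(self, qenc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """All (query_pos, global_subject_pos) exact k-mer hits."""
        qcodes, qvalid = _kmer_codes(qenc, self.k)
        qpos_all = np.nonzero(qvalid)[0]
        if qpos_all.size == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        qcodes = qcodes[qpos_all]
        lo = np.searchsorted(self._sorted_codes, qcodes, side="left")
        hi = np.searchsorted(self._sorted_codes, qcodes, side="right")
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        qout = np.repeat(qpos_all, counts)
        # expand ranges [lo, hi) into indices of _sorted_pos
        idx = np.repeat(lo, counts) + _ranges_arange(counts)
        sout = self._sorted_pos[idx]
        return qout, sout


def _ranges_arange(counts: np.ndarray) -> np.ndarray:
    """Concatenated arange(c) for each c in counts (0-length allowed)."""
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    ends = np.cumsum(counts)
    starts = ends - counts
    return np.arange(total, dtype=np.int64) - np.repeat(starts, counts)


def _kmer_codes(enc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(codes, valid) for every k-window; valid=False if any base is non-ACGT."""
    n = len(enc)
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    m = n - k + 1
    codes = np.zeros(m, dtype=np.int64)
    ok = np.ones(m, dtype=bool)
    e = enc.astype(np.int64)
    for j in range(k):
        win = e[j : j + m]
        codes = codes * 4 + np.where(win > 3, 0, win)
        ok &= win <= 3
    return codes, ok


def build_kmer_index(sequences: Sequence[tuple[str, str]], k: int = 11) -> SeqIndex:
    """Build an exact k-mer index over subject sequences (see SeqIndex)."""
    return SeqIndex(sequences, k=k)


# ---------------------------------------------------------------------------
# Banded affine-gap extension
# ---------------------------------------------------------------------------


def _banded_extend(q: np.ndarray, s: np.ndarray, scoring: Scoring):
    """Anchored banded extension of q against s, both starting at offset 0.

    Returns (best_score, ops) where ops is the list of alignment columns of
    the best-scoring path from the anchor, each ('M', is_match) / ('Q',) /
    ('S',) for diagonal / gap-in-subject (query consumed) / gap-in-query
    (subject consumed).  The band (half-width ``scoring.band``) is
    recentered each row on the best cell of the previous row; extension
    stops on X-drop or at ``scoring.max_extension`` rows.
    """
    W = scoring.band
    width = 2 * W + 1
    Lq = min(len(q), scoring.max_extension)
    Ls = len(s)
    if Lq == 0 or Ls == 0:
        return 0, []
    go, ge = scoring.gap_open + scoring.gap_extend, scoring.gap_extend  # -5, -1
    # row 0: alignment consuming 0 query chars; j in [0, min(W, Ls)]
    lo = 0
    hi = min(W, Ls)
    n0 = hi - lo + 1
    M = np.full(n0, NEG)
    Gq = np.full(n0, NEG)
    Gs = np.full(n0, NEG)
    M[0] = 0.0
    if n0 > 1:
        Gq[1:] = go + ge * np.arange(n0 - 1)
    rows = [(lo, M, Gq, Gs, None)]
    best = 0.0
    best_cell = (0, 0, "M")  # (row, j, matrix)
    for i in range(1, Lq + 1):
        plo, pM, pGq, pGs, _ = rows[-1]
        pbest = np.maximum(np.maximum(pM, pGq), pGs)
        center = plo + int(np.argmax(pbest)) + 1
        lo_i = max(0, center - W)
        hi_i = min(Ls, center + W)
        if lo_i > hi_i:
            break
        n = hi_i - lo_i + 1
        js = np.arange(lo_i, hi_i + 1)
        # previous-row values at j and j-1, aligned to this row's window
        pM_j = _window(pM, plo, lo_i, n)
        pGs_j = _window(pGs, plo, lo_i, n)
        pbest_jm1 = _window(pbest, plo, lo_i - 1, n)
        qc = int(q[i - 1])
        sw = s[lo_i - 1 : hi_i].astype(np.int64) if lo_i >= 1 else np.concatenate(
            ([4], s[:hi_i])
        ).astype(np.int64)
        # substitution score for column j (uses s[j-1]); j=0 cells can't be M
        match_mask = (sw == qc) & (sw <= 3) & (qc <= 3)
        sub = np.where(match_mask, float(scoring.match), float(scoring.mismatch))
        Mi = pbest_jm1 + sub
        if js[0] == 0:
            Mi[0] = NEG
        Gsi = np.maximum(pM_j + go, pGs_j + ge)
        # Gq (gap in query, consumes subject): within-row recurrence
        #   Gq[j] = max_{j'<j} Mi[j'] + go + ge*(j - j' - 1)
        # with ge = -1 this is (running max of Mi[j'] + j') + go - (j - 1),
        # computed with a prefix max and its argmax for traceback.
        A = Mi + js
        am = np.maximum.accumulate(A)
        newmax = np.empty(n, dtype=bool)
        newmax[0] = True
        if n > 1:
            newmax[1:] = A[1:] > am[:-1]
        src = np.where(newmax, np.arange(n), 0)
        src = np.maximum.accumulate(src)
        Gqi = np.full(n, NEG)
        gq_src = np.full(n, -1, dtype=np.int64)
        if n > 1:
            Gqi[1:] = am[:-1] + go + ge * (js[1:] - 1)
            gq_src[1:] = src[:-1]
        rows.append((lo_i, Mi, Gqi, Gsi, gq_src))
        cand = np.maximum(np.maximum(Mi, Gqi), Gsi)
        row_best = float(cand.max())
        if row_best > best:
            jrel = int(np.argmax(cand))
            v = cand[jrel]
            mat = "M" if Mi[jrel] == v else ("Gq" if Gqi[jrel] == v else "Gs")
            best = row_best
            best_cell = (i, lo_i + jrel, mat)
        if row_best < best - scoring.xdrop:
            break
    if best <= 0:
        return 0, []
    ops = _traceback(rows, best_cell, q, s)
    return int(round(best)), ops


def _window(arr: np.ndarray, arr_lo: int, want_lo: int, n: int) -> np.ndarray:
    """arr values at absolute positions [want_lo, want_lo+n), NEG-padded."""
    out = np.full(n, NEG)
    a0 = want_lo - arr_lo
    a1 = a0 + n
    src_lo = max(a0, 0)
    src_hi = min(a1, len(arr))
    if src_hi > src_lo:
        out[src_lo - a0 : src_hi - a0] = arr[src_lo:src_hi]
    return out


def _traceback(rows, best_cell, q, s):
    i, j, mat = best_cell
    ops: list[tuple] = []
    while not (i == 0 and j == 0):
        lo_i, M, Gq, Gs, gq_src = rows[i]
        jr = j - lo_i
        if i == 0:
            # row-0 Gq cells are a pure leading gap from the anchor
            for _ in range(j):
                ops.append(("S",))
            break
        if mat == "M":
            qc, sc = int(q[i - 1]), int(s[j - 1])
            ops.append(("M", qc == sc and qc <= 3))
            # choose predecessor among previous row's matrices at j-1
            plo, pM, pGq, pGs, _ = rows[i - 1]
            pj = j - 1 - plo
            vals = []
            for name, arr in (("M", pM), ("Gq", pGq), ("Gs", pGs)):
                v = arr[pj] if 0 <= pj < len(arr) else NEG
                vals.append((v, name))
            vmax = max(v for v, _ in vals)
            mat = next(name for v, name in vals if v == vmax)
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
        elif mat == "Gs":
            ops.append(("Q",))
            plo, pM, pGq, pGs, _ = rows[i - 1]
            pj = j - plo
            vM = pM[pj] if 0 <= pj < len(pM) else NEG
            vG = pGs[pj] if 0 <= pj < len(pGs) else NEG
            mat = "M" if vM - 5 >= vG - 1 else "Gs"
            i = i - 1
        else:  # Gq: jump back to origin column within the same row
            origin = int(gq_src[jr]) + lo_i
            for _ in range(j - origin):
                ops.append(("S",))
            j = origin
            mat = "M"
        if i == 0 and j == 0:
            break
        if i < 0 or j < 0:  # pragma: no cover - guards a logic error
            raise RuntimeError("traceback escaped the band")
    ops.reverse()
    return ops


def seed_extend(
    query: str,
    subject: str,
    seed_pos: tuple[int, int],
    scoring: Scoring = Scoring(),
    k: int = 11,
    query_id: str = "query",
    subject_id: str = "subject",
) -> AlignmentMatch | None:
    """Extend one exact k-mer seed into a trimmed local alignment.

    ``seed_pos`` is (query_pos, subject_pos) of the seed start.  Extension
    is banded and gapped in both directions; the result is trimmed to the
    maximal-scoring contiguous segment of alignment columns.  Returns None
    if nothing scores above zero (cannot happen for a valid exact seed).
    """
    qenc, senc = encode(query), encode(subject)
    m = _extend_from_seed(qenc, senc, seed_pos[0], seed_pos[1], k, scoring)
    if m is None:
        return None
    qs, qe, ss, se, cols, matches, score = m
    return AlignmentMatch(
        query_id=query_id,
        subject_id=subject_id,
        q_start=qs,
        q_end=qe,
        s_start=ss,
        s_end=se,
        strand="+",
        aligned_len=cols,
        identity=matches / cols if cols else 0.0,
        score=score,
    )


def _extend_from_seed(qenc, senc, qpos, spos, k, scoring):
    """Core extension: returns (qs, qe, ss, se, columns, matches, score)."""
    W = scoring.band
    lim = scoring.max_extension
    # right extension
    q_r = qenc[qpos + k : qpos + k + lim]
    s_r = senc[spos + k : spos + k + min(lim, len(q_r)) + W + 2]
    _, ops_r = _banded_extend(q_r, s_r, scoring)
    # left extension on reversed prefixes
    q_l = qenc[max(0, qpos - lim) : qpos][::-1]
    s_l = senc[max(0, spos - (len(q_l) + W + 2)) : spos][::-1]
    _, ops_l = _banded_extend(q_l, s_l, scoring)
    seed_ops = [("M", bool(qenc[qpos + t] == senc[spos + t])) for t in range(k)]
    ops = list(reversed(ops_l)) + seed_ops + list(ops_r)
    # per-column score deltas with affine gap-open on type changes
    deltas = np.empty(len(ops))
    prev = None
    for t, op in enumerate(ops):
        if op[0] == "M":
            deltas[t] = scoring.match if op[1] else scoring.mismatch
        else:
            opening = prev != op[0]
            deltas[t] = (scoring.gap_open if opening else 0) + scoring.gap_extend
        prev = op[0]
    a, b, seg_score = _max_segment(deltas)
    if b <= a or seg_score <= 0:
        return None
    # map the segment back to coordinates
    q0 = qpos - sum(1 for op in ops_l if op[0] != "S")
    s0 = spos - sum(1 for op in ops_l if op[0] != "Q")
    qc, sc = q0, s0
    qs = qe = ss = se = None
    matches = 0
    for t, op in enumerate(ops):
        if t == a:
            qs, ss = qc, sc
        if op[0] == "M":
            if a <= t < b and op[1]:
                matches += 1
            qc += 1
            sc += 1
        elif op[0] == "Q":
            qc += 1
        else:
            sc += 1
        if t == b - 1:
            qe, se = qc, sc
            break
    cols = b - a
    return qs, qe, ss, se, cols, matches, int(round(seg_score))


def _max_segment(deltas: np.ndarray) -> tuple[int, int, float]:
    """Kadane: (start, end, score) of the maximal-sum contiguous segment.

    Ties prefer the earliest, longest segment (deterministic).
    """
    best = -np.inf
    best_a = best_b = 0
    cur = 0.0
    cur_a = 0
    for t, d in enumerate(deltas):
        if cur <= 0:
            cur = float(d)
            cur_a = t
        else:
            cur += float(d)
        if cur > best:
            best = cur
            best_a, best_b = cur_a, t + 1
    return best_a, best_b, best


# ---------------------------------------------------------------------------
# Search
# ---------------------------------------------------------------------------

_BUCKET = 16  # diagonal bucket width for seed grouping


def _ungapped_score(qenc, senc, qpos, spos, k, scoring, span=400):
    """Cheap ungapped two-way extension score through the seed."""
    score = k * scoring.match
    # right
    n = min(span, len(qenc) - (qpos + k), len(senc) - (spos + k))
    if n > 0:
        a = qenc[qpos + k : qpos + k + n].astype(np.int16)
        b = senc[spos + k : spos + k + n].astype(np.int16)
        d = np.where((a == b) & (a <= 3), scoring.match, scoring.mismatch)
        c = np.cumsum(d)
        score += max(0, int(c.max()))
    # left
    n = min(span, qpos, spos)
    if n > 0:
        a = qenc[qpos - n : qpos][::-1].astype(np.int16)
        b = senc[spos - n : spos][::-1].astype(np.int16)
        d = np.where((a == b) & (a <= 3), scoring.match, scoring.mismatch)
        c = np.cumsum(d)
        score += max(0, int(c.max()))
    return score


def search_matches(
    query: str,
    index: SeqIndex,
    scoring: Scoring = Scoring(),
    query_id: str = "query",
    min_report_score: int = 15,
) -> list[AlignmentMatch]:
    """All non-redundant local alignments of the query against the index.

    Seeds are grouped into diagonal buckets per subject region; each bucket
    contributes at most one gapped extension, and seeds falling inside an
    alignment already produced are skipped, so a long homology yields one
    match rather than one per seed.  Both strands are searched.
    """
    k = index.k
    out: list[AlignmentMatch] = []
    for strand in ("+", "-"):
        qs = query if strand == "+" else revcomp(query)
        qenc = encode(qs)
        qp, sp = index._seed_hits(qenc)
        if qp.size == 0:
            continue
        diag = sp - qp
        bucket = diag // _BUCKET
        # bucket id must separate subject records: diag is global so records
        # are naturally separated by the concatenation offsets
        uniq, inverse, counts = np.unique(
            bucket, return_inverse=True, return_counts=True
        )
        # extend densest buckets first so masking suppresses the rest
        order = np.lexsort((uniq, -counts))
        accepted: list[tuple[int, int, int, int]] = []  # qs,qe,ss,se (this strand)
        for b in order:
            members = np.nonzero(inverse == b)[0]
            # deterministic representative: smallest query position
            rep = members[np.argmin(qp[members])]
            qpos, spos = int(qp[rep]), int(sp[rep])
            if any(
                a_qs <= qpos < a_qe and a_ss <= spos < a_se
                for a_qs, a_qe, a_ss, a_se in accepted
            ):
                continue
            # a bucket holding several exact seed hits is itself strong
            # evidence; sparse buckets must pass the ungapped trigger
            if len(members) < 3 and (
                _ungapped_score(qenc, index.concat, qpos, spos, k, scoring)
                < scoring.ungapped_trigger
            ):
                continue
            m = _extend_from_seed(qenc, index.concat, qpos, spos, k, scoring)
            if m is None:
                continue
            mqs, mqe, mss, mse, cols, matches, score = m
            if score < min_report_score:
                continue
            accepted.append((mqs, mqe, mss, mse))
            ridx = index.record_index(mss)
            roff = int(index.offsets[ridx])
            if strand == "+":
                oq_s, oq_e = mqs, mqe
            else:
                oq_s, oq_e = len(query) - mqe, len(query) - mqs
            out.append(
                AlignmentMatch(
                    query_id=query_id,
                    subject_id=index.names[ridx],
                    q_start=oq_s,
                    q_end=oq_e,
                    s_start=mss - roff,
                    s_end=mse - roff,
                    strand=strand,
                    aligned_len=cols,
                    identity=matches / cols,
                    score=score,
                )
            )
    # deduplicate identical spans found on both passes
    seen = set()
    uniq_out = []
    for m in sorted(out, key=AlignmentMatch.sort_key):
        key = (m.subject_id, m.q_start, m.q_end, m.s_start, m.s_end, m.strand)
        if key not in seen:
            seen.add(key)
            uniq_out.append(m)
    return uniq_out


def has_match(
    query: str,
    index: SeqIndex,
    criterion: MatchCriterion = MatchCriterion(),
    scoring: Scoring = Scoring(),
    query_id: str = "query",
    matches: Iterable[AlignmentMatch] | None = None,
) -> tuple[bool, AlignmentMatch | None]:
    """True iff some local alignment satisfies the match criterion.

    Returns the highest-scoring qualifying match (ties: higher identity,
    then lower subject id, then lower subject start).  ``matches`` may
    supply precomputed results of :func:`search_matches` for the same
    query/index to avoid repeating the search.
    """
    if matches is None:
        matches = search_matches(query, index, scoring, query_id=query_id)
    qualifying = [m for m in matches if criterion.accepts(m.identity, m.aligned_len)]
    if not qualifying:
        return False, None
    best = min(qualifying, key=AlignmentMatch.sort_key)
    return True, best
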