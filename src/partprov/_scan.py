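"""Low-level ungapped alignment primitives.

The segment search and the part annotator are both built on one primitive:
along a diagonal of the comparison matrix between two sequences, the
match/mismatch profile is decomposed into *maximal scoring segments* under the
megablast-style scheme (match +2, mismatch −8).  The decomposition rule is the
recursive one:

1. take the maximum-scoring contiguous run of the profile; ties are broken by
   shorter length, then smaller start coordinate;
2. remove it and recurse on the left and right remainders.

Segment endpoints are always matches (a flanking mismatch lowers the score),
so the rule is deterministic and, at ≥98 % identity, reproduces the
near-ungapped matches the stated scoring scheme was chosen to report: opening
a gap (4 + 6/bp) costs more than a mismatch (8), so optimal local alignments
at high identity are gap-free.

Candidate diagonals are anchored on shared exact k-words.  An exact word of
``word_size`` bases is also a *requirement* on reported segments (the seeded
search of the original procedure cannot discover a match without one), which
makes the word-index implementation exactly equivalent to an exhaustive scan
over every diagonal.

Significance uses Karlin–Altschul statistics ``E = K·m·n·exp(−λS)``.  λ is
the positive root of ``Σ p_i p_j exp(λ s_ij) = 1`` for uniform base
composition; for the default (+2, −8) scheme λ ≈ 0.6917 and K = 0.738 (the
tabulated ungapped value for this scheme).
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np

__all__ = [
    "encode",
    "kmer_hashes",
    "SeqIndex",
    "seed_matches",
    "diagonal_match_profile",
    "maximal_segments",
    "karlin_lambda",
    "karlin_k",
    "evalue",
]

# Base codes: A=0 C=1 G=2 T=3 N=4.  N never matches anything, including N.
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def encode(seq: str) -> np.ndarray:
    """Encode an uppercase A/C/G/T/N string as uint8 codes."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_hashes(codes: np.ndarray, k: int) -> np.ndarray:
    """2-bit packed k-mer values at every position; −1 where the window has an N.

    Requires ``k <= 31`` so values fit in int64.
    """
    n = codes.shape[0]
    if n < k:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    h = windows.astype(np.int64) @ powers
    invalid = np.lib.stride_tricks.sliding_window_view(codes == 4, k).any(axis=1)
    h[invalid] = -1
    return h


class SeqIndex:
    """A sequence with its code array and a sorted k-word index."""

    __slots__ = ("seq", "codes", "k", "hashes", "sorted_hashes",
                 "sorted_positions")

    def __init__(self, seq: str, k: int):
        self.seq = seq
        self.codes = encode(seq)
        self.k = k
        h = kmer_hashes(self.codes, k)
        self.hashes = h
        valid = np.flatnonzero(h >= 0)
        hv = h[valid]
        order = np.argsort(hv, kind="stable")
        self.sorted_hashes = hv[order]
        self.sorted_positions = valid[order]

    def __len__(self) -> int:
        return len(self.seq)


def seed_matches(query_hashes: np.ndarray, target: SeqIndex):
    """All (query_pos, target_pos) pairs sharing an exact k-word.

    Returns two int64 arrays of equal length.
    """
    valid = np.flatnonzero(query_hashes >= 0)
    if valid.size == 0 or target.sorted_hashes.size == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    qh = query_hashes[valid]
    t_sorted = target.sorted_hashes
    lo = np.searchsorted(t_sorted, qh, "left")
    # only query words actually present need an upper bound
    present = (lo < t_sorted.size) & (t_sorted[np.minimum(lo,
                                                          t_sorted.size - 1)]
                                      == qh)
    if not present.any():
        return np.empty(0, np.int64), np.empty(0, np.int64)
    sel_idx = np.flatnonzero(present)
    lo = lo[sel_idx]
    hi = np.searchsorted(t_sorted, qh[sel_idx], "right")
    cnt = hi - lo
    sel = cnt > 0
    qpos, lo, cnt = valid[sel_idx][sel], lo[sel], cnt[sel]
    total = int(cnt.sum())
    out_q = np.repeat(qpos, cnt)
    starts = np.repeat(lo, cnt)
    offsets = np.arange(total, dtype=np.int64) - np.repeat(
        np.cumsum(cnt) - cnt, cnt
    )
    out_t = target.sorted_positions[starts + offsets]
    return out_q.astype(np.int64), out_t


def diagonal_match_profile(q_codes: np.ndarray, t_codes: np.ndarray, diag: int):
    """Match profile along diagonal ``diag`` (t_pos − q_pos).

    Returns ``(q_start, matches)`` where ``matches`` is a boolean array over
    the overlap of the two sequences on that diagonal.  N matches nothing.
    """
    m, n = q_codes.shape[0], t_codes.shape[0]
    q_start = max(0, -diag)
    q_end = min(m, n - diag)
    if q_end <= q_start:
        return q_start, np.empty(0, dtype=bool)
    a = q_codes[q_start:q_end]
    b = t_codes[q_start + diag : q_end + diag]
    return q_start, (a == b) & (a < 4)


def maximal_segments(matches: np.ndarray, match_score: int = 2,
                     mismatch_score: int = -8, min_anchor: int = 0):
    """Recursive maximal-scoring-segment decomposition of a match profile.

    Parameters
    ----------
    matches : boolean array
        True where the two sequences agree at that diagonal position.
    match_score, mismatch_score : int
        Per-column scores; defaults are the megablast-style +2/−8.
    min_anchor : int
        If positive, sub-ranges containing no exact match run of at least this
        many columns are skipped: no segment there could pass the exact-word
        anchoring requirement, and pruning them keeps the recursion linear on
        the long random stretches that flank genuine shared content.

    Returns
    -------
    list of (start, end, n_matches) tuples
        Half-open column intervals sorted by start.  Every returned segment
        starts and ends on a match.  Segments whose longest exact run is below
        ``min_anchor`` are omitted when ``min_anchor > 0``.
    """
    L = matches.shape[0]
    if L == 0 or not matches.any():
        return []
    if matches.all():
        if min_anchor > 0 and L < min_anchor:
            return []
        return [(0, L, L)]
    # fast path: isolated mismatches.  When every mismatch is single and
    # every match run is long enough that bridging strictly pays
    # (run · match_score > −mismatch_score), the whole profile is the unique
    # maximal segment — the typical case of a part copy with scattered
    # point mutations.
    min_run = (-mismatch_score) // match_score + 1
    mm = np.flatnonzero(~matches)
    if (mm[0] >= min_run and L - 1 - mm[-1] >= min_run
            and (mm.size == 1 or int(np.diff(mm).min()) >= min_run + 1)):
        longest = max(int(mm[0]), int(L - 1 - mm[-1]),
                      int(np.diff(mm).max()) - 1 if mm.size > 1 else 0)
        if min_anchor > 0 and longest < min_anchor:
            return []
        return [(0, L, L - int(mm.size))]
    m = matches.view(np.int8)
    boundaries = np.flatnonzero(np.diff(m)) + 1
    run_starts = np.concatenate(([0], boundaries))
    run_ends = np.concatenate((boundaries, [L]))
    run_is_match = matches[run_starts]
    run_lens = run_ends - run_starts
    scores = np.where(run_is_match, match_score * run_lens,
                      mismatch_score * run_lens).astype(np.int64)
    # prefix sums over runs: P[i] = sum of scores[:i]
    P = np.concatenate(([0], np.cumsum(scores)))
    match_run_lens = np.where(run_is_match, run_lens, 0)

    n_runs = len(scores)
    if n_runs <= 24:
        # plain scalar Kadane beats array machinery on short run lists
        scores_l = scores.tolist()
        starts_l = run_starts.tolist()
        ends_l = run_ends.tolist()
        is_match_l = run_is_match.tolist()
        mlen_l = match_run_lens.tolist()
        P_l = P.tolist()
        out = []
        stack = [(0, n_runs)]
        while stack:
            lo, hi = stack.pop()
            if lo >= hi:
                continue
            if min_anchor > 0 and max(mlen_l[lo:hi], default=0) < min_anchor:
                continue
            best = None
            min_p = P_l[lo]
            min_i = lo
            for j in range(lo, hi):
                if P_l[j] <= min_p:
                    min_p = P_l[j]
                    min_i = j
                if not is_match_l[j]:
                    continue
                s = P_l[j + 1] - min_p
                blen = ends_l[j] - starts_l[min_i]
                cand = (s, -blen, -starts_l[min_i])
                if best is None or cand > best[0]:
                    best = (cand, min_i, j)
            if best is None or best[0][0] <= 0:
                continue
            _, i, j = best
            if min_anchor <= 0 or max(mlen_l[i:j + 1]) >= min_anchor:
                n_match = sum(mlen_l[i:j + 1])
                out.append((starts_l[i], ends_l[j], n_match))
            stack.append((lo, i))
            stack.append((j + 1, hi))
        out.sort()
        return out

    out = []
    stack = [(0, len(scores))]
    while stack:
        lo, hi = stack.pop()
        if lo >= hi:
            continue
        if min_anchor > 0 and match_run_lens[lo:hi].max(initial=0) < min_anchor:
            continue
        # max-sum subarray over runs with tie-break (min base length, then
        # min start): for each end run j, the best start is the latest
        # minimum of the prefix sums (later start = same sum, shorter)
        Pi = P[lo:hi]
        m = np.minimum.accumulate(Pi)
        latest = np.maximum.accumulate(
            np.where(Pi == m, np.arange(lo, hi), -1)
        )
        jj = np.arange(lo, hi)
        valid = run_is_match[lo:hi]
        if not valid.any():
            continue
        S = P[lo + 1 : hi + 1] - m
        S = np.where(valid, S, np.int64(-(10 ** 18)))
        best_sum = S.max()
        if best_sum <= 0:
            continue
        at_max = S == best_sum
        base_len = run_ends[jj] - run_starts[latest]
        base_len = np.where(at_max, base_len, np.int64(10 ** 18))
        shortest = base_len.min()
        picks = np.flatnonzero((base_len == shortest))
        # among equal (sum, length): smallest start, i.e. smallest i run
        k = picks[np.argmin(run_starts[latest[picks]])]
        i, j = int(latest[k]), int(lo + k)
        if min_anchor <= 0 or match_run_lens[i : j + 1].max(initial=0) >= min_anchor:
            n_match = int(match_run_lens[i : j + 1].sum())
            out.append((int(run_starts[i]), int(run_ends[j]), n_match))
        stack.append((lo, i))
        stack.append((j + 1, hi))
    out.sort()
    return out


@lru_cache(maxsize=None)
def karlin_lambda(match_score: int = 2, mismatch_score: int = -8) -> float:
    """Positive root of 0.25·e^(λ·match) + 0.75·e^(λ·mismatch) = 1.

    Uniform base composition; solved by bisection to machine precision.
    """
    if match_score <= 0 or mismatch_score >= 0:
        raise ValueError("need match_score > 0 > mismatch_score")

    def f(lam: float) -> float:
        return (
            0.25 * math.exp(lam * match_score)
            + 0.75 * math.exp(lam * mismatch_score)
            - 1.0
        )

    lo, hi = 1e-12, 10.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


#: Tabulated ungapped K for the default (+2, −8) uniform-composition scheme.
_K_DEFAULT = 0.738


def karlin_k(match_score: int = 2, mismatch_score: int = -8) -> float:
    """Karlin–Altschul K.  Known for the default scheme; conservative (K=1)
    upper bound otherwise, which only tightens the E-value filter."""
    if (match_score, mismatch_score) == (2, -8):
        return _K_DEFAULT
    return 1.0


def evalue(score: float, m: int, n: int, match_score: int = 2,
           mismatch_score: int = -8) -> float:
    """Karlin–Altschul expect value of an ungapped score in an m×n search."""
    lam = karlin_lambda(match_score, mismatch_score)
    k = karlin_k(match_score, mismatch_score)
    # exp underflows harmlessly to 0 for any decent score
    return k * m * n * math.exp(-lam * score)


def revcomp(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


_RC_TABLE = str.maketrans("ACGTN", "TGCAN")
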