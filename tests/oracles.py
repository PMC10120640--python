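"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's seeded k-word index and linear-scan
decomposition: every diagonal of the comparison matrix is enumerated, and
the maximal-scoring-segment rule (repeatedly take the maximum-scoring
subarray, ties broken by shorter length then smaller start, recurse on the
flanks) is applied by exhaustive enumeration of run-bounded subarrays via an
outer difference matrix.  Feasible for sequences up to a few hundred bp.
"""

from __future__ import annotations

import math

import numpy as np

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def match_vector(a: str, b: str, diag: int):
    """Boolean agreement along one diagonal (b_pos - a_pos = diag)."""
    start = max(0, -diag)
    end = min(len(a), len(b) - diag)
    if end <= start:
        return start, []
    out = []
    for i in range(start, end):
        ca, cb = a[i], b[i + diag]
        out.append(ca == cb and ca in "ACGT")
    return start, out


def _runs(matches):
    runs = []
    i = 0
    while i < len(matches):
        j = i
        while j < len(matches) and matches[j] == matches[i]:
            j += 1
        runs.append((i, j, matches[i]))
        i = j
    return runs


def decompose(matches, match_score=2, mismatch_score=-8):
    """All maximal scoring segments of a match profile (brute force).

    Returns (start, end, n_matches) tuples sorted by start.
    """
    runs = _runs(list(matches))
    scores = np.array(
        [
            (match_score if is_match else mismatch_score) * (e - s)
            for s, e, is_match in runs
        ],
        dtype=np.int64,
    )
    starts = np.array([s for s, _e, _m in runs], dtype=np.int64)
    ends = np.array([e for _s, e, _m in runs], dtype=np.int64)
    is_match = np.array([m for _s, _e, m in runs], dtype=bool)
    P = np.concatenate(([0], np.cumsum(scores)))

    out = []

    def recurse(lo, hi):
        if lo >= hi:
            return
        cand = [r for r in range(lo, hi) if is_match[r]]
        if not cand:
            return
        best = None
        # exhaustive enumeration of run-bounded subarrays [i..j];
        # key = (score, shorter, smaller start)
        for i in cand:
            for j in cand:
                if j < i:
                    continue
                score = int(P[j + 1] - P[i])
                length = int(ends[j] - starts[i])
                key = (score, -length, -int(starts[i]))
                if best is None or key > best[0]:
                    best = (key, i, j)
        _key, i, j = best
        score = int(P[j + 1] - P[i])
        if score > 0:
            n_match = int(
                sum((ends[r] - starts[r]) for r in range(i, j + 1)
                    if is_match[r])
            )
            out.append((int(starts[i]), int(ends[j]), n_match))
            recurse(lo, i)
            recurse(j + 1, hi)

    recurse(0, len(runs))
    return sorted(out)


def _max_exact_run(matches) -> int:
    best = cur = 0
    for m in matches:
        cur = cur + 1 if m else 0
        best = max(best, cur)
    return best


def karlin_lambda(match_score=2, mismatch_score=-8) -> float:
    lo, hi = 1e-12, 10.0
    for _ in range(200):
        mid = (lo + hi) / 2
        v = 0.25 * math.exp(mid * match_score) + 0.75 * math.exp(
            mid * mismatch_score
        )
        if v > 1:
            hi = mid
        else:
            lo = mid
    return (lo + hi) / 2


def evalue(score, m, n, match_score=2, mismatch_score=-8) -> float:
    k = 0.738 if (match_score, mismatch_score) == (2, -8) else 1.0
    return k * m * n * math.exp(-karlin_lambda(match_score, mismatch_score)
                                * score)


def shared_segments(a: str, b: str, params) -> list:
    """Oracle for pair segment search.

    Returns tuples (interval_a, interval_b, strand, n_matches, length)
    after identity / E-value / word-anchor filters and cross-containment
    suppression, sorted like the implementation.
    """
    results = []
    for strand, bb in (("+", b), ("-", revcomp(b))):
        for diag in range(-(len(a) - 1), len(bb)):
            start, matches = match_vector(a, bb, diag)
            if not matches or _max_exact_run(matches) < params.word_size:
                continue
            for s, e, n_match in decompose(
                matches, params.match_reward, params.mismatch_penalty
            ):
                qs, qe = start + s, start + e
                length = qe - qs
                if length < params.word_size:
                    continue
                if _max_exact_run(matches[s:e]) < params.word_size:
                    continue
                if n_match / length < params.min_identity:
                    continue
                score = (params.match_reward * n_match
                         + params.mismatch_penalty * (length - n_match))
                if evalue(score, len(a), len(b), params.match_reward,
                          params.mismatch_penalty) > params.max_evalue:
                    continue
                ts, te = qs + diag, qe + diag
                iv_b = (len(b) - te, len(b) - ts) if strand == "-" else (ts, te)
                results.append(((qs, qe), iv_b, strand, n_match, length))
    kept = []
    for r in results:
        contained = False
        for t in results:
            if t is r or t[2] != r[2]:
                continue
            if (t[4] > r[4]
                    and t[0][0] <= r[0][0] and r[0][1] <= t[0][1]
                    and t[1][0] <= r[1][0] and r[1][1] <= t[1][1]):
                contained = True
                break
        if not contained:
            kept.append(r)
    kept.sort(key=lambda r: (r[0], r[1], r[2]))
    return kept


def contains_segment(query: str, target: str, params) -> bool:
    """Oracle for the near-full-length containment test of frequency queries."""
    L = len(query)
    for q in (query, revcomp(query)):
        for diag in range(-(len(q) - 1), len(target)):
            start, matches = match_vector(q, target, diag)
            if not matches or _max_exact_run(matches) < params.word_size:
                continue
            for s, e, n_match in decompose(
                matches, params.match_reward, params.mismatch_penalty
            ):
                length = e - s
                if length < params.word_size:
                    continue
                if _max_exact_run(matches[s:e]) < params.word_size:
                    continue
                if n_match / length < params.min_identity:
                    continue
                score = (params.match_reward * n_match
                         + params.mismatch_penalty * (length - n_match))
                if evalue(score, L, len(target), params.match_reward,
                          params.mismatch_penalty) > params.max_evalue:
                    continue
                if L - length <= params.max_length_diff_bp:
                    return True
    return False


def segment_frequency(query: str, corpus, params) -> int:
    return sum(
        1 for pl in corpus if contains_segment(query, pl.sequence, params)
    )


def ds_score(x, p: int):
    """Independent DS evaluation: numpy log, plain left-to-right summation."""
    if len(x) == 0:
        return float("-inf")
    terms = [float(np.log(p / xi)) for xi in x]
    extra = 0.0
    for t in terms[1:]:
        extra += t
    return terms[0] + extra / len(x)


def connected_components(nodes, edges) -> int:
    """Component count by transitive closure of the adjacency matrix."""
    nodes = list(nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    reach = np.eye(n, dtype=bool)
    for a, b in edges:
        reach[idx[a], idx[b]] = reach[idx[b], idx[a]] = True
    for k in range(n):
        reach |= reach[:, k][:, None] & reach[k, :][None, :]
    seen = set()
    count = 0
    for i in range(n):
        key = tuple(np.flatnonzero(reach[i]))
        if key not in seen:
            seen.add(key)
            count += 1
    return count
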