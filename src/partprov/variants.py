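"""Part annotation on plasmids and the variant-calling filters.

Canonical parts are located on each plasmid by anchored local alignment
(matches lacking any 12 bp exact stretch are undiscoverable, as for any
seeded search).  A match is kept when it covers at least 95 % of the
reference part length.  A kept match is called a *variant observation* unless

* it is 100 % identical to the canonical nucleotide sequence, or
* the part is protein-coding and the translation equals the canonical
  translation (silent changes only), or
* the part is protein-coding and the alignment does not reach the first or
  last reference base (3′ or 5′ deletion).

Coding matches whose aligned length is not a multiple of 3 (internal indels
breaking frame) are retained and flagged frameshifted rather than dropped.
Identical variant sequences of the same part are grouped corpus-wide.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from . import _scan
from ._scan import SeqIndex, revcomp
from .io import PartReference, Plasmid
from .segments import AlignmentParams

__all__ = [
    "PartMatch",
    "VariantObservation",
    "VariantGroup",
    "annotate_parts",
    "classify_variant",
    "group_variants",
]

#: Exact-stretch anchor for part annotation (smaller than the 28 bp segment
#: word so that heavily diverged part copies remain discoverable).
ANNOTATION_ANCHOR = 12

#: Diagonal drift tolerated when chaining sub-threshold segments into a
#: gapped candidate (maximum total indel length).
_MAX_CHAIN_INDEL = 30


@dataclass(frozen=True)
class PartMatch:
    """A local alignment of a canonical part onto a plasmid.

    ``plasmid_interval`` is 0-based half-open on the search sequence, which is
    the plasmid doubled when its topology is circular (origin-spanning
    matches run past the junction; ``start`` is always below the plasmid
    length).  ``matched_sequence`` is the plasmid subsequence in part
    orientation.
    """

    plasmid_id: str
    part_id: str
    plasmid_interval: tuple
    strand: str
    coverage_fraction: float
    nt_identity_fraction: float
    matched_sequence: str
    covers_ref_start: bool
    covers_ref_end: bool
    score: int = 0
    ref_interval: tuple = (0, 0)


@dataclass(frozen=True)
class VariantObservation:
    """One plasmid's observation of a non-canonical part sequence."""

    plasmid_id: str
    lab: str
    part_id: str
    variant_sequence: str
    frameshifted: bool = False


@dataclass(frozen=True)
class VariantGroup:
    """All observations of one exact (part, variant sequence) combination."""

    variant_id: str
    part_id: str
    variant_sequence: str
    observations: tuple

    @property
    def n_observations(self) -> int:
        return len(self.observations)

    @property
    def n_labs(self) -> int:
        return len({o.lab for o in self.observations})

    @property
    def labs(self):
        return sorted({o.lab for o in self.observations})

    @property
    def plasmid_ids(self):
        return sorted({o.plasmid_id for o in self.observations})


def variant_id_for(part_id: str, variant_sequence: str) -> str:
    """Stable content hash identifying a (part, variant sequence) pair."""
    digest = hashlib.sha256(
        f"{part_id}|{variant_sequence}".encode("ascii")
    ).hexdigest()
    return digest[:12]


def _circular_overlap(iv1, iv2, modulus):
    """Do two half-open intervals on a doubled circular sequence overlap
    when projected onto the circle?"""
    (a1, b1), (a2, b2) = iv1, iv2
    for shift in (-modulus, 0, modulus):
        if a1 < b2 + shift and a2 + shift < b1:
            return True
    return False


def annotate_parts(plasmid: Plasmid, parts, min_coverage: float = 0.95,
                   params: AlignmentParams = None):
    """All maximal part matches on a plasmid with coverage ≥ ``min_coverage``.

    Both strands are searched; circular plasmids are searched on their
    doubled sequence with origin-equivalent matches deduplicated.
    Overlapping matches of the same part report only the best-scoring one.
    Matches of different parts are reported independently.
    """
    parts = list(parts)
    if not parts:
        raise ValueError("annotate_parts requires a non-empty part database")
    if params is None:
        params = AlignmentParams()

    L0 = len(plasmid.sequence)
    circular = plasmid.topology == "circular"
    search_seq = plasmid.sequence * 2 if circular else plasmid.sequence
    target = SeqIndex(search_seq, ANNOTATION_ANCHOR)

    matches = []
    for part in parts:
        candidates = []
        for strand in ("+", "-"):
            oriented = part.sequence if strand == "+" else revcomp(part.sequence)
            candidates.extend(
                _strand_candidates(
                    oriented, strand, part, target, search_seq,
                    min_coverage, params,
                )
            )
        # drop duplicates from the doubled sequence: every match starting in
        # the second copy has an equivalent starting in the first
        if circular:
            candidates = [c for c in candidates
                          if c.plasmid_interval[0] < L0]
        # best-scoring match wins among overlapping matches of this part
        candidates.sort(
            key=lambda c: (-c.score, c.plasmid_interval, c.strand)
        )
        kept = []
        for c in candidates:
            clash = any(
                _circular_overlap(c.plasmid_interval, k.plasmid_interval,
                                  L0 if circular else 10 ** 12)
                for k in kept
            )
            if not clash:
                kept.append(c)
        matches.extend(kept)

    matches.sort(key=lambda c: (c.part_id, c.plasmid_interval, c.strand))
    return [
        PartMatch(
            plasmid_id=plasmid.id,
            part_id=c.part_id,
            plasmid_interval=c.plasmid_interval,
            strand=c.strand,
            coverage_fraction=c.coverage_fraction,
            nt_identity_fraction=c.nt_identity_fraction,
            matched_sequence=c.matched_sequence,
            covers_ref_start=c.covers_ref_start,
            covers_ref_end=c.covers_ref_end,
            score=c.score,
            ref_interval=c.ref_interval,
        )
        for c in matches
    ]


@dataclass(frozen=True)
class _Candidate:
    part_id: str
    plasmid_interval: tuple
    strand: str
    coverage_fraction: float
    nt_identity_fraction: float
    matched_sequence: str
    covers_ref_start: bool
    covers_ref_end: bool
    score: int
    ref_interval: tuple


def _to_part_coords(qs, qe, strand, part_len):
    """Map query-orientation interval to reference part coordinates."""
    if strand == "+":
        return qs, qe
    return part_len - qe, part_len - qs


def _strand_candidates(oriented, strand, part, target, search_seq,
                       min_coverage, params):
    """Qualifying candidates of one part orientation on the search sequence."""
    Lp = len(part.sequence)
    q_idx = SeqIndex(oriented, ANNOTATION_ANCHOR)
    qpos, tpos = _scan.seed_matches(q_idx.hashes, target)
    if qpos.size == 0:
        return []

    ungapped = []   # qualifying single-diagonal candidates
    partial = []    # sub-threshold segments kept for gapped chaining
    for diag in np.unique(tpos - qpos):
        diag = int(diag)
        q_start, profile = _scan.diagonal_match_profile(
            q_idx.codes, target.codes, diag
        )
        for s, e, n_match in _scan.maximal_segments(
            profile, params.match_reward, params.mismatch_penalty,
            min_anchor=ANNOTATION_ANCHOR,
        ):
            qs, qe = q_start + s, q_start + e
            span = qe - qs
            coverage = span / Lp
            entry = (diag, qs, qe, n_match)
            if coverage >= min_coverage:
                ungapped.append(entry)
            elif coverage >= 0.2:
                partial.append(entry)

    out = []
    for diag, qs, qe, n_match in ungapped:
        ts, te = qs + diag, qe + diag
        rs, re = _to_part_coords(qs, qe, strand, Lp)
        span = qe - qs
        seg = search_seq[ts:te]
        out.append(
            _Candidate(
                part_id=part.part_id,
                plasmid_interval=(ts, te),
                strand=strand,
                coverage_fraction=span / Lp,
                nt_identity_fraction=n_match / span,
                matched_sequence=seg if strand == "+" else revcomp(seg),
                covers_ref_start=rs == 0,
                covers_ref_end=re == Lp,
                score=params.match_reward * n_match
                + params.mismatch_penalty * (span - n_match),
                ref_interval=(rs, re),
            )
        )

    # gapped rescue: chain nearby-diagonal partial segments and refine by
    # affine-gap DP over the spanned window
    if partial and not ungapped:
        out.extend(
            _gapped_candidates(partial, oriented, strand, part, search_seq,
                               min_coverage, params)
        )
    return out


def _gapped_candidates(partial, oriented, strand, part, search_seq,
                       min_coverage, params):
    Lp = len(part.sequence)
    partial = sorted(partial)
    groups = []
    for entry in partial:
        placed = False
        for g in groups:
            if abs(entry[0] - g[-1][0]) <= _MAX_CHAIN_INDEL:
                g.append(entry)
                placed = True
                break
        if not placed:
            groups.append([entry])

    out = []
    for g in groups:
        covered = set()
        for _d, qs, qe, _m in g:
            covered.update(range(qs, qe))
        if len(covered) / Lp < min_coverage * 0.9:
            continue
        t_lo = max(0, min(qs + d for d, qs, _qe, _m in g) - 20)
        t_hi = min(len(search_seq), max(qe + d for d, _qs, qe, _m in g) + 20)
        aln = _affine_local(oriented, search_seq[t_lo:t_hi], params)
        if aln is None:
            continue
        qs, qe, ts, te, n_match, n_cols = aln
        span_q = qe - qs
        if span_q / Lp < min_coverage:
            continue
        ts, te = ts + t_lo, te + t_lo
        rs, re = _to_part_coords(qs, qe, strand, Lp)
        seg = search_seq[ts:te]
        out.append(
            _Candidate(
                part_id=part.part_id,
                plasmid_interval=(ts, te),
                strand=strand,
                coverage_fraction=span_q / Lp,
                nt_identity_fraction=n_match / n_cols,
                matched_sequence=seg if strand == "+" else revcomp(seg),
                covers_ref_start=rs == 0,
                covers_ref_end=re == Lp,
                score=_affine_score(n_match, n_cols, span_q, te - ts, params),
                ref_interval=(rs, re),
            )
        )
    return out


def _affine_score(n_match, n_cols, span_q, span_t, params):
    n_gap_cols = n_cols - min(span_q, span_t)  # columns that are gaps
    n_mismatch = n_cols - n_match - n_gap_cols
    # gap-open count is not tracked; score is only used for ranking overlaps
    return (
        params.match_reward * n_match
        + params.mismatch_penalty * n_mismatch
        - (params.gap_open + params.gap_extend) * n_gap_cols
    )


def _affine_local(query: str, window: str, params: AlignmentParams):
    """Best local alignment of query vs window under affine gap costs.

    Gotoh dynamic programme; a gap of length L costs open + extend·L.
    Returns (q_start, q_end, t_start, t_end, matches, aligned_columns) or
    None when nothing scores above zero.
    """
    q = _scan.encode(query)
    t = _scan.encode(window)
    m, n = len(q), len(t)
    go, ge = params.gap_open, params.gap_extend
    first_gap = go + ge
    NEG = np.int32(-(10 ** 9))

    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    jidx = np.arange(n, dtype=np.int64)
    for i in range(1, m + 1):
        sub = np.where((t == q[i - 1]) & (t < 4) & (q[i - 1] < 4),
                       params.match_reward, params.mismatch_penalty)
        E[i, 1:] = np.maximum(H[i - 1, 1:] - first_gap, E[i - 1, 1:] - ge)
        H0 = np.maximum.reduce(
            [np.zeros(n, dtype=np.int64),
             H[i - 1, :-1].astype(np.int64) + sub,
             E[i, 1:].astype(np.int64)]
        )
        # horizontal affine gaps via prefix-max scan
        A = H0 + ge * jidx
        cm = np.maximum.accumulate(A)
        F = np.full(n, NEG, dtype=np.int64)
        if n > 1:
            F[1:] = cm[:-1] - go - ge * (jidx[1:] + 0)
            F[1:] = cm[:-1] - go - ge * jidx[1:]
        H[i, 1:] = np.maximum(H0, np.maximum(F, 0)).astype(np.int32)

    best_flat = int(np.argmax(H))
    bi, bj = divmod(best_flat, n + 1)
    if H[bi, bj] <= 0:
        return None

    # traceback; F rows are recomputed on demand from the stored H rows
    f_cache = {}

    def f_row(i):
        row = f_cache.get(i)
        if row is None:
            row = np.full(n + 1, NEG, dtype=np.int64)
            for j in range(1, n + 1):
                row[j] = max(H[i, j - 1] - first_gap, row[j - 1] - ge)
            f_cache[i] = row
        return row

    i, j = bi, bj
    n_match = 0
    n_cols = 0
    state = "H"
    while True:
        if state == "H":
            h = int(H[i, j])
            if h == 0:
                break
            sub = (params.match_reward
                   if (query[i - 1] == window[j - 1] and query[i - 1] in "ACGT")
                   else params.mismatch_penalty)
            if i > 0 and j > 0 and h == int(H[i - 1, j - 1]) + sub:
                n_cols += 1
                if sub == params.match_reward:
                    n_match += 1
                i, j = i - 1, j - 1
            elif h == int(E[i, j]):
                state = "E"
            else:
                state = "F"
        elif state == "E":
            e = int(E[i, j])
            n_cols += 1
            if e == int(E[i - 1, j]) - ge:
                i -= 1
            else:
                i -= 1
                state = "H"
        else:  # F
            row = f_row(i)
            f = int(row[j])
            n_cols += 1
            if f == int(row[j - 1]) - ge:
                j -= 1
            else:
                j -= 1
                state = "H"
    return i, bi, j, bj, n_match, n_cols


def translate_cds(seq: str) -> str:
    """Translate in frame 0, truncating any trailing partial codon."""
    usable = len(seq) - len(seq) % 3
    return str(Seq(seq[:usable]).translate())


def classify_variant(match: PartMatch, part: PartReference, lab: str = ""):
    """Apply the variant filters to a part match.

    Returns a :class:`VariantObservation`, or None when the match is the
    canonical sequence (nucleotide level; amino-acid level for coding parts)
    or a terminally deleted coding sequence.
    """
    if match.part_id != part.part_id:
        raise ValueError("match was not produced against this part")
    if match.matched_sequence == part.sequence:
        return None
    if part.is_coding:
        if not (match.covers_ref_start and match.covers_ref_end):
            return None
        # frame anchored at the aligned reference start
        offset = (3 - match.ref_interval[0] % 3) % 3
        in_frame = match.matched_sequence[offset:]
        frameshifted = len(in_frame) % 3 != 0
        if not frameshifted:
            canonical = part.sequence[match.ref_interval[0] + offset:]
            if translate_cds(in_frame) == translate_cds(canonical):
                return None
        return VariantObservation(
            plasmid_id=match.plasmid_id,
            lab=lab,
            part_id=part.part_id,
            variant_sequence=match.matched_sequence,
            frameshifted=frameshifted,
        )
    return VariantObservation(
        plasmid_id=match.plasmid_id,
        lab=lab,
        part_id=part.part_id,
        variant_sequence=match.matched_sequence,
    )


def group_variants(observations):
    """Group observations by exact (part_id, variant_sequence).

    Returns a list of :class:`VariantGroup` sorted by (part_id, variant_id);
    group ids are stable content hashes.
    """
    buckets = {}
    for obs in observations:
        buckets.setdefault((obs.part_id, obs.variant_sequence), []).append(obs)
    groups = []
    for (part_id, seq), obs_list in buckets.items():
        obs_list.sort(key=lambda o: (o.plasmid_id, o.lab))
        groups.append(
            VariantGroup(
                variant_id=variant_id_for(part_id, seq),
                part_id=part_id,
                variant_sequence=seq,
                observations=tuple(obs_list),
            )
        )
    groups.sort(key=lambda g: (g.part_id, g.variant_id))
    return groups
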