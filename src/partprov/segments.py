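"""Shared-segment discovery between plasmid pairs and corpus frequency queries.

A *shared segment* is a contiguous near-identical local alignment between two
plasmids.  A reported segment must:

* score maximally under the +2/−8 scheme (see :mod:`partprov._scan`),
* contain at least one exact run of ``word_size`` (28) bases — the seed size
  below which the original seeded search cannot discover a match,
* be at least ``word_size`` long,
* have ≥98 % nucleotide identity,
* have Karlin–Altschul E ≤ 1e−5,
* have an aligned-span length difference of at most 10 bp between the two
  plasmids (identically 0 for the gap-free matches this scoring scheme
  reports).

Each segment's *corpus frequency* is the number of plasmids in the whole
corpus containing a qualifying match to the segment sequence on either
strand; for these containment queries the length-difference filter is applied
as |segment length − aligned span| ≤ 10 bp, i.e. the match must cover nearly
the whole segment.  The ascending vector of frequencies over a pair's
segments is the input of the Design Similarity score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _scan
from ._scan import SeqIndex, revcomp
from .io import Plasmid, PlasmidCorpus

__all__ = [
    "AlignmentParams",
    "SharedSegment",
    "SharedSegmentSet",
    "CorpusIndex",
    "find_shared_segments",
    "segment_frequency",
    "build_segment_set",
]


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring scheme and match filters for segment search.

    Defaults are the megablast-style parameters chosen to maximise reporting
    of contiguous segments with few point mutations: reward +2, mismatch −8,
    gap open 4, gap extend 6, word size 28; matches must have ≥98 % identity,
    E ≤ 1e−5 and a length difference of at most 10 bp.
    """

    match_reward: int = 2
    mismatch_penalty: int = -8
    gap_open: int = 4
    gap_extend: int = 6
    word_size: int = 28
    min_identity: float = 0.98
    max_evalue: float = 1e-5
    max_length_diff_bp: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.min_identity <= 1):
            raise ValueError("min_identity must be in (0, 1]")
        if self.word_size < 1:
            raise ValueError("word_size must be >= 1")
        if self.max_length_diff_bp < 0:
            raise ValueError("max_length_diff_bp must be >= 0")
        if self.match_reward <= 0 or self.mismatch_penalty >= 0:
            raise ValueError("need match_reward > 0 > mismatch_penalty")


@dataclass(frozen=True)
class SharedSegment:
    """One qualifying local match between a plasmid pair.

    ``sequence`` is the segment as found on the first plasmid;
    ``interval_a``/``interval_b`` are 0-based half-open coordinates on each
    plasmid (``interval_b`` always on the forward strand of plasmid b);
    ``strand_b`` is '-' when the match is to the reverse complement of b.
    """

    sequence: str
    interval_a: tuple
    interval_b: tuple
    strand_b: str
    identity_fraction: float
    length_bp: int
    evalue: float

    def __len__(self) -> int:
        return self.length_bp


@dataclass
class SharedSegmentSet:
    """All shared segments of a plasmid pair plus their corpus frequencies.

    ``x`` is the ascending vector of per-segment corpus frequencies; every
    entry is at least 2 because both source plasmids contain the segment.
    """

    plasmid_a: str
    plasmid_b: str
    segments: list
    x: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.x)


class CorpusIndex:
    """Per-corpus k-word indexes, frequency cache and candidate prefilter.

    Shared across pair queries so that a segment sequence seen from several
    pairs is counted against the corpus only once (observable through
    ``frequency_queries``).
    """

    def __init__(self, corpus: PlasmidCorpus, params: AlignmentParams):
        self.corpus = corpus
        self.params = params
        self._fwd = {}
        self._rc = {}
        self._freq_cache = {}
        #: number of frequency computations actually performed (cache misses)
        self.frequency_queries = 0
        self._kmer_plasmids = None
        self._positional = None

    def fwd(self, plasmid: Plasmid) -> SeqIndex:
        idx = self._fwd.get(plasmid.id)
        if idx is None:
            idx = SeqIndex(plasmid.sequence, self.params.word_size)
            self._fwd[plasmid.id] = idx
        return idx

    def rc(self, plasmid: Plasmid) -> SeqIndex:
        idx = self._rc.get(plasmid.id)
        if idx is None:
            idx = SeqIndex(revcomp(plasmid.sequence), self.params.word_size)
            self._rc[plasmid.id] = idx
        return idx

    def _candidate_map(self):
        """Lazy corpus-wide map: k-word hash → sorted array of plasmid ordinals."""
        if self._kmer_plasmids is None:
            hashes = []
            owners = []
            for ordinal, pl in enumerate(self.corpus):
                h = np.unique(self.fwd(pl).sorted_hashes)
                hashes.append(h)
                owners.append(np.full(h.shape, ordinal, dtype=np.int32))
            all_h = np.concatenate(hashes)
            all_o = np.concatenate(owners)
            order = np.argsort(all_h, kind="stable")
            self._kmer_plasmids = (all_h[order], all_o[order])
        return self._kmer_plasmids

    def _positional_index(self):
        """Corpus-wide positional k-word index: sorted hashes with parallel
        (plasmid ordinal, position) arrays — one lookup finds every seed of a
        query across the whole corpus."""
        if self._positional is None:
            hashes, owners, positions = [], [], []
            for ordinal, pl in enumerate(self.corpus):
                idx = self.fwd(pl)
                hashes.append(idx.sorted_hashes)
                positions.append(idx.sorted_positions)
                owners.append(np.full(idx.sorted_hashes.shape, ordinal,
                                      dtype=np.int32))
            all_h = np.concatenate(hashes)
            all_o = np.concatenate(owners)
            all_p = np.concatenate(positions)
            order = np.argsort(all_h, kind="stable")
            self._positional = (all_h[order], all_o[order], all_p[order])
        return self._positional

    def seed_hits(self, query_hashes: np.ndarray):
        """(query_pos, plasmid_ordinal, target_pos) for every corpus seed."""
        g_hash, g_owner, g_pos = self._positional_index()
        valid = np.flatnonzero(query_hashes >= 0)
        if valid.size == 0 or g_hash.size == 0:
            empty = np.empty(0, np.int64)
            return empty, empty, empty
        qh = query_hashes[valid]
        lo = np.searchsorted(g_hash, qh, "left")
        hi = np.searchsorted(g_hash, qh, "right")
        cnt = hi - lo
        sel = cnt > 0
        if not sel.any():
            empty = np.empty(0, np.int64)
            return empty, empty, empty
        qpos, lo, cnt = valid[sel], lo[sel], cnt[sel]
        total = int(cnt.sum())
        out_q = np.repeat(qpos, cnt)
        starts = np.repeat(lo, cnt)
        offsets = np.arange(total, dtype=np.int64) - np.repeat(
            np.cumsum(cnt) - cnt, cnt
        )
        flat = starts + offsets
        return out_q.astype(np.int64), g_owner[flat].astype(np.int64), \
            g_pos[flat].astype(np.int64)

    def candidates(self, query_hashes: np.ndarray) -> np.ndarray:
        """Ordinals of plasmids sharing at least one k-word with the query."""
        h_sorted, owners = self._candidate_map()
        qh = np.unique(query_hashes[query_hashes >= 0])
        if qh.size == 0:
            return np.empty(0, dtype=np.int32)
        lo = np.searchsorted(h_sorted, qh, "left")
        hi = np.searchsorted(h_sorted, qh, "right")
        picks = [owners[a:b] for a, b in zip(lo, hi) if b > a]
        if not picks:
            return np.empty(0, dtype=np.int32)
        return np.unique(np.concatenate(picks))


def _scan_strand(q_idx: SeqIndex, t_idx: SeqIndex, params: AlignmentParams):
    """Qualifying maximal segments of q vs t on t's stored orientation.

    Yields (q_start, q_end, n_matches) in q/t-orientation coordinates; the
    t interval on this orientation is the same span shifted by the diagonal.
    """
    qpos, tpos = _scan.seed_matches(q_idx.hashes, t_idx)
    if qpos.size == 0:
        return
    m, n = len(q_idx), len(t_idx)
    for diag in np.unique(tpos - qpos):
        diag = int(diag)
        q_start, matches = _scan.diagonal_match_profile(
            q_idx.codes, t_idx.codes, diag
        )
        for s, e, n_match in _scan.maximal_segments(
            matches,
            params.match_reward,
            params.mismatch_penalty,
            min_anchor=params.word_size,
        ):
            length = e - s
            if length < params.word_size:
                continue
            identity = n_match / length
            if identity < params.min_identity:
                continue
            score = (
                params.match_reward * n_match
                + params.mismatch_penalty * (length - n_match)
            )
            ev = _scan.evalue(
                score, m, n, params.match_reward, params.mismatch_penalty
            )
            if ev > params.max_evalue:
                continue
            yield (q_start + s, q_start + e, diag, n_match, identity, ev)


def find_shared_segments(a: Plasmid, b: Plasmid, params: AlignmentParams = None,
                         index: CorpusIndex = None):
    """All qualifying shared segments between two distinct plasmids.

    Returns a deterministically ordered list of :class:`SharedSegment`;
    segments wholly contained within a longer returned segment (on both
    plasmids, same strand) are suppressed to avoid double counting.
    """
    if a.id == b.id:
        raise ValueError("find_shared_segments requires two distinct plasmids")
    if params is None:
        params = AlignmentParams()
    if index is not None:
        a_idx = index.fwd(a)
        targets = (("+", index.fwd(b)), ("-", index.rc(b)))
    else:
        a_idx = SeqIndex(a.sequence, params.word_size)
        targets = (
            ("+", SeqIndex(b.sequence, params.word_size)),
            ("-", SeqIndex(revcomp(b.sequence), params.word_size)),
        )

    nb = len(b.sequence)
    raw = []
    for strand, t_idx in targets:
        for qs, qe, diag, n_match, identity, ev in _scan_strand(
            a_idx, t_idx, params
        ):
            ts, te = qs + diag, qe + diag
            if strand == "-":
                interval_b = (nb - te, nb - ts)
            else:
                interval_b = (ts, te)
            # gap-free: aligned spans are equal, length difference 0
            raw.append(
                SharedSegment(
                    sequence=a.sequence[qs:qe],
                    interval_a=(qs, qe),
                    interval_b=interval_b,
                    strand_b=strand,
                    identity_fraction=identity,
                    length_bp=qe - qs,
                    evalue=ev,
                )
            )
    kept = _suppress_contained(raw)
    kept.sort(key=lambda s: (s.interval_a, s.interval_b, s.strand_b))
    return kept


def _suppress_contained(segments):
    """Drop segments strictly contained in a longer one on the same strand."""
    kept = []
    for s in segments:
        contained = False
        for t in segments:
            if t is s or t.strand_b != s.strand_b:
                continue
            if (
                t.length_bp > s.length_bp
                and t.interval_a[0] <= s.interval_a[0]
                and s.interval_a[1] <= t.interval_a[1]
                and t.interval_b[0] <= s.interval_b[0]
                and s.interval_b[1] <= t.interval_b[1]
            ):
                contained = True
                break
        if not contained:
            kept.append(s)
    return kept


def _contains_query(query: str, target_idx: SeqIndex,
                    params: AlignmentParams) -> bool:
    """Does the target contain a qualifying near-full-length match to query?"""
    L = len(query)
    n = len(target_idx)
    for oriented in (query, revcomp(query)):
        q_idx = SeqIndex(oriented, params.word_size)
        for qs, qe, _diag, n_match, identity, ev in _scan_strand(
            q_idx, target_idx, params
        ):
            if L - (qe - qs) <= params.max_length_diff_bp:
                return True
    return False


def segment_frequency(segment: SharedSegment, corpus: PlasmidCorpus,
                      params: AlignmentParams = None,
                      index: CorpusIndex = None) -> int:
    """Number of corpus plasmids containing the segment (either strand).

    A plasmid counts once however many times it contains the segment.  For a
    segment produced from two corpus plasmids the result is at least 2.
    """
    if params is None:
        params = AlignmentParams()
    seq = getattr(segment, "sequence", None) or str(segment)
    if index is not None:
        return index_frequency(seq, index)
    count = 0
    for pl in corpus:
        t_idx = SeqIndex(pl.sequence, params.word_size)
        if _contains_query(seq, t_idx, params):
            count += 1
    return count


def index_frequency(seq: str, index: CorpusIndex) -> int:
    """Cached corpus frequency of a segment sequence via the global index."""
    rc = revcomp(seq)
    key = min(seq, rc)
    cached = index._freq_cache.get(key)
    if cached is not None:
        return cached
    index.frequency_queries += 1
    params = index.params
    L = len(seq)
    hit_plasmids = set()
    for oriented in (seq, rc):
        q_codes = _scan.encode(oriented)
        q_hashes = _scan.kmer_hashes(q_codes, params.word_size)
        qpos, owner, tpos = index.seed_hits(q_hashes)
        if qpos.size == 0:
            continue
        diag = tpos - qpos
        # deduplicate (plasmid, diagonal) seed groups, then evaluate each
        # diagonal profile once; packed into one int64 key for speed
        offset = np.int64(1) << 24
        packed = np.unique(owner * (offset << 1) + (diag + offset))
        for packed_key in packed:
            ordinal = int(packed_key // (offset << 1))
            d = int(packed_key % (offset << 1)) - int(offset)
            if ordinal in hit_plasmids:
                continue
            t_idx = index.fwd(index.corpus.plasmids[ordinal])
            q_start, profile = _scan.diagonal_match_profile(
                q_codes, t_idx.codes, int(d)
            )
            if profile.shape[0] < L - params.max_length_diff_bp:
                continue
            for s, e, n_match in _scan.maximal_segments(
                profile, params.match_reward, params.mismatch_penalty,
                min_anchor=params.word_size,
            ):
                length = e - s
                if L - length > params.max_length_diff_bp:
                    continue
                if length < params.word_size:
                    continue
                if n_match / length < params.min_identity:
                    continue
                score = (params.match_reward * n_match
                         + params.mismatch_penalty * (length - n_match))
                ev = _scan.evalue(score, L, len(t_idx),
                                  params.match_reward,
                                  params.mismatch_penalty)
                if ev > params.max_evalue:
                    continue
                hit_plasmids.add(ordinal)
                break
    count = len(hit_plasmids)
    index._freq_cache[key] = count
    return count


def build_segment_set(a: Plasmid, b: Plasmid, corpus: PlasmidCorpus,
                      params: AlignmentParams = None,
                      index: CorpusIndex = None) -> SharedSegmentSet:
    """Shared segments of (a, b) with ascending corpus frequencies.

    Passing a shared :class:`CorpusIndex` caches per-segment-sequence
    frequencies across pairs within one run.
    """
    if params is None:
        params = AlignmentParams()
    if index is None:
        index = CorpusIndex(corpus, params)
    segments = find_shared_segments(a, b, params, index)
    x = sorted(index_frequency(s.sequence, index) for s in segments)
    return SharedSegmentSet(plasmid_a=a.id, plasmid_b=b.id,
                            segments=segments, x=x)
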