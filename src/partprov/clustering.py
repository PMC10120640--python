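"""Relatedness cutoff calibration and authorship-cluster counting.

The DS cutoff for calling two plasmids related is calibrated empirically:
sample random plasmid pairs whose depositing labs differ (pairs unlikely to
share construction history), score them, and take the DS value at the
nearest-rank 95th percentile — i.e. accept a 5 % false-positive rate on the
cross-lab null.  DS matrices of variant groups are then binarised at the
cutoff and the connected components of the resulting graph are counted; each
component is interpreted as one independent origin of the variant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import PlasmidCorpus
from .segments import AlignmentParams, CorpusIndex, build_segment_set
from .similarity import NO_EVIDENCE, ds_score

__all__ = [
    "NullCalibration",
    "AuthorshipClusters",
    "cross_lab_pairs",
    "sample_cross_lab_pairs",
    "score_pairs",
    "nearest_rank_quantile",
    "calibrate_cutoff",
    "build_graph",
    "count_components",
]


@dataclass
class NullCalibration:
    """A calibrated DS relatedness cutoff and the null sample behind it."""

    n_pairs: int
    fp_rate: float
    seed: int
    cutoff: float
    null_scores: np.ndarray
    pairs: list = field(default_factory=list)

    def write_tsv(self, path: str) -> None:
        """Audit dump of the null distribution (plasmid_a, plasmid_b, ds)."""
        with open(path, "w") as fh:
            fh.write("plasmid_a\tplasmid_b\tds\n")
            for (a, b), s in zip(self.pairs, self.null_scores):
                fh.write(f"{a}\t{b}\t{s!r}\n")


@dataclass(frozen=True)
class AuthorshipClusters:
    """Connected-component assignment of a variant group's plasmids."""

    variant_id: str
    component_assignment: dict
    n_components: int


def cross_lab_pairs(corpus: PlasmidCorpus) -> np.ndarray:
    """Ordinal index pairs (i, j), i < j, of plasmids from different labs."""
    labs = pd.factorize(pd.Series([pl.lab for pl in corpus]))[0]
    ii, jj = np.triu_indices(corpus.p, k=1)
    keep = labs[ii] != labs[jj]
    return np.stack([ii[keep], jj[keep]], axis=1)


def sample_cross_lab_pairs(corpus: PlasmidCorpus, n_pairs: int,
                           seed: int) -> np.ndarray:
    """Uniform seeded sample of distinct cross-lab pairs.

    When fewer than ``n_pairs`` cross-lab pairs exist, all of them are
    returned (in deterministic order).
    """
    pairs = cross_lab_pairs(corpus)
    if pairs.shape[0] == 0:
        raise ValueError(
            "corpus has a single depositing lab; cross-lab null calibration "
            "is impossible"
        )
    if pairs.shape[0] <= n_pairs:
        return pairs
    rng = np.random.default_rng(seed)
    pick = rng.choice(pairs.shape[0], size=n_pairs, replace=False)
    pick.sort()
    return pairs[pick]


def score_pairs(corpus: PlasmidCorpus, pairs: np.ndarray,
                params: AlignmentParams, index: CorpusIndex = None,
                heuristic: str = "log"):
    """DS scores for an array of ordinal plasmid pairs (shared-index cached)."""
    if index is None:
        index = CorpusIndex(corpus, params)
    scores = np.empty(pairs.shape[0], dtype=float)
    id_pairs = []
    for k, (i, j) in enumerate(pairs):
        a = corpus.plasmids[int(i)]
        b = corpus.plasmids[int(j)]
        seg_set = build_segment_set(a, b, corpus, params, index)
        scores[k] = ds_score(seg_set.x, corpus.p, heuristic)
        id_pairs.append((a.id, b.id))
    return scores, id_pairs


def nearest_rank_quantile(scores: np.ndarray, q: float) -> float:
    """Nearest-rank (ceiling) quantile of a sample; sentinels sort lowest."""
    s = np.sort(np.asarray(scores, dtype=float))
    n = s.shape[0]
    if n == 0:
        raise ValueError("cannot take a quantile of an empty sample")
    rank = max(1, math.ceil(q * n))
    return float(s[rank - 1])


def calibrate_cutoff(corpus: PlasmidCorpus, params: AlignmentParams = None,
                     n_pairs: int = 100_000, fp_rate: float = 0.05,
                     seed: int = 0, index: CorpusIndex = None,
                     heuristic: str = "log") -> NullCalibration:
    """Calibrate the DS relatedness cutoff from a cross-lab null sample.

    The cutoff is the nearest-rank (1 − fp_rate) quantile of the sampled DS
    scores; pairs with no shared segment enter the sample as the no-evidence
    sentinel (they are definitionally unrelated and sort below every finite
    score).  Reproducible for a fixed corpus and seed.
    """
    if params is None:
        params = AlignmentParams()
    pairs = sample_cross_lab_pairs(corpus, n_pairs, seed)
    scores, id_pairs = score_pairs(corpus, pairs, params, index, heuristic)
    cutoff = nearest_rank_quantile(scores, 1.0 - fp_rate)
    return NullCalibration(
        n_pairs=n_pairs,
        fp_rate=fp_rate,
        seed=seed,
        cutoff=cutoff,
        null_scores=scores,
        pairs=id_pairs,
    )


def build_graph(matrix: pd.DataFrame, cutoff: float) -> nx.Graph:
    """Binarise a DS matrix: undirected edge wherever DS >= cutoff.

    A score exactly at the cutoff forms an edge; the no-evidence sentinel
    never does, whatever the cutoff.
    """
    g = nx.Graph()
    ids = list(matrix.index)
    g.add_nodes_from(ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            s = matrix.loc[a, b]
            if s != NO_EVIDENCE and not np.isnan(s) and s >= cutoff:
                g.add_edge(a, b)
    return g


def count_components(graph: nx.Graph, variant_id: str = "") -> AuthorshipClusters:
    """Connected components of the binarised relatedness graph.

    Component indices are assigned deterministically in order of each
    component's smallest node id.
    """
    comps = sorted(nx.connected_components(graph), key=lambda c: min(c))
    assignment = {}
    for idx, comp in enumerate(comps):
        for node in comp:
            assignment[node] = idx
    return AuthorshipClusters(
        variant_id=variant_id,
        component_assignment=assignment,
        n_components=len(comps),
    )
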