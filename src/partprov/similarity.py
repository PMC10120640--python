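"""The Design Similarity (DS) score of a plasmid pair.

DS is an inverse-document-frequency style measure of how unusual the shared
content of two plasmids is within a corpus of ``p`` plasmids.  With ``x`` the
ascending vector of corpus frequencies of the pair's ``n`` shared segments,

    DS = ln(p / x1) + (1/n) * sum_{i=2..n} ln(p / xi)

The left term is the IDF of the rarest shared segment; the right term is an
extra-score heuristic applied when more than one segment is shared (the mean
of the remaining segments' IDF values).  A segment present in every plasmid
(x = p) contributes nothing.  Natural logarithms are used throughout; the
base only rescales scores and the calibrated cutoff is scale-free.

A pair with no qualifying shared segment has no evidence of relatedness at
all and scores the sentinel ``NO_EVIDENCE`` (−inf), which compares below
every finite score and never creates a graph edge.

The ``heuristic="ratio"`` switch replaces the per-segment log with the raw
ratio p/xi in the right term, for sensitivity analysis of the heuristic's
exact form.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .io import PlasmidCorpus
from .segments import AlignmentParams, CorpusIndex, build_segment_set

__all__ = ["NO_EVIDENCE", "ds_score", "pairwise_ds", "ObservationCapError"]

#: Sentinel for a pair sharing no qualifying segment; below every finite DS.
NO_EVIDENCE = float("-inf")


class ObservationCapError(ValueError):
    """Raised when a variant group exceeds the pairwise-analysis cap."""


def ds_score(x, p: int, heuristic: str = "log") -> float:
    """Design Similarity from ascending segment frequencies ``x`` and corpus size ``p``.

    Parameters
    ----------
    x : sequence of int
        Corpus frequency of each shared segment, sorted ascending; every
        value must lie in [2, p] (both source plasmids always count).
    p : int
        Number of plasmids in the corpus (p >= 2).
    heuristic : {"log", "ratio"}
        Form of the extra-score term for segments beyond the rarest one.

    Returns
    -------
    float
        The DS score; ``NO_EVIDENCE`` when ``x`` is empty.
    """
    if p < 2:
        raise ValueError("corpus size p must be >= 2")
    if heuristic not in ("log", "ratio"):
        raise ValueError(f"unknown heuristic {heuristic!r}")
    x = list(x)
    n = len(x)
    if n == 0:
        return NO_EVIDENCE
    for i, xi in enumerate(x):
        if xi < 2 or xi > p:
            raise ValueError(f"x[{i}] = {xi} outside [2, p={p}]")
        if i and xi < x[i - 1]:
            raise ValueError("x must be sorted ascending")
    first = math.log(p / x[0])
    if n == 1:
        return first
    if heuristic == "log":
        extra = math.fsum(math.log(p / xi) for xi in x[1:]) / n
    else:
        extra = math.fsum(p / xi for xi in x[1:]) / n
    return first + extra


def pairwise_ds(group, corpus: PlasmidCorpus, params: AlignmentParams = None,
                index: CorpusIndex = None, observation_cap: int = 1205,
                heuristic: str = "log") -> pd.DataFrame:
    """Symmetric DS matrix over the distinct plasmids of a variant group.

    The diagonal is NaN (a plasmid is not compared with itself); off-diagonal
    entries are DS scores or ``NO_EVIDENCE``.  Groups larger than
    ``observation_cap`` observations are refused — callers fall back to the
    widespread-only rule.
    """
    if params is None:
        params = AlignmentParams()
    if group.n_observations > observation_cap:
        raise ObservationCapError(
            f"variant group {group.variant_id} has {group.n_observations} "
            f"observations, above the pairwise-analysis cap of "
            f"{observation_cap}"
        )
    ids = group.plasmid_ids
    if len(ids) < 2:
        raise ValueError("pairwise_ds requires >= 2 distinct plasmids")
    if index is None:
        index = CorpusIndex(corpus, params)
    mat = pd.DataFrame(np.nan, index=ids, columns=ids, dtype=float)
    for i, a_id in enumerate(ids):
        for b_id in ids[i + 1:]:
            seg_set = build_segment_set(
                corpus[a_id], corpus[b_id], corpus, params, index
            )
            score = ds_score(seg_set.x, corpus.p, heuristic)
            mat.loc[a_id, b_id] = score
            mat.loc[b_id, a_id] = score
    return mat


def write_matrix(mat: pd.DataFrame, path: str) -> None:
    """Dump a DS matrix as long-form TSV (plasmid_i, plasmid_j, ds)."""
    with open(path, "w") as fh:
        fh.write("plasmid_i\tplasmid_j\tds\n")
        ids = list(mat.index)
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                fh.write(f"{a}\t{b}\t{mat.loc[a, b]!r}\n")
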