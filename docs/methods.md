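# Methods

This note documents the models, numerical choices and limitations behind
`partprov`.  Empirical statements here are the ones the test suite and
`scripts/acceptance.py` themselves compute.

## Segment model

All alignment in the package reduces to one primitive: along a diagonal of
the comparison matrix between two sequences, the match/mismatch profile is
decomposed into *maximal scoring segments* under the megablast-style scheme
(match +2, mismatch −8, gap open 4, gap extend 6).  Because one gap column
(4 + 6 = 10) costs more than a mismatch (8), optimal local alignments at the
≥ 98 % identity required of shared segments are gap-free, and the diagonal
decomposition is the exact local-alignment model rather than an
approximation.  The decomposition rule is deterministic: repeatedly take the
maximum-scoring contiguous stretch (ties resolved toward the shorter, then
the more leftward stretch) and recurse on the flanks.

A reported shared segment must additionally

* contain at least one exact run of `word_size` = 28 bases.  This mirrors the
  seeded search of the original procedure (a match without an exact word is
  undiscoverable) and is what makes the production k-word-indexed search
  *exactly* equivalent to an exhaustive scan over every diagonal — the
  equivalence the oracle tests assert.  A consequence worth knowing: a 50 bp
  segment with one central substitution (identity exactly 0.98) has maximal
  exact runs of 25/24 bp and is therefore not discoverable; the same
  substitution off-centre leaves the segment discoverable.
* have ≥ 98 % nucleotide identity over its span,
* have Karlin–Altschul E ≤ 10⁻⁵, with λ solved numerically from
  ¼·e^(2λ) + ¾·e^(−8λ) = 1 (λ ≈ 0.6917) and K = 0.738, the tabulated
  ungapped value for this scoring scheme under uniform base composition.  At
  desk-scale corpus sizes any ≥ 28 bp segment passes this filter by many
  orders of magnitude; it matters only as corpora grow.
* satisfy the length-difference filter (≤ 10 bp).  For pair search the two
  aligned spans of a gap-free segment are equal, so the filter is trivially
  met; for segment-vs-corpus frequency queries we read it as
  |segment length − aligned span| ≤ 10 bp, i.e. near-full containment of the
  query — otherwise any 28 bp sub-match would count as "containing" a
  kilobase segment.

Segments wholly contained in a longer segment of the same pair and strand
are suppressed so nested matches are not double-counted in DS.  Frequency
counts plasmids, not hits (a plasmid carrying a segment twice counts once),
and reverse-complement matches count.

Part annotation uses the same diagonal decomposition with a smaller
12 bp anchor (so more diverged part copies stay discoverable) and no
identity filter — the coverage threshold is the filter.  When no single
diagonal reaches the coverage threshold but nearby diagonals jointly cover
the part (an indel variant), a banded affine-gap Gotoh refinement over the
spanned window produces the gapped match; coding matches whose in-frame
length is not a multiple of 3 are flagged frameshifted rather than dropped.

## Design Similarity

With `p` the corpus size and `x` the ascending frequencies of a pair's `n`
shared segments,

    DS = ln(p/x₁) + (1/n) · Σᵢ₌₂ⁿ ln(p/xᵢ),     n ≥ 1

and a no-evidence sentinel (−∞) for n = 0, which sorts below every finite
score and never creates a graph edge.  Two choices deserve a note:

* **Logarithm base.** Natural log.  Base only rescales scores, and the
  calibrated cutoff is a quantile of the same scale, so classification is
  invariant to the choice; a fixed base is declared for reproducibility.
* **Form of the heuristic term.** The extra-score term applies the log to
  each p/xᵢ (a mean of per-segment IDF values).  An unlogged mean of p/xᵢ
  would dwarf the leading IDF term by orders of magnitude whenever any
  second segment is rare, inverting the intended dominance of the rarest
  segment; the logged form is the one consistent with an IDF-inspired
  metric.  The unlogged variant remains available
  (`ds_score(..., heuristic="ratio")`) for sensitivity analysis.

The variant-bearing part itself is not excluded from the shared-segment set.
This is deliberate: a variant within the identity tolerance of its canonical
part matches every plasmid carrying the part family, so its frequency is the
family frequency and its IDF contribution is small.  The flip side is a real
method boundary: if a variant differs from its canonical part by more than
the segment identity tolerance allows (e.g. 2 substitutions in a 60 bp
part: 58/60 < 98 %), the variant sequence itself becomes a *rare* shared
segment among its carriers and independent origins are pulled into one
cluster.  The method is designed for variants differing by one to a few
nucleotides on parts long enough to stay within the 98 % family-identity
regime.

## Null calibration

The relatedness cutoff is the nearest-rank (ceiling) 95th percentile of DS
over uniformly sampled distinct cross-lab pairs (100,000 by default; all
cross-lab pairs when fewer exist).  Nearest-rank is parameter-free and
conservative; sentinel scores enter the sample as −∞.  A pair exactly at
the cutoff is an edge (declared for determinism).  The acceptance suite
verifies on a 12 × 20 corpus that the cutoff calibrated from one 20,000-pair
sample yields a 5 % ± 1 % positive rate on an independently seeded
20,000-pair sample.

Note the calibration's logic: the top tail of the cross-lab null is not
noise — in any realistic corpus a few percent of cross-lab pairs genuinely
share construction history (backbones circulate between labs), and the 5 %
"false-positive" allowance effectively places the cutoff at the boundary
between those related pairs and the unrelated bulk.  The synthetic corpus
reproduces this structure on purpose (see below); on a corpus with no
related cross-lab pairs at all, the cutoff would sit inside the unrelated
score range and per-pair false positives would be a true 5 %.

## Synthetic corpus

The generator emulates the repository structure the method exploits, with
all randomness drawn from one root seed through named substreams:

* **Part library** — 3 origins (550–650 bp), 3 marker CDSs (660–840 bp,
  proper ORFs), 10 cargo parts (CDS/promoter/terminator/misc, 60–600 bp).
  Pools are small and heavily reused because real part usage is extremely
  top-heavy (a single origin family can appear in ~95 % of deposited
  plasmids and one resistance marker in ~60 %); with balanced round-robin
  assignment of backbone parts to lab lineages, no origin or marker is ever
  unique to a couple of labs, which would otherwise mimic shared authorship
  at desk scale.
* **Lab structure** — each lab lineage has a backbone (origin + linkers +
  marker + 80 bp lab-unique spacer) and a 40 bp lab-unique cloning scar in
  every plasmid.  With probability `backbone_sharing` (0.3) a lab adopts an
  earlier lab's backbone wholesale (spacer included; the scar never
  transfers).  These adopted cross-lab pairs are the realistic "related
  contamination" of the null described above.
* **Plasmids** — backbone + scar + 3–5 cargo parts in random orientation
  with random 15–40 bp spacers between all elements (including before the
  circular junction), a uniform random rotation of the circle, and a
  10⁻⁴/bp background substitution rate applied last.
* **Planted variants** — each independent origin is a separate convergent
  mutation event (same variant sequence, by construction) introduced into a
  lab lineage with a distinct backbone root.  Carriers within one origin are
  derivatives of one parent construct and share a 25 bp event-specific
  context on each side of the variant; independent origins get independent
  contexts.  `copy_backbone` mode instead spreads one event across many labs
  together with the origin lab's backbone (modelling a widespread copied
  variant).  Background mutations never touch planted intervals, so the
  emitted ground truth (carriers, origin count, labs) is exact.

What the generator does *not* model: indel variants (substitutions only),
realistic mutation spectra, copy-number or selection effects, shared
sub-part homology between library parts, and the sheer scale of a real
repository.  Passing tests therefore demonstrate that the implementation
detects the signals the method is built on — rare shared context versus
ubiquitous parts — not that desk-scale accuracy transfers quantitatively to
repository-scale data, where the IDF dynamic range is far wider (favourable
to the method) but annotation noise is real.

## Pipeline policies

* Widespread ⇔ observed in ≥ 20 distinct labs (inclusive).
* Recurrent ⇔ DS graph has ≥ 2 connected components; groups above the
  observation cap (1205, configurable — it encodes the quadratic cost of
  pairwise DS) are "not tested" and can only be catalogued as widespread.
* Single-lab multi-plasmid groups are still DS-tested (recurrence within a
  lab is informative); the run report counts them separately.
* Catalog rows are sorted by (part_id, variant_id); variant ids are content
  hashes of (part_id, variant sequence); the whole pipeline is byte-stable
  for fixed inputs and seed.

## Problem sizes used in the shipped checks

Unit and property tests run on sequences of a few hundred bp where the
exhaustive oracles are feasible.  The statistical acceptance checks use:
a 12 × 20 corpus with two 20,000-pair null samples (calibration property);
50 corpora of 12 labs × 10 plasmids, each planting 10 variants with 1–3
origins, calibrated on the full cross-lab null of 6,600 pairs (origin-count
recovery ≥ 90 %, with single-origin copied lineages ≥ 95 %).  Calibration
accuracy matters asymmetrically here: within-origin DS sits far above any
plausible cutoff, so an under-estimated cutoff (which merges independent
origins) is the error mode a small null sample produces.
`scripts/acceptance.py` uses the
10 × 20 corpus stated in its docstring, where the requested 20,000-pair
samples saturate to all 18,000 distinct cross-lab pairs by the sample-all
rule.
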