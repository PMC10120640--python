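# partprov

Detection and prioritisation of **genetic part variants** in corpora of
engineered plasmids, and classification of each variant as **widespread**
(deposited by many labs) or **recurrent** (multiple independent origins
inferred from sequence context).

## The problem

Engineered plasmids are assembled from a shared vocabulary of genetic parts —
replication origins, resistance markers, promoters, coding sequences.  Many
plasmids in public repositories carry *near*-canonical copies of these parts:
sequences that cover a database part almost completely but differ by one to a
few nucleotides.  Some of these variants are historical one-off mutations
copied along a single lineage; others arose independently several times
(convergent engineering or evolution) and may have reproducible functional
consequences worth cataloguing.

Distinguishing the two cases from sequence alone is an authorship problem:
plasmids that inherited a variant from a common ancestor share rare
construction context (backbone fragments, cloning scars, lab-specific
spacers), while independent origins share only ubiquitous parts.

## The method

1. **Variant calling.** Canonical parts are located on each plasmid by local
   alignment (both strands; circular plasmids are searched on their doubled
   sequence).  Matches covering ≥ 95 % of the part are kept; matches that are
   100 % identical at the nucleotide level — or, for coding parts, at the
   amino-acid level — are discarded, as are coding matches with 5′ or 3′
   terminal deletions.  Identical variant sequences of a part are grouped
   corpus-wide.

2. **Design Similarity (DS).**  For a pair of plasmids sharing a variant,
   contiguous shared segments are found (≥ 98 % identity, E ≤ 10⁻⁵, aligned
   length difference ≤ 10 bp, under a megablast-style scheme: match +2,
   mismatch −8, gap open 4, gap extend 6, word size 28).  Each segment is
   queried against the whole corpus to count the plasmids containing it
   (frequency `x_i`).  With `p` the corpus size and `x` sorted ascending,

   ```
   DS = ln(p / x₁) + (1/n) · Σᵢ₌₂ⁿ ln(p / xᵢ)
   ```

   — the inverse-document-frequency of the rarest shared segment plus an
   extra-score heuristic over the remaining segments.  A shared segment
   present in every plasmid carries no authorship signal (ln 1 = 0); a rare
   cloning scar dominates the score.

3. **Calibration and clustering.**  The DS cutoff for relatedness is the
   nearest-rank 95th percentile of DS scores over random *cross-lab* plasmid
   pairs (a 5 % false-positive rate by construction).  Each variant group's
   pairwise DS matrix is binarised at the cutoff; connected components of
   the resulting graph estimate the number of independent origins.  Groups
   with ≥ 2 components are **recurrent**; groups observed in ≥ 20 labs are
   **widespread**; either flag puts the variant in the final catalog.
   Pairwise DS analysis is run only for groups with ≤ 1205 observations
   (configurable); larger groups are assessed by the widespread rule alone.

A fully seeded synthetic-corpus generator (`partprov.simulate`) emulates the
multi-lab structure this method exploits — shared part libraries, lab
backbones and scars, wholesale backbone adoption between labs, and planted
variants with a known number of independent origins — so every stage is
testable with ground truth and no external data.

## Worked example

```python
from partprov import PipelineConfig, run_pipeline
from partprov.simulate import PlantedVariantSpec, SimDesign, generate_corpus

design = SimDesign(
    n_labs=12, plasmids_per_lab=10, seed=11,
    planted_variants=(
        # same variant sequence arising independently in 3 unrelated labs
        PlantedVariantSpec("other-cargo02", n_mutations=2, origin_count=3,
                           carriers_per_origin=2),
    ),
)
corpus, parts, truth = generate_corpus(design)
entries, report = run_pipeline(corpus, parts,
                               PipelineConfig(seed=3, null_pairs=3000))
print(report["ds_cutoff"], report["n_variant_groups"])
for e in entries:
    print(e.part_id, e.n_components, e.recurrent)
```

prints (exactly, for these seeds):

```
2.478164191894677 22
other-cargo02 3 True
```

The calibrated cutoff is ≈ 2.48 nats; 22 variant groups were found (the
planted one plus background single-observation mutations); the planted
variant is catalogued as recurrent with its three independent origins
recovered exactly.  The background singletons are not catalogued — they are
neither widespread nor testable for recurrence.  Recovery of the planted
origin count is a statistical property, not a certainty: across many seeded
corpora the clustering recovers the exact origin count for roughly 9 in 10
planted variants (the acceptance suite measures this), with merges of two
origins being the typical error mode.

A command-line interface mirrors the library:

```bash
partprov simulate --out sim --seed 7
partprov run --seqs sim/corpus.fasta --metadata sim/metadata.tsv \
             --parts sim/parts.fasta --out results --seed 3
partprov calibrate --seqs sim/corpus.fasta --metadata sim/metadata.tsv \
             --out null.tsv --null-pairs 5000
```

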