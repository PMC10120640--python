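"""End-to-end prioritisation pipeline.

annotate parts → call variants → group identical variant sequences →
calibrate the DS relatedness cutoff on a cross-lab null → per-group DS
clustering → final catalog.  A variant group enters the catalog when it is

* **widespread** — observed in plasmids from at least 20 distinct depositing
  labs, or
* **recurrent** — its DS-thresholded relatedness graph has two or more
  connected components (multiple inferred independent origins).

Pairwise DS analysis is only run for groups of at most ``observation_cap``
(default 1205) observations; larger groups are assessed by the widespread
rule alone.  Unlike a lab-count prefilter, groups spanning a single lab are
still DS-tested (recurrence within one lab is informative); the run report
counts them separately.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .clustering import build_graph, calibrate_cutoff, count_components
from .io import PlasmidCorpus, write_catalog
from .segments import AlignmentParams, CorpusIndex
from .similarity import ObservationCapError, pairwise_ds
from .variants import annotate_parts, classify_variant, group_variants

__all__ = [
    "PipelineConfig",
    "VariantCatalogEntry",
    "classify_widespread",
    "classify_recurrent",
    "run_pipeline",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable pipeline parameters.

    ``min_labs_widespread`` (20) and ``observation_cap`` (1205) are inclusive
    bounds; the cap reflects the pairwise cost of DS analysis and is
    configuration, not a constant.
    """

    min_coverage: float = 0.95
    min_labs_widespread: int = 20
    observation_cap: int = 1205
    alignment: AlignmentParams = field(default_factory=AlignmentParams)
    null_pairs: int = 100_000
    fp_rate: float = 0.05
    seed: int = 0
    ds_heuristic: str = "log"

    def __post_init__(self) -> None:
        if self.min_labs_widespread < 1:
            raise ValueError("min_labs_widespread must be >= 1")
        if self.observation_cap < 2:
            raise ValueError("observation_cap must be >= 2")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        alignment = AlignmentParams(**raw.pop("alignment", {}))
        return cls(alignment=alignment, **raw)


@dataclass(frozen=True)
class VariantCatalogEntry:
    """A catalogued variant: classification plus provenance counts.

    ``n_components`` is None ("not-tested") for groups above the observation
    cap; such groups can only be catalogued through the widespread rule.
    """

    variant_id: str
    part_id: str
    part_type: str
    variant_sequence: str
    n_observations: int
    n_labs: int
    n_components: int
    widespread: bool
    recurrent: bool


def classify_widespread(group, config: PipelineConfig) -> bool:
    """True iff the variant was deposited by at least ``min_labs_widespread``
    distinct labs (inclusive bound)."""
    return group.n_labs >= config.min_labs_widespread


def classify_recurrent(group, corpus: PlasmidCorpus, cutoff: float,
                       config: PipelineConfig, index: CorpusIndex = None):
    """DS-cluster a variant group and decide recurrence.

    Returns ``(recurrent, n_components)``; ``n_components`` is None when the
    group exceeds the observation cap (not tested), and 1 for single-plasmid
    groups (nothing to compare).
    """
    if group.n_observations > config.observation_cap:
        return False, None
    if len(group.plasmid_ids) < 2:
        return False, 1
    matrix = pairwise_ds(
        group, corpus, config.alignment, index,
        observation_cap=config.observation_cap,
        heuristic=config.ds_heuristic,
    )
    graph = build_graph(matrix, cutoff)
    clusters = count_components(graph, group.variant_id)
    return clusters.n_components >= 2, clusters.n_components


def _stage(name):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"pipeline stage '{name}': {exc}") from exc
            return False

    return _Ctx()


class _StageError(RuntimeError):
    pass


def run_pipeline(corpus: PlasmidCorpus, parts, config: PipelineConfig = None):
    """Run the full procedure and return (catalog entries, run report).

    Fully deterministic for fixed inputs and seed: the report carries the
    calibrated cutoff, the seed, a config echo and per-stage counts.
    """
    if config is None:
        config = PipelineConfig()
    parts = list(parts)
    part_by_id = {p.part_id: p for p in parts}

    with _stage("annotate"):
        observations = []
        n_matches = 0
        for plasmid in corpus:
            matches = annotate_parts(
                plasmid, parts, config.min_coverage, config.alignment
            )
            n_matches += len(matches)
            for match in matches:
                obs = classify_variant(
                    match, part_by_id[match.part_id], lab=plasmid.lab
                )
                if obs is not None:
                    observations.append(obs)

    with _stage("group"):
        groups = group_variants(observations)

    with _stage("calibrate"):
        index = CorpusIndex(corpus, config.alignment)
        calibration = calibrate_cutoff(
            corpus,
            config.alignment,
            n_pairs=config.null_pairs,
            fp_rate=config.fp_rate,
            seed=config.seed,
            index=index,
            heuristic=config.ds_heuristic,
        )

    entries = []
    n_recurrent = n_widespread = n_capped = n_single_lab_tested = 0
    with _stage("classify"):
        for group in groups:
            widespread = classify_widespread(group, config)
            recurrent, n_components = classify_recurrent(
                group, corpus, calibration.cutoff, config, index
            )
            if n_components is None:
                n_capped += 1
            elif group.n_labs == 1 and len(group.plasmid_ids) >= 2:
                n_single_lab_tested += 1
            if widespread:
                n_widespread += 1
            if recurrent:
                n_recurrent += 1
            if widespread or recurrent:
                part = part_by_id[group.part_id]
                entries.append(
                    VariantCatalogEntry(
                        variant_id=group.variant_id,
                        part_id=group.part_id,
                        part_type=part.part_type,
                        variant_sequence=group.variant_sequence,
                        n_observations=group.n_observations,
                        n_labs=group.n_labs,
                        n_components=n_components,
                        widespread=widespread,
                        recurrent=recurrent,
                    )
                )

    entries.sort(key=lambda e: (e.part_id, e.variant_id))
    report = {
        "p": corpus.p,
        "n_labs": len(corpus.labs),
        "n_parts": len(parts),
        "n_part_matches": n_matches,
        "n_variant_observations": len(observations),
        "n_variant_groups": len(groups),
        "n_catalog_entries": len(entries),
        "n_widespread": n_widespread,
        "n_recurrent": n_recurrent,
        "n_groups_above_cap": n_capped,
        "n_single_lab_groups_tested": n_single_lab_tested,
        "ds_cutoff": calibration.cutoff,
        "null_pairs_scored": int(len(calibration.null_scores)),
        "seed": config.seed,
        "config": config.to_dict(),
    }
    return entries, report


def run_and_write(corpus, parts, config, out_dir: str):
    """Run the pipeline and write catalog.tsv + report.json into ``out_dir``."""
    import json
    import os

    os.makedirs(out_dir, exist_ok=True)
    entries, report = run_pipeline(corpus, parts, config)
    write_catalog(entries, os.path.join(out_dir, "catalog.tsv"))
    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return entries, report
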