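"""Synthetic multi-lab plasmid corpora with known part provenance.

The generator emulates the structure of a public plasmid repository:

* a shared part library (replication origins, CDS markers, promoters,
  terminators, misc cargo) from which every lab draws;
* one backbone per lab — origin + marker + lab-specific linkers and an
  80 bp lab-unique spacer — occasionally adopted wholesale from another lab
  (``backbone_sharing``), mirroring how real backbones circulate;
* a 40 bp lab-unique cloning scar in every plasmid of a lab, never shared
  through adoption: the "small part or cloning scar" signal of shared
  authorship;
* per-plasmid random cargo drawn from the library, random inter-part
  spacers, a uniform random rotation of the final circle, and a low
  per-base background substitution rate.

Planted part variants come with ground truth: each *independent origin* is a
separate convergent mutation event introduced into an unrelated lab lineage;
within an origin the variant spreads by copying (same-lab plasmids, or other
labs that receive the whole backbone in ``copy_backbone`` mode).  Background
mutations never touch planted variant intervals, so the planted variant
sequences, carrier sets and origin counts remain exact ground truth.

All randomness flows from one root seed through named
``numpy.random.SeedSequence`` child streams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .io import PartReference, Plasmid, PlasmidCorpus
from .variants import translate_cds, variant_id_for

__all__ = [
    "PartLibrarySpec",
    "PlantedVariantSpec",
    "SimDesign",
    "PlantedTruth",
    "GroundTruth",
    "generate_part_library",
    "mutate_part",
    "generate_corpus",
]

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}

#: substitutions are kept this many bases away from part ends so that local
#: alignment cannot trim the mutated terminus off the match
MUTATION_END_MARGIN = 6


@dataclass(frozen=True)
class PartLibrarySpec:
    """Counts and length ranges per part category.

    ``cargo`` maps a part type to (count, (min_len, max_len)); origins and
    markers form the backbone pools.  CDS lengths are rounded to codons.
    """

    n_origins: int = 3
    origin_len: tuple = (550, 650)
    n_markers: int = 3
    marker_len: tuple = (660, 840)
    cargo: tuple = (
        ("CDS", 4, (300, 600)),
        ("promoter", 2, (90, 150)),
        ("terminator", 2, (60, 120)),
        ("other", 2, (150, 300)),
    )


@dataclass(frozen=True)
class PlantedVariantSpec:
    """A variant to plant with a known number of independent origins.

    ``spread`` may give an explicit per-origin list of (lab_ordinal,
    plasmid_ordinal) carrier assignments; otherwise ``carriers_per_origin``
    plasmids are chosen in each origin lab, origins placed in labs with
    pairwise-unrelated backbone lineages.  ``mode="copy_backbone"`` spreads a
    single-origin variant across labs by copying the origin lab's whole
    backbone into the carriers.
    """

    part_id: str
    n_mutations: int = 1
    origin_count: int = 1
    carriers_per_origin: int = 3
    spread: tuple = None
    mode: str = "within_lab"


@dataclass(frozen=True)
class SimDesign:
    """Study design of a synthetic corpus."""

    n_labs: int = 10
    plasmids_per_lab: int = 20
    library: PartLibrarySpec = field(default_factory=PartLibrarySpec)
    backbone_sharing: float = 0.3
    cargo_per_plasmid: tuple = (3, 5)
    planted_variants: tuple = ()
    #: length of the construction-event-specific sequence context flanking a
    #: planted variant on each side.  Carriers within one origin are
    #: derivatives of the same parent construct and share this context;
    #: independent origins get independent contexts.  0 disables it.
    planted_context_len: int = 25
    background_mutation_rate: float = 1e-4
    lab_spacer_len: int = 80
    lab_scar_len: int = 40
    inter_part_spacer_len: tuple = (15, 40)
    reverse_cargo_prob: float = 0.3
    rotate: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.backbone_sharing <= 1):
            raise ValueError("backbone_sharing must be a probability")
        if not (0 <= self.reverse_cargo_prob <= 1):
            raise ValueError("reverse_cargo_prob must be a probability")
        if self.background_mutation_rate < 0:
            raise ValueError("background_mutation_rate must be >= 0")
        for pv in self.planted_variants:
            if pv.origin_count < 1:
                raise ValueError("origin_count must be >= 1")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth for one planted variant."""

    part_id: str
    variant_id: str
    variant_sequence: str
    carriers: tuple
    origin_count: int
    labs: tuple
    origin_of: dict  # plasmid id -> origin ordinal


@dataclass(frozen=True)
class GroundTruth:
    variants: tuple

    def to_json(self, path: str) -> None:
        payload = [
            {
                "part_id": v.part_id,
                "variant_id": v.variant_id,
                "variant_sequence": v.variant_sequence,
                "carriers": list(v.carriers),
                "origin_count": v.origin_count,
                "labs": list(v.labs),
                "origin_of": v.origin_of,
            }
            for v in self.variants
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _random_seq(rng, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _random_orf(rng, length: int) -> str:
    """Random ORF: start codon, no internal stops, terminal stop codon."""
    length -= length % 3
    if length < 6:
        raise ValueError("a CDS needs at least 6 nt (start + stop codon)")
    codons = ["ATG"]
    for _ in range(length // 3 - 2):
        while True:
            c = _random_seq(rng, 3)
            if c not in _STOPS:
                break
        codons.append(c)
    codons.append(["TAA", "TAG", "TGA"][rng.integers(0, 3)])
    return "".join(codons)


class PartLibrary:
    """Generated library with role bookkeeping (origins / markers / cargo)."""

    def __init__(self, origins, markers, cargo):
        self.origins = origins
        self.markers = markers
        self.cargo = cargo

    @property
    def parts(self):
        return list(self.origins) + list(self.markers) + list(self.cargo)

    def by_id(self, part_id: str) -> PartReference:
        for part in self.parts:
            if part.part_id == part_id:
                return part
        raise KeyError(part_id)


def generate_part_library(spec: PartLibrarySpec, seed: int) -> PartLibrary:
    """Random part library; CDS entries are open reading frames."""
    rng = np.random.default_rng(seed)

    def lengths(count, lo_hi):
        lo, hi = lo_hi
        if hi < lo:
            raise ValueError("invalid length range")
        return rng.integers(lo, hi + 1, size=count)

    origins = [
        PartReference(f"ori{i + 1:02d}", _random_seq(rng, int(L)),
                      "origin of replication")
        for i, L in enumerate(lengths(spec.n_origins, spec.origin_len))
    ]
    markers = [
        PartReference(f"marker{i + 1:02d}", _random_orf(rng, int(L)), "CDS")
        for i, L in enumerate(lengths(spec.n_markers, spec.marker_len))
    ]
    cargo = []
    for part_type, count, lo_hi in spec.cargo:
        for i, L in enumerate(lengths(count, lo_hi)):
            name = f"{part_type.split()[0].lower()}-cargo{i + 1:02d}"
            seq = (_random_orf(rng, int(L)) if part_type == "CDS"
                   else _random_seq(rng, int(L)))
            cargo.append(PartReference(name, seq, part_type))
    return PartLibrary(origins, markers, cargo)


def mutate_part(sequence: str, n_mutations: int, seed: int,
                coding: bool = False) -> str:
    """Exactly ``n_mutations`` substitutions at distinct interior positions.

    For coding parts the draw is repeated (deterministically) until at least
    one substitution is non-synonymous, so the variant survives the
    amino-acid-identity filter.
    """
    if n_mutations == 0:
        return sequence
    L = len(sequence)
    lo, hi = MUTATION_END_MARGIN, L - MUTATION_END_MARGIN
    if n_mutations > max(0, hi - lo):
        raise ValueError(
            f"cannot place {n_mutations} substitutions in a part of "
            f"length {L}"
        )
    rng = np.random.default_rng(seed)
    for _attempt in range(200):
        positions = rng.choice(np.arange(lo, hi), size=n_mutations,
                               replace=False)
        out = list(sequence)
        for pos in positions:
            choices = [b for b in "ACGT" if b != sequence[pos]]
            out[pos] = choices[rng.integers(0, 3)]
        variant = "".join(out)
        if not coding:
            return variant
        if translate_cds(variant) != translate_cds(sequence):
            return variant
    raise RuntimeError("could not generate a non-synonymous variant")


def _plan_spread(pv: PlantedVariantSpec, design: SimDesign, lineage_root,
                 rng) -> list:
    """Per-origin carrier assignments [(lab_ordinal, plasmid_ordinal), ...]."""
    if pv.spread is not None:
        return [list(origin) for origin in pv.spread]
    roots = {}
    for lab in range(design.n_labs):
        roots.setdefault(lineage_root[lab], []).append(lab)
    distinct_roots = list(roots)
    if pv.origin_count > len(distinct_roots):
        raise ValueError(
            f"variant {pv.part_id}: {pv.origin_count} independent origins "
            f"requested but only {len(distinct_roots)} unrelated backbone "
            "lineages exist"
        )
    chosen_roots = rng.choice(len(distinct_roots), size=pv.origin_count,
                              replace=False)
    if pv.mode == "copy_backbone":
        # a single construction event copied (with its whole backbone)
        # into plasmids spread across many labs
        total = pv.carriers_per_origin
        if total > design.n_labs * design.plasmids_per_lab:
            raise ValueError(
                f"variant {pv.part_id}: {total} carriers requested but the "
                "corpus is smaller"
            )
        labs = list(range(design.n_labs))
        rng.shuffle(labs)
        seen = set()
        assignments = []
        for k in range(total):
            lab = labs[k % len(labs)]
            idx = int(rng.integers(design.plasmids_per_lab))
            while (lab, idx) in seen:
                idx = (idx + 1) % design.plasmids_per_lab
            seen.add((lab, idx))
            assignments.append((lab, idx))
        spread = [assignments]
        for origin_idx in chosen_roots[1:]:
            lab = roots[distinct_roots[int(origin_idx)]][0]
            picks = rng.choice(design.plasmids_per_lab,
                               size=min(pv.carriers_per_origin,
                                        design.plasmids_per_lab),
                               replace=False)
            spread.append([(lab, int(i)) for i in sorted(picks)])
        return spread
    spread = []
    for origin_idx in chosen_roots:
        lab = roots[distinct_roots[int(origin_idx)]][0]
        if pv.carriers_per_origin > design.plasmids_per_lab:
            raise ValueError(
                f"variant {pv.part_id}: {pv.carriers_per_origin} carriers "
                f"requested but labs have {design.plasmids_per_lab} plasmids"
            )
        picks = rng.choice(design.plasmids_per_lab,
                           size=pv.carriers_per_origin, replace=False)
        spread.append([(lab, int(i)) for i in sorted(picks)])
    return spread


def generate_corpus(design: SimDesign):
    """Generate (corpus, part library, ground truth) from a design.

    Deterministic for a fixed design; see the module docstring for the
    corpus structure.
    """
    streams = np.random.SeedSequence(design.seed).spawn(6)
    (lib_ss, backbone_ss, plasmid_ss, plant_ss, background_ss,
     rotate_ss) = streams
    library = generate_part_library(
        design.library, int(lib_ss.generate_state(1)[0] % (2 ** 31))
    )

    rng_bb = np.random.default_rng(backbone_ss)
    # adoption structure first: which labs inherit an earlier lab's backbone
    adopts = {}
    lineage_root = {}
    for lab in range(design.n_labs):
        if lab > 0 and rng_bb.random() < design.backbone_sharing:
            src = int(rng_bb.integers(0, lab))
            adopts[lab] = src
            lineage_root[lab] = lineage_root[src]
        else:
            lineage_root[lab] = lab
    roots = [lab for lab in range(design.n_labs) if lineage_root[lab] == lab]
    # backbone parts are assigned round-robin over shuffled lineages: every
    # origin and marker stays heavily used corpus-wide, as common backbone
    # parts are in real repositories (no origin is unique to a couple of labs)
    ori_order = rng_bb.permutation(len(roots))
    mark_order = rng_bb.permutation(len(roots))
    backbones = []
    for lab in range(design.n_labs):
        if lab in adopts:
            backbones.append(backbones[adopts[lab]])
            continue
        rank = roots.index(lab)
        origin = library.origins[int(ori_order[rank]) % len(library.origins)]
        marker = library.markers[int(mark_order[rank]) % len(library.markers)]
        backbones.append({
            "origin": origin,
            "marker": marker,
            "linker_a": _random_seq(rng_bb, int(rng_bb.integers(20, 41))),
            "linker_b": _random_seq(rng_bb, int(rng_bb.integers(20, 41))),
            "lab_spacer": _random_seq(rng_bb, design.lab_spacer_len),
        })
    scars = {
        lab: _random_seq(rng_bb, design.lab_scar_len)
        for lab in range(design.n_labs)
    }

    # planting plan: (lab, plasmid) -> list of (variant_seq, part, origin_idx,
    #                                           backbone override or None)
    rng_plant = np.random.default_rng(plant_ss)
    plan = {}
    truths = []
    used_variant_seqs = set()
    for pv in design.planted_variants:
        part = library.by_id(pv.part_id)
        for _ in range(50):
            vseed = int(rng_plant.integers(2 ** 31))
            vseq = mutate_part(part.sequence, pv.n_mutations, vseed,
                               coding=part.is_coding)
            if vseq not in used_variant_seqs:
                break
        used_variant_seqs.add(vseq)
        spread = _plan_spread(pv, design, lineage_root, rng_plant)
        carriers = []
        origin_of = {}
        labs = set()
        for origin_idx, assignments in enumerate(spread):
            origin_lab = assignments[0][0]
            ctx = design.planted_context_len
            context = (_random_seq(rng_plant, ctx),
                       _random_seq(rng_plant, ctx)) if ctx else ("", "")
            for lab, idx in assignments:
                pid = f"L{lab:02d}P{idx:02d}"
                override = (origin_lab if pv.mode == "copy_backbone"
                            and lab != origin_lab else None)
                plan.setdefault((lab, idx), []).append(
                    (vseq, part, origin_idx, override, context)
                )
                carriers.append(pid)
                origin_of[pid] = origin_idx
                labs.add(f"lab{lab:02d}")
        truths.append(
            PlantedTruth(
                part_id=pv.part_id,
                variant_id=variant_id_for(pv.part_id, vseq),
                variant_sequence=vseq,
                carriers=tuple(sorted(set(carriers))),
                origin_count=len(spread),
                labs=tuple(sorted(labs)),
                origin_of=origin_of,
            )
        )

    rng_pl = np.random.default_rng(plasmid_ss)
    rng_bg = np.random.default_rng(background_ss)
    rng_rot = np.random.default_rng(rotate_ss)
    lo_cargo, hi_cargo = design.cargo_per_plasmid
    lo_sp, hi_sp = design.inter_part_spacer_len
    plasmids = []
    for lab in range(design.n_labs):
        for idx in range(design.plasmids_per_lab):
            planted_here = plan.get((lab, idx), [])
            bb_lab = lab
            for _vseq, _part, _oidx, override, _ctx in planted_here:
                if override is not None:
                    bb_lab = override
            bb = backbones[bb_lab]
            # the scar follows the backbone lineage only for wholesale copies
            scar = scars[bb_lab]
            pieces = [
                bb["origin"].sequence,
                bb["linker_a"],
                bb["marker"].sequence,
                bb["linker_b"],
                bb["lab_spacer"],
                scar,
            ]
            protected_parts = {p.part_id for _v, p, _o, _ov, _c in planted_here}
            n_cargo = int(rng_pl.integers(lo_cargo, hi_cargo + 1))
            pool = [c for c in library.cargo
                    if c.part_id not in protected_parts]
            chosen = [pool[i] for i in rng_pl.choice(len(pool),
                                                     size=min(n_cargo,
                                                              len(pool)),
                                                     replace=False)]
            cargo_seqs = []
            for c in chosen:
                seq = c.sequence
                if rng_pl.random() < design.reverse_cargo_prob:
                    seq = _revcomp(seq)
                cargo_seqs.append(seq)
            planted_elems = set()
            for vseq, _part, _oidx, _ov, (ctx_l, ctx_r) in planted_here:
                elem = ctx_l + vseq + ctx_r
                planted_elems.add(elem)
                cargo_seqs.insert(int(rng_pl.integers(len(cargo_seqs) + 1)),
                                  elem)

            protected = []
            for seq in cargo_seqs:
                spacer = _random_seq(rng_pl, int(rng_pl.integers(lo_sp,
                                                                 hi_sp + 1)))
                pieces.append(spacer)
                start = sum(len(x) for x in pieces)
                pieces.append(seq)
                if seq in planted_elems:
                    protected.append((start, start + len(seq)))
            # final spacer so the circular junction never fuses the last
            # cargo element seamlessly to the origin part
            pieces.append(_random_seq(rng_pl, int(rng_pl.integers(lo_sp,
                                                                  hi_sp + 1))))
            full = "".join(pieces)

            full = _background_mutate(
                full, design.background_mutation_rate, protected, rng_bg
            )
            if design.rotate:
                off = int(rng_rot.integers(len(full)))
                full = full[off:] + full[:off]
            plasmids.append(
                Plasmid(
                    id=f"L{lab:02d}P{idx:02d}",
                    sequence=full,
                    lab=f"lab{lab:02d}",
                    topology="circular",
                )
            )

    corpus = PlasmidCorpus(plasmids)
    return corpus, library.parts, GroundTruth(variants=tuple(truths))


def _background_mutate(seq: str, rate: float, protected, rng) -> str:
    if rate <= 0:
        return seq
    n = rng.binomial(len(seq), rate)
    if n == 0:
        return seq
    out = list(seq)
    positions = rng.choice(len(seq), size=n, replace=False)
    for pos in positions:
        if any(lo <= pos < hi for lo, hi in protected):
            continue
        base = out[pos]
        if base not in "ACGT":
            continue
        choices = [b for b in "ACGT" if b != base]
        out[pos] = choices[rng.integers(0, 3)]
    return "".join(out)


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
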