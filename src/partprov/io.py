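"""Reading and writing plasmid corpora, part databases, metadata and catalogs.

A corpus is a FASTA or GenBank file of plasmid sequences plus a tab-separated
metadata table with columns ``plasmid_id``, ``lab`` and ``topology`` mapping
every record to its depositing lab and to circular/linear topology.  A part
database is a FASTA file whose headers are pipe-delimited ``>part_id|part_type``.
Annotation is always recomputed from sequence; GenBank feature tables are not
trusted.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "PART_TYPES",
    "Plasmid",
    "PartReference",
    "PlasmidCorpus",
    "read_corpus",
    "write_corpus",
    "read_part_db",
    "write_part_db",
    "write_catalog",
]

#: Allowed part-type categories for a part reference database.
PART_TYPES = frozenset(
    {
        "CDS",
        "origin of replication",
        "promoter",
        "terminator",
        "protein binding site",
        "ncRNA",
        "other",
    }
)

_VALID_BASES = frozenset("ACGTN")
_TOPOLOGIES = ("circular", "linear")


class CorpusError(ValueError):
    """Raised for malformed corpus, metadata or part-database inputs."""


@dataclass(frozen=True)
class Plasmid:
    """A single plasmid record: sequence plus depositing-lab metadata."""

    id: str
    sequence: str
    lab: str
    topology: str = "circular"

    def __post_init__(self) -> None:
        if not self.id:
            raise CorpusError("plasmid id must be non-empty")
        if not self.sequence:
            raise CorpusError(f"plasmid {self.id!r}: sequence must be non-empty")
        if not self.lab:
            raise CorpusError(f"plasmid {self.id!r}: lab must be non-empty")
        if self.topology not in _TOPOLOGIES:
            raise CorpusError(
                f"plasmid {self.id!r}: topology must be one of {_TOPOLOGIES}, "
                f"got {self.topology!r}"
            )
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise CorpusError(
                f"plasmid {self.id!r}: sequence contains characters outside "
                f"A/C/G/T/N: {sorted(bad)}. Ambiguity codes other than N are "
                "rejected because downstream filters are defined over exact "
                "identity fractions."
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PartReference:
    """A canonical genetic part: sequence plus functional category."""

    part_id: str
    sequence: str
    part_type: str
    is_coding: bool = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.part_id:
            raise CorpusError("part_id must be non-empty")
        if self.part_type not in PART_TYPES:
            raise CorpusError(
                f"part {self.part_id!r}: unknown part_type {self.part_type!r}; "
                f"expected one of {sorted(PART_TYPES)}"
            )
        if self.is_coding is None:
            object.__setattr__(self, "is_coding", self.part_type == "CDS")
        if not self.sequence:
            raise CorpusError(f"part {self.part_id!r}: sequence must be non-empty")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise CorpusError(
                f"part {self.part_id!r}: invalid sequence characters {sorted(bad)}"
            )
        if self.is_coding and len(self.sequence) % 3 != 0:
            raise CorpusError(
                f"part {self.part_id!r}: coding sequence length "
                f"{len(self.sequence)} is not a multiple of 3"
            )

    def __len__(self) -> int:
        return len(self.sequence)


class PlasmidCorpus:
    """An ordered collection of plasmids with unique ids.

    The corpus size ``p`` is the reference-set size used as the numerator of
    the inverse-frequency terms in the Design Similarity score.
    """

    def __init__(self, plasmids):
        self.plasmids = list(plasmids)
        if not self.plasmids:
            raise CorpusError("a corpus must contain at least one plasmid")
        self._by_id = {}
        for pl in self.plasmids:
            if pl.id in self._by_id:
                raise CorpusError(f"duplicate plasmid id {pl.id!r} in corpus")
            self._by_id[pl.id] = pl

    @property
    def p(self) -> int:
        """Number of plasmids in the corpus."""
        return len(self.plasmids)

    @property
    def labs(self):
        return sorted({pl.lab for pl in self.plasmids})

    def __len__(self) -> int:
        return len(self.plasmids)

    def __iter__(self):
        return iter(self.plasmids)

    def __getitem__(self, plasmid_id: str) -> Plasmid:
        return self._by_id[plasmid_id]

    def __contains__(self, plasmid_id: str) -> bool:
        return plasmid_id in self._by_id


def _sniff_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext in (".gb", ".gbk", ".genbank"):
        return "genbank"
    return "fasta"


def read_corpus(seq_path: str, metadata_path: str) -> PlasmidCorpus:
    """Read a plasmid corpus from a sequence file and its metadata table.

    Parameters
    ----------
    seq_path : str
        FASTA (default) or GenBank (``.gb``/``.gbk``/``.genbank``) file with one
        record per plasmid.
    metadata_path : str
        Tab-separated table with header columns ``plasmid_id``, ``lab`` and
        ``topology``.

    Returns
    -------
    PlasmidCorpus
        Sequences are uppercased; every record must have exactly one metadata
        row.
    """
    records = list(SeqIO.parse(seq_path, _sniff_format(seq_path)))
    if not records:
        raise CorpusError(f"no sequence records found in {seq_path!r}")

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = {"plasmid_id", "lab", "topology"}
    missing_cols = required - set(meta.columns)
    if missing_cols:
        raise CorpusError(
            f"metadata {metadata_path!r} is missing columns {sorted(missing_cols)}"
        )
    if meta["plasmid_id"].duplicated().any():
        dups = meta.loc[meta["plasmid_id"].duplicated(), "plasmid_id"].tolist()
        raise CorpusError(f"duplicate plasmid ids in metadata: {dups}")
    rows = meta.set_index("plasmid_id")

    plasmids = []
    seen = set()
    for rec in records:
        if rec.id in seen:
            raise CorpusError(f"duplicate record id {rec.id!r} in {seq_path!r}")
        seen.add(rec.id)
        if rec.id not in rows.index:
            raise CorpusError(
                f"plasmid {rec.id!r} has no metadata row in {metadata_path!r}"
            )
        row = rows.loc[rec.id]
        plasmids.append(
            Plasmid(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                lab=row["lab"],
                topology=row["topology"],
            )
        )
    return PlasmidCorpus(plasmids)


def write_corpus(corpus: PlasmidCorpus, seq_path: str, metadata_path: str) -> None:
    """Write a corpus as FASTA plus a metadata TSV (round-trips exactly)."""
    with open(seq_path, "w") as fh:
        for pl in corpus:
            fh.write(f">{pl.id}\n{pl.sequence}\n")
    with open(metadata_path, "w") as fh:
        fh.write("plasmid_id\tlab\ttopology\n")
        for pl in corpus:
            fh.write(f"{pl.id}\t{pl.lab}\t{pl.topology}\n")


def read_part_db(path: str):
    """Read a part reference database from FASTA with ``>part_id|part_type`` headers."""
    parts = []
    seen = set()
    for rec in SeqIO.parse(path, "fasta"):
        header = rec.description
        if "|" not in header:
            raise CorpusError(
                f"part header {header!r} lacks the pipe-delimited "
                "'part_id|part_type' format"
            )
        part_id, part_type = header.split("|", 1)
        part_id = part_id.strip()
        part_type = part_type.strip()
        if part_id in seen:
            raise CorpusError(f"duplicate part_id {part_id!r} in {path!r}")
        seen.add(part_id)
        parts.append(
            PartReference(
                part_id=part_id,
                sequence=str(rec.seq).upper(),
                part_type=part_type,
            )
        )
    if not parts:
        raise CorpusError(f"no part records found in {path!r}")
    return parts


def write_part_db(parts, path: str) -> None:
    with open(path, "w") as fh:
        for part in parts:
            fh.write(f">{part.part_id}|{part.part_type}\n{part.sequence}\n")


_CATALOG_COLUMNS = [
    "variant_id",
    "part_id",
    "part_type",
    "variant_sequence",
    "n_observations",
    "n_labs",
    "n_components",
    "widespread",
    "recurrent",
]


def write_catalog(entries, path: str) -> None:
    """Write the final variant catalog as a deterministic TSV.

    Rows are sorted by ``(part_id, variant_id)``; booleans are written as
    ``true``/``false``; groups above the observation cap carry
    ``not-tested`` in the ``n_components`` column.  Output is byte-identical
    for identical input.
    """
    rows = sorted(entries, key=lambda e: (e.part_id, e.variant_id))
    with open(path, "w") as fh:
        fh.write("\t".join(_CATALOG_COLUMNS) + "\n")
        for e in rows:
            n_comp = "not-tested" if e.n_components is None else str(e.n_components)
            fh.write(
                "\t".join(
                    [
                        e.variant_id,
                        e.part_id,
                        e.part_type,
                        e.variant_sequence,
                        str(e.n_observations),
                        str(e.n_labs),
                        n_comp,
                        "true" if e.widespread else "false",
                        "true" if e.recurrent else "false",
                    ]
                )
                + "\n"
            )


def reverse_complement(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return str(Seq(seq).reverse_complement())
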