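"""Protein records and plain-text IO.

The in-memory currency of the whole toolkit is :class:`ProteinRecord`: one
amino-acid sequence with an accession, a free-text description, and a coarse
taxonomic group used for network composition tables. Sequences are uppercase
strings over the 20 standard residues plus ``X`` (unknown).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = frozenset(AMINO_ACIDS + "X")

#: Coarse taxonomic groups used to paint similarity-network clusters.
TAXON_GROUPS = (
    "green_plants",
    "chlorophyta",
    "other_algae",
    "oomycota",
    "metazoa",
    "fungi",
    "protista",
    "bacteria",
    "archaea",
    "unknown",
)


class InvalidSequenceError(ValueError):
    """Raised when a sequence contains characters outside the alphabet."""


def validate_sequence(sequence: str) -> str:
    seq = sequence.upper()
    bad = set(seq) - ALPHABET
    if bad:
        raise InvalidSequenceError(
            f"sequence contains non-amino-acid characters: {sorted(bad)}"
        )
    if not seq:
        raise InvalidSequenceError("empty sequence")
    return seq


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with provenance.

    Parameters
    ----------
    accession:
        Unique identifier within a dataset (nonempty).
    sequence:
        Uppercase amino-acid string over the 20 standard residues plus X.
    description:
        Free-text description carried through to FASTA output.
    taxon_group:
        One of :data:`TAXON_GROUPS`; defaults to ``"unknown"``.
    """

    accession: str
    sequence: str
    description: str = ""
    taxon_group: str = "unknown"

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be nonempty")
        object.__setattr__(self, "sequence", validate_sequence(self.sequence))
        if self.taxon_group not in TAXON_GROUPS:
            raise ValueError(
                f"unknown taxon_group {self.taxon_group!r}; "
                f"expected one of {TAXON_GROUPS}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def check_unique_accessions(records: Sequence[ProteinRecord]) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.accession in seen:
            raise ValueError(f"duplicate accession in input: {rec.accession}")
        seen.add(rec.accession)


def read_fasta(
    path: str | Path, metadata: str | Path | None = None
) -> list[ProteinRecord]:
    """Read records from FASTA, optionally joining a metadata TSV.

    The metadata table must have columns ``accession`` and ``taxon_group``.
    """
    taxa: dict[str, str] = {}
    if metadata is not None:
        meta = pd.read_csv(metadata, sep="\t", dtype=str)
        taxa = dict(zip(meta["accession"], meta["taxon_group"]))
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            ProteinRecord(
                accession=rec.id,
                sequence=str(rec.seq),
                description=rec.description[len(rec.id):].strip(),
                taxon_group=taxa.get(rec.id, "unknown"),
            )
        )
    check_unique_accessions(records)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write FASTA wrapped at 60 columns."""
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.accession, description=r.description)
        for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=60)
        writer.write_file(seqrecords)


def write_metadata(records: Iterable[ProteinRecord], path: str | Path) -> None:
    frame = pd.DataFrame(
        [(r.accession, r.taxon_group) for r in records],
        columns=["accession", "taxon_group"],
    )
    frame.to_csv(path, sep="\t", index=False)
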