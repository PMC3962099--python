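"""Reading, validation and writing of protein and coding-sequence FASTA sets.

Protein sequences are plain strings over the 20 standard one-letter residue
codes.  The ambiguous / non-standard letters B, J, O, U, X, Z are tolerated on
input (they are excluded later, at counting time, rather than causing whole
sequences to be dropped), and ``'*'`` is kept as a hard fragment separator so
that translations of frameshifted coding sequences can flow through the same
pipeline without dipeptides ever spanning a stop.

Coding sequences are restricted to A/C/G/T after normalization (U is mapped
to T); records containing other letters are skipped with a warning by
default, or rejected in strict mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, List, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetical by one-letter code.
STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
#: Tolerated non-standard / ambiguity letters (kept in sequences, never counted).
NONSTANDARD_RESIDUES = "BJOUXZ"
#: Hard separator: no residue pair may span it.
SEPARATOR = "*"

PROTEIN_ALPHABET = frozenset(STANDARD_RESIDUES + NONSTANDARD_RESIDUES + SEPARATOR)
NUCLEOTIDE_ALPHABET = frozenset("ACGT")


@dataclass(frozen=True)
class ProteinSequence:
    """An identified amino-acid string (may be empty, e.g. a degenerate translation)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein sequence id must be non-empty")
        bad = set(self.residues) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid residue letters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class CodingSequence:
    """An identified nucleotide string over {A, C, G, T}."""

    id: str
    bases: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("coding sequence id must be non-empty")
        bad = set(self.bases) - NUCLEOTIDE_ALPHABET
        if bad:
            raise ValueError(
                f"coding sequence {self.id!r} contains invalid bases: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.bases)


class SequenceSet:
    """An ordered, labelled collection of :class:`ProteinSequence` with unique ids."""

    def __init__(self, members: Iterable[ProteinSequence] = (), label: str = ""):
        self.members: List[ProteinSequence] = list(members)
        self.label = label
        seen = set()
        for m in self.members:
            if m.id in seen:
                raise ValueError(f"duplicate sequence id {m.id!r} in set {label!r}")
            seen.add(m.id)

    def __iter__(self) -> Iterator[ProteinSequence]:
        return iter(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __getitem__(self, i: int) -> ProteinSequence:
        return self.members[i]

    def ids(self) -> List[str]:
        return [m.id for m in self.members]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SequenceSet):
            return NotImplemented
        return self.members == other.members

    def __repr__(self) -> str:
        return f"SequenceSet(label={self.label!r}, n={len(self)})"


def normalize_protein(raw: str) -> str:
    """Upper-case and strip gaps ('-') and whitespace.  Idempotent."""
    return "".join(raw.upper().split()).replace("-", "")


def normalize_nucleotide(raw: str) -> str:
    """Upper-case, strip gaps/whitespace and map U to T.  Idempotent."""
    return "".join(raw.upper().split()).replace("-", "").replace("U", "T")


def read_fasta_protein(path: Union[str, Path], label: str = "") -> SequenceSet:
    """Read a protein FASTA file into a :class:`SequenceSet`.

    Residues are upper-cased, gaps and whitespace stripped.  Duplicate record
    ids raise ``ValueError``; a missing file raises ``FileNotFoundError``;
    malformed FASTA (sequence data before any header) raises ``ValueError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    members = []
    with path.open() as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            members.append(ProteinSequence(rec.id, normalize_protein(str(rec.seq))))
    return SequenceSet(members, label=label or path.stem)


def read_fasta_nucleotide(
    path: Union[str, Path], strict: bool = False
) -> List[CodingSequence]:
    """Read a nucleotide FASTA file into a list of :class:`CodingSequence`.

    U is mapped to T.  Records containing letters outside {A, C, G, T, U}
    are skipped with a logged warning, or raise ``ValueError`` when
    ``strict`` is true.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: List[CodingSequence] = []
    seen = set()
    with path.open() as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            bases = normalize_nucleotide(str(rec.seq))
            bad = set(bases) - NUCLEOTIDE_ALPHABET
            if bad:
                msg = f"record {rec.id!r} contains non-ACGTU letters {sorted(bad)}"
                if strict:
                    raise ValueError(msg)
                log.warning("skipping %s", msg)
                continue
            if rec.id in seen:
                raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
            seen.add(rec.id)
            out.append(CodingSequence(rec.id, bases))
    return out


def write_fasta(
    seqs: Union[SequenceSet, Sequence[ProteinSequence], Sequence[CodingSequence]],
    path: Union[str, Path],
) -> None:
    """Write protein or coding sequences as FASTA with 60-column line wrap."""
    records = []
    for s in seqs:
        letters = s.residues if isinstance(s, ProteinSequence) else s.bases
        records.append(SeqRecord(Seq(letters), id=s.id, description=""))
    with Path(path).open("w") as handle:
        SeqIO.write(records, handle, "fasta")
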