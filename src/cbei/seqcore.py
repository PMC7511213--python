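"""Sequence I/O, genetic-code tables and strand/coordinate primitives.

Conventions used throughout the package:

* internal coordinates are 0-based half-open;
* every user-facing coordinate (tables, :class:`ExonSpec` input, CLI output)
  is 1-based inclusive, the convention biologists use;
* sequences are uppercased on ingest, RNA ``U`` is mapped to ``T``, and
  IUPAC ambiguity letters other than A/C/G/T are collapsed to ``N``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "NucSequence", "GeneticCode", "ExonSpec", "BUILTIN_TABLE_IDS",
    "read_fasta", "write_fasta", "reverse_complement", "splice_exons",
    "load_genetic_code",
]

_IUPAC = set("ACGTUNRYSWKMBDHV")
_AMBIGUOUS = str.maketrans({c: "N" for c in "RYSWKMBDHV"})
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: NCBI translation-table identifiers shipped with the package: the 25
#: assigned tables with ids <= 31 (ids 7, 8 and 17-20 were never assigned
#: by NCBI and do not exist).
BUILTIN_TABLE_IDS: tuple[int, ...] = (
    1, 2, 3, 4, 5, 6, 9, 10, 11, 12, 13, 14, 15, 16,
    21, 22, 23, 24, 25, 26, 27, 28, 29, 30, 31,
)

STOP = "*"


@dataclass
class NucSequence:
    """A named DNA sequence over the alphabet {A, C, G, T, N}."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        self.seq = normalize_seq(self.seq)
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GeneticCode:
    """A codon translation table (NCBI numbering) with start/stop sets."""

    table_id: int
    name: str
    codon_to_aa: dict[str, str]
    start_codons: frozenset[str]
    stop_codons: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise ValueError(
                f"genetic code {self.table_id} has {len(self.codon_to_aa)} codons, expected 64"
            )
        derived_stops = frozenset(c for c, aa in self.codon_to_aa.items() if aa == STOP)
        if derived_stops != self.stop_codons:
            raise ValueError(f"stop codon set inconsistent for table {self.table_id}")
        if not self.start_codons:
            raise ValueError(f"genetic code {self.table_id} has no start codons")

    def translate_codon(self, codon: str) -> str:
        """Translate one codon; codons containing N translate to 'X'."""
        return self.codon_to_aa.get(codon, "X")

    def is_start(self, codon: str) -> bool:
        return codon in self.start_codons

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons


@dataclass(frozen=True)
class ExonSpec:
    """Ordered exon spans on an input sequence, 1-based inclusive."""

    spans: tuple[tuple[int, int], ...]

    def __init__(self, spans: Iterable[tuple[int, int]]) -> None:
        object.__setattr__(self, "spans", tuple((int(a), int(b)) for a, b in spans))
        prev_end = 0
        for i, (a, b) in enumerate(self.spans):
            if a < 1 or b < a:
                raise ValueError(f"exon span {i + 1} ({a}, {b}) is not a valid 1-based span")
            if a <= prev_end:
                raise ValueError(
                    f"exon span {i + 1} ({a}, {b}) overlaps or is not strictly increasing"
                )
            prev_end = b


def normalize_seq(seq: str, *, context: str = "sequence") -> str:
    """Uppercase, map U->T, collapse non-ACGT IUPAC letters to N.

    Raises ``ValueError`` naming the first illegal (non-IUPAC) character.
    """
    s = "".join(seq.split()).upper()
    bad = set(s) - _IUPAC
    if bad:
        raise ValueError(f"illegal character {sorted(bad)[0]!r} in {context}")
    return s.replace("U", "T").translate(_AMBIGUOUS)


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N."""
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: Union[str, Path, io.TextIOBase]) -> list[NucSequence]:
    """Read FASTA (single or multi-record) or bare single-sequence text.

    A file whose first non-blank character is not ``>`` is treated as one
    plain-text sequence and given a generated id.  Sequences are normalized
    (uppercase, U->T, ambiguity letters to N); an empty file is an error.
    """
    if isinstance(path, io.TextIOBase):
        text = path.read()
        name = getattr(path, "name", "input")
    else:
        text = Path(path).read_text()
        name = Path(path).name
    stripped = text.strip()
    if not stripped:
        raise ValueError(f"{name}: file is empty")
    records: list[NucSequence] = []
    if stripped.startswith(">"):
        for rec in SeqIO.parse(io.StringIO(text), "fasta"):
            try:
                seq = normalize_seq(str(rec.seq), context=f"record {rec.id!r}")
            except ValueError as exc:
                raise ValueError(f"{name}: {exc}") from None
            if not seq:
                raise ValueError(f"{name}: record {rec.id!r} has an empty sequence")
            records.append(NucSequence(id=rec.id, seq=seq, description=rec.description))
        if not records:
            raise ValueError(f"{name}: no FASTA records found")
    else:
        for lineno, line in enumerate(stripped.splitlines(), start=1):
            try:
                normalize_seq(line, context=f"line {lineno}")
            except ValueError as exc:
                raise ValueError(f"{name}: {exc}") from None
        records.append(NucSequence(id="seq1", seq=normalize_seq(stripped)))
    return records


def write_fasta(records: Sequence[NucSequence], path: Union[str, Path]) -> None:
    """Write records as wrapped FASTA."""
    bio_records = [
        SeqRecord(Seq(r.seq), id=r.id, description=r.description) for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(bio_records, fh, "fasta")


def splice_exons(seq: NucSequence, exons: ExonSpec) -> NucSequence:
    """Concatenate exon substrings (1-based inclusive spans) into a spliced sequence."""
    parts: list[str] = []
    for i, (a, b) in enumerate(exons.spans):
        if b > len(seq.seq):
            raise ValueError(
                f"exon span {i + 1} ({a}, {b}) extends past the end of {seq.id!r} "
                f"(length {len(seq.seq)})"
            )
        parts.append(seq.seq[a - 1 : b])
    return NucSequence(id=f"{seq.id}|spliced", seq="".join(parts), description=seq.description)


def load_genetic_code(table_id: int = 1) -> GeneticCode:
    """Load one of the 25 built-in NCBI translation tables."""
    if table_id not in BUILTIN_TABLE_IDS:
        raise ValueError(
            f"unknown genetic code table {table_id}; available: {list(BUILTIN_TABLE_IDS)}"
        )
    table = CodonTable.unambiguous_dna_by_id[table_id]
    codon_to_aa = dict(table.forward_table)
    for stop in table.stop_codons:
        codon_to_aa[stop] = STOP
    return GeneticCode(
        table_id=table_id,
        name=table.names[0] if table.names else f"table{table_id}",
        codon_to_aa=codon_to_aa,
        start_codons=frozenset(table.start_codons),
        stop_codons=frozenset(table.stop_codons),
    )
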