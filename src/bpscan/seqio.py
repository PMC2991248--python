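"""Intron sequence I/O and the 3'-splice-site-anchored coordinate frame.

All intron sequences are handled 5'->3' on the transcribed strand and are
expected to end with the 3SS dinucleotide ``AG``.  Positions exchanged
between modules use the 3SS-anchored convention: the last intron nucleotide
is ``-1``, so the 3SS AG occupies ``-2, -1`` and a branch point "at -23"
means the branch adenosine is the 23rd nucleotide from the intron end.
This makes positions directly comparable to distances quoted for mapped
branch points (e.g. -229, -31).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

VALID_ALPHABET = frozenset("ACGTN")
PYRIMIDINES = frozenset("CT")
PURINES = frozenset("AG")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_sequence(raw: str, record_id: str = "<anonymous>") -> str:
    """Uppercase, map U->T, and validate the alphabet ({A,C,G,T,N})."""
    seq = raw.strip().upper().replace("U", "T")
    bad = set(seq) - VALID_ALPHABET
    if bad:
        raise ValueError(
            f"record {record_id!r}: non-IUPAC characters {sorted(bad)} in sequence"
        )
    return seq


@dataclass
class IntronRecord:
    """An intron sequence with identity and an optional genomic anchor.

    ``genome_coords`` is ``(chrom, start, end, strand)`` with BED semantics
    (0-based half-open, genomic plus-strand coordinates).
    """

    id: str
    sequence: str
    genome_coords: Optional[tuple] = None
    source: str = ""

    def __post_init__(self) -> None:
        self.sequence = normalize_sequence(self.sequence, self.id)
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def canonical_acceptor(self) -> bool:
        """True when the intron ends with the canonical 3SS AG."""
        return self.sequence.endswith("AG")

    def to_3ss(self, offset0: int) -> int:
        return to_3ss(len(self.sequence), offset0)

    def offset(self, pos3ss: int) -> int:
        return from_3ss(len(self.sequence), pos3ss)

    def at(self, pos3ss: int) -> str:
        """Nucleotide at a 3SS-anchored position."""
        return self.sequence[self.offset(pos3ss)]


def to_3ss(length: int, offset0: int) -> int:
    """Convert a 0-based offset into a (negative) 3SS-anchored position."""
    if not 0 <= offset0 < length:
        raise ValueError(f"offset {offset0} outside [0, {length})")
    return offset0 - length


def from_3ss(length: int, pos3ss: int) -> int:
    """Inverse of :func:`to_3ss`; the last nucleotide is position -1."""
    if not -length <= pos3ss <= -1:
        raise ValueError(f"position {pos3ss} outside [-{length}, -1]")
    return length + pos3ss


def read_fasta(path) -> list[IntronRecord]:
    """Read a multi-FASTA of intron sequences (ids split at first whitespace).

    Records not ending in AG are loaded but flagged (``canonical_acceptor``
    is False); a warning is emitted so non-canonical acceptors are visible
    without being fatal.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        intron = IntronRecord(id=rec.id, sequence=str(rec.seq), source=str(path))
        if not intron.canonical_acceptor:
            warnings.warn(
                f"record {intron.id!r} does not end in AG (non-canonical acceptor)",
                stacklevel=2,
            )
        records.append(intron)
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[IntronRecord], path) -> None:
    path = Path(path)
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seq_records, fh, "fasta-2line")


def read_intron_table(path, genome) -> list[IntronRecord]:
    """Read a BED-like intron table and extract sequences from a genome FASTA.

    Columns: chrom, start (0-based), end (half-open), name, [score,] strand.
    Minus-strand introns are reverse-complemented so the returned sequence is
    5'->3' of the transcript (ending at the 3SS).
    """
    import pyfaidx

    fasta = genome if isinstance(genome, pyfaidx.Fasta) else pyfaidx.Fasta(str(genome))
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 5:
                raise ValueError(f"{path}:{lineno}: need chrom,start,end,name,strand")
            chrom, start_s, end_s, name = cols[:4]
            strand = cols[5] if len(cols) >= 6 else cols[4]
            start, end = int(start_s), int(end_s)
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            if strand not in "+-":
                raise ValueError(f"{path}:{lineno}: missing/invalid strand {strand!r}")
            if chrom not in fasta:
                raise ValueError(f"{path}:{lineno}: unknown contig {chrom!r}")
            if end > len(fasta[chrom]):
                raise ValueError(
                    f"{path}:{lineno}: coordinate {end} outside contig {chrom!r}"
                )
            seq = str(fasta[chrom][start:end]).upper()
            if strand == "-":
                seq = reverse_complement(seq)
            records.append(
                IntronRecord(
                    id=name,
                    sequence=seq,
                    genome_coords=(chrom, start, end, strand),
                    source=str(path),
                )
            )
    if not records:
        raise ValueError(f"{path}: no intron rows found")
    return records


def read_truth_table(path) -> dict[str, list[int]]:
    """Read a TSV truth table (columns: intron_id, bp_pos_3ss) into a dict.

    Multiple rows per intron are allowed (introns with several mapped BPs).
    """
    truth: dict[str, list[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if cols[0] == "intron_id":  # header
                continue
            if len(cols) < 2:
                raise ValueError(f"{path}:{lineno}: need intron_id, bp_pos_3ss")
            pos = int(cols[1])
            if pos >= 0:
                raise ValueError(f"{path}:{lineno}: bp position must be negative")
            truth.setdefault(cols[0], []).append(pos)
    if not truth:
        raise ValueError(f"{path}: empty truth table")
    return truth
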