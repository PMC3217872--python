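"""Sequence records, FASTA I/O and nucleotide primitives.

All user-facing coordinates are 1-based inclusive, matching the residue/bp
numbering conventions used for SVMP domain boundaries (e.g. catalytic domain
residues 1-214, disintegrin residues 215-307).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from Bio.Seq import reverse_complement as _bio_revcomp
from Bio.Seq import translate as _bio_translate

NT_ALPHABET = frozenset("ACGTN")
# Standard amino-acid alphabet plus ambiguity/stop symbols produced by translation.
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYBZJUOX*")


class FastaFormatError(ValueError):
    """Raised when a FASTA file violates the format (reports the line number)."""


@dataclass(frozen=True)
class Region:
    """A named 1-based inclusive region on a sequence."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"region {self.name!r}: require 1 <= start <= end, got "
                f"({self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class SequenceRecord:
    """One nucleotide or protein sequence with identifier and optional regions."""

    id: str
    seq: str
    moltype: str = "nt"
    annotations: list[Region] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.moltype not in ("nt", "aa"):
            raise ValueError(f"moltype must be 'nt' or 'aa', got {self.moltype!r}")
        alphabet = NT_ALPHABET if self.moltype == "nt" else AA_ALPHABET
        bad = set(self.seq) - alphabet
        if bad:
            raise ValueError(
                f"record {self.id!r}: illegal {self.moltype} characters {sorted(bad)}"
            )
        for region in self.annotations:
            if region.end > len(self.seq):
                raise ValueError(
                    f"record {self.id!r}: annotation {region.name!r} ends at "
                    f"{region.end} beyond sequence length {len(self.seq)}"
                )

    def __len__(self) -> int:
        return len(self.seq)

    def subseq(self, start: int, end: int) -> str:
        """Extract the 1-based inclusive region [start, end]."""
        if not (1 <= start <= end <= len(self.seq)):
            raise ValueError(f"invalid region ({start}, {end}) for length {len(self.seq)}")
        return self.seq[start - 1 : end]


def _normalize_nt(raw: str) -> str:
    return raw.upper().replace("U", "T")


def read_fasta(path: str | os.PathLike, moltype: str = "nt") -> list[SequenceRecord]:
    """Read a (wrapped or unwrapped) multi-record FASTA file.

    Sequences are uppercased; for nucleotides U is mapped to T. Record order is
    preserved. Malformed headers or illegal characters raise
    :class:`FastaFormatError` naming the offending line; duplicate ids raise
    ``ValueError``.
    """
    if moltype not in ("nt", "aa"):
        raise ValueError(f"moltype must be 'nt' or 'aa', got {moltype!r}")
    alphabet = NT_ALPHABET if moltype == "nt" else AA_ALPHABET

    records: list[SequenceRecord] = []
    seen: set[str] = set()
    current_id: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        nonlocal current_id, chunks
        if current_id is not None:
            records.append(SequenceRecord(current_id, "".join(chunks), moltype))
            chunks = []

    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                if not header:
                    raise FastaFormatError(f"{path}: empty FASTA header at line {lineno}")
                current_id = header.split()[0]
                if current_id in seen:
                    raise ValueError(f"{path}: duplicate id {current_id!r} at line {lineno}")
                seen.add(current_id)
            else:
                if current_id is None:
                    raise FastaFormatError(
                        f"{path}: sequence data before any header at line {lineno}"
                    )
                piece = line.strip().upper()
                if moltype == "nt":
                    piece = piece.replace("U", "T")
                bad = set(piece) - alphabet
                if bad:
                    raise FastaFormatError(
                        f"{path}: illegal {moltype} characters {sorted(bad)} at line {lineno}"
                    )
                chunks.append(piece)
    flush()
    return records


def write_fasta(records: list[SequenceRecord], path: str | os.PathLike, width: int = 70) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width`` characters."""
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                handle.write(rec.seq[i : i + width] + "\n")


def write_region_table(records: list[SequenceRecord], path: str | os.PathLike) -> None:
    """Write all region annotations as a TSV: id, name, start, end."""
    with open(path, "w") as handle:
        handle.write("id\tname\tstart\tend\n")
        for rec in records:
            for region in rec.annotations:
                handle.write(f"{rec.id}\t{region.name}\t{region.start}\t{region.end}\n")


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement; N maps to N."""
    bad = set(seq) - NT_ALPHABET
    if bad:
        raise TypeError(f"reverse_complement requires nucleotides, got {sorted(bad)}")
    return _bio_revcomp(seq)


def translate(seq: str, frame: int = 0) -> str:
    """Standard-code translation of complete codons starting at ``frame``.

    Stops are rendered as ``*``; a trailing partial codon is dropped; codons
    containing N translate to ``X``.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    bad = set(seq) - NT_ALPHABET
    if bad:
        raise TypeError(f"translate requires nucleotides, got {sorted(bad)}")
    coding = seq[frame:]
    coding = coding[: len(coding) - len(coding) % 3]
    if not coding:
        return ""
    aa = str(_bio_translate(coding))
    if "N" in coding:
        # any N makes the codon render X, even when the standard code would
        # resolve the ambiguity (e.g. ACN)
        aa = "".join(
            "X" if "N" in coding[3 * k : 3 * k + 3] else c for k, c in enumerate(aa)
        )
    return aa


def extract_3utr(record: SequenceRecord, cds_start: int) -> tuple[int, int]:
    """Locate the 3'UTR: everything after the first in-frame stop codon.

    Returns the 1-based inclusive region ``(start, end)``; when the stop codon
    is terminal the region is empty, signalled by ``start == end + 1``.
    Raises ``ValueError`` when no in-frame stop exists downstream of
    ``cds_start``.
    """
    if record.moltype != "nt":
        raise TypeError("extract_3utr requires a nucleotide record")
    if not (1 <= cds_start <= len(record.seq)):
        raise ValueError(f"cds_start {cds_start} outside sequence of length {len(record.seq)}")
    seq = record.seq
    for pos in range(cds_start - 1, len(seq) - 2, 3):
        codon = seq[pos : pos + 3]
        if codon in ("TAA", "TAG", "TGA"):
            return (pos + 4, len(seq))
    raise ValueError(f"record {record.id!r}: no stop codon in frame from {cds_start}")
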