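"""Sequence I/O and core nucleotide-string utilities.

Readers/writers for FASTA, FASTQ (Sanger Phred+33), and GFF3 exon
annotation, plus the small string primitives (reverse complement, stop
codon scan, IUPAC matching) that every other module builds on.

Coordinates are 0-based half-open internally; user-facing reports are
1-based inclusive.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "AlphabetError",
    "FormatError",
    "PairingError",
    "NucleotideSequence",
    "QualifiedRead",
    "ExonAnnotation",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "read_fastq_pairs",
    "write_fastq",
    "read_gff3_exons",
    "reverse_complement",
    "stop_codons_by_frame",
    "iupac_match",
]

STRICT_ALPHABET = frozenset("ACGT")
REFERENCE_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# IUPAC nucleotide ambiguity codes -> the set of bases each one admits.
IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

MAX_PHRED = 93


class AlphabetError(ValueError):
    """A sequence contains characters outside the permitted alphabet."""


class FormatError(ValueError):
    """A sequence file violates its format contract."""


class PairingError(ValueError):
    """Paired FASTQ files cannot be matched record-for-record."""


@dataclass(frozen=True)
class NucleotideSequence:
    """A named DNA sequence over {A,C,G,T} (N allowed only in references)."""

    name: str
    seq: str
    allow_n: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not self.seq:
            raise FormatError(f"record {self.name!r}: empty sequence")
        alphabet = REFERENCE_ALPHABET if self.allow_n else STRICT_ALPHABET
        bad = set(self.seq) - alphabet
        if bad:
            raise AlphabetError(
                f"record {self.name!r}: invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class QualifiedRead:
    """A sequencing read with per-base Sanger Phred (+33) quality scores."""

    name: str
    seq: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "quals", tuple(self.quals))
        if len(self.quals) != len(self.seq):
            raise FormatError(
                f"read {self.name!r}: {len(self.seq)} bases but "
                f"{len(self.quals)} quality scores"
            )
        if any(q < 0 or q > MAX_PHRED for q in self.quals):
            raise FormatError(f"read {self.name!r}: Phred score outside [0, {MAX_PHRED}]")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ExonAnnotation:
    """Ordered, non-overlapping exon intervals of one transcript.

    Intervals are 0-based half-open on the reference strand.
    """

    contig: str
    exons: tuple[tuple[int, int], ...]
    strand: str = "+"

    def __post_init__(self) -> None:
        object.__setattr__(self, "exons", tuple(tuple(e) for e in self.exons))
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        prev_end = -1
        for start, end in self.exons:
            if start >= end:
                raise ValueError(f"empty/inverted exon interval ({start}, {end})")
            if start < prev_end:
                raise ValueError("exon intervals must be sorted and non-overlapping")
            prev_end = end

    def contains(self, start: int, end: int) -> bool:
        """True if [start, end) lies entirely within a single exon."""
        return any(s <= start and end <= e for s, e in self.exons)


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path, allow_n: bool = True) -> list[NucleotideSequence]:
    """Read a FASTA file into uppercased records, order preserved.

    ``allow_n`` permits N in reference inputs; designed outputs never
    carry N and should be re-validated with ``allow_n=False``.
    """
    records: list[NucleotideSequence] = []
    with _open_text(path) as handle:
        first = handle.read(1)
        if first != ">":
            raise FormatError(f"{path}: line 1: FASTA must start with '>'")
        handle.seek(0)
        for i, rec in enumerate(SeqIO.parse(handle, "fasta"), start=1):
            seq = str(rec.seq).upper()
            if not seq:
                raise FormatError(f"{path}: record {i} ({rec.id!r}) is empty")
            try:
                records.append(NucleotideSequence(rec.id, seq, allow_n=allow_n))
            except AlphabetError as exc:
                raise FormatError(f"{path}: record {i}: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(path: str | Path, records: Iterable[NucleotideSequence],
                width: int = 70) -> None:
    with _open_text(path, "wt") as out:
        for rec in records:
            out.write(f">{rec.name}\n")
            for i in range(0, len(rec.seq), width):
                out.write(rec.seq[i:i + width] + "\n")


def read_fastq(path: str | Path) -> list[QualifiedRead]:
    """Read a Sanger Phred+33 FASTQ file."""
    reads = []
    with _open_text(path) as handle:
        try:
            for rec in SeqIO.parse(handle, "fastq-sanger"):
                reads.append(
                    QualifiedRead(
                        rec.id,
                        str(rec.seq).upper(),
                        tuple(rec.letter_annotations["phred_quality"]),
                    )
                )
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    return reads


def read_fastq_pairs(
    path_r1: str | Path, path_r2: str | Path
) -> list[tuple[QualifiedRead, QualifiedRead]]:
    """Read paired FASTQ files, matching records by order.

    Mate names may differ by a trailing /1 and /2.
    """
    r1 = read_fastq(path_r1)
    r2 = read_fastq(path_r2)
    if len(r1) != len(r2):
        raise PairingError(
            f"{path_r1} has {len(r1)} records but {path_r2} has {len(r2)}"
        )
    return list(zip(r1, r2))


def write_fastq(path: str | Path, reads: Iterable[QualifiedRead]) -> None:
    with _open_text(path, "wt") as out:
        for read in reads:
            qual = "".join(chr(q + 33) for q in read.quals)
            out.write(f"@{read.name}\n{read.seq}\n+\n{qual}\n")


def _gff3_attributes(col9: str) -> dict[str, str]:
    attrs = {}
    for item in col9.strip().split(";"):
        if "=" in item:
            key, value = item.split("=", 1)
            attrs[key.strip()] = value.strip()
    return attrs


def read_gff3_exons(path: str | Path) -> list[ExonAnnotation]:
    """Collect exon features from a GFF3 file, one annotation per parent.

    Only ``exon`` rows are consumed; attribute parsing is limited to
    Parent/ID. Exons are grouped by (contig, Parent-or-ID) and sorted.
    """
    grouped: dict[tuple[str, str], dict] = {}
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}: line {lineno}: expected 9 columns")
            contig, _, ftype, start, end, _, strand, _, attrs_col = cols
            if ftype.lower() != "exon":
                continue
            attrs = _gff3_attributes(attrs_col)
            parent = attrs.get("Parent") or attrs.get("ID") or f"line{lineno}"
            key = (contig, parent)
            entry = grouped.setdefault(key, {"strand": strand, "exons": []})
            # GFF3 is 1-based inclusive; convert to 0-based half-open.
            entry["exons"].append((int(start) - 1, int(end)))
    annotations = []
    for (contig, _parent), entry in grouped.items():
        exons = tuple(sorted(entry["exons"]))
        strand = entry["strand"] if entry["strand"] in "+-" else "+"
        annotations.append(ExonAnnotation(contig, exons, strand))
    return annotations


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement (N self-complements)."""
    bad = set(seq) - REFERENCE_ALPHABET
    if bad:
        raise AlphabetError(f"invalid characters {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


def stop_codons_by_frame(seq: str) -> tuple[bool, bool, bool]:
    """Whether any stop codon occurs in each reading frame of one strand.

    Frames 0/1/2 are scanned as non-overlapping codons from each offset.
    """
    if len(seq) < 3:
        raise ValueError(f"sequence of length {len(seq)} has no complete codon")
    flags = []
    for frame in range(3):
        codons = (seq[i:i + 3] for i in range(frame, len(seq) - 2, 3))
        flags.append(any(c in STOP_CODONS for c in codons))
    return tuple(flags)  # type: ignore[return-value]


def iupac_match(pattern: str, seq: str) -> bool:
    """Positionwise IUPAC set-membership match of equal-length strings."""
    if len(pattern) != len(seq):
        raise ValueError(
            f"pattern length {len(pattern)} != sequence length {len(seq)}"
        )
    for code, base in zip(pattern, seq):
        try:
            allowed = IUPAC_CODES[code]
        except KeyError:
            raise ValueError(f"invalid IUPAC code {code!r}") from None
        if base not in allowed:
            return False
    return True
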