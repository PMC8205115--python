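"""Streaming read input and basic sequence utilities.

Amplicon reads arrive as per-sample FASTQ (optionally gzip-compressed) or
FASTA files. FASTA is the fast path: it carries no qualities and always
passes the optional quality pre-filter. Parsing is delegated to Biopython;
this module adds the toolkit's record type, the quality filter and the
strand utilities the motif matcher needs.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

from Bio import SeqIO

from .errors import ReadParseError, ValidationError

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: extensions recognised by directory walking, in match order
SEQ_EXTENSIONS = (
    ".fastq.gz", ".fq.gz", ".fastq", ".fq",
    ".fasta.gz", ".fa.gz", ".fasta", ".fa", ".fna",
)


@dataclass
class ReadRecord:
    """One sequencing read.

    ``qualities`` is None for FASTA input; when present its length equals the
    sequence length (enforced by the FASTQ parser).
    """

    read_id: str
    sequence: str
    qualities: Optional[Sequence[int]] = None
    mate: str = "R1"
    description: str = field(default="", repr=False)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()


def reverse_complement(seq: str) -> str:
    """Reverse-complement a DNA string over A/C/G/T/N (N maps to N).

    Raises ValidationError on any other character.
    """
    seq = seq.upper()
    if not set(seq) <= DNA_ALPHABET:
        bad = sorted(set(seq) - DNA_ALPHABET)
        raise ValidationError(f"invalid DNA character(s) {bad} in sequence")
    return seq.translate(_COMPLEMENT)[::-1]


def _open_maybe_gzip(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def sniff_format(path: str | os.PathLike) -> str:
    """Return 'fastq' or 'fasta' from the file extension."""
    name = str(path)
    if name.endswith(".gz"):
        name = name[:-3]
    ext = Path(name).suffix.lower()
    if ext in (".fastq", ".fq"):
        return "fastq"
    if ext in (".fasta", ".fa", ".fna"):
        return "fasta"
    raise ValidationError(f"cannot infer sequence format from filename {path!r}")


def stream_reads(
    path: str | os.PathLike,
    fmt: Optional[str] = None,
    mate: str = "R1",
) -> Iterator[ReadRecord]:
    """Yield ReadRecords from a FASTQ or FASTA file in file order.

    Malformed records raise ReadParseError carrying the index of the record
    being parsed when the underlying parser failed.
    """
    path = Path(path)
    fmt = fmt or sniff_format(path)
    n = 0
    with _open_maybe_gzip(path) as handle:
        try:
            for rec in SeqIO.parse(handle, fmt):
                quals = None
                if fmt == "fastq":
                    quals = rec.letter_annotations["phred_quality"]
                yield ReadRecord(
                    read_id=rec.id,
                    sequence=str(rec.seq),
                    qualities=quals,
                    mate=mate,
                    description=rec.description,
                )
                n += 1
        except ValueError as exc:
            raise ReadParseError(
                f"{path}: malformed {fmt} record at index {n}: {exc}"
            ) from exc


def mean_quality(read: ReadRecord) -> Optional[float]:
    """Arithmetic mean Phred quality; None for quality-less (FASTA) reads."""
    if read.qualities is None:
        return None
    return float(sum(read.qualities)) / len(read.qualities)


def quality_pass(read: ReadRecord, min_mean_q: Optional[float]) -> bool:
    """True iff the read passes the optional mean-quality pre-filter.

    Filtering disabled (min_mean_q None) or quality-less FASTA input always
    passes.
    """
    if min_mean_q is None:
        return True
    mq = mean_quality(read)
    if mq is None:
        return True
    return mq >= min_mean_q


def find_sequence_files(directory: str | os.PathLike) -> list[Path]:
    """All recognised sequence files directly inside ``directory``, sorted."""
    directory = Path(directory)
    out = [
        p
        for p in sorted(directory.iterdir())
        if p.is_file() and str(p).lower().endswith(SEQ_EXTENSIONS)
    ]
    return out
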