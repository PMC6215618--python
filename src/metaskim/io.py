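"""FASTQ/FASTA reading and writing.

Thin wrappers over :mod:`Bio.SeqIO` that speak :class:`SequenceRecord`,
accept gzip-compressed input transparently, and turn truncated 4-line FASTQ
blocks into errors that name the failing record index. Truth labels are
recovered from the id token on read (see :mod:`metaskim.records`).
"""

from __future__ import annotations

import gzip
import os
from typing import IO, Iterable, Iterator, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import SequenceRecord, with_truth_from_id

PathLike = Union[str, os.PathLike]

#: Constant Phred-40 quality written for simulated reads.
DEFAULT_QUALITY_CHAR = "I"


class FastqFormatError(ValueError):
    """Malformed FASTQ input (e.g. a truncated 4-line block)."""


def _open_text(path: PathLike, mode: str = "rt") -> IO[str]:
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def sniff_format(path: PathLike) -> str:
    """Guess 'fastq' or 'fasta' from the file name, falling back to content."""
    name = os.fspath(path)
    if name.endswith(".gz"):
        name = name[:-3]
    ext = os.path.splitext(name)[1].lower()
    if ext in {".fq", ".fastq"}:
        return "fastq"
    if ext in {".fa", ".fasta", ".fna"}:
        return "fasta"
    with _open_text(path) as fh:
        first = fh.read(1)
    return "fastq" if first == "@" else "fasta"


def read_records(path: PathLike, fmt: str | None = None) -> Iterator[SequenceRecord]:
    """Stream reads from a FASTQ or FASTA file (gzip accepted)."""
    fmt = fmt or sniff_format(path)
    with _open_text(path) as fh:
        index = 0
        try:
            for rec in SeqIO.parse(fh, fmt):
                yield with_truth_from_id(
                    SequenceRecord(
                        id=rec.id,
                        bases=str(rec.seq),
                        quality=_quality_string(rec),
                    )
                )
                index += 1
        except ValueError as exc:
            raise FastqFormatError(f"malformed {fmt} record at index {index}: {exc}") from exc


def _quality_string(rec: SeqRecord) -> str | None:
    phred = rec.letter_annotations.get("phred_quality")
    if phred is None:
        return None
    return "".join(chr(q + 33) for q in phred)


def _to_seqrecord(record: SequenceRecord, fmt: str) -> SeqRecord:
    out = SeqRecord(Seq(record.bases), id=record.id, description="")
    if fmt == "fastq":
        quality = record.quality or DEFAULT_QUALITY_CHAR * len(record.bases)
        out.letter_annotations["phred_quality"] = [ord(c) - 33 for c in quality]
    return out


def write_records(
    records: Iterable[SequenceRecord], path: PathLike, fmt: str | None = None
) -> int:
    """Write reads as FASTQ (4-line) or FASTA; returns the record count."""
    fmt = fmt or sniff_format_for_output(path)
    with _open_text(path, "wt") as fh:
        return SeqIO.write((_to_seqrecord(r, fmt) for r in records), fh, fmt)


def sniff_format_for_output(path: PathLike) -> str:
    name = os.fspath(path)
    if name.endswith(".gz"):
        name = name[:-3]
    ext = os.path.splitext(name)[1].lower()
    return "fasta" if ext in {".fa", ".fasta", ".fna"} else "fastq"


def write_truth_table(records: Iterable[SequenceRecord], path: PathLike) -> int:
    """Write a tab-separated (read_id, strain) truth table; returns row count."""
    n = 0
    with _open_text(path, "wt") as fh:
        fh.write("read_id\tstrain\n")
        for rec in records:
            fh.write(f"{rec.id}\t{rec.truth_label or ''}\n")
            n += 1
    return n
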