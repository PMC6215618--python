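"""Read records and the truth-label token.

A :class:`SequenceRecord` is one sequencing read. Simulated reads carry the
name of their source strain as a machine-parsable ``key=value`` token
appended to the read id with ``|`` (the strain name is percent-encoded so
the id stays whitespace-free and survives FASTQ round-trips through any
standard tool). Example id::

    r0000042|strain=Escherichia%20coli%20KCTC%202571
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional
from urllib.parse import quote, unquote

TRUTH_TOKEN_SEP = "|"
TRUTH_TOKEN_KEY = "strain="


class TruthTokenError(ValueError):
    """The read id carries no parsable source-strain token."""


@dataclass(frozen=True)
class SequenceRecord:
    """One read: id, bases, optional quality, optional truth strain label."""

    id: str
    bases: str
    quality: Optional[str] = None
    truth_label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError("bases must be non-empty")
        if self.quality is not None and len(self.quality) != len(self.bases):
            raise ValueError(
                f"quality length {len(self.quality)} != bases length {len(self.bases)}"
            )

    def __len__(self) -> int:
        return len(self.bases)


def encode_truth_id(read_id: str, strain: str) -> str:
    """Append the source-strain token to a bare read id."""
    return f"{read_id}{TRUTH_TOKEN_SEP}{TRUTH_TOKEN_KEY}{quote(strain)}"


def parse_truth_label(read_id: str) -> str:
    """Extract the source strain from a token-bearing read id.

    Raises
    ------
    TruthTokenError
        If the id carries no ``|strain=`` token.
    """
    sep = TRUTH_TOKEN_SEP + TRUTH_TOKEN_KEY
    head, found, tail = read_id.rpartition(sep)
    if not found or not tail:
        raise TruthTokenError(f"no truth token in read id {read_id!r}")
    return unquote(tail)


def with_truth_from_id(record: SequenceRecord) -> SequenceRecord:
    """Return a copy whose ``truth_label`` is parsed from the id token.

    Records whose id carries no token come back unchanged.
    """
    if record.truth_label is not None:
        return record
    try:
        label = parse_truth_label(record.id)
    except TruthTokenError:
        return record
    return SequenceRecord(record.id, record.bases, record.quality, label)
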