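"""Read-to-strain assignment and the per-strain hit table.

The relative-abundance proxy for a mock community is the hit ratio: each
strain's hit count n_i over the sum s of all strains' hit counts. This
module builds that table from any classifier — the truth classifier that
reads the strain token simulated reads carry, or an exact k-mer containment
classifier that stands in for a BLAST search against per-strain reference
genome databases at desk scale.

Hit counting is binary per read per strain: a read contributes at most one
hit to each strain it matches, reads matching nothing contribute nothing,
and a read matching several strains (e.g. two near-identical genomes) counts
once for each. Ratio denominators ignore reference genome size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .records import SequenceRecord, TruthTokenError, parse_truth_label

Classifier = Callable[[SequenceRecord], set[str]]

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lower case


@dataclass(frozen=True)
class HitTable:
    """Per-strain hit counts n_i, their sum s, and ratios n_i / s."""

    strains: tuple[str, ...]
    hits: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.strains) != len(self.hits):
            raise ValueError("strains and hits must align")
        if any(h < 0 for h in self.hits):
            raise ValueError("hit counts must be non-negative")

    @property
    def total(self) -> int:
        return sum(self.hits)

    @property
    def ratios(self) -> Optional[tuple[float, ...]]:
        """n_i / s, or None when s = 0 (the undefined-ratio sentinel)."""
        s = self.total
        if s == 0:
            return None
        return tuple(h / s for h in self.hits)

    def ratio_of(self, strain: str) -> float:
        ratios = self.ratios
        if ratios is None:
            raise ZeroDivisionError("hit table is empty (s = 0)")
        return ratios[self.strains.index(strain)]

    def __add__(self, other: "HitTable") -> "HitTable":
        if self.strains != other.strains:
            raise ValueError("strain rosters differ")
        return HitTable(self.strains, tuple(a + b for a, b in zip(self.hits, other.hits)))

    def to_frame(self) -> pd.DataFrame:
        ratios = self.ratios
        return pd.DataFrame(
            {
                "strain": self.strains,
                "hits": self.hits,
                "ratio": ratios if ratios is not None else [float("nan")] * len(self.hits),
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "HitTable":
        frame = pd.read_csv(path, sep="\t")
        return cls(tuple(frame["strain"].astype(str)), tuple(int(h) for h in frame["hits"]))

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "HitTable":
        return cls(tuple(counts), tuple(counts.values()))

    @classmethod
    def from_labels(cls, labels: Iterable[str], strains: Sequence[str]) -> "HitTable":
        """Tally single-label assignments (e.g. truth labels) over a roster."""
        index = {s: i for i, s in enumerate(strains)}
        hits = [0] * len(index)
        for label in labels:
            i = index.get(label)
            if i is not None:
                hits[i] += 1
        return cls(tuple(strains), tuple(hits))


def classify_truth(record: SequenceRecord) -> set[str]:
    """The singleton source strain encoded in a simulated read.

    Raises :class:`TruthTokenError` when the record carries no truth label.
    """
    if record.truth_label is not None:
        return {record.truth_label}
    return {parse_truth_label(record.id)}


def _kmer_codes(bases: str, k: int) -> np.ndarray:
    """Canonical (strand-minimum) integer codes of all valid k-mers."""
    arr = _CODE[np.frombuffer(bases.encode("ascii"), dtype=np.uint8)]
    if arr.size < k:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(arr, k).astype(np.int64)
    valid = ~(win > 3).any(axis=1)
    win = win[valid]
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    fwd = win @ powers
    rev = (3 - win) @ powers[::-1]
    return np.minimum(fwd, rev)


class ReferenceSet:
    """Per-strain genomes indexed by exact k-mers, a desk-scale BLAST stand-in.

    A read "hits" a strain when it shares at least ``min_shared`` exact
    k-mers (either strand) with that strain's genome — a cheap proxy for a
    low-E-value alignment hit on ~100 b reads. Defaults: k=21, min_shared=2.
    """

    def __init__(self, genomes: Mapping[str, str], k: int = 21, min_shared: int = 2):
        if k < 11:
            raise ValueError("k must be >= 11")
        if min_shared < 1:
            raise ValueError("min_shared must be >= 1")
        short = [name for name, g in genomes.items() if len(g) < k]
        if short:
            raise ValueError(f"genome shorter than k = {k}: {short}")
        self.k = k
        self.min_shared = min_shared
        self.strains = tuple(genomes)
        index: dict[int, int] = {}
        for bit, (name, genome) in enumerate(genomes.items()):
            mask = 1 << bit
            for code in _kmer_codes(genome, k).tolist():
                index[code] = index.get(code, 0) | mask
        self._index = index

    def classify(self, record: SequenceRecord) -> set[str]:
        """Every strain sharing >= min_shared exact k-mers with the read."""
        if len(record.bases) < self.k:
            raise ValueError(f"read shorter than k = {self.k}")
        shared = [0] * len(self.strains)
        for code in _kmer_codes(record.bases, self.k).tolist():
            mask = self._index.get(code, 0)
            bit = 0
            while mask:
                if mask & 1:
                    shared[bit] += 1
                mask >>= 1
                bit += 1
        return {s for s, c in zip(self.strains, shared) if c >= self.min_shared}


def classify_kmer(record: SequenceRecord, refs: ReferenceSet) -> set[str]:
    return refs.classify(record)


def count_hits(
    records: Iterable[SequenceRecord],
    classifier: Classifier,
    strains: Sequence[str],
) -> HitTable:
    """Tally binary per-read, per-strain hits over a roster into a HitTable."""
    if not strains:
        raise ValueError("empty strain roster")
    index = {s: i for i, s in enumerate(strains)}
    hits = [0] * len(index)
    for record in records:
        for strain in classifier(record):
            i = index.get(strain)
            if i is not None:
                hits[i] += 1
    return HitTable(tuple(strains), tuple(hits))
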