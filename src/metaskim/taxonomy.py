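"""Original-vs-sample comparison of taxonomic annotation tables.

An annotation service (MG-RAST-style) reduces a read set to rows of
(taxon, rank, count). The questions a small-sample preview can answer are
comparative: which taxon is annotated most at a rank, does the sample's
answer match the original's, and how many taxa survive an abundance
threshold (the 1% rule that suppresses over-/mis-annotation)?

Phylum and class lists are treated independently: rank totals are computed
per rank, and taxon names match by exact string equality after trimming —
"Actinobacteria (class)" at rank class and "Actinobacteria" at rank phylum
are distinct names, as annotation services print them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

RANKS = ("phylum", "class")


class TaxonCountTable:
    """Rows of (taxon, rank, count) with unique taxon names within a rank."""

    def __init__(self, frame: pd.DataFrame):
        required = {"taxon", "rank", "count"}
        if not required.issubset(frame.columns):
            raise ValueError(f"need columns {sorted(required)}")
        frame = frame.loc[:, ["taxon", "rank", "count"]].copy()
        frame["taxon"] = frame["taxon"].astype(str).str.strip()
        frame["rank"] = frame["rank"].astype(str).str.strip()
        frame["count"] = frame["count"].astype(int)
        if (frame["count"] < 0).any():
            raise ValueError("counts must be non-negative")
        if frame.duplicated(subset=["rank", "taxon"]).any():
            dupes = frame[frame.duplicated(subset=["rank", "taxon"])]["taxon"].tolist()
            raise ValueError(f"duplicate taxon names within a rank: {dupes}")
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, str, int]]) -> "TaxonCountTable":
        return cls(pd.DataFrame(rows, columns=["taxon", "rank", "count"]))

    @classmethod
    def from_tsv(cls, path) -> "TaxonCountTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def at_rank(self, rank: str) -> pd.DataFrame:
        return self.frame[self.frame["rank"] == rank]

    def total(self, rank: str) -> int:
        return int(self.at_rank(rank)["count"].sum())

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class PairComparison:
    """Most-annotated taxon at one rank: original vs sample of one project."""

    project_id: str
    rank: str
    original_top: str
    sample_top: str

    @property
    def match(self) -> bool:
        return self.original_top.strip() == self.sample_top.strip()


def most_annotated(table: TaxonCountTable, rank: str) -> str:
    """The taxon with the largest count at `rank`; ties break lexicographically."""
    sub = table.at_rank(rank)
    if sub.empty:
        raise ValueError(f"no rows at rank {rank!r}")
    best = sub.sort_values(["count", "taxon"], ascending=[False, True])
    return str(best.iloc[0]["taxon"])


def compare_pair(
    original: TaxonCountTable, sample: TaxonCountTable, rank: str, project_id: str = ""
) -> PairComparison:
    return PairComparison(
        project_id=project_id,
        rank=rank,
        original_top=most_annotated(original, rank),
        sample_top=most_annotated(sample, rank),
    )


def match_count(pairs: Sequence[PairComparison]) -> int:
    """How many original/sample pairs agree on the most-annotated taxon."""
    return sum(1 for p in pairs if p.match)


def diversity_count(table: TaxonCountTable, rank: str, threshold: float = 0.0) -> int:
    """Number of taxa at `rank` with count / rank-total >= threshold.

    Taxa with *less than* the threshold share are ignored (a share of exactly
    1% survives a 1% threshold). Threshold 0 counts all taxa with count > 0.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    sub = table.at_rank(rank)
    total = sub["count"].sum()
    if total == 0:
        return 0
    share = sub["count"] / total
    return int(((share >= threshold) & (sub["count"] > 0)).sum())


def pairs_to_frame(pairs: Sequence[PairComparison]) -> pd.DataFrame:
    """Tabulate comparisons with one row per project and rank."""
    return pd.DataFrame(
        [
            {
                "project_id": p.project_id,
                "rank": p.rank,
                "original_top": p.original_top,
                "sample_top": p.sample_top,
                "match": p.match,
            }
            for p in pairs
        ]
    )
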