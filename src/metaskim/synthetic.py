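"""Mock-community simulation.

Builds a defined mixture of bacterial strains entirely in silico: i.i.d.
random genomes with controlled GC content, and error-free single-end shotgun
reads drawn from them at specified proportions, so the true composition of
every read pool is known a priori. The default community mirrors a published
ten-strain HiSeq benchmark: proportions are the strains' full-run BLAST hit
ratios and GC targets are their genomic GC values, whose weighted mean puts
the pool near 53-54% GC.

Genomes are plain i.i.d. base strings, not repeat-structured; the downstream
statistics depend only on which strain each read came from, not on genome
realism. Reads are error-free by default (an optional uniform substitution
rate exists for stressing the k-mer classifier).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Optional, Sequence

import numpy as np

from . import datasets
from .records import SequenceRecord, encode_truth_id
from .taxonomy import TaxonCountTable

PROPORTION_TOL = 1e-6

_BASES = np.frombuffer(b"GCAT", dtype=np.uint8)


@dataclass(frozen=True)
class StrainProfile:
    """One community member: name, abundance proportion, GC target, genome length."""

    name: str
    proportion: float
    gc_target: float
    genome_length: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.proportion <= 1.0:
            raise ValueError(f"proportion {self.proportion} outside [0, 1]")
        if not 0.0 <= self.gc_target <= 1.0:
            raise ValueError(f"gc_target {self.gc_target} outside [0, 1]")
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")


def validate_profiles(profiles: Sequence[StrainProfile], read_length: int | None = None) -> None:
    if not profiles:
        raise ValueError("empty profile list")
    total = math.fsum(p.proportion for p in profiles)
    if abs(total - 1.0) > PROPORTION_TOL:
        raise ValueError(f"proportions sum to {total!r}, not 1")
    if read_length is not None:
        short = [p.name for p in profiles if p.genome_length < read_length]
        if short:
            raise ValueError(f"genome shorter than read length {read_length}: {short}")


def default_mock_community(genome_length: int = 100_000) -> list[StrainProfile]:
    """The ten-strain benchmark community.

    Proportions are exact hit-count fractions (they sum to 1 in rational
    arithmetic; the four-decimal printed ratios sum to 1.0001 and are not
    used). ``genome_length`` is uniform and deliberately modest — abundance
    ratios, GC and dominance statistics do not depend on genome size.
    """
    total = datasets.MOCK_COMMUNITY_TOTAL_HITS
    return [
        StrainProfile(
            name=name,
            proportion=hits / total,
            gc_target=datasets.MOCK_COMMUNITY_GC[name],
            genome_length=genome_length,
        )
        for name, hits in datasets.MOCK_COMMUNITY_HITS.items()
    ]


def load_profiles(path) -> list[StrainProfile]:
    """Read a tab-separated community profile: name, proportion, gc_target, genome_length."""
    profiles = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("name\t"):
                continue
            name, prop, gc, length = line.split("\t")
            profiles.append(StrainProfile(name, float(prop), float(gc), int(length)))
    return profiles


def save_profiles(profiles: Sequence[StrainProfile], path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tproportion\tgc_target\tgenome_length\n")
        for p in profiles:
            fh.write(f"{p.name}\t{p.proportion!r}\t{p.gc_target!r}\t{p.genome_length}\n")


def generate_genome(length: int, gc_target: float, seed: int) -> str:
    """An i.i.d. genome of `length` bases with P(G)=P(C)=gc_target/2, P(A)=P(T).

    Reproducible for a fixed seed.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0.0 <= gc_target <= 1.0:
        raise ValueError(f"gc_target {gc_target} outside [0, 1]")
    rng = np.random.default_rng(seed)
    probs = [gc_target / 2, gc_target / 2, (1 - gc_target) / 2, (1 - gc_target) / 2]
    codes = rng.choice(4, size=length, p=probs)
    return _BASES[codes].tobytes().decode("ascii")


def simulate_reads(
    profiles: Sequence[StrainProfile],
    n_reads: int,
    read_length: int = datasets.READ_LENGTH,
    seed: int = 0,
    error_rate: float = 0.0,
    genomes: Optional[dict[str, str]] = None,
) -> Iterator[SequenceRecord]:
    """Stream `n_reads` labelled single-end shotgun reads from the community.

    Each read's source strain is multinomial with the profile proportions and
    its start position is uniform on the strain genome. The source strain is
    stored in ``truth_label`` and encoded in the read id, so samples written
    to FASTQ remain classifiable after round-tripping. Output is
    byte-identical for identical arguments.

    Parameters
    ----------
    error_rate
        Per-base uniform substitution probability (default 0: error-free).
    genomes
        Pre-generated genomes keyed by strain name; generated from per-strain
        streams of `seed` when omitted.
    """
    validate_profiles(profiles, read_length)
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if genomes is None:
        genomes = community_genomes(profiles, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, n_reads, read_length]))
    props = np.array([p.proportion for p in profiles], dtype=float)
    props = props / props.sum()  # remove <=1e-6 float slack
    strain_idx = rng.choice(len(profiles), size=n_reads, p=props)
    max_start = np.array([p.genome_length - read_length for p in profiles])
    starts = rng.integers(0, max_start[strain_idx] + 1)
    width = len(str(max(n_reads - 1, 1)))
    for i in range(n_reads):
        prof = profiles[strain_idx[i]]
        start = int(starts[i])
        bases = genomes[prof.name][start : start + read_length]
        if error_rate > 0.0:
            bases = _substitute(bases, error_rate, rng)
        yield SequenceRecord(
            id=encode_truth_id(f"r{i:0{width}d}", prof.name),
            bases=bases,
            quality=None,
            truth_label=prof.name,
        )


def community_genomes(profiles: Sequence[StrainProfile], seed: int) -> dict[str, str]:
    """Deterministic per-strain genomes derived from one community seed."""
    children = np.random.SeedSequence([seed]).spawn(len(profiles))
    return {
        p.name: generate_genome(p.genome_length, p.gc_target, child)
        for p, child in zip(profiles, children)
    }


def _substitute(bases: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(bases.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def generate_taxon_table(
    n_taxa: int,
    dominant_share: float,
    total_hits: int,
    seed: int = 0,
    rank: str = "phylum",
    dominant_name: str | None = None,
) -> TaxonCountTable:
    """An annotation-service-style taxon count table with one dominant taxon.

    The dominant taxon gets ``ceil(dominant_share * total_hits)`` hits; the
    remainder is split over the other taxa by a Dirichlet draw with Zipf-like
    concentrations (a long tail of rare taxa). Counts sum to ``total_hits``
    and the dominant taxon's count is a strict maximum.
    """
    if n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    if not 0.0 < dominant_share <= 1.0:
        raise ValueError("dominant_share must be in (0, 1]")
    dominant = math.ceil(dominant_share * total_hits)
    if dominant < 1:
        raise ValueError("dominant_share * total_hits must be >= 1")
    dominant_name = dominant_name or "taxon_01"
    if n_taxa == 1:
        return TaxonCountTable.from_rows([(dominant_name, rank, total_hits)])
    rest = total_hits - dominant
    rng = np.random.default_rng(seed)
    alphas = 1.0 / np.arange(1, n_taxa)  # Zipf-like tail
    tail = rng.multinomial(rest, rng.dirichlet(alphas))
    # keep the constructed taxon a strict maximum
    cap = dominant - 1
    excess = int(np.maximum(tail - cap, 0).sum())
    if excess:
        tail = np.minimum(tail, cap)
        for i in np.argsort(tail):  # refill the emptiest taxa first
            add = min(cap - int(tail[i]), excess)
            tail[i] += add
            excess -= add
            if excess == 0:
                break
        if excess:
            raise ValueError("cannot keep dominant taxon strictly maximal")
    rows = [(dominant_name, rank, dominant)]
    rows += [(f"taxon_{i + 2:02d}", rank, int(c)) for i, c in enumerate(tail)]
    return TaxonCountTable.from_rows(rows)
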