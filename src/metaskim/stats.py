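"""GC content, dispersion-versus-depth summaries, and sample-size planning.

Three quantitative questions about a small read sample:

* fidelity — does the sample's GC content track the full pool's?
* dispersion — how much do the per-strain hit ratios scatter across the 16
  selection methods at each sample size, and does that scatter shrink with
  depth (binomial sampling error scales as 1/sqrt(n))?
* planning — how many reads does estimating a taxon proportion to within a
  margin of error E at a given confidence require? Treating a read's taxon
  as a Bernoulli outcome gives the classic proportion sample-size formula

      n = ceil( z_{alpha/2}^2 * p * (1 - p) / E^2 ),

  with the worst-case p = 1/2 when nothing is known. By z-table convention
  the normal quantile is rounded to two decimals before squaring (85%
  confidence gives z = 1.44 and n = 5184 at E = 1%; the exact quantile
  1.4395 would give 5181); exact quantiles are available via
  ``z_convention="exact"``. A Monte-Carlo coverage simulator and an exact
  binomial coverage computation validate any planned n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classify import HitTable
from .records import SequenceRecord


def base_counts(records: Iterable[Union[SequenceRecord, str]]) -> tuple[int, int]:
    """(G+C count, total unambiguous A/C/G/T count) over a read stream.

    Case-insensitive; N and other ambiguity codes are excluded from both
    numerator and denominator, so the statistic is scale-invariant in the
    amount of masking.
    """
    gc = 0
    at = 0
    for rec in records:
        bases = rec if isinstance(rec, str) else rec.bases
        up = bases.upper()
        gc += up.count("G") + up.count("C")
        at += up.count("A") + up.count("T")
    return gc, gc + at


def gc_content(records: Iterable[Union[SequenceRecord, str]]) -> float:
    """(#G + #C) / (#A + #C + #G + #T) over a read stream."""
    gc, counted = base_counts(records)
    if counted == 0:
        raise ValueError("no unambiguous bases to compute GC content from")
    return gc / counted


@dataclass(frozen=True)
class SampleSizeParams:
    """Inputs of the proportion sample-size formula."""

    margin_of_error: float
    confidence: float
    p: float = 0.5
    z_convention: str = "table"  # "table" (two-decimal z) or "exact"

    def __post_init__(self) -> None:
        if not 0.0 < self.margin_of_error < 1.0:
            raise ValueError("margin_of_error must be in (0, 1)")
        if not 0.0 < self.confidence < 1.0:
            raise ValueError("confidence must be in (0, 1)")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must be in [0, 1]")
        if self.z_convention not in ("table", "exact"):
            raise ValueError("z_convention must be 'table' or 'exact'")

    @property
    def z(self) -> float:
        return z_quantile(self.confidence, self.z_convention)


def z_quantile(confidence: float, convention: str = "table") -> float:
    """The standard-normal upper-alpha/2 quantile for a two-sided confidence.

    ``convention="table"`` rounds to two decimals, the way printed z-tables
    are read (85% -> 1.44); ``"exact"`` returns the full-precision quantile.
    """
    z = float(sps.norm.ppf(1.0 - (1.0 - confidence) / 2.0))
    return round(z, 2) if convention == "table" else z


def required_sample_size(
    margin_of_error: float,
    confidence: float,
    p: float = 0.5,
    z_convention: str = "table",
) -> int:
    """Reads needed to estimate a proportion to within +/- margin_of_error.

    n = ceil(z^2 * p * (1-p) / E^2), rounded up so planned sizes err on the
    conservative side.
    """
    params = SampleSizeParams(margin_of_error, confidence, p, z_convention)
    return math.ceil(params.z**2 * p * (1.0 - p) / margin_of_error**2)


def coverage_simulation(
    n: int, p: float, margin_of_error: float, reps: int, seed: int = 0
) -> float:
    """Monte-Carlo fraction of binomial samples with |p_hat - p| <= E.

    p_hat = Binomial(n, p) / n over `reps` replicates.
    """
    if n < 1 or reps < 1:
        raise ValueError("n and reps must be >= 1")
    rng = np.random.default_rng(seed)
    x = rng.binomial(n, p, size=reps)
    # compare in count space with a tiny guard so reads exactly on the
    # interval boundary (|p_hat - p| = E) are counted despite float rounding
    return float(np.mean(np.abs(x - n * p) <= n * margin_of_error + 1e-9))


def coverage_exact(n: int, p: float, margin_of_error: float) -> float:
    """Exact P(|X/n - p| <= E) for X ~ Binomial(n, p), by summing the pmf."""
    lo = math.ceil(n * (p - margin_of_error) - 1e-9)
    hi = math.floor(n * (p + margin_of_error) + 1e-9)
    lo = max(lo, 0)
    hi = min(hi, n)
    if lo > hi:
        return 0.0
    return float(sps.binom.cdf(hi, n, p) - sps.binom.cdf(lo - 1, n, p))


def sample_fraction(sample_bases: int, original_bases: int) -> float:
    """Sample size as a percentage of the original, in bases."""
    if original_bases <= 0:
        raise ValueError("original_bases must be positive")
    return 100.0 * sample_bases / original_bases


@dataclass(frozen=True)
class DispersionSummary:
    """Min/max/SD of per-strain hit ratios across method variants, by size.

    Each frame has strains as rows and sample sizes as columns; ``reference``
    holds the full-pool ratio per strain. The standard deviation is the
    population SD (divide by the variant count): the 16 method variants are
    the entire set under study, not a sample of methods.
    """

    minima: pd.DataFrame
    maxima: pd.DataFrame
    sd: pd.DataFrame
    reference: pd.Series

    def to_tsv(self, prefix) -> None:
        """Write <prefix>_min.tsv, _max.tsv, _sd.tsv with the reference ratio attached."""
        for name, frame in (("min", self.minima), ("max", self.maxima), ("sd", self.sd)):
            out = frame.copy()
            out.insert(0, "ratio_from_original", self.reference)
            out.to_csv(f"{prefix}_{name}.tsv", sep="\t", index_label="strain")


def summarize_dispersion(
    tables: Mapping[tuple[int, str], HitTable],
    reference: HitTable,
) -> DispersionSummary:
    """Summarize per-strain ratio scatter across method variants at each size.

    Parameters
    ----------
    tables
        Hit tables keyed by (sample size, method label) — one per selection
        configuration of the plan. At least two variants per size.
    reference
        The full-pool hit table supplying the reference ratios.
    """
    strains = reference.strains
    sizes = sorted({size for size, _ in tables})
    ratios_by_size: dict[int, list] = {size: [] for size in sizes}
    for (size, _label), table in tables.items():
        if table.strains != strains:
            raise ValueError("mismatched strain rosters across hit tables")
        if table.ratios is None:
            raise ValueError(f"empty hit table in variant at size {size}")
        ratios_by_size[size].append(table.ratios)
    for size, rows in ratios_by_size.items():
        if len(rows) < 2:
            raise ValueError(f"need >= 2 method variants at size {size}")
    minima, maxima, sd = {}, {}, {}
    for size in sizes:
        arr = np.array(ratios_by_size[size])  # variants x strains
        minima[size] = arr.min(axis=0)
        maxima[size] = arr.max(axis=0)
        sd[size] = arr.std(axis=0, ddof=0)
    index = pd.Index(strains, name="strain")
    return DispersionSummary(
        minima=pd.DataFrame(minima, index=index),
        maxima=pd.DataFrame(maxima, index=index),
        sd=pd.DataFrame(sd, index=index),
        reference=pd.Series(reference.ratios, index=index, name="ratio_from_original"),
    )
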