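"""Read selection: the four sampling families and the 176-configuration plan.

A "sample" here is a small ordered subset of a read stream, selected one of
four ways — from the start, from the end, at uniformly spaced positions
(each after skipping K reads), or uniformly at random without replacement
(reservoir sampling, seeded). Every selector preserves input order and
returns records byte-identical to the originals; asking for more records
than the stream holds is a hard error, because a silently truncated sample
would corrupt any size-versus-error analysis downstream.

Positions are 0-based and intervals half-open. K counts *records skipped*,
so K=0 from-the-start reproduces the classic "take the head of the file"
sample. The uniform selector uses a floor-division stride anchored at
position K; remainders are absorbed at the tail of the stream.

The default plan crosses 11 sample sizes with 16 method variants
(3 deterministic types x 4 K values + 1 random type x 4 seeds) = 176
configurations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, List, Optional, Sequence, TypeVar

import numpy as np

T = TypeVar("T")

#: 11 sample sizes spanning 100 to 50,000 reads, roughly log-spaced.
DEFAULT_SIZES: tuple[int, ...] = (
    100, 200, 500, 1000, 2000, 5000, 10000, 15000, 20000, 30000, 50000,
)
DEFAULT_K_VALUES: tuple[int, ...] = (0, 1000, 2000, 3000)
DEFAULT_SEEDS: tuple[int, ...] = (1, 2, 3, 4)


class SelectionType(str, Enum):
    FROM_START = "start"
    FROM_END = "end"
    UNIFORM = "uniform"
    RANDOM = "random"


DETERMINISTIC_TYPES = (SelectionType.FROM_START, SelectionType.FROM_END, SelectionType.UNIFORM)


class InsufficientReadsError(ValueError):
    """The stream holds fewer records than the selection requires."""


@dataclass(frozen=True)
class SamplingSpec:
    """One selection configuration: type, sample size, and K number or seed."""

    selection_type: SelectionType
    sample_size: int
    k_number: Optional[int] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sample_size < 1:
            raise ValueError("sample_size must be >= 1")
        if self.selection_type is SelectionType.RANDOM:
            if self.seed is None:
                raise ValueError("random selection requires a seed")
            if self.k_number is not None:
                raise ValueError("random selection takes no K number")
        else:
            if self.k_number is None or self.k_number < 0:
                raise ValueError("deterministic selection requires k_number >= 0")
            if self.seed is not None:
                raise ValueError("deterministic selection takes no seed")

    @property
    def label(self) -> str:
        """A compact method label, e.g. 'start_k0_n5000' or 'random_s2_n100'."""
        if self.selection_type is SelectionType.RANDOM:
            return f"random_s{self.seed}_n{self.sample_size}"
        return f"{self.selection_type.value}_k{self.k_number}_n{self.sample_size}"

    def select(self, records: Iterable[T], n_total: Optional[int] = None) -> List[T]:
        if self.selection_type is SelectionType.FROM_START:
            return select_from_start(records, self.sample_size, self.k_number)
        if self.selection_type is SelectionType.FROM_END:
            return select_from_end(records, self.sample_size, self.k_number, n_total)
        if self.selection_type is SelectionType.UNIFORM:
            return select_uniform(records, self.sample_size, self.k_number, n_total)
        return select_random(records, self.sample_size, self.seed)


@dataclass(frozen=True)
class SamplingPlan:
    """The cross product sizes x method variants."""

    sizes: tuple[int, ...]
    specs: tuple[SamplingSpec, ...]

    def __len__(self) -> int:
        return len(self.specs)


def enumerate_plan(
    sizes: Sequence[int] = DEFAULT_SIZES,
    k_values: Sequence[int] = DEFAULT_K_VALUES,
    seeds: Sequence[int] = DEFAULT_SEEDS,
) -> SamplingPlan:
    """One spec per (size x type x variant): 3 deterministic types x |k_values|
    plus the random type x |seeds|, for each size. Defaults give 11 x 16 = 176."""
    specs: list[SamplingSpec] = []
    for size in sizes:
        for sel_type, k in itertools.product(DETERMINISTIC_TYPES, k_values):
            specs.append(SamplingSpec(sel_type, size, k_number=k))
        for seed in seeds:
            specs.append(SamplingSpec(SelectionType.RANDOM, size, seed=seed))
    return SamplingPlan(sizes=tuple(sizes), specs=tuple(specs))


def select_from_start(records: Iterable[T], n: int, k: int = 0) -> List[T]:
    """Records at positions [k, k+n); single pass, stops consuming after k+n-1."""
    _check_args(n, k)
    out = list(itertools.islice(records, k, k + n))
    if len(out) < n:
        raise InsufficientReadsError(
            f"need {k + n} records (skip {k} + take {n}), stream ended early"
        )
    return out


def select_from_end(
    records: Iterable[T], n: int, k: int = 0, n_total: Optional[int] = None
) -> List[T]:
    """Records at positions [N-k-n, N-k) in original order.

    With ``n_total`` unknown the stream is consumed once, buffering only the
    trailing k+n records.
    """
    _check_args(n, k)
    if n_total is not None:
        if k + n > n_total:
            raise InsufficientReadsError(f"k + n = {k + n} > N = {n_total}")
        return select_from_start(records, n, n_total - k - n)
    from collections import deque

    tail: deque[T] = deque(maxlen=k + n)
    count = 0
    for item in records:
        tail.append(item)
        count += 1
    if k + n > count:
        raise InsufficientReadsError(f"k + n = {k + n} > N = {count}")
    return list(itertools.islice(tail, 0, n))


def select_uniform(
    records: Iterable[T], n: int, k: int = 0, n_total: Optional[int] = None
) -> List[T]:
    """Records at positions k, k+stride, ..., k+(n-1)*stride with
    stride = floor((N-k)/n); requires N (counted by materializing if unknown)."""
    _check_args(n, k)
    if n_total is None:
        records = list(records)
        n_total = len(records)
    if n > n_total - k:
        raise InsufficientReadsError(f"n = {n} > N - k = {n_total - k}")
    stride = (n_total - k) // n
    wanted = {k + i * stride for i in range(n)}
    out = [item for pos, item in enumerate(records) if pos in wanted]
    if len(out) < n:
        raise InsufficientReadsError(f"stream shorter than declared N = {n_total}")
    return out


def select_random(records: Iterable[T], n: int, seed: int) -> List[T]:
    """Uniform sample of n records without replacement, restored to stream order.

    Single-pass reservoir sampling with geometric skips ("Algorithm L"), so
    the stream length need not be known and the RNG cost is O(n log(N/n)).
    Reproducible for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    it = iter(records)
    reservoir: list[tuple[int, T]] = [(i, item) for i, item in enumerate(itertools.islice(it, n))]
    if len(reservoir) < n:
        raise InsufficientReadsError(f"n = {n} > stream length {len(reservoir)}")
    sentinel = object()
    w = math.exp(math.log(rng.random()) / n)
    pos = n - 1
    while True:
        skip = int(math.log(rng.random()) / math.log1p(-w))
        item = next(itertools.islice(it, skip, skip + 1), sentinel)
        if item is sentinel:
            break
        pos += skip + 1
        reservoir[int(rng.integers(n))] = (pos, item)
        w *= math.exp(math.log(rng.random()) / n)
    reservoir.sort(key=lambda pair: pair[0])
    return [item for _, item in reservoir]


def count_reads_and_bases(records: Iterable) -> tuple[int, int]:
    """Total record count and summed base count of a read stream."""
    n_reads = 0
    n_bases = 0
    for rec in records:
        n_reads += 1
        n_bases += len(rec)
    return n_reads, n_bases


def _check_args(n: int, k: int) -> None:
    if n < 1:
        raise ValueError("n must be >= 1")
    if k < 0:
        raise ValueError("k must be >= 0")
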