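"""End-to-end experiments: the mock-community sweep and the preview report.

``run_mock_experiment`` reproduces the full design in silico: simulate a
labelled read pool from a community profile, select every sample of the
sampling plan (by default 11 sizes x 16 method variants = 176 samples),
build a hit table and GC value for each, and summarize ratio dispersion
across the variants per size. ``run_preview`` is the practical use case:
take n reads from the start of a file and report the quick-look statistics
a researcher would want before committing to a full analysis.

A single global seed fixes every stochastic stage; per-stage seeds are
derived from it by fixed offsets, so identical config + seed yields a
byte-identical report bundle.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import sampling, synthetic
from .classify import HitTable, ReferenceSet, classify_truth, count_hits
from .io import read_records, write_records
from .records import SequenceRecord
from .sampling import SamplingSpec, SelectionType, enumerate_plan
from .stats import gc_content, summarize_dispersion
from .taxonomy import TaxonCountTable, diversity_count, most_annotated

log = logging.getLogger("metaskim")

# multiplier folding the global seed into per-variant selector seeds
_SEED_STRIDE = 100_003


@dataclass
class RunConfig:
    """Everything a mock-community experiment run needs."""

    out_dir: Path
    profile_path: Optional[Path] = None  # None: the built-in 10-strain community
    pool_size: int = 60_000
    read_length: int = 101
    genome_length: int = 100_000
    sizes: Sequence[int] = sampling.DEFAULT_SIZES
    k_values: Sequence[int] = sampling.DEFAULT_K_VALUES
    seeds: Sequence[int] = sampling.DEFAULT_SEEDS
    classifier: str = "truth"  # "truth" or "kmer"
    kmer_k: int = 21
    kmer_min_shared: int = 2
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.profile_path is not None:
            self.profile_path = Path(self.profile_path)
            if not self.profile_path.exists():
                raise FileNotFoundError(self.profile_path)
        if self.classifier not in ("truth", "kmer"):
            raise ValueError("classifier must be 'truth' or 'kmer'")
        max_needed = max(self.sizes) + max(self.k_values)
        if self.pool_size < max_needed:
            raise ValueError(
                f"pool_size {self.pool_size} < largest size + K = {max_needed}"
            )

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def profiles(self) -> list[synthetic.StrainProfile]:
        if self.profile_path is not None:
            return synthetic.load_profiles(self.profile_path)
        return synthetic.default_mock_community(self.genome_length)


def _spec_header(spec: SamplingSpec) -> str:
    parts = [f"selection_type={spec.selection_type.value}", f"sample_size={spec.sample_size}"]
    if spec.k_number is not None:
        parts.append(f"k_number={spec.k_number}")
    if spec.seed is not None:
        parts.append(f"seed={spec.seed}")
    return "# " + "\t".join(parts) + "\n"


def _stage(name: str, started: float, **counts) -> None:
    extra = " ".join(f"{k}={v}" for k, v in counts.items())
    log.info("%s done in %.2fs %s", name, time.perf_counter() - started, extra)


def run_mock_experiment(config: RunConfig) -> Path:
    """Run the full sampling sweep; returns the report bundle directory.

    The bundle holds the pool FASTQ, the full-pool reference hit table, one
    hit table per sampling configuration (each embedding its spec), a GC
    table, and the three dispersion tables (min, max, SD across variants).
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    profiles = config.profiles()
    stage = "generate"
    try:
        pool = list(
            synthetic.simulate_reads(
                profiles,
                config.pool_size,
                read_length=config.read_length,
                seed=config.seed,
                error_rate=config.error_rate,
            )
        )
        write_records(pool, out / "pool.fastq")
        _stage(stage, t0, reads=len(pool))

        stage = "classify-reference"
        t0 = time.perf_counter()
        roster = [p.name for p in profiles]
        if config.classifier == "kmer":
            genomes = synthetic.community_genomes(profiles, config.seed)
            refs = ReferenceSet(genomes, k=config.kmer_k, min_shared=config.kmer_min_shared)
            classifier = refs.classify
        else:
            classifier = classify_truth
        reference = count_hits(pool, classifier, roster)
        reference.to_tsv(out / "reference_hits.tsv")
        _stage(stage, t0, total_hits=reference.total)

        stage = "sample"
        t0 = time.perf_counter()
        plan = enumerate_plan(config.sizes, config.k_values, config.seeds)
        samples_dir = out / "samples"
        samples_dir.mkdir(exist_ok=True)
        tables: dict[tuple[int, str], HitTable] = {}
        gc_rows: list[tuple[str, int, float]] = []
        for spec in plan.specs:
            if spec.selection_type is SelectionType.RANDOM:
                run_spec = SamplingSpec(
                    spec.selection_type,
                    spec.sample_size,
                    seed=config.seed * _SEED_STRIDE + spec.seed,
                )
            else:
                run_spec = spec
            selected = run_spec.select(pool, n_total=len(pool))
            table = count_hits(selected, classifier, roster)
            tables[(spec.sample_size, spec.label)] = table
            gc_rows.append((spec.label, spec.sample_size, gc_content(selected)))
            path = samples_dir / f"{spec.label}.tsv"
            with open(path, "w") as fh:
                fh.write(_spec_header(spec))
                table.to_frame().to_csv(fh, sep="\t", index=False)
        _stage(stage, t0, samples=len(plan.specs))

        stage = "summarize"
        t0 = time.perf_counter()
        with open(out / "gc.tsv", "w") as fh:
            fh.write("method\tsample_size\tgc_content\n")
            for label, size, gc in gc_rows:
                fh.write(f"{label}\t{size}\t{gc:.6f}\n")
        summary = summarize_dispersion(tables, reference)
        summary.to_tsv(out / "dispersion")
        manifest = {
            "pool_size": config.pool_size,
            "read_length": config.read_length,
            "seed": config.seed,
            "classifier": config.classifier,
            "sizes": list(config.sizes),
            "k_values": list(config.k_values),
            "seeds": list(config.seeds),
            "n_samples": len(plan.specs),
            "strains": list(reference.strains),
            "pool_gc": gc_content(pool),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        _stage(stage, t0, sizes=len(config.sizes))
    except Exception:
        log.error("stage %r failed", stage)
        raise
    return out


@dataclass(frozen=True)
class PreviewReport:
    """Quick-look statistics from the head of a read file."""

    n_reads: int
    n_bases: int
    gc: float
    top_taxa: dict[str, str] = field(default_factory=dict)
    diversity: dict[str, tuple[int, int]] = field(default_factory=dict)  # rank -> (all, thresholded)
    threshold: float = 0.01

    def to_text(self) -> str:
        lines = [
            f"reads\t{self.n_reads}",
            f"bases\t{self.n_bases}",
            f"gc_content\t{self.gc:.4f}",
        ]
        for rank, taxon in self.top_taxa.items():
            lines.append(f"most_annotated_{rank}\t{taxon}")
        for rank, (full, thresh) in self.diversity.items():
            lines.append(f"n_{rank}\t{full}")
            lines.append(f"n_{rank}_over_{self.threshold:.0%}\t{thresh}")
        return "\n".join(lines) + "\n"


def run_preview(
    reads_path,
    n: int,
    annotations: Optional[TaxonCountTable] = None,
    threshold: float = 0.01,
    sample_out=None,
) -> PreviewReport:
    """Preview a read file from its first n reads (selection from the start, K=0)."""
    t0 = time.perf_counter()
    selected: list[SequenceRecord] = sampling.select_from_start(read_records(reads_path), n, 0)
    if sample_out is not None:
        write_records(selected, sample_out)
    n_reads, n_bases = sampling.count_reads_and_bases(selected)
    top: dict[str, str] = {}
    diversity: dict[str, tuple[int, int]] = {}
    if annotations is not None:
        for rank in sorted(annotations.frame["rank"].unique()):
            top[rank] = most_annotated(annotations, rank)
            diversity[rank] = (
                diversity_count(annotations, rank, 0.0),
                diversity_count(annotations, rank, threshold),
            )
    report = PreviewReport(
        n_reads=n_reads,
        n_bases=n_bases,
        gc=gc_content(selected),
        top_taxa=top,
        diversity=diversity,
        threshold=threshold,
    )
    _stage("preview", t0, reads=n_reads, bases=n_bases)
    return report
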