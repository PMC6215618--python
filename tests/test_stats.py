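"""GC content, the proportion sample-size planner, coverage, dispersion."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import metaskim as ms
from metaskim.stats import base_counts


class TestGcContent:
    @pytest.mark.parametrize(
        "bases,expected",
        [("GGCC", 1.0), ("ATAT", 0.0), ("ACGN", 2 / 3), ("acgn", 2 / 3), ("GcAt", 0.5)],
    )
    def test_stated_conventions(self, bases, expected):
        assert ms.gc_content([bases]) == pytest.approx(expected)

    def test_all_ambiguous_is_an_error(self):
        with pytest.raises(ValueError):
            ms.gc_content(["NNNN"])

    @given(st.lists(st.text(alphabet="ACGTN", min_size=1), min_size=1, max_size=8))
    @settings(max_examples=100, deadline=None)
    def test_concatenation_is_base_weighted_mean(self, chunks):
        # exact rational arithmetic: pooled GC == weighted mean of part GCs
        gc_all, n_all = base_counts(chunks)
        parts = [base_counts([c]) for c in chunks]
        assert gc_all == sum(g for g, _ in parts)
        assert n_all == sum(n for _, n in parts)
        if n_all:
            pooled = Fraction(gc_all, n_all)
            weighted = sum(Fraction(g, 1) for g, _ in parts) / n_all
            assert pooled == weighted

    def test_subsample_gc_converges_to_pool(self, pool):
        pool_gc = ms.gc_content(pool)
        for size in (500, 5000, 50_000):
            sample = ms.select_random(pool, size, seed=13)
            se = math.sqrt(pool_gc * (1 - pool_gc) / (size * 101))
            # reads are 101-base blocks from genomes of mixed GC, so
            # between-read variance dominates the binomial s.e.; widen by the
            # observed per-read GC spread
            per_read = np.array([ms.gc_content([r]) for r in sample[:2000]])
            se_blocks = per_read.std() / math.sqrt(size)
            assert abs(ms.gc_content(sample) - pool_gc) <= 3 * max(se, se_blocks)


class TestSampleSizePlanner:
    def test_worked_example_85_percent_1_percent(self):
        assert ms.z_quantile(0.85) == 1.44
        assert ms.required_sample_size(0.01, 0.85) == 5184

    def test_direct_evaluation_95_percent_5_percent(self):
        # ceil(1.96^2 * 0.25 / 0.0025) = ceil(384.16) = 385
        assert ms.required_sample_size(0.05, 0.95) == 385

    def test_halving_margin_quadruples_n(self):
        n1 = 1.44**2 * 0.25 / 0.01**2
        n2 = 1.44**2 * 0.25 / 0.005**2
        assert n2 == 4 * n1
        assert ms.required_sample_size(0.005, 0.85) == 4 * ms.required_sample_size(0.01, 0.85)

    def test_exact_z_convention(self):
        assert ms.required_sample_size(0.01, 0.85, z_convention="exact") == 5181

    def test_monotone_in_margin_and_confidence(self):
        margins = [0.1, 0.05, 0.02, 0.01, 0.005]
        ns = [ms.required_sample_size(e, 0.9) for e in margins]
        assert ns == sorted(ns)  # non-increasing in E means increasing as E shrinks
        confs = [0.8, 0.85, 0.9, 0.95, 0.99]
        ns = [ms.required_sample_size(0.01, c) for c in confs]
        assert ns == sorted(ns)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            ms.SampleSizeParams(0.0, 0.85)
        with pytest.raises(ValueError):
            ms.SampleSizeParams(0.01, 1.0)
        with pytest.raises(ValueError):
            ms.SampleSizeParams(0.01, 0.85, z_convention="nope")


class TestCoverage:
    def test_huge_margin_gives_full_coverage(self):
        assert ms.coverage_simulation(50, 0.5, 0.5, reps=2000, seed=1) == 1.0

    def test_simulation_matches_exact_pmf(self):
        # exact oracle: sum the Binomial(100, 1/2) pmf over |X/100 - .5| <= .01
        exact = ms.coverage_exact(100, 0.5, 0.01)
        sim = ms.coverage_simulation(100, 0.5, 0.01, reps=10_000, seed=3)
        se = math.sqrt(exact * (1 - exact) / 10_000)
        assert abs(sim - exact) <= 4 * se

    def test_exact_coverage_increases_with_n_on_average(self):
        cov = [ms.coverage_exact(n, 0.5, 0.05) for n in (50, 200, 800)]
        assert cov[0] < cov[1] < cov[2]

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            ms.coverage_simulation(0, 0.5, 0.01, reps=10)


class TestSampleFraction:
    def test_identity(self):
        assert ms.sample_fraction(12345, 12345) == 100.0

    def test_direct_division(self):
        assert ms.sample_fraction(306_684, 37_968_936_507) == pytest.approx(8.08e-4, rel=1e-3)

    def test_zero_original_rejected(self):
        with pytest.raises(ValueError):
            ms.sample_fraction(1, 0)


class TestDispersionSummary:
    def _table(self, ratios, total=10_000):
        strains = tuple(f"s{i}" for i in range(len(ratios)))
        return ms.HitTable(strains, tuple(int(round(r * total)) for r in ratios))

    def test_constant_variants_have_zero_sd(self):
        ref = self._table([0.5, 0.5])
        tables = {(100, f"m{i}"): self._table([0.5, 0.5]) for i in range(16)}
        summary = ms.summarize_dispersion(tables, ref)
        assert (summary.sd[100] == 0).all()
        assert (summary.minima[100] == summary.maxima[100]).all()

    def test_two_variant_hand_arithmetic(self):
        # ratios 0.1 and 0.3: min .1, max .3, population sd .1
        ref = self._table([0.2, 0.8])
        tables = {
            (100, "a"): self._table([0.1, 0.9]),
            (100, "b"): self._table([0.3, 0.7]),
        }
        summary = ms.summarize_dispersion(tables, ref)
        assert summary.minima.loc["s0", 100] == pytest.approx(0.1)
        assert summary.maxima.loc["s0", 100] == pytest.approx(0.3)
        assert summary.sd.loc["s0", 100] == pytest.approx(0.1)
        assert summary.reference["s0"] == pytest.approx(0.2)

    def test_single_variant_rejected(self):
        ref = self._table([1.0])
        with pytest.raises(ValueError, match=">= 2"):
            ms.summarize_dispersion({(100, "a"): self._table([1.0])}, ref)

    def test_mismatched_rosters_rejected(self):
        ref = self._table([0.5, 0.5])
        bad = ms.HitTable(("x", "y"), (1, 1))
        with pytest.raises(ValueError, match="roster"):
            ms.summarize_dispersion({(100, "a"): bad, (100, "b"): bad}, ref)

    def test_tsv_output(self, tmp_path):
        ref = self._table([0.25, 0.75])
        tables = {
            (100, "a"): self._table([0.2, 0.8]),
            (100, "b"): self._table([0.3, 0.7]),
            (200, "a"): self._table([0.24, 0.76]),
            (200, "b"): self._table([0.26, 0.74]),
        }
        summary = ms.summarize_dispersion(tables, ref)
        summary.to_tsv(tmp_path / "disp")
        for suffix in ("min", "max", "sd"):
            text = (tmp_path / f"disp_{suffix}.tsv").read_text()
            assert text.startswith("strain\tratio_from_original\t100\t200")

    def test_sd_shrinks_with_depth_small_simulation(self, mock_profiles, pool_labels):
        # binomial sd scales as 1/sqrt(n): mean sd over 16 random variants at
        # n = 5000 must undercut n = 100 for every strain
        roster = [p.name for p in mock_profiles]
        ref = ms.HitTable.from_labels(pool_labels, roster)
        tables = {}
        for size in (100, 5000):
            for v in range(16):
                labels = ms.select_random(pool_labels, size, seed=1000 + v)
                tables[(size, f"v{v}")] = ms.HitTable.from_labels(labels, roster)
        summary = ms.summarize_dispersion(tables, ref)
        assert (summary.sd[5000] < summary.sd[100]).all()
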