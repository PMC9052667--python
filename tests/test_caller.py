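"""Run merging, per-read counting, mixture genotyping, and telomere mode."""

import numpy as np
import pytest

from squigstr import caller
from squigstr.caller import (
    CallerConfig,
    CountHistogram,
    call_genotype,
    merge_predictions,
    per_read_count,
    quantify_telomere,
)


def brute_force_merge(labels, unit_len):
    """O(n^2)-style reference: explicit run scan, length filter, gap merge."""
    in_rep = [int(l) in (1, 2, 3) for l in labels]
    runs = []
    i = 0
    while i < len(in_rep):
        if in_rep[i]:
            j = i
            while j < len(in_rep) and in_rep[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    runs = [(a, b) for a, b in runs if b - a >= 3 * unit_len]
    changed = True
    while changed:
        changed = False
        for x in range(len(runs) - 1):
            if runs[x + 1][0] - runs[x][1] < unit_len:
                runs[x : x + 2] = [(runs[x][0], runs[x + 1][1])]
                changed = True
                break
    return runs


class TestMerge:
    def test_single_run(self):
        assert merge_predictions([0] * 2 + [1] * 30 + [0], 3) == [(2, 32)]

    def test_gap_shorter_than_unit_merges(self):
        labels = [1] * 15 + [0, 0] + [1] * 12
        assert merge_predictions(labels, 3) == [(0, 29)]

    def test_short_run_discarded(self):
        assert merge_predictions([1] * 6, 3) == []

    def test_gap_of_unit_length_stays_split(self):
        labels = [1] * 12 + [0, 0, 0] + [1] * 12
        assert merge_predictions(labels, 3) == [(0, 12), (15, 27)]

    def test_del_ins_classes_count_as_in_repeat(self):
        labels = [1] * 5 + [2] * 5 + [3] * 5
        assert merge_predictions(labels, 3) == [(0, 15)]

    def test_empty_input(self):
        assert merge_predictions([], 3) == []

    @pytest.mark.parametrize("unit_len", [2, 3, 4, 5, 6])
    def test_matches_brute_force(self, unit_len):
        rng = np.random.default_rng(unit_len)
        for _ in range(200):
            n = int(rng.integers(1, 201))
            labels = rng.choice([0, 0, 1, 1, 1, 2, 3], size=n)
            assert merge_predictions(labels, unit_len) == brute_force_merge(labels, unit_len)


class TestPerReadCount:
    def test_rounding_half_up(self):
        assert per_read_count([(0, 29)], 3).count == 10      # 29/3 = 9.67
        assert per_read_count([(0, 30)], 3).count == 10
        assert per_read_count([(0, 32)], 3).count == 11      # 32/3 = 10.67
        assert per_read_count([(0, 31)], 3).count == 10      # 31/3 = 10.33

    def test_longest_overlapping_segment_wins(self):
        call = per_read_count([(0, 30), (50, 59)], 3, locus_span=(0, 100))
        assert call.merged_len == 30 and call.count == 10

    def test_no_overlap_returns_none(self):
        assert per_read_count([(0, 30)], 3, locus_span=(100, 200)) is None
        assert per_read_count([], 3) is None


class TestHistogram:
    def test_conservation(self):
        values = [18, 18, 19, 40, 41, 41, 41]
        hist = CountHistogram.from_values(values)
        assert hist.total == len(values)
        assert hist.counts == {18: 2, 19: 1, 40: 1, 41: 3}


class TestGenotype:
    def test_heterozygous_recovery_from_known_mixture(self):
        """60 reads ~ N(18, 1) + 40 reads ~ N(40, 1.5): both alleles recovered
        within +-1 of the simulated truth."""
        rng = np.random.default_rng(11)
        counts = np.rint(
            np.concatenate([rng.normal(18, 1, 60), rng.normal(40, 1.5, 40)])
        ).astype(int)
        call = call_genotype(counts, seed=11)
        assert len(call.alleles) == 2
        assert abs(call.alleles[0] - 18) <= 1 and abs(call.alleles[1] - 40) <= 1
        assert call.support[0] >= 40 and call.support[1] >= 25
        assert 3 <= call.k <= 7 and not call.low_coverage

    def test_degenerate_identical_counts(self):
        call = call_genotype([20] * 100)
        assert call.alleles == (20,) and call.degenerate
        assert call.support == (100,)

    def test_low_coverage_returns_histogram_only(self):
        call = call_genotype([17, 18, 18, 19, 40, 41])
        assert call.low_coverage and call.alleles == ()
        assert call.histogram.total == 6

    def test_homozygous_with_jitter(self):
        rng = np.random.default_rng(4)
        counts = np.rint(rng.normal(22, 1.0, 50)).astype(int)
        call = call_genotype(counts, seed=4)
        assert len(call.alleles) == 1 and abs(call.alleles[0] - 22) <= 1

    def test_minor_component_below_weight_threshold_ignored(self):
        rng = np.random.default_rng(8)
        counts = np.concatenate(
            [np.rint(rng.normal(20, 1, 55)).astype(int), [40, 41, 40]]  # 5% stray reads
        )
        call = call_genotype(counts, seed=8)
        assert call.alleles == (20,)

    def test_recovery_across_seeded_simulations(self):
        """Heterozygous recovery: allele gaps >= 4, n >= 40, sd <= 1.5 =>
        both alleles within +-1 in >= 18/20 seeded runs."""
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(5000 + s)
            a1 = int(rng.integers(10, 30))
            a2 = a1 + 4 + int(rng.integers(0, 25))
            n1 = int(rng.integers(20, 41))
            n2 = max(40 - n1, 15)
            counts = np.rint(
                np.concatenate([rng.normal(a1, 1.2, n1), rng.normal(a2, 1.5, n2)])
            ).astype(int)
            call = call_genotype(counts, seed=s)
            if (
                len(call.alleles) == 2
                and abs(call.alleles[0] - a1) <= 1
                and abs(call.alleles[1] - a2) <= 1
            ):
                hits += 1
        assert hits >= 18

    def test_json_serialization(self):
        call = call_genotype([20] * 100)
        import json

        obj = json.loads(call.to_json())
        assert obj["alleles"] == [20] and obj["histogram"] == {"20": 100}


def test_monotonicity_of_called_counts():
    """Longer simulated repeat runs never yield a smaller median count."""
    medians = []
    for true_count in (10, 15, 20, 30, 50):
        counts = []
        rng = np.random.default_rng(true_count)
        for _ in range(30):
            run = 3 * true_count + int(rng.integers(-2, 3))
            labels = [0] * 20 + [1] * run + [0] * 20
            call = per_read_count(merge_predictions(labels, 3), 3)
            counts.append(call.count)
        medians.append(np.median(counts))
    assert all(a <= b for a, b in zip(medians, medians[1:]))


class TestTelomere:
    def _labels(self, flank, run, tail=0):
        return np.array([0] * flank + [1] * run + [0] * tail, dtype=np.int64)

    def test_anchored_run_count(self):
        reads = [("r1", self._labels(30, 300), 30, 60)]
        s = quantify_telomere(reads, 6)
        assert s.per_read == {"r1": 50}

    def test_truncated_read_gives_lower_bound(self):
        full = [("full", self._labels(30, 300), 30, 60)]
        trunc = [("trunc", self._labels(30, 180), 30, 60)]
        assert quantify_telomere(full, 6).per_read["full"] > quantify_telomere(trunc, 6).per_read["trunc"]

    def test_mapq_gate(self):
        reads = [
            ("good", self._labels(30, 300), 30, 60),
            ("bad", self._labels(30, 300), 30, 5),
        ]
        s = quantify_telomere(reads, 6)
        assert set(s.per_read) == {"good"}

    def test_no_anchored_reads_warns(self):
        with pytest.warns(UserWarning):
            s = quantify_telomere([("r", self._labels(30, 300), 30, 5)], 6)
        assert s.median is None

    def test_cohort_recovery_within_ten_percent(self):
        """Simulated cohort, truth 800 +- 100 copies, 20 reads: the median
        estimate lands within 10% of the truth."""
        from squigstr import simulate
        from conftest import bin_dataset

        rng = np.random.default_rng(5)
        spec = simulate.SimLocusSpec(
            unit="TTAGGG",
            left_flank=simulate.random_flank(rng, 80),
            right_flank="",
            alleles=(800,),
            fractions=(1.0,),
            n_reads=20,
            jitter_sd=100.0,
            seed=5,
        )
        ds = simulate.simulate_locus_dataset(spec)
        reads = [(rid, ds.truth_labels[rid], 80, 60) for rid in ds.truth_labels]
        s = quantify_telomere(reads, 6)
        assert len(s.per_read) == 20
        assert abs(s.median - 800) <= 80
        assert s.sd > 0
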