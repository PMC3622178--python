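"""Summit-window overlap against a quadratic oracle, Venn accounting,
top-site comparison and motif counting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from socmap import peaks, simulate
from socmap.peaks import PEAK_COLUMNS, PeakSet


def make_peaks(summits, chrom="chr1", scores=None, width=100):
    rows = []
    for i, s in enumerate(sorted(summits)):
        score = 1.0 if scores is None else scores[i]
        rows.append((chrom, s - width, s + width, s, score))
    return PeakSet(pd.DataFrame(rows, columns=PEAK_COLUMNS))


def brute_force_pairs(a: PeakSet, b: PeakSet, halfwidth=120):
    out = []
    for i, ra in a.peaks.iterrows():
        for j, rb in b.peaks.iterrows():
            if ra["chrom"] == rb["chrom"] and abs(ra["summit"] - rb["summit"]) <= 2 * halfwidth:
                out.append((i, j))
    return sorted(out)


class TestSummitOverlap:
    def test_boundary_inclusive(self):
        a = make_peaks([1000])
        assert len(peaks.summit_overlap(a, make_peaks([1240]))) == 1
        assert len(peaks.summit_overlap(a, make_peaks([1241]))) == 0

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a = make_peaks(np.cumsum(rng.integers(201, 2000, 30)) + 200)
        b = make_peaks(np.cumsum(rng.integers(201, 2000, 25)) + 300)
        ab = peaks.summit_overlap(a, b)
        ba = peaks.summit_overlap(b, a)
        assert sorted(map(tuple, ab)) == sorted((j, i) for i, j in map(tuple, ba))

    def test_different_chromosomes_never_overlap(self):
        a = make_peaks([1000], chrom="chr1")
        b = make_peaks([1000], chrom="chr2")
        assert len(peaks.summit_overlap(a, b)) == 0

    @given(st.integers(0, 2**31 - 1), st.integers(1, 60))
    def test_property_matches_quadratic_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        def random_set(k):
            chroms = rng.choice(["chr1", "chr2"], k)
            summits = rng.integers(200, 5000, k)
            rows = [
                (c, s - 100, s + 100, s, float(rng.random()))
                for c, s in zip(chroms, summits)
            ]
            df = pd.DataFrame(rows, columns=PEAK_COLUMNS)
            df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
            return PeakSet(df)

        a, b = random_set(n), random_set(max(1, n // 2))
        got = sorted(map(tuple, peaks.summit_overlap(a, b)))
        assert got == brute_force_pairs(a, b)


class TestVennCooccupancy:
    def test_printed_count_arithmetic(self):
        assert peaks.cooccupancy_fraction(1916, 5072) == pytest.approx(37.776, abs=1e-3)
        assert peaks.format_percent(peaks.cooccupancy_fraction(1916, 5072)) == "38%"
        assert peaks.cooccupancy_fraction(497, 3412) == pytest.approx(14.566, abs=1e-3)

    def test_identical_sets_fully_cooccupied(self):
        s = make_peaks(np.arange(1, 11) * 5000)
        rep = peaks.venn_cooccupancy(s, s, s)
        assert rep.fraction == 1.0
        triple = frozenset({"USF1", "CLOCK", "BMAL1"})
        assert rep.per_set["USF1"][triple] == len(s)

    def test_region_counts_sum_to_cardinality(self):
        a, b = simulate.simulate_peak_sets({"chr1": 30_000_000}, 40, 30, 20, 50.0, seed=1)
        c, _ = simulate.simulate_peak_sets({"chr1": 30_000_000}, 0, 25, 0, 0.0, seed=2)
        rep = peaks.venn_cooccupancy(a, b, c)
        for name, size in [("USF1", len(a)), ("CLOCK", len(b)), ("BMAL1", len(c))]:
            assert sum(rep.per_set[name].values()) == size

    def test_synthetic_construction_recovered_exactly(self):
        a, b = simulate.simulate_peak_sets({"chr1": 50_000_000}, 35, 25, 15, 0.0, seed=3)
        empty = PeakSet(pd.DataFrame(columns=PEAK_COLUMNS))
        rep = peaks.venn_cooccupancy(a, b, empty)
        pair = frozenset({"USF1", "CLOCK"})
        assert rep.per_set["USF1"][pair] == 35
        assert rep.per_set["USF1"][frozenset({"USF1"})] == 25
        assert rep.cb_sites == len(b) and rep.cooccupied == 35

    def test_merge_idempotent(self):
        a, b = simulate.simulate_peak_sets({"chr1": 10_000_000}, 20, 10, 5, 30.0, seed=4)
        merged = peaks.merge_summits([a, b])
        again = peaks.merge_summits([merged])
        pd.testing.assert_frame_equal(merged.peaks, again.peaks)


class TestTopSites:
    def test_identical_lists_no_difference(self):
        s = make_peaks(np.arange(1, 21) * 1000, scores=list(np.arange(20.0)))
        res = peaks.top_sites_compare(s, s, top=10)
        assert res.p_value == pytest.approx(1.0, abs=0.05)  # up to tie handling
        assert res.summary["median"].iloc[0] == res.summary["median"].iloc[1]

    def test_large_shift_detected(self):
        rng = np.random.default_rng(5)
        base = rng.normal(50, 2, 40)
        a = make_peaks(np.arange(1, 41) * 1000, scores=list(base))
        b = make_peaks(np.arange(1, 41) * 1000, scores=list(base + 30))
        res = peaks.top_sites_compare(a, b, top=20)
        assert res.p_value < 0.001
        assert res.summary["median"].iloc[1] > res.summary["median"].iloc[0]

    def test_top_full_set_equals_direct(self):
        scores = [3.0, 1.0, 2.0]
        s = make_peaks([1000, 3000, 5000], scores=scores)
        res = peaks.top_sites_compare(s, s, top=3)
        assert res.summary["median"].iloc[0] == np.median(scores)

    def test_fraction_top(self):
        s = make_peaks(np.arange(1, 41) * 1000, scores=list(np.arange(40.0)))
        res = peaks.top_sites_compare(s, s, top=0.1)
        assert res.n_top == 4


class TestMotifCount:
    def test_single_and_zero_occurrence(self):
        pk = PeakSet(pd.DataFrame([("p", 0, 10, 5, 1.0)], columns=PEAK_COLUMNS))
        assert peaks.motif_count(pk, {"p": "AACACGTGTT"}).total == 1
        assert peaks.motif_count(pk, {"p": "AATATATAAT"}).total == 0

    def test_palindrome_not_double_counted(self):
        pk = PeakSet(pd.DataFrame([("p", 0, 12, 5, 1.0)], columns=PEAK_COLUMNS))
        assert peaks.motif_count(pk, {"p": "AACACGTGTTAA"}, motif="CACGTG").total == 1

    def test_nonpalindromic_scanned_both_strands(self):
        pk = PeakSet(pd.DataFrame([("p", 0, 16, 5, 1.0)], columns=PEAK_COLUMNS))
        # GGGCCA on forward, TGGCCC (its reverse complement) also present
        counts = peaks.motif_count(pk, {"p": "GGGCCAATTGGCCCAA"}, motif="GGGCCA")
        assert counts.total == 2

    def test_window_clipping_warns(self):
        pk = PeakSet(pd.DataFrame([("p", 0, 10, 5, 1.0)], columns=PEAK_COLUMNS))
        with pytest.warns(UserWarning, match="clipped"):
            counts = peaks.motif_count(pk, {"p": "AACACGTGTT"}, flank=50)
        assert counts.total == 1

    @given(st.integers(0, 2**31 - 1))
    def test_property_matches_slice_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), 1000))
        starts = np.sort(rng.choice(800, 5, replace=False))
        pk = PeakSet(
            pd.DataFrame(
                [("c", int(s), int(s) + 120, int(s) + 60, 1.0) for s in starts],
                columns=PEAK_COLUMNS,
            )
        )
        got = peaks.motif_count(pk, {"c": seq}, motif="CACGTG")
        expected = []
        for s in starts:
            window = seq[s : s + 120]
            expected.append(
                sum(window[i : i + 6] == "CACGTG" for i in range(len(window) - 5))
            )
        assert got.per_peak.tolist() == expected
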