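"""Binomial peak calling, BH correction, overlap and Hi-C comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import binom

from modfoot import peaks, simulate, threshold, track
from modfoot.errors import DataQualityWarning, InsufficientDataError
from modfoot.io import GenomicBin


class TestEstimateNull:
    def test_simple_ratio(self, make_molecule):
        probs = np.concatenate([np.full(100, 0.9), np.full(900, 0.1)])
        m = make_molecule(np.arange(1000), probs)
        assert peaks.estimate_null([m], cutoff=0.5) == pytest.approx(0.1)

    def test_zero_flagged_clamped_with_warning(self, make_molecule):
        m = make_molecule([1, 2, 3], [0.0, 0.0, 0.0])
        with pytest.warns(DataQualityWarning):
            assert peaks.estimate_null([m], cutoff=0.5) == pytest.approx(1e-6)

    def test_pooled_counts_not_mean_of_ratios(self, make_molecule):
        # 1 of 2 flagged vs 0 of 98: pooled 1/100, not mean(0.5, 0)
        m1 = make_molecule([1, 2], [0.9, 0.1], read_id="a")
        m2 = make_molecule(np.arange(98) * 3, np.full(98, 0.1), read_id="b")
        assert peaks.estimate_null([m1, m2], cutoff=0.5) == pytest.approx(0.01)

    def test_empty_control_rejected(self):
        with pytest.raises(InsufficientDataError):
            peaks.estimate_null([], cutoff=0.5)


class TestBinomialTest:
    def test_zero_count_gives_one(self):
        assert peaks.binomial_region_test(0, 10, 0.3) == pytest.approx(1.0)

    def test_all_successes_closed_form(self):
        assert peaks.binomial_region_test(10, 10, 0.5) == pytest.approx(0.5**10)

    def test_matches_tail_summation_oracle(self):
        p = peaks.binomial_region_test(30, 100, 0.1)
        oracle = sum(binom.pmf(i, 100, 0.1) for i in range(30, 101))
        assert p == pytest.approx(oracle, rel=1e-10)

    def test_nonincreasing_in_k(self):
        vals = [peaks.binomial_region_test(k, 50, 0.2) for k in range(51)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            peaks.binomial_region_test(11, 10, 0.5)


def bh_oracle(p):
    """Brute-force BH: sort, p*m/rank, cumulative min from the top, unsort."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


class TestBhAdjust:
    def test_hand_example(self):
        out = peaks.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_value_unchanged(self):
        assert peaks.bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_ties_stay_equal(self):
        out = peaks.bh_adjust([0.2, 0.2, 0.2])
        assert np.allclose(out, 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            peaks.bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=50))
    def test_matches_brute_force_oracle(self, p):
        assert np.allclose(peaks.bh_adjust(p), bh_oracle(p))


def _binned_track(counts, a=200, width=200):
    n = len(counts)
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(n) * width,
            "end": np.arange(1, n + 1) * width,
            "meth_count": counts,
            "a_count": a,
        }
    )


class TestCallPeaks:
    def test_planted_footprint_recovered(self):
        cfg = simulate.SimConfig(
            genome_length=20_000, footprints=((5_000, 5_500),), depth=30,
            p_fg=0.6, p_bg=0.05, seed=4,
        )
        mols, _ = simulate.simulate_molecules(cfg)
        mols, _, _ = threshold.binarize_calls(mols, 0.53)
        bins = track.make_bins({"chrSim": 20_000}, width=200, step=200)
        sig = track.ratio_track(mols, bins)
        igg_cfg = simulate.SimConfig(genome_length=20_000, depth=10, p_bg=0.05, seed=5)
        igg, _ = simulate.simulate_molecules(igg_cfg)
        null_p = peaks.estimate_null(igg, cutoff=0.53)
        res = peaks.call_peaks(sig, null_p)
        hits = res.passing
        assert any(
            (row.start < 5_500) and (row.end > 5_000) for row in hits.itertuples()
        )

    def test_width_filter_is_strict(self):
        # a lone 50-bp significant bin fails "greater than 50"
        t = pd.DataFrame(
            {
                "chrom": ["chr1"],
                "start": [0],
                "end": [50],
                "meth_count": [50],
                "a_count": [50],
            }
        )
        res = peaks.call_peaks(t, null_p=0.05, min_width=50)
        assert len(res.peaks) == 1 and not bool(res.peaks["passes"].iloc[0])

    def test_adjacent_significant_bins_merged(self, rng):
        counts = rng.binomial(200, 0.05, size=50)
        counts[10:13] = 150
        res = peaks.call_peaks(_binned_track(counts), null_p=0.05)
        hit = res.passing
        assert len(hit) == 1
        assert (hit["start"].iloc[0], hit["end"].iloc[0]) == (2000, 2600)
        assert hit["width"].iloc[0] == 600

    def test_null_calibration_single_run(self, rng):
        counts = rng.binomial(200, 0.05, size=2000)
        res = peaks.call_peaks(_binned_track(counts), null_p=0.05)
        frac = res.table["significant"].mean()
        sd = np.sqrt(0.01 * 0.99 / 2000)
        assert frac <= 0.01 + 3 * sd

    def test_uncovered_bins_not_tested(self):
        t = _binned_track([5, 5], a=0)
        res = peaks.call_peaks(t, null_p=0.05)
        assert res.table.empty and res.peaks.empty


class TestPeakOverlap:
    def _bins(self, spans, chrom="chr1"):
        return [GenomicBin(chrom, s, e) for s, e in spans]

    def test_identical_sets(self):
        a = self._bins([(0, 100), (200, 300)])
        res = peaks.peak_overlap(a, a)
        assert res.a_with_overlap == 2 and res.a_only == 0 and res.b_only == 0

    def test_disjoint_sets(self):
        a = self._bins([(0, 100)])
        b = self._bins([(200, 300)])
        res = peaks.peak_overlap(a, b)
        assert res.a_with_overlap == 0 and res.a_only == 1 and res.b_only == 1

    def test_any_bp_overlap(self):
        a = self._bins([(0, 100)])
        b = self._bins([(99, 200)])
        assert peaks.peak_overlap(a, b).a_with_overlap == 1
        c = self._bins([(100, 200)])  # touching, half-open: no overlap
        assert peaks.peak_overlap(a, c).a_with_overlap == 0

    def test_empty_set_skips_test(self):
        res = peaks.peak_overlap([], self._bins([(0, 10)]))
        assert res.test_skipped and res.n_a == 0

    def test_wilcoxon_null_calibration(self, rng):
        # overlap grouping independent of the signal: p should be uniform
        rejections = 0
        reps = 200
        for _ in range(reps):
            n = 200
            b_spans = [(i * 1000, i * 1000 + 100) for i in range(n)]
            overlap_idx = rng.choice(n, size=n // 2, replace=False)
            a_spans = [b_spans[i] for i in overlap_idx]
            values = rng.normal(size=n)
            res = peaks.peak_overlap(
                self._bins(a_spans), self._bins(b_spans), track_b_values=values
            )
            rejections += res.wilcoxon_p < 0.05
        rate = rejections / reps
        sd = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) <= 3 * sd + 1e-9


def _flat_ratio_track(length=200_000, width=200, base=0.05):
    n = length // width
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(n) * width,
            "end": np.arange(1, n + 1) * width,
            "ratio": np.full(n, base),
        }
    )


class TestHicProximity:
    def test_planted_elevation_detected(self):
        t = _flat_ratio_track()
        peaks_set = [GenomicBin("chr1", 10_000, 10_500)]
        pair_rows = []
        for k in range(6):
            partner = 50_000 + k * 12_000
            pair_rows.append(("chr1", 10_250, partner))
            sel = (t["start"] >= partner - 2_500) & (t["end"] <= partner + 2_500)
            t.loc[sel, "ratio"] = 0.4
        pairs = pd.DataFrame(pair_rows, columns=["chrom", "pos1", "pos2"])
        res = peaks.hic_proximity_compare(pairs, peaks_set, t, n_background=40, seed=1)
        assert res.proximate_means.mean() > res.background_means.mean()
        assert res.p_value < 0.05
        assert res.attrition["one_end"] == 6

    def test_both_end_pairs_excluded(self):
        t = _flat_ratio_track(50_000)
        peaks_set = [GenomicBin("chr1", 10_000, 10_500), GenomicBin("chr1", 30_000, 30_500)]
        pairs = pd.DataFrame(
            [("chr1", 10_250, 30_250)], columns=["chrom", "pos1", "pos2"]
        )
        with pytest.raises(InsufficientDataError, match="attrition"):
            peaks.hic_proximity_compare(pairs, peaks_set, t, seed=0)

    def test_uniform_signal_null_calibration(self, rng):
        t = _flat_ratio_track()
        # jitter so rank sums are well-defined without heavy ties
        t["ratio"] = 0.05 + rng.normal(0, 0.001, size=len(t))
        peaks_set = [GenomicBin("chr1", 10_000, 10_500)]
        pairs = pd.DataFrame(
            [("chr1", 10_250, 50_000 + 9_000 * k) for k in range(8)],
            columns=["chrom", "pos1", "pos2"],
        )
        rejections = sum(
            peaks.hic_proximity_compare(
                pairs, peaks_set, t, n_background=30, seed=s
            ).p_value
            < 0.05
            for s in range(20)
        )
        assert rejections <= 5
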