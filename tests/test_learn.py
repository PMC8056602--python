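import numpy as np
import pytest

from chipsim import fixtures as fx
from chipsim.io_formats import AlnRecord, Peak
from chipsim.learn import (
    DuplicateHistogram,
    build_duplicate_histogram,
    estimate_f,
    estimate_fraglen_single_end,
    estimate_pcr_p,
    estimate_s,
    fit_fragment_gamma,
    learn_all,
)
from chipsim.model_params import ChipModel, ExperimentParams
from chipsim.pipeline import as_alignment_records, simulate_placements


class TestEstimatePcrP:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ({1: 100}, 1.0),
            ({1: 50, 2: 25, 3: 25}, 1 / 1.75),
            ({2: 10}, 0.5),
        ],
    )
    def test_printed_formula(self, counts, expected):
        assert estimate_pcr_p(DuplicateHistogram(counts)) == pytest.approx(expected)

    @pytest.mark.parametrize("n", [1, 7, 1000])
    def test_no_duplicates_gives_one(self, n):
        assert estimate_pcr_p(DuplicateHistogram({1: n})) == 1.0

    def test_empty_histogram_rejected(self):
        with pytest.raises(ValueError):
            estimate_pcr_p(DuplicateHistogram({}))


class TestDuplicateHistogram:
    def test_grouping_by_position(self):
        recs = [AlnRecord("c", 100)] * 3 + [AlnRecord("c", 500)]
        hist = build_duplicate_histogram(recs)
        assert hist.counts == {3: 1, 1: 1}

    def test_all_unique(self):
        recs = [AlnRecord("c", i) for i in range(50)]
        assert build_duplicate_histogram(recs).counts == {1: 50}

    def test_strand_distinguishes_groups(self):
        recs = [AlnRecord("c", 100, is_reverse=False), AlnRecord("c", 100, is_reverse=True)]
        assert build_duplicate_histogram(recs).counts == {1: 2}

    def test_paired_counts_leftmost_mate_only(self):
        recs = [
            AlnRecord("c", 100, is_proper_pair=True, template_len=300),
            AlnRecord("c", 360, is_reverse=True, is_proper_pair=True, template_len=-300),
            AlnRecord("c", 100, is_proper_pair=True, template_len=300),
            AlnRecord("c", 360, is_reverse=True, is_proper_pair=True, template_len=-300),
        ]
        assert build_duplicate_histogram(recs, paired=True).counts == {2: 1}


class TestFitFragmentGamma:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(101)
        draws = rng.gamma(2.0, 100.0, 10_000)
        shape, scale = fit_fragment_gamma(draws)
        assert shape == pytest.approx(2.0, rel=0.10)
        assert scale == pytest.approx(100.0, rel=0.10)

    def test_agrees_with_method_of_moments(self):
        rng = np.random.default_rng(102)
        draws = rng.gamma(5.0, 40.0, 5_000)
        shape, scale = fit_fragment_gamma(draws)
        mean, var = draws.mean(), draws.var()
        mom_shape, mom_scale = mean**2 / var, var / mean
        assert shape == pytest.approx(mom_shape, rel=0.15)
        assert scale == pytest.approx(mom_scale, rel=0.15)

    def test_degenerate_identical_lengths(self):
        with pytest.raises(ValueError):
            fit_fragment_gamma([200.0] * 100)

    def test_nonpositive_lengths_rejected_with_count(self):
        with pytest.raises(ValueError, match="2 non-positive"):
            fit_fragment_gamma([100.0] * 60 + [0.0, -5.0])

    def test_too_few_observations(self):
        with pytest.raises(ValueError, match=">= 50"):
            fit_fragment_gamma([100.0, 150.0])


class TestEstimateF:
    def test_direct_arithmetic(self):
        assert estimate_f([Peak("c", 0, 1000, 1.0)], 10_000) == pytest.approx(0.1)

    def test_score_weighted(self):
        assert estimate_f([Peak("c", 0, 1000, 0.5)], 10_000) == pytest.approx(0.05)

    def test_full_coverage_clipped(self):
        f = estimate_f([Peak("c", 0, 10_000, 1.0)], 10_000)
        assert 0 < f < 1
        assert f == pytest.approx(1.0 - 1e-6)

    def test_overlapping_peaks_not_double_counted(self):
        f = estimate_f([Peak("c", 0, 1000, 1.0), Peak("c", 500, 1500, 1.0)], 10_000)
        assert f == pytest.approx(0.15)

    def test_empty_peaks_rejected(self):
        with pytest.raises(ValueError):
            estimate_f([], 10_000)


class TestEstimateS:
    def _records(self, positions):
        return [AlnRecord("c", p) for p in positions]

    def test_direct_ratio(self):
        peaks = [Peak("c", 0, 1000, 1.0)]
        recs = self._records(list(range(0, 300)) + list(range(2000, 2700)))
        assert estimate_s(recs, peaks) == pytest.approx(0.3)

    def test_all_in_peaks_clipped_below_one(self):
        peaks = [Peak("c", 0, 5000, 1.0)]
        recs = self._records(range(1000))
        s = estimate_s(recs, peaks)
        assert s < 1.0 and s == pytest.approx(1.0, abs=1e-5)

    def test_uniform_reads_match_peak_coverage(self):
        rng = np.random.default_rng(103)
        genome = 100_000
        peaks = [Peak("c", i * 10_000, i * 10_000 + 1000, 1.0) for i in range(10)]
        n = 20_000
        recs = self._records(rng.integers(0, genome, n))
        s = estimate_s(recs, peaks)
        assert abs(s - 0.10) < 3 * np.sqrt(0.1 * 0.9 / n)

    def test_order_invariant(self):
        peaks = [Peak("c", 0, 1000, 1.0)]
        positions = list(range(0, 300)) + list(range(2000, 2700))
        s1 = estimate_s(self._records(positions), peaks)
        s2 = estimate_s(self._records(positions[::-1]), peaks)
        assert s1 == s2

    def test_too_few_records(self):
        with pytest.raises(ValueError):
            estimate_s(self._records(range(10)), [Peak("c", 0, 100, 1.0)])


class TestSingleEndFraglen:
    def test_constructed_shift_recovered_exactly(self):
        # reverse-read 5' profile = forward profile shifted by 150
        rng = np.random.default_rng(104)
        readlen = 36
        fwd_pos = np.sort(rng.integers(0, 90_000, 3000))
        recs = [AlnRecord("c", int(p)) for p in fwd_pos]
        recs += [AlnRecord("c", int(p + 150 - readlen + 1), is_reverse=True) for p in fwd_pos]
        d = estimate_fraglen_single_end(recs, {"c": 100_000}, readlen)
        assert d == 150

    def test_simulated_single_end_recovery(self):
        """Self-consistency: estimate near the simulated 200 bp mean."""
        ref_lengths = {"chr1": 1_000_000}
        spec = fx.ToySpec(chrom_length=1_000_000, n_peaks=50, peak_length=(150, 250), seed=1)
        peaks = fx.make_peaks(spec, ref_lengths)
        f = estimate_f(peaks, 1_000_000)
        model = ChipModel(frag_shape=10.0, frag_scale=20.0, f=f, s=0.5, pcr_p=1.0)
        params = ExperimentParams(numreads=50_000, readlen=36, paired=False,
                                  numcopies=1000, seed=5)
        placements, _ = simulate_placements(ref_lengths, peaks, model, params)
        recs = as_alignment_records(placements, 36, paired=False)
        d = estimate_fraglen_single_end(recs, ref_lengths, 36)
        assert d == pytest.approx(200, abs=25)

    def test_single_strand_rejected(self):
        recs = [AlnRecord("c", i * 7) for i in range(2000)]
        with pytest.raises(ValueError, match="strand"):
            estimate_fraglen_single_end(recs, {"c": 100_000}, 36)


class TestLearnAll:
    def _simulate(self, model, numreads=100_000, numcopies=1200, seed=9, paired=True):
        ref_lengths = {"chr1": 1_000_000}
        spec = fx.ToySpec(chrom_length=1_000_000, n_peaks=10, peak_length=(5000, 5000), seed=2)
        peaks = fx.make_peaks(spec, ref_lengths)
        params = ExperimentParams(numreads=numreads, readlen=36, paired=paired,
                                  numcopies=numcopies, seed=seed)
        placements, _ = simulate_placements(ref_lengths, peaks, model, params)
        return as_alignment_records(placements, 36, paired), peaks, ref_lengths

    def test_round_trip_recovery(self):
        truth_f = 0.05  # 10 peaks x 5 kb on 1 Mb
        model = ChipModel(frag_shape=4.0, frag_scale=50.0, f=truth_f, s=0.5, pcr_p=0.8)
        recs, peaks, ref_lengths = self._simulate(model)
        learned, report = learn_all(recs, peaks, ref_lengths, paired=True)
        assert learned.f == pytest.approx(truth_f, abs=1e-9)
        assert learned.s == pytest.approx(model.s, abs=0.05)
        assert learned.pcr_p == pytest.approx(model.pcr_p, abs=0.05)
        assert learned.frag_mean == pytest.approx(model.frag_mean, rel=0.10)
        assert report["fraglen_method"] == "paired_mle"

    def test_paired_without_pairs_falls_back_with_warning(self):
        model = ChipModel(frag_shape=10.0, frag_scale=20.0, f=0.05, s=0.5, pcr_p=1.0)
        recs, peaks, ref_lengths = self._simulate(model, numreads=50_000, paired=False)
        with pytest.warns(UserWarning, match="single-end"):
            learned, report = learn_all(recs, peaks, ref_lengths, paired=True, readlen=36)
        assert "single_end" in report["fraglen_method"]

    def test_peaks_on_absent_chrom_ignored_with_warning(self):
        model = ChipModel(frag_shape=4.0, frag_scale=50.0, f=0.05, s=0.5, pcr_p=0.9)
        recs, peaks, ref_lengths = self._simulate(model)
        extra = peaks + [Peak("chrMissing", 0, 1000, 1.0)]
        with pytest.warns(UserWarning, match="absent"):
            learned, _ = learn_all(recs, extra, ref_lengths, paired=True)
        assert learned.f == pytest.approx(0.05, abs=1e-9)
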