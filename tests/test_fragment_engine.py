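import numpy as np
import pytest

from chipsim.fragment_engine import (
    FragmentArray,
    assign_binding,
    pcr_amplify,
    pulldown_sample,
    shear_copy,
    shear_genome,
)
from chipsim.io_formats import Peak
from chipsim.learn import DuplicateHistogram, estimate_pcr_p


def make_frags(n, bound_mask=None, chrom_len=1_000_000):
    starts = np.arange(n, dtype=np.int64) * 200
    return FragmentArray(
        ("chr1",),
        np.zeros(n, np.int32),
        starts,
        starts + 200,
        np.zeros(n, bool) if bound_mask is None else np.asarray(bound_mask, bool),
        np.zeros(n, np.int32),
    )


class TestShear:
    def test_tiling_no_gaps_no_overlaps(self, rng):
        frags = shear_copy({"chr1": 100_000}, 2.0, 100.0, rng)
        starts, ends = frags.starts, frags.ends
        assert np.all(starts[1:] == ends[:-1])
        assert ends[-1] <= 100_000

    def test_lengths_match_gamma_mean(self):
        rng = np.random.default_rng(0)
        frags = shear_genome({"chr1": 100_000}, 2.0, 100.0, 2000, rng)
        # interior fragments only: the truncated tail biases the mean down
        interior = frags.lengths[frags.ends < 100_000]
        assert np.mean(interior) == pytest.approx(200.0, rel=0.02)

    def test_mean_longer_than_chrom_gives_single_fragment(self, rng):
        frags = shear_copy({"chr1": 500}, 10.0, 1000.0, rng)
        # one copy: a single fragment covering (almost) the whole chromosome
        assert len(frags) == 1
        assert frags.ends[0] == 500

    def test_copy_indices_recorded(self):
        rng = np.random.default_rng(3)
        frags = shear_genome({"chr1": 20_000}, 2.0, 100.0, 5, rng)
        assert set(np.unique(frags.copy_index)) == set(range(5))

    def test_min_final_len_drops_short_tail(self):
        # force many copies; no kept fragment that touches the chromosome
        # end may be shorter than the requested minimum
        rng = np.random.default_rng(4)
        frags = shear_genome({"chr1": 10_000}, 2.0, 100.0, 50, rng, min_final_len=36)
        tails = frags.lengths[frags.ends == 10_000]
        assert np.all(tails >= 36)

    def test_invalid_gamma_params(self, rng):
        with pytest.raises(ValueError):
            shear_copy({"chr1": 1000}, 0.0, 100.0, rng)


class TestAssignBinding:
    def test_score_one_peak_always_binds(self, rng):
        frags = make_frags(100)
        out = assign_binding(frags, [Peak("chr1", 0, 20_000, 1.0)], rng)
        assert out.bound[:100].all()

    def test_no_overlap_never_bound(self, rng):
        frags = make_frags(50)
        out = assign_binding(frags, [Peak("chr1", 500_000, 501_000, 1.0)], rng)
        assert not out.bound.any()

    def test_binomial_rate_at_score(self):
        rng = np.random.default_rng(5)
        n = 10_000
        frags = make_frags(n, chrom_len=int(3e6))
        out = assign_binding(frags, [Peak("chr1", 0, n * 200, 0.3)], rng)
        rate = out.bound.mean()
        tol = 3 * np.sqrt(0.3 * 0.7 / n)
        assert abs(rate - 0.3) < tol

    def test_max_score_under_multi_overlap(self):
        # fragment spans two peaks; binding must use the larger score
        frags = FragmentArray(
            ("chr1",), np.zeros(1, np.int32), np.array([90], np.int64),
            np.array([210], np.int64), np.zeros(1, bool), np.zeros(1, np.int32),
        )
        hits = 0
        for seed in range(300):
            out = assign_binding(
                frags, [Peak("chr1", 0, 100, 0.05), Peak("chr1", 200, 300, 0.95)],
                np.random.default_rng(seed),
            )
            hits += int(out.bound[0])
        assert hits / 300 > 0.8  # ~0.95, far above the 0.05 alternative


class TestPulldown:
    def test_subset_and_size(self, rng):
        frags = make_frags(1000)
        sel = pulldown_sample(frags, 2.0, 100, rng)
        assert len(sel) == 100
        assert set(sel.starts).issubset(set(frags.starts))

    def test_small_pool_returns_all_with_warning(self, rng):
        frags = make_frags(10)
        with pytest.warns(UserWarning, match="numcopies"):
            sel = pulldown_sample(frags, 2.0, 50, rng)
        assert len(sel) == 10

    def test_neutral_alpha_keeps_bound_fraction(self):
        rng = np.random.default_rng(6)
        bound = np.zeros(50_000, bool)
        bound[:5000] = True
        frags = make_frags(50_000, bound)
        sel = pulldown_sample(frags, 1.0, 10_000, rng)
        assert sel.bound.mean() == pytest.approx(0.1, abs=0.01)

    @pytest.mark.parametrize(
        "alpha,f_pool,n_target",
        [(5.0, 0.1, 100_000), (20.0, 0.02, 50_000), (0.5, 0.3, 100_000)],
    )
    def test_closed_form_bound_fraction(self, alpha, f_pool, n_target):
        """Selected-bound fraction matches alpha*f/(alpha*f + 1 - f).

        Sampling fractions are kept low enough that no weight saturates
        (the closed form assumes uncapped inclusion probabilities).
        """
        rng = np.random.default_rng(7)
        n = 1_000_000
        bound = rng.random(n) < f_pool
        frags = make_frags(n, bound)
        sel = pulldown_sample(frags, alpha, n_target, rng)
        fb = bound.mean()
        expected = alpha * fb / (alpha * fb + 1 - fb)
        assert sel.bound.mean() == pytest.approx(expected, rel=0.02)

    def test_empty_pool_rejected(self, rng):
        with pytest.raises(ValueError):
            pulldown_sample(make_frags(0), 1.0, 10, rng)


class TestPcrAmplify:
    def test_p_one_is_identity(self, rng):
        frags = make_frags(100)
        out, origin = pcr_amplify(frags, 1.0, rng)
        assert len(out) == 100
        assert np.array_equal(origin, np.arange(100))

    def test_mean_multiplicity_is_inverse_p(self):
        rng = np.random.default_rng(8)
        frags = make_frags(100_000)
        out, origin = pcr_amplify(frags, 0.5, rng)
        assert len(out) / 100_000 == pytest.approx(2.0, rel=0.02)

    def test_round_trip_with_pcr_estimator(self):
        """estimate_pcr_p recovers p from the emitted multiplicities."""
        rng = np.random.default_rng(9)
        frags = make_frags(100_000)
        for p in (0.5, 0.8):
            _, origin = pcr_amplify(frags, p, rng)
            mult = np.bincount(origin)[np.bincount(origin) > 0]
            vals, counts = np.unique(mult, return_counts=True)
            hist = DuplicateHistogram(dict(zip(vals.tolist(), counts.tolist())))
            assert estimate_pcr_p(hist) == pytest.approx(p, abs=0.02)

    def test_invalid_p(self, rng):
        with pytest.raises(ValueError):
            pcr_amplify(make_frags(5), 0.0, rng)


class TestDeterminism:
    def test_identical_seed_identical_stream(self):
        ref = {"chr1": 200_000}
        peaks = [Peak("chr1", 1000, 3000, 0.8)]
        outs = []
        for _ in range(2):
            rng = np.random.default_rng(42)
            frags = shear_genome(ref, 2.0, 100.0, 20, rng)
            frags = assign_binding(frags, peaks, np.random.default_rng(43))
            sel = pulldown_sample(frags, 3.0, 5000, np.random.default_rng(44))
            amp, origin = pcr_amplify(sel, 0.8, np.random.default_rng(45))
            outs.append((amp.starts.copy(), amp.ends.copy(), origin.copy()))
        assert np.array_equal(outs[0][0], outs[1][0])
        assert np.array_equal(outs[0][1], outs[1][1])
        assert np.array_equal(outs[0][2], outs[1][2])
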