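"""Weighted correlations, shuffle machinery, sequence classification, QR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hipposeq import sequences
from hipposeq.sequences import (
    circular_weighted_correlation,
    classify_frames,
    joint_threshold_comparison,
    quadrant_ratio,
    sequence_metrics,
    shuffled_weighted_correlations,
    weighted_correlation,
)


def diagonal_posterior(T, L, width=0.0):
    P = np.zeros((T, L))
    idx = np.linspace(0, L - 1, T).round().astype(int)
    P[np.arange(T), idx] = 1.0
    return P


def weighted_corr_bruteforce(P, locs=None, times=None):
    """Direct double-summation of the weighted moments (oracle)."""
    P = np.asarray(P, float)
    T, L = P.shape
    locs = np.arange(L, dtype=float) if locs is None else locs
    times = np.arange(T, dtype=float) if times is None else times
    W = P.sum()
    m_loc = sum(P[i, j] * locs[j] for i in range(T) for j in range(L)) / W
    m_t = sum(P[i, j] * times[i] for i in range(T) for j in range(L)) / W

    def cov(a_vals, b_vals):
        return sum(
            P[i, j] * a_vals[i][j] * b_vals[i][j]
            for i in range(T) for j in range(L)
        ) / W

    dl = [[locs[j] - m_loc for j in range(L)] for _ in range(T)]
    dt = [[times[i] - m_t for _ in range(L)] for i in range(T)]
    c_lt, c_ll, c_tt = cov(dl, dt), cov(dl, dl), cov(dt, dt)
    if c_ll * c_tt <= 0:
        return 0.0
    return c_lt / np.sqrt(c_ll * c_tt)


class TestWeightedCorrelation:
    def test_diagonal_is_one(self):
        assert weighted_correlation(diagonal_posterior(8, 8)) == pytest.approx(1.0)

    def test_antidiagonal_is_minus_one(self):
        assert weighted_correlation(
            diagonal_posterior(8, 8)[:, ::-1]) == pytest.approx(-1.0)

    def test_uniform_posterior_gives_zero(self):
        """Spatial variance is positive but cov(loc, t) vanishes: r = 0."""
        P = np.full((5, 10), 0.1)
        assert weighted_correlation(P) == pytest.approx(0.0, abs=1e-12)

    def test_matches_double_summation_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            P = rng.random((5, 10))
            P /= P.sum(axis=1, keepdims=True)
            assert weighted_correlation(P) == pytest.approx(
                weighted_corr_bruteforce(P), abs=1e-9)

    @given(st.integers(0, 1000))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_bounded_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.random((6, 12))
        P /= P.sum(axis=1, keepdims=True)
        assert -1.0 - 1e-12 <= weighted_correlation(P) <= 1.0 + 1e-12


class TestShuffles:
    def test_fast_and_direct_paths_agree_on_same_permutations(self):
        rng = np.random.default_rng(3)
        P = rng.random((9, 30))
        P /= P.sum(axis=1, keepdims=True)
        perms = np.vstack([rng.permutation(9) for _ in range(40)])
        fast = shuffled_weighted_correlations(P, 0, rng, method="fast",
                                              permutations=perms)
        direct = shuffled_weighted_correlations(P, 0, rng, method="direct",
                                                permutations=perms)
        assert np.allclose(fast, direct, atol=1e-12)

    def test_shuffle_preserves_column_multisets(self):
        """Time-bin permutation conserves each 20-ms column intact."""
        rng = np.random.default_rng(4)
        P = rng.random((7, 11))
        P /= P.sum(axis=1, keepdims=True)
        perm = rng.permutation(7)
        assert np.allclose(np.sort(P, axis=0), np.sort(P[perm], axis=0))

    def test_shuffle_mean_r_near_zero(self):
        rng = np.random.default_rng(5)
        P = rng.random((12, 25))
        P /= P.sum(axis=1, keepdims=True)
        shuf = shuffled_weighted_correlations(P, 2000, rng)
        assert abs(shuf.mean()) < 3 * shuf.std() / np.sqrt(shuf.size)


def circ_lin_bruteforce(P, track_length):
    """Sample (loc, t) pairs with probability Pr_ij, then the classical
    unweighted circular-linear coefficient on the sample (oracle)."""
    rng = np.random.default_rng(99)
    T, L = P.shape
    flat = (P / P.sum()).ravel()
    idx = rng.choice(T * L, size=60_000, p=flat)
    t = (idx // L).astype(float)
    theta = 2 * np.pi * (idx % L) / (track_length / 1.0)
    rxc = np.corrcoef(t, np.cos(theta))[0, 1]
    rxs = np.corrcoef(t, np.sin(theta))[0, 1]
    rcs = np.corrcoef(np.cos(theta), np.sin(theta))[0, 1]
    return np.sqrt(max(
        (rxc**2 + rxs**2 - 2 * rxc * rxs * rcs) / (1 - rcs**2), 0.0))


class TestCircular:
    def test_magnitude_matches_resampling_oracle(self):
        rng = np.random.default_rng(15)
        P = rng.random((8, 20)) ** 3
        P /= P.sum(axis=1, keepdims=True)
        ours = abs(circular_weighted_correlation(P, track_length=20))
        oracle = circ_lin_bruteforce(P, 20)
        assert ours == pytest.approx(oracle, abs=0.05)

    def test_full_track_diagonal_matches_linear_qualitatively(self):
        P = diagonal_posterior(10, 40)
        assert abs(circular_weighted_correlation(P)) > 0.6

    def test_wraparound_trajectory_high_circular_low_linear(self):
        L, T = 40, 10
        P = np.zeros((T, L))
        for t in range(T):
            P[t, (30 + 4 * t) % L] = 1.0   # runs off the end, wraps to start
        assert abs(weighted_correlation(P)) < 0.5
        assert abs(circular_weighted_correlation(P)) > 0.6

    def test_uniform_degenerate(self):
        assert circular_weighted_correlation(
            np.full((6, 10), 0.1)) == pytest.approx(0.0, abs=1e-12)


class TestSequenceMetrics:
    def test_stationary_posterior_zero_jumps(self):
        P = np.zeros((6, 10))
        P[:, 4] = 1.0
        st_ = sequence_metrics(P, track_length=10, n_shuffles=50,
                               rng=np.random.default_rng(0))
        assert st_.median_jump == 0.0 and st_.max_jump == 0.0

    def test_diagonal_five_bin_jump_is_fifth_of_track(self):
        """Perfect 5-bin diagonal with 20-cm steps on 100 cm: jump 0.2."""
        P = np.zeros((5, 100))
        for t in range(5):
            P[t, 10 + 20 * t] = 1.0
        st_ = sequence_metrics(P, track_length=100, n_shuffles=50,
                               rng=np.random.default_rng(0))
        assert st_.median_jump == pytest.approx(0.2)
        assert st_.max_jump == pytest.approx(0.2)

    def test_random_columns_sequence_score_zero_mean(self):
        rng = np.random.default_rng(6)
        scores = []
        for _ in range(60):
            P = rng.random((10, 30))
            P /= P.sum(axis=1, keepdims=True)
            scores.append(sequence_metrics(P, 30, 200, rng).r_Z)
        scores = np.asarray(scores)
        assert abs(scores.mean()) < 3 * scores.std() / np.sqrt(scores.size)

    def test_short_frames_rejected(self):
        with pytest.raises(ValueError):
            sequence_metrics(np.full((4, 10), 0.1), 10)


class TestClassifyFrames:
    def test_sequence_free_frames_near_chance(self):
        """Structureless frames: significant fraction inside binomial CI."""
        rng = np.random.default_rng(7)
        posts = []
        for _ in range(300):
            P = rng.random((rng.integers(5, 20), 50))
            P /= P.sum(axis=1, keepdims=True)
            posts.append(P)
        res = classify_frames(posts, 50.0, n_shuffles=200,
                              rng=np.random.default_rng(8))
        from scipy.stats import binom
        lo, hi = binom.interval(0.999, 300, 0.05)
        assert lo <= res["n_significant"] <= hi

    def test_perfect_replays_all_significant(self):
        posts = [diagonal_posterior(8, 50) for _ in range(20)]
        res = classify_frames(posts, 50.0, n_shuffles=200,
                              rng=np.random.default_rng(9))
        assert res["proportion"] == 1.0
        assert res["binomial_p"] < 1e-10

    def test_zero_frames_raises(self):
        with pytest.raises(ValueError):
            classify_frames([], 50.0)


class TestJointThresholds:
    def test_no_threshold_pair_passes_everything(self):
        df = pd.DataFrame(dict(r_Z=[0.5, 1.2], median_jump=[0.1, 0.3],
                               r=[0.2, 0.4], max_jump=[0.2, 0.5]))
        out = joint_threshold_comparison(df, df, kind="score_jump")
        assert out["prop_a"][0, -1] == 1.0   # no score threshold, jump < 1

    def test_identical_populations_rarely_significant(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame(dict(
            r_Z=rng.normal(0, 1, 400), median_jump=rng.uniform(0, 1, 400),
            r=rng.uniform(-1, 1, 400), max_jump=rng.uniform(0, 1, 400)))
        df2 = df.sample(frac=1.0, random_state=0)
        out = joint_threshold_comparison(df, df2, kind="score_jump")
        assert np.nanmin(out["p"]) > 0.4   # identical proportions, p = 0.5

    def test_contrast_concentrates_at_stringent_thresholds(self):
        rng = np.random.default_rng(11)
        seq = pd.DataFrame(dict(
            r_Z=rng.normal(2.5, 0.5, 300), median_jump=rng.uniform(0, 0.3, 300),
            r=rng.uniform(0.6, 1, 300), max_jump=rng.uniform(0, 0.4, 300)))
        null = pd.DataFrame(dict(
            r_Z=rng.normal(0, 1, 300), median_jump=rng.uniform(0, 1, 300),
            r=rng.uniform(-1, 1, 300), max_jump=rng.uniform(0, 1, 300)))
        out = joint_threshold_comparison(seq, null, kind="score_jump")
        # the printed pair: score > 1.6 (grid index 5), jump < 0.375 (idx 2)
        i = np.where(np.isclose(out["score_grid"], 1.6))[0][0]
        j = np.where(np.isclose(out["jump_grid"], 0.375))[0][0]
        assert out["p"][i, j] < 0.001

    def test_surrogate_percentile_mode(self):
        rng = np.random.default_rng(12)
        mk = lambda n, hi: pd.DataFrame(dict(
            r=rng.uniform(0, hi, n), max_jump=rng.uniform(0, 1, n),
            r_Z=rng.normal(0, 1, n), median_jump=rng.uniform(0, 1, n)))
        data = mk(200, 1.0)
        surr = [mk(200, 0.5) for _ in range(50)]
        out = joint_threshold_comparison(data, surr, kind="wcorr_maxjump")
        assert out["p"][-1].min() < 0.05   # |r| > 0.9 never reached by surrogates


class TestQuadrantRatio:
    def test_mass_in_q1_q3_gives_one(self):
        m = np.zeros((5, 5))
        m[3:, 3:] = 1.0   # future-ahead
        m[:2, :2] = 1.0   # past-behind
        assert quadrant_ratio(m) == 1.0

    def test_uniform_matrix_gives_zero(self):
        assert quadrant_ratio(np.ones((6, 8))) == pytest.approx(0.0)

    def test_matches_manual_quadrant_sums(self):
        rng = np.random.default_rng(13)
        m = rng.random((7, 9))
        q1 = m[4:, 5:].sum()
        q3 = m[:3, :4].sum()
        q2 = m[:3, 5:].sum()
        q4 = m[4:, :4].sum()
        expected = (q1 + q3 - q2 - q4) / (q1 + q2 + q3 + q4)
        assert quadrant_ratio(m) == pytest.approx(expected, abs=1e-12)

    def test_generator_theta_sequences_detected(self, base_config,
                                                run_session, encoding_model):
        from hipposeq import decoding, events, synth
        lfp = synth.generate_lfp(base_config, run=run_session)
        cycles = events.extract_theta_cycles(
            lfp, run_session.spikes, run_session.time, run_session.position,
            run_session.velocity, run_session.direction,
            run_session.track_length, which_direction=1)
        posts = [decoding.decode(c.counts[encoding_model.unit_ids],
                                 encoding_model, 0.02) for c in cycles]
        res = sequences.theta_quadrant_ratio(
            posts, [c.meta["position"] for c in cycles],
            [c.meta["direction"] for c in cycles],
            run_session.track_length, n_shuffles=200,
            rng=np.random.default_rng(14))
        assert res["quadrant_ratio"] > 0
        assert res["significant"]


class TestTrackSpecific:
    def test_single_track_rejected(self, sleep_frames, encoding_model):
        with pytest.raises(ValueError):
            sequences.track_specific_events(sleep_frames[:4],
                                            {"t1": encoding_model}, 100.0)

    def test_identical_models_give_zero_specific(self, sleep_frames,
                                                 encoding_model):
        res = sequences.track_specific_events(
            sleep_frames[:30], {"t1": encoding_model, "t2": encoding_model},
            100.0, n_shuffles=100, rng=np.random.default_rng(0))
        assert res["proportion_specific"] == 0.0


class TestRobustness:
    def test_zero_bin_removal_matches_baseline(self, sleep_frames,
                                               encoding_model):
        res = sequences.robustness_suite(
            sleep_frames[:25], encoding_model, "bin_removal_start_end",
            100.0, n_shuffles=100, rng=np.random.default_rng(1),
            max_remove=1)
        assert res["cumulative_proportion"][0] == pytest.approx(
            res["baseline_proportion"])
        assert (res["cumulative_proportion"][1]
                >= res["cumulative_proportion"][0])

    def test_unknown_variant_rejected(self, sleep_frames, encoding_model):
        with pytest.raises(ValueError):
            sequences.robustness_suite(sleep_frames[:5], encoding_model,
                                       "nope", 100.0)

    @staticmethod
    def _symmetric_model_and_primary(rng, n_units=40):
        """Encoding model whose every map is exactly mirror-symmetric (so a
        decoded posterior cannot tell a location from its track mirror),
        plus the true one-sided tuning the spikes are drawn from."""
        from hipposeq.decoding import DecodingModel
        from hipposeq.synth import tuning_rate
        centres = rng.uniform(0, 100, n_units)
        x = np.arange(100) + 0.5
        sym = np.vstack([
            tuning_rate(x, c, 6.0, 12.0, mirror_weight=1.0, track_length=100.0)
            for c in centres])
        primary = np.vstack([
            tuning_rate(x, c, 6.0, 12.0, mirror_weight=0.0, track_length=100.0)
            for c in centres])
        model = DecodingModel(rates=sym, unit_ids=np.arange(n_units),
                              bin_centres=x, direction=1, track_length=100.0)
        return model, primary

    def test_end_truncation_rescues_end_ambiguous_frames(self):
        """Sequences decoded by mirror-symmetric maps carry no net
        direction (every row is end-ambiguous); removing 30 cm of one
        end's maps disambiguates them and they become significant."""
        from conftest import make_frame
        rng = np.random.default_rng(2)
        model, primary = self._symmetric_model_and_primary(rng)
        path = np.array([5.0, 15.0, 25.0, 35.0, 45.0, 55.0, 65.0])
        frames = []
        for _ in range(10):
            counts = np.zeros((model.rates.shape[0], path.size))
            for b, x in enumerate(path):
                counts[:, b] = rng.poisson(primary[:, int(x)] * 0.02 * 15)
            frames.append(make_frame(counts))
        res = sequences.robustness_suite(
            frames, model, "map_truncation_ends", 100.0, n_shuffles=200,
            rng=np.random.default_rng(3))
        assert (max(res["reduced_proportion"].values())
                > res["baseline_proportion"] + 0.3)

    def test_bin_removal_rescues_end_swapped_frames(self, encoding_model):
        """Frames whose two leading bins depict the wrong track end become
        significant once those bins are removed from the frame start."""
        from conftest import make_frame
        rng = np.random.default_rng(6)
        model = encoding_model
        path = np.array([95.0, 90.0, 25.0, 35.0, 45.0, 55.0, 65.0, 75.0])
        frames = []
        for _ in range(10):
            counts = np.zeros((max(model.unit_ids) + 1, path.size))
            for b, x in enumerate(path):
                j = np.argmin(np.abs(model.bin_centres - x))
                counts[model.unit_ids, b] = rng.poisson(
                    model.rates[:, j] * 0.02 * 15)
            frames.append(make_frame(counts))
        res = sequences.robustness_suite(
            frames, model, "bin_removal_start_end", 100.0, n_shuffles=200,
            rng=np.random.default_rng(7), max_remove=2)
        assert (res["cumulative_proportion"][2]
                > res["cumulative_proportion"][0] + 0.3)

    def test_poisson_surrogate_of_structureless_frames_indistinguishable(
            self, encoding_model):
        from conftest import make_frame
        rng = np.random.default_rng(4)
        model = encoding_model
        mean_rate = model.rates.mean(axis=1)
        frames = []
        for _ in range(40):
            T = int(rng.integers(6, 15))
            counts = np.zeros((max(model.unit_ids) + 1, T))
            counts[model.unit_ids] = rng.poisson(
                mean_rate[:, None] * 0.02 * 5, size=(mean_rate.size, T))
            frames.append(make_frame(counts))
        res = sequences.robustness_suite(
            frames, model, "poisson_surrogate_single", 100.0,
            n_shuffles=100, rng=np.random.default_rng(5))
        assert res["p"] > 0.05
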