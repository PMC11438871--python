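"""Cell-pair / frame-pair similarity, clustering and cluster specificity."""

import numpy as np
import pytest
from scipy.stats import kstest

from hipposeq import ensembles
from hipposeq.ensembles import (
    cell_pair_correlations,
    cluster_frames,
    cluster_specificity,
    cosine_distance_matrix,
    frame_run_similarity,
    frame_similarity,
)


def planted_cluster_counts(rng, n_units=30, n_frames=90, k=3, gain=4.0):
    sets = np.array_split(rng.permutation(n_units), k)
    counts = rng.poisson(0.1, size=(n_units, n_frames)).astype(float)
    labels = np.arange(n_frames) % k
    for j in range(n_frames):
        counts[sets[labels[j]], j] += rng.poisson(gain, size=sets[labels[j]].size)
    return counts, labels


class TestCellPairs:
    def test_proportional_coactive_pair_is_significant(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(3.0, 50).astype(float) + 1
        counts = np.vstack([base, 2 * base, rng.poisson(2.0, 50)])
        df = cell_pair_correlations(counts, n_shuffles=300,
                                    rng=np.random.default_rng(1))
        pair = df[(df.unit_i == 0) & (df.unit_j == 1)].iloc[0]
        assert pair.r == pytest.approx(1.0)
        assert pair.percentile > 0.95 and pair.significant

    def test_independent_counts_near_five_percent_significant(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(2.0, size=(16, 120))
        df = cell_pair_correlations(counts, n_shuffles=200,
                                    rng=np.random.default_rng(3))
        prop = df.significant.mean()
        assert 0.01 <= prop <= 0.10   # 120 pairs, nominal 0.05

    def test_silent_unit_flagged(self):
        rng = np.random.default_rng(4)
        counts = np.vstack([np.zeros(20), rng.poisson(2.0, size=(3, 20))])
        df = cell_pair_correlations(counts, n_shuffles=50,
                                    rng=np.random.default_rng(5))
        assert df[df.unit_i == 0].flagged.all()


class TestFrameSimilarity:
    def test_identical_frames_score_high(self):
        rng = np.random.default_rng(6)
        v = rng.poisson(3.0, 20).astype(float)
        counts = np.column_stack([v, v, rng.poisson(3.0, 20)])
        scores, sig, corr = frame_similarity(counts, n_shuffles=300,
                                             rng=np.random.default_rng(7))
        assert scores[0, 1] > 0.95 and sig[0, 1]
        assert corr[0, 1] == pytest.approx(1.0)

    def test_disjoint_cell_sets_score_low(self):
        counts = np.zeros((12, 2))
        counts[:6, 0] = 5.0
        counts[6:, 1] = 5.0
        scores, sig, corr = frame_similarity(counts, n_shuffles=300,
                                             rng=np.random.default_rng(8))
        assert corr[0, 1] < 0
        assert not sig[0, 1]

    def test_matrix_symmetric_with_zero_diagonal(self):
        rng = np.random.default_rng(9)
        counts = rng.poisson(2.0, size=(15, 25)).astype(float)
        scores, sig, _ = frame_similarity(counts, n_shuffles=100,
                                          rng=np.random.default_rng(10))
        assert np.allclose(scores, scores.T, atol=1e-12, equal_nan=True)
        assert np.all(np.diag(scores) == 0)
        assert not np.any(np.diag(sig))

    def test_self_shuffle_percentiles_uniform(self):
        """Scoring IID frames against their own null: percentiles ~ U(0,1)."""
        rng = np.random.default_rng(11)
        counts = rng.poisson(2.0, size=(25, 60)).astype(float)
        scores, _, _ = frame_similarity(counts, n_shuffles=400,
                                        rng=np.random.default_rng(12))
        iu = np.triu_indices(60, k=1)
        vals = scores[iu]
        vals = vals[~np.isnan(vals)]
        assert kstest(vals, "uniform").pvalue > 1e-4

    def test_scores_invariant_under_joint_relabeling(self):
        """Relabeling cells leaves pair correlations identical and the
        shuffle percentiles statistically unchanged (the null is over
        random relabelings, so exact equality holds only in distribution)."""
        rng = np.random.default_rng(13)
        counts = rng.poisson(2.0, size=(18, 40)).astype(float)
        s1, g1, c1 = frame_similarity(counts, n_shuffles=400,
                                      rng=np.random.default_rng(14))
        perm = np.random.default_rng(15).permutation(18)
        s2, g2, c2 = frame_similarity(counts[perm], n_shuffles=400,
                                      rng=np.random.default_rng(14))
        assert np.allclose(c1, c2, atol=1e-12)
        iu = np.triu_indices(40, k=1)
        assert abs(np.nanmean(s1[iu] - s2[iu])) < 0.02
        assert np.mean(g1[iu] == g2[iu]) > 0.9


class TestClustering:
    def test_planted_clusters_recovered(self):
        from sklearn.metrics import adjusted_rand_score
        rng = np.random.default_rng(16)
        counts, labels = planted_cluster_counts(rng)
        scores, sig, _ = frame_similarity(counts, n_shuffles=300,
                                          rng=np.random.default_rng(17))
        res = cluster_frames(sig.astype(float), k_range=(2, 8), n_iter=20,
                             rng=np.random.default_rng(18))
        assert res.k_optimal == 3
        assert adjusted_rand_score(labels, res.labels) >= 0.9

    def test_duplicated_frames_trivial_two_clusters(self):
        a, b = np.zeros(10), np.zeros(10)
        a[:5] = 1.0
        b[5:] = 1.0
        X = np.vstack([a] * 25 + [b] * 25)
        res = cluster_frames(X, k_range=(2, 6), n_iter=10,
                             rng=np.random.default_rng(19))
        assert res.k_optimal == 2
        assert res.silhouette > 0.95

    def test_cell_id_shuffle_destroys_recovery(self):
        from sklearn.metrics import adjusted_rand_score
        rng = np.random.default_rng(20)
        counts, labels = planted_cluster_counts(rng)
        shuffled = np.column_stack([
            counts[rng.permutation(counts.shape[0]), j]
            for j in range(counts.shape[1])
        ])
        scores, sig, _ = frame_similarity(shuffled, n_shuffles=300,
                                          rng=np.random.default_rng(21))
        if not sig.any():
            return  # no structure at all: recovery trivially fails
        res = cluster_frames(sig.astype(float), k_range=(2, 8), n_iter=10,
                             rng=np.random.default_rng(22))
        assert adjusted_rand_score(labels, res.labels) < 0.5

    def test_within_cluster_similarity_exceeds_across(self):
        rng = np.random.default_rng(23)
        counts, _ = planted_cluster_counts(rng)
        scores, sig, corr = frame_similarity(counts, n_shuffles=200,
                                             rng=np.random.default_rng(24))
        res = cluster_frames(sig.astype(float), k_range=(2, 8), n_iter=10,
                             rng=np.random.default_rng(25))
        same = res.labels[:, None] == res.labels[None, :]
        iu = np.triu_indices(len(res.labels), k=1)
        within = corr[iu][same[iu]]
        across = corr[iu][~same[iu]]
        assert within.mean() > across.mean()

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            cluster_frames(np.zeros((10, 10)))

    def test_cosine_distance_properties(self):
        rng = np.random.default_rng(26)
        X = rng.random((8, 5))
        X[2] = 0.0
        d = cosine_distance_matrix(X)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert d[2, 3] == 1.0   # zero row: similarity 0 to everything


class TestClusterSpecificity:
    def test_single_track_cluster_is_fully_specific(self):
        labels = np.zeros(10, int)
        sig = np.zeros((10, 3), bool)
        sig[:, 1] = True
        assert cluster_specificity(labels, sig)[0] == pytest.approx(1.0)

    def test_equal_probability_gives_one_over_tracks(self):
        labels = np.zeros(30, int)
        sig = np.zeros((30, 3), bool)
        sig[:10, 0] = sig[10:20, 1] = sig[20:, 2] = True
        assert cluster_specificity(labels, sig)[0] == pytest.approx(1 / 3)

    def test_direct_ratio_evaluation(self):
        """Pr = (0.2, 0.1, 0.1) -> CSI = 0.2 / 0.4 = 0.5."""
        labels = np.zeros(10, int)
        sig = np.zeros((10, 3), bool)
        sig[:2, 0] = True
        sig[2, 1] = True
        sig[3, 2] = True
        assert cluster_specificity(labels, sig)[0] == pytest.approx(0.5)

    def test_no_significant_frames_is_nan(self):
        out = cluster_specificity(np.zeros(5, int), np.zeros((5, 2), bool))
        assert np.isnan(out[0])


class TestFrameRunSimilarity:
    def test_rate_matched_frame_significant(self):
        rng = np.random.default_rng(27)
        peaks = rng.uniform(1, 15, 30)
        counts = np.column_stack([
            rng.poisson(peaks * 0.5), rng.poisson(peaks[::-1] * 0.5)])
        df = frame_run_similarity(counts, peaks, n_shuffles=300,
                                  rng=np.random.default_rng(28))
        assert df.iloc[0].significant
        assert not df.iloc[1].significant

    def test_constant_peak_vector_rejected(self):
        with pytest.raises(ValueError):
            frame_run_similarity(np.ones((5, 3)), np.ones(5))
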