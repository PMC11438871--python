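"""Frame-level ensemble structure across sleep frames.

Frames are summarised by per-unit spike-count vectors.  Cell-pair
correlations are normalised by frame-ID shuffles; frame-pair similarity is
the shuffle percentile (0-1) of the Pearson correlation of the two count
vectors against cell-ID permutations, significant above 0.95.  The
binarised frame-pair significance matrix is clustered by k-means with
cosine dissimilarity, selecting k by the modal argmax of a cluster-level
silhouette over random restarts; cluster specificity (CSI) measures the
dominance of one track's significant-sequence probability within a cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import shuffle_percentile

__all__ = [
    "frame_count_matrix",
    "cell_pair_correlations",
    "frame_similarity",
    "cosine_distance_matrix",
    "cosine_kmeans",
    "cluster_silhouettes",
    "cluster_frames",
    "ClusterResult",
    "cluster_specificity",
    "frame_run_similarity",
]


def frame_count_matrix(frames) -> np.ndarray:
    """Units x frames matrix of within-frame spike counts."""
    return np.column_stack([f.counts.sum(axis=1) for f in frames])


def _pearson(x, y):
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def cell_pair_correlations(
    counts: np.ndarray,
    n_shuffles: int = 500,
    rng: np.random.Generator | None = None,
    alpha_percentile: float = 0.95,
) -> pd.DataFrame:
    """Shuffle-normalised Pearson correlations for all unit pairs.

    For each pair, both units' frame vectors are randomly reassigned frame
    IDs ``n_shuffles`` times; the normalised value is the percentile (0-1)
    of the real correlation within the shuffles.  Pairs involving a
    constant (e.g. silent) vector are flagged and skipped.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    counts = np.asarray(counts, float)
    n_units, n_frames = counts.shape
    if n_units < 2 or n_frames < 10:
        raise ValueError("need >= 2 units and >= 10 frames")
    rows = []
    for i in range(n_units):
        for j in range(i + 1, n_units):
            x, y = counts[i], counts[j]
            if x.std() == 0 or y.std() == 0:
                rows.append(dict(unit_i=i, unit_j=j, r=float("nan"),
                                 percentile=float("nan"), significant=False,
                                 flagged=True))
                continue
            r = _pearson(x, y)
            xs = x[np.argsort(rng.random((n_shuffles, n_frames)), axis=1)]
            ys = y[np.argsort(rng.random((n_shuffles, n_frames)), axis=1)]
            xc = xs - xs.mean(axis=1, keepdims=True)
            yc = ys - ys.mean(axis=1, keepdims=True)
            shuf = (xc * yc).sum(axis=1) / (
                np.linalg.norm(xc, axis=1) * np.linalg.norm(yc, axis=1)
            )
            pct = shuffle_percentile(r, shuf)
            rows.append(dict(unit_i=i, unit_j=j, r=r, percentile=pct,
                             significant=pct > alpha_percentile, flagged=False))
    return pd.DataFrame(rows)


def frame_similarity(
    counts: np.ndarray,
    n_shuffles: int = 500,
    rng: np.random.Generator | None = None,
    alpha_percentile: float = 0.95,
):
    """Frame-pair similarity scores (cell-ID-shuffle percentiles, 0-1).

    Returns (scores, significant, correlations): symmetric frames x frames
    matrices with zeroed diagonals.  A shared set of ``n_shuffles`` cell-ID
    permutations is applied to one side of every pair.  Pairs involving a
    zero-spike frame are NaN-flagged.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    X = np.asarray(counts, float)
    n_units, n_frames = X.shape
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    sd = X.std(axis=0)
    valid = sd > 0
    Xc = X - X.mean(axis=0, keepdims=True)
    norm = np.linalg.norm(Xc, axis=0)
    norm[~valid] = 1.0
    Xn = Xc / norm
    corr = Xn.T @ Xn

    count_ge = np.zeros((n_frames, n_frames))
    count_eq = np.zeros((n_frames, n_frames))
    for _ in range(n_shuffles):
        perm = rng.permutation(n_units)
        Yc = X[perm] - X.mean(axis=0, keepdims=True)
        Yn = Yc / norm
        shuf_corr = Xn.T @ Yn
        # similarity of pair (i, j): real corr vs corr(frame_i, shuffled frame_j)
        count_ge += shuf_corr < corr
        count_eq += shuf_corr == corr
    scores = (count_ge + 0.5 * count_eq) / n_shuffles
    scores = 0.5 * (scores + scores.T)
    bad = ~valid
    scores[bad, :] = np.nan
    scores[:, bad] = np.nan
    np.fill_diagonal(scores, 0.0)
    significant = np.zeros_like(scores, dtype=bool)
    ok = ~np.isnan(scores)
    significant[ok] = scores[ok] > alpha_percentile
    np.fill_diagonal(significant, False)
    corr = corr.copy()
    np.fill_diagonal(corr, 0.0)
    return scores, significant, corr


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def cosine_distance_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise cosine distances of row vectors; zero rows -> distance 1."""
    X = np.asarray(X, float)
    norms = np.linalg.norm(X, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    Xn = X / safe[:, None]
    sim = Xn @ Xn.T
    sim[norms == 0, :] = 0.0
    sim[:, norms == 0] = 0.0
    d = 1.0 - sim
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def cosine_kmeans(X, k, rng, n_iter=50):
    """Spherical k-means (cosine dissimilarity), random data-point init.

    Zero rows have no direction; they are assigned to the nearest centroid
    by cosine distance convention (similarity 0 to everything), i.e. the
    first centroid, and do not steer the centroids.
    """
    X = np.asarray(X, float)
    n = X.shape[0]
    norms = np.linalg.norm(X, axis=1)
    Xn = X / np.where(norms > 0, norms, 1.0)[:, None]
    nonzero = norms > 0
    init = rng.choice(np.where(nonzero)[0] if nonzero.any() else n, size=k,
                      replace=nonzero.sum() < k)
    C = Xn[init].copy()
    labels = np.zeros(n, int)
    for _ in range(n_iter):
        sim = Xn @ C.T
        new_labels = np.argmax(sim, axis=1)
        if np.array_equal(new_labels, labels) and _ > 0:
            break
        labels = new_labels
        for c in range(k):
            members = nonzero & (labels == c)
            if members.any():
                v = Xn[members].sum(axis=0)
                nv = np.linalg.norm(v)
                C[c] = v / nv if nv > 0 else C[c]
            else:  # re-seed empty cluster
                C[c] = Xn[rng.integers(n)]
    return labels


def cluster_silhouettes(dist: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Cluster-level silhouette (a - w) / max(w, a) per cluster.

    ``w`` is the mean within-cluster pairwise distance and ``a`` the mean
    pairwise distance to the nearest other cluster.
    """
    labs = np.unique(labels)
    out = np.full(labs.size, np.nan)
    for idx, c in enumerate(labs):
        mc = labels == c
        within = dist[np.ix_(mc, mc)]
        iu = np.triu_indices(int(mc.sum()), k=1)
        w = within[iu].mean() if iu[0].size else 0.0
        a = np.inf
        for c2 in labs:
            if c2 == c:
                continue
            m2 = labels == c2
            a = min(a, dist[np.ix_(mc, m2)].mean())
        if not np.isfinite(a):
            continue
        denom = max(w, a)
        out[idx] = (a - w) / denom if denom > 0 else 0.0
    return out


@dataclass
class ClusterResult:
    labels: np.ndarray
    k_optimal: int
    silhouette: float                 # mean cluster silhouette at k_optimal
    k_votes: dict                     # k -> number of iterations voting for it
    per_cluster_silhouette: np.ndarray


def cluster_frames(
    significant: np.ndarray,
    k_range=(2, 30),
    n_iter: int = 100,
    rng: np.random.Generator | None = None,
) -> ClusterResult:
    """Cluster frames on their binary pair-significance rows.

    For each of ``n_iter`` random restarts, k-means with cosine
    dissimilarity is run at every k in ``k_range`` and the k with the
    highest mean cluster silhouette recorded; the optimal k is the mode of
    those votes (ties broken toward smaller k) and the final labels come
    from the restart with the best silhouette at that k.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    X = np.asarray(significant, float)
    if not X.any():
        raise ValueError("all-zero similarity matrix: nothing to cluster")
    n = X.shape[0]
    k_lo, k_hi = k_range
    k_hi = min(k_hi, n - 1)
    dist = cosine_distance_matrix(X)
    votes: dict[int, int] = {}
    best_at_k: dict[int, tuple[float, np.ndarray]] = {}
    for _ in range(n_iter):
        best_k, best_sil = None, -np.inf
        for k in range(k_lo, k_hi + 1):
            labels = cosine_kmeans(X, k, rng)
            sil = np.nanmean(cluster_silhouettes(dist, labels))
            if np.isnan(sil):
                continue
            if sil > best_sil:
                best_sil, best_k = sil, k
            prev = best_at_k.get(k)
            if prev is None or sil > prev[0]:
                best_at_k[k] = (sil, labels)
        if best_k is not None:
            votes[best_k] = votes.get(best_k, 0) + 1
    if not votes:
        raise ValueError("no valid clustering found")
    top = max(votes.values())
    k_opt = min(k for k, v in votes.items() if v == top)
    sil, labels = best_at_k[k_opt]
    return ClusterResult(
        labels=labels, k_optimal=k_opt, silhouette=float(sil),
        k_votes=votes,
        per_cluster_silhouette=cluster_silhouettes(dist, labels),
    )


def cluster_specificity(labels: np.ndarray, sig_table: np.ndarray):
    """CSI = max_i(Pr_i) / sum_i(Pr_i) per cluster over I tracks.

    ``sig_table`` is frames x tracks (bool): significance of each frame for
    each track's template.  Pr_i is the within-cluster probability of
    significance for track i.  Clusters with no significant frame are NaN.
    """
    sig = np.asarray(sig_table, float)
    out = {}
    for c in np.unique(labels):
        pr = sig[labels == c].mean(axis=0)
        total = pr.sum()
        out[int(c)] = float(pr.max() / total) if total > 0 else float("nan")
    return out


def frame_run_similarity(
    counts: np.ndarray,
    peak_rates: np.ndarray,
    n_shuffles: int = 500,
    rng: np.random.Generator | None = None,
    alpha_percentile: float = 0.95,
) -> pd.DataFrame:
    """Frame-vs-run ensemble similarity against cell-ID shuffles.

    Each frame's count vector is correlated with the run peak-rate
    population vector; significance is a percentile above 0.95 over
    ``n_shuffles`` cell-ID permutations of the frame vector.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    X = np.asarray(counts, float)
    v = np.asarray(peak_rates, float)
    if v.std() == 0:
        raise ValueError("degenerate (constant) peak-rate vector")
    rows = []
    n_units = X.shape[0]
    for j in range(X.shape[1]):
        x = X[:, j]
        if x.std() == 0:
            rows.append(dict(frame=j, r=float("nan"),
                             percentile=float("nan"), significant=False,
                             flagged=True))
            continue
        r = _pearson(x, v)
        xs = x[np.argsort(rng.random((n_shuffles, n_units)), axis=1)]
        xc = xs - xs.mean(axis=1, keepdims=True)
        vc = v - v.mean()
        shuf = (xc @ vc) / (np.linalg.norm(xc, axis=1) * np.linalg.norm(vc))
        pct = shuffle_percentile(r, shuf)
        rows.append(dict(frame=j, r=r, percentile=pct,
                         significant=pct > alpha_percentile, flagged=False))
    return pd.DataFrame(rows)
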