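"""Population-vector geometry of linear space.

The stacked 2-cm place maps of an ensemble define a population vector (PV)
per location.  Location-by-location PV correlation matrices expose
track-end similarity (mean correlation between the 15%-of-length end
zones) and representational "warping" — elevated similarity between
symmetric, equidistant locations about the track middle, quantified by the
correlation and least-squares slope of PV similarity vs separation over
24-88 cm.  Across tracks, matched-location PV correlations measure pattern
separation against a cell-ID-shuffle chance floor.  A decoded-frame
contingency analysis quantifies track-end specificity of short-timescale
sequential structure.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from sklearn.decomposition import PCA

__all__ = [
    "stack_maps",
    "pv_matrix",
    "track_end_similarity",
    "warp_profile",
    "manifold_pca",
    "pattern_separation",
    "end_specificity",
]


def stack_maps(maps) -> np.ndarray:
    """Units x locations matrix from a rate-map collection."""
    return np.vstack([np.asarray(m.rates, float) for m in maps])


def pv_matrix(maps) -> np.ndarray:
    """Location-by-location Pearson correlation of population vectors.

    Locations whose population vector is constant (e.g. all-zero) give NaN
    rows/columns.
    """
    X = stack_maps(maps) if not isinstance(maps, np.ndarray) else maps
    if X.shape[0] < 2:
        raise ValueError("need at least 2 units")
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(X.T)
    C[sd == 0, :] = np.nan
    C[:, sd == 0] = np.nan
    return C


def track_end_similarity(maps, end_fraction: float = 0.15) -> float:
    """Mean PV correlation between the two track-end zones.

    End zones cover ``end_fraction`` of the track length at each end; the
    value is the mean correlation over all end-1 x end-2 bin pairs.
    """
    X = stack_maps(maps) if not isinstance(maps, np.ndarray) else maps
    C = pv_matrix(X)
    L = X.shape[1]
    k = max(int(round(end_fraction * L)), 1)
    block = C[:k, L - k:]
    if np.all(np.isnan(block)):
        raise ValueError("end-zone population vectors are all undefined")
    return float(np.nanmean(block))


def warp_profile(
    maps,
    bin_size: float = 2.0,
    min_sep_cm: float = 24.0,
    max_sep_cm: float = 88.0,
):
    """PV similarity of symmetric two-bin segments vs their separation.

    Two-bin segments tile outward from the track middle; each symmetric
    pair contributes its mean cross-segment PV correlation at its
    centre-to-centre separation.  The terminal segments are excluded.
    Returns separations, correlations, and the Pearson R and least-squares
    slope (per cm) over separations within [min_sep_cm, max_sep_cm].
    """
    X = stack_maps(maps) if not isinstance(maps, np.ndarray) else maps
    C = pv_matrix(X)
    L = X.shape[1]
    mid = L // 2
    n_seg = mid // 2
    seps, corrs = [], []
    for k in range(n_seg):
        right = [mid + 2 * k, mid + 2 * k + 1]
        left = [mid - 2 - 2 * k, mid - 1 - 2 * k]
        if right[1] >= L or left[0] < 0:
            break
        if k == n_seg - 1 or right[1] >= L - 1 or left[0] <= 0:
            break  # terminal segments not considered
        vals = C[np.ix_(left, right)]
        if np.all(np.isnan(vals)):
            continue
        centre_sep = (np.mean(right) - np.mean(left)) * bin_size
        seps.append(centre_sep)
        corrs.append(float(np.nanmean(vals)))
    seps = np.asarray(seps)
    corrs = np.asarray(corrs)
    sel = (seps >= min_sep_cm) & (seps <= max_sep_cm)
    if sel.sum() < 3 or np.std(corrs[sel]) < 1e-12:
        return {"separation_cm": seps, "pv_correlation": corrs,
                "R": float("nan"), "p": float("nan"),
                "slope": float("nan"), "flagged": True}
    R, p = sps.pearsonr(seps[sel], corrs[sel])
    slope = np.polyfit(seps[sel], corrs[sel], 1)[0]
    return {"separation_cm": seps, "pv_correlation": corrs,
            "R": float(R), "p": float(p), "slope": float(slope),
            "flagged": False}


def manifold_pca(maps, n_components: int = 3):
    """Low-dimensional embedding of the spatial population trajectory.

    Each spatial bin's population vector is min-max normalised (maximally
    active unit set to 1, zeros preserved), then PCA is run over locations.
    Returns the first ``n_components`` coordinates per location and the
    cumulative explained-variance curve.
    """
    X = stack_maps(maps) if not isinstance(maps, np.ndarray) else maps
    if X.shape[0] < 4:
        raise ValueError("need at least 4 units")
    col_max = X.max(axis=0)
    keep = col_max > 0
    Xn = X[:, keep] / col_max[keep]
    pca = PCA(n_components=min(Xn.shape) - 1)
    coords = pca.fit_transform(Xn.T)
    return {
        "coords": coords[:, :n_components],
        "cumulative_variance": np.cumsum(pca.explained_variance_ratio_),
        "kept_bins": np.where(keep)[0],
    }


def pattern_separation(
    maps_a,
    maps_b,
    mode: str = "full",
    n_shuffles: int = 500,
    rng: np.random.Generator | None = None,
    window_bins: int = 10,
    bin_size: float = 2.0,
):
    """Across-track PV correlations with a cell-ID-shuffle chance floor.

    ``mode="full"``: Pearson correlation of the two tracks' population
    vectors at every matched location.  ``mode="ends"``/``"middles"``: the
    correlation of 10-bin (20-cm) windows at opposite track ends / at the
    two middles.  ``mode="rates"``: correlations of the per-unit peak-rate
    and mean-rate vectors across tracks.  Chance comes from ``n_shuffles``
    random cell-ID shuffles of one track's maps.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    A = stack_maps(maps_a) if not isinstance(maps_a, np.ndarray) else maps_a
    B = stack_maps(maps_b) if not isinstance(maps_b, np.ndarray) else maps_b
    if A.shape != B.shape:
        raise ValueError("tracks must share the unit universe and length")
    n, L = A.shape

    def col_corr(X, Y):
        sx, sy = X.std(axis=0), Y.std(axis=0)
        ok = (sx > 0) & (sy > 0)
        Xc = X - X.mean(axis=0)
        Yc = Y - Y.mean(axis=0)
        out = np.full(L, np.nan)
        out[ok] = (Xc[:, ok] * Yc[:, ok]).sum(axis=0) / (n * sx[ok] * sy[ok])
        return out

    if mode == "full":
        corr = col_corr(A, B)
        chance = np.array([
            np.nanmean(col_corr(A[rng.permutation(n)], B))
            for _ in range(n_shuffles)
        ])
        return {"correlations": corr, "mean": float(np.nanmean(corr)),
                "chance_mean": chance, "chance_p95": float(np.percentile(chance, 95))}
    if mode in ("ends", "middles"):
        if mode == "ends":
            wa = A[:, :window_bins].mean(axis=1)
            wb = B[:, L - window_bins:].mean(axis=1)
        else:
            lo = L // 2 - window_bins // 2
            wa = A[:, lo:lo + window_bins].mean(axis=1)
            wb = B[:, lo:lo + window_bins].mean(axis=1)
        if wa.std() == 0 or wb.std() == 0:
            return {"correlation": float("nan"), "chance": np.full(n_shuffles, np.nan)}
        r = float(np.corrcoef(wa, wb)[0, 1])
        chance = np.array([
            np.corrcoef(wa[rng.permutation(n)], wb)[0, 1]
            for _ in range(n_shuffles)
        ])
        return {"correlation": r, "chance": chance,
                "chance_p95": float(np.percentile(chance, 95))}
    if mode == "rates":
        peak_r = float(np.corrcoef(A.max(axis=1), B.max(axis=1))[0, 1])
        mean_r = float(np.corrcoef(A.mean(axis=1), B.mean(axis=1))[0, 1])
        return {"peak_rate_correlation": peak_r, "mean_rate_correlation": mean_r}
    raise ValueError(f"unknown mode: {mode}")


def end_specificity(
    posteriors,
    track_length: float,
    end_cm: float = 15.0,
):
    """T-1 time-space contingency of decoded frames and track-end specificity.

    For every 20-ms frame bin after the first, the full posterior of the
    preceding bin is accumulated by the current bin's peak decoded
    location.  End specificity is the mean prior-bin probability mass in
    the correct 15-cm end zone divided by the mass in the opposite end, for
    bins peaking in an end zone; the middle control replaces the correct
    end with a 15-cm window on the track middle vs both ends.
    """
    from .sequences import _as_prob

    first = _as_prob(posteriors[0])
    L = first[0].shape[1]
    locs = first[1]
    contingency = np.zeros((L, L))
    counts = np.zeros(L)
    n_bins = 0
    for post in posteriors:
        prob, _ = _as_prob(post)
        peaks = np.argmax(prob, axis=1)
        for t in range(1, prob.shape[0]):
            contingency[peaks[t]] += prob[t - 1]
            counts[peaks[t]] += 1
            n_bins += 1
    if n_bins < 100:
        raise ValueError("need at least 100 decoded frame bins")
    ok = counts > 0
    contingency[ok] /= counts[ok, None]

    end1 = locs <= end_cm
    end2 = locs >= track_length - end_cm
    mid_lo = track_length / 2 - end_cm / 2
    middle = (locs >= mid_lo) & (locs < mid_lo + end_cm)

    def zone_ratio(peak_zone, same_zone, other_zone):
        sel = ok & peak_zone
        if not sel.any():
            return float("nan")
        same = contingency[np.ix_(sel, same_zone)].mean()
        other = contingency[np.ix_(sel, other_zone)].mean()
        return float(same / other) if other > 0 else float("inf")

    r1 = zone_ratio(end1, end1, end2)
    r2 = zone_ratio(end2, end2, end1)
    spec = float(np.nanmean([r1, r2]))
    mid_spec = zone_ratio(middle, middle, end1 | end2)
    return {
        "contingency": contingency,
        "end_specificity": spec,
        "per_end": (r1, r2),
        "middle_specificity": mid_spec,
        "n_bins": n_bins,
    }
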