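"""Trajectory-sequence statistics for decoded frames and theta cycles.

The core replay statistic is the weighted space-time correlation of a
frame's decoded posterior: the product-moment correlation between time-bin
and location, weighted by the posterior probability mass Pr_ij.  Its
significance is judged against within-frame time-bin permutation shuffles
(which conserve each 20-ms column of decoded probabilities intact): a frame
is a forward (reverse) sequence when r exceeds the 97.5th (falls below the
2.5th) shuffle percentile.  The sequence score is the shuffle z of |r|;
jump distances summarise the per-bin peak-location displacements; the theta
quadrant ratio summarises forward sweep content of animal-centred decoded
matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats as hstats
from .decoding import DecodingModel, Posterior, decode

__all__ = [
    "SequenceStats",
    "weighted_correlation",
    "circular_weighted_correlation",
    "shuffled_weighted_correlations",
    "sequence_metrics",
    "classify_frames",
    "joint_threshold_comparison",
    "track_specific_events",
    "robustness_suite",
    "quadrant_ratio",
    "theta_quadrant_ratio",
    "SCORE_GRID",
    "MEDIAN_JUMP_GRID",
    "WCORR_GRID",
    "MAX_JUMP_GRID",
]

# printed threshold grids for the joint comparisons
SCORE_GRID = np.r_[-np.inf, np.arange(0.0, 2.81, 0.4)]
MEDIAN_JUMP_GRID = np.arange(0.125, 1.001, 0.125)
WCORR_GRID = np.arange(0.0, 0.91, 0.1)
MAX_JUMP_GRID = np.arange(0.1, 1.001, 0.1)


def _as_prob(post) -> tuple[np.ndarray, np.ndarray]:
    """(T x L probability matrix, location values) from Posterior or array."""
    if isinstance(post, Posterior):
        return np.asarray(post.prob, float), np.asarray(post.bin_centres_cm, float)
    p = np.asarray(post, float)
    return p, np.arange(p.shape[1], dtype=float)


def _weighted_moments(prob, locs, times):
    w = prob.sum()
    m_loc = (prob * locs[None, :]).sum() / w
    m_t = (prob * times[:, None]).sum() / w
    dl = locs[None, :] - m_loc
    dt = times[:, None] - m_t
    cov_lt = (prob * dl * dt).sum() / w
    cov_ll = (prob * dl * dl).sum() / w
    cov_tt = (prob * dt * dt).sum() / w
    return cov_lt, cov_ll, cov_tt


def weighted_correlation(post, locs=None, times=None) -> float:
    """Posterior-weighted space-time correlation r in [-1, 1].

    Degenerate inputs (zero weighted variance in either axis, e.g. a
    uniform posterior) return 0.0.
    """
    prob, default_locs = _as_prob(post)
    locs = default_locs if locs is None else np.asarray(locs, float)
    times = (np.arange(prob.shape[0], dtype=float)
             if times is None else np.asarray(times, float))
    cov_lt, cov_ll, cov_tt = _weighted_moments(prob, locs, times)
    denom = cov_ll * cov_tt
    if denom <= 0:
        return 0.0
    return float(cov_lt / np.sqrt(denom))


def circular_weighted_correlation(post, track_length=None) -> float:
    """Weighted circular-linear correlation treating space as circular.

    Locations map to angles 2*pi*loc/L; the magnitude is the weighted form
    of the standard circular-linear coefficient (square root of the R^2 of
    the sine/cosine regression on time), signed by the fitted rotation
    direction.  Degenerate posteriors return 0.0.
    """
    prob, locs = _as_prob(post)
    if track_length is None:
        track_length = locs[-1] + (locs[1] - locs[0]) if locs.size > 1 else 1.0
    theta = 2 * np.pi * locs / track_length
    T = prob.shape[0]
    t = np.arange(T, dtype=float)
    W = prob.sum()
    if W <= 0:
        return 0.0
    cos_j, sin_j = np.cos(theta), np.sin(theta)

    def joint_corr(row_vals, col_vals):
        # weighted correlation over the joint (time, space) mass
        ma = (prob * row_vals[:, None]).sum() / W if row_vals is not None else None
        a = (row_vals[:, None] - ma) if row_vals is not None else None
        mb = (prob * col_vals[None, :]).sum() / W
        b = col_vals[None, :] - mb
        cov = (prob * a * b).sum() / W
        va = (prob * a * a).sum() / W
        vb = (prob * b * b).sum() / W
        if va * vb <= 0:
            return 0.0
        return cov / np.sqrt(va * vb)

    def col_col_corr(u, v):
        q = prob.sum(axis=0) / W                  # space marginal
        mu, mv = (q * u).sum(), (q * v).sum()
        cov = (q * (u - mu) * (v - mv)).sum()
        vu = (q * (u - mu) ** 2).sum()
        vv = (q * (v - mv) ** 2).sum()
        if vu * vv <= 0:
            return 0.0
        return cov / np.sqrt(vu * vv)

    r_tc = joint_corr(t, cos_j)
    r_ts = joint_corr(t, sin_j)
    r_cs = col_col_corr(cos_j, sin_j)
    denom = 1.0 - r_cs ** 2
    if denom <= 0 or (r_tc == 0.0 and r_ts == 0.0):
        return 0.0
    r2 = (r_tc ** 2 + r_ts ** 2 - 2 * r_tc * r_ts * r_cs) / denom
    r = float(np.sqrt(max(r2, 0.0)))
    # rotation sign: cross product of the mean resultant and its time drift
    w_t = prob.sum(axis=1)
    cbar = (prob @ cos_j) / np.maximum(w_t, 1e-300)
    sbar = (prob @ sin_j) / np.maximum(w_t, 1e-300)
    tc = t - t.mean()
    sign = np.sign(cbar.mean() * (tc * sbar).sum()
                   - sbar.mean() * (tc * cbar).sum())
    return r * (sign if sign != 0 else 1.0)


def shuffled_weighted_correlations(
    post, n_shuffles: int, rng: np.random.Generator, method: str = "fast",
    locs=None, permutations: np.ndarray | None = None,
) -> np.ndarray:
    """Weighted correlations of time-bin-permutation shuffles of a frame.

    ``method="fast"`` exploits that row sums of a posterior are 1, so a row
    permutation leaves the weighted time and space marginals unchanged and
    only the cross-covariance term varies; ``method="direct"`` permutes the
    matrix and recomputes from scratch (oracle path).
    """
    prob, default_locs = _as_prob(post)
    locs = default_locs if locs is None else np.asarray(locs, float)
    T = prob.shape[0]
    times = np.arange(T, dtype=float)
    if permutations is None:
        perms = None
    else:
        perms = np.asarray(permutations)
        n_shuffles = perms.shape[0]
    if method == "direct" or not np.allclose(prob.sum(axis=1), 1.0, atol=1e-9):
        out = np.empty(n_shuffles)
        for k in range(n_shuffles):
            perm = rng.permutation(T) if perms is None else perms[k]
            out[k] = weighted_correlation(prob[perm], locs=locs)
        return out
    m_loc = (prob * locs[None, :]).sum() / T
    s = prob @ (locs - m_loc)                      # per-row location deviation
    tc = times - times.mean()
    cov_ll = (prob * (locs[None, :] - m_loc) ** 2).sum() / T
    cov_tt = (tc ** 2).mean()
    denom = np.sqrt(cov_ll * cov_tt)
    if denom <= 0:
        return np.zeros(n_shuffles)
    if perms is None:
        perms = np.argsort(rng.random((n_shuffles, T)), axis=1)
    return (s[perms] @ tc) / T / denom


@dataclass
class SequenceStats:
    """Per-frame trajectory-sequence statistics."""

    r: float
    r_Z: float
    median_jump: float
    max_jump: float
    sig_forward: bool
    sig_reverse: bool
    degenerate: bool
    r_circ: float = float("nan")
    shuffle_p975: float = float("nan")
    shuffle_p025: float = float("nan")

    @property
    def significant(self) -> bool:
        return self.sig_forward or self.sig_reverse


def sequence_metrics(
    post,
    track_length: float | None = None,
    n_shuffles: int = 500,
    rng: np.random.Generator | None = None,
    compute_circular: bool = False,
    forward_pct: float = 97.5,
    reverse_pct: float = 2.5,
) -> SequenceStats:
    """Weighted correlation, sequence score, jumps, and shuffle significance.

    Frames need at least 5 time bins.  r_Z = (|r| - mean|r_shuf|) / SD|r_shuf|;
    jump distances are |delta peak location| / track length over consecutive
    bins.
    """
    prob, locs = _as_prob(post)
    if prob.shape[0] < 5:
        raise ValueError("frame has fewer than 5 time bins")
    rng = np.random.default_rng(0) if rng is None else rng
    if track_length is None:
        track_length = locs[-1] - locs[0] + (locs[1] - locs[0] if locs.size > 1 else 1)

    times = np.arange(prob.shape[0], dtype=float)
    cov_lt, cov_ll, cov_tt = _weighted_moments(prob, locs, times)
    degenerate = cov_ll * cov_tt <= 0
    r = 0.0 if degenerate else float(cov_lt / np.sqrt(cov_ll * cov_tt))
    shuf = shuffled_weighted_correlations(prob, n_shuffles, rng, locs=locs)
    abs_shuf = np.abs(shuf)
    sd = abs_shuf.std()
    r_z = (abs(r) - abs_shuf.mean()) / sd if sd > 0 else float("nan")
    p_hi = float(np.percentile(shuf, forward_pct))
    p_lo = float(np.percentile(shuf, reverse_pct))
    # exact Monte Carlo convention: "above the 97.5th percentile" tested as
    # (1 + #{shuffles >= r}) / (n + 1) <= 0.025, which has exact size (the
    # interpolated empirical percentile overshoots alpha by ~n^-1)
    alpha_fwd = (100.0 - forward_pct) / 100.0
    alpha_rev = reverse_pct / 100.0
    p_fwd = (1 + (shuf >= r).sum()) / (n_shuffles + 1)
    p_rev = (1 + (shuf <= r).sum()) / (n_shuffles + 1)

    peaks = locs[np.argmax(prob, axis=1)]
    jumps = np.abs(np.diff(peaks)) / track_length
    return SequenceStats(
        r=r,
        r_Z=float(r_z),
        median_jump=float(np.median(jumps)),
        max_jump=float(np.max(jumps)),
        sig_forward=(not degenerate) and p_fwd <= alpha_fwd,
        sig_reverse=(not degenerate) and p_rev <= alpha_rev,
        degenerate=degenerate,
        r_circ=(circular_weighted_correlation(prob, track_length)
                if compute_circular else float("nan")),
        shuffle_p975=p_hi,
        shuffle_p025=p_lo,
    )


def _frame_rngs(rng: np.random.Generator, n: int) -> list[np.random.Generator]:
    """Per-frame generators derived from one root stream (reproducible)."""
    seeds = rng.integers(0, 2**31 - 1, size=n)
    return [np.random.default_rng(int(s)) for s in seeds]


def frames_to_posteriors(frames, model: DecodingModel, tau: float = 0.02):
    """Decode each frame's 20-ms counts with the given encoding model."""
    return [decode(f.counts[model.unit_ids], model, tau) for f in frames]


def classify_frames(
    posteriors,
    track_length: float | None = None,
    n_shuffles: int = 500,
    rng: np.random.Generator | None = None,
    group_ids=None,
    chance: float = 0.05,
):
    """Significant-sequence proportion with the three chance comparisons.

    Each frame's weighted correlation is tested against its own time-bin
    shuffles (two-sided 97.5/2.5 rule).  The proportion of significant
    frames is compared to (1) the proportion in a one-permutation shuffled
    dataset (two-proportion z), (2) binomial chance, and (3) across groups
    (one-sample t vs chance) when ``group_ids`` is given.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    frame_rngs = _frame_rngs(rng, 2 * len(posteriors))
    rows, shuffled_sig = [], []
    for k, post in enumerate(posteriors):
        prob, locs = _as_prob(post)
        if prob.shape[0] < 5:
            rows.append(None)
            continue
        st = sequence_metrics(prob, track_length, n_shuffles,
                              frame_rngs[2 * k], forward_pct=97.5,
                              reverse_pct=2.5)
        rows.append(st)
        # shuffled-dataset counterpart: one permutation, same test
        r2 = frame_rngs[2 * k + 1]
        perm = r2.permutation(prob.shape[0])
        st_s = sequence_metrics(prob[perm], track_length, n_shuffles, r2)
        shuffled_sig.append(st_s.significant)
    kept = [s for s in rows if s is not None]
    if not kept:
        raise ValueError("no frames with at least 5 time bins")
    sig = np.array([s.significant for s in kept])
    prop = float(sig.mean())
    shuffled_prop = float(np.mean(shuffled_sig))
    z, p_vs_shuffle = hstats.two_proportion_ztest(
        sig.sum(), sig.size, int(np.sum(shuffled_sig)), len(shuffled_sig),
        alternative="greater",
    )
    binom_p = sps.binomtest(int(sig.sum()), sig.size, chance,
                            alternative="greater").pvalue
    out = {
        "proportion": prop,
        "n_frames": int(sig.size),
        "n_significant": int(sig.sum()),
        "shuffled_proportion": shuffled_prop,
        "p_vs_shuffled": float(p_vs_shuffle),
        "binomial_p": float(binom_p),
        "per_frame": pd.DataFrame(
            [dict(r=s.r, r_Z=s.r_Z, median_jump=s.median_jump,
                  max_jump=s.max_jump, sig_forward=s.sig_forward,
                  sig_reverse=s.sig_reverse, degenerate=s.degenerate)
             for s in kept]
        ),
    }
    if group_ids is not None:
        gid = np.asarray([g for g, s in zip(group_ids, rows) if s is not None])
        props = [sig[gid == g].mean() for g in np.unique(gid)]
        t, p = sps.ttest_1samp(props, chance)
        out["p_vs_chance_groups"] = float(p / 2 if t > 0 else 1 - p / 2)
    return out


def joint_threshold_comparison(
    stats_a: pd.DataFrame,
    stats_b,
    kind: str = "score_jump",
):
    """Proportion-passing matrices over joint threshold grids, with tests.

    ``kind="score_jump"``: sequence score (increasing grid, incl. no
    threshold) x median jump (decreasing); A vs B compared per cell by a
    one-sided two-proportion z-test.  ``kind="wcorr_maxjump"``: |weighted
    correlation| x maximum jump; when ``stats_b`` is a list of surrogate
    stat tables, the p-value is 1 - percentile of A's proportion among the
    surrogates.
    """
    if kind == "score_jump":
        s_grid, j_grid, s_col, j_col = SCORE_GRID, MEDIAN_JUMP_GRID, "r_Z", "median_jump"
        abs_stat = False
    elif kind == "wcorr_maxjump":
        s_grid, j_grid, s_col, j_col = WCORR_GRID, MAX_JUMP_GRID, "r", "max_jump"
        abs_stat = True
    else:
        raise ValueError(f"unknown kind: {kind}")

    def prop_matrix(df):
        s = np.abs(df[s_col].to_numpy()) if abs_stat else df[s_col].to_numpy()
        j = df[j_col].to_numpy()
        return np.array([
            [np.mean((s > st) & (j < jt)) for jt in j_grid] for st in s_grid
        ])

    pa = prop_matrix(stats_a)
    if isinstance(stats_b, pd.DataFrame):
        pb = prop_matrix(stats_b)
        na, nb = len(stats_a), len(stats_b)
        pvals = np.empty_like(pa)
        for i in range(pa.shape[0]):
            for k in range(pa.shape[1]):
                _, pvals[i, k] = hstats.two_proportion_ztest(
                    int(round(pa[i, k] * na)), na,
                    int(round(pb[i, k] * nb)), nb, alternative="greater",
                )
        return {"prop_a": pa, "prop_b": pb, "p": pvals,
                "score_grid": s_grid, "jump_grid": j_grid}
    surr = np.stack([prop_matrix(df) for df in stats_b])
    pct = (surr < pa[None]).mean(axis=0)
    return {"prop_a": pa, "prop_surrogates": surr, "p": 1.0 - pct,
            "score_grid": s_grid, "jump_grid": j_grid}


def track_specific_events(
    frames,
    models: dict,
    track_length: float,
    tau: float = 0.02,
    n_shuffles: int = 500,
    rng: np.random.Generator | None = None,
):
    """Proportion of frames significant for exactly one of several tracks.

    Each frame is decoded with every track's encoding model and tested with
    the two-sided shuffle rule; a frame counts as track-specific when it is
    significant for one track and non-significant for all others.  The
    shuffled-dataset control applies the same exclusive-significance rule.
    """
    if len(models) < 2:
        raise ValueError("need at least 2 track models")
    rng = np.random.default_rng(0) if rng is None else rng
    track_ids = list(models)
    sig = np.zeros((len(frames), len(track_ids)), bool)
    sig_shuf = np.zeros_like(sig)
    # one seed per frame, re-used across tracks: identical models then see
    # identical shuffle draws and reach identical decisions
    frame_seeds = rng.integers(0, 2**31 - 1, size=len(frames))
    usable = np.ones(len(frames), bool)
    for i, frame in enumerate(frames):
        for j, tid in enumerate(track_ids):
            model = models[tid]
            post = decode(frame.counts[model.unit_ids], model, tau)
            if post.prob.shape[0] < 5:
                usable[i] = False
                break
            r_i = np.random.default_rng(int(frame_seeds[i]))
            st = sequence_metrics(post, track_length, n_shuffles, r_i)
            sig[i, j] = st.significant
            perm = r_i.permutation(post.prob.shape[0])
            st_s = sequence_metrics(post.prob[perm], track_length,
                                    n_shuffles, r_i)
            sig_shuf[i, j] = st_s.significant
    sig, sig_shuf = sig[usable], sig_shuf[usable]
    specific = sig.sum(axis=1) == 1
    specific_shuf = sig_shuf.sum(axis=1) == 1
    n = int(usable.sum())
    return {
        "proportion_specific": float(specific.mean()) if n else float("nan"),
        "proportion_specific_shuffled": float(specific_shuf.mean()) if n else float("nan"),
        "per_frame_significance": sig,
        "track_ids": track_ids,
        "n_frames": n,
    }


def _truncate_model(model: DecodingModel, lo_cm: float, hi_cm: float) -> DecodingModel:
    """Drop spatial bins with centre in [lo_cm, hi_cm) from the model."""
    keep = ~((model.bin_centres >= lo_cm) & (model.bin_centres < hi_cm))
    return DecodingModel(
        rates=model.rates[:, keep], unit_ids=model.unit_ids,
        bin_centres=model.bin_centres[keep], direction=model.direction,
        track_length=model.track_length, rate_floor=model.rate_floor,
    )


def robustness_suite(
    frames,
    model: DecodingModel,
    variant: str,
    track_length: float,
    tau: float = 0.02,
    n_shuffles: int = 500,
    rng: np.random.Generator | None = None,
    max_remove: int = 3,
    truncate_cm: float = 30.0,
    n_surrogates: int = 500,
):
    """Re-run the significance analysis under a robustness variant.

    Variants: ``bin_removal_start_end`` / ``bin_removal_middle`` report the
    cumulative significant proportion (originally significant frames plus
    frames that become significant after removing 1..max_remove time bins,
    keeping frames with >= 5 remaining bins); ``map_truncation_ends`` /
    ``map_truncation_middle`` drop 0-30 cm of the encoding maps and
    re-decode; ``poisson_surrogate_single`` / ``poisson_surrogate_500``
    build rate-matched homogeneous-Poisson counterparts of the frames.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    known = {"bin_removal_start_end", "bin_removal_middle",
             "map_truncation_ends", "map_truncation_middle",
             "poisson_surrogate_single", "poisson_surrogate_500"}
    if variant not in known:
        raise ValueError(f"unknown variant: {variant}")

    def significant_mask(posts, r):
        out = []
        for post in posts:
            prob, _ = _as_prob(post)
            if prob.shape[0] < 5:
                out.append(False)
                continue
            out.append(sequence_metrics(prob, track_length, n_shuffles,
                                        r).significant)
        return np.asarray(out, bool)

    posts = frames_to_posteriors(frames, model, tau)

    if variant.startswith("bin_removal"):
        base_rng = _frame_rngs(rng, 1)[0]
        base_sig = significant_mask(posts, base_rng)
        cumulative = {0: float(base_sig.mean())}
        cum_sig = base_sig.copy()
        for k in range(1, max_remove + 1):
            variants = []
            for post in posts:
                prob, _ = _as_prob(post)
                if variant == "bin_removal_middle":
                    mid = prob.shape[0] // 2
                    lo, hi = mid - k // 2, mid - k // 2 + k
                    variants.append([np.delete(prob, slice(lo, hi), axis=0)])
                else:
                    variants.append([prob[k:], prob[:-k] if k else prob])
            new_sig = np.zeros(len(posts), bool)
            r = _frame_rngs(rng, 1)[0]
            for i, plist in enumerate(variants):
                for prob in plist:
                    if prob.shape[0] < 5:
                        continue
                    if sequence_metrics(prob, track_length, n_shuffles,
                                        r).significant:
                        new_sig[i] = True
            cum_sig |= new_sig
            cumulative[k] = float(cum_sig.mean())
        return {"variant": variant, "cumulative_proportion": cumulative,
                "baseline_proportion": float(base_sig.mean())}

    if variant.startswith("map_truncation"):
        r = _frame_rngs(rng, 1)[0]
        base_sig = significant_mask(posts, r)
        L = model.track_length
        if variant == "map_truncation_ends":
            reduced = {
                "low_end": _truncate_model(model, 0.0, truncate_cm),
                "high_end": _truncate_model(model, L - truncate_cm, L),
            }
        else:
            mid = L / 2
            reduced = {"middle": _truncate_model(
                model, mid - truncate_cm / 2, mid + truncate_cm / 2)}
        out = {"variant": variant, "baseline_proportion": float(base_sig.mean()),
               "reduced_proportion": {}}
        for name, m in reduced.items():
            p2 = frames_to_posteriors(frames, m, tau)
            out["reduced_proportion"][name] = float(
                significant_mask(p2, _frame_rngs(rng, 1)[0]).mean())
        return out

    # poisson surrogates: rate-matched homogeneous counts per frame
    mean_rate = np.mean(
        [f.counts.mean(axis=1) / 0.02 for f in frames], axis=0
    )

    def surrogate_stats(r):
        rows = []
        for f in frames:
            counts = r.poisson(mean_rate[:, None] * 0.02,
                               size=f.counts.shape)
            post = decode(counts[model.unit_ids], model, tau)
            if post.prob.shape[0] < 5:
                continue
            st = sequence_metrics(post, track_length, n_shuffles, r)
            rows.append(dict(r=st.r, r_Z=st.r_Z, median_jump=st.median_jump,
                             max_jump=st.max_jump,
                             significant=st.significant))
        return pd.DataFrame(rows)

    r = _frame_rngs(rng, 1)[0]
    base_sig = significant_mask(posts, r)
    if variant == "poisson_surrogate_single":
        surr = surrogate_stats(r)
        z, p = hstats.two_proportion_ztest(
            int(base_sig.sum()), base_sig.size,
            int(surr["significant"].sum()), len(surr), alternative="greater")
        return {"variant": variant, "data_proportion": float(base_sig.mean()),
                "surrogate_proportion": float(surr["significant"].mean()),
                "p": float(p)}
    props = []
    for _ in range(n_surrogates):
        surr = surrogate_stats(r)
        props.append(surr["significant"].mean())
    props = np.asarray(props)
    return {"variant": variant, "data_proportion": float(base_sig.mean()),
            "surrogate_proportions": props,
            "p": float(1.0 - (props < base_sig.mean()).mean())}


def quadrant_ratio(matrix: np.ndarray) -> float:
    """QR = (Q1 + Q3 - Q2 - Q4) / total on a centred space-time matrix.

    Rows are time (past -> future), columns space (behind -> ahead), both
    centred on the animal; with odd dimensions the central row/column
    belongs to no quadrant.  Q1 = future-ahead, Q3 = past-behind.
    """
    m = np.asarray(matrix, float)
    T, L = m.shape
    t_mid, l_mid = T // 2, L // 2
    t_lo = slice(0, t_mid)
    t_hi = slice(t_mid + 1 if T % 2 else t_mid, T)
    l_lo = slice(0, l_mid)
    l_hi = slice(l_mid + 1 if L % 2 else l_mid, L)
    q1 = m[t_hi, l_hi].sum()
    q3 = m[t_lo, l_lo].sum()
    q2 = m[t_lo, l_hi].sum()
    q4 = m[t_hi, l_lo].sum()
    total = q1 + q2 + q3 + q4
    if total <= 0:
        return 0.0
    return float((q1 + q3 - q2 - q4) / total)


def theta_quadrant_ratio(
    cycle_posteriors,
    positions,
    directions,
    track_length: float,
    window_bins: int = 5,
    half_window_cm: float = 30.0,
    n_shuffles: int = 500,
    rng: np.random.Generator | None = None,
):
    """Average animal-centred decoded matrix and its quadrant ratio.

    Each cycle's posterior is re-centred on the animal's position (columns
    within +/- ``half_window_cm``), oriented so "ahead" in the running
    direction is positive, averaged across cycles, and the QR taken on the
    ``window_bins`` (100 ms at 20-ms bins) central time window.
    Significance compares the QR to 500 per-cycle time-bin shuffles at the
    95th percentile.
    """
    if len(cycle_posteriors) == 0:
        raise ValueError("no theta cycles supplied")
    rng = np.random.default_rng(0) if rng is None else rng

    prob0, locs = _as_prob(cycle_posteriors[0])
    bin_cm = locs[1] - locs[0] if locs.size > 1 else 1.0
    half_bins = int(round(half_window_cm / bin_cm))
    width = 2 * half_bins + 1

    def centred(prob, x, d):
        c = int(round((x - locs[0]) / bin_cm))
        out = np.zeros((prob.shape[0], width))
        lo, hi = c - half_bins, c + half_bins + 1
        src_lo, src_hi = max(lo, 0), min(hi, prob.shape[1])
        out[:, src_lo - lo: src_lo - lo + (src_hi - src_lo)] = prob[:, src_lo:src_hi]
        return out[:, ::-1] if d < 0 else out

    mats = [centred(_as_prob(p)[0], x, d)
            for p, x, d in zip(cycle_posteriors, positions, directions)]
    T = mats[0].shape[0]
    t_mid = T // 2
    t_lo = t_mid - window_bins // 2
    window = slice(t_lo, t_lo + window_bins)

    avg = np.mean(mats, axis=0)
    qr = quadrant_ratio(avg[window])

    shuffle_qr = np.empty(n_shuffles)
    for s in range(n_shuffles):
        acc = np.zeros_like(mats[0])
        for m in mats:
            acc += m[rng.permutation(T)]
        shuffle_qr[s] = quadrant_ratio((acc / len(mats))[window])
    p95 = float(np.percentile(shuffle_qr, 95))
    p_mc = (1 + (shuffle_qr >= qr).sum()) / (n_shuffles + 1)
    return {
        "quadrant_ratio": qr,
        "shuffle_p95": p95,
        "significant": p_mc <= 0.05,
        "p": float(p_mc),
        "average_matrix": avg,
        "shuffle_qr": shuffle_qr,
    }
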