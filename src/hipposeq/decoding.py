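"""Memoryless Bayesian position decoding from binned ensemble spiking.

Under Poisson spiking and unit independence, the posterior over track
locations for one time bin of duration tau is

    Pr(loc | spk)  propto  Pr(loc) * prod_i f_i(loc)^{sp_i} * exp(-tau sum_i f_i(loc))

with a uniform spatial prior.  Encoding models use 1-cm spatial bins
smoothed with a 5-cm Gaussian and include units with at least 10 run
spikes; run decoding uses non-overlapping 0.5-s bins at velocity > 10 cm/s,
frame decoding 20-ms bins.  All likelihoods are computed in the log domain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .place_fields import EmptyMapError, compute_rate_map
from .synth import RunSession

__all__ = [
    "DecodingModel",
    "Posterior",
    "build_encoding_model",
    "decode",
    "bin_spike_counts",
    "run_decoding_error",
]


@dataclass
class DecodingModel:
    """Per-direction encoding model: smoothed rate curves on 1-cm bins."""

    rates: np.ndarray            # included units x spatial bins, Hz
    unit_ids: np.ndarray
    bin_centres: np.ndarray      # cm
    direction: int
    track_length: float
    rate_floor: float = 0.01     # Hz, added before logs

    @property
    def n_bins(self) -> int:
        return self.rates.shape[1]


@dataclass
class Posterior:
    """Time-bin x space-bin decoded probability matrix; rows sum to 1."""

    prob: np.ndarray
    tau: float
    bin_edges: np.ndarray        # s, len T+1
    bin_centres_cm: np.ndarray
    degenerate_rows: np.ndarray = None   # rows that fell back to uniform

    @property
    def n_time_bins(self) -> int:
        return self.prob.shape[0]

    def argmax_positions(self) -> np.ndarray:
        """Peak decoded location per time bin (cm); ties -> lower bin."""
        return self.bin_centres_cm[np.argmax(self.prob, axis=1)]


def build_encoding_model(
    run: RunSession,
    direction: int,
    bin_size: float = 1.0,
    smooth_sd_cm: float = 5.0,
    min_spikes: int = 10,
    vmin: float = 5.0,
    rate_floor: float = 0.01,
    place_cells_only: bool = False,
    lap_mask: np.ndarray | None = None,
) -> DecodingModel:
    """Estimate per-unit tuning curves for one run direction.

    Units need at least ``min_spikes`` run spikes (in this direction, under
    the velocity filter) to enter the model.  ``lap_mask`` restricts
    estimation to a boolean subset of position samples (cross-validated
    encoding).
    """
    direction_labels = run.direction
    if lap_mask is not None:
        direction_labels = np.where(lap_mask, run.direction, 99)
    rates, ids = [], []
    for i, st in enumerate(run.spikes):
        try:
            m = compute_rate_map(
                st, run.time, run.position, run.velocity, direction_labels,
                direction, run.track_length, bin_size=bin_size,
                smooth_sd_cm=smooth_sd_cm, vmin=vmin, unit_id=i,
            )
        except EmptyMapError:
            continue
        # count filtered spikes, not map mass
        keep = (np.abs(run.velocity) > vmin) & (direction_labels == direction)
        samp = np.clip(np.searchsorted(run.time, st) - 1, 0, run.time.size - 1)
        n_spk = int(keep[samp].sum()) if st.size else 0
        if n_spk < min_spikes:
            continue
        if place_cells_only and not m.is_place_cell:
            continue
        rates.append(m.rates)
        ids.append(i)
    if not rates:
        raise EmptyMapError("no unit passed the spike-count filter")
    m0 = m  # any successful map carries the bin grid
    return DecodingModel(
        rates=np.vstack(rates), unit_ids=np.asarray(ids),
        bin_centres=m0.bin_centres, direction=direction,
        track_length=run.track_length, rate_floor=rate_floor,
    )


def decode(
    counts: np.ndarray,
    model: DecodingModel,
    tau: float,
    bin_edges: np.ndarray | None = None,
) -> Posterior:
    """Decode a units x T count matrix into a T x L posterior.

    Computed in the log domain; a time bin whose likelihood underflows in
    every spatial bin falls back to the uniform prior and is flagged in
    ``degenerate_rows``.
    """
    counts = np.atleast_2d(np.asarray(counts, float))
    if counts.shape[0] != model.rates.shape[0]:
        raise ValueError("counts rows must match model units")
    if tau <= 0:
        raise ValueError("tau must be positive")
    f = model.rates + model.rate_floor
    with np.errstate(divide="ignore"):
        logf = np.log(f)
    # 0 * log(0) = 0 convention; a positive count at a zero-rate location
    # gives that spatial bin -inf log-likelihood
    finite_logf = np.where(np.isfinite(logf), logf, 0.0)
    loglik = counts.T @ finite_logf - tau * f.sum(axis=0)   # T x L
    zero_rate = ~np.isfinite(logf)
    if zero_rate.any():
        impossible = (counts > 0).T.astype(float) @ zero_rate > 0
        loglik[impossible] = -np.inf
    bad = ~np.isfinite(loglik).any(axis=1)
    loglik[bad] = 0.0
    prob = np.exp(loglik - logsumexp(loglik, axis=1, keepdims=True))
    T = counts.shape[1]
    if bin_edges is None:
        bin_edges = np.arange(T + 1) * tau
    return Posterior(prob=prob, tau=tau, bin_edges=np.asarray(bin_edges, float),
                     bin_centres_cm=model.bin_centres, degenerate_rows=bad)


def bin_spike_counts(
    spikes: list[np.ndarray],
    unit_ids: np.ndarray,
    t_start: float,
    t_end: float,
    tau: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Counts (units x T) on non-overlapping tau bins over [t_start, t_end)."""
    edges = np.arange(t_start, t_end + tau / 2, tau)
    if len(edges) < 2:
        edges = np.array([t_start, t_start + tau])
    counts = np.vstack([
        np.histogram(spikes[i], bins=edges)[0] for i in unit_ids
    ])
    return counts, edges


def run_decoding_error(
    run: RunSession,
    model: DecodingModel,
    tau: float = 0.5,
    vmin: float = 10.0,
    n_shuffles: int = 500,
    rng: np.random.Generator | None = None,
):
    """Median decode error during movement, with a time-permutation null.

    Decodes non-overlapping ``tau`` bins whose mean speed exceeds ``vmin``
    (in the model's direction), takes the median |peak decoded - true|
    distance, and compares it to medians after randomly permuting the
    decoded posterior rows in time.  Significant if the data median falls
    below the 5th percentile of shuffle medians.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    counts, edges = bin_spike_counts(
        run.spikes, model.unit_ids, 0.0, run.duration, tau
    )
    mids = 0.5 * (edges[:-1] + edges[1:])
    speed = np.interp(mids, run.time, np.abs(run.velocity))
    dsign = run.direction[np.clip(np.searchsorted(run.time, mids), 0,
                                  run.time.size - 1)]
    keep = (speed > vmin) & (dsign == model.direction)
    if not keep.any():
        raise ValueError("no movement bins at velocity > vmin")
    post = decode(counts[:, keep], model, tau, bin_edges=None)
    decoded = post.argmax_positions()
    true_pos = np.interp(mids[keep], run.time, run.position)
    errors = np.abs(decoded - true_pos)
    median_error = float(np.median(errors))

    shuffle_medians = np.empty(n_shuffles)
    for s in range(n_shuffles):
        perm = rng.permutation(decoded.size)
        shuffle_medians[s] = np.median(np.abs(decoded[perm] - true_pos))
    p5 = float(np.percentile(shuffle_medians, 5))
    return {
        "median_error_cm": median_error,
        "errors_cm": errors,
        "shuffle_medians_cm": shuffle_medians,
        "shuffle_p5_cm": p5,
        "significant": median_error < p5,
        "n_bins": int(keep.sum()),
    }
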