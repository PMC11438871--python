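"""Event segmentation: NREM epochs, population-burst frames, ripples, theta.

Frames are epochs where the 15-ms-Gaussian-smoothed 1-ms-binned population
rate exceeds its context mean by 2 SD for 100-800 ms with at least 5
distinct active units; they are re-binned at 20 ms for decoding.  NREM is
immobility (velocity < 2 cm/s) with the 10-s-smoothed Hilbert theta/delta
amplitude ratio below its session mean.  Ripples are 140-250 Hz envelope
peaks above 3 SD.  Theta cycles are 400-ms windows on 5-9 Hz troughs while
the animal runs (> 10 cm/s) through the middle 2/5 of the track.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import butter, filtfilt, hilbert, periodogram

from .synth import LfpTrace

__all__ = [
    "Frame",
    "segment_nrem",
    "detect_frames",
    "detect_ripples",
    "peak_theta_frequency",
    "extract_theta_cycles",
    "intervals_overlap_fraction",
]


@dataclass
class Frame:
    """A candidate reactivation event with 20-ms binned counts."""

    start: float
    end: float
    counts: np.ndarray            # units x n_bins, 20-ms bins
    n_active_units: int
    context: str                  # sleep | awake_rest | theta_cycle
    ripple_cooccurring: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]


def _bandpass(x, fs, lo, hi, order=3):
    b, a = butter(order, [lo / (fs / 2), hi / (fs / 2)], btype="band")
    return filtfilt(b, a, x)


def _intervals_from_mask(mask: np.ndarray, time: np.ndarray):
    """(start, end) pairs of contiguous True runs."""
    m = np.asarray(mask, bool)
    if not m.any():
        return []
    d = np.diff(m.astype(int))
    starts = np.where(d == 1)[0] + 1
    ends = np.where(d == -1)[0] + 1
    if m[0]:
        starts = np.r_[0, starts]
    if m[-1]:
        ends = np.r_[ends, m.size]
    return [(float(time[a]), float(time[b - 1])) for a, b in zip(starts, ends)]


def segment_nrem(
    lfp: LfpTrace | None,
    velocity_time: np.ndarray,
    velocity: np.ndarray,
    vmax: float = 2.0,
    theta_band=(5.0, 9.0),
    delta_band=(1.0, 4.0),
    smooth_s: float = 10.0,
) -> pd.DataFrame:
    """NREM intervals: immobility AND theta/delta ratio below its mean.

    Without an LFP the segmentation falls back to immobility only and the
    result carries label ``nrem_immobility_only``.
    """
    immobile = np.abs(velocity) < vmax
    if lfp is None:
        iv = _intervals_from_mask(immobile, velocity_time)
        return pd.DataFrame(
            [("nrem_immobility_only", a, b) for a, b in iv],
            columns=["label", "start", "end"],
        )
    theta = np.abs(hilbert(_bandpass(lfp.samples, lfp.fs, *theta_band)))
    delta = np.abs(hilbert(_bandpass(lfp.samples, lfp.fs, *delta_band)))
    sigma = smooth_s * lfp.fs
    ratio = gaussian_filter1d(theta, sigma) / np.maximum(
        gaussian_filter1d(delta, sigma), 1e-12
    )
    low_ratio = ratio < ratio.mean()
    imm_on_lfp = np.interp(lfp.time, velocity_time, np.abs(velocity)) < vmax
    iv = _intervals_from_mask(low_ratio & imm_on_lfp, lfp.time)
    return pd.DataFrame(
        [("nrem", a, b) for a, b in iv], columns=["label", "start", "end"]
    )


def detect_frames(
    spikes: list[np.ndarray],
    epochs: pd.DataFrame,
    context: str = "sleep",
    duration: float | None = None,
    sd_threshold: float = 2.0,
    min_units: int = 5,
    duration_bounds=(0.1, 0.8),
    frame_bin: float = 0.02,
    smooth_ms: float = 15.0,
) -> list[Frame]:
    """Population-burst frames inside the given epochs.

    The summed population activity in 1-ms bins is convolved with a 15-ms
    Gaussian; frame boundaries are the up/down crossings of mean + ``sd_threshold``
    SD (statistics taken within the epochs), kept for durations within
    ``duration_bounds`` and at least ``min_units`` distinct active units.
    """
    if len(spikes) < min_units:
        return []
    if duration is None:
        duration = max((s[-1] for s in spikes if s.size), default=0.0)
    if duration <= 0:
        return []
    fs = 1000.0
    n = int(np.ceil(duration * fs)) + 1
    pop = np.zeros(n)
    for st in spikes:
        if st.size:
            idx = np.clip((st * fs).astype(int), 0, n - 1)
            np.add.at(pop, idx, 1.0)
    rate = gaussian_filter1d(pop, smooth_ms / 1000.0 * fs)
    t = np.arange(n) / fs

    in_epoch = np.zeros(n, bool)
    for _, ep in epochs.iterrows():
        in_epoch |= (t >= ep.start) & (t < ep.end)
    if not in_epoch.any():
        return []
    mu, sd = rate[in_epoch].mean(), rate[in_epoch].std()
    above = (rate > mu + sd_threshold * sd) & in_epoch

    # merge bursts separated by less than one frame bin: re-binning at
    # 20 ms would otherwise make neighbouring frames overlap
    regions: list[list[float]] = []
    for a, b in _intervals_from_mask(above, t):
        if regions and a - regions[-1][1] < frame_bin:
            regions[-1][1] = b
        else:
            regions.append([a, b])

    frames: list[Frame] = []
    lo_d, hi_d = duration_bounds
    for a, b in regions:
        if not (lo_d <= b - a <= hi_d):
            continue
        n_bins = max(int(np.ceil((b - a) / frame_bin)), 1)
        edges = a + np.arange(n_bins + 1) * frame_bin
        counts = np.vstack([np.histogram(st, bins=edges)[0] for st in spikes])
        n_active = int((counts.sum(axis=1) > 0).sum())
        if n_active < min_units:
            continue
        frames.append(Frame(start=a, end=a + n_bins * frame_bin, counts=counts,
                            n_active_units=n_active, context=context))
    return frames


def detect_ripples(
    lfp: LfpTrace,
    band=(140.0, 250.0),
    sd_threshold: float = 3.0,
    edge_sd: float = 1.0,
) -> list[tuple[float, float]]:
    """Ripple intervals: band envelope regions (above mean + ``edge_sd`` SD)
    containing a peak above mean + ``sd_threshold`` SD."""
    if lfp.fs < 600:
        raise ValueError("sampling rate too low for the ripple band")
    env = np.abs(hilbert(_bandpass(lfp.samples, lfp.fs, *band)))
    env = gaussian_filter1d(env, 0.004 * lfp.fs)
    mu, sd = env.mean(), env.std()
    if sd == 0:
        return []
    regions = _intervals_from_mask(env > mu + edge_sd * sd, lfp.time)
    out = []
    for a, b in regions:
        m = (lfp.time >= a) & (lfp.time <= b)
        if env[m].max() > mu + sd_threshold * sd:
            out.append((a, b))
    return out


def flag_ripple_frames(frames: list[Frame], ripples) -> None:
    """Set ``ripple_cooccurring`` on frames overlapping any ripple interval."""
    for f in frames:
        f.ripple_cooccurring = any(
            f.start < b and a < f.end for a, b in ripples
        )


def peak_theta_frequency(
    lfp: LfpTrace,
    velocity_time: np.ndarray,
    velocity: np.ndarray,
    vmin: float = 10.0,
    band=(5.0, 9.0),
) -> float:
    """Peak 5-9 Hz frequency of the movement-epoch spectrum."""
    moving = np.interp(lfp.time, velocity_time, np.abs(velocity)) > vmin
    if not moving.any():
        raise ValueError("no movement epochs")
    x = lfp.samples[moving]
    f, p = periodogram(x, fs=lfp.fs)
    sel = (f >= band[0]) & (f <= band[1])
    return float(f[sel][np.argmax(p[sel])])


def extract_theta_cycles(
    lfp: LfpTrace,
    spikes: list[np.ndarray],
    time: np.ndarray,
    position: np.ndarray,
    velocity: np.ndarray,
    direction: np.ndarray,
    track_length: float,
    which_direction: int | None = None,
    vmin: float = 10.0,
    window_s: float = 0.4,
    frame_bin: float = 0.02,
    min_units: int = 2,
    middle_fraction: float = 0.4,
) -> list[Frame]:
    """400-ms spike windows centred on theta troughs in the track middle.

    Troughs are local minima of the 5-9 Hz band-passed trace.  A window is
    kept when the animal moves faster than ``vmin`` through the middle
    ``middle_fraction`` of the track and at least ``min_units`` units fire.
    The animal's position at the trough is stored in ``meta['position']``.
    """
    filt = _bandpass(lfp.samples, lfp.fs, 5.0, 9.0)
    trough = np.where(
        (filt[1:-1] < filt[:-2]) & (filt[1:-1] < filt[2:])
    )[0] + 1
    lo = (track_length - middle_fraction * track_length) / 2
    hi = track_length - lo
    cycles: list[Frame] = []
    for idx in trough:
        tc = lfp.time[idx]
        v = np.interp(tc, time, np.abs(velocity))
        x = np.interp(tc, time, position)
        d = direction[np.clip(np.searchsorted(time, tc), 0, time.size - 1)]
        if v <= vmin or not (lo <= x <= hi):
            continue
        if which_direction is not None and d != which_direction:
            continue
        a = tc - window_s / 2
        n_bins = int(round(window_s / frame_bin))
        edges = a + np.arange(n_bins + 1) * frame_bin
        counts = np.vstack([np.histogram(st, bins=edges)[0] for st in spikes])
        n_active = int((counts.sum(axis=1) > 0).sum())
        if n_active < min_units:
            continue
        cycles.append(Frame(start=a, end=a + window_s, counts=counts,
                            n_active_units=n_active, context="theta_cycle",
                            meta={"position": float(x), "direction": int(d),
                                  "trough": float(tc)}))
    return cycles


def intervals_overlap_fraction(truth, detected) -> float:
    """Fraction of truth intervals overlapped by any detected interval."""
    if len(truth) == 0:
        return float("nan")
    hit = 0
    for a, b in truth:
        if any(a < d_b and d_a < b for d_a, d_b in detected):
            hit += 1
    return hit / len(truth)
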