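"""Synthetic linear-track sessions with ground truth.

Emulates the data a developmental CA1 recording yields: lap running on a
~1 m track with direction-specific Gaussian place tuning and
inhomogeneous-Poisson spiking, NREM-like sleep carrying brief
high-population-activity frames (a controllable fraction of which embed
time-compressed place-field-ordered trajectory sequences), planted
frame-ensemble clusters and co-activation assemblies, and a band-structured
field-potential trace (run theta, sleep delta, ripple bursts at frames).

Every random draw descends from one root seed through named substreams, so
a configuration maps to a bit-identical session.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfigError",
    "GeneratorConfig",
    "RunSession",
    "SleepSession",
    "LfpTrace",
    "generate_run_session",
    "generate_sleep_session",
    "generate_lfp",
    "generate_assembly_activity",
    "session_hash",
]


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic study conditions.

    Defaults echo the recorded scales of the emulated preparation: 1-m
    tracks, a few dozen simultaneously held CA1 units, ~6.7 Hz run theta,
    100-800 ms sleep frames.  ``mirror_weight`` adds a field component
    mirrored about the track middle (the symmetric-mapping phenotype of
    sphere-reared animals); ``seq_compression`` is the fraction of the
    track a planted sleep sequence traverses per 20-ms bin.
    """

    seed: int = 0
    track_length: float = 100.0           # cm
    n_cells: int = 50
    field_width_range: tuple[float, float] = (5.0, 12.0)   # Gaussian SD, cm
    peak_rate_range: tuple[float, float] = (3.0, 15.0)     # Hz
    mirror_weight: float = 0.0
    low_tuned_fraction: float = 0.1
    n_laps: int = 20                      # one-way traversals per direction pair
    run_speed: float = 20.0               # cm/s
    theta_freq: float = 6.7               # Hz
    theta_sweep_cm: float = 10.0          # look-behind/ahead sweep per cycle
    seq_frame_fraction: float = 0.0
    seq_compression: float = 0.1          # track fraction per 20-ms bin
    n_clusters_planted: int = 0
    n_assemblies_planted: int = 0
    frame_rate: float = 10.0              # frames / min of NREM
    sleep_duration: float = 600.0         # s
    # sampling choices (video-tracking / ephys timescales)
    position_fs: float = 25.0             # Hz
    lfp_fs: float = 1250.0                # Hz
    # nuisance rates
    pause_s: float = 1.0                  # end-of-lap pause
    sleep_baseline_rate: float = 0.5      # Hz outside frames
    frame_gain: float = 5.0               # within-frame rate boost
    assembly_gain: float = 1.0            # scales planted co-activation strength

    def validate(self) -> None:
        for name in ("mirror_weight", "low_tuned_fraction", "seq_frame_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.track_length <= 0:
            raise ConfigError("track_length must be positive")
        if self.n_cells < 1:
            raise ConfigError("n_cells must be >= 1")
        if self.seq_frame_fraction > 0 and self.seq_compression <= 0:
            raise ConfigError("seq_compression must be > 0 when sequences are planted")

    def with_(self, **kwargs) -> "GeneratorConfig":
        return replace(self, **kwargs)


def _rng(config: GeneratorConfig, stream: str) -> np.random.Generator:
    """Named substream of the root seed (stable across runs/platforms)."""
    key = zlib.crc32(stream.encode())
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(key,)))


@dataclass
class RunSession:
    """Lap running on a linear track with per-unit spike trains.

    ``direction`` is +1/-1 per position sample (0 at end-of-lap pauses).
    ``ground_truth`` holds one row per unit x direction with the true field
    centre, width (SD), peak rate, mirror weight and low-tuned flag.
    """

    time: np.ndarray
    position: np.ndarray
    velocity: np.ndarray
    direction: np.ndarray
    spikes: list[np.ndarray]
    ground_truth: pd.DataFrame
    track_length: float
    config: GeneratorConfig = field(repr=False, default=None)

    @property
    def n_cells(self) -> int:
        return len(self.spikes)

    @property
    def duration(self) -> float:
        return float(self.time[-1]) if self.time.size else 0.0


@dataclass
class SleepSession:
    """NREM-like sleep with planted population-burst frames.

    ``frame_truth`` has one row per planted frame: start/end (s), kind
    ("seq" or "noise"), the embedded trajectory's direction/start/slope when
    present, planted cluster id (-1 if none) and active assembly ids.
    """

    spikes: list[np.ndarray]
    epochs: pd.DataFrame              # label, start, end
    frame_truth: pd.DataFrame
    duration: float
    assemblies: list[np.ndarray]      # planted member index sets
    config: GeneratorConfig = field(repr=False, default=None)

    @property
    def n_cells(self) -> int:
        return len(self.spikes)


@dataclass
class LfpTrace:
    """Band-structured field-potential surrogate (arbitrary units)."""

    time: np.ndarray
    samples: np.ndarray
    fs: float
    context: str = ""


# ---------------------------------------------------------------------------
# run sessions
# ---------------------------------------------------------------------------

def _draw_tuning(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    n_low = int(round(config.low_tuned_fraction * config.n_cells))
    low_ids = set(rng.choice(config.n_cells, size=n_low, replace=False).tolist())
    L = config.track_length
    for direction in (1, -1):
        centres = rng.uniform(0.0, L, size=config.n_cells)
        widths = rng.uniform(*config.field_width_range, size=config.n_cells)
        peaks = rng.uniform(*config.peak_rate_range, size=config.n_cells)
        low_rates = rng.uniform(0.5, 2.0, size=config.n_cells)
        # the symmetric-mapping phenotype is end-weighted: fields near the
        # track ends mirror strongly, middle fields barely at all, so the
        # symmetric-location similarity grows with separation
        end_frac = (2.0 * np.abs(centres - L / 2) / L) ** 2
        w_eff = config.mirror_weight * end_frac
        for i in range(config.n_cells):
            rows.append(
                dict(
                    unit_id=i,
                    direction=direction,
                    centre=centres[i],
                    width=widths[i],
                    peak_rate=peaks[i],
                    mirror_weight=w_eff[i],
                    low_tuned=i in low_ids,
                    low_rate=low_rates[i],
                )
            )
    return pd.DataFrame(rows)


def tuning_rate(
    x: np.ndarray,
    centre: float,
    width: float,
    peak: float,
    mirror_weight: float,
    track_length: float,
) -> np.ndarray:
    """Gaussian field with an optional component mirrored about the middle.

    lambda(x) = peak * [G(x; c, sigma) + w G(L - x; c, sigma)] / (1 + w)

    The mirror weight w is the relative amplitude of the component
    reflected about the track middle: w = 0 is a single field, w = 1 two
    equal fields (a map exactly symmetric about the middle).
    """
    g = np.exp(-0.5 * ((np.asarray(x, float) - centre) / width) ** 2)
    gm = np.exp(-0.5 * ((track_length - np.asarray(x, float) - centre) / width) ** 2)
    return peak * (g + mirror_weight * gm) / (1.0 + mirror_weight)


def _trajectory(config: GeneratorConfig):
    """Back-and-forth laps with a pause at each end, sampled at position_fs."""
    dt = 1.0 / config.position_fs
    L, v = config.track_length, config.run_speed
    lap_t = L / v
    n_pause = max(int(round(config.pause_s * config.position_fs)), 1)
    pos_chunks: list[np.ndarray] = []
    dir_chunks: list[np.ndarray] = []
    if config.n_laps == 0:
        return (np.zeros(0), np.zeros(0), np.zeros(0), np.zeros(0, int))
    for lap in range(config.n_laps):
        d = 1 if lap % 2 == 0 else -1
        n = int(round(lap_t / dt))
        frac = (np.arange(n) + 0.5) / n
        x = frac * L if d == 1 else (1.0 - frac) * L
        pos_chunks.append(x)
        dir_chunks.append(np.full(n, d))
        pos_chunks.append(np.full(n_pause, L if d == 1 else 0.0))
        dir_chunks.append(np.zeros(n_pause, int))
    position = np.concatenate(pos_chunks)
    direction = np.concatenate(dir_chunks).astype(int)
    time = np.arange(position.size) * dt
    velocity = np.gradient(position, dt)
    return time, position, velocity, direction


def generate_run_session(config: GeneratorConfig) -> RunSession:
    """Simulate lap running with inhomogeneous-Poisson place-cell spiking.

    Spikes are drawn by thinning a 1-kHz Bernoulli approximation of the
    position-dependent rate; both run directions carry independent field
    draws for every unit.
    """
    config.validate()
    if config.n_cells == 0:
        raise ConfigError("cannot generate a session with zero cells")
    truth = _draw_tuning(config, _rng(config, "tuning"))
    time, position, velocity, direction = _trajectory(config)

    spikes: list[np.ndarray] = [np.zeros(0) for _ in range(config.n_cells)]
    if time.size:
        fs = 1000.0
        t_hi = np.arange(0.0, time[-1], 1.0 / fs)
        x_hi = np.interp(t_hi, time, position)
        d_hi = direction[np.minimum(np.searchsorted(time, t_hi), time.size - 1)]
        # theta sweep: the represented position runs from behind to ahead of
        # the animal within each theta cycle (zero-crossing at the LFP
        # trough), producing theta sequences at the configured frequency
        sweep = config.theta_sweep_cm * np.cos(
            2 * np.pi * config.theta_freq * t_hi
        )
        x_rep = np.clip(x_hi + d_hi * sweep, 0.0, config.track_length)
        rng = _rng(config, "run-spikes")
        for i in range(config.n_cells):
            lam = np.full(t_hi.size, 0.1)  # pause baseline, Hz
            for d in (1, -1):
                row = truth[(truth.unit_id == i) & (truth.direction == d)].iloc[0]
                mask = d_hi == d
                if row.low_tuned:
                    lam[mask] = row.low_rate
                else:
                    lam[mask] = tuning_rate(
                        x_rep[mask], row.centre, row.width, row.peak_rate,
                        row.mirror_weight, config.track_length,
                    )
            fires = rng.random(t_hi.size) < lam / fs
            spikes[i] = t_hi[fires] + 0.5 / fs
    return RunSession(
        time=time, position=position, velocity=velocity, direction=direction,
        spikes=spikes, ground_truth=truth, track_length=config.track_length,
        config=config,
    )


# ---------------------------------------------------------------------------
# sleep sessions
# ---------------------------------------------------------------------------

def _template_rates(templates) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-unit rate curves, bin centres and bin size from a RateMap collection."""
    rates = np.vstack([np.asarray(t.rates, float) for t in templates])
    centres = np.asarray(templates[0].bin_centres, float)
    bin_size = float(templates[0].bin_size)
    return rates, centres, bin_size


def _sleep_epochs(config: GeneratorConfig) -> pd.DataFrame:
    """Alternate NREM (60 s) and intermediate (15 s) blocks."""
    rows, t = [], 0.0
    while t < config.sleep_duration:
        nrem_end = min(t + 60.0, config.sleep_duration)
        rows.append(("nrem", t, nrem_end))
        t = nrem_end
        if t < config.sleep_duration:
            other_end = min(t + 15.0, config.sleep_duration)
            rows.append(("other", t, other_end))
            t = other_end
    return pd.DataFrame(rows, columns=["label", "start", "end"])


def generate_sleep_session(
    config: GeneratorConfig,
    templates: Sequence,
    post_assembly_gain: float | None = None,
) -> SleepSession:
    """Simulate NREM sleep with planted population-burst frames.

    A ``seq_frame_fraction`` of frames emit spikes from cells ordered by
    their template field centres along a virtual trajectory advancing
    ``seq_compression * track_length`` per 20-ms bin; the remainder draw
    each unit's count from a rate-matched Poisson.  Planted clusters give
    each cluster a distinct participating-cell subset; planted assemblies
    inject shared-bin co-activation among their members.
    """
    config.validate()
    if len(templates) == 0:
        raise ConfigError("templates must be non-empty")
    rates, centres, _ = _template_rates(templates)
    n_units = rates.shape[0]
    mean_rates = rates.mean(axis=1)
    L = config.track_length
    tau = 0.02
    epochs = _sleep_epochs(config)
    rng = _rng(config, "sleep")

    # planted structure ----------------------------------------------------
    cluster_sets: list[np.ndarray] = []
    if config.n_clusters_planted > 0:
        perm = rng.permutation(n_units)
        cluster_sets = [
            np.sort(s) for s in np.array_split(perm, config.n_clusters_planted)
        ]
    assemblies: list[np.ndarray] = []
    if config.n_assemblies_planted > 0:
        size = max(4, n_units // (3 * config.n_assemblies_planted))
        perm = rng.permutation(n_units)
        assemblies = [
            np.sort(perm[k * size:(k + 1) * size])
            for k in range(config.n_assemblies_planted)
        ]
    a_gain = config.assembly_gain if post_assembly_gain is None else post_assembly_gain

    # frame placement ------------------------------------------------------
    frames = []
    gap_mean = 60.0 / config.frame_rate
    for _, ep in epochs[epochs.label == "nrem"].iterrows():
        t = ep.start + rng.exponential(gap_mean)
        while True:
            # cap at 0.7 s: threshold-crossing smoothing extends detected
            # bursts by ~2 kernel widths, which must stay inside the 0.8-s
            # duration bound of frame detection
            n_bins = int(rng.integers(5, 36))
            dur = n_bins * tau
            if t + dur > ep.end:
                break
            is_seq = rng.random() < config.seq_frame_fraction
            frames.append((t, n_bins, is_seq))
            t += dur + max(rng.exponential(gap_mean), 0.5)

    # spike emission -------------------------------------------------------
    spk: list[list[np.ndarray]] = [[] for _ in range(n_units)]
    truth_rows = []
    for start, n_bins, is_seq in frames:
        cluster_id, seq_dir, seq_start = -1, 0, np.nan
        if is_seq:
            seq_dir = 1 if rng.random() < 0.5 else -1
            # a trajectory at this compression can sustain at most 1/c bins
            # before running off the track; longer frames would sit clipped
            # at an end, which carries no sequential structure
            n_bins = max(5, min(n_bins, int(1.0 / config.seq_compression)))
            span = config.seq_compression * L * n_bins
            span = min(span, L)
            lo = 0.0 if seq_dir == 1 else span
            seq_start = rng.uniform(lo, L - span + lo) if L > span else lo
            x_t = seq_start + seq_dir * config.seq_compression * L * np.arange(n_bins)
            x_t = np.clip(x_t, 0.0, L)
            lam = np.vstack(
                [np.interp(x_t, centres, rates[i]) for i in range(n_units)]
            )
            counts = rng.poisson(tau * lam * config.frame_gain)
        else:
            active = np.arange(n_units)
            if cluster_sets:
                cluster_id = int(rng.integers(len(cluster_sets)))
                active = cluster_sets[cluster_id]
            lam = np.zeros(n_units)
            lam[active] = np.maximum(mean_rates[active], 1.0)
            counts = rng.poisson(
                tau * lam[:, None] * config.frame_gain, size=(n_units, n_bins)
            )
        active_assemblies = []
        for a_id, members in enumerate(assemblies):
            if rng.random() < 0.5:
                active_assemblies.append(a_id)
                events = rng.random(n_bins) < 0.5
                counts[np.ix_(members, np.where(events)[0])] += rng.poisson(
                    2.0 * a_gain, size=(members.size, int(events.sum()))
                )
        for i in range(n_units):
            for b in np.nonzero(counts[i])[0]:
                spk[i].append(
                    start + (b + rng.random(counts[i, b])) * tau
                )
        truth_rows.append(
            dict(
                start=start, end=start + n_bins * tau, n_bins=n_bins,
                kind="seq" if is_seq else "noise",
                seq_direction=seq_dir, seq_start=seq_start,
                cluster_id=cluster_id,
                assembly_ids=tuple(active_assemblies),
            )
        )

    # background spiking outside frames
    bg = _rng(config, "sleep-bg")
    frame_iv = [(r["start"], r["end"]) for r in truth_rows]
    for i in range(n_units):
        n_bg = bg.poisson(config.sleep_baseline_rate * config.sleep_duration)
        t_bg = np.sort(bg.uniform(0.0, config.sleep_duration, size=n_bg))
        if frame_iv:
            starts = np.array([a for a, _ in frame_iv])
            ends = np.array([b for _, b in frame_iv])
            idx = np.searchsorted(starts, t_bg) - 1
            inside = (idx >= 0) & (t_bg < ends[np.clip(idx, 0, len(ends) - 1)])
            t_bg = t_bg[~inside]
        spk[i].append(t_bg)

    spikes = [
        np.sort(np.concatenate(s)) if s else np.zeros(0) for s in spk
    ]
    frame_truth = pd.DataFrame(
        truth_rows,
        columns=["start", "end", "n_bins", "kind", "seq_direction", "seq_start",
                 "cluster_id", "assembly_ids"],
    )
    return SleepSession(
        spikes=spikes, epochs=epochs, frame_truth=frame_truth,
        duration=config.sleep_duration, assemblies=assemblies, config=config,
    )


# ---------------------------------------------------------------------------
# field potential
# ---------------------------------------------------------------------------

def _band_noise(rng, n, fs, lo, hi, amp):
    """Gaussian noise band-limited to [lo, hi] Hz via FFT masking."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    spec[(f < lo) | (f > hi)] = 0.0
    out = np.fft.irfft(spec, n)
    sd = out.std()
    return out * (amp / sd) if sd > 0 else out


def generate_lfp(
    config: GeneratorConfig,
    run: RunSession | None = None,
    sleep: SleepSession | None = None,
):
    """Band-structured LFP surrogate for a run and/or sleep session.

    Run: theta sinusoid at ``config.theta_freq`` during movement plus broad
    noise.  Sleep: delta-band (1-4 Hz) noise in NREM, theta-band noise in
    intermediate epochs, and a 140-250 Hz ripple burst at every planted
    frame.  Returns one trace, or a (run, sleep) tuple when both given.
    """
    config.validate()
    fs = config.lfp_fs
    out = []
    if run is not None:
        rng = _rng(config, "lfp-run")
        t = np.arange(0.0, run.duration, 1.0 / fs)
        theta = np.sin(2 * np.pi * config.theta_freq * t)
        moving = np.interp(t, run.time, np.abs(run.velocity)) > 5.0
        x = theta * np.where(moving, 1.0, 0.15) + 0.3 * rng.standard_normal(t.size)
        out.append(LfpTrace(time=t, samples=x, fs=fs, context="run"))
    if sleep is not None:
        rng = _rng(config, "lfp-sleep")
        t = np.arange(0.0, sleep.duration, 1.0 / fs)
        x = 0.2 * rng.standard_normal(t.size)
        for _, ep in sleep.epochs.iterrows():
            m = (t >= ep.start) & (t < ep.end)
            n = int(m.sum())
            if n == 0:
                continue
            if ep.label == "nrem":
                x[m] += _band_noise(rng, n, fs, 1.0, 4.0, 1.0)
                x[m] += _band_noise(rng, n, fs, 5.0, 9.0, 0.2)
            else:
                x[m] += _band_noise(rng, n, fs, 5.0, 9.0, 1.0)
                x[m] += _band_noise(rng, n, fs, 1.0, 4.0, 0.2)
        ripple_f = 190.0
        for _, fr in sleep.frame_truth.iterrows():
            m = (t >= fr.start) & (t < fr.end)
            if not m.any():
                continue
            tt = t[m]
            mid = 0.5 * (fr.start + fr.end)
            env = np.exp(-0.5 * ((tt - mid) / ((fr.end - fr.start) / 4.0)) ** 2)
            x[m] += 1.5 * env * np.sin(2 * np.pi * ripple_f * (tt - fr.start))
        out.append(LfpTrace(time=t, samples=x, fs=fs, context="sleep"))
    if not out:
        raise ConfigError("need at least one of run or sleep")
    return out[0] if len(out) == 1 else tuple(out)


# ---------------------------------------------------------------------------
# planted assembly activity (binned)
# ---------------------------------------------------------------------------

def generate_assembly_activity(
    n_units: int,
    n_bins: int,
    assemblies: Sequence[np.ndarray],
    rng: np.random.Generator,
    baseline: float = 0.2,
    event_prob: float = 0.05,
    boost: float = 3.0,
) -> np.ndarray:
    """20-ms binned spike counts with planted co-activation groups.

    Each bin is baseline Poisson; with probability ``event_prob`` per
    assembly per bin, all members receive an extra Poisson(``boost``) count,
    creating the 20-ms-timescale correlation structure that PCA assembly
    detection targets.
    """
    counts = rng.poisson(baseline, size=(n_units, n_bins))
    probs = np.broadcast_to(np.asarray(event_prob, float), (len(assemblies),))
    boosts = np.broadcast_to(np.asarray(boost, float), (len(assemblies),))
    # distinct per-assembly strengths keep the leading eigenvalues apart;
    # exactly matched assemblies make the PCA components rotationally
    # degenerate and mix memberships
    scale = np.linspace(1.0, 0.6, len(assemblies)) if len(assemblies) > 1 else [1.0]
    for k, members in enumerate(assemblies):
        events = rng.random(n_bins) < probs[k] * scale[k]
        idx = np.where(events)[0]
        counts[np.ix_(np.asarray(members), idx)] += rng.poisson(
            boosts[k], size=(len(members), idx.size)
        )
    return counts


def session_hash(session) -> str:
    """Stable hash of a generated session (determinism checks)."""
    h = zlib.crc32(b"")
    arrays: list[np.ndarray] = []
    if isinstance(session, RunSession):
        arrays += [session.time, session.position, session.velocity,
                   session.direction.astype(float)]
        arrays += session.spikes
        arrays.append(session.ground_truth[
            ["centre", "width", "peak_rate"]].to_numpy().ravel())
    elif isinstance(session, SleepSession):
        arrays += session.spikes
        arrays.append(session.frame_truth[["start", "end"]].to_numpy().ravel())
    elif isinstance(session, LfpTrace):
        arrays += [session.time, session.samples]
    for a in arrays:
        h = zlib.crc32(np.ascontiguousarray(a, dtype=float).tobytes(), h)
    return f"{h:08x}"
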