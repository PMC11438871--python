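"""Direction-specific rate maps, place-cell classification and tuning metrics.

Rate maps count spikes at velocity > 5 cm/s in non-overlapping 2-cm bins,
smooth the spike-count and occupancy-time maps with the same 2-cm Gaussian
kernel, and divide.  Units with peak rate above 1 Hz are place cells.
Single-cell metrics: spatial information (bits/spike), first-vs-last-fifth
lap stability (Spearman), and primary-field length at the 20%-of-peak level.
Map-level classification separates low-tuned, symmetric-mapping and
well-tuned maps via the squared-mean-to-variance ratio (SMV) and the
symmetry index (SI).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.stats import spearmanr

__all__ = [
    "RateMap",
    "TuningMetrics",
    "RateMapClass",
    "EmptyMapError",
    "compute_rate_map",
    "spatial_information",
    "map_stability",
    "primary_field_length",
    "classify_rate_map",
    "detect_laps",
    "smv",
    "symmetry_index",
    "recalibrate_smv_threshold",
]

PLACE_CELL_PEAK_HZ = 1.0
SMV_THRESHOLD = 3.62
SI_THRESHOLD = 0.67
END_ZONE_CM = 30.0


class EmptyMapError(ValueError):
    """No occupancy under the velocity/direction filter."""


@dataclass
class RateMap:
    """Occupancy-normalised firing map on one track direction."""

    rates: np.ndarray            # Hz per spatial bin
    occupancy: np.ndarray        # Pr(loc_j), sums to 1
    bin_edges: np.ndarray        # cm
    direction: int
    unit_id: int = -1
    occupied: np.ndarray = None  # bins ever visited

    @property
    def bin_centres(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_size(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def mean_rate(self) -> float:
        return float(np.sum(self.occupancy * self.rates))

    @property
    def peak_rate(self) -> float:
        return float(self.rates.max()) if self.rates.size else 0.0

    @property
    def track_length(self) -> float:
        return float(self.bin_edges[-1] - self.bin_edges[0])

    @property
    def is_place_cell(self) -> bool:
        return self.peak_rate > PLACE_CELL_PEAK_HZ


@dataclass
class TuningMetrics:
    unit_id: int
    direction: int
    peak_rate: float
    spatial_information: float
    stability: float
    primary_field_length: float
    is_place_cell: bool


@dataclass
class RateMapClass:
    smv: float
    symmetry_index: float
    category: str                 # low_tuned | symmetric | well_tuned
    symmetry_applicable: bool     # peak within the end zones
    flagged: bool = False


def _bin_position(x, track_length, bin_size):
    edges = np.arange(0.0, track_length + bin_size / 2, bin_size)
    if edges[-1] < track_length:
        edges = np.append(edges, track_length)
    # half-open [left, right); values at exactly track_length go to last bin
    idx = np.minimum(np.searchsorted(edges, x, side="right") - 1, len(edges) - 2)
    return edges, idx


def compute_rate_map(
    spike_times: np.ndarray,
    time: np.ndarray,
    position: np.ndarray,
    velocity: np.ndarray,
    direction: np.ndarray,
    which_direction: int,
    track_length: float,
    bin_size: float = 2.0,
    smooth_sd_cm: float = 2.0,
    vmin: float = 5.0,
    unit_id: int = -1,
) -> RateMap:
    """Velocity-filtered, Gaussian-smoothed occupancy-normalised rate map.

    The same kernel (SD ``smooth_sd_cm``, truncated at 3 SD) is applied to
    the spike-count and occupancy-time maps before division; never-occupied
    bins get rate 0 and are flagged in ``occupied``.
    """
    time = np.asarray(time, float)
    keep = (np.abs(velocity) > vmin) & (direction == which_direction)
    if not keep.any():
        raise EmptyMapError("no occupancy at velocity > vmin in this direction")
    dt = np.median(np.diff(time)) if time.size > 1 else 0.0

    edges, pos_idx = _bin_position(position, track_length, bin_size)
    n_bins = len(edges) - 1
    occ_t = np.bincount(pos_idx[keep], minlength=n_bins) * dt

    st = np.asarray(spike_times, float)
    if st.size and time.size:
        samp = np.clip(np.searchsorted(time, st) - 1, 0, time.size - 1)
        ok = keep[samp]
        spike_x = np.interp(st[ok], time, position)
        _, sp_idx = _bin_position(spike_x, track_length, bin_size)
        spk = np.bincount(sp_idx, minlength=n_bins).astype(float)
    else:
        spk = np.zeros(n_bins)

    sigma = smooth_sd_cm / bin_size
    occ_s = gaussian_filter1d(occ_t, sigma, truncate=3.0, mode="constant")
    spk_s = gaussian_filter1d(spk, sigma, truncate=3.0, mode="constant")
    occupied = occ_s > 0
    rates = np.zeros(n_bins)
    rates[occupied] = spk_s[occupied] / occ_s[occupied]

    total = occ_t.sum()
    if total <= 0:
        raise EmptyMapError("zero total occupancy")
    occ_p = gaussian_filter1d(occ_t / total, sigma, truncate=3.0, mode="constant")
    occ_p = occ_p / occ_p.sum()
    return RateMap(rates=rates, occupancy=occ_p, bin_edges=edges,
                   direction=which_direction, unit_id=unit_id, occupied=occupied)


def spatial_information(rate_map: RateMap) -> float:
    """Spatial information in bits per spike.

    SpInfo = sum_j Pr(loc_j) (fr_j / fr_mean) log2(fr_j / fr_mean); bins
    with zero rate contribute 0.  Undefined (NaN) when the mean rate is 0.
    """
    fr = np.asarray(rate_map.rates, float)
    p = np.asarray(rate_map.occupancy, float)
    fr_mean = float(np.sum(p * fr))
    if fr_mean <= 0:
        return float("nan")
    ratio = fr / fr_mean
    terms = np.zeros_like(fr)
    pos = ratio > 0
    terms[pos] = p[pos] * ratio[pos] * np.log2(ratio[pos])
    return float(terms.sum())


def detect_laps(time, position, direction, track_length, end_fraction=0.05):
    """End-zone-to-opposite-end-zone traversals in one direction.

    Returns (start, end) times of laps in `direction`; a lap runs from the
    last exit of one 5%-of-length end zone to the first entry of the other.
    """
    z = end_fraction * track_length
    d = np.asarray(direction)
    x = np.asarray(position, float)
    laps = []
    in_lap = False
    for i in range(len(x)):
        if not in_lap and d[i] != 0:
            near_start = x[i] < z if d[i] == 1 else x[i] > track_length - z
            if near_start or (0 < i and d[i - 1] == 0):
                in_lap, lap_dir, t0 = True, d[i], time[i]
        if in_lap:
            done = (x[i] > track_length - z) if lap_dir == 1 else (x[i] < z)
            if done or d[i] != lap_dir:
                laps.append((t0, time[i], lap_dir))
                in_lap = False
    return laps


def map_stability(
    spike_times, time, position, velocity, direction, which_direction,
    track_length, **map_kwargs,
) -> float:
    """Spearman correlation of maps from the first vs last fifth of laps."""
    laps = [l for l in detect_laps(time, position, direction, track_length)
            if l[2] == which_direction]
    if len(laps) < 5:
        raise ValueError("need at least 5 laps in this direction")
    k = max(len(laps) // 5, 1)
    time = np.asarray(time, float)

    def submap(lap_subset):
        mask = np.zeros(time.size, bool)
        for a, b, _ in lap_subset:
            mask |= (time >= a) & (time <= b)
        d_masked = np.where(mask, direction, 99)
        st = np.asarray(spike_times, float)
        return compute_rate_map(
            st, time, position, velocity, d_masked, which_direction,
            track_length, **map_kwargs,
        )

    m1 = submap(laps[:k])
    m2 = submap(laps[-k:])
    rho, _ = spearmanr(m1.rates, m2.rates)
    return float(rho)


def primary_field_length(rate_map: RateMap, threshold_fraction: float = 0.2):
    """Contiguous extent around the peak where rate >= 20% of peak (cm).

    Returns NaN for non-place cells (peak <= 1 Hz).
    """
    fr = np.asarray(rate_map.rates, float)
    if rate_map.peak_rate <= PLACE_CELL_PEAK_HZ:
        return float("nan")
    peak = int(np.argmax(fr))
    level = threshold_fraction * fr[peak]
    lo = peak
    while lo > 0 and fr[lo - 1] >= level:
        lo -= 1
    hi = peak
    while hi < fr.size - 1 and fr[hi + 1] >= level:
        hi += 1
    return float((hi - lo + 1) * rate_map.bin_size)


def smv(rates: np.ndarray) -> float:
    """Squared-mean-to-variance ratio of a rate map (high = flat/untuned)."""
    fr = np.asarray(rates, float)
    v = fr.var()
    if v == 0:
        return float("inf")
    return float(fr.mean() ** 2 / v)


def symmetry_index(rate_map: RateMap, window_bins: int = 5):
    """SI = 1 - (PF - PF_sym) / (PF + PF_sym).

    PF is the mean rate in ``window_bins`` bins centred on the peak, PF_sym
    the mean in the window centred on the location mirrored about the track
    middle.  In [0, 2]; 1 means equal rates at the two symmetric locations.
    """
    fr = np.asarray(rate_map.rates, float)
    n = fr.size
    half = window_bins // 2

    def win_mean(c):
        lo, hi = max(c - half, 0), min(c + half + 1, n)
        return fr[lo:hi].mean()

    peak = int(np.argmax(fr))
    pf = win_mean(peak)
    pf_sym = win_mean(n - 1 - peak)
    if pf + pf_sym == 0:
        return float("nan")
    return float(1.0 - (pf - pf_sym) / (pf + pf_sym))


def classify_rate_map(
    rate_map: RateMap,
    smv_threshold: float = SMV_THRESHOLD,
    si_threshold: float = SI_THRESHOLD,
    end_zone_cm: float = END_ZONE_CM,
) -> RateMapClass:
    """Two-step classification: low-tuned by SMV, then symmetric by SI.

    Maps with SMV above the threshold are low-tuned.  Among the rest, only
    maps peaking within ``end_zone_cm`` of a track end are tested for
    symmetric mapping (SI above threshold); middle-peaked maps skip the
    symmetry step and classify well-tuned.
    """
    s = smv(rate_map.rates)
    si = symmetry_index(rate_map)
    if s > smv_threshold:
        return RateMapClass(s, si, "low_tuned", False)
    peak_x = rate_map.bin_centres[int(np.argmax(rate_map.rates))]
    near_end = (peak_x <= end_zone_cm) or (
        peak_x >= rate_map.track_length - end_zone_cm
    )
    if not near_end:
        return RateMapClass(s, si, "well_tuned", False)
    if np.isnan(si):
        return RateMapClass(s, si, "well_tuned", True, flagged=True)
    category = "symmetric" if si > si_threshold else "well_tuned"
    return RateMapClass(s, si, category, True)


def recalibrate_smv_threshold(reference_maps, percentile: float = 99.0) -> float:
    """SMV threshold from a reference (adult) map population's 99th percentile."""
    vals = [smv(m.rates) for m in reference_maps]
    vals = [v for v in vals if np.isfinite(v)]
    if not vals:
        raise ValueError("no finite SMV values in the reference population")
    return float(np.percentile(vals, percentile))
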