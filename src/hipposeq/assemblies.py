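"""Cell-assembly detection via PCA with a Marcenko-Pastur bound.

Run activity is binned at 20 ms and z-scored per unit; principal components
of the resulting correlation matrix whose eigenvalues exceed the
Marcenko-Pastur upper edge lambda_max = (1 + sqrt(n/M))^2 are significant
co-activation assemblies.  Each assembly's sleep activation strength is the
quadratic form A_c(t) = z(t)^T P_c z(t) with the projection matrix
P_c = p_c p_c^T diagonal-zeroed (so a single unit cannot drive activation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import stats as hstats

__all__ = [
    "BinnedActivity",
    "AssemblyModel",
    "AssemblyActivation",
    "bin_and_zscore",
    "detect_assemblies",
    "activation_strength",
    "reactivation_plasticity",
]


@dataclass
class BinnedActivity:
    """Z-scored 20-ms binned counts (units x bins) with raw counts kept."""

    Z: np.ndarray
    counts: np.ndarray
    unit_ids: np.ndarray
    bin_width: float
    dropped_units: np.ndarray      # constant-count units removed before PCA


def bin_and_zscore(
    spikes,
    t_start: float,
    t_end: float,
    bin_width: float = 0.02,
    epochs=None,
) -> BinnedActivity:
    """Bin spike trains and z-score each unit's counts across bins.

    ``epochs`` (DataFrame with start/end) restricts bins to those lying
    inside the intervals (e.g. NREM only).  Zero-variance units are dropped
    with their ids recorded.
    """
    edges = np.arange(t_start, t_end + bin_width / 2, bin_width)
    counts = np.vstack([np.histogram(st, bins=edges)[0] for st in spikes])
    if epochs is not None:
        mids = 0.5 * (edges[:-1] + edges[1:])
        keep = np.zeros(mids.size, bool)
        for _, ep in epochs.iterrows():
            keep |= (mids >= ep.start) & (mids < ep.end)
        counts = counts[:, keep]
    counts = counts.astype(float)
    mu = counts.mean(axis=1, keepdims=True)
    sd = counts.std(axis=1, keepdims=True)
    ok = sd[:, 0] > 0
    Z = (counts[ok] - mu[ok]) / sd[ok]
    return BinnedActivity(
        Z=Z, counts=counts[ok], unit_ids=np.where(ok)[0],
        bin_width=bin_width, dropped_units=np.where(~ok)[0],
    )


@dataclass
class AssemblyModel:
    eigenvalues: np.ndarray        # descending
    components: np.ndarray         # n_significant x n_units weight vectors
    lambda_max: float
    unit_ids: np.ndarray
    projections: np.ndarray        # n_significant x n x n, diagonal zeroed

    @property
    def n_significant(self) -> int:
        return self.components.shape[0]

    def memberships(self, sd_factor: float = 2.0) -> list[np.ndarray]:
        """Units whose |weight| exceeds sd_factor SD of the component."""
        return [
            self.unit_ids[np.abs(p) > sd_factor * p.std()]
            for p in self.components
        ]


def detect_assemblies(
    activity: BinnedActivity,
    normalization: str = "bins",
) -> AssemblyModel:
    """Significant PCA assemblies of z-scored run activity.

    ``normalization="bins"`` uses the correlation matrix (1/M) Z Z^T of the
    z-scored rows, consistent with the unit-variance assumption of the
    Marcenko-Pastur bound; ``"units"`` uses (1/n) Z Z^T (compatibility
    switch).  Components with eigenvalue above
    lambda_max = (1 + sqrt(n/M))^2 are retained; each projection matrix has
    its diagonal zeroed.
    """
    Z = activity.Z
    n, M = Z.shape
    if n < 2 or M < n:
        raise ValueError("need n >= 2 units and M >= n bins")
    scale = M if normalization == "bins" else n
    C = (Z @ Z.T) / scale
    lam, vec = np.linalg.eigh(C)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    lam_max = (1.0 + np.sqrt(n / M)) ** 2
    sig = lam > lam_max
    comps = vec[:, sig].T
    projections = np.empty((comps.shape[0], n, n))
    for k, p in enumerate(comps):
        P = np.outer(p, p)
        np.fill_diagonal(P, 0.0)
        projections[k] = P
    return AssemblyModel(
        eigenvalues=lam, components=comps, lambda_max=float(lam_max),
        unit_ids=activity.unit_ids, projections=projections,
    )


@dataclass
class AssemblyActivation:
    strengths: np.ndarray          # assemblies x bins, A_c(t)
    event_bins: list[np.ndarray]   # per assembly, peak bin of each event
    event_strengths: list[np.ndarray]
    mean_activation: np.ndarray    # per assembly, mean over events (NaN if none)


def activation_strength(
    model: AssemblyModel,
    sleep: BinnedActivity,
    threshold: float = 5.0,
    min_active_units: int = 2,
    place_cell_units: np.ndarray | None = None,
) -> AssemblyActivation:
    """A_c(t) for every assembly over z-scored sleep bins, with events.

    Model units absent from the sleep activity are treated as zero-rate
    rows.  Events are contiguous supra-threshold runs (A_c > threshold)
    collapsed to their peak bin, requiring at least ``min_active_units``
    spiking units in that bin (including one of ``place_cell_units`` when
    given).
    """
    n_units = model.unit_ids.size
    M = sleep.Z.shape[1]
    Z = np.zeros((n_units, M))
    counts = np.zeros((n_units, M))
    sleep_pos = {u: i for i, u in enumerate(sleep.unit_ids)}
    for i, u in enumerate(model.unit_ids):
        j = sleep_pos.get(u)
        if j is not None:
            Z[i] = sleep.Z[j]
            counts[i] = sleep.counts[j]
    # z^T P z with zeroed diagonal = (p.z)^2 - sum_i p_i^2 z_i^2
    P = model.components                      # k x n
    proj = P @ Z                              # k x M
    diag = (P ** 2) @ (Z ** 2)
    A = proj ** 2 - diag

    event_bins, event_strengths, means = [], [], []
    if place_cell_units is not None:
        pc_mask = np.isin(model.unit_ids, place_cell_units)
    else:
        pc_mask = np.ones(n_units, bool)
    active_ok = (counts > 0).sum(axis=0) >= min_active_units
    pc_ok = (counts[pc_mask] > 0).any(axis=0)
    for c in range(A.shape[0]):
        above = A[c] > threshold
        bins, vals = [], []
        i = 0
        while i < M:
            if above[i]:
                j = i
                while j + 1 < M and above[j + 1]:
                    j += 1
                seg = slice(i, j + 1)
                peak = i + int(np.argmax(A[c, seg]))
                if active_ok[peak] and pc_ok[peak]:
                    bins.append(peak)
                    vals.append(A[c, peak])
                i = j + 1
            else:
                i += 1
        event_bins.append(np.asarray(bins, int))
        event_strengths.append(np.asarray(vals, float))
        means.append(np.mean(vals) if vals else float("nan"))
    return AssemblyActivation(
        strengths=A, event_bins=event_bins, event_strengths=event_strengths,
        mean_activation=np.asarray(means),
    )


def reactivation_plasticity(
    model: AssemblyModel,
    pre: AssemblyActivation,
    post: AssemblyActivation,
):
    """Experience-dependent change in assembly activation across sleeps.

    Delta_c = mean event activation in post-run sleep minus pre-run sleep;
    per-assembly rank-sum test across activation instances and a
    group-level signed-rank test across assemblies.
    """
    deltas, pvals = [], []
    for c in range(model.n_significant):
        a, b = pre.event_strengths[c], post.event_strengths[c]
        if a.size == 0 or b.size == 0:
            deltas.append(float("nan"))
            pvals.append(float("nan"))
            continue
        deltas.append(float(b.mean() - a.mean()))
        pvals.append(hstats.ranksum(b, a))
    deltas = np.asarray(deltas)
    ok = np.isfinite(deltas)
    group_p = (
        hstats.signed_rank(deltas[ok]) if ok.sum() >= 2 and
        np.any(deltas[ok] != 0) else float("nan")
    )
    return {
        "delta": deltas,
        "per_assembly_p": np.asarray(pvals),
        "group_p": group_p,
    }
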