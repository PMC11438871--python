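# Methods

This note documents the models, parameter choices and numerical decisions
behind `hipposeq`, in the spirit of a package methods appendix.  Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## The synthetic preparation

The generator emulates a developmental CA1 recording: a 1-m linear track run
in laps, a few dozen simultaneously held units, and flanking NREM-like sleep.
Its defaults are the study conditions every test runs under.

**Run.** Position is sampled at 25 Hz (video-tracking timescale): constant
20 cm/s traversals with a 1-s pause at each end, both directions.  Each unit
gets an independent field draw per direction: Gaussian tuning with centre
uniform on the track, SD 5–12 cm (field lengths at the 20 %-of-peak level of
roughly 30–50 cm, the large fields of developing animals), peak 3–15 Hz.  A
`low_tuned_fraction` (default 0.1) of units fire position-independently at
0.5–2 Hz.  Spikes are drawn by thinning a 1-kHz Bernoulli approximation of
the inhomogeneous Poisson rate.

**Mirror (symmetric-mapping) component.** The geometry-deprivation phenotype
is modelled as a second field mirrored about the track middle:
`λ(x) = peak·(G(x;c,σ) + w·G(L−x;c,σ))/(1+w)`, so `w = 1` yields a map
exactly symmetric about the middle.  The per-cell weight is end-weighted,
`w_i = mirror_weight · (2|c_i − L/2|/L)²`: fields near the ends mirror
strongly, middle fields barely at all.  This is deliberate — a constant
weight elevates symmetric-location similarity *uniformly* at every
separation and therefore cannot produce the defining signature of the
warped phenotype, a *positive* slope of population-vector similarity versus
symmetric-location separation; end-weighting produces it directly, and is
consistent with symmetric maps being an end-field phenomenon (the map
classification only tests end-peaked cells for symmetry).

**Theta.** The represented position sweeps behind→ahead of the animal within
each 6.7-Hz theta cycle (±10 cm, zero-crossing at the LFP trough), which is
what makes theta sequences and a positive quadrant ratio exist in the
synthetic data at all.

**Sleep.** NREM (60-s blocks) alternates with intermediate epochs (15 s).
Population-burst frames are placed in NREM at 10/min with exponential gaps;
durations are 5–35 bins of 20 ms.  The 0.7-s cap (not 0.8 s) leaves room for
the detector's 15-ms smoothing, which extends threshold crossings by roughly
two kernel widths — a planted 0.8-s frame would be rejected by the detector's
own 100–800 ms duration bound.  A `seq_frame_fraction` of frames embed a
time-compressed trajectory: a virtual position advancing
`seq_compression·L` (default 10 cm) per 20-ms bin, spikes Poisson from the
run tuning with a ×5 rate gain; sequence frames are capped at
`1/seq_compression` bins because a longer frame would clip at a track end
and carry no further sequential structure.  Non-sequence frames draw each
unit's count from a rate-matched Poisson.  Planted frame clusters partition
the units into disjoint participating subsets; planted assemblies inject
shared-bin co-activation among their members, with per-assembly strengths
deliberately unequal (exactly matched assemblies make the leading PCA
eigenvalues degenerate and the components mix).  Background spiking outside
frames is 0.5 Hz per unit.

**Field potential.** 1250 Hz.  Run: a theta sinusoid during movement plus
noise.  Sleep: delta-band (1–4 Hz) noise in NREM, theta-band noise in
intermediate epochs, and a 190-Hz ripple burst under every planted frame.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: spike-sorting noise and unit instability, phase
precession beyond the rigid population sweep, behavioural variability
(variable speeds, incomplete laps), REM sleep proper, non-stationary
baseline rates, and 2-D or curved-track geometry.  Tests validate the
*statistics* under their stated assumptions, not robustness to these
nuisances.

## Analysis conventions

* Rate maps: 2-cm bins, velocity filter > 5 cm/s on spikes and occupancy,
  the same Gaussian kernel (SD 2 cm, truncated at ±3 SD) applied to the
  spike-count and occupancy maps before division.  Bins are half-open with
  positions exactly at `L` assigned to the last bin.  Laps are end-zone to
  opposite-end-zone traversals with 5 %-of-length end zones.
* Place cells: peak rate > 1 Hz.  Spatial information is Skaggs bits/spike;
  zero-rate bins contribute zero and a silent map returns NaN.
* Map classification: low-tuned if squared-mean-to-variance SMV > 3.62 (a
  constant map, variance 0, is low-tuned by convention); among end-peaked
  maps (peak within 30 cm of an end), symmetric if
  SI = 1 − (PF − PF_sym)/(PF + PF_sym) > 0.67 with 5-bin windows; the SMV
  threshold can be recalibrated as the 99th percentile of a supplied
  reference map population.
* Encoding models: 1-cm bins, 5-cm smoothing, units with ≥ 10 filtered run
  spikes, per direction, never pooled.  A 0.01-Hz rate floor keeps logs
  finite (configurable to 0, in which case a spike from a zero-rate unit
  makes the bin's likelihood exactly −∞; an all-−∞ row falls back to the
  uniform prior and is flagged).  Ties in the argmax location break toward
  the lower bin.  Theta-cycle decoding uses 2-cm smoothing.
* Frames: 1-ms population rate, 15-ms Gaussian smoothing, boundaries at the
  up/down crossings of mean + 2 SD (statistics within the context epochs),
  bursts closer than 20 ms merged, 100–800 ms, ≥ 5 distinct units, binned
  at 20 ms.  Awake rest uses velocity < 1 cm/s, sleep < 2 cm/s via NREM.
* NREM: immobility AND Hilbert theta/delta (5–9 / 1–4 Hz) amplitude ratio,
  10-s Gaussian smoothed, below its session mean; immobility-only fallback
  when no LFP is available, flagged in the epoch label.
* Ripples: 140–250 Hz envelope; events are regions above mean + 1 SD
  containing a peak above mean + 3 SD (the edge rule is a package choice;
  only the 3-SD peak criterion is load-bearing).
* Shuffles: the time-bin permutation is the only null for sequence
  significance.  Row permutation leaves the weighted time and space
  marginals of a row-normalised posterior unchanged, so shuffle correlations
  reduce to permuted cross-covariances — a fast path that tests verify
  against direct recomputation at 1e-12.  Per-frame shuffle generators are
  derived from one root seed, and in multi-track comparisons the same
  per-frame seed is reused across tracks so identical models reach
  identical decisions.
* Circular-linear correlation: locations map to angles `2π·x/L`; the
  magnitude is the weighted analogue of the classical
  `√((r_tc² + r_ts² − 2 r_tc r_ts r_cs)/(1 − r_cs²))` computed over the
  joint posterior mass, signed by the rotation direction of the mean
  resultant over time.  Verified against a resampling oracle.
* Quadrant ratio: with odd matrix dimensions the central row/column belongs
  to no quadrant; "ahead" is oriented by running direction.
* Clustering: spherical k-means on the binarised pair-significance rows
  (cosine dissimilarity; zero rows have similarity 0 to everything),
  random data-point initialisation per restart, the cluster-level
  silhouette (a − w)/max(w, a) with `w` the mean within-cluster and `a` the
  nearest-cluster mean pairwise distance; the optimal k is the modal argmax
  over restarts, ties toward smaller k.  scikit-learn's k-means is
  Euclidean and its silhouette sample-level, so these two pieces are
  implemented in-package.
* Assemblies: the correlation matrix of z-scored rows is `(1/M)ZZᵀ`
  (consistent with the unit-variance assumption of the Marcenko–Pastur
  bound); a compatibility switch provides the `(1/n)` normalisation.
  Activation events are contiguous supra-threshold (A > 5) runs collapsed
  to their peak bin, requiring ≥ 2 spiking units including a place cell
  when a place-cell list is supplied.  Mean activation averages over
  events, not all bins.
* Geometry: PV correlations are Pearson; warp segments are two 2-cm bins
  tiling outward from the middle, terminal segments excluded, fitted over
  24–88 cm separations; manifold PCA min-max normalises each spatial bin
  (max unit → 1, zeros preserved); end-specificity zones are 15 cm,
  configurable.
* Statistics: two-sided tests by default; one-sided only against
  chance/shuffle references.  Binomial tests against 0.05 chance; pooled
  two-proportion z-tests for the joint-threshold and bin-removal
  comparisons; Wilcoxon rank-sum / signed-rank for activation plasticity;
  OLS with likelihood-ratio chi-square tests for the six-predictor
  pattern-separation regression.

## Problem sizes

Validation runs use desk-scale versions of the study conditions chosen once:
40–50 units, 10–20 laps, 10–20 min sleeps, 500 shuffles for calibration and
power runs (100–200 where only a direction of effect is asserted), 10-seed
recovery runs for Marcenko–Pastur and cluster recovery, and 20 seeded cohort
pairs for the warp discrimination.  The null-calibration run uses 1,000
frames × 500 shuffles.  The regression "recovered within 2 SE" claim is
checked as per-coefficient coverage over repeated simulations (a single
six-coefficient draw is jointly inside ±2 SE only ~74 % of the time even for
a perfectly calibrated estimator).

## Known limitations

The lap detector assumes complete traversals; the ripple-edge rule and the
frame-boundary rule are simple crossing conventions; the recovery index
reports clipped ratios alongside raw values but the choice of baseline
time point is the caller's; `robustness_suite`'s 500-surrogate variant is
expensive and sized down by callers; and the generator's planted effects are
stylised — effect sizes in real recordings need not match.
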