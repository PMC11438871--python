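# hipposeq

Analysis stack for hippocampal CA1 ensemble recordings on linear tracks in
developing rodents, with a ground-truth spike-train simulator that lets every
stage be validated without raw recordings.  It targets the question of how
early-life experience of Euclidean geometry shapes place maps, time-compressed
sequences and the intrinsic sleep repertoire: direction-specific place-field
estimation and classification, memoryless Bayesian position decoding,
theta-sequence and sleep replay/preplay detection with shuffle nulls,
frame-ensemble similarity clustering, Marcenko–Pastur cell-assembly detection,
and population-vector geometry (track-end similarity, symmetric-location
warping, pattern separation).

## The statistics at the core

**Bayesian decoding.** With per-unit tuning curves `f_i(x)` (1-cm bins, 5-cm
Gaussian smoothing, units with ≥ 10 run spikes) and Poisson, independent
spiking, a time bin of width τ with counts `sp_i` decodes as

    Pr(x | sp) ∝ Pr(x) · Π_i f_i(x)^{sp_i} · exp(−τ Σ_i f_i(x)),

with a uniform prior; τ = 0.5 s during running, 0.02 s inside sleep frames.

**Weighted correlation.** A frame's sequential content is the product-moment
correlation between time bin and track location, weighted by the decoded
posterior mass `Pr_ij`.  Significance comes from 500 within-frame permutations
of the 20-ms time bins (each bin's spatial profile kept intact): a frame is a
forward (reverse) sequence when `r` exceeds the 97.5th (falls below the 2.5th)
shuffle percentile.  The sequence score is `r_Z = (|r| − mean|r_shuf|) /
SD|r_shuf|`; jump distances track per-bin peak-location displacements.

**Theta quadrant ratio.** Decoded matrices of 400-ms windows on theta troughs
are re-centred on the animal; `QR = (Q1 + Q3 − Q2 − Q4) / Σ` measures
forward-sweep content, tested against time-bin shuffles at the 95th percentile.

**Assemblies.** 20-ms binned, z-scored run activity is decomposed by PCA;
components with eigenvalues above the Marcenko–Pastur edge `(1 + √(n/M))²` are
assemblies, and their sleep activation is the quadratic form
`A_c(t) = z(t)ᵀ P_c z(t)` with a diagonal-zeroed projection matrix.

**Geometry.** Stacked 2-cm place maps give a population vector per location;
the analyses quantify track-end PV similarity (15 % end zones), the slope of
symmetric-segment similarity vs separation over 24–88 cm ("warping"), PCA
manifolds, and across-track pattern separation against cell-ID-shuffle chance.

## Worked example

```python
import numpy as np
from hipposeq import synth, place_fields, decoding, events, sequences

cfg = synth.GeneratorConfig(seed=2, n_cells=40, n_laps=12,
                            seq_frame_fraction=0.4, sleep_duration=600.0)
run = synth.generate_run_session(cfg)
maps = [place_fields.compute_rate_map(
            run.spikes[i], run.time, run.position, run.velocity,
            run.direction, 1, run.track_length, unit_id=i)
        for i in range(run.n_cells)]
model = decoding.build_encoding_model(run, direction=1)
print(decoding.run_decoding_error(run, model,
      rng=np.random.default_rng(0))["median_error_cm"])   # 1.90

sleep = synth.generate_sleep_session(cfg, maps)
frames = events.detect_frames(sleep.spikes,
                              sleep.epochs[sleep.epochs.label == "nrem"],
                              duration=sleep.duration)
posts = sequences.frames_to_posteriors(frames, model)
res = sequences.classify_frames(posts, run.track_length, n_shuffles=500,
                                rng=np.random.default_rng(2))
print(len(frames), round(res["proportion"], 2))           # 72 0.38
```

The decoder recovers the simulated animal's position with a median error of
1.9 cm (the time-permutation null sits near 33 cm ≈ track length / 3), and
38 % of detected sleep frames carry significant trajectory sequences —
tracking the 40 % of frames the generator embedded, with the two-sided test's
~5 % false-positive floor on the rest.

A narrative walk through the whole stack lives in `analysis/01…05_*.py`; each
script prints what it found and writes tidy tables under `results/`.

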