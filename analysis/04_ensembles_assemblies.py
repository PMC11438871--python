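#!/usr/bin/env python
"""Frame-ensemble clustering and cell-assembly reactivation.

Two demonstrations on ground-truth synthetics.  (1) Sleep frames drawing on
three disjoint planted cell subsets are clustered by their
shuffle-normalised ensemble similarity (k-means, cosine dissimilarity,
silhouette model selection) and compared to the planted labels.  (2) Two
planted co-activation assemblies are detected in 20-ms binned activity via
the Marcenko-Pastur bound, and their activation change from a pre- to a
strengthened post-run sleep is measured.  Writes
results/ensembles_assemblies.csv.
"""

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from hipposeq import assemblies, ensembles, events, place_fields, synth
from common import RESULTS, SEED

# --- frame-ensemble clustering ------------------------------------------
cfg = synth.GeneratorConfig(seed=SEED + 2, n_cells=45, n_laps=12,
                            n_clusters_planted=3, sleep_duration=900.0)
run = synth.generate_run_session(cfg)
maps = [place_fields.compute_rate_map(
    run.spikes[i], run.time, run.position, run.velocity, run.direction, 1,
    run.track_length, unit_id=i) for i in range(run.n_cells)]
sleep = synth.generate_sleep_session(cfg, maps)
frames = events.detect_frames(sleep.spikes,
                              sleep.epochs[sleep.epochs.label == "nrem"],
                              duration=sleep.duration)
counts = ensembles.frame_count_matrix(frames)
rng = np.random.default_rng(SEED)
_, sig, _ = ensembles.frame_similarity(counts, n_shuffles=500, rng=rng)
clust = ensembles.cluster_frames(sig.astype(float), k_range=(2, 10),
                                 n_iter=50, rng=rng)
ft = sleep.frame_truth
truth = np.array([
    int(ft[(ft.start < f.end) & (f.start < ft.end)].cluster_id.iloc[0])
    if len(ft[(ft.start < f.end) & (f.start < ft.end)]) else -1
    for f in frames])
keep = truth >= 0
ari = adjusted_rand_score(truth[keep], clust.labels[keep])

# --- assemblies: detection and reactivation plasticity -------------------
arng = np.random.default_rng(SEED + 9)
planted = [np.arange(0, 8), np.arange(10, 18)]
run_counts = synth.generate_assembly_activity(45, 5000, planted, arng)


def as_activity(c):
    c = c.astype(float)
    mu, sd = c.mean(1, keepdims=True), c.std(1, keepdims=True)
    ok = sd[:, 0] > 0
    return assemblies.BinnedActivity(Z=(c[ok] - mu[ok]) / sd[ok],
                                     counts=c[ok],
                                     unit_ids=np.where(ok)[0],
                                     bin_width=0.02,
                                     dropped_units=np.where(~ok)[0])


model = assemblies.detect_assemblies(as_activity(run_counts))
pre = synth.generate_assembly_activity(45, 5000, planted, arng, boost=2.0)
post = synth.generate_assembly_activity(45, 5000, planted, arng, boost=5.0)
a_pre = assemblies.activation_strength(model, as_activity(pre))
a_post = assemblies.activation_strength(model, as_activity(post))
plast = assemblies.reactivation_plasticity(model, a_pre, a_post)

row = dict(
    n_frames=len(frames), k_planted=3, k_recovered=clust.k_optimal,
    cluster_ari=ari, mean_silhouette=clust.silhouette,
    n_assemblies_planted=2, n_assemblies_significant=model.n_significant,
    lambda_max=model.lambda_max,
    mean_delta_activation=float(np.nanmean(plast["delta"])),
    min_per_assembly_p=float(np.nanmin(plast["per_assembly_p"])),
)
df = pd.DataFrame([row])
RESULTS.mkdir(exist_ok=True)
df.to_csv(RESULTS / "ensembles_assemblies.csv", index=False)
print(df.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(f"clustering recovered k={clust.k_optimal} (planted 3) with label "
      f"agreement ARI {ari:.2f}; Marcenko-Pastur found "
      f"{model.n_significant} assemblies (planted 2) whose post-run "
      f"activation rose by {row['mean_delta_activation']:.1f} on average; "
      "wrote results/ensembles_assemblies.csv")
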