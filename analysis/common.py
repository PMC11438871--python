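"""Shared study configuration for the analysis scripts."""

from pathlib import Path

from hipposeq import pipeline

SEED = 7
RESULTS = Path(__file__).resolve().parent.parent / "results"
GROUPS = {
    "cuboid_like": dict(mirror_weight=0.0, low_tuned_fraction=0.1),
    "sphere_like": dict(mirror_weight=0.8, low_tuned_fraction=0.2),
}
N_RATS = 5


def study_design(n_shuffles: int = 200) -> pipeline.StudyDesign:
    sessions = []
    for group, tweaks in GROUPS.items():
        for _ in range(N_RATS):
            sessions.append({
                "group": group,
                "config": dict(n_cells=40, n_laps=12, sleep_duration=600.0,
                               seq_frame_fraction=0.25, **tweaks),
            })
    return pipeline.StudyDesign(sessions=sessions, seed=SEED,
                                n_shuffles=n_shuffles)
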