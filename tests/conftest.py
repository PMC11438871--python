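"""Shared synthetic fixtures.

Everything is generated programmatically from fixed seeds; session-scoped
fixtures cache the expensive simulations for reuse across test modules.
"""

import numpy as np
import pytest

from hipposeq import decoding, events, place_fields, synth


@pytest.fixture(scope="session")
def base_config():
    return synth.GeneratorConfig(
        seed=42, n_cells=40, n_laps=12, low_tuned_fraction=0.1,
        sleep_duration=600.0, seq_frame_fraction=0.3,
    )


@pytest.fixture(scope="session")
def run_session(base_config):
    return synth.generate_run_session(base_config)


@pytest.fixture(scope="session")
def rate_maps(run_session):
    maps = []
    for i in range(run_session.n_cells):
        maps.append(place_fields.compute_rate_map(
            run_session.spikes[i], run_session.time, run_session.position,
            run_session.velocity, run_session.direction, 1,
            run_session.track_length, unit_id=i,
        ))
    return maps


@pytest.fixture(scope="session")
def encoding_model(run_session):
    return decoding.build_encoding_model(run_session, direction=1)


@pytest.fixture(scope="session")
def sleep_session(base_config, rate_maps):
    return synth.generate_sleep_session(base_config, rate_maps)


@pytest.fixture(scope="session")
def sleep_frames(sleep_session):
    return events.detect_frames(
        sleep_session.spikes,
        sleep_session.epochs[sleep_session.epochs.label == "nrem"],
        duration=sleep_session.duration,
    )


def make_frame(counts, start=0.0, bin_width=0.02, context="sleep"):
    counts = np.asarray(counts)
    return events.Frame(
        start=start, end=start + counts.shape[1] * bin_width,
        counts=counts, n_active_units=int((counts.sum(axis=1) > 0).sum()),
        context=context,
    )
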