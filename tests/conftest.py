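import numpy as np
import pytest

from gazecells.config import (
    ArenaConfig,
    BehaviorConfig,
    EyeCalibration,
    TaskConfig,
)
from gazecells.behavior import generate_session
from gazecells import segmentation as seg


@pytest.fixture(scope="session")
def arena():
    return ArenaConfig()


@pytest.fixture(scope="session")
def calib():
    return EyeCalibration()


@pytest.fixture(scope="session")
def short_session(arena):
    """A 4-minute default session: (trace, events, ground_truth)."""
    return generate_session(
        arena, BehaviorConfig(), TaskConfig(), duration=240.0, rng_seed=5
    )


@pytest.fixture(scope="session")
def segmented(short_session, arena, calib):
    """Full segmentation of the short session: (features, spec, table)."""
    trace, events, truth = short_session
    feats = seg.compute_kinematic_features(trace, arena)
    spec = seg.build_hmm_spec(arena, feats)
    spec = seg.fit_observation_means(feats, spec, train_samples=60000)
    path, _ = seg.viterbi_decode(feats, spec)
    table = seg.refine_segments(path, feats, trace, spec)
    table = seg.annotate_saccade_gaze(table, trace, arena, calib)
    return feats, spec, table


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """A small simulated bundle on disk."""
    from gazecells import io as gio

    out = tmp_path_factory.mktemp("bundle")
    return gio.simulate_session(seed=5, out_dir=out, duration=150.0,
                                n_excitatory=8, n_inh_peak=2, n_inh_trough=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
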