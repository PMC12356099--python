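import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from gazecells.behavior import (
    draw_isi,
    draw_saccade_duration,
    generate_session,
    sample_saccade_kinematics,
    DASH,
    FEED,
    FIXATION,
    SACCADE,
)
from gazecells.config import BehaviorConfig, TaskConfig


def test_trace_well_formed(short_session):
    trace, events, truth = short_session
    assert len(trace.t) == len(trace.position) == len(trace.quat_wxyz)
    dt = np.diff(trace.t)
    assert np.allclose(dt, dt[0], atol=1e-9)
    assert np.allclose(np.linalg.norm(trace.quat_wxyz, axis=1), 1.0, atol=1e-9)
    assert len(events.light_state) == len(trace.t)


def test_saccade_pulse_integrates_to_amplitude(rng):
    cfg = BehaviorConfig()
    t, vel = sample_saccade_kinematics(40.0, cfg, rng, duration=0.08)
    assert np.all(vel >= 0)
    area = np.sum(vel) * (t[1] - t[0])
    assert abs(area - 40.0) < 2.0  # discrete sampling tolerance
    # peak velocity of a raised-cosine pulse is 2A/D
    assert abs(vel.max() - 2 * 40.0 / 0.08) < 0.05 * 2 * 40.0 / 0.08


def test_duration_distribution(rng):
    cfg = BehaviorConfig()
    d = np.array([draw_saccade_duration(cfg, rng) for _ in range(20000)])
    assert d.min() >= 0.03 and d.max() <= 0.122
    assert abs(d.mean() - 0.076) < 0.001
    assert abs(d.std() - 0.021) < 0.003


def test_isi_rate_distribution(rng):
    cfg = BehaviorConfig()
    isi = np.array([draw_isi(cfg, rng) for _ in range(20000)])
    rates = 1.0 / isi
    assert abs(rates.mean() - 3.8) < 0.05
    assert abs(rates.std() - 1.4) < 0.1


def test_ground_truth_saccade_stats(short_session):
    trace, events, truth = short_session
    sac = truth.saccades
    assert len(sac) > 100
    assert (sac["t_end"] > sac["t_start"]).all()
    assert sac["duration_s"].between(0.02, 0.135).all()
    # main sequence: amplitude and peak velocity (2A/D) strongly rank-correlated
    peak_vel = 2.0 * sac["amplitude_deg"] / sac["duration_s"]
    rho = spearmanr(sac["amplitude_deg"], peak_vel).statistic
    assert rho > 0.8


def test_state_labels_consistent(short_session):
    trace, events, truth = short_session
    assert set(np.unique(truth.state)) <= {FIXATION, SACCADE, DASH, FEED}
    # dashes move, fixations do not (99th percentile linear speed comparison)
    speed = np.linalg.norm(np.diff(trace.position, axis=0), axis=1) * trace.sample_rate
    dash_speed = np.median(speed[truth.state[:-1] == DASH])
    fix_speed = np.median(speed[truth.state[:-1] == FIXATION])
    assert dash_speed > 10 * fix_speed


def test_trials_and_light(short_session):
    trace, events, truth = short_session
    trials = events.trials
    assert (trials["target"] != trials["source"]).all()
    lit = events.light_state
    for row in trials.itertuples():
        if row.catch or not np.isfinite(row.t_light_on):
            continue
        i = int(row.t_light_on * trace.sample_rate) + 1
        assert lit[i] == row.target


def test_blocked_variant_catch_balance(arena):
    task = TaskConfig(variant="blocked", block_length=6, catch_per_block=2)
    trace, events, truth = generate_session(
        arena, BehaviorConfig(), task, duration=600.0, rng_seed=9,
    )
    trials = events.trials
    full_blocks = trials[trials["block"] >= 0].groupby("block")
    for _, blk in full_blocks:
        if len(blk) == task.block_length:
            assert blk["catch"].sum() == task.catch_per_block


def test_session_reproducible(arena):
    a = generate_session(arena, BehaviorConfig(), TaskConfig(), duration=60.0,
                         rng_seed=4)
    b = generate_session(arena, BehaviorConfig(), TaskConfig(), duration=60.0,
                         rng_seed=4)
    assert np.array_equal(a[0].position, b[0].position)
    assert np.array_equal(a[0].quat_wxyz, b[0].quat_wxyz)
    pd.testing.assert_frame_equal(a[2].saccades, b[2].saccades)
    c = generate_session(arena, BehaviorConfig(), TaskConfig(), duration=60.0,
                         rng_seed=5)
    assert not np.array_equal(a[0].position, c[0].position)
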