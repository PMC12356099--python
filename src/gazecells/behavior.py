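"""Ground-truthed synthetic sessions: head-pose traces with
saccade/fixation/dash/feed structure and closed-loop task events.

The generator emulates the discrete visual-search tasks: a bird perched at
a site makes head saccades between gaze fixations; when an eligible eye's
gaze stays within the trigger threshold of the current target for enough
consecutive samples, the target light turns on and the bird dashes to it,
feeds, and (in the X-shaped tasks) returns to the center.

Statistical structure of the defaults:

* saccade durations ~ N(76, 21) ms (truncated to [30, 160] ms);
* instantaneous saccade rates (reciprocal inter-saccade intervals) drawn
  from a gamma distribution with mean 3.8 Hz and sd 1.4 Hz, so the mean
  reciprocal ISI is 3.8 Hz and the median ISI is ~275 ms;
* saccade amplitudes are the geodesic angles between successive fixation
  orientations, which aim at task sites (with ~5 deg error) or at random
  directions — together with the near-constant durations this yields the
  main-sequence amplitude/peak-velocity correlation;
* saccade angular-velocity profiles are raised-cosine (Hann) pulses;
* fixation micro-jitter is a smooth Ornstein-Uhlenbeck wobble (sd 1 deg).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.spatial.transform import Rotation, Slerp

from .config import ArenaConfig, BehaviorConfig, EyeCalibration, TaskConfig
from .geometry import (
    GazeSample,
    aim_orientation,
    angular_distances_to_sites,
    calibrated_gaze_axes,
    gaze_rays,
    wxyz_from_rotations,
)

# Behavioral state codes shared with the segmentation ground truth.
SACCADE, FIXATION, DASH, FEED = 0, 1, 2, 3
STATE_NAMES = {SACCADE: "saccade", FIXATION: "fixation", DASH: "dash", FEED: "feed"}


@dataclass
class BehaviorTrace:
    """Uniformly sampled head pose: time (s), position (mm), quaternion."""

    t: np.ndarray  # (n,)
    position: np.ndarray  # (n, 3) mm
    quat_wxyz: np.ndarray  # (n, 4) unit quaternions, scalar first

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t)))

    def __len__(self):
        return len(self.t)


@dataclass
class TaskEvents:
    """Trial table plus the per-sample state of the target light."""

    trials: pd.DataFrame
    light_state: np.ndarray  # (n,) lit site index, -1 when no target is lit


@dataclass
class GroundTruthLabels:
    """Exact per-sample states and per-event tables for a generated session."""

    state: np.ndarray  # (n,) codes from STATE_NAMES
    site: np.ndarray  # (n,) perch site (fixation/feed/saccade) or dash dst
    src: np.ndarray  # (n,) dash source site, -1 otherwise
    gaze_site: np.ndarray  # (n,) site fixated at (aim), -1 otherwise
    saccades: pd.DataFrame  # t_start, t_end, t_peak, amplitude_deg, ...
    dashes: pd.DataFrame  # t_start, t_end, src, dst, trial


def sample_saccade_kinematics(
    amplitude: float,
    cfg: BehaviorConfig,
    rng: np.random.Generator,
    duration: Optional[float] = None,
):
    """Angular-velocity profile (deg/s) of one head saccade.

    A raised-cosine (Hann) velocity pulse integrating to ``amplitude``;
    the duration is drawn from the configured normal distribution unless
    given. Returns ``(t, velocity)`` sampled at the behavior rate; peak
    velocity is 2 * amplitude / duration.
    """
    if amplitude < 0:
        raise ValueError("saccade amplitude must be non-negative")
    if duration is None:
        duration = draw_saccade_duration(cfg, rng)
    fs = cfg.sample_rate
    n = max(2, int(round(duration * fs)))
    t = (np.arange(n) + 0.5) / n * duration
    vel = (amplitude / duration) * (1.0 - np.cos(2.0 * np.pi * t / duration))
    return t, vel


def draw_saccade_duration(cfg: BehaviorConfig, rng: np.random.Generator) -> float:
    for _ in range(100):
        d = rng.normal(cfg.saccade_duration_mean, cfg.saccade_duration_sd)
        # symmetric truncation about the mean keeps the realized mean equal
        # to the configured mean
        if 0.03 <= d <= 0.122:
            return float(d)
    return cfg.saccade_duration_mean


def draw_isi(cfg: BehaviorConfig, rng: np.random.Generator) -> float:
    """Peak-to-peak inter-saccade interval, as a reciprocal gamma rate."""
    k = (cfg.saccade_rate_mean / cfg.saccade_rate_sd) ** 2
    theta = cfg.saccade_rate_mean / k
    rate = float(rng.gamma(k, theta))
    rate = min(max(rate, 0.5), 8.5)
    return 1.0 / rate


class TaskController:
    """Closed-loop target selection and gaze-trigger logic.

    ``process`` consumes blocks of per-sample angular deviations (deg) of
    each eye to each site and returns the light-on time when the current
    target is triggered. Detection requires an eligible eye to stay within
    the threshold for at least ``gaze_trigger_min_samples`` consecutive
    samples; after a detection the eye must leave the threshold before it
    can re-arm. On catch trials the first detection leaves the light off.
    """

    def __init__(
        self,
        arena: ArenaConfig,
        task: TaskConfig,
        rng: np.random.Generator,
        hemisphere: str = "left",
    ):
        if task.variant == "all_to_all" and arena.center_site_index is not None:
            raise ValueError("the all-to-all task uses a layout with no center site")
        self.arena = arena
        self.task = task
        self.rng = rng
        self.contra_eye = 1 if hemisphere == "left" else 0
        self.trials: list[dict] = []
        self._target_counts = np.zeros(arena.n_sites, int)
        self._pair_counts = np.zeros((arena.n_sites, arena.n_sites), int)
        self._catch_pos_counts = np.zeros(task.block_length + 1, int)
        self._visit_history: list[int] = []
        self._block_index = -1
        self._block_pos = task.block_length  # force a new block at start
        self._block_target = None
        self._catch_positions: set[int] = set()
        self.current_target: Optional[int] = None
        self.current_source: Optional[int] = None
        self._consec = np.zeros(2, int)
        self._armed = np.ones(2, bool)
        self._trial: Optional[dict] = None

    # -- target selection -------------------------------------------------
    def _eligible_eyes(self) -> list[int]:
        if self.task.eligible_eyes == "contra_only":
            return [self.contra_eye]
        return [0, 1]

    def _pick_random_target(self, prev: Optional[int]) -> int:
        cands = [i for i in self.arena.outer_site_indices if i != prev]
        counts = self._target_counts[cands]
        best = [c for c, n in zip(cands, counts) if n == counts.min()]
        return int(self.rng.choice(best))

    def _pick_all_to_all_target(self, source: int) -> int:
        hist = self._visit_history
        cands = []
        for t in self.arena.outer_site_indices:
            if t == source:
                continue
            if (
                len(hist) >= 2
                and self.arena.adjacent(hist[-2], hist[-1])
                and self.arena.adjacent(hist[-1], t)
            ):
                continue  # no three adjacent sites in a row
            cands.append(t)
        counts = self._pair_counts[source, cands]
        best = [c for c, n in zip(cands, counts) if n == counts.min()]
        return int(self.rng.choice(best))

    def start_trial(self, source_site: int) -> dict:
        """Begin a new trial from ``source_site``; returns trial metadata."""
        prev_target = self.current_target
        is_catch = False
        if self.task.variant == "blocked":
            self._block_pos += 1
            if self._block_pos > self.task.block_length:
                self._block_index += 1
                self._block_pos = 1
                self._block_target = self._pick_random_target(prev_target)
                self._catch_positions = self._draw_catch_positions()
            target = self._block_target
            is_catch = self._block_pos in self._catch_positions
        elif self.task.variant == "all_to_all":
            target = self._pick_all_to_all_target(source_site)
            self._pair_counts[source_site, target] += 1
        else:
            target = self._pick_random_target(prev_target)
        self._target_counts[target] += 1
        self.current_target = target
        self.current_source = source_site
        self._consec[:] = 0
        self._armed[:] = True
        self._trial = {
            "trial": len(self.trials),
            "target": target,
            "source": source_site,
            "t_light_on": np.nan,
            "t_light_off": np.nan,
            "t_first_detection": np.nan,
            "reward": bool(self.rng.random() < self.task.reward_probability),
            "catch": is_catch,
            "block": self._block_index if self.task.variant == "blocked" else -1,
            "block_pos": self._block_pos if self.task.variant == "blocked" else -1,
        }
        return dict(self._trial)

    def _draw_catch_positions(self) -> set[int]:
        # Catch trials occupy within-block positions 2..block_length, kept
        # balanced across positions over the session (within +/- 1).
        positions = np.arange(2, self.task.block_length + 1)
        counts = self._catch_pos_counts[positions]
        order = self.rng.permutation(len(positions))
        ranked = positions[order[np.argsort(counts[order], kind="stable")]]
        chosen = set(int(p) for p in ranked[: self.task.catch_per_block])
        for p in chosen:
            self._catch_pos_counts[p] += 1
        return chosen

    # -- gaze trigger ------------------------------------------------------
    def process(self, t: np.ndarray, deviations: np.ndarray) -> Optional[float]:
        """Feed per-sample deviations; return the light-on time if triggered.

        ``deviations`` has shape (n, 2, n_sites) in degrees. Only the
        current target and eligible eyes participate. Returns None when the
        light did not turn on during this block.
        """
        if self._trial is None or not np.isnan(self._trial["t_light_on"]):
            return None
        thr = self.task.gaze_trigger_threshold
        need = self.task.gaze_trigger_min_samples
        tgt = self.current_target
        for i in range(len(t)):
            for eye in self._eligible_eyes():
                below = deviations[i, eye, tgt] < thr
                if not below:
                    self._consec[eye] = 0
                    self._armed[eye] = True
                    continue
                if not self._armed[eye]:
                    continue
                self._consec[eye] += 1
                if self._consec[eye] >= need:
                    self._consec[eye] = 0
                    self._armed[eye] = False
                    detection = float(t[i])
                    if self._trial["catch"] and np.isnan(
                        self._trial["t_first_detection"]
                    ):
                        self._trial["t_first_detection"] = detection
                        continue
                    if np.isnan(self._trial["t_first_detection"]):
                        self._trial["t_first_detection"] = detection
                    t_on = detection + self.task.trigger_latency_median
                    self._trial["t_light_on"] = t_on
                    return t_on
        return None

    def notify_gaze_shift(self) -> None:
        """Reset consecutive-sample counters after a saccade moved the gaze."""
        self._consec[:] = 0
        self._armed[:] = True

    @property
    def has_active_trial(self) -> bool:
        return self._trial is not None

    def complete_trial(self, t_feed: float) -> None:
        """Close the current trial at seed retrieval (light turns off)."""
        if self._trial is None:
            return
        self._trial["t_light_off"] = float(t_feed)
        self.trials.append(self._trial)
        if self.task.variant == "all_to_all":
            self._visit_history.append(self._trial["target"])
        self._trial = None

    def abandon_trial(self) -> None:
        """Drop an unfinished trial at session end."""
        self._trial = None

    def trial_table(self) -> pd.DataFrame:
        cols = [
            "trial", "target", "source", "t_light_on", "t_light_off",
            "t_first_detection", "reward", "catch", "block", "block_pos",
        ]
        if not self.trials:
            return pd.DataFrame(columns=cols)
        return pd.DataFrame(self.trials)[cols]


def run_task_controller(
    controller: TaskController, t: np.ndarray, gaze_state: np.ndarray
) -> Optional[float]:
    """Functional wrapper over :meth:`TaskController.process`."""
    return controller.process(t, gaze_state)


class _OU:
    """AR(1)-discretized Ornstein-Uhlenbeck process with stationary sd."""

    def __init__(self, dim, sd, tau, dt, rng):
        self.rng = rng
        self.sd = sd
        self.a = float(np.exp(-dt / tau))
        self.innov = sd * np.sqrt(max(1.0 - self.a**2, 1e-12))
        self.x = rng.normal(0.0, sd, dim)

    def sample(self, n: int) -> np.ndarray:
        eps = self.rng.normal(0.0, self.innov, (n, len(self.x)))
        out = np.empty_like(eps)
        for d in range(eps.shape[1]):
            zi = np.array([self.a * self.x[d]])
            out[:, d], _ = lfilter([1.0], [1.0, -self.a], eps[:, d], zi=zi)
        self.x = out[-1].copy()
        return out


class _SessionBuilder:
    """Accumulates rendered intervals into per-sample session arrays."""

    def __init__(self, fs: float):
        self.fs = fs
        self.quats: list[np.ndarray] = []  # scalar-last (scipy) format blocks
        self.pos: list[np.ndarray] = []
        self.state: list[np.ndarray] = []
        self.site: list[np.ndarray] = []
        self.src: list[np.ndarray] = []
        self.gaze_site: list[np.ndarray] = []
        self.n = 0

    @property
    def t(self) -> float:
        return self.n / self.fs

    def append(self, quats_xyzw, pos, state, site, src=-1, gaze_site=-1):
        n = len(quats_xyzw)
        self.quats.append(np.asarray(quats_xyzw))
        self.pos.append(np.asarray(pos))
        self.state.append(np.full(n, state, dtype=np.int8))
        self.site.append(np.full(n, site, dtype=np.int8))
        self.src.append(np.full(n, src, dtype=np.int8))
        self.gaze_site.append(np.full(n, gaze_site, dtype=np.int8))
        self.n += n

    def finalize(self, n_total: int):
        quats = np.vstack(self.quats)[:n_total]
        pos = np.vstack(self.pos)[:n_total]
        state = np.concatenate(self.state)[:n_total]
        site = np.concatenate(self.site)[:n_total]
        src = np.concatenate(self.src)[:n_total]
        gaze = np.concatenate(self.gaze_site)[:n_total]
        # pad by holding the last pose if generation stopped mid-trial
        if len(quats) < n_total:
            deficit = n_total - len(quats)
            quats = np.vstack([quats, np.repeat(quats[-1:], deficit, axis=0)])
            pos = np.vstack([pos, np.repeat(pos[-1:], deficit, axis=0)])
            state = np.concatenate([state, np.full(deficit, FIXATION, np.int8)])
            site = np.concatenate([site, np.full(deficit, site[-1], np.int8)])
            src = np.concatenate([src, np.full(deficit, -1, np.int8)])
            gaze = np.concatenate([gaze, np.full(deficit, -1, np.int8)])
        return quats, pos, state, site, src, gaze


def _geodesic_deg(qa: Rotation, qb: Rotation) -> float:
    return float(np.rad2deg((qa.inv() * qb).magnitude()))


def _heading(rot: Rotation) -> float:
    v = rot.apply([0.0, 1.0, 0.0])
    return float(np.arctan2(v[1], v[0]))


def _feed_quat(rot: Rotation) -> Rotation:
    psi = _heading(rot) - np.pi / 2.0
    return Rotation.from_euler("z", psi) * Rotation.from_euler("x", np.deg2rad(-60.0))


def generate_session(
    arena: ArenaConfig,
    beh: BehaviorConfig,
    task: TaskConfig,
    duration: float = 1800.0,
    rng_seed: Optional[int] = None,
    hemisphere: str = "left",
    calib: Optional[EyeCalibration] = None,
):
    """Generate one closed-loop session.

    Returns ``(BehaviorTrace, TaskEvents, GroundTruthLabels)``. The output
    is a deterministic function of ``rng_seed`` (defaults to
    ``beh.rng_seed``).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if calib is None:
        calib = EyeCalibration(
            gaze_down_offset=beh.gaze_down_offset, inter_eye_angle=beh.inter_eye_angle
        )
    seed = beh.rng_seed if rng_seed is None else rng_seed
    rng = np.random.default_rng(seed)
    fs = beh.sample_rate
    dt = 1.0 / fs
    n_total = int(round(duration * fs))

    controller = TaskController(arena, task, rng, hemisphere=hemisphere)
    builder = _SessionBuilder(fs)
    gaze_axes_head = calibrated_gaze_axes(calib)
    frontal_axis = Rotation.from_euler(
        "x", -np.deg2rad(beh.gaze_down_offset)
    ).apply([0.0, 1.0, 0.0])

    head_z = float(np.clip(rng.normal(beh.head_height_mean, beh.head_height_sd), 30, 90))
    sites3d = np.c_[arena.site_positions, np.zeros(arena.n_sites)]

    ang_jitter = _OU(2, beh.fixation_jitter_sd, beh.jitter_corr_time, dt, rng)
    pos_jitter = _OU(2, 1.0, 1.0, dt, rng)

    sacc_rows: list[dict] = []
    dash_rows: list[dict] = []

    # perched position at a site (head above the perch, small offset)
    def perch_pos(site: int) -> np.ndarray:
        off = rng.normal(0.0, 3.0, 2)
        return np.array([sites3d[site, 0] + off[0], sites3d[site, 1] + off[1], head_z])

    def jittered(base: Rotation, n: int) -> Rotation:
        ang = ang_jitter.sample(n)
        wobble = Rotation.from_euler("zx", np.deg2rad(ang))
        return base * wobble

    def jittered_pos(base: np.ndarray, n: int) -> np.ndarray:
        j = pos_jitter.sample(n)
        out = np.tile(base, (n, 1))
        out[:, :2] += j
        return out

    def render_fixation(base: Rotation, pos, n, site, gaze_site):
        rots = jittered(base, n)
        builder.append(rots.as_quat(), jittered_pos(pos, n), FIXATION, site, -1, gaze_site)
        return rots

    def render_saccade(q0: Rotation, q1: Rotation, dur, pos, site, gaze_site, eye, kind, trial):
        n = max(2, int(round(dur * fs)))
        tau = (np.arange(n) + 0.5) / n
        s = tau - np.sin(2 * np.pi * tau) / (2 * np.pi)
        key = Rotation.from_quat(np.vstack([q0.as_quat(), q1.as_quat()]))
        rots = Slerp([0.0, 1.0], key)(s)
        t0 = builder.t
        builder.append(rots.as_quat(), jittered_pos(pos, n), SACCADE, site, -1, -1)
        amp = _geodesic_deg(q0, q1)
        sacc_rows.append(
            dict(
                t_start=t0,
                t_end=t0 + n * dt,
                t_peak=t0 + 0.5 * n * dt,
                amplitude_deg=amp,
                duration_s=n * dt,
                gaze_site=gaze_site,
                eye=eye,
                kind=kind,
                trial=trial,
                site=site,
            )
        )

    def aim_at_site(site: int, eye: int) -> Rotation:
        """Orientation pointing the given eye's gaze at a site, with error."""
        d = sites3d[site] - np.array([*cur_pos[:2], head_z])
        d = d / np.linalg.norm(d)
        err = Rotation.from_euler("zx", np.deg2rad(rng.normal(0, beh.aim_sd, 2)))
        axis = gaze_axes_head[eye] if eye >= 0 else frontal_axis
        q = Rotation.from_quat(aim_orientation(axis, d)[[1, 2, 3, 0]])
        return q * err

    def aim_random(eye: int) -> Rotation:
        # random search fixations stay within ~a quadrant of the current
        # heading; large re-orientations come from site-to-site gazes
        az = _heading(cur_rot) + np.deg2rad(rng.normal(0.0, 60.0))
        el = np.deg2rad(rng.normal(-10.0, 6.0))
        d = np.array([np.sin(az) * np.cos(el), np.cos(az) * np.cos(el), np.sin(el)])
        return Rotation.from_quat(aim_orientation(gaze_axes_head[eye], d)[[1, 2, 3, 0]])

    def next_eye(eye: int) -> int:
        # the viewing eye is sticky: wholesale head re-orientations that
        # swap eyes are occasional, not per-fixation
        return 1 - eye if rng.random() < 0.2 else eye

    def fixation_deviations(rots: Rotation, pos_block: np.ndarray) -> np.ndarray:
        quats = wxyz_from_rotations(rots)
        sample = gaze_rays(pos_block, quats, calib)
        return angular_distances_to_sites(sample, arena)

    # ---- main loop -------------------------------------------------------
    start_site = (
        arena.center_site_index
        if arena.center_site_index is not None
        else arena.outer_site_indices[0]
    )
    cur_site = start_site
    cur_pos = perch_pos(cur_site)
    cur_rot = Rotation.identity()
    cur_eye = int(rng.integers(0, 2))
    cur_rot = aim_random(cur_eye)
    gaze_aim = -1
    next_dur = draw_saccade_duration(beh, rng)

    controller.start_trial(cur_site)
    searching = True
    pending_target: Optional[int] = None

    while builder.n < n_total:
        if searching:
            # fixation under the current orientation, then a saccade to the
            # next aim; the ISI is the peak-to-peak interval
            cur_dur = next_dur
            next_dur = draw_saccade_duration(beh, rng)
            for _ in range(50):
                isi = draw_isi(beh, rng)
                fix_dur = isi - 0.5 * cur_dur - 0.5 * next_dur
                if fix_dur >= 0.03:
                    break
            else:
                fix_dur = 0.05
            n_fix = max(1, int(round(fix_dur * fs)))
            t_block = builder.t + (np.arange(n_fix) + 0.5) * dt
            rots = render_fixation(cur_rot, cur_pos, n_fix, cur_site, gaze_aim)
            dev = fixation_deviations(rots, builder.pos[-1])
            controller.notify_gaze_shift()
            t_on = controller.process(t_block, dev)
            if t_on is not None:
                pending_target = controller.current_target
                searching = False
                # orient saccade: frontal gaze toward the dash target
                new_rot = aim_at_site(pending_target, -1)
                render_saccade(
                    cur_rot, new_rot, next_dur, cur_pos, cur_site,
                    pending_target, -1, "orient", len(controller.trials),
                )
                cur_rot = new_rot
                continue
            # choose the next search fixation target
            for _ in range(20):
                eye_next = next_eye(cur_eye)
                if rng.random() < beh.p_gaze_site:
                    gaze_next = int(
                        rng.choice([s for s in arena.outer_site_indices if s != cur_site])
                    )
                    new_rot = aim_at_site(gaze_next, eye_next)
                else:
                    gaze_next = -1
                    new_rot = aim_random(eye_next)
                if _geodesic_deg(cur_rot, new_rot) >= beh.min_saccade_amplitude:
                    break
            render_saccade(
                cur_rot, new_rot, next_dur, cur_pos, cur_site,
                gaze_next, eye_next, "search", len(controller.trials),
            )
            cur_rot, gaze_aim, cur_eye = new_rot, gaze_next, eye_next
        else:
            # short pre-dash fixation (the bird has oriented frontally)
            n_fix = max(1, int(round(rng.uniform(0.12, 0.22) * fs)))
            render_fixation(cur_rot, cur_pos, n_fix, cur_site, pending_target)
            # dash along a straight line with a raised-cosine speed profile
            target = pending_target
            p0, p1 = cur_pos.copy(), perch_pos(target)
            dist = float(np.linalg.norm(p1[:2] - p0[:2]))
            t_dash = 2.0 * dist / beh.dash_speed
            n_dash = max(2, int(round(t_dash * fs)))
            tau = (np.arange(n_dash) + 0.5) / n_dash
            prog = tau - np.sin(2 * np.pi * tau) / (2 * np.pi)
            pos_path = p0[None, :] + prog[:, None] * (p1 - p0)[None, :]
            # head pitches down toward the feeder over the last 30% of travel
            fq = _feed_quat(cur_rot)
            blend = np.clip((tau - 0.7) / 0.3, 0.0, 1.0)
            key = Rotation.from_quat(np.vstack([cur_rot.as_quat(), fq.as_quat()]))
            rots = Slerp([0.0, 1.0], key)(blend)
            t0 = builder.t
            builder.append(rots.as_quat(), pos_path, DASH, target, cur_site, -1)
            dash_rows.append(
                dict(t_start=t0, t_end=t0 + n_dash * dt, src=cur_site, dst=target,
                     trial=len(controller.trials))
            )
            cur_site, cur_pos, cur_rot = target, p1, fq
            # feeding (seed retrieval closes the trial and the light)
            if controller.current_target == target and controller.has_active_trial:
                controller.complete_trial(builder.t)
            feed_dur = max(0.5, rng.normal(beh.feed_duration_mean, beh.feed_duration_sd))
            render_fixation(cur_rot, cur_pos, int(round(feed_dur * fs)), cur_site, -1)
            # relabel the interval we just wrote as feeding
            builder.state[-1][:] = FEED
            if arena.center_site_index is not None and cur_site != arena.center_site_index:
                # return leg: orient frontally to the center and dash back
                center = arena.center_site_index
                new_rot = aim_at_site(center, -1)
                render_saccade(
                    cur_rot, new_rot, draw_saccade_duration(beh, rng), cur_pos,
                    cur_site, center, -1, "orient", len(controller.trials),
                )
                cur_rot = new_rot
                pending_target = center
                # brief fixation then dash handled by re-entering this branch
                searching = False
                continue
            # ready for the next trial from the current site
            controller.start_trial(cur_site)
            next_aim = aim_random(cur_eye)
            render_saccade(
                cur_rot, next_aim, draw_saccade_duration(beh, rng), cur_pos,
                cur_site, -1, -1, "orient", len(controller.trials),
            )
            cur_rot, gaze_aim = next_aim, -1
            searching = True
            pending_target = None

    controller.abandon_trial()
    quats_xyzw, pos, state, site, src, gaze = builder.finalize(n_total)
    t = np.arange(n_total) / fs
    trace = BehaviorTrace(
        t=t, position=pos, quat_wxyz=quats_xyzw[:, [3, 0, 1, 2]]
    )

    trials = controller.trial_table()
    light = np.full(n_total, -1, np.int8)
    for _, row in trials.iterrows():
        if np.isnan(row.t_light_on):
            continue
        i0 = int(np.ceil(row.t_light_on * fs))
        i1 = n_total if np.isnan(row.t_light_off) else int(row.t_light_off * fs)
        light[i0:i1] = int(row.target)
    events = TaskEvents(trials=trials, light_state=light)

    saccades = pd.DataFrame(
        sacc_rows,
        columns=[
            "t_start", "t_end", "t_peak", "amplitude_deg", "duration_s",
            "gaze_site", "eye", "kind", "trial", "site",
        ],
    )
    saccades = saccades[saccades.t_end <= t[-1] + dt].reset_index(drop=True)
    dashes = pd.DataFrame(
        dash_rows, columns=["t_start", "t_end", "src", "dst", "trial"]
    )
    dashes = dashes[dashes.t_end <= t[-1] + dt].reset_index(drop=True)
    labels = GroundTruthLabels(
        state=state, site=site, src=src, gaze_site=gaze, saccades=saccades,
        dashes=dashes,
    )
    return trace, events, labels


def saccade_index_from_dash(saccade_peaks: np.ndarray, dash_starts: np.ndarray):
    """Backward index of each saccade relative to the next dash.

    Index 0 is the saccade immediately preceding a dash; -1 marks saccades
    with no upcoming dash (or separated from it by another dash).
    """
    saccade_peaks = np.asarray(saccade_peaks, float)
    dash_starts = np.sort(np.asarray(dash_starts, float))
    idx = np.full(len(saccade_peaks), -1, int)
    if len(dash_starts) == 0:
        return idx
    next_dash = np.searchsorted(dash_starts, saccade_peaks)
    for d in range(len(dash_starts)):
        lo = dash_starts[d - 1] if d > 0 else -np.inf
        group = np.where((next_dash == d) & (saccade_peaks > lo))[0]
        for rank, g in enumerate(group[np.argsort(-saccade_peaks[group])]):
            idx[g] = rank
    return idx
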