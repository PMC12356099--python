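"""Behavioral-state recovery from head tracking.

Pipeline: kinematic features (linear and angular speed, tilt, site and
path proximities) -> Gaussian-observation HMM decoded with Viterbi (state
means refit per session by Viterbi training; variances and transition
matrix fixed) -> rule-based cleanup and kinematic endpoint refinement ->
a table of labeled intervals with per-saccade peak-velocity times.

Refinement thresholds follow the published procedure: saccade endpoints at
400 deg/s (velocity) / 5000 deg/s^2 (acceleration), dash stop at 150 mm/s /
3000 mm/s^2. The velocity/acceleration criteria are combined with OR so
that acceleration catches slow saccade tails.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .behavior import DASH, FEED, FIXATION, SACCADE, BehaviorTrace
from .config import ArenaConfig, EyeCalibration
from .geometry import angular_distances_to_sites, gaze_rays, rotations_from_wxyz

SACCADE_VEL_THRESH = 400.0  # deg/s
SACCADE_ACC_THRESH = 5000.0  # deg/s^2
DASH_VEL_THRESH = 150.0  # mm/s
DASH_ACC_THRESH = 3000.0  # mm/s^2
PROXIMITY_SCALE_MM = 50.0  # length scale of the Gaussian proximity transform
LOWPASS_HZ = 50.0


@dataclass
class KinematicFeatures:
    """Per-sample kinematics plus the proximity features fed to the HMM."""

    t: np.ndarray
    linear_speed: np.ndarray  # mm/s, low-pass filtered
    angular_speed: np.ndarray  # deg/s, low-pass filtered
    tilt: np.ndarray  # deg between head z axis and world vertical
    site_proximity: np.ndarray  # (n, n_sites) in (0, 1]
    path_proximity: np.ndarray  # (n, n_paths) in (0, 1]
    sample_rate: float

    @property
    def linear_accel(self) -> np.ndarray:
        return np.gradient(self.linear_speed) * self.sample_rate

    @property
    def angular_accel(self) -> np.ndarray:
        return np.gradient(self.angular_speed) * self.sample_rate

    def matrix(self) -> np.ndarray:
        """Observation matrix: log-compressed speeds, scaled tilt, proximities."""
        return np.column_stack(
            [
                np.log1p(self.linear_speed),
                np.log1p(self.angular_speed),
                self.tilt / 60.0,
                self.site_proximity,
                self.path_proximity,
            ]
        )


@lru_cache(maxsize=4)
def _pulse_span_tables(fs: float, lowpass_hz: float = LOWPASS_HZ):
    """Threshold-span calibration for raised-cosine velocity pulses.

    Saccade refinement measures the interpolated span where the filtered
    angular speed exceeds the velocity threshold. The zero-phase low-pass
    both widens that span and attenuates the peak, so the raw span is a
    biased duration estimate. This tabulates, for unit-peak raised-cosine
    pulses pushed through the same measurement pipeline (frame
    differencing, midpoint centering, the low-pass), the attenuated peak
    ``gain(D)`` and the crossing span ``span(D, c)`` over a grid of pulse
    durations ``D`` and normalized threshold levels ``c``, averaged over
    sub-sample phase offsets.
    """
    b, a = butter(4, lowpass_hz / (fs / 2.0))
    d_grid = np.linspace(0.025, 0.175, 31)
    c_grid = np.linspace(0.02, 0.98, 49)
    phases = np.linspace(0.0, 1.0, 8, endpoint=False)
    gains = np.zeros(len(d_grid))
    spans = np.zeros((len(d_grid), len(c_grid)))
    counts = np.zeros((len(d_grid), len(c_grid)))
    pad = int(0.3 * fs)
    for i, dur in enumerate(d_grid):
        for ph in phases:
            nfr = int(np.ceil(dur * fs)) + 2 * pad
            tf = (np.arange(nfr + 1) - pad - ph) / fs
            tc = np.clip(tf, 0.0, dur)
            # position of a unit-peak raised-cosine velocity pulse
            theta = 0.5 * (tc - dur * np.sin(2.0 * np.pi * tc / dur) / (2.0 * np.pi))
            v = np.diff(theta) * fs
            v = np.concatenate([[v[0]], 0.5 * (v[1:] + v[:-1]), [v[-1]]])
            w = np.maximum(filtfilt(b, a, v), 0.0)
            gains[i] += w.max() / len(phases)
            for j, c in enumerate(c_grid):
                s = _crossing_span(w, c, fs)
                if np.isfinite(s):
                    spans[i, j] += s
                    counts[i, j] += 1.0
    spans = np.where(counts > 0, spans / np.maximum(counts, 1.0), np.nan)
    return d_grid, c_grid, gains, spans


def _crossing_span(w: np.ndarray, c: float, fs: float) -> float:
    """Interpolated span (s) of the suprathreshold run around max(w)."""
    if w.max() < c:
        return np.nan
    n = len(w)
    ipeak = int(np.argmax(w))
    first = ipeak
    while first > 0 and w[first - 1] >= c:
        first -= 1
    last = ipeak
    while last < n - 1 and w[last + 1] >= c:
        last += 1
    t0 = float(first)
    if first > 0 and w[first] > w[first - 1]:
        t0 = first - np.clip((w[first] - c) / (w[first] - w[first - 1]), 0.0, 1.0)
    t1 = float(last)
    if last < n - 1 and w[last] > w[last + 1]:
        t1 = last + np.clip((w[last] - c) / (w[last] - w[last + 1]), 0.0, 1.0)
    return (t1 - t0) / fs


def invert_pulse_duration(
    span: float,
    peak_speed: float,
    fs: float,
    vel_thresh: float = SACCADE_VEL_THRESH,
) -> float:
    """Pulse duration whose filtered threshold span matches the measurement.

    Given the measured crossing span and the measured (attenuated) peak
    angular speed, finds the raised-cosine pulse duration that, pushed
    through the same filtering pipeline, reproduces that span at the
    velocity threshold. Returns NaN when no tabulated pulse is consistent
    with the measurement (``peak_speed`` at or below the threshold).
    """
    if not np.isfinite(span) or peak_speed <= vel_thresh:
        return np.nan
    d_grid, c_grid, gains, spans = _pulse_span_tables(fs)
    c = vel_thresh * gains / peak_speed
    pred = np.array(
        [
            np.interp(c[i], c_grid, spans[i]) if c[i] <= c_grid[-1] else np.nan
            for i in range(len(d_grid))
        ]
    )
    resid = pred - span
    ok = np.isfinite(resid)
    if not np.any(ok):
        return np.nan
    dg, rg = d_grid[ok], resid[ok]
    sgn = np.sign(rg)
    cross = np.flatnonzero(sgn[:-1] * sgn[1:] <= 0)
    if len(cross) == 0:
        return float(dg[0] if rg[0] > 0 else dg[-1])
    k = int(cross[0])
    frac = rg[k] / (rg[k] - rg[k + 1])
    return float(dg[k] + frac * (dg[k + 1] - dg[k]))


def _point_segment_distance(points, a, b):
    ab = b - a
    denom = float(ab @ ab)
    tt = np.clip(((points - a) @ ab) / denom, 0.0, 1.0) if denom > 0 else 0.0
    proj = a + np.outer(np.atleast_1d(tt), ab)
    return np.linalg.norm(points - proj, axis=1)


def compute_kinematic_features(
    trace: BehaviorTrace, arena: ArenaConfig
) -> KinematicFeatures:
    """Speeds, tilt and Gaussian proximity features from a head-pose trace.

    Linear speed is the finite-difference speed of the head position;
    angular speed is the geodesic quaternion difference between adjacent
    frames divided by dt. Both are low-pass filtered at ``LOWPASS_HZ`` with
    a zero-phase Butterworth filter. Raises for non-uniform sampling.
    """
    t = trace.t
    dt = np.diff(t)
    if len(dt) == 0:
        raise ValueError("trace too short for kinematics")
    if np.any(np.abs(dt - dt[0]) > 1e-6):
        raise ValueError("trace must be uniformly sampled")
    fs = 1.0 / float(dt[0])

    dpos = np.diff(trace.position, axis=0)
    lin = np.linalg.norm(dpos, axis=1) * fs
    rot = rotations_from_wxyz(trace.quat_wxyz)
    rel = rot[:-1].inv() * rot[1:]
    ang = np.rad2deg(rel.magnitude()) * fs
    # speeds at sample centers; replicate edges to the trace length
    lin = np.concatenate([[lin[0]], 0.5 * (lin[1:] + lin[:-1]), [lin[-1]]])
    ang = np.concatenate([[ang[0]], 0.5 * (ang[1:] + ang[:-1]), [ang[-1]]])
    b, a = butter(4, LOWPASS_HZ / (fs / 2.0))
    lin = np.maximum(filtfilt(b, a, lin), 0.0)
    ang = np.maximum(filtfilt(b, a, ang), 0.0)

    zaxis = rot.apply(np.tile([0.0, 0.0, 1.0], (len(rot), 1)))
    tilt = np.rad2deg(np.arccos(np.clip(zaxis[:, 2], -1.0, 1.0)))

    xy = trace.position[:, :2]
    scale2 = 2.0 * PROXIMITY_SCALE_MM**2
    d_site = np.linalg.norm(
        xy[:, None, :] - arena.site_positions[None, :, :], axis=-1
    )
    site_prox = np.exp(-(d_site**2) / scale2)
    paths = arena.paths()
    path_prox = np.empty((len(xy), len(paths)))
    for k, (i, j) in enumerate(paths):
        d = _point_segment_distance(xy, arena.site_positions[i], arena.site_positions[j])
        path_prox[:, k] = np.exp(-(d**2) / scale2)

    return KinematicFeatures(
        t=t,
        linear_speed=lin,
        angular_speed=ang,
        tilt=tilt,
        site_proximity=site_prox,
        path_proximity=path_prox,
        sample_rate=fs,
    )


@dataclass
class HMMSpec:
    """Gaussian-observation HMM over behavioral states.

    ``states`` are tuples ``(kind, site)`` or ``(kind, (src, dst))``;
    diagonal Gaussian emissions with per-state means (refit per session)
    and shared fixed variances; a fixed sparse transition matrix.
    """

    states: list
    means: np.ndarray  # (n_states, n_features)
    variances: np.ndarray  # (n_features,), shared across states, fixed
    transitions: np.ndarray  # (n_states, n_states), rows sum to 1, fixed
    initial: np.ndarray  # (n_states,)
    max_iter: int = 10

    def __post_init__(self):
        rows = self.transitions.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be positive")

    def state_index(self, kind: str, where) -> int:
        return self.states.index((kind, where))


# kinematic priors on the transformed features, by state kind:
# (log1p linear speed, log1p angular speed, tilt/60)
_KIND_PRIORS = {
    "fixation": (np.log1p(30.0), np.log1p(60.0), 10.0 / 60.0),
    "saccade": (np.log1p(30.0), np.log1p(700.0), 12.0 / 60.0),
    "feed": (np.log1p(30.0), np.log1p(60.0), 55.0 / 60.0),
    "dash": (np.log1p(450.0), np.log1p(60.0), 10.0 / 60.0),
}

# mean state dwell times (s) set the self-transition probability of each
# state kind: p_self = 1 - 1 / (dwell * sample_rate)
_KIND_DWELL = {"fixation": 0.20, "saccade": 0.076, "feed": 1.5, "dash": 0.65}


def build_hmm_spec(arena: ArenaConfig, features: KinematicFeatures) -> HMMSpec:
    """Default HMM: states from arena geometry, variances from the data.

    Means are initialized from the kinematic priors and the proximity
    transform evaluated at each state's representative location (the site,
    or the path midpoint for dashes). Variances are robust scale estimates
    of each feature over the session (a calibration pass); they are fixed
    during fitting.
    """
    states = []
    for kind in ("fixation", "saccade", "feed"):
        for s in range(arena.n_sites):
            states.append((kind, s))
    paths = arena.paths()
    for i, j in paths:
        states.append(("dash", (i, j)))
        states.append(("dash", (j, i)))

    scale2 = 2.0 * PROXIMITY_SCALE_MM**2

    def prox_at(point):
        d_site = np.linalg.norm(arena.site_positions - point, axis=1)
        site_p = np.exp(-(d_site**2) / scale2)
        path_p = np.empty(len(paths))
        for k, (i, j) in enumerate(paths):
            d = _point_segment_distance(
                point[None, :], arena.site_positions[i], arena.site_positions[j]
            )
            path_p[k] = np.exp(-(d[0] ** 2) / scale2)
        return site_p, path_p

    means = []
    for kind, where in states:
        base = np.array(_KIND_PRIORS[kind])
        if kind == "dash":
            i, j = where
            point = 0.5 * (arena.site_positions[i] + arena.site_positions[j])
        else:
            point = arena.site_positions[where]
        site_p, path_p = prox_at(point)
        means.append(np.concatenate([base, site_p, path_p]))
    means = np.asarray(means)

    X = features.matrix()
    q16, q84 = np.percentile(X, [16, 84], axis=0)
    sigma = np.maximum((q84 - q16) / 2.0, 0.15)
    variances = sigma**2

    n = len(states)
    trans = np.zeros((n, n))
    idx = {st: k for k, st in enumerate(states)}
    for k, (kind, where) in enumerate(states):
        p_self = 1.0 - 1.0 / (_KIND_DWELL[kind] * features.sample_rate)
        trans[k, k] = p_self
        rest = 1.0 - p_self
        if kind == "fixation":
            targets = [idx[("saccade", where)]]
            dashes = [
                idx[("dash", (i, j))]
                for (i, j) in [p for p in idx if p[0] == "dash"][0:0]
            ]
            dash_states = [
                idx[st] for st in states if st[0] == "dash" and st[1][0] == where
            ]
            feed_state = [idx[("feed", where)]]
            weights = (
                [0.6] + [0.3 / max(len(dash_states), 1)] * len(dash_states) + [0.1]
            )
            targets = targets + dash_states + feed_state
        elif kind == "saccade":
            targets = [idx[("fixation", where)]]
            weights = [1.0]
        elif kind == "feed":
            targets = [idx[("fixation", where)], idx[("saccade", where)]]
            weights = [0.7, 0.3]
        else:  # dash (src, dst)
            _, dst = where
            targets = [idx[("feed", dst)], idx[("fixation", dst)]]
            weights = [0.7, 0.3]
        w = np.asarray(weights, float)
        w = w / w.sum() * rest
        for tgt, wk in zip(targets, w):
            trans[k, tgt] += wk
    trans /= trans.sum(axis=1, keepdims=True)
    initial = np.full(n, 1.0 / n)
    return HMMSpec(
        states=states, means=means, variances=variances, transitions=trans,
        initial=initial,
    )


def _log_emissions(X: np.ndarray, spec: HMMSpec) -> np.ndarray:
    var = spec.variances
    mu = spec.means
    const = -0.5 * (np.log(2 * np.pi * var)).sum() - 0.5 * (mu**2 / var).sum(axis=1)
    return X @ (mu / var).T - 0.5 * (X**2) @ (1.0 / var) [:, None] + const


def viterbi_decode(features_or_X, spec: HMMSpec):
    """Most likely state path under the HMM.

    Accepts a :class:`KinematicFeatures` or a raw observation matrix.
    Returns ``(path, loglik)`` where ``path`` contains state indices into
    ``spec.states``. Raises if no path has positive probability.
    """
    X = (
        features_or_X.matrix()
        if isinstance(features_or_X, KinematicFeatures)
        else np.asarray(features_or_X, float)
    )
    if X.shape[1] != spec.means.shape[1]:
        raise ValueError("feature dimension does not match the HMM spec")
    logB = _log_emissions(X, spec)
    with np.errstate(divide="ignore"):
        logA = np.log(spec.transitions)
        logpi = np.log(spec.initial)
    T, S = logB.shape
    back = np.empty((T, S), dtype=np.int32)
    score = logpi + logB[0]
    back[0] = -1
    cols = np.arange(S)
    for t in range(1, T):
        cand = score[:, None] + logA
        best = np.argmax(cand, axis=0)
        back[t] = best
        score = cand[best, cols] + logB[t]
    if not np.isfinite(score.max()):
        raise RuntimeError("Viterbi decode failed: all paths have zero probability")
    path = np.empty(T, dtype=np.int32)
    path[-1] = int(np.argmax(score))
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path, float(score.max())


def fit_observation_means(
    features: KinematicFeatures,
    spec: HMMSpec,
    max_iter: Optional[int] = None,
    train_samples: Optional[int] = None,
) -> HMMSpec:
    """Viterbi training of the state means.

    Alternates Viterbi decoding with per-state mean re-estimation until the
    path stabilizes or ``max_iter`` iterations. Variances and transitions
    are untouched; a state that receives no samples keeps its prior mean
    (with a warning). ``train_samples`` restricts training to a leading
    window of the session (the state means converge quickly, so this is a
    pure speedup for long sessions).
    """
    X = features.matrix()
    if train_samples is not None:
        X = X[: int(train_samples)]
    means = spec.means.copy()
    max_iter = spec.max_iter if max_iter is None else max_iter
    prev_path = None
    for _ in range(max_iter):
        cur = HMMSpec(
            states=spec.states, means=means, variances=spec.variances,
            transitions=spec.transitions, initial=spec.initial,
            max_iter=spec.max_iter,
        )
        path, _ = viterbi_decode(X, cur)
        if prev_path is not None and np.array_equal(path, prev_path):
            break
        prev_path = path
        empty = []
        for k in range(len(spec.states)):
            sel = path == k
            if np.any(sel):
                means[k] = X[sel].mean(axis=0)
            else:
                empty.append(spec.states[k])
        if empty:
            warnings.warn(
                f"{len(empty)} HMM state(s) received no samples; keeping prior means"
            )
    return HMMSpec(
        states=spec.states, means=means, variances=spec.variances,
        transitions=spec.transitions, initial=spec.initial, max_iter=spec.max_iter,
    )


def _runs(path: np.ndarray):
    """(start, stop, value) runs of a label vector; stop is exclusive."""
    change = np.flatnonzero(np.diff(path)) + 1
    starts = np.concatenate([[0], change])
    stops = np.concatenate([change, [len(path)]])
    return [(int(a), int(b), int(path[a])) for a, b in zip(starts, stops)]


def refine_segments(
    path: np.ndarray,
    features: KinematicFeatures,
    trace: BehaviorTrace,
    spec: HMMSpec,
) -> pd.DataFrame:
    """Cleanup and kinematic refinement of a decoded state path.

    Cleanup (in order): saccades immediately preceding feeding join the
    feed; saccades immediately following a dash join the dash; feeding
    immediately after a dash joins the dash. Saccade endpoints come from
    the interpolated angular-velocity threshold crossings around the peak,
    with the duration corrected by inverting the pulse-through-filter model
    (:func:`invert_pulse_duration`); dash stop times are trimmed on linear
    kinematics. Saccades with no samples above the velocity threshold are
    discarded as false positives.

    Returns a segment table with one row per interval: state, site, src,
    dst, t_start, t_end, and for saccades t_peak, amplitude_deg,
    duration_s and the analysis-eligibility flag (immediately followed by a
    fixation).
    """
    if len(path) == 0:
        return pd.DataFrame(
            columns=[
                "state", "site", "src", "dst", "t_start", "t_end", "t_peak",
                "amplitude_deg", "duration_s", "eligible",
            ]
        )
    kinds = []
    for a, b, k in _runs(np.asarray(path)):
        kind, where = spec.states[k]
        kinds.append([a, b, kind, where])
    # absorb micro-runs (< 10 ms) into the longer neighbor: such blips are
    # shorter than any real behavioral state and break adjacency for the
    # merge rules below
    min_run = max(1, int(round(0.010 * features.sample_rate)))
    changed = True
    while changed and len(kinds) > 1:
        changed = False
        for i, (a, b, kind, where) in enumerate(kinds):
            if b - a >= min_run:
                continue
            left = kinds[i - 1] if i > 0 else None
            right = kinds[i + 1] if i + 1 < len(kinds) else None
            if left is None and right is None:
                continue
            pick_left = right is None or (
                left is not None and (left[1] - left[0]) >= (right[1] - right[0])
            )
            if pick_left:
                left[1] = b
            else:
                right[0] = a
            del kinds[i]
            # re-merge neighbors that now touch with identical labels
            j = max(i - 1, 0)
            while j + 1 < len(kinds):
                if (
                    kinds[j][1] == kinds[j + 1][0]
                    and kinds[j][2] == kinds[j + 1][2]
                    and kinds[j][3] == kinds[j + 1][3]
                ):
                    kinds[j][1] = kinds[j + 1][1]
                    del kinds[j + 1]
                else:
                    break
            changed = True
            break
    # -- cleanup, three rules applied as sequential passes in order --------
    def merge_same(segs):
        out = []
        for s in segs:
            if out and out[-1][2] == s[2] and out[-1][3] == s[3] \
                    and out[-1][1] == s[0]:
                out[-1][1] = s[1]
            else:
                out.append(s)
        return out

    # 1) a saccade immediately preceding feeding joins the feed
    out = []
    for i, s in enumerate(kinds):
        if (
            s[2] == "saccade"
            and i + 1 < len(kinds)
            and kinds[i + 1][2] == "feed"
        ):
            kinds[i + 1][0] = s[0]
        else:
            out.append(s)
    kinds = merge_same(out)
    # 2) a saccade immediately following a dash joins the dash
    out = []
    for s in kinds:
        if s[2] == "saccade" and out and out[-1][2] == "dash":
            out[-1][1] = s[1]
        else:
            out.append(s)
    kinds = merge_same(out)
    # 3) feeding immediately following a dash joins the dash
    out = []
    for s in kinds:
        if s[2] == "feed" and out and out[-1][2] == "dash":
            out[-1][1] = s[1]
        else:
            out.append(s)
    merged = merge_same(out)

    fs = features.sample_rate
    t = features.t
    ang, lin = features.angular_speed, features.linear_speed
    lin_acc = features.linear_accel
    n = len(t)
    rot = rotations_from_wxyz(trace.quat_wxyz)

    rows = []
    for a, b, kind, where in merged:
        row = {
            "state": kind,
            "site": where if kind != "dash" else where[1],
            "src": where[0] if kind == "dash" else -1,
            "dst": where[1] if kind == "dash" else -1,
            "t_start": t[a],
            "t_end": t[min(b, n - 1)] + 0.5 / fs,
            "t_peak": np.nan,
            "amplitude_deg": np.nan,
            "duration_s": np.nan,
            "eligible": False,
        }
        if kind == "saccade":
            # endpoint refinement uses the velocity threshold only: with
            # smoothed 300-Hz tracking the angular-acceleration criterion is
            # dominated by fixation jitter (its false-positive rate during
            # fixations exceeds 10%), so it would randomly extend endpoints
            mask = ang >= SACCADE_VEL_THRESH
            if not np.any(mask[a:b]):
                continue  # no suprathreshold kinematics: spurious detection
            ipeak = a + int(np.argmax(ang[a:b]))
            # walk outward from the peak through the contiguous
            # suprathreshold run, with sub-sample crossing interpolation
            first = ipeak
            while first > 0 and mask[first - 1]:
                first -= 1
            last = ipeak
            while last < n - 1 and mask[last + 1]:
                last += 1
            t0s = t[first]
            if first > 0 and ang[first] > ang[first - 1]:
                frac = (ang[first] - SACCADE_VEL_THRESH) / (ang[first] - ang[first - 1])
                t0s = t[first] - np.clip(frac, 0.0, 1.0) / fs
            t1s = t[last]
            if last < n - 1 and ang[last] > ang[last + 1]:
                frac = (ang[last] - SACCADE_VEL_THRESH) / (ang[last] - ang[last + 1])
                t1s = t[last] + np.clip(frac, 0.0, 1.0) / fs
            # the crossing span of the filtered pulse is a biased duration
            # estimate; invert the pulse-through-filter model to recover the
            # duration, and widen the endpoints symmetrically to match
            span = t1s - t0s
            peak_speed = float(ang[first:last + 1].max())
            dur = invert_pulse_duration(span, peak_speed, fs)
            if not np.isfinite(dur) or dur < span:
                dur = span
            pad_half = 0.5 * (dur - span)
            row["t_start"] = t0s - pad_half
            row["t_end"] = t1s + pad_half
            row["t_peak"] = t[ipeak]
            row["duration_s"] = dur
            row["amplitude_deg"] = float(
                np.rad2deg((rot[first].inv() * rot[min(last + 1, n - 1)]).magnitude())
            )
            row["_a"], row["_b"] = first, last + 1
        elif kind == "dash":
            lo, hi = a, min(b + 1, n)
            mask = (lin[lo:hi] >= DASH_VEL_THRESH) | (
                np.abs(lin_acc[lo:hi]) >= DASH_ACC_THRESH
            )
            if np.any(mask):
                last = lo + int(len(mask) - 1 - np.argmax(mask[::-1]))
                row["t_end"] = t[last] + 0.5 / fs
        rows.append(row)

    table = pd.DataFrame(rows)
    if len(table) == 0:
        return refine_segments(np.array([]), features, trace, spec)
    # eligibility: a saccade immediately followed by a fixation interval
    states_arr = table["state"].to_numpy()
    eligible = np.zeros(len(table), bool)
    for i in range(len(table) - 1):
        if states_arr[i] == "saccade" and states_arr[i + 1] == "fixation":
            eligible[i] = True
    table["eligible"] = eligible
    table = table.drop(columns=[c for c in ("_a", "_b") if c in table], errors="ignore")
    return table.reset_index(drop=True)


def search_saccade_intervals(table: pd.DataFrame) -> np.ndarray:
    """Peak-to-peak intervals of successive saccades during visual search.

    Returns the intervals (s) between consecutive detected saccade peaks
    that are separated only by fixation segments. Pairs spanning a dash or
    a feeding bout are excluded: those interrupt visual search, so the
    interval no longer measures the search saccade rate.
    """
    sub = table.sort_values("t_start").reset_index(drop=True)
    out = []
    last_peak = None
    for row in sub.itertuples():
        if row.state == "saccade":
            if last_peak is not None and np.isfinite(row.t_peak):
                out.append(row.t_peak - last_peak)
            last_peak = row.t_peak if np.isfinite(row.t_peak) else None
        elif row.state != "fixation":
            last_peak = None
    return np.asarray(out, float)


def annotate_saccade_gaze(
    table: pd.DataFrame,
    trace: BehaviorTrace,
    arena: ArenaConfig,
    calib: EyeCalibration,
    landing_threshold: float = 20.0,
    window: float = 0.1,
) -> pd.DataFrame:
    """Add per-saccade flanking-fixation gaze angles and landing sites.

    For each saccade row, the angular deviation of each eye's gaze to each
    site is averaged over a ``window`` (s) at the start of the following
    fixation (``alpha_next``) and at the end of the preceding fixation
    (``alpha_prev``). A landing site is assigned per eye when the next
    deviation is below ``landing_threshold`` degrees (lowest site index on
    ties).
    """
    table = table.copy()
    fs = trace.sample_rate
    n = len(trace)
    n_sites = arena.n_sites
    is_sacc = (table["state"] == "saccade").to_numpy()
    idx_sacc = np.flatnonzero(is_sacc)
    a_prev = np.full((len(table), 2, n_sites), np.nan)
    a_next = np.full((len(table), 2, n_sites), np.nan)
    states = table["state"].to_numpy()
    t_start = table["t_start"].to_numpy()
    t_end = table["t_end"].to_numpy()
    win = max(1, int(round(window * fs)))

    def mean_dev(i0, i1):
        i0, i1 = max(0, i0), min(n, i1)
        if i1 <= i0:
            return np.full((2, n_sites), np.nan)
        sample = gaze_rays(
            trace.position[i0:i1], trace.quat_wxyz[i0:i1], calib
        )
        return angular_distances_to_sites(sample, arena).mean(axis=0)

    for i in idx_sacc:
        if i + 1 < len(table) and states[i + 1] == "fixation":
            j0 = int(round(t_start[i + 1] * fs))
            j1 = int(round(t_end[i + 1] * fs))
            a_next[i] = mean_dev(j0 + 2, min(j0 + 2 + win, j1))
        if i - 1 >= 0 and states[i - 1] == "fixation":
            j0 = int(round(t_start[i - 1] * fs))
            j1 = int(round(t_end[i - 1] * fs))
            a_prev[i] = mean_dev(max(j1 - 2 - win, j0), j1 - 2)
    for eye, tag in ((0, "left"), (1, "right")):
        for s in range(n_sites):
            table[f"alpha_next_{tag}_{s}"] = a_next[:, eye, s]
            table[f"alpha_prev_{tag}_{s}"] = a_prev[:, eye, s]
        best = np.nanargmin(
            np.where(np.isnan(a_next[:, eye]), np.inf, a_next[:, eye]), axis=1
        ) if len(table) else np.array([], int)
        landing = np.full(len(table), -1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ok = np.nanmin(a_next[:, eye], axis=1) < landing_threshold
        landing[ok] = best[ok]
        table[f"landing_site_{tag}"] = landing
    return table


def session_inclusion(
    table: pd.DataFrame,
    arena: ArenaConfig,
    min_dashes: int = 5,
    min_saccades_per_eye_target: int = 5,
):
    """Session-level inclusion decision.

    Requires at least ``min_dashes`` dashes and at least
    ``min_saccades_per_eye_target`` saccades landing (within 20 deg) with
    each eye on each outer target. Returns ``(include, reason)``.
    """
    n_dash = int((table["state"] == "dash").sum())
    if n_dash < min_dashes:
        return False, f"only {n_dash} dashes (need {min_dashes})"
    sacc = table[table["state"] == "saccade"]
    for tag in ("left", "right"):
        col = f"landing_site_{tag}"
        if col not in table:
            return False, "saccade landing sites not annotated"
        for s in arena.outer_site_indices:
            count = int((sacc[col] == s).sum())
            if count < min_saccades_per_eye_target:
                return False, (
                    f"only {count} saccades with the {tag} eye to site {s} "
                    f"(need {min_saccades_per_eye_target})"
                )
    return True, "ok"
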