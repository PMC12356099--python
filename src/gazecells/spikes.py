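"""Synthetic spike trains with known place and gaze tuning.

Each neuron's ground-truth rate is a sum of interpretable components:

* excitatory cells: a Gaussian place field around a preferred site, plus
  two saccade-locked Gaussian kernels — an early (predictive) bump at
  +17 ms and a late (visual) bump at +187 ms after peak saccade velocity —
  each scaled by the angular closeness exp(-alpha^2 / (2 tau^2)) of the
  relevant fixation's gaze to the preferred site;
* interneurons: a saccade-locked windowed sinusoid (quasi-period 0.27 s)
  whose phase at the late latency distinguishes the peak and trough
  subtypes. Interneurons carry no site tuning.

Spike times are drawn from the rate by thinning an upper-bounding
homogeneous Poisson process, which is exact for the piecewise-constant
rates used here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .behavior import BehaviorTrace
from .config import ArenaConfig, EyeCalibration, NeuronSpec
from .geometry import angular_distances_to_sites, gaze_rays

LEFT, RIGHT = 0, 1

# class-typical waveform parameters: (mean rate Hz, trough-to-peak width ms,
# asymmetry, waveform amplitude ratio of the pre-trough bump)
CLASS_TEMPLATES = {
    "excitatory": dict(rate=1.3, width_ms=0.51, asymmetry=-0.04),
    "inh_peak": dict(rate=14.0, width_ms=0.27, asymmetry=0.55),
    "inh_trough": dict(rate=7.1, width_ms=0.33, asymmetry=0.56),
}

WAVEFORM_FS = 30000.0
WAVEFORM_SAMPLES = 90  # 3 ms


def contralateral_eye(hemisphere: str) -> int:
    """Index of the eye contralateral to the recorded hemisphere."""
    if hemisphere not in ("left", "right"):
        raise ValueError(f"unknown hemisphere {hemisphere!r}")
    return RIGHT if hemisphere == "left" else LEFT


def saccade_gaze_angles(
    trace: BehaviorTrace,
    saccades: pd.DataFrame,
    arena: ArenaConfig,
    calib: EyeCalibration,
    window: float = 0.1,
):
    """Flanking-fixation gaze deviations for every saccade.

    Returns ``(alpha_prev, alpha_next)``, each ``(n_saccades, 2, n_sites)``
    in degrees: the mean angular distance of each eye's gaze ray to each
    site over a ``window`` immediately before ``t_start`` (prev) and
    immediately after ``t_end`` (next).
    """
    fs = trace.sample_rate
    n = len(trace)
    win = max(1, int(round(window * fs)))
    n_s = len(saccades)
    out_prev = np.full((n_s, 2, arena.n_sites), np.nan)
    out_next = np.full((n_s, 2, arena.n_sites), np.nan)

    def mean_dev(i0, i1):
        i0, i1 = max(0, i0), min(n, i1)
        if i1 <= i0:
            return np.full((2, arena.n_sites), np.nan)
        sample = gaze_rays(trace.position[i0:i1], trace.quat_wxyz[i0:i1], calib)
        return angular_distances_to_sites(sample, arena).mean(axis=0)

    for k, row in enumerate(saccades.itertuples(index=False)):
        ia = int(round(row.t_start * fs))
        ib = int(round(row.t_end * fs))
        out_prev[k] = mean_dev(ia - win, ia)
        out_next[k] = mean_dev(ib, ib + win)
    return out_prev, out_next


def _closeness(alpha_deg: np.ndarray, tau_deg: float) -> np.ndarray:
    out = np.exp(-(alpha_deg**2) / (2.0 * tau_deg**2))
    return np.nan_to_num(out, nan=0.0)


@dataclass
class SaccadeContext:
    """Per-saccade quantities the rate model depends on."""

    t_peak: np.ndarray  # (n_s,)
    closeness_prev: np.ndarray  # (n_s, 2) toward a given site, per eye
    closeness_next: np.ndarray  # (n_s, 2)
    landing_site: np.ndarray  # (n_s,) contralateral-eye landing, -1 if none
    lit_landing: np.ndarray  # (n_s,) bool: landing site lit at response time
    catch_expected: np.ndarray  # (n_s,) bool: catch trial, expected target


def build_saccade_context(
    spec: NeuronSpec,
    saccades: pd.DataFrame,
    alpha_prev: np.ndarray,
    alpha_next: np.ndarray,
    light_state: np.ndarray,
    trace: BehaviorTrace,
    trials: Optional[pd.DataFrame] = None,
    hemisphere: str = "left",
    landing_threshold: float = 20.0,
) -> SaccadeContext:
    """Assemble the per-saccade drive terms for one neuron."""
    fs = trace.sample_rate
    pref = spec.preferred_site
    tau = spec.gaze_tuning_width
    c_prev = _closeness(alpha_prev[:, :, pref], tau)
    c_next = _closeness(alpha_next[:, :, pref], tau)
    contra = contralateral_eye(hemisphere)
    an = np.where(np.isnan(alpha_next[:, contra]), np.inf, alpha_next[:, contra])
    landing = np.where(an.min(axis=1) < landing_threshold, an.argmin(axis=1), -1)
    t_peak = saccades["t_peak"].to_numpy()
    idx = np.clip((t_peak * fs).round().astype(int), 0, len(light_state) - 1)
    lit_landing = (landing >= 0) & (light_state[idx] == landing)
    catch_expected = np.zeros(len(t_peak), bool)
    if trials is not None and len(trials) and "catch" in trials:
        catch = trials[(trials["catch"]) & trials["t_first_detection"].notna()]
        for row in catch.itertuples(index=False):
            t_det = row.t_first_detection
            t_end = row.t_light_off if pd.notna(row.t_light_off) else t_det + 5.0
            inwin = (t_peak >= t_det) & (t_peak <= t_end)
            catch_expected |= inwin & (landing == row.target)
    return SaccadeContext(
        t_peak=t_peak,
        closeness_prev=c_prev,
        closeness_next=c_next,
        landing_site=landing,
        lit_landing=lit_landing,
        catch_expected=catch_expected,
    )


def rate_function(
    spec: NeuronSpec,
    trace: BehaviorTrace,
    context: SaccadeContext,
    arena: ArenaConfig,
    hemisphere: str = "left",
) -> np.ndarray:
    """Ground-truth firing rate (Hz) at every trace sample."""
    n = len(trace)
    fs = trace.sample_rate
    t = trace.t
    rate = np.full(n, float(spec.baseline_rate))

    if spec.cell_type == "excitatory":
        d = np.linalg.norm(
            trace.position[:, :2] - arena.site_positions[spec.preferred_site],
            axis=1,
        )
        rate += spec.place_gain * np.exp(-(d**2) / (2.0 * spec.place_field_sigma**2))

        contra = contralateral_eye(hemisphere)
        w_eye = np.array([1.0 - spec.contra_fraction, 1.0 - spec.contra_fraction])
        w_eye[contra] = spec.contra_fraction
        c_next = context.closeness_next @ w_eye
        c_prev = np.nan_to_num(context.closeness_prev @ w_eye)
        c_early = (
            spec.early_prev_weight * c_prev + spec.early_next_weight * c_next
        )
        pred = np.where(
            context.lit_landing | context.catch_expected,
            spec.prediction_modulation,
            1.0,
        )
        amp_early = spec.gaze_gain * spec.early_amplitude * c_early * pred
        light_factor = np.where(
            context.lit_landing,
            spec.light_modulation,
            np.where(
                context.catch_expected, 0.5 * (1.0 + spec.light_modulation), 1.0
            ),
        )
        amp_late = spec.gaze_gain * spec.late_amplitude * c_next * light_factor
        for lat, width, amps in (
            (spec.early_latency, spec.early_width, amp_early),
            (spec.late_latency, spec.late_width, amp_late),
        ):
            half = 4.0 * width
            for tp, a in zip(context.t_peak, amps):
                if a <= 0:
                    continue
                i0 = max(0, int((tp + lat - half) * fs))
                i1 = min(n, int((tp + lat + half) * fs) + 1)
                # rate[i] is constant over [t_i, t_i + 1/fs): evaluate the
                # kernel at the bin midpoint so realized spikes center on it
                dtk = t[i0:i1] + 0.5 / fs - (tp + lat)
                rate[i0:i1] += a * np.exp(-(dtk**2) / (2.0 * width**2))
    else:
        # interneurons: windowed sinusoid locked to every saccade, phase at
        # the late latency set by phase_offset (0 -> peak, pi -> trough)
        period = spec.cycle_period
        env_sd = 1.2 * period
        half = 2.5 * env_sd
        for tp in context.t_peak:
            i0 = max(0, int((tp + spec.late_latency - half) * fs))
            i1 = min(n, int((tp + spec.late_latency + half) * fs) + 1)
            dtk = t[i0:i1] + 0.5 / fs - (tp + spec.late_latency)
            env = np.exp(-(dtk**2) / (2.0 * env_sd**2))
            rate[i0:i1] += spec.gaze_gain * env * np.cos(
                2.0 * np.pi * dtk / period + spec.phase_offset
            )
    return np.maximum(rate, 0.0)


def sample_spikes_thinning(
    rate: np.ndarray, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Exact inhomogeneous-Poisson spike times by thinning.

    ``rate`` is piecewise constant on bins of width 1/fs. Candidates come
    from a homogeneous process at the maximum rate and are accepted with
    probability rate(t)/max_rate.
    """
    lam_max = float(rate.max())
    if lam_max <= 0:
        return np.empty(0)
    duration = len(rate) / fs
    n_cand = rng.poisson(lam_max * duration)
    t_cand = np.sort(rng.uniform(0.0, duration, n_cand))
    idx = np.minimum((t_cand * fs).astype(int), len(rate) - 1)
    keep = rng.uniform(0.0, 1.0, n_cand) < rate[idx] / lam_max
    return t_cand[keep]


def waveform_template(
    width_ms: float,
    asymmetry: float,
    fs: float = WAVEFORM_FS,
    n_samples: int = WAVEFORM_SAMPLES,
) -> np.ndarray:
    """Extracellular spike waveform with a given trough-to-peak width.

    A negative trough flanked by two positive bumps; the post-trough bump
    peaks ``width_ms`` after the trough and the pre/post bump amplitudes
    satisfy the asymmetry index (post - pre) / (post + pre).
    """
    if not (-1.0 < asymmetry < 1.0):
        raise ValueError("asymmetry must lie in (-1, 1)")
    t = (np.arange(n_samples) - n_samples // 3) / fs * 1000.0  # ms, trough at 0
    width = float(width_ms)
    post = 0.35 * (1.0 + asymmetry)
    pre = 0.35 * (1.0 - asymmetry)
    trough_sd = 0.30 * width
    wf = (
        -np.exp(-(t**2) / (2.0 * trough_sd**2))
        + post * np.exp(-((t - width) ** 2) / (2.0 * (0.75 * width) ** 2))
        + pre * np.exp(-((t + 0.6 * width) ** 2) / (2.0 * (0.55 * width) ** 2))
    )
    return wf / np.abs(wf.min())


def default_population(
    n_excitatory: int,
    n_inh_peak: int,
    n_inh_trough: int,
    arena: ArenaConfig,
    rng: np.random.Generator,
    **overrides,
) -> list[NeuronSpec]:
    """NeuronSpecs with class-typical rates and preferred sites.

    Excitatory preferred sites rotate through the outer sites; interneuron
    phase offsets are 0 (peak class) or pi (trough class). ``overrides``
    are applied to every spec.
    """
    specs = []
    outer = arena.outer_site_indices
    for i in range(n_excitatory):
        base = float(np.exp(rng.normal(np.log(CLASS_TEMPLATES["excitatory"]["rate"]), 0.3)))
        specs.append(
            NeuronSpec(
                cell_type="excitatory",
                baseline_rate=base,
                preferred_site=outer[i % len(outer)],
                **overrides,
            )
        )
    for kind, phase, n_k in (
        ("inh_peak", 0.0, n_inh_peak),
        ("inh_trough", np.pi, n_inh_trough),
    ):
        for _ in range(n_k):
            base = float(
                np.exp(rng.normal(np.log(CLASS_TEMPLATES[kind]["rate"]), 0.2))
            )
            specs.append(
                NeuronSpec(
                    cell_type=kind,
                    baseline_rate=base,
                    preferred_site=outer[0],
                    gaze_gain=0.35 * base,
                    phase_offset=phase,
                    **overrides,
                )
            )
    return specs


def generate_spike_population(
    specs: Sequence[NeuronSpec],
    trace: BehaviorTrace,
    saccades: pd.DataFrame,
    light_state: np.ndarray,
    arena: ArenaConfig,
    calib: EyeCalibration,
    rng: np.random.Generator,
    trials: Optional[pd.DataFrame] = None,
    hemisphere: str = "left",
):
    """Spike times, waveforms and metadata for a population of neurons.

    Returns ``(spikes, waveforms, cells)``: a long-format DataFrame with
    columns ``cell_id, t``; a ``(n_cells, n_samples)`` waveform array; and
    a per-cell metadata DataFrame (cell_type, preferred_site, rates).
    """
    alpha_prev, alpha_next = saccade_gaze_angles(trace, saccades, arena, calib)
    fs = trace.sample_rate
    rows, wfs, meta = [], [], []
    for cid, spec in enumerate(specs):
        ctx = build_saccade_context(
            spec, saccades, alpha_prev, alpha_next, light_state, trace,
            trials=trials, hemisphere=hemisphere,
        )
        rate = rate_function(spec, trace, ctx, arena, hemisphere=hemisphere)
        times = sample_spikes_thinning(rate, fs, rng)
        rows.append(pd.DataFrame({"cell_id": cid, "t": times}))
        tpl = CLASS_TEMPLATES[spec.cell_type]
        width = tpl["width_ms"] * float(np.exp(rng.normal(0.0, 0.06)))
        asym = float(np.clip(tpl["asymmetry"] + rng.normal(0.0, 0.05), -0.9, 0.9))
        wfs.append(waveform_template(width, asym))
        meta.append(
            dict(
                cell_id=cid,
                cell_type=spec.cell_type,
                preferred_site=spec.preferred_site,
                baseline_rate=spec.baseline_rate,
                n_spikes=len(times),
                mean_rate=len(times) / (len(trace) / fs),
            )
        )
    spikes = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["cell_id", "t"])
    )
    return spikes, np.asarray(wfs), pd.DataFrame(meta)
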