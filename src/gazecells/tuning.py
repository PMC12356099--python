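"""Place and gaze tuning statistics.

The central statistic is the information rate of a discretized tuning
curve,

    I = sum_x p(x) (lambda_x / lambda_bar) log2(lambda_x / lambda_bar),

with lambda_bar = sum_x p(x) lambda_x and 0 * log 0 = 0. Significance is
assessed against circular time-shift shuffles of the spike train, which
preserve the spike autocorrelation while destroying its alignment to
behavior; a cell is significantly tuned when its information exceeds the
99th percentile of the shuffle distribution.

Rate maps are spike counts divided by occupancy on a 40x40 grid (place)
or a gaze-projection grid (gaze), smoothed with a 2-D Hamming window
renormalized over valid bins so edges are unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal.windows import hamming

from .behavior import BehaviorTrace
from .config import ArenaConfig, EyeCalibration
from .geometry import floor_bin_centers, gaze_rays, project_gaze_to_floor


def site_information(rates: np.ndarray, occupancy: np.ndarray) -> float:
    """Information (bits/spike) of a discrete tuning curve.

    ``rates`` are mean rates per state (Hz), ``occupancy`` the time
    fraction spent in each state (normalized internally). States with zero
    occupancy are ignored; 0 * log 0 is treated as 0.
    """
    rates = np.asarray(rates, float)
    occ = np.asarray(occupancy, float)
    if rates.shape != occ.shape:
        raise ValueError("rates and occupancy must have the same shape")
    if np.any(occ < 0) or np.any(rates < 0):
        raise ValueError("rates and occupancy must be non-negative")
    total = occ.sum()
    if total <= 0:
        raise ValueError("occupancy must have positive total")
    p = (occ / total).ravel()
    lam = rates.ravel()
    valid = p > 0
    p, lam = p[valid], lam[valid]
    lam_bar = float(p @ lam)
    if lam_bar <= 0:
        return 0.0
    ratio = lam / lam_bar
    pos = ratio > 0
    return float(np.sum(p[pos] * ratio[pos] * np.log2(ratio[pos])))


def site_rates_and_occupancy(
    spike_times: np.ndarray,
    intervals: pd.DataFrame,
    n_sites: int,
    site_column: str = "site",
):
    """Mean rate and occupancy per site over a set of labeled intervals.

    ``intervals`` needs columns ``t_start``, ``t_end`` and ``site_column``.
    Returns ``(rates, occupancy_seconds)``, each of length ``n_sites``.
    """
    spike_times = np.asarray(spike_times)
    occ = np.zeros(n_sites)
    counts = np.zeros(n_sites)
    for row in intervals.itertuples(index=False):
        s = int(getattr(row, site_column))
        if not (0 <= s < n_sites):
            continue
        occ[s] += row.t_end - row.t_start
        counts[s] += np.count_nonzero(
            (spike_times >= row.t_start) & (spike_times < row.t_end)
        )
    rates = np.divide(counts, occ, out=np.zeros_like(counts), where=occ > 0)
    return rates, occ


def shuffle_significance(
    spike_times: np.ndarray,
    information_fn,
    duration: float,
    n_shuffles: int = 200,
    min_shift: float = 10.0,
    rng: Optional[np.random.Generator] = None,
    percentile: float = 99.0,
):
    """Circular-shift shuffle test of an information statistic.

    ``information_fn(spike_times) -> float`` is evaluated on the original
    train and on ``n_shuffles`` circularly time-shifted copies (uniform
    shifts in [min_shift, duration - min_shift]). Returns a dict with the
    observed value, the shuffle values, the permutation p-value
    (1 + #{shuffle >= observed}) / (n + 1), and ``significant`` = observed
    exceeds the given percentile of the shuffles.
    """
    rng = np.random.default_rng() if rng is None else rng
    if duration <= 2 * min_shift:
        raise ValueError("duration too short for the requested minimum shift")
    observed = float(information_fn(spike_times))
    shifts = rng.uniform(min_shift, duration - min_shift, n_shuffles)
    values = np.empty(n_shuffles)
    for i, sh in enumerate(shifts):
        values[i] = information_fn(np.sort((spike_times + sh) % duration))
    p = (1.0 + np.sum(values >= observed)) / (n_shuffles + 1.0)
    return dict(
        observed=observed,
        shuffles=values,
        p_value=float(p),
        significant=bool(observed > np.percentile(values, percentile)),
    )


def _hamming2d(size: int) -> np.ndarray:
    w = hamming(size)
    k = np.outer(w, w)
    return k / k.sum()


def smooth_map(values: np.ndarray, valid: np.ndarray, size: int) -> np.ndarray:
    """Hamming-window smoothing with edge renormalization.

    Convolves ``values`` (NaN outside ``valid``) and the valid-bin
    indicator with the same kernel and divides, so bins near edges or
    holes are averages over observed neighbors only.
    """
    from scipy.signal import convolve2d

    kern = _hamming2d(size)
    v = np.where(valid, values, 0.0)
    num = convolve2d(v, kern, mode="same")
    den = convolve2d(valid.astype(float), kern, mode="same")
    out = np.full_like(num, np.nan)
    ok = den > 1e-12
    out[ok] = num[ok] / den[ok]
    out[~valid & ~ok] = np.nan
    return out


@dataclass
class RateMap:
    rate: np.ndarray  # (n_bins, n_bins) Hz, NaN where unvisited
    occupancy: np.ndarray  # (n_bins, n_bins) seconds
    information: float
    offset: float = 0.0  # s, spike-time offset applied (place maps)


def _binned_rate_map(
    spike_times, t_samples, positions_xy, half_extent, n_bins, fs, smooth_size
):
    edges = np.linspace(-half_extent, half_extent, n_bins + 1)
    ix = np.clip(np.digitize(positions_xy[:, 0], edges) - 1, 0, n_bins - 1)
    iy = np.clip(np.digitize(positions_xy[:, 1], edges) - 1, 0, n_bins - 1)
    occ = np.zeros((n_bins, n_bins))
    np.add.at(occ, (iy, ix), 1.0 / fs)  # row = y bin, column = x bin
    # spike positions by nearest behavioral sample
    order = np.searchsorted(t_samples, spike_times)
    order = np.clip(order, 0, len(t_samples) - 1)
    counts = np.zeros((n_bins, n_bins))
    np.add.at(counts, (iy[order], ix[order]), 1.0)
    valid = occ > 0
    raw = np.divide(counts, occ, out=np.zeros_like(counts), where=valid)
    occ_s = smooth_map(occ, valid, smooth_size)
    rate_s = smooth_map(raw, valid, smooth_size)
    info = site_information(
        np.nan_to_num(rate_s), np.nan_to_num(occ_s)
    )
    return rate_s, occ_s, info


def place_rate_map(
    spike_times: np.ndarray,
    trace: BehaviorTrace,
    include_mask: np.ndarray,
    arena: ArenaConfig,
    n_bins: int = 40,
    smooth_size: int = 11,
    offsets: Optional[Sequence[float]] = None,
) -> RateMap:
    """Spatial rate map over the arena floor.

    Only samples where ``include_mask`` is true contribute (typically the
    vicinity of dashes, when the bird translates). If ``offsets`` is given,
    the spike train is shifted by each candidate offset and the map with
    the highest spatial information is returned (accounting for conduction
    and behavioral lags).
    """
    if offsets is None:
        offsets = [0.0]
    t = trace.t[include_mask]
    xy = trace.position[include_mask, :2]
    if len(t) == 0:
        raise ValueError("include_mask selects no samples")
    fs = trace.sample_rate
    half = arena.arena_side / 2.0  # same grid as the gaze floor projection
    spike_times = np.asarray(spike_times)
    # keep only spikes within included time (nearest-sample tolerance)
    best = None
    for off in offsets:
        st = spike_times + off
        keep = np.zeros(len(st), bool)
        idx = np.clip(np.searchsorted(t, st), 0, len(t) - 1)
        keep = np.abs(t[idx] - st) <= 1.0 / fs
        rate_s, occ_s, info = _binned_rate_map(
            st[keep], t, xy, half, n_bins, fs, smooth_size
        )
        if best is None or info > best.information:
            best = RateMap(rate=rate_s, occupancy=occ_s, information=info,
                           offset=float(off))
    return best


def dash_vicinity_mask(
    trace: BehaviorTrace, dashes: pd.DataFrame, pad: float = 1.0
) -> np.ndarray:
    """Samples within ``pad`` seconds of any dash interval."""
    mask = np.zeros(len(trace), bool)
    fs = trace.sample_rate
    for row in dashes.itertuples(index=False):
        i0 = max(0, int((row.t_start - pad) * fs))
        i1 = min(len(trace), int((row.t_end + pad) * fs) + 1)
        mask[i0:i1] = True
    return mask


def gaze_rate_map(
    spike_times: np.ndarray,
    trace: BehaviorTrace,
    include_mask: np.ndarray,
    arena: ArenaConfig,
    calib: EyeCalibration,
    eye: int,
    cone_radius: float = 10.0,
    n_bins: int = 40,
    smooth_size: int = 9,
) -> RateMap:
    """Rate map in gaze-projection coordinates.

    For every included sample the selected eye's gaze cone (half-angle
    ``cone_radius`` degrees) is projected onto the floor grid; occupancy
    accumulates the per-bin dwell of the projection and spikes add to the
    bins their concurrent projection covers.
    """
    idx = np.flatnonzero(include_mask)
    if len(idx) == 0:
        raise ValueError("include_mask selects no samples")
    fs = trace.sample_rate
    sample = gaze_rays(trace.position[idx], trace.quat_wxyz[idx], calib)
    occ = np.zeros((n_bins, n_bins))
    counts = np.zeros((n_bins, n_bins))
    t_inc = trace.t[idx]
    spike_times = np.asarray(spike_times)
    j = np.clip(np.searchsorted(t_inc, spike_times), 0, len(t_inc) - 1)
    near = np.abs(t_inc[j] - spike_times) <= 1.0 / fs
    spikes_at = np.bincount(j[near], minlength=len(t_inc))
    for k in range(len(idx)):
        cover = project_gaze_to_floor(
            sample.origins[k, eye], sample.directions[k, eye],
            cone_radius, arena, n_bins=n_bins,
        )
        if cover is None:
            continue
        occ[cover] += 1.0 / fs
        if spikes_at[k]:
            counts[cover] += float(spikes_at[k])
    valid = occ > 0
    raw = np.divide(counts, occ, out=np.zeros_like(counts), where=valid)
    occ_s = smooth_map(occ, valid, smooth_size)
    rate_s = smooth_map(raw, valid, smooth_size)
    info = site_information(np.nan_to_num(rate_s), np.nan_to_num(occ_s))
    return RateMap(rate=rate_s, occupancy=occ_s, information=info)


def map_site_rates(rate_map: RateMap, arena: ArenaConfig, n_bins: int = 40,
                   radius: float = 60.0) -> np.ndarray:
    """Mean map rate within ``radius`` mm of each site center."""
    centers = floor_bin_centers(arena, n_bins=n_bins)[:, :, :2]
    out = np.full(arena.n_sites, np.nan)
    for s, site in enumerate(arena.site_positions):
        d = np.linalg.norm(centers - site, axis=-1)
        sel = (d <= radius) & ~np.isnan(rate_map.rate)
        if np.any(sel):
            out[s] = float(np.nanmean(rate_map.rate[sel]))
    return out


def selectivity_index(site_rates: np.ndarray) -> float:
    """Difference between the two largest normalized site rates.

    Rates are scaled so the maximum is 1; the index is 1 - (second/max),
    i.e. 1 for a perfectly selective cell and 0 for a two-way tie.
    """
    r = np.sort(np.asarray(site_rates, float))[::-1]
    if len(r) < 2 or r[0] <= 0:
        return 0.0
    return float(1.0 - r[1] / r[0])


def preferred_site(site_rates: np.ndarray) -> int:
    return int(np.nanargmax(site_rates))


def preferred_match_stats(
    pref_a: np.ndarray,
    pref_b: np.ndarray,
    n_scrambles: int = 1000,
    rng: Optional[np.random.Generator] = None,
):
    """Observed vs chance agreement of two preferred-site assignments.

    Chance is estimated by scrambling ``pref_b`` across cells. Returns a
    dict with the observed match fraction, the scramble distribution, and
    a permutation p-value for observed > chance.
    """
    pref_a = np.asarray(pref_a)
    pref_b = np.asarray(pref_b)
    if pref_a.shape != pref_b.shape:
        raise ValueError("assignments must have equal length")
    rng = np.random.default_rng() if rng is None else rng
    observed = float(np.mean(pref_a == pref_b))
    scr = np.empty(n_scrambles)
    for i in range(n_scrambles):
        scr[i] = np.mean(pref_a == rng.permutation(pref_b))
    p = (1.0 + np.sum(scr >= observed)) / (n_scrambles + 1.0)
    return dict(observed=observed, scrambles=scr, chance=float(scr.mean()),
                p_value=float(p))


def tuning_correlation(map_a: RateMap, map_b: RateMap) -> float:
    """Pearson correlation between two rate maps over shared valid bins."""
    a, b = map_a.rate, map_b.rate
    ok = ~np.isnan(a) & ~np.isnan(b)
    if ok.sum() < 3:
        return np.nan
    return float(np.corrcoef(a[ok], b[ok])[0, 1])


def rate_vs_gaze_angle(
    spike_counts: np.ndarray,
    alpha_deg: np.ndarray,
    bin_width: float = 10.0,
    max_angle: float = 90.0,
    window: float = 0.4,
):
    """Mean response rate binned by angular gaze distance.

    ``spike_counts`` are per-event spike counts in a ``window``-second
    response window and ``alpha_deg`` the matching gaze deviations from the
    preferred site. Returns ``(bin_centers, mean_rates, n_per_bin)``.
    """
    alpha = np.asarray(alpha_deg, float)
    counts = np.asarray(spike_counts, float)
    ok = np.isfinite(alpha) & (alpha <= max_angle)
    edges = np.arange(0.0, max_angle + bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    which = np.digitize(alpha[ok], edges) - 1
    rates = np.full(len(centers), np.nan)
    n = np.zeros(len(centers), int)
    for b in range(len(centers)):
        sel = which == b
        n[b] = sel.sum()
        if n[b]:
            rates[b] = counts[ok][sel].mean() / window
    return centers, rates, n


def fit_gaussian_decay(
    centers: np.ndarray, rates: np.ndarray, n: Optional[np.ndarray] = None
):
    """Fit r(alpha) = a * exp(-alpha^2 / (2 tau^2)) + b.

    Returns ``(a, tau, b)``; NaN bins are ignored. When per-bin event
    counts ``n`` are given the fit is weighted by sqrt(n), so sparsely
    sampled bins cannot dominate. Raises if fewer than 4 finite bins are
    available.
    """
    ok = np.isfinite(rates)
    if n is not None:
        ok &= np.asarray(n) > 0
    if ok.sum() < 4:
        raise ValueError("need at least 4 finite bins to fit the decay")
    x, y = np.asarray(centers)[ok], np.asarray(rates)[ok]
    sigma = None if n is None else 1.0 / np.sqrt(np.asarray(n, float)[ok])

    def model(alpha, a, tau, b):
        return a * np.exp(-(alpha**2) / (2.0 * tau**2)) + b

    a0 = max(y.max() - y.min(), 1e-6)
    p0 = [a0, 45.0, max(y.min(), 0.0)]
    popt, _ = curve_fit(
        model, x, y, p0=p0, sigma=sigma,
        bounds=([0.0, 1.0, 0.0], [np.inf, 180.0, np.inf]), maxfev=10000,
    )
    return float(popt[0]), float(popt[1]), float(popt[2])
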