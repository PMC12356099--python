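"""Event-aligned temporal structure of saccade and dash responses.

PSTHs are built on 3.33-ms bins (one 300-Hz behavioral sample) and
smoothed with a truncated, renormalized Gaussian — 30 ms sigma for
saccade-aligned and 100 ms for dash-aligned responses. The biphasic
saccade response is summarized by the rates in +/-50 ms windows around
the early (+17 ms) and late (+187 ms) latencies; cells are ordered by the
early-minus-late contrast.

The early response's dependence on where gaze lands versus where it came
from is quantified two ways: a bivariate matrix of mean early rate as a
function of the previous and next fixation's angular distance to the
preferred site, and a linear model of the early rate on eight gaze
covariates with per-cell intercepts, Bonferroni-corrected over the eight
coefficients.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

PSTH_BIN = 1.0 / 300.0
EARLY_LATENCY = 0.017
LATE_LATENCY = 0.187
PEAK_HALF_WINDOW = 0.050


def _gauss_kernel(sigma: float, bin_width: float) -> np.ndarray:
    half = max(1, int(np.ceil(4.0 * sigma / bin_width)))
    x = np.arange(-half, half + 1) * bin_width
    k = np.exp(-(x**2) / (2.0 * sigma**2))
    return k / k.sum()


def smooth_psth(counts: np.ndarray, sigma: float, bin_width: float = PSTH_BIN):
    """Gaussian smoothing with edge renormalization (area preserving)."""
    k = _gauss_kernel(sigma, bin_width)
    num = np.convolve(counts, k, mode="same")
    den = np.convolve(np.ones_like(counts), k, mode="same")
    return num / den


def event_aligned_rate(
    spike_times: np.ndarray,
    event_times: np.ndarray,
    window: tuple = (-0.5, 0.5),
    sigma: float = 0.030,
    bin_width: float = PSTH_BIN,
):
    """Smoothed event-aligned firing rate.

    Returns ``(bin_centers, rate_hz, n_events)``. Each event contributes
    its spike counts on ``bin_width`` bins; the average across events is
    divided by the bin width and smoothed with a truncated renormalized
    Gaussian of the given ``sigma``.
    """
    spike_times = np.sort(np.asarray(spike_times))
    event_times = np.asarray(event_times, float)
    event_times = event_times[np.isfinite(event_times)]
    n_bins = int(round((window[1] - window[0]) / bin_width))
    edges = window[0] + np.arange(n_bins + 1) * bin_width
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = np.zeros(n_bins)
    for te in event_times:
        rel = spike_times[
            np.searchsorted(spike_times, te + window[0]):
            np.searchsorted(spike_times, te + window[1])
        ] - te
        counts += np.histogram(rel, bins=edges)[0]
    if len(event_times) == 0:
        return centers, np.full(n_bins, np.nan), 0
    rate = counts / (len(event_times) * bin_width)
    return centers, smooth_psth(rate, sigma, bin_width), len(event_times)


def early_late_rates(
    centers: np.ndarray,
    rate: np.ndarray,
    early_latency: float = EARLY_LATENCY,
    late_latency: float = LATE_LATENCY,
    half_window: float = PEAK_HALF_WINDOW,
):
    """Mean rates in +/-half_window around the early and late latencies."""
    out = []
    for lat in (early_latency, late_latency):
        sel = np.abs(centers - lat) <= half_window
        out.append(float(np.nanmean(rate[sel])) if np.any(sel) else np.nan)
    return out[0], out[1]


def early_late_ordering(psths: np.ndarray, centers: np.ndarray):
    """Sort key (descending early-minus-late contrast) for a PSTH stack.

    ``psths`` is (n_cells, n_bins), baseline-normalized or raw. Returns
    ``(order, contrast)`` where ``order`` sorts early-dominated cells
    first.
    """
    contrast = np.empty(len(psths))
    for i, p in enumerate(psths):
        e, l = early_late_rates(centers, p)
        contrast[i] = e - l
    return np.argsort(-contrast), contrast


def bivariate_early_matrix(
    early_rate: np.ndarray,
    alpha_prev: np.ndarray,
    alpha_next: np.ndarray,
    bin_width: float = 10.0,
    max_angle: float = 90.0,
):
    """Early response vs previous and next gaze distance, jointly binned.

    Returns a dict with the (n_bins, n_bins) mean-rate matrix (rows =
    previous-fixation bins, columns = next), the per-bin counts, the two
    marginals, and the next-distance tuning computed separately for
    trials whose previous distance falls in [30, 40) degrees (a slice that
    holds the previous fixation approximately constant).
    """
    edges = np.arange(0.0, max_angle + bin_width, bin_width)
    nb = len(edges) - 1
    ok = (
        np.isfinite(alpha_prev) & np.isfinite(alpha_next)
        & (alpha_prev < max_angle) & (alpha_next < max_angle)
        & np.isfinite(early_rate)
    )
    ip = np.digitize(alpha_prev[ok], edges) - 1
    inx = np.digitize(alpha_next[ok], edges) - 1
    r = early_rate[ok]
    mat_sum = np.zeros((nb, nb))
    mat_n = np.zeros((nb, nb))
    np.add.at(mat_sum, (ip, inx), r)
    np.add.at(mat_n, (ip, inx), 1.0)
    with np.errstate(invalid="ignore"):
        mat = np.where(mat_n > 0, mat_sum / np.maximum(mat_n, 1), np.nan)
    marg_prev = np.array(
        [r[ip == b].mean() if np.any(ip == b) else np.nan for b in range(nb)]
    )
    marg_next = np.array(
        [r[inx == b].mean() if np.any(inx == b) else np.nan for b in range(nb)]
    )
    clamp = (alpha_prev[ok] >= 30.0) & (alpha_prev[ok] < 40.0)
    clamped_next = np.array(
        [
            r[clamp & (inx == b)].mean() if np.any(clamp & (inx == b)) else np.nan
            for b in range(nb)
        ]
    )
    centers = 0.5 * (edges[:-1] + edges[1:])
    return dict(
        centers=centers, matrix=mat, counts=mat_n,
        marginal_prev=marg_prev, marginal_next=marg_next,
        clamped_next=clamped_next,
    )


def condition_psth(
    spike_times: np.ndarray,
    event_times: np.ndarray,
    condition: np.ndarray,
    window: tuple = (-0.5, 0.5),
    sigma: float = 0.030,
    min_events: int = 5,
    min_rate: float = 1.0,
    normalize_to: Optional[str] = None,
):
    """Per-condition event-aligned rates with optional normalization.

    ``condition`` holds a label per event. Conditions with fewer than
    ``min_events`` events are dropped. If ``normalize_to`` names a
    condition, every PSTH is divided by that condition's peak rate; a cell
    whose reference peak is below ``min_rate`` Hz yields None.
    """
    condition = np.asarray(condition)
    labels = pd.unique(condition)
    out = {}
    centers = None
    for lab in labels:
        ev = np.asarray(event_times)[condition == lab]
        if len(ev) < min_events:
            continue
        centers, rate, n = event_aligned_rate(
            spike_times, ev, window=window, sigma=sigma
        )
        out[lab] = dict(rate=rate, n=n)
    if not out:
        return None
    if normalize_to is not None:
        if normalize_to not in out:
            return None
        ref = float(np.nanmax(out[normalize_to]["rate"]))
        if ref < min_rate:
            return None
        for lab in out:
            out[lab]["rate"] = out[lab]["rate"] / ref
    return dict(centers=centers, conditions=out)


def early_response_model(
    table: pd.DataFrame,
    response_column: str = "early_rate",
    alpha: float = 0.05,
):
    """Linear model of the early response on gaze geometry covariates.

    ``table`` must hold one row per (cell, saccade) with columns
    ``cell_id``, the response, and ``h_prev, v_prev, h_next, v_next`` —
    the horizontal/vertical angular deviations of the previous and next
    fixation's gaze from the preferred site. The model regresses the
    response on the four deviations and their squares (8 covariates) with
    one intercept per cell; coefficient significance is Bonferroni
    corrected across the 8 covariates.

    Returns a dict with the statsmodels results, the coefficient table and
    the boolean ``significant`` array.
    """
    needed = ["cell_id", response_column, "h_prev", "v_prev", "h_next", "v_next"]
    for c in needed:
        if c not in table:
            raise ValueError(f"missing column {c!r}")
    df = table.dropna(subset=needed).copy()
    cov_names = []
    X_cols = []
    for c in ("h_prev", "v_prev", "h_next", "v_next"):
        X_cols.append(df[c].to_numpy(float))
        cov_names.append(c)
    for c in ("h_prev", "v_prev", "h_next", "v_next"):
        X_cols.append(df[c].to_numpy(float) ** 2)
        cov_names.append(c + "_sq")
    X = np.column_stack(X_cols)
    # standardize covariates so coefficients are comparable
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    cells = pd.get_dummies(df["cell_id"], prefix="cell", dtype=float)
    design = np.column_stack([X, cells.to_numpy()])
    names = cov_names + list(cells.columns)
    res = sm.OLS(df[response_column].to_numpy(float), design).fit()
    k = len(cov_names)
    pvals = res.pvalues[:k]
    coefs = res.params[:k]
    significant = pvals < alpha / k
    coef_table = pd.DataFrame(
        dict(covariate=cov_names, coef=coefs, p_value=pvals,
             significant=significant)
    )
    return dict(result=res, coefficients=coef_table,
                significant=significant, names=names)
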