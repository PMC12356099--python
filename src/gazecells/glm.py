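"""Poisson lasso GLM linking saccade responses to gaze direction.

For each analysed saccade, the response is the spike count in a window
[-0.1, +0.3] s around peak saccade velocity. The design has one column per
(eye, site) pair — four contralateral and four ipsilateral sites — each a
Gaussian basis of the angular distance alpha between that eye's landing
gaze and the site:

    x = exp(-alpha^2 / (2 tau^2)),   tau = 45 deg.

Coefficients are fit by maximizing the L1-penalized Poisson likelihood
(lasso, lambda = 0.005, intercept unpenalized) with FISTA proximal
gradient descent. With lambda = 0 the fit reduces to an ordinary Poisson
GLM, which is cross-checked against statsmodels in the test suite.

Laterality is summarized by the normalized difference
(c - i) / (c + i) between the contralateral and ipsilateral coefficients
at the cell's preferred site.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import ArenaConfig

DEFAULT_TAU = 45.0
DEFAULT_LAMBDA = 0.005
RESPONSE_WINDOW = (-0.1, 0.3)


def gaussian_basis(alpha_deg: np.ndarray, tau: float = DEFAULT_TAU,
                   half_exponent: bool = False) -> np.ndarray:
    """Gaussian closeness basis exp(-alpha^2 / (2 tau^2)).

    ``half_exponent`` switches to exp(-alpha^2 / tau^2), the convention
    without the factor 2; kept explicit so the two are never silently
    conflated.
    """
    a = np.asarray(alpha_deg, float)
    denom = tau**2 if half_exponent else 2.0 * tau**2
    return np.exp(-(a**2) / denom)


def saccade_inclusion_mask(
    saccades: pd.DataFrame,
    alpha_next: np.ndarray,
    dashes: pd.DataFrame,
    contra_eye: int,
    landing_threshold: float = 20.0,
    min_gap_to_dash: float = 0.5,
) -> np.ndarray:
    """Saccades analysed by the GLM.

    Included saccades are analysis-eligible (followed by a fixation), land
    within ``landing_threshold`` degrees of some site with either eye, and
    end at least ``min_gap_to_dash`` s before the next dash (so dash
    responses never leak into the window).
    """
    n = len(saccades)
    ok = np.ones(n, bool)
    if "eligible" in saccades:
        ok &= saccades["eligible"].to_numpy().astype(bool)
    amin = np.nanmin(np.where(np.isnan(alpha_next), np.inf, alpha_next), axis=(1, 2))
    ok &= amin < landing_threshold
    t_end = saccades["t_end"].to_numpy()
    dash_starts = np.sort(dashes["t_start"].to_numpy()) if len(dashes) else np.array([])
    if len(dash_starts):
        nxt = np.searchsorted(dash_starts, t_end)
        gap = np.where(
            nxt < len(dash_starts), dash_starts[np.minimum(nxt, len(dash_starts) - 1)] - t_end,
            np.inf,
        )
        ok &= gap >= min_gap_to_dash
    return ok


def build_gaze_design(
    spike_times: np.ndarray,
    saccades: pd.DataFrame,
    alpha_next: np.ndarray,
    arena: ArenaConfig,
    contra_eye: int,
    tau: float = DEFAULT_TAU,
    include: Optional[np.ndarray] = None,
    window: tuple = RESPONSE_WINDOW,
):
    """Design matrix and response counts for the gaze GLM.

    Columns are ordered contralateral sites first, then ipsilateral, both
    in outer-site order. Returns ``(X, y, column_names, kept_index)``.
    """
    outer = arena.outer_site_indices
    if include is None:
        include = np.ones(len(saccades), bool)
    t_peak = saccades["t_peak"].to_numpy()
    spike_times = np.sort(np.asarray(spike_times))
    cols, names = [], []
    ipsi = 1 - contra_eye
    for eye, label in ((contra_eye, "contra"), (ipsi, "ipsi")):
        for s in outer:
            cols.append(gaussian_basis(alpha_next[:, eye, s], tau))
            names.append(f"{label}_site{s}")
    X = np.column_stack(cols)
    keep = include & np.all(np.isfinite(X), axis=1)
    lo = np.searchsorted(spike_times, t_peak + window[0])
    hi = np.searchsorted(spike_times, t_peak + window[1])
    y = (hi - lo).astype(float)
    return X[keep], y[keep], names, np.flatnonzero(keep)


@dataclass
class LassoFit:
    intercept: float
    coef: np.ndarray
    names: list
    converged: bool
    n_iter: int
    objective: float


def _poisson_objective(X, y, beta0, beta, lam):
    eta = beta0 + X @ beta
    return float(np.mean(np.exp(eta) - y * eta) + lam * np.abs(beta).sum())


def fit_poisson_lasso(
    X: np.ndarray,
    y: np.ndarray,
    lam: float = DEFAULT_LAMBDA,
    max_iter: int = 5000,
    tol: float = 1e-9,
) -> LassoFit:
    """L1-penalized Poisson regression via FISTA.

    Minimizes (1/n) sum_k (exp(eta_k) - y_k eta_k) + lam * ||beta||_1 with
    eta = beta0 + X beta; the intercept beta0 is unpenalized. The step size
    adapts by halving whenever the objective would increase (the Poisson
    loss has no global Lipschitz bound).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    if len(y) != n:
        raise ValueError("X and y are inconsistent")
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    def smooth_loss(b0, b):
        eta = np.clip(b0 + X @ b, -30, 30)
        return float(np.mean(np.exp(eta) - y * eta))

    beta0 = np.log(max(y.mean(), 1e-12))
    beta = np.zeros(p)
    z0, z = beta0, beta.copy()
    t_mom = 1.0
    step = 1.0 / max(np.exp(beta0) * ((X**2).sum(axis=1).max() + 1.0), 1e-3)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(z0 + X @ z, -30, 30)
        mu = np.exp(eta)
        fz = float(np.mean(mu - y * eta))
        g0 = np.mean(mu - y)
        g = X.T @ (mu - y) / n
        # backtracking on the smooth part's quadratic majorization at z
        while True:
            new0 = z0 - step * g0
            raw = z - step * g
            new = np.sign(raw) * np.maximum(np.abs(raw) - step * lam, 0.0)
            d0, d = new0 - z0, new - z
            quad = fz + g0 * d0 + g @ d + (d0**2 + d @ d) / (2.0 * step)
            if smooth_loss(new0, new) <= quad + 1e-12 or step < 1e-14:
                break
            step *= 0.5
        # adaptive restart: drop momentum whenever the step direction
        # opposes the previous move (prevents late-stage cycling)
        if (z0 - new0) * (new0 - beta0) + (z - new) @ (new - beta) > 0:
            t_next, mom = 1.0, 0.0
        else:
            t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2))
            mom = (t_mom - 1.0) / t_next
        z0 = new0 + mom * (new0 - beta0)
        z = new + mom * (new - beta)
        delta = max(abs(new0 - beta0), np.abs(new - beta).max() if p else 0.0)
        beta0, beta, t_mom = new0, new, t_next
        if delta < tol:
            converged = True
            break
        step *= 1.05  # gentle growth so halving stays responsive
    return LassoFit(
        intercept=float(beta0), coef=beta, names=[], converged=converged,
        n_iter=it, objective=_poisson_objective(X, y, beta0, beta, lam),
    )


def fit_poisson_glm_reference(X: np.ndarray, y: np.ndarray):
    """Unpenalized Poisson GLM via statsmodels (IRLS), as a cross-check."""
    model = sm.GLM(y, sm.add_constant(X, has_constant="add"),
                   family=sm.families.Poisson())
    res = model.fit()
    return float(res.params[0]), np.asarray(res.params[1:])


def poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    """Poisson deviance 2*sum(y*log(y/mu) - (y - mu)) with 0*log(0) = 0."""
    y = np.asarray(y, float)
    mu = np.asarray(mu, float)
    if np.any(mu <= 0):
        raise ValueError("predicted means must be positive")
    term = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def predicted_means(X: np.ndarray, fit: LassoFit) -> np.ndarray:
    """exp(eta) under a fitted model."""
    return np.exp(fit.intercept + np.asarray(X, float) @ fit.coef)


def normalized_difference(c: float, i: float) -> float:
    """Laterality index (c - i) / (c + i) of two model coefficients.

    ``c`` and ``i`` are the contralateral and ipsilateral coefficients at a
    cell's preferred site, taken as fitted (not rectified). Returns NaN in
    the degenerate c + i = 0 case, where the index is undefined.
    """
    c, i = float(c), float(i)
    if c + i == 0:
        return float("nan")
    return (c - i) / (c + i)


def light_tuning_glm(
    counts: np.ndarray,
    closeness: np.ndarray,
    light_on: np.ndarray,
):
    """Nested Poisson GLM test for light modulation of the gaze response.

    The full model has intercept, closeness, light and closeness x light;
    the reduced model drops the light terms. Returns a dict with both fits
    and the likelihood-ratio p-value (chi-squared, 2 df).
    """
    from scipy.stats import chi2

    closeness = np.asarray(closeness, float)
    light = np.asarray(light_on, float)
    X_full = np.column_stack([closeness, light, closeness * light])
    X_red = closeness[:, None]
    full = sm.GLM(counts, sm.add_constant(X_full, has_constant="add"),
                  family=sm.families.Poisson()).fit()
    red = sm.GLM(counts, sm.add_constant(X_red, has_constant="add"),
                 family=sm.families.Poisson()).fit()
    lr = 2.0 * (full.llf - red.llf)
    p = float(chi2.sf(max(lr, 0.0), df=2))
    return dict(full=full, reduced=red, lr_stat=float(lr), p_value=p)


def all_to_all_selectivity(
    spike_times: np.ndarray,
    dashes: pd.DataFrame,
    saccades: pd.DataFrame,
    arena: ArenaConfig,
    min_events_per_pair: int = 4,
    selectivity_threshold: float = 0.67,
    min_response_rate: float = 0.5,
):
    """Pairwise dash/saccade responses in the all-to-all (pentagon) task.

    Responses are baseline-subtracted rates: for dashes, the mean rate in
    [t_start - 0.5, t_end + 0.5] minus the rate in [t_start - 2,
    t_start - 1]; for saccades, the rate in [0, 0.3] after peak velocity
    minus the rate in [-1, -0.2]. Per-cell selectivity over directed pairs
    is (max - mean) / max of the pairwise mean responses (clipped at 0).

    Returns a dict with the pairwise response tables and the inclusion
    decision (>= ``min_events_per_pair`` events per directed pair with any
    events, selectivity above threshold and peak response above
    ``min_response_rate`` Hz).
    """
    spike_times = np.sort(np.asarray(spike_times))

    def rate_in(t0, t1):
        if t1 <= t0:
            return 0.0
        a, b = np.searchsorted(spike_times, [t0, t1])
        return (b - a) / (t1 - t0)

    pair_resp: dict = {}
    for row in dashes.itertuples(index=False):
        r = rate_in(row.t_start - 0.5, row.t_end + 0.5) - rate_in(
            row.t_start - 2.0, row.t_start - 1.0
        )
        pair_resp.setdefault((int(row.src), int(row.dst)), []).append(r)
    dash_table = {
        k: (float(np.mean(v)), len(v)) for k, v in pair_resp.items()
    }

    sacc_resp: dict = {}
    has_site = "site" in saccades and "gaze_site" in saccades
    for row in saccades.itertuples(index=False):
        r = rate_in(row.t_peak, row.t_peak + 0.3) - rate_in(
            row.t_peak - 1.0, row.t_peak - 0.2
        )
        if has_site and getattr(row, "gaze_site") >= 0:
            key = (int(getattr(row, "site")), int(getattr(row, "gaze_site")))
            sacc_resp.setdefault(key, []).append(r)
    sacc_table = {k: (float(np.mean(v)), len(v)) for k, v in sacc_resp.items()}

    means = np.array([v[0] for v in dash_table.values()]) if dash_table else np.array([])
    ns = np.array([v[1] for v in dash_table.values()]) if dash_table else np.array([])
    if len(means) == 0:
        return dict(dash=dash_table, saccade=sacc_table, selectivity=np.nan,
                    include=False, reason="no dash events")
    pos = np.maximum(means, 0.0)
    peak = pos.max()
    selectivity = float((peak - pos.mean()) / peak) if peak > 0 else 0.0
    include = bool(
        np.all(ns >= min_events_per_pair)
        and selectivity > selectivity_threshold
        and peak > min_response_rate
    )
    reason = "ok" if include else "below inclusion thresholds"
    return dict(dash=dash_table, saccade=sacc_table, selectivity=selectivity,
                include=include, reason=reason)
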