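"""Waveform-based cell classification and interneuron phase clustering.

Units are described by four features: log mean firing rate, spike width
(trough to the following peak), waveform asymmetry (post- vs pre-trough
peak contrast) and the log ratio of the waveform derivative's peak to its
trough. A two-component Gaussian mixture over the standardized features
separates putative excitatory cells (the lower-rate component) from
interneurons; units farther than 3 Mahalanobis units from both components
stay unclassified, and units with under 500 spikes are excluded outright.

Interneurons are subdivided by the phase of their saccade-aligned
response: the analytic (Hilbert) phase of the mean-subtracted PSTH is
read out at +187 ms, and phases are clustered with circular k-means
(k = 2); the cluster whose centroid lies nearer phase 0 is the "peak"
class, the other the "trough" class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import hilbert
from sklearn.mixture import GaussianMixture

from .spikes import WAVEFORM_FS

MIN_SPIKES = 500
MAHALANOBIS_MAX = 3.0
PHASE_READOUT = 0.187


def extract_waveform_features(
    waveform: np.ndarray,
    n_spikes: int,
    duration: float,
    fs: float = WAVEFORM_FS,
) -> dict:
    """Four classification features from a mean waveform.

    Returns a dict with ``log_rate`` (log10 Hz), ``width_ms`` (trough to
    next positive peak), ``asymmetry`` ((post - pre)/(post + pre) of the
    flanking positive peaks) and ``log_deriv_ratio`` (log10 of the
    derivative's max over |min|), plus ``excluded`` when the unit has
    fewer than ``MIN_SPIKES`` spikes. Raises if the waveform has no
    trough or no post-trough peak.
    """
    wf = np.asarray(waveform, float)
    if wf.ndim != 1 or len(wf) < 8:
        raise ValueError("waveform must be a 1-D vector")
    itr = int(np.argmin(wf))
    if wf[itr] >= 0:
        raise ValueError("waveform has no negative trough")
    post = wf[itr:]
    if len(post) < 3 or post.max() <= wf[itr]:
        raise ValueError("waveform has no post-trough peak")
    ipk = itr + int(np.argmax(post))
    width_ms = (ipk - itr) / fs * 1000.0
    a = float(wf[:itr].max()) if itr > 0 else 0.0
    b = float(wf[ipk])
    a, b = max(a, 0.0), max(b, 0.0)
    asym = (b - a) / (b + a) if (a + b) > 0 else 0.0
    dv = np.diff(wf)
    dmax, dmin = float(dv.max()), float(dv.min())
    if dmax <= 0 or dmin >= 0:
        raise ValueError("waveform derivative lacks a peak or a trough")
    if duration <= 0:
        raise ValueError("duration must be positive")
    rate = n_spikes / duration
    return dict(
        log_rate=float(np.log10(max(rate, 1e-6))),
        width_ms=float(width_ms),
        asymmetry=float(asym),
        log_deriv_ratio=float(np.log10(dmax / -dmin)),
        excluded=bool(n_spikes < MIN_SPIKES),
    )


@dataclass
class EIClassification:
    labels: np.ndarray  # 'excitatory' | 'interneuron' | 'unclassified' | 'excluded'
    means: np.ndarray  # component means in standardized feature space
    mahalanobis: np.ndarray  # (n_units, 2) distance to each component
    feature_names: list


def classify_ei_gmm(
    features: pd.DataFrame,
    rng_seed: int = 0,
    mahalanobis_max: float = MAHALANOBIS_MAX,
) -> EIClassification:
    """Two-component GMM split into excitatory cells and interneurons.

    ``features`` needs columns log_rate, width_ms, asymmetry,
    log_deriv_ratio and excluded. Excluded units never enter the fit. The
    component with the lower mean log rate is labeled excitatory. Units
    beyond ``mahalanobis_max`` of both components are unclassified.
    """
    names = ["log_rate", "width_ms", "asymmetry", "log_deriv_ratio"]
    X = features[names].to_numpy(float)
    excluded = features["excluded"].to_numpy(bool)
    fit_mask = ~excluded
    if fit_mask.sum() < 4:
        raise ValueError("too few units to fit the mixture")
    mu = X[fit_mask].mean(axis=0)
    sd = X[fit_mask].std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (X - mu) / sd
    gmm = GaussianMixture(
        n_components=2, covariance_type="full", n_init=5,
        random_state=rng_seed,
    ).fit(Z[fit_mask])
    exc_comp = int(np.argmin(gmm.means_[:, 0]))  # lower log rate
    d = np.empty((len(X), 2))
    for k in range(2):
        diff = Z - gmm.means_[k]
        prec = np.linalg.inv(gmm.covariances_[k])
        d[:, k] = np.sqrt(np.einsum("ni,ij,nj->n", diff, prec, diff))
    hard = gmm.predict(Z)
    labels = np.where(hard == exc_comp, "excitatory", "interneuron").astype(object)
    labels[d.min(axis=1) > mahalanobis_max] = "unclassified"
    labels[excluded] = "excluded"
    return EIClassification(
        labels=labels.astype(str), means=gmm.means_, mahalanobis=d,
        feature_names=names,
    )


def interneuron_phase(
    psth_rate: np.ndarray,
    centers: np.ndarray,
    readout: float = PHASE_READOUT,
) -> float:
    """Analytic phase of a saccade-aligned PSTH at the readout latency.

    The PSTH is mean-subtracted before the Hilbert transform; returns the
    phase in radians at the bin nearest ``readout`` (0 = local peak, pi =
    trough). Raises for a constant PSTH (phase undefined).
    """
    r = np.asarray(psth_rate, float)
    if np.allclose(r, r[0]):
        raise ValueError("constant PSTH: phase undefined")
    analytic = hilbert(r - r.mean())
    idx = int(np.argmin(np.abs(np.asarray(centers) - readout)))
    return float(np.angle(analytic[idx]))


def _circ_dist(a, b):
    return np.angle(np.exp(1j * (a - b)))


def circular_kmeans(
    phases: np.ndarray,
    k: int = 2,
    n_restarts: int = 10,
    rng: Optional[np.random.Generator] = None,
    max_iter: int = 100,
):
    """k-means on the circle minimizing within-cluster circular variance.

    Centroids are circular means; assignment uses the wrapped distance.
    Returns ``(labels, centroids, score)`` with ``score`` the mean
    resultant length across clusters (1 = tight clusters); the best of
    ``n_restarts`` random initializations wins.
    """
    phases = np.asarray(phases, float)
    if len(phases) < k:
        raise ValueError("need at least k phases")
    rng = np.random.default_rng() if rng is None else rng
    best = None
    for _ in range(n_restarts):
        cent = rng.uniform(-np.pi, np.pi, k)
        labels = np.zeros(len(phases), int)
        for _ in range(max_iter):
            dmat = np.abs(_circ_dist(phases[:, None], cent[None, :]))
            new_labels = dmat.argmin(axis=1)
            new_cent = cent.copy()
            for j in range(k):
                sel = new_labels == j
                if np.any(sel):
                    new_cent[j] = np.angle(np.mean(np.exp(1j * phases[sel])))
            if np.array_equal(new_labels, labels) and np.allclose(new_cent, cent):
                break
            labels, cent = new_labels, new_cent
        # mean resultant length, averaged over clusters weighted by size
        score = 0.0
        for j in range(k):
            sel = labels == j
            if np.any(sel):
                score += np.abs(np.mean(np.exp(1j * phases[sel]))) * sel.sum()
        score /= len(phases)
        if best is None or score > best[2]:
            best = (labels.copy(), cent.copy(), float(score))
    return best


def classify_interneuron_phases(
    phases: np.ndarray,
    rng: Optional[np.random.Generator] = None,
):
    """Peak/trough interneuron classes from response phases.

    Clusters the phases with circular k-means (k = 2) and maps the cluster
    whose centroid is closer to 0 to ``peak`` and the other to ``trough``.
    Returns a dict with labels ('peak'/'trough'), centroids, and the
    clustering score.
    """
    labels, cent, score = circular_kmeans(np.asarray(phases, float), k=2, rng=rng)
    peak_cluster = int(np.argmin(np.abs(_circ_dist(cent, 0.0))))
    named = np.where(labels == peak_cluster, "peak", "trough")
    return dict(
        labels=named, centroids=cent, score=score,
        separation=float(np.abs(_circ_dist(cent[0], cent[1]))),
    )
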