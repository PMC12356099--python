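import numpy as np
import pandas as pd
import pytest

from gazecells import celltypes
from gazecells.spikes import WAVEFORM_FS, waveform_template


def test_extract_waveform_features_basic():
    wf = waveform_template(0.4, 0.4)
    feats = celltypes.extract_waveform_features(wf, 2000, 600.0)
    assert set(feats) == {
        "log_rate", "width_ms", "asymmetry", "log_deriv_ratio", "excluded"
    }
    assert feats["log_rate"] == pytest.approx(np.log10(2000 / 600.0))
    assert 0.1 < feats["width_ms"] < 1.5
    assert -1.0 <= feats["asymmetry"] <= 1.0
    assert not feats["excluded"]
    assert celltypes.extract_waveform_features(wf, 100, 600.0)["excluded"]


def test_extract_waveform_features_errors():
    with pytest.raises(ValueError):
        celltypes.extract_waveform_features(np.abs(np.sin(np.arange(90))), 1000, 60.0)
    with pytest.raises(ValueError):
        celltypes.extract_waveform_features(np.array([1.0, 2.0]), 1000, 60.0)
    with pytest.raises(ValueError):
        celltypes.extract_waveform_features(waveform_template(0.4, 0.4), 1000, 0.0)


def _feature_table(rng, n_exc=30, n_int=15):
    rows = []
    for _ in range(n_exc):
        rows.append(dict(
            log_rate=rng.normal(0.3, 0.15),
            width_ms=rng.normal(0.55, 0.05),
            asymmetry=rng.normal(0.45, 0.1),
            log_deriv_ratio=rng.normal(-0.25, 0.08),
            excluded=False, truth="excitatory",
        ))
    for _ in range(n_int):
        rows.append(dict(
            log_rate=rng.normal(1.1, 0.15),
            width_ms=rng.normal(0.28, 0.04),
            asymmetry=rng.normal(0.05, 0.1),
            log_deriv_ratio=rng.normal(0.1, 0.08),
            excluded=False, truth="interneuron",
        ))
    return pd.DataFrame(rows)


def test_classify_ei_gmm_separates_populations(rng):
    df = _feature_table(rng)
    res = celltypes.classify_ei_gmm(df, rng_seed=0)
    classified = res.labels != "unclassified"
    acc = np.mean(res.labels[classified] == df["truth"].to_numpy()[classified])
    assert acc >= 0.95
    assert classified.mean() > 0.9


def test_classify_ei_gmm_excluded_and_outlier(rng):
    df = _feature_table(rng)
    df.loc[0, "excluded"] = True
    # moderately extreme so it stays an outlier rather than capturing a
    # mixture component of its own
    out = dict(log_rate=2.0, width_ms=1.1, asymmetry=-0.6,
               log_deriv_ratio=0.9, excluded=False, truth="?")
    df = pd.concat([df, pd.DataFrame([out])], ignore_index=True)
    res = celltypes.classify_ei_gmm(df, rng_seed=0)
    assert res.labels[0] == "excluded"
    assert res.labels[len(df) - 1] == "unclassified"


def test_interneuron_phase_peak_and_trough():
    centers = np.linspace(-0.5, 0.5, 301)
    bump = np.exp(-((centers - 0.187) ** 2) / (2 * 0.05**2))
    assert abs(celltypes.interneuron_phase(bump, centers)) < 0.5
    trough_phase = celltypes.interneuron_phase(1.0 - bump, centers)
    assert abs(abs(trough_phase) - np.pi) < 0.5
    with pytest.raises(ValueError):
        celltypes.interneuron_phase(np.ones(301), centers)


def test_circular_kmeans_recovers_opposed_modes(rng):
    """Two clusters 180 degrees apart are recovered within 10 degrees."""
    a = rng.vonmises(0.2, 12.0, 60)
    b = rng.vonmises(0.2 + np.pi, 12.0, 60)
    phases = np.concatenate([a, b])
    labels, cent, score = celltypes.circular_kmeans(
        phases, k=2, rng=np.random.default_rng(3)
    )
    sep = np.abs(np.angle(np.exp(1j * (cent[0] - cent[1]))))
    assert abs(np.rad2deg(sep) - 180.0) < 10.0
    assert score > 0.9
    # cluster assignment matches the generating mode
    truth = np.array([0] * 60 + [1] * 60)
    agree = max(np.mean(labels == truth), np.mean(labels != truth))
    assert agree > 0.95


def test_circular_kmeans_wraparound(rng):
    """A mode straddling +/-pi is found at the wrap point, not split."""
    phases = np.concatenate([
        rng.vonmises(np.pi, 15.0, 50),
        rng.vonmises(0.0, 15.0, 50),
    ])
    labels, cent, score = celltypes.circular_kmeans(
        phases, k=2, rng=np.random.default_rng(4)
    )
    d0 = np.min(np.abs(np.angle(np.exp(1j * (cent - np.pi)))))
    assert d0 < np.deg2rad(10.0)


def test_classify_interneuron_phases(rng):
    peak = rng.vonmises(0.0, 10.0, 40)
    trough = rng.vonmises(np.pi, 10.0, 40)
    res = celltypes.classify_interneuron_phases(
        np.concatenate([peak, trough]), rng=np.random.default_rng(5)
    )
    assert np.mean(res["labels"][:40] == "peak") > 0.95
    assert np.mean(res["labels"][40:] == "trough") > 0.95
    assert abs(np.rad2deg(res["separation"]) - 180.0) < 10.0


def test_circular_kmeans_too_few():
    with pytest.raises(ValueError):
        celltypes.circular_kmeans(np.array([0.1]), k=2)
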