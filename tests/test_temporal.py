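import numpy as np
import pandas as pd
import pytest

from gazecells import temporal


def test_smooth_psth_preserves_constant():
    x = np.full(300, 7.0)
    out = temporal.smooth_psth(x, sigma=0.03)
    assert np.allclose(out, 7.0, atol=1e-12)


def test_smooth_psth_preserves_area_interior():
    x = np.zeros(301)
    x[150] = 1.0
    out = temporal.smooth_psth(x, sigma=0.02)
    assert out.sum() == pytest.approx(1.0, abs=1e-9)
    assert out[150] == out.max()


def test_event_aligned_rate_constant_train(rng):
    """A homogeneous Poisson train yields a flat PSTH at its rate."""
    lam, T = 30.0, 400.0
    spikes = np.sort(rng.uniform(0, T, rng.poisson(lam * T)))
    events = rng.uniform(1.0, T - 1.0, 300)
    centers, rate, n = temporal.event_aligned_rate(spikes, events)
    assert n == 300
    assert len(centers) == len(rate) == 300
    assert rate.mean() == pytest.approx(lam, rel=0.05)
    assert rate.std() < 0.2 * lam


def test_event_aligned_rate_localized_peak(rng):
    """Spikes injected 17 ms after each event produce a peak there."""
    events = np.arange(5.0, 600.0, 2.0)
    jitter = rng.normal(0.0, 0.004, len(events))
    spikes = np.sort(events + 0.017 + jitter)
    centers, rate, n = temporal.event_aligned_rate(spikes, events)
    assert abs(centers[np.argmax(rate)] - 0.017) < 0.012
    e, l = temporal.early_late_rates(centers, rate)
    assert e > 10 * max(l, 1e-9)


def test_event_aligned_rate_empty():
    centers, rate, n = temporal.event_aligned_rate(np.array([1.0]), np.array([]))
    assert n == 0 and np.all(np.isnan(rate))


def test_event_aligned_rate_deterministic(rng):
    spikes = np.sort(rng.uniform(0, 100, 2000))
    events = rng.uniform(1, 99, 50)
    a = temporal.event_aligned_rate(spikes, events)
    b = temporal.event_aligned_rate(spikes, events)
    assert np.array_equal(a[1], b[1])


def test_early_late_ordering():
    centers = np.linspace(-0.5, 0.5, 301)
    early = np.exp(-((centers - 0.017) ** 2) / (2 * 0.02**2))
    late = np.exp(-((centers - 0.187) ** 2) / (2 * 0.02**2))
    psths = np.stack([late, early, 0.5 * early + 0.5 * late])
    order, contrast = temporal.early_late_ordering(psths, centers)
    assert order.tolist() == [1, 2, 0]
    assert contrast[1] > contrast[2] > contrast[0]


def test_bivariate_early_matrix(rng):
    n = 20000
    a_prev = rng.uniform(0, 90, n)
    a_next = rng.uniform(0, 90, n)
    # early rate depends only on the NEXT fixation's distance
    r = 10.0 * np.exp(-(a_next**2) / (2 * 45.0**2)) + rng.normal(0, 0.3, n)
    out = temporal.bivariate_early_matrix(r, a_prev, a_next)
    assert out["matrix"].shape == (9, 9)
    assert out["counts"].sum() == n
    # next marginal decreases, prev marginal is flat
    mn, mp = out["marginal_next"], out["marginal_prev"]
    assert mn[0] > mn[-1] + 3.0
    assert abs(mp[0] - mp[-1]) < 1.0
    # clamping the previous distance leaves the next tuning intact
    cn = out["clamped_next"]
    assert cn[0] > cn[-1] + 3.0


def test_condition_psth_normalization(rng):
    spikes = np.sort(rng.uniform(0, 200, 6000))
    events = rng.uniform(1, 199, 120)
    cond = np.array(["a", "b"] * 60)
    out = temporal.condition_psth(spikes, events, cond, normalize_to="a")
    assert set(out["conditions"]) == {"a", "b"}
    assert np.nanmax(out["conditions"]["a"]["rate"]) == pytest.approx(1.0)
    # too few events in a condition drops it
    cond2 = np.array(["a"] * 118 + ["b"] * 2)
    out2 = temporal.condition_psth(spikes, events, cond2)
    assert "b" not in out2["conditions"]


def test_early_response_model_detects_next_dependence(rng):
    n = 4000
    df = pd.DataFrame(
        dict(
            cell_id=rng.integers(0, 5, n),
            h_prev=rng.normal(0, 20, n),
            v_prev=rng.normal(0, 20, n),
            h_next=rng.normal(0, 20, n),
            v_next=rng.normal(0, 20, n),
        )
    )
    df["early_rate"] = (
        5.0 - 0.002 * df["h_next"] ** 2 - 0.002 * df["v_next"] ** 2
        + rng.normal(0, 0.5, n)
    )
    out = temporal.early_response_model(df)
    coef = out["coefficients"].set_index("covariate")
    assert coef.loc["h_next_sq", "significant"]
    assert coef.loc["v_next_sq", "significant"]
    assert not coef.loc["h_prev", "significant"]
    assert not coef.loc["h_prev_sq", "significant"]
    with pytest.raises(ValueError):
        temporal.early_response_model(df.drop(columns=["h_prev"]))
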