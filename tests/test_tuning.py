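import numpy as np
import pandas as pd
import pytest

from gazecells import tuning


def _brute_force_information(rates, occupancy):
    """Independent oracle: literal sum over states of p*r/rbar*log2(r/rbar)."""
    p = np.asarray(occupancy, float) / np.sum(occupancy)
    r = np.asarray(rates, float)
    rbar = float(np.sum(p * r))
    if rbar == 0:
        return 0.0
    total = 0.0
    for pi, ri in zip(p, r):
        if pi > 0 and ri > 0:
            total += pi * (ri / rbar) * np.log2(ri / rbar)
    return total


def test_site_information_matches_brute_force(rng):
    for _ in range(200):
        k = int(rng.integers(2, 9))
        rates = rng.uniform(0.0, 20.0, k)
        occ = rng.uniform(0.0, 5.0, k)
        occ[int(rng.integers(k))] = 0.0  # include a zero-occupancy state
        if occ.sum() == 0:
            occ[0] = 1.0
        ref = _brute_force_information(rates, occ)
        assert tuning.site_information(rates, occ) == pytest.approx(ref, abs=1e-12)


def test_site_information_uniform_is_zero(rng):
    for _ in range(20):
        occ = rng.uniform(0.1, 2.0, 6)
        rates = np.full(6, float(rng.uniform(0.5, 10.0)))
        assert tuning.site_information(rates, occ) == pytest.approx(0.0, abs=1e-12)


def test_site_information_one_hot_uniform_p():
    """One-hot rates with uniform occupancy over 4 states give exactly 2 bits."""
    rates = np.array([8.0, 0.0, 0.0, 0.0])
    occ = np.ones(4)
    assert tuning.site_information(rates, occ) == pytest.approx(2.0, abs=1e-12)


def test_site_information_validation():
    with pytest.raises(ValueError):
        tuning.site_information([1.0, 2.0], [1.0])
    with pytest.raises(ValueError):
        tuning.site_information([-1.0, 2.0], [1.0, 1.0])
    with pytest.raises(ValueError):
        tuning.site_information([1.0, 2.0], [0.0, 0.0])


def test_site_rates_and_occupancy():
    intervals = pd.DataFrame(
        dict(t_start=[0.0, 10.0, 20.0], t_end=[5.0, 12.0, 30.0],
             site=[0, 1, 0])
    )
    spikes = np.array([0.5, 1.5, 11.0, 25.0, 29.9, 40.0])
    rates, occ = tuning.site_rates_and_occupancy(spikes, intervals, 3)
    assert np.allclose(occ, [15.0, 2.0, 0.0])
    assert np.allclose(rates, [4.0 / 15.0, 0.5, 0.0])


def test_shuffle_significance_detects_tuning(rng):
    """A strongly modulated train is significant; shuffles destroy it."""
    duration = 600.0
    intervals = pd.DataFrame(
        dict(t_start=np.arange(0.0, duration, 10.0),
             t_end=np.arange(5.0, duration + 5.0, 10.0))
    )
    # random (not periodic) site schedule so circular shifts destroy alignment
    intervals["site"] = rng.integers(0, 4, len(intervals))
    # spikes only while at site 0
    on = intervals[intervals["site"] == 0]
    spikes = np.sort(np.concatenate(
        [rng.uniform(r.t_start, r.t_end, 40) for r in on.itertuples()]
    ))

    def info(st):
        r, o = tuning.site_rates_and_occupancy(st, intervals, 4)
        return tuning.site_information(r, o)

    res = tuning.shuffle_significance(spikes, info, duration, n_shuffles=100,
                                      rng=np.random.default_rng(7))
    assert res["significant"]
    assert res["p_value"] < 0.02
    assert res["observed"] > np.max(res["shuffles"]) * 0.99


def test_shuffle_significance_deterministic():
    spikes = np.sort(np.random.default_rng(3).uniform(0, 300.0, 500))
    fn = lambda st: float(np.mean(st))  # arbitrary statistic
    a = tuning.shuffle_significance(spikes, fn, 300.0, n_shuffles=50,
                                    rng=np.random.default_rng(11))
    b = tuning.shuffle_significance(spikes, fn, 300.0, n_shuffles=50,
                                    rng=np.random.default_rng(11))
    assert np.array_equal(a["shuffles"], b["shuffles"])


def test_smooth_map_preserves_constant_and_handles_holes():
    valid = np.ones((20, 20), bool)
    valid[5:8, 5:8] = False
    vals = np.full((20, 20), 3.5)
    out = tuning.smooth_map(vals, valid, 7)
    # constant field stays constant wherever defined, even near edges/holes
    assert np.allclose(out[~np.isnan(out)], 3.5, atol=1e-12)


def test_selectivity_and_preferred_site():
    assert tuning.selectivity_index(np.array([10.0, 2.0, 1.0, 0.0])) == pytest.approx(0.8)
    assert tuning.selectivity_index(np.array([5.0, 5.0, 1.0])) == pytest.approx(0.0)
    assert tuning.preferred_site(np.array([0.1, np.nan, 3.0, 1.0])) == 2


def test_preferred_match_stats_chance_level(rng):
    """Scramble chance for uniform 4-way assignments is ~25%."""
    n = 300
    a = rng.integers(0, 4, n)
    b = a.copy()
    res = tuning.preferred_match_stats(a, b, n_scrambles=500,
                                       rng=np.random.default_rng(5))
    assert res["observed"] == 1.0
    assert res["chance"] == pytest.approx(0.25, abs=0.01)
    assert res["p_value"] < 0.01


def test_rate_vs_gaze_angle_binning():
    alpha = np.array([2.0, 7.0, 12.0, 18.0, 95.0, np.nan])
    counts = np.array([4.0, 2.0, 1.0, 3.0, 9.0, 9.0])
    centers, rates, n = tuning.rate_vs_gaze_angle(counts, alpha, window=0.4)
    assert centers[0] == 5.0 and len(centers) == 9
    assert rates[0] == pytest.approx(3.0 / 0.4)
    assert n[1] == 2 and rates[1] == pytest.approx(2.0 / 0.4)
    assert n[2:].sum() == 0  # 95 deg and NaN excluded


def test_fit_gaussian_decay_recovers_parameters(rng):
    centers = np.arange(5.0, 90.0, 10.0)
    a, tau, b = 12.0, 45.0, 1.5
    y = a * np.exp(-(centers**2) / (2 * tau**2)) + b
    y_noisy = y + rng.normal(0, 0.05, len(y))
    n = np.full(len(centers), 400)
    ah, tauh, bh = tuning.fit_gaussian_decay(centers, y_noisy, n)
    assert tauh == pytest.approx(tau, rel=0.05)
    assert ah == pytest.approx(a, rel=0.05)
    assert bh == pytest.approx(b, abs=0.3)


def test_fit_gaussian_decay_too_few_bins():
    with pytest.raises(ValueError):
        tuning.fit_gaussian_decay(np.array([5.0, 15.0, 25.0]),
                                  np.array([1.0, 0.5, 0.2]))
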