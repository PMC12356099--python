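import numpy as np
import pandas as pd
import pytest

from gazecells import glm


def _simulate_design(rng, n=800, p=5):
    X = rng.uniform(0.0, 1.0, size=(n, p))
    beta0 = 0.3
    beta = np.array([1.2, -0.8, 0.0, 0.5, 0.0])[:p]
    mu = np.exp(beta0 + X @ beta)
    y = rng.poisson(mu).astype(float)
    return X, y, beta0, beta


def test_lasso_lambda_zero_matches_poisson_oracle(rng):
    """FISTA with lambda=0 equals the unpenalized statsmodels Poisson GLM."""
    X, y, _, _ = _simulate_design(rng)
    fit = glm.fit_poisson_lasso(X, y, lam=0.0, max_iter=20000, tol=1e-12)
    ref_params = glm.fit_poisson_glm_reference(X, y)
    assert fit.converged
    assert fit.intercept == pytest.approx(ref_params[0], abs=1e-5)
    assert np.allclose(fit.coef, ref_params[1:], atol=1e-5)


def test_lasso_recovers_signs_and_shrinks(rng):
    X, y, beta0, beta = _simulate_design(rng, n=4000)
    fit = glm.fit_poisson_lasso(X, y, lam=0.01)
    assert fit.converged
    # active coefficients keep their sign and approximate magnitude
    assert fit.coef[0] > 0.8 and fit.coef[1] < -0.4 and fit.coef[3] > 0.2
    # lasso shrinks the l1 norm relative to the unpenalized solution
    free = glm.fit_poisson_lasso(X, y, lam=0.0)
    assert np.abs(fit.coef).sum() < np.abs(free.coef).sum()


def test_lasso_strong_penalty_zeroes_everything(rng):
    X, y, _, _ = _simulate_design(rng)
    fit = glm.fit_poisson_lasso(X, y, lam=50.0)
    assert np.allclose(fit.coef, 0.0)
    # the intercept alone reproduces the mean rate
    assert np.exp(fit.intercept) == pytest.approx(y.mean(), rel=1e-3)


def test_gaussian_basis_conventions():
    alpha = np.array([0.0, 45.0, 90.0])
    full = glm.gaussian_basis(alpha, tau=45.0)
    half = glm.gaussian_basis(alpha, tau=45.0, half_exponent=True)
    assert np.allclose(full, np.exp(-(alpha**2) / (2 * 45.0**2)))
    assert np.allclose(half, np.exp(-(alpha**2) / (45.0**2)))
    assert full[0] == 1.0 and half[0] == 1.0
    assert np.all(half <= full)


def test_normalized_difference():
    assert glm.normalized_difference(3.0, 1.0) == pytest.approx(0.5)
    assert glm.normalized_difference(1.0, 3.0) == pytest.approx(-0.5)
    assert glm.normalized_difference(2.0, 0.0) == pytest.approx(1.0)
    assert np.isnan(glm.normalized_difference(0.0, 0.0))
    # antisymmetric under swapping contra and ipsi
    assert glm.normalized_difference(0.7, 0.2) == pytest.approx(
        -glm.normalized_difference(0.2, 0.7)
    )


def test_poisson_deviance():
    y = np.array([0.0, 2.0, 5.0])
    assert glm.poisson_deviance(y, y + 1e-300 * (y == 0)) == pytest.approx(0.0, abs=1e-9)
    mu = np.array([1.0, 1.0, 1.0])
    with np.errstate(divide="ignore", invalid="ignore"):
        ref = 2 * np.sum(np.where(y > 0, y * np.log(y / mu), 0.0) - (y - mu))
    assert glm.poisson_deviance(y, mu) == pytest.approx(ref)
    with pytest.raises(ValueError):
        glm.poisson_deviance(y, np.array([1.0, -1.0, 1.0]))


def test_predicted_means_roundtrip(rng):
    X, y, _, _ = _simulate_design(rng, n=500)
    fit = glm.fit_poisson_lasso(X, y, lam=0.0)
    mu = glm.predicted_means(X, fit)
    assert np.all(mu > 0)
    # at the optimum the mean residual is ~0 (score equation for intercept)
    assert np.mean(y - mu) == pytest.approx(0.0, abs=1e-6)


def test_saccade_inclusion_mask():
    saccades = pd.DataFrame(
        dict(t_start=[0.0, 1.0, 2.0, 3.0, 4.0],
             t_end=[0.08, 1.08, 2.08, 3.08, 4.08],
             eligible=[True, True, False, True, True])
    )
    alpha = np.full((5, 2, 5), 50.0)
    alpha[0, 1, 1] = 5.0   # lands at a site
    alpha[1, 0, 2] = 10.0  # lands at a site
    alpha[2, 1, 1] = 5.0   # lands but ineligible
    alpha[3, 1, 3] = np.nan
    alpha[4, 0, 4] = 8.0   # lands but too close to a dash
    dashes = pd.DataFrame(dict(t_start=[4.3], t_end=[4.9]))
    mask = glm.saccade_inclusion_mask(saccades, alpha, dashes, contra_eye=1)
    assert mask.tolist() == [True, True, False, False, False]


def test_build_gaze_design_layout(arena, rng):
    n = 40
    saccades = pd.DataFrame(
        dict(t_start=np.arange(n, dtype=float),
             t_end=np.arange(n) + 0.08,
             t_peak=np.arange(n) + 0.04)
    )
    alpha = rng.uniform(0.0, 90.0, size=(n, 2, arena.n_sites))
    spikes = np.sort(rng.uniform(0.0, n, 300))
    X, y, names, kept = glm.build_gaze_design(
        spikes, saccades, alpha, arena, contra_eye=1, tau=45.0
    )
    assert X.shape == (n, 8) and len(y) == n and len(kept) == n
    assert names[:4] == [f"contra_site{s}" for s in arena.outer_site_indices]
    assert names[4:] == [f"ipsi_site{s}" for s in arena.outer_site_indices]
    # first contra column is the basis of eye-1 angles at the first outer site
    s0 = arena.outer_site_indices[0]
    assert np.allclose(X[:, 0], glm.gaussian_basis(alpha[:, 1, s0], 45.0))
    # counts match a manual window count for one saccade
    tp = saccades["t_peak"].iloc[3]
    manual = np.count_nonzero((spikes >= tp - 0.1) & (spikes < tp + 0.3))
    assert y[3] == manual


def test_design_drops_nonfinite_rows(arena, rng):
    saccades = pd.DataFrame(
        dict(t_start=[0.0, 1.0], t_end=[0.08, 1.08], t_peak=[0.04, 1.04])
    )
    alpha = rng.uniform(0, 60, size=(2, 2, arena.n_sites))
    alpha[1, 0, arena.outer_site_indices[0]] = np.nan
    X, y, names, kept = glm.build_gaze_design(
        np.array([0.1]), saccades, alpha, arena, contra_eye=0
    )
    assert kept.tolist() == [0]
    assert X.shape == (1, 8)
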