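"""Sampler correctness: oracle agreement, recovery, simplex invariants, pooling."""

import numpy as np
import pytest

from lifecourse.model import (
    PosteriorDraws,
    SamplerConfig,
    effective_sample_size,
    fit_single,
    pool_posteriors,
    summarize,
)


def _simulate(n, beta0, delta, w, sigma, seed):
    rng = np.random.default_rng(seed)
    c = rng.binomial(1, 0.45, (n, 3)).sum(axis=1)
    a = rng.binomial(1, 0.35, (n, 3)).sum(axis=1)
    y = beta0 + delta * (w * c + (1 - w) * a) + rng.normal(0, sigma, n)
    return y, c.astype(float), a.astype(float)


def _flat_prior_posterior(y, z):
    """Independent oracle: closed-form Bayesian linear regression under the
    (effectively flat) reference prior -- marginal t posterior centered at OLS."""
    X = np.column_stack([np.ones_like(z), z])
    XtX = X.T @ X
    bhat = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ bhat
    nu = y.size - 2
    s2 = resid @ resid / nu
    cov = s2 * np.linalg.inv(XtX) * nu / (nu - 2)
    return bhat, np.sqrt(np.diag(cov))


class TestConjugateOracle:
    """With w fixed at truth the sampler must match the closed form."""

    def test_posterior_mean_and_sd(self):
        y, c, a = _simulate(2000, 0.5, 1.0, 0.8, 1.0, seed=42)
        z = 0.8 * c + 0.2 * a
        mean_o, sd_o = _flat_prior_posterior(y, z)
        d = fit_single(y, c, a, SamplerConfig(draws=10_000, warmup=1000, seed=7, fix_w=0.8))
        assert abs(d.beta0.mean() - mean_o[0]) < 0.02
        assert abs(d.delta.mean() - mean_o[1]) < 0.02
        assert abs(d.beta0.std() - sd_o[0]) < 0.02
        assert abs(d.delta.std() - sd_o[1]) < 0.02
        assert (d.w_childhood == 0.8).all()


def test_parameter_recovery_single_replicate():
    y, c, a = _simulate(2000, 0.0, 1.0, 0.8, 1.0, seed=1)
    d = fit_single(y, c, a, SamplerConfig(seed=2))
    assert abs(d.delta.mean() - 1.0) < 0.15
    assert abs(d.w_childhood.mean() - 0.8) < 0.12


def test_null_posterior_probability_centered():
    """Under delta = 0 the PP of a single dataset is close to uniform, so the
    calibration check averages PP over repeated simulations."""
    pps = []
    for s in range(12):
        y, c, a = _simulate(2000, 0.0, 0.0, 0.8, 1.0, seed=1000 + s)
        d = fit_single(y, c, a, SamplerConfig(draws=600, warmup=600, seed=s))
        pps.append((d.delta > 0).mean())
    assert 0.3 <= np.mean(pps) <= 0.7


def test_simplex_constraint_and_sigma_positive():
    y, c, a = _simulate(500, 0.0, 0.5, 0.3, 1.0, seed=5)
    d = fit_single(y, c, a, SamplerConfig(seed=6))
    assert ((d.w_childhood >= 0) & (d.w_childhood <= 1)).all()
    assert (d.sigma > 0).all()


def test_child_adult_swap_symmetry():
    """Swapping the period columns maps the weight posterior to its mirror."""
    y, c, a = _simulate(2000, 0.0, 1.0, 0.75, 1.0, seed=8)
    d1 = fit_single(y, c, a, SamplerConfig(draws=4000, seed=9))
    d2 = fit_single(y, a, c, SamplerConfig(draws=4000, seed=9))
    assert abs(d1.w_childhood.mean() - (1 - d2.w_childhood.mean())) < 0.03
    assert abs(d1.delta.mean() - d2.delta.mean()) < 0.05


def test_sampler_reproducible_given_seed():
    y, c, a = _simulate(300, 0.0, 1.0, 0.5, 1.0, seed=10)
    d1 = fit_single(y, c, a, SamplerConfig(draws=200, warmup=200, seed=11))
    d2 = fit_single(y, c, a, SamplerConfig(draws=200, warmup=200, seed=11))
    np.testing.assert_array_equal(d1.delta, d2.delta)
    np.testing.assert_array_equal(d1.w_childhood, d2.w_childhood)


def test_diagnostics_recorded():
    y, c, a = _simulate(500, 0.0, 1.0, 0.5, 1.0, seed=12)
    d = fit_single(y, c, a, SamplerConfig(draws=500, warmup=500, seed=13))
    assert set(d.diagnostics["ess"]) == {"beta0", "delta", "w_childhood", "sigma"}
    assert 0 <= d.diagnostics["accept_rate_w"] <= 1


def _draws(vals, rid=0):
    v = np.asarray(vals, float)
    return PosteriorDraws(replicate_id=rid, beta0=np.zeros_like(v), delta=v,
                          w_childhood=np.full_like(v, 0.5), sigma=np.ones_like(v))


class TestPoolingAndSummaries:
    def test_pool_keeps_equal_draws_per_replicate(self):
        pooled = pool_posteriors([_draws(np.arange(10), 0), _draws(np.arange(12), 1)])
        assert pooled.draws_per_replicate == 10
        assert pooled.delta.size == 20
        assert pooled.n_replicates == 2

    def test_pool_empty_rejected(self):
        with pytest.raises(ValueError, match="no posterior"):
            pool_posteriors([])

    def test_pp_is_fraction_of_positive_draws(self):
        assert summarize(pool_posteriors([_draws([-1, 2, 3, 4])])).pp_delta_gt0 == 0.75
        assert summarize(pool_posteriors([_draws([1, 2, 3, 4])])).pp_delta_gt0 == 1.0

    def test_degenerate_weight_draws_collapse_cri(self):
        fit = summarize(pool_posteriors([_draws([1.0, 1.0, 1.0, 1.0])]))
        assert fit.w_childhood_cri == (0.5, 0.5)
        assert fit.w_adulthood_cri == (0.5, 0.5)

    def test_reported_weights_sum_to_one(self):
        rng = np.random.default_rng(14)
        d = _draws(rng.normal(size=100))
        d.w_childhood = rng.uniform(size=100)
        fit = summarize(pool_posteriors([d]))
        assert fit.w_childhood_mean + fit.w_adulthood_mean == pytest.approx(1.0)

    def test_summary_order_invariant(self):
        rng = np.random.default_rng(15)
        v = rng.normal(size=200)
        f1 = summarize(pool_posteriors([_draws(v, 0), _draws(v[::-1], 1)]))
        f2 = summarize(pool_posteriors([_draws(v[::-1], 1), _draws(v, 0)]))
        assert f1.delta_mean == pytest.approx(f2.delta_mean)
        assert f1.delta_cri == pytest.approx(f2.delta_cri)


def test_effective_sample_size_sane():
    rng = np.random.default_rng(16)
    iid = rng.normal(size=2000)
    ess_iid = effective_sample_size(iid)
    assert ess_iid > 1000
    # strongly autocorrelated AR(1) should have much lower ESS
    ar = np.empty(2000)
    ar[0] = 0.0
    for i in range(1, 2000):
        ar[i] = 0.97 * ar[i - 1] + rng.normal()
    assert effective_sample_size(ar) < ess_iid / 5
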