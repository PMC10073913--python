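"""SMC-ABC engine: prior, proposal, distance, refinement, mode finding."""

import numpy as np
import pytest

from burstgtm import (
    ABCConfig,
    batch_summary_stats_gamma,
    burst_kinetics_posterior,
    distance,
    posterior_mode_kde,
    propose,
    run_abc_smc,
    sample_prior,
    theta_burst_kinetics,
)
from burstgtm.abc_smc import ABCError, in_prior_support

QUICK = ABCConfig(n_coarse=2000, n_keep=200, rounds=3)


def test_prior_support_and_shape(rng):
    th = sample_prior(rng, 100_000)
    assert np.all(in_prior_support(th))
    assert np.all((th[:, 0] > 0) & (th[:, 0] <= 5))
    assert np.all((th[:, 1] >= 0.1) & (th[:, 1] <= 10))
    assert np.all((th[:, 4] >= 0) & (th[:, 4] <= 50))
    # log-uniform rates: half the mass below 1
    frac = np.mean(th[:, 1] <= 1.0)
    assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / th.shape[0])


def test_prior_deterministic_under_seed():
    a = sample_prior(np.random.default_rng(3), 5)
    b = sample_prior(np.random.default_rng(3), 5)
    np.testing.assert_array_equal(a, b)


def test_proposal_median_and_support(rng):
    prev = np.array([1.0, 1.0, 1.0, 1.0, 25.0])
    props = propose(np.tile(prev, (100_000, 1)), 0.2, rng)
    assert np.all(in_prior_support(props))
    med = np.median(props, axis=0)
    np.testing.assert_allclose(med, prev, rtol=0.02)


def test_proposal_degenerate_sigma_is_identity(rng):
    prev = np.array([[2.0, 0.5, 1.0, 3.0, 10.0]])
    np.testing.assert_array_equal(propose(prev, 0.0, rng), prev)


def test_proposal_never_leaves_support(rng):
    # ancestor pinned at the r_syn boundary: redraws keep proposals inside
    prev = np.tile([1.0, 1.0, 1.0, 1.0, 49.9], (10_000, 1))
    props = propose(prev, 0.5, rng)
    assert np.all(props[:, 4] <= 50.0)


def test_distance_properties():
    s = np.array([8.0, 1.0, 8.0, 0.6, 2.2, 0.6])
    assert distance(s, s) == 0.0
    s2 = s.copy()
    s2[0] *= np.e
    assert distance(s, s2) == pytest.approx(1.0, rel=1e-12)
    s3 = s.copy()
    s3[3] = -0.1
    assert distance(s, s3) == np.inf


def test_abc_rejects_invalid_observed_stats():
    bad = np.array([8.0, 1.0, 8.0, -0.6, 2.2, 0.6])
    with pytest.raises(ABCError):
        run_abc_smc(bad, QUICK, seed=0)


def test_smc_refinement_and_determinism():
    theta_star = np.array([3.0, 0.5, 2.0, 0.5, 20.0])
    s_obs = batch_summary_stats_gamma(theta_star[None])[0]
    a = run_abc_smc(s_obs, QUICK, seed=11)
    b = run_abc_smc(s_obs, QUICK, seed=11)
    np.testing.assert_array_equal(a.thetas, b.thetas)  # byte-identical
    np.testing.assert_array_equal(a.rhos, b.rhos)
    eps = a.thresholds
    assert all(x > y for x, y in zip(eps, eps[1:]))  # strictly decreasing
    assert np.all(a.rhos <= eps[-1])
    assert np.all(in_prior_support(a.thetas))
    assert a.thetas.shape == (QUICK.n_keep, 5)


def test_mode_recovery_with_exact_statistics():
    # with exact observed statistics the (BF, BS) joint mode should sit
    # near the generating parameters even though single parameters and
    # the posterior mean are not identified
    for theta_star in ([3.0, 0.5, 2.0, 0.5, 20.0], [1.0, 1.0, 1.0, 1.0, 25.0]):
        theta_star = np.array(theta_star)
        s_obs = batch_summary_stats_gamma(theta_star[None])[0]
        ens = run_abc_smc(s_obs, ABCConfig(), seed=5)
        kin = burst_kinetics_posterior(ens)
        bf_t, bs_t = theta_burst_kinetics(theta_star)
        assert kin.bf_mode == pytest.approx(bf_t, rel=0.30)
        assert kin.bs_mode == pytest.approx(bs_t, rel=0.30)
        assert kin.bf_ci95[0] <= bf_t <= kin.bf_ci95[1]
        assert kin.bs_ci95[0] <= bs_t <= kin.bs_ci95[1]


def test_burst_kinetics_from_theta():
    assert theta_burst_kinetics([3, 0.5, 2, 0.5, 20]) == (
        pytest.approx(0.1),
        pytest.approx(80.0),
    )
    bf, bs = theta_burst_kinetics([5, 3, 1, 0.8, 30])
    assert bf == pytest.approx(1 / (5 / 3 + 1.25))
    assert bs == pytest.approx(37.5)
    bf_off, _ = theta_burst_kinetics([3, 0.5, 2, 0.5, 20], definition="off_only")
    assert bf_off == pytest.approx(1 / 6)


def test_kde_mode_constant_sample():
    assert posterior_mode_kde(np.full(500, 3.7)) == pytest.approx(3.7)


def test_kde_mode_lognormal(rng):
    mu, sigma = 0.0, 0.3
    x = rng.lognormal(mu, sigma, 10_000)
    true_mode = np.exp(mu - sigma**2)
    assert posterior_mode_kde(x) == pytest.approx(true_mode, rel=0.05)


def test_kde_mode_picks_dominant_component(rng):
    x = np.concatenate(
        [rng.normal(1.0, 0.1, 9000), rng.normal(5.0, 0.1, 1000)]
    )
    assert posterior_mode_kde(x) == pytest.approx(1.0, abs=0.3)


def test_config_validation():
    with pytest.raises(ValueError):
        ABCConfig(n_coarse=10, n_keep=100)
    with pytest.raises(ValueError):
        ABCConfig(rounds=0)
    with pytest.raises(ValueError):
        ABCConfig(bf_definition="bogus")
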