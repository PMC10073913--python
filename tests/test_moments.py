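"""Binomial-moment analytics: recursion, statistics, reconstruction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from burstgtm import (
    BinomialMomentVector,
    GTMParameters,
    batch_summary_stats_gamma,
    binomial_moments,
    central_moments,
    cv2,
    make_exponential,
    mean_expression,
    reconstruct_pmf,
    summary_stats_from_counts,
    summary_stats_from_moments,
)
from burstgtm.moments import (
    ConditioningError,
    DegenerateDistributionError,
    InsufficientMomentsError,
    stirling2,
)


def poisson_bvec(lam: float, order: int) -> BinomialMomentVector:
    b = np.array([lam**n / math.factorial(n) for n in range(1, order + 1)])
    return BinomialMomentVector(b=b)


def test_stirling_numbers():
    assert stirling2(3, 2) == 3
    assert stirling2(4, 2) == 7
    assert stirling2(5, 5) == 1
    assert stirling2(4, 0) == 0
    # row sums are the Bell numbers
    assert sum(stirling2(4, k) for k in range(5)) == 15


def test_mean_is_first_binomial_moment(bimodal_params, unimodal_params):
    for p in (bimodal_params, unimodal_params):
        b = binomial_moments(p, 4)
        assert b[1] == pytest.approx(mean_expression(p), rel=1e-10)
    assert mean_expression(bimodal_params) == pytest.approx(8.0, rel=1e-10)
    # second example: r_syn <tau_on> / (<tau_off> + <tau_on>)
    assert mean_expression(unimodal_params) == pytest.approx(
        30 * 1.25 / (5 / 3 + 1.25), rel=1e-10
    )


def test_cv2_equals_binomial_moment_identity(bimodal_params, unimodal_params, rng):
    thetas = [None, None] + list(np.column_stack([
        rng.uniform(0.2, 5, 8),
        10 ** rng.uniform(-1, 1, 8),
        rng.uniform(0.2, 5, 8),
        10 ** rng.uniform(-1, 1, 8),
        rng.uniform(1, 50, 8),
    ]))
    params = [bimodal_params, unimodal_params] + [
        GTMParameters.from_gamma(*t) for t in thetas[2:]
    ]
    for p in params:
        b = binomial_moments(p, 2)
        identity = (2 * b[2] + b[1] - b[1] ** 2) / b[1] ** 2
        assert cv2(p) == pytest.approx(identity, rel=1e-8)


def test_poisson_limit_of_cv2():
    # vanishing OFF time: CV^2 -> 1/mean
    p = GTMParameters(
        off_model=make_exponential(1e8),
        on_model=make_exponential(1.0),
        r_syn=20.0,
        r_deg=1.0,
    )
    assert cv2(p) == pytest.approx(1.0 / mean_expression(p), rel=1e-6)


def test_poisson_limit_of_binomial_moments():
    p = GTMParameters(
        off_model=make_exponential(1e6),
        on_model=make_exponential(1.0),
        r_syn=20.0,
        r_deg=1.0,
    )
    b = binomial_moments(p, 6)
    for n in range(1, 7):
        assert b[n] == pytest.approx(20.0**n / math.factorial(n), rel=1e-4)


def test_central_moments_of_poisson():
    b = poisson_bvec(4.0, 4)
    mu = central_moments(b, 4)
    assert mu[0] == pytest.approx(0.0, abs=1e-10)
    assert mu[1] == pytest.approx(4.0, rel=1e-10)
    assert mu[2] == pytest.approx(4.0, rel=1e-10)
    assert mu[3] == pytest.approx(3 * 16 + 4, rel=1e-10)
    with pytest.raises(InsufficientMomentsError):
        central_moments(b, 5)


def test_summary_stats_of_poisson_moments():
    s = summary_stats_from_moments(poisson_bvec(4.0, 4))
    assert s.fano == pytest.approx(1.0, rel=1e-10)
    assert s.skewness == pytest.approx(0.5, rel=1e-10)
    assert s.excess_kurtosis == pytest.approx(0.25, rel=1e-10)
    assert s.kurtosis == pytest.approx(3.25, rel=1e-10)
    assert 0 < s.bimodality <= 1


def test_stats_from_moments_equal_central_moment_definitions(bimodal_params):
    b = binomial_moments(bimodal_params, 4)
    s = summary_stats_from_moments(b)
    mu = central_moments(b, 4)
    assert s.noise_strength == pytest.approx(mu[1] / b[1] ** 2, rel=1e-10)
    assert s.fano == pytest.approx(mu[1] / b[1], rel=1e-10)
    assert s.skewness == pytest.approx(mu[2] / mu[1] ** 1.5, rel=1e-10)
    assert s.excess_kurtosis == pytest.approx(mu[3] / mu[1] ** 2 - 3, rel=1e-10)
    assert s.bimodality == pytest.approx(
        (s.skewness**2 + 1) / (mu[3] / mu[1] ** 2), rel=1e-10
    )


def test_stats_from_counts_hand_example():
    s = summary_stats_from_counts([0, 0, 4, 4])
    assert s.mean == pytest.approx(2.0)
    assert s.fano == pytest.approx(2.0)
    assert s.skewness == pytest.approx(0.0, abs=1e-12)


def test_stats_from_counts_poisson_sample(rng):
    x = rng.poisson(8.0, 100_000)
    s = summary_stats_from_counts(x)
    n = x.size
    assert abs(s.mean - 8.0) < 3 * np.sqrt(8.0 / n)
    assert s.fano == pytest.approx(1.0, abs=0.02)
    # moment-estimator sampling error for the shape statistics is wider
    # than sqrt(6/n)/sqrt(24/n) under a skewed parent; allow ~5 SE
    assert s.skewness == pytest.approx(8.0**-0.5, abs=0.04)
    assert s.excess_kurtosis == pytest.approx(0.125, abs=0.08)


def test_stats_degenerate_inputs():
    with pytest.raises(DegenerateDistributionError):
        summary_stats_from_counts([3, 3, 3, 3])
    with pytest.raises(ValueError):
        summary_stats_from_counts([1])


def test_reconstruct_poisson_pmf():
    pmf, err = reconstruct_pmf(poisson_bvec(2.0, 30), 10)
    assert pmf[0] == pytest.approx(np.exp(-2.0), abs=1e-8)
    assert pmf.sum() == pytest.approx(1.0, abs=0.02)
    assert np.all(err[: 11] < 1e-6)


def test_reconstruct_point_mass_at_zero():
    b = BinomialMomentVector(b=np.zeros(10))
    pmf, _ = reconstruct_pmf(b, 5)
    assert pmf[0] == pytest.approx(1.0)
    assert np.all(pmf[1:] == 0)


def test_reconstruct_detects_unconverged_order():
    with pytest.raises(ConditioningError):
        reconstruct_pmf(poisson_bvec(10.0, 20), 15)


def test_high_order_warns(bimodal_params):
    with pytest.warns(UserWarning):
        binomial_moments(bimodal_params, 14)


def test_moment_ratios_eventually_decrease(bimodal_params):
    b = binomial_moments(bimodal_params, 8)
    ratios = b.b[1:] / b.b[:-1]
    assert np.all(np.diff(ratios[2:]) < 0)
    assert np.all(b.b >= 0)


def test_batch_stats_agree_with_scalar_path(rng):
    from burstgtm import sample_prior

    th = sample_prior(rng, 30)
    batch = batch_summary_stats_gamma(th)
    for i in range(30):
        p = GTMParameters.from_gamma(*th[i])
        s = summary_stats_from_moments(binomial_moments(p, 4)).as_array()
        np.testing.assert_allclose(batch[i], s, rtol=1e-9)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    k_off=st.floats(0.1, 5),
    r_off=st.floats(0.1, 10),
    k_on=st.floats(0.1, 5),
    r_on=st.floats(0.1, 10),
    r_syn=st.floats(0.5, 50),
)
def test_moment_identities_hold_across_parameter_space(
    k_off, r_off, k_on, r_on, r_syn
):
    p = GTMParameters.from_gamma(k_off, r_off, k_on, r_on, r_syn)
    b = binomial_moments(p, 4)
    assert b[1] == pytest.approx(mean_expression(p), rel=1e-8)
    identity = (2 * b[2] + b[1] - b[1] ** 2) / b[1] ** 2
    assert cv2(p) == pytest.approx(identity, rel=1e-6)
    s = summary_stats_from_moments(b)
    assert 0 < s.bimodality <= 1
    assert s.fano > 0
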