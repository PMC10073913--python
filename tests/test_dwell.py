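"""Dwell-time distribution contract: pdf/survival/hazard/Laplace/sampling."""

import numpy as np
import pytest
from scipy import integrate, stats

from burstgtm import make_exponential, make_gamma, make_weibull
from burstgtm.dwell import DwellModel, Family, InvalidParameterError

MODELS = [
    make_gamma(3.0, 0.5),
    make_gamma(0.7, 2.0),  # shape < 1 is a valid continuous shape
    make_exponential(1.0),
    make_weibull(2.0, 1.0),
    make_weibull(0.8, 3.0),
]


@pytest.mark.parametrize("model", MODELS, ids=str)
def test_pdf_normalization_and_mean(model):
    total, _ = integrate.quad(model.pdf, 0, np.inf, limit=200)
    assert total == pytest.approx(1.0, abs=1e-6)
    m, _ = integrate.quad(lambda t: t * model.pdf(t), 0, np.inf, limit=200)
    assert m == pytest.approx(model.mean(), rel=1e-6)


@pytest.mark.parametrize(
    "model, s, expected",
    [
        (make_gamma(1.0, 2.0), 2.0, 0.5),
        (make_gamma(2.0, 0.5), 1.0, 1.0 / 9.0),
        (make_gamma(3.0, 0.5), 1.0, 1.0 / 27.0),
        (make_exponential(1.0), 1.0, 0.5),
    ],
)
def test_laplace_closed_forms(model, s, expected):
    assert model.laplace(s) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("model", MODELS, ids=str)
def test_laplace_is_one_at_zero_and_decreasing(model):
    assert model.laplace(0.0) == 1.0
    grid = [0.0, 0.3, 1.0, 3.0, 10.0]
    vals = [model.laplace(s) for s in grid]
    assert all(a > b for a, b in zip(vals, vals[1:]))
    assert all(0 < v <= 1 for v in vals)


def test_weibull_laplace_matches_quadrature():
    model = make_weibull(2.0, 1.0)
    ref, _ = integrate.quad(
        lambda t: np.exp(-t) * stats.weibull_min(c=2.0, scale=1.0).pdf(t),
        0,
        np.inf,
    )
    assert model.laplace(1.0) == pytest.approx(ref, rel=1e-8)


@pytest.mark.parametrize(
    "model, s, expected",
    [
        (make_gamma(2.0, 0.5), 0.0, 4.0),  # S~(0) = mean
        (make_exponential(1.0), 1.0, 0.5),
        (make_gamma(3.0, 0.5), 1.0, 26.0 / 27.0),
    ],
)
def test_survival_laplace(model, s, expected):
    assert model.survival_laplace(s) == pytest.approx(expected, rel=1e-12)


def test_survival_and_hazard_definitions():
    model = make_gamma(3.0, 0.5)
    ts = np.array([0.5, 2.0, 6.0, 15.0])
    np.testing.assert_allclose(model.survival(ts), 1 - model.cdf(ts), rtol=1e-12)
    np.testing.assert_allclose(
        model.hazard(ts), model.pdf(ts) / model.survival(ts), rtol=1e-12
    )


def test_exponential_hazard_constant_gamma_hazard_increasing():
    exp = make_exponential(2.0)
    ts = np.linspace(0.1, 10, 25)
    np.testing.assert_allclose(exp.hazard(ts), 2.0, rtol=1e-12)
    gam = make_gamma(3.0, 0.5)
    h = gam.hazard(ts)
    assert np.all(np.diff(h) > 0)


def test_gamma_shape_one_is_exponential():
    g = make_gamma(1.0, 1.7)
    e = make_exponential(1.7)
    ts = np.linspace(0.01, 8, 40)
    np.testing.assert_allclose(g.pdf(ts), e.pdf(ts), rtol=1e-12)
    for s in (0.0, 0.5, 2.0):
        assert g.laplace(s) == pytest.approx(e.laplace(s), abs=1e-12)
    assert g.mean() == pytest.approx(e.mean(), rel=1e-12)


@pytest.mark.parametrize("model", MODELS, ids=str)
def test_samples_match_cdf(model, rng):
    x = model.sample(100_000, rng)
    d = stats.kstest(x, model.cdf).statistic
    assert d < 0.01


def test_sample_moments(rng):
    g = make_gamma(3.0, 0.5)
    x = g.sample(1_000_000, rng)
    se = x.std() / np.sqrt(x.size)
    assert abs(x.mean() - 6.0) < 3 * se
    e = make_exponential(1.0)
    y = e.sample(1_000_000, rng)
    # variance of an exponential(1) is 1; SE of the sample variance
    se_var = np.sqrt((np.var((y - y.mean()) ** 2)) / y.size)
    assert abs(y.var() - 1.0) < 3 * se_var


def test_sampling_deterministic_under_seed():
    g = make_weibull(1.5, 2.0)
    a = g.sample(5, np.random.default_rng(123))
    b = g.sample(5, np.random.default_rng(123))
    np.testing.assert_array_equal(a, b)


@pytest.mark.parametrize("bad", [(0.0, 1.0), (-1.0, 1.0), (1.0, 0.0), (1.0, -2.0)])
def test_invalid_parameters_rejected(bad):
    with pytest.raises(InvalidParameterError):
        make_gamma(*bad)


def test_negative_laplace_argument_rejected():
    with pytest.raises(ValueError):
        make_gamma(2.0, 1.0).laplace(-0.1)


def test_serialization_round_trip():
    for model in MODELS:
        clone = DwellModel.from_dict(model.to_dict())
        assert clone.family == model.family
        assert clone.mean() == pytest.approx(model.mean(), rel=1e-12)
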