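"""Dwell-time distributions for promoter ON/OFF states.

The generalized telegraph model replaces the exponential state-holding
times of the classical two-state promoter with arbitrary dwell-time
distributions f_off(t) and f_on(t).  Multi-step promoter kinetics
("molecular memory") are conventionally summarized by a Gamma dwell
time whose shape parameter plays the role of an effective number of
rate-limiting steps; the exponential is the memoryless special case
(shape 1) and Weibull is provided as an alternative ageing family.

Everything downstream needs only a small functional surface from a
dwell model: pdf, CDF/survival, hazard, mean, a sampler, and the
Laplace transform f~(s) = ∫ e^{-st} f(t) dt through which the dwell
distribution enters the stationary binomial-moment recursion.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from functools import lru_cache

import mpmath
import numpy as np
from scipy import integrate, stats


class Family(str, enum.Enum):
    """Supported dwell-time distribution families."""

    GAMMA = "gamma"
    EXPONENTIAL = "exponential"
    WEIBULL = "weibull"


class InvalidParameterError(ValueError):
    """Raised for non-positive shape/rate/scale parameters."""


@lru_cache(maxsize=4096)
def _weibull_laplace(shape: float, scale: float, s: float) -> float:
    """Laplace transform of a Weibull pdf by adaptive quadrature.

    No elementary closed form exists; the integrand e^{-st} f(t) is
    smooth and rapidly decaying, so scipy's adaptive quadrature reaches
    relative error well below 1e-10.
    """
    dist = stats.weibull_min(c=shape, scale=scale)
    val, _ = integrate.quad(
        lambda t: math.exp(-s * t) * dist.pdf(t),
        0.0,
        np.inf,
        epsabs=1e-13,
        epsrel=1e-12,
        limit=200,
    )
    return val


@dataclass(frozen=True)
class DwellModel:
    """A dwell-time distribution for one promoter state.

    Parameters
    ----------
    family
        Distribution family (gamma, exponential, weibull).
    shape
        Dimensionless shape parameter k (ignored/fixed at 1 for
        exponential).  Continuous positive real; values in (0, 1] are
        valid even though integer k has a multi-step interpretation.
    rate_or_scale
        Rate r (1/time) for gamma/exponential, scale (time) for
        weibull.
    """

    family: Family
    shape: float
    rate_or_scale: float

    def __post_init__(self) -> None:
        if not (self.shape > 0):
            raise InvalidParameterError(f"shape must be > 0, got {self.shape}")
        if not (self.rate_or_scale > 0):
            raise InvalidParameterError(
                f"rate/scale must be > 0, got {self.rate_or_scale}"
            )

    # -- scipy frozen distribution backing pdf/cdf/rvs ------------------
    @property
    def _dist(self):
        if self.family is Family.WEIBULL:
            return stats.weibull_min(c=self.shape, scale=self.rate_or_scale)
        # gamma and exponential share the gamma backing (exponential has
        # shape pinned to 1 by the constructor)
        return stats.gamma(a=self.shape, scale=1.0 / self.rate_or_scale)

    def pdf(self, t):
        return self._dist.pdf(t)

    def cdf(self, t):
        return self._dist.cdf(t)

    def survival(self, t):
        """S(t) = 1 - CDF(t), probability the state outlives t."""
        return self._dist.sf(t)

    def hazard(self, t):
        """Instantaneous switching propensity f(t)/S(t).

        Constant (= rate) iff the dwell time is exponential.
        """
        t = np.asarray(t, dtype=float)
        sf = self._dist.sf(t)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(sf > 0, self._dist.pdf(t) / sf, np.inf)

    def mean(self) -> float:
        if self.family is Family.WEIBULL:
            return self.rate_or_scale * math.gamma(1.0 + 1.0 / self.shape)
        return self.shape / self.rate_or_scale

    def var(self) -> float:
        return float(self._dist.var())

    def laplace(self, s: float) -> float:
        """Laplace transform f~(s) of the pdf, for s >= 0.

        Closed form (r/(r+s))^k for gamma/exponential; adaptive
        quadrature (cached) for weibull.
        """
        if s < 0:
            raise ValueError(f"Laplace transform requires s >= 0, got {s}")
        if s == 0:
            return 1.0
        if self.family is Family.WEIBULL:
            return _weibull_laplace(self.shape, self.rate_or_scale, float(s))
        r = self.rate_or_scale
        return (r / (r + s)) ** self.shape

    def laplace_mp(self, s) -> mpmath.mpf:
        """Arbitrary-precision Laplace transform (for the high-order
        moment recursion, which is an ill-conditioned alternating sum in
        double precision)."""
        s = mpmath.mpf(s)
        if s < 0:
            raise ValueError("Laplace transform requires s >= 0")
        if s == 0:
            return mpmath.mpf(1)
        if self.family is Family.WEIBULL:
            k = mpmath.mpf(self.shape)
            lam = mpmath.mpf(self.rate_or_scale)
            f = lambda t: mpmath.e ** (-s * t) * (k / lam) * (t / lam) ** (
                k - 1
            ) * mpmath.e ** (-((t / lam) ** k))
            return mpmath.quad(f, [0, mpmath.inf])
        r = mpmath.mpf(self.rate_or_scale)
        return (r / (r + s)) ** mpmath.mpf(self.shape)

    def survival_laplace(self, s: float) -> float:
        """S~(s) = (1 - f~(s))/s, with the continuous limit S~(0) = mean."""
        if s < 0:
            raise ValueError(f"requires s >= 0, got {s}")
        if s == 0:
            return self.mean()
        return (1.0 - self.laplace(s)) / s

    def survival_laplace_mp(self, s) -> mpmath.mpf:
        s = mpmath.mpf(s)
        if s == 0:
            if self.family is Family.WEIBULL:
                lam = mpmath.mpf(self.rate_or_scale)
                return lam * mpmath.gamma(1 + 1 / mpmath.mpf(self.shape))
            return mpmath.mpf(self.shape) / mpmath.mpf(self.rate_or_scale)
        return (1 - self.laplace_mp(s)) / s

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n i.i.d. dwell times."""
        if n < 1:
            raise ValueError("n must be >= 1")
        if self.family is Family.WEIBULL:
            return self.rate_or_scale * rng.weibull(self.shape, size=n)
        return rng.gamma(self.shape, 1.0 / self.rate_or_scale, size=n)

    # -- (de)serialization ----------------------------------------------
    def to_dict(self) -> dict:
        return {
            "family": self.family.value,
            "shape": self.shape,
            "rate": self.rate_or_scale,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DwellModel":
        fam = Family(d["family"])
        if fam is Family.EXPONENTIAL:
            return make_exponential(float(d["rate"]))
        shape = float(d["shape"])
        if fam is Family.GAMMA:
            return make_gamma(shape, float(d["rate"]))
        return make_weibull(shape, float(d.get("scale", d.get("rate"))))


def make_gamma(shape: float, rate: float) -> DwellModel:
    """Gamma dwell time: pdf r^k t^{k-1} e^{-rt}/Γ(k), mean k/r."""
    return DwellModel(Family.GAMMA, float(shape), float(rate))


def make_exponential(rate: float) -> DwellModel:
    """Exponential (memoryless) dwell time, mean 1/rate."""
    return DwellModel(Family.EXPONENTIAL, 1.0, float(rate))


def make_weibull(shape: float, scale: float) -> DwellModel:
    """Weibull dwell time in the shape-scale parameterization."""
    return DwellModel(Family.WEIBULL, float(shape), float(scale))
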