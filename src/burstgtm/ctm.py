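"""Classical telegraph model (CTM): closed forms, pmf, and ML fitting.

With exponential dwell times the GTM collapses to the classical
two-state promoter with activation rate r_off = 1/<tau_off> and
inactivation rate r_on = 1/<tau_on>.  Its stationary copy-number law is
the Beta-mixed Poisson ("beta-Poisson"): with a = r_off/r_deg,
c = r_on/r_deg and lam = r_syn/r_deg,

    M | p ~ Poisson(lam * p),   p ~ Beta(a, c)

whose binomial moments are the Pochhammer ratio

    b_n = lam^n / n! * (a)_n / (a + c)_n.

Note the *activation* rate a sits in the numerator Pochhammer — that
assignment is pinned by requiring b_1 to equal the stationary mean
r_syn <tau_on> / (r_deg (<tau_off> + <tau_on>)), and is verified in the
test suite against the general dwell-time recursion with exponential
dwells (the two must agree identically).

The module also provides multi-start maximum-likelihood fitting of the
CTM to count vectors, which is the genome-wide baseline the GTM
inference is compared against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import mpmath
import numpy as np
from scipy import optimize, special

from .model import GTMParameters
from .moments import BinomialMomentVector


@dataclass(frozen=True)
class CTMParameters:
    """Classical telegraph parameters.

    ``r_off`` is the OFF->ON activation rate (1/<tau_off>) and ``r_on``
    the ON->OFF inactivation rate (1/<tau_on>); the names follow the
    dwell state being left.
    """

    r_off: float
    r_on: float
    r_syn: float
    r_deg: float = 1.0

    def __post_init__(self) -> None:
        if not (self.r_off > 0 and self.r_on > 0):
            raise ValueError("switching rates must be > 0")
        if self.r_syn < 0 or not (self.r_deg > 0):
            raise ValueError("invalid r_syn or r_deg")

    def to_gtm(self) -> GTMParameters:
        return GTMParameters.from_exponential(
            self.r_off, self.r_on, self.r_syn, self.r_deg
        )

    def mean(self) -> float:
        return (
            self.r_syn
            * self.r_off
            / (self.r_deg * (self.r_off + self.r_on))
        )


def ctm_binomial_moments(params: CTMParameters, N: int) -> BinomialMomentVector:
    """b_1..b_N via the Pochhammer-ratio closed form."""
    if N < 1:
        raise ValueError("N must be >= 1")
    a = params.r_off / params.r_deg
    c = params.r_on / params.r_deg
    lam = params.r_syn / params.r_deg
    b = np.empty(N)
    val = 1.0
    for n in range(1, N + 1):
        # b_n = b_{n-1} * lam/n * (a+n-1)/(a+c+n-1)
        val *= lam / n * (a + n - 1) / (a + c + n - 1)
        b[n - 1] = val
    return BinomialMomentVector(b=b, params=params.to_gtm())


def ctm_pmf(params: CTMParameters, n_max: int) -> np.ndarray:
    """Stationary pmf P(0..n_max) of the CTM.

    Evaluated through the Kummer form

        P(n) = e^{-lam} lam^n/n! (a)_n/(a+c)_n 1F1(c; a+c+n; lam)

    whose confluent-hypergeometric series has all-positive terms (no
    cancellation).  Log-space prefactors avoid overflow; entries where
    scipy's 1F1 overflows fall back to mpmath.
    """
    if n_max < 0:
        raise ValueError("n_max must be >= 0")
    a = params.r_off / params.r_deg
    c = params.r_on / params.r_deg
    lam = params.r_syn / params.r_deg
    n = np.arange(n_max + 1)
    if lam == 0:
        return (n == 0).astype(float)

    log_pref = (
        -lam
        + n * math.log(lam)
        - special.gammaln(n + 1)
        + special.gammaln(a + n)
        - special.gammaln(a)
        - special.gammaln(a + c + n)
        + special.gammaln(a + c)
    )
    with np.errstate(over="ignore", invalid="ignore"):
        hyp = special.hyp1f1(c, a + c + n, lam)
        pmf = np.exp(log_pref) * hyp
    bad = ~np.isfinite(pmf)
    if bad.any():
        for i in np.nonzero(bad)[0]:
            with mpmath.workdps(40):
                val = mpmath.exp(log_pref[i]) * mpmath.hyp1f1(
                    c, a + c + int(n[i]), lam
                )
            pmf[i] = float(val)
    return pmf


def ctm_burst_kinetics(params: CTMParameters) -> tuple[float, float]:
    """(BF, BS) under the CTM: BF = 1/(1/r_off + 1/r_on), BS = r_syn/r_on."""
    bf = 1.0 / (1.0 / params.r_off + 1.0 / params.r_on)
    return bf, params.r_syn / params.r_on


@dataclass
class CTMFit:
    """Result of a maximum-likelihood CTM fit (r_deg fixed at 1)."""

    params: Optional[CTMParameters]
    log_likelihood: float
    success: bool
    message: str = ""

    def burst_kinetics(self) -> tuple[float, float]:
        if not self.success:
            raise RuntimeError("fit failed; no kinetics available")
        return ctm_burst_kinetics(self.params)


_RATE_BOUNDS = (1e-3, 1e3)


def _neg_log_lik(x: np.ndarray, values: np.ndarray, weights: np.ndarray) -> float:
    r_off, r_on, r_syn = np.exp(x)
    try:
        p = ctm_pmf(CTMParameters(r_off, r_on, r_syn), int(values[-1]))
    except (ValueError, OverflowError):
        return 1e300
    pv = p[values]
    if not np.all(np.isfinite(pv)) or np.any(pv <= 0):
        return 1e300
    return -float(np.dot(weights, np.log(pv)))


def _moment_matched_start(counts: np.ndarray) -> Optional[np.ndarray]:
    """Closed-form moment inversion (factorial-moment ratios) used as a
    warm start; returns None when the sample moments are incompatible
    with a telegraph law."""
    x = counts.astype(float)
    m1 = x.mean()
    m2 = np.mean(x * (x - 1))
    m3 = np.mean(x * (x - 1) * (x - 2))
    if m1 <= 0 or m2 <= 0 or m3 <= 0:
        return None
    r1, r2, r3 = m1, m2 / m1, m3 / m2
    denom = r1 - 2 * r2 + r3
    denom2 = r1 * r2 - 2 * r1 * r3 + r2 * r3
    if denom == 0 or denom2 == 0:
        return None
    lam = (2 * r1 * r3 - r1 * r2 - r2 * r3) / denom
    a = 2 * r1 * (r3 - r2) / denom2
    c = a * (lam - r1) / r1 if r1 > 0 else None
    if lam is None or a is None or c is None:
        return None
    if not (lam > 0 and a > 0 and c > 0):
        return None
    return np.log([a, c, lam])


def ctm_mle_fit(
    counts: Sequence[int],
    n_starts: int = 5,
    rng: Optional[np.random.Generator] = None,
) -> CTMFit:
    """Fit the CTM to a count vector by maximum likelihood.

    Multi-start L-BFGS-B in log-parameter space: one moment-matched
    start plus random starts with rates log-uniform in [1e-3, 1e3] and
    r_syn log-uniform up to 10x the max count.  r_deg is fixed at 1
    (time in mRNA lifetimes), which is the only identifiable scaling
    from snapshot data.
    """
    rng = np.random.default_rng() if rng is None else rng
    counts = np.asarray(counts, dtype=np.int64)
    if counts.size < 2 or counts.min() < 0:
        return CTMFit(None, -np.inf, False, "need >= 2 non-negative counts")
    if counts.max() == counts.min():
        return CTMFit(None, -np.inf, False, "degenerate (constant) counts")

    values, weights = np.unique(counts, return_counts=True)
    syn_hi = max(10.0 * counts.max(), 10.0)
    lo = np.log([_RATE_BOUNDS[0], _RATE_BOUNDS[0], 1e-3])
    hi = np.log([_RATE_BOUNDS[1], _RATE_BOUNDS[1], syn_hi])
    bounds = list(zip(lo, hi))

    starts = []
    mm = _moment_matched_start(counts)
    if mm is not None:
        starts.append(np.clip(mm, lo, hi))
    while len(starts) < n_starts:
        starts.append(lo + rng.random(3) * (hi - lo))

    best = None
    for x0 in starts:
        res = optimize.minimize(
            _neg_log_lik,
            x0,
            args=(values, weights),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 200, "ftol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e299:
        return CTMFit(None, -np.inf, False, "all starts failed")
    r_off, r_on, r_syn = np.exp(best.x)
    return CTMFit(
        params=CTMParameters(r_off, r_on, r_syn, 1.0),
        log_likelihood=-float(best.fun),
        success=True,
        message=str(best.message),
    )
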