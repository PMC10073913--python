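"""Stationary binomial-moment analytics of the generalized telegraph model.

The stationary copy-number law P(n) of the GTM is characterized through
its binomial moments b_n = sum_{m>=n} C(m,n) P(m), which satisfy a
double recursion driven entirely by the Laplace transforms of the dwell
distributions evaluated at multiples of the degradation rate:

    b_n = (1/n!) (r_syn/r_deg)^n
          * sum_{i=0}^{n-1} C(n-1,i) C_i
            sum_{j=0}^{n-1-i} C(n-1-i,j) (-1)^{n-1-i-j}
                S~_on((n-1-j) r_deg)

    C_n = f~_off(n r_deg) / (1 - f~_off(n r_deg) f~_on(n r_deg))
          * sum_{i=0}^{n-1} C(n,i) C_i
            sum_{j=0}^{n-i} C(n-i,j) (-1)^{n-i-j} f~_on((n-j) r_deg)

with C_0 = 1/(<tau_off> + <tau_on>) — the burst frequency — and
S~_on(s) = (1 - f~_on(s))/s, S~_on(0) = <tau_on>.

From b_1..b_4 the six snapshot summary statistics (mean, noise
strength, Fano factor, skewness, kurtosis, bimodality coefficient)
follow in closed form; higher orders let P(n) itself be reconstructed
by the alternating inversion P(n) = sum_m (-1)^{m-n} C(m,n) b_m.

Both the recursion and the inversion are alternating binomial sums, so
beyond order ~8 they are evaluated in arbitrary precision (mpmath);
the order-4 vectors used during inference are safe in double precision.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import mpmath
import numpy as np

from .model import GTMParameters

#: order beyond which the recursion switches to arbitrary precision
DOUBLE_PRECISION_MAX_ORDER = 8

STAT_NAMES = (
    "mean",
    "noise_strength",
    "fano",
    "skewness",
    "kurtosis",
    "bimodality",
)


class DegenerateDistributionError(ValueError):
    """Summary statistics undefined (zero mean or zero variance)."""


class InsufficientMomentsError(ValueError):
    """More binomial moments are needed than were computed."""


class ConditioningError(ArithmeticError):
    """The truncated alternating sum has not converged at this order."""


@lru_cache(maxsize=None)
def stirling2(n: int, k: int) -> int:
    """Stirling number of the second kind S(n, k)."""
    if k < 0 or k > n:
        return 0
    if n == 0 and k == 0:
        return 1
    if n == 0 or k == 0:
        return 0
    return k * stirling2(n - 1, k) + stirling2(n - 1, k - 1)


@dataclass(frozen=True)
class BinomialMomentVector:
    """b_1..b_N of the stationary copy-number distribution.

    ``b[i]`` holds b_{i+1}; b_0 = 1 is implicit.  ``exact`` carries the
    mpmath values when the vector was computed in extended precision.
    """

    b: np.ndarray
    params: Optional[GTMParameters] = None
    exact: Optional[tuple] = None

    @property
    def order(self) -> int:
        return len(self.b)

    def __getitem__(self, n: int) -> float:
        """b_n with the natural 1-based index (b_0 == 1)."""
        if n == 0:
            return 1.0
        return float(self.b[n - 1])


def _recursion(laplace_off, laplace_on, surv_on, c0, r_ratio, r_deg, N, fac, binom):
    """Shared body of the moment recursion; the callables and the
    arithmetic (float or mpmath) are supplied by the caller."""
    C = [c0]
    for n in range(1, N):
        acc = 0
        for i in range(n):
            inner = 0
            for j in range(n - i + 1):
                inner += (
                    binom(n - i, j)
                    * (-1) ** (n - i - j)
                    * laplace_on((n - j) * r_deg)
                )
            acc += binom(n, i) * C[i] * inner
        lo = laplace_off(n * r_deg)
        C.append(lo / (1 - lo * laplace_on(n * r_deg)) * acc)

    b = []
    for n in range(1, N + 1):
        acc = 0
        for i in range(n):
            inner = 0
            for j in range(n - i):
                inner += (
                    binom(n - 1 - i, j)
                    * (-1) ** (n - 1 - i - j)
                    * surv_on((n - 1 - j) * r_deg)
                )
            acc += binom(n - 1, i) * C[i] * inner
        b.append(r_ratio**n / fac(n) * acc)
    return C, b


def binomial_moments(
    params: GTMParameters,
    N: int,
    precision: Optional[int] = None,
) -> BinomialMomentVector:
    """Compute b_1..b_N for the stationary copy-number law.

    ``precision`` (decimal digits) forces the mpmath path; by default
    orders above DOUBLE_PRECISION_MAX_ORDER use extended precision
    automatically, with digits scaled to the worst intermediate term.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    rd = params.r_deg
    use_mp = precision is not None or N > DOUBLE_PRECISION_MAX_ORDER
    if N > 12 and precision is None:
        warnings.warn(
            "binomial moments beyond order 12: alternating sums are "
            "evaluated in extended precision",
            stacklevel=2,
        )

    if not use_mp:
        c0 = params.burst_frequency()
        _, b = _recursion(
            lambda s: params.off_model.laplace(s),
            lambda s: params.on_model.laplace(s),
            lambda s: params.on_model.survival_laplace(s),
            c0,
            params.r_syn / rd,
            rd,
            N,
            math.factorial,
            math.comb,
        )
        return BinomialMomentVector(b=np.array(b, dtype=float), params=params)

    # mpmath path: digits sized to the largest alternating term,
    # roughly (r_syn/r_deg)^n/n! against binomial weights 2^N.
    lam = max(params.r_syn / rd, 1.0)
    peak = lam * math.log10(math.e)  # log10 max_n lam^n/n! <= lam*log10(e)
    digits = precision if precision is not None else int(40 + 0.35 * N + peak)
    with mpmath.workdps(digits):
        c0 = 1 / (
            params.off_model.survival_laplace_mp(0)
            + params.on_model.survival_laplace_mp(0)
        )
        loff = lru_cache(maxsize=None)(params.off_model.laplace_mp)
        lon = lru_cache(maxsize=None)(params.on_model.laplace_mp)
        son = lru_cache(maxsize=None)(params.on_model.survival_laplace_mp)
        # exact integer combinatorics: Python ints mix cheaply with mpf
        _, b = _recursion(
            loff,
            lon,
            son,
            c0,
            mpmath.mpf(params.r_syn) / mpmath.mpf(rd),
            rd,
            N,
            math.factorial,
            math.comb,
        )
        return BinomialMomentVector(
            b=np.array([float(x) for x in b]),
            params=params,
            exact=tuple(b),
        )


def mean_expression(params: GTMParameters) -> float:
    """Stationary mean copy number
    r_syn <tau_on> / (r_deg (<tau_off> + <tau_on>)) — equivalently
    burst size times burst frequency over the degradation rate."""
    return (
        params.r_syn
        * params.mean_on
        / (params.r_deg * params.mean_cycle_time())
    )


def cv2(params: GTMParameters) -> float:
    """Squared coefficient of variation (noise) of the stationary law.

    Closed form in terms of the dwell-time Laplace transforms at the
    degradation rate; identical to (2 b_2 + b_1 - b_1^2)/b_1^2.
    """
    rd = params.r_deg
    t_off, t_on = params.mean_off, params.mean_on
    f_off = params.off_model.laplace(rd)
    f_on = params.on_model.laplace(rd)
    m = mean_expression(params)
    return (
        1.0 / m
        + t_off / t_on
        - (t_off + t_on)
        / (rd * t_on**2)
        * (1.0 - f_off)
        * (1.0 - f_on)
        / (1.0 - f_off * f_on)
    )


def central_moments(b: BinomialMomentVector, order: int = 4) -> np.ndarray:
    """Central moments mu_1..mu_order from binomial moments.

    Uses mu_k = (-b_1)^k + sum_{i<k} sum_{j<=k-i} R(k,i,j) j! b_1^i b_j
    with R(k,i,j) = (-1)^i C(k,i) S(k-i,j) and S the Stirling numbers of
    the second kind (j! b_j is the j-th factorial moment).  mu_1 is 0 by
    construction.
    """
    if order > b.order:
        raise InsufficientMomentsError(
            f"need binomial moments to order {order}, have {b.order}"
        )
    b1 = b[1]
    mu = np.empty(order)
    for k in range(1, order + 1):
        total = (-b1) ** k
        for i in range(k):
            for j in range(k - i + 1):
                r = (-1) ** i * math.comb(k, i) * stirling2(k - i, j)
                if r:
                    total += r * math.factorial(j) * b1**i * b[j]
        mu[k - 1] = total
    return mu


@dataclass(frozen=True)
class SummaryStatVector:
    """The six snapshot summary statistics.

    The statistic vector used for inference carries the *non-excess*
    kurtosis mu_4/mu_2^2, which Pearson's inequality keeps >= 1 so the
    log-scale discrepancy stays defined even for flat or bimodal count
    distributions (whose excess kurtosis is negative); excess kurtosis
    is stored alongside for reporting.  The bimodality coefficient is
    Sarle's (skew^2 + 1)/(mu_4/mu_2^2), which lives in (0, 1] with the
    usual 5/9 bimodality rule.
    """

    mean: float
    noise_strength: float
    fano: float
    skewness: float
    excess_kurtosis: float
    bimodality: float

    @property
    def kurtosis(self) -> float:
        """Non-excess kurtosis mu_4/mu_2^2 (>= 1)."""
        return self.excess_kurtosis + 3.0

    def as_array(self) -> np.ndarray:
        """The 6-vector in STAT_NAMES order (non-excess kurtosis)."""
        return np.array(
            [
                self.mean,
                self.noise_strength,
                self.fano,
                self.skewness,
                self.kurtosis,
                self.bimodality,
            ]
        )


def _stats_from_b1234(b1: float, b2: float, b3: float, b4: float) -> SummaryStatVector:
    mu2 = 2 * b2 + b1 - b1**2
    if b1 <= 0 or mu2 <= 0:
        raise DegenerateDistributionError(
            "summary statistics undefined for zero mean or zero variance"
        )
    noise = mu2 / b1**2
    fano = mu2 / b1
    skew = (6 * b3 + 6 * b2 + b1 - 3 * b1 * (2 * b2 + b1) + 2 * b1**3) / mu2**1.5
    kurt = (
        24 * b4
        + 36 * b3
        + 14 * b2
        + b1
        - 4 * b1 * (6 * b3 + 6 * b2 + b1)
        + 6 * b1**2 * (2 * b2 + b1)
        - 3 * b1**4
    ) / mu2**2
    return SummaryStatVector(
        mean=b1,
        noise_strength=noise,
        fano=fano,
        skewness=skew,
        excess_kurtosis=kurt - 3.0,
        bimodality=(skew**2 + 1.0) / kurt,
    )


def summary_stats_from_moments(b: BinomialMomentVector) -> SummaryStatVector:
    """Six summary statistics from b_1..b_4 in closed form."""
    if b.order < 4:
        raise InsufficientMomentsError("need binomial moments to order 4")
    return _stats_from_b1234(b[1], b[2], b[3], b[4])


def summary_stats_from_counts(counts: Sequence[int]) -> SummaryStatVector:
    """Six summary statistics of an observed count vector.

    Central moments use the 1/n (population) convention, matching the
    closed forms used for model statistics so observed and model vectors
    are directly comparable.
    """
    x = np.asarray(counts, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 cells")
    m = x.mean()
    d = x - m
    mu2 = np.mean(d**2)
    if m <= 0 or mu2 <= 0:
        raise DegenerateDistributionError("constant or all-zero counts")
    mu3 = np.mean(d**3)
    mu4 = np.mean(d**4)
    skew = mu3 / mu2**1.5
    kurt = mu4 / mu2**2
    return SummaryStatVector(
        mean=m,
        noise_strength=mu2 / m**2,
        fano=mu2 / m,
        skewness=skew,
        excess_kurtosis=kurt - 3.0,
        bimodality=(skew**2 + 1.0) / kurt,
    )


def reconstruct_pmf(
    b: BinomialMomentVector,
    n_max: int,
    tol: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Invert binomial moments to P(0..n_max).

    P(n) = sum_{m>=n} (-1)^{m-n} C(m,n) b_m, truncated at the available
    order and evaluated in arbitrary precision (the terms alternate and
    can exceed the result by many orders of magnitude).  Returns
    (pmf, err) where err[n] is the magnitude of the last included term
    — a proxy for the truncation error.  Raises ConditioningError when
    that proxy exceeds ``tol`` anywhere, i.e. when the moment order is
    too low for the requested support.
    """
    if n_max >= b.order:
        raise InsufficientMomentsError(
            f"reconstruction to n={n_max} needs order > {n_max}, have {b.order}"
        )
    N = b.order
    lam = max(float(b[1]), 1.0)
    digits = int(40 + 0.35 * N + lam)
    with mpmath.workdps(digits):
        if b.exact is not None:
            bm = (mpmath.mpf(1),) + tuple(b.exact)
        else:
            bm = (mpmath.mpf(1),) + tuple(mpmath.mpf(float(x)) for x in b.b)
        pmf = np.empty(n_max + 1)
        err = np.empty(n_max + 1)
        for n in range(n_max + 1):
            total = mpmath.mpf(0)
            last = mpmath.mpf(0)
            for m in range(n, N + 1):
                last = (-1) ** (m - n) * math.comb(m, n) * bm[m]
                total += last
            pmf[n] = float(total)
            err[n] = abs(float(last))
    if np.max(err) > tol:
        raise ConditioningError(
            "binomial-moment series not converged at this order; increase "
            "the moment order or reduce r_syn/r_deg"
        )
    return np.clip(pmf, 0.0, 1.0), err


def stationary_pmf(
    params: GTMParameters,
    n_max: int,
    order: Optional[int] = None,
) -> np.ndarray:
    """Convenience wrapper: stationary P(0..n_max) for a parameter set.

    The moment order defaults to a margin above both the support bound
    and the scale r_syn/r_deg at which the moments b_n start to decay.
    """
    lam = params.r_syn / params.r_deg
    if order is None:
        # the inversion terms are bounded by (2 lam)^m / m!, so the
        # series is safe once the order clears ~2e*lam with margin
        order = int(max(n_max + 10, 6.0 * lam + 30))
    b = binomial_moments(params, order, precision=int(60 + 0.4 * order + lam))
    pmf, _ = reconstruct_pmf(b, n_max)
    return pmf


# ---------------------------------------------------------------------------
# Vectorized Gamma-dwell path used by the inference engine.
# ---------------------------------------------------------------------------

def batch_summary_stats_gamma(theta: np.ndarray, r_deg: float = 1.0) -> np.ndarray:
    """Summary statistics for a batch of Gamma-dwell parameter vectors.

    ``theta`` has columns (k_off, r_off, k_on, r_on, r_syn).  Returns an
    (m, 6) array in STAT_NAMES order with NaN rows wherever the
    statistics are degenerate (e.g. r_syn = 0).  This is the hot path of
    ABC — the order-4 recursion unrolled over numpy arrays.
    """
    th = np.atleast_2d(np.asarray(theta, dtype=float))
    k_off, r_off, k_on, r_on, r_syn = (th[:, i] for i in range(5))
    rd = r_deg

    def loff(s):
        return (r_off / (r_off + s)) ** k_off

    def lon(s):
        return (r_on / (r_on + s)) ** k_on

    tau_on = k_on / r_on
    tau_off = k_off / r_off

    def son(s):
        if s == 0:
            return tau_on
        return (1.0 - lon(s)) / s

    m = th.shape[0]
    C = [1.0 / (tau_off + tau_on)]
    for n in range(1, 4):
        acc = np.zeros(m)
        for i in range(n):
            inner = np.zeros(m)
            for j in range(n - i + 1):
                inner += (
                    math.comb(n - i, j) * (-1) ** (n - i - j) * lon((n - j) * rd)
                )
            acc += math.comb(n, i) * C[i] * inner
        lo = loff(n * rd)
        C.append(lo / (1.0 - lo * lon(n * rd)) * acc)

    b = []
    for n in range(1, 5):
        acc = np.zeros(m)
        for i in range(n):
            inner = np.zeros(m)
            for j in range(n - i):
                inner += (
                    math.comb(n - 1 - i, j)
                    * (-1) ** (n - 1 - i - j)
                    * son((n - 1 - j) * rd)
                )
            acc += math.comb(n - 1, i) * C[i] * inner
        b.append((r_syn / rd) ** n / math.factorial(n) * acc)
    b1, b2, b3, b4 = b

    mu2 = 2 * b2 + b1 - b1**2
    out = np.full((m, 6), np.nan)
    ok = (b1 > 0) & (mu2 > 0)
    b1, b2, b3, b4, mu2 = (a[ok] for a in (b1, b2, b3, b4, mu2))
    skew = (6 * b3 + 6 * b2 + b1 - 3 * b1 * (2 * b2 + b1) + 2 * b1**3) / mu2**1.5
    kurt = (
        24 * b4
        + 36 * b3
        + 14 * b2
        + b1
        - 4 * b1 * (6 * b3 + 6 * b2 + b1)
        + 6 * b1**2 * (2 * b2 + b1)
        - 3 * b1**4
    ) / mu2**2
    out[ok, 0] = b1
    out[ok, 1] = mu2 / b1**2
    out[ok, 2] = mu2 / b1
    out[ok, 3] = skew
    out[ok, 4] = kurt  # non-excess, keeps the log-distance defined
    out[ok, 5] = (skew**2 + 1.0) / kurt
    return out
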