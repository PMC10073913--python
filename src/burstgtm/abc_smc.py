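"""Moment-based sequential Monte Carlo ABC for burst-kinetics inference.

The likelihood of the generalized telegraph model is intractable, but
its six summary statistics are available in closed form from the
binomial-moment recursion.  Inference therefore proceeds likelihood
free: draw parameter vectors theta = (k_off, r_off, k_on, r_on, r_syn)
(Gamma dwell times, r_deg = 1), compute the model's summary-statistic
vector *analytically* — never by simulation — and accept theta when the
squared log-Euclidean discrepancy

    rho = sum_i (ln s_obs_i - ln s_model_i)^2

falls below the current threshold.  Rounds shrink the threshold to the
median discrepancy of the previous round's accepted set; proposals are
component-wise multiplicative lognormal perturbations of ancestors
resampled uniformly from that set.

Because the acceptance decision is deterministic given theta, this
scheme is not a calibrated Bayesian posterior: its spread is narrower
than the true posterior, and only the location (mode/mean) of derived
quantities — burst frequency and burst size, which are identifiable —
should be interpreted.  Individual dwell parameters are largely
unidentifiable from snapshot data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sstats

from .moments import STAT_NAMES, SummaryStatVector, batch_summary_stats_gamma

PARAM_NAMES = ("k_off", "r_off", "k_on", "r_on", "r_syn")

#: prior bounds: k ~ U(0, 5], r = 10^U[-1, 1], r_syn ~ U[0, 50]
PRIOR_LO = np.array([0.0, 0.1, 0.0, 0.1, 0.0])
PRIOR_HI = np.array([5.0, 10.0, 5.0, 10.0, 50.0])


class ABCError(RuntimeError):
    """Inference could not proceed (e.g. incompatible observed stats)."""


@dataclass(frozen=True)
class ABCConfig:
    """Hyperparameters of the SMC-ABC scheme.

    Defaults: initial threshold eps0 = 1, T = 5 refinement rounds,
    10 000 coarse round-0 acceptances trimmed to the best 1000, and a
    lognormal proposal scale sigma = 0.2.
    """

    eps0: float = 1.0
    rounds: int = 5
    n_coarse: int = 10_000
    n_keep: int = 1_000
    proposal_sigma: float = 0.2
    bf_definition: str = "cycle"  # or "off_only" (1/<tau_off>)
    max_prior_draws: int = 10_000_000
    batch_size: int = 100_000

    def __post_init__(self) -> None:
        if self.n_keep > self.n_coarse:
            raise ValueError("n_keep must not exceed n_coarse")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if self.bf_definition not in ("cycle", "off_only"):
            raise ValueError("bf_definition must be 'cycle' or 'off_only'")


def sample_prior(rng: np.random.Generator, size: int = 1) -> np.ndarray:
    """Draw theta from the prior: k_off, k_on ~ U(0,5], r_off, r_on
    log-uniform over [0.1, 10], r_syn ~ U[0, 50].  The measure-zero
    k = 0 boundary (invalid Gamma shape) is redrawn."""
    th = np.empty((size, 5))
    for col in (0, 2):
        k = rng.uniform(0.0, 5.0, size)
        while True:
            zero = k == 0.0
            if not zero.any():
                break
            k[zero] = rng.uniform(0.0, 5.0, int(zero.sum()))
        th[:, col] = k
    th[:, 1] = 10.0 ** rng.uniform(-1.0, 1.0, size)
    th[:, 3] = 10.0 ** rng.uniform(-1.0, 1.0, size)
    th[:, 4] = rng.uniform(0.0, 50.0, size)
    return th


def in_prior_support(theta: np.ndarray) -> np.ndarray:
    """Boolean mask of rows inside the prior support."""
    th = np.atleast_2d(theta)
    ok = np.ones(th.shape[0], dtype=bool)
    ok &= (th[:, 0] > 0) & (th[:, 0] <= 5)
    ok &= (th[:, 2] > 0) & (th[:, 2] <= 5)
    ok &= (th[:, 1] >= 0.1) & (th[:, 1] <= 10)
    ok &= (th[:, 3] >= 0.1) & (th[:, 3] <= 10)
    ok &= (th[:, 4] >= 0) & (th[:, 4] <= 50)
    return ok


def propose(
    theta_prev: np.ndarray,
    sigma: float,
    rng: np.random.Generator,
    max_redraws: int = 10_000,
) -> np.ndarray:
    """Component-wise lognormal perturbation with median at the
    previous value: theta* = theta_prev * exp(sigma * Z).

    Out-of-support proposals are redrawn (per ancestor) rather than
    clipped, which would pile probability mass on the prior bounds.
    """
    prev = np.atleast_2d(np.asarray(theta_prev, dtype=float))
    if sigma == 0:
        return prev.copy()
    out = prev * np.exp(sigma * rng.standard_normal(prev.shape))
    for _ in range(max_redraws):
        bad = ~in_prior_support(out)
        if not bad.any():
            return out
        out[bad] = prev[bad] * np.exp(
            sigma * rng.standard_normal((int(bad.sum()), 5))
        )
    raise ABCError("proposal stuck outside prior support")


def _as_stat_array(s) -> np.ndarray:
    if isinstance(s, SummaryStatVector):
        return s.as_array()
    return np.asarray(s, dtype=float)


def distance(s_obs, s_model) -> float:
    """Squared log-Euclidean discrepancy over the six statistics.

    Any non-positive (or non-finite) component of either vector makes
    the log undefined; such pairs get +inf — a rejection, not an error.
    """
    a = _as_stat_array(s_obs)
    b = _as_stat_array(s_model)
    if np.any(a <= 0) or np.any(b <= 0) or not (
        np.all(np.isfinite(a)) and np.all(np.isfinite(b))
    ):
        return np.inf
    return float(np.sum((np.log(a) - np.log(b)) ** 2))


def _batch_distance(log_s_obs: np.ndarray, s_model: np.ndarray) -> np.ndarray:
    rho = np.full(s_model.shape[0], np.inf)
    ok = np.all(np.isfinite(s_model), axis=1) & np.all(s_model > 0, axis=1)
    if ok.any():
        rho[ok] = np.sum((np.log(s_model[ok]) - log_s_obs) ** 2, axis=1)
    return rho


@dataclass
class PosteriorEnsemble:
    """Accepted parameter sample of the final SMC round plus run trace."""

    thetas: np.ndarray  # (n_keep, 5)
    rhos: np.ndarray
    thresholds: list  # eps_0 .. eps_T
    acceptance: list  # (accepted, attempted) per round
    config: ABCConfig

    def burst_frequency_samples(self, definition: Optional[str] = None) -> np.ndarray:
        """Per-sample BF; 'cycle' uses 1/(<tau_off>+<tau_on>),
        'off_only' the alternative 1/<tau_off>."""
        definition = definition or self.config.bf_definition
        tau_off = self.thetas[:, 0] / self.thetas[:, 1]
        tau_on = self.thetas[:, 2] / self.thetas[:, 3]
        if definition == "off_only":
            return 1.0 / tau_off
        return 1.0 / (tau_off + tau_on)

    def burst_size_samples(self) -> np.ndarray:
        """Per-sample BS = r_syn * <tau_on>."""
        return self.thetas[:, 4] * self.thetas[:, 2] / self.thetas[:, 3]

    def dwell_mean_samples(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            self.thetas[:, 0] / self.thetas[:, 1],
            self.thetas[:, 2] / self.thetas[:, 3],
        )


def run_abc_smc(
    s_obs,
    config: ABCConfig = ABCConfig(),
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> PosteriorEnsemble:
    """Run the full SMC-ABC scheme against an observed statistic vector.

    Round 0 draws from the prior until ``n_coarse`` samples satisfy
    rho <= eps0, then keeps the ``n_keep`` smallest-discrepancy samples.
    Each later round resamples ancestors uniformly from the previous
    accepted set, perturbs them, and accepts at the median-of-previous
    threshold until ``n_keep`` acceptances.  Model statistics come from
    the closed-form order-4 binomial moments (Gamma dwells, r_deg = 1).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    s_obs = _as_stat_array(s_obs)
    if s_obs.shape != (6,):
        raise ValueError("s_obs must have 6 components")
    if np.any(s_obs <= 0) or not np.all(np.isfinite(s_obs)):
        raise ABCError(
            "observed summary statistics must be finite and positive "
            f"({dict(zip(STAT_NAMES, s_obs))})"
        )
    log_s_obs = np.log(s_obs)

    # -- round 0: rejection sampling from the prior ---------------------
    kept_th, kept_rho = [], []
    n_found = 0
    drawn = 0
    while n_found < config.n_coarse and drawn < config.max_prior_draws:
        m = min(config.batch_size, config.max_prior_draws - drawn)
        th = sample_prior(rng, m)
        drawn += m
        rho = _batch_distance(log_s_obs, batch_summary_stats_gamma(th))
        acc = rho <= config.eps0
        if acc.any():
            kept_th.append(th[acc])
            kept_rho.append(rho[acc])
            n_found += int(acc.sum())
    if n_found < config.n_keep:
        raise ABCError(
            f"round-0 acceptance rate {n_found}/{drawn} too low; observed "
            "statistics are likely incompatible with the prior ranges"
        )
    th = np.concatenate(kept_th)[: config.n_coarse]
    rho = np.concatenate(kept_rho)[: config.n_coarse]
    order = np.argsort(rho, kind="stable")[: config.n_keep]
    th, rho = th[order], rho[order]
    thresholds = [config.eps0]
    acceptance = [(n_found, drawn)]

    # -- rounds 1..T: resample / perturb / accept -----------------------
    for _ in range(config.rounds):
        eps = float(np.median(rho))
        thresholds.append(eps)
        new_th, new_rho = [], []
        n_acc, n_try = 0, 0
        while n_acc < config.n_keep:
            m = max(config.n_keep - n_acc, 1) * 2
            anc = th[rng.integers(0, th.shape[0], m)]
            prop = propose(anc, config.proposal_sigma, rng)
            r = _batch_distance(log_s_obs, batch_summary_stats_gamma(prop))
            acc = r <= eps
            n_try += m
            if acc.any():
                new_th.append(prop[acc])
                new_rho.append(r[acc])
                n_acc += int(acc.sum())
            if n_try > 50_000_000:
                raise ABCError("SMC round failed to accept enough particles")
        th = np.concatenate(new_th)[: config.n_keep]
        rho = np.concatenate(new_rho)[: config.n_keep]
        acceptance.append((n_acc, n_try))

    return PosteriorEnsemble(
        thetas=th,
        rhos=rho,
        thresholds=thresholds,
        acceptance=acceptance,
        config=config,
    )


def posterior_mode_kde(values: np.ndarray) -> np.ndarray:
    """Mode of a sample via a Gaussian KDE (Silverman bandwidth)
    evaluated at the sample points; handles 1-D vectors or (n, d)
    matrices (product kernel).  Degenerate zero-variance samples return
    the common value."""
    x = np.asarray(values, dtype=float)
    one_d = x.ndim == 1
    pts = x[None, :] if one_d else x.T  # gaussian_kde wants (d, n)
    if np.allclose(pts.var(axis=1), 0):
        out = pts[:, 0]
        return out[0] if one_d else out
    kde = sstats.gaussian_kde(pts, bw_method="silverman")
    dens = kde(pts)
    best = pts[:, np.argmax(dens)]
    return best[0] if one_d else best


@dataclass
class BurstKineticsPosterior:
    """Derived burst-kinetics summary of a posterior ensemble."""

    bf_samples: np.ndarray
    bs_samples: np.ndarray
    bf_mode: float
    bs_mode: float
    bf_ci95: tuple
    bs_ci95: tuple
    definition: str


def burst_kinetics_posterior(
    ensemble: PosteriorEnsemble,
    definition: Optional[str] = None,
) -> BurstKineticsPosterior:
    """Burst frequency and size samples, joint-KDE modes, and
    equal-tailed 95% credible intervals."""
    definition = definition or ensemble.config.bf_definition
    bf = ensemble.burst_frequency_samples(definition)
    bs = ensemble.burst_size_samples()
    mode = posterior_mode_kde(np.column_stack([bf, bs]))
    return BurstKineticsPosterior(
        bf_samples=bf,
        bs_samples=bs,
        bf_mode=float(mode[0]),
        bs_mode=float(mode[1]),
        bf_ci95=tuple(np.quantile(bf, [0.025, 0.975])),
        bs_ci95=tuple(np.quantile(bs, [0.025, 0.975])),
        definition=definition,
    )


def theta_burst_kinetics(theta: Sequence[float], definition: str = "cycle"):
    """(BF, BS) for a single Gamma-dwell parameter vector."""
    k_off, r_off, k_on, r_on, r_syn = theta
    tau_off, tau_on = k_off / r_off, k_on / r_on
    bf = 1.0 / tau_off if definition == "off_only" else 1.0 / (tau_off + tau_on)
    return bf, r_syn * tau_on
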