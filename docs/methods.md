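# Methods

## Model

A gene alternates between an OFF state with dwell-time density
f_off(t) and an ON state with density f_on(t); while ON, transcription
fires as a Poisson process with rate r_syn, and every transcript
degrades independently at rate r_deg (first-order decay). The classical
telegraph model is the special case of exponential dwell times, with
activation rate r_off = 1/⟨τ_off⟩ and inactivation rate
r_on = 1/⟨τ_on⟩ (rates are named for the state being *left*). Burst
frequency is BF = 1/(⟨τ_off⟩+⟨τ_on⟩) (bursts per unit time; an
alternative convention 1/⟨τ_off⟩ is available as `bf_definition =
"off_only"`), and burst size is BS = r_syn⟨τ_on⟩.

Dwell-time families: Gamma(shape k, rate r) with Laplace transform
(r/(r+s))^k — the shape k acts as an effective number of rate-limiting
promoter steps but is treated as a continuous parameter (the prior is
continuous, and values in (0,1] are admissible); exponential is
Gamma(k=1); Weibull(shape, scale) has no elementary Laplace transform
and is integrated by adaptive quadrature (cached, relative error
≤ 1e-10).

Out of scope by design: cell division, extrinsic noise, transcript
maturation/splicing, technical sampling noise, multi-state (>2)
promoters, and time-dependent (transient) moments.

## Stationary analytics

The stationary law P(n) is handled through its binomial moments
b_n = Σ_m C(m,n) P(m), which obey a double recursion whose only inputs
are the dwell-time Laplace transforms at multiples of r_deg (see the
`moments` module docstring for the formulas). C_0 = BF exactly; b_1
equals the stationary mean r_syn⟨τ_on⟩/(r_deg(⟨τ_off⟩+⟨τ_on⟩)); the
closed-form CV² is verified in the tests against the independent
identity CV² = (2b_2 + b_1 − b_1²)/b_1², which also pins down the
otherwise ambiguous typography of the noise formula. Central moments
come from the factorial moments j!·b_j via Stirling numbers of the
second kind.

With exponential dwells the recursion collapses to the Pochhammer
ratio b_n = (r_syn/r_deg)^n/n! · (a)_n/(a+c)_n with a = r_off/r_deg,
c = r_on/r_deg. The assignment of the *activation* rate to the
numerator Pochhammer is fixed by equating against the general recursion
(an independent oracle, asserted to 1e-10 in the tests) rather than
trusted from any printed source; the same nesting makes the
beta-Poisson pmf (evaluated via the Kummer-transformed confluent
hypergeometric series, which has all-positive terms, with log-space
prefactors and an arbitrary-precision fallback) consistent with the
moment engine.

### Numerical policy

Both the moment recursion and the inversion
P(n) = Σ_m (−1)^(m−n) C(m,n) b_m are alternating binomial sums whose
terms exceed the result by orders of magnitude. Orders ≤ 8 are safe in
double precision (the inference path needs only b_1..b_4); beyond that
the engine switches to arbitrary-precision arithmetic with the digit
count scaled to the largest intermediate term
(≈ 40 + 0.35·N + (r_syn/r_deg)·log10 e). The inversion requires the
moments to have started decaying against the binomial weights, which
happens once the order clears roughly 2e·(r_syn/r_deg); the default
order is 6·(r_syn/r_deg)+30 and every reconstruction carries a
truncation-error proxy (the magnitude of the last included term), with
a hard error if that proxy exceeds 1% anywhere. Combinatorial factors
use exact integer arithmetic.

## Exact simulation

Trajectories: epoch durations are drawn from the dwell models; within
an epoch the synthesis/degradation subsystem is a time-homogeneous
Markov birth–death chain, simulated by Gillespie's direct method and
truncated at the epoch boundary (exact, because the within-epoch
reactions are memoryless).

Snapshots: cells start at count 0 in a state randomized with the
stationary weights ⟨τ_on⟩/(⟨τ_off⟩+⟨τ_on⟩) and are observed after a
burn-in T_b = max(20/r_deg, 20·(⟨τ_off⟩+⟨τ_on⟩)) — long relative to
both relaxation timescales; one cell per independent trajectory, so
snapshot counts are i.i.d. Starting epochs at a state boundary rather
than with a length-biased residual is a transient whose effect the
burn-in suppresses; the tests verify that doubling T_b moves the mean
by less than 2 combined standard errors. Conditional on the epoch
sequence the observed count is *exactly* Poisson: an ON epoch of
effective length d ending a time R before observation contributes
independent survivors with mean (r_syn/r_deg)(1−e^(−r_deg·d))e^(−r_deg·R).
The sampler therefore accumulates this mean epoch-by-epoch (vectorized
across cells, single seeded generator, reproducible under a fixed
seed) and draws one Poisson variate per cell — statistically identical
to event-resolved simulation and fast enough for 1e5-cell oracles even
at sub-millisecond switching cycles.

The same machinery doubles as the synthetic-data generator for all
tests. It emulates ideal snapshot data: stationary, i.i.d. cells,
exact molecule counts. It does not emulate capture/sequencing noise,
cell-to-cell extrinsic variability, or cell-cycle structure, so
passing tests demonstrate correctness of model, analytics and
inference machinery on in-model data — not robustness to the technical
artefacts of real scRNA-seq.

## Summary statistics and discrepancy

Six statistics summarize a count distribution: mean, noise strength
(μ₂/μ₁²), Fano factor (μ₂/μ₁), skewness (μ₃/μ₂^1.5), kurtosis, and the
bimodality coefficient (Sarle's (skew²+1)/(μ₄/μ₂²), in (0,1] with the
5/9 bimodality rule). Two conventions matter:

- **Kurtosis.** The inference vector carries *non-excess* kurtosis
  μ₄/μ₂², which Pearson's inequality keeps ≥ 1. Excess kurtosis is
  negative precisely in the flat/bimodal regimes this model produces
  (the bimodal worked example has excess kurtosis −0.86), and a
  log-scale distance over a statistic that crosses zero would reject
  every such target. Excess kurtosis is stored alongside for
  reporting.
- **Empirical moments** use the 1/n (population) convention, matching
  the closed-form model statistics so observed and model vectors are
  commensurate; at small cell numbers this biases both sides equally.

The discrepancy is ρ = Σᵢ (ln s_obs⁽ⁱ⁾ − ln s_model⁽ⁱ⁾)², the squared
log-Euclidean distance (no square root — the threshold scale assumes
this). Any non-positive or non-finite component in either vector gives
ρ = +∞, a rejection rather than an error.

## Sequential Monte Carlo ABC

Priors (r_deg ≡ 1): k_off, k_on ~ U(0,5] (a drawn 0 is redrawn —
measure-zero, invalid shape); r_off, r_on = 10^u with u ~ U[−1,1];
r_syn ~ U[0,50]. Round 0 draws from the prior until 10 000 samples
satisfy ρ ≤ ε₀ = 1 (batched, hard cap 10⁷ draws) and keeps the 1000
with the smallest discrepancy. Each of the T = 5 subsequent rounds
resamples ancestors uniformly from the previous accepted set, perturbs
each component multiplicatively by exp(σZ) with σ = 0.2 (lognormal
with median at the ancestor; out-of-support proposals are redrawn for
the same ancestor rather than clipped, which would pile mass on the
bounds), and accepts ρ ≤ ε_t until 1000 particles, with ε_t the median
discrepancy of the previous round (inclusive ties). Model statistics
are always computed analytically from the order-4 moment recursion —
the design choice that makes per-gene inference take well under a
second — via a vectorized Gamma-dwell path verified against the scalar
engine.

No importance weights are used: canonical ABC-SMC reweights particles,
but with deterministic analytic statistics the accept/reject decision
is itself deterministic, the scheme is not a calibrated posterior, and
its spread is narrower than the true posterior regardless. We
therefore summarize burst kinetics by the **mode** of a 2-D Gaussian
KDE (Silverman bandwidth, evaluated at the sample points) over the
(BF, BS) plane, plus equal-tailed 95% intervals of the samples.

### Identifiability

The six statistics do not point-identify burst frequency: distinct
dwell structures — e.g. small-shape, fast-cycling promoters versus
slow multi-step ones — reproduce all six statistics to within a few
percent while differing in BF by an order of magnitude (the test suite
constructs such a pair explicitly and confirms the equivalence by
simulation). The accepted ensemble therefore sits on a ridge: its
*mean* is biased away from the generating values and does not converge
to them even as thresholds are driven to ~1e-4, while the KDE *mode*
recovers BF and BS to within ~25% on 1e4-cell snapshots. One
acceptance test records the mean-recovery property and fails by
design of the statistics, documenting this limit; mode-based recovery
is the supported claim. Individual parameters (k's and r's separately)
are not recoverable; mean dwell times ⟨τ_off⟩, ⟨τ_on⟩ and r_syn are
approximately so.

## Classical-telegraph baseline and its bias

`ctm_mle_fit` maximizes the exact beta-Poisson likelihood over
(log r_off, log r_on, log r_syn) with L-BFGS-B, rate bounds [1e-3, 1e3],
r_syn bounded by 10× the maximum count, and multi-start: one
closed-form moment-matched start (factorial-moment ratios) plus random
log-uniform starts (5 total). r_deg is fixed at 1 — snapshot data only
constrain rates relative to the mRNA lifetime. Degenerate inputs
(constant counts) return a failure status consumed by the driver.

Fitting this memoryless model to multi-step (k > 1) data reproduces
the count histogram closely but maps the sharpened dwell-time
distributions onto faster effective switching: across 50 replicates of
1e4-cell snapshots at the bimodal worked example, 100% of fits
overestimate BF and underestimate BS. The genome-wide driver reports
both GTM and CTM estimates per gene so this direction can be checked
on any dataset.

## Data handling

QC applies three strict (<) filters in a fixed order: genes expressed
(count > 0) in fewer than 50 cells; then cells expressing fewer than
2000 genes; then genes whose mean over the remaining cells is below 2.
The order is part of the contract (later steps see earlier removals);
permuting input gene order cannot change the retained set. "Expressed"
means a nonzero UMI count. Allele-resolved matrices are pooled by
concatenating cells (suffixed labels), treating each allele as an
independent observation of the same kinetics, not by summing counts.
The genome-wide driver derives per-gene seeds from
SHA-256(base_seed, gene label), records every gene as a status row
(failures never abort a batch), and resumes from a JSONL manifest.

## Default problem sizes

Analytic-vs-simulation oracles use 1e5 cells (standard errors small
enough to resolve sub-percent biases in b_1..b_4); inference
validation uses 1e4-cell snapshots and the default ABC budget
(10 000 coarse / 1000 kept / 5 rounds); the classical-bias experiment
uses 50 replicates. These sizes make the full validation suite run in
a few minutes on one CPU while keeping every statistical gate at 3
standard errors or tighter.
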