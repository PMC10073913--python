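# burstgtm

Transcriptional burst kinetics from static single-cell snapshots, under a
**generalized telegraph model** (GTM) in which the promoter's ON and OFF
dwell times follow arbitrary distributions instead of the exponential
dwell times of the classical telegraph model (CTM).

## The problem

Most genes transcribe in bursts: the promoter alternates between a
transcriptionally silent OFF state and an active ON state in which mRNA
is made at rate *r*<sub>syn</sub>, while each transcript degrades at rate
*r*<sub>deg</sub>. Burst kinetics are summarized by

- **burst frequency**  BF = 1 / (⟨τ<sub>off</sub>⟩ + ⟨τ<sub>on</sub>⟩),
- **burst size**  BS = *r*<sub>syn</sub> · ⟨τ<sub>on</sub>⟩.

Promoter switching is usually a multi-step molecular process, so the
dwell times τ<sub>off</sub>, τ<sub>on</sub> are generally *not*
exponential ("molecular memory"). Fitting the memoryless CTM to data
generated by a multi-step promoter can reproduce the count histogram
almost perfectly while systematically **overestimating burst frequency
and underestimating burst size** — a bias this package quantifies and
avoids.

## What the package provides

- `dwell` — Gamma / exponential / Weibull dwell-time models (pdf,
  survival, hazard, Laplace transform f̃(s), sampling).
- `simulate` — statistically exact simulation: event-resolved
  trajectories, stationary snapshots (one cell per independent
  trajectory), dwell-time records.
- `moments` — the stationary binomial moments
  *b*<sub>n</sub> = Σ<sub>m</sub> C(m,n) P(m) by a double recursion in the
  dwell-time Laplace transforms; mean and CV²; central moments via
  Stirling numbers; the six snapshot summary statistics (mean, noise
  strength, Fano factor, skewness, kurtosis, bimodality coefficient);
  pmf reconstruction P(n) = Σ<sub>m</sub> (−1)^(m−n) C(m,n) b<sub>m</sub>
  in extended precision.
- `ctm` — the classical limit: Pochhammer-ratio moments, beta-Poisson
  stationary pmf, multi-start maximum-likelihood fitting, CTM burst
  kinetics.
- `abc_smc` — likelihood-free sequential Monte Carlo ABC over
  θ = (k_off, r_off, k_on, r_on, r_syn) with Gamma dwells and
  r_deg = 1: model statistics are computed *analytically* from the
  moment recursion (never by simulation), the discrepancy is the squared
  log-Euclidean distance over the six statistics, thresholds shrink to
  the median of the previous round, and burst kinetics are summarized by
  a 2-D kernel-density mode with 95% credible intervals.
- `io` — genes×cells TSV/CSV/MatrixMarket readers and writers, the
  three-step QC filter, allele pooling by cell concatenation, and a
  resumable per-gene genome-wide driver with a CTM baseline.

## Worked example

Simulate a snapshot of 10 000 cells for a bursty gene with Gamma dwell
times (k_off = 3, r_off = 0.5, k_on = 2, r_on = 0.5, r_syn = 20,
r_deg = 1; true BF = 0.1, BS = 80), then infer the kinetics back:

```sh
cat > params.yaml <<'YAML'
off: {family: gamma, shape: 3.0, rate: 0.5}
on:  {family: gamma, shape: 2.0, rate: 0.5}
r_syn: 20.0
r_deg: 1.0
YAML
burstgtm simulate --params params.yaml --n-cells 10000 --seed 1 --out counts.tsv
burstgtm stats --params params.yaml
```

prints the analytic moments and statistics,

```json
{
  "binomial_moments": [8.0, 62.8099173553719, 364.32207066591883, 1650.599134745239],
  "mean": 8.0,
  "noise_strength": 1.0878099173553721,
  "fano": 8.702479338842977,
  "skewness": 0.6677872050675504,
  "kurtosis": 2.140325089953572,
  "bimodality": 0.6755701542905783
}
```

— the mean is exactly r_syn⟨τ_on⟩/(r_deg(⟨τ_off⟩+⟨τ_on⟩)) = 8, the Fano
factor ≫ 1 flags strong bursting, and the bimodality coefficient above
5/9 flags the bimodal count distribution. Inference from the simulated
counts:

```python
import pandas as pd
from burstgtm import ABCConfig, run_abc_smc, burst_kinetics_posterior, summary_stats_from_counts

counts = pd.read_csv("counts.tsv", sep="\t")["count"].to_numpy()
ens = run_abc_smc(summary_stats_from_counts(counts), ABCConfig(), seed=1)
kin = burst_kinetics_posterior(ens)
```

```
BF mode 0.1075  95% CI (0.0833, 0.4870)
BS mode 75.5  95% CI (16.9, 94.3)
thresholds [1.     0.1209 0.0719 0.0428 0.0254 0.0157]
```

The posterior *modes* land within ~7% of the true BF = 0.1 and BS = 80.
Because the acceptance decision is deterministic given θ, the ensemble
is narrower than a calibrated posterior, and individual dwell
parameters are largely unidentifiable — the mode of (BF, BS) is the
defensible point estimate (see `docs/methods.md`).

A genome-wide run over a QC-filtered matrix:

```sh
burstgtm qc --counts matrix.tsv --out filtered.tsv
burstgtm infer --counts filtered.tsv --out results/ --seed 1
burstgtm fit-ctm --counts filtered.tsv --out ctm_fits.tsv
```

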