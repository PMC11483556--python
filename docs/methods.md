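# Methods

## Model and simulator

The population model is single-species logistic growth,
dN/dt = rN(K−N)/K, with pulse disturbances that change the state N
instantaneously but leave the parameters (r, K) untouched. Two disturbance
scenarios are supported:

* **single pulse** — the population starts at equilibrium N(0) = K and
  loses a fixed amount at a given time;
* **pulse train** — events arrive with exponential waiting times (rate λ)
  and jump sizes drawn from Normal(μ, σ), emulating environmental
  stochasticity acting in both directions.

The simulator is a stochastic hybrid process: the deterministic flow
between events is evaluated with the analytic logistic solution
N(t) = K / (1 + (K/n₀ − 1)e^{−rt}) (implemented in the decaying-exponential
form, which is stable for arbitrarily large r·t), not a numerical ODE
solver, so inter-event dynamics carry no integration error and the
semigroup property holds to near machine precision. Jump sizes and waiting
times are consumed from a single seeded generator in event order (waiting
time before magnitude), so a seed fully determines a trajectory, and two
species simulated from the same seed experience the identical disturbance
sequence — the construction needed for paired fast/slow comparisons.

Choices where the model itself is silent:

* **Negative abundance.** A jump below zero is floored at 0, which the
  deterministic flow treats as absorbing (a later positive jump can
  re-seed the population). With the default regime (σ = 10 against
  K = 50) flooring is rare (≈1 event in 200 long runs); occurrences are
  counted on the trajectory and logged.
* **Observation convention.** The sampling grid is decoupled from the
  event process and only reads states off; a sample falling exactly on an
  event time records the post-jump value (right-continuous paths).
  Refining the grid never changes event times or values at shared times.

## Realised metrics

Given a trajectory and its first disturbance at t_dist with
pre-disturbance abundance N_pre (the last sample strictly before t_dist,
falling back to K when the series starts at the disturbance):

* temporal stability = mean/std of the series (invariability, 1/CV),
  sample (n−1) standard deviation; reported only for pulse-train data —
  for a single transient it has no meaning and is flagged NaN; a constant
  series returns +inf with a warning;
* resistance = N(first sample ≥ t_dist)/N_pre;
* recovery = N(t_end)/N_pre, t_end defaulting to the last observation;
* resilience = −(x(t+ε) − x(t))/(x̄(t)·ε) on the displacement
  x = |N − K|, with x̄ the average of the two displacements and ε one
  sampling interval. The raw difference quotient is negative during
  recovery; the sign is flipped so that positive values mean return
  toward K. The default uses the first post-disturbance pair; an
  averaging mode pools all consecutive pairs while x(t) > 5% of K
  (below that the estimate degrades into sampling noise). For logistic
  dynamics the displacement decays at per-capita rate rN/K, so the
  averaged mode reads higher than the first pair after a deep pulse —
  both modes are exposed, first-pair is the default.

Multi-pulse trajectories reference the first event by default; the event
index is configurable.

## Intrinsic metrics

* **Temporal stability.** The linearised (Ornstein–Uhlenbeck-like)
  process has stationary variance var(N) = (μ²+σ²)λ/(2r), hence
  CV·√r = const; intrinsic invariability is realised invariability
  divided by √r. The division (rather than multiplication) is fixed by
  the requirement that the corrected quantity equal the r-free constant
  K/√((μ²+σ²)λ/2). The formula is exact only for the linear system: for
  logistic simulations at the default regime the measured variance runs
  ≈7–9% above the formula (slow recovery through the low-abundance
  exponential phase inflates excursions), which is why simulation
  cross-checks use a ±15% band.
* **Resilience** = realised resilience / r, i.e. dN/dτ on the
  growth-scaled axis τ = r·t.
* **Recovery** is evaluated at a common growth-scaled horizon τ_ref:
  N(t_dist + τ_ref/r)/N_pre. When comparing a case set, τ_ref defaults to
  the *shared span* min_i r_i·(t_end,i − t_dist,i) — the τ range every
  case actually covers; a fixed τ_ref may be supplied for cross-study
  comparability.
* **Resistance** stretches the fastest grower's post-disturbance sampling
  lag: each case is evaluated at t_dist + (r_fast/r)·dt_fast, giving
  every species the same opportunity to rebound before being "sampled".
  r_fast defaults to the largest growth rate in the comparison set and
  dt_fast to that case's own first post-disturbance lag.

Abundance between samples is interpolated **linearly in abundance** (not
log-abundance): the metrics are ratios of raw abundances and the
interpolation error is second-order in the sampling interval (<0.5% at
dt_obs = 0.1 for the reference scenario). Extrapolation beyond a series is
refused; a case whose rescaled evaluation time falls outside its
observations reports NaN rather than a guess.

## Treatment/control ratio pipeline

Comparative syntheses report log-response ratios ln(N_treat/N_contr) per
case over time. Exponentiating gives ratio series with equilibrium 1, and
the metrics above apply with N_pre = K = 1 (resistance = first
post-disturbance ratio, resilience on x = |ratio − 1|, and so on). The
disturbance time defaults to the start of each series (treatments are
assumed disturbed at the first sample); it can be overridden per case,
since source datasets rarely record it explicitly.

Cleaning applies three rules **in order** — (1) drop species groups with
fewer than 10 total observations (a switch counts cases instead of time
points, since either reading of "observations" is defensible), (2) drop
groups on a configured exclusion list (e.g. mixtures spanning wildly
different growth rates), (3) drop cases whose realised resistance exceeds
50× the median resistance of the pool surviving the first two rules
(optionally per group) — each exclusion logged with the rule that fired.
The median is computed once per invocation; on the datasets the generator
produces, cleaning is idempotent.

Group growth rates are arithmetic means of literature RGR estimates,
RGR = (ln w_t − ln w_i)/Δt; fewer than three estimates triggers a warning
rather than an error. Group summaries report n, mean, median and the
25th/75th percentiles per metric, excluding missing values metric-by-metric
with counts.

## Synthetic comparative dataset

The fixture generator emulates the *shape* of a multi-group disturbance
synthesis: seven species groups with growth rates from 0.08 to 1.38 day⁻¹
(macrophytes → microbes), eight cases per group, 8–15 irregular sampling
times per case. Every regular case follows one latent recovery curve in
growth-scaled time — a logistic rebound from ratio 0.2 toward 1 — so true
intrinsic resistance, recovery and resilience are *equal across groups by
construction*, while realised metrics differ with r. The first two τ
coordinates (0.1, 0.25) and the endpoint (τ = 4) are pinned across cases
so the first post-disturbance pair and the shared span are well defined;
interior times are drawn uniformly in τ. Noise is Gaussian on the log
scale (sd 0.05), keeping ratios positive.

Known violations are injected deliberately: one under-sampled group
(3 cases × 3 observations = 9 < 10) and three cases whose ratio series
start near 60 (resistance far above 50× the median). Tests verify that
cleaning removes exactly these.

What the generator does **not** emulate: between-case heterogeneity in
disturbance magnitude and direction, serially correlated observation
error, missing controls, and growth-rate error — in real syntheses the
group-level rates are noisy literature averages, which blurs intrinsic
estimates substantially. Passing tests therefore demonstrate correctness
of the partitioning arithmetic under its own assumptions, not robustness
to those field realities.

## Problem sizes and numerical tolerances

Stationary-variance and invariability checks simulate to t_max = 2000
(observation step 0.1, first 10% discarded as burn-in), averaging 20–40
seeds per regime; the invariability sweep uses 100 series per growth rate
over r ∈ {0.05, 0.1, 0.25, 0.5, 1, 2}. At these sizes the Monte-Carlo
error of a mean invariability is ≈1–2%, against which the flatness of the
corrected metric is judged; closed-form fast/slow comparisons use a 1%
band dominated by interpolation error; the linearisation check
(resilience/r ≈ 1 for a pulse of 2 on K = 50) uses 5%, reflecting the
first-order bias x/K of the finite displacement.
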