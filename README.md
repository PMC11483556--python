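# pulsestab

Growth-rate-aware stability analysis for populations responding to pulse
perturbations.

## The problem

Comparative studies of ecological stability routinely contrast resilience,
resistance, recovery and temporal stability across taxa whose intrinsic
growth rates span orders of magnitude — microbes near 1.4 day⁻¹, macrophytes
near 0.08 day⁻¹. All four classic metrics are confounded with the growth
rate *r*: under the *identical* disturbance regime a fast grower rebounds
further per unit clock time and therefore looks more "stable" on every
axis. `pulsestab` computes the classic (**realised**) metrics exactly as
defined, and alongside them **intrinsic** counterparts that remove the
expected effect of *r*, so that a microbe and a macrophyte responding
identically *relative to their own pace of life* receive the same score.

For a population with logistic dynamics dN/dt = rN(K−N)/K disturbed by
pulses (instantaneous changes to N, not to parameters):

| aspect | realised | intrinsic correction |
|---|---|---|
| temporal stability | mean(N)/std(N) (invariability, 1/CV) | divide by √r |
| resilience | per-capita decay of displacement x(t)=\|N−K\|: −(x(t+ε)−x(t))/(x̄·ε) | divide by r |
| recovery | N(t_end)/N_pre | evaluate at the shared growth-scaled horizon τ_ref: N(t_dist + τ_ref/r)/N_pre |
| resistance | N(first sample ≥ t_dist)/N_pre | stretch the sampling lag: N(t_dist + (r_fast/r)·dt_fast)/N_pre |

The √r rule follows from the stationary variance of the linearised jump
process, var(N) = (μ²+σ²)λ/(2r), for pulses of mean μ, sd σ arriving at
rate λ; the time rescaling τ = r·t makes the logistic recovery curve
identical for all species.

The package bundles an exact event-driven simulator (closed-form logistic
flow between stochastic pulses), the closed-form moments above as oracles,
and a pipeline for treatment/control log-response-ratio (LRR) datasets as
produced by disturbance-experiment syntheses, including the customary
cleaning rules (minimum observations per group, extreme-resistance
outliers) and per-group summaries.

## Worked example

Two species differing only in growth rate (r = 0.5 vs 0.1, K = 50) lose
40 units of biomass — 80% of K — at t = 4 and are observed every 0.1 days:

```python
import pulsestab as ps

obs = ps.ObservationScheme(t_max=60.0, dt_obs=0.1)
pulse = ps.SinglePulse(t_dist=4.05, magnitude=40.0)
fast = ps.simulate_single_pulse(ps.GrowthParams(r=0.5, K=50.0), pulse, obs)
slow = ps.simulate_single_pulse(ps.GrowthParams(r=0.1, K=50.0), pulse, obs)

print(ps.resistance_realised(fast), ps.resistance_realised(slow))
# 0.20403... 0.20080...          <- fast grower already looks tougher

tau = ps.shared_tau_span([0.5, 0.1], [4.05, 4.05], [60.0, 60.0])
print(ps.recovery_intrinsic(fast, 0.5, tau),
      ps.recovery_intrinsic(slow, 0.1, tau))
# 0.985348... 0.985352...        <- intrinsically identical

dt_fast = 0.05   # fast grower's first post-pulse sampling lag
print(ps.resistance_intrinsic(fast, 0.5, 0.5, dt_fast),
      ps.resistance_intrinsic(slow, 0.1, 0.5, dt_fast))
# 0.20403... 0.20403...          <- lag stretched 5x for the slow grower
```

Realised resistance differs because discrete sampling lets the fast grower
recover before the first post-pulse sample; after rescaling, both species
are measured at the same point of the shared recovery curve in τ = r·t and
agree to machine precision.

The same partitioning runs on comparative LRR datasets from the command
line:

```sh
pulsestab fixtures --seed 1 --outdir fixtures
pulsestab partition --input fixtures/ratio_cases.csv \
    --groups fixtures/group_rates.csv --outdir out
# wrote 56 case reports, 7 group summaries, 6 exclusions
```

The exclusion log lists each dropped case with the rule that fired
(under-sampled group, configured exclusion list, or resistance above 50×
the median); `out/group_summary.csv` holds per-group means, medians and
quartiles of all eight metrics.

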