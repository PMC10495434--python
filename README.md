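# spinedyn

Stochastic modeling of dendritic spine size dynamics: how spontaneous
(activity-independent) fluctuations of individual synapses coexist with a
stable population-level size distribution, and how structural long-term
potentiation (sLTP) shifts that distribution.

The package is aimed at computational neuroscientists studying synaptic
tenacity and structural plasticity. It provides, as a tested library with a
CLI:

* discrete-time generative models of spine head area `V_i` (μm², one step
  per imaging acquisition): a hard-walled Gaussian random walk, a discrete
  Ornstein–Uhlenbeck (OU) process, a negative-momentum process, a
  size-dependent shifted log-normal (LN) model, and the combined **LN-OU
  model**

  ```
  V_{i+1} = V_i + Lognormal(μ_log(V_i), σ_log(V_i), −δ̂)      (noise)
                − θ̃ (V_i − μ̃)                                 (drift)
                − θ (V_i − V_{i−1})                            (momentum)
  ```

  where `μ_log(V), σ_log(V)` come from linear maps `f_μ, f_σ` of the mean
  and SD of stepwise changes onto spine size via the exact moment
  transforms of a shifted log-normal;
* stimulation protocols: a one-step substitution of the noise fits
  (optionally only for spines < 0.35 μm²) plus a persistent or
  exponentially decaying shift `μ̃_post(t) = μ̃_pre + Δμ e^{−t/τ}` of the
  drift target;
* the estimation pipeline: stepwise changes, 0.15 μm² size-binned moments
  with studentized bootstrap CIs, weighted linear fits, shift selection,
  and regression-based recovery of `(θ, θ̃, μ̃)`;
* population statistics: Shannon entropy (bits) of the binned size
  distribution, lag correlation matrices, KS-based distribution ranking
  and subsampled two-sample tests, pre/post t tests, one-way ANOVA with
  Tukey HSD, per-size-bin KS comparisons;
* a synthetic-data generator emulating the imaging study design (eight
  acquisitions at −15…40 min; 830-spine spontaneous cohort; 7- or
  15-spine stimulation cohorts with homo-/heterosynaptic labels).

## Worked example

```python
import spinedyn as sd

# a synthetic spontaneous cohort: 830 spines x 8 timepoints
cfg = sd.GeneratorConfig.for_cohort("activity_independent", seed=3)
data = sd.generate_baseline_dataset(cfg)

changes = sd.compute_stepwise_changes(data)
pooled = sd.pooled_change_stats(changes)
lag1 = sd.lag_correlation_matrix(changes).lag1_mean()
rec = sd.recover_parameters(data)
print(f"pooled change: mean {pooled.mu:+.4f}, SD {pooled.sigma:.4f}")
print(f"lag-1 change correlation: {lag1:+.3f}")
print(f"theta = {rec.theta_hat:.3f} +- {rec.se_theta:.3f}, "
      f"theta~ = {rec.theta_tilde_hat:.3f}, mu~ = {rec.mu_tilde_hat:.3f}")
```

prints

```
pooled change: mean -0.0002, SD 0.0739
lag-1 change correlation: -0.329
theta = 0.283 +- 0.014, theta~ = 0.108, mu~ = 0.362
```

The pooled stepwise changes are zero-mean and approximately Gaussian with
SD ≈ 0.074 μm²; successive changes of a spine are anti-correlated with
coefficient ≈ −θ (the momentum strength); and the estimator recovers the
generator's parameters (θ = 0.3, θ̃ = 0.1, μ̃ = 0.35 μm²) to within its
standard errors. The same workflow applies to measured data loaded with
`sd.read_series` (or `read_series_mapped` for foreign CSV layouts).

The CLI mirrors the library:

```bash
spinedyn generate --cohort stim15 --seed 1 --out stim.csv
spinedyn fit --data stim.csv --out fit.json
spinedyn analyze --data stim.csv --report report.json
```

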