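# Methods

## The modeling problem

Dendritic spine head area is a standard structural proxy for synaptic
strength. Imaged over tens of minutes, individual spines fluctuate
substantially even without induced activity, yet the population-level size
distribution — right-skewed with a long tail — is remarkably stable, and
stepwise size changes show a characteristic structure: pooled changes are
approximately Gaussian with zero mean; changes of small spines are on
average positive with a small SD while changes of large spines are on
average negative with a large SD; and successive changes of the same spine
are negatively correlated. This package models those dynamics in discrete
time (one model step per imaging acquisition; the experimental grid
−15, −10, −5, 2, 10, 20, 30, 40 min is treated as equally weighted steps
with no dt rescaling, since the recursions are defined per acquisition).

## Models

**Walled Gaussian.** `V_{i+1} = V_i + N(μ, σ)`, reset into `[W_l, W_r]`
when a proposal exits (default: "no change", i.e. the spine keeps its
previous size; a bounce-back reflection is available as an option — the
model's failure modes do not depend on the choice). Walls are constructor
inputs, intended to be the 5th percentile and the maximum of the observed
sizes. This model is retained as a documented failure case: it folds all
sub-wall mass up against the left wall (zero density below the wall, an
excess just above it relative to an unwalled walk), lets the population
mean climb toward the midpoint of the admissible interval, and has
memoryless increments, so successive changes are uncorrelated.

**Discrete OU.** `V_{i+1} = V_i + θ(μ̄ − V_i) + N(0, σ)`, the AR(1)
mean-reverting benchmark with stationary variance `σ²/(1 − (1−θ)²)`.

**Negative momentum.** `V_{i+1} = V_i + θ(V_{i−1} − V_i) + N(0, σ)`.
The change process satisfies `ΔV_{i+1} = −θ ΔV_i + η`, an AR(1) with
coefficient −θ, so the stationary lag-1 correlation of successive changes
is exactly −θ. This term supplies the observed anti-correlation without
pinning any spine to a fixed set point.

**Shifted log-normal noise.** Signed increments are modeled as
`exp(N(μ_log, σ_log)) − δ̂`, supported on `(−δ̂, ∞)`. Given a target mean
`μ_s` and SD `σ_s` of changes, the underlying-normal parameters are the
exact moment transforms

```
μ_log = log((μ_s + δ̂)² / sqrt(σ_s² + (μ_s + δ̂)²))
σ_log = sqrt(log((σ_s / (μ_s + δ̂))² + 1))
```

`δ̂` is a single dataset-level shift chosen as `|min(ΔV)|` plus a margin of
1% of the change range (minimum 10⁻⁶), so every observed change is
positive after shifting and `μ_log` stays comparable across size bins.
The size dependence enters through two linear maps `f_μ(V)` and `f_σ(V)`
(optionally linear in V², which fits the data about equally well); `f_σ`
must be positive over its declared validity range, which is checked at
construction.

**LN-OU.** The full model adds three terms to `V_i`: the size-dependent
shifted log-normal increment, a global drift `−θ̃(V_i − μ̃)` toward a
population set point, and the negative momentum `−θ(V_i − V_{i−1})`.
Individual increments are skewed, but the pooled population change is
approximately Gaussian by the central limit theorem across independent
spines. The increasing SD map makes large sizes noisier, which produces
the right-skewed stationary distribution.

Numerical choices: proposals below a floor of 0.01 μm² are clipped there
and counted (`floor_hits`); areas are physical and the recursion can
otherwise propose non-positive values. The first step of any momentum
model uses `V_{−1} = V_0`, so there is no spurious initial kick.
Simulations draw one RNG substream per step from a single root seed
(`numpy` `SeedSequence.spawn`), so changing the number of spines never
reorders draws across steps, and identical (config, init, seed) gives
bit-identical traces.

## Stimulation

Structural LTP is modeled as a perturbation of the baseline LN-OU
dynamics at one marked transition (into the +2 min acquisition, column 3
of the 8-point grid):

* the noise fits are replaced by stimulation-snapshot fits (`stim_fit`);
  in the *small-spine-only* variant only the mean map is substituted and
  only for spines below 0.35 μm², their SD staying at baseline;
* the momentum term is deactivated at the stimulation step (default).
  Deactivation also resets the momentum memory: the stimulation-induced
  jump does not enter the momentum term of the first post-stimulation
  step. Momentum is understood as a stabilization feature of spontaneous
  dynamics; letting it react to the induced jump would immediately claw
  back part of the potentiation and would make the first post-stimulation
  mean change significantly negative, contrary to the observation that
  only the stimulation transition differs from spontaneous fluctuations;
* the drift term remains active throughout (an open choice; the
  deactivation argument applies to momentum, not to the slow drift), and
  after the stimulation the target follows
  `μ̃_post(t) = μ̃_pre + Δμ e^{−t/τ}` with the post-step clock starting at
  0. `τ = ∞` gives the persistent shift seen with 15 stimulated spines;
  a finite `τ` (default 3 steps for the 7-spine protocol) decays back to
  baseline.

The phenomenology follows: substituting only the noise fits produces an
immediate jump that relaxes back (transient); shifting only the drift
produces a slow sustained rise without the jump; both together reproduce
a rapid and sustained shift with a significant entropy increase; and the
small-spine-only variant is indistinguishable in entropy from the full
substitution, because the two share the drift shift and therefore the
same relaxed distribution.

## Estimation and identifiability

Stepwise changes are binned by their start-of-step size in half-open
0.15 μm² bins anchored at 0. Per bin we report the count, sample mean and
SD, and studentized (bootstrap-t) 95% CIs with plug-in standard errors —
`s/√n` for the mean and the normal-theory `s/√(2(n−1))` for the SD —
rather than a nested bootstrap, for tractability at B = 1000. Bins with
fewer than 5 observations are flagged and excluded from fits; the linear
maps are fitted by weighted least squares with bin counts as weights and
bin centers (or squared centers) as regressors.

Drift and momentum are estimated jointly by pooled OLS of the next change
on the centered current size and the current change,

```
ΔV_{i+1} = c + b (V_i − V̄) + a ΔV_i + ε,
```

with HC1-robust standard errors (the noise SD grows with size). The
conditional mean is exactly linear in the regressors, so `θ̂ = −a` is
consistent. The drift and the noise mean map are **not separately
identifiable**: both enter the conditional mean linearly in `V_i`, and
only the combined map `f_μ(V) − θ̃(V − μ̃)` can be learned from data. The
estimator therefore adopts a canonical gauge in which the drift absorbs
the whole systematic linear mean map: `θ̃̂ = −b`,
`μ̃̂ = V̄ + c/θ̃̂` (delta-method SE; flagged NaN when `|b| < 2 SE`), and
the noise fit is made on residual changes with drift and momentum
removed, so its mean map is approximately zero while its SD map is fully
identified. Any gauge of the same law yields an observationally
equivalent recovered configuration, which is what matters for
resimulation. The raw binned fit (what one sees when plotting binned
changes against size) is reported alongside; note that it also contains a
momentum-induced component, since `E[ΔV_i | V_i] ≠ 0` under the momentum
term, so the identifiable combined slope is estimated as
`fit.slope_mu − θ̃̂` from the partial regression instead. When a series
marks a stimulation step, the changes at that transition are excluded
from baseline fitting and fitted separately.

## Synthetic data

The generator stands in for the two-photon imaging study: spine-by-
timepoint area matrices on the 8-point acquisition grid, with per-spine
labels (homosynaptic = stimulated; heterosynaptic = unstimulated
neighbors within 4 μm, emulated purely as a label since the analysis uses
no geometry; sham/baseline otherwise). Cohort defaults mirror the study
design: 830 spines for the spontaneous cohort and 204 / 338 total spines
for the 7- and 15-spine stimulation protocols. Ground truth is the LN-OU
model in the canonical gauge: `f_μ ≡ 0`, `f_σ(V) = 0.0375 + 0.085 V`,
`θ = 0.3`, `θ̃ = 0.1`, `μ̃ = 0.35 μm²`, `δ̂ = 1`. These defaults were set
once to the study conditions: pooled change SD ≈ 0.074 μm², zero-mean
Gaussian pooled changes, a stable right-skewed size distribution around
0.35 μm², lag-1 change correlation ≈ −0.3, and — via the drift — small
spines growing on average while large spines shrink, with SD increasing
in size. Initial sizes are drawn from a log-normal (median 0.32 μm²,
σ_log = 0.55) and burned in for 20 LN-OU steps so the recorded columns
are near-stationary. Stimulated spines are drawn from the middle tercile
of the pre-stimulation sizes (medium-sized spines were preferentially
targeted experimentally).

What the generator does not emulate: measurement noise of microscopy and
ROI segmentation, spatial correlations along the dendrite, missing-data
patterns of real imaging, day-scale dynamics, and any molecular
mechanism. Tests that pass on this synthetic data therefore validate the
estimator and the model's internal consistency, not the biological
correctness of the fitted dynamics on real data.

## Statistics

Shannon entropy is computed on the binned size histogram in bits
(`−Σ p log₂ p`, with `0·log 0 = 0`), using shared fixed-width 0.15 μm²
bins spanning the pooled range of all compared samples — entropies on
different supports are not comparable, so comparisons always share edges.
Absolute entropy values depend on the bin width; only differences and
orderings are interpreted. Two-sample KS tests deterministically
subsample to 500 observations per side. Distribution families (normal,
log-normal, gamma, exponential, Weibull) are fitted by maximum likelihood
and ranked by their one-sample KS statistic. Pre/post comparisons use a
two-sided t test on per-timepoint metric values, a one-way ANOVA across
per-transition change distributions, and Tukey HSD to identify which
transition deviates; raw p values are reported without multiplicity
correction, matching the analysis practice the package reproduces.

## Validation experiment sizes

The validation suite uses: 10⁴ spines × 50 steps for the momentum law;
n = 10⁶ per grid point for the moment round trip; 5000 spines × 250 steps
for the OU variance; 1000 spines with 100-step burn-in and 50 recorded
steps for stability; 100 replicates of 830 × 8 for recovery; 100
independent runs of 300 spines with a 50-step post horizon for the
stimulation sign tests (the slow AR mode of the default parameters,
≈0.92 per step, needs ~50 steps to relax, so the experimental 5-column
window shows only the onset of the decay). These sizes keep every
Monte-Carlo standard error several times smaller than the tolerance it is
checked against.

## Known limitations

* The drift/noise-mean decomposition is a convention (see
  identifiability); statements about `f_μ` alone are gauge-dependent.
* Maximum-likelihood or Bayesian fitting of the full LN-OU, per-spine
  random effects, and continuous-time SDE limits are out of scope.
* The bootstrap CIs use plug-in standard errors; for very small bins the
  studentized interval can be unstable (such bins are excluded from fits
  anyway).
* Entropy estimates on few spines are dominated by histogram sampling
  noise; analyses resample to at least ~300 spines before comparing
  entropies.
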