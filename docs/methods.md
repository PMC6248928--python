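# Methods

## The estimator

Given a spike train `t_1 < … < t_n` on a window `(0, T]`, the firing rate is
estimated by a Gaussian kernel sum whose bandwidth varies with the
evaluation time `t`.  The bandwidth is treated as a random variable: the
kernel precision `σ(t) = 1/h(t)²` gets a Gamma(α, β) prior, which is
conjugate to the Gaussian kernel likelihood (the kernel density of the
train evaluated at `t`).  The posterior of `h(t)` is then a finite mixture
with one component per spike, and its mean has the closed form

    ĥ(t) = Γ(α) Σᵢ cᵢ^(−α)  /  [ Γ(α+½) Σᵢ cᵢ^(−α−½) ],    cᵢ = (t−tᵢ)²/2 + 1/β,

so no numerical integration is ever needed at estimation time.  The rate is

    λ̂(t) = Σᵢ exp(−(t−tᵢ)² / (2 ĥ(t)²)) / (√(2π) ĥ(t)).

Intuition: near a cluster of spikes many `cᵢ` are close to their floor
`1/β`, the mixture concentrates on small `h`, and the kernel narrows;
far from all spikes every `cᵢ` is large and the bandwidth grows.

### Hyperparameters

- `alpha` (shape, dimensionless, default 4): the single tuning knob.
  Larger α shrinks the prior-mean bandwidth, tracking fast rate changes at
  the cost of variance.  The default is the MISE-minimizing value over the
  six-scenario synthetic benchmark (see below).  Prior moments of `h`
  require α > 1; the posterior-mean formula itself is finite for any
  α > 0, so the tuning grid may include α = 1 while `prior_moments`
  rejects it.
- `beta` (scale, dimensionless, default `n^(4/5)`): tied to the spike
  count so the bandwidth contracts as data accumulate, the exponent
  matching the MISE convergence rate of a fixed-bandwidth Gaussian kernel.
  For pooled multi-trial trains, `n` is the pooled count.

### Numerical choices

- All spike sums are computed as log-sum-exp of `−α log cᵢ` (and
  `−(α+½) log cᵢ`), with Γ ratios via `gammaln`; naive powers overflow for
  α near 10 with second-scale spike distances.  A test verifies the log
  path agrees with naive evaluation to 1e−10 where the latter is in range.
- The evaluation grid is uniform with step 1 ms over `[0, T]` by default
  (configurable); this resolves every benchmark rate (≤ 2 Hz).
- No boundary correction is applied: the raw kernel sum is reported near
  `t = 0` and `t = T`, which biases the estimate low at the edges.  The
  integrated estimate over a widened window recovers ≈ n (tested at 5%).
- Empty trains are an error by default (β = n^(4/5) and the bandwidth are
  undefined at n = 0); `allow_empty=True` opts into an all-zero curve.
  Single-spike trains are fine and have fully closed-form output.

## Spike-train simulators

Ground-truth spike trains come from renewal models driven through the
time-rescaling transform.  The integrated intensity
`Λ(t) = m ∫₀ᵗ λ(u) du` (multiplier `m` = γ for the inhomogeneous-Gamma
model, 1 for the inhomogeneous-inverse-Gaussian model) is computed by
cumulative trapezoid on the same 1 ms grid; i.i.d. rescaled ISIs —
Gamma(γ, θ) or inverse-Gaussian(μ, γ) — are partial-summed and mapped back
through `Λ⁻¹` by monotone linear interpolation.  Conventions the
literature leaves open, fixed here:

- the process starts fresh at `t = 0` (no stationary first-interval
  correction);
- rescaled times beyond `Λ(T)` are dropped (no events outside `(0, T]`);
- ISIs are drawn in blocks of `⌈1.5 Λ(T)/E[ISI]⌉`, extended on demand;
- exact ties after inversion (float resolution) are nudged apart by 1 ns.

The inverse-Gaussian sampler is the Michael–Schucany–Haas transformation
(chi-square root with conjugate-root rejection); it is validated by a KS
test against the closed-form CDF.  Gamma ISIs use numpy's generator.
With γ = 1 the IG model reduces exactly to an inhomogeneous Poisson
process, which the count mean/variance tests exploit.

## Rate-function families and what the synthetic data does not emulate

Five parametric intensities (chirp, sine, sawtooth, Gaussian-damped
sinusoid, square) cover slow, oscillatory, frequency-modulated and
discontinuous dynamics between ~2 and ~200 spikes/s.  The sawtooth is
evaluated through the identity `arctan(cot x) = π/2 − (x mod π)`, exact
and pole-free, with the right-limit value at each jump.  The square wave
(no published parametrization exists for it) is
`η + A·sign(sin(2πft+φ))` with `sign(0) → +1`, chosen to mirror the
sawtooth's parameter names; it is exercised by unit tests but has no
benchmark presets because its tested frequency/intensity values are not
published.  Parameter sets that would produce a negative rate anywhere
are rejected at construction via the families' closed-form minima
(`A ≤ η`, or `A ≤ 1` for the damped sinusoid).

The simulators emulate single-unit renewal firing with refractoriness
(γ > 1) or bursting (γ < 1).  They do not emulate slow nonstationarity
across trials, rate–history coupling (adaptation, Hawkes-style
self-excitation), recording artifacts, or spike-sorting errors — passing
benchmarks here says nothing about robustness to those.

## Benchmarking protocol

`integrated_squared_error` is the Riemann sum `Δt Σ (λ̂−λ)²` on the
shared grid; `mise_experiment` averages it over seeded repetitions and
attaches a normal-approximation 95% CI (mean ± 1.96·SE).  Zero-spike
repetitions (vanishingly rare at benchmark intensities) are redrawn from
the next substream and logged rather than scored as infinite.
Substreams are keyed as `[seed, crc32(scenario label), repetition,
attempt]`, so a scenario generates identical trains whether scored alone
or inside a sweep, and repetitions are independent and reproducible.

Multi-trial scenarios superimpose k trials into one train, smooth it as a
single train (β from the pooled count), and divide the estimate by k
before scoring: the pooled train's kernel estimate integrates to the
pooled count, i.e. it estimates k·λ(t), and without the normalization the
benchmark error would grow ~k² instead of showing the multi-trial
improvement the protocol measures.

`tune_alpha` scores the *same* generated trains at every α on the grid
(default 1…10 in 0.5 steps), per scenario, sharing each train's
spike-to-grid distance matrix across the α loop for speed; the selected α
minimizes the across-scenario average MISE, ties toward the smaller α.
The weighted variant `weighted_mise` divides the pointwise error by an
asymmetric credible-interval width (upper interval where the estimate
exceeds the reference, lower otherwise) before squaring, for use when the
reference itself is an uncertain multi-trial estimate.

The six benchmark tuning scenarios (IG and IIG × chirp/sine/sawtooth at
η = 50, A = 25 spikes/s, medium frequency, 2 s, 100 repetitions) put the
average-MISE optimum at α = 4, the shipped default.  A caveat worth
stating: near the optimum the MISE-versus-α curve is flat relative to its
Monte-Carlo error (adjacent grid points differ by ≲ 1 (spikes/s)²·s
against CIs of ± ≈ 9 at 100 repetitions), so the *argmin* on a 0.5-step
grid wanders by about one grid step across seeds — per-scenario
minimizers land at 3–6 depending on scenario, with the sine scenarios'
minimum (α = 3) the most stable.  The test suite therefore asserts
minimizers to within one to two grid steps at reduced repetition counts,
not exact grid points.

On consistency: the absolute ISE of an intensity estimate grows with the
rate level (estimator variance scales like λ/ĥ), so raising a homogeneous
rate 10× *increases* raw ISE even as the estimate improves relative to
the signal; the consistency test accordingly checks that the relative
error ISE/(λ²T) decreases.

## Problem sizes

Defaults follow the benchmark protocol (100 repetitions per scenario, 19
α values, 1 ms grids).  The test suite runs the tuning sweep at 20
repetitions and trend checks at 15 repetitions — enough to resolve the
orderings they assert while keeping the whole suite around a minute of
compute; the acceptance script runs the full 100-repetition protocol
(about three minutes).

## Known limitations

- Edge bias at the window boundaries (no reflection or renormalization).
- The bandwidth posterior conditions on one evaluation time at a time;
  nothing enforces smoothness of ĥ(t) beyond what the formula implies.
- β = n^(4/5) assumes stationarity of the overall spike budget; strongly
  inhomogeneous trains with very few spikes can oversmooth.
- Benchmarks are renewal-model synthetic data; see the caveats above.
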