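# baks — Bayesian adaptive kernel smoothing of spike trains

Estimating a neuron's firing rate λ(t) from a **single trial** is hard:
one spike train is a sparse sample of its intensity, fixed-bandwidth
kernel smoothers simultaneously over-smooth fast transients and
under-smooth quiet stretches, and trial averaging (PSTHs) destroys exactly
the single-trial dynamics many analyses — trial-to-trial variability,
brain-machine-interface decoding, single-trial cognitive signatures — need.

This package implements the Bayesian adaptive kernel smoother (BAKS): a
Gaussian-kernel rate estimator whose bandwidth `h(t)` is a random variable
at each evaluation time.  A Gamma(α, β) prior on the kernel *precision*
`1/h(t)²` is conjugate to the Gaussian kernel likelihood, so the posterior
mean bandwidth is available in closed form:

```
ĥ(t)  =  Γ(α)   Σᵢ [ (t−tᵢ)²/2 + 1/β ]^(−α)
         ─────────────────────────────────────── ,
         Γ(α+½) Σᵢ [ (t−tᵢ)²/2 + 1/β ]^(−α−½)

λ̂(t)  =  Σᵢ  exp( −(t−tᵢ)² / 2ĥ(t)² ) / ( √(2π) ĥ(t) )
```

The bandwidth contracts where spikes are dense and dilates where they are
sparse, with no numerical integration and no iteration — a single pass
over the spikes per grid point.  Defaults are α = 4 (the MISE-optimal
value on the synthetic benchmark below) and β = n^(4/5) (tied to the spike
count so the bandwidth shrinks as data accumulate).

The package also provides everything needed to validate such an estimator:

- **`baks.rates`** — parametric ground-truth intensities (chirp, sine,
  sawtooth, Gaussian-damped sinusoid, square) and their integrated forms;
- **`baks.simulate`** — inhomogeneous Gamma (IG) and inverse-Gaussian
  (IIG) renewal spike-train generators via time rescaling, including a
  Michael–Schucany–Haas inverse-Gaussian sampler and trial superposition;
- **`baks.evaluation`** — ISE/MISE and credible-interval-weighted MISE
  metrics, the α-tuning sweep, and a registry of the benchmark scenarios;
- **`baks.cli`** — a `baks` command with `simulate`, `estimate`, `tune`
  and `evaluate` subcommands.

See `docs/methods.md` for the model assumptions, numerical choices and
known limitations.

## Worked example

Simulate one 2 s spike train from the benchmark sine-rate IG scenario
(η = 50, A = 25 spikes/s, f = 1 Hz, φ = −π/2; Gamma ISIs with γ = 4,
θ = 1), then smooth it:

```sh
$ baks simulate --preset tuning/IG/sine --seed 7 --out spikes.txt
$ wc -l < spikes.txt
110
$ baks estimate --spikes spikes.txt --duration 2 --alpha 4 --out est.csv
$ head -3 est.csv
time_s,bandwidth_s,rate_hz
0.000000000,0.087820049,14.736490801
0.001000000,0.087733471,14.904211669
```

The output CSV holds the adaptive bandwidth and the rate estimate on a
1 ms grid.  With 110 spikes the bandwidths hover near 85 ms and the
estimate tracks the true rate within its sampling error:

| t (s) | ĥ(t) (s) | λ̂(t) (spikes/s) | true λ(t) |
|-------|----------|------------------|-----------|
| 0.5   | 0.0838   | 76.09            | 75.00     |
| 1.0   | 0.0861   | 31.44            | 25.00     |
| 1.5   | 0.0835   | 85.17            | 75.00     |

Scoring the estimator over 20 fresh trains of the same scenario:

```sh
$ baks evaluate --preset tuning/IG/sine --reps 20 --seed 7
MISE = 105.3259 +/- 24.8690 (95% CI)
```

i.e. a mean integrated squared error of ≈ 105 (spikes/s)²·s over the 2 s
window, with its 95% confidence half-width.  The same protocol drives the
hyperparameter sweep (`baks tune`), which scores every α on a grid against
the six benchmark scenarios and prints the per-scenario and overall
MISE-minimizing α.

The same functionality is available as a library:

```python
import numpy as np
from baks import BAKSConfig, SpikeTrain, adaptive_bandwidth, estimate_rate, time_grid

train = SpikeTrain(np.loadtxt("spikes.txt"), duration=2.0)
grid = time_grid(2.0, 1e-3)
curve = estimate_rate(train, BAKSConfig(alpha=4.0), grid)   # beta = n^(4/5)
```

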