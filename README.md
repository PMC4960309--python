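# spikemap

Spike inference from single-neuron calcium fluorescence traces by
maximum-a-posteriori estimation on a discretized continuous state space,
with per-neuron autocalibration of the model parameters.

Two-photon calcium imaging reports action potentials only indirectly: each
spike triggers a fluorescence transient of amplitude *A* (ΔF/F) that decays
with time constant *τ*, distorted by the indicator's nonlinearity, riding on
a slowly drifting baseline *B(t)*, and buried in photonic and systemic
noise. `spikemap` inverts this generative model. It is aimed at
experimenters who need actual spike trains (not just smoothed rates) from
noisy population recordings, and at methodologists who want a transparent,
testable reference implementation of histogram-filter MAP spike inference.

## Model and algorithm

The forward model, discretized at the frame interval Δt, is

    c_t = c_{t−1} · exp(−Δt/τ) + n_t              (normalized calcium)
    B_t = B_{t−1} + η √Δt · w_t                   (baseline drift)
    y_t = B_t · (1 + A·g(c_t)) + σ ε_t            (measurement)

with `n_t` the spike count in frame *t* (Poisson prior with rate λ,
truncated at `nmax`), and `g` a normalized probe response — saturating for
organic dyes (γ = inverse of the half-saturation spike count), cubic
polynomial or Hill-type for GECIs, optionally with a finite binding time
τ_on and a fixed onset delay.

The MAP spike train maximizes p(x₁…x_T | y₁…y_T) over the hidden states
x_t = (c_t, B_t) by a backward Viterbi recursion on a grid (histogram
filter), with cubic-spline interpolation along calcium and a locally
refined baseline search, followed by a forward collecting sweep — linear
time in trace length. The same machinery, with sums in place of maxima,
returns per-bin spike probabilities P(n_t = k | y) and posterior sample
trajectories. An autocalibration routine estimates *A* (from the peak
structure of the isolated-transient amplitude histogram), *τ*
(least-squares transient fits) and *σ* (3–20 Hz band RMS with a
Monte-Carlo corrective factor) from the fluorescence alone.

Noise is quantified throughout as the 0.1–3 Hz band RMS divided by *A* —
the frequency band that actually competes with the calcium transient.

## Worked example

```python
import numpy as np
from spikemap import (ModelParams, gen_poisson_train, simulate_trace,
                      NoiseSpec, map_spikes, match_spikes, error_rate)

params = ModelParams(A=0.10, tau=1.0, probe="saturating", gamma=0.1,
                     sigma=0.03, lam=0.1)
spikes = gen_poisson_train(rate=0.5, duration=10.0, seed=1)
trace, _ = simulate_trace(spikes, params, duration=10.0, dt=0.01,
                          noise=NoiseSpec(kind="white", level=0.1), seed=2)

result = map_spikes(trace, params)
m = match_spikes(spikes, result.spikes, tolerance=0.5)
sens, prec, er = error_rate(m)
print("true:", np.round(spikes.times, 2))
print("est :", np.round(result.spikes.times, 2))
print(f"sensitivity={sens:.2f} precision={prec:.2f} ER={er:.2%}")
```

Output:

```
true: [0.28 3.03 3.3  5.38 5.5  7.54 7.88]
est : [0.3  3.04 3.3  5.38 5.5  7.52 7.9 ]
sensitivity=1.00 precision=1.00 ER=0.00%
```

All seven spikes are recovered within one or two 10 ms frames of their true
times; the error rate is 1 minus the harmonic mean of sensitivity and
precision at a 0.5 s matching tolerance.

The same operations are available from the shell:

```bash
spikemap simulate --rate 0.5 --duration 30 --noise-level 0.1 --seed 1 --out sim
spikemap infer sim.csv --mode map --out est
spikemap evaluate sim.spikes.txt est.spikes.txt
spikemap autocalibrate sim.csv --probe ogb --out cal.yaml
spikemap benchmark --n-trials 20 --noise-level 0.2
```

Every run writes a YAML manifest (parameters, seed, version) from which it
can be replayed.

## Layout

| module | contents |
|---|---|
| `spikemap.model` | parameter/trace/spike-train types, probe nonlinearities, forward simulation |
| `spikemap.synth` | Poisson and bursty spike generators, calibrated white/drift/pink noise |
| `spikemap.engine` | grid construction, backward MAP pass, collection, smoothing, sampling, exhaustive oracles |
| `spikemap.autocal` | σ estimator, calcium-event detection, amplitude histogram, (A, τ) calibration |
| `spikemap.metrics` | spike matching, error rates, rate correlation, noise level, PMT gain |
| `spikemap.bench` | the simulation benchmark harness |
| `spikemap.io`, `spikemap.cli` | text formats, manifests, command-line entry points |

See `docs/methods.md` for the full model description, numerical choices and
limitations.
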