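# Methods

## Generative model

A neuron's fluorescence trace is modelled in three layers.

**Calcium.** A normalized intracellular calcium variable `c` is 0 at rest and
jumps by 1 per action potential; between spikes it relaxes exponentially with
time constant `tau` (seconds). Discretized at the frame interval `dt`, with
`n_t` the number of spikes emitted in frame `t`:

    c_t = c_{t-1} * exp(-dt/tau) + n_t

Decay is applied before the spike increment, so an isolated spike from rest
gives `c = 1` exactly and hence a transient of amplitude exactly `A`.

**Probe response.** A dimensionless response curve `g(c)` normalized so that
`g(0) = 0` and `g(1) = 1` maps calcium to relative fluorescence change:

| probe        | g(c)                                              | used for |
|--------------|---------------------------------------------------|----------|
| `linear`     | `c`                                               | idealized dye |
| `saturating` | `(1+gamma) c / (1 + gamma c)`                     | OGB-type organic dyes |
| `polynomial` | `(1-p2-p3) c + p2 c^2 + p3 c^3`                   | GECIs (phenomenological) |
| `hill`       | `(h(c)-h(0)) / (h(1)-h(0))`, `h` a Hill curve     | GECIs (cooperative binding) |
| `hill_rise`  | Hill curve reached with first-order kinetics      | GECIs with finite rise time |

`gamma` is the inverse of the number of spikes at which the dye reaches half
saturation (the saturating `g` is bounded by `(1+gamma)/gamma` and crosses
half that bound at `c = 1/gamma`). The polynomial coefficients are constrained
so the unit response is exact; standard fixed values are `gamma = 0.1` (OGB),
`[p2, p3] = [0.73, -0.05]` (GCaMP6s) and `[0.55, 0.03]` (GCaMP6f). Cubic fits
are local approximations: with `p3 < 0` the GCaMP6s curve necessarily turns
over near `c ~ 10`, so it is trusted only on the physiological range (about
`c <= 8`). The `hill` probe with `n = 1, c0 = 0` reduces algebraically to the
saturating curve. For `hill_rise`, the normalized bound-probe fraction `p`
relaxes toward `g(c)` with time constant `tau_on` (exact exponential update,
stable for any `dt`), and the measurement reads `p` instead of `g(c)`.
GECI onset latency is modelled as a pure time shift `delay` of spike effect
(20 ms GCaMP6s, 10 ms GCaMP6f); estimated spike times are shifted back by the
same amount.

**Measurement.** Fluorescence is the product of a drifting baseline with the
probe response, plus white noise:

    F_t = B_t * (1 + A * g(c_t)) + sigma * eps_t,    eps_t ~ N(0, 1)

Traces are handled in relative units with resting baseline near 1. The
baseline performs a Gaussian random walk of amplitude `eta` (dF/F s^-1/2),
simulated additively and reflected at zero; the drift prior in the estimator
uses the matching Gaussian step density with SD `eta*sqrt(dt)`.

Parameters and defaults: `A` (unitary amplitude, dF/F; typical 4-10%), `tau`
(decay, s; 0.4-1.6 s), `sigma` (noise SD per frame, dF/F), `eta` (drift,
default 0.02 dF/F s^-1/2 — the estimator-side value is deliberately fixed
rather than estimated, see Autocalibration), `lam` (a-priori spike rate,
fixed to 0.1 sp/s in estimation because `lam` and `sigma` act redundantly),
`nmax` (spike cap per frame, default 3).

## Noise level

Estimation difficulty is quantified by the RMS of the noise restricted to the
0.1-3 Hz band (computed by periodogram masking, Parseval-consistent) divided
by the unitary amplitude `A` — the band that overlaps the spectrum of the
calcium transient itself. The synthetic generators produce white, drifting
(white + a <0.1 Hz low-passed random walk at equal total RMS; the in-band
mixing ratio is degenerate because the walk lies below the band) and pink
(1/f power, inverse-FFT synthesis with random phases, zero DC) noise, each
rescaled against its *realized* periodogram so the prescribed level holds per
trial exactly. At a matched band level, pink noise carries *less* total
variance than white noise because its power is concentrated in the band;
equivalently, at matched total RMS pink noise has the higher noise level.
For real recordings, the residual against the model prediction replaces the
noise, and `A` is replaced by the effective one-spike amplitude
`A' = A*g(2)/2` (or `A*g(15)/15` for GCaMP5k), which is below `A` for
saturating probes and above it for supra-linear ones. A PMT photonic-gain
calibration from high-rate bead recordings (variance of the >200 Hz component,
rescaled for the flat shot-noise spectrum, divided by the mean) separates the
photonic contribution.

## MAP estimation on a discretized state space

The hidden state per frame is `x_t = (c_t, B_t)` (plus `p_t` for
`hill_rise`). Spike counts have a Poisson(`lam*dt`) prior truncated at `nmax`
*without* renormalization (the truncated mass is negligible for
`lam*dt << 1`). The MAP path maximizes the posterior via a backward Viterbi
recursion over a grid (default 100 calcium x 100 baseline values) storing the
conditional best log probability `m_t(x_t)` of trajectories starting at each
grid state:

    m_T(x) = log p(y_T | x)
    m_t(x) = log p(y_t | x) + max_{n, B'} [ log P(n) + log p(B' | B)
                                            + m_{t+1}(c e^{-dt/tau} + n, B') ]

Numerical choices:

- **Calcium interpolation.** Children `c e^{-dt/tau} + n` fall off the grid;
  `m_{t+1}` is evaluated there through a precomputed natural-cubic-spline
  interpolation matrix per spike count (one matrix multiply per count and
  step). Interpolating the log table keeps the operation well conditioned
  because log emissions are locally near-quadratic.
- **Saturating grid top.** Children are clamped at the top of the calcium
  grid (`c' = min(., c_max)`, default `c_max = 10`) rather than excluded. A
  hard exclusion makes `m_t` discontinuous at the branch cut-offs and spline
  interpolation rings at discontinuities, which measurably corrupts the
  tables; the saturating dynamics keep `m_t` continuous, and `c_max` is set
  well above the active range so clamped paths carry negligible mass. The
  exhaustive oracles apply the identical clamped dynamics.
- **Baseline maximization.** For each parent, only a window of grid children
  (default 5, centered) is scanned; the discrete winner is refined by
  analytic maximization of the local three-point quadratic, so the chosen
  baseline need not lie on the grid. With `eta = 0` the baseline dimension is
  frozen and each column runs an independent recursion; the final argmax then
  selects the best constant baseline, which is how an unknown flat baseline
  is estimated.
- **Grid placement.** Calcium values use square-root spacing on
  `[0, c_max]` (denser near 0 to resolve single spikes); the baseline grid
  spans +/-30% around the trace's 10th percentile. Both sizes can be reduced
  to ~30 without changing benchmark error rates (verified by test).
- **Collection.** A single forward sweep emits the path. At each step the
  one-step objective is re-maximized *at the actual (off-grid) parent state*
  from the stored `m_{t+1}` table (spline basis along calcium, window plus
  quadratic refinement along the baseline). Snapping the decision to the
  nearest grid point instead was measured to flip near-marginal spike
  decisions (posterior gaps of order 0.03 log units) on a few percent of
  small instances; local re-maximization restores exact agreement with
  exhaustive enumeration. The reported log posterior is recomputed exactly
  from the emitted path, never read off the interpolated tables.
- **Initial state.** `c_1` and `B_1` carry uniform priors over the grid; a
  truncated-normal prior on `c_1` derived from the a-priori rate (stationary
  mean `lam*tau`, variance `lam*dt/(1-e^{-2dt/tau})`) is available behind a
  flag, and a known initial calcium or baseline can be pinned in the
  configuration. Log-space arithmetic with per-step shift normalization
  prevents underflow. Ties in the argmax resolve to the lowest spike count
  (numpy argmax keeps the first maximum).
- **hill_rise.** The bound fraction evolves deterministically, so it enters
  as a companion dimension handled by one extra precomputed interpolation
  (per spike count and parent calcium), not an extra maximization. Memory
  scales as `T * nc * n_p * nb`; the default grids suit traces up to a few
  hundred frames, which covers the intended use (short GECI segments).

Runtime is linear in trace length; a 30 s, 100 Hz trace with the default
grids runs in a few seconds on one core.

## Spike probabilities and posterior samples

Replacing max by sum in the same recursions gives forward filtering
`p(x_t | y_1..t)` and the backward conditional likelihood
`p(y_t..y_T | x_t)`, using the same spline operators (the forward pass uses
their transposes as mass-spreading adjoints — the small negative weights of
the cubic cardinal functions are deliberately *not* clipped, since clipping
breaks the adjoint pairing and biases the marginals) and a row-normalized
discrete Gaussian kernel for the baseline step. Per-bin spike marginals
`P(n_t = k | y)` pair the two passes across each transition and sum to one;
per-step normalizers accumulate into the log evidence. Posterior sample
trajectories are drawn ancestrally from the backward tables (calcium kept
continuous, baseline sampled on the grid, backward table evaluated by linear
interpolation along calcium); empirical sample frequencies reproduce the
marginals within Monte-Carlo error.

## Autocalibration of A, tau, sigma

- **sigma**: RMS of the 3-20 Hz zero-phase band-passed trace (order-2
  Butterworth, `sosfiltfilt`) times a corrective factor determined once per
  (frame rate, band) by Monte-Carlo on unit white noise so that pure white
  noise returns its true SD; for the OGB and GCaMP6f profiles the result is
  deliberately multiplied by 0.7 — underestimating `sigma` balances misses
  against false detections at low SNR. Estimated per session; scale
  equivariant by construction.
- **Event detection**: the MAP engine runs with the discrete spike choice
  replaced by "no event" versus a calcium jump of arbitrary amplitude at
  least `A_min` (4% for OGB), implemented by a suffix maximum over the
  calcium grid, with working parameters `A = 10%`, `tau = 0.8 s` and a
  detection grid that is linearly spaced (the grid pitch is the amplitude
  resolution).
- **Event selection**: events closer than 1 s to a neighbour or larger than
  25% dF/F are excluded and their predicted transients subtracted; kept
  amplitudes and a shared `tau` are re-fit by least squares (amplitudes and a
  flat offset enter linearly; `tau` by bounded scalar search).
- **Amplitude histogram**: 40 bins on `[0, 1.2*max]`; smoothed with a
  1-bin-SD Gaussian (`x1`); peak-enhanced by dividing by an 8-bin-SD
  low-passed copy (`x2`); scored by `x3(A) = x2(A) + x2(amp2(A))/2` where
  `amp2(A) = A*g(2)` is the two-spike amplitude under the probe nonlinearity;
  `A` is the argmax of `x3` on `[4%, 10%]`. Kernel widths are package
  choices (the scheme fixes their roles, not their values) sized to resolve
  peaks separated by `A_min` at realistic event counts; all are exposed as
  arguments.
- **Count assignment**: the boundary between `k` and `k+1` spikes sits at
  the response to `k + 0.3` spikes, i.e. `A*g(k+0.3)` (linear probe:
  `(k+0.3)A`); events at or below `g(0.3)A` are dropped.
- **Final calibration**: `(A, tau)` by least squares of the forward model
  against the cleaned traces given the assigned spike trains, optimized in
  log space with per-trial flat offsets profiled out.
- Trials are pooled for `A` and `tau`; `sigma` stays per session. `lam` is
  fixed at 0.1 sp/s, `eta` at 0.02 dF/F s^-1/2, and the nonlinearity at the
  per-probe profile values; nonlinearity parameters and `tau_on` are not
  autocalibrated (they mainly shape high-rate episodes where single-spike
  information is scarce). When fewer than three usable isolated events
  survive, the result falls back to per-profile mean values and is flagged.

## Spike-train metrics

Reference and estimated trains are aligned by a minimum-cost,
order-preserving dynamic program with insertion/deletion cost 1 and shift
cost `|dt| / tolerance`; shifts beyond the tolerance (default 0.5 s) are
disallowed, making the tolerance the exact matching radius. The error rate
is `ER = 1 - F1`, one minus the harmonic mean of sensitivity and precision,
which is biased toward the worse of misses and false detections; multi-trial
reports pool the matched/missed/false counts before computing rates. The
mean temporal error averages `|dt|` over matched pairs. Rate-based
comparisons bin true counts at 40 ms and smooth estimated counts with a
100 ms Gaussian kernel before Pearson correlation (note this measure is
invariant to affine rescaling of the estimated rate, a documented
shortcoming; identical trains only reach r = 1 when no smoothing is applied).

## Synthetic designs and what they show

The benchmark harness draws homogeneous Poisson trains (rate uniform in
0.1-1 sp/s per trial by default), simulates 30 s at 100 Hz with a flat
baseline withheld from the estimator, adds calibrated noise, and gives the
estimator the generating `A`, `tau`, nonlinearity and the realized noise SD.
The autocalibration study uses bursty trains — Poisson events at 0.3 /s,
geometric spike counts of mean 1 (zero allowed), within-burst intervals
Gaussian with 10 ms mean and 2 ms SD (the SD is a package choice) — with
`A` log-uniform on 4-10% and `tau` log-uniform on 0.4-1.6 s, three 30 s
trials per neuron at 50 Hz, the noise-level sweep reusing the same neurons
and noise shapes at every level.

Problem sizes in the shipped tests (20 benchmark trials; 200 oracle
instances of 12 bins; 8-10 neurons for the autocalibration comparisons) are
chosen as the smallest designs at which the pooled quantities are stable;
they are statements about these synthetic conditions, not about real
recordings. In particular the simulations contain no photobleaching,
movement artifacts, neuropil contamination, or model mismatch in `g`; on
real data those effects dominate the error budget, so error levels on real
recordings cannot be predicted from these simulations alone and require
electrophysiology-paired data to measure.

## Known limitations

- Grid memory for `hill_rise` restricts MAP to moderate trace lengths, and
  the probability/sampling modes support the instantaneous-binding probes
  only.
- The exhaustive oracles require a fixed (or few-valued constant) baseline
  and `eta = 0`; with drift the baseline search-space cannot be enumerated.
- Autocalibration degrades above noise level ~0.2 and at high spike rates,
  where amplitude histogram peaks merge; the fallback then returns profile
  means.
- The MAP log posterior is exact for the emitted path, but the path itself
  is optimal only up to grid/interpolation resolution; agreement with
  exhaustive search is verified on small instances, not provable in general.
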