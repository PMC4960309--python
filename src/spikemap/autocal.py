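"""Per-neuron autocalibration of the model parameters A, tau and sigma.

The measurement-noise SD sigma is read from the 3-20 Hz spectral
content of the trace, where calcium transients contribute little.  The
unitary amplitude A exploits the discreteness of spiking: transient
amplitudes cluster at the responses to 1, 2, ... spikes, so a peak-
enhanced histogram of isolated-event amplitudes locates A.  The decay
tau comes from least-squares fitting of the transient shapes.  The
remaining parameters (nonlinearity, drift amplitude eta, a-priori rate
lam) influence the estimation much less and stay at fixed per-probe
defaults.

Pipeline (:func:`autocalibrate`): detect calcium events of arbitrary
amplitude with working parameters -> keep isolated, moderate events and
refit their amplitudes -> histogram cost over A -> assign per-event
spike counts -> final least-squares calibration of (A, tau).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sp_signal
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import least_squares, minimize_scalar

from .engine import EngineConfig, map_calcium_events
from .model import ModelParams, PROBE_PROFILES, SpikeTrain, Trace, nonlinearity

__all__ = [
    "CalibrationResult",
    "estimate_sigma",
    "detect_events",
    "select_isolated_events",
    "histogram_cost_A",
    "assign_spike_counts",
    "calibrate_A_tau",
    "fit_single_exponential",
    "autocalibrate",
]

# estimation-time defaults that are deliberately not autocalibrated
FIXED_LAM = 0.1      # a-priori event/spike rate, sp/s
FIXED_ETA = 0.02     # baseline drift amplitude, dF/F * s^(-1/2)
WORKING_A = 0.10     # working amplitude for event detection
WORKING_TAU = 0.8    # working decay for event detection, s
SIGMA_BIAS = 0.7     # deliberate underestimation for OGB / GCaMP6f

# fallback parameter means per probe profile when no usable events are found
PROFILE_FALLBACK = {
    "ogb": (0.052, 0.81),
    "gcamp6s": (0.07, 0.8),
    "gcamp6f": (0.07, 0.4),
    "linear": (0.07, 0.8),
}


@dataclass
class CalibrationResult:
    A_hat: float
    tau_hat: float
    sigma_hat: List[float]
    events: List[Tuple[float, float]] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)
    fallback: bool = False


_SIGMA_FACTOR_CACHE: dict = {}


def _sigma_corrective_factor(fs: float, band: Tuple[float, float]) -> float:
    """Factor mapping band-filtered RMS back to the white-noise SD.

    Determined by Monte-Carlo: the 3-20 Hz zero-phase band-pass applied
    to unit white noise retains a known RMS fraction; the inverse of
    that fraction makes the estimator unbiased on pure white noise.
    Cached per (frame rate, band).
    """
    key = (round(fs, 6), band)
    if key not in _SIGMA_FACTOR_CACHE:
        sos = _sigma_sos(fs, band)
        rng = np.random.default_rng(12345)
        x = rng.standard_normal(2**20)
        y = sp_signal.sosfiltfilt(sos, x)
        _SIGMA_FACTOR_CACHE[key] = 1.0 / float(y.std())
    return _SIGMA_FACTOR_CACHE[key]


def _sigma_sos(fs: float, band: Tuple[float, float]):
    nyq = fs / 2.0
    hi = min(band[1], 0.95 * nyq)
    return sp_signal.butter(2, [band[0] / nyq, hi / nyq], btype="band", output="sos")


def estimate_sigma(
    trace: Trace,
    probe_profile: str = "",
    band: Tuple[float, float] = (3.0, 20.0),
    bias: Optional[float] = None,
) -> float:
    """Noise SD from the RMS of the 3-20 Hz band-passed trace.

    The RMS of the zero-phase band-passed signal is multiplied by a
    Monte-Carlo corrective factor so that pure white noise returns its
    true SD, then by a deliberate 0.7 bias for the OGB and GCaMP6f
    profiles (underestimating sigma balances misses against false
    detections at low SNR).
    """
    fs = trace.rate
    if fs <= 2 * band[0]:
        raise ValueError("frame rate too low for the sigma estimation band")
    if fs < 2 * band[1]:
        warnings.warn("estimation band clipped at the Nyquist frequency")
    if len(trace) < 30:
        raise ValueError("trace shorter than the filter transient")
    sos = _sigma_sos(fs, band)
    y = sp_signal.sosfiltfilt(sos, trace.values)
    sigma = float(y.std()) * _sigma_corrective_factor(fs, band)
    if bias is None:
        bias = SIGMA_BIAS if probe_profile.lower() in ("ogb", "gcamp6f") else 1.0
    return sigma * bias


def working_params(probe_profile: str, sigma: float) -> ModelParams:
    """Event-detection parameters: A = 10%, tau = 0.8 s, fixed defaults."""
    prof = PROBE_PROFILES.get(probe_profile.lower(), PROBE_PROFILES["linear"])
    return ModelParams(
        A=WORKING_A,
        tau=WORKING_TAU,
        sigma=max(sigma, 1e-4),
        eta=FIXED_ETA,
        lam=FIXED_LAM,
        **prof,
    )


# detection grid: linear calcium spacing sets the amplitude resolution
# (c_max = 3.5 working-A units covers events up to ~35% dF/F; larger ones
# are excluded downstream anyway)
DETECT_CONFIG = EngineConfig(nc=100, nb=60, c_max=3.5, c_spacing="linear")


def detect_events(
    trace: Trace,
    params: ModelParams,
    a_min: float = 0.04,
    config: Optional[EngineConfig] = None,
) -> List[Tuple[float, float]]:
    """Detect calcium events of arbitrary amplitude >= a_min.

    Runs the MAP engine with the discrete spike-count maximization
    replaced by a continuous amplitude maximization (minimum amplitude
    imposed); returns (time, amplitude) pairs.
    """
    events, _ = map_calcium_events(
        trace, params, config=config or DETECT_CONFIG, a_min=a_min
    )
    return events


def _event_kernel(t: np.ndarray, t_event: float, tau: float) -> np.ndarray:
    # include the event's own frame: times are bin centers, so an event
    # anywhere inside a bin peaks at that bin
    dt = t[1] - t[0] if t.size > 1 else 0.0
    k = np.exp(-np.maximum(t - t_event, 0.0) / tau)
    k[t < t_event - 0.5 * dt] = 0.0
    return k


def merge_burst_events(
    events: Sequence[Tuple[float, float]], window: float = 0.1
) -> List[Tuple[float, float]]:
    """Merge detections closer than ``window`` into single calcium events.

    A spike burst is one calcium event; at low noise the detector can
    resolve it into separate jumps a frame or two apart, which would then
    be discarded wholesale by the isolation rule.  Amplitudes add.
    """
    merged: List[list] = []
    for t, a in sorted(events):
        if merged and t - merged[-1][0] < window:
            merged[-1][1] += a
        else:
            merged.append([t, a])
    return [(t, a) for t, a in merged]


def select_isolated_events(
    events: Sequence[Tuple[float, float]],
    trace: Trace,
    params: ModelParams,
    min_separation: float = 1.0,
    max_amplitude: float = 0.25,
    tau_bounds: Tuple[float, float] = (0.05, 5.0),
    merge_window: float = 0.1,
):
    """Keep isolated, moderate events; refit their amplitudes and tau.

    Detections closer than ``merge_window`` are first merged (a burst is
    one event).  Events closer than ``min_separation`` (1 s) to another
    event or of amplitude above ``max_amplitude`` (25% dF/F) are
    excluded; their predicted transients are subtracted from the trace.
    The kept events' amplitudes and a shared decay tau are then
    re-estimated by least squares on the cleaned trace (amplitudes and a
    constant baseline enter linearly, tau by a bounded scalar search).

    Returns (kept events with refitted amplitudes, tau_refit, cleaned
    trace values).
    """
    events = merge_burst_events(events, merge_window)
    times = np.array([e[0] for e in events])
    amps = np.array([e[1] for e in events])
    keep = np.ones(times.size, dtype=bool)
    if times.size > 1:
        gaps_prev = np.diff(times, prepend=-np.inf)
        gaps_next = np.diff(times, append=np.inf)
        keep &= (gaps_prev >= min_separation) & (gaps_next >= min_separation)
    keep &= amps <= max_amplitude
    t = trace.t
    cleaned = trace.values.astype(float).copy()
    for tc, a in zip(times[~keep], amps[~keep]):
        cleaned -= a * _event_kernel(t, tc, params.tau)
    kept_times = times[keep]
    if kept_times.size == 0:
        return [], params.tau, cleaned

    def design(tau):
        cols = [np.ones_like(t)]
        cols += [_event_kernel(t, tc, tau) for tc in kept_times]
        return np.column_stack(cols)

    def sse(tau):
        X = design(tau)
        beta, *_ = np.linalg.lstsq(X, cleaned, rcond=None)
        r = cleaned - X @ beta
        return float(r @ r)

    res = minimize_scalar(sse, bounds=tau_bounds, method="bounded")
    tau_refit = float(res.x)
    X = design(tau_refit)
    beta, *_ = np.linalg.lstsq(X, cleaned, rcond=None)
    refit = [(float(tc), float(a)) for tc, a in zip(kept_times, beta[1:])]
    refit = [(tc, a) for tc, a in refit if a > 0]
    return refit, tau_refit, cleaned


def two_spike_amplitude(A: float, params: ModelParams) -> float:
    """dF/F amplitude of a two-spike transient under the probe nonlinearity."""
    return A * float(nonlinearity(2.0, params))


def histogram_cost_A(
    amplitudes: Sequence[float],
    params: ModelParams,
    bounds: Tuple[float, float] = (0.04, 0.10),
    n_bins: int = 40,
    smooth_sd_bins: float = 1.0,
    lowpass_sd_bins: float = 8.0,
):
    """Estimate A from the peak structure of the event-amplitude histogram.

    The histogram is smoothed (x1), peak-enhanced by dividing by a
    low-passed version of itself (x2), and scored by
    x3(A) = x2(A) + x2(amp2(A))/2, where amp2(A) is the amplitude of a
    two-spike transient under the probe nonlinearity (2A for a linear
    probe).  Returns (A_hat, diagnostics) with A_hat the argmax of x3
    over [A_min, A_max].
    """
    amps = np.asarray(list(amplitudes), dtype=float)
    if amps.size == 0:
        raise ValueError("no event amplitudes")
    if amps.size < 3:
        warnings.warn("fewer than 3 amplitudes; A estimate will be coarse")
    top = 1.2 * amps.max()
    edges = np.linspace(0.0, top, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    hist = np.histogram(amps, bins=edges)[0].astype(float)
    x1 = gaussian_filter1d(hist, smooth_sd_bins)
    low = gaussian_filter1d(x1, lowpass_sd_bins)
    x2 = x1 / np.maximum(low, 1e-12)

    a_grid = np.linspace(bounds[0], min(bounds[1], top), 400)
    x2_at = lambda a: np.interp(a, centers, x2, left=0.0, right=0.0)
    amp2 = np.array([two_spike_amplitude(a, params) for a in a_grid])
    x3 = x2_at(a_grid) + 0.5 * x2_at(amp2)
    A_hat = float(a_grid[np.argmax(x3)])
    diags = {"centers": centers, "x1": x1, "x2": x2, "a_grid": a_grid, "x3": x3}
    return A_hat, diags


def assign_spike_counts(
    amplitudes: Sequence[float], A_hat: float, params: ModelParams, k_max: int = 20
) -> np.ndarray:
    """Spike count per event amplitude given the estimated A.

    The separation between k and k+1 spikes sits at the response to
    k + 0.3 spikes: boundaries b_k = A_hat * g(k + 0.3), so a linear
    probe separates at (k + 0.3) * A_hat.  Amplitudes at or below b_0
    get zero spikes (event dropped).
    """
    if A_hat <= 0:
        raise ValueError("A_hat must be > 0")
    bnd = np.array(
        [A_hat * float(nonlinearity(k + 0.3, params)) for k in range(k_max + 1)]
    )
    amps = np.asarray(list(amplitudes), dtype=float)
    return np.searchsorted(bnd, amps, side="left").astype(int)


def calibrate_A_tau(
    traces: Sequence[Trace],
    assigned_spikes: Sequence[SpikeTrain],
    params: ModelParams,
    A0: Optional[float] = None,
    tau0: Optional[float] = None,
):
    """Final least-squares calibration of (A, tau).

    Fits the noiseless forward model (fixed probe nonlinearity, flat
    per-trial baseline profiled out as an additive constant) to the
    cleaned traces given the assigned spike trains.  Optimizes in log
    space for positivity.
    """
    spike_counts = []
    n_total = 0
    for tr, st in zip(traces, assigned_spikes):
        cnt = st.counts(len(tr), tr.dt)
        spike_counts.append(cnt)
        n_total += int(cnt.sum())
    if n_total == 0:
        raise ValueError("no assigned spikes to calibrate on")
    A0 = A0 if A0 else params.A
    tau0 = tau0 if tau0 else params.tau

    def residuals(x):
        A, tau = math.exp(x[0]), math.exp(x[1])
        p = params.with_(A=A, tau=tau, sigma=params.sigma, eta=0.0)
        out = []
        for tr, cnt in zip(traces, spike_counts):
            decay = math.exp(-tr.dt / tau)
            c = sp_signal.lfilter([1.0], [1.0, -decay], cnt.astype(float))
            pred = 1.0 + A * nonlinearity(c, p)
            r = tr.values - pred
            out.append(r - r.mean())  # profile a flat additive baseline
        return np.concatenate(out)

    res = least_squares(
        residuals, x0=[math.log(A0), math.log(tau0)], method="trf", xtol=1e-12
    )
    if not res.success:
        raise RuntimeError(f"calibration did not converge: {res.message}")
    return float(math.exp(res.x[0])), float(math.exp(res.x[1]))


def fit_single_exponential(t, y, tau_bounds: Tuple[float, float] = (1e-4, 50.0)):
    """Unweighted least-squares fit of a*exp(-t/tau).

    The amplitude is profiled out linearly; tau is found by a bounded
    scalar minimization of the residual sum of squares.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 points")
    if np.allclose(y, 0.0):
        return 0.0, float(tau_bounds[1])

    def sse(tau):
        k = np.exp(-t / tau)
        a = float(k @ y) / float(k @ k)
        r = y - a * k
        return float(r @ r)

    res = minimize_scalar(
        sse, bounds=tau_bounds, method="bounded", options={"xatol": 1e-12}
    )
    tau = float(res.x)
    k = np.exp(-t / tau)
    a = float(k @ y) / float(k @ k)
    if a <= 0:
        raise ValueError("data do not decay from a positive amplitude")
    return a, tau


def autocalibrate(
    traces: Sequence[Trace],
    probe_profile: str = "ogb",
    a_min: float = 0.04,
    a_bounds: Tuple[float, float] = (0.04, 0.10),
    config: Optional[EngineConfig] = None,
) -> CalibrationResult:
    """Estimate A, tau and sigma for one neuron from its traces alone.

    sigma is estimated per trace (session); all trials are pooled for
    the estimation of A and tau.  lam, eta and the probe nonlinearity
    stay at fixed defaults.  Falls back to per-profile mean parameters
    (with a warning and ``fallback=True``) when no usable isolated
    events are found.
    """
    if not traces:
        raise ValueError("need at least one trace")
    sigmas = [estimate_sigma(tr, probe_profile) for tr in traces]
    all_events = []
    per_trace_kept: List[list] = []
    cleaned_values = []
    tau_refits = []
    wp = None
    for tr, sg in zip(traces, sigmas):
        wp = working_params(probe_profile, sg)
        events = detect_events(tr, wp, a_min=a_min, config=config)
        kept, tau_r, cleaned = select_isolated_events(events, tr, wp)
        per_trace_kept.append(kept)
        cleaned_values.append(cleaned)
        if kept:
            tau_refits.append(tau_r)
        all_events.extend(kept)

    amps = [a for _, a in all_events]
    if len(amps) < 3:
        warnings.warn("too few isolated events; falling back to profile means")
        A_fb, tau_fb = PROFILE_FALLBACK.get(
            probe_profile.lower(), PROFILE_FALLBACK["linear"]
        )
        return CalibrationResult(
            A_hat=A_fb, tau_hat=tau_fb, sigma_hat=sigmas, events=all_events,
            fallback=True,
        )

    A_first, diags = histogram_cost_A(amps, wp, bounds=a_bounds)
    tau_first = float(np.median(tau_refits)) if tau_refits else wp.tau

    cleaned_traces = [
        Trace(values=v, dt=tr.dt) for v, tr in zip(cleaned_values, traces)
    ]
    spike_trains = []
    for kept in per_trace_kept:
        times, counts = [], []
        if kept:
            ks = assign_spike_counts([a for _, a in kept], A_first, wp)
            for (tc, _), k in zip(kept, ks):
                times.extend([tc] * int(k))
        spike_trains.append(SpikeTrain(times=np.asarray(times)))
    if sum(len(st) for st in spike_trains) == 0:
        warnings.warn("no events above the zero-spike boundary; fallback")
        A_fb, tau_fb = PROFILE_FALLBACK.get(
            probe_profile.lower(), PROFILE_FALLBACK["linear"]
        )
        return CalibrationResult(
            A_hat=A_fb, tau_hat=tau_fb, sigma_hat=sigmas, events=all_events,
            fallback=True, diagnostics=diags,
        )
    A_final, tau_final = calibrate_A_tau(
        cleaned_traces, spike_trains, wp, A0=A_first, tau0=tau_first
    )
    return CalibrationResult(
        A_hat=A_final,
        tau_hat=tau_final,
        sigma_hat=sigmas,
        events=all_events,
        diagnostics=diags,
    )


def calibrated_params(result: CalibrationResult, probe_profile: str = "ogb") -> ModelParams:
    """ModelParams for inference from an autocalibration result."""
    prof = PROBE_PROFILES.get(probe_profile.lower(), PROBE_PROFILES["linear"])
    return ModelParams(
        A=result.A_hat,
        tau=result.tau_hat,
        sigma=float(np.mean(result.sigma_hat)),
        eta=FIXED_ETA,
        lam=FIXED_LAM,
        **prof,
    )
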