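"""Generative model of spiking-driven calcium fluorescence.

The model maps a spike train to a fluorescence trace in three stages:

1.  Calcium dynamics.  A normalized intracellular calcium variable ``c``
    (0 at rest, +1 per action potential) decays exponentially with time
    constant ``tau`` and jumps by the number of spikes in each time bin.

2.  Probe response.  A dimensionless nonlinearity ``g(c)`` with
    ``g(0) = 0`` and ``g(1) = 1`` converts calcium into relative
    fluorescence change, so a single isolated spike always produces a
    transient of amplitude exactly ``A``.  Saturating (organic dye),
    polynomial and Hill (GECI) response curves are supported; the
    ``hill_rise`` variant adds a finite probe binding time ``tau_on``
    via an extra latent state, the normalized bound-probe fraction.

3.  Measurement.  Fluorescence is the product of a slowly drifting
    baseline ``B(t)`` (Brownian drift of amplitude ``eta``) with
    ``1 + A*g(c)``, plus white measurement noise of SD ``sigma``.
    Traces are handled in relative units where the resting baseline
    is approximately 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "ModelParams",
    "SpikeTrain",
    "Trace",
    "LatentPath",
    "PROBE_KINDS",
    "evolve_calcium",
    "nonlinearity",
    "evolve_probe",
    "probe_saturation_level",
    "measure",
    "simulate_trace",
    "bin_spikes",
]

PROBE_KINDS = ("linear", "saturating", "polynomial", "hill", "hill_rise")


@dataclass
class ModelParams:
    """Parameters of the generative fluorescence model.

    Attributes
    ----------
    A : float
        Unitary transient amplitude (dF/F fraction per spike), > 0.
    tau : float
        Calcium decay time constant in seconds, > 0.
    probe : str
        Response curve: one of ``linear``, ``saturating``, ``polynomial``,
        ``hill``, ``hill_rise``.
    gamma : float
        Saturation parameter: inverse of the number of spikes at which the
        dye reaches half saturation (saturating / hill probes).
    p2, p3 : float
        Cubic polynomial coefficients (polynomial probe); the linear
        coefficient is ``1 - p2 - p3`` so the response to one spike is
        exactly ``A``.
    n_hill : float
        Hill exponent (hill / hill_rise probes), > 0.
    c0 : float
        Normalized resting calcium in spike-equivalent units (hill probes).
    tau_on : float
        Probe binding time constant in seconds (hill_rise probe).
    delay : float
        Fixed spike-to-onset delay in seconds (20 ms for GCaMP6s, 10 ms
        for GCaMP6f).
    sigma : float
        Measurement white-noise SD, dF/F units per sample.
    eta : float
        Baseline drift amplitude, dF/F * s^(-1/2).
    lam : float
        A-priori spike rate (sp/s) of the Poisson prior.
    nmax : int
        Maximum number of spikes per time bin, >= 1.
    """

    A: float = 0.1
    tau: float = 1.0
    probe: str = "linear"
    gamma: float = 0.0
    p2: float = 0.0
    p3: float = 0.0
    n_hill: float = 1.0
    c0: float = 0.0
    tau_on: float = 0.0
    delay: float = 0.0
    sigma: float = 0.02
    eta: float = 0.0
    lam: float = 0.1
    nmax: int = 3

    def __post_init__(self) -> None:
        if self.probe not in PROBE_KINDS:
            raise ValueError(f"unknown probe kind {self.probe!r}")
        if self.A <= 0:
            raise ValueError("A must be > 0")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.probe in ("hill", "hill_rise") and self.n_hill <= 0:
            raise ValueError("n_hill must be > 0")
        if self.sigma < 0 or self.eta < 0:
            raise ValueError("sigma and eta must be >= 0")
        if self.lam <= 0:
            raise ValueError("lam must be > 0")
        if self.nmax < 1:
            raise ValueError("nmax must be >= 1")
        if self.delay < 0 or self.tau_on < 0:
            raise ValueError("delay and tau_on must be >= 0")
        if self.probe in ("hill", "hill_rise") and self.c0 < 0:
            raise ValueError("c0 must be >= 0")

    def with_(self, **kw) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kw)


# Probe profiles with field-standard fixed nonlinearity values: gamma=0.1
# for OGB; polynomial [p2, p3] = [0.73, -0.05] for GCaMP6s and
# [0.55, 0.03] for GCaMP6f, with onset delays of 20 and 10 ms.
PROBE_PROFILES = {
    "ogb": dict(probe="saturating", gamma=0.1),
    "gcamp6s": dict(probe="polynomial", p2=0.73, p3=-0.05, delay=0.020),
    "gcamp6f": dict(probe="polynomial", p2=0.55, p3=0.03, delay=0.010),
    "linear": dict(probe="linear"),
}


@dataclass
class SpikeTrain:
    """A spike train: ascending spike times in seconds.

    May alternatively be built from integer per-bin counts via
    :meth:`from_counts`; counts place spikes at bin centers.
    """

    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).ravel()
        if self.times.size and np.any(np.diff(self.times) < 0):
            self.times = np.sort(self.times)

    @classmethod
    def from_counts(cls, counts, dt: float) -> "SpikeTrain":
        counts = np.asarray(counts)
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            counts = counts.astype(float)
            if np.any(counts < 0) or np.any(counts != np.round(counts)):
                raise ValueError("counts must be non-negative integers")
            counts = counts.astype(int)
        times = np.repeat((np.arange(counts.size) + 0.5) * dt, counts)
        return cls(times=times)

    def counts(self, n_bins: int, dt: float) -> np.ndarray:
        """Spike counts per bin; bin t covers ((t-1)*dt, t*dt]."""
        return bin_spikes(self.times, n_bins, dt)

    @property
    def n(self) -> int:
        return int(self.times.size)

    def __len__(self) -> int:
        return self.n


@dataclass
class Trace:
    """A fluorescence time series in dF/F (relative) units at fixed dt."""

    values: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")

    @property
    def rate(self) -> float:
        return 1.0 / self.dt

    @property
    def duration(self) -> float:
        return self.values.size * self.dt

    @property
    def t(self) -> np.ndarray:
        """Bin-center times in seconds."""
        return (np.arange(self.values.size) + 0.5) * self.dt

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass
class LatentPath:
    """Latent state trajectory underlying a trace.

    c is the normalized calcium per bin, B the baseline per bin and p
    (hill_rise only) the normalized bound-probe fraction.
    """

    c: np.ndarray
    B: np.ndarray
    p: Optional[np.ndarray] = None


def evolve_calcium(c: float, n: int, dt: float, tau: float):
    """One-bin calcium update: decay first, then add spikes.

    c_t = c_{t-1} * exp(-dt/tau) + n_t, so spikes emitted in the bin
    (t-1, t] take full effect at t and one spike from rest gives c = 1.
    """
    n_arr = np.asarray(n)
    if np.any(n_arr < 0) or np.any(n_arr != np.round(n_arr)):
        raise ValueError("spike count n must be a non-negative integer")
    if dt <= 0 or tau <= 0:
        raise ValueError("dt and tau must be > 0")
    c_arr = np.asarray(c, dtype=float)
    if np.any(c_arr < 0):
        raise ValueError("calcium must be >= 0")
    out = c_arr * math.exp(-dt / tau) + n_arr
    return out.item() if np.isscalar(c) and np.isscalar(n) else out


def _hill_raw(x, c0: float, gamma: float, n_hill: float):
    """Unnormalized Hill measure h(x) = (c0+x)^n / ((c0+x)^n + (c0+1/gamma)^n)."""
    if gamma <= 0:
        raise ValueError("hill probe requires gamma > 0")
    xn = np.power(np.asarray(x, dtype=float) + c0, n_hill)
    kn = (c0 + 1.0 / gamma) ** n_hill
    return xn / (xn + kn)


def nonlinearity(c, params: ModelParams):
    """Normalized probe response g(c), with g(0)=0 and g(1)=1.

    linear:      g(c) = c
    saturating:  g(c) = (1+gamma) c / (1 + gamma c)
    polynomial:  g(c) = (1-p2-p3) c + p2 c^2 + p3 c^3
    hill:        g(c) = (h(c)-h(0)) / (h(1)-h(0)), Hill curve h
    """
    c_arr = np.asarray(c, dtype=float)
    if np.any(c_arr < 0):
        raise ValueError("calcium must be >= 0")
    kind = params.probe
    if kind == "linear":
        g = c_arr.copy()
    elif kind == "saturating":
        if params.gamma < 0:
            raise ValueError("gamma must be >= 0")
        g = (1.0 + params.gamma) * c_arr / (1.0 + params.gamma * c_arr)
    elif kind == "polynomial":
        p2, p3 = params.p2, params.p3
        g = (1.0 - p2 - p3) * c_arr + p2 * c_arr**2 + p3 * c_arr**3
    elif kind in ("hill", "hill_rise"):
        h = _hill_raw(c_arr, params.c0, params.gamma, params.n_hill)
        h0 = _hill_raw(0.0, params.c0, params.gamma, params.n_hill)
        h1 = _hill_raw(1.0, params.c0, params.gamma, params.n_hill)
        g = (h - h0) / (h1 - h0)
    else:  # pragma: no cover - guarded by ModelParams
        raise ValueError(f"unknown probe kind {kind!r}")
    return g.item() if np.isscalar(c) else g


def probe_saturation_level(params: ModelParams) -> float:
    """Upper bound of the normalized bound-probe fraction p (hill probes)."""
    h0 = _hill_raw(0.0, params.c0, params.gamma, params.n_hill)
    h1 = _hill_raw(1.0, params.c0, params.gamma, params.n_hill)
    return float((1.0 - h0) / (h1 - h0))


def evolve_probe(p, c, dt: float, params: ModelParams):
    """One-bin update of the bound-probe fraction (hill_rise probe).

    First-order relaxation of p toward its equilibrium g_hill(c) with
    time constant tau_on; sub-stepped so the discrete update stays
    stable and accurate when dt > tau_on.  With tau_on = 0 binding is
    instantaneous and p' = g_hill(c) exactly.
    """
    if params.probe != "hill_rise":
        raise ValueError("evolve_probe applies to the hill_rise probe only")
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr < 0):
        raise ValueError("bound fraction must be >= 0")
    g_eq = np.asarray(nonlinearity(c, params), dtype=float)
    if params.tau_on == 0.0:
        out = g_eq + 0.0 * p_arr
    else:
        # exact solution of dp/dt = (g_eq - p)/tau_on over dt
        decay = math.exp(-dt / params.tau_on)
        out = g_eq + (p_arr - g_eq) * decay
    return out.item() if np.isscalar(p) and np.isscalar(c) else out


def measure(c, B, params: ModelParams, p=None):
    """Noiseless fluorescence F = B * (1 + A*g(c)) (or B * (1 + A*p))."""
    if params.probe == "hill_rise":
        if p is None:
            raise ValueError("hill_rise probe requires the bound fraction p")
        resp = np.asarray(p, dtype=float)
    else:
        resp = np.asarray(nonlinearity(c, params), dtype=float)
    out = np.asarray(B, dtype=float) * (1.0 + params.A * resp)
    return out.item() if out.ndim == 0 else out


def bin_spikes(times, n_bins: int, dt: float) -> np.ndarray:
    """Count spikes per bin; bin t (0-based) covers (t*dt, (t+1)*dt]."""
    times = np.asarray(times, dtype=float)
    edges = np.arange(n_bins + 1) * dt
    # right-closed bins: a spike exactly at an edge belongs to the earlier bin
    idx = np.ceil(times / dt).astype(int) - 1
    idx = np.clip(idx, 0, n_bins - 1)
    counts = np.zeros(n_bins, dtype=int)
    np.add.at(counts, idx, 1)
    del edges
    return counts


def simulate_trace(
    spikes: SpikeTrain,
    params: ModelParams,
    duration: float,
    dt: float,
    noise=None,
    seed=None,
    c1: float = 0.0,
    B1: float = 1.0,
):
    """Simulate a fluorescence trace from a spike train.

    Spikes are shifted by ``params.delay``, binned at ``dt``, and pushed
    through the calcium / probe / measurement model.  The baseline
    follows a reflected Gaussian random walk of amplitude ``params.eta``
    (flat if eta = 0).  Measurement noise is taken from ``noise``: a
    :class:`spikemap.synth.NoiseSpec` (band-RMS-calibrated white, drift
    or pink noise) or None for pure white noise of SD ``params.sigma``.

    Returns ``(Trace, LatentPath)``; deterministic given ``seed``.
    """
    from . import synth  # deferred: synth builds on the types defined here

    times = np.asarray(spikes.times, dtype=float)
    if times.size and (times.min() < 0 or times.max() >= duration):
        raise ValueError("spike times must lie within [0, duration)")
    n_bins = int(round(duration / dt))
    counts = bin_spikes(times + params.delay, n_bins, dt)

    rng = np.random.default_rng(seed)
    decay = math.exp(-dt / params.tau)
    from scipy.signal import lfilter

    c = lfilter([1.0], [1.0, -decay], counts.astype(float))
    if c1:
        c += c1 * decay ** np.arange(1, n_bins + 1)

    B = np.empty(n_bins)
    if params.eta > 0:
        steps = params.eta * math.sqrt(dt) * rng.standard_normal(n_bins)
        B[:] = np.abs(B1 + np.cumsum(steps))  # reflected at 0
    else:
        B[:] = B1

    p = None
    if params.probe == "hill_rise":
        p = np.empty(n_bins)
        prev_p = float(nonlinearity(c1, params))
        for t in range(n_bins):
            prev_p = evolve_probe(prev_p, c[t], dt, params)
            p[t] = prev_p
        F = measure(c, B, params, p=p)
    else:
        F = measure(c, B, params)

    if noise is not None:
        eps = synth.gen_noise(noise.kind, n_bins, dt, rng)
        eps = synth.scale_noise_to_level(eps, noise.level, params.A, dt, noise.band)
        F = F + eps
    elif params.sigma > 0:
        F = F + params.sigma * rng.standard_normal(n_bins)

    return Trace(values=F, dt=dt), LatentPath(c=c, B=B, p=p)
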