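"""MAP spike-train estimation on a discretized continuous state space.

The hidden state per frame is x_t = (c_t, B_t), normalized calcium and
baseline (plus the bound-probe fraction p_t for the ``hill_rise`` probe).
Calcium evolves deterministically given the spike count n_t, which has a
truncated Poisson(lam*dt) prior; the baseline takes Gaussian steps of SD
eta*sqrt(dt); the measurement y_t is Gaussian around B_t*(1 + A*g(c_t)).

The MAP spike train is found with a backward Viterbi recursion over a
(c, B) grid, storing for every grid state the conditional best
log-probability m_t(x_t) of trajectories starting there:

    m_T(x) = log p(y_T | x)
    m_t(x) = log p(y_t | x) + max_{n, B'} [ log P(n) + log p(B'|B)
                                            + m_{t+1}(c*exp(-dt/tau)+n, B') ]

Children along calcium fall off the grid, so m_{t+1} is evaluated by a
precomputed natural cubic-spline interpolation matrix (one per spike
count).  The baseline maximization scans a small window of grid values
and refines the winner by analytic maximization of a local quadratic
fit, so the chosen B' need not lie on the grid.  A single forward
"collecting" sweep then reads off the stored argmax decisions.

Replacing max by sum in the same recursions yields forward filtering
p(x_t | y_1..t) and the backward conditional likelihood p(y_t..y_T|x_t),
from which per-bin spike marginals P(n_t = k | y) and posterior samples
of entire trajectories are obtained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.special import gammaln, logsumexp

from .model import (
    LatentPath,
    ModelParams,
    SpikeTrain,
    Trace,
    measure,
    nonlinearity,
    probe_saturation_level,
)

__all__ = [
    "EngineConfig",
    "StateGrid",
    "MapResult",
    "PosteriorArrays",
    "build_grid",
    "transition_logprob",
    "emission_logprob",
    "backward_map_pass",
    "forward_collect",
    "map_spikes",
    "smoothed_spike_probabilities",
    "sample_posterior",
    "map_calcium_events",
    "brute_force_map",
    "exhaustive_spike_marginals",
    "path_log_posterior",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass
class EngineConfig:
    """Numerical configuration of the estimation grid and priors.

    nc, nb : number of calcium / baseline grid values (default 100).
    c_max : top of the calcium grid, in spike-equivalent units.
    c_spacing : "sqrt" (denser near 0, resolving single spikes) or "linear".
    n_p : number of bound-probe grid values (hill_rise probe only).
    b_halfwidth : relative half-range of the baseline grid around its
        initial estimate (10th percentile of the trace).
    b_window : size of the local baseline search window (default 5).
    c1 : known initial calcium; None (default) leaves c_1 free with a
        uniform prior over the grid.
    B_known : known constant baseline; None (default) estimates it.
    c1_prior : "uniform" (default) or "rate" for a truncated-normal
        prior on c_1 derived from the a-priori spike rate.
    """

    nc: int = 100
    nb: int = 100
    c_max: float = 10.0
    c_spacing: str = "sqrt"
    n_p: int = 40
    b_halfwidth: float = 0.3
    b_window: int = 5
    c1: Optional[float] = None
    B_known: Optional[float] = None
    c1_prior: str = "uniform"


@dataclass
class StateGrid:
    """Discretization of the state space with precomputed operators."""

    c_values: np.ndarray
    B_values: np.ndarray
    dt: float
    decay: float
    W: List[np.ndarray]          # spline interpolation matrix per spike count
    valid: List[np.ndarray]      # per count: parents whose child stays on-grid
    c_basis: object              # cardinal spline basis; c_basis(x) gives weights
    logpois: np.ndarray          # truncated Poisson prior, counts 0..nmax
    b_idx: Optional[np.ndarray]  # (nb, w) baseline window child indices
    b_logprior: Optional[np.ndarray]  # (nb, w) Gaussian step log densities
    G: Optional[np.ndarray]      # (nb, nb) row-normalized step kernel (sum mode)
    p_values: Optional[np.ndarray] = None
    P: Optional[np.ndarray] = None  # (nmax+1, nc, n_p, n_p) probe interpolation
    c1_logprior: Optional[np.ndarray] = None

    @property
    def nc(self) -> int:
        return self.c_values.size

    @property
    def nb(self) -> int:
        return self.B_values.size


@dataclass
class MapResult:
    """MAP estimate: spike train, latent path, exact path log posterior.

    ``log_posterior`` is the unnormalized log posterior of the returned
    path: sum of Gaussian emission log densities, truncated-Poisson spike
    log priors and (when eta > 0) Gaussian baseline-step log densities.
    Uniform initial-state prior constants are omitted; values are
    therefore comparable across candidate paths for the same trace.
    """

    spikes: SpikeTrain
    counts: np.ndarray
    path: LatentPath
    log_posterior: float
    fit: np.ndarray


@dataclass
class PosteriorArrays:
    """Filtering/smoothing tables and per-bin spike marginals.

    alpha[t] is p(x_t | y_1..t) normalized to sum 1 on the grid;
    beta[t] is p(y_t..y_T | x_t) normalized per step (scale factors in
    ``beta_logscale``); spike_marginals[t, k] = P(n_t = k | y), with the
    first bin's spikes absorbed into the initial state (row [1, 0, ...]).
    """

    alpha: np.ndarray
    beta: np.ndarray
    beta_logscale: np.ndarray
    spike_marginals: np.ndarray
    expected_counts: np.ndarray
    log_evidence: float


# ---------------------------------------------------------------------------
# probabilities


def _log_poisson(nmax: int, mu: float) -> np.ndarray:
    n = np.arange(nmax + 1)
    return -mu + n * math.log(mu) - gammaln(n + 1)


def transition_logprob(n: int, dB: float, params: ModelParams, dt: float) -> float:
    """Log prior of a one-bin transition: spike count and baseline step.

    The spike count follows Poisson(lam*dt) truncated at nmax without
    renormalization (the truncated mass is negligible for lam*dt << 1);
    counts above nmax have probability zero.  The baseline step is
    Gaussian with SD eta*sqrt(dt); with eta = 0 the baseline is frozen
    and only dB = 0 is allowed.
    """
    if n < 0 or n != int(n):
        raise ValueError("spike count must be a non-negative integer")
    if n > params.nmax:
        return -np.inf
    mu = params.lam * dt
    lp = -mu + n * math.log(mu) - gammaln(n + 1)
    if params.eta > 0:
        s = params.eta * math.sqrt(dt)
        lp += -0.5 * (dB / s) ** 2 - math.log(s) - 0.5 * _LOG_2PI
    elif dB != 0.0:
        return -np.inf
    return float(lp)


def emission_logprob(y: float, c, B, params: ModelParams, p=None):
    """Gaussian measurement log density log N(y; B*(1+A*g(c)), sigma^2)."""
    pred = measure(c, B, params, p=p)
    if params.sigma == 0:
        out = np.where(np.asarray(pred) == y, 0.0, -np.inf)
        return float(out) if np.ndim(out) == 0 else out
    z = (y - pred) / params.sigma
    out = -0.5 * z**2 - math.log(params.sigma) - 0.5 * _LOG_2PI
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# grid construction


def _spline_matrix(x: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Matrix M with (M @ f)(i) = natural-cubic-spline of f at targets[i]."""
    cs = CubicSpline(x, np.eye(x.size), axis=0, bc_type="natural")
    return cs(targets)


def _c_grid(config: EngineConfig) -> np.ndarray:
    u = np.linspace(0.0, 1.0, config.nc)
    if config.c_spacing == "sqrt":
        return config.c_max * u**2
    if config.c_spacing == "linear":
        return config.c_max * u
    raise ValueError(f"unknown c_spacing {config.c_spacing!r}")


def _c1_rate_logprior(c_values, params: ModelParams, dt: float) -> np.ndarray:
    # stationary c_1 = sum_k n_{-k} decay^k, n ~ Poisson(lam*dt):
    # approximated by a normal truncated at 0
    d = math.exp(-dt / params.tau)
    mu = params.lam * dt / (1.0 - d)
    var = params.lam * dt / (1.0 - d * d)
    lp = -0.5 * (c_values - mu) ** 2 / var
    lp -= logsumexp(lp)
    return lp


def build_grid(
    trace: Trace, params: ModelParams, config: Optional[EngineConfig] = None
) -> StateGrid:
    """Build the state grid and its precomputed operators for a trace."""
    config = config or EngineConfig()
    if config.nc < 2:
        raise ValueError("need nc >= 2")
    dt = trace.dt
    decay = math.exp(-dt / params.tau)
    c_values = _c_grid(config)

    if config.B_known is not None:
        B_values = np.array([float(config.B_known)])
    elif config.nb == 1:
        B_values = np.array([float(np.percentile(trace.values, 10))])
    else:
        b0 = float(np.percentile(trace.values, 10))
        B_values = np.linspace(
            b0 * (1 - config.b_halfwidth), b0 * (1 + config.b_halfwidth), config.nb
        )

    # calcium children are clamped (not excluded) at the grid top:
    # c' = min(c*decay + n, c_max).  A hard exclusion would make the
    # conditional-best tables discontinuous at the branch cut-offs, and
    # spline interpolation rings at discontinuities; the saturating
    # dynamics keep the tables continuous.  c_max is chosen well above
    # the active calcium range, so clamped paths carry negligible mass.
    c_basis = CubicSpline(c_values, np.eye(c_values.size), axis=0, bc_type="natural")
    W, valid = [], []
    for n in range(params.nmax + 1):
        targets = c_values * decay + n
        ok = targets <= c_values[-1] + 1e-12
        W.append(c_basis(np.clip(targets, None, c_values[-1])))
        valid.append(ok)

    logpois = _log_poisson(params.nmax, params.lam * dt)

    nb = B_values.size
    b_idx = b_logprior = G = None
    if nb > 1 and params.eta > 0:
        w = min(config.b_window, nb)
        w2 = (w - 1) // 2
        starts = np.clip(np.arange(nb) - w2, 0, nb - w)
        b_idx = starts[:, None] + np.arange(w)[None, :]
        s = params.eta * math.sqrt(dt)
        dB = B_values[b_idx] - B_values[:, None]
        b_logprior = -0.5 * (dB / s) ** 2 - math.log(s) - 0.5 * _LOG_2PI
        dBG = B_values[None, :] - B_values[:, None]
        Gk = np.exp(-0.5 * (dBG / s) ** 2)
        G = Gk / Gk.sum(axis=1, keepdims=True)
    elif nb > 1:
        G = np.eye(nb)

    p_values = P = None
    if params.probe == "hill_rise":
        p_sat = probe_saturation_level(params)
        p_values = np.linspace(0.0, p_sat, config.n_p)
        g_child = np.empty((params.nmax + 1, config.nc))
        for n in range(params.nmax + 1):
            g_child[n] = nonlinearity(
                np.minimum(c_values * decay + n, c_values[-1]), params
            )
        rho = math.exp(-dt / params.tau_on) if params.tau_on > 0 else 0.0
        P = np.empty((params.nmax + 1, config.nc, config.n_p, config.n_p))
        base = CubicSpline(p_values, np.eye(config.n_p), axis=0, bc_type="natural")
        for n in range(params.nmax + 1):
            for i in range(config.nc):
                tgt = g_child[n, i] + (p_values - g_child[n, i]) * rho
                P[n, i] = base(np.clip(tgt, p_values[0], p_values[-1]))

    c1_logprior = None
    if config.c1_prior == "rate":
        c1_logprior = _c1_rate_logprior(c_values, params, dt)
    elif config.c1_prior != "uniform":
        raise ValueError(f"unknown c1_prior {config.c1_prior!r}")

    return StateGrid(
        c_values=c_values,
        B_values=B_values,
        dt=dt,
        decay=decay,
        W=W,
        c_basis=c_basis,
        valid=valid,
        logpois=logpois,
        b_idx=b_idx,
        b_logprior=b_logprior,
        G=G,
        p_values=p_values,
        P=P,
        c1_logprior=c1_logprior,
    )


def _emission_table(y: float, grid: StateGrid, params: ModelParams) -> np.ndarray:
    """Log emission density on the grid: (nc, nb), or (n_p, nb) for hill_rise."""
    if params.probe == "hill_rise":
        F = grid.B_values[None, :] * (1.0 + params.A * grid.p_values[:, None])
    else:
        g = nonlinearity(grid.c_values, params)
        F = grid.B_values[None, :] * (1.0 + params.A * g[:, None])
    z = (y - F) / params.sigma
    return -0.5 * z**2 - math.log(params.sigma) - 0.5 * _LOG_2PI


# ---------------------------------------------------------------------------
# backward MAP recursion


def _b_max_step(M1: np.ndarray, grid: StateGrid):
    """Maximize over the baseline step with local quadratic refinement.

    M1 has shape (..., nb) over child baselines.  Returns the maximized
    values (..., nb) over parent baselines and the refined (off-grid)
    child baseline per parent state.
    """
    nb = grid.nb
    if nb == 1 or grid.b_idx is None:
        Bnext = np.broadcast_to(grid.B_values, M1.shape).copy()
        return M1.copy(), Bnext
    lead = M1.shape[:-1]
    M2 = M1.reshape(-1, nb)
    f = np.take(M2, grid.b_idx, axis=1) + grid.b_logprior  # (L, nb, w)
    w = f.shape[-1]
    k = np.argmax(f, axis=-1)
    base = np.arange(k.size) * w
    kf = k.ravel()
    fr = f.ravel()
    f0 = fr[base + kf].reshape(k.shape)
    fm = fr[base + np.maximum(kf - 1, 0)].reshape(k.shape)
    fp = fr[base + np.minimum(kf + 1, w - 1)].reshape(k.shape)
    jc = grid.b_idx.ravel()[np.arange(nb) * w + k].reshape(k.shape)
    interior = (k > 0) & (k < w - 1) & (jc > 0) & (jc < nb - 1)
    a2 = fm + fp - 2.0 * f0  # 2a of the local parabola
    b1 = 0.5 * (fp - fm)
    x = np.zeros_like(f0)
    good = interior & (a2 < 0)
    np.divide(-b1, a2, out=x, where=good)
    np.clip(x, -1.0, 1.0, out=x)
    Mb = f0 + (0.5 * a2 * x + b1) * x
    h = grid.B_values[1] - grid.B_values[0]
    Bnext = grid.B_values[jc] + x * h
    return Mb.reshape(lead + (nb,)), Bnext.reshape(lead + (nb,))


def backward_map_pass(trace: Trace, params: ModelParams, grid: StateGrid):
    """Backward Viterbi recursion; returns per-step tables.

    Returns (m_tables, best_n, best_B): m_tables[t] is the table of
    conditional best log probabilities m_t on the grid, best_n[t] the
    argmax spike count indexed by (c_parent, B_child) and best_B[t] the
    refined child baseline indexed by (c_parent, B_parent), for
    transitions t -> t+1.  All arithmetic is in log space; each step is
    shift-normalized so the tables stay finite (constant shifts do not
    affect any argmax).
    """
    y = trace.values
    if not np.all(np.isfinite(y)):
        raise ValueError("trace contains non-finite values")
    if params.sigma <= 0:
        raise ValueError("inference requires sigma > 0")
    T = y.size
    if T < 1:
        raise ValueError("empty trace")
    if params.probe == "hill_rise":
        return _backward_map_pass_rise(trace, params, grid)
    nmax = params.nmax
    m = _emission_table(y[T - 1], grid, params)
    ms: List[np.ndarray] = [None] * T
    ms[T - 1] = m.astype(np.float32)
    best_n: List[np.ndarray] = [None] * max(T - 1, 0)
    best_B: List[np.ndarray] = [None] * max(T - 1, 0)
    for t in range(T - 2, -1, -1):
        cand = np.empty((nmax + 1,) + m.shape)
        for n in range(nmax + 1):
            cand[n] = grid.W[n] @ m + grid.logpois[n]
        bn = np.argmax(cand, axis=0)
        M1 = np.take_along_axis(cand, bn[None], axis=0)[0]
        Mb, Bnext = _b_max_step(M1, grid)
        m = _emission_table(y[t], grid, params) + Mb
        mx = m.max()
        if not np.isfinite(mx):
            raise FloatingPointError("log-probability table underflowed")
        m -= mx
        ms[t] = m.astype(np.float32)
        best_n[t] = bn.astype(np.int8)
        best_B[t] = Bnext.astype(np.float32)
    return ms, best_n, best_B


def _backward_map_pass_rise(trace: Trace, params: ModelParams, grid: StateGrid):
    """Backward recursion with the bound-probe companion dimension.

    The bound fraction p evolves deterministically, so it adds an extra
    interpolation (precomputed per spike count and parent calcium), not
    an extra maximization.  Memory per step scales with nc*n_p*nb.
    """
    y = trace.values
    T = y.size
    nmax = params.nmax
    nc, n_p, nb = grid.nc, grid.p_values.size, grid.nb
    emis = lambda t: _emission_table(y[t], grid, params)[None, :, :]  # (1, n_p, nb)
    m = np.broadcast_to(emis(T - 1), (nc, n_p, nb)).copy()
    ms: List[np.ndarray] = [None] * T
    ms[T - 1] = m.astype(np.float32)
    best_n: List[np.ndarray] = [None] * max(T - 1, 0)
    best_B: List[np.ndarray] = [None] * max(T - 1, 0)
    for t in range(T - 2, -1, -1):
        cand = np.empty((nmax + 1, nc, n_p, nb))
        for n in range(nmax + 1):
            Tc = np.einsum("ij,jqb->iqb", grid.W[n], m)  # c interpolation
            cand[n] = np.einsum("ipq,iqb->ipb", grid.P[n], Tc) + grid.logpois[n]
        bn = np.argmax(cand, axis=0)
        M1 = np.take_along_axis(cand, bn[None], axis=0)[0]
        Mb, Bnext = _b_max_step(M1, grid)
        m = emis(t) + Mb
        m -= m.max()
        ms[t] = m.astype(np.float32)
        best_n[t] = bn.astype(np.int8)
        best_B[t] = Bnext.astype(np.float32)
    return ms, best_n, best_B


# ---------------------------------------------------------------------------
# forward collection


def _nearest(grid_values: np.ndarray, x: float) -> int:
    i = np.searchsorted(grid_values, x)
    if i == 0:
        return 0
    if i >= grid_values.size:
        return grid_values.size - 1
    return int(i if grid_values[i] - x < x - grid_values[i - 1] else i - 1)


def _interp_B_table(tbl: np.ndarray, grid: StateGrid, c: float, B: float) -> float:
    """Bilinear interpolation of a (nc, nb) decision table at (c, B)."""
    cv, bv = grid.c_values, grid.B_values
    i1 = int(np.clip(np.searchsorted(cv, c), 1, cv.size - 1))
    i0 = i1 - 1
    wc = 0.0 if cv[i1] == cv[i0] else (c - cv[i0]) / (cv[i1] - cv[i0])
    wc = min(max(wc, 0.0), 1.0)
    if bv.size == 1:
        return float((1 - wc) * tbl[i0, 0] + wc * tbl[i1, 0])
    j1 = int(np.clip(np.searchsorted(bv, B), 1, bv.size - 1))
    j0 = j1 - 1
    wb = (B - bv[j0]) / (bv[j1] - bv[j0])
    wb = min(max(wb, 0.0), 1.0)
    return float(
        (1 - wc) * ((1 - wb) * tbl[i0, j0] + wb * tbl[i0, j1])
        + wc * ((1 - wb) * tbl[i1, j0] + wb * tbl[i1, j1])
    )


def _local_transition_argmax(
    c: float, B: float, m_next: np.ndarray, params: ModelParams, grid: StateGrid
):
    """Exact one-step argmax at an (off-grid) parent state.

    Re-evaluates log P(n) + log p(B'|B) + m_{t+1}(c*decay + n, B') at the
    actual parent (c, B) using the spline basis along calcium, with the
    usual local window and analytic quadratic refinement along the
    baseline.  More faithful than snapping the decision to the nearest
    grid point, which can flip near-marginal choices.
    """
    nmax = params.nmax
    cv, bv = grid.c_values, grid.B_values
    nb = bv.size
    children = np.minimum(c * grid.decay + np.arange(nmax + 1), cv[-1])
    rows = grid.c_basis(children)
    V = rows @ m_next + grid.logpois[:, None]
    if nb == 1 or grid.b_idx is None:
        # baseline frozen (eta = 0): stay in the column of the current B
        j = 0 if nb == 1 else _nearest(bv, B)
        n_best = int(np.argmax(V[:, j]))
        return n_best, B
    # local window of baseline children around the parent value
    w = grid.b_idx.shape[1]
    w2 = (w - 1) // 2
    jc = _nearest(bv, B)
    j_lo = int(np.clip(jc - w2, 0, nb - w))
    cols = np.arange(j_lo, j_lo + w)
    s = params.eta * math.sqrt(grid.dt)
    prior = -0.5 * ((bv[cols] - B) / s) ** 2 - math.log(s) - 0.5 * _LOG_2PI
    f = V[:, cols] + prior[None, :]
    n_best, k = np.unravel_index(np.argmax(f), f.shape)
    jn = cols[k]
    if 0 < k < w - 1 and 0 < jn < nb - 1:
        fm, f0, fp = f[n_best, k - 1], f[n_best, k], f[n_best, k + 1]
        a2 = fm + fp - 2.0 * f0
        if a2 < 0:
            x = float(np.clip(0.5 * (fp - fm) / (-a2), -1.0, 1.0))
            h = bv[1] - bv[0]
            return int(n_best), float(bv[jn] + x * h)
    return int(n_best), float(bv[jn])


def forward_collect(
    trace: Trace,
    params: ModelParams,
    grid: StateGrid,
    m_tables: list,
    best_n: list,
    best_B: list,
    config: Optional[EngineConfig] = None,
) -> MapResult:
    """Forward sweep emitting the MAP spike train and latent path.

    Starts at the argmax of m_1 (restricted to the known initial calcium
    when configured).  At each step the transition out of the current,
    generally off-grid, state is re-maximized locally from the stored
    m_{t+1} table; the hill_rise variant instead reads the stored argmax
    decisions from the nearest grid point.  The returned log posterior
    is recomputed exactly from the emitted path.
    """
    config = config or EngineConfig()
    T = len(trace)
    rise = params.probe == "hill_rise"
    start = m_tables[0].astype(float).copy()
    if grid.c1_logprior is not None:
        start += (
            grid.c1_logprior[:, None, None] if rise else grid.c1_logprior[:, None]
        )
    if config.c1 is not None:
        i0 = _nearest(grid.c_values, config.c1)
        rest = np.unravel_index(np.argmax(start[i0]), start[i0].shape)
        idx = (i0,) + rest
        c = float(config.c1)
    else:
        idx = np.unravel_index(np.argmax(start), start.shape)
        c = float(grid.c_values[idx[0]])
    if rise:
        q = idx[1]
        p = float(grid.p_values[q])
        B = float(grid.B_values[idx[2]])
    else:
        p = None
        B = float(grid.B_values[idx[-1]])

    counts = np.zeros(T, dtype=int)
    c_path = np.empty(T)
    B_path = np.empty(T)
    p_path = np.empty(T) if rise else None
    c_path[0], B_path[0] = c, B
    if rise:
        p_path[0] = p
    rho = (
        math.exp(-trace.dt / params.tau_on)
        if (rise and params.tau_on > 0)
        else 0.0
    )
    for t in range(T - 1):
        if rise:
            i = _nearest(grid.c_values, c)
            qn = _nearest(grid.p_values, p)
            # refined-B table is indexed (c, p, B_parent): interpolate over B only
            bv = grid.B_values
            if bv.size == 1:
                Bnext = float(best_B[t][i, qn, 0])
            else:
                j1 = int(np.clip(np.searchsorted(bv, B), 1, bv.size - 1))
                j0 = j1 - 1
                wb = min(max((B - bv[j0]) / (bv[j1] - bv[j0]), 0.0), 1.0)
                Bnext = float((1 - wb) * best_B[t][i, qn, j0] + wb * best_B[t][i, qn, j1])
            jn = _nearest(grid.B_values, Bnext)
            n = int(best_n[t][i, qn, jn])
            c = c * grid.decay + n
            g_c = float(nonlinearity(min(c, grid.c_values[-1]), params))
            p = g_c + (p - g_c) * rho
            p_path[t + 1] = p
        else:
            n, Bnext = _local_transition_argmax(c, B, m_tables[t + 1], params, grid)
            c = min(c * grid.decay + n, grid.c_values[-1])
        counts[t + 1] = n
        B = Bnext
        c_path[t + 1], B_path[t + 1] = c, B

    path = LatentPath(c=c_path, B=B_path, p=p_path)
    lp = path_log_posterior(
        trace, params, counts, c_path[0], B_path, p=p_path,
        c_cap=float(grid.c_values[-1]),
    )
    fit = measure(c_path, B_path, params, p=p_path)
    times = (np.flatnonzero(counts) + 0.5) * trace.dt
    times = np.repeat(times, counts[counts > 0]) - params.delay
    spikes = SpikeTrain(times=np.clip(times, 0.0, None))
    return MapResult(
        spikes=spikes, counts=counts, path=path, log_posterior=lp, fit=fit
    )


def path_log_posterior(
    trace: Trace,
    params: ModelParams,
    counts: np.ndarray,
    c1: float,
    B_path,
    p=None,
    c_cap: Optional[float] = None,
) -> float:
    """Exact unnormalized log posterior of a spike/baseline path.

    Shared by the grid estimator and the exhaustive oracle so their
    results are directly comparable.  ``c_cap`` applies the engine's
    saturating calcium dynamics (c' = min(c*decay + n, c_cap)).
    """
    y = trace.values
    T = y.size
    counts = np.asarray(counts, dtype=int)
    B_path = np.broadcast_to(np.asarray(B_path, dtype=float), (T,))
    decay = math.exp(-trace.dt / params.tau)
    from scipy.signal import lfilter

    c = np.empty(T)
    c[0] = c1
    c[1:] = lfilter([1.0], [1.0, -decay], counts[1:].astype(float))
    c[1:] += c1 * decay ** np.arange(1, T)
    if c_cap is not None and c.max() > c_cap:
        prev = min(c1, c_cap)
        c[0] = prev
        for t in range(1, T):
            prev = min(prev * decay + counts[t], c_cap)
            c[t] = prev
    mu = params.lam * trace.dt
    n = counts[1:]
    lp = float(np.sum(-mu + n * math.log(mu) - gammaln(n + 1)))
    if params.eta > 0:
        s = params.eta * math.sqrt(trace.dt)
        dB = np.diff(B_path)
        lp += float(
            np.sum(-0.5 * (dB / s) ** 2 - math.log(s) - 0.5 * _LOG_2PI)
        )
    if p is not None:
        pred = B_path * (1.0 + params.A * np.asarray(p))
    else:
        pred = measure(c, B_path, params)
    z = (y - pred) / params.sigma
    lp += float(np.sum(-0.5 * z**2 - math.log(params.sigma) - 0.5 * _LOG_2PI))
    return lp


def map_spikes(
    trace: Trace, params: ModelParams, config: Optional[EngineConfig] = None
) -> MapResult:
    """MAP spike-train estimation: grid build + backward pass + collection."""
    config = config or EngineConfig()
    grid = build_grid(trace, params, config)
    ms, best_n, best_B = backward_map_pass(trace, params, grid)
    return forward_collect(trace, params, grid, ms, best_n, best_B, config)


# ---------------------------------------------------------------------------
# sum-product: filtering, smoothing, sampling


def _check_not_rise(params: ModelParams, what: str) -> None:
    if params.probe == "hill_rise":
        raise NotImplementedError(
            f"{what} supports the instantaneous-binding probes only"
        )


def smoothed_spike_probabilities(
    trace: Trace, params: ModelParams, config: Optional[EngineConfig] = None
) -> PosteriorArrays:
    """Forward filtering / backward likelihood and per-bin spike marginals.

    Runs the same grid recursions with sums in place of maxima: the
    forward pass propagates masses through the transposed interpolation
    operators and a discretized Gaussian baseline kernel, normalizing
    each step (the normalizers accumulate into the log evidence); the
    backward pass evaluates the conditional likelihood by interpolation.
    Per-bin marginals P(n_t = k | y) pair the two passes across each
    transition and sum to 1.
    """
    _check_not_rise(params, "smoothed_spike_probabilities")
    if params.sigma <= 0:
        raise ValueError("inference requires sigma > 0")
    config = config or EngineConfig()
    grid = build_grid(trace, params, config)
    y = trace.values
    T = y.size
    nmax = params.nmax
    nc, nb = grid.nc, grid.nb
    pois = np.exp(grid.logpois)

    emis_log = np.empty((T, nc, nb))
    for t in range(T):
        emis_log[t] = _emission_table(y[t], grid, params)

    # backward conditional likelihood, normalized per step
    beta = np.empty((T, nc, nb))
    beta_scale = np.empty(T)
    e = emis_log[T - 1] - emis_log[T - 1].max()
    beta[T - 1] = np.exp(e)
    beta_scale[T - 1] = emis_log[T - 1].max()
    for t in range(T - 2, -1, -1):
        acc = np.zeros((nc, nb))
        for n in range(nmax + 1):
            acc += pois[n] * np.clip(grid.W[n] @ beta[t + 1], 0.0, None)
        if nb > 1:
            acc = acc @ grid.G.T
        lt = emis_log[t] - emis_log[t].max()
        b = np.exp(lt) * acc
        s = b.max()
        if s <= 0:
            raise FloatingPointError("backward pass underflowed")
        beta[t] = b / s
        beta_scale[t] = beta_scale[t + 1] + emis_log[t].max() + math.log(s)

    # forward filter, normalized per step
    alpha = np.empty((T, nc, nb))
    prior = np.zeros((nc, nb))
    if config.c1 is not None:
        prior[:] = -np.inf
        prior[_nearest(grid.c_values, config.c1), :] = 0.0
    if grid.c1_logprior is not None:
        prior += grid.c1_logprior[:, None]
    a0 = emis_log[0] + prior
    a0 = np.exp(a0 - a0.max())
    log_evidence = 0.0
    alpha[0] = a0 / a0.sum()
    log_evidence += math.log(a0.sum() / a0.size) + (emis_log[0] + prior).max()

    marg = np.zeros((T, nmax + 1))
    marg[0, 0] = 1.0
    for t in range(1, T):
        pred = np.zeros((nc, nb))
        s_k = np.empty(nmax + 1)
        for n in range(nmax + 1):
            WkT = grid.W[n].T @ alpha[t - 1]
            pred += pois[n] * WkT
            # marginal pairing: alpha_{t-1} . (W_k beta_t G^T)
            Ck = np.clip(grid.W[n] @ beta[t], 0.0, None)
            if nb > 1:
                Ck = Ck @ grid.G.T
            s_k[n] = pois[n] * float(np.sum(alpha[t - 1] * Ck))
        if nb > 1:
            pred = pred @ grid.G
        # note: pred may carry small negative entries from the oscillating
        # cubic-spline adjoint weights; clipping them would bias the
        # filter, so they are kept and only the total mass is checked
        a = np.exp(emis_log[t] - emis_log[t].max()) * pred
        tot = a.sum()
        if tot <= 0:
            raise FloatingPointError("forward pass underflowed")
        alpha[t] = a / tot
        log_evidence += math.log(tot) + emis_log[t].max()
        marg[t] = s_k / s_k.sum()

    expected = marg @ np.arange(nmax + 1)
    return PosteriorArrays(
        alpha=alpha,
        beta=beta,
        beta_logscale=beta_scale,
        spike_marginals=marg,
        expected_counts=expected,
        log_evidence=log_evidence,
    )


def sample_posterior(
    trace: Trace,
    params: ModelParams,
    config: Optional[EngineConfig] = None,
    n_samples: int = 100,
    seed=None,
):
    """Ancestral sampling of spike trains from the posterior p(x | y).

    Uses the backward conditional-likelihood tables, then draws x_1 from
    prior * beta_1 and each subsequent state from transition * beta_t,
    with the calcium value kept continuous (baseline sampled on the
    grid, beta evaluated by linear interpolation along calcium).
    Reproducible given ``seed``.
    """
    _check_not_rise(params, "sample_posterior")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    config = config or EngineConfig()
    post = smoothed_spike_probabilities(trace, params, config)
    grid = build_grid(trace, params, config)
    rng = np.random.default_rng(seed)
    y = trace.values
    T = y.size
    nmax = params.nmax
    nc, nb = grid.nc, grid.nb
    pois = np.exp(grid.logpois)
    cv, bv = grid.c_values, grid.B_values
    S = n_samples

    w0 = post.beta[0].copy()
    if config.c1 is not None:
        keep = np.zeros(nc, dtype=bool)
        keep[_nearest(cv, config.c1)] = True
        w0[~keep] = 0.0
    if grid.c1_logprior is not None:
        w0 *= np.exp(grid.c1_logprior)[:, None]
    flat = w0.ravel() / w0.sum()
    draw = rng.choice(flat.size, size=S, p=flat)
    ci, bj = np.unravel_index(draw, (nc, nb))
    c = cv[ci].astype(float)
    if config.c1 is not None:
        c[:] = config.c1
    counts = np.zeros((S, T), dtype=int)
    c_paths = np.empty((S, T))
    B_paths = np.empty((S, T))
    c_paths[:, 0] = c
    B_paths[:, 0] = bv[bj]

    for t in range(1, T):
        child = c[:, None] * grid.decay + np.arange(nmax + 1)[None, :]  # (S, K)
        np.minimum(child, cv[-1], out=child)  # saturating dynamics
        i1 = np.clip(np.searchsorted(cv, child), 1, nc - 1)
        i0 = i1 - 1
        wc = (child - cv[i0]) / (cv[i1] - cv[i0])
        wc = np.clip(wc, 0.0, 1.0)
        bt = post.beta[t]
        val = (1 - wc)[..., None] * bt[i0] + wc[..., None] * bt[i1]  # (S, K, nb)
        if nb > 1:
            Grow = grid.G[bj]  # (S, nb)
            wgt = pois[None, :, None] * val * Grow[:, None, :]
        else:
            wgt = pois[None, :, None] * val
        flatw = wgt.reshape(S, -1)
        tot = flatw.sum(axis=1, keepdims=True)
        if np.any(tot <= 0):
            raise FloatingPointError("sampling weights underflowed")
        cdf = np.cumsum(flatw, axis=1) / tot
        u = rng.random((S, 1))
        pick = (u > cdf).sum(axis=1)
        k = pick // nb
        bj = pick % nb
        c = np.minimum(c * grid.decay + k, cv[-1])
        counts[:, t] = k
        c_paths[:, t] = c
        B_paths[:, t] = bv[bj]

    out = []
    for s in range(S):
        times = (np.flatnonzero(counts[s]) + 0.5) * trace.dt
        times = np.repeat(times, counts[s][counts[s] > 0]) - params.delay
        out.append(
            (
                SpikeTrain(times=np.clip(times, 0.0, None)),
                LatentPath(c=c_paths[s], B=B_paths[s]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# amplitude-mode detection (autocalibration front end)


def map_calcium_events(
    trace: Trace,
    params: ModelParams,
    config: Optional[EngineConfig] = None,
    a_min: float = 0.04,
):
    """MAP estimation with continuous event amplitudes instead of counts.

    The per-bin maximization over discrete spike counts is replaced by a
    choice between "no event" and a calcium jump of arbitrary amplitude
    at least ``a_min`` (dF/F units): for each parent the best admissible
    child is found by a suffix maximum over the calcium grid, so the
    amplitude resolution equals the grid resolution.  Returns a list of
    (time, amplitude) events and the MAP latent path.
    """
    _check_not_rise(params, "map_calcium_events")
    config = config or EngineConfig()
    grid = build_grid(trace, params, config)
    y = trace.values
    T = y.size
    nc, nb = grid.nc, grid.nb
    cv = grid.c_values
    mu = params.lam * trace.dt
    lp0 = -mu
    lp1 = -mu + math.log(mu)

    # first admissible child index per parent
    child_min = cv * grid.decay + a_min / params.A
    idx_min = np.searchsorted(cv, child_min)
    feasible = idx_min < nc

    m = _emission_table(y[T - 1], grid, params)
    dec_event = [None] * max(T - 1, 0)
    dec_child = [None] * max(T - 1, 0)
    best_B = [None] * max(T - 1, 0)
    for t in range(T - 2, -1, -1):
        M0 = grid.W[0] @ m + lp0
        # suffix max of m over the calcium grid, per baseline column, and
        # the (lowest) index attaining it
        suff = np.maximum.accumulate(m[::-1], axis=0)[::-1]
        attains = m >= suff  # equality where the suffix max is attained
        cand_idx = np.where(attains, np.arange(nc)[:, None], nc)
        suff_arg = np.minimum.accumulate(cand_idx[::-1], axis=0)[::-1]
        Mev = np.full((nc, nb), -np.inf)
        child_idx = np.zeros((nc, nb), dtype=np.int32)
        ok = feasible
        Mev[ok] = suff[idx_min[ok]] + lp1
        child_idx[ok] = suff_arg[idx_min[ok]]
        ev = Mev > M0
        M1 = np.where(ev, Mev, M0)
        Mb, Bnext = _b_max_step(M1, grid)
        m = _emission_table(y[t], grid, params) + Mb
        m -= m.max()
        dec_event[t] = ev
        dec_child[t] = child_idx
        best_B[t] = Bnext.astype(np.float32)

    # forward collection
    idx = np.unravel_index(np.argmax(m), m.shape)
    c = float(cv[idx[0]])
    B = float(grid.B_values[idx[-1]])
    events = []
    c_path = np.empty(T)
    B_path = np.empty(T)
    c_path[0], B_path[0] = c, B
    for t in range(T - 1):
        i = _nearest(cv, c)
        Bnext = _interp_B_table(best_B[t], grid, c, B)
        jn = _nearest(grid.B_values, Bnext)
        if dec_event[t][i, jn]:
            c_new = float(cv[dec_child[t][i, jn]])
            amp = max((c_new - c * grid.decay) * params.A, a_min)
            events.append(((t + 1 + 0.5) * trace.dt, amp))
            c = c * grid.decay + amp / params.A
        else:
            c = c * grid.decay
        B = Bnext
        c_path[t + 1], B_path[t + 1] = c, B
    return events, LatentPath(c=c_path, B=B_path)


# ---------------------------------------------------------------------------
# exhaustive oracles


class EnumerationError(ValueError):
    """Raised when the exhaustive search space exceeds the safe cap."""


def _enumerate_logposts(
    trace: Trace,
    params: ModelParams,
    c1_values: np.ndarray,
    B_values: np.ndarray,
    c_cap: Optional[float],
):
    """Log posterior of every (c1, constant B, spike sequence) path."""
    if params.eta > 0:
        raise ValueError("exhaustive enumeration requires eta = 0")
    y = trace.values
    T = y.size
    K = params.nmax + 1
    n_seq = K ** (T - 1)
    total = n_seq * c1_values.size * B_values.size
    if total > 5e7:
        raise EnumerationError(f"search space {total:.2g} exceeds cap")
    seqs = np.indices((K,) * (T - 1)).reshape(T - 1, -1).T.astype(np.int8)
    decay = math.exp(-trace.dt / params.tau)
    mu = params.lam * trace.dt
    logpois = _log_poisson(params.nmax, mu)
    lp_seq = logpois[seqs].sum(axis=1)

    out = np.empty((c1_values.size, B_values.size, n_seq))
    for a, c1 in enumerate(c1_values):
        c = np.full(n_seq, float(c1))
        for b, B in enumerate(B_values):
            out[a, b, :] = emission_logprob(y[0], c1, B, params)
        cs = [None] * T
        cs[0] = np.full(n_seq, float(c1))
        for t in range(1, T):
            c = c * decay + seqs[:, t - 1]
            if c_cap is not None:
                np.minimum(c, c_cap, out=c)  # saturating dynamics, as on the grid
            cs[t] = c.copy()
        for b, B in enumerate(B_values):
            lp = np.zeros(n_seq)
            for t in range(1, T):
                pred = B * (1.0 + params.A * nonlinearity(cs[t], params))
                z = (y[t] - pred) / params.sigma
                lp += -0.5 * z**2 - math.log(params.sigma) - 0.5 * _LOG_2PI
            out[a, b, :] += lp + lp_seq
        del cs
    return seqs, out


def brute_force_map(
    trace: Trace,
    params: ModelParams,
    c1_values=0.0,
    B_values=1.0,
    c_cap: Optional[float] = None,
) -> MapResult:
    """Exact MAP by exhaustive enumeration (test oracle).

    Enumerates every spike-count sequence (and each candidate initial
    calcium / constant baseline), evaluates the exact log posterior via
    :func:`path_log_posterior` semantics, and returns the maximum.
    Bounded: total search space is capped, eta must be 0.  ``c_cap``
    excludes paths whose calcium exceeds a grid ceiling, mirroring the
    grid estimator's finite state space.
    """
    c1_values = np.atleast_1d(np.asarray(c1_values, dtype=float))
    B_values = np.atleast_1d(np.asarray(B_values, dtype=float))
    seqs, lps = _enumerate_logposts(trace, params, c1_values, B_values, c_cap)
    a, b, s = np.unravel_index(np.argmax(lps), lps.shape)
    T = len(trace)
    counts = np.zeros(T, dtype=int)
    counts[1:] = seqs[s]
    c1 = float(c1_values[a])
    B = float(B_values[b])
    decay = math.exp(-trace.dt / params.tau)
    c_path = np.empty(T)
    c_path[0] = c1
    for t in range(1, T):
        c_path[t] = c_path[t - 1] * decay + counts[t]
        if c_cap is not None:
            c_path[t] = min(c_path[t], c_cap)
    B_path = np.full(T, B)
    lp = path_log_posterior(trace, params, counts, c1, B_path, c_cap=c_cap)
    times = (np.flatnonzero(counts) + 0.5) * trace.dt
    times = np.repeat(times, counts[counts > 0]) - params.delay
    return MapResult(
        spikes=SpikeTrain(times=np.clip(times, 0.0, None)),
        counts=counts,
        path=LatentPath(c=c_path, B=B_path),
        log_posterior=lp,
        fit=measure(c_path, B_path, params),
    )


def exhaustive_spike_marginals(
    trace: Trace,
    params: ModelParams,
    c1_values=0.0,
    B_values=1.0,
    c_cap: Optional[float] = None,
) -> np.ndarray:
    """Exact per-bin spike marginals by exhaustive enumeration (oracle)."""
    c1_values = np.atleast_1d(np.asarray(c1_values, dtype=float))
    B_values = np.atleast_1d(np.asarray(B_values, dtype=float))
    seqs, lps = _enumerate_logposts(trace, params, c1_values, B_values, c_cap)
    w = np.exp(lps - lps.max())
    w_seq = w.sum(axis=(0, 1))  # marginalize c1 and B
    w_seq /= w_seq.sum()
    T = len(trace)
    K = params.nmax + 1
    marg = np.zeros((T, K))
    marg[0, 0] = 1.0
    for t in range(1, T):
        marg[t] = np.bincount(seqs[:, t - 1], weights=w_seq, minlength=K)
    return marg
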