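"""Stochastic Euler integration of two delayed-coupling neural-mass models.

Both models place one neural mass per ROI, coupled through the structural
weight matrix C with per-pair conduction delays tau_np:

Firing Rate (linear, relaxational; stable for k < c1 at sigma = 0)::

    tau0 * dr_n/dt = -r_n(t) + (k / c1) * sum_p C_np r_p(t - tau_np) + sigma * n(t)

Kuramoto (phase oscillators, natural frequencies ~ Normal(60, 2) rad/s)::

    dtheta_n/dt = omega_n + k * sum_p C_np sin(theta_p(t - tau_np) - theta_n(t))
                  + sigma * n(t)

Integration is Euler-Maruyama: the deterministic drift advances by dt, the
noise term adds sigma * sqrt(dt) * N(0, 1) per node per step. Delays are
rounded to integer multiples of dt and read from a ring buffer; history
before t = 0 is the (constant) initial state. The Kuramoto observable
passed downstream is sin(theta).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .connectome import Connectome
from .errors import IntegrationError, InvalidArgumentError

__all__ = [
    "SimulationConfig",
    "NeuralTimeSeries",
    "leading_eigenvalue",
    "simulate_firing_rate",
    "simulate_kuramoto",
    "simulate",
]

#: coupling presets per model: (low, default, high)
COUPLING_PRESETS = {
    "firing_rate": {"low": 0.3, "default": 0.9, "high": 0.999},
    "kuramoto": {"low": 3.0, "default": 13.0, "high": 60.0},
}


@dataclass
class SimulationConfig:
    """Parameters of one simulation run.

    ``sigma`` is the SD of the Gaussian white noise. By default it is
    2 for the firing-rate model (whose stationary fluctuations are
    noise-driven) and 0 for Kuramoto: the delayed Kuramoto network is
    run deterministically, as in the lineage models, because its
    BOLD-band structure rides on slow beats of partially locked phase
    clusters that white phase noise of any appreciable size buries
    under a broadband floor. ``tau0`` is the firing-rate relaxation
    constant (20 ms);
    ``omega_mean``/``omega_sd`` parameterize the Kuramoto natural
    frequencies in rad/s, entering the phase equation directly (the
    lineage implementations feed the nominal oscillation numbers into
    dtheta/dt unconverted; with the stated couplings this is the only
    reading that places k = 3/13/60 in the incoherent / partially
    synchronized / fully synchronized regimes).
    """

    model: str = "firing_rate"
    k: float | None = None
    dt: float = 1e-4
    duration: float = 900.0
    discard: float = 20.0
    sigma: float | None = None
    tau0: float = 0.020
    omega_mean: float = 60.0
    omega_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.model not in ("firing_rate", "kuramoto"):
            raise InvalidArgumentError(f"unknown model {self.model!r}")
        if self.dt <= 0:
            raise InvalidArgumentError("dt must be positive")
        if not self.discard < self.duration:
            raise InvalidArgumentError("discard must be smaller than duration")
        if self.tau0 <= 0:
            raise InvalidArgumentError("tau0 must be positive")
        if self.sigma is None:
            self.sigma = 2.0 if self.model == "firing_rate" else 0.0
        if self.sigma < 0:
            raise InvalidArgumentError("sigma must be non-negative")
        if self.k is None:
            self.k = COUPLING_PRESETS[self.model]["default"]


@dataclass
class NeuralTimeSeries:
    """ROI x step trajectory at integration resolution.

    ``values[:, j]`` is the observable at time ``discard + j * dt``:
    the firing rate r for the firing-rate model, sin(theta) for
    Kuramoto. Raw wrapped phases are kept in ``phases`` when requested.
    """

    values: np.ndarray
    dt: float
    model: str
    config: SimulationConfig
    phases: np.ndarray | None = None

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    @property
    def n_steps(self) -> int:
        return self.values.shape[1]


def leading_eigenvalue(W: np.ndarray) -> float:
    """Largest eigenvalue c1 of a symmetric matrix."""
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise InvalidArgumentError(f"expected a square matrix, got shape {W.shape}")
    return float(np.linalg.eigvalsh(W)[-1])


def _edge_arrays(conn: Connectome, dt: float):
    """Flatten the nonzero couplings into edge lists with delay steps."""
    i_idx, p_idx = np.nonzero(conn.weights)
    w = conn.weights[i_idx, p_idx]
    dsteps = np.rint(conn.delays[i_idx, p_idx] / dt).astype(np.int64)
    return (
        i_idx.astype(np.int64),
        p_idx.astype(np.int64),
        w.astype(np.float64),
        dsteps,
    )


@njit(cache=True, fastmath=True)
def _fr_kernel(i_idx, p_idx, w, dsteps, r0, n_total, keep, dt, tau0, k_over_c1,
               sigma, noise_seed):
    n = r0.shape[0]
    H = int(dsteps.max()) + 1 if dsteps.size else 1
    hist = np.empty((n, H))
    for i in range(n):
        for j in range(H):
            hist[i, j] = r0[i]
    out = np.empty((n, n_total - keep))
    r = r0.copy()
    sqrt_dt = np.sqrt(dt)
    np.random.seed(noise_seed)
    for t in range(n_total):
        pos = t % H
        for i in range(n):
            if t >= keep:
                out[i, t - keep] = r[i]
            hist[i, pos] = r[i]
        acc = np.zeros(n)
        for e in range(w.shape[0]):
            acc[i_idx[e]] += w[e] * hist[p_idx[e], (t - dsteps[e]) % H]
        bad = -1
        for i in range(n):
            noise = sigma * sqrt_dt * np.random.normal() if sigma > 0 else 0.0
            r[i] = r[i] + (dt / tau0) * (-r[i] + k_over_c1 * acc[i]) + noise
            # magnitude guard: fastmath elides NaN checks, so trip on the
            # way to overflow instead
            if np.abs(r[i]) > 1e12:
                bad = t
        if bad >= 0:
            return out, bad
    return out, -1


@njit(cache=True, fastmath=True)
def _km_kernel(i_idx, p_idx, w, dsteps, theta0, omega, n_total, keep, dt, k,
               sigma, noise_seed, store_phases):
    n = theta0.shape[0]
    H = int(dsteps.max()) + 1 if dsteps.size else 1
    hist_s = np.empty((n, H))
    hist_c = np.empty((n, H))
    for i in range(n):
        s0, c0 = np.sin(theta0[i]), np.cos(theta0[i])
        for j in range(H):
            hist_s[i, j] = s0
            hist_c[i, j] = c0
    out = np.empty((n, n_total - keep))
    phases = np.empty((n, n_total - keep)) if store_phases else np.empty((1, 1))
    theta = theta0.copy()
    sn = np.empty(n)
    cn = np.empty(n)
    sqrt_dt = np.sqrt(dt)
    two_pi = 2.0 * np.pi
    np.random.seed(noise_seed)
    for t in range(n_total):
        pos = t % H
        for i in range(n):
            sn[i] = np.sin(theta[i])
            cn[i] = np.cos(theta[i])
            hist_s[i, pos] = sn[i]
            hist_c[i, pos] = cn[i]
            if t >= keep:
                out[i, t - keep] = sn[i]
                if store_phases:
                    phases[i, t - keep] = theta[i] % two_pi
        acc_s = np.zeros(n)
        acc_c = np.zeros(n)
        for e in range(w.shape[0]):
            jd = (t - dsteps[e]) % H
            p = p_idx[e]
            acc_s[i_idx[e]] += w[e] * hist_s[p, jd]
            acc_c[i_idx[e]] += w[e] * hist_c[p, jd]
        bad = -1
        for i in range(n):
            # sin(theta_p_delayed - theta_i) = sin_p cos_i - cos_p sin_i
            coupling = acc_s[i] * cn[i] - acc_c[i] * sn[i]
            noise = sigma * sqrt_dt * np.random.normal() if sigma > 0 else 0.0
            theta[i] = theta[i] + dt * (omega[i] + k * coupling) + noise
            if np.abs(theta[i]) > 1e12:
                bad = t
        if bad >= 0:
            return out, phases, bad
    return out, phases, -1


def _seeds(seed: int):
    ss = np.random.SeedSequence(seed)
    init_state, noise_state = ss.generate_state(2)
    return np.random.default_rng(int(init_state)), np.uint32(noise_state)


def simulate_firing_rate(
    conn: Connectome, cfg: SimulationConfig, r0: np.ndarray | None = None
) -> NeuralTimeSeries:
    """Integrate the linear firing-rate model on ``conn``.

    The coupling term is scaled by 1/c1 (largest eigenvalue of C), so the
    system is linearly stable at sigma = 0 whenever k < 1 for a symmetric
    non-negative weight matrix. Initial rates are Uniform(0, 1) unless
    ``r0`` pins them.
    """
    if cfg.model != "firing_rate":
        raise InvalidArgumentError(f"config model is {cfg.model!r}, expected firing_rate")
    rng, noise_seed = _seeds(cfg.seed)
    if r0 is None:
        r0 = rng.uniform(0.0, 1.0, size=conn.n_rois)
    r0 = np.asarray(r0, dtype=float)
    c1 = leading_eigenvalue(conn.weights)
    i_idx, p_idx, w, dsteps = _edge_arrays(conn, cfg.dt)
    n_total = int(round(cfg.duration / cfg.dt))
    keep = int(round(cfg.discard / cfg.dt))
    out, bad = _fr_kernel(
        i_idx, p_idx, w, dsteps, r0, n_total, keep, cfg.dt, cfg.tau0,
        cfg.k / c1, cfg.sigma, noise_seed,
    )
    if bad >= 0 or not np.all(np.isfinite(out)):
        step = bad if bad >= 0 else -1
        raise IntegrationError(
            f"firing rate diverged at step {step} (t={max(step, 0) * cfg.dt:.4f} s)"
        )
    return NeuralTimeSeries(values=out, dt=cfg.dt, model="firing_rate", config=cfg)


def simulate_kuramoto(
    conn: Connectome,
    cfg: SimulationConfig,
    store_phases: bool = False,
    omega: np.ndarray | None = None,
    theta0: np.ndarray | None = None,
) -> NeuralTimeSeries:
    """Integrate the delayed Kuramoto model on ``conn``.

    Natural frequencies (rad/s) are drawn once per run from
    Normal(omega_mean, omega_sd); pass ``omega`` to pin them (used by
    closed-form tests). The returned observable is sin(theta); wrapped
    phases are stored when ``store_phases`` is true.
    """
    if cfg.model != "kuramoto":
        raise InvalidArgumentError(f"config model is {cfg.model!r}, expected kuramoto")
    rng, noise_seed = _seeds(cfg.seed)
    if theta0 is None:
        theta0 = rng.uniform(0.0, 2 * np.pi, size=conn.n_rois)
    theta0 = np.asarray(theta0, dtype=float)
    if omega is None:
        omega = rng.normal(cfg.omega_mean, cfg.omega_sd, size=conn.n_rois)
    omega = np.asarray(omega, dtype=float)
    i_idx, p_idx, w, dsteps = _edge_arrays(conn, cfg.dt)
    n_total = int(round(cfg.duration / cfg.dt))
    keep = int(round(cfg.discard / cfg.dt))
    out, phases, bad = _km_kernel(
        i_idx, p_idx, w, dsteps, theta0, omega, n_total, keep, cfg.dt, cfg.k,
        cfg.sigma, noise_seed, store_phases,
    )
    if bad >= 0 or not np.all(np.isfinite(out)):
        step = bad if bad >= 0 else -1
        raise IntegrationError(
            f"phase diverged at step {step} (t={max(step, 0) * cfg.dt:.4f} s)"
        )
    return NeuralTimeSeries(
        values=out,
        dt=cfg.dt,
        model="kuramoto",
        config=cfg,
        phases=phases if store_phases else None,
    )


def simulate(conn: Connectome, cfg: SimulationConfig, **kwargs) -> NeuralTimeSeries:
    """Dispatch to the model named in ``cfg.model``."""
    if cfg.model == "firing_rate":
        return simulate_firing_rate(conn, cfg)
    return simulate_kuramoto(conn, cfg, **kwargs)
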