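"""Balloon-Windkessel hemodynamics and downsampling to the scanner TR.

Each ROI's neural drive x(t) feeds an independent 4-state ODE
(vasodilatory signal s, inflow f, venous volume v, deoxyhemoglobin q)::

    ds/dt = x - kappa * s - gamma * (f - 1)
    df/dt = s
    tau * dv/dt = f - v**(1/alpha)
    tau * dq/dt = f * E(f)/E0 - q * v**(1/alpha - 1)

with oxygen extraction E(f) = 1 - (1 - E0)**(1/f), and BOLD observation

    y = V0 * (k1 * (1 - q) + k2 * (1 - q/v) + k3 * (1 - v)).

Constants default to the canonical Friston set. Integration is Euler at
the neural dt; the resting state (s=0, f=v=q=1) maps to y = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .errors import IntegrationError, InvalidArgumentError
from .simulate import NeuralTimeSeries

__all__ = ["BalloonParams", "BoldTimeSeries", "balloon_windkessel", "downsample_to_tr"]


@dataclass(frozen=True)
class BalloonParams:
    """Hemodynamic constants (canonical Friston values)."""

    kappa: float = 0.65   # signal decay, 1/s
    gamma: float = 0.41   # flow-dependent feedback, 1/s
    tau: float = 0.98     # mean transit time, s
    alpha: float = 0.32   # Grubb vessel stiffness exponent
    E0: float = 0.34      # resting oxygen extraction fraction
    V0: float = 0.02      # resting venous blood volume fraction
    k1: float = 7 * 0.34
    k2: float = 2.0
    k3: float = 2 * 0.34 - 0.2
    gain: float = 1.0     # scale applied to the neural drive

    def __post_init__(self):
        for name in ("kappa", "gamma", "tau", "E0", "V0"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be positive")
        if not 0 < self.alpha < 1:
            raise InvalidArgumentError("alpha must lie in (0, 1)")


@dataclass
class BoldTimeSeries:
    """ROI x TR BOLD signal with its preprocessing provenance."""

    values: np.ndarray
    tr: float
    preprocessing_flags: list = field(default_factory=list)

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    @property
    def n_trs(self) -> int:
        return self.values.shape[1]


@njit(cache=True, fastmath=True)
def _balloon_kernel(x, dt, kappa, gamma, tau, alpha, E0, V0, k1, k2, k3):
    n, T = x.shape
    y = np.empty((n, T))
    inv_alpha = 1.0 / alpha
    one_minus_E0 = 1.0 - E0
    bad_roi, bad_t = -1, -1
    for i in range(n):
        s = 0.0
        f = 1.0
        v = 1.0
        q = 1.0
        for t in range(T):
            y[i, t] = V0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v) + k3 * (1.0 - v))
            vexp = v ** inv_alpha
            E = 1.0 - one_minus_E0 ** (1.0 / f)
            ds = x[i, t] - kappa * s - gamma * (f - 1.0)
            df = s
            dv = (f - vexp) / tau
            dq = (f * E / E0 - q * vexp / v) / tau
            s += dt * ds
            f += dt * df
            v += dt * dv
            q += dt * dq
            if f <= 1e-6 or not (np.isfinite(s) and np.isfinite(q)):
                bad_roi, bad_t = i, t
                break
        if bad_roi >= 0:
            break
    return y, bad_roi, bad_t


def balloon_windkessel(
    neural: NeuralTimeSeries | np.ndarray,
    params: BalloonParams = BalloonParams(),
    dt: float | None = None,
) -> np.ndarray:
    """Hemodynamic response of each ROI to its neural drive.

    Accepts either a :class:`NeuralTimeSeries` or a raw (n, T) array
    with an explicit ``dt``. Returns the BOLD observable at the same dt.
    """
    if isinstance(neural, NeuralTimeSeries):
        x, dt = neural.values, neural.dt
    else:
        x = np.asarray(neural, dtype=float)
        if dt is None:
            raise InvalidArgumentError("dt is required for raw-array input")
    if not np.all(np.isfinite(x)):
        raise InvalidArgumentError("neural input contains non-finite values")
    y, bad_roi, bad_t = _balloon_kernel(
        np.ascontiguousarray(x * params.gain), dt,
        params.kappa, params.gamma, params.tau, params.alpha,
        params.E0, params.V0, params.k1, params.k2, params.k3,
    )
    if bad_roi >= 0:
        raise IntegrationError(
            f"hemodynamic state left its physical range at ROI {bad_roi}, "
            f"step {bad_t} (t={bad_t * dt:.3f} s); dt may be too large"
        )
    return y


def downsample_to_tr(
    signal: np.ndarray,
    dt: float,
    tr: float = 0.72,
    antialias: bool = True,
) -> BoldTimeSeries:
    """Decimate a dt-resolution signal to one sample per TR.

    A zero-phase low-pass guard at the TR Nyquist precedes decimation
    (skippable for signals already bandlimited). Output length is
    floor(T * dt / tr).
    """
    from scipy import signal as sps

    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    if tr < dt:
        raise InvalidArgumentError(f"tr ({tr}) must be >= dt ({dt})")
    step = int(round(tr / dt))
    n_out = int(np.floor(signal.shape[1] * dt / tr))
    if antialias and step > 1:
        nyq_tr = 0.5 / tr
        sos = sps.butter(4, nyq_tr, btype="low", fs=1.0 / dt, output="sos")
        # filter in ROI blocks to bound the filtfilt temporaries on long runs
        out = np.empty((signal.shape[0], n_out))
        for lo in range(0, signal.shape[0], 8):
            block = sps.sosfiltfilt(sos, signal[lo : lo + 8], axis=1)
            out[lo : lo + 8] = block[:, : n_out * step : step]
    else:
        out = signal[:, : n_out * step : step]
    return BoldTimeSeries(values=np.ascontiguousarray(out), tr=tr,
                          preprocessing_flags=["downsample"])
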