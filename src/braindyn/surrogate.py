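"""Surrogate resting-state BOLD generator.

Emulates the features of parcellated human resting-state fMRI that the
analysis metrics are sensitive to, without any scan data: a hidden
Markov chain over a few covariance regimes (switching network states),
1/f^n spectral shaping (empirical unfiltered rs-fMRI shows n near 0.9),
and a quasiperiodically recurring traveling motif about 20 s long in
which ROI activations peak at staggered times. It is a statistical
stand-in, not a biophysical model: it has no hemodynamic nonlinearity,
no head motion, and no physiological noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bold import BoldTimeSeries
from .errors import InvalidArgumentError

__all__ = ["SurrogateRestConfig", "generate_surrogate_rest"]


@dataclass
class SurrogateRestConfig:
    """Defaults mirror one ~15 min scan at TR 0.72 s with 3 network
    states dwelling ~45 s and a 20 s (28-TR) motif."""

    n_rois: int = 66
    n_trs: int = 1250
    tr: float = 0.72
    n_states: int = 3
    state_dwell_mean: float = 60.0     # TRs
    motif_length: int = 28             # TRs
    motif_amplitude: float = 1.0       # in noise-SD units
    spectral_exponent: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if self.n_states < 1:
            raise InvalidArgumentError("n_states must be >= 1")
        if self.motif_length >= self.n_trs:
            raise InvalidArgumentError("motif_length must be shorter than the scan")
        if self.spectral_exponent < 0:
            raise InvalidArgumentError("spectral_exponent must be >= 0")


#: motif recurrence period, in units of motif_length; 1.5 puts a 20 s
#: motif at two occurrences per minute, the rate reported for real scans
MOTIF_PERIOD_FACTOR = 1.5


def _state_covariances(n_rois: int, n_states: int, rng: np.random.Generator):
    """Random low-rank-plus-diagonal correlation matrices, one per state."""
    covs = []
    rank = max(2, n_rois // 12)
    for _ in range(n_states):
        B = rng.normal(size=(n_rois, rank))
        S = B @ B.T + 0.8 * np.eye(n_rois)
        d = np.sqrt(np.diag(S))
        covs.append(S / np.outer(d, d))
    return covs


def _markov_states(n_trs: int, n_states: int, dwell_mean: float,
                   rng: np.random.Generator) -> np.ndarray:
    """State index per TR; dwell times geometric with the given mean."""
    switch_p = 1.0 / dwell_mean
    states = np.empty(n_trs, dtype=int)
    s = int(rng.integers(n_states))
    for t in range(n_trs):
        states[t] = s
        if n_states > 1 and rng.random() < switch_p:
            others = [j for j in range(n_states) if j != s]
            s = others[int(rng.integers(len(others)))]
    return states


def _shape_spectrum(x: np.ndarray, exponent: float) -> np.ndarray:
    """Impose a 1/f^exponent amplitude envelope along time."""
    if exponent == 0:
        return x
    T = x.shape[1]
    freqs = np.fft.rfftfreq(T)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2)
    scale[nz] /= scale[nz].mean()  # keep overall power comparable
    X = np.fft.rfft(x, axis=1) * scale
    return np.fft.irfft(X, n=T, axis=1)


def _traveling_motif(n_rois: int, length: int, rng: np.random.Generator) -> np.ndarray:
    """ROI x length template: Gaussian bumps peaking at staggered times,
    with a fixed random sign per ROI (activation vs deactivation).

    The stagger order is a random ROI permutation, so the template has
    negligible temporal autocorrelation at nonzero lags (a monotone
    stagger would give the sliding-correlation trace strong sidelobes).
    """
    t = np.arange(length)
    offsets = length * (0.2 + 0.6 * np.arange(n_rois) / max(1, n_rois - 1))
    centers = rng.permutation(offsets)
    width = length / 8
    bumps = np.exp(-((t[None, :] - centers[:, None]) ** 2) / (2 * width**2))
    signs = np.where(rng.random(n_rois) < 0.5, -1.0, 1.0)
    return signs[:, None] * bumps


def generate_surrogate_rest(cfg: SurrogateRestConfig) -> BoldTimeSeries:
    """Generate one surrogate scan; deterministic per ``cfg.seed``.

    The returned series carries two introspection attributes used by
    validation code: ``state_sequence`` (hidden state per TR) and
    ``motif`` (the planted ROI x motif_length template, or None).
    """
    rng = np.random.default_rng(cfg.seed)
    covs = _state_covariances(cfg.n_rois, cfg.n_states, rng)
    chols = [np.linalg.cholesky(S) for S in covs]
    states = _markov_states(cfg.n_trs, cfg.n_states, cfg.state_dwell_mean, rng)

    innov = rng.standard_normal((cfg.n_rois, cfg.n_trs))
    x = np.empty_like(innov)
    for s in range(cfg.n_states):
        idx = states == s
        x[:, idx] = chols[s] @ innov[:, idx]

    x = _shape_spectrum(x, cfg.spectral_exponent)
    x /= x.std(axis=1, keepdims=True)

    motif = None
    if cfg.motif_amplitude > 0:
        motif = _traveling_motif(cfg.n_rois, cfg.motif_length, rng)
        period = int(round(MOTIF_PERIOD_FACTOR * cfg.motif_length))
        for start in range(cfg.motif_length, cfg.n_trs - cfg.motif_length, period):
            x[:, start : start + cfg.motif_length] += cfg.motif_amplitude * motif

    out = BoldTimeSeries(values=x, tr=cfg.tr, preprocessing_flags=["surrogate"])
    out.state_sequence = states
    out.motif = motif
    return out
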