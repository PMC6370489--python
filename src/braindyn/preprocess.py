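"""Shared final preprocessing chain for simulated and surrogate BOLD.

The same four steps, in this order, are applied to every dataset being
compared: z-score each ROI, zero-phase band-pass 0.01-0.25 Hz, global
signal regression, final z-score. Z-scoring uses the population (1/N)
standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .bold import BoldTimeSeries
from .errors import DegenerateInputError, InvalidArgumentError

__all__ = [
    "PreprocessConfig",
    "zscore_series",
    "bandpass_filter",
    "global_signal_regression",
    "preprocess_pipeline",
]


@dataclass(frozen=True)
class PreprocessConfig:
    band_lo: float = 0.01
    band_hi: float = 0.25
    filter_order: int = 5
    gsr: bool = True


def zscore_series(x: np.ndarray) -> np.ndarray:
    """Z-score each row (population SD convention)."""
    x = np.asarray(x, dtype=float)
    sd = x.std(axis=1, ddof=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise DegenerateInputError(f"constant time series at ROI index {bad[0]}")
    return (x - x.mean(axis=1, keepdims=True)) / sd[:, None]


def bandpass_filter(x: np.ndarray, tr: float, cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Zero-phase Butterworth band-pass along time."""
    x = np.asarray(x, dtype=float)
    fs = 1.0 / tr
    if cfg.band_hi >= fs / 2:
        raise InvalidArgumentError(
            f"band_hi {cfg.band_hi} Hz reaches the Nyquist frequency {fs / 2:.3f} Hz"
        )
    if not 0 < cfg.band_lo < cfg.band_hi:
        raise InvalidArgumentError("band must satisfy 0 < lo < hi")
    if x.shape[1] <= 6 * cfg.filter_order:
        raise InvalidArgumentError("series too short for the filter order")
    sos = sps.butter(cfg.filter_order, [cfg.band_lo, cfg.band_hi],
                     btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=1)


def global_signal_regression(x: np.ndarray) -> np.ndarray:
    """Regress the across-ROI mean time course out of each ROI.

    Each row is replaced by its residual from an ordinary least-squares
    fit on [1, global_mean]; residuals are uncorrelated with the global
    mean by construction.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 2:
        raise InvalidArgumentError("global signal regression needs at least 2 ROIs")
    g = x.mean(axis=0)
    design = np.column_stack([np.ones_like(g), g])
    beta, *_ = np.linalg.lstsq(design, x.T, rcond=None)
    return x - (design @ beta).T


def preprocess_pipeline(
    x: np.ndarray | BoldTimeSeries,
    tr: float | None = None,
    cfg: PreprocessConfig = PreprocessConfig(),
) -> BoldTimeSeries:
    """Apply z-score, band-pass, (optional) GSR, final z-score, in order."""
    if isinstance(x, BoldTimeSeries):
        prior_flags = list(x.preprocessing_flags)
        x, tr = x.values, x.tr
    else:
        prior_flags = []
        if tr is None:
            raise InvalidArgumentError("tr is required for raw-array input")
    flags = prior_flags + ["zscore", "bandpass"]
    out = bandpass_filter(zscore_series(x), tr, cfg)
    if cfg.gsr:
        out = global_signal_regression(out)
        flags.append("gsr")
    out = zscore_series(out)
    flags.append("zscore")
    return BoldTimeSeries(values=out, tr=tr, preprocessing_flags=flags)
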