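"""Average FC, FC similarity, spectral slope, and point-process coactivation.

The coactivation (point-process) matrix counts, for each ROI pair, how
often the two cross an activation threshold together: a crossing at ROI
i, time t, is an upward threshold crossing (x >= theta after x < theta),
and entry (i, j) is the fraction of i's crossings for which j also
crosses within +-max_lag TRs. On resting-state-like signals this matrix
tracks average FC closely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps, stats

from .bold import BoldTimeSeries
from .errors import DegenerateInputError, InvalidArgumentError

__all__ = [
    "FCMatrix",
    "CoactivationMatrix",
    "average_fc",
    "fc_similarity",
    "spectral_slope",
    "coactivation_matrix",
]


@dataclass
class FCMatrix:
    """Pairwise Pearson correlation over the full scan."""

    values: np.ndarray

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n_rois, k=1)
        return self.values[iu]


@dataclass
class CoactivationMatrix:
    """Fraction of shared threshold crossings per directed ROI pair.

    ``values`` is the raw (asymmetric) matrix; rows of ROIs with zero
    crossings are NaN (undefined, not zero). ``symmetric`` averages the
    matrix with its transpose for comparison against FC.
    """

    values: np.ndarray
    threshold: float
    max_lag: int
    crossings_per_roi: np.ndarray

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    @property
    def symmetric(self) -> np.ndarray:
        return (self.values + self.values.T) / 2

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n_rois, k=1)
        return self.symmetric[iu]


def _as_array(bold) -> np.ndarray:
    return bold.values if isinstance(bold, BoldTimeSeries) else np.asarray(bold, dtype=float)


def average_fc(bold) -> FCMatrix:
    """Full-scan pairwise Pearson correlation matrix."""
    x = _as_array(bold)
    if x.shape[1] < 3:
        raise InvalidArgumentError("need at least 3 time points for correlation")
    sd = x.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise DegenerateInputError(f"constant time series at ROI index {bad[0]}")
    return FCMatrix(values=np.corrcoef(x))


def fc_similarity(a, b) -> float:
    """Pearson correlation of the strictly-upper-triangle entries."""
    va = a.values if isinstance(a, FCMatrix) else np.asarray(a, dtype=float)
    vb = b.values if isinstance(b, FCMatrix) else np.asarray(b, dtype=float)
    if va.shape != vb.shape:
        raise InvalidArgumentError(f"shape mismatch: {va.shape} vs {vb.shape}")
    iu = np.triu_indices(va.shape[0], k=1)
    return float(stats.pearsonr(va[iu], vb[iu])[0])


def spectral_slope(
    bold,
    tr: float | None = None,
    band: tuple[float, float] = (0.01, 0.25),
    nperseg: int = 256,
) -> float:
    """Exponent n of the (1/f)^n trend in the ROI-averaged power spectrum.

    Welch periodograms are computed per ROI, averaged across ROIs, and a
    least-squares line is fitted to log power vs log frequency inside
    ``band``; the returned value is the negated slope, so a 1/f signal
    gives +1.
    """
    x = _as_array(bold)
    if tr is None:
        if not isinstance(bold, BoldTimeSeries):
            raise InvalidArgumentError("tr is required for raw-array input")
        tr = bold.tr
    if x.shape[1] < 128:
        raise InvalidArgumentError("need at least 128 TRs for a stable spectrum")
    fs = 1.0 / tr
    freqs, psd = sps.welch(x, fs=fs, nperseg=min(nperseg, x.shape[1]), axis=1)
    mean_psd = psd.mean(axis=0)
    sel = (freqs >= band[0]) & (freqs <= band[1]) & (mean_psd > 0)
    if sel.sum() < 4:
        raise InvalidArgumentError(f"band {band} not resolvable at fs={fs:.3f} Hz")
    slope, _ = np.polyfit(np.log(freqs[sel]), np.log(mean_psd[sel]), 1)
    return float(-slope)


def _upward_crossings(row: np.ndarray, threshold: float) -> np.ndarray:
    """Times t with row[t] >= threshold and row[t-1] < threshold.

    The sample before the scan is treated as below threshold, so a
    series that starts above threshold crosses at t = 0.
    """
    above = np.concatenate([[False], row >= threshold])
    return np.flatnonzero(above[1:] & ~above[:-1])


def coactivation_matrix(
    bold,
    threshold: float = 1.0,
    max_lag_trs: int = 3,
) -> CoactivationMatrix:
    """Point-process coactivation fractions on a z-scored signal."""
    x = _as_array(bold)
    n = x.shape[0]
    crossings = [_upward_crossings(x[i], threshold) for i in range(n)]
    counts = np.array([len(c) for c in crossings])
    M = np.full((n, n), np.nan)
    for i in range(n):
        ci = crossings[i]
        if ci.size == 0:
            continue  # undefined row, stays NaN
        for j in range(n):
            cj = crossings[j]
            if cj.size == 0:
                M[i, j] = 0.0
                continue
            # for each crossing of i, is there a j crossing within the lag window
            pos = np.searchsorted(cj, ci)
            left = np.abs(cj[np.clip(pos - 1, 0, cj.size - 1)] - ci)
            right = np.abs(cj[np.clip(pos, 0, cj.size - 1)] - ci)
            hit = np.minimum(left, right) <= max_lag_trs
            M[i, j] = hit.mean()
    return CoactivationMatrix(
        values=M, threshold=threshold, max_lag=max_lag_trs, crossings_per_roi=counts
    )
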