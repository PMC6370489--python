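"""Quasiperiodic-pattern discovery by iterative template refinement.

The algorithm seeds a spatiotemporal template with a randomly chosen
chunk of the scan (about 20 s), slides it across the whole scan
computing the Pearson correlation of the flattened template with every
window, averages the windows at supra-threshold correlation peaks into a
new template, and iterates until the template stops changing. Several
random starts are run and the template with the strongest set of peaks
is kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps, stats

from .bold import BoldTimeSeries
from .errors import DegenerateInputError, InvalidArgumentError

__all__ = ["QPPResult", "find_qpp", "align_templates", "template_occurrence_stats"]


@dataclass
class QPPResult:
    """Recovered template with its sliding-correlation trace."""

    template: np.ndarray          # n_rois x window
    corr_vector: np.ndarray       # length T - window + 1
    peaks: np.ndarray             # TR indices of occurrences
    n_iterations: int
    seed_start: int               # TR index of the winning starting chunk
    converged: bool

    @property
    def window(self) -> int:
        return self.template.shape[1]

    def peak_score(self) -> float:
        """Mean supra-threshold peak correlation (0 without peaks).

        Candidates with fewer than 3 occurrences are heavily penalized
        so a single lucky window cannot win the multi-start selection.
        Selecting by the mean rather than the summed peak correlation
        keeps phase-rolled templates - which split every occurrence into
        two weaker peaks and would win any sum-based score - from being
        preferred over the properly phased template.
        """
        if self.peaks.size == 0:
            return 0.0
        mean = float(self.corr_vector[self.peaks].mean())
        return mean if self.peaks.size >= 3 else mean / 100.0


def _window_matrix(x: np.ndarray, window: int) -> np.ndarray:
    """Row-normalized matrix of all flattened sliding windows.

    Row t is window x[:, t:t+window] flattened, centered and scaled to
    unit norm, so template correlations reduce to a matrix-vector dot.
    """
    n, T = x.shape
    n_win = T - window + 1
    sw = np.lib.stride_tricks.sliding_window_view(x, window, axis=1)  # n x n_win x w
    flat = sw.transpose(1, 0, 2).reshape(n_win, n * window).astype(float)
    flat = flat - flat.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(flat, axis=1)
    if np.any(norms == 0):
        raise DegenerateInputError(
            f"zero-variance window at TR {int(np.flatnonzero(norms == 0)[0])}"
        )
    return flat / norms[:, None]


def _normalize(v: np.ndarray) -> np.ndarray:
    v = v - v.mean()
    nrm = np.linalg.norm(v)
    if nrm == 0:
        raise DegenerateInputError("zero-variance template")
    return v / nrm


def find_qpp(
    bold,
    tr: float | None = None,
    window_s: float = 20.0,
    seed: int = 0,
    peak_thresh_initial: float = 0.1,
    peak_thresh_final: float = 0.2,
    max_iter: int = 20,
    n_starts: int = 10,
) -> QPPResult:
    """Find the most prominent repeating spatiotemporal pattern.

    ``window_s`` is converted to TRs (28 at TR = 0.72 s). The looser
    threshold applies in the first two iterations, the stricter one
    after; peaks must be separated by at least half a window. The best
    of ``n_starts`` random starting chunks (by summed peak correlation)
    is returned. A start whose iteration finds no peaks yields a
    degenerate unconverged candidate rather than an error.
    """
    if isinstance(bold, BoldTimeSeries):
        x, tr = bold.values, bold.tr
    else:
        x = np.asarray(bold, dtype=float)
        if tr is None:
            raise InvalidArgumentError("tr is required for raw-array input")
    n, T = x.shape
    window = int(round(window_s / tr))
    if T < 4 * window:
        raise InvalidArgumentError(f"scan too short: {T} TRs < 4 x window ({window})")

    W = _window_matrix(x, window)  # precomputed normalized windows
    n_win = W.shape[0]
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, n_win, size=n_starts)
    min_sep = max(1, window // 2)

    best: QPPResult | None = None
    for start in starts:
        template = x[:, start : start + window].astype(float)
        tvec = _normalize(template.ravel())
        corr = W @ tvec
        n_it = 0
        converged = False
        peaks = np.array([], dtype=int)
        for n_it in range(1, max_iter + 1):
            thresh = peak_thresh_initial if n_it <= 2 else peak_thresh_final
            peaks, _ = sps.find_peaks(corr, height=thresh, distance=min_sep)
            if peaks.size == 0:
                break
            new_template = np.mean(
                [x[:, p : p + window] for p in peaks], axis=0
            )
            new_tvec = _normalize(new_template.ravel())
            drift = float(new_tvec @ tvec)
            template, tvec = new_template, new_tvec
            corr = W @ tvec
            if drift > 0.9999:
                converged = True
                break
        cand = QPPResult(
            template=template,
            corr_vector=corr,
            peaks=peaks,
            n_iterations=n_it,
            seed_start=int(start),
            converged=converged,
        )
        if best is None or cand.peak_score() > best.peak_score():
            best = cand
    return best


def align_templates(a: np.ndarray, b: np.ndarray) -> tuple[int, float]:
    """Best circular time-shift of ``b`` against ``a``.

    Returns (shift, correlation) maximizing the Pearson correlation of
    the flattened templates over all circular shifts of b along time;
    ties go to the smallest non-negative shift.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise InvalidArgumentError(f"template shapes differ: {a.shape} vs {b.shape}")
    window = a.shape[1]
    av = _normalize(a.ravel())
    best_shift, best_corr = 0, -np.inf
    for shift in range(window):
        shifted = np.roll(b, shift, axis=1)
        c = float(av @ _normalize(shifted.ravel()))
        if c > best_corr + 1e-15:
            best_shift, best_corr = shift, c
    return best_shift, best_corr


def template_occurrence_stats(results: list[QPPResult], bins: int = 50) -> dict:
    """Pooled correlation-trace histograms and pairwise KS comparisons."""
    if len(results) < 2:
        raise InvalidArgumentError("need at least 2 datasets to compare")
    vectors = []
    for r in results:
        v = np.asarray(r.corr_vector if isinstance(r, QPPResult) else r, dtype=float)
        if v.size == 0:
            raise InvalidArgumentError("empty correlation vector")
        vectors.append(v)
    edges = np.linspace(-1, 1, bins + 1)
    hists = [np.histogram(v, bins=edges)[0] for v in vectors]
    ks = {}
    for i in range(len(vectors)):
        for j in range(i + 1, len(vectors)):
            stat, p = stats.ks_2samp(vectors[i], vectors[j])
            ks[(i, j)] = {"statistic": float(stat), "pvalue": float(p)}
    return {"bin_edges": edges, "histograms": hists, "ks": ks}
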