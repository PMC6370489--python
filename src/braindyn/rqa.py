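"""Recurrence plots and recurrence quantification analysis.

The recurrence plot marks pairs of time points whose spatial activity
patterns (the ROI vector at each TR) correlate at or above a threshold
(0.3 by default). Three statistics summarize it: the recurrence rate
RR (fraction of recurrent cells over all N^2, main diagonal included),
the mean diagonal line length L, and the Shannon entropy (nats) of the
normalized diagonal-length distribution. Diagonal lines are maximal
runs of recurrent cells parallel to — and excluding — the line of
identity, counted once per symmetric pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bold import BoldTimeSeries
from .errors import DegenerateInputError, InvalidArgumentError

__all__ = [
    "RecurrencePlot",
    "RQAMetrics",
    "recurrence_plot",
    "diagonal_length_distribution",
    "rqa_metrics",
]


@dataclass
class RecurrencePlot:
    R: np.ndarray          # N x N binary
    threshold: float

    @property
    def n(self) -> int:
        return self.R.shape[0]


@dataclass
class RQAMetrics:
    rr: float
    avg_diag_len: float
    entropy: float
    l_min: int
    p_l: dict              # diagonal length -> frequency
    has_lines: bool


def recurrence_plot(bold, threshold: float = 0.3) -> RecurrencePlot:
    """Binary time-by-time recurrence matrix from spatial correlations."""
    x = bold.values if isinstance(bold, BoldTimeSeries) else np.asarray(bold, dtype=float)
    if x.shape[0] < 3:
        raise InvalidArgumentError("need at least 3 ROIs for spatial correlation")
    sd = x.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise DegenerateInputError(f"constant spatial pattern at TR {bad[0]}")
    C = np.corrcoef(x, rowvar=False)
    return RecurrencePlot(R=(C >= threshold).astype(np.uint8), threshold=threshold)


def diagonal_length_distribution(rp: RecurrencePlot, l_min: int = 2) -> dict:
    """Frequencies of maximal diagonal run lengths >= l_min.

    Scans the diagonals of the upper triangle only (the plot is
    symmetric, so each line is counted once) and excludes the line of
    identity.
    """
    R = rp.R
    N = R.shape[0]
    table: dict[int, int] = {}
    for offset in range(1, N):
        diag = np.diagonal(R, offset=offset)
        # run lengths of consecutive ones
        padded = np.concatenate([[0], diag, [0]])
        changes = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(changes == 1)
        ends = np.flatnonzero(changes == -1)
        for length in ends - starts:
            if length >= l_min:
                table[int(length)] = table.get(int(length), 0) + 1
    return table


def rqa_metrics(rp: RecurrencePlot, l_min: int = 2) -> RQAMetrics:
    """RR, mean diagonal length L, and diagonal-length entropy.

    RR sums every cell of R including the main diagonal. L and the
    entropy use the normalized length distribution p(l) = P(l)/sum P(l);
    when no diagonal line reaches l_min both are reported as 0 and
    flagged via ``has_lines``.
    """
    R = rp.R
    N = R.shape[0]
    rr = float(R.sum() / N**2)
    p_l = diagonal_length_distribution(rp, l_min=l_min)
    if not p_l:
        return RQAMetrics(rr=rr, avg_diag_len=0.0, entropy=0.0, l_min=l_min,
                          p_l={}, has_lines=False)
    lengths = np.array(sorted(p_l))
    freqs = np.array([p_l[int(l)] for l in lengths], dtype=float)
    total = freqs.sum()
    avg_len = float((lengths * freqs).sum() / total)
    p = freqs / total
    entropy = float(-(p * np.log(p)).sum())
    return RQAMetrics(rr=rr, avg_diag_len=avg_len, entropy=entropy, l_min=l_min,
                      p_l=p_l, has_lines=True)
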