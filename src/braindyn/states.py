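"""Sliding-window FC, L1 k-means state clustering, and transition statistics.

Windows of 60 TRs (stepped by one TR) give pairwise Pearson matrices,
Fisher-z transformed and vectorized; windows pooled across all runs
being compared are clustered with k = 7 under Manhattan distance
(median centroid updates, best of 30 seeded restarts by total
within-cluster distance), and per-run summaries (states visited, dwell
time, centroid spread) plus the pooled transition matrix are derived
from the label sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .bold import BoldTimeSeries
from .errors import DegenerateInputError, InvalidArgumentError

__all__ = [
    "WindowedFCStack",
    "StateModel",
    "StateStats",
    "sliding_window_fc",
    "stack_runs",
    "cluster_states",
    "per_run_state_stats",
    "transition_analysis",
]

_CLIP = 1 - 1e-6  # correlation clip before atanh


@dataclass
class WindowedFCStack:
    """Fisher-z upper-triangle FC vectors, one row per window."""

    windows: np.ndarray          # n_windows x d, d = n(n-1)/2
    window_trs: int
    run_ids: np.ndarray          # run index per row
    n_rois: int
    tr: float = 0.72


@dataclass
class StateModel:
    centroids: np.ndarray        # k x d
    labels: np.ndarray           # state index in [0, k)
    k: int
    inertia: float               # summed L1 distance to assigned centroids
    distance: str = "manhattan"


@dataclass
class StateStats:
    states_per_run: np.ndarray
    mean_dwell_s: np.ndarray
    centroid_distances: np.ndarray   # mean pairwise L2 among visited centroids, NaN if 1 state
    transition_matrix: np.ndarray
    sparsity_fraction: float


def sliding_window_fc(
    bold,
    tr: float | None = None,
    window_trs: int = 60,
    step: int = 1,
    run_id: int = 0,
) -> WindowedFCStack:
    """Windowed FC vectors for one run."""
    if isinstance(bold, BoldTimeSeries):
        x, tr = bold.values, bold.tr
    else:
        x = np.asarray(bold, dtype=float)
        tr = 0.72 if tr is None else tr
    n, T = x.shape
    if T <= window_trs:
        raise InvalidArgumentError(f"scan length {T} must exceed the window {window_trs}")
    iu = np.triu_indices(n, k=1)
    rows = []
    for start in range(0, T - window_trs + 1, step):
        seg = x[:, start : start + window_trs]
        if np.any(seg.std(axis=1) == 0):
            raise DegenerateInputError(f"constant ROI inside window starting at TR {start}")
        r = np.corrcoef(seg)[iu]
        rows.append(np.arctanh(np.clip(r, -_CLIP, _CLIP)))
    windows = np.asarray(rows)
    return WindowedFCStack(
        windows=windows,
        window_trs=window_trs,
        run_ids=np.full(len(rows), run_id),
        n_rois=n,
        tr=tr,
    )


def stack_runs(stacks: list[WindowedFCStack]) -> WindowedFCStack:
    """Pool windows from several runs, renumbering run ids."""
    if not stacks:
        raise InvalidArgumentError("no stacks to pool")
    windows = np.vstack([s.windows for s in stacks])
    run_ids = np.concatenate(
        [np.full(len(s.windows), i) for i, s in enumerate(stacks)]
    )
    return WindowedFCStack(
        windows=windows,
        window_trs=stacks[0].window_trs,
        run_ids=run_ids,
        n_rois=stacks[0].n_rois,
        tr=stacks[0].tr,
    )


def _kmeans_l1_once(X: np.ndarray, k: int, rng: np.random.Generator,
                    max_iter: int = 100):
    n = X.shape[0]
    centroids = X[rng.choice(n, size=k, replace=False)].copy()
    labels = np.full(n, -1)
    for _ in range(max_iter):
        D = cdist(X, centroids, metric="cityblock")
        new_labels = D.argmin(axis=1)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            members = X[labels == j]
            if len(members):
                centroids[j] = np.median(members, axis=0)
            else:  # re-seed an empty cluster at the worst-fit point
                centroids[j] = X[D.min(axis=1).argmax()]
    D = cdist(X, centroids, metric="cityblock")
    labels = D.argmin(axis=1)
    inertia = float(D[np.arange(n), labels].sum())
    return centroids, labels, inertia


def cluster_states(
    stack: WindowedFCStack,
    k: int = 7,
    replicates: int = 30,
    seed: int = 0,
) -> StateModel:
    """L1 k-means over pooled windows; best of ``replicates`` restarts."""
    X = stack.windows
    if k > X.shape[0]:
        raise InvalidArgumentError(f"k={k} exceeds the {X.shape[0]} available windows")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(replicates):
        centroids, labels, inertia = _kmeans_l1_once(X, k, rng)
        if best is None or inertia < best[2]:
            best = (centroids, labels, inertia)
    centroids, labels, inertia = best
    return StateModel(centroids=centroids, labels=labels, k=k, inertia=inertia)


def _segments(labels: np.ndarray) -> list[tuple[int, int]]:
    """(label, run length) for consecutive same-label segments."""
    segs = []
    start = 0
    for t in range(1, len(labels) + 1):
        if t == len(labels) or labels[t] != labels[start]:
            segs.append((int(labels[start]), t - start))
            start = t
    return segs


def per_run_state_stats(model: StateModel, stack: WindowedFCStack,
                        tr: float | None = None) -> StateStats:
    """Per-run state counts, dwell times and centroid spread, plus the
    pooled transition matrix."""
    tr = stack.tr if tr is None else tr
    runs = np.unique(stack.run_ids)
    n_states, dwell, dist = [], [], []
    for run in runs:
        lab = model.labels[stack.run_ids == run]
        segs = _segments(lab)
        visited = np.unique(lab)
        n_states.append(len(visited))
        dwell.append(float(np.mean([length for _, length in segs]) * tr))
        if len(visited) >= 2:
            C = model.centroids[visited]
            pd = cdist(C, C, metric="euclidean")
            iu = np.triu_indices(len(visited), k=1)
            dist.append(float(pd[iu].mean()))
        else:
            dist.append(np.nan)  # undefined with a single state
    trans, sparsity = transition_analysis(model, stack)
    return StateStats(
        states_per_run=np.asarray(n_states),
        mean_dwell_s=np.asarray(dwell),
        centroid_distances=np.asarray(dist),
        transition_matrix=trans,
        sparsity_fraction=sparsity,
    )


def transition_analysis(model: StateModel, stack: WindowedFCStack):
    """Pooled between-state transition probabilities (self-transitions 0).

    Counts label changes i -> j (i != j) over consecutive windows within
    each run, divides by the total number of changes, and reports the
    occupied fraction of the k(k-1) possible off-diagonal cells.
    """
    k = model.k
    counts = np.zeros((k, k))
    for run in np.unique(stack.run_ids):
        lab = model.labels[stack.run_ids == run]
        for a, b in zip(lab[:-1], lab[1:]):
            if a != b:
                counts[a, b] += 1
    total = counts.sum()
    if total == 0:
        return np.zeros((k, k)), 0.0
    probs = counts / total
    sparsity = float((counts > 0).sum() / (k * (k - 1)))
    return probs, sparsity
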