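"""Quality and optimality metrics for sets of trade-off designs.

A *front* is a 2-D array of objective vectors (rows; all objectives
minimized). The hypervolume of a front within the ideal–nadir box is the
Lebesgue measure of the region of the box weakly dominated by at least one
front member — the volume between the front and the nadir — so a front
sitting at the ideal point scores the full box and the normalized
hypervolume (hypervolume divided by the box volume) approaches 1 for
near-optimal fronts.

The hypervolume is computed exactly: a sweep for two objectives, and
recursive slicing along the last objective for three or more (the slab
between consecutive coordinate levels is the 2-D/(k-1)-D hypervolume of the
points below the slab, times the slab height).

:func:`global_pareto_union` pools fronts from independent runs into an
approximate globally optimal set, and :func:`r_theta` measures the share
of that set recovered by one parameter setting, normalized by the pool
size.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "non_dominated_filter",
    "hypervolume",
    "normalized_hypervolume",
    "global_pareto_union",
    "r_theta",
]


def _as_front(vectors) -> np.ndarray:
    F = np.atleast_2d(np.asarray(vectors, dtype=float))
    if F.size == 0:
        raise ValueError("empty vector set")
    return F


def non_dominated_filter(vectors) -> np.ndarray:
    """Maximal mutually non-dominated subset (duplicates collapse to one).

    Input order of the surviving rows is preserved.
    """
    F = _as_front(vectors)
    _, first = np.unique(F, axis=0, return_index=True)
    F = F[np.sort(first)]
    le = np.all(F[:, None, :] <= F[None, :, :], axis=-1)
    lt = np.any(F[:, None, :] < F[None, :, :], axis=-1)
    dominated = (le & lt).any(axis=0)
    return F[~dominated]


def _hv(F: np.ndarray, nadir: np.ndarray) -> float:
    """Exact hypervolume of non-dominated minimization points w.r.t. nadir."""
    k = F.shape[1]
    if k == 1:
        return float(nadir[0] - F[:, 0].min())
    if k == 2:
        order = np.lexsort((F[:, 1], F[:, 0]))
        pts = F[order]
        vol = 0.0
        y_prev = nadir[1]
        for x, y in pts:
            if y < y_prev:
                vol += (nadir[0] - x) * (y_prev - y)
                y_prev = y
        return float(vol)
    # slice along the last objective
    levels = np.unique(F[:, -1])
    vol = 0.0
    uppers = np.append(levels[1:], nadir[-1])
    for z, z_next in zip(levels, uppers):
        if z_next <= z:
            continue
        slab = F[F[:, -1] <= z, :-1]
        slab = non_dominated_filter(slab)
        vol += _hv(slab, nadir[:-1]) * (z_next - z)
    return float(vol)


def hypervolume(front, ideal, nadir) -> float:
    """Hypervolume of ``front`` within the box [ideal, nadir].

    Front points are clipped into the box; the result is the measure of
    the box region weakly dominated by at least one point.
    """
    F = _as_front(front)
    ideal = np.asarray(ideal, dtype=float)
    nadir = np.asarray(nadir, dtype=float)
    if ideal.shape != (F.shape[1],) or nadir.shape != (F.shape[1],):
        raise ValueError("ideal/nadir dimension does not match the front")
    if np.any(ideal > nadir):
        raise ValueError("ideal must be <= nadir in every coordinate")
    F = np.clip(F, ideal, nadir)
    F = non_dominated_filter(F)
    return _hv(F, nadir)


def normalized_hypervolume(front, ideal, nadir) -> float:
    """Hypervolume divided by the ideal–nadir box volume; in [0, 1]."""
    ideal = np.asarray(ideal, dtype=float)
    nadir = np.asarray(nadir, dtype=float)
    box = np.prod(nadir - ideal)
    if box <= 0:
        raise ValueError(
            "degenerate normalization box: some objective has ideal == nadir"
        )
    return hypervolume(front, ideal, nadir) / float(box)


def global_pareto_union(run_fronts) -> np.ndarray:
    """Non-dominated union of fronts from independent runs/settings."""
    fronts = [_as_front(f) for f in run_fronts]
    if not fronts:
        raise ValueError("no fronts given")
    dims = {f.shape[1] for f in fronts}
    if len(dims) != 1:
        raise ValueError(f"fronts have mixed dimensions: {sorted(dims)}")
    return non_dominated_filter(np.vstack(fronts))


def r_theta(setting_front, global_front, pool_size: int) -> float:
    """Share of the global Pareto set recovered by one parameter setting.

    Membership is exact objective-vector equality; the count is divided by
    ``min(|global|, pool_size)`` so a setting whose pool cannot hold the
    whole global set can still score 1.
    """
    S = {tuple(row) for row in _as_front(setting_front)}
    G = {tuple(row) for row in _as_front(global_front)}
    if not G:
        raise ValueError("global Pareto set is empty")
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    return len(S & G) / min(len(G), pool_size)
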