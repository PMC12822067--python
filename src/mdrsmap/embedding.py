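"""Multiview state-space reconstruction: views, simplex ranking, distances.

A *view* is a small delay-coordinate embedding — an ordered set of
(variable, lag) pairs — much smaller than the community size.  Candidate
views are sampled at random (always containing the target at lag 0), ranked
by leave-one-out simplex-projection forecast skill for the target, and the
top-ranked views' pairwise Euclidean distance matrices are averaged into a
single *multiview distance* used to weight the local regressions.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["SSRView", "propose_views", "simplex_skill", "rank_views", "multiview_distance"]


@dataclass(frozen=True)
class SSRView:
    """One delay-coordinate embedding: (variable index, lag) pairs + skill."""

    coords: tuple  # tuple of (var, lag)
    skill: float = field(default=np.nan, compare=False)

    @property
    def dimension(self) -> int:
        return len(self.coords)

    @property
    def max_lag(self) -> int:
        return max(lag for _, lag in self.coords)


def make_view_matrix(data: np.ndarray, coords) -> np.ndarray:
    """Delay-coordinate matrix (T x E); rows with undefined lags are NaN."""
    T = data.shape[0]
    out = np.full((T, len(coords)), np.nan)
    for k, (var, lag) in enumerate(coords):
        if lag == 0:
            out[:, k] = data[:, var]
        else:
            out[lag:, k] = data[:-lag, var]
    return out


def propose_views(
    n_vars: int,
    target: int,
    e_cap: int,
    tau: int,
    n_candidate_views: int,
    rng: np.random.Generator,
) -> list[SSRView]:
    """Sample distinct candidate views of fixed dimension ``e_cap``.

    Every view contains the target's lag-0 coordinate; the remaining
    ``e_cap - 1`` coordinates are drawn without replacement from all
    (variable, lag) pairs with lag in {0, tau, ..., (e_cap-1)*tau}.  When the
    number of distinct views does not exceed ``n_candidate_views``, all of
    them are enumerated instead.
    """
    lags = [k * tau for k in range(e_cap)]
    pool = [(v, l) for v in range(n_vars) for l in lags if (v, l) != (target, 0)]
    n_extra = e_cap - 1
    total = comb(len(pool), n_extra)
    mandatory = (target, 0)
    if total <= n_candidate_views:
        return [
            SSRView(coords=tuple(sorted(((mandatory,) + c))))
            for c in itertools.combinations(pool, n_extra)
        ]
    seen: set = set()
    views: list[SSRView] = []
    while len(views) < n_candidate_views:
        pick = rng.choice(len(pool), size=n_extra, replace=False)
        coords = tuple(sorted([mandatory] + [pool[i] for i in pick]))
        if coords not in seen:
            seen.add(coords)
            views.append(SSRView(coords=coords))
    return views


def simplex_skill(view_matrix: np.ndarray, y: np.ndarray) -> float:
    """Leave-one-out simplex-projection forecast skill (Pearson rho).

    One-step-ahead forecasts of ``y`` are built from the E+1 nearest
    neighbours of each embedded point (self excluded), weighted by
    exp(-d/d_min).  Returns -inf when the correlation is undefined.
    """
    T, E = view_matrix.shape
    valid = np.where(np.all(np.isfinite(view_matrix), axis=1))[0]
    valid = valid[valid + 1 < T]
    if len(valid) < E + 3:
        return -np.inf
    lib = view_matrix[valid]
    obs = y[valid + 1]
    D = cdist(lib, lib)
    np.fill_diagonal(D, np.inf)
    k = min(E + 1, len(valid) - 1)
    nn = np.argpartition(D, kth=k - 1, axis=1)[:, :k]
    d = np.take_along_axis(D, nn, axis=1)
    order = np.argsort(d, axis=1)
    d = np.take_along_axis(d, order, axis=1)
    nn = np.take_along_axis(nn, order, axis=1)
    d0 = np.maximum(d[:, [0]], 1e-12)
    w = np.exp(-d / d0)
    preds = (w * obs[nn]).sum(axis=1) / w.sum(axis=1)
    if np.std(preds) == 0 or np.std(obs) == 0:
        return -np.inf
    rho = np.corrcoef(preds, obs)[0, 1]
    return float(rho) if np.isfinite(rho) else -np.inf


def rank_views(
    data: np.ndarray,
    target: int,
    e_cap: int,
    tau: int,
    n_candidate_views: int,
    rng: np.random.Generator,
) -> list[SSRView]:
    """Propose candidate views and sort them by forecast skill, descending."""
    cands = propose_views(data.shape[1], target, e_cap, tau, n_candidate_views, rng)
    y = data[:, target]
    scored = [
        SSRView(coords=v.coords, skill=simplex_skill(make_view_matrix(data, v.coords), y))
        for v in cands
    ]
    scored.sort(key=lambda v: -v.skill if np.isfinite(v.skill) else np.inf)
    return scored


def multiview_distance(views, data: np.ndarray, t0: int | None = None):
    """Element-wise mean of per-view Euclidean distance matrices.

    All views are evaluated on the common valid time range ``t0..T-1``
    (``t0`` defaults to the largest lag across the views, so every embedded
    point is fully defined).  Returns ``(D, t0)`` where ``D`` is symmetric
    with a zero diagonal over time points ``t0 .. T-1``.
    """
    views = list(views)
    if not views:
        raise ValueError("need at least one view")
    if t0 is None:
        t0 = max(v.max_lag for v in views)
    T = data.shape[0]
    if T - t0 < 2:
        raise ValueError("not enough valid time points for multiview distances")
    D = np.zeros((T - t0, T - t0))
    for v in views:
        Vm = make_view_matrix(data, v.coords)[t0:]
        D += cdist(Vm, Vm)
    D /= len(views)
    return D, t0
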