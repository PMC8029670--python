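"""Shared independent oracles for the test suite."""

from __future__ import annotations

import itertools
from collections import Counter

import numpy as np


def segmented_grid_oracle(d, y, bounds, step=1e-4):
    """Exhaustive break-point search: min RSS of OLS on {1, d, (d-psi)+}.

    Batched normal equations over a dense psi grid — independent of the
    profile-search fitter's grid/refinement strategy.
    """
    d = np.asarray(d, float)
    y = np.asarray(y, float)
    psis = np.arange(bounds[0], bounds[1] + step / 2, step)
    hinge = np.maximum(d[None, :] - psis[:, None], 0.0)  # (G, n)
    ones = np.ones_like(d)
    X = np.stack(
        [np.broadcast_to(ones, hinge.shape),
         np.broadcast_to(d, hinge.shape), hinge], axis=-1)  # (G, n, 3)
    A = np.einsum("gni,gnj->gij", X, X)
    b = np.einsum("gni,n->gi", X, y)
    coef = np.linalg.solve(A, b[..., None])[..., 0]
    rss = y @ y - np.einsum("gi,gi->g", b, coef)
    i = int(np.argmin(rss))
    return float(psis[i]), float(rss[i])


def ols_normal_equations(d, y):
    """Closed-form simple regression coefficients (textbook formulas)."""
    d = np.asarray(d, float)
    y = np.asarray(y, float)
    beta = ((d - d.mean()) * (y - y.mean())).sum() / ((d - d.mean()) ** 2).sum()
    alpha = y.mean() - beta * d.mean()
    return alpha, beta


def best_balanced_selection_variance(obs):
    """Brute force: min per-distance count variance over all one-dance-per-bee
    subsets (only feasible for a handful of bees)."""
    by_bee = {}
    for o in obs:
        by_bee.setdefault(o.bee_id, []).append(o)
    best = np.inf
    for combo in itertools.product(*by_bee.values()):
        counts = Counter(o.feeder_distance_km for o in combo)
        all_d = {o.feeder_distance_km for o in obs}
        vals = [counts.get(d, 0) for d in all_d]
        best = min(best, float(np.var(vals)))
    return best


def selection_count_variance(selected, all_distances):
    counts = Counter(o.feeder_distance_km for o in selected)
    return float(np.var([counts.get(d, 0) for d in all_distances]))
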