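"""Firefly-algorithm search for the optimal synchronization radius.

The firefly algorithm (FA) is a population metaheuristic: each candidate
radius eps is a firefly whose light intensity is the clustering objective at
that radius.  Dimmer fireflies move toward brighter ones with an
attractiveness that decays with squared distance, plus a uniform random
perturbation scaled by the step size alpha.  Here the search space is the
one-dimensional interval of plausible radii, bounded below by the mean
nearest-neighbor distance of the embedded objects (below which everything
is a singleton) and above by the embedding diameter (above which everything
is one cluster).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.spatial.distance import pdist

from .sync_clustering import Clustering, knn_distances, shc_cluster

logger = logging.getLogger(__name__)

__all__ = [
    "FAParams",
    "FireflySwarm",
    "light_intensity",
    "attractiveness",
    "move_firefly",
    "default_eps_bounds",
    "optimize_epsilon",
]


@dataclass
class FAParams:
    """Firefly-algorithm parameters.

    Defaults are the standard working point for this clustering task:
    6 fireflies for 30 iterations, maximum attractiveness beta0 = 1, light
    absorption gamma = 1 and step size alpha = 0.9.
    """

    n_fireflies: int = 6
    beta0: float = 1.0
    gamma: float = 1.0
    alpha: float = 0.9
    maxiter: int = 30
    eps_min: float | None = None
    eps_max: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fireflies < 1:
            raise ValueError("n_fireflies must be >= 1")
        if self.maxiter < 1:
            raise ValueError("maxiter must be >= 1")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.beta0 <= 0:
            raise ValueError("beta0 must be > 0")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.eps_min is not None and self.eps_max is not None:
            if not 0 < self.eps_min < self.eps_max:
                raise ValueError("need 0 < eps_min < eps_max")


@dataclass
class FireflySwarm:
    """Optimizer state: positions, intensities and the global best."""

    positions: np.ndarray
    intensities: np.ndarray
    best_eps: float
    best_value: float
    best_clustering: Clustering | None = None


def light_intensity(I0: float, gamma: float, r: float) -> float:
    """Perceived intensity at distance r: I0 * exp(-gamma * r)."""
    if r < 0:
        raise ValueError("r must be >= 0")
    return I0 * float(np.exp(-gamma * r))


def attractiveness(beta0: float, gamma: float, r: float) -> float:
    """Attractiveness at distance r: beta0 * exp(-gamma * r^2)."""
    if r < 0:
        raise ValueError("r must be >= 0")
    return beta0 * float(np.exp(-gamma * r * r))


def move_firefly(xi: float, xj: float, beta: float, alpha: float, u: float) -> float:
    """One attraction move of firefly i toward brighter firefly j.

    xi(t+1) = xi + beta * (xj - xi) + alpha * (u - 1/2), with u the caller's
    uniform [0, 1] draw.
    """
    return xi + beta * (xj - xi) + alpha * (u - 0.5)


def default_eps_bounds(X: np.ndarray) -> tuple[float, float]:
    """Search interval: [mean 1-NN distance, max pairwise distance]."""
    X = np.asarray(X, dtype=float)
    lo = float(np.mean(knn_distances(X, 1)))
    hi = float(pdist(X).max())
    if lo <= 0:
        lo = max(hi * 1e-6, 1e-12)
    if hi <= lo:
        hi = lo * 10.0
    return lo, hi


def optimize_epsilon(
    X: np.ndarray,
    params: FAParams,
    objective: Callable[[Clustering], float],
    max_steps: int = 100,
) -> tuple[float, Clustering, list[float]]:
    """Run the firefly search for the radius maximizing the objective.

    Every iteration each firefly's intensity is the objective of the SHC
    clustering at its radius (memoized on the radius).  Fireflies then sweep
    in index order: firefly i moves once toward every j brighter than it at
    the iteration start, with attractiveness beta0*exp(-gamma*r^2) at
    r = |eps_i - eps_j|, and is clipped back into the search interval.  The
    brightest firefly stays put.  Returns the globally best radius, its
    clustering and the per-iteration trace of the best value seen so far.
    """
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(params.seed)
    eps_min, eps_max = params.eps_min, params.eps_max
    if eps_min is None or eps_max is None:
        auto_lo, auto_hi = default_eps_bounds(X)
        eps_min = auto_lo if eps_min is None else eps_min
        eps_max = auto_hi if eps_max is None else eps_max
    if not 0 < eps_min < eps_max:
        raise ValueError(f"invalid search interval [{eps_min}, {eps_max}]")

    cache: dict[float, tuple[float, Clustering]] = {}

    def evaluate(eps: float) -> tuple[float, Clustering]:
        key = round(eps, 12)
        if key not in cache:
            clu = shc_cluster(X, eps, max_steps=max_steps)
            val = objective(clu)
            if not np.isfinite(val):
                logger.warning("objective returned non-finite value at eps=%g", eps)
                val = -np.inf
            cache[key] = (val, clu)
        return cache[key]

    positions = rng.uniform(eps_min, eps_max, size=params.n_fireflies)
    best_eps, best_value, best_clu = np.nan, -np.inf, None
    trace: list[float] = []

    for _ in range(params.maxiter):
        evals = [evaluate(p) for p in positions]
        intensities = np.array([v for v, _ in evals])
        for val, clu, pos in zip(intensities, (c for _, c in evals), positions):
            if val > best_value:
                best_value, best_eps, best_clu = float(val), float(pos), clu
        brightest = int(np.argmax(intensities))
        for i in range(params.n_fireflies):
            if i == brightest:
                continue
            for j in range(params.n_fireflies):
                if intensities[j] > intensities[i]:
                    r = abs(positions[i] - positions[j])
                    beta = attractiveness(params.beta0, params.gamma, r)
                    u = rng.uniform()
                    positions[i] = move_firefly(positions[i], positions[j], beta, params.alpha, u)
                    positions[i] = float(np.clip(positions[i], eps_min, eps_max))
        trace.append(best_value)

    assert best_clu is not None
    return best_eps, best_clu, trace


def write_trace(trace: list[float], path) -> None:
    """Dump the per-iteration best-value trace as TSV."""
    with open(path, "w") as fh:
        fh.write("iteration\tbest_value\n")
        for it, val in enumerate(trace, start=1):
            fh.write(f"{it}\t{val:.17g}\n")
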