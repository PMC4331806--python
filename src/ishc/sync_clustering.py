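"""Synchronization-based hierarchical clustering (SHC).

Each embedded protein is a phase oscillator; objects within Euclidean
distance ``eps`` of one another couple through a Kuramoto-style update.  A
set of objects whose closed eps-neighborhoods all equal the set itself (an
*eps-neighborhood closure*) is guaranteed to synchronize completely, so it
is declared a cluster immediately — no need to iterate the dynamics to
coordinate coincidence.  The clustering loop alternates closure detection
(marking and freezing the members) with one synchronous coupling step for
the remaining objects, until every object is assigned.

``hierarchical_search`` is the baseline radius optimizer: scan eps from the
mean 3-nearest-neighbor distance upward in increments given by the 4-NN/3-NN
gap, and keep the radius with the best objective.  The firefly optimizer in
:mod:`ishc.firefly_optimizer` replaces this scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

__all__ = [
    "Clustering",
    "epsilon_neighborhood",
    "find_closures",
    "sync_step",
    "shc_cluster",
    "hierarchical_search",
]


@dataclass
class Clustering:
    """A partition of object indices 0..n-1 into disjoint clusters.

    ``epsilon`` records the synchronization radius that produced it and
    ``n_sync_steps`` how many coupling iterations were needed.
    """

    clusters: list[set[int]]
    epsilon: float
    n_sync_steps: int = 0

    @property
    def n_objects(self) -> int:
        return sum(len(c) for c in self.clusters)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def labels(self) -> np.ndarray:
        """Cluster id per object index."""
        lab = np.full(self.n_objects, -1, dtype=int)
        for cid, members in enumerate(self.clusters):
            for i in members:
                lab[i] = cid
        return lab

    def as_node_sets(self, nodes: Sequence[str]) -> list[set[str]]:
        return [{nodes[i] for i in c} for c in self.clusters]

    def validate_partition(self, n: int) -> None:
        seen: set[int] = set()
        for c in self.clusters:
            if seen & c:
                raise ValueError("clusters overlap")
            seen |= c
        if seen != set(range(n)):
            raise ValueError("clusters do not cover all objects")


def epsilon_neighborhood(coords: np.ndarray, i: int, eps: float) -> set[int]:
    """Indices of objects within distance ``eps`` of object ``i`` (self excluded).

    The boundary is inclusive: an object at distance exactly ``eps`` belongs
    to the neighborhood.
    """
    if eps <= 0:
        raise ValueError(f"eps must be > 0, got {eps}")
    coords = np.asarray(coords, dtype=float)
    d = np.linalg.norm(coords - coords[i], axis=1)
    members = set(np.flatnonzero(d <= eps).tolist())
    members.discard(i)
    return members


def _neighbor_matrix(coords: np.ndarray, eps: float) -> np.ndarray:
    """Boolean n×n matrix: within-eps and not self."""
    d = squareform(pdist(coords))
    close = d <= eps
    np.fill_diagonal(close, False)
    return close


def find_closures(coords: np.ndarray, eps: float, active: set[int] | Sequence[int] | None = None) -> list[set[int]]:
    """All eps-neighborhood closures among the ``active`` objects.

    A closure is a set S such that for every member x the closed
    eps-neighborhood of x restricted to active objects equals S, i.e. a
    connected component of the eps-graph in which every member already sees
    the whole component.  An object with no active neighbor within eps forms
    a singleton closure.  Components failing the closure test yield nothing.
    """
    if eps <= 0:
        raise ValueError(f"eps must be > 0, got {eps}")
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    act = sorted(range(n)) if active is None else sorted(active)
    if not act:
        return []
    sub = coords[act]
    close = _neighbor_matrix(sub, eps)

    # connected components of the eps-graph on active objects
    m = len(act)
    comp = np.full(m, -1, dtype=int)
    ncomp = 0
    for start in range(m):
        if comp[start] >= 0:
            continue
        stack = [start]
        comp[start] = ncomp
        while stack:
            u = stack.pop()
            for v in np.flatnonzero(close[u]):
                if comp[v] < 0:
                    comp[v] = ncomp
                    stack.append(v)
        ncomp += 1

    closures: list[set[int]] = []
    deg = close.sum(axis=1)
    for c in range(ncomp):
        members = np.flatnonzero(comp == c)
        # every member must be within eps of every other member
        if np.all(deg[members] == len(members) - 1):
            closures.append({act[u] for u in members})
    return closures


def sync_step(coords: np.ndarray, eps: float, active: set[int] | Sequence[int] | None = None) -> np.ndarray:
    """One synchronous Kuramoto-style coupling step.

    Every active object x moves per dimension i by the mean phase attraction
    over its closed eps-neighborhood (x itself counts in the average; its
    own term sin(0) contributes nothing to the sum but does to the divisor):

        x_i(t+1) = x_i(t) + (1/|N_eps(x)|) * sum_{y in N_eps(x)} sin(y_i(t) - x_i(t)).

    An isolated object (closed neighborhood = itself) is therefore an exact
    fixed point.  All updates use the time-t snapshot; inactive (already
    clustered) objects neither move nor attract.
    """
    if eps <= 0:
        raise ValueError(f"eps must be > 0, got {eps}")
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    act = sorted(range(n)) if active is None else sorted(active)
    out = coords.copy()
    if len(act) < 2:
        return out
    sub = coords[act]
    close = _neighbor_matrix(sub, eps)
    counts = close.sum(axis=1) + 1  # closed neighborhood: self included
    # pairwise per-dimension phase differences y - x
    diff = np.sin(sub[None, :, :] - sub[:, None, :])  # diff[x, y, dim]
    coupled = np.einsum("xy,xyd->xd", close.astype(float), diff)
    out[act] = sub + coupled / counts[:, None]
    return out


def shc_cluster(
    X: np.ndarray,
    eps: float,
    max_steps: int = 100,
    merge_tol: float = 1e-9,
) -> Clustering:
    """Cluster embedded objects by alternating closure detection and coupling.

    Repeats: (a) every eps-neighborhood closure among unmarked objects
    becomes a cluster and its members are marked and frozen; (b) if objects
    remain, one synchronous coupling step is applied to them.  If the
    dynamics have not resolved everything after ``max_steps`` coupling steps
    (possible for oscillating configurations), each remaining eps-graph
    connected component becomes a cluster, with a warning.

    Returns a full partition of all objects; singletons are the natural
    outlier behavior (an isolated object never synchronizes with anyone).
    """
    if eps <= 0:
        raise ValueError(f"eps must be > 0, got {eps}")
    if max_steps < 1:
        raise ValueError(f"max_steps must be >= 1, got {max_steps}")
    coords = np.array(X, dtype=float, copy=True)
    n = coords.shape[0]
    unmarked: set[int] = set(range(n))
    clusters: list[set[int]] = []
    steps = 0

    while unmarked:
        for closure in find_closures(coords, eps, unmarked):
            clusters.append(closure)
            unmarked -= closure
        if not unmarked:
            break
        if steps >= max_steps:
            logger.warning(
                "synchronization did not resolve %d objects within %d steps; "
                "falling back to eps-graph components",
                len(unmarked),
                max_steps,
            )
            act = sorted(unmarked)
            close = _neighbor_matrix(coords[act], eps)
            comp_sets = _components(close)
            clusters.extend({act[u] for u in members} for members in comp_sets)
            unmarked.clear()
            break
        coords = sync_step(coords, eps, unmarked)
        steps += 1

    result = Clustering(clusters=clusters, epsilon=float(eps), n_sync_steps=steps)
    result.validate_partition(n)
    return result


def _components(close: np.ndarray) -> list[list[int]]:
    m = close.shape[0]
    comp = np.full(m, -1, dtype=int)
    out: list[list[int]] = []
    for start in range(m):
        if comp[start] >= 0:
            continue
        members = [start]
        comp[start] = len(out)
        stack = [start]
        while stack:
            u = stack.pop()
            for v in np.flatnonzero(close[u]):
                if comp[v] < 0:
                    comp[v] = len(out)
                    members.append(v)
                    stack.append(v)
        out.append(members)
    return out


def knn_distances(X: np.ndarray, k: int) -> np.ndarray:
    """Distance of each object to its k-th nearest other object."""
    X = np.asarray(X, dtype=float)
    d = squareform(pdist(X))
    np.fill_diagonal(d, np.inf)
    d.sort(axis=1)
    return d[:, k - 1]


def hierarchical_search(
    X: np.ndarray,
    objective: Callable[[Clustering], float],
    max_levels: int = 20,
    max_steps: int = 100,
) -> tuple[float, Clustering]:
    """Baseline scan over synchronization radii.

    The initial radius is the mean distance to the 3rd nearest neighbor and
    the increment is the mean 4-NN minus mean 3-NN distance; candidate radii
    eps0, eps0 + d, ... are evaluated until ``max_levels`` is exhausted or a
    single cluster swallows everything.  Returns the radius maximizing the
    objective (ties broken toward the smaller radius) and its clustering.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 5:
        raise ValueError("hierarchical search needs at least 5 objects")
    if max_levels < 1:
        raise ValueError("max_levels must be >= 1")
    eps0 = float(np.mean(knn_distances(X, 3)))
    delta = float(np.mean(knn_distances(X, 4))) - eps0
    if eps0 <= 0:
        eps0 = 1e-12
    if delta <= 0:
        d_max = float(pdist(X).max())
        delta = max((d_max - eps0), 1e-12) / max_levels
        logger.warning("degenerate geometry: falling back to linear increment %.3g", delta)

    best_eps, best_val, best_clu = None, -np.inf, None
    eps = eps0
    for _ in range(max_levels):
        clu = shc_cluster(X, eps, max_steps=max_steps)
        val = objective(clu)
        if val > best_val:
            best_eps, best_val, best_clu = eps, val, clu
        if clu.n_clusters == 1:
            break
        eps += delta
    assert best_clu is not None
    return best_eps, best_clu
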