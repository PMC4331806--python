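"""Spectral preprocessing: edge similarity, degree normalization, 3-D embedding.

The raw interaction graph is turned into an n×3 coordinate matrix in three
steps.  First an edge-similarity matrix ``A`` mixes the aggregation
coefficient of each edge (common-neighbor count relative to the smaller
endpoint degree) with its weighted counterpart, balanced by ``eta``.  Then
``A`` is symmetrically normalized by its row sums, ``L = D^{-1/2} A D^{-1/2}``.
Finally the eigenvectors of the three largest eigenvalues of ``L`` become the
columns of the embedding ``X``, whose rows are normalized to unit length.
These rows are the phase coordinates the synchronization dynamics act on.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.linalg import eigh

from .network_model import PPINetwork

logger = logging.getLogger(__name__)

__all__ = ["edge_similarity", "normalized_matrix", "spectral_embed", "embed_network", "write_embedding"]


def edge_similarity(net: PPINetwork, eta: float = 0.5) -> np.ndarray:
    """Edge-aggregation similarity matrix of the network.

    For each edge (i, j), with N_i the neighbor set of i and I_ij the common
    neighbors,

        A_ij = eta * (|I_ij| + 1) / min(|N_i|, |N_j|)
             + (1 - eta) * [sum_{k in I_ij} w(i,k) * sum_{k in I_ij} w(j,k)]
                         / [sum_{s in N_i} w(i,s) * sum_{t in N_j} w(j,t)]

    Non-edges and the diagonal are zero: both terms describe properties of
    an existing interaction, and similarity between unlinked proteins is
    undefined.

    Parameters
    ----------
    net
        The interaction network (every edge endpoint has degree >= 1).
    eta
        Mixing weight in [0, 1] between the unweighted and weighted
        aggregation coefficients.  Default 0.5 gives them equal influence.
    """
    if not 0.0 <= eta <= 1.0:
        raise ValueError(f"eta must be in [0, 1], got {eta}")
    if net.n_nodes < 2:
        raise ValueError("network must have at least 2 nodes")

    n = net.n_nodes
    adj = net.adjacency_lists()
    nbr_sets = [frozenset(j for j, _ in lst) for lst in adj]
    wdict = [{j: w for j, w in lst} for lst in adj]
    strength = np.array([sum(w for _, w in lst) for lst in adj])

    A = np.zeros((n, n))
    for (a, b), _w in net.weights.items():
        i, j = net.index_of(a), net.index_of(b)
        common = nbr_sets[i] & nbr_sets[j]
        first = eta * (len(common) + 1) / min(len(nbr_sets[i]), len(nbr_sets[j]))
        if common and strength[i] > 0 and strength[j] > 0:
            wi = sum(wdict[i][k] for k in common)
            wj = sum(wdict[j][k] for k in common)
            second = (1.0 - eta) * (wi * wj) / (strength[i] * strength[j])
        else:
            second = 0.0
        A[i, j] = A[j, i] = first + second
    return A


def normalized_matrix(A: np.ndarray) -> np.ndarray:
    """Symmetric degree normalization ``L_ij = A_ij / sqrt(D_ii D_jj)``.

    ``D_ii`` is the i-th row sum of ``A``.  Rows/columns with zero degree
    (isolated nodes) are left entirely zero.
    """
    A = np.asarray(A, dtype=float)
    d = A.sum(axis=1)
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 0.0)
    return A * inv_sqrt[:, None] * inv_sqrt[None, :]


def spectral_embed(L: np.ndarray, k: int = 3) -> np.ndarray:
    """Embed nodes via the eigenvectors of the k largest eigenvalues of L.

    Columns are ordered by decreasing eigenvalue.  Each eigenvector's sign is
    fixed by forcing its first nonzero component positive, then each row of
    the resulting n×k matrix is scaled to unit Euclidean norm (all-zero rows,
    from isolated nodes, stay zero).
    """
    L = np.asarray(L, dtype=float)
    n = L.shape[0]
    if L.shape != (n, n):
        raise ValueError("L must be square")
    if n < k:
        raise ValueError(f"need at least k={k} nodes, got {n}")
    if not np.allclose(L, L.T, atol=1e-10):
        raise ValueError("L must be symmetric")

    # eigh returns ascending eigenvalues; take the top k, reversed.
    vals, vecs = eigh(L, subset_by_index=(n - k, n - 1))
    order = np.argsort(vals)[::-1]
    X = vecs[:, order].copy()

    for c in range(k):
        col = X[:, c]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            X[:, c] = -col

    norms = np.linalg.norm(X, axis=1)
    nonzero = norms > 1e-300
    X[nonzero] /= norms[nonzero, None]
    X[~nonzero] = 0.0
    return X


def embed_network(net: PPINetwork, eta: float = 0.5, k: int = 3) -> np.ndarray:
    """Full preprocessing pipeline: similarity -> normalization -> embedding."""
    if net.n_nodes < k:
        raise ValueError(f"network must have at least {k} nodes to embed in {k} dimensions")
    return spectral_embed(normalized_matrix(edge_similarity(net, eta)), k=k)


def write_embedding(net: PPINetwork, X: np.ndarray, path) -> None:
    """Dump the embedding as TSV: node_id, then one column per coordinate."""
    with open(path, "w") as fh:
        for node, row in zip(net.nodes, X):
            fh.write(node + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")
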