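"""Weighted modularity objective and cluster-vs-complex evaluation metrics.

The objective scores a partition of the interaction network cluster by
cluster, mixing an unweighted and an edge-weighted internal-connectivity
ratio with the exponent ``rho``:

    fval = sum_H  [2 m_H / (2 m_H + n_H)]^rho * [w_in(H) / w_tot(H)]^(1-rho)

where m_H counts internal edges of cluster H, n_H its boundary edges,
w_in(H) twice the summed internal edge weights (each internal edge
contributes to both endpoints' in-degree) and w_tot(H) the summed weighted
degree of H's nodes.  A dense, well-separated cluster contributes close
to 1; a cluster with no incident edges contributes 0.

Evaluation against a reference complex catalogue uses maximum-matching
precision/recall: each predicted cluster is credited with its largest
overlap with any reference complex (and vice versa for recall), and the
f-measure is their harmonic mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network_model import ComplexSet, PPINetwork

__all__ = [
    "EvalReport",
    "modularity_objective",
    "f_measure",
    "precision_recall_f",
    "pearson_r",
]


@dataclass
class EvalReport:
    precision: float = float("nan")
    recall: float = float("nan")
    f_measure: float = float("nan")
    fval: float = float("nan")
    per_cluster: list[float] = field(default_factory=list)


def modularity_objective(
    clusters: list[set[str]] | ComplexSet,
    net: PPINetwork,
    rho: float = 0.8,
) -> float:
    """Weighted modularity of a partition of the network's nodes.

    Parameters
    ----------
    clusters
        Disjoint node sets covering every network node.
    net
        The interaction network supplying edges and weights.
    rho
        Exponent in [0, 1] weighting the unweighted (rho) versus the
        weighted (1-rho) connectivity ratio.  rho=1 ignores weights
        entirely; rho=0 uses only them.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho must be in [0, 1], got {rho}")
    sets = list(clusters.complexes if isinstance(clusters, ComplexSet) else clusters)
    assigned: dict[str, int] = {}
    for cid, members in enumerate(sets):
        for v in members:
            if v in assigned:
                raise ValueError(f"node {v!r} appears in more than one cluster")
            assigned[v] = cid
    if set(assigned) != set(net.nodes):
        raise ValueError("clusters must partition exactly the network's nodes")

    ncl = len(sets)
    m = np.zeros(ncl)        # internal edge counts
    bnd = np.zeros(ncl)      # boundary edge counts
    w_in = np.zeros(ncl)     # 2 * summed internal weights
    w_tot = np.zeros(ncl)    # summed weighted degree of members
    for (a, b), w in net.weights.items():
        ca, cb = assigned[a], assigned[b]
        w_tot[ca] += w
        w_tot[cb] += w
        if ca == cb:
            m[ca] += 1
            w_in[ca] += 2.0 * w
        else:
            bnd[ca] += 1
            bnd[cb] += 1

    fval = 0.0
    for c in range(ncl):
        if m[c] == 0 and bnd[c] == 0:
            continue  # cluster with no incident edges contributes nothing
        if w_tot[c] == 0:
            continue
        unweighted = 2.0 * m[c] / (2.0 * m[c] + bnd[c])
        weighted = w_in[c] / w_tot[c]
        fval += unweighted ** rho * weighted ** (1.0 - rho)
    return fval


def f_measure(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def precision_recall_f(pred: ComplexSet, ref: ComplexSet) -> EvalReport:
    """Maximum-matching precision, recall and f-measure of predicted clusters.

    precision = sum over predicted clusters of their largest overlap with
    any reference complex, divided by the total predicted node count
    (multiset — overlapping clusters count their shared nodes once per
    cluster).  recall is the symmetric quantity over reference complexes.
    """
    if len(pred) == 0 or len(ref) == 0:
        raise ValueError("predicted and reference sets must be non-empty")
    mms_pred = sum(max(len(c & f) for f in ref) for c in pred)
    size_pred = sum(len(c) for c in pred)
    mms_ref = sum(max(len(c & f) for c in pred) for f in ref)
    size_ref = sum(len(f) for f in ref)
    precision = mms_pred / size_pred
    recall = mms_ref / size_ref
    return EvalReport(precision=precision, recall=recall, f_measure=f_measure(precision, recall))


def pearson_r(x, y) -> float:
    """Pearson correlation via standardized products with n-1 normalization.

    r = 1/(n-1) * sum_i ((x_i - mean(x)) / s_x) * ((y_i - mean(y)) / s_y)

    with s the sample standard deviation.  Raises for constant input, where
    the correlation is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-D vectors with n >= 2")
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("correlation undefined for constant input")
    n = x.size
    return float(np.sum((x - x.mean()) / sx * (y - y.mean()) / sy) / (n - 1))
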