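"""Planted-module network generator for end-to-end pipeline testing.

Emulates what the clustering method assumes about protein-interaction data —
dense intra-complex connectivity, sparse cross-talk — with a planted
partition (stochastic block) model: every within-module pair is an edge with
probability ``p_in``, every between-module pair with ``p_out``.  The planted
modules double as the ground-truth reference complexes, so the whole
pipeline is testable without any external interaction database.  No attempt
is made to reproduce scale-free degree distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .network_model import ComplexSet, PPINetwork

logger = logging.getLogger(__name__)

__all__ = ["PlantedSpec", "planted_partition_network"]


@dataclass
class PlantedSpec:
    """Parameters of a planted-partition network.

    ``weight_law`` is either ``("constant", 1.0)`` (unweighted network) or
    ``("uniform", lo, hi)`` for i.i.d. uniform edge weights.
    """

    module_sizes: list[int]
    p_in: float = 0.9
    p_out: float = 0.02
    weight_law: tuple = ("constant", 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.module_sizes):
            raise ValueError("every module size must be >= 1")
        if not (0.0 <= self.p_in <= 1.0 and 0.0 <= self.p_out <= 1.0):
            raise ValueError("p_in and p_out must be probabilities")
        if self.p_in <= self.p_out:
            logger.warning(
                "p_in (%g) <= p_out (%g): planted structure will not be detectable",
                self.p_in,
                self.p_out,
            )
        kind = self.weight_law[0]
        if kind not in ("constant", "uniform"):
            raise ValueError(f"unknown weight law {kind!r}")
        if kind == "uniform" and not 0 < self.weight_law[1] <= self.weight_law[2]:
            raise ValueError("uniform weight law needs 0 < lo <= hi")

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    @property
    def n_nodes(self) -> int:
        return sum(self.module_sizes)


def planted_partition_network(spec: PlantedSpec) -> tuple[PPINetwork, ComplexSet]:
    """Sample a planted-partition network and its ground-truth modules.

    Node identifiers are ``m{module}_{index}`` so that mismatches in test
    failures are human-readable.  Fully reproducible from ``spec.seed``.
    """
    if spec.n_nodes < 2:
        raise ValueError("need at least 2 nodes in total")
    rng = np.random.default_rng(spec.seed)

    nodes: list[str] = []
    membership: list[int] = []
    for m, size in enumerate(spec.module_sizes):
        for i in range(size):
            nodes.append(f"m{m}_{i}")
            membership.append(m)

    weights: dict[tuple[str, str], float] = {}
    for ia, ib in combinations(range(len(nodes)), 2):
        p = spec.p_in if membership[ia] == membership[ib] else spec.p_out
        if rng.uniform() < p:
            weights[(nodes[ia], nodes[ib])] = _draw_weight(spec.weight_law, rng)

    net = PPINetwork(nodes=nodes, weights=weights)
    modules = ComplexSet(
        complexes=[
            {nodes[i] for i in range(len(nodes)) if membership[i] == m}
            for m in range(spec.n_modules)
        ],
        label="planted",
    )
    return net, modules


def _draw_weight(law: tuple, rng: np.random.Generator) -> float:
    if law[0] == "constant":
        return float(law[1])
    return float(rng.uniform(law[1], law[2]))
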