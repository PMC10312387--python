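"""Degree distributions, rank correlations, subgraphs, and communities.

The weighted degree of a concept is the sum of the weights of its incident
edges; in directed (affix) networks in-degree and out-degree are kept apart,
since they measure different things — a concept with high out-degree
contributes its word as building material to other words (lexical root
productivity), one with high in-degree tends to be expressed by
morphologically complex words (compoundhood).  Degree vectors of two
networks over the same concepts are compared with the Spearman rank
correlation.
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass
from itertools import permutations
from typing import Callable, Literal

import numpy as np
from scipy import stats

from .errors import CapabilityError
from .inference import ColexNetwork

logger = logging.getLogger(__name__)

Mode = Literal["undirected", "in", "out"]
WeightAttr = Literal["forms", "languages", "families", "unweighted"]

_WEIGHT_COLUMNS = {
    "forms": "weight_forms",
    "languages": "weight_languages",
    "families": "weight_families",
    "unweighted": None,
}


@dataclass(frozen=True)
class DegreeVector:
    """Concept-indexed (weighted) degrees of one network."""

    values: dict[str, float]
    mode: Mode = "undirected"
    weight_attr: WeightAttr = "families"

    @property
    def concepts(self) -> set[str]:
        return set(self.values)


@dataclass(frozen=True)
class CorrelationResult:
    """A Spearman rank correlation over the shared concepts of two vectors."""

    rho: float
    p_value: float
    n: int


def degree_vector(
    net: ColexNetwork,
    mode: Mode = "undirected",
    weight_attr: WeightAttr = "families",
) -> DegreeVector:
    """Degree of every concept in the network, isolated concepts included.

    ``weight_attr`` selects which edge weight is summed; ``"families"`` is
    the default because counting families rather than raw forms damps the
    contribution of family-internal homophony.  ``mode`` must match the
    network: ``in``/``out`` only for directed (affix) networks,
    ``undirected`` only for undirected ones.
    """
    if weight_attr not in _WEIGHT_COLUMNS:
        raise ValueError(f"unknown weight_attr: {weight_attr!r}")
    weight = _WEIGHT_COLUMNS[weight_attr]
    if mode in ("in", "out"):
        if not net.directed:
            raise ValueError(f"{mode}-degree is undefined on an undirected network")
        view = net.graph.in_degree if mode == "in" else net.graph.out_degree
    elif mode == "undirected":
        if net.directed:
            raise ValueError(
                "use mode='in' or 'out' on a directed network"
            )
        view = net.graph.degree
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    return DegreeVector(
        values={node: float(deg) for node, deg in view(weight=weight)},
        mode=mode,
        weight_attr=weight_attr,
    )


def compare_degrees(
    va: DegreeVector, vb: DegreeVector, exact: bool = False
) -> CorrelationResult:
    """Spearman rank correlation of two degree vectors.

    The comparison is restricted to the intersection of the two concept
    sets; ties receive average ranks.  The p-value is the standard
    large-sample two-sided approximation, or an exact two-sided permutation
    p-value when ``exact`` is requested (n <= 10 only).
    """
    shared = sorted(va.concepts & vb.concepts)
    n = len(shared)
    if n < 3:
        raise ValueError(f"need >= 3 shared concepts, got {n}")
    x = np.array([va.values[c] for c in shared])
    y = np.array([vb.values[c] for c in shared])
    rho, p = stats.spearmanr(x, y)
    if exact:
        p = _exact_permutation_p(x, y, float(rho))
    return CorrelationResult(rho=float(rho), p_value=float(p), n=n)


def _exact_permutation_p(x: np.ndarray, y: np.ndarray, observed: float) -> float:
    """Two-sided exact permutation p for Spearman's rho by full enumeration."""
    n = len(x)
    if n > 10:
        raise ValueError("exact permutation p-value limited to n <= 10")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / (rx.std() or 1.0)
    ry = (ry - ry.mean()) / (ry.std() or 1.0)
    # rho of a permuted pairing is the mean product of standardised ranks
    count = 0
    total = 0
    chunk: list[tuple[int, ...]] = []

    def flush(chunk: list[tuple[int, ...]]) -> int:
        perm_y = ry[np.array(chunk)]
        rhos = perm_y @ rx / n
        return int(np.sum(np.abs(rhos) >= abs(observed) - 1e-12))

    for perm in permutations(range(n)):
        chunk.append(perm)
        total += 1
        if len(chunk) == 20000:
            count += flush(chunk)
            chunk = []
    if chunk:
        count += flush(chunk)
    return count / total


def extract_subgraph(net: ColexNetwork, concepts: list[str]) -> ColexNetwork:
    """Induced subgraph on the given concepts, annotations preserved.

    Concepts absent from the network are added as isolated nodes (with a
    warning) so that downstream degree comparisons keep a common index.
    """
    if not concepts:
        raise ValueError("concepts must be non-empty")
    requested = sorted(set(concepts))
    present = [c for c in requested if c in net.graph]
    missing = [c for c in requested if c not in net.graph]
    if missing:
        logger.warning("concepts not in network, added isolated: %s", missing)
    sub = net.graph.subgraph(present).copy()
    for concept in missing:
        sub.add_node(concept, n_forms=0, n_languages=0, n_families=0, forms={})
    return ColexNetwork(kind=net.kind, graph=sub, config=net.config)


def _igraph_infomap(graph, weights, seed: int):
    import igraph

    g = igraph.Graph.from_networkx(graph)
    random.seed(seed)
    return g, g.community_infomap(edge_weights=weights)


def _igraph_label_propagation(graph, weights, seed: int):
    import igraph

    g = igraph.Graph.from_networkx(graph)
    random.seed(seed)
    return g, g.community_label_propagation(weights=weights)


_COMMUNITY_BACKENDS: dict[str, Callable] = {
    "infomap": _igraph_infomap,
    "label-propagation": _igraph_label_propagation,
}


def detect_communities(
    net: ColexNetwork,
    algorithm: str = "infomap",
    seed: int = 0,
    weight_attr: WeightAttr = "families",
) -> dict[str, int]:
    """Partition the concepts of an undirected network into communities.

    Delegates to igraph's implementations (``infomap`` or
    ``label-propagation``); the partition is total (isolated concepts get
    their own community) and deterministic for a fixed seed.
    """
    if net.directed:
        raise ValueError("communities are computed on undirected networks")
    if algorithm not in _COMMUNITY_BACKENDS:
        raise CapabilityError(
            f"unknown community backend {algorithm!r}; "
            f"available: {sorted(_COMMUNITY_BACKENDS)}"
        )
    if net.graph.number_of_nodes() == 0:
        return {}
    weight_col = _WEIGHT_COLUMNS[weight_attr]
    weights = (
        [net.graph.edges[e][weight_col] for e in net.graph.edges]
        if weight_col and net.graph.number_of_edges()
        else None
    )
    g, clustering = _COMMUNITY_BACKENDS[algorithm](net.graph, weights, seed)
    membership = clustering.membership
    names = g.vs["_nx_name"]
    return {name: int(community) for name, community in zip(names, membership)}
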