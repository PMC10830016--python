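"""Connector-based structural metrics of tripartite networks.

The shared species set stitches the two interaction layers together.  Three
metrics quantify how:

* ``C`` — proportion of shared species that are *connectors*, i.e. have at
  least one link in each layer.
* ``H_C`` — proportion of shared-set *hubs* (top 20% by total degree, at
  least one) that are connectors.
* ``PC`` — participation coefficient of a connector, ``2 * k_min / k_tot``:
  1 when its links are split evenly between the layers, approaching 0 as
  the split grows more uneven.  ``PC_C`` is the mean over connectors.

Degree heterogeneity (sigma_k / <k>) summarizes how right-skewed the total
degree distribution is over all species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import DomainError, StructuralError
from .model import TripartiteNetwork


@dataclass(frozen=True)
class StructuralMetrics:
    """Connector metrics and degree heterogeneity of one network."""

    C: float
    H_C: float
    PC_C: float
    degree_heterogeneity: float
    hub_threshold: float
    per_node_PC: Mapping[str, float]


def connector_nodes(net: TripartiteNetwork) -> frozenset[str]:
    """Shared-set species with links simultaneously in both layers."""
    return net.connectors()


def connector_proportion(net: TripartiteNetwork) -> float:
    """C: fraction of the shared set that are connectors."""
    n_shared = len(net.shared_set)
    if n_shared == 0:
        raise StructuralError("empty shared set")
    return len(net.connectors()) / n_shared


def hub_connector_proportion(net: TripartiteNetwork, threshold: float = 0.2) -> float:
    """H_C: fraction of shared-set hubs that are connectors.

    Hubs are the top ``ceil(threshold * |shared|)`` shared species by total
    degree (both layers pooled); the ceiling guarantees at least one hub.
    Degree ties are broken by lexicographic species id, so the hub set is
    deterministic.
    """
    shared = net.shared_set.members
    if not shared:
        raise StructuralError("empty shared set")
    n_hubs = math.ceil(threshold * len(shared))
    n_hubs = max(1, min(n_hubs, len(shared)))
    degs = net.total_degrees()
    ranked = sorted(shared, key=lambda m: (-degs[m], m))
    hubs = ranked[:n_hubs]
    connectors = net.connectors()
    return sum(1 for h in hubs if h in connectors) / n_hubs


def participation_coefficient(net: TripartiteNetwork, node: str) -> float:
    """PC = 2 * k_min / k_tot for a connector node.

    Raises :class:`DomainError` for non-connectors: with zero links in one
    layer the coefficient is identically 0 and carries no information about
    how the node participates in both layers.
    """
    if node not in net.connectors():
        raise DomainError(f"{node!r} is not a connector; PC is defined on connectors")
    k1 = net.degree(node, 0)
    k2 = net.degree(node, 1)
    return 2.0 * min(k1, k2) / (k1 + k2)


def mean_connector_participation(net: TripartiteNetwork) -> float:
    """PC_C: arithmetic mean of PC over all connector nodes."""
    connectors = net.connectors()
    if not connectors:
        raise DomainError("network has no connector nodes")
    return float(
        np.mean([participation_coefficient(net, c) for c in sorted(connectors)])
    )


def degree_heterogeneity(net: TripartiteNetwork, kind: str = "cv") -> float:
    """Heterogeneity of the total-degree distribution over all species.

    ``kind="cv"`` (default) is the coefficient of variation, population SD
    of total degree divided by the mean — dimensionless, 0 iff all degrees
    are equal.  ``kind="vmr"`` is the variance-to-mean ratio, provided
    because the two readings of "sigma_k / <k>" differ and some sources use
    either.
    """
    degs = np.array(list(net.total_degrees().values()), dtype=float)
    mean = degs.mean()
    if mean == 0:
        raise DomainError("all degrees are zero")
    if kind == "cv":
        return float(degs.std() / mean)
    if kind == "vmr":
        return float(degs.var() / mean)
    raise ValueError(f"unknown heterogeneity kind {kind!r}")


def structural_metrics(
    net: TripartiteNetwork,
    hub_threshold: float = 0.2,
    heterogeneity: str = "cv",
) -> StructuralMetrics:
    """All connector metrics of one network in a single record."""
    per_node = {
        c: participation_coefficient(net, c) for c in sorted(net.connectors())
    }
    return StructuralMetrics(
        C=connector_proportion(net),
        H_C=hub_connector_proportion(net, hub_threshold),
        PC_C=mean_connector_participation(net),
        degree_heterogeneity=degree_heterogeneity(net, heterogeneity),
        hub_threshold=hub_threshold,
        per_node_PC=per_node,
    )
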