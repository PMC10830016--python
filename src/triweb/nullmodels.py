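"""Constrained randomizations of tripartite networks and ensemble comparison.

Four null models of increasing constraint, applied layer by layer:

1. keeps the number of species in each set and the number of links in each
   layer (uniform random simple bipartite graph);
2. additionally keeps each consumer's layer degree (consumers rewire their
   stubs to uniformly chosen resources);
3. keeps both degree multisets per layer but independently permutes the
   shared-set node identities within each layer, destroying the cross-layer
   degree correlation of shared species;
4. keeps every node's per-layer degree exactly, reshuffling links within a
   layer by bipartite-safe double-edge swaps.

``null_compare`` measures any statistic on an ensemble of replicates and
reports the observed value against the null mean, SD, z-score and an
empirical two-sided percentile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .errors import RandomizationError, TriwebError
from .model import Edge, Layer, SpeciesSet, TripartiteNetwork

Rng = np.random.Generator
Statistic = Callable[[TripartiteNetwork], float]


@dataclass(frozen=True)
class NullModelSpec:
    """Which null model, how many replicates, and the swap budget (model 4)."""

    model: int
    n_replicates: int = 100
    seed: Optional[int] = None
    n_swaps_factor: int = 10

    def __post_init__(self) -> None:
        if self.model not in (1, 2, 3, 4):
            raise TriwebError(f"null model must be 1-4, got {self.model}")
        if self.n_replicates < 1:
            raise TriwebError("n_replicates must be >= 1")


@dataclass(frozen=True)
class NullComparison:
    """Observed statistic versus its null-model ensemble."""

    statistic: str
    model: int
    observed: float
    null_values: tuple[float, ...]
    n_dropped: int

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_values))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_values))

    @property
    def z(self) -> float:
        sd = self.null_sd
        if sd == 0:
            return 0.0 if self.observed == self.null_mean else float("inf")
        return (self.observed - self.null_mean) / sd

    @property
    def percentile(self) -> float:
        """Fraction of null values at or below the observed value."""
        vals = np.asarray(self.null_values)
        return float(np.mean(vals <= self.observed))

    @property
    def p_two_sided(self) -> float:
        """Empirical two-sided tail probability (add-one corrected)."""
        vals = np.asarray(self.null_values)
        n = len(vals)
        lo = (np.sum(vals <= self.observed) + 1) / (n + 1)
        hi = (np.sum(vals >= self.observed) + 1) / (n + 1)
        return float(min(1.0, 2.0 * min(lo, hi)))


# ---------------------------------------------------------------------- #
# Layer randomizers
# ---------------------------------------------------------------------- #


def _uniform_bipartite(
    resources: Sequence[str], consumers: Sequence[str], n_edges: int, rng: Rng
) -> frozenset[Edge]:
    n_r, n_c = len(resources), len(consumers)
    if n_edges > n_r * n_c:
        raise RandomizationError("more edges than resource x consumer pairs")
    flat = rng.choice(n_r * n_c, size=n_edges, replace=False)
    return frozenset((resources[i // n_c], consumers[i % n_c]) for i in flat)


def _fixed_consumer_degrees(
    resources: Sequence[str], layer: Layer, rng: Rng
) -> frozenset[Edge]:
    degs: dict[str, int] = {}
    for _, c in layer.edges:
        degs[c] = degs.get(c, 0) + 1
    n_r = len(resources)
    edges: set[Edge] = set()
    for c, k in degs.items():
        if k > n_r:
            raise RandomizationError(f"consumer {c!r} degree {k} exceeds resource count")
        for i in rng.choice(n_r, size=k, replace=False):
            edges.add((resources[i], c))
    return frozenset(edges)


def _permute_shared(
    layer: Layer, shared_members: Sequence[str], shared_is_resource: bool, rng: Rng
) -> frozenset[Edge]:
    perm_idx = rng.permutation(len(shared_members))
    mapping = {
        shared_members[i]: shared_members[perm_idx[i]]
        for i in range(len(shared_members))
    }
    if shared_is_resource:
        return frozenset((mapping[r], c) for r, c in layer.edges)
    return frozenset((r, mapping[c]) for r, c in layer.edges)


def _double_edge_swaps(layer: Layer, target_swaps: int, rng: Rng) -> frozenset[Edge]:
    """Degree-preserving bipartite reshuffle.

    Two edges (r1,c1),(r2,c2) become (r1,c2),(r2,c1) when neither new edge
    already exists; this keeps every node on its own side, so per-layer
    degrees are conserved exactly.  Attempts are bounded; sparse or tiny
    layers that admit few swaps simply return less randomized.
    """
    edges = list(layer.edges)
    if len(edges) < 2:
        return layer.edges
    index = {e: i for i, e in enumerate(edges)}
    accepted = 0
    attempts = 0
    max_attempts = max(1000, 100 * target_swaps)
    while accepted < target_swaps and attempts < max_attempts:
        attempts += 1
        i, j = rng.integers(len(edges)), rng.integers(len(edges))
        if i == j:
            continue
        r1, c1 = edges[i]
        r2, c2 = edges[j]
        if r1 == r2 or c1 == c2:
            continue
        e1, e2 = (r1, c2), (r2, c1)
        if e1 in index or e2 in index:
            continue
        del index[(r1, c1)], index[(r2, c2)]
        edges[i], edges[j] = e1, e2
        index[e1], index[e2] = i, j
        accepted += 1
    return frozenset(edges)


def randomize(
    net: TripartiteNetwork,
    model: int,
    rng: Optional[Rng] = None,
    n_swaps_factor: int = 10,
) -> TripartiteNetwork:
    """One randomized replicate of the network under null model 1-4.

    Weighted networks are randomized on topology only (weights dropped);
    redraw dependencies afterwards with
    :func:`triweb.synth.assign_weights` if needed.
    """
    if model not in (1, 2, 3, 4):
        raise TriwebError(f"null model must be 1-4, got {model}")
    if rng is None:
        rng = np.random.default_rng()
    shared = net.shared_set.name
    new_layers = []
    for layer in net.layers:
        resources = net.get_set(layer.resource_set).members
        consumers = net.get_set(layer.consumer_set).members
        if model == 1:
            edges = _uniform_bipartite(resources, consumers, layer.n_edges, rng)
        elif model == 2:
            edges = _fixed_consumer_degrees(resources, layer, rng)
        elif model == 3:
            edges = _permute_shared(
                layer,
                net.shared_set.members,
                shared_is_resource=(layer.resource_set == shared),
                rng=rng,
            )
        else:
            edges = _double_edge_swaps(layer, n_swaps_factor * layer.n_edges, rng)
        new_layers.append(
            Layer(
                name=layer.name,
                sign=layer.sign,
                resource_set=layer.resource_set,
                consumer_set=layer.consumer_set,
                edges=edges,
            )
        )
    return TripartiteNetwork(
        sets=[SpeciesSet(s.name, s.members) for s in net.sets],
        layers=new_layers,
        name=f"{net.name}|null{model}",
    )


def null_compare(
    net: TripartiteNetwork,
    statistic: Union[str, Statistic],
    spec: NullModelSpec,
) -> NullComparison:
    """Compare a statistic on the network against a null-model ensemble.

    ``statistic`` is a callable ``net -> float`` or the name of a registered
    one (``C``, ``H_C``, ``PC_C``, ``heterogeneity``, ``n_edges``).
    Replicates on which the statistic is undefined (e.g. a randomization
    left no connectors) are dropped and counted.
    """
    fn, name = _resolve_statistic(statistic)
    observed = fn(net)
    rng = np.random.default_rng(spec.seed)
    values: list[float] = []
    dropped = 0
    for _ in range(spec.n_replicates):
        rep = randomize(net, spec.model, rng, spec.n_swaps_factor)
        try:
            values.append(float(fn(rep)))
        except TriwebError:
            dropped += 1
    if dropped:
        warnings.warn(
            f"statistic {name!r} undefined on {dropped}/{spec.n_replicates} "
            f"replicates of null model {spec.model}",
            stacklevel=2,
        )
    if not values:
        raise RandomizationError(
            f"statistic {name!r} undefined on every replicate"
        )
    return NullComparison(
        statistic=name,
        model=spec.model,
        observed=float(observed),
        null_values=tuple(values),
        n_dropped=dropped,
    )


def _resolve_statistic(
    statistic: Union[str, Statistic]
) -> tuple[Statistic, str]:
    if callable(statistic):
        return statistic, getattr(statistic, "__name__", "statistic")
    from . import metrics

    registry: dict[str, Statistic] = {
        "C": metrics.connector_proportion,
        "H_C": metrics.hub_connector_proportion,
        "PC_C": metrics.mean_connector_participation,
        "heterogeneity": metrics.degree_heterogeneity,
        "n_edges": lambda n: float(sum(layer.n_edges for layer in n.layers)),
    }
    try:
        return registry[statistic], statistic
    except KeyError:
        raise TriwebError(
            f"unknown statistic {statistic!r}; known: {sorted(registry)}"
        ) from None
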