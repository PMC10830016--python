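"""Data model for tripartite ecological networks.

A tripartite network is three species sets joined by two bipartite
interaction layers that share exactly one set.  Each layer is signed
(mutualistic ``+`` or antagonistic ``-``) and oriented: its edges run from a
*resource* set to a *consumer* set.  Depending on where the shared set sits,
the network is a *fan* (shared set is the resource of both layers, e.g.
plants shared between pollinators and herbivores), a *chain* (the shared set
consumes one layer and is consumed in the other, e.g. herbivores between
plants and parasitoids), or an *apex* (shared set consumes both layers).

The sign pair classifies the network as antagonism-antagonism (AA),
mutualism-antagonism (MA) or mutualism-mutualism (MM).
"""

from __future__ import annotations


from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Optional

from .errors import ConfigurationError, StructuralError, NodeReferenceError

Edge = tuple[str, str]  # (resource id, consumer id)

MUTUALISM = "+"
ANTAGONISM = "-"
_SIGNS = {MUTUALISM, ANTAGONISM}


class NetworkClass(Enum):
    """Sign-pair classification of a tripartite network."""

    AA = "AA"
    MA = "MA"
    MM = "MM"


class Topology(Enum):
    """Position of the shared species set relative to the two layers."""

    FAN = "fan"      # shared set is the resource of both layers
    CHAIN = "chain"  # shared set consumes one layer, is consumed in the other
    APEX = "apex"    # shared set consumes both layers


@dataclass(frozen=True)
class SpeciesSet:
    """A named, ordered collection of species identifiers."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(self.members))
        if len(set(self.members)) != len(self.members):
            dup = sorted({m for m in self.members if list(self.members).count(m) > 1})
            raise StructuralError(
                f"species set {self.name!r} has duplicate members: {dup}"
            )

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, item: str) -> bool:
        return item in set(self.members)


@dataclass(frozen=True)
class Layer:
    """One signed, oriented bipartite interaction layer.

    Edges are ``(resource, consumer)`` pairs; ``weights``, when present, map
    every edge to a positive dependency value (the consumer's reliance on
    that resource).
    """

    name: str
    sign: str
    resource_set: str
    consumer_set: str
    edges: frozenset[Edge]
    weights: Optional[Mapping[Edge, float]] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", frozenset(self.edges))
        if self.sign not in _SIGNS:
            raise ConfigurationError(
                f"layer {self.name!r}: sign must be '+' or '-', got {self.sign!r}"
            )
        if self.resource_set == self.consumer_set:
            raise StructuralError(
                f"layer {self.name!r}: resource and consumer set are both "
                f"{self.resource_set!r}"
            )
        if self.weights is not None:
            w = dict(self.weights)
            missing = self.edges - w.keys()
            if missing:
                raise ConfigurationError(
                    f"layer {self.name!r}: {len(missing)} edges lack weights"
                )
            bad = [e for e, v in w.items() if not v > 0]
            if bad:
                raise ConfigurationError(
                    f"layer {self.name!r}: non-positive weight on {sorted(bad)[:3]}"
                )
            object.__setattr__(self, "weights", w)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree_of(self, node: str) -> int:
        """Number of links of ``node`` in this layer (either role)."""
        return sum(1 for r, c in self.edges if r == node or c == node)

    def sorted_edges(self) -> list[Edge]:
        return sorted(self.edges)


@dataclass(frozen=True)
class BipartiteNetwork:
    """A standalone bipartite network obtained by splitting a tripartite one.

    ``contains_basal`` records whether the resource side is the basal
    (primary-removal) set of the parent network; plant-removal robustness is
    only defined when it is.
    """

    name: str
    sign: str
    resources: tuple[str, ...]
    consumers: tuple[str, ...]
    edges: frozenset[Edge]
    contains_basal: bool = True
    weights: Optional[Mapping[Edge, float]] = None

    @property
    def n_species(self) -> int:
        return len(self.resources) + len(self.consumers)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of :func:`validate_network`."""

    n_connectors: int
    species_with_no_resource: tuple[str, ...]
    passes_connector_filter: bool
    warnings: tuple[str, ...] = ()


class TripartiteNetwork:
    """Three species sets plus two bipartite layers sharing exactly one set.

    Construction validates all structural invariants: member identifiers are
    unique across the network, every edge endpoint belongs to the layer's
    declared sets, no duplicate edges within a layer, and exactly one set
    appears in both layers.  The shared set, basal set and topology are
    inferred, never declared.
    """

    def __init__(
        self,
        sets: Iterable[SpeciesSet],
        layers: Iterable[Layer],
        name: str = "",
    ) -> None:
        self.sets: tuple[SpeciesSet, ...] = tuple(sets)
        self.layers: tuple[Layer, ...] = tuple(layers)
        self.name = name
        if len(self.sets) != 3:
            raise StructuralError(f"need exactly 3 species sets, got {len(self.sets)}")
        if len(self.layers) != 2:
            raise StructuralError(f"need exactly 2 layers, got {len(self.layers)}")

        names = [s.name for s in self.sets]
        if len(set(names)) != 3:
            raise StructuralError(f"species set names not unique: {names}")
        self._set_map = {s.name: s for s in self.sets}

        all_members: dict[str, str] = {}
        for s in self.sets:
            for m in s.members:
                if m in all_members:
                    raise StructuralError(
                        f"species {m!r} belongs to both {all_members[m]!r} and {s.name!r}"
                    )
                all_members[m] = s.name
        self._member_set = all_members

        set_usage: dict[str, int] = {n: 0 for n in names}
        for layer in self.layers:
            for role in (layer.resource_set, layer.consumer_set):
                if role not in self._set_map:
                    raise StructuralError(
                        f"layer {layer.name!r} references unknown set {role!r}"
                    )
            res = set(self._set_map[layer.resource_set].members)
            con = set(self._set_map[layer.consumer_set].members)
            for r, c in layer.edges:
                if r not in res:
                    raise NodeReferenceError(
                        f"layer {layer.name!r}: resource {r!r} not in set "
                        f"{layer.resource_set!r}"
                    )
                if c not in con:
                    raise NodeReferenceError(
                        f"layer {layer.name!r}: consumer {c!r} not in set "
                        f"{layer.consumer_set!r}"
                    )
        for layer in self.layers:
            set_usage[layer.resource_set] += 1
            set_usage[layer.consumer_set] += 1
        shared = [n for n, k in set_usage.items() if k == 2]
        unused = [n for n, k in set_usage.items() if k == 0]
        if unused:
            raise StructuralError(f"species set(s) {unused} appear in no layer")
        if len(shared) != 1:
            raise StructuralError(
                f"exactly one set must appear in both layers; found {shared or 'none'}"
            )
        self._shared = shared[0]

        roles = tuple(
            "resource" if layer.resource_set == self._shared else "consumer"
            for layer in self.layers
        )
        if roles == ("resource", "resource"):
            self._topology = Topology.FAN
        elif roles == ("consumer", "consumer"):
            self._topology = Topology.APEX
        else:
            self._topology = Topology.CHAIN

        self._degree_cache: Optional[list[dict[str, int]]] = None

    # ------------------------------------------------------------------ #

    @property
    def set_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.sets)

    @property
    def shared_set(self) -> SpeciesSet:
        """The set with potential links in both layers."""
        return self._set_map[self._shared]

    @property
    def topology(self) -> Topology:
        return self._topology

    @property
    def basal_set(self) -> SpeciesSet:
        """The set that is never a consumer (plants).

        For fan topology this is the shared set itself; for chain topology
        it is the resource set of the layer the shared set consumes.  Apex
        networks have two never-consumer sets, so no unique basal set.
        """
        if self._topology is Topology.FAN:
            return self.shared_set
        if self._topology is Topology.APEX:
            raise StructuralError("apex topology has no unique basal set")
        for layer in self.layers:
            if layer.consumer_set == self._shared:
                return self._set_map[layer.resource_set]
        raise AssertionError("unreachable")

    @property
    def non_basal_sets(self) -> tuple[SpeciesSet, ...]:
        """The sets subject to secondary extinction, in declaration order."""
        basal = self.basal_set.name
        return tuple(s for s in self.sets if s.name != basal)

    def get_set(self, name: str) -> SpeciesSet:
        return self._set_map[name]

    def set_of(self, species: str) -> str:
        """Name of the set a species belongs to."""
        try:
            return self._member_set[species]
        except KeyError:
            raise NodeReferenceError(f"unknown species {species!r}") from None

    def layer_degrees(self) -> list[dict[str, int]]:
        """Per-layer degree of every species (zero included), cached."""
        if self._degree_cache is None:
            out = []
            for layer in self.layers:
                deg = {m: 0 for m in self._member_set}
                for r, c in layer.edges:
                    deg[r] += 1
                    deg[c] += 1
                out.append(deg)
            self._degree_cache = out
        return self._degree_cache

    def degree(self, node: str, layer_index: Optional[int] = None) -> int:
        """Degree of ``node`` in one layer, or total over both if ``None``."""
        degs = self.layer_degrees()
        if layer_index is not None:
            return degs[layer_index][node]
        return degs[0][node] + degs[1][node]

    def total_degrees(self) -> dict[str, int]:
        degs = self.layer_degrees()
        return {m: degs[0][m] + degs[1][m] for m in self._member_set}

    def connectors(self) -> frozenset[str]:
        """Shared-set species with at least one link in each layer."""
        degs = self.layer_degrees()
        return frozenset(
            m for m in self.shared_set.members if degs[0][m] >= 1 and degs[1][m] >= 1
        )

    def resources_of(self, species: str) -> frozenset[str]:
        """All resources ``species`` consumes, pooled over layers."""
        out: set[str] = set()
        for layer in self.layers:
            if species in set(self._set_map[layer.consumer_set].members):
                out.update(r for r, c in layer.edges if c == species)
        return frozenset(out)

    @property
    def is_weighted(self) -> bool:
        return all(layer.weights is not None for layer in self.layers)

    def __repr__(self) -> str:
        sizes = ", ".join(f"{s.name}:{len(s)}" for s in self.sets)
        return (
            f"TripartiteNetwork({self.name or 'unnamed'}; {sizes}; "
            f"{self._topology.value}; {classify_network(self).value})"
        )


# ---------------------------------------------------------------------- #
# Operations
# ---------------------------------------------------------------------- #


def classify_network(net: TripartiteNetwork) -> NetworkClass:
    """AA if both layers antagonistic, MM if both mutualistic, MA otherwise.

    Symmetric in the order of the layers.
    """
    signs = {layer.sign for layer in net.layers}
    if signs == {ANTAGONISM}:
        return NetworkClass.AA
    if signs == {MUTUALISM}:
        return NetworkClass.MM
    return NetworkClass.MA


def combine_layers(layers: Iterable[Layer], new_name: str) -> Layer:
    """Merge layers of the same kind into one (e.g. several herbivory webs).

    All inputs must share sign and orientation.  The edge set is the union;
    weights of duplicate edges are summed (interaction-intensity reading).
    """
    layers = list(layers)
    if not layers:
        raise ConfigurationError("no layers to combine")
    first = layers[0]
    for layer in layers[1:]:
        if (
            layer.sign != first.sign
            or layer.resource_set != first.resource_set
            or layer.consumer_set != first.consumer_set
        ):
            raise StructuralError(
                f"cannot combine {layer.name!r} with {first.name!r}: "
                "sign or orientation differ"
            )
    edges: set[Edge] = set()
    for layer in layers:
        edges |= layer.edges
    weighted = [layer for layer in layers if layer.weights is not None]
    weights: Optional[dict[Edge, float]] = None
    if weighted:
        if len(weighted) != len(layers):
            raise ConfigurationError("cannot combine weighted with unweighted layers")
        weights = {}
        for layer in layers:
            assert layer.weights is not None
            for e, w in layer.weights.items():
                weights[e] = weights.get(e, 0.0) + w
    return Layer(
        name=new_name,
        sign=first.sign,
        resource_set=first.resource_set,
        consumer_set=first.consumer_set,
        edges=frozenset(edges),
        weights=weights,
    )


def validate_network(net: TripartiteNetwork, min_connectors: int = 5) -> ValidationReport:
    """Report connector count, resource-less species, and the connector filter.

    The filter (at least ``min_connectors`` connector nodes, default 5) is a
    verdict only — small networks load fine but are flagged as below the
    threshold used to assemble comparable data sets.
    """
    n_conn = len(net.connectors())
    no_resource: list[str] = []
    warnings: list[str] = []
    try:
        basal = net.basal_set.name
    except StructuralError:
        basal = None
        warnings.append("apex topology: every non-shared set is basal-like")
    degs = net.layer_degrees()
    for s in net.sets:
        if s.name == basal:
            continue
        for m in s.members:
            if basal is None and s.name != net.shared_set.name:
                continue
            if not net.resources_of(m):
                no_resource.append(m)
    for s in net.sets:
        for m in s.members:
            if degs[0][m] + degs[1][m] == 0:
                warnings.append(f"species {m!r} is isolated (degree 0 in both layers)")
    return ValidationReport(
        n_connectors=n_conn,
        species_with_no_resource=tuple(sorted(no_resource)),
        passes_connector_filter=n_conn >= min_connectors,
        warnings=tuple(warnings),
    )


def split_bipartite(
    net: TripartiteNetwork,
) -> tuple[BipartiteNetwork, BipartiteNetwork]:
    """Split the tripartite network into two standalone bipartite networks.

    Shared-set species without links in a layer are dropped from that
    layer's bipartite network (they are not part of it as a standalone web).
    Returns ``(larger, smaller)`` by total species count, ties broken by
    layer declaration order.  For chain topology the layer not adjacent to
    the basal set is flagged ``contains_basal=False``: plant-removal
    robustness cannot be computed on it.
    """
    try:
        basal = net.basal_set.name
    except StructuralError:
        basal = None
    parts: list[BipartiteNetwork] = []
    for layer in net.layers:
        res_members = net.get_set(layer.resource_set).members
        con_members = net.get_set(layer.consumer_set).members
        linked = {n for e in layer.edges for n in e}
        shared = net.shared_set.name
        res = tuple(
            m
            for m in res_members
            if layer.resource_set != shared or m in linked
        )
        con = tuple(
            m
            for m in con_members
            if layer.consumer_set != shared or m in linked
        )
        parts.append(
            BipartiteNetwork(
                name=layer.name,
                sign=layer.sign,
                resources=res,
                consumers=con,
                edges=layer.edges,
                contains_basal=(layer.resource_set == basal),
                weights=layer.weights,
            )
        )
    a, b = parts
    if b.n_species > a.n_species:
        return b, a
    return a, b
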