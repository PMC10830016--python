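"""Synthetic tripartite networks: canonical fixtures and a parametric generator.

The generator emulates the statistical structure of published tripartite
webs: three species sets of tens of species, right-skewed consumer degree
distributions, a tunable fraction of shared-set species acting as
connectors, and a tunable mean participation coefficient of those
connectors.  It does *not* fit any empirical data set; all parameters are
explicit knobs.

Design: degree distributions are attached to consumers (animals choose
resources, as bipartite webs are sampled); resource degrees emerge.  The
connector count is exact by construction — only designated connector
species are eligible in both layers, and each receives at least one link
per layer.  The connector-PC mean is steered in two stages: each connector
draws a layer-split fraction from a symmetric Beta whose parameter is
solved so the expected PC matches the target, biasing how consumer stubs
land on it; a bounded greedy rewiring pass (moving single edges between
resource species, consumer degrees untouched) then nudges the realized mean
the rest of the way.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence, Union

import numpy as np
from scipy import optimize, special

from .errors import ConfigurationError, GenerationError
from .model import Edge, Layer, SpeciesSet, TripartiteNetwork

Rng = np.random.Generator

_FIXTURE_NAMES = ("F_MA_small", "F_sym", "F_AA_chain", "F_keystone")


# ---------------------------------------------------------------------- #
# Canonical fixtures
# ---------------------------------------------------------------------- #


def fixture(name: str) -> TripartiteNetwork:
    """One of the four canonical hand-built networks.

    * ``F_MA_small`` — 3 plants, 2 pollinators, 2 herbivores; one connector.
    * ``F_sym``      — 2 plants, two mirror-image mutualistic layers.
    * ``F_AA_chain`` — plant - herbivore - parasitoid chain of single species.
    * ``F_keystone`` — 3 plants, one of which supports all four animals.
    """
    if name == "F_MA_small":
        return TripartiteNetwork(
            sets=[
                SpeciesSet("plants", ("p1", "p2", "p3")),
                SpeciesSet("pollinators", ("a1", "a2")),
                SpeciesSet("herbivores", ("b1", "b2")),
            ],
            layers=[
                Layer(
                    "pollination", "+", "plants", "pollinators",
                    frozenset({("p1", "a1"), ("p2", "a1"), ("p2", "a2")}),
                ),
                Layer(
                    "herbivory", "-", "plants", "herbivores",
                    frozenset({("p2", "b1"), ("p3", "b1"), ("p3", "b2")}),
                ),
            ],
            name="F_MA_small",
        )
    if name == "F_sym":
        return TripartiteNetwork(
            sets=[
                SpeciesSet("plants", ("p1", "p2")),
                SpeciesSet("setA", ("a1", "a2")),
                SpeciesSet("setB", ("b1", "b2")),
            ],
            layers=[
                Layer(
                    "layerX", "+", "plants", "setA",
                    frozenset({("p1", "a1"), ("p1", "a2"), ("p2", "a2")}),
                ),
                Layer(
                    "layerY", "+", "plants", "setB",
                    frozenset({("p1", "b1"), ("p1", "b2"), ("p2", "b2")}),
                ),
            ],
            name="F_sym",
        )
    if name == "F_AA_chain":
        return TripartiteNetwork(
            sets=[
                SpeciesSet("plants", ("p1",)),
                SpeciesSet("herbivores", ("h1",)),
                SpeciesSet("parasitoids", ("q1",)),
            ],
            layers=[
                Layer("herbivory", "-", "plants", "herbivores",
                      frozenset({("p1", "h1")})),
                Layer("parasitism", "-", "herbivores", "parasitoids",
                      frozenset({("h1", "q1")})),
            ],
            name="F_AA_chain",
        )
    if name == "F_keystone":
        return TripartiteNetwork(
            sets=[
                SpeciesSet("plants", ("p1", "p2", "p3")),
                SpeciesSet("setA", ("a1", "a2")),
                SpeciesSet("setB", ("b1", "b2")),
            ],
            layers=[
                Layer(
                    "layerX", "+", "plants", "setA",
                    frozenset({("p1", "a1"), ("p2", "a1"), ("p1", "a2")}),
                ),
                Layer(
                    "layerY", "-", "plants", "setB",
                    frozenset({("p1", "b1"), ("p3", "b1"), ("p1", "b2")}),
                ),
            ],
            name="F_keystone",
        )
    raise ConfigurationError(
        f"unknown fixture {name!r}; choose from {_FIXTURE_NAMES}"
    )


# ---------------------------------------------------------------------- #
# Degree models
# ---------------------------------------------------------------------- #


@dataclass(frozen=True)
class DegreeModel:
    """Consumer degree distribution: ``poisson(mean)`` or ``powerlaw(exponent, k_min)``."""

    kind: str
    mean: float = 2.0       # poisson
    exponent: float = 2.5   # powerlaw
    k_min: int = 1          # powerlaw

    def __post_init__(self) -> None:
        if self.kind not in ("poisson", "powerlaw"):
            raise ConfigurationError(f"unknown degree model {self.kind!r}")
        if self.kind == "powerlaw" and self.exponent <= 1:
            raise ConfigurationError("power-law exponent must exceed 1")

    def sample(self, n: int, k_max: int, rng: Rng) -> np.ndarray:
        """Draw n consumer degrees truncated to [1, k_max] (or [k_min, k_max])."""
        if self.kind == "poisson":
            k = rng.poisson(self.mean, size=n)
            return np.clip(k, 1, k_max)
        lo = max(1, self.k_min)
        if lo > k_max:
            lo = k_max
        support = np.arange(lo, k_max + 1)
        p = support.astype(float) ** (-self.exponent)
        p /= p.sum()
        return rng.choice(support, size=n, p=p)


def poisson(mean: float) -> DegreeModel:
    return DegreeModel(kind="poisson", mean=mean)


def powerlaw(exponent: float, k_min: int = 1) -> DegreeModel:
    return DegreeModel(kind="powerlaw", exponent=exponent, k_min=k_min)


# ---------------------------------------------------------------------- #
# Generator configuration
# ---------------------------------------------------------------------- #


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of one random tripartite network.

    ``sizes`` is ``(n_shared_plants, n_consumers_1, n_consumers_2)`` for fan
    topology and ``(n_plants, n_shared, n_top)`` for chain topology.
    ``degree_model`` applies to both consumer sets, or give a pair.
    ``target_C`` is the fraction of the shared set that ends up connecting
    both layers (exact after rounding); ``target_PC`` the mean participation
    coefficient those connectors are steered towards.
    """

    sizes: tuple[int, int, int] = (40, 40, 40)
    topology: str = "fan"
    signs: tuple[str, str] = ("+", "-")
    degree_model: Union[DegreeModel, tuple[DegreeModel, DegreeModel]] = field(
        default_factory=lambda: powerlaw(2.5, 1)
    )
    target_C: float = 0.35
    target_PC: float = 0.6
    weighted: bool = False
    concentration: float = 1.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.sizes) != 3 or any(s < 1 for s in self.sizes):
            raise ConfigurationError(f"sizes must be 3 positive counts, got {self.sizes}")
        if self.topology not in ("fan", "chain"):
            raise ConfigurationError(f"topology must be fan or chain, got {self.topology!r}")
        if not 0.0 <= self.target_C <= 1.0:
            raise ConfigurationError("target_C must lie in [0, 1]")
        if not 0.0 < self.target_PC <= 1.0:
            raise ConfigurationError("target_PC must lie in (0, 1]")

    @property
    def degree_models(self) -> tuple[DegreeModel, DegreeModel]:
        if isinstance(self.degree_model, DegreeModel):
            return (self.degree_model, self.degree_model)
        return tuple(self.degree_model)  # type: ignore[return-value]


@lru_cache(maxsize=128)
def _beta_param_for_pc(target_pc: float) -> float:
    """Solve for a in Beta(a, a) so that E[1 - 2|f - 1/2|] = target_pc.

    Closed form: E[PC] = 2 * I_{1/2}(a+1, a) with I the regularized
    incomplete beta function, increasing in a from 0 to 1.
    """
    def g(a: float) -> float:
        return 2.0 * float(special.betainc(a + 1.0, a, 0.5)) - target_pc

    hi = 1e4
    if g(hi) < 0:  # target so close to 1 that the split is essentially even
        return hi
    lo = 1e-6
    return float(optimize.brentq(g, lo, hi, xtol=1e-9))


def _ids(prefix: str, n: int) -> tuple[str, ...]:
    width = len(str(n))
    return tuple(f"{prefix}{i + 1:0{width}d}" for i in range(n))


def _weighted_sample(
    rng: Rng, candidates: list[str], weights: dict[str, float], k: int
) -> list[str]:
    w = np.array([weights[c] for c in candidates], dtype=float)
    w /= w.sum()
    idx = rng.choice(len(candidates), size=k, replace=False, p=w)
    return [candidates[i] for i in idx]


def _pc_of(k1: int, k2: int) -> float:
    return 2.0 * min(k1, k2) / (k1 + k2)


def _steer_mean_pc(
    adj: list[dict[str, set[str]]],
    connectors: Sequence[str],
    eligible: list[set[str]],
    rewirable: Sequence[int],
    target: float,
    rng: Rng,
    tol: float = 0.02,
    max_iter: int = 3000,
) -> None:
    """Greedy single-edge rewiring of the connectors' layer split.

    ``adj[l]`` maps resource -> set of consumers in layer ``l``.  Moves an
    edge from one resource to another within a rewirable layer (consumer
    degrees are untouched) whenever that shifts the connector-PC mean
    towards the target.  Connectors never drop below one link per layer and
    edges only land on layer-eligible resources, so the connector set is
    invariant.
    """
    conn = list(connectors)
    if not conn:
        return
    conn_set = set(conn)

    def degs(p: str) -> tuple[int, int]:
        return len(adj[0].get(p, ())), len(adj[1].get(p, ()))

    for _ in range(max_iter):
        pcs = {p: _pc_of(*degs(p)) for p in conn}
        mean = sum(pcs.values()) / len(conn)
        if abs(mean - target) <= tol:
            return
        best: tuple[float, int, str, str] | None = None
        for layer in rewirable:
            other = 1 - layer
            for p in eligible[layer]:
                kp = len(adj[layer].get(p, ()))
                min_keep = 1 if p in conn_set else 0
                if kp <= min_keep:
                    continue
                d_p = 0.0
                if p in conn_set:
                    ks = degs(p)
                    new = list(ks)
                    new[layer] -= 1
                    d_p = _pc_of(*new) - pcs[p]
                for q in eligible[layer]:
                    if q == p:
                        continue
                    d_q = 0.0
                    if q in conn_set:
                        ks = degs(q)
                        new = list(ks)
                        new[layer] += 1
                        d_q = _pc_of(*new) - pcs[q]
                    gain = (d_p + d_q) * (1.0 if target > mean else -1.0)
                    if gain > 1e-12 and (best is None or gain > best[0]):
                        # a consumer of p not already on q must exist
                        movable = adj[layer].get(p, set()) - adj[layer].get(q, set())
                        if movable:
                            best = (gain, layer, p, q)
        if best is None:
            return
        _, layer, p, q = best
        movable = sorted(adj[layer][p] - adj[layer].get(q, set()))
        c = movable[int(rng.integers(len(movable)))]
        adj[layer][p].discard(c)
        adj[layer].setdefault(q, set()).add(c)


def generate(config: GeneratorConfig) -> TripartiteNetwork:
    """Draw one random tripartite network from the configuration.

    Fully reproducible from ``config.seed``; the same configuration and
    seed always yield the same network.
    """
    rng = np.random.default_rng(config.seed)
    if config.topology == "fan":
        net = _generate_fan(config, rng)
    else:
        net = _generate_chain(config, rng)
    if config.weighted:
        net = assign_weights(net, config.concentration, rng=rng)
    return net


def _generate_fan(config: GeneratorConfig, rng: Rng) -> TripartiteNetwork:
    n_p, n_a, n_b = config.sizes
    plants = _ids("p", n_p)
    cons = [_ids("a", n_a), _ids("b", n_b)]
    n_conn = int(np.floor(config.target_C * n_p + 0.5))
    conn_idx = rng.choice(n_p, size=n_conn, replace=False)
    connectors = [plants[i] for i in sorted(conn_idx)]
    conn_set = set(connectors)
    others = [p for p in plants if p not in conn_set]
    side = rng.integers(2, size=len(others))
    eligible = [set(connectors), set(connectors)]
    for p, s in zip(others, side):
        eligible[int(s)].add(p)
    if not eligible[0] or not eligible[1]:
        raise GenerationError(
            "a layer has no eligible plants; raise target_C or the plant count"
        )

    a = _beta_param_for_pc(config.target_PC)
    split = {p: float(rng.beta(a, a)) for p in connectors}
    layer_weight = [
        {p: (2.0 * split[p] if p in conn_set else 1.0) for p in eligible[0]},
        {p: (2.0 * (1.0 - split[p]) if p in conn_set else 1.0) for p in eligible[1]},
    ]
    for w in layer_weight:
        for p in w:
            w[p] = max(w[p], 1e-6)

    adj: list[dict[str, set[str]]] = [{}, {}]
    dms = config.degree_models
    for li in (0, 1):
        cands = sorted(eligible[li])
        degrees = dms[li].sample(len(cons[li]), len(cands), rng)
        assigned: dict[str, set[str]] = {c: set() for c in cons[li]}
        # one forced consumer per connector so the connector count is exact
        for p in connectors:
            c = cons[li][int(rng.integers(len(cons[li])))]
            assigned[c].add(p)
            adj[li].setdefault(p, set()).add(c)
        for c, k in zip(cons[li], degrees):
            need = int(k) - len(assigned[c])
            if need <= 0:
                continue
            pool = [p for p in cands if p not in assigned[c]]
            take = _weighted_sample(rng, pool, layer_weight[li], min(need, len(pool)))
            for p in take:
                assigned[c].add(p)
                adj[li].setdefault(p, set()).add(c)

    _steer_mean_pc(adj, connectors, eligible, (0, 1), config.target_PC, rng)

    layers = [
        Layer(
            name=f"layer{li + 1}",
            sign=config.signs[li],
            resource_set="plants",
            consumer_set=("set_a", "set_b")[li],
            edges=frozenset(
                (p, c) for p, cs in adj[li].items() for c in cs
            ),
        )
        for li in (0, 1)
    ]
    return TripartiteNetwork(
        sets=[
            SpeciesSet("plants", plants),
            SpeciesSet("set_a", cons[0]),
            SpeciesSet("set_b", cons[1]),
        ],
        layers=layers,
        name=f"synthetic_fan_seed{config.seed}",
    )


def _generate_chain(config: GeneratorConfig, rng: Rng) -> TripartiteNetwork:
    n_p, n_h, n_q = config.sizes
    plants = _ids("p", n_p)
    shared = _ids("h", n_h)
    top = _ids("q", n_q)
    n_conn = int(np.floor(config.target_C * n_h + 0.5))
    if n_conn < 1:
        raise GenerationError(
            "chain topology needs at least one connector (target_C too small)"
        )
    dms = config.degree_models

    # layer 1: every shared species consumes >=1 plant.  The largest degree
    # draws go to the connectors-to-be (random ties): generalist consumers
    # tend to be the connectors in empirical webs, and it widens the range
    # of connector-PC means the layer-2 steering can reach.
    draws = sorted((int(k) for k in dms[0].sample(n_h, n_p, rng)), reverse=True)
    order = list(rng.permutation(n_h))
    connectors = sorted(shared[i] for i in order[:n_conn])
    ranked = [shared[i] for i in order]  # connectors first, then the rest
    k1 = {h: k for h, k in zip(ranked, draws)}
    conn_set = set(connectors)
    adj1: dict[str, set[str]] = {}
    for h in shared:
        take = rng.choice(n_p, size=k1[h], replace=False)
        for i in take:
            adj1.setdefault(plants[i], set()).add(h)

    # layer 2: top consumers attach only to designated connectors
    adj2: dict[str, set[str]] = {}
    weight = {h: float(max(k1[h], 1e-6)) for h in connectors}
    degrees2 = dms[1].sample(n_q, n_conn, rng)
    assigned: dict[str, set[str]] = {q: set() for q in top}
    for h in connectors:
        q = top[int(rng.integers(n_q))]
        assigned[q].add(h)
        adj2.setdefault(h, set()).add(q)
    for q, k in zip(top, degrees2):
        need = int(k) - len(assigned[q])
        if need <= 0:
            continue
        pool = [h for h in connectors if h not in assigned[q]]
        take = _weighted_sample(rng, pool, weight, min(need, len(pool)))
        for h in take:
            assigned[q].add(h)
            adj2.setdefault(h, set()).add(q)

    # steering can only rewire layer 2 (layer-1 degrees are the shared
    # species' own consumption draws); adj[l] maps shared species -> its
    # neighbours in that layer, which is all the PC computation needs
    adj_shared: list[dict[str, set[str]]] = [
        {h: {p for p, hs in adj1.items() if h in hs} for h in shared},
        adj2,
    ]
    _steer_mean_pc(
        adj_shared, connectors, [set(shared), conn_set], (1,), config.target_PC, rng
    )

    layers = [
        Layer(
            name="herbivory",
            sign=config.signs[0],
            resource_set="plants",
            consumer_set="shared",
            edges=frozenset(
                (p, h) for h, ps in adj_shared[0].items() for p in ps
            ),
        ),
        Layer(
            name="parasitism",
            sign=config.signs[1],
            resource_set="shared",
            consumer_set="top",
            edges=frozenset(
                (h, q) for h, qs in adj_shared[1].items() for q in qs
            ),
        ),
    ]
    return TripartiteNetwork(
        sets=[
            SpeciesSet("plants", plants),
            SpeciesSet("shared", shared),
            SpeciesSet("top", top),
        ],
        layers=layers,
        name=f"synthetic_chain_seed{config.seed}",
    )


def assign_weights(
    net: TripartiteNetwork,
    concentration: float = 1.0,
    seed: Optional[int] = None,
    rng: Optional[Rng] = None,
) -> TripartiteNetwork:
    """Attach per-consumer dependency weights from a symmetric Dirichlet.

    Each consumer's weights over its resource links sum to 1; a consumer
    with a single resource depends on it fully.  Large ``concentration``
    approaches an even 1/k split; small values concentrate dependence on
    one resource.
    """
    if net.is_weighted:
        raise ConfigurationError("network is already weighted")
    if concentration <= 0:
        raise ConfigurationError("concentration must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    new_layers = []
    for layer in net.layers:
        by_consumer: dict[str, list[str]] = {}
        for r, c in layer.edges:
            by_consumer.setdefault(c, []).append(r)
        weights: dict[Edge, float] = {}
        for c in net.get_set(layer.consumer_set).members:
            res = sorted(by_consumer.get(c, []))
            if not res:
                warnings.warn(
                    f"layer {layer.name!r}: consumer {c!r} has no resources; skipped",
                    stacklevel=2,
                )
                continue
            w = rng.dirichlet(np.full(len(res), concentration))
            for r, wi in zip(res, w):
                weights[(r, c)] = max(float(wi), 1e-300)  # guard exact-0 draws
        new_layers.append(
            Layer(
                name=layer.name,
                sign=layer.sign,
                resource_set=layer.resource_set,
                consumer_set=layer.consumer_set,
                edges=layer.edges,
                weights=weights,
            )
        )
    return TripartiteNetwork(sets=net.sets, layers=new_layers, name=net.name)
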