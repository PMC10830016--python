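"""Coextinction simulation and robustness of tripartite networks.

Plants (the basal set) are removed one at a time in a given *extinction
sequence*; animals are under bottom-up control and go secondarily extinct
when they have lost all their resource links.  In fan-topology networks
(plants shared by, e.g., pollinators and herbivores) one plant removal can
cause *simultaneous* losses in both animal sets; in chain-topology networks
(plants - herbivores - parasitoids) losses *cascade* upward.  Both cases are
realized by one rule: a species dies when its last resource link disappears,
and its own disappearance severs the links of whatever consumes it.

Robustness ``R`` is the area under the curve of surviving animal fraction
versus fraction of plants removed, computed by the trapezoid rule on the
piecewise-linear curve through all P+1 points, starting at (0, 1).  R is
near 1 for a robust community and tends to 0 when the sequence tears the
community down immediately.  A step-function variant is available for
sensitivity analyses.

A stochastic variant uses per-link dependency weights: when resource ``j``
disappears, consumer ``i`` dies with probability ``R_i * d_ij`` (intrinsic
demographic dependence times interaction weight); loss of all resources
still kills deterministically.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .errors import ConfigurationError, DomainError, StructuralError
from .model import BipartiteNetwork, TripartiteNetwork, split_bipartite

Rng = np.random.Generator

STRATEGIES = ("random", "degree_desc", "degree_asc", "custom")


@dataclass(frozen=True)
class ExtinctionSequence:
    """An order in which the basal (plant) species are removed."""

    order: tuple[str, ...]
    strategy: str = "custom"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "order", tuple(self.order))
        if len(set(self.order)) != len(self.order):
            raise ConfigurationError("extinction sequence repeats a species")

    def position_of(self, plant: str) -> int:
        """1-based position of a plant in the sequence."""
        return self.order.index(plant) + 1


@dataclass(frozen=True)
class ExtinctionTrajectory:
    """Survivor counts per species set after each removal step.

    ``survivors[set_name][m]`` is the count after ``m`` removals
    (``m = 0 .. P``); step 0 holds the initial counts.  Only species with at
    least one resource link at the outset are counted (resource-less species
    cannot undergo secondary extinction, so by default they are excluded
    from both numerator and denominator).
    """

    removed_fraction: tuple[float, ...]
    survivors: Mapping[str, tuple[int, ...]]

    @property
    def n_steps(self) -> int:
        return len(self.removed_fraction) - 1

    def initial(self, scope: str = "whole") -> int:
        if scope == "whole":
            return sum(v[0] for v in self.survivors.values())
        return self.survivors[scope][0]

    def curve(self, scope: str = "whole") -> np.ndarray:
        """Surviving fraction at each step for one scope."""
        n0 = self.initial(scope)
        if n0 == 0:
            raise DomainError(f"scope {scope!r} has no initially supported species")
        if scope == "whole":
            counts = np.sum([v for v in self.survivors.values()], axis=0)
        else:
            counts = np.asarray(self.survivors[scope])
        return counts / n0


@dataclass(frozen=True)
class RobustnessRecord:
    """Robustness statistics for one extinction sequence."""

    R: float
    R_per_set: Mapping[str, float]
    R_L: Optional[float] = None
    R_S: Optional[float] = None


@dataclass(frozen=True)
class StochasticParams:
    """Parameters of the stochastic coextinction variant.

    ``intrinsic_dependence`` maps set name -> R_i in [0, 1]; unspecified
    sets default to 1 for non-basal (animal) sets and 0 for the basal set,
    preserving bottom-up control.  ``renormalize`` redistributes a
    consumer's dependencies over its surviving resources after each loss;
    the default keeps baseline dependencies fixed.
    """

    intrinsic_dependence: Optional[Mapping[str, float]] = None
    renormalize: bool = False

    def r_for(self, net: TripartiteNetwork, set_name: str) -> float:
        if self.intrinsic_dependence and set_name in self.intrinsic_dependence:
            r = float(self.intrinsic_dependence[set_name])
        else:
            r = 0.0 if set_name == net.basal_set.name else 1.0
        if not 0.0 <= r <= 1.0:
            raise ConfigurationError(f"intrinsic dependence for {set_name!r} not in [0,1]")
        return r


@dataclass
class EnsembleResult:
    """Robustness records over many extinction sequences of one network."""

    network: str
    sequences: list[ExtinctionSequence]
    records: list[RobustnessRecord]
    seed: Optional[int] = None

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    def series(self, scope: str) -> np.ndarray:
        """Per-sequence robustness for one scope.

        ``scope`` is ``"whole"``, a set name, ``"R_L"`` or ``"R_S"``.
        """
        if scope == "whole":
            return np.array([rec.R for rec in self.records])
        if scope == "R_L":
            return np.array(
                [math.nan if rec.R_L is None else rec.R_L for rec in self.records]
            )
        if scope == "R_S":
            return np.array(
                [math.nan if rec.R_S is None else rec.R_S for rec in self.records]
            )
        return np.array([rec.R_per_set[scope] for rec in self.records])


# ---------------------------------------------------------------------- #
# Sequences
# ---------------------------------------------------------------------- #


def make_sequence(
    net: TripartiteNetwork,
    strategy: str = "random",
    rng: Optional[Rng] = None,
    order: Optional[Sequence[str]] = None,
) -> ExtinctionSequence:
    """Build an extinction sequence over the basal set.

    ``random`` draws a uniform permutation; ``degree_desc``/``degree_asc``
    sort by *initial* total plant degree (most/least connected first) with
    ties randomized; ``custom`` uses the given ``order`` verbatim.
    """
    basal = net.basal_set.members
    if not basal:
        raise StructuralError("empty basal set")
    if strategy == "custom":
        if order is None:
            raise ConfigurationError("custom strategy requires an explicit order")
        if sorted(order) != sorted(basal):
            raise ConfigurationError("custom order is not a permutation of the basal set")
        return ExtinctionSequence(order=tuple(order), strategy="custom")
    if strategy not in STRATEGIES:
        raise ConfigurationError(f"unknown strategy {strategy!r}")
    if rng is None:
        rng = np.random.default_rng()
    if strategy == "random":
        perm = rng.permutation(len(basal))
        return ExtinctionSequence(
            order=tuple(basal[i] for i in perm), strategy="random"
        )
    degs = net.total_degrees()
    tiebreak = {m: rng.random() for m in basal}
    sign = -1 if strategy == "degree_desc" else 1
    ordered = sorted(basal, key=lambda m: (sign * degs[m], tiebreak[m]))
    return ExtinctionSequence(order=tuple(ordered), strategy=strategy)


# ---------------------------------------------------------------------- #
# Deterministic simulation
# ---------------------------------------------------------------------- #


def _consumer_maps(
    net: TripartiteNetwork,
) -> tuple[dict[str, set[str]], dict[str, list[str]], dict[str, str]]:
    """Resource sets of every supported non-basal species, reverse map, set of each."""
    basal = net.basal_set.name
    resources: dict[str, set[str]] = {}
    set_of: dict[str, str] = {}
    for s in net.sets:
        if s.name == basal:
            continue
        for m in s.members:
            res = set(net.resources_of(m))
            if res:
                resources[m] = res
                set_of[m] = s.name
    dependents: dict[str, list[str]] = {}
    for consumer, res in resources.items():
        for r in res:
            dependents.setdefault(r, []).append(consumer)
    return resources, dependents, set_of


def simulate(
    net: TripartiteNetwork, sequence: ExtinctionSequence
) -> ExtinctionTrajectory:
    """Deterministic bottom-up coextinction along one sequence.

    At each step the next plant and its links are removed; any species left
    with zero resource links goes extinct, cascading to its own consumers
    until a fixed point.
    """
    basal = net.basal_set.members
    if sorted(sequence.order) != sorted(basal):
        raise ConfigurationError("sequence is not a permutation of the basal set")
    resources, dependents, set_of = _consumer_maps(net)
    remaining = {c: len(res) for c, res in resources.items()}
    alive = {c: True for c in resources}
    counts = {s.name: 0 for s in net.non_basal_sets}
    for c, sname in set_of.items():
        counts[sname] += 1

    P = len(basal)
    traj: dict[str, list[int]] = {name: [counts[name]] for name in counts}
    for plant in sequence.order:
        queue = [plant]
        while queue:
            gone = queue.pop()
            for consumer in dependents.get(gone, ()):
                if not alive[consumer]:
                    continue
                remaining[consumer] -= 1
                if remaining[consumer] == 0:
                    alive[consumer] = False
                    counts[set_of[consumer]] -= 1
                    queue.append(consumer)
        for name in traj:
            traj[name].append(counts[name])
    return ExtinctionTrajectory(
        removed_fraction=tuple(m / P for m in range(P + 1)),
        survivors={name: tuple(v) for name, v in traj.items()},
    )


def _area(y: np.ndarray, method: str) -> float:
    P = len(y) - 1
    if P == 0:
        raise DomainError("trajectory has no removal steps")
    if method == "trapezoid":
        return float(np.trapezoid(y, dx=1.0 / P))
    if method == "step":
        return float(np.sum(y[1:]) / P)
    raise ValueError(f"unknown area method {method!r}")


def robustness(
    traj: ExtinctionTrajectory, scope: str = "whole", method: str = "trapezoid"
) -> float:
    """Area under the surviving-fraction curve for one scope.

    ``scope="whole"`` pools all non-basal species irrespective of set; a set
    name restricts to that set (fractions relative to the set's own initial
    count).  Values lie in [0, 1]; 0 means maximal impact.
    """
    return _area(traj.curve(scope), method)


def robustness_record(
    net: TripartiteNetwork,
    sequence: ExtinctionSequence,
    method: str = "trapezoid",
    include_bipartite: bool = True,
) -> RobustnessRecord:
    """All robustness scopes (whole, per set, per bipartite) for one sequence."""
    traj = simulate(net, sequence)
    per_set = {
        s.name: robustness(traj, s.name, method)
        for s in net.non_basal_sets
        if traj.survivors[s.name][0] > 0
    }
    r_l = r_s = None
    if include_bipartite:
        r_l, r_s = bipartite_robustness(net, sequence, method)
    return RobustnessRecord(
        R=robustness(traj, "whole", method), R_per_set=per_set, R_L=r_l, R_S=r_s
    )


def _bipartite_r(
    part: BipartiteNetwork, sequence: ExtinctionSequence, method: str
) -> Optional[float]:
    """Robustness of one standalone bipartite network under the induced
    subsequence of its own resource species; None when it has no basal side."""
    if not part.contains_basal:
        return None
    present = set(part.resources)
    order = [p for p in sequence.order if p in present]
    P = len(order)
    if P == 0:
        return None
    res_of: dict[str, set[str]] = {}
    for r, c in part.edges:
        res_of.setdefault(c, set()).add(r)
    consumers = {c for c in part.consumers if res_of.get(c)}
    if not consumers:
        return None
    dependents: dict[str, list[str]] = {}
    remaining = {}
    for c in consumers:
        remaining[c] = len(res_of[c])
        for r in res_of[c]:
            dependents.setdefault(r, []).append(c)
    n_alive = len(consumers)
    y = [1.0]
    n0 = n_alive
    alive = {c: True for c in consumers}
    for plant in order:
        for c in dependents.get(plant, ()):
            if alive[c]:
                remaining[c] -= 1
                if remaining[c] == 0:
                    alive[c] = False
                    n_alive -= 1
        y.append(n_alive / n0)
    return _area(np.asarray(y), method)


def bipartite_robustness(
    net: TripartiteNetwork,
    sequence: ExtinctionSequence,
    method: str = "trapezoid",
) -> tuple[Optional[float], Optional[float]]:
    """(R_L, R_S): robustness of the larger and smaller bipartite network.

    Each layer is detached via :func:`~triweb.model.split_bipartite` and the
    removal protocol replayed on the plants present in that network (plants
    dropped by the split are skipped; the x-axis renormalizes to that
    network's own plant count).  In chain (e.g. AA) networks the layer with
    no plants has no plant-removal robustness and returns ``None``.
    """
    larger, smaller = split_bipartite(net)
    return (
        _bipartite_r(larger, sequence, method),
        _bipartite_r(smaller, sequence, method),
    )


def run_ensemble(
    net: TripartiteNetwork,
    n: int = 3000,
    strategy: str = "random",
    seed: Optional[Union[int, Rng]] = None,
    method: str = "trapezoid",
    include_bipartite: bool = True,
) -> EnsembleResult:
    """Simulate ``n`` extinction sequences and collect all robustness scopes."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sequences = [make_sequence(net, strategy, rng) for _ in range(n)]
    records = [
        robustness_record(net, seq, method, include_bipartite) for seq in sequences
    ]
    return EnsembleResult(
        network=net.name,
        sequences=sequences,
        records=records,
        seed=seed if isinstance(seed, int) else None,
    )


def run_exhaustive(
    net: TripartiteNetwork,
    method: str = "trapezoid",
    include_bipartite: bool = True,
) -> EnsembleResult:
    """Robustness over *all* P! extinction sequences (exact, small P only)."""
    basal = net.basal_set.members
    if len(basal) > 8:
        raise DomainError(f"{len(basal)}! sequences is too many to enumerate")
    sequences = [
        ExtinctionSequence(order=perm, strategy="custom")
        for perm in itertools.permutations(basal)
    ]
    records = [
        robustness_record(net, seq, method, include_bipartite) for seq in sequences
    ]
    return EnsembleResult(network=net.name, sequences=sequences, records=records)


# ---------------------------------------------------------------------- #
# Stochastic variant
# ---------------------------------------------------------------------- #


def simulate_stochastic(
    net: TripartiteNetwork,
    sequence: ExtinctionSequence,
    params: Optional[StochasticParams] = None,
    rng: Optional[Rng] = None,
) -> ExtinctionTrajectory:
    """Stochastic coextinction: loss of resource j kills consumer i with
    probability ``R_i * d_ij``; loss of *all* resources kills outright.

    Requires a fully weighted network whose dependencies sum to 1 per
    consumer at baseline (see :func:`triweb.synth.assign_weights`).
    Dependencies are not renormalized after partial loss unless
    ``params.renormalize`` is set.
    """
    if params is None:
        params = StochasticParams()
    if rng is None:
        rng = np.random.default_rng()
    if not net.is_weighted:
        raise ConfigurationError("stochastic simulation requires a weighted network")
    basal = net.basal_set.members
    if sorted(sequence.order) != sorted(basal):
        raise ConfigurationError("sequence is not a permutation of the basal set")

    # dependency of consumer i on resource j, pooled over layers
    dep: dict[str, dict[str, float]] = {}
    for layer in net.layers:
        assert layer.weights is not None
        for (r, c), w in layer.weights.items():
            dep.setdefault(c, {})[r] = w
    basal_name = net.basal_set.name
    set_of = {
        m: s.name for s in net.non_basal_sets for m in s.members if m in dep
    }
    r_i = {m: params.r_for(net, sname) for m, sname in set_of.items()}

    dependents: dict[str, list[str]] = {}
    for c, res in dep.items():
        for r in res:
            dependents.setdefault(r, []).append(c)
    for r in dependents:
        dependents[r].sort()  # deterministic draw order given the rng

    alive = {c: True for c in set_of}
    counts = {s.name: 0 for s in net.non_basal_sets}
    for c, sname in set_of.items():
        counts[sname] += 1
    P = len(basal)
    traj: dict[str, list[int]] = {name: [counts[name]] for name in counts}

    def kill(species: str, queue: list[str]) -> None:
        alive[species] = False
        counts[set_of[species]] -= 1
        queue.append(species)

    for plant in sequence.order:
        queue = [plant]
        while queue:
            gone = queue.pop()
            for consumer in dependents.get(gone, ()):
                if not alive[consumer]:
                    continue
                d = dep[consumer].pop(gone, None)
                if d is None:
                    continue
                if not dep[consumer]:
                    kill(consumer, queue)  # lost every resource
                    continue
                if rng.random() < r_i[consumer] * d:
                    kill(consumer, queue)
                elif params.renormalize:
                    total = sum(dep[consumer].values())
                    for k in dep[consumer]:
                        dep[consumer][k] /= total
        for name in traj:
            traj[name].append(counts[name])
    return ExtinctionTrajectory(
        removed_fraction=tuple(m / P for m in range(P + 1)),
        survivors={name: tuple(v) for name, v in traj.items()},
    )
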