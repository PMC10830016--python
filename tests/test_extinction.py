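"""Coextinction simulation, robustness statistics, stochastic variant."""

import itertools

import numpy as np
import pytest

import triweb as tw
from triweb.errors import ConfigurationError, DomainError
from triweb.model import Layer, SpeciesSet


class TestSequences:
    def test_degree_targeting(self, net_ma_small):
        rng = np.random.default_rng(0)
        desc = tw.make_sequence(net_ma_small, "degree_desc", rng)
        asc = tw.make_sequence(net_ma_small, "degree_asc", rng)
        assert desc.order[0] == "p2"  # degree 3
        assert asc.order[0] == "p1"   # degree 1

    def test_random_is_reproducible(self, fan_net):
        s1 = tw.make_sequence(fan_net, "random", np.random.default_rng(9))
        s2 = tw.make_sequence(fan_net, "random", np.random.default_rng(9))
        assert s1.order == s2.order

    def test_custom_must_be_permutation(self, net_ma_small):
        with pytest.raises(ConfigurationError):
            tw.make_sequence(net_ma_small, "custom", order=("p1", "p2"))

    def test_unknown_strategy(self, net_ma_small):
        with pytest.raises(ConfigurationError):
            tw.make_sequence(net_ma_small, "betweenness")


class TestSimulate:
    def test_hand_trajectory_fan(self, net_ma_small):
        seq = tw.make_sequence(net_ma_small, "custom", order=("p2", "p1", "p3"))
        traj = tw.simulate(net_ma_small, seq)
        whole = np.sum([traj.survivors[s] for s in traj.survivors], axis=0)
        assert list(whole) == [4, 3, 2, 0]

    def test_hand_trajectory_chain_cascade(self, net_aa_chain):
        seq = tw.make_sequence(net_aa_chain, "custom", order=("p1",))
        traj = tw.simulate(net_aa_chain, seq)
        assert traj.survivors["herbivores"] == (1, 0)
        assert traj.survivors["parasitoids"] == (1, 0)

    def test_step_zero_is_initial_counts(self, fan_net):
        seq = tw.make_sequence(fan_net, "random", np.random.default_rng(1))
        traj = tw.simulate(fan_net, seq)
        for s in fan_net.non_basal_sets:
            supported = sum(1 for m in s.members if fan_net.resources_of(m))
            assert traj.survivors[s.name][0] == supported

    def test_survivors_never_increase(self, fan_net, chain_net):
        for net in (fan_net, chain_net):
            seq = tw.make_sequence(net, "random", np.random.default_rng(2))
            traj = tw.simulate(net, seq)
            for counts in traj.survivors.values():
                assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestRobustness:
    def test_hand_values(self, net_ma_small):
        seq = tw.make_sequence(net_ma_small, "custom", order=("p2", "p1", "p3"))
        traj = tw.simulate(net_ma_small, seq)
        assert tw.robustness(traj) == pytest.approx(7 / 12)
        assert tw.robustness(traj, "pollinators") == pytest.approx(1 / 3)
        assert tw.robustness(traj, "herbivores") == pytest.approx(5 / 6)

    def test_disjoint_halves_give_half(self):
        # pollinator on p1 only, herbivore on p2 only: any order gives R = 0.5
        net = tw.TripartiteNetwork(
            sets=[
                SpeciesSet("P", ("p1", "p2")),
                SpeciesSet("A", ("a1",)),
                SpeciesSet("B", ("b1",)),
            ],
            layers=[
                Layer("l1", "+", "P", "A", frozenset({("p1", "a1")})),
                Layer("l2", "-", "P", "B", frozenset({("p2", "b1")})),
            ],
        )
        for order in itertools.permutations(("p1", "p2")):
            traj = tw.simulate(net, tw.make_sequence(net, "custom", order=order))
            assert tw.robustness(traj) == pytest.approx(0.5)

    def test_maximal_robustness_closed_form(self):
        # all consumers generalists on every plant: nothing dies until the
        # last removal, so R = 1 - 1/(2P) under the trapezoid rule
        P = 5
        plants = tuple(f"p{i}" for i in range(P))
        net = tw.TripartiteNetwork(
            sets=[
                SpeciesSet("P", plants),
                SpeciesSet("A", ("a1",)),
                SpeciesSet("B", ("b1",)),
            ],
            layers=[
                Layer("l1", "+", "P", "A", frozenset((p, "a1") for p in plants)),
                Layer("l2", "-", "P", "B", frozenset((p, "b1") for p in plants)),
            ],
        )
        seq = tw.make_sequence(net, "custom", order=plants)
        traj = tw.simulate(net, seq)
        assert tw.robustness(traj) == pytest.approx(1 - 1 / (2 * P))
        # the step-function variant excludes the triangle under the last drop
        assert tw.robustness(traj, method="step") == pytest.approx(1 - 1 / P)

    def test_whole_between_per_set_extremes(self, fan_net, chain_net):
        rng = np.random.default_rng(3)
        for net in (fan_net, chain_net):
            for _ in range(5):
                traj = tw.simulate(net, tw.make_sequence(net, "random", rng))
                per_set = [
                    tw.robustness(traj, s.name) for s in net.non_basal_sets
                ]
                r = tw.robustness(traj)
                assert min(per_set) - 1e-12 <= r <= max(per_set) + 1e-12
                assert 0.0 <= r <= 1.0

    def test_empty_scope_is_domain_error(self, net_ma_small):
        seq = tw.make_sequence(net_ma_small, "custom", order=("p1", "p2", "p3"))
        traj = tw.simulate(net_ma_small, seq)
        with pytest.raises(KeyError):
            traj.curve("no_such_set")


class TestBipartiteRobustness:
    def test_fixture_hand_values(self, net_ma_small):
        seq = tw.make_sequence(net_ma_small, "custom", order=("p2", "p1", "p3"))
        r_l, r_s = tw.bipartite_robustness(net_ma_small, seq)
        # pollination bipartite replays (p2, p1): R = 0.5
        # herbivory bipartite replays (p2, p3): R = 0.75
        assert r_l == pytest.approx(0.5)
        assert r_s == pytest.approx(0.75)

    def test_chain_parasitism_layer_undefined(self, net_aa_chain):
        seq = tw.make_sequence(net_aa_chain, "custom", order=("p1",))
        r_l, r_s = tw.bipartite_robustness(net_aa_chain, seq)
        assert r_l == pytest.approx(0.5)
        assert r_s is None


class TestEnsembles:
    def test_reproducible_from_seed(self, net_ma_small):
        e1 = tw.run_ensemble(net_ma_small, n=50, seed=8)
        e2 = tw.run_ensemble(net_ma_small, n=50, seed=8)
        assert [s.order for s in e1.sequences] == [s.order for s in e2.sequences]
        assert np.array_equal(e1.series("whole"), e2.series("whole"))

    def test_length_one(self, net_ma_small):
        assert tw.run_ensemble(net_ma_small, n=1, seed=0).n_sequences == 1

    def test_monte_carlo_matches_enumeration(self, net_ma_small):
        exact = tw.run_exhaustive(net_ma_small)
        mc = tw.run_ensemble(net_ma_small, n=600, seed=13)
        for scope in ("whole", "pollinators", "herbivores"):
            mu = exact.series(scope).mean()
            sample = mc.series(scope)
            se = sample.std(ddof=1) / np.sqrt(len(sample))
            assert abs(sample.mean() - mu) <= 3 * se + 1e-12


class TestStochastic:
    def test_degenerate_weights_reproduce_deterministic(self, net_aa_chain):
        net = tw.assign_weights(net_aa_chain, seed=0)
        seq = tw.make_sequence(net, "custom", order=("p1",))
        det = tw.simulate(net, seq)
        sto = tw.simulate_stochastic(net, seq, rng=np.random.default_rng(5))
        assert sto.survivors == det.survivors

    def test_single_resource_fan_reduction(self):
        # every consumer depends on exactly one plant: d = 1 everywhere, so
        # the stochastic rule fires with probability 1 and both simulators
        # agree step for step
        plants = ("p1", "p2", "p3")
        net = tw.TripartiteNetwork(
            sets=[
                SpeciesSet("P", plants),
                SpeciesSet("A", ("a1", "a2", "a3")),
                SpeciesSet("B", ("b1", "b2", "b3")),
            ],
            layers=[
                Layer("l1", "+", "P", "A",
                      frozenset({("p1", "a1"), ("p2", "a2"), ("p3", "a3")})),
                Layer("l2", "-", "P", "B",
                      frozenset({("p1", "b1"), ("p2", "b2"), ("p3", "b3")})),
            ],
        )
        net = tw.assign_weights(net, seed=0)
        for perm in itertools.permutations(plants):
            seq = tw.make_sequence(net, "custom", order=perm)
            det = tw.simulate(net, seq)
            sto = tw.simulate_stochastic(net, seq, rng=np.random.default_rng(1))
            assert sto.survivors == det.survivors

    def test_zero_intrinsic_dependence_means_topological_only(self, fan_net):
        net = tw.assign_weights(fan_net, seed=2)
        seq = tw.make_sequence(net, "random", np.random.default_rng(3))
        params = tw.StochasticParams(
            intrinsic_dependence={s.name: 0.0 for s in net.non_basal_sets}
        )
        det = tw.simulate(net, seq)
        sto = tw.simulate_stochastic(net, seq, params, np.random.default_rng(4))
        assert sto.survivors == det.survivors

    def test_unweighted_network_rejected(self, fan_net):
        seq = tw.make_sequence(fan_net, "random", np.random.default_rng(0))
        with pytest.raises(ConfigurationError):
            tw.simulate_stochastic(fan_net, seq)

    def test_half_dependency_survival_frequency(self):
        net = _two_plant_shared_consumer()
        rng = np.random.default_rng(21)
        survived = 0
        n = 4000
        seq = tw.make_sequence(net, "custom", order=("p1", "p2"))
        for _ in range(n):
            traj = tw.simulate_stochastic(net, seq, rng=rng)
            survived += traj.survivors["A"][1]  # after removing p1 only
        freq = survived / n
        se = np.sqrt(0.25 / n)
        assert abs(freq - 0.5) <= 3 * se


def _two_plant_shared_consumer() -> tw.TripartiteNetwork:
    """Consumer a1 depends on p1 and p2 with d = (1/2, 1/2) exactly."""
    return tw.TripartiteNetwork(
        sets=[
            SpeciesSet("P", ("p1", "p2")),
            SpeciesSet("A", ("a1",)),
            SpeciesSet("B", ("b1",)),
        ],
        layers=[
            Layer("l1", "+", "P", "A",
                  frozenset({("p1", "a1"), ("p2", "a1")}),
                  weights={("p1", "a1"): 0.5, ("p2", "a1"): 0.5}),
            Layer("l2", "-", "P", "B", frozenset({("p2", "b1")}),
                  weights={("p2", "b1"): 1.0}),
        ],
    )
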