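"""Interdependence, plant importance, driver classes, regressions, t-tests."""

import numpy as np
import pandas as pd
import pytest

import triweb as tw
from triweb.errors import DomainError
from triweb.model import Layer, SpeciesSet


class TestInterdependence:
    def test_mirror_network_perfect_correlation(self, net_sym):
        ens = tw.run_exhaustive(net_sym)
        pairs = sorted(
            zip(ens.series("setA").round(12), ens.series("setB").round(12))
        )
        assert pairs == [(0.5, 0.5), (0.75, 0.75)]
        assert tw.interdependence(ens).I == pytest.approx(1.0)

    def test_constant_series_flagged_undefined(self, net_aa_chain):
        ens = tw.run_exhaustive(net_aa_chain)  # single plant: one sequence
        ens.sequences *= 2
        ens.records *= 2
        res = tw.interdependence(ens)
        assert not res.defined
        assert res.I is None

    def test_disjoint_halves_brute_force(self):
        # layers on disjoint plant pairs: the two animal sets' robustness
        # responds to different plants, so I cannot be positive.  At this
        # tiny size the anti-coupling is exact: each specialist dies when
        # its plant does, and the halves compete for early slots, giving
        # I = -1 by exhaustive enumeration (24 sequences).
        net = tw.TripartiteNetwork(
            sets=[
                SpeciesSet("P", ("p1", "p2", "p3", "p4")),
                SpeciesSet("A", ("a1", "a2")),
                SpeciesSet("B", ("b1", "b2")),
            ],
            layers=[
                Layer("l1", "+", "P", "A",
                      frozenset({("p1", "a1"), ("p2", "a2")})),
                Layer("l2", "-", "P", "B",
                      frozenset({("p3", "b1"), ("p4", "b2")})),
            ],
        )
        ens = tw.run_exhaustive(net)
        res = tw.interdependence(ens)
        assert res.I == pytest.approx(-1.0)

    def test_symmetric_in_set_order(self, net_keystone):
        ens = tw.run_exhaustive(net_keystone)
        a, b = ens.series("setA"), ens.series("setB")
        r_ab = np.corrcoef(a, b)[0, 1]
        assert tw.interdependence(ens).I == pytest.approx(r_ab)

    def test_spearman_option(self, net_keystone):
        ens = tw.run_exhaustive(net_keystone)
        res = tw.interdependence(ens, method="spearman")
        assert res.method == "spearman"
        assert -1 <= res.I <= 1


class TestImportance:
    def test_keystone_plant_ranks_first(self, net_keystone):
        ens = tw.run_exhaustive(net_keystone)
        imp = tw.plant_importance(ens, "whole")
        assert imp.ranks["p1"] == 1
        assert imp.scores["p1"] < imp.scores["p2"]
        assert imp.scores["p1"] < imp.scores["p3"]

    def test_private_support_plants_swap_between_sets(self, net_keystone):
        # p2 only supports setA (via a1); p3 only supports setB (via b1)
        ens = tw.run_exhaustive(net_keystone)
        imp_a = tw.plant_importance(ens, "setA")
        imp_b = tw.plant_importance(ens, "setB")
        assert imp_a.ranks["p2"] < imp_a.ranks["p3"]
        assert imp_b.ranks["p3"] < imp_b.ranks["p2"]

    def test_tied_scores_break_by_id(self):
        # fabricated ensemble in which robustness depends only on where
        # plant z falls, so x and y get identical scores by symmetry
        orders = [("x", "y", "z"), ("y", "x", "z"), ("z", "x", "y"), ("z", "y", "x")]
        r_values = [0.9, 0.9, 0.3, 0.3]  # sequences starting with z are harmful
        ens = tw.EnsembleResult(
            network="toy",
            sequences=[
                tw.ExtinctionSequence(order=o, strategy="custom") for o in orders
            ],
            records=[
                tw.RobustnessRecord(R=r, R_per_set={}) for r in r_values
            ],
        )
        imp = tw.plant_importance(ens, "whole")
        assert imp.scores["x"] == pytest.approx(imp.scores["y"])
        assert imp.ranks["z"] == 1  # early z means low robustness
        assert imp.ranking() == ["z", "x", "y"]  # ids break the x/y tie

    def test_duplicate_sequences_leave_scores_unchanged(self, net_keystone):
        ens = tw.run_exhaustive(net_keystone)
        doubled = tw.EnsembleResult(
            network=ens.network,
            sequences=ens.sequences * 2,
            records=ens.records * 2,
        )
        a = tw.plant_importance(ens, "whole")
        b = tw.plant_importance(doubled, "whole")
        for p in a.scores:
            assert a.scores[p] == pytest.approx(b.scores[p])
        assert a.ranks == b.ranks

    def test_ranks_are_permutation_and_anticorrelate_with_scores(self, fan_net):
        ens = tw.run_ensemble(fan_net, n=150, seed=17, include_bipartite=False)
        imp = tw.plant_importance(ens, "whole")
        P = len(fan_net.basal_set)
        assert sorted(imp.ranks.values()) == list(range(1, P + 1))
        scores = np.array([imp.scores[p] for p in sorted(imp.scores)])
        ranks = np.array([imp.ranks[p] for p in sorted(imp.scores)])
        if len(set(scores)) == len(scores):
            assert np.corrcoef(np.argsort(np.argsort(scores)) + 1, ranks)[0, 1] == pytest.approx(1.0)

    def test_single_sequence_rejected(self, net_ma_small):
        ens = tw.run_ensemble(net_ma_small, n=1, seed=0)
        with pytest.raises(DomainError):
            tw.plant_importance(ens)


class TestDriverClassification:
    def _imp(self, scope, ranks):
        scores = {p: float(r) for p, r in ranks.items()}
        return tw.ImportanceResult(scope=scope, scores=scores, ranks=ranks)

    def test_identical_ranking_is_driven(self):
        whole = self._imp("whole", {"p1": 1, "p2": 2, "p3": 3})
        per_set = {
            "A": self._imp("A", {"p1": 1, "p2": 2, "p3": 3}),
            "B": self._imp("B", {"p1": 3, "p2": 1, "p3": 2}),
        }
        res = tw.driver_classification(whole, per_set)
        assert res.S["A"] == pytest.approx(1.0)
        assert res.category == "driven"

    def test_reversed_ranking_also_scores_one(self):
        # squared correlation is direction-blind; the flag records the sign
        whole = self._imp("whole", {"p1": 1, "p2": 2, "p3": 3})
        per_set = {
            "A": self._imp("A", {"p1": 3, "p2": 2, "p3": 1}),
            "B": self._imp("B", {"p1": 3, "p2": 2, "p3": 1}),
        }
        res = tw.driver_classification(whole, per_set)
        assert res.S["A"] == pytest.approx(1.0)
        assert res.category == "driven"
        assert res.negative_correlation == ("A", "B")

    def test_intermediate_similarity_is_mixed(self):
        whole = self._imp("whole", {"p1": 1, "p2": 2, "p3": 3, "p4": 4, "p5": 5})
        shuffled = {"p1": 2, "p2": 1, "p3": 4, "p4": 3, "p5": 5}  # r^2 = 0.64
        per_set = {
            "A": self._imp("A", shuffled),
            "B": self._imp("B", shuffled),
        }
        res = tw.driver_classification(whole, per_set)
        assert 0.5 < res.S["A"] < 0.9
        assert res.category == "mixed"

    def test_unrelated_rankings_are_emergent(self):
        whole = self._imp("whole", {"p1": 1, "p2": 2, "p3": 3, "p4": 4})
        per_set = {
            "A": self._imp("A", {"p1": 3, "p2": 4, "p3": 1, "p4": 2}),  # r^2 = 0.2^2
            "B": self._imp("B", {"p1": 2, "p2": 4, "p3": 3, "p4": 1}),
        }
        res = tw.driver_classification(whole, per_set)
        assert max(res.S.values()) < 0.5
        assert res.category == "emergent"

    def test_mismatched_plants_rejected(self):
        whole = self._imp("whole", {"p1": 1, "p2": 2})
        with pytest.raises(DomainError):
            tw.driver_classification(
                whole, {"A": self._imp("A", {"x1": 1, "x2": 2})}
            )


class TestCompositionFit:
    def test_exact_linear_recovery(self):
        rng = np.random.default_rng(0)
        rl = rng.uniform(0.3, 0.9, 20)
        rs = rng.uniform(0.3, 0.9, 20)
        df = pd.DataFrame({"R_L": rl, "R_S": rs, "R": 0.6 * rl + 0.4 * rs})
        fit = tw.composition_fit(df)
        assert fit.a == pytest.approx(0.6, abs=1e-10)
        assert fit.b == pytest.approx(0.4, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_two_predictors_beat_single(self):
        nets = [tw.generate(tw.GeneratorConfig(sizes=(15, 15, 15), seed=s))
                for s in range(12)]
        rows = []
        for net in nets:
            ens = tw.run_ensemble(net, n=40, seed=1)
            rows.append({
                "R": ens.series("whole").mean(),
                "R_L": np.nanmean(ens.series("R_L")),
                "R_S": np.nanmean(ens.series("R_S")),
            })
        df = pd.DataFrame(rows)
        both = tw.composition_fit(df)
        singles = tw.single_layer_fits(df)
        assert both.r_squared >= singles["R_L"].r_squared - 1e-12
        assert both.r_squared >= singles["R_S"].r_squared - 1e-12

    def test_too_few_rows_rejected(self):
        df = pd.DataFrame({"R": [0.5, 0.6], "R_L": [0.5, 0.7], "R_S": [0.4, 0.5]})
        with pytest.raises(DomainError):
            tw.composition_fit(df)


class TestFeatureRegression:
    def _features(self, n, rng):
        return pd.DataFrame({
            "heterogeneity": rng.uniform(0.2, 1.5, n),
            "C": rng.uniform(0.05, 0.9, n),
            "H_C": rng.uniform(0.0, 1.0, n),
            "PC_C": rng.uniform(0.1, 1.0, n),
        })

    def test_recovers_planted_predictor(self):
        rng = np.random.default_rng(5)
        feats = self._features(40, rng)
        z = (feats["H_C"] - feats["H_C"].mean()) / feats["H_C"].std(ddof=0)
        y = 0.7 * z + rng.normal(0, 0.1, 40)
        res = tw.feature_regression(feats, y)
        assert "H_C" in res.predictors
        assert 0.6 <= res.coefficients["H_C"] <= 0.8

    def test_pure_noise_has_low_adjusted_r2(self):
        rng = np.random.default_rng(6)
        vals = []
        for _ in range(5):
            feats = self._features(40, rng)
            y = rng.normal(size=40)
            vals.append(tw.feature_regression(feats, y).adj_r_squared)
        assert np.mean(vals) < 0.15

    def test_selection_is_deterministic(self):
        rng = np.random.default_rng(7)
        feats = self._features(30, rng)
        y = 0.5 * feats["C"] + rng.normal(0, 0.2, 30)
        r1 = tw.feature_regression(feats, y)
        r2 = tw.feature_regression(feats, y)
        assert r1.predictors == r2.predictors
        assert r1.aic == r2.aic
        assert len(r1.all_aic) == 15

    def test_minimal_aic_among_candidates(self):
        rng = np.random.default_rng(8)
        feats = self._features(30, rng)
        y = feats["PC_C"] + rng.normal(0, 0.3, 30)
        res = tw.feature_regression(feats, y)
        assert res.aic == min(res.all_aic.values())

    def test_constant_predictor_dropped(self):
        rng = np.random.default_rng(9)
        feats = self._features(30, rng)
        feats["C"] = 0.5
        y = feats["PC_C"] + rng.normal(0, 0.3, 30)
        with pytest.warns(UserWarning, match="constant predictor"):
            res = tw.feature_regression(feats, y)
        assert "C" not in res.predictors


class TestGroupComparison:
    def test_identical_groups(self):
        res = tw.compare_groups({"MA": [1.0, 2.0, 3.0], "AA": [1.0, 2.0, 3.0]})
        assert len(res) == 1
        assert res[0].t == pytest.approx(0.0)
        assert res[0].p == pytest.approx(1.0)
        assert res[0].stars == "ns"

    def test_separated_groups_are_significant(self):
        rng = np.random.default_rng(10)
        res = tw.compare_groups({
            "MA": rng.normal(0, 1, 30),
            "AA": rng.normal(5, 1, 30),
        })
        assert res[0].p < 1e-4
        assert res[0].stars == "****"

    def test_three_classes_give_three_pairs(self):
        rng = np.random.default_rng(11)
        res = tw.compare_groups({
            "MA": rng.normal(size=5), "AA": rng.normal(size=5),
            "MM": rng.normal(size=5),
        })
        assert len(res) == 3
        assert {(r.group_a, r.group_b) for r in res} == {
            ("AA", "MA"), ("AA", "MM"), ("MA", "MM")
        }

    def test_small_group_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            res = tw.compare_groups({"MA": [1.0, 2.0], "AA": [1.0]})
        assert res == []
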