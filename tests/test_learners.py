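"""Structure learners: recovery, constraints, determinism, degeneracies."""

import itertools

import numpy as np
import pandas as pd
import pytest

from bcnkit.exceptions import ConfigurationError, ConstraintConflictError
from bcnkit.graphs import (
    DAG,
    PDAG,
    ArcConstraintSet,
    consistent_extension,
    cpdag_of,
    enumerate_dags,
    is_acyclic,
)
from bcnkit.learners import (
    GrowShrink,
    HillClimbing,
    IAMB,
    LearnerConfig,
    MMHC,
    RSMax2,
    TabuSearch,
    hill_climb,
    mmpc_skeleton,
)
from bcnkit.scoring import GaussianSuffStats, LocalScoreCache, ScoreConfig, network_score

from conftest import DIAMOND, random_gaussian_sem

ALL_LEARNERS = [HillClimbing, TabuSearch, GrowShrink, IAMB, MMHC, RSMax2]
DIAMOND_CPDAG = cpdag_of(DIAMOND)


def chain_frame(seed: int, n: int = 5000, beta: float = 0.7) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    a = rng.normal(size=n)
    b = beta * a + np.sqrt(1 - beta**2) * rng.normal(size=n)
    c = beta * b + np.sqrt(1 - beta**2) * rng.normal(size=n)
    return pd.DataFrame({"A": a, "B": b, "C": c})


def collider_frame(seed: int, n: int = 5000) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    a = rng.normal(size=n)
    b = rng.normal(size=n)
    c = 0.6 * a + 0.6 * b + 0.5 * rng.normal(size=n)
    return pd.DataFrame({"A": a, "B": b, "C": c})


def equivalence_class(graph):
    if isinstance(graph, PDAG):
        graph = consistent_extension(graph)
    return cpdag_of(graph)


class TestScoreBased:
    def test_independent_noise_yields_empty_global_optimum(self, noise_data):
        frame = noise_data(0)
        est = HillClimbing().fit(frame)
        assert est.dag_.arcs == frozenset()
        # exhaustive oracle on a 4-column subset
        sub = frame.iloc[:, :4]
        cache = LocalScoreCache(GaussianSuffStats(sub), ScoreConfig())
        best = max(
            network_score(sub, g, cache=cache)
            for g in enumerate_dags(list(sub.columns))
        )
        est_sub = HillClimbing().fit(sub)
        assert est_sub.score_value_ == pytest.approx(best, abs=1e-9)

    def test_blacklisted_arc_never_returned(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=3000)
        y = 0.8 * x + 0.6 * rng.normal(size=3000)
        frame = pd.DataFrame({"X": x, "Y": y})
        cons = ArcConstraintSet(blacklist=[("X", "Y")])
        est = HillClimbing(constraints=cons).fit(frame)
        assert ("X", "Y") not in est.dag_.arcs
        assert ("Y", "X") in est.dag_.arcs  # dependence still represented

    def test_whitelisted_arc_always_present(self, noise_data):
        cons = ArcConstraintSet(whitelist=[("N0", "N1")])
        est = HillClimbing(constraints=cons).fit(noise_data(1))
        assert ("N0", "N1") in est.dag_.arcs

    def test_whitelist_cycle_rejected(self, noise_data):
        cons = ArcConstraintSet(
            whitelist=[("N0", "N1"), ("N1", "N2"), ("N2", "N0")]
        )
        with pytest.raises(ConstraintConflictError):
            HillClimbing(constraints=cons).fit(noise_data(2))

    def test_restarted_search_recovers_diamond_class(self, diamond_data):
        # the diamond has one deep spurious local optimum (fork plus an
        # extra edge) that a minority of restart draws fail to escape
        hits = 0
        for seed in range(10):
            est = HillClimbing(
                restarts=5, perturbations=5, random_state=seed
            ).fit(diamond_data(seed))
            hits += cpdag_of(est.dag_) == DIAMOND_CPDAG
        assert hits >= 8

    def test_random_start_requires_seed_in_config(self):
        with pytest.raises(ConfigurationError):
            LearnerConfig(algorithm="hc", start="random")

    def test_tabu_never_worse_than_hill_climbing(self, diamond_data):
        for seed in range(20):
            frame = diamond_data(seed, n=1000)
            hc = HillClimbing().fit(frame)
            tabu = TabuSearch().fit(frame)
            assert tabu.score_value_ >= hc.score_value_ - 1e-9

    def test_tabu_length_zero_degenerates_to_hill_climbing(self, diamond_data):
        frame = diamond_data(3)
        hc = HillClimbing().fit(frame)
        tabu = TabuSearch(tabu_length=0).fit(frame)
        assert tabu.score_value_ == pytest.approx(hc.score_value_)

    def test_tabu_beats_empty_graph(self, diamond_data):
        frame = diamond_data(1)
        est = TabuSearch().fit(frame)
        empty_score = network_score(frame, DAG(frame.columns, []))
        assert est.score_value_ >= empty_score


class TestConstraintBased:
    @pytest.mark.parametrize("cls", [GrowShrink, IAMB])
    def test_chain_skeleton_recovered(self, cls):
        pdag = cls().fit(chain_frame(0)).pdag_
        assert pdag.skeleton() == {("A", "B"), ("B", "C")}

    @pytest.mark.parametrize("cls", [GrowShrink, IAMB])
    def test_collider_orientation_recovered(self, cls):
        pdag = cls().fit(collider_frame(0)).pdag_
        assert ("A", "C") in pdag.directed_arcs
        assert ("B", "C") in pdag.directed_arcs

    @pytest.mark.parametrize("cls", [GrowShrink, IAMB])
    def test_false_edge_rate_on_noise(self, cls, noise_data):
        """Empty-graph data: expected false edges governed by alpha."""
        edges = 0
        trials = 30
        for seed in range(trials):
            pdag = cls().fit(noise_data(seed, n=1000)).pdag_
            edges += len(pdag.skeleton())
        # 10 pairs per trial at alpha 0.05 with AND-symmetry: a few percent
        assert edges / (trials * 10) < 0.08

    def test_fully_blacklisted_pair_absent_from_skeleton(self):
        frame = chain_frame(1)
        cons = ArcConstraintSet(blacklist=[("A", "B"), ("B", "A")])
        pdag = GrowShrink(constraints=cons).fit(frame).pdag_
        assert ("A", "B") not in pdag.skeleton()

    def test_one_direction_blacklist_resolves_orientation(self):
        frame = chain_frame(2)
        cons = ArcConstraintSet(blacklist=[("B", "A")])
        pdag = GrowShrink(constraints=cons).fit(frame).pdag_
        assert ("A", "B") in pdag.directed_arcs

    def test_markov_blankets_exposed(self):
        est = GrowShrink().fit(chain_frame(3))
        assert est.blankets_["A"] == {"B"}
        assert est.blankets_["B"] == {"A", "C"}


class TestHybrid:
    def test_mmpc_chain_skeleton(self):
        pdag = mmpc_skeleton(chain_frame(4))
        assert pdag.undirected_edges == {("A", "B"), ("B", "C")}
        assert pdag.directed_arcs == frozenset()

    def test_mmpc_complete_for_common_cause_with_huge_effects(self):
        rng = np.random.default_rng(8)
        w = rng.normal(size=4000)
        frame = pd.DataFrame({
            "A": w + 0.2 * rng.normal(size=4000),
            "B": w + 0.2 * rng.normal(size=4000),
            "C": w + 0.2 * rng.normal(size=4000),
        })
        pdag = mmpc_skeleton(frame)
        assert len(pdag.undirected_edges) == 3

    def test_blacklisted_pair_absent(self):
        cons = ArcConstraintSet(blacklist=[("A", "B"), ("B", "A")])
        pdag = mmpc_skeleton(chain_frame(5), constraints=cons)
        assert ("A", "B") not in pdag.undirected_edges

    def test_mmhc_arcs_within_skeleton(self):
        frame = random_gaussian_sem(3, n_nodes=5, n=1500)
        est = MMHC().fit(frame)
        for a, b in est.dag_.arcs:
            assert tuple(sorted((a, b))) in est.skeleton_ or \
                (a, b) in est.skeleton_ or (b, a) in est.skeleton_

    def test_empty_skeleton_returns_empty_dag(self, noise_data):
        est = MMHC().fit(noise_data(7, n=500, k=4))
        assert est.dag_.arcs == frozenset() or len(est.dag_.arcs) <= 1

    @pytest.mark.parametrize("cls", [MMHC, RSMax2])
    def test_diamond_class_recovery(self, cls, diamond_data):
        hits = sum(
            cpdag_of(cls().fit(diamond_data(seed)).dag_) == DIAMOND_CPDAG
            for seed in range(10)
        )
        assert hits >= 9

    def test_rsmax2_without_restrict_equals_hill_climbing(self, diamond_data):
        frame = diamond_data(6)
        hc = HillClimbing().fit(frame)
        rs = RSMax2(restrict="none").fit(frame)
        assert rs.dag_ == hc.dag_


class TestCrossCutting:
    def test_consistency_across_all_classes(self, diamond_data):
        """Strongly identified ground truth: every algorithm family lands
        in the true Markov equivalence class in >= 90% of seeds."""
        configs = [
            HillClimbing(restarts=5, perturbations=5, random_state=0),
            TabuSearch(),
            GrowShrink(),
            IAMB(),
            MMHC(),
            RSMax2(),
        ]
        for est in configs:
            hits = 0
            for seed in range(10):
                fitted = type(est)(**est.get_params()).fit(diamond_data(seed))
                try:
                    hits += equivalence_class(fitted.learned_graph()) == DIAMOND_CPDAG
                except Exception:
                    pass
            assert hits >= 9, type(est).__name__

    def test_determinism_same_data_same_graph(self):
        frame = random_gaussian_sem(17, n_nodes=6, n=800)
        for cls in ALL_LEARNERS:
            kw = {"random_state": 3} if cls in (HillClimbing, TabuSearch) else {}
            g1 = cls(**kw).fit(frame).learned_graph()
            g2 = cls(**kw).fit(frame).learned_graph()
            assert g1 == g2, cls.__name__

    def test_constraint_fuzz_no_violations(self, noise_data):
        """Random blacklists: no learner ever emits a forbidden arc or a
        cycle (reduced-size version of the full compliance sweep)."""
        frame = random_gaussian_sem(23, n_nodes=6, n=600)
        cols = list(frame.columns)
        rng = np.random.default_rng(23)
        pairs = list(itertools.permutations(cols, 2))
        for trial in range(5):
            k = int(rng.integers(1, 10))
            bl = [pairs[i] for i in rng.choice(len(pairs), k, replace=False)]
            cons = ArcConstraintSet(blacklist=bl)
            for cls in ALL_LEARNERS:
                g = cls(constraints=cons).fit(frame).learned_graph()
                directed = g.arcs if isinstance(g, DAG) else g.directed_arcs
                assert not (set(directed) & cons.blacklist)
                assert is_acyclic(directed, g.nodes)
                if isinstance(g, PDAG):
                    for e in g.undirected_edges:
                        assert not cons.pair_fully_blacklisted(*e)

    def test_functional_wrapper_matches_estimator(self, diamond_data):
        frame = diamond_data(9)
        assert hill_climb(frame) == HillClimbing().fit(frame).dag_
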