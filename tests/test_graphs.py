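"""Graph primitives: acyclicity, d-separation, enumeration, CPDAG,
consistent extension."""

import itertools

import numpy as np
import pytest

from bcnkit.exceptions import (
    CapacityError,
    ConstraintConflictError,
    ExtensionFailureError,
    InvalidInputError,
)
from bcnkit.graphs import (
    DAG,
    PDAG,
    ArcConstraintSet,
    consistent_extension,
    cpdag_of,
    d_separated,
    enumerate_dags,
    is_acyclic,
)

from conftest import brute_force_d_separated, random_dag


class TestAcyclicity:
    @pytest.mark.parametrize(
        "arcs, expected",
        [
            ([("A", "B"), ("B", "C"), ("A", "C")], True),
            ([("A", "B"), ("B", "C"), ("C", "A")], False),
            ([], True),
        ],
    )
    def test_examples(self, arcs, expected):
        nodes = [f"V{i}" for i in range(17)] if not arcs else "ABC"
        assert is_acyclic(arcs, nodes) is expected

    def test_unknown_node_rejected(self):
        with pytest.raises(InvalidInputError):
            is_acyclic([("A", "Z")], "ABC")

    def test_dag_constructor_rejects_cycles_and_antiparallel(self):
        with pytest.raises(InvalidInputError):
            DAG("ABC", [("A", "B"), ("B", "C"), ("C", "A")])
        with pytest.raises(InvalidInputError):
            DAG("AB", [("A", "B"), ("B", "A")])
        with pytest.raises(InvalidInputError):
            DAG("AB", [("A", "A")])


class TestDSeparation:
    def test_blocked_chain(self):
        chain = DAG("ABC", [("A", "B"), ("B", "C")])
        assert d_separated(chain, "A", "C", {"B"})
        assert not d_separated(chain, "A", "C", set())

    def test_conditioned_collider_opens_path(self):
        collider = DAG("ABC", [("A", "C"), ("B", "C")])
        assert d_separated(collider, "A", "B", set())
        assert not d_separated(collider, "A", "B", {"C"})

    def test_overlapping_query_rejected(self):
        chain = DAG("ABC", [("A", "B")])
        with pytest.raises(InvalidInputError):
            d_separated(chain, "A", "A", set())
        with pytest.raises(InvalidInputError):
            d_separated(chain, "A", "B", {"A"})

    def test_matches_path_enumeration_oracle(self):
        """All (x, y, z) queries on 200 random DAGs of <= 5 nodes agree
        with the naive blocking-rule oracle."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(3, 6))
            dag = random_dag(rng, n)
            nodes = dag.nodes
            for x, y in itertools.combinations(nodes, 2):
                rest = [v for v in nodes if v not in (x, y)]
                for k in range(len(rest) + 1):
                    for z in itertools.combinations(rest, k):
                        assert d_separated(dag, x, y, z) == \
                            brute_force_d_separated(dag, x, y, z)


class TestEnumeration:
    @pytest.mark.parametrize("n, count", [(1, 1), (2, 3), (3, 25), (4, 543)])
    def test_known_dag_counts(self, n, count):
        nodes = [f"V{i}" for i in range(n)]
        assert sum(1 for _ in enumerate_dags(nodes)) == count

    def test_capacity_guard(self):
        with pytest.raises(CapacityError):
            list(enumerate_dags([f"V{i}" for i in range(6)]))

    def test_each_dag_unique_and_constrained(self):
        cons = ArcConstraintSet(blacklist=[("A", "B")], whitelist=[("B", "C")])
        seen = set()
        for dag in enumerate_dags("ABC", cons):
            assert ("A", "B") not in dag.arcs
            assert ("B", "C") in dag.arcs
            assert dag.arcs not in seen
            seen.add(dag.arcs)
        # oracle: filter the unconstrained enumeration
        expected = sum(
            1 for d in enumerate_dags("ABC")
            if ("A", "B") not in d.arcs and ("B", "C") in d.arcs
        )
        assert len(seen) == expected


class TestCPDAG:
    def test_chain_fully_undirected(self):
        pdag = cpdag_of(DAG("ABC", [("A", "B"), ("B", "C")]))
        assert pdag.directed_arcs == frozenset()
        assert pdag.undirected_edges == {("A", "B"), ("B", "C")}

    def test_v_structure_compelled(self):
        pdag = cpdag_of(DAG("ABC", [("A", "C"), ("B", "C")]))
        assert pdag.directed_arcs == {("A", "C"), ("B", "C")}
        assert pdag.undirected_edges == frozenset()

    def test_single_arc_undirected(self):
        pdag = cpdag_of(DAG("AB", [("A", "B")]))
        assert pdag.undirected_edges == {("A", "B")}

    def test_equivalence_class_sizes_match_enumeration(self):
        """Chain CPDAG groups exactly the 3 Markov-equivalent DAGs."""
        chain_class = [
            d for d in enumerate_dags("ABC")
            if cpdag_of(d) == cpdag_of(DAG("ABC", [("A", "B"), ("B", "C")]))
        ]
        assert len(chain_class) == 3

    def test_meek_closure_orients_compelled_arc(self):
        # A -> B, B - C with A, C nonadjacent: rule 1 compels B -> C
        dag = DAG("ABC", [("A", "B"), ("B", "C")])
        # the compelled situation appears in DAGs like A->B->C plus a
        # v-structure upstream; check via a 4-node example
        g = DAG("ABCD", [("A", "C"), ("B", "C"), ("C", "D")])
        pdag = cpdag_of(g)
        assert ("C", "D") in pdag.directed_arcs
        del dag


class TestConsistentExtension:
    def test_single_undirected_edge_deterministic(self):
        pdag = PDAG("AB", undirected=[("A", "B")])
        ext1 = consistent_extension(pdag)
        ext2 = consistent_extension(pdag)
        assert ext1 == ext2
        assert len(ext1.arcs) == 1

    def test_fully_directed_identity(self):
        pdag = PDAG("ABC", directed=[("A", "B"), ("B", "C")])
        assert consistent_extension(pdag).arcs == {("A", "B"), ("B", "C")}

    def test_no_extension_raises(self):
        # chordless undirected 4-cycle: every acyclic orientation creates
        # a collider between two nonadjacent neighbours
        square = PDAG(
            "ABCD",
            undirected=[("A", "B"), ("B", "C"), ("C", "D"), ("A", "D")],
        )
        with pytest.raises(ExtensionFailureError):
            consistent_extension(square)

    def test_round_trip_preserves_equivalence_class(self):
        """Extension of a CPDAG lands in the source DAG's class."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            dag = random_dag(rng, int(rng.integers(3, 6)))
            pdag = cpdag_of(dag)
            ext = consistent_extension(pdag)
            assert cpdag_of(ext) == pdag

    def test_cpdag_idempotent_through_extension(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            dag = random_dag(rng, int(rng.integers(3, 7)))
            c = cpdag_of(dag)
            assert cpdag_of(consistent_extension(c)) == c


class TestArcConstraintSet:
    def test_blacklist_whitelist_overlap_rejected(self):
        with pytest.raises(ConstraintConflictError):
            ArcConstraintSet(blacklist=[("A", "B")], whitelist=[("A", "B")])

    def test_both_orientations_whitelisted_rejected(self):
        with pytest.raises(ConstraintConflictError):
            ArcConstraintSet(whitelist=[("A", "B"), ("B", "A")])

    def test_csv_round_trip(self, tmp_path):
        cons = ArcConstraintSet(blacklist=[("X", "Y"), ("B", "A")])
        path = tmp_path / "bl.csv"
        path.write_text(cons.blacklist_csv())
        again = ArcConstraintSet.from_csv(str(path))
        assert again.blacklist == cons.blacklist

    def test_bad_header_rejected(self, tmp_path):
        path = tmp_path / "bl.csv"
        path.write_text("source,target\nA,B\n")
        with pytest.raises(InvalidInputError):
            ArcConstraintSet.from_csv(str(path))


class TestExports:
    def test_dot_and_tsv_contain_arcs(self):
        dag = DAG("AB", [("A", "B")])
        assert '"A" -> "B"' in dag.to_dot()
        assert "A\tB" in dag.arc_tsv()

    def test_graphml_round_trip(self, tmp_path):
        import networkx as nx

        dag = DAG("ABC", [("A", "B"), ("B", "C")])
        path = tmp_path / "g.graphml"
        dag.to_graphml(str(path))
        g = nx.read_graphml(str(path))
        assert set(g.edges()) == {("A", "B"), ("B", "C")}
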