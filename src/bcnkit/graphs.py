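"""Directed and partially directed graphs over named variables.

Graphs are defined over variable *names* (case-sensitive strings), not
integer indices, so that blacklists and whitelists expressed as ordered
name pairs are unambiguous.  :class:`DAG` and :class:`PDAG` are immutable
value objects; structure-learning code builds mutable adjacency structures
internally and converts at the boundary.

Besides the two graph classes this module provides the exact primitives
the learners and the test oracles rely on: acyclicity, d-separation,
exhaustive DAG enumeration (small n only), the CPDAG of a DAG (v-structures
plus Meek-rule closure) and the Dor–Tarsi consistent extension of a PDAG.
"""

from __future__ import annotations

import itertools
from collections.abc import Iterable, Iterator
from typing import Optional

import networkx as nx

from .exceptions import (
    CapacityError,
    ConstraintConflictError,
    ExtensionFailureError,
    InvalidInputError,
)

Arc = tuple[str, str]

__all__ = [
    "DAG",
    "PDAG",
    "ArcConstraintSet",
    "is_acyclic",
    "d_separated",
    "enumerate_dags",
    "cpdag_of",
    "consistent_extension",
]


def _check_arcs(arcs: Iterable[Arc], nodes: tuple[str, ...]) -> frozenset[Arc]:
    node_set = set(nodes)
    arc_set = frozenset((str(a), str(b)) for a, b in arcs)
    for a, b in arc_set:
        if a not in node_set or b not in node_set:
            raise InvalidInputError(f"arc ({a!r}, {b!r}) references an unknown node")
        if a == b:
            raise InvalidInputError(f"self-loop on {a!r}")
    return arc_set


class DAG:
    """An immutable directed acyclic graph over named nodes.

    Parameters
    ----------
    nodes : iterable of str
        Variable names; order is preserved and used for deterministic
        iteration and tie-breaking (lexicographic order of names governs
        all tie-breaks elsewhere in the package).
    arcs : iterable of (parent, child) pairs
        Directed arcs.  Self-loops, antiparallel pairs and cycles raise
        :class:`~bcnkit.exceptions.InvalidInputError`.
    """

    __slots__ = ("_nodes", "_arcs", "_parents", "_children")

    def __init__(self, nodes: Iterable[str], arcs: Iterable[Arc] = ()) -> None:
        self._nodes = tuple(dict.fromkeys(str(n) for n in nodes))
        arc_set = _check_arcs(arcs, self._nodes)
        for a, b in arc_set:
            if (b, a) in arc_set:
                raise InvalidInputError(f"antiparallel arcs between {a!r} and {b!r}")
        if not is_acyclic(arc_set, self._nodes):
            raise InvalidInputError("arc set contains a directed cycle")
        self._arcs = arc_set
        self._parents: dict[str, frozenset[str]] = {n: frozenset() for n in self._nodes}
        self._children: dict[str, frozenset[str]] = {n: frozenset() for n in self._nodes}
        pa: dict[str, set[str]] = {n: set() for n in self._nodes}
        ch: dict[str, set[str]] = {n: set() for n in self._nodes}
        for a, b in arc_set:
            pa[b].add(a)
            ch[a].add(b)
        self._parents = {n: frozenset(pa[n]) for n in self._nodes}
        self._children = {n: frozenset(ch[n]) for n in self._nodes}

    @property
    def nodes(self) -> tuple[str, ...]:
        return self._nodes

    @property
    def arcs(self) -> frozenset[Arc]:
        return self._arcs

    def parents(self, node: str) -> frozenset[str]:
        try:
            return self._parents[node]
        except KeyError:
            raise InvalidInputError(f"unknown node {node!r}") from None

    def children(self, node: str) -> frozenset[str]:
        try:
            return self._children[node]
        except KeyError:
            raise InvalidInputError(f"unknown node {node!r}") from None

    def adjacent(self, x: str, y: str) -> bool:
        return (x, y) in self._arcs or (y, x) in self._arcs

    def topological_order(self) -> list[str]:
        """A topological order; ties broken lexicographically."""
        g = self.to_networkx()
        return list(nx.lexicographical_topological_sort(g))

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self._nodes)
        g.add_edges_from(sorted(self._arcs))
        return g

    def sorted_arcs(self) -> list[Arc]:
        return sorted(self._arcs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DAG):
            return NotImplemented
        return set(self._nodes) == set(other._nodes) and self._arcs == other._arcs

    def __hash__(self) -> int:
        return hash((frozenset(self._nodes), self._arcs))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"DAG(nodes={len(self._nodes)}, arcs={sorted(self._arcs)})"

    # ---------------------------------------------------------------- export
    def to_dot(self) -> str:
        """Graphviz DOT serialization (plain digraph, one arc per line)."""
        lines = ["digraph G {"]
        for n in self._nodes:
            lines.append(f'  "{n}";')
        for a, b in self.sorted_arcs():
            lines.append(f'  "{a}" -> "{b}";')
        lines.append("}")
        return "\n".join(lines) + "\n"

    def to_graphml(self, path: str) -> None:
        nx.write_graphml(self.to_networkx(), path)

    def arc_tsv(self) -> str:
        """Arc list as TSV text with a ``parent\\tchild`` header."""
        lines = ["parent\tchild"]
        lines.extend(f"{a}\t{b}" for a, b in self.sorted_arcs())
        return "\n".join(lines) + "\n"


class PDAG:
    """A partially directed acyclic graph (directed arcs plus undirected edges).

    Intermediate output of the constraint-based learners and the canonical
    representation of a Markov equivalence class (CPDAG).  Undirected edges
    are stored as sorted 2-tuples.
    """

    __slots__ = ("_nodes", "_directed", "_undirected")

    def __init__(
        self,
        nodes: Iterable[str],
        directed: Iterable[Arc] = (),
        undirected: Iterable[Arc] = (),
    ) -> None:
        self._nodes = tuple(dict.fromkeys(str(n) for n in nodes))
        d = _check_arcs(directed, self._nodes)
        u_raw = _check_arcs(undirected, self._nodes)
        u = frozenset(tuple(sorted(e)) for e in u_raw)
        for a, b in d:
            if (b, a) in d:
                raise InvalidInputError(f"antiparallel directed arcs {a!r}/{b!r}")
            if tuple(sorted((a, b))) in u:
                raise InvalidInputError(
                    f"edge {a!r}-{b!r} both directed and undirected"
                )
        self._directed = d
        self._undirected = u

    @property
    def nodes(self) -> tuple[str, ...]:
        return self._nodes

    @property
    def directed_arcs(self) -> frozenset[Arc]:
        return self._directed

    @property
    def undirected_edges(self) -> frozenset[Arc]:
        return self._undirected

    def skeleton(self) -> frozenset[Arc]:
        """All edges as unordered (sorted) pairs."""
        return frozenset(tuple(sorted(e)) for e in self._directed) | self._undirected

    def adjacent(self, x: str, y: str) -> bool:
        return tuple(sorted((x, y))) in self.skeleton()

    def is_fully_directed(self) -> bool:
        return not self._undirected

    def to_dag(self) -> DAG:
        if self._undirected:
            raise InvalidInputError("PDAG has undirected edges; use consistent_extension")
        return DAG(self._nodes, self._directed)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PDAG):
            return NotImplemented
        return (
            set(self._nodes) == set(other._nodes)
            and self._directed == other._directed
            and self._undirected == other._undirected
        )

    def __hash__(self) -> int:
        return hash((frozenset(self._nodes), self._directed, self._undirected))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"PDAG(nodes={len(self._nodes)}, directed={sorted(self._directed)}, "
            f"undirected={sorted(self._undirected)})"
        )

    # ---------------------------------------------------------------- export
    def to_dot(self) -> str:
        lines = ["digraph G {"]
        for n in self._nodes:
            lines.append(f'  "{n}";')
        for a, b in sorted(self._directed):
            lines.append(f'  "{a}" -> "{b}";')
        for a, b in sorted(self._undirected):
            lines.append(f'  "{a}" -> "{b}" [dir=none];')
        lines.append("}")
        return "\n".join(lines) + "\n"

    def to_graphml(self, path: str) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self._nodes)
        for a, b in sorted(self._directed):
            g.add_edge(a, b, directed=True)
        for a, b in sorted(self._undirected):
            g.add_edge(a, b, directed=False)
        nx.write_graphml(g, path)

    def arc_tsv(self) -> str:
        lines = ["parent\tchild\tdirected"]
        lines.extend(f"{a}\t{b}\ttrue" for a, b in sorted(self._directed))
        lines.extend(f"{a}\t{b}\tfalse" for a, b in sorted(self._undirected))
        return "\n".join(lines) + "\n"


class ArcConstraintSet:
    """Blacklisted and whitelisted ordered arcs restricting structure search.

    A blacklisted arc may never appear in a learned graph; a whitelisted
    arc must always appear.  The same ordered pair cannot be both.
    """

    __slots__ = ("blacklist", "whitelist")

    def __init__(
        self,
        blacklist: Iterable[Arc] = (),
        whitelist: Iterable[Arc] = (),
    ) -> None:
        bl = frozenset((str(a), str(b)) for a, b in blacklist)
        wl = frozenset((str(a), str(b)) for a, b in whitelist)
        for a, b in bl | wl:
            if a == b:
                raise InvalidInputError(f"self-loop constraint on {a!r}")
        overlap = bl & wl
        if overlap:
            raise ConstraintConflictError(
                f"arcs both blacklisted and whitelisted: {sorted(overlap)}"
            )
        for a, b in wl:
            if (b, a) in wl:
                raise ConstraintConflictError(
                    f"both orientations of {a!r}/{b!r} whitelisted"
                )
        self.blacklist = bl
        self.whitelist = wl

    def allows(self, arc: Arc) -> bool:
        return arc not in self.blacklist

    def pair_fully_blacklisted(self, x: str, y: str) -> bool:
        return (x, y) in self.blacklist and (y, x) in self.blacklist

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ArcConstraintSet):
            return NotImplemented
        return self.blacklist == other.blacklist and self.whitelist == other.whitelist

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ArcConstraintSet(blacklist={sorted(self.blacklist)}, "
            f"whitelist={sorted(self.whitelist)})"
        )

    # ------------------------------------------------------------------ I/O
    @staticmethod
    def _read_pairs(path: str) -> list[Arc]:
        import csv

        pairs: list[Arc] = []
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or [
                f.strip().lower() for f in reader.fieldnames[:2]
            ] != ["from", "to"]:
                raise InvalidInputError(
                    f"{path}: expected a CSV header starting with 'from,to'"
                )
            for row in reader:
                pairs.append((row["from"].strip(), row["to"].strip()))
        return pairs

    @classmethod
    def from_csv(
        cls, blacklist_path: Optional[str] = None, whitelist_path: Optional[str] = None
    ) -> "ArcConstraintSet":
        bl = cls._read_pairs(blacklist_path) if blacklist_path else []
        wl = cls._read_pairs(whitelist_path) if whitelist_path else []
        return cls(bl, wl)

    def blacklist_csv(self) -> str:
        lines = ["from,to"]
        lines.extend(f"{a},{b}" for a, b in sorted(self.blacklist))
        return "\n".join(lines) + "\n"


EMPTY_CONSTRAINTS = ArcConstraintSet()


# ---------------------------------------------------------------------------
# exact primitives
# ---------------------------------------------------------------------------

def is_acyclic(arcs: Iterable[Arc], nodes: Iterable[str]) -> bool:
    """True iff ``arcs`` over ``nodes`` admits a topological order."""
    node_list = tuple(dict.fromkeys(str(n) for n in nodes))
    arc_set = _check_arcs(arcs, node_list)
    g = nx.DiGraph()
    g.add_nodes_from(node_list)
    g.add_edges_from(arc_set)
    return nx.is_directed_acyclic_graph(g)


def d_separated(dag: DAG, x: str, y: str, z: Iterable[str] = ()) -> bool:
    """Decide d-separation of ``x`` and ``y`` given conditioning set ``z``.

    Standard graphical criterion: every path between x and y must be
    blocked by z (a non-collider in z, or a collider whose descendants
    avoid z).
    """
    zs = frozenset(str(v) for v in z)
    if x == y or x in zs or y in zs:
        raise InvalidInputError("x, y and z must be disjoint")
    for v in (x, y, *zs):
        if v not in dag._parents:
            raise InvalidInputError(f"unknown node {v!r}")
    return nx.is_d_separator(dag.to_networkx(), {x}, {y}, set(zs))


def enumerate_dags(
    nodes: Iterable[str], constraints: Optional[ArcConstraintSet] = None
) -> Iterator[DAG]:
    """Yield every DAG on ``nodes`` satisfying ``constraints``, exactly once.

    Exhaustive (3^(n(n-1)/2) orientation patterns filtered for acyclicity),
    guarded to n <= 5; intended for exact-optimum test oracles, not for
    learning.
    """
    node_list = tuple(dict.fromkeys(str(n) for n in nodes))
    if len(node_list) > 5:
        raise CapacityError("enumerate_dags is limited to 5 nodes")
    cons = constraints or EMPTY_CONSTRAINTS
    pairs = list(itertools.combinations(sorted(node_list), 2))
    for pattern in itertools.product((0, 1, 2), repeat=len(pairs)):
        arcs: list[Arc] = []
        for (a, b), state in zip(pairs, pattern):
            if state == 1:
                arcs.append((a, b))
            elif state == 2:
                arcs.append((b, a))
        arc_set = set(arcs)
        if not cons.whitelist <= arc_set:
            continue
        if any(arc in cons.blacklist for arc in arc_set):
            continue
        if not is_acyclic(arc_set, node_list):
            continue
        yield DAG(node_list, arc_set)


# -------------------------------------------------------------- CPDAG / Meek

def _v_structures(dag: DAG) -> set[Arc]:
    """Arcs participating in a collider x -> z <- y with x, y nonadjacent."""
    compelled: set[Arc] = set()
    for z in dag.nodes:
        pa = sorted(dag.parents(z))
        for x, y in itertools.combinations(pa, 2):
            if not dag.adjacent(x, y):
                compelled.add((x, z))
                compelled.add((y, z))
    return compelled


def apply_meek_rules(
    nodes: tuple[str, ...],
    directed: set[Arc],
    undirected: set[Arc],
    forbidden: frozenset[Arc] = frozenset(),
) -> None:
    """Orient undirected edges in place by Meek's rules 1-3 until fixpoint.

    ``forbidden`` arcs (e.g. blacklisted orientations) are never created;
    an edge whose only compelled orientation is forbidden stays undirected
    and is resolved by the caller.  Rule 4 is omitted: it only fires in the
    presence of background-knowledge arcs that rules 1-3 cannot reach, a
    situation the learners here do not produce.
    """

    def adj(a: str, b: str) -> bool:
        return (
            (a, b) in directed
            or (b, a) in directed
            or tuple(sorted((a, b))) in undirected
        )

    changed = True
    while changed:
        changed = False
        for edge in sorted(undirected):
            for b, c in (edge, edge[::-1]):
                if (b, c) in forbidden:
                    continue
                orient = False
                # R1: a -> b, b - c, a and c nonadjacent  =>  b -> c
                for a, b2 in list(directed):
                    if b2 == b and a != c and not adj(a, c):
                        orient = True
                        break
                # R2: b -> k -> c and b - c  =>  b -> c
                if not orient:
                    for k in nodes:
                        if (b, k) in directed and (k, c) in directed:
                            orient = True
                            break
                # R3: b - a1, b - a2, a1 -> c, a2 -> c, a1/a2 nonadjacent, b - c
                if not orient:
                    ins = [a for a in nodes if (a, c) in directed]
                    for a1, a2 in itertools.combinations(sorted(ins), 2):
                        if (
                            tuple(sorted((b, a1))) in undirected
                            and tuple(sorted((b, a2))) in undirected
                            and not adj(a1, a2)
                        ):
                            orient = True
                            break
                if orient:
                    undirected.discard(edge)
                    directed.add((b, c))
                    changed = True
                    break
            if changed:
                break


def cpdag_of(dag: DAG) -> PDAG:
    """The completed PDAG (Markov equivalence class representative) of a DAG.

    Skeleton is preserved; v-structure arcs stay directed; the Meek-rule
    closure orients the remaining compelled arcs; everything else becomes
    undirected.
    """
    directed = _v_structures(dag)
    undirected = {
        tuple(sorted((a, b)))
        for a, b in dag.arcs
        if (a, b) not in directed and (b, a) not in directed
    }
    apply_meek_rules(dag.nodes, directed, undirected)
    return PDAG(dag.nodes, directed, undirected)


def consistent_extension(pdag: PDAG) -> DAG:
    """Orient all undirected edges of a PDAG without new v-structures or cycles.

    Dor–Tarsi procedure: repeatedly find a node x whose outgoing arcs are
    all absent in the remaining subgraph and whose undirected neighbours
    are adjacent to every other neighbour of x; orient x's undirected edges
    into x and remove x.  Candidate nodes are tried in lexicographic order
    so the extension is deterministic.

    Raises
    ------
    ExtensionFailureError
        If no consistent extension exists.
    """
    nodes = set(pdag.nodes)
    directed = set(pdag.directed_arcs)
    undirected = set(pdag.undirected_edges)
    oriented: set[Arc] = set(pdag.directed_arcs)

    def neighbours(x: str) -> set[str]:
        out = set()
        for a, b in directed:
            if a == x:
                out.add(b)
            elif b == x:
                out.add(a)
        for a, b in undirected:
            if a == x:
                out.add(b)
            elif b == x:
                out.add(a)
        return out

    while nodes:
        found = None
        for x in sorted(nodes):
            if any(a == x for a, _ in directed):  # x has outgoing arc
                continue
            und_nb = {
                (b if a == x else a) for a, b in undirected if x in (a, b)
            }
            nb = neighbours(x)
            ok = True
            for y in und_nb:
                nb_y = neighbours(y)
                if not (nb - {y}) <= (nb_y | {y}):
                    ok = False
                    break
            if ok:
                found = x
                break
        if found is None:
            raise ExtensionFailureError("PDAG admits no consistent extension")
        x = found
        for a, b in list(undirected):
            if x in (a, b):
                y = b if a == x else a
                oriented.add((y, x))
                undirected.discard((a, b))
        directed = {(a, b) for a, b in directed if x not in (a, b)}
        nodes.discard(x)

    return DAG(pdag.nodes, oriented)
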