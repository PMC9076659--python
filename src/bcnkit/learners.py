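"""Structure-learning algorithms over Gaussian cohort data.

Three algorithm families, all constraint-aware (blacklists forbid arcs,
whitelists force them):

* score-based  — greedy hill climbing and tabu search over single-arc
  add/delete/reverse moves, maximizing a decomposable BIC/AIC score;
* constraint-based — Grow-Shrink and IAMB Markov-blanket discovery,
  followed by neighbour identification, collider orientation and the
  Meek-rule closure; these return a :class:`~bcnkit.graphs.PDAG`;
* hybrid — restrict-maximize (RSMAX2): an MMPC skeleton restricts the
  arcs hill climbing may add; MMHC is RSMAX2 with the MMPC restrict phase.

Every learner is a scikit-learn estimator (``fit`` on a DataFrame or
:class:`~bcnkit.preprocess.CohortTable`, learned graph in ``dag_`` /
``pdag_``), so they compose with sklearn tooling; the module-level
functions (``hill_climb`` etc.) are thin wrappers driven by a
:class:`LearnerConfig`.

All searches work on sufficient statistics (means/covariance), so a
single fit on a ~600-subject, ~20-variable table takes milliseconds —
cheap enough for 10^3-10^4 bootstrap refits.

Determinism: all tie-breaks (move enumeration, blanket candidate order,
extension order) follow lexicographic variable order, and any randomness
(random starts, perturbation restarts) is driven by ``random_state``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .ci_tests import CI_METHODS, result_from_partial_r
from .exceptions import (
    CollinearityError,
    ConfigurationError,
    ConstraintConflictError,
    ExtensionFailureError,
    InvalidInputError,
)
from .graphs import (
    DAG,
    PDAG,
    ArcConstraintSet,
    EMPTY_CONSTRAINTS,
    apply_meek_rules,
    consistent_extension,
)
from .scoring import GaussianSuffStats, ScoreConfig

__all__ = [
    "LearnerConfig",
    "BaseStructureLearner",
    "HillClimbing",
    "TabuSearch",
    "GrowShrink",
    "IAMB",
    "MMHC",
    "RSMax2",
    "make_learner",
    "hill_climb",
    "tabu_search",
    "grow_shrink",
    "iamb",
    "mmpc_skeleton",
    "mmhc",
    "rsmax2",
]

_TOL = 1e-6  # minimal score improvement counted as an improvement
# score-equivalent moves are equal only to floating-point precision; deltas
# within _TIE are treated as exact ties and the lexicographically first
# move wins, keeping the search deterministic across platforms
_TIE = 1e-6

ALGORITHMS = ("hc", "tabu", "gs", "iamb", "mmhc", "rsmax2")


@dataclass(frozen=True)
class LearnerConfig:
    """Declarative description of one structure-learning configuration."""

    algorithm: str = "hc"
    score: str = "bic"
    ci_method: str = "mi-g"
    alpha: float = 0.05
    start: str = "empty"
    restarts: int = 0
    perturbations: int = 0
    tabu_length: int = 10
    seed: Optional[int] = None
    restrict_algorithm: str = "mmpc"
    max_cond_size: Optional[int] = None

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ConfigurationError(f"unknown algorithm {self.algorithm!r}")
        if self.ci_method not in CI_METHODS:
            raise ConfigurationError(f"unknown CI method {self.ci_method!r}")
        if self.start not in ("empty", "random"):
            raise ConfigurationError(f"unknown start {self.start!r}")
        if min(self.restarts, self.perturbations, self.tabu_length) < 0:
            raise ConfigurationError("counts must be non-negative")
        if self.start == "random" and self.seed is None:
            raise ConfigurationError("random start requires a seed")
        if self.restrict_algorithm not in ("mmpc", "none"):
            raise ConfigurationError(
                f"unknown restrict algorithm {self.restrict_algorithm!r}"
            )


# ---------------------------------------------------------------------------
# internal engines (integer-index, sufficient-statistics based)
# ---------------------------------------------------------------------------


class _IndexScorer:
    """Cached local scores on integer node indices."""

    def __init__(self, stats: GaussianSuffStats, cfg: ScoreConfig) -> None:
        self.stats = stats
        self.cfg = cfg
        self.cov = stats.cov
        self.n = stats.n
        self._cache: dict[tuple[int, frozenset[int]], float] = {}
        self._log_n = float(np.log(self.n))
        self._const = float(np.log(2.0 * np.pi)) + 1.0

    def score(self, node: int, parents: frozenset[int]) -> float:
        key = (node, parents)
        val = self._cache.get(key)
        if val is not None:
            return val
        cov = self.cov
        s_yy = cov[node, node]
        if parents:
            pidx = sorted(parents)
            s_pp = cov[np.ix_(pidx, pidx)]
            s_py = cov[pidx, node]
            try:
                np.linalg.cholesky(s_pp)
                coef = np.linalg.solve(s_pp, s_py)
            except np.linalg.LinAlgError:
                raise CollinearityError("collinear parent set") from None
            sigma2 = s_yy - float(s_py @ coef)
            if sigma2 <= s_yy * 1e-12:
                raise CollinearityError("vanishing residual variance")
        else:
            sigma2 = s_yy
        n = self.n
        loglik = -0.5 * n * (float(np.log(sigma2)) + self._const)
        k = len(parents) + 2
        if self.cfg.criterion == "bic":
            pen = 0.5 * k * self._log_n
        else:
            pen = float(k)
        val = loglik - pen
        self._cache[key] = val
        return val


class _CIEngine:
    """Cached conditional-independence p-values on integer indices."""

    def __init__(self, stats: GaussianSuffStats, method: str, alpha: float) -> None:
        self.cov = stats.cov
        self.n = stats.n
        self.method = method
        self.alpha = alpha
        self._cache: dict[tuple[int, int, frozenset[int]], float] = {}

    def p_value(self, x: int, y: int, z: frozenset[int]) -> float:
        if x > y:
            x, y = y, x
        key = (x, y, z)
        val = self._cache.get(key)
        if val is not None:
            return val
        cov = self.cov
        if z:
            iz = sorted(z)
            czz = cov[np.ix_(iz, iz)]
            cxz = cov[iz, x]
            cyz = cov[iz, y]
            try:
                np.linalg.cholesky(czz)
                sol = np.linalg.solve(czz, np.column_stack([cxz, cyz]))
            except np.linalg.LinAlgError:
                raise CollinearityError("collinear conditioning set") from None
            vx = cov[x, x] - float(cxz @ sol[:, 0])
            vy = cov[y, y] - float(cyz @ sol[:, 1])
            cxy = cov[x, y] - float(cxz @ sol[:, 1])
            if vx <= 0 or vy <= 0:
                raise CollinearityError("zero residual variance")
            r = cxy / float(np.sqrt(vx * vy))
        else:
            r = cov[x, y] / float(np.sqrt(cov[x, x] * cov[y, y]))
        r = float(np.clip(r, -1.0, 1.0))
        res = result_from_partial_r(r, self.n, len(z), self.method)
        self._cache[key] = res.p_value
        return res.p_value

    def dependent(self, x: int, y: int, z: frozenset[int]) -> bool:
        return self.p_value(x, y, z) < self.alpha


def _reachable(children: list[set[int]], src: int, dst: int) -> bool:
    """True iff a directed path src -> ... -> dst exists."""
    if src == dst:
        return True
    stack = [src]
    seen = {src}
    while stack:
        u = stack.pop()
        for v in children[u]:
            if v == dst:
                return True
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return False


class _GreedySearch:
    """Hill climbing / tabu search over add/delete/reverse arc moves."""

    def __init__(
        self,
        scorer: _IndexScorer,
        n_vars: int,
        blacklist: set[tuple[int, int]],
        whitelist: set[tuple[int, int]],
        restrict_pairs: Optional[set[tuple[int, int]]] = None,
        max_iter: int = 10_000,
    ) -> None:
        self.scorer = scorer
        self.nv = n_vars
        self.blacklist = blacklist
        self.whitelist = whitelist
        # restrict_pairs: unordered pairs (i<j) hill climbing may connect
        self.restrict_pairs = restrict_pairs
        self.max_iter = max_iter

    # -- state helpers ------------------------------------------------------
    def _init_state(self, arcs: Iterable[tuple[int, int]]):
        parents: list[set[int]] = [set() for _ in range(self.nv)]
        children: list[set[int]] = [set() for _ in range(self.nv)]
        for a, b in arcs:
            parents[b].add(a)
            children[a].add(b)
        return parents, children

    def _total(self, parents: list[set[int]]) -> float:
        return sum(
            self.scorer.score(v, frozenset(parents[v])) for v in range(self.nv)
        )

    def _pair_allowed(self, x: int, y: int) -> bool:
        if (x, y) in self.blacklist:
            return False
        if self.restrict_pairs is not None and (x, y) not in self.whitelist:
            key = (x, y) if x < y else (y, x)
            if key not in self.restrict_pairs:
                return False
        return True

    def _moves(self, parents, children):
        """Yield (delta, move) in lexicographic (parent, child) order."""
        score = self.scorer.score
        for x in range(self.nv):
            for y in range(self.nv):
                if x == y:
                    continue
                if x not in parents[y] and y not in parents[x]:
                    if not self._pair_allowed(x, y):
                        continue
                    if _reachable(children, y, x):
                        continue
                    base_y = score(y, frozenset(parents[y]))
                    delta = score(y, frozenset(parents[y] | {x})) - base_y
                    yield delta, ("add", x, y)
                elif x in parents[y]:
                    if (x, y) in self.whitelist:
                        continue
                    base_y = score(y, frozenset(parents[y]))
                    delta = score(y, frozenset(parents[y] - {x})) - base_y
                    yield delta, ("del", x, y)
                    # reversal = delete (x,y) + add (y,x)
                    if (y, x) in self.blacklist:
                        continue
                    children[x].discard(y)
                    cyc = _reachable(children, x, y)
                    children[x].add(y)
                    if cyc:
                        continue
                    base_x = score(x, frozenset(parents[x]))
                    delta_rev = (
                        delta
                        + score(x, frozenset(parents[x] | {y}))
                        - base_x
                    )
                    yield delta_rev, ("rev", x, y)

    @staticmethod
    def _apply(move, parents, children):
        kind, x, y = move
        if kind == "add":
            parents[y].add(x)
            children[x].add(y)
        elif kind == "del":
            parents[y].discard(x)
            children[x].discard(y)
        else:  # rev
            parents[y].discard(x)
            children[x].discard(y)
            parents[x].add(y)
            children[y].add(x)

    # -- searches -----------------------------------------------------------
    def hill_climb(self, start_arcs: Iterable[tuple[int, int]]):
        parents, children = self._init_state(start_arcs)
        total = self._total(parents)
        for _ in range(self.max_iter):
            best_delta, best_move = _TOL, None
            for delta, move in self._moves(parents, children):
                if delta > best_delta + _TIE:
                    best_delta, best_move = delta, move
            if best_move is None:
                break
            self._apply(best_move, parents, children)
            total += best_delta
        return parents, total

    def tabu(self, start_arcs, tabu_length: int, max_stagnant: int):
        parents, children = self._init_state(start_arcs)
        total = self._total(parents)

        def key(par):
            return frozenset(
                (x, y) for y in range(self.nv) for x in par[y]
            )

        best_parents = [set(p) for p in parents]
        best_total = total
        from collections import deque

        tabu_list: deque[frozenset] = deque(maxlen=max(tabu_length, 1))
        tabu_list.append(key(parents))
        stagnant = 0
        for _ in range(self.max_iter):
            best_delta, best_move = -np.inf, None
            for delta, move in self._moves(parents, children):
                if delta <= best_delta + _TIE:
                    continue
                self._apply(move, parents, children)
                k = key(parents)
                self._undo(move, parents, children)
                if tabu_length > 0 and k in tabu_list:
                    continue
                best_delta, best_move = delta, move
            if best_move is None:
                break
            self._apply(best_move, parents, children)
            total += best_delta
            if tabu_length > 0:
                tabu_list.append(key(parents))
            if total > best_total + _TOL:
                best_total = total
                best_parents = [set(p) for p in parents]
                stagnant = 0
            else:
                stagnant += 1
                if stagnant >= max_stagnant:
                    break
        return best_parents, best_total

    @staticmethod
    def _undo(move, parents, children):
        kind, x, y = move
        if kind == "add":
            parents[y].discard(x)
            children[x].discard(y)
        elif kind == "del":
            parents[y].add(x)
            children[x].add(y)
        else:
            parents[x].discard(y)
            children[y].discard(x)
            parents[y].add(x)
            children[x].add(y)

    # -- starts -------------------------------------------------------------
    def whitelist_arcs(self) -> list[tuple[int, int]]:
        parents, children = self._init_state(self.whitelist)
        for x, y in self.whitelist:
            children[x].discard(y)
            cyc = _reachable(children, y, x)
            children[x].add(y)
            if cyc:
                raise ConstraintConflictError("whitelist forces a cycle")
        return sorted(self.whitelist)

    def random_start(self, rng: np.random.Generator) -> list[tuple[int, int]]:
        """Sparse random DAG: random topological order, each admissible
        forward arc included with probability 2/(V-1), whitelist repaired in."""
        order = list(rng.permutation(self.nv))
        pos = {v: i for i, v in enumerate(order)}
        p = 2.0 / max(self.nv - 1, 1)
        arcs = set(self.whitelist_arcs())
        parents, children = self._init_state(arcs)
        for i, u in enumerate(order):
            for v in order[i + 1:]:
                if (u, v) in arcs or (v, u) in arcs:
                    continue
                if not self._pair_allowed(u, v):
                    continue
                if rng.random() >= p:
                    continue
                if _reachable(children, v, u):
                    continue  # repair: skip arcs that would close a cycle
                arcs.add((u, v))
                parents[v].add(u)
                children[u].add(v)
        del pos
        return sorted(arcs)

    def perturb(
        self, arcs: Iterable[tuple[int, int]], k: int, rng: np.random.Generator
    ) -> list[tuple[int, int]]:
        """Apply k random legal add/delete/reverse moves to an arc set."""
        parents, children = self._init_state(arcs)
        for _ in range(k):
            legal = [m for _, m in self._moves(parents, children)]
            if not legal:
                break
            move = legal[int(rng.integers(len(legal)))]
            self._apply(move, parents, children)
        return sorted(
            (x, y) for y in range(self.nv) for x in parents[y]
        )


# ---------------------------------------------------------------------------
# Markov-blanket / skeleton engines
# ---------------------------------------------------------------------------


def _subsets(items: Sequence[int], max_size: Optional[int]):
    limit = len(items) if max_size is None else min(max_size, len(items))
    for size in range(limit + 1):
        yield from itertools.combinations(items, size)


class _ConstraintEngine:
    """Blanket discovery, neighbour search and orientation shared by the
    constraint-based learners."""

    def __init__(
        self,
        ci: _CIEngine,
        n_vars: int,
        blacklist: set[tuple[int, int]],
        whitelist: set[tuple[int, int]],
        max_cond_size: Optional[int] = None,
    ) -> None:
        self.ci = ci
        self.nv = n_vars
        self.blacklist = blacklist
        self.whitelist = whitelist
        self.max_cond = max_cond_size
        self.sepsets: dict[tuple[int, int], frozenset[int]] = {}

    def _candidates(self, t: int) -> list[int]:
        out = []
        for v in range(self.nv):
            if v == t:
                continue
            if (t, v) in self.blacklist and (v, t) in self.blacklist:
                continue
            out.append(v)
        return out

    def _forced(self, t: int) -> set[int]:
        return {
            a if b == t else b
            for a, b in self.whitelist
            if t in (a, b)
        }

    # -- blankets -----------------------------------------------------------
    def gs_blanket(self, t: int) -> set[int]:
        blanket = self._forced(t)
        changed = True
        while changed:
            changed = False
            for v in self._candidates(t):
                if v in blanket:
                    continue
                if self.ci.dependent(t, v, frozenset(blanket)):
                    blanket.add(v)
                    changed = True
        forced = self._forced(t)
        for v in sorted(blanket):
            if v in forced:
                continue
            if not self.ci.dependent(t, v, frozenset(blanket - {v})):
                blanket.discard(v)
        return blanket

    def iamb_blanket(self, t: int) -> set[int]:
        blanket = self._forced(t)
        while True:
            best_v, best_p = None, self.ci.alpha
            for v in self._candidates(t):
                if v in blanket:
                    continue
                p = self.ci.p_value(t, v, frozenset(blanket))
                if p < best_p:
                    best_v, best_p = v, p
            if best_v is None:
                break
            blanket.add(best_v)
        forced = self._forced(t)
        for v in sorted(blanket):
            if v in forced:
                continue
            if not self.ci.dependent(t, v, frozenset(blanket - {v})):
                blanket.discard(v)
        return blanket

    # -- MMPC ---------------------------------------------------------------
    def mmpc_cpc(self, t: int) -> set[int]:
        cpc: list[int] = sorted(self._forced(t))
        candidates = [v for v in self._candidates(t) if v not in cpc]
        while True:
            best_v, best_maxp = None, self.ci.alpha
            for v in candidates:
                maxp = 0.0
                for s in _subsets(sorted(cpc), self.max_cond):
                    p = self.ci.p_value(t, v, frozenset(s))
                    if p > maxp:
                        maxp = p
                    if maxp >= best_maxp:
                        break
                if maxp < best_maxp:
                    best_v, best_maxp = v, maxp
            if best_v is None:
                break
            cpc.append(best_v)
            candidates.remove(best_v)
        forced = self._forced(t)
        for v in list(cpc):
            if v in forced:
                continue
            rest = sorted(set(cpc) - {v})
            for s in _subsets(rest, self.max_cond):
                if self.ci.p_value(t, v, frozenset(s)) >= self.ci.alpha:
                    cpc.remove(v)
                    break
        return set(cpc)

    # -- skeleton from blankets --------------------------------------------
    def neighbours_from_blankets(
        self, blankets: list[set[int]]
    ) -> set[tuple[int, int]]:
        """Neighbour identification inside symmetrized blankets, recording
        separating sets for the orientation phase."""
        edges: set[tuple[int, int]] = set()
        for t in range(self.nv):
            for v in sorted(blankets[t]):
                if v < t:
                    continue
                if t not in blankets[v]:
                    continue  # AND symmetry
                if (t, v) in self.whitelist or (v, t) in self.whitelist:
                    edges.add((t, v))
                    continue
                base = blankets[t] - {v}
                other = blankets[v] - {t}
                pool = sorted(base if len(base) <= len(other) else other)
                separated = False
                for s in _subsets(pool, self.max_cond):
                    if self.ci.p_value(t, v, frozenset(s)) >= self.ci.alpha:
                        self.sepsets[(t, v)] = frozenset(s)
                        separated = True
                        break
                if not separated:
                    edges.add((t, v))
        # default sepset for pairs outside each other's blanket
        for t in range(self.nv):
            for v in range(t + 1, self.nv):
                if (t, v) in edges or (t, v) in self.sepsets:
                    continue
                self.sepsets[(t, v)] = frozenset(blankets[t] - {v})
        return edges

    # -- orientation --------------------------------------------------------
    def orient(self, skeleton: set[tuple[int, int]]) -> tuple[set, set]:
        """V-structure orientation plus Meek closure, blacklist-aware.

        Returns (directed, undirected) arc sets over integer indices.
        """
        adj: dict[int, set[int]] = {v: set() for v in range(self.nv)}
        for a, b in skeleton:
            adj[a].add(b)
            adj[b].add(a)
        proposed: set[tuple[int, int]] = set(
            (a, b) for a, b in self.whitelist
            if (min(a, b), max(a, b)) in skeleton
        )
        for z in range(self.nv):
            for x, y in itertools.combinations(sorted(adj[z]), 2):
                if y in adj[x]:
                    continue
                sep = self.sepsets.get((min(x, y), max(x, y)), frozenset())
                if z in sep:
                    continue
                if (x, z) not in self.blacklist:
                    proposed.add((x, z))
                if (y, z) not in self.blacklist:
                    proposed.add((y, z))
        # conflicting collider orientations cancel out
        directed = {
            (a, b) for a, b in proposed if (b, a) not in proposed
        }
        undirected = {
            (min(a, b), max(a, b))
            for a, b in skeleton
            if (a, b) not in directed and (b, a) not in directed
        }
        self._close(directed, undirected)
        # an undirected edge with one orientation blacklisted resolves to
        # the permitted orientation
        changed = True
        while changed:
            changed = False
            for a, b in sorted(undirected):
                fwd_ok = (a, b) not in self.blacklist
                rev_ok = (b, a) not in self.blacklist
                if fwd_ok != rev_ok:
                    undirected.discard((a, b))
                    directed.add((a, b) if fwd_ok else (b, a))
                    changed = True
            if changed:
                self._close(directed, undirected)
        self._break_cycles(directed, undirected)
        return directed, undirected

    def _break_cycles(self, directed: set, undirected: set) -> None:
        """Safety net: orientation with inconsistent separating sets can in
        principle direct a cycle; demote the lexicographically largest arc
        of each cycle back to undirected (deterministic repair), preferring
        arcs whose reverse orientation is not blacklisted so the demoted
        edge stays free of constraint conflicts."""
        import networkx as nx

        while True:
            g = nx.DiGraph(sorted(directed))
            try:
                cycle = nx.find_cycle(g)
            except nx.NetworkXNoCycle:
                return
            arcs = sorted((a, b) for a, b, *_ in cycle)
            free = [a for a in arcs if (a[1], a[0]) not in self.blacklist]
            arc = max(free) if free else max(arcs)
            directed.discard(arc)
            undirected.add((min(arc), max(arc)))

    def _close(self, directed: set, undirected: set) -> None:
        names = tuple(str(i) for i in range(self.nv))
        d = {(names[a], names[b]) for a, b in directed}
        u = {tuple(sorted((names[a], names[b]))) for a, b in undirected}
        forbidden = frozenset(
            (names[a], names[b]) for a, b in self.blacklist
        )
        apply_meek_rules(names, d, u, forbidden)
        directed.clear()
        directed.update((int(a), int(b)) for a, b in d)
        undirected.clear()
        undirected.update(tuple(sorted((int(a), int(b)))) for a, b in u)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


def _extract_frame(X) -> pd.DataFrame:
    if hasattr(X, "data") and isinstance(getattr(X, "data"), pd.DataFrame):
        return X.data
    if isinstance(X, pd.DataFrame):
        return X
    raise InvalidInputError(
        "expected a pandas DataFrame or CohortTable with named columns"
    )


def _index_constraints(
    constraints: Optional[ArcConstraintSet], columns: list[str]
) -> tuple[set, set]:
    cons = constraints or EMPTY_CONSTRAINTS
    idx = {c: i for i, c in enumerate(columns)}
    known = set(columns)
    bl = {
        (idx[a], idx[b])
        for a, b in cons.blacklist
        if a in known and b in known
    }
    wl = set()
    for a, b in cons.whitelist:
        if a not in known or b not in known:
            raise InvalidInputError(
                f"whitelisted arc ({a!r}, {b!r}) references unknown variables"
            )
        wl.add((idx[a], idx[b]))
    return bl, wl


class BaseStructureLearner(BaseEstimator):
    """Shared plumbing: input validation, constraint indexing, fit surface.

    Subclasses implement ``_learn(stats, rng)`` over a
    :class:`~bcnkit.scoring.GaussianSuffStats` and return a DAG or PDAG on
    integer-index names which is relabelled here.
    """

    constraints: Optional[ArcConstraintSet]
    random_state: Optional[int]

    def fit(self, X, y=None) -> "BaseStructureLearner":
        frame = _extract_frame(X)
        if frame.shape[1] < 2:
            raise InvalidInputError("need at least 2 variables")
        self.feature_names_in_ = np.asarray(frame.columns, dtype=object)
        stats = GaussianSuffStats(frame)
        rng = np.random.default_rng(self.random_state)
        self._fit_stats(stats, rng)
        return self

    # bootstrap entry point: refit on precomputed sufficient statistics
    def _fit_stats(self, stats: GaussianSuffStats, rng: np.random.Generator):
        self._columns_ = list(stats.columns)
        self._bl_, self._wl_ = _index_constraints(
            getattr(self, "constraints", None), self._columns_
        )
        self._learn(stats, rng)
        return self

    def _relabel_dag(self, parents: list[set[int]]) -> DAG:
        cols = self._columns_
        arcs = [
            (cols[x], cols[y])
            for y in range(len(cols))
            for x in parents[y]
        ]
        return DAG(cols, arcs)

    def learned_graph(self) -> Union[DAG, PDAG]:
        """The learned graph (DAG for score-based/hybrid, PDAG otherwise)."""
        if getattr(self, "dag_", None) is not None:
            return self.dag_
        return self.pdag_


class _ScoreBasedMixin:
    def _search(self, stats: GaussianSuffStats) -> _GreedySearch:
        scorer = _IndexScorer(stats, ScoreConfig(self.score))
        restrict = getattr(self, "_restrict_pairs_", None)
        return _GreedySearch(
            scorer, len(self._columns_), self._bl_, self._wl_, restrict
        )

    def _start_arcs(self, search: _GreedySearch, rng) -> list[tuple[int, int]]:
        if self.start == "random":
            return search.random_start(rng)
        return search.whitelist_arcs()


class HillClimbing(_ScoreBasedMixin, BaseStructureLearner):
    """Greedy score-based search over add/delete/reverse arc moves.

    Parameters
    ----------
    score : {"bic", "aic"}
        Penalized Gaussian network score (higher is better).
    start : {"empty", "random"}
        Initial graph.  ``"empty"`` starts from the whitelist arcs only;
        ``"random"`` draws a sparse random DAG (requires ``random_state``).
    restarts : int
        Number of perturbation restarts: after each local optimum the
        current best graph is perturbed and search resumes; the best local
        optimum over all runs is returned.
    perturbations : int
        Random arc moves applied per restart.
    constraints : ArcConstraintSet, optional
        Blacklist/whitelist enforced throughout the search.
    random_state : int, optional
        Seed for random starts and perturbations.

    Attributes
    ----------
    dag_ : DAG
        The best local optimum found.
    score_value_ : float
        Its penalized score.
    """

    def __init__(
        self,
        score: str = "bic",
        start: str = "empty",
        restarts: int = 0,
        perturbations: int = 0,
        constraints: Optional[ArcConstraintSet] = None,
        random_state: Optional[int] = None,
    ) -> None:
        self.score = score
        self.start = start
        self.restarts = restarts
        self.perturbations = perturbations
        self.constraints = constraints
        self.random_state = random_state

    def _learn(self, stats: GaussianSuffStats, rng: np.random.Generator) -> None:
        search = self._search(stats)
        parents, total = search.hill_climb(self._start_arcs(search, rng))
        best, best_total = parents, total
        # alternating restart policy: perturb the incumbent (local
        # exploration) on even restarts, fresh sparse random start (basin
        # hopping) on odd ones — random perturbation alone rarely escapes
        # deep optima, random starts alone rarely refine the incumbent
        for r in range(self.restarts):
            if r % 2 == 0:
                arcs = sorted(
                    (x, y) for y in range(len(best)) for x in best[y]
                )
                start = search.perturb(arcs, max(self.perturbations, 1), rng)
            else:
                start = search.random_start(rng)
            parents, total = search.hill_climb(start)
            if total > best_total + _TOL:
                best, best_total = parents, total
        self.dag_ = self._relabel_dag(best)
        self.score_value_ = float(best_total)


class TabuSearch(_ScoreBasedMixin, BaseStructureLearner):
    """Tabu-list greedy search: may accept non-improving moves to escape
    local optima, forbidding return to the last ``tabu_length`` visited
    structures; the best structure visited is returned.

    ``tabu_length = 0`` degenerates to plain hill climbing.
    """

    def __init__(
        self,
        score: str = "bic",
        start: str = "empty",
        tabu_length: int = 10,
        max_stagnant: Optional[int] = None,
        constraints: Optional[ArcConstraintSet] = None,
        random_state: Optional[int] = None,
    ) -> None:
        self.score = score
        self.start = start
        self.tabu_length = tabu_length
        self.max_stagnant = max_stagnant
        self.constraints = constraints
        self.random_state = random_state

    def _learn(self, stats, rng) -> None:
        search = self._search(stats)
        start_arcs = self._start_arcs(search, rng)
        if self.tabu_length == 0:
            parents, total = search.hill_climb(start_arcs)
        else:
            stagnant = (
                self.max_stagnant
                if self.max_stagnant is not None
                else self.tabu_length
            )
            parents, total = search.tabu(start_arcs, self.tabu_length, stagnant)
        self.dag_ = self._relabel_dag(parents)
        self.score_value_ = float(total)


class _ConstraintBasedLearner(BaseStructureLearner):
    """Shared fit path for Grow-Shrink and IAMB."""

    def __init__(
        self,
        ci_method: str = "mi-g",
        alpha: float = 0.05,
        max_cond_size: Optional[int] = None,
        constraints: Optional[ArcConstraintSet] = None,
        random_state: Optional[int] = None,
    ) -> None:
        self.ci_method = ci_method
        self.alpha = alpha
        self.max_cond_size = max_cond_size
        self.constraints = constraints
        self.random_state = random_state

    _blanket_method = "gs_blanket"

    def _learn(self, stats, rng) -> None:
        ci = _CIEngine(stats, self.ci_method, self.alpha)
        eng = _ConstraintEngine(
            ci, len(self._columns_), self._bl_, self._wl_, self.max_cond_size
        )
        blankets = [
            getattr(eng, self._blanket_method)(t)
            for t in range(len(self._columns_))
        ]
        skeleton = eng.neighbours_from_blankets(blankets)
        directed, undirected = eng.orient(skeleton)
        cols = self._columns_
        self.pdag_ = PDAG(
            cols,
            [(cols[a], cols[b]) for a, b in directed],
            [(cols[a], cols[b]) for a, b in undirected],
        )
        self.blankets_ = {
            cols[t]: frozenset(cols[v] for v in blankets[t])
            for t in range(len(cols))
        }
        self.dag_ = None
        try:
            ext = consistent_extension(self.pdag_)
            # Dor-Tarsi is constraint-blind; discard extensions that
            # orient a leftover edge against the blacklist
            bl = (self.constraints.blacklist
                  if self.constraints is not None else frozenset())
            if not (ext.arcs & bl):
                self.dag_ = ext
        except (ExtensionFailureError, InvalidInputError):
            pass  # ensemble falls back to half-weight direction counting

    def learned_graph(self):
        """Constraint-based learners report the partially directed graph;
        the DAG extension in ``dag_`` is a counting convenience."""
        return self.pdag_


class GrowShrink(_ConstraintBasedLearner):
    """Grow-Shrink: greedy Markov-blanket growth then shrinkage per node,
    neighbour identification within blankets, collider orientation and
    Meek closure.  ``pdag_`` holds the learned partially directed graph;
    ``dag_`` a consistent extension (None if none exists)."""

    _blanket_method = "gs_blanket"


class IAMB(_ConstraintBasedLearner):
    """Incremental Association Markov Blanket: forward step adds the
    variable with strongest association (smallest p-value) given the
    current blanket, then backward removal; otherwise as Grow-Shrink."""

    _blanket_method = "iamb_blanket"


class RSMax2(_ScoreBasedMixin, BaseStructureLearner):
    """Generic restrict-maximize hybrid learner.

    The restrict phase learns an undirected skeleton (MMPC by default);
    the maximize phase is hill climbing whose add moves are limited to
    skeleton pairs.  With ``restrict="none"`` it degenerates to plain
    hill climbing.
    """

    def __init__(
        self,
        score: str = "bic",
        ci_method: str = "mi-g",
        alpha: float = 0.05,
        restrict: str = "mmpc",
        max_cond_size: Optional[int] = None,
        constraints: Optional[ArcConstraintSet] = None,
        random_state: Optional[int] = None,
    ) -> None:
        self.score = score
        self.ci_method = ci_method
        self.alpha = alpha
        self.restrict = restrict
        self.max_cond_size = max_cond_size
        self.constraints = constraints
        self.random_state = random_state

    start = "empty"

    def _skeleton_pairs(self, stats) -> Optional[set[tuple[int, int]]]:
        if self.restrict == "none":
            return None
        ci = _CIEngine(stats, self.ci_method, self.alpha)
        eng = _ConstraintEngine(
            ci, len(self._columns_), self._bl_, self._wl_, self.max_cond_size
        )
        cpcs = [eng.mmpc_cpc(t) for t in range(len(self._columns_))]
        pairs = set()
        for t in range(len(self._columns_)):
            for v in cpcs[t]:
                if t in cpcs[v]:  # AND symmetry
                    pairs.add((min(t, v), max(t, v)))
        return pairs

    def _learn(self, stats, rng) -> None:
        pairs = self._skeleton_pairs(stats)
        cols = self._columns_
        self.skeleton_ = (
            None
            if pairs is None
            else frozenset((cols[a], cols[b]) for a, b in pairs)
        )
        self._restrict_pairs_ = pairs
        search = self._search(stats)
        parents, total = search.hill_climb(search.whitelist_arcs())
        self.dag_ = self._relabel_dag(parents)
        self.score_value_ = float(total)


class MMHC(RSMax2):
    """Max-Min Hill Climbing: MMPC skeleton restricts the arcs hill
    climbing may add (the canonical restrict-maximize instance)."""

    def __init__(
        self,
        score: str = "bic",
        ci_method: str = "mi-g",
        alpha: float = 0.05,
        max_cond_size: Optional[int] = None,
        constraints: Optional[ArcConstraintSet] = None,
        random_state: Optional[int] = None,
    ) -> None:
        super().__init__(
            score=score,
            ci_method=ci_method,
            alpha=alpha,
            restrict="mmpc",
            max_cond_size=max_cond_size,
            constraints=constraints,
            random_state=random_state,
        )


# ---------------------------------------------------------------------------
# config-driven functional surface
# ---------------------------------------------------------------------------


def make_learner(
    cfg: LearnerConfig, constraints: Optional[ArcConstraintSet] = None
) -> BaseStructureLearner:
    """Instantiate the estimator described by a :class:`LearnerConfig`."""
    kw = dict(constraints=constraints, random_state=cfg.seed)
    if cfg.algorithm == "hc":
        return HillClimbing(
            score=cfg.score,
            start=cfg.start,
            restarts=cfg.restarts,
            perturbations=cfg.perturbations,
            **kw,
        )
    if cfg.algorithm == "tabu":
        return TabuSearch(
            score=cfg.score, start=cfg.start, tabu_length=cfg.tabu_length, **kw
        )
    if cfg.algorithm == "gs":
        return GrowShrink(
            ci_method=cfg.ci_method, alpha=cfg.alpha,
            max_cond_size=cfg.max_cond_size, **kw,
        )
    if cfg.algorithm == "iamb":
        return IAMB(
            ci_method=cfg.ci_method, alpha=cfg.alpha,
            max_cond_size=cfg.max_cond_size, **kw,
        )
    if cfg.algorithm == "mmhc":
        return MMHC(
            score=cfg.score, ci_method=cfg.ci_method, alpha=cfg.alpha,
            max_cond_size=cfg.max_cond_size, **kw,
        )
    return RSMax2(
        score=cfg.score, ci_method=cfg.ci_method, alpha=cfg.alpha,
        restrict=cfg.restrict_algorithm, max_cond_size=cfg.max_cond_size, **kw,
    )


def _run(cfg: LearnerConfig, data, constraints) -> BaseStructureLearner:
    return make_learner(cfg, constraints).fit(data)


def hill_climb(data, cfg: Optional[LearnerConfig] = None,
               constraints: Optional[ArcConstraintSet] = None) -> DAG:
    cfg = cfg or LearnerConfig(algorithm="hc")
    if cfg.algorithm != "hc":
        cfg = LearnerConfig(**{**cfg.__dict__, "algorithm": "hc"})
    return _run(cfg, data, constraints).dag_


def tabu_search(data, cfg: Optional[LearnerConfig] = None,
                constraints: Optional[ArcConstraintSet] = None) -> DAG:
    cfg = cfg or LearnerConfig(algorithm="tabu")
    if cfg.algorithm != "tabu":
        cfg = LearnerConfig(**{**cfg.__dict__, "algorithm": "tabu"})
    return _run(cfg, data, constraints).dag_


def grow_shrink(data, cfg: Optional[LearnerConfig] = None,
                constraints: Optional[ArcConstraintSet] = None) -> PDAG:
    cfg = cfg or LearnerConfig(algorithm="gs")
    return GrowShrink(
        ci_method=cfg.ci_method, alpha=cfg.alpha,
        max_cond_size=cfg.max_cond_size, constraints=constraints,
    ).fit(data).pdag_


def iamb(data, cfg: Optional[LearnerConfig] = None,
         constraints: Optional[ArcConstraintSet] = None) -> PDAG:
    cfg = cfg or LearnerConfig(algorithm="iamb")
    return IAMB(
        ci_method=cfg.ci_method, alpha=cfg.alpha,
        max_cond_size=cfg.max_cond_size, constraints=constraints,
    ).fit(data).pdag_


def mmpc_skeleton(data, cfg: Optional[LearnerConfig] = None,
                  constraints: Optional[ArcConstraintSet] = None) -> PDAG:
    """Undirected MMPC skeleton as a PDAG with only undirected edges."""
    cfg = cfg or LearnerConfig(algorithm="mmhc")
    est = MMHC(
        score=cfg.score, ci_method=cfg.ci_method, alpha=cfg.alpha,
        max_cond_size=cfg.max_cond_size, constraints=constraints,
    )
    frame = _extract_frame(data)
    est.feature_names_in_ = np.asarray(frame.columns, dtype=object)
    stats = GaussianSuffStats(frame)
    est._columns_ = list(stats.columns)
    est._bl_, est._wl_ = _index_constraints(constraints, est._columns_)
    pairs = est._skeleton_pairs(stats) or set()
    cols = est._columns_
    return PDAG(cols, [], [(cols[a], cols[b]) for a, b in sorted(pairs)])


def mmhc(data, cfg: Optional[LearnerConfig] = None,
         constraints: Optional[ArcConstraintSet] = None) -> DAG:
    cfg = cfg or LearnerConfig(algorithm="mmhc")
    return MMHC(
        score=cfg.score, ci_method=cfg.ci_method, alpha=cfg.alpha,
        max_cond_size=cfg.max_cond_size, constraints=constraints,
    ).fit(data).dag_


def rsmax2(data, cfg: Optional[LearnerConfig] = None,
           constraints: Optional[ArcConstraintSet] = None) -> DAG:
    cfg = cfg or LearnerConfig(algorithm="rsmax2")
    return RSMax2(
        score=cfg.score, ci_method=cfg.ci_method, alpha=cfg.alpha,
        restrict=cfg.restrict_algorithm, max_cond_size=cfg.max_cond_size,
        constraints=constraints,
    ).fit(data).dag_
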