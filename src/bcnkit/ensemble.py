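"""Bootstrap model averaging of learned network structures.

The learner is refit on ``B`` nonparametric bootstrap resamples (n rows
drawn with replacement, resample size = n).  Each learned graph
contributes to per-orientation arc counts; an undirected edge from a
constraint-based learner contributes 1/2 to each orientation (or the
PDAG is first extended to a DAG when ``extend_pdags=True``).  From the
counts:

* strength  S(x, y) = fraction of the B networks containing an edge
  between x and y in either orientation;
* direction D(x -> y) = fraction of the networks containing the edge in
  which it is oriented x -> y, so D(x->y) + D(y->x) = 1 whenever S > 0.

The summary network retains edges with S at or above a threshold
(reported default 0.90, edges with strength strictly under the threshold
are removed); thresholding only filters the rendered summary — the full
table is always available.

Reproducibility: one master seed spawns an independent random substream
per replicate, so changing B does not reshuffle earlier replicates.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone

from .exceptions import BootstrapFailureError, InvalidInputError
from .graphs import DAG, PDAG, ArcConstraintSet, consistent_extension
from .learners import (
    BaseStructureLearner,
    LearnerConfig,
    _extract_frame,
    make_learner,
)
from .scoring import GaussianSuffStats

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeEnsemble",
    "AveragedNetwork",
    "BootstrapNetwork",
    "bootstrap_learn",
    "strength_direction",
    "threshold_network",
    "count_graph",
]

DEFAULT_B = 10_000
DEFAULT_STRENGTH_THRESHOLD = 0.90


@dataclass
class EdgeEnsemble:
    """Weighted directed arc counts over B bootstrapped networks."""

    B: int
    directed_counts: dict[tuple[str, str], float]
    nodes: tuple[str, ...]
    seed: Optional[int] = None
    learner_desc: str = ""
    n_redraws: int = 0

    def __post_init__(self) -> None:
        for (x, y), c in self.directed_counts.items():
            if not 0.0 <= c <= self.B:
                raise InvalidInputError(f"count for ({x}, {y}) outside [0, B]")
        for x, y in list(self.directed_counts):
            tot = self.directed_counts.get((x, y), 0.0) + self.directed_counts.get(
                (y, x), 0.0
            )
            if tot > self.B + 1e-9:
                raise InvalidInputError(
                    f"counts for pair ({x}, {y}) exceed the bootstrap count"
                )

    def count(self, x: str, y: str) -> float:
        return self.directed_counts.get((x, y), 0.0)


@dataclass
class AveragedNetwork:
    """Per-pair strength/direction table derived from an EdgeEnsemble.

    ``table`` has one row per unordered pair with any support, columns
    ``from, to, strength, direction`` where (from, to) is the majority
    orientation; ``threshold`` records the strength cutoff applied (or
    None for the full table).
    """

    table: pd.DataFrame
    B: int
    threshold: Optional[float] = None
    directed_counts: dict[tuple[str, str], float] = field(default_factory=dict)

    def strength(self, x: str, y: str) -> float:
        c = self.directed_counts
        return (c.get((x, y), 0.0) + c.get((y, x), 0.0)) / self.B

    def direction(self, x: str, y: str) -> float:
        """D(x -> y): oriented share among networks containing the edge."""
        c = self.directed_counts
        tot = c.get((x, y), 0.0) + c.get((y, x), 0.0)
        if tot == 0.0:
            raise InvalidInputError(f"no support for pair ({x}, {y})")
        return c.get((x, y), 0.0) / tot

    # ------------------------------------------------------------------ I/O
    def to_tsv(self) -> str:
        lines = ["from\tto\tstrength\tdirection"]
        for row in self.table.itertuples(index=False):
            lines.append(
                f"{row[0]}\t{row[1]}\t{row.strength:.6g}\t{row.direction:.6g}"
            )
        return "\n".join(lines) + "\n"

    def to_dot(self) -> str:
        """Graphviz summary graph with 'S = …% / D = …%' arc labels."""
        lines = ["digraph summary {"]
        nodes = sorted(
            set(self.table["from"]).union(self.table["to"])
        )
        for n in nodes:
            lines.append(f'  "{n}";')
        for row in self.table.itertuples(index=False):
            label = (
                f"S = {100 * row.strength:.0f}%, D = {100 * row.direction:.0f}%"
            )
            lines.append(f'  "{row[0]}" -> "{row[1]}" [label="{label}"];')
        lines.append("}")
        return "\n".join(lines) + "\n"

    def to_graphml(self, path: str) -> None:
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(
            sorted(set(self.table["from"]).union(self.table["to"]))
        )
        for row in self.table.itertuples(index=False):
            g.add_edge(
                row[0], row[1],
                strength=float(row.strength), direction=float(row.direction),
            )
        nx.write_graphml(g, path)


def count_graph(
    graph, counts: dict[tuple[str, str], float], extend_pdags: bool = False
) -> None:
    """Add one learned graph's arcs into a directed-count accumulator."""
    if isinstance(graph, DAG):
        for arc in graph.arcs:
            counts[arc] = counts.get(arc, 0.0) + 1.0
        return
    if not isinstance(graph, PDAG):
        raise InvalidInputError("expected a DAG or PDAG")
    pdag = graph
    if extend_pdags:
        try:
            dag = consistent_extension(pdag)
        except Exception:
            dag = None
        if dag is not None:
            count_graph(dag, counts)
            return
    for arc in pdag.directed_arcs:
        counts[arc] = counts.get(arc, 0.0) + 1.0
    for a, b in pdag.undirected_edges:
        counts[(a, b)] = counts.get((a, b), 0.0) + 0.5
        counts[(b, a)] = counts.get((b, a), 0.0) + 0.5


class BootstrapNetwork(BaseEstimator):
    """Bootstrap model averaging around any structure learner.

    Parameters
    ----------
    learner : BaseStructureLearner
        The estimator refit on each resample (cloned once at fit time).
    n_bootstrap : int, default 10000
        Number of bootstrap replicates.  Values below ~1000 give coarse
        strength estimates and trigger a log warning.
    extend_pdags : bool, default False
        Extend partially directed outputs to DAGs before counting instead
        of half-weighting undirected edges.
    max_failure_rate : float, default 0.01
        A failed replicate is logged and redrawn; if more than this share
        of B fail, the run errors out.
    random_state : int, optional
        Master seed; spawns one substream per replicate.

    Attributes
    ----------
    ensemble_ : EdgeEnsemble
    averaged_ : AveragedNetwork
        Full (unthresholded) strength/direction table.
    """

    def __init__(
        self,
        learner: Optional[BaseStructureLearner] = None,
        n_bootstrap: int = DEFAULT_B,
        extend_pdags: bool = False,
        max_failure_rate: float = 0.01,
        random_state: Optional[int] = None,
    ) -> None:
        self.learner = learner
        self.n_bootstrap = n_bootstrap
        self.extend_pdags = extend_pdags
        self.max_failure_rate = max_failure_rate
        self.random_state = random_state

    def fit(self, X, y=None) -> "BootstrapNetwork":
        if self.learner is None:
            raise InvalidInputError("a learner estimator is required")
        if self.n_bootstrap < 1:
            raise InvalidInputError("n_bootstrap must be >= 1")
        if self.n_bootstrap < 1000:
            logger.warning(
                "n_bootstrap=%d is small; strength/direction coefficients "
                "will be coarse", self.n_bootstrap,
            )
        frame = _extract_frame(X)
        mat = frame.to_numpy(float)
        columns = list(frame.columns)
        n = mat.shape[0]
        if n == 0:
            raise InvalidInputError("empty data")
        base = clone(self.learner)
        master = np.random.SeedSequence(self.random_state)
        streams = list(master.spawn(self.n_bootstrap))
        counts: dict[tuple[str, str], float] = {}
        redraws = 0
        max_failures = max(1, int(self.max_failure_rate * self.n_bootstrap))
        b = 0
        queue = list(streams)
        while b < self.n_bootstrap:
            ss = queue.pop(0)
            rng = np.random.default_rng(ss)
            idx = rng.integers(0, n, size=n)
            stats = GaussianSuffStats(mat[idx], columns)
            try:
                base._fit_stats(stats, rng)
            except Exception as exc:  # redraw-and-log policy
                redraws += 1
                logger.info("bootstrap replicate failed (%s); redrawing", exc)
                if redraws > max_failures:
                    raise BootstrapFailureError(
                        f"{redraws} bootstrap replicates failed "
                        f"(> {self.max_failure_rate:.0%} of B={self.n_bootstrap})"
                    ) from exc
                queue.append(master.spawn(1)[0])
                continue
            graph = base.learned_graph()
            if self.extend_pdags and getattr(base, "dag_", None) is not None:
                graph = base.dag_  # constraint-checked extension
            count_graph(graph, counts, self.extend_pdags)
            b += 1
        self.ensemble_ = EdgeEnsemble(
            B=self.n_bootstrap,
            directed_counts=counts,
            nodes=tuple(columns),
            seed=self.random_state,
            learner_desc=repr(base),
            n_redraws=redraws,
        )
        self.averaged_ = strength_direction(self.ensemble_)
        return self


def strength_direction(ens: EdgeEnsemble) -> AveragedNetwork:
    """Aggregate directed counts into the strength/direction table.

    One row per unordered pair with S > 0; (from, to) is the majority
    orientation (lexicographic tie-break at exactly 50/50).
    """
    rows = []
    pairs = {tuple(sorted(arc)) for arc in ens.directed_counts}
    for a, b in sorted(pairs):
        c_ab = ens.count(a, b)
        c_ba = ens.count(b, a)
        total = c_ab + c_ba
        if total == 0.0:
            continue
        s = total / ens.B
        if c_ab >= c_ba:
            rows.append((a, b, s, c_ab / total))
        else:
            rows.append((b, a, s, c_ba / total))
    table = pd.DataFrame(rows, columns=["from", "to", "strength", "direction"])
    return AveragedNetwork(
        table=table, B=ens.B, threshold=None,
        directed_counts=dict(ens.directed_counts),
    )


def threshold_network(
    avg: AveragedNetwork, min_strength: float = DEFAULT_STRENGTH_THRESHOLD
) -> AveragedNetwork:
    """Retain exactly the rows with strength >= min_strength (edges with
    strength strictly under the cutoff are removed)."""
    if not 0.0 <= min_strength <= 1.0:
        raise InvalidInputError("min_strength must be in [0, 1]")
    kept = avg.table[avg.table["strength"] >= min_strength].reset_index(drop=True)
    return AveragedNetwork(
        table=kept, B=avg.B, threshold=min_strength,
        directed_counts=dict(avg.directed_counts),
    )


def bootstrap_learn(
    data,
    cfg: LearnerConfig,
    constraints: Optional[ArcConstraintSet] = None,
    B: int = DEFAULT_B,
    seed: Optional[int] = None,
    extend_pdags: bool = False,
) -> EdgeEnsemble:
    """Config-driven wrapper: B bootstrap refits of the configured learner."""
    est = BootstrapNetwork(
        learner=make_learner(cfg, constraints),
        n_bootstrap=B,
        extend_pdags=extend_pdags,
        random_state=seed,
    ).fit(data)
    return est.ensemble_
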