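"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive re-implementations (path
enumeration, explicit residual regressions, exhaustive enumeration) kept
separate from the package code paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from bcnkit.graphs import DAG


# ---------------------------------------------------------------------------
# independent d-separation oracle: enumerate undirected paths, apply the
# blocking rules directly
# ---------------------------------------------------------------------------

def descendants_of(dag: DAG, node: str) -> set[str]:
    out, stack = set(), [node]
    while stack:
        v = stack.pop()
        for c in dag.children(v):
            if c not in out:
                out.add(c)
                stack.append(c)
    return out


def path_blocked(dag: DAG, path: list[str], z: set[str]) -> bool:
    for i in range(1, len(path) - 1):
        prev, mid, nxt = path[i - 1], path[i], path[i + 1]
        into_mid_left = (prev, mid) in dag.arcs
        into_mid_right = (nxt, mid) in dag.arcs
        if into_mid_left and into_mid_right:  # collider
            if mid not in z and not (descendants_of(dag, mid) & z):
                return True
        else:  # chain or fork
            if mid in z:
                return True
    return False


def brute_force_d_separated(dag: DAG, x: str, y: str, z) -> bool:
    """Enumerate every simple undirected path x..y; blocked iff all paths
    are blocked given z."""
    zs = set(z)
    adj: dict[str, set[str]] = {v: set() for v in dag.nodes}
    for a, b in dag.arcs:
        adj[a].add(b)
        adj[b].add(a)

    def paths(current, target, visited):
        if current == target:
            yield list(visited)
            return
        for nxt in sorted(adj[current]):
            if nxt not in visited:
                yield from paths(nxt, target, visited + [nxt])

    for path in paths(x, y, [x]):
        if not path_blocked(dag, path, zs):
            return False
    return True


# ---------------------------------------------------------------------------
# independent partial-correlation oracles
# ---------------------------------------------------------------------------

def partial_r_by_residuals(frame: pd.DataFrame, x: str, y: str, z) -> float:
    """Explicit two-regression residual correlation."""
    zs = list(z)
    xv = frame[x].to_numpy(float)
    yv = frame[y].to_numpy(float)
    design = np.column_stack(
        [np.ones(len(frame))] + [frame[c].to_numpy(float) for c in zs]
    )
    rx = xv - design @ np.linalg.lstsq(design, xv, rcond=None)[0]
    ry = yv - design @ np.linalg.lstsq(design, yv, rcond=None)[0]
    return float(np.corrcoef(rx, ry)[0, 1])


def partial_r_by_precision(frame: pd.DataFrame, x: str, y: str, z) -> float:
    """Inverse-correlation-matrix formula on the {x, y} + z submatrix."""
    cols = [x, y, *z]
    corr = np.corrcoef(frame[cols].to_numpy(float), rowvar=False)
    omega = np.linalg.inv(corr)
    return float(-omega[0, 1] / np.sqrt(omega[0, 0] * omega[1, 1]))


# ---------------------------------------------------------------------------
# random DAGs and simulated datasets
# ---------------------------------------------------------------------------

def random_dag(rng: np.random.Generator, n_nodes: int,
               edge_prob: float = 0.5) -> DAG:
    names = [f"V{i}" for i in range(n_nodes)]
    order = list(rng.permutation(names))
    arcs = [
        (order[i], order[j])
        for i, j in itertools.combinations(range(n_nodes), 2)
        if rng.random() < edge_prob
    ]
    return DAG(names, arcs)


def simulate_sem(dag: DAG, weights: dict, n: int,
                 rng: np.random.Generator,
                 noise_sd: dict | None = None) -> pd.DataFrame:
    """Tiny ad-hoc linear-Gaussian sampler, independent of the package's
    generator (unit noise unless given, unstandardized)."""
    values: dict[str, np.ndarray] = {}
    for v in dag.topological_order():
        sd = 1.0 if noise_sd is None else noise_sd.get(v, 1.0)
        val = rng.normal(0.0, sd, size=n)
        for p in sorted(dag.parents(v)):
            val = val + weights[(p, v)] * values[p]
        values[v] = val
    return pd.DataFrame({v: values[v] for v in dag.nodes})


DIAMOND = DAG("ABCD", [("A", "B"), ("A", "C"), ("B", "D"), ("C", "D")])
DIAMOND_WEIGHTS = {("A", "B"): 0.6, ("A", "C"): 0.6,
                   ("B", "D"): 0.6, ("C", "D"): 0.6}
# roughly standardized: strong signal relative to noise at every node
DIAMOND_NOISE = {"A": 1.0, "B": 0.8, "C": 0.8, "D": 0.4}


@pytest.fixture
def diamond_data():
    def _make(seed: int, n: int = 2000) -> pd.DataFrame:
        return simulate_sem(DIAMOND, DIAMOND_WEIGHTS, n,
                            np.random.default_rng(seed), DIAMOND_NOISE)
    return _make


@pytest.fixture
def noise_data():
    def _make(seed: int, n: int = 1000, k: int = 5) -> pd.DataFrame:
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.normal(size=(n, k)), columns=[f"N{i}" for i in range(k)]
        )
    return _make


def random_gaussian_sem(seed: int, n_nodes: int = 4, n: int = 2000,
                        edge_prob: float = 0.5) -> pd.DataFrame:
    """Random DAG + random +-U(0.3, 0.7) weights, sampled at size n."""
    rng = np.random.default_rng(seed)
    dag = random_dag(rng, n_nodes, edge_prob)
    weights = {
        arc: float(rng.uniform(0.3, 0.7) * rng.choice([-1.0, 1.0]))
        for arc in dag.arcs
    }
    return simulate_sem(dag, weights, n, rng)
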