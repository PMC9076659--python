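"""Decomposable Gaussian network scores (BIC / AIC).

Each node's local score is the maximized log-likelihood of the linear
regression of the node on its parents, penalized per criterion:

    score(node | parents) = l_hat - pen
    l_hat = -n/2 * (ln(2*pi*sigma2_hat) + 1)

with ``sigma2_hat`` the maximum-likelihood (1/n) residual variance and
``k = |parents| + 2`` free parameters (intercept, slopes, residual
variance).  ``pen = (k/2) ln n`` for BIC and ``pen = k`` for AIC, on a
higher-is-better scale.  The 1/n variance estimator (rather than the
unbiased 1/(n-k) one) makes the score exactly equal across
Markov-equivalent DAGs, which the searches and the directional model
comparison rely on.

Scores are computed from sufficient statistics (means and the ML
covariance matrix), so a local score costs O(|parents|^3) independent of
the sample size once the statistics are built — the property that makes
bootstrap learning at realistic cohort sizes cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .exceptions import CollinearityError, DegenerateDataError, InvalidInputError
from .graphs import DAG

__all__ = [
    "ScoreConfig",
    "GaussianSuffStats",
    "LocalScoreCache",
    "local_score",
    "network_score",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class ScoreConfig:
    """Which penalized Gaussian likelihood to use.

    ``criterion`` is ``"bic"`` or ``"aic"``; the penalty convention is
    fixed to higher-is-better (score = logLik - penalty).
    """

    criterion: str = "bic"

    def __post_init__(self) -> None:
        crit = self.criterion.lower()
        if crit not in ("bic", "aic"):
            raise InvalidInputError(f"unknown criterion {self.criterion!r}")
        object.__setattr__(self, "criterion", crit)

    def penalty(self, k: int, n: int) -> float:
        if self.criterion == "bic":
            return 0.5 * k * float(np.log(n))
        return float(k)


class GaussianSuffStats:
    """Sample size, means and ML (1/n) covariance of a numeric table."""

    __slots__ = ("n", "columns", "index", "cov")

    def __init__(self, data: Union[pd.DataFrame, np.ndarray],
                 columns: Optional[Iterable[str]] = None) -> None:
        if isinstance(data, pd.DataFrame):
            columns = list(data.columns)
            mat = data.to_numpy(float)
        else:
            mat = np.asarray(data, dtype=float)
            if columns is None:
                raise InvalidInputError("column names required for array input")
            columns = list(columns)
        if mat.ndim != 2 or mat.shape[1] != len(columns):
            raise InvalidInputError("data shape does not match column names")
        self.n = mat.shape[0]
        self.columns = columns
        self.index = {c: i for i, c in enumerate(columns)}
        centered = mat - mat.mean(axis=0)
        self.cov = centered.T @ centered / self.n

    def local_score(self, node: str, parents: tuple[str, ...],
                    cfg: ScoreConfig) -> float:
        try:
            i = self.index[node]
            pidx = [self.index[p] for p in parents]
        except KeyError as exc:
            raise InvalidInputError(f"unknown variable {exc.args[0]!r}") from None
        if node in parents:
            raise InvalidInputError(f"{node!r} cannot be its own parent")
        n = self.n
        if n <= len(parents) + 2:
            raise InvalidInputError(
                f"n={n} too small for {len(parents)} parents"
            )
        s_yy = self.cov[i, i]
        if s_yy <= 0.0:
            raise DegenerateDataError(f"column {node!r} is constant")
        if pidx:
            s_pp = self.cov[np.ix_(pidx, pidx)]
            s_py = self.cov[pidx, i]
            try:
                np.linalg.cholesky(s_pp)  # positive-definiteness check
                coef = np.linalg.solve(s_pp, s_py)
            except np.linalg.LinAlgError:
                raise CollinearityError(
                    f"parents of {node!r} are collinear: {parents}"
                ) from None
            sigma2 = s_yy - float(s_py @ coef)
            if sigma2 <= s_yy * 1e-12:
                raise CollinearityError(
                    f"residual variance of {node!r} vanished; "
                    "parents nearly deterministic"
                )
        else:
            sigma2 = s_yy
        loglik = -0.5 * n * (np.log(sigma2) + _LOG_2PI + 1.0)
        k = len(parents) + 2
        return float(loglik - cfg.penalty(k, n))


class LocalScoreCache:
    """Memoized local scores for one dataset and one score configuration."""

    def __init__(self, stats: GaussianSuffStats, cfg: ScoreConfig) -> None:
        self.stats = stats
        self.cfg = cfg
        self._entries: dict[tuple[str, frozenset[str]], float] = {}
        self.hits = 0
        self.misses = 0

    def __call__(self, node: str, parents: Iterable[str]) -> float:
        key = (node, frozenset(parents))
        try:
            value = self._entries[key]
            self.hits += 1
            return value
        except KeyError:
            self.misses += 1
            value = self.stats.local_score(node, tuple(sorted(key[1])), self.cfg)
            self._entries[key] = value
            return value

    def __len__(self) -> int:
        return len(self._entries)


def _as_frame(data) -> pd.DataFrame:
    # accept CohortTable without importing it (duck typing keeps the
    # module import graph acyclic)
    if hasattr(data, "data") and isinstance(data.data, pd.DataFrame):
        return data.data
    return pd.DataFrame(data)


def local_score(data, node: str, parents: Iterable[str],
                cfg: Optional[ScoreConfig] = None) -> float:
    """Penalized Gaussian log-likelihood of ``node`` given ``parents``."""
    cfg = cfg or ScoreConfig()
    stats = GaussianSuffStats(_as_frame(data))
    return stats.local_score(node, tuple(parents), cfg)


def network_score(data, dag: DAG, cfg: Optional[ScoreConfig] = None,
                  cache: Optional[LocalScoreCache] = None) -> float:
    """Sum of local scores over all nodes of ``dag`` (decomposability)."""
    cfg = cfg or ScoreConfig()
    frame = _as_frame(data)
    missing = [c for c in dag.nodes if c not in frame.columns]
    if missing:
        raise InvalidInputError(f"graph nodes not in data: {missing}")
    if cache is None:
        cache = LocalScoreCache(GaussianSuffStats(frame), cfg)
    return float(sum(cache(v, dag.parents(v)) for v in dag.nodes))
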