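"""Conditional-independence tests for Gaussian data.

All three tests are functions of the sample partial correlation
``r = cor(x, y | z)``:

* ``mi-g``   — Gaussian mutual information, G = -n * ln(1 - r^2),
  referred to a chi-square distribution with 1 degree of freedom
  (G = 2 n * MI for bivariate Gaussian data);
* ``fisher-z`` — z = sqrt(n - |z| - 3) * atanh(r), standard normal,
  two-sided;
* ``pearson``  — t = r * sqrt((n - |z| - 2) / (1 - r^2)), Student t with
  n - |z| - 2 degrees of freedom, two-sided.

The partial correlation is computed from the covariance matrix by the
Schur complement, which is algebraically identical to correlating the OLS
residuals of x and y on z.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .exceptions import CollinearityError, InvalidInputError

__all__ = ["CITestResult", "partial_correlation", "ci_test", "CI_METHODS"]

CI_METHODS = ("mi-g", "fisher-z", "pearson")


@dataclass(frozen=True)
class CITestResult:
    """Outcome of a single conditional-independence test."""

    statistic: float
    statistic_kind: str  # "G", "z" or "t"
    df: Optional[float]
    p_value: float
    partial_r: float
    n: int
    cond_size: int
    degenerate: bool = False

    def dependent(self, alpha: float) -> bool:
        return self.p_value < alpha


def _frame(data) -> pd.DataFrame:
    if hasattr(data, "data") and isinstance(data.data, pd.DataFrame):
        return data.data
    return pd.DataFrame(data)


def _partial_r_from_cov(cov: np.ndarray, ix: int, iy: int,
                        iz: list[int]) -> float:
    if iz:
        czz = cov[np.ix_(iz, iz)]
        cxz = cov[iz, ix]
        cyz = cov[iz, iy]
        try:
            np.linalg.cholesky(czz)
            sol = np.linalg.solve(czz, np.column_stack([cxz, cyz]))
        except np.linalg.LinAlgError:
            raise CollinearityError("conditioning set is collinear") from None
        vx = cov[ix, ix] - float(cxz @ sol[:, 0])
        vy = cov[iy, iy] - float(cyz @ sol[:, 1])
        cxy = cov[ix, iy] - float(cxz @ sol[:, 1])
    else:
        vx, vy, cxy = cov[ix, ix], cov[iy, iy], cov[ix, iy]
    if vx <= 0 or vy <= 0:
        raise CollinearityError("zero residual variance in partial correlation")
    r = cxy / np.sqrt(vx * vy)
    return float(np.clip(r, -1.0, 1.0))


def partial_correlation(data, x: str, y: str,
                        z: Iterable[str] = ()) -> float:
    """Correlation of x and y after linearly removing the variables in z.

    Equals the plain Pearson correlation when z is empty.
    """
    frame = _frame(data)
    zs = [str(v) for v in z]
    _validate_names(frame, x, y, zs)
    cols = [x, y, *zs]
    mat = frame[cols].to_numpy(float)
    if mat.shape[0] <= len(zs) + 3:
        raise InvalidInputError("too few rows for the conditioning set")
    centered = mat - mat.mean(axis=0)
    cov = centered.T @ centered / mat.shape[0]
    return _partial_r_from_cov(cov, 0, 1, list(range(2, 2 + len(zs))))


def _validate_names(frame: pd.DataFrame, x: str, y: str, zs: list[str]) -> None:
    if x == y or x in zs or y in zs:
        raise InvalidInputError("x, y and z must be disjoint")
    for v in (x, y, *zs):
        if v not in frame.columns:
            raise InvalidInputError(f"unknown variable {v!r}")


def result_from_partial_r(r: float, n: int, cond_size: int,
                          method: str) -> CITestResult:
    """Build a CITestResult from a partial correlation (shared by the
    learners, which compute r from cached covariance submatrices)."""
    if method not in CI_METHODS:
        raise InvalidInputError(f"unknown CI method {method!r}")
    degenerate = bool(abs(r) >= 1.0 - 1e-15)
    if method == "mi-g":
        kind, df = "G", 1.0
        if degenerate:
            stat, p = float("inf"), 0.0
        else:
            stat = -n * float(np.log(1.0 - r * r))
            p = float(sstats.chi2.sf(stat, df=1))
    elif method == "fisher-z":
        kind, df = "z", None
        if degenerate:
            stat, p = float("inf") * np.sign(r), 0.0
        else:
            stat = float(np.sqrt(n - cond_size - 3) * np.arctanh(r))
            p = float(2.0 * sstats.norm.sf(abs(stat)))
    else:  # pearson
        kind = "t"
        df = float(n - cond_size - 2)
        if degenerate:
            stat, p = float("inf") * np.sign(r), 0.0
        else:
            stat = float(r * np.sqrt(df / (1.0 - r * r)))
            p = float(2.0 * sstats.t.sf(abs(stat), df=df))
    return CITestResult(
        statistic=stat,
        statistic_kind=kind,
        df=df,
        p_value=p,
        partial_r=r,
        n=n,
        cond_size=cond_size,
        degenerate=degenerate,
    )


def ci_test(data, x: str, y: str, z: Iterable[str] = (),
            method: str = "mi-g", alpha: float = 0.05) -> CITestResult:
    """Test conditional independence of x and y given z.

    ``alpha`` is validated but the decision is left to the caller via
    :meth:`CITestResult.dependent`.
    """
    if not 0.0 < alpha < 1.0:
        raise InvalidInputError("alpha must be in (0, 1)")
    zs = [str(v) for v in z]
    frame = _frame(data)
    _validate_names(frame, x, y, zs)
    r = partial_correlation(frame, x, y, zs)
    return result_from_partial_r(r, len(frame), len(zs), method)
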