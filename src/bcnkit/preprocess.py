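"""Cohort tables and the preprocessing stages applied before network learning.

A :class:`CohortTable` carries the numeric analysis columns, the categorical
nuisance covariates (acquisition site, sex) and a provenance log.  The
preprocessing pipeline mirrors a standard imaging-cohort workflow:

* ordinary-least-squares residualization of every analysis column on site
  and sex (so the networks cannot pick up scanner or sex differences);
* first-principal-component composites of left/right hemispheric
  measurements, computed on the correlation matrix so the leading
  eigenvalue of two inputs equals ``1 + r``;
* longitudinal change scores (follow-up minus baseline);
* a pairwise Pearson correlation screen.

The transformers (:class:`NuisanceResidualizer`, :class:`PC1Composite`)
follow the scikit-learn estimator contract; the module-level functions are
thin wrappers kept for script use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import DegenerateDataError, InvalidInputError

__all__ = [
    "CohortTable",
    "CompositeResult",
    "NuisanceResidualizer",
    "PC1Composite",
    "residualize",
    "pc1_composite",
    "change_score",
    "correlation_table",
]


@dataclass
class CohortTable:
    """Subjects-by-variables table plus nuisance covariates.

    Attributes
    ----------
    data : pandas.DataFrame
        Numeric analysis columns, one row per subject.
    nuisance : pandas.DataFrame
        Categorical/binary nuisance covariates aligned with ``data``
        (typically ``site`` with 8 levels and binary ``sex``).
    provenance : list of str
        Free-text log of the transformations applied so far.
    """

    data: pd.DataFrame
    nuisance: pd.DataFrame = field(default_factory=pd.DataFrame)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = pd.DataFrame(self.data)
        self.nuisance = pd.DataFrame(self.nuisance)
        if len(self.nuisance) and len(self.nuisance) != len(self.data):
            raise InvalidInputError("nuisance rows do not match data rows")
        if self.data.isna().any().any():
            raise InvalidInputError(
                "analysis columns contain missing values; drop incomplete rows first"
            )

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def log(self, message: str) -> None:
        self.provenance.append(message)

    def copy(self) -> "CohortTable":
        return CohortTable(
            self.data.copy(), self.nuisance.copy(), list(self.provenance)
        )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, nuisance_columns: Sequence[str] = ()
    ) -> "CohortTable":
        """Split a flat table into analysis and nuisance parts, dropping
        rows with missing analysis values (count logged)."""
        frame = pd.DataFrame(frame)
        nuis = list(nuisance_columns)
        analysis = [c for c in frame.columns if c not in nuis]
        complete = frame[analysis].notna().all(axis=1)
        dropped = int((~complete).sum())
        frame = frame.loc[complete]
        table = cls(frame[analysis].reset_index(drop=True),
                    frame[nuis].reset_index(drop=True))
        if dropped:
            table.log(f"dropped {dropped} rows with missing analysis values")
        return table


@dataclass(frozen=True)
class CompositeResult:
    """First-principal-component composite with its diagnostics."""

    scores: np.ndarray
    eigenvalue: float
    pct_variance: float
    loadings: np.ndarray
    columns: tuple[str, ...]


def _nuisance_design(nuisance: pd.DataFrame, n: int) -> np.ndarray:
    """Intercept plus full-rank treatment contrasts for every nuisance column.

    The lexicographically first level of each categorical is the reference;
    the choice cannot affect the residuals (same column space).
    """
    blocks = [np.ones((n, 1))]
    for col in nuisance.columns:
        series = nuisance[col]
        levels = sorted(series.astype(str).unique())
        counts = series.astype(str).value_counts()
        if (counts < 2).any():
            warnings.warn(
                f"nuisance column {col!r} has a level with fewer than 2 subjects",
                stacklevel=3,
            )
        for lev in levels[1:]:
            blocks.append((series.astype(str) == lev).to_numpy(float)[:, None])
    return np.hstack(blocks)


class NuisanceResidualizer(BaseEstimator, TransformerMixin):
    """Replace analysis columns by their OLS residuals on site and sex.

    Fits one linear model per column on an intercept plus treatment
    contrasts of every nuisance covariate, and returns the residuals.
    After the transform each analysis column is exactly orthogonal to every
    nuisance indicator.

    Parameters
    ----------
    columns : sequence of str, optional
        Columns to residualize; default all analysis columns.
    """

    def __init__(self, columns: Optional[Sequence[str]] = None) -> None:
        self.columns = columns

    def fit(self, X: CohortTable, y: None = None) -> "NuisanceResidualizer":
        if not isinstance(X, CohortTable):
            raise InvalidInputError("NuisanceResidualizer expects a CohortTable")
        if X.nuisance.shape[1] == 0:
            raise InvalidInputError("cohort has no nuisance covariates")
        self.columns_ = list(self.columns) if self.columns is not None else X.columns
        missing = [c for c in self.columns_ if c not in X.columns]
        if missing:
            raise InvalidInputError(f"unknown analysis columns: {missing}")
        self.design_ = _nuisance_design(X.nuisance, X.n)
        self.n_features_in_ = len(self.columns_)
        return self

    def transform(self, X: CohortTable) -> CohortTable:
        design = self.design_
        out = X.copy()
        for col in self.columns_:
            y = out.data[col].to_numpy(float)
            if np.ptp(y) == 0:
                raise DegenerateDataError(f"column {col!r} is constant")
            beta, *_ = np.linalg.lstsq(design, y, rcond=None)
            out.data[col] = y - design @ beta
        out.log(
            f"residualized {len(self.columns_)} columns for "
            f"{list(X.nuisance.columns)}"
        )
        return out


class PC1Composite(BaseEstimator, TransformerMixin):
    """First-principal-component composite of a set of columns.

    PCA is performed on the correlation matrix (columns standardized
    internally), so with two inputs of correlation ``r`` the leading
    eigenvalue is ``1 + r`` and the percent variance explained is
    ``(1 + r) / 2 * 100``.  The component sign is fixed so that the loading
    of the lexicographically first input column is positive.

    Parameters
    ----------
    columns : sequence of str
        Input columns (at least two).
    name : str
        Name of the composite column added by :meth:`transform`.
    drop_inputs : bool, default True
        Remove the input columns after adding the composite.
    """

    def __init__(
        self, columns: Sequence[str] = (), name: str = "pc1", drop_inputs: bool = True
    ) -> None:
        self.columns = columns
        self.name = name
        self.drop_inputs = drop_inputs

    def fit(self, X: CohortTable, y: None = None) -> "PC1Composite":
        cols = list(self.columns)
        if len(cols) < 2:
            raise InvalidInputError("PC1Composite needs at least 2 input columns")
        mat = X.data[cols].to_numpy(float)
        sd = mat.std(axis=0)
        if np.any(sd == 0):
            raise DegenerateDataError("constant input column in PC1 composite")
        corr = np.corrcoef(mat, rowvar=False)
        eigvals, eigvecs = np.linalg.eigh(corr)
        lead = eigvals[-1]
        vec = eigvecs[:, -1]
        first = cols.index(min(cols))
        if vec[first] < 0:
            vec = -vec
        self.columns_ = cols
        self.eigenvalue_ = float(lead)
        self.pct_variance_ = float(lead / len(cols) * 100.0)
        self.loadings_ = vec
        self.mean_ = mat.mean(axis=0)
        self.scale_ = sd
        return self

    def transform(self, X: CohortTable) -> CohortTable:
        mat = X.data[self.columns_].to_numpy(float)
        z = (mat - self.mean_) / self.scale_
        scores = z @ self.loadings_
        out = X.copy()
        if self.name in out.data.columns:
            raise InvalidInputError(f"column {self.name!r} already exists")
        out.data[self.name] = scores
        if self.drop_inputs:
            out.data = out.data.drop(columns=self.columns_)
        out.log(
            f"pc1 composite {self.name!r} from {self.columns_} "
            f"(eigenvalue={self.eigenvalue_:.3f}, pct={self.pct_variance_:.1f}%)"
        )
        return out

    def result_(self, X: CohortTable) -> CompositeResult:
        mat = X.data[self.columns_].to_numpy(float)
        z = (mat - self.mean_) / self.scale_
        return CompositeResult(
            scores=z @ self.loadings_,
            eigenvalue=self.eigenvalue_,
            pct_variance=self.pct_variance_,
            loadings=self.loadings_.copy(),
            columns=tuple(self.columns_),
        )


# ----------------------------------------------------------- thin wrappers

def residualize(
    table: CohortTable, targets: Optional[Sequence[str]] = None
) -> CohortTable:
    """Residualize ``targets`` (default: all analysis columns) on the
    cohort's nuisance covariates."""
    return NuisanceResidualizer(columns=targets).fit(table).transform(table)


def pc1_composite(
    table: CohortTable, input_cols: Sequence[str]
) -> CompositeResult:
    """First-principal-component composite of ``input_cols`` with
    eigenvalue and percent-variance diagnostics."""
    est = PC1Composite(columns=input_cols, name="__pc1__").fit(table)
    return est.result_(table)


def change_score(
    table: CohortTable, baseline: str, followup: str, name: Optional[str] = None
) -> CohortTable:
    """Add a ``followup - baseline`` change column."""
    for col in (baseline, followup):
        if col not in table.data.columns:
            raise InvalidInputError(f"unknown column {col!r}")
    name = name or f"change_{baseline}"
    if name in table.data.columns:
        raise InvalidInputError(f"column {name!r} already exists")
    out = table.copy()
    out.data[name] = out.data[followup] - out.data[baseline]
    out.log(f"change score {name!r} = {followup!r} - {baseline!r}")
    return out


def correlation_table(
    table: CohortTable,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations with two-sided p-values.

    Returns ``(r, p)`` DataFrames indexed by column name; the diagonal of
    ``r`` is 1 and of ``p`` is 0.
    """
    cols = table.columns
    if len(cols) < 2:
        raise InvalidInputError("need at least 2 columns")
    mat = table.data.to_numpy(float)
    if np.any(mat.std(axis=0) == 0):
        raise DegenerateDataError("constant column in correlation screen")
    n = table.n
    r = np.corrcoef(mat, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(p, 0.0)
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )
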