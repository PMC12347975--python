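"""KMO-gated principal-component factor analysis.

The Kaiser-Meyer-Olkin measure of sampling adequacy compares observed
correlations with anti-image partial correlations computed from the inverse
correlation matrix:

    p_ij  = -inv_ij / sqrt(inv_ii * inv_jj)
    KMO   = sum_{i!=j} r_ij^2 / (sum_{i!=j} r_ij^2 + sum_{i!=j} p_ij^2)

with the per-variable analogue restricted to row i. Models with KMO > 0.6
are deemed adequate. Extraction is principal components on the Pearson
correlation matrix of complete cases (listwise deletion), retaining
components with eigenvalue >= 1 by default, with optional varimax rotation.

The canonical 8-variable candidate set groups coagulation times, the
renal-metabolic panel, and the immune counts into three components; that
structural recovery — not any published loading values — is what the
synthetic-cohort tests assert.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from statsmodels.multivariate.factor_rotation import rotate_factors

from .exceptions import (DegenerateDataError, NoAdequateModelError,
                         SingularMatrixError, ValidationError)

__all__ = [
    "MODEL3_VARIABLES",
    "kmo",
    "PCAFactorModel",
    "extract_factors",
    "select_model",
    "ModelSelectionResult",
]

#: The selected candidate variable set (coagulation / renal-metabolic /
#: immune blocks). Count fields carry the admission differential under the
#: package's default units policy.
MODEL3_VARIABLES = (
    "prothrombin_time", "inr", "aptt",
    "urea", "serum_creatinine", "glucose",
    "neutrophil_count", "lymphocyte_count",
)

_KMO_THRESHOLD = 0.6
_SINGULAR_RCOND = 1e-10


def _as_correlation(corr, variables=None):
    if isinstance(corr, pd.DataFrame):
        variables = list(corr.columns)
        corr = corr.to_numpy(dtype=float)
    corr = np.asarray(corr, dtype=float)
    p = corr.shape[0]
    if corr.ndim != 2 or corr.shape[1] != p:
        raise ValidationError("correlation matrix must be square")
    if variables is None:
        variables = [f"v{i}" for i in range(p)]
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValidationError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-8):
        raise ValidationError("correlation matrix must have unit diagonal")
    return corr, list(variables)


def _invert_or_name_collinear(corr, variables):
    eigvals, eigvecs = np.linalg.eigh(corr)
    if eigvals.min() <= _SINGULAR_RCOND * eigvals.max():
        null = eigvecs[:, eigvals <= _SINGULAR_RCOND * eigvals.max()]
        weight = np.abs(null).max(axis=1)
        involved = [v for v, w in zip(variables, weight) if w > 0.1]
        raise SingularMatrixError(involved or variables)
    return eigvecs @ np.diag(1.0 / eigvals) @ eigvecs.T


def kmo(corr, variables=None) -> tuple[float, pd.Series]:
    """Overall and per-variable Kaiser-Meyer-Olkin sampling adequacy.

    Parameters
    ----------
    corr : array-like or DataFrame
        Positive-definite correlation matrix of >= 3 variables.

    Returns
    -------
    (overall, per_variable)
        ``overall`` in (0, 1]; ``per_variable`` indexed by variable name.

    Raises
    ------
    SingularMatrixError
        If the matrix is numerically rank-deficient (names the variables
        spanning the null space).
    """
    corr, variables = _as_correlation(corr, variables)
    if corr.shape[0] < 3:
        raise ValidationError("KMO needs at least 3 variables")
    inv = _invert_or_name_collinear(corr, variables)
    d = np.sqrt(np.diag(inv))
    partial = -inv / np.outer(d, d)
    off = ~np.eye(corr.shape[0], dtype=bool)
    r2 = (corr ** 2) * off
    p2 = (partial ** 2) * off
    denom = r2.sum() + p2.sum()
    denom_i = r2.sum(axis=1) + p2.sum(axis=1)
    # exactly diagonal input: 0/0, whose small-correlation limit is 1/2
    overall = r2.sum() / denom if denom > 0 else 0.5
    with np.errstate(invalid="ignore"):
        per_var = np.where(denom_i > 0, r2.sum(axis=1) / denom_i, 0.5)
    return float(overall), pd.Series(per_var, index=variables, name="kmo")


class PCAFactorModel(BaseEstimator):
    """Principal-component factor model with KMO diagnostics.

    Parameters
    ----------
    n_components : int or None
        Fixed number of retained components; None (default) retains
        components with eigenvalue >= `min_eigenvalue` (Kaiser criterion).
    min_eigenvalue : float, default 1.0
    rotation : {None, "varimax"}
        Orthogonal rotation of the retained loadings (off by default).

    Attributes
    ----------
    variables_ : list of str
    correlation_ : DataFrame          Pearson correlation (complete cases).
    kmo_overall_ : float
    kmo_per_variable_ : Series
    eigenvalues_ : ndarray            All eigenvalues, descending.
    loadings_ : DataFrame             variables x retained components;
                                      signed so each component's largest-
                                      magnitude loading is positive.
    variance_explained_ : ndarray     Percent per retained component.
    cumulative_variance_ : ndarray
    membership_ : dict                variable -> component index
                                      (argmax |loading|).
    n_samples_ : int                  Complete cases used.
    """

    def __init__(self, n_components: int | None = None,
                 min_eigenvalue: float = 1.0, rotation: str | None = None):
        self.n_components = n_components
        self.min_eigenvalue = min_eigenvalue
        self.rotation = rotation

    def fit(self, X, y=None):
        if self.rotation not in (None, "varimax"):
            raise ValidationError(f"unknown rotation {self.rotation!r}")
        if isinstance(X, pd.DataFrame):
            data = X.apply(pd.to_numeric, errors="coerce").dropna()
            self.variables_ = list(X.columns)
            self.n_samples_ = len(data)
            if self.n_samples_ < len(self.variables_) + 1:
                raise DegenerateDataError(
                    f"only {self.n_samples_} complete cases for "
                    f"{len(self.variables_)} variables")
            corr = data.corr(method="pearson").to_numpy()
        else:
            corr, self.variables_ = _as_correlation(X)
            self.n_samples_ = None
        corr, _ = _as_correlation(corr, self.variables_)
        self.correlation_ = pd.DataFrame(corr, index=self.variables_,
                                         columns=self.variables_)
        self.kmo_overall_, self.kmo_per_variable_ = kmo(corr, self.variables_)

        eigvals, eigvecs = np.linalg.eigh(corr)
        order = np.argsort(eigvals)[::-1]
        eigvals, eigvecs = eigvals[order], eigvecs[:, order]
        self.eigenvalues_ = eigvals
        if self.n_components is not None:
            k = int(self.n_components)
        else:
            k = int(np.sum(eigvals >= self.min_eigenvalue))
        if k < 1:
            raise DegenerateDataError("retention policy keeps 0 components")
        k = min(k, len(self.variables_))

        loadings = eigvecs[:, :k] * np.sqrt(np.clip(eigvals[:k], 0, None))
        if self.rotation == "varimax" and k > 1:
            loadings, _ = rotate_factors(loadings, "varimax")
        # sign convention: dominant loading of each component positive
        for j in range(k):
            if loadings[np.argmax(np.abs(loadings[:, j])), j] < 0:
                loadings[:, j] = -loadings[:, j]
        self.loadings_ = pd.DataFrame(
            loadings, index=self.variables_,
            columns=[f"component_{j + 1}" for j in range(k)])
        # after rotation, variance per component = column sum of squared loadings
        ssq = (loadings ** 2).sum(axis=0)
        self.variance_explained_ = 100.0 * ssq / len(self.variables_)
        self.cumulative_variance_ = np.cumsum(self.variance_explained_)
        self.membership_ = {v: int(np.argmax(np.abs(loadings[i])))
                            for i, v in enumerate(self.variables_)}
        self.n_components_ = k
        return self

    def component_members(self) -> list[frozenset]:
        """Variables grouped by their dominant component."""
        groups = [set() for _ in range(self.n_components_)]
        for v, c in self.membership_.items():
            groups[c].add(v)
        return [frozenset(g) for g in groups]


def extract_factors(corr_or_data, *, n_components=None, min_eigenvalue=1.0,
                    rotation=None) -> PCAFactorModel:
    """Functional wrapper over :class:`PCAFactorModel`."""
    return PCAFactorModel(n_components=n_components,
                          min_eigenvalue=min_eigenvalue,
                          rotation=rotation).fit(corr_or_data)


class ModelSelectionResult:
    """Outcome of KMO-based candidate selection for one subgroup."""

    def __init__(self, best_name, model, kmo_table: pd.DataFrame):
        self.best_name = best_name
        self.model = model
        self.kmo_table = kmo_table

    @property
    def adequate(self) -> bool:
        return self.best_name is not None

    def __repr__(self):
        return (f"ModelSelectionResult(best={self.best_name!r}, "
                f"adequate={self.adequate})")


def select_model(candidates: dict[str, list[str]], data,
                 threshold: float = _KMO_THRESHOLD, *,
                 raise_if_none: bool = False):
    """Rank candidate variable sets by overall KMO and pick the winner.

    Parameters
    ----------
    candidates : dict
        Candidate name -> variable list. Ties break toward the
        first-listed candidate (dict order).
    data : DataFrame or dict of DataFrames
        One cohort table, or subgroup-name -> table for stratified fits
        (e.g. per surgical stage). Complete cases of each candidate set.
    threshold : float, default 0.6
        Models with KMO <= threshold are discarded.
    raise_if_none : bool
        Raise :class:`NoAdequateModelError` instead of returning an
        inadequate result.

    Returns
    -------
    ModelSelectionResult or dict of them (one per subgroup).
    """
    if not candidates:
        raise ValidationError("need at least one candidate variable set")
    if isinstance(data, dict):
        return {name: select_model(candidates, df, threshold,
                                   raise_if_none=raise_if_none)
                for name, df in data.items()}
    rows, fitted = [], {}
    for name, variables in candidates.items():
        missing = [v for v in variables if v not in data.columns]
        if missing:
            raise ValidationError(f"candidate {name!r} uses absent "
                                  f"variables: {missing}")
        try:
            model = PCAFactorModel().fit(data[list(variables)])
        except (DegenerateDataError, SingularMatrixError) as exc:
            rows.append({"candidate": name, "kmo": np.nan,
                         "n_components": np.nan, "note": str(exc)})
            continue
        fitted[name] = model
        rows.append({"candidate": name, "kmo": model.kmo_overall_,
                     "n_components": model.n_components_, "note": ""})
    table = pd.DataFrame(rows)
    eligible = table.dropna(subset=["kmo"])
    eligible = eligible[eligible["kmo"] > threshold]
    if eligible.empty:
        if raise_if_none:
            raise NoAdequateModelError(
                f"no candidate exceeded KMO threshold {threshold}")
        return ModelSelectionResult(None, None, table)
    best = eligible.loc[eligible["kmo"].idxmax(), "candidate"]
    # idxmax returns the first maximum -> deterministic first-listed tie-break
    return ModelSelectionResult(best, fitted[best], table)
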