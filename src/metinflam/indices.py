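"""Metabolic-inflammatory indices from routine admission labs.

Nine scores are derived from glucose (G, mg/dL), serum creatinine (Cr,
mg/dL), and the CBC counts for neutrophils (N), lymphocytes (L) and
platelets (P), all in 10^3/uL under the default units policy::

    NLR   = N / L                PLR  = P / L          SII   = P * N / L
    IMI   = G * N / L            GLR  = G / L          NLCR  = Cr * N / L
    CLR   = Cr / L               GCNLI = (G / Cr) * (N / L)
    MISI  = G * Cr / L

IMI (Inflammatory Metabolic Index) and MISI (Metabolic-Inflammatory Stress
Index) combine the stress-hyperglycemia and immune axes; the remaining
ratios are standard inflammation markers or single-analyte variants.

Missing inputs propagate to missing index values — no imputation. Zero or
negative lymphocytes are a domain error, not a silent infinity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dataclass_fields

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import InvalidLabValueError, ValidationError
from .published import INDEX_NAMES, PUBLISHED_CUTOFFS

__all__ = [
    "LabPanel",
    "IndexPanel",
    "IndexCalculator",
    "compute_index_panel",
    "compute_index_frame",
    "classify_at_cutoff",
    "INDEX_NAMES",
    "UNITS_POLICIES",
]

#: Which CBC columns feed N and L: absolute counts (default) or percent
#: differentials. Published cutoffs are only meaningful under one fixed
#: convention; outputs always record the policy used.
UNITS_POLICIES = ("count", "percent")


@dataclass
class LabPanel:
    """One admission's routine laboratory panel. Any field may be missing (None)."""

    glucose: float | None = None            # mg/dL
    urea: float | None = None               # mg/dL
    serum_creatinine: float | None = None   # mg/dL
    leukocytes: float | None = None         # 10^3/uL
    neutrophil_count: float | None = None   # 10^3/uL
    lymphocyte_count: float | None = None   # 10^3/uL
    neutrophil_pct: float | None = None     # %
    lymphocyte_pct: float | None = None     # %
    platelets: float | None = None          # 10^3/uL
    prothrombin_time: float | None = None   # seconds
    inr: float | None = None                # ratio
    aptt: float | None = None               # seconds
    chloride: float | None = None           # mmol/L
    potassium: float | None = None          # mmol/L
    sodium: float | None = None             # mmol/L
    magnesium: float | None = None          # mg/dL
    calcium: float | None = None            # mg/dL
    phosphorus: float | None = None         # mg/dL
    bun: float | None = None                # mg/dL

    def __post_init__(self):
        for f in dataclass_fields(self):
            v = getattr(self, f.name)
            if v is None:
                continue
            v = float(v)
            if math.isnan(v):
                setattr(self, f.name, None)
                continue
            if v < 0:
                raise InvalidLabValueError(f.name, v, "must be non-negative")
            if f.name.endswith("_pct") and v > 100:
                raise InvalidLabValueError(f.name, v, "percent must be in [0, 100]")
            setattr(self, f.name, v)

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in dataclass_fields(cls))

    def as_dict(self) -> dict[str, float | None]:
        return {f.name: getattr(self, f.name) for f in dataclass_fields(self)}


@dataclass
class IndexPanel:
    """The nine derived scores for one patient; missing where inputs were missing."""

    nlr: float | None = None
    plr: float | None = None
    sii: float | None = None
    imi: float | None = None
    glr: float | None = None
    nlcr: float | None = None
    clr: float | None = None
    gcnli: float | None = None
    misi: float | None = None
    units_policy: str = "count"

    def as_dict(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in INDEX_NAMES}


def _index_values(g, cr, n, l, p) -> dict[str, float | None]:
    """Evaluate all nine formulas; operands may be NaN (propagates)."""

    def safe(value):
        return None if value is None or not np.isfinite(value) else float(value)

    def div(a, b):
        if a is None or b is None:
            return None
        return a / b

    def mul(a, b):
        if a is None or b is None:
            return None
        return a * b

    nl = div(n, l)
    return {
        "nlr": safe(nl),
        "plr": safe(div(p, l)),
        "sii": safe(mul(p, nl)),
        "imi": safe(mul(g, nl)),
        "glr": safe(div(g, l)),
        "nlcr": safe(mul(cr, nl)),
        "clr": safe(div(cr, l)),
        "gcnli": safe(mul(div(g, cr), nl)),
        "misi": safe(div(mul(g, cr), l)),
    }


def compute_index_panel(labs: LabPanel, units_policy: str = "count") -> IndexPanel:
    """Compute the nine indices for one patient.

    Parameters
    ----------
    labs : LabPanel
        Validated laboratory values; missing fields yield missing indices.
    units_policy : {"count", "percent"}
        Whether N and L are taken from the absolute-count fields (default)
        or the percent-differential fields.

    Raises
    ------
    InvalidLabValueError
        If the lymphocyte denominator is present but zero, or creatinine is
        present but zero (GCNLI divides by it).
    """
    if units_policy not in UNITS_POLICIES:
        raise ValidationError(f"unknown units policy {units_policy!r}")
    if units_policy == "count":
        n, l = labs.neutrophil_count, labs.lymphocyte_count
        l_field = "lymphocyte_count"
    else:
        n, l = labs.neutrophil_pct, labs.lymphocyte_pct
        l_field = "lymphocyte_pct"
    if l is not None and l <= 0:
        raise InvalidLabValueError(l_field, l, "lymphocyte denominator must be > 0")
    g, cr, p = labs.glucose, labs.serum_creatinine, labs.platelets
    if cr is not None and cr == 0:
        raise InvalidLabValueError("serum_creatinine", cr, "must be > 0 when present")
    return IndexPanel(units_policy=units_policy, **_index_values(g, cr, n, l, p))


class IndexCalculator(BaseEstimator, TransformerMixin):
    """Stateless transformer mapping a cohort lab table to the nine index columns.

    Parameters
    ----------
    units_policy : {"count", "percent"}, default "count"
        Source of the neutrophil/lymphocyte operands.

    Examples
    --------
    >>> df = pd.DataFrame({"glucose": [100.0], "neutrophil_count": [8.0],
    ...                    "lymphocyte_count": [2.0], "serum_creatinine": [1.0],
    ...                    "platelets": [200.0]})
    >>> IndexCalculator().fit_transform(df)[["nlr", "imi"]].iloc[0].tolist()
    [4.0, 400.0]
    """

    def __init__(self, units_policy: str = "count"):
        self.units_policy = units_policy

    def fit(self, X, y=None):
        if self.units_policy not in UNITS_POLICIES:
            raise ValidationError(f"unknown units policy {self.units_policy!r}")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Append/derive the nine index columns from a lab DataFrame."""
        if not isinstance(X, pd.DataFrame):
            raise ValidationError("IndexCalculator requires a pandas DataFrame "
                                  "with named lab columns")
        if self.units_policy == "count":
            n_col, l_col = "neutrophil_count", "lymphocyte_count"
        else:
            n_col, l_col = "neutrophil_pct", "lymphocyte_pct"

        def col(name):
            if name in X.columns:
                return pd.to_numeric(X[name], errors="coerce").astype(float)
            return pd.Series(np.nan, index=X.index)

        g, cr = col("glucose"), col("serum_creatinine")
        n, l, p = col(n_col), col(l_col), col("platelets")
        for name, s in [("glucose", g), ("serum_creatinine", cr),
                        (n_col, n), (l_col, l), ("platelets", p)]:
            bad = s.dropna()
            if (bad < 0).any():
                raise InvalidLabValueError(name, float(bad[bad < 0].iloc[0]),
                                           "must be non-negative")
        if (l.dropna() == 0).any():
            raise InvalidLabValueError(l_col, 0.0,
                                       "lymphocyte denominator must be > 0")
        nl = n / l
        out = pd.DataFrame({
            "nlr": nl,
            "plr": p / l,
            "sii": p * nl,
            "imi": g * nl,
            "glr": g / l,
            "nlcr": cr * nl,
            "clr": cr / l,
            "gcnli": (g / cr) * nl,
            "misi": g * cr / l,
        }, index=X.index)
        return out

    def get_feature_names_out(self, input_features=None):
        return np.asarray(INDEX_NAMES, dtype=object)


def compute_index_frame(labs: pd.DataFrame, units_policy: str = "count") -> pd.DataFrame:
    """Functional wrapper over :class:`IndexCalculator`."""
    return IndexCalculator(units_policy=units_policy).fit(labs).transform(labs)


def classify_at_cutoff(
    panel: IndexPanel | dict,
    index_name: str,
    cutoff: float | None = None,
    *,
    classification: str | None = None,
    strict: bool = True,
) -> str:
    """Dichotomize one index score at a cutoff.

    Positivity is oriented as higher score = disease-positive. With
    ``strict`` (default) a score exactly at the cutoff is negative
    ("values above the fixed cutoff"); set ``strict=False`` for >=.

    Either pass an explicit ``cutoff`` or name a published preset via
    ``classification`` ("histopathological" or "surgical"). The presets are
    the published fixed cutoffs; their count/percent convention is
    unverified in the source.

    Returns
    -------
    str
        "positive", "negative", or "indeterminate" (score missing).
    """
    name = index_name.lower()
    if name not in INDEX_NAMES:
        raise ValidationError(f"unknown index {index_name!r}; "
                              f"expected one of {INDEX_NAMES}")
    if cutoff is None:
        if classification not in PUBLISHED_CUTOFFS:
            raise ValidationError(
                "provide a cutoff or a classification in "
                f"{tuple(PUBLISHED_CUTOFFS)} for the published presets")
        cutoff = PUBLISHED_CUTOFFS[classification][name]
    cutoff = float(cutoff)
    if not math.isfinite(cutoff):
        raise ValidationError("cutoff must be finite")
    score = panel.get(name) if isinstance(panel, dict) else getattr(panel, name)
    if score is None or (isinstance(score, float) and math.isnan(score)):
        return "indeterminate"
    positive = score > cutoff if strict else score >= cutoff
    return "positive" if positive else "negative"
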