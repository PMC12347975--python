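"""Synthetic appendicitis cohort generator.

Emulates the statistical structure the downstream analysis assumes: two
outcome-conditional lab distributions (disease-positive vs negative under a
chosen classification), a latent 3-factor correlation structure
(coagulation: PT/INR/aPTT; renal-metabolic: urea/creatinine/glucose;
immune: neutrophils +, lymphocytes -), ordinal severity labels for both the
histopathological class and the surgical stage, and MCAR missingness.

The default configuration carries the study's printed group means and SDs
verbatim, including several internally implausible entries (listed in
``CohortConfig.flagged_implausible``); they are used as printed rather than
silently corrected. Marginals are normal, rescaled to the group target
mean/SD and winsorised at physiological bounds — so for fields whose
printed mean sits close to a bound (e.g. the positive-group lymphocyte
count) the realised sample mean is pulled away from the printed one.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .indices import LabPanel
from .published import GROUP_SIZES

__all__ = [
    "HISTOPATH_CLASSES",
    "SURGICAL_STAGES",
    "PatientRecord",
    "CohortConfig",
    "default_config",
    "generate_cohort",
    "generate_cohort_frame",
    "cohort_to_frame",
]

HISTOPATH_CLASSES = ("edematous", "suppurative", "gangrenous", "perforated")
SURGICAL_STAGES = ("I", "II", "III", "IV")

#: Printed case-mix percentages across the severity spectrum.
HISTOPATH_PROPORTIONS = (17.48, 63.82, 10.16, 8.54)
SURGICAL_PROPORTIONS = (1.63, 29.27, 36.18, 32.92)

# Per-classification (positive-group, negative-group) (mean, SD) pairs for
# every field printed in the study's descriptive table. "Positive" means
# perforated (histopathological) or complicated, stages III-IV (surgical).
_GROUP_PARAMS = {
    "histopathological": {
        "age":              ((36.67, 24.58), (23.68, 18.43)),
        "hospital_days":    ((4.71, 3.64),   (3.10, 2.75)),
        "platelets":        ((245.52, 81.02), (273.91, 80.15)),
        "leukocytes":       ((13.34, 4.63),  (14.77, 5.10)),
        "lymphocyte_count": ((0.1, 0.57),    (1.52, 0.80)),
        "neutrophil_count": ((11.55, 4.21),  (11.85, 4.97)),
        "lymphocyte_pct":   ((9.64, 5.2),    (12.8, 9.17)),
        "neutrophil_pct":   ((8.0, 79.07),   (75.66, 12.29)),
        "prothrombin_time": ((15.62, 2.23),  (17.57, 5.47)),
        "inr":              ((1.9, 0.47),    (1.21, 0.2)),
        "aptt":             ((17.57, 5.5),   (33.45, 5.53)),
        "glucose":          ((125.73, 30.49), (109.27, 39.66)),
        "urea":             ((40.0, 46.48),  (26.82, 17.66)),
        "serum_creatinine": ((0.96, 0.41),   (0.77, 0.57)),
        "phosphorus":       ((3.47, 1.74),   (4.53, 9.28)),
        "calcium":          ((14.54, 21.8),  (9.11, 1.29)),
        "chloride":         ((98.78, 6.16),  (101.3, 9.37)),
        "potassium":        ((3.82, 0.55),   (3.9, 0.43)),
        "sodium":           ((133.84, 5.33), (135.41, 10.98)),
        "magnesium":        ((2.08, 0.37),   (1.98, 0.4)),
        "bun":              ((18.66, 21.77), (12.49, 7.48)),
    },
    "surgical": {
        "age":              ((24.75, 20.23), (24.90, 17.23)),
        "hospital_days":    ((3.46, 2.74),   (2.45, 2.96)),
        "platelets":        ((274.15, 84.18), (265.43, 71.5)),
        "leukocytes":       ((15.26, 5.3),   (13.25, 4.21)),
        "lymphocyte_count": ((1.35, 0.79),   (1.77, 0.75)),
        "neutrophil_count": ((12.45, 5.12),  (10.43, 4.09)),
        "lymphocyte_pct":   ((11.34, 7.98),  (15.54, 10.47)),
        "neutrophil_pct":   ((76.51, 12.06), (74.51, 12.79)),
        "prothrombin_time": ((16.22, 2.95),  (14.89, 1.84)),
        "inr":              ((1.27, 0.26),   (1.15, 0.16)),
        "aptt":             ((34.74, 6.17),  (31.82, 3.84)),
        "glucose":          ((117.01, 43.58), (96.65, 20.61)),
        "urea":             ((28.63, 23.28), (26.69, 19.25)),
        "serum_creatinine": ((0.77, 0.46),   (0.84, 0.74)),
        "phosphorus":       ((4.68, 10.51),  (3.86, 2.31)),
        "calcium":          ((9.8, 8.42),    (9.35, 0.61)),
        "chloride":         ((100.23, 10.56), (102.95, 3.9)),
        "potassium":        ((3.94, 0.48),   (3.77, 0.33)),
        "sodium":           ((135.37, 5.44), (135.04, 17.3)),
        "magnesium":        ((2.01, 0.33),   (1.97, 0.52)),
        "bun":              ((13.59, 11.17), (11.94, 5.93)),
    },
}

_MALE_FRACTION = {
    "histopathological": (11 / 21, 116 / 225),
    "surgical": (36 / 76, 91 / 170),
}

#: Latent-factor loadings: field -> (factor name, loading). Within-block
#: loadings of 0.85 give communalities ~0.72, consistent with the ~78%
#: accumulated variance the 3-component solution is expected to explain.
_DEFAULT_LOADINGS = {
    "prothrombin_time": ("coagulation", 0.85),
    "inr": ("coagulation", 0.85),
    "aptt": ("coagulation", 0.85),
    "urea": ("renal_metabolic", 0.85),
    "serum_creatinine": ("renal_metabolic", 0.85),
    "glucose": ("renal_metabolic", 0.85),
    "neutrophil_count": ("immune", 0.85),
    "lymphocyte_count": ("immune", -0.85),
}

_FACTOR_ORDER = ("coagulation", "renal_metabolic", "immune")

_POSITIVE_FLOOR = 0.01  # winsorisation floor: concentrations/counts stay > 0

_DEFAULT_BOUNDS = {
    "age": (0.0, 110.0),
    "hospital_days": (0.0, 365.0),
    "lymphocyte_pct": (0.0, 100.0),
    "neutrophil_pct": (0.0, 100.0),
}  # every other field defaults to (_POSITIVE_FLOOR, inf)

#: Printed descriptive entries that are internally implausible (scale/unit
#: inconsistencies, direction conflicts with the running text). Kept as
#: printed; surfaced here and in the simulate sidecar.
_FLAGGED_IMPLAUSIBLE = (
    "lymphocyte_count",   # count-scale values printed under a percent label
    "lymphocyte_pct",     # percent-scale values printed under a count label
    "neutrophil_pct",     # positive-group entry 8 +/- 79.07 is garbled
    "aptt",               # positive-group 17.57 +/- 5.5 vs negative 33.45
    "prothrombin_time",   # group direction contradicts the narrative
    "calcium",            # positive-group SD 21.8 mg/dL is non-physiological
)


@dataclass
class PatientRecord:
    """One simulated admission."""

    id: str
    sex: str                      # "male" | "female"
    age: float | None
    hospital_days: float | None
    labs: LabPanel
    histopath: str                # HISTOPATH_CLASSES
    surgical_stage: str           # SURGICAL_STAGES

    @property
    def perforated(self) -> bool:
        return self.histopath == "perforated"

    @property
    def complicated(self) -> bool:
        return self.surgical_stage in ("III", "IV")


@dataclass
class CohortConfig:
    """Full parameterisation of the simulated cohort.

    ``classification`` selects which binary outcome conditions the lab
    distributions; both label sets (histopathological class and surgical
    stage) are always assigned, consistently, from one latent severity
    score. Group sizes for both classifications must sum to the same total.
    """

    classification: str = "histopathological"
    histo_sizes: tuple[int, int] = GROUP_SIZES["histopathological"]
    surg_sizes: tuple[int, int] = GROUP_SIZES["surgical"]
    group_params: dict = field(
        default_factory=lambda: copy.deepcopy(_GROUP_PARAMS["histopathological"]))
    loadings: dict = field(default_factory=lambda: dict(_DEFAULT_LOADINGS))
    male_fraction: tuple[float, float] = _MALE_FRACTION["histopathological"]
    missing_rate: float | dict = 0.0
    bounds: dict = field(default_factory=lambda: dict(_DEFAULT_BOUNDS))
    histo_proportions: tuple = HISTOPATH_PROPORTIONS
    surg_proportions: tuple = SURGICAL_PROPORTIONS
    seed: int = 0
    flagged_implausible: tuple = _FLAGGED_IMPLAUSIBLE

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if self.classification not in ("histopathological", "surgical"):
            raise ConfigError(f"unknown classification {self.classification!r}")
        for sizes in (self.histo_sizes, self.surg_sizes):
            if len(sizes) != 2 or any(int(s) < 2 for s in sizes):
                raise ConfigError("need >= 2 patients per outcome group")
        if sum(self.histo_sizes) != sum(self.surg_sizes):
            raise ConfigError("histopathological and surgical group sizes "
                              "must sum to the same cohort total")
        for name, ((m1, s1), (m0, s0)) in self.group_params.items():
            if s1 <= 0 or s0 <= 0:
                raise ConfigError(f"SD must be > 0 for {name!r}")
            lo, hi = self._bounds_for(name)
            if not lo < hi:
                raise ConfigError(f"empty bounds for {name!r}: ({lo}, {hi})")
            for m in (m1, m0):
                if not lo <= m <= hi:
                    raise ConfigError(
                        f"infeasible config: mean {m} of {name!r} lies "
                        f"outside its bounds ({lo}, {hi})")
        for name, (factor, lam) in self.loadings.items():
            if abs(lam) > 1:
                raise ConfigError(f"loading magnitude > 1 for {name!r}")
            if factor not in _FACTOR_ORDER:
                raise ConfigError(f"unknown latent factor {factor!r}")
        for rate in (self.missing_rate.values()
                     if isinstance(self.missing_rate, dict)
                     else [self.missing_rate]):
            if not 0 <= rate < 1:
                raise ConfigError("missingness rate must be in [0, 1)")

    def _bounds_for(self, name: str) -> tuple[float, float]:
        return self.bounds.get(name, (_POSITIVE_FLOOR, np.inf))

    def _missing_rate_for(self, name: str) -> float:
        if isinstance(self.missing_rate, dict):
            return float(self.missing_rate.get(name, 0.0))
        return float(self.missing_rate)

    @property
    def n_total(self) -> int:
        return int(sum(self.histo_sizes))

    @property
    def conditioning_sizes(self) -> tuple[int, int]:
        return (self.histo_sizes if self.classification == "histopathological"
                else self.surg_sizes)

    # -- derived configurations -----------------------------------------
    def zeroed_separation(self) -> "CohortConfig":
        """Null-model variant: both groups draw from the negative group's
        distribution (labels become independent of the labs)."""
        params = {name: (neg, neg) for name, (_pos, neg) in self.group_params.items()}
        return replace(self, group_params=params,
                       male_fraction=(self.male_fraction[1],) * 2)

    def with_total(self, n_total: int) -> "CohortConfig":
        """Rescale both classifications' group sizes to a new cohort total,
        preserving proportions (largest remainder, min 2 per group)."""
        def scale(sizes):
            out = _apportion([s / sum(sizes) * 100 for s in sizes], n_total)
            out = [max(2, c) for c in out]
            out[out.index(max(out))] -= sum(out) - n_total
            return tuple(out)
        return replace(self, histo_sizes=scale(self.histo_sizes),
                       surg_sizes=scale(self.surg_sizes))

    def to_jsonable(self) -> dict:
        cfg = {
            "classification": self.classification,
            "histo_sizes": list(self.histo_sizes),
            "surg_sizes": list(self.surg_sizes),
            "group_params": {k: [list(v[0]), list(v[1])]
                             for k, v in self.group_params.items()},
            "loadings": {k: [v[0], v[1]] for k, v in self.loadings.items()},
            "male_fraction": list(self.male_fraction),
            "missing_rate": self.missing_rate,
            "bounds": {k: [v[0], None if np.isinf(v[1]) else v[1]]
                       for k, v in ((n, self._bounds_for(n))
                                    for n in self.group_params)},
            "histo_proportions": list(self.histo_proportions),
            "surg_proportions": list(self.surg_proportions),
            "seed": self.seed,
            "flagged_implausible": list(self.flagged_implausible),
        }
        return cfg


def default_config(classification: str = "histopathological") -> CohortConfig:
    """The study-conditions configuration: printed group sizes, printed
    per-group means/SDs for the chosen conditioning classification, the
    3-factor latent structure, no missingness."""
    if classification not in _GROUP_PARAMS:
        raise ConfigError(f"unknown classification {classification!r}")
    return CohortConfig(
        classification=classification,
        group_params=copy.deepcopy(_GROUP_PARAMS[classification]),
        male_fraction=_MALE_FRACTION[classification],
    )


def _apportion(percentages, total: int) -> list[int]:
    """Integer counts proportional to `percentages`, summing to `total`
    (largest-remainder method)."""
    shares = np.asarray(percentages, dtype=float)
    shares = shares / shares.sum() * total
    counts = np.floor(shares).astype(int)
    remainder = total - counts.sum()
    order = np.argsort(-(shares - counts))
    counts[order[:remainder]] += 1
    return counts.tolist()


def _severity_labels(config: CohortConfig, severity_rank: np.ndarray):
    """Assign both ordinal label sets by thresholding the severity ranking.

    The binary splits reproduce the configured group sizes exactly; within
    each binary side the sub-stages follow the printed case-mix proportions
    (renormalised). Higher rank = more severe.
    """
    n = len(severity_rank)
    n_perf = round(config.histo_sizes[0] / config.n_total * n)
    n_compl = round(config.surg_sizes[0] / config.n_total * n)
    if config.classification == "histopathological":
        n_perf = config.histo_sizes[0] if n == config.n_total else n_perf
    else:
        n_compl = config.surg_sizes[0] if n == config.n_total else n_compl

    histo = np.empty(n, dtype=object)
    lower = _apportion(config.histo_proportions[:3], n - n_perf)
    cuts = np.cumsum(lower)
    histo[severity_rank < cuts[0]] = HISTOPATH_CLASSES[0]
    histo[(severity_rank >= cuts[0]) & (severity_rank < cuts[1])] = HISTOPATH_CLASSES[1]
    histo[(severity_rank >= cuts[1]) & (severity_rank < cuts[2])] = HISTOPATH_CLASSES[2]
    histo[severity_rank >= cuts[2]] = HISTOPATH_CLASSES[3]

    stage = np.empty(n, dtype=object)
    n_uncompl = n - n_compl
    low = _apportion(config.surg_proportions[:2], n_uncompl)
    high = _apportion(config.surg_proportions[2:], n_compl)
    cuts = np.cumsum([low[0], low[1], high[0]])
    stage[severity_rank < cuts[0]] = SURGICAL_STAGES[0]
    stage[(severity_rank >= cuts[0]) & (severity_rank < cuts[1])] = SURGICAL_STAGES[1]
    stage[(severity_rank >= cuts[1]) & (severity_rank < cuts[2])] = SURGICAL_STAGES[2]
    stage[severity_rank >= cuts[2]] = SURGICAL_STAGES[3]
    return histo, stage


def generate_cohort(config: CohortConfig | None = None,
                    seed: int | None = None) -> list[PatientRecord]:
    """Draw a reproducible synthetic cohort.

    Parameters
    ----------
    config : CohortConfig, optional
        Defaults to :func:`default_config`.
    seed : int, optional
        Overrides ``config.seed``.
    """
    config = config if config is not None else default_config()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_total

    severity = rng.random(n)
    severity_rank = np.argsort(np.argsort(severity))  # 0 = mildest
    histo, stage = _severity_labels(config, severity_rank)
    if config.classification == "histopathological":
        positive = histo == "perforated"
    else:
        positive = np.isin(stage, ("III", "IV"))
    group = np.where(positive, 0, 1)  # index into (pos, neg) param pairs

    factor_scores = rng.standard_normal((n, len(_FACTOR_ORDER)))
    factor_index = {name: k for k, name in enumerate(_FACTOR_ORDER)}

    values: dict[str, np.ndarray] = {}
    for name in config.group_params:  # fixed iteration order -> reproducible
        eps = rng.standard_normal(n)
        if name in config.loadings:
            fac, lam = config.loadings[name]
            z = lam * factor_scores[:, factor_index[fac]] + np.sqrt(1 - lam ** 2) * eps
        else:
            z = eps
        (m1, s1), (m0, s0) = config.group_params[name]
        mean = np.where(positive, m1, m0)
        sd = np.where(positive, s1, s0)
        lo, hi = config._bounds_for(name)
        x = np.clip(mean + sd * z, lo, hi)
        rate = config._missing_rate_for(name)
        if rate > 0:
            x[rng.random(n) < rate] = np.nan
        values[name] = x

    male = rng.random(n) < np.asarray(config.male_fraction)[group]
    lab_fields = set(LabPanel.field_names())
    records = []
    for i in range(n):
        labs = LabPanel(**{k: (None if np.isnan(v[i]) else float(v[i]))
                           for k, v in values.items() if k in lab_fields})
        age = values.get("age", np.full(n, np.nan))[i]
        stay = values.get("hospital_days", np.full(n, np.nan))[i]
        records.append(PatientRecord(
            id=f"P{i + 1:04d}",
            sex="male" if male[i] else "female",
            age=None if np.isnan(age) else float(age),
            hospital_days=None if np.isnan(stay) else float(stay),
            labs=labs,
            histopath=str(histo[i]),
            surgical_stage=str(stage[i]),
        ))
    return records


def cohort_to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    """Flatten records to the canonical cohort table (one row per patient)."""
    rows = []
    for r in records:
        row = {"id": r.id, "sex": r.sex, "age": r.age,
               "hospital_days": r.hospital_days,
               "histopath": r.histopath, "surgical_stage": r.surgical_stage}
        row.update(r.labs.as_dict())
        rows.append(row)
    df = pd.DataFrame(rows)
    df["perforated"] = (df["histopath"] == "perforated").astype(int)
    df["complicated"] = df["surgical_stage"].isin(["III", "IV"]).astype(int)
    return df


def generate_cohort_frame(config: CohortConfig | None = None,
                          seed: int | None = None) -> pd.DataFrame:
    return cohort_to_frame(generate_cohort(config, seed))
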