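"""Cohort CSV reading/validation and the end-to-end pipeline runner.

The cohort format is a flat CSV, one row per admission, with columns named
as the LabPanel fields plus ``id, sex, age, hospital_days, histopath,
surgical_stage`` (case-insensitive). Unparseable numeric cells become
missing with a logged warning carrying 1-based row and column identity;
categorical labels are validated against the diagnostic vocabularies.

``run_pipeline`` executes screen -> factors -> index computation ->
evaluate -> power, writes one report per stage plus a JSON manifest (input
hash, seed, config, package version), and never mutates the cohort.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .exceptions import DegenerateDataError, ValidationError
from .factors import MODEL3_VARIABLES, select_model
from .indices import INDEX_NAMES, IndexCalculator, LabPanel
from .published import GROUP_SIZES
from .rocdx import evaluate_indices
from .synthetic import (HISTOPATH_CLASSES, SURGICAL_STAGES, PatientRecord,
                        cohort_to_frame)
from .univariate import screen
from .power import power_table

__all__ = ["read_cohort", "write_cohort", "read_cohort_frame",
           "PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

_META_COLUMNS = ("id", "sex", "age", "hospital_days",
                 "histopath", "surgical_stage")
_SEXES = ("male", "female")


def _canonical_columns(columns) -> dict[str, str]:
    known = {c.lower(): c for c in (*_META_COLUMNS, *LabPanel.field_names())}
    mapping = {}
    for col in columns:
        key = col.strip().lower()
        if key in known:
            mapping[col] = known[key]
        else:
            logger.warning("unrecognized column %r ignored", col)
    return mapping


def _parse_category(value, vocab, column, row_number):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    text = str(value).strip().lower()
    canon = {v.lower(): v for v in vocab}
    if text in canon:
        return canon[text]
    logger.warning("row %d: unrecognized %s label %r set to missing",
                   row_number, column, value)
    return None


def read_cohort_frame(path) -> pd.DataFrame:
    """Read and validate a cohort CSV into the canonical table."""
    raw = pd.read_csv(path, dtype=str)
    mapping = _canonical_columns(raw.columns)
    df = raw[list(mapping)].rename(columns=mapping)
    if "id" in df.columns:
        dup = df["id"].duplicated()
        if dup.any():
            raise ValidationError(
                f"duplicate patient ids: {sorted(df.loc[dup, 'id'].unique())}")
    else:
        df["id"] = [f"R{i + 1:04d}" for i in range(len(df))]
    numeric = [c for c in df.columns
               if c in LabPanel.field_names() or c in ("age", "hospital_days")]
    for col in numeric:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna() & (df[col].str.strip() != "")
        for i in df.index[bad]:
            logger.warning("row %d, column %s: unparseable cell %r set to "
                           "missing", i + 2, col, df.loc[i, col])
        df[col] = parsed.astype(float)
    for col, vocab in (("histopath", HISTOPATH_CLASSES),
                       ("surgical_stage", SURGICAL_STAGES),
                       ("sex", _SEXES)):
        if col in df.columns:
            df[col] = [_parse_category(v, vocab, col, i + 2)
                       for i, v in zip(df.index, df[col])]
    if "histopath" in df.columns:
        df["perforated"] = (df["histopath"] == "perforated").astype(int)
    if "surgical_stage" in df.columns:
        df["complicated"] = df["surgical_stage"].isin(["III", "IV"]).astype(int)
    return df


def read_cohort(path) -> list[PatientRecord]:
    """Read a cohort CSV into typed patient records."""
    df = read_cohort_frame(path)
    records = []
    for _, row in df.iterrows():
        labs = LabPanel(**{f: (None if f not in row or pd.isna(row[f])
                               else float(row[f]))
                           for f in LabPanel.field_names()})
        records.append(PatientRecord(
            id=str(row.get("id")),
            sex=row.get("sex") or "female",
            age=None if pd.isna(row.get("age", np.nan)) else float(row["age"]),
            hospital_days=(None if pd.isna(row.get("hospital_days", np.nan))
                           else float(row["hospital_days"])),
            labs=labs,
            histopath=row.get("histopath") or "edematous",
            surgical_stage=row.get("surgical_stage") or "I",
        ))
    return records


def write_cohort(records: list[PatientRecord], path) -> None:
    """Write patient records to the canonical cohort CSV."""
    df = cohort_to_frame(records).drop(columns=["perforated", "complicated"])
    df.to_csv(path, index=False)


@dataclass
class PipelineConfig:
    """End-to-end run parameters. Exactly one input source: a cohort CSV
    path or a simulation config (None path means simulate)."""

    input_path: str | None = None
    outcome: str = "histopathological"
    indices: tuple = INDEX_NAMES
    units_policy: str = "count"
    cutoff_mode: str = "youden"      # youden | published
    alpha: float = 0.05
    output_dir: str = "metinflam_out"
    seed: int = 0
    report_format: str = "csv"
    run_factors: bool = True
    simulate_config: object | None = None

    def validate(self):
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if self.outcome not in ("histopathological", "surgical"):
            raise ValidationError(f"unknown outcome {self.outcome!r}")
        if (self.input_path is None) == (self.simulate_config is None):
            raise ValidationError("exactly one input source: input_path or "
                                  "simulate_config")


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run screen -> factors -> indices -> evaluate -> power; write reports.

    Returns the in-memory report bundle; on a degenerate-data abort the
    stage identity is attached and partial outputs are preserved on disk.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"package": "metinflam", "version": __version__,
                "seed": config.seed, "outcome": config.outcome,
                "units_policy": config.units_policy,
                "cutoff_mode": config.cutoff_mode, "alpha": config.alpha}

    if config.input_path is not None:
        cohort = read_cohort_frame(config.input_path)
        manifest["input"] = {"path": str(config.input_path),
                             "sha256": _sha256(config.input_path)}
    else:
        from .synthetic import generate_cohort_frame
        cohort = generate_cohort_frame(config.simulate_config, seed=config.seed)
        manifest["input"] = {"simulated": True,
                             "config": config.simulate_config.to_jsonable()
                             if config.simulate_config is not None else "default"}
    bundle: dict = {"cohort": cohort}

    stage = "screen"
    try:
        report = screen(cohort, config.outcome, alpha=config.alpha)
        report.to_csv(out / "screen.csv", index=False)
        bundle["screen"] = report

        if config.run_factors:
            stage = "factors"
            sel = select_model({"model3": list(MODEL3_VARIABLES)}, cohort)
            bundle["factors"] = sel
            sel.kmo_table.to_csv(out / "factors_kmo.csv", index=False)
            if sel.adequate:
                sel.model.loadings_.to_csv(out / "factors_loadings.csv")

        stage = "indices"
        scores = IndexCalculator(config.units_policy).fit(cohort).transform(cohort)
        scored = pd.concat([cohort, scores], axis=1)
        scores.assign(id=cohort["id"]).to_csv(out / "indices.csv", index=False)
        bundle["indices"] = scores

        stage = "evaluate"
        evaluation = evaluate_indices(scored, config.outcome,
                                      list(config.indices),
                                      cutoff_mode=config.cutoff_mode,
                                      units_policy=config.units_policy)
        evaluation.to_csv(out / "evaluate.csv", index=False)
        bundle["evaluate"] = evaluation

        stage = "power"
        n_pos = int(scored[{"histopathological": "perforated",
                            "surgical": "complicated"}[config.outcome]].sum())
        n_neg = len(scored) - n_pos
        rows = [(r["index"], r["odds_ratio"], n_pos, n_neg)
                for _, r in evaluation.iterrows()
                if np.isfinite(r["odds_ratio"]) and r["odds_ratio"] > 0]
        power = power_table(rows, alpha=config.alpha)
        power.attrs["or_precision"] = "full-precision (from data)"
        power.to_csv(out / "power.csv", index=False)
        bundle["power"] = power
    except DegenerateDataError as exc:
        raise DegenerateDataError(f"stage {stage!r}: {exc}") from exc

    manifest["n_patients"] = int(len(cohort))
    manifest["group_sizes_default"] = {k: list(v) for k, v in GROUP_SIZES.items()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    bundle["manifest"] = manifest
    return bundle
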