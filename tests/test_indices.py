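"""Index formulas, their algebraic identities, and cutoff classification."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from metinflam import (INDEX_NAMES, IndexCalculator, InvalidLabValueError,
                       LabPanel, ValidationError, classify_at_cutoff,
                       compute_index_frame, compute_index_panel)

WORKED = {"nlr": 4.0, "plr": 100.0, "sii": 800.0, "imi": 400.0, "glr": 50.0,
          "nlcr": 4.0, "clr": 0.5, "gcnli": 400.0, "misi": 50.0}


def make_labs(g=100.0, n=8.0, l=2.0, cr=1.0, p=200.0, **extra):
    return LabPanel(glucose=g, neutrophil_count=n, lymphocyte_count=l,
                    serum_creatinine=cr, platelets=p, **extra)


def test_worked_example_all_nine():
    panel = compute_index_panel(make_labs())
    assert panel.as_dict() == WORKED
    assert panel.units_policy == "count"


def test_unit_nlr_when_counts_equal():
    panel = compute_index_panel(make_labs(n=7.3, l=7.3))
    assert panel.nlr == pytest.approx(1.0)


positive = st.floats(min_value=0.05, max_value=500.0, allow_nan=False)


@settings(max_examples=1000, derandomize=True, deadline=None)
@given(g=positive, n=positive, l=positive, cr=positive, p=positive)
def test_identity_battery(g, n, l, cr, p):
    """sii = nlr*P, imi = glr*N, nlcr = nlr*Cr, gcnli = imi/Cr, misi = glr*Cr."""
    x = compute_index_panel(make_labs(g=g, n=n, l=l, cr=cr, p=p))
    rel = 1e-12
    assert x.sii == pytest.approx(x.nlr * p, rel=rel)
    assert x.imi == pytest.approx(x.glr * n, rel=rel)
    assert x.nlcr == pytest.approx(x.nlr * cr, rel=rel)
    assert x.gcnli == pytest.approx(x.imi / cr, rel=rel)
    assert x.misi == pytest.approx(x.glr * cr, rel=rel)
    assert all(v >= 0 and math.isfinite(v) for v in x.as_dict().values())


@settings(max_examples=100, derandomize=True, deadline=None)
@given(g=positive, n=positive, l=positive, cr=positive, p=positive,
       k=st.floats(min_value=0.1, max_value=10.0))
def test_glucose_scaling(g, n, l, cr, p, k):
    """Scaling glucose by k scales IMI/GLR/GCNLI/MISI by k, fixes the rest."""
    a = compute_index_panel(make_labs(g=g, n=n, l=l, cr=cr, p=p)).as_dict()
    b = compute_index_panel(make_labs(g=k * g, n=n, l=l, cr=cr, p=p)).as_dict()
    for name in ("imi", "glr", "gcnli", "misi"):
        assert b[name] == pytest.approx(k * a[name], rel=1e-9)
    for name in ("nlr", "plr", "sii", "nlcr", "clr"):
        assert b[name] == pytest.approx(a[name], rel=1e-9)


@settings(max_examples=100, derandomize=True, deadline=None)
@given(g=positive, n=positive, l=positive, cr=positive, p=positive,
       k=st.floats(min_value=0.1, max_value=10.0))
def test_cell_count_scaling(g, n, l, cr, p, k):
    """Scaling N, L, P jointly by k fixes all ratios, scales SII/PLR by k
    only through their platelet operand (PLR fixed, SII scaled by k)."""
    a = compute_index_panel(make_labs(g=g, n=n, l=l, cr=cr, p=p)).as_dict()
    b = compute_index_panel(
        make_labs(g=g, n=k * n, l=k * l, cr=cr, p=k * p)).as_dict()
    assert b["sii"] == pytest.approx(k * a["sii"], rel=1e-9)
    for name in ("nlr", "plr", "nlcr", "imi", "gcnli"):
        assert b[name] == pytest.approx(a[name], rel=1e-9)
    for name in ("glr", "clr", "misi"):
        assert b[name] == pytest.approx(a[name] / k, rel=1e-9)


def test_missing_inputs_propagate_not_imputed():
    panel = compute_index_panel(LabPanel(neutrophil_count=8,
                                         lymphocyte_count=2))
    assert panel.nlr == 4.0
    assert panel.imi is None and panel.glr is None and panel.misi is None
    assert panel.plr is None


@pytest.mark.parametrize("bad", [0.0, -1.0])
def test_zero_or_negative_lymphocytes_is_domain_error(bad):
    if bad < 0:
        with pytest.raises(InvalidLabValueError, match="lymphocyte_count"):
            make_labs(l=bad)
    else:
        with pytest.raises(InvalidLabValueError, match="lymphocyte_count"):
            compute_index_panel(make_labs(l=bad))


def test_negative_input_rejected_by_name():
    with pytest.raises(InvalidLabValueError, match="glucose"):
        LabPanel(glucose=-5.0)


def test_percent_policy_uses_percent_fields():
    labs = make_labs(neutrophil_pct=80.0, lymphocyte_pct=10.0)
    panel = compute_index_panel(labs, units_policy="percent")
    assert panel.nlr == pytest.approx(8.0)
    assert panel.units_policy == "percent"
    with pytest.raises(ValidationError):
        compute_index_panel(labs, units_policy="absolute")


class TestCutoffClassification:
    def test_published_preset_histopathological(self):
        panel = {"imi": 658.72}
        assert classify_at_cutoff(panel, "imi",
                                  classification="histopathological") == "positive"

    def test_published_preset_surgical(self):
        assert classify_at_cutoff({"misi": 54.82}, "misi",
                                  classification="surgical") == "positive"

    def test_tie_is_negative_under_strict_policy(self):
        assert classify_at_cutoff({"imi": 658.71}, "imi",
                                  cutoff=658.71) == "negative"
        assert classify_at_cutoff({"imi": 658.71}, "imi", cutoff=658.71,
                                  strict=False) == "positive"

    def test_missing_score_is_indeterminate(self):
        assert classify_at_cutoff({"imi": None}, "imi",
                                  cutoff=1.0) == "indeterminate"

    def test_unknown_index_rejected(self):
        with pytest.raises(ValidationError, match="unknown index"):
            classify_at_cutoff({"imi": 1.0}, "foo", cutoff=1.0)


class TestIndexCalculator:
    def test_matches_per_patient_computation(self, default_cohort):
        frame = compute_index_frame(default_cohort)
        row = default_cohort.iloc[7]
        labs = LabPanel(**{f: (None if pd.isna(row[f]) else float(row[f]))
                           for f in LabPanel.field_names()})
        panel = compute_index_panel(labs)
        for name in INDEX_NAMES:
            assert frame.iloc[7][name] == pytest.approx(panel.as_dict()[name])

    def test_sklearn_protocol(self):
        calc = IndexCalculator(units_policy="percent")
        assert clone(calc).get_params() == {"units_policy": "percent"}
        df = pd.DataFrame({"glucose": [100.0], "neutrophil_pct": [80.0],
                           "lymphocyte_pct": [10.0]})
        out = calc.fit_transform(df)
        assert list(out.columns) == list(INDEX_NAMES)
        assert out["glr"].iloc[0] == pytest.approx(10.0)
        assert np.isnan(out["plr"].iloc[0])

    def test_negative_column_rejected(self):
        df = pd.DataFrame({"glucose": [-1.0], "neutrophil_count": [1.0],
                           "lymphocyte_count": [1.0]})
        with pytest.raises(InvalidLabValueError, match="glucose"):
            compute_index_frame(df)
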