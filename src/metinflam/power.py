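"""Post-hoc power from odds ratios.

An odds ratio is mapped to an approximate standardized effect size by the
logistic-to-normal scaling d = ln(OR) * sqrt(3) / pi, and achieved power for
a two-group comparison at two-tailed alpha is the normal-approximation

    power = Phi(|d| / sqrt(1/n1 + 1/n2) - z_{1-a/2})
          + Phi(-|d| / sqrt(1/n1 + 1/n2) - z_{1-a/2}).

The opposite-tail term is negligible at the magnitudes of interest but is
kept so that d = 0 gives power = alpha exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .published import GROUP_SIZES, PUBLISHED_POWER_TABLE

__all__ = [
    "PowerResult",
    "or_to_cohens_d",
    "power_two_group",
    "power_table",
    "published_power_inputs",
]

_LOGIT_SCALE = np.sqrt(3.0) / np.pi


@dataclass
class PowerResult:
    odds_ratio: float
    n1: int
    n2: int
    alpha: float
    cohens_d: float
    power: float

    @property
    def power_rounded(self) -> float:
        return round(self.power, 3)


def or_to_cohens_d(odds_ratio: float) -> float:
    """Cohen's d from an odds ratio: d = ln(OR) * sqrt(3) / pi.

    Negative for OR < 1; zero at OR = 1.
    """
    odds_ratio = float(odds_ratio)
    if not odds_ratio > 0:
        raise ValidationError("odds ratio must be > 0")
    return float(np.log(odds_ratio) * _LOGIT_SCALE)


def power_two_group(d: float, n1: int, n2: int, alpha: float = 0.05) -> float:
    """Achieved two-tailed power of a standardized two-group difference."""
    if n1 < 2 or n2 < 2:
        raise ValidationError("group sizes must be >= 2")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    z = stats.norm.ppf(1 - alpha / 2)
    ncp = abs(float(d)) / np.sqrt(1 / n1 + 1 / n2)
    return float(stats.norm.cdf(ncp - z) + stats.norm.cdf(-ncp - z))


def power_table(rows, alpha: float = 0.05) -> pd.DataFrame:
    """Post-hoc power report from (label, OR, n1, n2) rows.

    Effect sizes and power are reported at 5 decimals, plus a 3-decimal
    rounded power column. Row-level errors propagate with the row label.
    """
    out = []
    for row in rows:
        label, odds, n1, n2 = row
        try:
            d = or_to_cohens_d(odds)
            p = power_two_group(d, int(n1), int(n2), alpha)
        except ValidationError as exc:
            raise ValidationError(f"row {label!r}: {exc}") from exc
        out.append({"index": label, "odds_ratio": odds,
                    "n1": int(n1), "n2": int(n2),
                    "effect_size": round(d, 5), "power": round(p, 5),
                    "power_rounded": round(p, 3)})
    report = pd.DataFrame(out, columns=["index", "odds_ratio", "n1", "n2",
                                        "effect_size", "power",
                                        "power_rounded"])
    report.attrs["alpha"] = alpha
    report.attrs["or_precision"] = "as-supplied"
    return report


def published_power_inputs(classification: str) -> list[tuple]:
    """(label, OR, n1, n2) rows from the published power table for one
    classification; inputs are the printed (rounded) odds ratios."""
    if classification not in PUBLISHED_POWER_TABLE:
        raise ValidationError(f"unknown classification {classification!r}")
    n1, n2 = GROUP_SIZES[classification]
    return [(label, odds, n1, n2)
            for label, odds, *_ in PUBLISHED_POWER_TABLE[classification]]
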