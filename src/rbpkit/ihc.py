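"""Composite immunohistochemistry scoring and grade association.

Staining intensity (0-3) and the percent of positive tumor cells (binned
0-3: 0 for none, 1 below 25%, 2 for the closed 25-75% bin, 3 above 75%) are
combined into a total expression score — by product under the operative rule,
with the alternative sum rule selectable — and classified: >= 6 strong (+++),
4-5 moderate (++), 1-3 weak (+), 0 null (-). "High expression" is moderate or
strong. Under the product rule the attainable totals are {0,1,2,3,4,6,9}, so
the printed moderate bound of 5 is reachable only under the sum rule; both
modes are kept for that reason.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd
from scipy import stats

__all__ = [
    "IHCSample",
    "IHCScore",
    "percent_category",
    "total_score",
    "classify",
    "score_sample",
    "grade_association",
]

CATEGORIES = ("null", "weak", "moderate", "strong")
LOW_GRADES = ("I", "II")
HIGH_GRADES = ("III", "IV")


@dataclass(frozen=True)
class IHCSample:
    sample_id: str
    intensity: int
    percent_positive: float
    grade: str | None = None  # WHO grade I-IV

    def __post_init__(self) -> None:
        if self.intensity not in (0, 1, 2, 3):
            raise ValueError("intensity must be one of 0, 1, 2, 3")
        if not (0 <= self.percent_positive <= 100):
            raise ValueError("percent_positive must lie in [0, 100]")
        if self.grade is not None and self.grade not in LOW_GRADES + HIGH_GRADES:
            raise ValueError("grade must be a WHO grade I-IV")


@dataclass(frozen=True)
class IHCScore:
    percent_category: int
    total: int
    category: str
    binary: str
    mode: str


def percent_category(pct: float) -> int:
    """Bin the percent of positive cells: 0 for none, 1 below 25%, 2 for
    25-75% inclusive, 3 above 75%."""
    if not (0 <= pct <= 100):
        raise ValueError("percent must lie in [0, 100]")
    if pct == 0:
        return 0
    if pct < 25:
        return 1
    if pct <= 75:
        return 2
    return 3


def total_score(intensity: int, pcat: int, mode: str = "product") -> int:
    """Combine intensity and percent category into the total expression score."""
    if intensity not in (0, 1, 2, 3) or pcat not in (0, 1, 2, 3):
        raise ValueError("intensity and percent category must be in 0-3")
    if mode == "product":
        return intensity * pcat
    if mode == "sum":
        return intensity + pcat
    raise ValueError("mode must be 'product' or 'sum'")


def classify(total: int) -> tuple[str, str]:
    """Map a total score to (category, binary expression level)."""
    if total < 0:
        raise ValueError("total score must be non-negative")
    if total >= 6:
        cat = "strong"
    elif total >= 4:
        cat = "moderate"
    elif total >= 1:
        cat = "weak"
    else:
        cat = "null"
    binary = "high" if cat in ("moderate", "strong") else "low"
    return cat, binary


def score_sample(sample: IHCSample, mode: str = "product") -> IHCScore:
    pcat = percent_category(sample.percent_positive)
    total = total_score(sample.intensity, pcat, mode)
    cat, binary = classify(total)
    return IHCScore(percent_category=pcat, total=total, category=cat, binary=binary, mode=mode)


def grade_association(
    samples: Iterable[IHCSample], mode: str = "product"
) -> tuple[float, float, pd.DataFrame]:
    """Pearson chi-square of binary expression (low/high) against grade group
    (low grade I-II vs high grade III-IV); no continuity correction. Returns
    (statistic, p, contingency table)."""
    rows = []
    for s in samples:
        if s.grade is None:
            continue
        grade_group = "low_grade" if s.grade in LOW_GRADES else "high_grade"
        rows.append({"grade_group": grade_group, "expression": score_sample(s, mode).binary})
    if not rows:
        raise ValueError("no graded samples")
    df = pd.DataFrame(rows)
    table = pd.crosstab(df["grade_group"], df["expression"])
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("degenerate contingency table: need variation in both margins")
    chi2, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return float(chi2), float(p), table
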