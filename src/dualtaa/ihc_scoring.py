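"""Immunohistochemistry quantification: H-scores, tiers, co-positivity.

The H-score condenses a slide's staining into a single number in [0, 300]:

    H = 1 * (% cells weak, 1+) + 2 * (% moderate, 2+) + 3 * (% strong, 3+)

Expression tiers are nested: positive (H > 0), medium (H >= 100), high
(H >= 200), with both tier boundaries inclusive. A sample is co-positive for
two markers when at least 1% of tumor cells stain for each marker, at any
intensity. Cohort positivity rates are reported as percentages rounded
half-up to one decimal, matching the rounding of published counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "IHCRecord",
    "HScore",
    "TIERS",
    "h_score",
    "tier_of",
    "meets_tier",
    "sample_co_positive",
    "cohort_positivity_rate",
    "tier_co_occurrence",
    "cohort_tier_co_occurrence",
    "read_ihc_table",
]

#: Tier thresholds on the H-score; positive additionally requires H > 0.
TIERS = {"positive": 0.0, "medium": 100.0, "high": 200.0}


@dataclass(frozen=True)
class IHCRecord:
    """Staining percentages of one marker on one sample."""

    sample_id: str
    marker: str
    pct_weak: float
    pct_moderate: float
    pct_strong: float

    def validate(self) -> None:
        pcts = (self.pct_weak, self.pct_moderate, self.pct_strong)
        if any(p < 0 or p > 100 for p in pcts):
            raise ValueError("staining percentages must lie in [0, 100]")
        if sum(pcts) > 100 + 1e-9:
            raise ValueError(
                f"staining percentages of {self.sample_id}/{self.marker} "
                f"sum to {sum(pcts):g} > 100"
            )

    @property
    def total_positive_pct(self) -> float:
        """Percentage of cells stained at any intensity."""
        return self.pct_weak + self.pct_moderate + self.pct_strong


@dataclass(frozen=True)
class HScore:
    sample_id: str
    marker: str
    value: float
    tier: str


def tier_of(value: float) -> str:
    if value >= TIERS["high"]:
        return "high"
    if value >= TIERS["medium"]:
        return "medium"
    if value > 0:
        return "positive"
    return "negative"


def h_score(record: IHCRecord) -> HScore:
    """Compute the H-score and its tier from staining percentages."""
    record.validate()
    value = record.pct_weak + 2 * record.pct_moderate + 3 * record.pct_strong
    return HScore(record.sample_id, record.marker, value, tier_of(value))


def meets_tier(score: HScore, tier: str) -> bool:
    """Whether the score reaches a (nested, inclusive) tier threshold."""
    if tier not in TIERS:
        raise ValueError(f"unknown tier {tier!r}; expected one of {sorted(TIERS)}")
    if tier == "positive":
        return score.value > 0
    return score.value >= TIERS[tier]


def sample_co_positive(
    rec_a: IHCRecord, rec_b: IHCRecord, min_pct: float = 1.0
) -> bool:
    """Dual staining call: >= ``min_pct`` cells stained for BOTH markers,
    regardless of intensity."""
    if rec_a.sample_id != rec_b.sample_id:
        raise ValueError(
            f"sample ids differ: {rec_a.sample_id!r} vs {rec_b.sample_id!r}"
        )
    rec_a.validate()
    rec_b.validate()
    return (
        rec_a.total_positive_pct >= min_pct and rec_b.total_positive_pct >= min_pct
    )


def cohort_positivity_rate(calls: Iterable[bool]) -> tuple[int, int, float]:
    """(n_positive, n_total, percentage rounded half-up to one decimal)."""
    calls = list(calls)
    if not calls:
        raise ValueError("empty cohort")
    n_pos = sum(bool(c) for c in calls)
    n_total = len(calls)
    pct = Decimal(100 * n_pos) / Decimal(n_total)
    return n_pos, n_total, float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def tier_co_occurrence(score_a: HScore, score_b: HScore, tier: str) -> bool:
    """Whether both markers of one sample reach the tier threshold."""
    if score_a.sample_id != score_b.sample_id:
        raise ValueError(
            f"sample ids differ: {score_a.sample_id!r} vs {score_b.sample_id!r}"
        )
    return meets_tier(score_a, tier) and meets_tier(score_b, tier)


def cohort_tier_co_occurrence(
    scores_a: Sequence[HScore], scores_b: Sequence[HScore], tier: str
) -> tuple[int, int, float]:
    """Cohort rate of dual tier attainment over paired score lists."""
    if len(scores_a) != len(scores_b):
        raise ValueError("paired score lists must have equal length")
    calls = [tier_co_occurrence(a, b, tier) for a, b in zip(scores_a, scores_b)]
    return cohort_positivity_rate(calls)


def read_ihc_table(path) -> list[IHCRecord]:
    """Read IHC records from CSV with columns sample_id, marker,
    pct_1plus, pct_2plus, pct_3plus."""
    df = pd.read_csv(path)
    required = {"sample_id", "marker", "pct_1plus", "pct_2plus", "pct_3plus"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"IHC table missing columns: {sorted(missing)}")
    records = [
        IHCRecord(
            str(r.sample_id), str(r.marker),
            float(r.pct_1plus), float(r.pct_2plus), float(r.pct_3plus),
        )
        for r in df.itertuples()
    ]
    for rec in records:
        rec.validate()
    return records
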