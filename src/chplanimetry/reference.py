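"""Cohort inclusion filters and the 50th-percentile reference standard.

Bone-age validation needs a subgroup whose chronological age can stand in
for skeletal age. The convention implemented here: a child qualifies if
their height lies within the growth chart's 50th-percentile band for
their age — between the median height of a child Δ months younger and Δ
months older (Δ = 1 below 36 months of age, Δ = 6 at or above), bounds
inclusive.

The shipped chart is synthetic (a smooth, strictly increasing
median-height curve per sex, clearly labelled as such); a real national
growth chart can be supplied as a CSV with columns
``sex, age_months, p50_height_cm``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SEXES = ("male", "female")

MIN_AGE_MONTHS = 1
MAX_AGE_MONTHS = 180  # inclusion cut-off: younger than 15 years
CHART_MAX_AGE_MONTHS = 216

#: age (months) at which the selection half-window widens from 1 to 6 months
WINDOW_SWITCH_AGE = 36


class ChartDomainError(KeyError):
    """Requested (sex, age) is outside the growth chart's domain."""


@dataclass
class GrowthChart:
    """Median (50th-percentile) height-for-age lookup table, monthly.

    ``table`` columns: sex, age_months, p50_height_cm. Heights must be
    strictly increasing in age within each sex; lookups are exact (no
    interpolation — the chart is monthly).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sex", "age_months", "p50_height_cm"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"growth chart missing columns: {sorted(missing)}")
        self.table = self.table.copy()
        self.table["age_months"] = self.table["age_months"].astype(int)
        for sex, grp in self.table.groupby("sex"):
            if sex not in SEXES:
                raise ValueError(f"unknown sex {sex!r} in growth chart")
            g = grp.sort_values("age_months")
            if g["age_months"].duplicated().any():
                raise ValueError(f"duplicate ages in growth chart for {sex}")
            if not np.all(np.diff(g["p50_height_cm"].to_numpy()) > 0):
                raise ValueError(f"growth chart not strictly increasing for {sex}")
        self._lut = {
            (row.sex, row.age_months): row.p50_height_cm
            for row in self.table.itertuples()
        }
        self._age_range = {
            sex: (int(g["age_months"].min()), int(g["age_months"].max()))
            for sex, g in self.table.groupby("sex")
        }

    def lookup(self, sex: str, age_months: int) -> float:
        """Exact 50th-percentile height (cm) for *sex* at *age_months*."""
        key = (sex, int(age_months))
        try:
            return float(self._lut[key])
        except KeyError:
            raise ChartDomainError(
                f"age {age_months} for sex {sex!r} outside chart domain"
            ) from None

    def age_range(self, sex: str) -> tuple[int, int]:
        return self._age_range[sex]


def chart_lookup(chart: GrowthChart, sex: str, age_months: int) -> float:
    """Functional form of :meth:`GrowthChart.lookup`."""
    return chart.lookup(sex, age_months)


def synthetic_growth_chart(max_age_months: int = CHART_MAX_AGE_MONTHS) -> GrowthChart:
    """A synthetic monotone median-height chart, ages 1..max_age_months.

    Shape: rapid infant growth saturating exponentially plus a slow
    linear component — strictly increasing by construction, with adult
    heights near 169 cm (male) / 160 cm (female). Synthetic stand-in for
    a national reference chart; not measured data.
    """
    ages = np.arange(1, max_age_months + 1)
    rows = []
    for sex, h0, gain, lin in (("male", 50.0, 65.0, 0.25), ("female", 49.5, 60.5, 0.232)):
        h = h0 + gain * (1.0 - np.exp(-ages / 30.0)) + lin * ages
        rows.append(pd.DataFrame({"sex": sex, "age_months": ages, "p50_height_cm": h}))
    return GrowthChart(pd.concat(rows, ignore_index=True))


# ---------------------------------------------------------------------------
# inclusion filters


def exclusion_reason(record: pd.Series) -> str:
    """Why a subject record fails the cohort inclusion criteria ('' if none).

    Criteria: PA radiographs of both hands, age 1-180 months, no
    excluded chronic diagnosis, majority ethnicity. The first failing
    criterion (in that order) is reported.
    """
    hands = str(record.get("hands_available", ""))
    have = {h for h in hands.replace(",", ";").split(";") if h}
    if have != {"left", "right"}:
        return "single-hand"
    age = record.get("age_months")
    try:
        age = int(age)
    except (TypeError, ValueError):
        return "malformed-age"
    if not (MIN_AGE_MONTHS <= age <= MAX_AGE_MONTHS):
        return "age"
    if bool(record.get("chronic_illness", False)):
        return "chronic-illness"
    if bool(record.get("other_ethnicity", False)):
        return "other-ethnicity"
    return ""


def apply_inclusion_filters(
    records: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition subject records into (included, exclusion_log).

    The log has one row per excluded record — columns ``subject_id``,
    ``reason`` — in stable input order. Malformed records become log
    entries rather than aborting the run.
    """
    reasons = records.apply(exclusion_reason, axis=1) if len(records) else pd.Series(dtype=str)
    keep = reasons == ""
    included = records.loc[keep].copy()
    log = pd.DataFrame(
        {
            "subject_id": records.loc[~keep, "subject_id"].to_numpy(),
            "reason": reasons[~keep].to_numpy(),
        }
    )
    return included, log


# ---------------------------------------------------------------------------
# 50th-percentile reference subgroup


def height_window(
    chart: GrowthChart, sex: str, age_months: int
) -> tuple[float, float]:
    """Inclusive height band [chart(a-Δ), chart(a+Δ)] for one child.

    Δ = 1 month below age 36 months, 6 months at or above. Window edges
    falling outside the chart domain are clamped to the domain edge.
    """
    delta = 1 if age_months < WINDOW_SWITCH_AGE else 6
    lo_age, hi_age = chart.age_range(sex)
    a_lo = max(age_months - delta, lo_age)
    a_hi = min(age_months + delta, hi_age)
    return chart.lookup(sex, a_lo), chart.lookup(sex, a_hi)


def select_fiftieth_percentile(
    records: pd.DataFrame, chart: GrowthChart
) -> pd.DataFrame:
    """Subjects whose height brackets the chart median for their age.

    A child of age *a* months with height *h* is selected iff
    chart(a-Δ) <= h <= chart(a+Δ) for their sex, Δ as in
    :func:`height_window`. Idempotent: re-selecting the selected
    subgroup returns it unchanged.
    """
    if len(records) == 0:
        return records.copy()
    keep = []
    for row in records.itertuples():
        lo, hi = height_window(chart, row.sex, int(row.age_months))
        keep.append(lo <= float(row.height_cm) <= hi)
    return records.loc[np.asarray(keep, dtype=bool)].copy()
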