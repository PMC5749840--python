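"""Seasonality index per year and stabilization detection.

The index contrasts each year's humid-season campaign (July–September)
with its driest-season campaign (January–March):

    SI = (humid − dry) / humid × 100   [percent]

SI near 100 means a strong seasonal contrast, near 0 means the contrast has
vanished, and negative values mean the normally dry month exceeded the
humid one (a full inversion of seasonality).  SI is undefined when the
humid-month value is 0 and is then recorded as absent rather than 0.
"""

from __future__ import annotations

import math

import pandas as pd

from .community_metrics import CHARACTERISTICS, CampaignSummary
from .errors import AmbiguityError, UndefinedIndexError

DRY_MONTHS = (1, 2, 3)
HUMID_MONTHS = (7, 8, 9)


def seasonality_index(dry_value: float, humid_value: float) -> float:
    """``(humid − dry) / humid × 100``; raises when the humid value is 0."""
    if humid_value == 0:
        raise UndefinedIndexError("seasonality index undefined: humid-month value is 0")
    return (humid_value - dry_value) / humid_value * 100.0


def _year_month(date: str) -> tuple[int, int]:
    y, m = date.split("-")
    return int(y), int(m)


def _pick(summaries: list[CampaignSummary], year: int, months: tuple[int, ...]):
    hits = [s for s in summaries if _year_month(s.date)[0] == year and _year_month(s.date)[1] in months]
    if len(hits) > 1:
        ids = [s.campaign_id for s in hits]
        raise AmbiguityError(
            f"year {year}: {len(hits)} campaigns {ids} fall in months {months}; expected at most one"
        )
    return hits[0] if hits else None


def _value(summary: CampaignSummary, characteristic: str) -> float | None:
    v = getattr(summary, characteristic)
    return None if v is None else float(v)


def si_series(summaries: list[CampaignSummary]) -> pd.DataFrame:
    """One SI record per (year, characteristic) where both seasonal
    endpoints exist and are usable.

    The Jul–Sep campaign stands in for "August" and the Jan–Mar campaign
    for "February", so e.g. a September campaign is a valid humid endpoint.
    Cover SI is absent for years where either endpoint campaign is
    cover-flagged (its ``mean_cover`` is already absent upstream).
    Returns columns ``year, characteristic, si``.
    """
    years = sorted({_year_month(s.date)[0] for s in summaries})
    rows = []
    for year in years:
        dry = _pick(summaries, year, DRY_MONTHS)
        humid = _pick(summaries, year, HUMID_MONTHS)
        if dry is None or humid is None:
            continue
        for ch in CHARACTERISTICS:
            dv, hv = _value(dry, ch), _value(humid, ch)
            if dv is None or hv is None:
                continue
            try:
                si = seasonality_index(dv, hv)
            except UndefinedIndexError:
                continue
            rows.append({"year": year, "characteristic": ch, "si": si})
    return pd.DataFrame(rows, columns=["year", "characteristic", "si"])


def detect_stabilization(
    series: pd.DataFrame, characteristic: str, tol: float = 10.0
) -> int | None:
    """Earliest year ``y`` such that ``|SI_y − SI_{y+1}| ≤ tol`` for
    consecutive years; None when the series never settles.
    """
    sub = (
        series[series["characteristic"] == characteristic]
        .sort_values("year")
        .reset_index(drop=True)
    )
    for i in range(len(sub) - 1):
        if int(sub.loc[i + 1, "year"]) != int(sub.loc[i, "year"]) + 1:
            continue
        if math.isfinite(sub.loc[i, "si"]) and abs(sub.loc[i, "si"] - sub.loc[i + 1, "si"]) <= tol:
            return int(sub.loc[i, "year"])
    return None
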