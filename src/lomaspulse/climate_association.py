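"""Rank-correlation screens of community responses against monthly climate.

Two screens, corrected as two separate Bonferroni families:

* the *characteristic screen* — the five per-campaign community
  characteristics against precipitation and temperature (family of 10 tests);
* the *species screen* — per-campaign densities of the k most abundant
  species against the same two predictors (family of 2k tests).

Spearman's rho uses midranks for ties; two-sided p-values come from the
t-approximation on n − 2 degrees of freedom (the conventional default at
the sample sizes involved here).  Climate is joined by the calendar month
of each campaign, with an optional lag in months.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .community_metrics import CHARACTERISTICS, CampaignSummary, top_abundant_species
from .errors import UndefinedIndexError
from .survey_io import ClimateSeries, SurveyTable

PREDICTORS = ("precipitation", "temperature")
_PRED_COL = {"precipitation": "precip_mm", "temperature": "temp_c"}


@dataclass(frozen=True)
class CorrelationResult:
    response: str
    predictor: str
    rho: float
    p: float
    p_bonf: float
    m: int  # family size used for the Bonferroni adjustment
    n: int  # paired observations


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho and two-sided p (midranks, t-approximation on n−2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D series of equal length")
    if x.size < 3:
        raise ValueError(f"need at least 3 paired observations, got {x.size}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedIndexError("Spearman rho undefined for a constant series")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def bonferroni(p: float, m: int) -> float:
    """Exactly ``min(1, m·p)``."""
    return min(1.0, m * p)


def _shift_month(month: str, lag: int) -> str:
    return str(pd.Period(month, freq="M") - lag)


def _climate_vector(
    climate: ClimateSeries, dates: list[str], predictor: str, lag: int
) -> np.ndarray:
    col = _PRED_COL[predictor]
    out = []
    for d in dates:
        month = _shift_month(d, lag)
        row = climate.data[climate.data["month"] == month]
        if row.empty:
            raise LookupError(f"campaign month {month} missing from climate series")
        out.append(float(row[col].iloc[0]))
    return np.asarray(out)


def characteristic_screen(
    summaries: list[CampaignSummary],
    climate: ClimateSeries,
    *,
    lag: int = 0,
) -> list[CorrelationResult]:
    """Correlate each community characteristic with each climate predictor.

    Cover-flagged campaigns (``mean_cover`` absent) are dropped pairwise for
    the mean-cover tests only; the family size stays 5 × 2 = 10.
    """
    m = len(CHARACTERISTICS) * len(PREDICTORS)
    results = []
    for ch in CHARACTERISTICS:
        pairs = [
            (s.date, getattr(s, ch)) for s in summaries if getattr(s, ch) is not None
        ]
        dates = [d for d, _ in pairs]
        values = np.asarray([v for _, v in pairs], dtype=float)
        for pred in PREDICTORS:
            clim = _climate_vector(climate, dates, pred, lag)
            rho, p = spearman(values, clim)
            results.append(
                CorrelationResult(ch, pred, rho, p, bonferroni(p, m), m, len(values))
            )
    return results


def species_density_by_campaign(table: SurveyTable, species: list[str]) -> pd.DataFrame:
    """Per-campaign density (ind·m⁻², pooled over plots / roster size) for
    the given species; campaigns in chronological order."""
    n_plots = len(table.plots)
    recs = table.records[table.records["species"].isin(species)]
    pooled = (
        recs.groupby(["campaign_id", "species"])["abundance"].sum().unstack(fill_value=0)
    )
    pooled = pooled.reindex(
        index=table.campaign_ids, columns=species, fill_value=0
    ).astype(float)
    return pooled / n_plots


def species_screen(
    table: SurveyTable,
    climate: ClimateSeries,
    k: int = 20,
    *,
    lag: int = 0,
) -> list[CorrelationResult]:
    """Correlate the densities of the k most abundant species with climate.

    Family size is 2k.  Species whose density is constant across campaigns
    (cannot happen for a top-k species unless every campaign has the same
    pooled count) are skipped with an undefined-rho error propagated.
    """
    species = top_abundant_species(table, k)
    density = species_density_by_campaign(table, species)
    dates = [table.campaign_date(cid) for cid in density.index]
    m = 2 * k
    results = []
    for pred in PREDICTORS:
        clim = _climate_vector(climate, dates, pred, lag)
        for sp in species:
            rho, p = spearman(density[sp].to_numpy(), clim)
            results.append(
                CorrelationResult(sp, pred, rho, p, bonferroni(p, m), m, len(dates))
            )
    return results


def results_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "response": r.response,
                "predictor": r.predictor,
                "rho": r.rho,
                "p": r.p,
                "p_bonf": r.p_bonf,
                "n": r.n,
                "m": r.m,
            }
            for r in results
        ]
    )
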