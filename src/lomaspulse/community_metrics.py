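"""Per-plot and per-campaign community characteristics.

Five characteristics are computed per campaign:

* **density** — individuals per m², summed over species within a plot;
* **cover** — cm² of projected vegetation per m² plot, summed over species;
* **alpha diversity** — Shannon index (log base 2 by default) on within-plot
  relative abundances; zero for a plot with a single species;
* **gamma diversity** — the same index on abundances pooled over all plots
  of the campaign (whole-study-area scale);
* **total richness** — number of species with pooled abundance > 0.

Campaign means and ranges are taken over the *full plot roster*: plots with
no records contribute density 0, cover 0 and alpha 0.  The importance value
index per species is the average of its relative abundance and relative
cover within a campaign, so each campaign's IVI column sums to exactly 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedIndexError
from .survey_io import SurveyTable

CHARACTERISTICS = ("mean_density", "mean_cover", "mean_alpha", "gamma", "richness")


def shannon(counts, base: float = 2.0) -> float:
    """Shannon diversity ``H = -Σ p_i log(p_i)`` of a vector of abundances.

    Zeros are ignored; an empty or all-zero vector has H = 0 (no
    individuals ⇒ no diversity), as does a single-species vector.
    """
    c = np.asarray(counts, dtype=float)
    c = c[c > 0]
    if c.size == 0:
        return 0.0
    p = c / c.sum()
    return float(-(p * (np.log(p) / np.log(base))).sum()) + 0.0


@dataclass(frozen=True)
class CampaignSummary:
    """Table-1-style per-campaign aggregate.  ``mean_cover``/``cover_range``
    are None when the campaign's cover is flagged as overestimated."""

    campaign_id: str
    date: str
    mean_density: float
    density_range: tuple[float, float]
    mean_cover: float | None
    cover_range: tuple[float, float] | None
    mean_alpha: float
    alpha_range: tuple[float, float]
    gamma: float
    richness: int


def plot_metrics(
    table: SurveyTable, campaign_id: str, *, base: float = 2.0
) -> pd.DataFrame:
    """Per-plot density, cover and Shannon alpha for one campaign.

    Returns one row per roster plot (empty plots included with zeros),
    indexed 0..n_plots-1, columns
    ``campaign_id, plot_id, density, cover, alpha``.
    """
    recs = table.campaign_records(campaign_id)
    grouped = recs.groupby("plot_id")
    density = grouped["abundance"].sum()
    cover = grouped["cover_cm2"].sum()
    alpha = grouped["abundance"].apply(lambda a: shannon(a, base=base))
    rows = []
    for plot in table.plots:
        rows.append(
            {
                "campaign_id": campaign_id,
                "plot_id": plot,
                "density": float(density.get(plot, 0.0)),
                "cover": float(cover.get(plot, 0.0)),
                "alpha": float(alpha.get(plot, 0.0)),
            }
        )
    return pd.DataFrame(rows)


def all_plot_metrics(table: SurveyTable, *, base: float = 2.0) -> pd.DataFrame:
    """``plot_metrics`` stacked over every campaign, in campaign order."""
    return pd.concat(
        [plot_metrics(table, cid, base=base) for cid in table.campaign_ids],
        ignore_index=True,
    )


def campaign_summary(
    table: SurveyTable, campaign_id: str, *, base: float = 2.0
) -> CampaignSummary:
    """Aggregate one campaign over the full plot roster."""
    pm = plot_metrics(table, campaign_id, base=base)
    recs = table.campaign_records(campaign_id)
    pooled = recs.groupby("species")["abundance"].sum()
    flagged = table.is_cover_flagged(campaign_id)
    return CampaignSummary(
        campaign_id=campaign_id,
        date=table.campaign_date(campaign_id),
        mean_density=float(pm["density"].mean()),
        density_range=(float(pm["density"].min()), float(pm["density"].max())),
        mean_cover=None if flagged else float(pm["cover"].mean()),
        cover_range=None
        if flagged
        else (float(pm["cover"].min()), float(pm["cover"].max())),
        mean_alpha=float(pm["alpha"].mean()),
        alpha_range=(float(pm["alpha"].min()), float(pm["alpha"].max())),
        gamma=shannon(pooled.to_numpy(), base=base),
        richness=int((pooled > 0).sum()),
    )


def all_campaign_summaries(
    table: SurveyTable, *, base: float = 2.0
) -> list[CampaignSummary]:
    return [campaign_summary(table, cid, base=base) for cid in table.campaign_ids]


def summaries_frame(summaries: list[CampaignSummary]) -> pd.DataFrame:
    """Flatten summaries into a DataFrame (None covers become NaN)."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "campaign_id": s.campaign_id,
                "date": s.date,
                "mean_density": s.mean_density,
                "density_min": s.density_range[0],
                "density_max": s.density_range[1],
                "mean_cover": np.nan if s.mean_cover is None else s.mean_cover,
                "cover_min": np.nan if s.cover_range is None else s.cover_range[0],
                "cover_max": np.nan if s.cover_range is None else s.cover_range[1],
                "mean_alpha": s.mean_alpha,
                "alpha_min": s.alpha_range[0],
                "alpha_max": s.alpha_range[1],
                "gamma": s.gamma,
                "richness": s.richness,
            }
        )
    return pd.DataFrame(rows)


def ivi(table: SurveyTable, campaign_id: str) -> pd.Series:
    """Importance value of every species present in a campaign.

    ``IVI_i = (n_i / N_t + c_i / C_t) / 2`` where n is abundance and c is
    cover; the result sums to 1 over the campaign's species.  Cover is used
    even for cover-flagged campaigns because only relative values enter.
    """
    recs = table.campaign_records(campaign_id)
    n = recs.groupby("species")["abundance"].sum().astype(float)
    c = recs.groupby("species")["cover_cm2"].sum().astype(float)
    if n.sum() <= 0:
        raise UndefinedIndexError(
            f"IVI undefined: campaign {campaign_id!r} has zero total abundance"
        )
    if c.sum() <= 0:
        raise UndefinedIndexError(
            f"IVI undefined: campaign {campaign_id!r} has zero total cover"
        )
    if ((n > 0) & (c == 0)).any():
        warnings.warn(
            f"campaign {campaign_id!r}: species with individuals but zero cover "
            "contribute only through the abundance term",
            stacklevel=2,
        )
    values = (n / n.sum() + c / c.sum()) / 2.0
    values.name = campaign_id
    return values.sort_index()


def ivi_matrix(table: SurveyTable) -> pd.DataFrame:
    """Species × campaign matrix of importance values.

    Rows: every species observed anywhere, sorted; columns: campaigns in
    chronological order.  Absent species have entry 0; each column sums to 1.
    """
    cols = {cid: ivi(table, cid) for cid in table.campaign_ids}
    mat = pd.DataFrame(index=table.species)
    for cid, col in cols.items():
        mat[cid] = col.reindex(mat.index).fillna(0.0)
    return mat


def top_abundant_species(table: SurveyTable, k: int) -> list[str]:
    """The ``k`` species with the highest total abundance over all campaigns.

    Ties are broken lexicographically by species label.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    totals = table.records.groupby("species")["abundance"].sum()
    if k > len(totals):
        raise ValueError(f"k={k} exceeds the {len(totals)} observed species")
    ranked = totals.sort_index().sort_values(ascending=False, kind="stable")
    return list(ranked.index[:k])


# Print precisions used by report writers (internal math is full precision):
# 1 decimal for density, nearest integer for cover, 2 decimals for diversity.
REPORT_ROUNDING = {
    "mean_density": 1,
    "mean_cover": 0,
    "mean_alpha": 2,
    "gamma": 2,
}


def round_for_report(value: float, characteristic: str) -> float:
    nd = REPORT_ROUNDING.get(characteristic)
    if nd is None:
        return value
    rounded = round(value, nd)
    return int(rounded) if nd == 0 else rounded
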