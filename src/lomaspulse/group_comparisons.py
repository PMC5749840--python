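"""Between-campaign and between-zone tests on per-plot values.

All unordered campaign pairs are compared with paired t-tests on
log10(x + 1)-transformed per-plot values (the +1 accommodates the zeros of
empty plots), Bonferroni-corrected over the pairs actually tested for each
characteristic.  Zone differences use the Kruskal–Wallis rank test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .community_metrics import all_plot_metrics
from .survey_io import SurveyTable

PLOT_CHARACTERISTICS = ("density", "cover", "alpha")


def log10p1(x):
    """Default transform before paired differencing: log10(x + 1)."""
    return np.log10(np.asarray(x, dtype=float) + 1.0)


@dataclass(frozen=True)
class PairwiseTestResult:
    campaign_a: str
    campaign_b: str
    characteristic: str
    t: float
    df: int
    p: float
    p_bonf: float
    n_pairs: int


@dataclass(frozen=True)
class ZoneTestResult:
    characteristic: str
    campaign_id: str  # a campaign or "all"
    h: float
    df: int
    p: float


def paired_t(x, y) -> tuple[float, int, float]:
    """Paired t-test of x vs y; returns (t, df, p).

    A degenerate comparison (all paired differences zero) yields t = 0,
    p = 1 rather than an exception.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = x - y
    if np.allclose(d, 0) or np.std(d, ddof=1) == 0:
        return 0.0, len(d) - 1, 1.0
    t, p = stats.ttest_rel(x, y)
    return float(t), len(d) - 1, float(p)


def paired_campaign_tests(
    table: SurveyTable,
    characteristic: str,
    *,
    transform: Callable = log10p1,
    base: float = 2.0,
) -> list[PairwiseTestResult]:
    """Paired t-tests between every unordered pair of campaigns.

    For cover, cover-flagged campaigns are excluded before pairing, so 15
    campaigns with 2 flags test 13·12/2 = 78 pairs instead of 105.  The
    Bonferroni family size is the number of pairs actually tested for this
    characteristic.
    """
    if characteristic not in PLOT_CHARACTERISTICS:
        raise ValueError(f"characteristic must be one of {PLOT_CHARACTERISTICS}")
    metrics = all_plot_metrics(table, base=base)
    campaigns = list(table.campaign_ids)
    if characteristic == "cover":
        campaigns = [c for c in campaigns if not table.is_cover_flagged(c)]
    if len(campaigns) < 2:
        raise ValueError("need at least 2 campaigns to compare")

    wide = metrics.pivot(index="plot_id", columns="campaign_id", values=characteristic)
    pairs = list(itertools.combinations(campaigns, 2))
    m = len(pairs)
    results = []
    for a, b in pairs:
        sub = wide[[a, b]].dropna()
        xa = transform(sub[a].to_numpy())
        xb = transform(sub[b].to_numpy())
        t, df, p = paired_t(xa, xb)
        results.append(
            PairwiseTestResult(a, b, characteristic, t, df, p, min(1.0, m * p), len(sub))
        )
    return results


def pairwise_frame(results: list[PairwiseTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "campaign_a": r.campaign_a,
                "campaign_b": r.campaign_b,
                "characteristic": r.characteristic,
                "t": r.t,
                "df": r.df,
                "p": r.p,
                "p_bonf": r.p_bonf,
                "n_pairs": r.n_pairs,
            }
            for r in results
        ]
    )


def kruskal_zones(
    table: SurveyTable,
    characteristic: str,
    campaign_id: str = "all",
    *,
    zones: dict[str, str] | None = None,
    base: float = 2.0,
) -> ZoneTestResult:
    """Kruskal–Wallis H across tourist-use zones (midrank ties correction).

    ``campaign_id="all"`` pools every plot × campaign value; a specific
    campaign tests that campaign's 31 plot values only.  The plot→zone map
    defaults to the zones recorded in the survey; plots without a zone
    (e.g. never-observed roster plots when no map is given) are dropped.
    """
    if characteristic not in PLOT_CHARACTERISTICS:
        raise ValueError(f"characteristic must be one of {PLOT_CHARACTERISTICS}")
    metrics = all_plot_metrics(table, base=base)
    if campaign_id != "all":
        metrics = metrics[metrics["campaign_id"] == campaign_id]
        if metrics.empty:
            raise LookupError(f"unknown campaign_id {campaign_id!r}")
    if zones is not None:
        zone_of = pd.Series(zones)
    else:
        zone_of = (
            table.records[["plot_id", "zone"]]
            .drop_duplicates()
            .set_index("plot_id")["zone"]
        )
    metrics = metrics.assign(zone=metrics["plot_id"].map(zone_of))
    metrics = metrics.dropna(subset=["zone"])
    groups = [g[characteristic].to_numpy() for _, g in metrics.groupby("zone")]
    if len(groups) < 2:
        raise ValueError("need at least 2 zones with plots")
    if all(np.all(g == groups[0][0]) for g in groups):
        # identical constant values in every group: no rank variation
        return ZoneTestResult(characteristic, campaign_id, 0.0, len(groups) - 1, 1.0)
    h, p = stats.kruskal(*groups)
    if math.isnan(h):  # all values tied across groups
        h, p = 0.0, 1.0
    return ZoneTestResult(characteristic, campaign_id, float(h), len(groups) - 1, float(p))


def compact_letters(
    results: list[PairwiseTestResult], alpha: float = 0.05
) -> dict[str, str]:
    """Greedy compact-letter display from the pairwise significance matrix.

    Campaigns sharing a letter are *not* significantly different at
    ``p_bonf < alpha``.  A reporting convenience, not an inferential method:
    the greedy insertion order (chronological) determines the lettering.
    """
    campaigns: list[str] = []
    for r in results:
        for c in (r.campaign_a, r.campaign_b):
            if c not in campaigns:
                campaigns.append(c)
    differs = {
        frozenset((r.campaign_a, r.campaign_b)) for r in results if r.p_bonf < alpha
    }
    letters: list[set[str]] = []  # each set = campaigns sharing one letter
    for c in campaigns:
        placed = False
        for group in letters:
            if all(frozenset((c, other)) not in differs for other in group):
                group.add(c)
                placed = True
        if not placed:
            letters.append({c})
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {c: "" for c in campaigns}
    for i, group in enumerate(letters):
        for c in campaigns:
            if c in group:
                out[c] += alphabet[i % len(alphabet)]
    return out
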