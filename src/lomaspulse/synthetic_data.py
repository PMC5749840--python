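"""Synthetic survey generator with known ground truth.

Emulates the statistical structure the analysis assumes: a fixed panel of
plots visited in repeated campaigns, a lognormal rank-abundance law with a
tunable dominance parameter, per-species precipitation responses for a
configurable fraction of "responder" species, negative-binomial counts
(zero inflation arises through the seasonal mean, not a separate mixture),
and per-record cover equal to the count times a lognormal individual size.

The default climate is a 4-year monthly series: a dry-season/humid-season
sinusoid topping out around 30 mm plus a ~100 mm wet pulse in designated
months (an "ENSO year" at the start of the record).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survey_io import ClimateSeries, SurveyTable, build_survey_table

_MONTH_ABBR = [
    "Jan", "Feb", "Mar", "Apr", "May", "Jun",
    "Jul", "Aug", "Sep", "Oct", "Nov", "Dec",
]


def default_precip_series(
    n_months: int = 48,
    start_year: int = 1998,
    *,
    amplitude: float = 30.0,
    pulse_months: tuple[int, ...] = (0, 1, 2, 3),
    pulse_mm: float = 100.0,
) -> pd.DataFrame:
    """Monthly climate: seasonal sinusoid peaking in August plus a wet
    pulse (default: the first four months of the record)."""
    months, precip, temp = [], [], []
    for i in range(n_months):
        year = start_year + i // 12
        mon = i % 12 + 1
        months.append(f"{year:04d}-{mon:02d}")
        seasonal = amplitude * max(0.0, np.cos((mon - 8) / 12 * 2 * np.pi))
        p = seasonal + (pulse_mm if i in pulse_months else 0.0)
        precip.append(round(p, 1))
        temp.append(round(18.0 + 4.5 * np.cos((mon - 2) / 12 * 2 * np.pi), 1))
    return pd.DataFrame({"month": months, "precip_mm": precip, "temp_c": temp})


def default_campaign_months(n_campaigns: int = 15, start_year: int = 1998) -> list[str]:
    """Quarterly campaign months (Feb, May, Aug, Nov of successive years)."""
    months = []
    year, cycle = start_year, [2, 5, 8, 11]
    i = 0
    while len(months) < n_campaigns:
        months.append(f"{year + i // 4:04d}-{cycle[i % 4]:02d}")
        i += 1
    return months


@dataclass(frozen=True)
class SimulationConfig:
    n_plots: int = 31
    n_campaigns: int = 15
    n_species: int = 60
    seed: int = 0
    precip_series: pd.DataFrame | None = None  # defaults to default_precip_series()
    responder_fraction: float = 0.3
    response_strength: float = 1.0  # b_i scale for responders
    dominance: float = 1.0  # sd of the lognormal rank-abundance law
    dispersion: float = 2.0  # negative-binomial size parameter (larger = closer to Poisson)
    cover_size_log_sd: float = 0.6
    base_log_abundance: float = -1.0
    plot_effect_sd: float = 0.5
    season_floor: float = 0.05  # relative mean outside the growing season

    def __post_init__(self):
        if min(self.n_plots, self.n_campaigns, self.n_species) < 1:
            raise ValueError("n_plots, n_campaigns and n_species must be positive")
        if not 0 <= self.responder_fraction <= 1:
            raise ValueError("responder_fraction must lie in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted, serialized next to the outputs so tests
    and reports never have to re-derive it."""

    species: list[str]
    b: dict[str, float]  # per-species precipitation response (log scale)
    responders: list[str]
    base_log_abundance: dict[str, float]
    campaign_months: list[str]
    config: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "species": self.species,
                    "b": self.b,
                    "responders": self.responders,
                    "base_log_abundance": self.base_log_abundance,
                    "campaign_months": self.campaign_months,
                    "config": self.config,
                },
                fh,
                indent=1,
                sort_keys=True,
            )


def _campaign_label(month: str) -> str:
    y, m = month.split("-")
    return f"{_MONTH_ABBR[int(m) - 1]}-{y[2:]}"


def simulate_survey(
    config: SimulationConfig,
) -> tuple[SurveyTable, ClimateSeries, GroundTruth]:
    """Generate a survey table, its climate series and the planted truth.

    Expected count of species i in plot j at campaign t:

        mu = season_t · exp(a_i + b_i·log(1 + P_t) + e_j)

    where ``a_i`` follows the lognormal rank-abundance law (sd =
    ``dominance``), ``b_i`` is ``response_strength``-scaled for responder
    species and 0 otherwise, ``e_j`` is a plot effect, ``P_t`` the monthly
    precipitation and ``season_t`` a soft growing-season factor that
    supplies the structural zeros of the dry season.  Counts are negative
    binomial; cover per record is the count times a lognormal size draw.
    Fixed seed ⇒ bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    climate_df = (
        config.precip_series
        if config.precip_series is not None
        else default_precip_series()
    )
    climate = ClimateSeries(data=climate_df.reset_index(drop=True))

    start_year = int(climate_df["month"].iloc[0].split("-")[0])
    campaign_months = default_campaign_months(config.n_campaigns, start_year)
    known = set(climate_df["month"])
    missing = [m for m in campaign_months if m not in known]
    if missing:
        raise ValueError(f"campaign months {missing} absent from precip_series")

    species = [f"species_{i:03d}" for i in range(config.n_species)]
    plots = [f"P{j:02d}" for j in range(config.n_plots)]
    zones = rng.permutation(
        [("low", "medium", "high")[j % 3] for j in range(config.n_plots)]
    )

    a = config.base_log_abundance + rng.normal(0.0, config.dominance, config.n_species)
    n_resp = int(round(config.responder_fraction * config.n_species))
    responder_idx = rng.choice(config.n_species, size=n_resp, replace=False)
    b = np.zeros(config.n_species)
    b[responder_idx] = config.response_strength * (
        0.75 + 0.5 * rng.random(n_resp)
    )
    plot_effect = rng.normal(0.0, config.plot_effect_sd, config.n_plots)

    rows = []
    for month in campaign_months:
        cid = _campaign_label(month)
        precip, _temp = climate.lookup(month)
        mon = int(month.split("-")[1])
        in_season = mon in (6, 7, 8, 9) or precip > 20
        season = 1.0 if in_season else config.season_floor
        log_p = np.log1p(precip)
        for j, plot in enumerate(plots):
            log_mu = np.clip(a + b * log_p + plot_effect[j] + np.log(season), -700, 80)
            mu = np.exp(log_mu)
            # NB(mean mu, size k) via gamma-Poisson mixture; the rate cap
            # keeps extreme dominance settings inside Poisson's range
            # without flattening the ratios between abundant species
            lam = np.minimum(rng.gamma(config.dispersion, mu / config.dispersion), 1e12)
            counts = rng.poisson(lam)
            present = np.flatnonzero(counts)
            sizes = np.exp(rng.normal(2.5, config.cover_size_log_sd, len(present)))
            for idx, sp_i in enumerate(present):
                rows.append(
                    {
                        "campaign_id": cid,
                        "date": month,
                        "plot_id": plot,
                        "zone": zones[j],
                        "species": species[sp_i],
                        "abundance": int(counts[sp_i]),
                        "cover_cm2": round(float(counts[sp_i] * sizes[idx]), 2),
                    }
                )

    df = pd.DataFrame(
        rows,
        columns=[
            "campaign_id",
            "date",
            "plot_id",
            "zone",
            "species",
            "abundance",
            "cover_cm2",
        ],
    )
    table = build_survey_table(df, plots, cover_cap=float("inf"))
    truth = GroundTruth(
        species=species,
        b={s: float(v) for s, v in zip(species, b)},
        responders=[species[i] for i in sorted(responder_idx)],
        base_log_abundance={s: float(v) for s, v in zip(species, a)},
        campaign_months=campaign_months,
        config={
            "n_plots": config.n_plots,
            "n_campaigns": config.n_campaigns,
            "n_species": config.n_species,
            "seed": config.seed,
            "responder_fraction": config.responder_fraction,
            "response_strength": config.response_strength,
            "dominance": config.dominance,
            "dispersion": config.dispersion,
        },
    )
    return table, climate, truth


def fixture_small() -> SurveyTable:
    """Deterministic 3-campaign × 4-plot × 5-species table with
    hand-computable metrics.

    By construction: plot P1 in campaign C1 has abundances (2, 1, 1), so
    its Shannon alpha is 1.5 bits; campaign richness is (5, 3, 2).
    """
    rows = [
        # C1 (1998-02): all five species somewhere; P1 holds (2,1,1)
        ("C1", "1998-02", "P1", "low", "sp_a", 2, 40.0),
        ("C1", "1998-02", "P1", "low", "sp_b", 1, 15.0),
        ("C1", "1998-02", "P1", "low", "sp_c", 1, 5.0),
        ("C1", "1998-02", "P2", "medium", "sp_b", 3, 60.0),
        ("C1", "1998-02", "P2", "medium", "sp_d", 2, 25.0),
        ("C1", "1998-02", "P3", "high", "sp_e", 4, 100.0),
        # C2 (1998-05): three species
        ("C2", "1998-05", "P1", "low", "sp_a", 5, 80.0),
        ("C2", "1998-05", "P2", "medium", "sp_b", 2, 30.0),
        ("C2", "1998-05", "P3", "high", "sp_c", 1, 10.0),
        ("C2", "1998-05", "P4", "high", "sp_a", 1, 12.0),
        # C3 (1998-08): two species
        ("C3", "1998-08", "P2", "medium", "sp_d", 6, 90.0),
        ("C3", "1998-08", "P4", "high", "sp_e", 2, 20.0),
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "campaign_id",
            "date",
            "plot_id",
            "zone",
            "species",
            "abundance",
            "cover_cm2",
        ],
    )
    return build_survey_table(df, ["P1", "P2", "P3", "P4"])
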