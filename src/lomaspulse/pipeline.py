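"""End-to-end orchestration: run every analysis stage from one config.

All writers are deterministic: fixed column order, fixed float formatting,
no timestamps — running twice on the same inputs yields byte-identical
outputs.  On a stage failure every file written so far is removed and the
error is re-raised with the stage name prepended.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import pandas as pd

from . import __version__
from .climate_association import characteristic_screen, results_frame, species_screen
from .community_metrics import (
    all_campaign_summaries,
    all_plot_metrics,
    ivi_matrix,
    summaries_frame,
)
from .group_comparisons import (
    PLOT_CHARACTERISTICS,
    compact_letters,
    kruskal_zones,
    pairwise_frame,
    paired_campaign_tests,
)
from .ordination import dca
from .seasonality import detect_stabilization, si_series
from .survey_io import flag_overestimated_cover, read_climate, read_survey

FLOAT_FMT = "%.10g"


@dataclass(frozen=True)
class RunConfig:
    survey_path: str
    climate_path: str
    out_dir: str
    flag_cover: tuple[str, ...] = ()
    plot_roster: tuple[str, ...] | None = None
    species_k: int = 20
    si_tol: float = 10.0
    dca_segments: int = 26
    dca_downweight: bool = True
    log_base: float = 2.0
    climate_lag: int = 0

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class _Sink:
    out_dir: str
    written: list[str] = field(default_factory=list)

    def path(self, name: str) -> str:
        os.makedirs(self.out_dir, exist_ok=True)
        p = os.path.join(self.out_dir, name)
        self.written.append(p)
        return p

    def tsv(self, df: pd.DataFrame, name: str, index: bool = False) -> None:
        df.to_csv(self.path(name), sep="\t", index=index, float_format=FLOAT_FMT)

    def json(self, obj, name: str) -> None:
        with open(self.path(name), "w") as fh:
            json.dump(obj, fh, indent=1, sort_keys=True)
            fh.write("\n")

    def rollback(self) -> None:
        for p in self.written:
            if os.path.exists(p):
                os.remove(p)


def run_all(config: RunConfig) -> dict:
    """Execute the whole pipeline and return the run summary dict."""
    sink = _Sink(config.out_dir)
    stage = "setup"
    try:
        stage = "survey_io"
        table = read_survey(
            config.survey_path,
            list(config.plot_roster) if config.plot_roster else None,
        )
        if config.flag_cover:
            table = flag_overestimated_cover(table, list(config.flag_cover))
        climate = read_climate(config.climate_path)

        stage = "community_metrics"
        summaries = all_campaign_summaries(table, base=config.log_base)
        sdf = summaries_frame(summaries)
        sink.tsv(sdf, "campaign_summary.tsv")
        sink.tsv(all_plot_metrics(table, base=config.log_base), "plot_metrics.tsv")
        ivi = ivi_matrix(table)
        sink.tsv(ivi, "ivi_matrix.tsv", index=True)

        stage = "ordination"
        ord_res = dca(
            ivi,
            n_axes=2,
            downweight=config.dca_downweight,
            n_segments=config.dca_segments,
        )
        sink.tsv(ord_res.site_scores, "dca_site_scores.tsv", index=True)
        sink.tsv(ord_res.species_scores, "dca_species_scores.tsv", index=True)
        sink.tsv(
            pd.DataFrame(
                {
                    "axis": [f"axis{i+1}" for i in range(len(ord_res.eigenvalues))],
                    "eigenvalue": ord_res.eigenvalues,
                    "inertia_fraction": ord_res.axis_inertia_fraction,
                }
            ),
            "dca_eigenvalues.tsv",
        )

        stage = "seasonality"
        si = si_series(summaries)
        sink.tsv(si, "seasonality.tsv")
        stab = {
            ch: detect_stabilization(si, ch, tol=config.si_tol)
            for ch in sorted(si["characteristic"].unique())
        }
        sink.json(stab, "stabilization.json")

        stage = "climate_association"
        char_res = characteristic_screen(summaries, climate, lag=config.climate_lag)
        sink.tsv(results_frame(char_res), "correlations_characteristics.tsv")
        k = min(config.species_k, len(table.species))
        spec_res = species_screen(table, climate, k, lag=config.climate_lag)
        sink.tsv(results_frame(spec_res), "correlations_species.tsv")

        stage = "group_comparisons"
        zone_rows = []
        for ch in PLOT_CHARACTERISTICS:
            tests = paired_campaign_tests(table, ch, base=config.log_base)
            sink.tsv(pairwise_frame(tests), f"pairwise_tests_{ch}.tsv")
            letters = compact_letters(tests)
            sink.tsv(
                pd.DataFrame(
                    {"campaign_id": list(letters), "letters": list(letters.values())}
                ),
                f"letters_{ch}.tsv",
            )
            z = kruskal_zones(table, ch)
            zone_rows.append(
                {
                    "characteristic": z.characteristic,
                    "campaign_id": z.campaign_id,
                    "h": z.h,
                    "df": z.df,
                    "p": z.p,
                }
            )
        sink.tsv(pd.DataFrame(zone_rows), "zone_tests.tsv")

        stage = "summary"
        gamma_precip = next(
            r
            for r in char_res
            if r.response == "gamma" and r.predictor == "precipitation"
        )
        summary = {
            "version": __version__,
            "config": asdict(config),
            "config_hash": config.digest(),
            "n_campaigns": len(table.campaign_ids),
            "n_plots": len(table.plots),
            "n_species": len(table.species),
            "n_records": int(len(table.records)),
            "cover_flagged": sorted(
                c for c, v in table.cover_flags.items() if v
            ),
            "headline": {
                "gamma_uncorrelated_with_precipitation": bool(
                    gamma_precip.p_bonf >= 0.05
                ),
                "stabilization_year": stab,
            },
        }
        sink.json(summary, "summary.json")
        return summary
    except Exception as exc:
        sink.rollback()
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
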