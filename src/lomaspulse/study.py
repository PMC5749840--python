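"""Conventions for the original four-year monitoring dataset.

The raw per-plot abundance/cover records of the monitoring study are
distributed as a supplementary spreadsheet by the journal and are not
bundled here.  To reproduce the published per-campaign table, convert the
spreadsheet to the canonical long CSV (``lomaspulse convert`` helps for
matrix-layout workbooks) and place the files at::

    data/study/survey.csv    # canonical long format
    data/study/climate.csv   # month,precip_mm,temp_c

relative to the repository/working root.  :func:`load_study` then applies
the study's fixed conventions: the 31-plot panel and the two campaigns
whose absolute cover is known to be overestimated.
"""

from __future__ import annotations

import os

from .survey_io import (
    ClimateSeries,
    SurveyTable,
    flag_overestimated_cover,
    read_climate,
    read_survey,
)

#: Campaigns measured with the overlapping-projection protocol error;
#: absolute cover from these is excluded, relative cover retained.
COVER_OVERESTIMATED = ("Feb-98", "Aug-98")

#: Campaigns on the humid end of the composition gradient.
HUMID_CAMPAIGNS = ("Feb-98", "Aug-00", "Sep-01")

#: Dry-season campaigns of 2000–2001 (the dry extreme of the gradient).
DRY_CAMPAIGNS_2000_2001 = ("Feb-00", "May-00", "Nov-00", "Feb-01")

DEFAULT_DIR = os.path.join("data", "study")


def study_paths(root: str = ".") -> tuple[str, str]:
    base = os.path.join(root, DEFAULT_DIR)
    return os.path.join(base, "survey.csv"), os.path.join(base, "climate.csv")


def study_data_available(root: str = ".") -> bool:
    survey, climate = study_paths(root)
    return os.path.exists(survey) and os.path.exists(climate)


def load_study(root: str = ".") -> tuple[SurveyTable, ClimateSeries]:
    """Load the converted study data with its fixed conventions applied.

    Raises :class:`FileNotFoundError` with instructions when the converted
    files are absent.
    """
    survey_path, climate_path = study_paths(root)
    if not os.path.exists(survey_path) or not os.path.exists(climate_path):
        raise FileNotFoundError(
            f"study data not found under {os.path.join(root, DEFAULT_DIR)!r}; "
            "convert the supplementary raw-data spreadsheet to survey.csv / "
            "climate.csv as described in lomaspulse.study"
        )
    table = read_survey(survey_path)
    flags = [c for c in COVER_OVERESTIMATED if c in table.campaign_ids]
    if flags:
        table = flag_overestimated_cover(table, flags)
    climate = read_climate(climate_path)
    return table, climate
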