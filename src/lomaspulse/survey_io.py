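"""Reading, validation and writing of survey and climate tables.

The canonical survey input is a long-format CSV with columns
``campaign_id,date,plot_id,zone,species,abundance,cover_cm2`` — one row per
(campaign, plot, species) with at least one individual.  Plots with no
records in a campaign are *not* rows; they are carried by the plot roster
and treated as empty (zero individuals, zero cover) downstream.

The climate input is a monthly CSV with columns ``month,precip_mm,temp_c``
where ``month`` is ISO ``YYYY-MM``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import pandas as pd

from .errors import SchemaError, ValidationError

SURVEY_COLUMNS = [
    "campaign_id",
    "date",
    "plot_id",
    "zone",
    "species",
    "abundance",
    "cover_cm2",
]
CLIMATE_COLUMNS = ["month", "precip_mm", "temp_c"]
ZONES = ("low", "medium", "high")

#: Physical plausibility cap for a single cover record (cm² on a 1 m² plot).
#: Overlapping-projection measurement protocols can legitimately exceed it,
#: so exceeding the cap warns by default and only errors in strict mode.
DEFAULT_COVER_CAP = 10_000.0


@dataclass(frozen=True)
class SurveyTable:
    """A validated panel survey.

    Attributes
    ----------
    records
        Long-format observations, one row per (campaign, plot, species)
        with ``abundance`` ≥ 1.
    plots
        The fixed plot roster.  Campaign-invariant: every campaign is
        interpreted as a full visit of this panel, with roster plots that
        have no records counted as empty.
    campaigns
        Ordered roster of campaigns with their calendar month
        (columns ``campaign_id``, ``date``; chronological order).
    cover_flags
        campaign_id -> True when the campaign's absolute cover values are
        known to be overestimated and must be excluded from statistics that
        need absolute cover.  Relative-cover uses (the importance value
        index) retain flagged campaigns.
    """

    records: pd.DataFrame
    plots: tuple[str, ...]
    campaigns: pd.DataFrame
    cover_flags: dict[str, bool] = field(default_factory=dict)

    @property
    def campaign_ids(self) -> list[str]:
        return list(self.campaigns["campaign_id"])

    @property
    def species(self) -> list[str]:
        return sorted(self.records["species"].unique())

    def campaign_records(self, campaign_id: str) -> pd.DataFrame:
        if campaign_id not in set(self.campaign_ids):
            raise LookupError(f"unknown campaign_id: {campaign_id!r}")
        return self.records[self.records["campaign_id"] == campaign_id]

    def campaign_date(self, campaign_id: str) -> str:
        row = self.campaigns[self.campaigns["campaign_id"] == campaign_id]
        if row.empty:
            raise LookupError(f"unknown campaign_id: {campaign_id!r}")
        return str(row["date"].iloc[0])

    def is_cover_flagged(self, campaign_id: str) -> bool:
        return bool(self.cover_flags.get(campaign_id, False))


@dataclass(frozen=True)
class ClimateSeries:
    """Monthly climate series: total precipitation (mm) and mean temperature (°C)."""

    data: pd.DataFrame  # columns: month (str YYYY-MM), precip_mm, temp_c

    def __len__(self) -> int:
        return len(self.data)

    def lookup(self, month: str) -> tuple[float, float]:
        row = self.data[self.data["month"] == month]
        if row.empty:
            raise LookupError(f"month {month!r} missing from climate series")
        return float(row["precip_mm"].iloc[0]), float(row["temp_c"].iloc[0])


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{what} is missing required column {col!r}")


def _parse_month(value: str) -> pd.Period:
    try:
        return pd.Period(str(value), freq="M")
    except Exception as exc:  # noqa: BLE001 - re-raise as format error
        raise ValidationError(f"unparseable month {value!r} (expected YYYY-MM)") from exc


def validate_survey_frame(
    df: pd.DataFrame,
    *,
    cover_cap: float = DEFAULT_COVER_CAP,
    strict: bool = False,
) -> pd.DataFrame:
    """Validate a long-format survey frame and return a normalized copy.

    Raises :class:`SchemaError` or :class:`ValidationError` with the
    offending column / row number in the message.
    """
    _require_columns(df, SURVEY_COLUMNS, "survey table")
    df = df[SURVEY_COLUMNS].copy()
    for col in ("campaign_id", "date", "plot_id", "zone", "species"):
        df[col] = df[col].astype(str).str.strip()

    bad_zone = ~df["zone"].isin(ZONES)
    if bad_zone.any():
        row = int(df.index[bad_zone][0])
        raise ValidationError(
            f"row {row}: zone {df.loc[row, 'zone']!r} not one of {ZONES}"
        )

    abundance = pd.to_numeric(df["abundance"], errors="coerce")
    cover = pd.to_numeric(df["cover_cm2"], errors="coerce")
    if abundance.isna().any():
        row = int(df.index[abundance.isna()][0])
        raise ValidationError(f"row {row}: non-numeric abundance")
    if cover.isna().any():
        row = int(df.index[cover.isna()][0])
        raise ValidationError(f"row {row}: non-numeric cover_cm2")
    if (abundance < 0).any():
        row = int(df.index[abundance < 0][0])
        raise ValidationError(f"row {row}: negative abundance")
    if (abundance % 1 != 0).any():
        row = int(df.index[abundance % 1 != 0][0])
        raise ValidationError(f"row {row}: abundance must be an integer count")
    if (cover < 0).any():
        row = int(df.index[cover < 0][0])
        raise ValidationError(f"row {row}: negative cover_cm2")
    zero_abund_cover = (abundance == 0) & (cover > 0)
    if zero_abund_cover.any():
        row = int(df.index[zero_abund_cover][0])
        raise ValidationError(
            f"row {row}: cover_cm2 > 0 with abundance 0 violates the record invariant"
        )
    df["abundance"] = abundance.astype(int)
    df["cover_cm2"] = cover.astype(float)

    over_cap = df["cover_cm2"] > cover_cap
    if over_cap.any():
        msg = (
            f"{int(over_cap.sum())} record(s) exceed the cover cap "
            f"of {cover_cap:g} cm² per plot"
        )
        if strict:
            raise ValidationError(msg)
        warnings.warn(msg, stacklevel=2)

    dup = df.duplicated(subset=["campaign_id", "plot_id", "species"])
    if dup.any():
        row = int(df.index[dup][0])
        key = tuple(df.loc[row, ["campaign_id", "plot_id", "species"]])
        raise ValidationError(f"row {row}: duplicate (campaign, plot, species) {key}")

    for cid, dates in df.groupby("campaign_id")["date"]:
        if dates.nunique() > 1:
            raise ValidationError(
                f"campaign {cid!r} maps to multiple dates: {sorted(dates.unique())}"
            )

    # rows with zero individuals carry no information once validated
    return df[df["abundance"] > 0].reset_index(drop=True)


def build_survey_table(
    df: pd.DataFrame,
    plot_roster: list[str] | None = None,
    *,
    cover_cap: float = DEFAULT_COVER_CAP,
    strict: bool = False,
) -> SurveyTable:
    """Assemble a :class:`SurveyTable` from a long-format frame.

    When ``plot_roster`` is None the roster is the set of plot_ids observed
    anywhere in the data; supplying the roster explicitly is how empty plots
    (never observed at all) enter the panel.
    """
    df = validate_survey_frame(df, cover_cap=cover_cap, strict=strict)
    observed_plots = set(df["plot_id"])
    if plot_roster is None:
        roster = tuple(sorted(observed_plots))
    else:
        roster = tuple(str(p) for p in plot_roster)
        stray = observed_plots - set(roster)
        if stray:
            raise ValidationError(
                f"records reference plot_ids absent from the roster: {sorted(stray)}"
            )
    campaigns = (
        df[["campaign_id", "date"]]
        .drop_duplicates()
        .assign(_month=lambda d: d["date"].map(_parse_month))
        .sort_values(["_month", "campaign_id"], kind="stable")
        .drop(columns="_month")
        .reset_index(drop=True)
    )
    return SurveyTable(records=df, plots=roster, campaigns=campaigns)


def read_survey(
    path,
    plot_roster: list[str] | None = None,
    *,
    cover_cap: float = DEFAULT_COVER_CAP,
    strict: bool = False,
) -> SurveyTable:
    """Read the canonical long-format survey CSV."""
    df = pd.read_csv(path, dtype=str)
    return build_survey_table(df, plot_roster, cover_cap=cover_cap, strict=strict)


def write_survey(table: SurveyTable, path) -> None:
    """Write the canonical CSV; ``read_survey`` round-trips it record-identically."""
    out = table.records.copy()
    out["cover_cm2"] = out["cover_cm2"].map(lambda v: f"{v:.17g}")
    out.to_csv(path, index=False)


def flag_overestimated_cover(table: SurveyTable, campaigns: list[str]) -> SurveyTable:
    """Return a copy of ``table`` with the listed campaigns' cover flagged.

    Flagged campaigns are excluded from statistics that need absolute cover
    (mean cover, cover t-tests, cover seasonality) but keep their cover in
    relative-cover statistics such as the importance value index.
    """
    known = set(table.campaign_ids)
    flags = dict(table.cover_flags)
    for cid in campaigns:
        if cid not in known:
            raise LookupError(f"cannot flag unknown campaign_id {cid!r}")
        flags[cid] = True
    return replace(table, cover_flags=flags)


def read_climate(path) -> ClimateSeries:
    """Read and validate the monthly climate CSV, sorted chronologically."""
    df = pd.read_csv(path)
    _require_columns(df, CLIMATE_COLUMNS, "climate table")
    df = df[CLIMATE_COLUMNS].copy()
    periods = df["month"].map(_parse_month)
    if periods.duplicated().any():
        dup_month = str(periods[periods.duplicated()].iloc[0])
        raise ValidationError(f"duplicate month {dup_month} in climate series")
    df["precip_mm"] = pd.to_numeric(df["precip_mm"], errors="raise").astype(float)
    df["temp_c"] = pd.to_numeric(df["temp_c"], errors="raise").astype(float)
    if (df["precip_mm"] < 0).any():
        row = int(df.index[df["precip_mm"] < 0][0])
        raise ValidationError(f"row {row}: negative precipitation")
    df["month"] = periods.map(str)
    df = df.iloc[periods.argsort(kind="stable")].reset_index(drop=True)
    return ClimateSeries(data=df)


def write_climate(series: ClimateSeries, path) -> None:
    series.data.to_csv(path, index=False)


def convert_matrix_workbook(path, *, zone_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Convert a species×plot matrix workbook into the canonical long format.

    Expected layout (one common way raw survey spreadsheets are organized):
    for each campaign two worksheets named ``"<campaign_id> abundance"`` and
    ``"<campaign_id> cover"``, each with species labels in the first column,
    a header row of plot_ids, and a cell per (species, plot).  A cell that is
    blank or 0 means the species was absent from that plot.  The campaign's
    calendar month must appear in cell A1 notes column header named ``date``
    or be encoded as ``Mon-YY`` in the campaign id (e.g. ``Feb-98``).

    This is a convenience utility, not a dependency of the core pipeline:
    the canonical input remains the long CSV.  Requires ``openpyxl``.
    """
    from openpyxl import load_workbook  # local import: optional dependency

    wb = load_workbook(path, read_only=True, data_only=True)
    frames = []
    names = set(wb.sheetnames)
    for name in sorted(n for n in names if n.endswith(" abundance")):
        cid = name[: -len(" abundance")]
        cover_sheet = f"{cid} cover"
        if cover_sheet not in names:
            raise SchemaError(f"workbook lacks sheet {cover_sheet!r}")
        abund = _sheet_to_frame(wb[name])
        cover = _sheet_to_frame(wb[cover_sheet])
        long_a = abund.melt(id_vars="species", var_name="plot_id", value_name="abundance")
        long_c = cover.melt(id_vars="species", var_name="plot_id", value_name="cover_cm2")
        merged = long_a.merge(long_c, on=["species", "plot_id"], how="outer").fillna(0)
        merged = merged[merged["abundance"] > 0]
        merged.insert(0, "campaign_id", cid)
        merged.insert(1, "date", _campaign_id_to_date(cid))
        frames.append(merged)
    if not frames:
        raise SchemaError("workbook contains no '<campaign> abundance' sheets")
    df = pd.concat(frames, ignore_index=True)
    df["zone"] = df["plot_id"].map(zone_map or {}).fillna("low")
    return df[SURVEY_COLUMNS]


def _sheet_to_frame(ws) -> pd.DataFrame:
    rows = list(ws.values)
    header = ["species", *[str(h) for h in rows[0][1:] if h is not None]]
    body = [list(r[: len(header)]) for r in rows[1:] if r[0] is not None]
    df = pd.DataFrame(body, columns=header)
    for col in header[1:]:
        df[col] = pd.to_numeric(df[col], errors="coerce").fillna(0)
    return df


_MONTHS = {
    "Jan": 1, "Feb": 2, "Mar": 3, "Apr": 4, "May": 5, "Jun": 6,
    "Jul": 7, "Aug": 8, "Sep": 9, "Oct": 10, "Nov": 11, "Dec": 12,
}


def _campaign_id_to_date(cid: str) -> str:
    """'Feb-98' -> '1998-02' (two-digit years < 50 are 20xx, else 19xx)."""
    try:
        mon, yy = cid.split("-")
        year = int(yy)
        year += 2000 if year < 50 else 1900
        return f"{year:04d}-{_MONTHS[mon]:02d}"
    except Exception as exc:  # noqa: BLE001
        raise ValidationError(f"cannot infer a date from campaign id {cid!r}") from exc
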