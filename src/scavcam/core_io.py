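"""Data schemas, validated readers/writers, and central configuration.

The pipeline operates on three plain-CSV tables:

``detections``
    One row per classified camera image of one species at one site at one
    instant.  Columns: ``image_id, site_id, species, timestamp, behavior,
    n_individuals, year_label``.
``snow``
    One row per calendar date with the daily snow depth (cm) at the study
    area centroid.  Columns: ``date, depth_cm``.
``operability``
    Camera up/down intervals per site and winter, dates inclusive.
    Columns: ``site_id, year_label, start, end, operable``.

Readers validate against the schema and return a :class:`ValidationReport`
alongside the data; validation never mutates values — rows are either kept,
flagged, or the whole read fails with a named error.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml


class Species(str, enum.Enum):
    MARTEN = "marten"
    FISHER = "fisher"
    OTHER = "other"


class Behavior(str, enum.Enum):
    VIGILANT = "vigilant"
    FEEDING = "feeding"
    OTHER_NONVIGILANT = "other_nonvigilant"
    UNCLASSIFIABLE = "unclassifiable"


DETECTION_COLUMNS = [
    "image_id",
    "site_id",
    "species",
    "timestamp",
    "behavior",
    "n_individuals",
    "year_label",
]
SNOW_COLUMNS = ["date", "depth_cm"]
OPERABILITY_COLUMNS = ["site_id", "year_label", "start", "end", "operable"]


class SchemaError(ValueError):
    """A structural problem with an input table (missing/duplicate columns, duplicate keys)."""


class RowError(ValueError):
    """A row-level parse or invariant failure, carrying 1-based CSV line numbers."""


class MissingDataError(KeyError):
    """A required lookup (e.g. snow depth for a detection date) has no entry."""


@dataclass
class ValidationReport:
    """Outcome of a validated read: rows kept, and why any were flagged.

    ``flags`` maps an image_id (or row key) to a human-readable reason.
    Flagged rows are *retained* in the returned table; downstream stages
    decide whether to exclude them (e.g. 'unclassifiable' behavior is kept
    here but excluded from the vigilance analysis).
    """

    n_rows: int = 0
    flags: dict[str, str] = field(default_factory=dict)

    @property
    def n_flagged(self) -> int:
        return len(self.flags)


@dataclass
class AnalysisConfig:
    """Tunable constants of the analysis, every one overridable from YAML.

    Durations are minutes unless suffixed otherwise.  ``analysis_start``
    is the last *excluded* calendar day (month-day): observations dated on
    or before it are dropped from the vigilance and diel-activity analyses
    so that every site has a minimum history of monitoring before its
    heterospecific-use class is trusted.
    """

    independence_gap_min: float = 30.0
    displacement_window_min: float = 10.0
    histogram_bin_min: float = 5.0
    histogram_halfwidth_min: float = 120.0
    histogram_convention: str = "interval"  # or "arrival"
    recent_use_window_h: float = 24.0
    analysis_start: str = "01-22"
    bootstrap_iterations: int = 1000
    conf_level: float = 0.95
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "independence_gap_min",
            "displacement_window_min",
            "histogram_bin_min",
            "histogram_halfwidth_min",
            "recent_use_window_h",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.conf_level < 1.0:
            raise ValueError("conf_level must be in (0, 1)")
        if self.histogram_convention not in ("interval", "arrival"):
            raise ValueError("histogram_convention must be 'interval' or 'arrival'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing required column(s): {missing}")


def read_detections(path: str | Path) -> tuple[pd.DataFrame, ValidationReport]:
    """Read and validate a detections CSV.

    Returns the table sorted by ``(site_id, timestamp)`` together with a
    :class:`ValidationReport`.  Raises :class:`SchemaError` on missing
    columns or duplicated ``image_id``, :class:`RowError` (with CSV line
    numbers) on unparseable timestamps or invalid enum/count values.
    """
    df = pd.read_csv(path, dtype={"site_id": str, "year_label": str, "image_id": str})
    _require_columns(df, DETECTION_COLUMNS, "detections")

    dupes = df["image_id"][df["image_id"].duplicated()].unique()
    if len(dupes):
        raise SchemaError(f"duplicate image_id values: {sorted(dupes)[:10]}")

    ts = pd.to_datetime(df["timestamp"], format="ISO8601", errors="coerce")
    bad = df.index[ts.isna()]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:10]]  # +2: header + 1-based
        raise RowError(f"unparseable timestamp(s) at CSV line(s) {lines}")
    df = df.assign(timestamp=ts)

    bad_species = ~df["species"].isin([s.value for s in Species])
    if bad_species.any():
        lines = [int(i) + 2 for i in df.index[bad_species][:10]]
        raise RowError(f"unknown species at CSV line(s) {lines}")
    bad_behavior = ~df["behavior"].isin([b.value for b in Behavior])
    if bad_behavior.any():
        lines = [int(i) + 2 for i in df.index[bad_behavior][:10]]
        raise RowError(f"unknown behavior at CSV line(s) {lines}")
    n_ind = pd.to_numeric(df["n_individuals"], errors="coerce")
    bad_n = n_ind.isna() | (n_ind < 1) | (n_ind != n_ind.round())
    if bad_n.any():
        lines = [int(i) + 2 for i in df.index[bad_n][:10]]
        raise RowError(f"n_individuals must be a positive integer; bad at line(s) {lines}")
    df = df.assign(n_individuals=n_ind.astype(int))

    report = ValidationReport(n_rows=len(df))
    for iid in df.loc[df["behavior"] == Behavior.UNCLASSIFIABLE.value, "image_id"]:
        report.flags[iid] = "behavior unclassifiable: excluded from vigilance analysis"

    df = df.sort_values(["site_id", "timestamp", "image_id"], kind="mergesort").reset_index(drop=True)
    return df, report


def write_detections(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out[DETECTION_COLUMNS].to_csv(path, index=False)


def read_snow(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, SNOW_COLUMNS, "snow")
    dates = pd.to_datetime(df["date"], format="ISO8601", errors="coerce")
    if dates.isna().any():
        lines = [int(i) + 2 for i in df.index[dates.isna()][:10]]
        raise RowError(f"unparseable snow date(s) at CSV line(s) {lines}")
    if dates.duplicated().any():
        raise SchemaError("duplicate dates in snow table")
    depth = pd.to_numeric(df["depth_cm"], errors="coerce")
    if (depth.isna() | (depth < 0)).any():
        raise RowError("snow depth_cm must be non-negative real")
    return pd.DataFrame({"date": dates.dt.normalize(), "depth_cm": depth.astype(float)}).sort_values(
        "date"
    ).reset_index(drop=True)


def write_snow(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out[SNOW_COLUMNS].to_csv(path, index=False)


def read_operability(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"site_id": str, "year_label": str})
    _require_columns(df, OPERABILITY_COLUMNS, "operability")
    start = pd.to_datetime(df["start"], format="ISO8601")
    end = pd.to_datetime(df["end"], format="ISO8601")
    if (end < start).any():
        raise RowError("operability interval with end before start")
    operable = df["operable"].astype(str).str.lower().map({"true": True, "false": False, "1": True, "0": False})
    if operable.isna().any():
        raise RowError("operable must be boolean")
    out = pd.DataFrame(
        {
            "site_id": df["site_id"],
            "year_label": df["year_label"],
            "start": start.dt.normalize(),
            "end": end.dt.normalize(),
            "operable": operable.astype(bool),
        }
    ).sort_values(["site_id", "year_label", "start"]).reset_index(drop=True)
    # intervals within a (site, winter) must not overlap (dates inclusive)
    for (site, year), g in out.groupby(["site_id", "year_label"], sort=False):
        if (g["start"].iloc[1:].values <= g["end"].iloc[:-1].values).any():
            raise SchemaError(f"overlapping operability intervals for site {site}, winter {year}")
    return out


def write_operability(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["start"] = pd.to_datetime(out["start"]).dt.strftime("%Y-%m-%d")
    out["end"] = pd.to_datetime(out["end"]).dt.strftime("%Y-%m-%d")
    out["operable"] = out["operable"].map({True: "true", False: "false"})
    out[OPERABILITY_COLUMNS].to_csv(path, index=False)


def join_snow(detections: pd.DataFrame, snow: pd.DataFrame) -> pd.DataFrame:
    """Annotate each detection with the snow depth of its calendar date.

    Every detection date must be present in the snow table; missing dates
    raise :class:`MissingDataError` listing them (no silent interpolation).
    """
    det_dates = pd.to_datetime(detections["timestamp"]).dt.normalize()
    lookup = snow.set_index("date")["depth_cm"]
    missing = sorted(set(det_dates) - set(lookup.index))
    if missing:
        days = [d.strftime("%Y-%m-%d") for d in missing[:10]]
        raise MissingDataError(f"no snow depth for detection date(s): {days}")
    out = detections.copy()
    out["depth_cm"] = det_dates.map(lookup).values
    return out


def filter_after_analysis_start(df: pd.DataFrame, analysis_start: str = "01-22") -> pd.DataFrame:
    """Drop observations dated on or before the ``analysis_start`` month-day of their winter.

    The cutoff guarantees a minimum monitored history at every site before
    heterospecific-use covariates are computed; the default drops the first
    three weeks of January (2–22 January inclusive).
    """
    month, day = (int(p) for p in analysis_start.split("-"))
    ts = pd.to_datetime(df["timestamp"])
    cutoff = pd.to_datetime(
        {"year": ts.dt.year, "month": month, "day": day}
    )
    return df[ts.dt.normalize() > cutoff].reset_index(drop=True)
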