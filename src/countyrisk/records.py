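"""Incident-record I/O: reading, cleaning, deduplication, aggregation.

Incident CSVs hold one police-shooting record per row (columns ``name``,
``year`` and/or ``date``, ``race``, ``armed``, optionally ``state``,
``county``, ``fips``, ``age``).  Census CSVs hold race-specific county
populations (``fips``, ``pop_black``, ``pop_hispanic``, ``pop_white``);
covariate CSVs hold one row of county-level predictors per county (see
:data:`COVARIATE_COLUMNS`).  County keys are always 5-character zero-padded
FIPS strings; county names are never used as join keys.

Aggregated counts are returned as a :class:`pandas.DataFrame` with one row
per county and columns ``fips``, ``S_BU .. S_WA`` (shooting counts for the
six race x armed-status cells) and ``N_B, N_H, N_W`` (race-specific census
denominators).
"""

from __future__ import annotations

import json
import re
from collections import defaultdict
from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import numpy as np
import pandas as pd

__all__ = [
    "Race",
    "Armed",
    "ShootingRecord",
    "CleaningReport",
    "AggregationResult",
    "CELLS",
    "CELL_COLUMNS",
    "POP_COLUMNS",
    "COVARIATE_COLUMNS",
    "read_records",
    "clean_records",
    "deduplicate",
    "aggregate_counts",
    "counts_to_arrays",
    "read_census",
    "read_covariates",
]


class Race(str, Enum):
    B = "B"
    H = "H"
    W = "W"
    OTHER = "OTHER"
    UNKNOWN = "UNKNOWN"


class Armed(str, Enum):
    ARMED = "ARMED"
    UNARMED = "UNARMED"
    UNKNOWN = "UNKNOWN"


#: Cell ordering of the six per-county shooting probabilities; this fixed
#: order is shared by every array in the hierarchical model.
CELLS: tuple[tuple[str, str], ...] = (
    ("B", "U"),
    ("B", "A"),
    ("H", "U"),
    ("H", "A"),
    ("W", "U"),
    ("W", "A"),
)
CELL_COLUMNS = tuple(f"S_{r}{a}" for r, a in CELLS)
POP_COLUMNS = ("N_B", "N_H", "N_W")

#: Order matters: it is the canonical predictor order of the ecological
#: regression (population, % black, income, Gini, racism proxy, then the
#: four race-specific arrest rates).
COVARIATE_COLUMNS = (
    "pop_total",
    "pct_black",
    "median_income",
    "gini",
    "racism_proxy",
    "assault_rate_W",
    "assault_rate_B",
    "weapons_rate_W",
    "weapons_rate_B",
)

_RACE_TOKENS = {
    "b": Race.B,
    "black": Race.B,
    "african american": Race.B,
    "african-american": Race.B,
    "h": Race.H,
    "hispanic": Race.H,
    "latino": Race.H,
    "latina": Race.H,
    "latinx": Race.H,
    "w": Race.W,
    "white": Race.W,
    "caucasian": Race.W,
    "o": Race.OTHER,
    "other": Race.OTHER,
    "asian": Race.OTHER,
    "native american": Race.OTHER,
    "pacific islander": Race.OTHER,
}

_ARMED_TOKENS = {
    "armed": Armed.ARMED,
    "yes": Armed.ARMED,
    "y": Armed.ARMED,
    "true": Armed.ARMED,
    "gun": Armed.ARMED,
    "firearm": Armed.ARMED,
    "knife": Armed.ARMED,
    "unarmed": Armed.UNARMED,
    "no": Armed.UNARMED,
    "n": Armed.UNARMED,
    "false": Armed.UNARMED,
}


@dataclass
class ShootingRecord:
    """One incident: who was shot, where, when, and their armed status."""

    victim_name: str = ""
    year: int | None = None
    race: Race = Race.UNKNOWN
    armed: Armed = Armed.UNKNOWN
    county_fips: str | None = None
    age: int | None = None


@dataclass
class CleaningReport:
    """Per-rule drop counts from :func:`clean_records`.

    A record violating several rules increments every matching counter, so
    the rule counters can sum to more than ``n_dropped``.
    """

    n_input: int = 0
    n_kept: int = 0
    n_dropped: int = 0
    armed_unknown: int = 0
    race_excluded: int = 0
    year_out_of_range: int = 0
    missing_county: int = 0
    duplicates_dropped: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


@dataclass
class AggregationResult:
    counts: pd.DataFrame
    #: records whose county is absent from the census table: fips -> n records
    uncovered: dict[str, int] = field(default_factory=dict)


class SchemaError(ValueError):
    """An input table is missing a required column."""


class DataConsistencyError(ValueError):
    """Counts contradict denominators (more shootings than residents)."""


def _normalize_fips(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    text = str(value).strip()
    if text.endswith(".0"):
        text = text[:-2]
    if not text or not text.isdigit() or len(text) > 5:
        return None
    return text.zfill(5)


def _parse_year(row: pd.Series) -> int | None:
    if "year" in row.index and not pd.isna(row["year"]):
        try:
            return int(float(row["year"]))
        except (TypeError, ValueError):
            pass
    if "date" in row.index and not pd.isna(row["date"]):
        stamp = pd.to_datetime(row["date"], errors="coerce")
        if stamp is not pd.NaT:
            return int(stamp.year)
    return None


def _parse_int(value) -> int | None:
    if value is None or pd.isna(value):
        return None
    try:
        return int(float(value))
    except (TypeError, ValueError):
        return None


def read_records(
    path: str | Path,
    county_lookup: str | Path | pd.DataFrame | None = None,
) -> list[ShootingRecord]:
    """Read an incident CSV into records, never silently dropping rows.

    Unparseable race/armed fields become ``UNKNOWN``; unparseable years,
    ages, and FIPS become missing.  Filtering happens later, in
    :func:`clean_records`.

    Parameters
    ----------
    path
        Incident CSV with a header row.  Requires ``name``, ``race``,
        ``armed``, and either ``year`` or ``date``.  ``fips`` may be
        omitted if ``county_lookup`` resolves (state, county) pairs.
    county_lookup
        Optional CSV or frame with columns ``state``, ``county``, ``fips``.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=True)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("name", "race", "armed"):
        if col not in df.columns:
            raise SchemaError(f"incident CSV is missing required column {col!r}")
    if "year" not in df.columns and "date" not in df.columns:
        raise SchemaError("incident CSV needs a 'year' or 'date' column")

    lookup: dict[tuple[str, str], str] = {}
    if county_lookup is not None:
        ldf = (
            county_lookup
            if isinstance(county_lookup, pd.DataFrame)
            else pd.read_csv(county_lookup, dtype=str)
        )
        ldf.columns = [c.strip().lower() for c in ldf.columns]
        for col in ("state", "county", "fips"):
            if col not in ldf.columns:
                raise SchemaError(f"county lookup CSV is missing column {col!r}")
        for _, lrow in ldf.iterrows():
            key = (str(lrow["state"]).strip().lower(), str(lrow["county"]).strip().lower())
            fips = _normalize_fips(lrow["fips"])
            if fips:
                lookup[key] = fips

    records: list[ShootingRecord] = []
    for _, row in df.iterrows():
        race_raw = "" if pd.isna(row["race"]) else str(row["race"]).strip().lower()
        armed_raw = "" if pd.isna(row["armed"]) else str(row["armed"]).strip().lower()
        fips = _normalize_fips(row["fips"]) if "fips" in row.index else None
        if fips is None and lookup:
            state = str(row.get("state", "")).strip().lower()
            county = str(row.get("county", "")).strip().lower()
            fips = lookup.get((state, county))
        records.append(
            ShootingRecord(
                victim_name="" if pd.isna(row["name"]) else str(row["name"]),
                year=_parse_year(row),
                race=_RACE_TOKENS.get(race_raw, Race.UNKNOWN),
                armed=_ARMED_TOKENS.get(armed_raw, Armed.UNKNOWN),
                county_fips=fips,
                age=_parse_int(row["age"]) if "age" in row.index else None,
            )
        )
    return records


def clean_records(
    records: Iterable[ShootingRecord],
    year_range: tuple[int, int] = (2011, 2014),
) -> tuple[list[ShootingRecord], CleaningReport]:
    """Apply the four record-selection rules.

    A record is kept only when (1) its armed status is clearly armed or
    unarmed, (2) its race/ethnicity is black, hispanic, or white, (3) its
    year falls inside ``year_range``, and (4) it carries a county FIPS.
    """
    report = CleaningReport()
    kept: list[ShootingRecord] = []
    lo, hi = year_range
    for rec in records:
        report.n_input += 1
        ok = True
        if rec.armed not in (Armed.ARMED, Armed.UNARMED):
            report.armed_unknown += 1
            ok = False
        if rec.race not in (Race.B, Race.H, Race.W):
            report.race_excluded += 1
            ok = False
        if rec.year is None or not (lo <= rec.year <= hi):
            report.year_out_of_range += 1
            ok = False
        if not rec.county_fips:
            report.missing_county += 1
            ok = False
        if ok:
            kept.append(rec)
            report.n_kept += 1
        else:
            report.n_dropped += 1
    return kept, report


def _normalize_name(name: str) -> str:
    text = re.sub(r"[^a-z ]", " ", name.lower())
    return re.sub(r"\s+", " ", text).strip()


def deduplicate(
    records: Sequence[ShootingRecord],
) -> tuple[list[ShootingRecord], int]:
    """Drop duplicate listings of the same victim, keeping first occurrences.

    Two records are duplicates when their normalized names match exactly and
    they share (year, county), or when they agree exactly on (year, age,
    race, county) and their normalized names are within edit distance 2 —
    the spelling-variation rule.  The operation is idempotent and keeps the
    earliest record of each duplicate group.
    """
    kept: list[ShootingRecord] = []
    dropped = 0
    seen_exact: set[tuple[str, int | None, str | None]] = set()
    # candidates for the fuzzy rule, grouped by the exact-match fields
    fuzzy_groups: dict[tuple, list[str]] = defaultdict(list)

    for rec in records:
        name = _normalize_name(rec.victim_name)
        exact_key = (name, rec.year, rec.county_fips)
        fuzzy_key = (rec.year, rec.age, rec.race, rec.county_fips)
        if name and exact_key in seen_exact:
            dropped += 1
            continue
        is_fuzzy_dup = False
        if name:
            for other in fuzzy_groups[fuzzy_key]:
                if other == name:
                    continue
                res = edlib.align(name, other, task="distance", k=2)
                if res["editDistance"] != -1:
                    is_fuzzy_dup = True
                    break
        if is_fuzzy_dup:
            dropped += 1
            continue
        if name:
            seen_exact.add(exact_key)
            fuzzy_groups[fuzzy_key].append(name)
        kept.append(rec)
    return kept, dropped


def aggregate_counts(
    records: Iterable[ShootingRecord],
    census: pd.DataFrame,
) -> AggregationResult:
    """Tabulate cleaned records into per-county 6-cell count tables.

    Only counties with at least one record appear in the output.  Records in
    counties absent from the census are excluded and reported in
    ``uncovered`` rather than silently lost.

    Raises
    ------
    DataConsistencyError
        If any cell count exceeds its race-specific census denominator.
    """
    census = census.copy()
    census["fips"] = [_normalize_fips(v) for v in census["fips"]]
    census = census.set_index("fips")

    cell_index = {cell: i for i, cell in enumerate(CELLS)}
    tallies: dict[str, np.ndarray] = {}
    uncovered: dict[str, int] = defaultdict(int)
    for rec in records:
        fips = rec.county_fips
        if fips not in census.index:
            uncovered[fips] += 1
            continue
        if fips not in tallies:
            tallies[fips] = np.zeros(6, dtype=int)
        tallies[fips][cell_index[(rec.race.value, "A" if rec.armed is Armed.ARMED else "U")]] += 1

    rows = []
    for fips in sorted(tallies):
        S = tallies[fips]
        N = census.loc[fips, ["N_B", "N_H", "N_W"]].astype(int).to_numpy()
        # race index of each of the six cells: B,B,H,H,W,W
        n_per_cell = N[[0, 0, 1, 1, 2, 2]]
        bad = S > n_per_cell
        if bad.any():
            cell = CELL_COLUMNS[int(np.argmax(bad))]
            raise DataConsistencyError(
                f"county {fips}: {cell}={S[np.argmax(bad)]} exceeds its census population"
            )
        rows.append({"fips": fips, **dict(zip(CELL_COLUMNS, S)), **dict(zip(POP_COLUMNS, N))})

    counts = pd.DataFrame(rows, columns=["fips", *CELL_COLUMNS, *POP_COLUMNS])
    return AggregationResult(counts=counts, uncovered=dict(uncovered))


def counts_to_arrays(counts: pd.DataFrame) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Split a counts frame into (fips labels, S of shape (C,6), N of shape (C,3))."""
    fips = [str(v).zfill(5) for v in counts["fips"]]
    S = counts.loc[:, list(CELL_COLUMNS)].to_numpy(dtype=float)
    N = counts.loc[:, list(POP_COLUMNS)].to_numpy(dtype=float)
    return fips, S, N


def read_census(path: str | Path) -> pd.DataFrame:
    """Read a census CSV into columns fips, N_B, N_H, N_W."""
    df = pd.read_csv(path, dtype={"fips": str})
    df.columns = [c.strip().lower() for c in df.columns]
    rename = {"pop_black": "N_B", "pop_hispanic": "N_H", "pop_white": "N_W"}
    for col in ("fips", *rename):
        if col not in df.columns:
            raise SchemaError(f"census CSV is missing required column {col!r}")
    df = df.rename(columns=rename)
    df["fips"] = [_normalize_fips(v) for v in df["fips"]]
    return df[["fips", "N_B", "N_H", "N_W"]]


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Read a county covariate CSV; empty cells become NaN (missing)."""
    df = pd.read_csv(path, dtype={"fips": str})
    df.columns = [c.strip().lower() for c in df.columns]
    lower_map = {c.lower(): c for c in COVARIATE_COLUMNS}
    df = df.rename(columns=lower_map)
    if "fips" not in df.columns:
        raise SchemaError("covariate CSV is missing required column 'fips'")
    missing = [c for c in COVARIATE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"covariate CSV is missing columns {missing}")
    df["fips"] = [_normalize_fips(v) for v in df["fips"]]
    out = df[["fips", *COVARIATE_COLUMNS]].copy()
    for col in COVARIATE_COLUMNS:
        out[col] = pd.to_numeric(out[col], errors="coerce")
    bad_gini = out["gini"].dropna()
    if ((bad_gini <= 0) | (bad_gini >= 1)).any():
        raise DataConsistencyError("gini values must lie strictly in (0, 1)")
    return out
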