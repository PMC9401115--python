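"""CSV readers/writers for intervals, trawls, TS tables and estimate reports.

All tables are plain CSV. Readers validate domain invariants up front and
raise :class:`~krillsurvey.model.SchemaError` / :class:`ValidationError`
with the offending column or row named, rather than propagating NaNs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    INTERVAL_COLUMNS,
    MIN_LENGTH_MM,
    TRAWL_COLUMNS,
    SchemaError,
    SurveyEstimate,
    TSTable,
    ValidationError,
)


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s): {', '.join(missing)}")


def read_intervals(path, northern_limit: float | None = None) -> pd.DataFrame:
    """Read echo-integration intervals from CSV.

    Parameters
    ----------
    path
        CSV with columns ``transect_id, interval_index, timestamp, lat, lon,
        nasc`` and optional ``delta_lat_planned, delta_lat_made_good,
        swarm_count``.
    northern_limit
        Latitude (degrees, south-negative) of the survey-division boundary.
        Intervals north of it are *flagged* (``in_division = False``), never
        silently dropped, mirroring how boundary-crossing transect ends are
        excluded from density estimation.

    Returns
    -------
    DataFrame sorted by transect then interval index, with UTC timestamps
    and an ``in_division`` boolean column.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, INTERVAL_COLUMNS, "intervals")
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    nasc = df["nasc"].to_numpy(float)
    bad = np.where(~(nasc >= 0))[0]
    if len(bad):
        # +2: one for the header line, one for 0- vs 1-based rows
        raise ValidationError(f"intervals: negative NASC in CSV row {bad[0] + 2}")
    lat = df["lat"].to_numpy(float)
    if np.any(lat < -90) or np.any(lat > 0):
        raise ValidationError("intervals: latitude outside [-90, 0]")
    if northern_limit is not None:
        df["in_division"] = lat <= northern_limit
    else:
        df["in_division"] = True
    df = df.sort_values(["transect_id", "interval_index"], kind="mergesort")
    return df.reset_index(drop=True)


def read_trawls(path, min_length_mm: float = MIN_LENGTH_MM) -> pd.DataFrame:
    """Read per-individual krill length (and optional wetmass) records.

    Individuals shorter than ``min_length_mm`` are excluded (the survey's
    global length filter); wetmass may be missing — such records take part
    in the length-frequency distribution but not in length-weight fitting.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, TRAWL_COLUMNS, "trawls")
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    if "wetmass_g" in df.columns:
        ww = df["wetmass_g"].to_numpy(float)
        if np.any(ww[~np.isnan(ww)] <= 0):
            raise ValidationError("trawls: non-positive wetmass")
    else:
        df["wetmass_g"] = np.nan
    df = df[df["total_length_mm"] >= min_length_mm]
    return df.reset_index(drop=True)


def read_ts_table(path) -> TSTable:
    """Read a length-to-TS table (120 kHz column; extra frequencies ignored).

    The length grid must be strictly increasing; duplicate lengths are
    rejected. A single-row table is accepted (lookups are then restricted
    to that exact length).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["length_mm", "ts_120_db"], "ts table")
    lengths = df["length_mm"].to_numpy(float)
    if len(lengths) > 1 and not np.all(np.diff(lengths) > 0):
        raise ValidationError("ts table: lengths must be strictly increasing (no duplicates)")
    return TSTable(lengths=lengths, ts=df["ts_120_db"].to_numpy(float))


# Table-2-style human-readable column layout
_REPORT_COLUMNS = [
    "transect",
    "length_nmile",
    "length_weight",
    "transect_weight",
    "density_gm2",
    "weighted_density_gm2",
    "density_deviation",
]


def write_estimate_report(estimate: SurveyEstimate, path) -> None:
    """Write a survey estimate as JSON (full precision) plus a human CSV.

    ``path`` gets the lossless JSON; ``path.with_suffix('.csv')`` gets a
    seven-column per-transect table rounded to one decimal, laid out like
    the survey report's transect-level results table.
    """
    if estimate is None or estimate.n_transects == 0:
        raise ValidationError("cannot write an empty estimate")
    path = Path(path)
    path.write_text(json.dumps(estimate.to_dict(), indent=1))
    table = pd.DataFrame(
        {
            "transect": estimate.transect_ids,
            "length_nmile": np.round(estimate.effective_lengths / estimate.coverage_weights, 1),
            "length_weight": estimate.coverage_weights,
            "transect_weight": np.round(estimate.transect_weights, 3),
            "density_gm2": np.round(estimate.transect_densities, 1),
            "weighted_density_gm2": np.round(estimate.weighted_densities, 1),
            "density_deviation": np.round(estimate.deviations, 2),
        },
        columns=_REPORT_COLUMNS,
    )
    table.to_csv(path.with_suffix(".csv"), index=False)


def read_estimate_report(path) -> SurveyEstimate:
    """Read back the lossless JSON written by :func:`write_estimate_report`."""
    return SurveyEstimate.from_dict(json.loads(Path(path).read_text()))
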