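"""Event aggregation, internal standardization, and temporal profiles.

Event-level incident records (area ID + timestamp) are aggregated to an
area x year panel of observed counts ``Y_it``.  Internal (indirect)
standardization turns populations ``N_it`` into expected counts

    E_it = (sum_it Y_it / sum_it N_it) * N_it,

i.e. the rate pooled over *all* areas and years applied to each cell's
population, so that ``sum E = sum Y`` by construction.  The
standardized incidence ratio ``SIR_it = Y_it / E_it`` then measures
excess incidence: above 1 marks a candidate hot spot, below 1 a cold
spot.

Panels are plain pandas DataFrames with columns
``area_id, year, Y [, N, E, SIR]``, one row per (area, year), ordered
area-major in lattice order.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .lattice import Lattice

__all__ = [
    "aggregate_events",
    "expected_counts",
    "sir",
    "classify_sir",
    "temporal_profile",
    "read_events_csv",
    "write_panel_csv",
    "read_panel_csv",
]

PANEL_COLUMNS = ["area_id", "year", "Y", "N", "E", "SIR"]

_MONTHS = ["Jan", "Feb", "Mar", "Apr", "May", "Jun",
           "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"]
_WEEKDAYS = ["Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun"]


def read_events_csv(path) -> pd.DataFrame:
    """Read an events CSV with columns ``area_id,timestamp`` (ISO-8601)."""
    events = pd.read_csv(path, dtype={"area_id": str})
    if not {"area_id", "timestamp"} <= set(events.columns):
        raise ValueError("events CSV must have columns area_id,timestamp")
    events["timestamp"] = pd.to_datetime(events["timestamp"])
    return events


def _as_events_frame(events) -> pd.DataFrame:
    ev = pd.DataFrame(events, columns=["area_id", "timestamp"]) if not isinstance(
        events, pd.DataFrame
    ) else events.copy()
    ev["timestamp"] = pd.to_datetime(ev["timestamp"])
    return ev


def aggregate_events(
    events,
    lattice: Lattice,
    years: Sequence[int],
) -> tuple[pd.DataFrame, int]:
    """Aggregate event records into an area x year count panel.

    Years are closed-open calendar windows: an event at Jan 1 00:00 of
    year *t* counts in year *t*.  Events whose area is not on the
    lattice, or whose timestamp falls outside the year range, are
    excluded and counted in the returned tally.

    Returns
    -------
    (panel, n_excluded)
        ``panel`` has one row per (area, year) with column ``Y``
        (areas with no events get 0); ``n_excluded`` is the number of
        dropped events.
    """
    years = list(years)
    if not years:
        raise ValueError("years must be nonempty")
    if years != list(range(years[0], years[0] + len(years))):
        raise ValueError("years must be consecutive")
    ev = _as_events_frame(events)
    if len(ev) == 0:
        warnings.warn("empty event list: panel counts are all zero", UserWarning)

    known = set(map(str, lattice.area_ids))
    counts = {}
    n_excluded = 0
    for aid, ts in zip(ev["area_id"].astype(str), ev["timestamp"]):
        yr = ts.year
        if aid not in known or yr not in years:
            n_excluded += 1
            continue
        counts[(aid, yr)] = counts.get((aid, yr), 0) + 1

    rows = [
        {"area_id": str(a), "year": t, "Y": counts.get((str(a), t), 0)}
        for a in lattice.area_ids
        for t in years
    ]
    return pd.DataFrame(rows), n_excluded


def expected_counts(panel: pd.DataFrame) -> pd.DataFrame:
    """Add expected counts ``E`` by internal standardization.

    The pooled rate ``sum(Y) / sum(N)`` across every area and year is
    applied to each cell's population, guaranteeing ``sum E == sum Y``.
    """
    if not {"Y", "N"} <= set(panel.columns):
        raise ValueError("panel must have Y and N columns")
    N = panel["N"].to_numpy(dtype=float)
    Y = panel["Y"].to_numpy(dtype=float)
    if np.any(N <= 0):
        bad = panel.loc[N <= 0, ["area_id", "year"]].to_records(index=False)
        raise ValueError(f"nonpositive populations in cells {list(bad)}")
    total_y = Y.sum()
    if total_y <= 0:
        raise ValueError("total observed count is zero: pooled rate degenerate")
    out = panel.copy()
    out["E"] = (total_y / N.sum()) * N
    return out


def sir(panel: pd.DataFrame) -> pd.DataFrame:
    """Add the standardized incidence ratio ``SIR = Y / E``."""
    if not {"Y", "E"} <= set(panel.columns):
        raise ValueError("panel must have Y and E columns")
    E = panel["E"].to_numpy(dtype=float)
    if np.any(E <= 0):
        bad = panel.loc[E <= 0, ["area_id", "year"]].to_records(index=False)
        raise ValueError(f"zero expected counts in cells {list(bad)}")
    out = panel.copy()
    out["SIR"] = out["Y"] / out["E"]
    return out


def classify_sir(sir_values) -> np.ndarray:
    """Label each cell 'hot' (SIR > 1), 'cold' (SIR < 1) or 'null'."""
    s = np.asarray(sir_values, dtype=float)
    return np.where(s > 1, "hot", np.where(s < 1, "cold", "null"))


def temporal_profile(events, binning: str) -> pd.Series:
    """Histogram of event counts by a calendar binning.

    ``binning`` is one of ``year``, ``month_of_year``, ``day_of_week``
    or ``hour_of_day``.  Every bin of the scheme is present (with 0 for
    empty bins) and labelled canonically: months Jan-Dec, weekdays
    Mon-Sun, clock hours 0-23 (timestamps truncated to the hour).
    """
    ev = _as_events_frame(events)
    ts = ev["timestamp"]
    if binning == "year":
        if len(ts) == 0:
            return pd.Series(dtype=int, name="count")
        keys = ts.dt.year
        index = pd.Index(range(keys.min(), keys.max() + 1), name="year")
    elif binning == "month_of_year":
        keys = ts.dt.month.map(lambda m: _MONTHS[m - 1]) if len(ts) else ts
        index = pd.Index(_MONTHS, name="month")
    elif binning == "day_of_week":
        keys = ts.dt.dayofweek.map(lambda d: _WEEKDAYS[d]) if len(ts) else ts
        index = pd.Index(_WEEKDAYS, name="weekday")
    elif binning == "hour_of_day":
        keys = ts.dt.hour
        index = pd.Index(range(24), name="hour")
    else:
        raise ValueError(
            "binning must be one of year, month_of_year, day_of_week, hour_of_day"
        )
    counts = pd.Series(keys).value_counts()
    return counts.reindex(index, fill_value=0).rename("count").astype(int)


def write_panel_csv(panel: pd.DataFrame, path) -> None:
    cols = [c for c in PANEL_COLUMNS if c in panel.columns]
    panel[cols].to_csv(path, index=False)


def read_panel_csv(path) -> pd.DataFrame:
    panel = pd.read_csv(path, dtype={"area_id": str})
    if not {"area_id", "year", "Y"} <= set(panel.columns):
        raise ValueError("panel CSV must have at least area_id,year,Y")
    return panel
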