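"""Competitor dyads: concurrency matching, daily minimum distances,
close-encounter flags, and dyad exclusion rules.

A dyad is a dominant/subordinate pair tracked concurrently.  Fixes are
*concurrent* when sampled within 2.5 min of one another (half the
highest sampling frequency).  A *close encounter* is a calendar day on
which the dyad's minimum concurrent distance falls at or below the
encounter threshold (400 m by default, with 600/800/1000 m sensitivity
settings).  Dyads whose members were never recorded within the
proximity floor (1000 m default; 5000/10000 m sensitivity) of one
another are excluded as pairs that occupied disjoint parts of the
landscape.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .tracking import GapError, validate_fixes

logger = logging.getLogger(__name__)

CONCURRENCY_MAX_GAP_S = 150.0
ENCOUNTER_THRESHOLDS_M = (400.0, 600.0, 800.0, 1000.0)
EXCLUSION_FLOORS_M = (1000.0, 5000.0, 10000.0)


def match_concurrent_fixes(
    track_a: pd.DataFrame,
    track_b: pd.DataFrame,
    max_gap_s: float = CONCURRENCY_MAX_GAP_S,
) -> pd.DataFrame:
    """Greedy one-to-one pairing of fixes within the concurrency window.

    Candidate pairs (|dt| <= max_gap_s) are taken in order of
    increasing |dt| (ties: earlier fix of ``track_a``); each fix joins
    at most one pair.  Operates on full-resolution data.
    """
    ta = track_a.sort_values("timestamp")
    tb = track_b.sort_values("timestamp")
    at = ta["timestamp"].values
    bt = tb["timestamp"].values
    if len(at) == 0 or len(bt) == 0:
        return pd.DataFrame(
            columns=["t_a", "t_b", "x_a", "y_a", "x_b", "y_b", "dt_s", "distance"]
        )
    gap = np.timedelta64(int(max_gap_s * 1e9), "ns")
    cand = []
    j0 = 0
    for i, t in enumerate(at):
        while j0 < len(bt) and bt[j0] < t - gap:
            j0 += 1
        j = j0
        while j < len(bt) and bt[j] <= t + gap:
            dt = abs(t - bt[j])
            cand.append((dt, t, i, j))
            j += 1
    cand.sort(key=lambda c: (c[0], c[1]))
    used_a: set = set()
    used_b: set = set()
    rows = []
    ax = ta["x"].to_numpy()
    ay = ta["y"].to_numpy()
    bx = tb["x"].to_numpy()
    by = tb["y"].to_numpy()
    for dt, _t, i, j in cand:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        rows.append(
            (
                at[i],
                bt[j],
                ax[i],
                ay[i],
                bx[j],
                by[j],
                dt / np.timedelta64(1, "s"),
                float(np.hypot(ax[i] - bx[j], ay[i] - by[j])),
            )
        )
    out = pd.DataFrame(
        rows, columns=["t_a", "t_b", "x_a", "y_a", "x_b", "y_b", "dt_s", "distance"]
    ).sort_values("t_a").reset_index(drop=True)
    return out


def build_dyad_days(
    pairs: pd.DataFrame,
    temperatures: pd.DataFrame,
    encounter_threshold: float = 400.0,
    dyad_id: str = "dyad",
    species_pair: str = "",
) -> pd.DataFrame:
    """Daily minimum concurrent distance and encounter flag for one dyad.

    Days without any concurrent pair yield no row (minimum distance is
    undefined there).  Lagged standardized temperatures, season and day
    of year are joined by UTC calendar date; a date missing from the
    temperature table raises :class:`GapError`.
    """
    if pairs.empty:
        return pd.DataFrame(
            columns=[
                "dyad_id", "species_pair", "date", "season", "min_distance",
                "encounter", "z_lag0", "z_lag1", "day_of_year",
            ]
        )
    p = pairs.copy()
    p["date"] = pd.to_datetime(p["t_a"], utc=True).dt.date
    daily = p.groupby("date")["distance"].min().reset_index()
    daily.columns = ["date", "min_distance"]
    tcols = temperatures.set_index("date")[["season", "z_lag0", "z_lag1", "day_of_year"]]
    missing = [d for d in daily["date"] if d not in tcols.index]
    if missing:
        raise GapError(missing)
    joined = daily.join(tcols, on="date")
    joined["encounter"] = (joined["min_distance"] <= encounter_threshold).astype(int)
    joined["dyad_id"] = dyad_id
    joined["species_pair"] = species_pair
    return joined[
        [
            "dyad_id", "species_pair", "date", "season", "min_distance",
            "encounter", "z_lag0", "z_lag1", "day_of_year",
        ]
    ]


def apply_dyad_exclusion(
    dyad_days: pd.DataFrame, proximity_floor: float = 1000.0
) -> pd.DataFrame:
    """Drop dyads never recorded within the proximity floor of each other."""
    if dyad_days.empty:
        return dyad_days
    gmin = dyad_days.groupby("dyad_id")["min_distance"].min()
    keep = gmin[gmin <= proximity_floor].index
    dropped = sorted(set(gmin.index) - set(keep))
    if dropped:
        logger.info(
            "dyad exclusion at %.0f m removed %d dyads: %s",
            proximity_floor, len(dropped), dropped,
        )
    return dyad_days[dyad_days["dyad_id"].isin(keep)].reset_index(drop=True)


def build_all_dyads(
    fixes: pd.DataFrame,
    temperatures: pd.DataFrame,
    encounter_threshold: float = 400.0,
    max_gap_s: float = CONCURRENCY_MAX_GAP_S,
) -> pd.DataFrame:
    """Dyad-day table for every dominant x subordinate pair in a fix table.

    Requires ``role`` and ``species`` columns; dyads span only the
    overlapping deployment window of both members.
    """
    fixes = validate_fixes(fixes)
    if "role" not in fixes:
        raise ValueError("fix table needs a 'role' column to form dyads")
    dominants = fixes[fixes["role"] == "dominant"]
    subs = fixes[fixes["role"].isin(["subordinate_a", "subordinate_b"])]
    if dominants.empty:
        raise ValueError("no dominant-species data: cannot form any dyad")
    out = []
    for did, dtrack in dominants.groupby("individual_id"):
        for sid, strack in subs.groupby("individual_id"):
            lo = max(dtrack["timestamp"].min(), strack["timestamp"].min())
            hi = min(dtrack["timestamp"].max(), strack["timestamp"].max())
            if lo >= hi:
                continue
            dwin = dtrack[(dtrack["timestamp"] >= lo) & (dtrack["timestamp"] <= hi)]
            swin = strack[(strack["timestamp"] >= lo) & (strack["timestamp"] <= hi)]
            pairs = match_concurrent_fixes(swin, dwin, max_gap_s=max_gap_s)
            sp = f"{strack['species'].iloc[0]}-{dtrack['species'].iloc[0]}"
            dd = build_dyad_days(
                pairs,
                temperatures,
                encounter_threshold=encounter_threshold,
                dyad_id=f"{sid}:{did}",
                species_pair=sp,
            )
            dd["subordinate_role"] = strack["role"].iloc[0]
            out.append(dd)
    if not out:
        return pd.DataFrame()
    return pd.concat(out, ignore_index=True)


def dyad_summary(dyad_days: pd.DataFrame) -> pd.DataFrame:
    """Per-dyad day counts, encounter counts and global minimum distance."""
    return (
        dyad_days.groupby(["dyad_id", "species_pair"])
        .agg(
            n_days=("date", "nunique"),
            n_encounters=("encounter", "sum"),
            global_min_distance=("min_distance", "min"),
        )
        .reset_index()
    )
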