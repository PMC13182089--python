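"""Canonical trajectory handling and preprocessing rules.

Implements the preprocessing applied to raw GPS collar data before any
modelling: hourly regularisation (nearest fix within +/-30 min, ties to
the earlier hour), the 20 m active/inactive classification, season
labelling, centring/scaling of daily maximum temperature with one-day
lags, the pseudoreplication filter for group-living animals whose
members travel together, and optional per-individual date-interval
exclusions (e.g. denning periods).
"""

from __future__ import annotations

import logging
from datetime import date

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FIX_COLUMNS = ["individual_id", "species", "group_id", "timestamp", "x", "y"]

ACTIVITY_THRESHOLD_M = 20.0


class GapError(ValueError):
    """A required daily series has missing dates."""

    def __init__(self, dates):
        self.dates = list(dates)
        super().__init__(f"missing dates in daily series: {self.dates[:10]}")


def validate_fixes(fixes: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("individual_id", "timestamp", "x", "y") if c not in fixes]
    if missing:
        raise ValueError(f"fix table missing columns {missing}")
    out = fixes.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True)
    if not np.isfinite(out[["x", "y"]].to_numpy()).all():
        raise ValueError("non-finite coordinates in fix table")
    out = out.sort_values(["individual_id", "timestamp"], kind="mergesort")
    before = len(out)
    out = out.drop_duplicates(["individual_id", "timestamp"])
    if len(out) < before:
        logger.info("dropped %d duplicate-timestamp fixes", before - len(out))
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# hourly regularisation
# ---------------------------------------------------------------------------

def _regularize_one(track: pd.DataFrame, tol: pd.Timedelta) -> pd.DataFrame:
    ts = track["timestamp"]
    lo = ts.min().floor("h")
    hi = ts.max().ceil("h")
    hours = pd.date_range(lo, hi, freq="h")
    # candidate (hour, fix) pairs within tolerance, greedy by |dt| then
    # earlier hour, each hour and each fix used at most once
    cand = []
    tvals = ts.values
    hvals = hours.values
    for fi, t in enumerate(tvals):
        h0 = np.searchsorted(hvals, t)
        for hi_ in (h0 - 1, h0):
            if 0 <= hi_ < len(hvals):
                dt = abs(t - hvals[hi_])
                if dt <= tol.to_numpy():
                    cand.append((dt, hvals[hi_], fi))
    cand.sort(key=lambda c: (c[0], c[1]))
    used_hours: set = set()
    used_fixes: set = set()
    assign: dict = {}
    for dt, hour, fi in cand:
        if hour in used_hours or fi in used_fixes:
            continue
        used_hours.add(hour)
        used_fixes.add(fi)
        assign[hour] = fi
    if not assign:
        return track.iloc[0:0]
    rows = track.iloc[[assign[h] for h in sorted(assign)]].copy()
    rows["hour"] = pd.to_datetime(sorted(assign), utc=True)
    return rows


def regularize_hourly(
    fixes: pd.DataFrame, tolerance_minutes: float = 30.0
) -> pd.DataFrame:
    """Downsample to at most one fix per top-of-hour per individual.

    Each hour mark receives the nearest raw fix within the tolerance;
    each raw fix serves at most one hour; ties go to the earlier hour.
    The returned table carries an extra ``hour`` column with the mark.
    """
    fixes = validate_fixes(fixes)
    tol = pd.Timedelta(minutes=tolerance_minutes)
    if fixes.empty:
        out = fixes.copy()
        out["hour"] = pd.Series([], dtype="datetime64[ns, UTC]")
        return out
    parts = [
        _regularize_one(track, tol)
        for _, track in fixes.groupby("individual_id", sort=True)
    ]
    out = pd.concat(parts, ignore_index=True)
    logger.info("hourly regularisation: %d raw -> %d hourly fixes", len(fixes), len(out))
    return out


# ---------------------------------------------------------------------------
# activity
# ---------------------------------------------------------------------------

def classify_activity(hourly: pd.DataFrame) -> pd.DataFrame:
    """Active (1) iff displacement to the next hour's fix is >= 20 m.

    The record is attributed to the start hour; hours whose successor
    hour has no fix are dropped.
    """
    rows = []
    for ind, track in hourly.groupby("individual_id", sort=True):
        track = track.sort_values("hour")
        h = track["hour"].values
        x = track["x"].to_numpy()
        y = track["y"].to_numpy()
        nxt = h + np.timedelta64(1, "h")
        pos = {t: i for i, t in enumerate(h)}
        for i in range(len(h)):
            j = pos.get(nxt[i])
            if j is None:
                continue
            disp = float(np.hypot(x[j] - x[i], y[j] - y[i]))
            rows.append((ind, h[i], disp, int(disp >= ACTIVITY_THRESHOLD_M)))
    return pd.DataFrame(rows, columns=["individual_id", "hour", "displacement", "active"])


# ---------------------------------------------------------------------------
# temperature
# ---------------------------------------------------------------------------

def season_of_month(month: int, dry_months=frozenset({5, 6, 7, 8, 9, 10})) -> str:
    return "dry" if month in dry_months else "wet"


def prepare_temperatures(
    temperature: pd.DataFrame, scope: str = "season"
) -> pd.DataFrame:
    """Standardize daily maxima and attach one-day lags and seasons.

    ``scope`` sets the population over which z-scores are computed:
    ``"season"`` (default; matches season-specific models) or ``"all"``.
    ``z_lag1`` of day d is defined as ``z_lag0`` of day d-1, so the lag
    alignment is exact regardless of scope.
    """
    t = temperature.copy()
    t["date"] = pd.to_datetime(t["date"]).dt.date
    t = t.sort_values("date").reset_index(drop=True)
    dates = pd.to_datetime(t["date"])
    full = pd.date_range(dates.min(), dates.max(), freq="D")
    missing = full.difference(pd.DatetimeIndex(dates))
    if len(missing) > 0:
        raise GapError(missing.date)
    if "season" not in t:
        t["season"] = [season_of_month(d.month) for d in dates]
    if scope == "all":
        groups = pd.Series("all", index=t.index)
    elif scope == "season":
        groups = t["season"]
    else:
        raise ValueError("scope must be 'all' or 'season'")
    z = np.empty(len(t))
    for _, idx in groups.groupby(groups).groups.items():
        vals = t.loc[idx, "t_max"].to_numpy(dtype=float)
        sd = vals.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError("degenerate temperature series: zero variance")
        z[idx] = (vals - vals.mean()) / sd
    t["z_lag0"] = z
    t["z_lag1"] = np.concatenate([[np.nan], z[:-1]])
    t["day_of_year"] = dates.dt.dayofyear
    return t


def standardize(values: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Centre/scale with the n-1 denominator; errors on zero variance."""
    values = np.asarray(values, dtype=float)
    sd = values.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("cannot standardize a constant series")
    mean = values.mean()
    return (values - mean) / sd, float(mean), float(sd)


# ---------------------------------------------------------------------------
# pseudoreplication filter
# ---------------------------------------------------------------------------

def pairwise_overlap(
    track_a: pd.DataFrame,
    track_b: pd.DataFrame,
    distance_threshold: float = 400.0,
    max_gap_s: float = 150.0,
) -> float:
    """Fraction of concurrent fix pairs within the distance threshold."""
    from .dyads import match_concurrent_fixes

    pairs = match_concurrent_fixes(track_a, track_b, max_gap_s=max_gap_s)
    if pairs.empty:
        return 0.0
    return float((pairs["distance"] <= distance_threshold).mean())


def filter_pseudoreplicates(
    fixes: pd.DataFrame,
    distance_threshold: float = 400.0,
    overlap_threshold: float = 0.5,
    seed: int = 0,
) -> list[str]:
    """Retained individual ids after removing co-travelling pairs.

    For every within-group pair, the fraction of concurrent fixes (2.5
    min rule) within 400 m is computed once; while any retained pair
    exceeds the overlap threshold, one member of the first offending
    pair (id order) is removed by a seeded uniform draw.
    """
    fixes = validate_fixes(fixes)
    rng = np.random.default_rng(seed)
    retained: list[str] = sorted(fixes["individual_id"].unique())
    if "group_id" in fixes:
        group_of = fixes.groupby("individual_id")["group_id"].first().to_dict()
    else:
        group_of = {i: "all" for i in retained}
    tracks = {i: t for i, t in fixes.groupby("individual_id")}
    overlaps: dict[tuple[str, str], float] = {}
    for i, a in enumerate(retained):
        for b in retained[i + 1 :]:
            if group_of[a] != group_of[b]:
                continue
            overlaps[(a, b)] = pairwise_overlap(
                tracks[a], tracks[b], distance_threshold
            )
    while True:
        offending = [
            p
            for p in sorted(overlaps)
            if p[0] in retained and p[1] in retained
            and overlaps[p] > overlap_threshold
        ]
        if not offending:
            break
        pair = offending[0]
        drop = pair[int(rng.integers(2))]
        logger.info("pseudoreplication filter: removing %s (pair %s)", drop, pair)
        retained.remove(drop)
    return retained


# ---------------------------------------------------------------------------
# exclusions and I/O
# ---------------------------------------------------------------------------

def apply_exclusions(fixes: pd.DataFrame, exclusions: pd.DataFrame) -> pd.DataFrame:
    """Drop fixes inside per-individual [start_date, end_date] intervals."""
    fixes = validate_fixes(fixes)
    keep = np.ones(len(fixes), dtype=bool)
    d = fixes["timestamp"].dt.date
    for _, row in exclusions.iterrows():
        start = pd.to_datetime(row["start_date"]).date()
        end = pd.to_datetime(row["end_date"]).date()
        mask = (fixes["individual_id"] == row["individual_id"]) & (d >= start) & (d <= end)
        keep &= ~mask.to_numpy()
    dropped = int((~keep).sum())
    if dropped:
        logger.info("exclusion intervals removed %d fixes", dropped)
    return fixes.loc[keep].reset_index(drop=True)


def read_fixes(path) -> pd.DataFrame:
    return validate_fixes(pd.read_csv(path))


def read_temperature(path) -> pd.DataFrame:
    t = pd.read_csv(path)
    t["date"] = pd.to_datetime(t["date"]).dt.date
    return t


def read_sun_table(path) -> pd.DataFrame:
    s = pd.read_csv(path)
    s["date"] = pd.to_datetime(s["date"]).dt.date
    s["sunrise"] = pd.to_datetime(s["sunrise"], utc=True)
    s["sunset"] = pd.to_datetime(s["sunset"], utc=True)
    return s


def read_exclusions(path) -> pd.DataFrame:
    return pd.read_csv(path)
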