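"""Rolling 30-day Brownian bridge movement model (BBMM) home ranges.

The utilization distribution (UD) for a window of hourly fixes is the
duration-weighted average, over consecutive-fix bridges, of the time
integral of the bridge's Gaussian density:

    f(c) = (1/sum_i T_i) * sum_i T_i * Int_0^1 N(c; (1-a) z_i + a z_{i+1},
                 [T_i a (1-a) sigma2_m + ((1-a)^2 + a^2) delta^2] I) da

with sigma2_m the Brownian motion variance (m^2/s) and delta the
location-error sd (m).  sigma2_m is estimated by the leave-one-out
likelihood in which every odd-indexed fix is modelled as a draw from
the bridge spanned by its neighbours.  The home-range polygon is the
highest-density region: the smallest set of grid cells holding the
isopleth level (0.95 default) of UD mass.

The rolling statistic is the proportion of a focal animal's hourly
fixes falling inside the competitor's home range built from the
competitor's preceding 30 days (d-30 .. d-1), requiring at least 24
distinct days of competitor data in the window.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)

DEFAULT_DELTA_M = 20.0  # matches the collar-error-motivated movement threshold
DEFAULT_ISOPLETH = 0.95
MAX_BRIDGE_GAP_H = 6.0
WINDOW_DAYS = 30
MIN_DATA_DAYS = 24


@dataclass
class GridSpec:
    xll: float
    yll: float
    cellsize: float
    ncols: int
    nrows: int

    @property
    def xcenters(self) -> np.ndarray:
        return self.xll + (np.arange(self.ncols) + 0.5) * self.cellsize

    @property
    def ycenters(self) -> np.ndarray:
        return self.yll + (np.arange(self.nrows) + 0.5) * self.cellsize

    def cell_of(self, x, y):
        ix = np.floor((np.asarray(x) - self.xll) / self.cellsize).astype(int)
        iy = np.floor((np.asarray(y) - self.yll) / self.cellsize).astype(int)
        return ix, iy

    @classmethod
    def around(cls, x, y, cellsize: float, buffer: float) -> "GridSpec":
        xmin, xmax = np.min(x) - buffer, np.max(x) + buffer
        ymin, ymax = np.min(y) - buffer, np.max(y) + buffer
        return cls(
            xll=float(xmin),
            yll=float(ymin),
            cellsize=cellsize,
            ncols=max(int(np.ceil((xmax - xmin) / cellsize)), 1),
            nrows=max(int(np.ceil((ymax - ymin) / cellsize)), 1),
        )


@dataclass
class UtilizationDistribution:
    grid: GridSpec
    pdf: np.ndarray  # [iy, ix], sums to 1
    window: tuple[date, date] | None = None
    individual_id: str = ""
    sigma2_m: float = 0.0
    delta: float = DEFAULT_DELTA_M

    def hdr_mask(self, level: float = DEFAULT_ISOPLETH) -> np.ndarray:
        """Smallest cell set whose mass >= level (cells ranked by density)."""
        flat = self.pdf.ravel()
        order = np.argsort(flat)[::-1]
        csum = np.cumsum(flat[order])
        k = int(np.searchsorted(csum, level - 1e-12)) + 1
        mask = np.zeros(flat.shape, dtype=bool)
        mask[order[:k]] = True
        return mask.reshape(self.pdf.shape)

    def contains(self, x, y, level: float = DEFAULT_ISOPLETH) -> np.ndarray:
        mask = self.hdr_mask(level)
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ix, iy = self.grid.cell_of(x, y)
        inside = (
            (ix >= 0) & (ix < self.grid.ncols) & (iy >= 0) & (iy < self.grid.nrows)
        )
        out = np.zeros(x.shape, dtype=bool)
        out[inside] = mask[iy[inside], ix[inside]]
        return out

    def hdr_polygon(self, level: float = DEFAULT_ISOPLETH):
        """Isopleth region as a shapely (multi)polygon of cell squares."""
        from shapely.geometry import box
        from shapely.ops import unary_union

        mask = self.hdr_mask(level)
        g = self.grid
        cells = [
            box(
                g.xll + ix * g.cellsize,
                g.yll + iy * g.cellsize,
                g.xll + (ix + 1) * g.cellsize,
                g.yll + (iy + 1) * g.cellsize,
            )
            for iy, ix in zip(*np.nonzero(mask))
        ]
        return unary_union(cells)


# ---------------------------------------------------------------------------
# sigma estimation
# ---------------------------------------------------------------------------

def _bridge_triples(track: pd.DataFrame, max_gap_h: float = MAX_BRIDGE_GAP_H):
    t = track["timestamp"].values
    xy = track[["x", "y"]].to_numpy(dtype=float)
    secs = (t - t[0]) / np.timedelta64(1, "s")
    triples = []
    for i in range(1, len(t) - 1, 2):
        dt_total = secs[i + 1] - secs[i - 1]
        if dt_total <= 0 or dt_total > 2 * max_gap_h * 3600:
            continue
        alpha = (secs[i] - secs[i - 1]) / dt_total
        triples.append((xy[i - 1], xy[i], xy[i + 1], dt_total, alpha))
    return triples


def fit_bbmm_sigma(
    track: pd.DataFrame,
    delta: float = DEFAULT_DELTA_M,
    max_gap_h: float = MAX_BRIDGE_GAP_H,
    on_degenerate: str = "raise",
    default_sigma2: float = 0.05,
) -> float:
    """Leave-one-out ML estimate of the motion variance sigma2_m (m^2/s).

    Odd-indexed fixes are predicted from the linear interpolation of
    their neighbours with variance ``T a (1-a) sigma2_m +
    ((1-a)^2 + a^2) delta^2``.
    """
    track = track.sort_values("timestamp")
    if len(track) < 2:
        raise ValueError("need at least two fixes")
    triples = _bridge_triples(track, max_gap_h)
    if not triples:
        if on_degenerate == "default":
            return default_sigma2
        raise ValueError("no interior fix available to estimate sigma2_m")
    a = np.array([tr[0] for tr in triples])
    m = np.array([tr[1] for tr in triples])
    b = np.array([tr[2] for tr in triples])
    T = np.array([tr[3] for tr in triples])
    al = np.array([tr[4] for tr in triples])
    mu = (1 - al)[:, None] * a + al[:, None] * b
    r2 = ((m - mu) ** 2).sum(axis=1)
    if np.allclose(r2, 0.0) and delta == 0:
        warnings.warn("all fixes identical along bridges: sigma2_m = 0")
        return 0.0

    def nll(log_s2: float) -> float:
        s2 = np.exp(log_s2)
        v = T * al * (1 - al) * s2 + ((1 - al) ** 2 + al**2) * delta**2
        v = np.maximum(v, 1e-12)
        return float(np.sum(np.log(v) + r2 / (2 * v)))

    res = minimize_scalar(nll, bounds=(np.log(1e-8), np.log(1e6)), method="bounded")
    s2 = float(np.exp(res.x))
    if s2 <= 2e-8:
        warnings.warn("sigma2_m at lower bound; track may be deterministic")
    return s2


# ---------------------------------------------------------------------------
# UD construction
# ---------------------------------------------------------------------------

def _gauss_legendre_01(n: int):
    """Composite Gauss-Legendre rule on [0, 1] with ~n nodes.

    The bridge integrand narrows sharply near the endpoints (variance
    collapses to delta^2), so a composite rule over panels converges
    much faster than a single high-order rule.
    """
    per = 8 if n >= 8 else max(n, 2)
    panels = max(1, round(n / per))
    base_x, base_w = np.polynomial.legendre.leggauss(per)
    base_x = (base_x + 1) / 2
    base_w = base_w / 2
    edges = np.linspace(0.0, 1.0, panels + 1)
    u = np.concatenate(
        [edges[i] + (edges[i + 1] - edges[i]) * base_x for i in range(panels)]
    )
    wu = np.concatenate(
        [(edges[i + 1] - edges[i]) * base_w for i in range(panels)]
    )
    # substitution a = sin^2(pi u / 2) clusters nodes at the endpoints,
    # where the bridge variance collapses to delta^2 over a thin layer
    nodes = np.sin(np.pi * u / 2) ** 2
    weights = wu * (np.pi / 2) * np.sin(np.pi * u)
    return nodes, weights


def _bridge_density(
    grid: GridSpec,
    a: np.ndarray,
    b: np.ndarray,
    T: float,
    sigma2_m: float,
    delta: float,
    nodes: np.ndarray,
    weights: np.ndarray,
    out: np.ndarray,
    truncate_sd: float = 6.0,
) -> None:
    """Accumulate T * Int N(c; mu(a), s2(a)) da onto ``out`` (local box)."""
    xc = grid.xcenters
    yc = grid.ycenters
    for al, w in zip(nodes, weights):
        mu = (1 - al) * a + al * b
        s2 = T * al * (1 - al) * sigma2_m + ((1 - al) ** 2 + al**2) * delta**2
        if s2 <= 0:
            # degenerate: all mass in the containing cell
            ix = int(np.clip((mu[0] - grid.xll) / grid.cellsize, 0, grid.ncols - 1))
            iy = int(np.clip((mu[1] - grid.yll) / grid.cellsize, 0, grid.nrows - 1))
            out[iy, ix] += T * w / grid.cellsize**2
            continue
        sd = np.sqrt(s2)
        r = truncate_sd * sd
        i0 = max(int((mu[0] - r - grid.xll) / grid.cellsize), 0)
        i1 = min(int((mu[0] + r - grid.xll) / grid.cellsize) + 1, grid.ncols)
        j0 = max(int((mu[1] - r - grid.yll) / grid.cellsize), 0)
        j1 = min(int((mu[1] + r - grid.yll) / grid.cellsize) + 1, grid.nrows)
        if i0 >= i1 or j0 >= j1:
            continue
        gx = np.exp(-((xc[i0:i1] - mu[0]) ** 2) / (2 * s2))
        gy = np.exp(-((yc[j0:j1] - mu[1]) ** 2) / (2 * s2))
        out[j0:j1, i0:i1] += (T * w / (2 * np.pi * s2)) * gy[:, None] * gx[None, :]


def bbmm_ud(
    track: pd.DataFrame,
    sigma2_m: float,
    delta: float = DEFAULT_DELTA_M,
    grid: GridSpec | None = None,
    cellsize: float = 100.0,
    n_alpha: int = 128,
    max_gap_h: float = MAX_BRIDGE_GAP_H,
    min_days: int | None = MIN_DATA_DAYS,
    alpha_nodes: tuple[np.ndarray, np.ndarray] | None = None,
    individual_id: str = "",
) -> UtilizationDistribution:
    """Brownian-bridge UD of one window of hourly fixes on a grid.

    ``alpha_nodes`` overrides the Gauss-Legendre rule (used to recover
    the closed-form endpoint limits a=0 / a=1).  ``min_days=None``
    disables the data-coverage gate for single-bridge diagnostics.
    """
    track = track.sort_values("timestamp").reset_index(drop=True)
    if min_days is not None:
        ndays = track["timestamp"].dt.date.nunique()
        if ndays < min_days:
            raise ValueError(
                f"window has {ndays} distinct data days; {min_days} required"
            )
    xy = track[["x", "y"]].to_numpy(dtype=float)
    t = track["timestamp"].values
    if grid is None:
        steps = np.hypot(*np.diff(xy, axis=0).T)
        buffer = 3.0 * (steps.max() if len(steps) else cellsize) + 5 * delta
        grid = GridSpec.around(xy[:, 0], xy[:, 1], cellsize, buffer)
    if alpha_nodes is None:
        nodes, weights = _gauss_legendre_01(n_alpha)
    else:
        nodes, weights = (np.asarray(v, dtype=float) for v in alpha_nodes)
    dens = np.zeros((grid.nrows, grid.ncols))
    total_T = 0.0
    for i in range(len(track) - 1):
        T = float((t[i + 1] - t[i]) / np.timedelta64(1, "s"))
        if T <= 0 or T > max_gap_h * 3600:
            continue
        _bridge_density(grid, xy[i], xy[i + 1], T, sigma2_m, delta, nodes, weights, dens)
        total_T += T
    if total_T == 0.0:
        raise ValueError("no usable bridge in window (all gaps exceed the limit)")
    s = dens.sum()
    if s <= 0:
        raise ValueError("UD mass vanished on the grid; enlarge the grid")
    dates = pd.to_datetime(track["timestamp"]).dt.date
    return UtilizationDistribution(
        grid=grid,
        pdf=dens / s,
        window=(dates.min(), dates.max()),
        individual_id=individual_id,
        sigma2_m=sigma2_m,
        delta=delta,
    )


# ---------------------------------------------------------------------------
# rolling windows
# ---------------------------------------------------------------------------

def rolling_home_ranges(
    hourly: pd.DataFrame,
    sigma2_m: float,
    delta: float = DEFAULT_DELTA_M,
    grid: GridSpec | None = None,
    cellsize: float = 100.0,
    window_days: int = WINDOW_DAYS,
    min_days: int = MIN_DATA_DAYS,
    n_alpha: int = 12,
    max_gap_h: float = MAX_BRIDGE_GAP_H,
    individual_id: str = "",
) -> dict[date, UtilizationDistribution]:
    """UD per target date from the preceding ``window_days`` of data.

    Bridges are binned by the date of their starting fix and evaluated
    once on a shared grid; a rolling sum over day layers then yields
    each window's UD, so the cost is linear in tracking days.  Exactly
    the dates with >= ``min_days`` distinct data days in d-30..d-1
    receive a home range.
    """
    track = hourly.sort_values("timestamp").reset_index(drop=True)
    xy = track[["x", "y"]].to_numpy(dtype=float)
    if len(track) < 2:
        return {}
    if grid is None:
        steps = np.hypot(*np.diff(xy, axis=0).T)
        buffer = 3.0 * steps.max() + 5 * delta
        grid = GridSpec.around(xy[:, 0], xy[:, 1], cellsize, buffer)
    nodes, weights = _gauss_legendre_01(n_alpha)
    t = track["timestamp"].values
    fix_dates = track["timestamp"].dt.date.to_numpy()
    all_days = sorted(set(fix_dates))
    day_layers: dict[date, np.ndarray] = {}
    day_T: dict[date, float] = {}
    for i in range(len(track) - 1):
        T = float((t[i + 1] - t[i]) / np.timedelta64(1, "s"))
        if T <= 0 or T > max_gap_h * 3600:
            continue
        d = fix_dates[i]
        layer = day_layers.get(d)
        if layer is None:
            layer = day_layers[d] = np.zeros((grid.nrows, grid.ncols), dtype=np.float32)
            day_T[d] = 0.0
        _bridge_density(grid, xy[i], xy[i + 1], T, sigma2_m, delta, nodes, weights, layer)
        day_T[d] += T
    if not day_layers:
        return {}
    first, last = all_days[0], all_days[-1]
    out: dict[date, UtilizationDistribution] = {}
    acc = np.zeros((grid.nrows, grid.ncols))
    in_window: list[date] = []
    d = first + timedelta(days=1)
    end = last + timedelta(days=window_days + 1)
    data_days = set(all_days)
    while d <= end:
        lo = d - timedelta(days=window_days)
        new_day = d - timedelta(days=1)
        if new_day in day_layers:
            acc += day_layers[new_day]
        if new_day in data_days:
            in_window.append(new_day)
        while in_window and in_window[0] < lo:
            old = in_window.pop(0)
            if old in day_layers:
                acc -= day_layers[old]
        n_window_days = len(in_window)
        s = acc.sum()
        if n_window_days >= min_days and s > 0:
            out[d] = UtilizationDistribution(
                grid=grid,
                pdf=np.maximum(acc, 0.0) / s,
                window=(lo, d - timedelta(days=1)),
                individual_id=individual_id,
                sigma2_m=sigma2_m,
                delta=delta,
            )
        d += timedelta(days=1)
    return out


def rolling_proportion_in_range(
    focal_hourly: pd.DataFrame,
    competitor_uds: dict[date, UtilizationDistribution],
    level: float = DEFAULT_ISOPLETH,
) -> pd.DataFrame:
    """Per-date proportion of focal fixes inside the competitor range.

    Dates without a valid competitor UD are skipped (logged).
    """
    rows = []
    skipped = 0
    focal = focal_hourly.copy()
    focal["date"] = focal["timestamp"].dt.date
    for d, day_fixes in focal.groupby("date"):
        ud = competitor_uds.get(d)
        if ud is None:
            skipped += 1
            continue
        inside = ud.contains(
            day_fixes["x"].to_numpy(), day_fixes["y"].to_numpy(), level
        )
        ind = (
            day_fixes["individual_id"].iloc[0]
            if "individual_id" in day_fixes
            else ""
        )
        rows.append((ind, d, len(day_fixes), int(inside.sum()), float(inside.mean())))
    if skipped:
        logger.info("proportion-in-range: skipped %d dates without competitor UD", skipped)
    return pd.DataFrame(
        rows, columns=["individual_id", "date", "n_fixes", "n_inside", "proportion"]
    )
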