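"""Integrated step selection analysis (iSSA).

Habitat selection during movement is estimated in a use-availability
design: every hourly movement step (displacement >= 20 m) is contrasted
against 150 available steps simulated from gamma step lengths and von
Mises turning angles fitted to the observed steps.  Selection follows
the exponential form w(x) = exp(beta' x) with covariates

    habitat one-hots (reference = mopane),
    habitat x z_lag0 and habitat x z_lag1 interactions,
    step length, log step length, cos(turning angle),
    a 4-df m-spline of day of year,

estimated by maximizing the stratum-conditional logistic likelihood
prod exp(beta' x_used) / sum_j exp(beta' x_j), with cluster-robust
(GEE sandwich) standard errors treating each individual as a cluster.
Temperature main effects are constant within a stratum and drop out of
the likelihood, which is exactly why they enter only through habitat
interactions.  The day-of-year block is likewise constant within each
stratum, so it carries no information and its coefficients shrink to
zero under a tiny ridge kept for numerical stability.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.interpolate import BSpline

from .raster import HABITAT_LEGEND, Raster
from .tracking import GapError

logger = logging.getLogger(__name__)

MOVEMENT_THRESHOLD_M = 20.0
N_AVAILABLE = 150
KAPPA_CAP = 500.0
REFERENCE_HABITAT = "mopane"
HABITAT_NAMES = ("grassland", "floodplain", "mixed_woodland")  # non-reference


# ---------------------------------------------------------------------------
# steps
# ---------------------------------------------------------------------------

def build_steps(hourly: pd.DataFrame) -> pd.DataFrame:
    """Movement steps between consecutive hourly fixes (>= 20 m).

    A turning angle is defined only when the previous *retained* step is
    contiguous (ends where this one starts, one hour earlier).
    """
    rows = []
    for ind, track in hourly.groupby("individual_id", sort=True):
        track = track.sort_values("hour")
        h = track["hour"].values
        x = track["x"].to_numpy(dtype=float)
        y = track["y"].to_numpy(dtype=float)
        prev_end_hour = None
        prev_bearing = np.nan
        for i in range(len(h) - 1):
            if h[i + 1] - h[i] != np.timedelta64(1, "h"):
                continue
            dx, dy = x[i + 1] - x[i], y[i + 1] - y[i]
            length = float(np.hypot(dx, dy))
            if length < MOVEMENT_THRESHOLD_M:
                continue
            bearing = float(np.arctan2(dy, dx))
            turn = np.nan
            if prev_end_hour is not None and prev_end_hour == h[i]:
                turn = float(
                    np.angle(np.exp(1j * (bearing - prev_bearing)))
                )
            start = pd.Timestamp(h[i])
            rows.append(
                (
                    ind, start, pd.Timestamp(h[i + 1]), x[i], y[i],
                    x[i + 1], y[i + 1], length, bearing, turn,
                    start.dayofyear, start.date(),
                )
            )
            prev_end_hour = h[i + 1]
            prev_bearing = bearing
    return pd.DataFrame(
        rows,
        columns=[
            "individual_id", "t_start", "t_end", "x_start", "y_start",
            "x_end", "y_end", "step_length", "bearing", "turn_angle",
            "day_of_year", "date",
        ],
    )


@dataclass
class StepDistributions:
    shape: float
    scale: float
    mu: float
    kappa: float
    species: str = ""
    season: str = ""


def fit_step_distributions(
    steps: pd.DataFrame, min_steps: int = 30, species: str = "", season: str = ""
) -> StepDistributions:
    """ML gamma fit to step lengths and von Mises fit to turning angles."""
    lengths = steps["step_length"].to_numpy(dtype=float)
    if (lengths < 0).any():
        raise ValueError("negative step length in input")
    if len(lengths) < min_steps:
        raise ValueError(
            f"too few steps ({len(lengths)} < {min_steps}) for {species}/{season}"
        )
    shape, _, scale = stats.gamma.fit(lengths, floc=0)
    angles = steps["turn_angle"].dropna().to_numpy(dtype=float)
    if len(angles) < 2 or np.allclose(angles, angles[0]):
        warnings.warn("degenerate turning angles: kappa capped")
        mu = float(angles[0]) if len(angles) else 0.0
        kappa = KAPPA_CAP
    else:
        kappa, mu, _ = stats.vonmises.fit(angles, fscale=1)
        if kappa > KAPPA_CAP:
            warnings.warn("kappa capped at %.0f" % KAPPA_CAP)
            kappa = KAPPA_CAP
    return StepDistributions(
        shape=float(shape), scale=float(scale), mu=float(mu),
        kappa=float(kappa), species=species, season=season,
    )


def sample_available_steps(
    used: pd.Series,
    dists: StepDistributions,
    n: int = N_AVAILABLE,
    rng: np.random.Generator | None = None,
    habitat: Raster | None = None,
    max_retries: int = 10,
) -> pd.DataFrame:
    """Simulate n available steps from the used step's start fix.

    Headings apply a von Mises turning angle to the previous bearing;
    for a step without one (start of a contiguous run) the heading is
    uniform.  Endpoints outside the habitat raster are resampled a
    bounded number of times, then dropped with a log message.
    """
    rng = rng or np.random.default_rng()
    prev = used.get("prev_bearing", np.nan)
    rows = []
    dropped = 0
    for _ in range(n):
        for _try in range(max_retries):
            length = rng.gamma(dists.shape, dists.scale)
            if np.isnan(prev):
                hdg = rng.uniform(-np.pi, np.pi)
            else:
                hdg = prev + dists.mu + rng.vonmises(0.0, dists.kappa)
            ex = used["x_start"] + length * np.cos(hdg)
            ey = used["y_start"] + length * np.sin(hdg)
            if habitat is None or habitat.contains(ex, ey):
                turn = float(np.angle(np.exp(1j * (hdg - prev)))) if not np.isnan(prev) else np.nan
                rows.append((ex, ey, float(length), float(hdg), turn))
                break
        else:
            dropped += 1
    if dropped:
        logger.info("dropped %d available steps outside the raster", dropped)
    return pd.DataFrame(
        rows, columns=["x_end", "y_end", "step_length", "bearing", "turn_angle"]
    )


def build_strata(
    steps: pd.DataFrame,
    dists: StepDistributions,
    habitat: Raster,
    temperatures: pd.DataFrame,
    n_available: int = N_AVAILABLE,
    seed: int = 0,
) -> pd.DataFrame:
    """Used + available steps with habitat/temperature covariates.

    One stratum per used step: the used step (case=1) and
    ``n_available`` simulated alternatives (case=0), all sharing the
    stratum's date covariates.  Habitat is annotated at the step
    endpoint; temperatures are looked up by the step's start date.
    """
    tcols = temperatures.set_index("date")[["z_lag0", "z_lag1", "season"]]
    rng = np.random.default_rng(seed)
    steps = steps.sort_values(["individual_id", "t_start"]).reset_index(drop=True)
    # previous bearing per step: bearing of the contiguous predecessor
    prev_bearing = np.full(len(steps), np.nan)
    for i in range(1, len(steps)):
        if (
            steps.at[i, "individual_id"] == steps.at[i - 1, "individual_id"]
            and steps.at[i, "t_start"] == steps.at[i - 1, "t_end"]
        ):
            prev_bearing[i] = steps.at[i - 1, "bearing"]
    steps = steps.assign(prev_bearing=prev_bearing)
    out = []
    for i, used in steps.iterrows():
        d = used["date"]
        if d not in tcols.index:
            raise GapError([d])
        trow = tcols.loc[d]
        sid = f"{used['individual_id']}:{used['t_start'].isoformat()}"
        if not habitat.contains(used["x_end"], used["y_end"]):
            continue
        base = {
            "stratum_id": sid,
            "individual_id": used["individual_id"],
            "date": d,
            "day_of_year": used["day_of_year"],
            "season": trow["season"],
            "z_lag0": trow["z_lag0"],
            "z_lag1": trow["z_lag1"],
        }
        used_row = dict(
            base,
            case=1,
            step_length=used["step_length"],
            turn_angle=used["turn_angle"],
            habitat=HABITAT_LEGEND[int(habitat.sample(used["x_end"], used["y_end"]))],
        )
        avail = sample_available_steps(
            used, dists, n=n_available, rng=rng, habitat=habitat
        )
        if len(avail) < n_available:
            continue  # stratum must hold exactly 1 + n_available steps
        hclasses = habitat.sample(avail["x_end"].to_numpy(), avail["y_end"].to_numpy())
        out.append(pd.DataFrame([used_row]))
        arows = pd.DataFrame(
            {
                "case": 0,
                "step_length": avail["step_length"],
                "turn_angle": avail["turn_angle"],
                "habitat": [HABITAT_LEGEND[int(c)] for c in hclasses],
            }
        )
        for kcol, v in base.items():
            arows[kcol] = v
        out.append(arows)
    if not out:
        return pd.DataFrame()
    strata = pd.concat(out, ignore_index=True)
    # steps on days without a defined temperature lag carry no usable
    # interaction covariates; drop the whole stratum
    bad = strata.loc[strata[["z_lag0", "z_lag1"]].isna().any(axis=1), "stratum_id"]
    if len(bad):
        strata = strata[~strata["stratum_id"].isin(set(bad))]
    return strata.reset_index(drop=True)


# ---------------------------------------------------------------------------
# m-spline of day of year
# ---------------------------------------------------------------------------

def mspline_basis(doy: np.ndarray, df: int = 4, lo: float = 1.0, hi: float = 366.0):
    """df cubic spline basis functions normalized to integrate to one
    (m-spline convention)."""
    degree = 3
    n_interior = df - degree - 1
    interior = (
        np.linspace(lo, hi, n_interior + 2)[1:-1] if n_interior > 0 else np.array([])
    )
    t = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    B = BSpline.design_matrix(np.clip(doy, lo, hi), t, degree).toarray()
    norms = (degree + 1) / (t[degree + 1 : degree + 1 + df] - t[:df])
    return B * norms


# ---------------------------------------------------------------------------
# conditional logistic likelihood
# ---------------------------------------------------------------------------

def fit_conditional_logistic(
    X: np.ndarray,
    case: np.ndarray,
    stratum: np.ndarray,
    cluster: np.ndarray,
    ridge: float = 1e-8,
    max_iter: int = 100,
    tol: float = 1e-10,
    coef_cap: float = 15.0,
):
    """Newton maximization of the stratum-conditional likelihood.

    Returns (beta, model covariance, cluster-robust covariance, loglik).
    """
    order = np.argsort(stratum, kind="mergesort")
    X = np.asarray(X, dtype=float)[order]
    case = np.asarray(case)[order]
    stratum = np.asarray(stratum)[order]
    cluster = np.asarray(cluster)[order]
    starts = np.r_[0, np.nonzero(stratum[1:] != stratum[:-1])[0] + 1]
    n_strata = len(starts)
    seg = np.repeat(np.arange(n_strata), np.diff(np.r_[starts, len(stratum)]))
    used_mask = case == 1
    n, p = X.shape

    def _stratum_quantities(beta):
        eta = X @ beta
        m = np.maximum.reduceat(eta, starts)
        w = np.exp(eta - m[seg])
        denom = np.add.reduceat(w, starts)
        w = w / denom[seg]
        XB = np.zeros((n_strata, p))
        for j in range(p):
            XB[:, j] = np.add.reduceat(w * X[:, j], starts)
        ll = float(eta[used_mask].sum() - (np.log(denom) + m).sum())
        grad = X[used_mask].sum(axis=0) - XB.sum(axis=0)
        H = (X * w[:, None]).T @ X - XB.T @ XB
        return ll, grad, H, XB

    beta = np.zeros(p)
    ll_prev = -np.inf
    for _ in range(max_iter):
        ll, grad, H, _ = _stratum_quantities(beta)
        H_r = H + ridge * np.eye(p)
        grad_r = grad - ridge * beta
        try:
            step = linalg.solve(H_r, grad_r, assume_a="pos")
        except linalg.LinAlgError:
            step = linalg.lstsq(H_r, grad_r)[0]
        beta = beta + step
        if np.abs(beta).max() > coef_cap:
            warnings.warn("coefficient capped: possible separation")
            beta = np.clip(beta, -coef_cap, coef_cap)
        if abs(ll - ll_prev) < tol * (abs(ll) + 1.0):
            break
        ll_prev = ll
    # covariances at the optimum
    ll, grad, H, XB = _stratum_quantities(beta)
    H += ridge * np.eye(p)
    Hinv = linalg.inv(H)
    g_strata = X[used_mask] - XB  # one used row per stratum, stratum order
    clus_of_stratum = cluster[starts]
    meat = np.zeros((p, p))
    for c in np.unique(clus_of_stratum):
        g = g_strata[clus_of_stratum == c].sum(axis=0)
        meat += np.outer(g, g)
    cov_robust = Hinv @ meat @ Hinv
    return beta, Hinv, cov_robust, ll


@dataclass
class ISSAFit:
    names: list[str]
    beta: np.ndarray
    cov_model: np.ndarray
    cov_robust: np.ndarray
    loglik: float
    n_strata: int
    n_individuals: int
    include_log_step: bool = True
    mspline_df: int = 4

    @property
    def coef(self) -> pd.Series:
        return pd.Series(self.beta, index=self.names)

    def se(self, robust: bool = True) -> pd.Series:
        cov = self.cov_robust if robust else self.cov_model
        return pd.Series(np.sqrt(np.clip(np.diag(cov), 0.0, None)), index=self.names)

    def summary(self) -> pd.DataFrame:
        se = self.se(robust=True)
        z = self.coef / se
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se_robust": se,
                "z": z,
                "p": 2 * stats.norm.sf(np.abs(z)),
                "ci_low": self.coef - 1.96 * se,
                "ci_high": self.coef + 1.96 * se,
            }
        )


def _issa_design(strata: pd.DataFrame, include_log_step: bool, mspline_df: int):
    names = []
    cols = []
    hab = strata["habitat"].astype(str)
    for h in HABITAT_NAMES:
        ind = (hab == h).astype(float).to_numpy()
        cols += [ind, ind * strata["z_lag0"].to_numpy(), ind * strata["z_lag1"].to_numpy()]
        names += [h, f"{h}:z_lag0", f"{h}:z_lag1"]
    sl = strata["step_length"].to_numpy(dtype=float)
    cols.append(sl)
    names.append("step_length")
    if include_log_step:
        cols.append(np.log(np.maximum(sl, 1e-6)))
        names.append("log_step_length")
    ta = strata["turn_angle"].to_numpy(dtype=float)
    cos_ta = np.where(np.isnan(ta), 0.0, np.cos(ta))
    cols.append(cos_ta)
    names.append("cos_turn_angle")
    M = mspline_basis(strata["day_of_year"].to_numpy(dtype=float), df=mspline_df)
    for j in range(M.shape[1]):
        cols.append(M[:, j])
        names.append(f"doy_mspline_{j + 1}")
    return np.column_stack(cols), names


def fit_issa(
    strata: pd.DataFrame,
    include_log_step: bool = True,
    mspline_df: int = 4,
    ridge: float = 1e-6,
) -> ISSAFit:
    """Conditional-logistic fit of the selection model on one
    species x season stratum table, with cluster-robust covariance by
    individual."""
    if strata["stratum_id"].nunique() < 2:
        raise ValueError("need at least two strata")
    if strata["habitat"].nunique() < 2:
        raise ValueError("need at least two realized habitat classes")
    # warn on classes realized only among available steps
    used_habs = set(strata.loc[strata["case"] == 1, "habitat"])
    for h in HABITAT_NAMES:
        if h in set(strata["habitat"]) and h not in used_habs:
            warnings.warn(f"habitat {h} never used: coefficient may be capped")
    X, names = _issa_design(strata, include_log_step, mspline_df)
    beta, cov_m, cov_r, ll = fit_conditional_logistic(
        X,
        strata["case"].to_numpy(dtype=int),
        strata["stratum_id"].to_numpy(),
        strata["individual_id"].to_numpy(),
        ridge=ridge,
    )
    return ISSAFit(
        names=names,
        beta=beta,
        cov_model=cov_m,
        cov_robust=cov_r,
        loglik=ll,
        n_strata=int(strata["stratum_id"].nunique()),
        n_individuals=int(strata["individual_id"].nunique()),
        include_log_step=include_log_step,
        mspline_df=mspline_df,
    )


def relative_selection(
    fit: ISSAFit, habitat: str, z_lag0: float = 0.0, z_lag1: float = 0.0,
    level: float = 0.95,
) -> dict:
    """RSS = exp(b_h + b_h:lag0 * z0 + b_h:lag1 * z1) vs the mopane
    reference, with a delta-method CI on the robust covariance."""
    if habitat == REFERENCE_HABITAT:
        return {"habitat": habitat, "rss": 1.0, "ci_low": 1.0, "ci_high": 1.0,
                "z_lag0": z_lag0, "z_lag1": z_lag1}
    if habitat not in HABITAT_NAMES:
        raise ValueError(f"unknown habitat {habitat!r}")
    v = np.zeros(len(fit.names))
    v[fit.names.index(habitat)] = 1.0
    v[fit.names.index(f"{habitat}:z_lag0")] = z_lag0
    v[fit.names.index(f"{habitat}:z_lag1")] = z_lag1
    log_rss = float(v @ fit.beta)
    sd = float(np.sqrt(max(v @ fit.cov_robust @ v, 0.0)))
    zq = stats.norm.ppf(0.5 + level / 2)
    return {
        "habitat": habitat,
        "z_lag0": z_lag0,
        "z_lag1": z_lag1,
        "rss": float(np.exp(log_rss)),
        "ci_low": float(np.exp(log_rss - zq * sd)),
        "ci_high": float(np.exp(log_rss + zq * sd)),
    }
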