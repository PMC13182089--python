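"""Penalized-spline generalized additive mixed models.

The three response models in the pipeline — daily encounter
probability, proportion of fixes inside a competitor's range, and
hourly activity — share one structure: a binomial additive model with
penalized-spline smooths of standardized daily-maximum temperature at
lag 0 and lag 1, a day-of-year smooth, a random intercept per dyad (or
individual), and an AR(1) working correlation within group.

Estimation is penalized IRLS (P-splines with difference penalties;
Eilers & Marx style) with smoothing parameters chosen by minimizing a
GCV score on the deviance scale with an inflation factor gamma = 1.4,
the random intercept handled as an extra ridge-penalized coefficient
block, and the AR(1) parameter estimated from lag-1 autocorrelation of
standardized working residuals and applied by whitening the working
model within groups.  Per-smooth significance uses a Wald statistic on
the smooth's coefficient block against the Bayesian posterior
covariance with rank set by the rounded effective degrees of freedom;
this is an acknowledged approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.interpolate import BSpline
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import chi2, norm

GCV_GAMMA = 1.4


class NoContrastError(ValueError):
    """The response takes a single value; no model can be fitted."""


# ---------------------------------------------------------------------------
# bases
# ---------------------------------------------------------------------------

def _bspline_matrix(x: np.ndarray, lo: float, hi: float, k: int, degree: int = 3):
    """Evaluate k uniform B-spline basis functions on [lo, hi]."""
    if k < degree + 1:
        raise ValueError(f"basis dimension must be >= {degree + 1}")
    n_interior = k - degree - 1
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    t = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    xc = np.clip(x, lo, hi)
    return BSpline.design_matrix(xc, t, degree).toarray(), t


def _cyclic_matrix(x: np.ndarray, period: float, k: int, degree: int = 3):
    """k wrapped B-spline basis functions with period ``period``."""
    h = period / k
    t = np.arange(-degree, k + degree + 1) * h
    xm = np.mod(x, period)
    B = BSpline.design_matrix(xm, t, degree).toarray()
    out = np.zeros((len(x), k))
    for j in range(B.shape[1]):
        out[:, j % k] += B[:, j]
    return out


def _difference_penalty(k: int, order: int = 2) -> np.ndarray:
    D = np.diff(np.eye(k), n=order, axis=0)
    return D.T @ D


def _greville_penalty(t: np.ndarray, degree: int, k: int) -> np.ndarray:
    """Second-divided-difference penalty on the Greville abscissae.

    Its null space is exactly the linear functions of the covariate
    (clamped B-splines are linear iff their coefficients are linear in
    the Greville points), so an infinite penalty collapses a smooth to
    a straight line rather than a boundary-bent curve.
    """
    g = np.array([t[i + 1 : i + 1 + degree].mean() for i in range(k)])
    D1 = np.diff(np.eye(k), axis=0) / np.diff(g)[:, None]
    D2 = np.diff(D1, axis=0) / (0.5 * (g[2:] - g[:-2]))[:, None]
    # scale to keep lambda magnitudes comparable to the classic penalty
    h = np.mean(np.diff(g))
    D2 = D2 * h**2
    return D2.T @ D2


def _cyclic_penalty(k: int, order: int = 2) -> np.ndarray:
    D = np.zeros((k, k))
    for i in range(k):
        if order == 2:
            D[i, i] = 1.0
            D[i, (i + 1) % k] = -2.0
            D[i, (i + 2) % k] = 1.0
        else:
            D[i, i] = 1.0
            D[i, (i + 1) % k] = -1.0
    return D.T @ D


def _center_constraint(B: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the sum-to-zero null space of column means."""
    c = B.mean(axis=0, keepdims=True)
    return linalg.null_space(c)


# ---------------------------------------------------------------------------
# model terms
# ---------------------------------------------------------------------------

class Smooth1D:
    """Centred penalized spline of one covariate."""

    def __init__(self, var: str, k: int = 10, cyclic: bool = False,
                 period: float = 2 * np.pi, name: str | None = None):
        self.var = var
        self.k = k
        self.cyclic = cyclic
        self.period = period
        self.name = name or f"s({var})"
        self.is_smooth = True

    def setup(self, data: pd.DataFrame) -> None:
        x = data[self.var].to_numpy(dtype=float)
        if self.cyclic:
            self.lo, self.hi = 0.0, self.period
            B = _cyclic_matrix(x, self.period, self.k)
            S = _cyclic_penalty(self.k)
        else:
            self.lo, self.hi = float(x.min()), float(x.max())
            if self.hi <= self.lo:
                raise ValueError(f"covariate {self.var} is constant")
            B, t = _bspline_matrix(x, self.lo, self.hi, self.k)
            S = _greville_penalty(t, 3, self.k)
        self.Z = _center_constraint(B)
        self.S = [self.Z.T @ S @ self.Z]
        self.ncol = self.Z.shape[1]

    def build(self, data: pd.DataFrame) -> np.ndarray:
        x = data[self.var].to_numpy(dtype=float)
        if self.cyclic:
            B = _cyclic_matrix(x, self.period, self.k)
        else:
            B, _ = _bspline_matrix(x, self.lo, self.hi, self.k)
        return B @ self.Z


class TensorInteraction:
    """Double-centred interaction of two marginal spline bases.

    Equivalent to an mgcv ``ti()`` term: the marginal main effects are
    removed by applying both sum-to-zero constraints, so the term only
    carries how one covariate *modulates* the other's shape.  Two
    penalties, one per margin.
    """

    def __init__(self, var1: str, var2: str, k1: int = 8, k2: int = 5,
                 cyclic1: bool = False, period1: float = 2 * np.pi,
                 name: str | None = None):
        self.var1, self.var2 = var1, var2
        self.k1, self.k2 = k1, k2
        self.cyclic1 = cyclic1
        self.period1 = period1
        self.name = name or f"ti({var1},{var2})"
        self.is_smooth = True

    def _marginal(self, x, which):
        if which == 1:
            if self.cyclic1:
                return _cyclic_matrix(x, self.period1, self.k1)
            return _bspline_matrix(x, self.lo1, self.hi1, self.k1)[0]
        return _bspline_matrix(x, self.lo2, self.hi2, self.k2)[0]

    def setup(self, data: pd.DataFrame) -> None:
        x1 = data[self.var1].to_numpy(dtype=float)
        x2 = data[self.var2].to_numpy(dtype=float)
        if self.cyclic1:
            self.lo1, self.hi1 = 0.0, self.period1
            S1 = _cyclic_penalty(self.k1)
        else:
            self.lo1, self.hi1 = float(x1.min()), float(x1.max())
            _, t1 = _bspline_matrix(x1, self.lo1, self.hi1, self.k1)
            S1 = _greville_penalty(t1, 3, self.k1)
        self.lo2, self.hi2 = float(x2.min()), float(x2.max())
        _, t2 = _bspline_matrix(x2, self.lo2, self.hi2, self.k2)
        S2 = _greville_penalty(t2, 3, self.k2)
        B1 = self._marginal(x1, 1)
        B2 = self._marginal(x2, 2)
        self.Z1 = _center_constraint(B1)
        self.Z2 = _center_constraint(B2)
        S1c = self.Z1.T @ S1 @ self.Z1
        S2c = self.Z2.T @ S2 @ self.Z2
        p1, p2 = self.Z1.shape[1], self.Z2.shape[1]
        self.S = [np.kron(S1c, np.eye(p2)), np.kron(np.eye(p1), S2c)]
        self.ncol = p1 * p2

    def build(self, data: pd.DataFrame) -> np.ndarray:
        B1 = self._marginal(data[self.var1].to_numpy(dtype=float), 1) @ self.Z1
        B2 = self._marginal(data[self.var2].to_numpy(dtype=float), 2) @ self.Z2
        n = B1.shape[0]
        return (B1[:, :, None] * B2[:, None, :]).reshape(n, -1)


class RandomIntercept:
    """Ridge-penalized indicator block, one column per group level."""

    def __init__(self, var: str, name: str | None = None):
        self.var = var
        self.name = name or f"re({var})"
        self.is_smooth = False

    def setup(self, data: pd.DataFrame) -> None:
        self.levels = sorted(map(str, data[self.var].unique()))
        self.index = {lv: i for i, lv in enumerate(self.levels)}
        self.ncol = len(self.levels)
        self.S = [np.eye(self.ncol)]

    def build(self, data: pd.DataFrame, population: bool = False) -> np.ndarray:
        n = len(data)
        out = np.zeros((n, self.ncol))
        if population:
            return out
        for r, lv in enumerate(data[self.var].astype(str)):
            j = self.index.get(lv)
            if j is not None:
                out[r, j] = 1.0
        return out


# ---------------------------------------------------------------------------
# fit container
# ---------------------------------------------------------------------------

@dataclass
class TermSummary:
    name: str
    cols: tuple[int, int]
    edf: float
    lam: list[float]
    chi_sq: float | None = None
    p_value: float | None = None


@dataclass
class AdditiveModelFit:
    terms: list
    beta: np.ndarray
    cov: np.ndarray              # Bayesian posterior covariance
    term_summaries: list[TermSummary]
    rho: float
    re_variance: float
    deviance: float
    null_deviance: float
    n: int
    family: str
    response: str
    trials_col: str | None
    train_data: pd.DataFrame = field(repr=False, default=None)
    scaling: dict = field(default_factory=dict)

    def model_matrix(self, data: pd.DataFrame, population: bool = False) -> np.ndarray:
        cols = [np.ones((len(data), 1))]
        for term in self.terms:
            if isinstance(term, RandomIntercept):
                cols.append(term.build(data, population=population))
            else:
                cols.append(term.build(data))
        return np.hstack(cols)

    def predict(self, data: pd.DataFrame, population: bool = True,
                link: bool = False) -> np.ndarray:
        X = self.model_matrix(data, population=population)
        eta = X @ self.beta
        return eta if link else expit(eta)

    def smooth_p_values(self) -> dict[str, float]:
        return {
            ts.name: ts.p_value
            for ts in self.term_summaries
            if ts.p_value is not None
        }

    def summary(self) -> dict:
        return {
            "n": self.n,
            "family": self.family,
            "deviance": self.deviance,
            "null_deviance": self.null_deviance,
            "pseudo_r2": 1.0 - self.deviance / max(self.null_deviance, 1e-12),
            "rho": self.rho,
            "random_intercept_variance": self.re_variance,
            "terms": [
                {
                    "name": ts.name,
                    "edf": round(ts.edf, 3),
                    "lambda": [float(l) for l in ts.lam],
                    "chi_sq": None if ts.chi_sq is None else round(ts.chi_sq, 3),
                    "p_value": ts.p_value,
                }
                for ts in self.term_summaries
            ],
        }


# ---------------------------------------------------------------------------
# core fitting
# ---------------------------------------------------------------------------

def _deviance(y, trials, mu):
    mu = np.clip(mu, 1e-10, 1 - 1e-10)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / (trials * mu)), 0.0)
        t2 = np.where(
            trials - y > 0,
            (trials - y) * np.log((trials - y) / (trials * (1 - mu))),
            0.0,
        )
    return 2.0 * float(np.sum(t1 + t2))


def _whiten(M: np.ndarray, rho: float, group_starts: np.ndarray) -> np.ndarray:
    """AR(1) innovations transform applied within contiguous group blocks."""
    out = M.copy()
    c = 1.0 / np.sqrt(1.0 - rho**2)
    out[1:] = (M[1:] - rho * M[:-1]) * c
    out[group_starts] = M[group_starts]
    return out


def _pirls(X, y, trials, S_total, rho, group_starts, beta0=None, max_iter=60, tol=1e-9):
    n, p = X.shape
    if beta0 is None:
        mu0 = (y + 0.5) / (trials + 1.0)
        eta = np.log(mu0 / (1 - mu0))
        beta = np.zeros(p)
        beta[0] = eta.mean()
    else:
        beta = beta0.copy()
    dev_prev = np.inf
    H = None
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = np.maximum(trials * mu * (1 - mu), 1e-10)
        z = eta + (y - trials * mu) / w
        sw = np.sqrt(w)
        Xw = X * sw[:, None]
        zw = z * sw
        if rho != 0.0:
            Xw = _whiten(Xw, rho, group_starts)
            zw = _whiten(zw[:, None], rho, group_starts)[:, 0]
        H = Xw.T @ Xw
        rhs = Xw.T @ zw
        try:
            beta_new = linalg.solve(H + S_total, rhs, assume_a="pos")
        except linalg.LinAlgError:
            beta_new = linalg.lstsq(H + S_total, rhs)[0]

        def pdev(b):
            return _deviance(y, trials, expit(X @ b)) + float(b @ S_total @ b)

        # trust region: never let one update explode the linear predictor
        delta = beta_new - beta
        dnorm = float(np.abs(delta).max())
        cap = 10.0 * (1.0 + float(np.abs(beta).max()))
        if dnorm > cap:
            delta *= cap / dnorm
            beta_new = beta + delta
        dev = pdev(beta_new)
        if rho == 0.0:
            # with independent working model the penalized deviance is a
            # true objective: enforce monotone descent by step halving
            step = 1.0
            while (not np.isfinite(dev) or dev > dev_prev + 1e-8) and step > 1e-6:
                step /= 2
                beta_new = beta + step * delta
                dev = pdev(beta_new)
        else:
            step = 1.0
            while not np.isfinite(dev) and step > 1e-6:
                step /= 2
                beta_new = beta + step * delta
                dev = pdev(beta_new)
        moved = float(np.abs(beta_new - beta).max())
        beta = beta_new
        if moved < 1e-7 * (1.0 + float(np.abs(beta).max())):
            break
        if abs(dev - dev_prev) < tol * (abs(dev) + 0.1):
            break
        dev_prev = dev
    # recompute H at the final beta for downstream covariances
    eta = X @ beta
    mu = expit(eta)
    w = np.maximum(trials * mu * (1 - mu), 1e-10)
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    if rho != 0.0:
        Xw = _whiten(Xw, rho, group_starts)
    H = Xw.T @ Xw
    return beta, H, _deviance(y, trials, mu)


def fit_gamm(
    data: pd.DataFrame,
    response: str,
    terms: list,
    trials: str | None = None,
    random: str | None = None,
    ar1_group: str | None = None,
    time_col: str | None = None,
    estimate_ar1: bool = True,
    gcv_gamma: float = GCV_GAMMA,
    maxfev: int = 80,
    scaling: dict | None = None,
) -> AdditiveModelFit:
    """Fit a binomial additive model with optional random intercept and AR(1).

    ``trials`` names a column of binomial denominators (None = Bernoulli).
    ``random`` adds a ridge-penalized intercept per level of that column.
    ``ar1_group`` + ``time_col`` activate the AR(1) working correlation
    within each group, applied in time order.
    """
    data = data.copy()
    sort_cols = [c for c in (ar1_group, time_col) if c]
    if sort_cols:
        data = data.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
    y = data[response].to_numpy(dtype=float)
    tr = data[trials].to_numpy(dtype=float) if trials else np.ones(len(y))
    if np.any(y < 0) or np.any(y > tr):
        raise ValueError("response outside [0, trials]")
    if np.all(y == 0) or np.all(y == tr):
        raise NoContrastError("response shows a single outcome")

    all_terms = list(terms)
    if random is not None:
        n_levels = data[random].nunique()
        if n_levels < 2:
            warnings.warn("single grouping level: random intercept dropped")
        else:
            all_terms = all_terms + [RandomIntercept(random)]
    for term in all_terms:
        term.setup(data)

    # assemble design and penalty bookkeeping
    blocks = [np.ones((len(data), 1))]
    col_ranges = []
    pen_list = []  # (term_index_in_all_terms, full-size S)
    start = 1
    for ti_, term in enumerate(all_terms):
        B = term.build(data)
        blocks.append(B)
        col_ranges.append((start, start + term.ncol))
        start += term.ncol
    X = np.hstack(blocks)
    p = X.shape[1]
    for ti_, term in enumerate(all_terms):
        s0, s1 = col_ranges[ti_]
        for S in term.S:
            Sf = np.zeros((p, p))
            Sf[s0:s1, s0:s1] = S
            pen_list.append((ti_, Sf))

    if ar1_group is not None:
        grp = data[ar1_group].astype(str).to_numpy()
        group_starts = np.r_[0, np.nonzero(grp[1:] != grp[:-1])[0] + 1]
    else:
        group_starts = np.array([0])

    n = len(data)
    state = {"beta": None}

    def total_penalty(theta):
        lams = np.exp(np.clip(theta, -12.0, 16.0))
        S_total = np.zeros((p, p))
        for lam, (_, Sf) in zip(lams, pen_list):
            S_total += lam * Sf
        return lams, S_total

    def gcv(theta, rho):
        _, S_total = total_penalty(theta)
        beta, H, dev = _pirls(
            X, y, tr, S_total, rho, group_starts, beta0=state["beta"]
        )
        state["beta"] = beta
        A = linalg.inv(H + S_total + 1e-10 * np.eye(p))
        edf = float(np.trace(A @ H))
        denom = max(n - gcv_gamma * edf, 1.0)
        return n * dev / denom**2

    theta0 = np.zeros(len(pen_list))
    rho = 0.0
    for ar_round in range(2 if (ar1_group and estimate_ar1) else 1):
        res = minimize(
            gcv, theta0, args=(rho,), method="Nelder-Mead",
            options={"maxfev": maxfev, "xatol": 0.15, "fatol": 1e-8},
        )
        theta0 = res.x
        if not (ar1_group and estimate_ar1) or ar_round == 1:
            break
        # estimate rho from standardized working residuals
        lams, S_total = total_penalty(theta0)
        beta, H, dev = _pirls(X, y, tr, S_total, 0.0, group_starts, state["beta"])
        eta = X @ beta
        mu = expit(eta)
        w = np.maximum(tr * mu * (1 - mu), 1e-10)
        r = (y - tr * mu) / np.sqrt(w)
        valid = np.ones(n - 1, dtype=bool)
        valid[group_starts[1:] - 1] = False
        num = float(np.sum(r[1:][valid] * r[:-1][valid]))
        den = float(np.sum(r[:-1][valid] ** 2))
        rho = float(np.clip(num / den if den > 0 else 0.0, -0.9, 0.9))

    lams, S_total = total_penalty(theta0)
    beta, H, dev = _pirls(X, y, tr, S_total, rho, group_starts, state["beta"])
    A = linalg.inv(H + S_total + 1e-10 * np.eye(p))
    Fmat = A @ H
    edf_diag = np.diag(Fmat)
    # quasi-binomial scale for counts responses (proportions of hourly
    # fixes are strongly overdispersed relative to binomial sampling)
    phi = 1.0
    if trials is not None:
        mu_hat = expit(X @ beta)
        vfun = np.maximum(tr * mu_hat * (1 - mu_hat), 1e-10)
        pearson = float(np.sum((y - tr * mu_hat) ** 2 / vfun))
        phi = max(pearson / max(n - float(edf_diag.sum()), 1.0), 1.0)
    A = A * phi

    # per-term summaries with Wald tests on smooth blocks
    lam_of_term: dict[int, list[float]] = {}
    for lam, (ti_, _) in zip(lams, pen_list):
        lam_of_term.setdefault(ti_, []).append(float(lam))
    summaries = []
    re_variance = 0.0
    for ti_, term in enumerate(all_terms):
        s0, s1 = col_ranges[ti_]
        edf_t = float(edf_diag[s0:s1].sum())
        chi = pv = None
        if term.is_smooth:
            bj = beta[s0:s1]
            Vj = A[s0:s1, s0:s1]
            evals, evecs = linalg.eigh(Vj)
            r_rank = int(min(max(1, round(edf_t)), len(bj)))
            idx = np.argsort(evals)[::-1][:r_rank]
            inv_vals = 1.0 / np.maximum(evals[idx], 1e-12)
            proj = evecs[:, idx].T @ bj
            chi = float(np.sum(inv_vals * proj**2))
            pv = float(chi2.sf(chi, r_rank))
        elif isinstance(term, RandomIntercept):
            lam_re = lam_of_term[ti_][0]
            re_variance = 1.0 / lam_re
        summaries.append(
            TermSummary(
                name=term.name,
                cols=(s0, s1),
                edf=edf_t,
                lam=lam_of_term[ti_],
                chi_sq=chi,
                p_value=pv,
            )
        )

    mu_null = np.full(n, y.sum() / tr.sum())
    fit = AdditiveModelFit(
        terms=all_terms,
        beta=beta,
        cov=A,
        term_summaries=summaries,
        rho=rho,
        re_variance=re_variance,
        deviance=dev,
        null_deviance=_deviance(y, tr, mu_null),
        n=n,
        family="binomial" if trials is None else "binomial-counts",
        response=response,
        trials_col=trials,
        train_data=data,
        scaling=scaling or {},
    )
    return fit


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def diagnostics(fit: AdditiveModelFit, concurvity_flag: float = 0.8,
                vif_flag: float = 10.0) -> dict:
    """Pairwise concurvity between smooths and VIF of the lag covariates.

    Concurvity(i -> j) is the R^2 of projecting smooth i's fitted
    contribution onto the column span of smooth j's basis.
    """
    data = fit.train_data
    smooths = [
        (ts, term)
        for ts, term in zip(fit.term_summaries, fit.terms)
        if term.is_smooth
    ]
    rows = []
    for ts_i, term_i in smooths:
        s0, s1 = ts_i.cols
        f_i = term_i.build(data) @ fit.beta[s0:s1]
        f_i = f_i - f_i.mean()
        denom = float(f_i @ f_i)
        for ts_j, term_j in smooths:
            if ts_j.name == ts_i.name:
                continue
            Bj = term_j.build(data)
            Bj = np.hstack([np.ones((len(data), 1)), Bj])
            if denom <= 1e-12:
                c = 0.0
            else:
                coef, *_ = linalg.lstsq(Bj, f_i)
                resid = f_i - Bj @ coef
                c = float(max(0.0, 1.0 - (resid @ resid) / denom))
            rows.append(
                {
                    "smooth": ts_i.name,
                    "against": ts_j.name,
                    "concurvity": c,
                    "flag": bool(c >= concurvity_flag),
                }
            )
    vifs = {}
    lag_cols = [c for c in ("z_lag0", "z_lag1") if c in data.columns]
    if len(lag_cols) >= 2:
        Z = data[lag_cols].to_numpy(dtype=float)
        for j, name in enumerate(lag_cols):
            others = np.hstack(
                [np.ones((len(Z), 1)), np.delete(Z, j, axis=1)]
            )
            coef, *_ = linalg.lstsq(others, Z[:, j])
            resid = Z[:, j] - others @ coef
            tss = float(((Z[:, j] - Z[:, j].mean()) ** 2).sum())
            r2 = max(0.0, 1.0 - float(resid @ resid) / max(tss, 1e-12))
            v = 1.0 / max(1.0 - r2, 1e-12)
            vifs[name] = {"vif": v, "flag": bool(v >= vif_flag)}
    return {"concurvity": rows, "vif": vifs}


# ---------------------------------------------------------------------------
# fold changes
# ---------------------------------------------------------------------------

@dataclass
class FoldChangeEstimate:
    lag: str
    quantile_ref: float
    quantile_cmp: float
    t_ref: float
    t_cmp: float
    p_ref: float
    p_cmp: float
    ratio: float
    ci_low: float
    ci_high: float


def predict_fold_change(
    fit: AdditiveModelFit,
    lag: str = "z_lag1",
    quantile_ref: float = 0.5,
    quantile_cmp: float = 0.8,
    level: float = 0.95,
) -> FoldChangeEstimate:
    """Response ratio between two temperature quantiles of the training data.

    Predictions are population-level (random effects at zero) with
    day-of-year and the other temperature lag at their training
    medians; the CI comes from the delta method on the log ratio.
    """
    data = fit.train_data
    other = {"z_lag0": "z_lag1", "z_lag1": "z_lag0"}.get(lag)
    if "t_max" in fit.scaling:
        t = np.asarray(fit.scaling["t_max"], dtype=float)
        mean, sd = fit.scaling["mean"], fit.scaling["sd"]
        t_ref, t_cmp = np.quantile(t, [quantile_ref, quantile_cmp])
        z_ref, z_cmp = (t_ref - mean) / sd, (t_cmp - mean) / sd
    else:
        z = data[lag].to_numpy(dtype=float)
        z_ref, z_cmp = np.quantile(z, [quantile_ref, quantile_cmp])
        t_ref, t_cmp = z_ref, z_cmp
    if not (data[lag].min() - 1e-9 <= z_cmp <= data[lag].max() + 1e-9):
        warnings.warn("fold-change quantile extrapolates beyond training range")
    row = {}
    for col in data.columns:
        if np.issubdtype(np.asarray(data[col]).dtype, np.number):
            row[col] = float(np.median(data[col]))
        else:
            row[col] = data[col].iloc[0]
    rows = pd.DataFrame([dict(row, **{lag: z_ref}), dict(row, **{lag: z_cmp})])
    if other and other in rows:
        med = float(np.median(data[other]))
        rows[other] = med
    X = fit.model_matrix(rows, population=True)
    eta = np.clip(X @ fit.beta, -30.0, 30.0)  # guard against underflow to 0
    p_ref, p_cmp = expit(eta)
    ratio = p_cmp / p_ref
    # delta method on log ratio: d log p / d eta = 1 - p
    g = (1 - p_cmp) * X[1] - (1 - p_ref) * X[0]
    var = float(g @ fit.cov @ g)
    zq = norm.ppf(0.5 + level / 2)
    half = min(zq * np.sqrt(max(var, 0.0)), 700.0)
    return FoldChangeEstimate(
        lag=lag,
        quantile_ref=quantile_ref,
        quantile_cmp=quantile_cmp,
        t_ref=float(t_ref),
        t_cmp=float(t_cmp),
        p_ref=float(p_ref),
        p_cmp=float(p_cmp),
        ratio=float(ratio),
        ci_low=float(ratio * np.exp(-half)),
        ci_high=float(ratio * np.exp(half)),
    )


# ---------------------------------------------------------------------------
# model wrappers
# ---------------------------------------------------------------------------

def fit_encounter_model(
    dyad_days: pd.DataFrame,
    k_temp: int = 10,
    k_doy: int = 8,
    doy_cyclic: bool = False,
    estimate_ar1: bool = True,
    maxfev: int = 80,
    scaling: dict | None = None,
) -> AdditiveModelFit:
    """Binomial GAMM of daily encounter occurrence for one species pair
    and season: s(z_lag0) + s(z_lag1) + s(day_of_year) + dyad random
    intercept + AR(1) within dyad by date."""
    d = dyad_days.dropna(subset=["z_lag0", "z_lag1"]).copy()
    if d["encounter"].nunique() < 2:
        raise NoContrastError("encounter response has no contrast")
    if d["dyad_id"].nunique() < 2:
        random = None
        warnings.warn("single dyad: random effect dropped")
    else:
        random = "dyad_id"
    terms = [
        Smooth1D("z_lag0", k=k_temp),
        Smooth1D("z_lag1", k=k_temp),
        Smooth1D("day_of_year", k=k_doy, cyclic=doy_cyclic, period=366.0),
    ]
    return fit_gamm(
        d, "encounter", terms, random=random,
        ar1_group="dyad_id", time_col="date",
        estimate_ar1=estimate_ar1, maxfev=maxfev, scaling=scaling,
    )


def fit_overlap_model(
    proportions: pd.DataFrame,
    k_temp: int = 10,
    k_doy: int = 8,
    doy_cyclic: bool = False,
    estimate_ar1: bool = True,
    maxfev: int = 80,
    scaling: dict | None = None,
) -> AdditiveModelFit:
    """Binomial-counts GAMM of n_inside / n_fixes with the encounter
    model structure (individual as the grouping factor)."""
    d = proportions.dropna(subset=["z_lag0", "z_lag1"]).copy()
    if (d["n_inside"] > d["n_fixes"]).any():
        raise ValueError("n_inside exceeds n_fixes")
    if d["n_inside"].sum() == 0 or (d["n_inside"] == d["n_fixes"]).all():
        raise NoContrastError("proportion response has no contrast")
    group = "individual_id" if d["individual_id"].nunique() >= 2 else None
    if group is None:
        warnings.warn("single individual: random effect dropped")
    terms = [
        Smooth1D("z_lag0", k=k_temp),
        Smooth1D("z_lag1", k=k_temp),
        Smooth1D("day_of_year", k=k_doy, cyclic=doy_cyclic, period=366.0),
    ]
    return fit_gamm(
        d, "n_inside", terms, trials="n_fixes", random=group,
        ar1_group="individual_id", time_col="date",
        estimate_ar1=estimate_ar1, maxfev=maxfev, scaling=scaling,
    )


def fit_activity_model(
    activity: pd.DataFrame,
    k_sun: int = 8,
    k_temp: int = 9,
    k_tensor: tuple[int, int] = (8, 5),
    k_doy: int = 8,
    doy_cyclic: bool = False,
    estimate_ar1: bool = True,
    maxfev: int = 60,
    scaling: dict | None = None,
) -> AdditiveModelFit:
    """Binomial GAMM of hourly activity with a cyclic sun-time smooth,
    tensor interactions of sun time with each temperature lag, a
    day-of-year smooth, individual random intercept and AR(1) by hour."""
    d = activity.dropna(subset=["z_lag0", "z_lag1", "suntime"]).copy()
    st = d["suntime"].to_numpy(dtype=float)
    if (st < 0).any() or (st >= 2 * np.pi).any():
        raise ValueError("sun time must lie in [0, 2*pi)")
    if d["active"].nunique() < 2:
        raise NoContrastError("activity response has no contrast")
    group = "individual_id" if d["individual_id"].nunique() >= 2 else None
    terms = [
        Smooth1D("suntime", k=k_sun, cyclic=True),
        Smooth1D("z_lag0", k=k_temp),
        Smooth1D("z_lag1", k=k_temp),
        TensorInteraction("suntime", "z_lag0", k1=k_tensor[0], k2=k_tensor[1],
                          cyclic1=True),
        TensorInteraction("suntime", "z_lag1", k1=k_tensor[0], k2=k_tensor[1],
                          cyclic1=True),
        Smooth1D("day_of_year", k=k_doy, cyclic=doy_cyclic, period=366.0),
    ]
    return fit_gamm(
        d, "active", terms, random=group,
        ar1_group="individual_id", time_col="hour",
        estimate_ar1=estimate_ar1, maxfev=maxfev, scaling=scaling,
    )
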