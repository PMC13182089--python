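"""Step construction, distribution fits, and conditional-logistic core."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import minimize

from conftest import make_track
from thermoguild.issa import (
    StepDistributions,
    build_steps,
    fit_conditional_logistic,
    fit_issa,
    fit_step_distributions,
    relative_selection,
    sample_available_steps,
)
from thermoguild.tracking import regularize_hourly

T0 = pd.Timestamp("2015-05-01", tz="UTC")


def _hourly(xy, iid="a"):
    xy = np.asarray(xy, dtype=float)
    t = make_track(T0 + pd.to_timedelta(np.arange(len(xy)), unit="h"), xy, iid)
    return regularize_hourly(t)


class TestBuildSteps:
    def test_sub_threshold_interval_breaks_turn_chain(self):
        # displacements 25, 5, 30 -> two used steps, second without a turn
        xy = [(0, 0), (25, 0), (25, 5), (25, 35)]
        steps = build_steps(_hourly(xy))
        assert len(steps) == 2
        assert np.isnan(steps["turn_angle"].iloc[1])
        assert not np.isnan(steps["turn_angle"].iloc[0]) or len(steps) == 2

    def test_straight_track_zero_turns(self):
        xy = [(i * 100.0, 0.0) for i in range(10)]
        steps = build_steps(_hourly(xy))
        turns = steps["turn_angle"].dropna()
        assert len(turns) == 8
        assert np.allclose(turns, 0.0)

    def test_matches_bruteforce_scan(self, rng):
        xy = np.cumsum(rng.normal(0, 30, (500, 2)), axis=0)
        steps = build_steps(_hourly(xy))
        expected = [
            i for i in range(499) if np.hypot(*(xy[i + 1] - xy[i])) >= 20.0
        ]
        assert len(steps) == len(expected)
        assert np.allclose(
            steps["step_length"],
            [np.hypot(*(xy[i + 1] - xy[i])) for i in expected],
        )


class TestStepDistributions:
    def _steps_frame(self, lengths, angles):
        return pd.DataFrame({"step_length": lengths, "turn_angle": angles})

    def test_mle_recovery(self, rng):
        n = 5000
        lengths = rng.gamma(2.0, 100.0, n)
        angles = rng.vonmises(0.0, 1.0, n)
        d = fit_step_distributions(self._steps_frame(lengths, angles))
        assert abs(d.shape - 2.0) / 2.0 < 0.05
        assert abs(d.scale - 100.0) / 100.0 < 0.05
        assert abs(d.kappa - 1.0) < 0.1
        # independent numerical MLE for the gamma part
        def nll(p):
            return -stats.gamma.logpdf(lengths, a=p[0], scale=p[1]).sum()
        ref = minimize(nll, [1.5, 80.0], method="Nelder-Mead").x
        assert abs(d.shape - ref[0]) < 1e-3 * ref[0] + 1e-3
        assert abs(d.scale - ref[1]) < 1e-3 * ref[1] + 1e-2

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            fit_step_distributions(self._steps_frame([-1.0] * 40, [0.0] * 40))

    def test_too_few_steps(self):
        with pytest.raises(ValueError, match="too few"):
            fit_step_distributions(self._steps_frame([10.0] * 5, [0.0] * 5))

    def test_degenerate_angles_cap_kappa(self):
        with pytest.warns(UserWarning, match="kappa"):
            d = fit_step_distributions(
                self._steps_frame(np.random.default_rng(0).gamma(2, 100, 100),
                                  [0.0] * 100)
            )
        assert d.kappa == 500.0 and d.mu == 0.0


class TestAvailableSteps:
    def test_stratum_size(self, rng):
        used = pd.Series(
            {"x_start": 0.0, "y_start": 0.0, "prev_bearing": 0.0}
        )
        d = StepDistributions(shape=2.0, scale=100.0, mu=0.0, kappa=1.0)
        avail = sample_available_steps(used, d, n=150, rng=rng)
        assert len(avail) == 150

    def test_sampled_lengths_pass_ks(self, rng):
        used = pd.Series({"x_start": 0.0, "y_start": 0.0, "prev_bearing": 0.5})
        d = StepDistributions(shape=2.0, scale=100.0, mu=0.0, kappa=1.0)
        lengths = np.concatenate(
            [
                sample_available_steps(used, d, n=150, rng=rng)["step_length"]
                for _ in range(200)
            ]
        )
        ks = stats.kstest(lengths, stats.gamma(a=2.0, scale=100.0).cdf)
        assert ks.pvalue > 0.01


def _toy_strata(rng, n_strata=20, n_avail=5, beta=(0.8, -0.5)):
    beta = np.asarray(beta)
    X, case, strat, clus = [], [], [], []
    for s in range(n_strata):
        Xs = rng.normal(0, 1, (n_avail + 1, len(beta)))
        w = np.exp(Xs @ beta)
        used = rng.choice(n_avail + 1, p=w / w.sum())
        for j in range(n_avail + 1):
            X.append(Xs[j])
            case.append(int(j == used))
            strat.append(f"s{s}")
            clus.append(f"i{s % 4}")
    return (np.array(X), np.array(case), np.array(strat), np.array(clus))


class TestConditionalLogistic:
    def test_uniform_probability_at_null(self, rng):
        X, case, strat, clus = _toy_strata(rng)
        # at beta = 0 every stratum's used-step probability is 1/(n+1)
        _, _, _, ll0 = fit_conditional_logistic(
            X * 0.0, case, strat, clus, max_iter=1
        )
        assert ll0 == pytest.approx(20 * np.log(1 / 6), rel=1e-10)

    def test_matches_bruteforce_optimum(self, rng):
        X, case, strat, clus = _toy_strata(rng)
        beta, _, _, _ = fit_conditional_logistic(X, case, strat, clus, ridge=0.0)

        def nll(b):
            tot = 0.0
            for s in range(20):
                sl = slice(6 * s, 6 * s + 6)
                e = X[sl] @ b
                tot -= e[case[sl] == 1][0] - np.log(np.exp(e).sum())
            return tot

        ref = minimize(
            nll, np.zeros(2), method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxfev": 5000},
        ).x
        assert np.abs(beta - ref).max() < 1e-3

    def test_within_stratum_constant_covariate_is_inert(self, rng):
        X, case, strat, clus = _toy_strata(rng, n_strata=30)
        beta0, *_ = fit_conditional_logistic(X, case, strat, clus)
        # append a covariate constant within each stratum
        const = np.array([float(s[1:]) for s in strat])[:, None]
        Xc = np.hstack([X, const / const.max()])
        beta1, *_ = fit_conditional_logistic(Xc, case, strat, clus)
        assert np.abs(beta1[:2] - beta0).max() < 1e-4
        assert abs(beta1[2]) < 1e-3


def _issa_strata(seed, n_ind=8, n_strata=30, n_avail=30,
                 b_grass=0.7, b_gl1=0.4):
    rng = np.random.default_rng(seed)
    habs = np.array(["grassland", "floodplain", "mixed_woodland", "mopane"])
    rows = []
    for i in range(n_ind):
        for s in range(n_strata):
            z1, z0 = rng.normal(), rng.normal()
            h = rng.integers(0, 4, n_avail + 1)
            lin = b_grass * (h == 0) + b_gl1 * (h == 0) * z1
            w = np.exp(lin)
            used = rng.choice(n_avail + 1, p=w / w.sum())
            frame = pd.DataFrame(
                {
                    "stratum_id": f"i{i}s{s}",
                    "individual_id": f"i{i}",
                    "case": (np.arange(n_avail + 1) == used).astype(int),
                    "habitat": habs[h],
                    "step_length": rng.gamma(2, 100, n_avail + 1),
                    "turn_angle": rng.vonmises(0, 1, n_avail + 1),
                    "z_lag0": z0,
                    "z_lag1": z1,
                    "day_of_year": 100 + s % 100,
                    "season": "dry",
                }
            )
            rows.append(frame)
    return pd.concat(rows, ignore_index=True)


class TestISSAFit:
    def test_recovers_selection_and_interaction(self):
        strata = _issa_strata(5)
        fit = fit_issa(strata)
        se = fit.se()
        for name, truth in (("grassland", 0.7), ("grassland:z_lag1", 0.4)):
            assert abs(fit.coef[name] - truth) < 3 * se[name] + 0.1
        # inert blocks: day-of-year spline is constant within strata
        doy = [n for n in fit.names if n.startswith("doy_")]
        assert np.abs(fit.coef[doy]).max() < 1e-3

    def test_relative_selection_identities(self):
        strata = _issa_strata(6)
        fit = fit_issa(strata)
        assert relative_selection(fit, "mopane")["rss"] == 1.0
        r = relative_selection(fit, "grassland", 0.0, 0.0)
        assert r["rss"] == pytest.approx(np.exp(fit.coef["grassland"]))
        r2 = relative_selection(fit, "grassland", 0.5, -1.0)
        expected = np.exp(
            fit.coef["grassland"]
            + 0.5 * fit.coef["grassland:z_lag0"]
            - 1.0 * fit.coef["grassland:z_lag1"]
        )
        assert r2["rss"] == pytest.approx(expected)
        with pytest.raises(ValueError, match="unknown habitat"):
            relative_selection(fit, "swamp")

    def test_validation_errors(self):
        strata = _issa_strata(7, n_ind=1, n_strata=1)
        with pytest.raises(ValueError, match="two strata"):
            fit_issa(strata)
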