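"""Additive-model engine: recovery, calibration, diagnostics, fold changes."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from thermoguild import gamm
from thermoguild.gamm import (
    NoContrastError,
    Smooth1D,
    _difference_penalty,
    _pirls,
    diagnostics,
    fit_activity_model,
    fit_encounter_model,
    fit_gamm,
    fit_overlap_model,
    predict_fold_change,
)


def simulate_dyad_days(seed, beta1=0.8, n=3000, n_dyads=6, intercept=-3.0):
    """Bernoulli dyad-day table with logit p = intercept + beta1 * z_lag1."""
    rng = np.random.default_rng(seed)
    rows = []
    per = n // n_dyads
    for d in range(n_dyads):
        z = np.empty(per)
        e = 0.0
        for i in range(per):
            e = 0.6 * e + rng.normal(0, 0.8)
            z[i] = e
        z = (z - z.mean()) / z.std(ddof=1)
        zl1 = np.r_[0.0, z[:-1]]
        y = rng.binomial(1, expit(intercept + beta1 * zl1))
        rows.append(
            pd.DataFrame(
                {
                    "dyad_id": f"d{d}",
                    "date": np.arange(per),
                    "z_lag0": z,
                    "z_lag1": zl1,
                    "day_of_year": (np.arange(per) % 300) + 1,
                    "encounter": y,
                    "t_max": 30 + 3 * z,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


class TestCore:
    def test_matches_plain_penalized_logistic_without_ar1_or_re(self, rng):
        """With rho=0 and no random effect the PIRLS fixed point equals an
        independently coded penalized logistic fit at the same penalty."""
        n = 400
        x = rng.uniform(-2, 2, n)
        y = rng.binomial(1, expit(0.5 + 0.8 * x))
        data = pd.DataFrame({"x": x, "y": y})
        term = Smooth1D("x", k=8)
        term.setup(data)
        X = np.hstack([np.ones((n, 1)), term.build(data)])
        lam = 2.5
        S = np.zeros((X.shape[1],) * 2)
        S[1:, 1:] = lam * term.S[0]
        beta, H, dev = _pirls(X, y, np.ones(n), S, 0.0, np.array([0]))
        # reference: plain Newton-IRLS on the penalized log-likelihood
        b = np.zeros(X.shape[1])
        for _ in range(100):
            mu = expit(X @ b)
            w = mu * (1 - mu)
            g = X.T @ (y - mu) - S @ b
            Hn = (X * w[:, None]).T @ X + S
            step = np.linalg.solve(Hn, g)
            b = b + step
            if np.abs(step).max() < 1e-12:
                break
        assert np.abs(beta - b).max() < 1e-6

    def test_infinite_penalty_collapses_to_null_space(self, rng):
        n = 500
        x = rng.uniform(-2, 2, n)
        y = rng.binomial(1, expit(np.sin(2 * x)))
        data = pd.DataFrame({"x": x, "y": y})
        term = Smooth1D("x", k=10)
        term.setup(data)
        B = term.build(data)
        X = np.hstack([np.ones((n, 1)), B])
        S = np.zeros((X.shape[1],) * 2)
        S[1:, 1:] = 1e9 * term.S[0]
        beta, *_ = _pirls(X, y, np.ones(n), S, 0.0, np.array([0]))
        f = B @ beta[1:]
        # second-difference penalty null space: linear functions of x
        design = np.column_stack([np.ones(n), x])
        resid = f - design @ np.linalg.lstsq(design, f, rcond=None)[0]
        assert np.abs(resid).max() < 1e-4 * (np.abs(f).max() + 1)

    def test_no_contrast_error(self):
        d = simulate_dyad_days(0)
        d["encounter"] = 0
        with pytest.raises(NoContrastError):
            fit_encounter_model(d)

    def test_single_dyad_drops_random_effect(self):
        d = simulate_dyad_days(1)
        d = d[d.dyad_id == "d0"]
        with pytest.warns(UserWarning, match="random effect dropped"):
            fit = fit_encounter_model(d)
        assert all(
            not ts.name.startswith("re(") for ts in fit.term_summaries
        )

    def test_prediction_reproduces_training_fit(self):
        d = simulate_dyad_days(2, n=1200, n_dyads=4)
        fit = fit_encounter_model(d)
        eta1 = fit.predict(fit.train_data, population=False, link=True)
        X = fit.model_matrix(fit.train_data, population=False)
        assert np.allclose(eta1, X @ fit.beta)


class TestEncounterRecovery:
    def test_effect_detected_and_monotone(self):
        d = simulate_dyad_days(11, beta1=0.8)
        fit = fit_encounter_model(d)
        assert fit.smooth_p_values()["s(z_lag1)"] < 0.05
        # fitted lag-1 smooth increases over [-1, 2]
        zgrid = np.linspace(-1, 2, 31)
        frame = d.iloc[[0] * 31].copy().reset_index(drop=True)
        frame["z_lag1"] = zgrid
        frame["z_lag0"] = 0.0
        frame["day_of_year"] = 150
        eta = fit.predict(frame, population=True, link=True)
        assert np.all(np.diff(eta) > -1e-3)

    def test_fold_change_near_generative_ratio(self):
        d = simulate_dyad_days(12, beta1=0.8)
        fit = fit_encounter_model(d)
        fc = predict_fold_change(fit, lag="z_lag1", quantile_cmp=0.8)
        z = d["z_lag1"].to_numpy()
        z80, z50 = np.quantile(z, [0.8, 0.5])
        truth = expit(-3 + 0.8 * z80) / expit(-3 + 0.8 * z50)
        assert abs(fc.ratio - truth) / truth < 0.2

    def test_null_fold_change_near_one(self):
        d = simulate_dyad_days(13, beta1=0.0, intercept=-2.2)
        fit = fit_encounter_model(d)
        fc = predict_fold_change(fit, lag="z_lag1", quantile_cmp=0.8)
        assert 0.8 < fc.ratio < 1.25

    def test_same_quantile_gives_unit_ratio(self):
        d = simulate_dyad_days(14, n=1200, n_dyads=4)
        fit = fit_encounter_model(d)
        fc = predict_fold_change(fit, lag="z_lag1", quantile_ref=0.5, quantile_cmp=0.5)
        assert fc.ratio == pytest.approx(1.0, abs=1e-12)


class TestOverlapModel:
    def _prop_table(self, seed, beta1=0.6, n=2000, n_ind=4, n_fixes=24):
        rng = np.random.default_rng(seed)
        rows = []
        per = n // n_ind
        for i in range(n_ind):
            z = rng.normal(0, 1, per)
            zl1 = np.r_[0.0, z[:-1]]
            p = expit(-1 + beta1 * zl1)
            y = rng.binomial(n_fixes, p)
            rows.append(
                pd.DataFrame(
                    {
                        "individual_id": f"i{i}",
                        "date": np.arange(per),
                        "z_lag0": z,
                        "z_lag1": zl1,
                        "day_of_year": (np.arange(per) % 300) + 1,
                        "n_fixes": n_fixes,
                        "n_inside": y,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def test_invalid_counts_rejected(self):
        d = self._prop_table(0)
        d.loc[0, "n_inside"] = 99
        with pytest.raises(ValueError, match="exceeds"):
            fit_overlap_model(d)

    def test_flat_truth_fold_change_near_one(self):
        d = self._prop_table(1, beta1=0.0)
        d["n_inside"] = np.random.default_rng(1).binomial(24, 0.5, len(d))
        fit = fit_overlap_model(d)
        fc = predict_fold_change(fit, lag="z_lag1", quantile_cmp=0.8)
        assert 0.9 < fc.ratio < 1.1

    def test_link_scale_recovery(self):
        d = self._prop_table(2, beta1=0.6, n=3000)
        fit = fit_overlap_model(d)
        zgrid = np.linspace(-1.5, 1.5, 41)
        frame = d.iloc[[0] * 41].copy().reset_index(drop=True)
        frame["z_lag1"] = zgrid
        frame["z_lag0"] = 0.0
        frame["day_of_year"] = 150
        eta = fit.predict(frame, population=True, link=True)
        truth = -1 + 0.6 * zgrid
        rmse = np.sqrt(np.mean((eta - truth) ** 2))
        assert rmse < 0.2


class TestActivityModel:
    def _activity_table(self, seed, temp_shift=0.0, n_ind=3, n_days=60):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n_ind):
            z = rng.normal(0, 1, n_days)
            zl1 = np.r_[0.0, z[:-1]]
            for d in range(n_days):
                st = (np.arange(24) + 0.5) * 2 * np.pi / 24
                # nocturnal baseline; optionally shifted by z_lag0
                eta = 1.2 * np.cos(st) + temp_shift * z[d] * np.cos(st)
                act = rng.binomial(1, expit(eta))
                rows.append(
                    pd.DataFrame(
                        {
                            "individual_id": f"i{i}",
                            "hour": d * 24 + np.arange(24),
                            "suntime": st,
                            "z_lag0": z[d],
                            "z_lag1": zl1[d],
                            "day_of_year": (d % 300) + 1,
                            "active": act,
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)

    def test_suntime_validation(self):
        d = self._activity_table(0)
        d.loc[0, "suntime"] = 7.0
        with pytest.raises(ValueError, match="sun time"):
            fit_activity_model(d)

    def test_temperature_free_predictions_coincide(self):
        from thermoguild.activity import activity_density, overlap_coefficient

        d = self._activity_table(1, temp_shift=0.0)
        fit = fit_activity_model(d, k_sun=6, k_tensor=(6, 4), maxfev=30)
        d20 = activity_density(fit, 0.2, lag="z_lag0")
        d80 = activity_density(fit, 0.8, lag="z_lag0")
        assert overlap_coefficient(d20, d80) >= 0.95

    def test_temperature_modulation_shifts_night_mass(self):
        from thermoguild.activity import activity_density, sun_time_grid

        d = self._activity_table(2, temp_shift=0.8)
        fit = fit_activity_model(d, k_sun=6, k_tensor=(6, 4), maxfev=30)
        grid = sun_time_grid()
        night = (grid < np.pi / 2) | (grid > 3 * np.pi / 2)
        d20 = activity_density(fit, 0.2, lag="z_lag0", grid=grid)
        d80 = activity_density(fit, 0.8, lag="z_lag0", grid=grid)
        h = 2 * np.pi / len(grid)
        assert d80[night].sum() * h > d20[night].sum() * h


class TestDiagnostics:
    def test_duplicated_covariate_flags_concurvity(self):
        d = simulate_dyad_days(21, n=1500, n_dyads=4)
        d["z_lag0"] = d["z_lag1"]
        fit = fit_encounter_model(d)
        diag = diagnostics(fit)
        pair = [
            r for r in diag["concurvity"]
            if r["smooth"] == "s(z_lag1)" and r["against"] == "s(z_lag0)"
        ][0]
        assert pair["concurvity"] > 0.95 and pair["flag"]
        assert diag["vif"]["z_lag0"]["vif"] > 10

    def test_independent_covariates_low_concurvity(self, rng):
        n = 2000
        d = pd.DataFrame(
            {
                "y": rng.binomial(1, 0.4, n),
                "u": rng.uniform(-1, 1, n),
                "v": rng.uniform(-1, 1, n),
            }
        )
        d["y"] = rng.binomial(1, expit(0.8 * d["u"]))
        fit = fit_gamm(d, "y", [Smooth1D("u", k=8), Smooth1D("v", k=8)])
        diag = diagnostics(fit)
        uv = [r for r in diag["concurvity"] if r["smooth"] == "s(u)"][0]
        assert uv["concurvity"] < 0.2

    def test_single_smooth_empty_pairwise(self, rng):
        n = 500
        d = pd.DataFrame({"y": rng.binomial(1, 0.5, n), "u": rng.uniform(0, 1, n)})
        fit = fit_gamm(d, "y", [Smooth1D("u", k=6)])
        assert diagnostics(fit)["concurvity"] == []


class TestExternalOracle:
    def test_smooth_fit_agrees_with_mgcv(self, tmp_path):
        """Independent cross-check: on a strong single-smooth binomial
        problem, fitted probabilities agree with an mgcv GAM fit.

        Smoothing-parameter criteria differ between engines, so the
        comparison is on predictions, not coefficients."""
        import subprocess

        rng = np.random.default_rng(17)
        n = 1500
        x = np.sort(rng.uniform(-2, 2, n))
        eta_true = np.sin(1.5 * x) * 1.5
        y = rng.binomial(1, expit(eta_true))
        data = pd.DataFrame({"x": x, "y": y})
        fit = fit_gamm(data, "y", [gamm.Smooth1D("x", k=10)])
        p_py = fit.predict(data)

        csv = tmp_path / "d.csv"
        out = tmp_path / "p.csv"
        data.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            'd <- read.csv("%s")\n'
            "library(mgcv)\n"
            'm <- gam(y ~ s(x, k = 10), family = binomial, data = d, method = "REML")\n'
            'write.csv(data.frame(p = predict(m, type = "response")), "%s", row.names = FALSE)\n'
            % (csv, out)
        )
        try:
            subprocess.run(
                ["Rscript", "--vanilla", str(script)], check=True,
                capture_output=True, timeout=300,
            )
        except (FileNotFoundError, subprocess.CalledProcessError) as e:
            pytest.fail(f"mgcv oracle unavailable: {e}")
        p_r = pd.read_csv(out)["p"].to_numpy()
        rmse = np.sqrt(np.mean((p_py - p_r) ** 2))
        assert rmse < 0.03
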