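"""BBMM correctness: sigma likelihood, UD quadrature, HDR rules."""

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from conftest import make_track
from thermoguild.homerange import (
    GridSpec,
    UtilizationDistribution,
    bbmm_ud,
    fit_bbmm_sigma,
    rolling_home_ranges,
    rolling_proportion_in_range,
)

T0 = pd.Timestamp("2015-05-01", tz="UTC")


def _hourly_track(xy, iid="a"):
    xy = np.asarray(xy, dtype=float)
    return make_track(
        T0 + pd.to_timedelta(np.arange(len(xy)), unit="h"), xy, iid
    )


class TestSigma:
    def test_linear_track_gives_zero_motion_variance(self):
        xy = np.column_stack([np.arange(50) * 100.0, np.zeros(50)])
        with pytest.warns(UserWarning):
            s2 = fit_bbmm_sigma(_hourly_track(xy), delta=0.0)
        assert s2 < 1e-6

    def test_two_fixes_degenerate(self):
        tr = _hourly_track([(0, 0), (10, 10)])
        with pytest.raises(ValueError, match="interior"):
            fit_bbmm_sigma(tr)
        assert fit_bbmm_sigma(tr, on_degenerate="default", default_sigma2=0.3) == 0.3

    def test_brownian_recovery_within_15pct(self):
        rng = np.random.default_rng(1)
        s2_true = 0.5
        xy = np.cumsum(rng.normal(0, np.sqrt(s2_true * 3600), (2000, 2)), axis=0)
        s2 = fit_bbmm_sigma(_hourly_track(xy), delta=0.0)
        assert abs(s2 - s2_true) / s2_true < 0.15
        # grid-search oracle over the same leave-one-out likelihood
        grid = np.linspace(0.2, 1.0, 81)
        m = xy[1:-1:2]
        mu = 0.5 * (xy[:-2:2] + xy[2::2])
        r2 = ((m - mu) ** 2).sum(axis=1)
        nll = [np.sum(np.log(7200 * 0.25 * s) + r2 / (2 * 7200 * 0.25 * s)) for s in grid]
        s2_oracle = grid[int(np.argmin(nll))]
        assert abs(s2 - s2_oracle) < 0.05


class TestUD:
    def test_mass_normalized(self):
        rng = np.random.default_rng(2)
        xy = np.cumsum(rng.normal(0, 50, (30 * 24, 2)), axis=0)
        ud = bbmm_ud(_hourly_track(xy), sigma2_m=1.0, delta=20.0)
        assert ud.pdf.sum() == pytest.approx(1.0, abs=1e-6)
        assert (ud.pdf >= 0).all()

    def test_single_bridge_matches_fine_quadrature(self):
        tr = _hourly_track([(0.0, 0.0), (300.0, 150.0)])
        grid = GridSpec(xll=-500, yll=-500, cellsize=200, ncols=5, nrows=5)
        ud = bbmm_ud(tr, 100.0, delta=20.0, grid=grid, min_days=None)
        T, s2m, d2 = 3600.0, 100.0, 400.0
        a, b = np.array([0.0, 0.0]), np.array([300.0, 150.0])
        oracle = np.zeros((5, 5))
        for j, yv in enumerate(grid.ycenters):
            for i, xv in enumerate(grid.xcenters):
                def f(al):
                    s2 = T * al * (1 - al) * s2m + ((1 - al) ** 2 + al**2) * d2
                    mu = (1 - al) * a + al * b
                    return np.exp(
                        -((mu[0] - xv) ** 2 + (mu[1] - yv) ** 2) / (2 * s2)
                    ) / (2 * np.pi * s2)
                oracle[j, i] = quad(f, 0, 1, limit=200, epsabs=1e-13, epsrel=1e-12)[0]
        oracle /= oracle.sum()
        assert np.abs(oracle - ud.pdf).max() < 1e-6

    def test_endpoint_limit_is_gaussian_at_first_fix(self):
        tr = _hourly_track([(0.0, 0.0), (300.0, 150.0)])
        grid = GridSpec(xll=-500, yll=-500, cellsize=200, ncols=5, nrows=5)
        ud = bbmm_ud(
            tr, 100.0, delta=20.0, grid=grid, min_days=None,
            alpha_nodes=([0.0], [1.0]),
        )
        gx = np.exp(-((grid.xcenters - 0.0) ** 2) / (2 * 400.0))
        gy = np.exp(-((grid.ycenters - 0.0) ** 2) / (2 * 400.0))
        closed = gy[:, None] * gx[None, :]
        closed /= closed.sum()
        assert np.abs(closed - ud.pdf).max() < 1e-12

    def test_window_day_gate(self):
        xy = np.zeros((23 * 24, 2))
        with pytest.raises(ValueError, match="distinct data days"):
            bbmm_ud(_hourly_track(xy), 1.0, min_days=24)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(3)
        xy = np.cumsum(rng.normal(0, 50, (48, 2)), axis=0)
        g1 = GridSpec(xll=-2000, yll=-2000, cellsize=100, ncols=50, nrows=50)
        g2 = GridSpec(xll=-2000 + 5000, yll=-2000 - 3000, cellsize=100, ncols=50, nrows=50)
        u1 = bbmm_ud(_hourly_track(xy), 1.0, grid=g1, min_days=None)
        u2 = bbmm_ud(_hourly_track(xy + [5000.0, -3000.0]), 1.0, grid=g2, min_days=None)
        assert np.allclose(u1.pdf, u2.pdf, atol=1e-12)


class TestHDR:
    def _toy_ud(self, seed=4, n=10):
        rng = np.random.default_rng(seed)
        pdf = rng.random((n, n))
        pdf /= pdf.sum()
        grid = GridSpec(xll=0, yll=0, cellsize=10, ncols=n, nrows=n)
        return UtilizationDistribution(grid=grid, pdf=pdf)

    def test_hdr_mass_and_minimality(self):
        ud = self._toy_ud()
        mask = ud.hdr_mask(0.95)
        assert ud.pdf[mask].sum() >= 0.95
        # dropping the least-dense included cell dips below the level
        included = ud.pdf[mask]
        assert ud.pdf[mask].sum() - included.min() < 0.95

    def test_hdr_nesting(self):
        ud = self._toy_ud()
        assert (ud.hdr_mask(0.5) <= ud.hdr_mask(0.95)).all()

    def test_proportion_matches_per_fix_lookup(self):
        ud = self._toy_ud()
        rng = np.random.default_rng(5)
        n = 200
        xs = rng.uniform(-20, 120, n)
        ys = rng.uniform(-20, 120, n)
        day = date(2015, 6, 1)
        fixes = make_track(
            pd.Timestamp("2015-06-01", tz="UTC")
            + pd.to_timedelta(np.arange(n), unit="min"),
            np.column_stack([xs, ys]),
        )
        out = rolling_proportion_in_range(fixes, {day: ud}, level=0.95)
        mask = ud.hdr_mask(0.95)
        expected = 0
        for x, y in zip(xs, ys):
            ix, iy = int(x // 10), int(y // 10)
            if 0 <= ix < 10 and 0 <= iy < 10 and mask[iy, ix]:
                expected += 1
        assert out["n_inside"].iloc[0] == expected
        assert out["proportion"].iloc[0] == pytest.approx(expected / n)

    def test_modal_and_distant_fixes(self):
        ud = self._toy_ud()
        iy, ix = np.unravel_index(np.argmax(ud.pdf), ud.pdf.shape)
        modal = (ud.grid.xcenters[ix], ud.grid.ycenters[iy])
        day = date(2015, 6, 1)
        inside = make_track(
            [pd.Timestamp("2015-06-01 10:00", tz="UTC")], [modal]
        )
        far = make_track(
            [pd.Timestamp("2015-06-01 11:00", tz="UTC")], [(10_000.0, 10_000.0)]
        )
        assert rolling_proportion_in_range(inside, {day: ud})["proportion"].iloc[0] == 1.0
        assert rolling_proportion_in_range(far, {day: ud})["proportion"].iloc[0] == 0.0


class TestRollingWindows:
    def test_exactly_qualifying_dates_receive_ranges(self):
        rng = np.random.default_rng(6)
        # 40 days of data with days 10-14 missing
        days = [d for d in range(40) if d not in (10, 11, 12, 13, 14)]
        times, xys = [], []
        for d in days:
            for h in range(24):
                times.append(T0 + pd.Timedelta(days=d, hours=h))
        xys = np.cumsum(rng.normal(0, 30, (len(times), 2)), axis=0)
        track = make_track(times, xys)
        uds = rolling_home_ranges(track, sigma2_m=0.3, cellsize=200, n_alpha=8)
        have = set(uds)
        data_days = {T0.date() + timedelta(days=d) for d in days}
        lo = T0.date()
        hi = max(data_days) + timedelta(days=31)
        expected = set()
        d = lo
        while d <= hi:
            window = {d - timedelta(days=k) for k in range(1, 31)}
            if len(window & data_days) >= 24:
                expected.add(d)
            d += timedelta(days=1)
        assert have == expected

    def test_rolling_ud_matches_direct_window_fit(self):
        rng = np.random.default_rng(7)
        n_days = 32
        times = [
            T0 + pd.Timedelta(days=d, hours=h) for d in range(n_days) for h in range(24)
        ]
        xys = np.cumsum(rng.normal(0, 30, (len(times), 2)), axis=0)
        track = make_track(times, xys)
        grid = GridSpec(
            xll=xys[:, 0].min() - 500, yll=xys[:, 1].min() - 500,
            cellsize=200,
            ncols=int((np.ptp(xys[:, 0]) + 1000) // 200) + 1,
            nrows=int((np.ptp(xys[:, 1]) + 1000) // 200) + 1,
        )
        uds = rolling_home_ranges(track, 0.3, grid=grid, n_alpha=16)
        target = T0.date() + timedelta(days=31)
        window = track[
            (track.timestamp.dt.date >= target - timedelta(days=30))
            & (track.timestamp.dt.date < target)
        ]
        direct = bbmm_ud(window, 0.3, grid=grid, n_alpha=16)
        assert np.abs(uds[target].pdf - direct.pdf).max() < 1e-5
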